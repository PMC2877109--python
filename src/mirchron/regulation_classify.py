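"""Regulation-mode classification and genomic miRNA clusters.

Two modes of miRNA action are distinguished by combining the mRNA-layer
and protein-layer direct-target calls:

* **Pattern 1 (mRNA downregulation)** — the miRNA anti-correlates with a
  predicted target's mRNA: the classic degradation signature.
* **Pattern 2 (translational repression)** — the miRNA anti-correlates
  with the target's *protein* while the mRNA shows no detectable change
  (the gene is outside the dynamically regulated mRNA set and is not an
  mRNA-layer direct target of that miRNA).

Edges direct at both layers are labeled ``both``; protein-direct edges
whose mRNA does change but was not itself called direct are
``unsupported``.  The summary reports, among other fractions, the share
of protein-level direct pairs without an mRNA change — the signature of
translation-only repression.

Separately, miRNA loci are chained into genomic clusters: per chromosome,
consecutive loci at most ``window`` (1 Mb) apart form a chain, and chains
with more than two members are reported as clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import IdMap, MirnaLocus, percentage

logger = logging.getLogger(__name__)

MODE_PATTERN1 = "pattern1_mrna_down"
MODE_PATTERN2 = "pattern2_translational"
MODE_BOTH = "both"
MODE_UNSUPPORTED = "unsupported"
ALL_MODES = (MODE_PATTERN1, MODE_PATTERN2, MODE_BOTH, MODE_UNSUPPORTED)

CALL_COLUMNS = [
    "mirna", "gene", "mode",
    "mrna_direct", "protein_direct", "mrna_dynamic",
    "r_mrna", "r_protein",
]


def classify_regulation(
    mrna_pairs: pd.DataFrame,
    protein_pairs: pd.DataFrame,
    dynamic_mrna: Iterable[str],
    probe_to_gene: Mapping[str, str] | None = None,
    protein_idmap: IdMap | None = None,
    mrna_r: Mapping[tuple[str, str], float] | None = None,
    mrna_r_ceiling: float | None = None,
) -> pd.DataFrame:
    """Label every direct edge with a regulation mode.

    ``mrna_pairs`` / ``protein_pairs`` are pair tables with a ``direct``
    column (targets: probes / proteins respectively).  Genes are
    canonicalized via ``probe_to_gene`` (identity when None); proteins
    reach genes through ``protein_idmap`` (protein → probe) — proteins
    with no probe mapping are skipped and logged.  When
    ``mrna_r_ceiling`` is set, pattern 2 additionally requires the edge's
    |r| on the mRNA layer (``mrna_r`` lookup) to stay at or below it.
    """
    p2g = dict(probe_to_gene) if probe_to_gene else {}

    def gene_of_probe(probe: str) -> str:
        return p2g.get(probe, probe)

    mrna_direct: dict[tuple[str, str], float] = {}
    for row in mrna_pairs.loc[mrna_pairs.get("direct", False) == True].itertuples():  # noqa: E712
        key = (row.mirna, gene_of_probe(row.target))
        mrna_direct[key] = min(mrna_direct.get(key, 1.0), row.r)

    protein_direct: dict[tuple[str, str], float] = {}
    skipped = 0
    for row in protein_pairs.loc[protein_pairs.get("direct", False) == True].itertuples():  # noqa: E712
        probes = (
            protein_idmap.lookup(row.target) if protein_idmap is not None else {row.target}
        )
        if not probes:
            skipped += 1
            continue
        for gene in {gene_of_probe(p) for p in probes}:
            key = (row.mirna, gene)
            protein_direct[key] = min(protein_direct.get(key, 1.0), row.r)
    if skipped:
        logger.warning("%d protein-direct pairs skipped: protein unmappable to a probe", skipped)

    dynamic_genes = {gene_of_probe(p) for p in dynamic_mrna}

    records = []
    for key in sorted(set(mrna_direct) | set(protein_direct)):
        mirna, gene = key
        m_dir = key in mrna_direct
        p_dir = key in protein_direct
        dyn = gene in dynamic_genes
        r_m = mrna_direct.get(key)
        if r_m is None and mrna_r is not None:
            r_m = mrna_r.get(key)
        if m_dir and p_dir:
            mode = MODE_BOTH
        elif m_dir:
            mode = MODE_PATTERN1
        elif p_dir and not dyn:
            mode = MODE_PATTERN2
            if mrna_r_ceiling is not None and r_m is not None and abs(r_m) > mrna_r_ceiling:
                mode = MODE_UNSUPPORTED
        else:
            mode = MODE_UNSUPPORTED
        records.append(
            {
                "mirna": mirna, "gene": gene, "mode": mode,
                "mrna_direct": m_dir, "protein_direct": p_dir, "mrna_dynamic": dyn,
                "r_mrna": r_m, "r_protein": protein_direct.get(key),
            }
        )
    return pd.DataFrame(records, columns=CALL_COLUMNS)


def summarize_modes(calls: pd.DataFrame) -> dict:
    """Counts and fractions per mode, plus the translational-repression share.

    ``translational_fraction_pairs`` — among protein-level direct pairs,
    the fraction whose mRNA shows no detectable change (pattern 2);
    ``translational_fraction_genes`` — the same on distinct genes.  Both
    are NaN when no protein layer contributed.  An empty call set yields
    an all-zero summary with a warning.
    """
    if len(calls) == 0:
        logger.warning("empty regulation call set")
        return {
            "n_calls": 0,
            "mode_counts": {m: 0 for m in ALL_MODES},
            "mode_fractions": {m: 0.0 for m in ALL_MODES},
            "per_mirna_mrna_direct": {},
            "per_mirna_protein_direct": {},
            "n_protein_direct_pairs": 0,
            "translational_fraction_pairs": float("nan"),
            "translational_fraction_genes": float("nan"),
        }
    counts = {m: int((calls["mode"] == m).sum()) for m in ALL_MODES}
    n = len(calls)
    prot = calls[calls["protein_direct"]]
    pat2 = calls[calls["mode"] == MODE_PATTERN2]
    summary = {
        "n_calls": n,
        "mode_counts": counts,
        "mode_fractions": {m: counts[m] / n for m in ALL_MODES},
        "per_mirna_mrna_direct": (
            calls[calls["mrna_direct"]].groupby("mirna").size().to_dict()
        ),
        "per_mirna_protein_direct": prot.groupby("mirna").size().to_dict(),
        "n_protein_direct_pairs": len(prot),
        "translational_fraction_pairs": (
            len(pat2) / len(prot) if len(prot) else float("nan")
        ),
        "translational_fraction_genes": (
            pat2["gene"].nunique() / prot["gene"].nunique() if len(prot) else float("nan")
        ),
    }
    return summary


@dataclass(frozen=True)
class GenomicCluster:
    """A chain of miRNA loci on one chromosome with gaps ≤ the window."""

    cluster_id: int
    chrom: str
    members: tuple[str, ...]
    span: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a genomic cluster needs at least two members")


def genomic_cluster_mirnas(
    loci: Sequence[MirnaLocus],
    window: int = 1_000_000,
    min_members: int = 3,
) -> list[GenomicCluster]:
    """Single-linkage chaining of miRNA loci into genomic clusters.

    Per chromosome, loci sorted by start are chained while consecutive
    starts are ≤ ``window`` apart; maximal chains with at least
    ``min_members`` members (default 3 — "more than two") are emitted.
    Strand is carried on the loci but does not affect chaining.  The span
    (first-to-last start) is reported so stricter total-span filters can
    be applied downstream.
    """
    clusters: list[GenomicCluster] = []
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    cid = 0
    for chrom in sorted(by_chrom):
        chain: list[MirnaLocus] = []
        for locus in sorted(by_chrom[chrom], key=lambda l: (l.start, l.mirna)):
            if chain and locus.start - chain[-1].start > window:
                if len(chain) >= min_members:
                    cid += 1
                    clusters.append(_emit(cid, chrom, chain))
                chain = []
            chain.append(locus)
        if len(chain) >= min_members:
            cid += 1
            clusters.append(_emit(cid, chrom, chain))
    return clusters


def _emit(cid: int, chrom: str, chain: list[MirnaLocus]) -> GenomicCluster:
    return GenomicCluster(
        cluster_id=cid,
        chrom=chrom,
        members=tuple(l.mirna for l in chain),
        span=chain[-1].start - chain[0].start,
    )
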