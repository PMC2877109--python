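"""Seed-reproducible synthetic multi-layer time-course data.

The generator emulates the statistical structure the pipeline assumes:
miRNA abundances follow one of five temporal archetypes over the seven
RNA time points and are emitted as qPCR CT values (CT = U6 + ΔCT with
ΔCT = −expression, plus replicate noise); target mRNAs and proteins carry
planted regulatory edges of two modes —

* **mode A (mRNA degradation)**: the target mRNA is an affine negative
  transform of its miRNA's latent profile, so the pair is anti-correlated
  at the mRNA layer (and the protein, which tracks its mRNA, follows);
* **mode B (translational repression)**: the target mRNA is flat while
  the target *protein* is the negative transform of the miRNA profile.

Protein spectral counts are drawn per organelle fraction from a Poisson
law (optionally negative binomial) with total mean 2^latent, split across
the three fractions, on the six-point protein axis.  The bundle also
contains a prediction table (planted edges ∪ decoy predictions pointing
at flat genes), transcript→probe and protein→probe id maps, BED loci with
one planted genomic cluster of three miRNAs within 1 Mb, and a truth
table, so every pipeline stage is testable without any download.

Everything is deterministic for a given (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    CtMatrix,
    ExpressionMatrix,
    IdMap,
    MirnaLocus,
    TargetPredictionTable,
    TimeCourseDesign,
    write_ct_matrix,
    write_expression_matrix,
    write_loci,
)
from .regulation_classify import MODE_BOTH, MODE_PATTERN1, MODE_PATTERN2

MODE_A = "A_mrna_degradation"
MODE_B = "B_translational"

#: Five miRNA temporal archetypes (normalized 0..1 over the 7 time points):
#: gradual rise to an adult peak, peaks at E18 or P10 from a low embryonic
#: start, a high-embryonic profile peaking at E18, and a monotone decline.
MIRNA_ARCHETYPES: dict[str, np.ndarray] = {
    "up_to_adult": np.array([0.0, 0.1, 0.25, 0.45, 0.65, 0.85, 1.0]),
    "peak_E18": np.array([0.0, 0.3, 0.7, 1.0, 0.55, 0.25, 0.1]),
    "peak_P10": np.array([0.0, 0.1, 0.3, 0.5, 0.8, 1.0, 0.6]),
    "high_embryonic_peak_E18": np.array([0.7, 0.8, 0.9, 1.0, 0.4, 0.15, 0.0]),
    "down_from_E12": np.array([1.0, 0.9, 0.75, 0.55, 0.25, 0.1, 0.0]),
}

#: Six mRNA archetypes mirroring the observed temporal patterns (early-high
#: decline, rise to adult, E18 peak, E18 trough, postnatal peak, late plateau).
MRNA_ARCHETYPES: dict[str, np.ndarray] = {
    "early_high_decline": np.array([1.0, 0.95, 0.8, 0.45, 0.2, 0.1, 0.0]),
    "rise_to_adult": np.array([0.0, 0.05, 0.15, 0.35, 0.6, 0.85, 1.0]),
    "peak_E18": np.array([0.1, 0.3, 0.65, 1.0, 0.5, 0.25, 0.1]),
    "trough_E18": np.array([1.0, 0.7, 0.35, 0.0, 0.35, 0.7, 1.0]),
    "postnatal_peak": np.array([0.0, 0.1, 0.2, 0.45, 1.0, 0.7, 0.4]),
    "late_plateau": np.array([0.0, 0.2, 0.5, 0.8, 0.95, 1.0, 1.0]),
}


@dataclass(frozen=True)
class SimParams:
    """Synthetic-instance sizes, effect scales, and noise levels.

    Defaults are the study conditions the recovery tests run under: a
    two-replicate, seven-time-point design; miRNA log2 amplitudes of 4
    (16-fold, comfortably above the Range > 2.2 filter); mRNA amplitudes
    of 4 on a base of 8 (above the Max > 7, Range > 1.2 filters); flat
    decoys at log2 9; replicate noise sd 0.1 log2 units; 20 mode-A and 10
    mode-B planted edges (translational fraction 1/3) among 30 miRNAs.
    """

    n_mirna: int = 30
    n_mrna: int = 200
    n_protein: int = 120
    n_edges_mode_a: int = 20
    n_edges_mode_b: int = 10
    n_decoy_predictions: int = 40
    noise_sd_rna: float = 0.1
    noise_sd_ct: float = 0.1
    replicates: int = 2
    u6_ct: float = 18.0
    mirna_base: float = 2.0
    mirna_amplitude: float = 4.0
    mrna_base: float = 8.0
    mrna_amplitude: float = 4.0
    mrna_flat_level: float = 9.0
    protein_log2_offset: float = 12.0
    protein_count_scale: float = 1.0
    nb_dispersion: float = 0.0  # 0 → Poisson; >0 → negative binomial
    fraction_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_mrna, self.n_protein) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd_rna < 0 or self.noise_sd_ct < 0:
            raise ValueError("noise sds must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_edges(self) -> int:
        return self.n_edges_mode_a + self.n_edges_mode_b

    @property
    def planted_translational_fraction(self) -> float:
        return self.n_edges_mode_b / self.n_edges if self.n_edges else float("nan")


@dataclass
class SyntheticTruth:
    """Planted ground truth: edges, archetype assignments, noise, seed."""

    edges: pd.DataFrame  # columns: mirna, gene, mode, effect_size
    mirna_archetypes: dict[str, str]
    noise_sd: float
    seed: int

    def edges_of_mode(self, mode: str) -> set[tuple[str, str]]:
        sub = self.edges[self.edges["mode"] == mode]
        return set(zip(sub["mirna"], sub["gene"]))


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the truth table."""

    ct: CtMatrix
    mrna: ExpressionMatrix
    protein_table: pd.DataFrame
    predictions: TargetPredictionTable
    tx_to_probe: IdMap
    protein_to_probe: IdMap
    probe_to_gene: dict[str, str]
    loci: list[MirnaLocus]
    truth: SyntheticTruth
    design: TimeCourseDesign
    params: SimParams
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full TSV/BED bundle (the CLI simulate output)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "ct": "ct.tsv", "samples": "samples.tsv", "mrna": "mrna.tsv",
            "protein": "protein.tsv", "predictions": "predictions.tsv",
            "tx_to_probe": "tx_to_probe.tsv", "protein_to_probe": "protein_to_probe.tsv",
            "probe_to_gene": "probe_to_gene.tsv", "loci": "mirna_loci.bed",
            "truth": "truth.tsv",
        }.items()}
        write_ct_matrix(self.ct, paths["ct"])
        sheet = pd.DataFrame(
            sorted(self.design.replicate_map.items()), columns=["sample", "timepoint"]
        )
        sheet.to_csv(paths["samples"], sep="\t", index=False)
        write_expression_matrix(self.mrna, paths["mrna"])
        self.protein_table.to_csv(paths["protein"], sep="\t", index=False)
        self.predictions.write(paths["predictions"])
        self.tx_to_probe.write(paths["tx_to_probe"])
        self.protein_to_probe.write(paths["protein_to_probe"])
        pd.DataFrame(
            sorted(self.probe_to_gene.items()), columns=["probe_id", "gene"]
        ).to_csv(paths["probe_to_gene"], sep="\t", index=False)
        write_loci(self.loci, paths["loci"])
        self.truth.edges.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate(params: SimParams = SimParams(), seed: int = 0) -> SyntheticBundle:
    """Draw one complete synthetic input bundle (deterministic per seed)."""
    if params.n_edges > params.n_mrna:
        raise ValueError("more planted edges than mRNA genes")
    if params.n_edges_mode_b + params.n_edges_mode_a > params.n_protein:
        raise ValueError("more planted edges than proteins")
    if params.n_edges > params.n_mirna * params.n_mrna:
        raise ValueError("more edges than possible pairs")
    rng = np.random.default_rng(seed)
    design = TimeCourseDesign.default(replicates=params.replicates)
    tps = list(design.rna_timepoints)
    n_tp = len(tps)
    samples = [f"{tp}_{i}" for tp in tps for i in range(1, params.replicates + 1)]

    mirna_ids = [f"miR-s{i+1:03d}" for i in range(params.n_mirna)]
    genes = [f"G{i+1:04d}" for i in range(params.n_mrna)]
    probe_of = {g: f"probe_{g}" for g in genes}
    tx_of = {g: f"tx_{g}" for g in genes}

    # --- miRNA latent log2 expression profiles ---------------------------
    arch_names = list(MIRNA_ARCHETYPES)
    mirna_arch = {m: arch_names[i % len(arch_names)] for i, m in enumerate(mirna_ids)}
    mirna_latent: dict[str, np.ndarray] = {}
    for m in mirna_ids:
        shape = MIRNA_ARCHETYPES[mirna_arch[m]]
        jitter = rng.normal(0.0, params.noise_sd_rna, n_tp)
        mirna_latent[m] = params.mirna_base + params.mirna_amplitude * shape + jitter

    # --- planted edges ----------------------------------------------------
    edge_mirnas = [mirna_ids[i % params.n_mirna] for i in range(params.n_edges)]
    mode_a_genes = genes[: params.n_edges_mode_a]
    mode_b_genes = genes[params.n_edges_mode_a : params.n_edges]
    edge_rows = []
    gene_mode: dict[str, tuple[str, str]] = {}  # gene -> (mirna, mode)
    for i, g in enumerate(mode_a_genes):
        edge_rows.append((edge_mirnas[i], g, MODE_A, params.mrna_amplitude))
        gene_mode[g] = (edge_mirnas[i], MODE_A)
    for j, g in enumerate(mode_b_genes):
        m = edge_mirnas[params.n_edges_mode_a + j]
        edge_rows.append((m, g, MODE_B, params.mrna_amplitude))
        gene_mode[g] = (m, MODE_B)

    # --- mRNA matrix ------------------------------------------------------
    free_genes = genes[params.n_edges :]
    n_dynamic_decoys = len(free_genes) // 2
    mrna_arch_names = list(MRNA_ARCHETYPES)
    gene_latent: dict[str, np.ndarray] = {}
    scale = params.mrna_amplitude / params.mirna_amplitude
    for g in genes:
        if g in gene_mode:
            m, mode = gene_mode[g]
            if mode == MODE_A:
                top = params.mrna_base + params.mrna_amplitude
                gene_latent[g] = top - (mirna_latent[m] - params.mirna_base) * scale
            else:
                gene_latent[g] = np.full(n_tp, params.mrna_flat_level)
        else:
            idx = free_genes.index(g)
            if idx < n_dynamic_decoys:
                shape = MRNA_ARCHETYPES[mrna_arch_names[idx % len(mrna_arch_names)]]
                gene_latent[g] = params.mrna_base + params.mrna_amplitude * shape
            else:
                gene_latent[g] = np.full(n_tp, params.mrna_flat_level)
    flat_genes = [g for g in free_genes if free_genes.index(g) >= n_dynamic_decoys]

    mrna_vals = np.empty((params.n_mrna, len(samples)))
    for r, g in enumerate(genes):
        profile = gene_latent[g]
        for c, s in enumerate(samples):
            tp_idx = tps.index(design.timepoint_of(s))
            mrna_vals[r, c] = profile[tp_idx] + rng.normal(0.0, params.noise_sd_rna)
    mrna = ExpressionMatrix(
        layer="mRNA",
        values=pd.DataFrame(mrna_vals, index=[probe_of[g] for g in genes], columns=samples),
        design=design,
    )

    # --- miRNA CT matrix (CT = U6 + ΔCT, ΔCT = −expression) ---------------
    ct_vals = np.empty((params.n_mirna + 1, len(samples)))
    for r, m in enumerate(mirna_ids):
        for c, s in enumerate(samples):
            tp_idx = tps.index(design.timepoint_of(s))
            dct = -mirna_latent[m][tp_idx]
            ct_vals[r, c] = params.u6_ct + dct + rng.normal(0.0, params.noise_sd_ct)
    ct_vals[-1, :] = params.u6_ct
    ct = CtMatrix(
        values=pd.DataFrame(ct_vals, index=mirna_ids + ["U6"], columns=samples),
        reference_assay="U6",
    )

    # --- protein layer ----------------------------------------------------
    # proteins: every edge gene, then dynamic decoys / flat genes up to n_protein
    protein_genes = list(gene_mode)
    for g in free_genes:
        if len(protein_genes) >= params.n_protein:
            break
        protein_genes.append(g)
    prot_of = {g: f"prot_{g}" for g in protein_genes}
    rna_axis = [tp for tp in design.rna_timepoints if tp in design.rna_to_protein_map]
    rna_idx = [tps.index(tp) for tp in rna_axis]
    prot_tps = [design.rna_to_protein_map[tp] for tp in rna_axis]

    prot_rows = []
    for g in protein_genes:
        if g in gene_mode and gene_mode[g][1] == MODE_B:
            m = gene_mode[g][0]
            latent6 = params.protein_log2_offset - mirna_latent[m][rna_idx]
        else:
            # protein tracks its own mRNA (mode-A targets and decoys alike)
            latent6 = gene_latent[g][rna_idx] - 4.0
        means = params.protein_count_scale * np.power(2.0, latent6)
        for t, ptp in enumerate(prot_tps):
            for frac, w in zip(("nuclear", "mitochondrion", "cytosol"), params.fraction_weights):
                mu = w * means[t]
                if params.nb_dispersion > 0:
                    size = 1.0 / params.nb_dispersion
                    count = rng.negative_binomial(size, size / (size + mu))
                else:
                    count = rng.poisson(mu)
                prot_rows.append((prot_of[g], frac, ptp, int(count)))
    protein_table = pd.DataFrame(
        prot_rows, columns=["protein_id", "fraction", "timepoint", "count"]
    )

    # --- prediction table: planted edges ∪ decoys pointing at flat genes --
    pred_pairs = {(m, tx_of[g]) for m, g, _, _ in edge_rows}
    decoy_pool = [(m, tx_of[g]) for m in mirna_ids for g in flat_genes
                  if (m, tx_of[g]) not in pred_pairs]
    n_decoys = min(params.n_decoy_predictions, len(decoy_pool))
    if n_decoys:
        chosen = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
        pred_pairs |= {decoy_pool[i] for i in sorted(chosen)}
    predictions = TargetPredictionTable(pred_pairs, source="synthetic")

    # --- id maps and loci -------------------------------------------------
    tx_to_probe = IdMap((tx_of[g], probe_of[g]) for g in genes)
    protein_to_probe = IdMap((prot_of[g], probe_of[g]) for g in protein_genes)
    probe_to_gene = {probe_of[g]: g for g in genes}

    loci: list[MirnaLocus] = []
    for i, m in enumerate(mirna_ids):
        if i < 3:  # planted genomic cluster: three loci within 1 Mb on chr14
            loci.append(MirnaLocus(m, "chr14", 1_000_000 + i * 300_000, 1_000_090 + i * 300_000))
        else:
            chrom = f"chr{(i % 10) + 1}"
            start = 5_000_000 * (i + 1)
            loci.append(MirnaLocus(m, chrom, start, start + 90))

    truth = SyntheticTruth(
        edges=pd.DataFrame(edge_rows, columns=["mirna", "gene", "mode", "effect_size"]),
        mirna_archetypes=mirna_arch,
        noise_sd=params.noise_sd_rna,
        seed=seed,
    )
    return SyntheticBundle(
        ct=ct, mrna=mrna, protein_table=protein_table, predictions=predictions,
        tx_to_probe=tx_to_probe, protein_to_probe=protein_to_probe,
        probe_to_gene=probe_to_gene, loci=loci, truth=truth,
        design=design, params=params, seed=seed,
    )


def score_recovery(truth: SyntheticTruth, calls: pd.DataFrame) -> dict:
    """Mode-wise precision/recall of regulation calls against the truth.

    A planted mode-A edge counts as recovered when called pattern 1 or
    ``both`` (its protein, tracking the degraded mRNA, is legitimately
    anti-correlated too); a mode-B edge when called pattern 2.  Precision
    is NaN when no call of that kind was made.
    """
    truth_a = truth.edges_of_mode(MODE_A)
    truth_b = truth.edges_of_mode(MODE_B)
    if len(calls):
        called_a = set(
            zip(calls.loc[calls["mode"].isin([MODE_PATTERN1, MODE_BOTH]), "mirna"],
                calls.loc[calls["mode"].isin([MODE_PATTERN1, MODE_BOTH]), "gene"])
        )
        called_b = set(
            zip(calls.loc[calls["mode"] == MODE_PATTERN2, "mirna"],
                calls.loc[calls["mode"] == MODE_PATTERN2, "gene"])
        )
    else:
        called_a, called_b = set(), set()

    def prf(truth_set: set, called: set) -> dict:
        tp = len(truth_set & called)
        return {
            "n_true": len(truth_set),
            "n_called": len(called),
            "precision": tp / len(called) if called else float("nan"),
            "recall": tp / len(truth_set) if truth_set else float("nan"),
        }

    return {
        "mode_a": prf(truth_a, called_a),
        "mode_b": prf(truth_b, called_b),
        "confusion": {
            "a_called_b": len(truth_a & called_b),
            "b_called_a": len(truth_b & called_a),
        },
    }
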