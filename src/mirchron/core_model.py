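"""Shared domain types and file formats for the time-course pipeline.

The analysis spans three molecular layers measured over mouse lung
development: miRNA (TaqMan qPCR arrays, seven time points E12..Adult),
mRNA (log2 microarray intensities on the same axis), and protein
(MudPIT spectral counts on a six-point axis E13.5..Adult).  Everything
downstream — filtering, clustering, correlation, classification — works
on the containers defined here.

All on-disk tables are UTF-8 TSV with a header row; missing values are
empty strings or "NA".  Genomic coordinates from BED-like files are
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered RNA time points (embryonic day / postnatal day / adult).
RNA_TIMEPOINTS: tuple[str, ...] = ("E12", "E14", "E16", "E18", "P2", "P10", "Adult")

#: Ordered protein time points of the MudPIT time course.
PROTEIN_TIMEPOINTS: tuple[str, ...] = ("E13.5", "E16", "E18", "P2", "P14", "Adult")

#: Partial mapping RNA → protein time axis; E12 has no protein counterpart.
RNA_TO_PROTEIN: dict[str, str] = {
    "E14": "E13.5",
    "E16": "E16",
    "E18": "E18",
    "P2": "P2",
    "P10": "P14",
    "Adult": "Adult",
}

#: Morphological stage of lung development at each RNA time point.
STAGE_OF_TIMEPOINT: dict[str, str] = {
    "E12": "pseudoglandular",
    "E14": "pseudoglandular",
    "E16": "pseudoglandular",
    "E18": "saccular",
    "P2": "saccular",
    "P10": "alveolar",
    "Adult": "adult",
}

VALID_LAYERS = ("miRNA", "mRNA", "protein")


@dataclass(frozen=True)
class TimeCourseDesign:
    """Experimental design: sample → time point, and the two time axes."""

    rna_timepoints: tuple[str, ...] = RNA_TIMEPOINTS
    replicate_map: Mapping[str, str] = field(default_factory=dict)
    protein_timepoints: tuple[str, ...] = PROTEIN_TIMEPOINTS
    rna_to_protein_map: Mapping[str, str] = field(default_factory=lambda: dict(RNA_TO_PROTEIN))
    stages: Mapping[str, str] = field(default_factory=lambda: dict(STAGE_OF_TIMEPOINT))

    def __post_init__(self) -> None:
        known = set(self.rna_timepoints) | set(self.protein_timepoints)
        for sample, tp in self.replicate_map.items():
            if tp not in known:
                raise ValueError(f"sample {sample!r} assigned to unknown time point {tp!r}")

    @classmethod
    def default(cls, replicates: int = 2) -> "TimeCourseDesign":
        """Default 7×`replicates` design with samples named '<tp>_<i>'."""
        rep_map = {f"{tp}_{i}": tp for tp in RNA_TIMEPOINTS for i in range(1, replicates + 1)}
        return cls(replicate_map=rep_map)

    def with_samples(self, replicate_map: Mapping[str, str]) -> "TimeCourseDesign":
        return replace(self, replicate_map=dict(replicate_map))

    def samples_for(self, timepoint: str) -> list[str]:
        return [s for s, tp in self.replicate_map.items() if tp == timepoint]

    def timepoint_of(self, sample: str) -> str:
        try:
            return self.replicate_map[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in the design's replicate map") from None


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a TSV sample sheet (columns: sample, timepoint[, replicate])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "timepoint" not in cols:
        raise ValueError(f"sample sheet {path} needs 'sample' and 'timepoint' columns")
    pairs = list(zip(df[cols["sample"]], df[cols["timepoint"]]))
    seen: dict[str, str] = {}
    for sample, tp in pairs:
        if sample in seen and seen[sample] != tp:
            raise ValueError(f"sample {sample!r} assigned to two time points")
        seen[sample] = tp
    return seen


@dataclass
class ExpressionMatrix:
    """A log2-scale feature × sample matrix bound to a time-course design.

    ``orientation`` distinguishes ordinary log2 expression ("expression",
    larger = more abundant) from qPCR ΔCT ("dct", larger = less abundant).
    """

    layer: str
    values: pd.DataFrame
    design: TimeCourseDesign
    orientation: str = "expression"

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"layer must be one of {VALID_LAYERS}, got {self.layer!r}")
        if self.orientation not in ("expression", "dct"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        for s in self.values.columns:
            self.design.timepoint_of(s)  # raises on unbound sample
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")

    @property
    def timepoint_order(self) -> tuple[str, ...]:
        order = (
            self.design.protein_timepoints
            if self.layer == "protein"
            else self.design.rna_timepoints
        )
        present = {self.design.timepoint_of(s) for s in self.values.columns}
        return tuple(tp for tp in order if tp in present)

    def timepoint_means(self) -> pd.DataFrame:
        """Average replicates: feature × time point matrix in design order."""
        groups = self.values.T.groupby(
            [self.design.timepoint_of(s) for s in self.values.columns]
        )
        means = groups.mean().T
        return means.reindex(columns=list(self.timepoint_order))

    def n_timepoints(self) -> int:
        return len(self.timepoint_order)


def read_expression_matrix(
    path: str | Path,
    layer: str,
    sample_sheet: str | Path | Mapping[str, str],
    design: TimeCourseDesign | None = None,
    orientation: str = "expression",
) -> ExpressionMatrix:
    """Load a feature × sample TSV and bind each column to a time point.

    Raises a hard error naming the sample if a header sample is absent from
    the sample sheet, and on duplicate feature ids.
    """
    rep_map = (
        dict(sample_sheet)
        if isinstance(sample_sheet, Mapping)
        else read_sample_sheet(sample_sheet)
    )
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""], float_precision="round_trip"
    )
    unknown = [s for s in df.columns if s not in rep_map]
    if unknown:
        raise ValueError(
            f"samples {unknown} in {path} are missing from the sample sheet"
        )
    base = design if design is not None else TimeCourseDesign()
    return ExpressionMatrix(
        layer=layer,
        values=df,
        design=base.with_samples(rep_map),
        orientation=orientation,
    )


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    # %.17g keeps read→write→read lossless for doubles
    em.values.to_csv(path, sep="\t", index_label="feature", na_rep="NA", float_format="%.17g")


@dataclass
class CtMatrix:
    """Raw qPCR cycle-threshold values, miRNA × sample (missing allowed)."""

    values: pd.DataFrame
    reference_assay: str = "U6"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate miRNA ids in CT matrix")


def read_ct_matrix(path: str | Path, reference_assay: str = "U6") -> CtMatrix:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""], float_precision="round_trip"
    )
    return CtMatrix(values=df, reference_assay=reference_assay)


def write_ct_matrix(ct: CtMatrix, path: str | Path) -> None:
    ct.values.to_csv(path, sep="\t", index_label="mirna", na_rep="NA", float_format="%.17g")


@dataclass(frozen=True)
class FilterThresholds:
    """Layer-specific cutoffs for the dynamic-regulation filter.

    ``max_min_kind`` selects the thresholded extremum: "max_above" keeps
    features whose Max exceeds the cutoff (mRNA log2 intensity), while
    "min_below" keeps features whose Min falls below it (miRNA ΔCT, where
    small ΔCT means abundant).
    """

    layer: str
    max_min_kind: str
    extremum_cutoff: float
    range_cutoff: float
    q_cutoff: float

    def __post_init__(self) -> None:
        if self.max_min_kind not in ("max_above", "min_below"):
            raise ValueError(f"unknown extremum kind {self.max_min_kind!r}")
        if not (0.0 < self.q_cutoff < 1.0):
            raise ValueError("q_cutoff must be in (0, 1)")


#: Published defaults: mRNA Max > 7, Range > 1.2 (fold change > 2.3), q < 0.05.
MRNA_THRESHOLDS = FilterThresholds("mRNA", "max_above", 7.0, 1.2, 0.05)

#: Published defaults: miRNA Min ΔCT < 10, Range > 2.2 (fold change > 4.6), q < 0.05.
MIRNA_THRESHOLDS = FilterThresholds("miRNA", "min_below", 10.0, 2.2, 0.05)


class TargetPredictionTable:
    """De-duplicated set of predicted (miRNA, target transcript) pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]], source: str = "unknown"):
        self.pairs: set[tuple[str, str]] = set(pairs)
        self.source = source

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, mirna: str) -> set[str]:
        return {t for m, t in self.pairs if m == mirna}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["mirna", "target"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_prediction_table(path: str | Path, source: str = "unknown") -> TargetPredictionTable:
    """Load a two-column (mirna, target) TSV; header optional.

    Malformed rows (wrong column count) raise with the offending line number.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: malformed prediction row at line {lineno}: {line!r}")
            if lineno == 1 and fields[0].lower() in ("mirna", "mir", "mirna_id"):
                continue  # header
            pairs.append((fields[0], fields[1]))
    table = TargetPredictionTable(pairs, source=source)
    if not table.pairs:
        logger.warning("prediction table %s is empty", path)
    logger.info("loaded %d unique prediction pairs from %s", len(table), path)
    return table


class IdMap:
    """Many-to-many source-id → probe-id mapping (e.g. transcript → probe)."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.mapping: dict[str, set[str]] = {}
        for src, probe in pairs:
            self.mapping.setdefault(src, set()).add(probe)

    def lookup(self, source_id: str) -> set[str]:
        return set(self.mapping.get(source_id, set()))

    def __len__(self) -> int:
        return len(self.mapping)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((s, p) for s, probes in self.mapping.items() for p in probes)
        return pd.DataFrame(rows, columns=["source_id", "probe_id"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_idmap(path: str | Path) -> IdMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"id map {path} needs two columns (source_id, probe_id)")
    return IdMap(zip(df.iloc[:, 0], df.iloc[:, 1]))


def map_ids(ids: Iterable[str], idmap: IdMap) -> set[str]:
    """Union of probe ids mapped from any input id; unmapped ids are logged."""
    probes: set[str] = set()
    unmapped: list[str] = []
    for i in ids:
        hits = idmap.lookup(i)
        if hits:
            probes |= hits
        else:
            unmapped.append(i)
    if unmapped:
        logger.info("map_ids: %d unmapped ids: %s", len(unmapped), sorted(unmapped)[:20])
    return probes


@dataclass(frozen=True)
class MirnaLocus:
    """Genomic position of a miRNA gene (0-based half-open, BED convention)."""

    mirna: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.mirna}: negative start {self.start}")
        if not self.chrom:
            raise ValueError(f"{self.mirna}: empty chromosome")


def read_loci(path: str | Path) -> list[MirnaLocus]:
    """Read a BED-like TSV: chrom, start, end, mirna_id[, score, strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    loci = []
    for _, row in df.iterrows():
        strand = row[5] if df.shape[1] > 5 and pd.notna(row[5]) else "+"
        loci.append(
            MirnaLocus(
                mirna=str(row[3]), chrom=str(row[0]),
                start=int(row[1]), end=int(row[2]), strand=strand,
            )
        )
    return loci


def write_loci(loci: Sequence[MirnaLocus], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.mirna}\t0\t{l.strand}\n")


def percentage(part: float, whole: float) -> float:
    """100 · part / whole; NaN for an empty denominator."""
    if whole == 0:
        return float("nan")
    return 100.0 * part / whole
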