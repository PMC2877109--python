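"""Protein-layer integration: fraction merging, axis alignment, targets.

The proteomic input is a long table of spectral counts per (protein,
organelle fraction, time point) from a MudPIT time course with its own
six-point axis (E13.5, E16, E18, P2, P14, Adult).  Counts from the three
fractions (nuclear, mitochondrion, cytosol) are combined into one unified
value per protein and time point — by default their sum, since spectral
counts are additive evidence — and converted to log2 with a +1 pseudocount
(zeros are common).  The RNA axis is then restricted to the six mapped
time points (E14→E13.5, E16→E16, E18→E18, P2→P2, P10→P14, Adult→Adult;
E12 is unmapped) and miRNA–protein pairs are screened exactly like
miRNA–mRNA pairs, with |r| > 0.8 by default and prediction-table
intersection through the protein → probe id map.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import ExpressionMatrix, IdMap, TargetPredictionTable, TimeCourseDesign
from .correlation_targets import correlate_profiles, intersect_predictions

logger = logging.getLogger(__name__)

VALID_FRACTIONS = ("nuclear", "mitochondrion", "cytosol")
PROTEIN_TABLE_COLUMNS = ["protein_id", "fraction", "timepoint", "count"]


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Load the long-format spectral-count TSV and validate it."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PROTEIN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"protein table {path} missing columns: {sorted(missing)}")
    return validate_protein_table(df[PROTEIN_TABLE_COLUMNS])


def validate_protein_table(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["fraction"]) - set(VALID_FRACTIONS)
    if bad:
        raise ValueError(f"unknown fraction labels: {sorted(bad)}")
    if (df["count"] < 0).any():
        raise ValueError("negative spectral counts")
    if df.duplicated(["protein_id", "fraction", "timepoint"]).any():
        raise ValueError("duplicate (protein, fraction, timepoint) rows")
    return df


def merge_fractions(
    table: pd.DataFrame,
    design: TimeCourseDesign | None = None,
    aggregate: str = "sum",
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Unify the three organelle fractions into one log2 profile per protein.

    unified(p, tp) aggregates the counts of the fractions present (absent
    fractions contribute 0); value = log2(unified + pseudocount).  The
    aggregation is a documented choice: "sum" (default; additive spectral
    evidence), "mean", or "max".
    """
    validate_protein_table(table)
    if aggregate not in ("sum", "mean", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if design is None:
        design = TimeCourseDesign()
    # a fraction absent from the table is a zero count, for every aggregate
    full = (
        table.set_index(["protein_id", "timepoint", "fraction"])["count"]
        .unstack("fraction")
        .reindex(columns=list(VALID_FRACTIONS))
        .fillna(0.0)
    )
    unified = getattr(full, aggregate)(axis=1).unstack("timepoint")
    unknown_tps = set(unified.columns) - set(design.protein_timepoints)
    if unknown_tps:
        raise ValueError(f"unknown protein time points: {sorted(unknown_tps)}")
    unified = unified.reindex(columns=list(design.protein_timepoints)).fillna(0.0)
    values = np.log2(unified + pseudocount)
    rep_map = dict(design.replicate_map) | {tp: tp for tp in design.protein_timepoints}
    return ExpressionMatrix(
        layer="protein",
        values=values,
        design=design.with_samples(rep_map),
        orientation="expression",
    )


def align_time_axes(
    protein: ExpressionMatrix,
    rna: ExpressionMatrix,
    design: TimeCourseDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair RNA and protein profiles on the six mapped time points.

    Returns (rna_profiles, protein_profiles) with identical columns labeled
    by the *protein* time points, in axis order; the unmapped RNA time
    point (E12) never appears.
    """
    if design is None:
        design = protein.design
    mapping = dict(design.rna_to_protein_map)
    rna_means = rna.timepoint_means()
    prot_means = protein.timepoint_means()
    rna_tps = [tp for tp in design.rna_timepoints if tp in mapping]
    for tp in rna_tps:
        if tp not in rna_means.columns:
            raise ValueError(f"mapped RNA time point {tp!r} missing from the RNA matrix")
        if mapping[tp] not in prot_means.columns:
            raise ValueError(
                f"mapped protein time point {mapping[tp]!r} missing from the protein matrix"
            )
    rna_aligned = rna_means[rna_tps].copy()
    rna_aligned.columns = [mapping[tp] for tp in rna_tps]
    prot_aligned = prot_means[list(rna_aligned.columns)]
    return rna_aligned, prot_aligned


def protein_correlation_targets(
    mirnas: ExpressionMatrix,
    proteins: ExpressionMatrix,
    cutoff: float = 0.8,
    predictions: TargetPredictionTable | None = None,
    prediction_idmap: IdMap | None = None,
    protein_idmap: IdMap | None = None,
    design: TimeCourseDesign | None = None,
) -> pd.DataFrame:
    """miRNA–protein pair screen on the aligned 6-point axis + direct calls.

    The miRNA matrix must be in expression orientation.  Direct flags need
    ``predictions`` plus the transcript → probe map; the pair's protein id
    is converted to probes via ``protein_idmap`` for the intersection.
    """
    if mirnas.orientation != "expression":
        raise ValueError("miRNA matrix must be converted to expression orientation first")
    mirna_aligned, prot_aligned = align_time_axes(proteins, mirnas, design=design)
    pairs = correlate_profiles(mirna_aligned, prot_aligned, cutoff)
    if predictions is not None:
        pairs = intersect_predictions(
            pairs, predictions,
            prediction_idmap=prediction_idmap, target_idmap=protein_idmap,
        )
    return pairs
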