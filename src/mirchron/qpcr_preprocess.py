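"""TaqMan-array CT preprocessing: censoring, ΔCT normalization, copy numbers.

Raw cycle-threshold values are censored at a detection ceiling (undetected
and CT > 35 both become 35), normalized per sample against the U6 small
nuclear RNA reference (ΔCT = CT(miRNA) − CT(U6)), and optionally converted
to estimated copies per cell via a calibration line (10-fold per 3.34
cycles, anchored at 40 cycles, divided by 22), assuming 30 pg total RNA
per cell.  ΔCT behaves as a *negative* log2 abundance: greater ΔCT means
lower expression.  ``dct_to_log2_expression`` negates it so that all three
layers share the convention larger = more abundant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_model import CtMatrix, ExpressionMatrix, TimeCourseDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QpcrConfig:
    """Censoring ceiling, reference assay, and calibration constants.

    The calibration constants (intercept 40 cycles, slope 3.34 cycles per
    10-fold, divisor 22) come from a synthetic lin-4 standard curve; the
    per-cell RNA content (30 pg) is metadata for the copies-per-cell
    interpretation only.
    """

    ct_ceiling: float = 35.0
    reference_assay: str = "U6"
    calib_intercept: float = 40.0
    calib_slope: float = 3.34
    calib_divisor: float = 22.0
    cell_rna_pg: float = 30.0

    def __post_init__(self) -> None:
        if self.ct_ceiling <= 0 or self.calib_slope <= 0 or self.calib_divisor <= 0:
            raise ValueError("ct_ceiling, calib_slope and calib_divisor must be positive")


def censor_ct(raw: CtMatrix, cfg: QpcrConfig = QpcrConfig()) -> CtMatrix:
    """Replace missing values and values above the ceiling by the ceiling.

    Idempotent.  Negative CT values are physically impossible and raise;
    CT = 0 is allowed with a warning.
    """
    vals = raw.values.astype(float)
    if (vals < 0).any().any():
        bad = vals.stack()
        bad = bad[bad < 0]
        raise ValueError(f"negative CT values are impossible: {bad.head().to_dict()}")
    if (vals == 0).any().any():
        logger.warning("CT values of exactly 0 present; they imply enormous copy numbers")
    vals = vals.fillna(cfg.ct_ceiling)
    vals = vals.mask(vals > cfg.ct_ceiling, cfg.ct_ceiling)
    return CtMatrix(values=vals, reference_assay=raw.reference_assay)


def delta_ct(
    censored: CtMatrix,
    cfg: QpcrConfig = QpcrConfig(),
    design: TimeCourseDesign | None = None,
) -> ExpressionMatrix:
    """Per-sample ΔCT against the reference assay; reference row removed.

    ΔCT(m, s) = CT(m, s) − CT(reference, s), computed against each sample's
    own reference value (the reference is a per-card internal control).
    """
    ref = cfg.reference_assay
    if ref not in censored.values.index:
        raise ValueError(f"reference assay {ref!r} absent from the CT matrix")
    ref_row = censored.values.loc[ref]
    missing = ref_row[ref_row.isna()]
    if len(missing):
        raise ValueError(
            f"reference assay {ref!r} missing in samples: {list(missing.index)}"
        )
    dct = censored.values.sub(ref_row, axis=1).drop(index=ref)
    if design is None:
        design = TimeCourseDesign()
    rep_map = {s: s.rsplit("_", 1)[0] for s in dct.columns} if not design.replicate_map else None
    if rep_map is not None:
        design = design.with_samples(rep_map)
    return ExpressionMatrix(layer="miRNA", values=dct, design=design, orientation="dct")


def copies_per_cell(ct, cfg: QpcrConfig = QpcrConfig()):
    """Estimated miRNA copies per cell from a raw CT value (vectorized).

    copies = 10^((intercept − CT)/slope) / divisor — strictly decreasing in
    CT, with an exact 10-fold change per ``slope`` cycles.
    """
    ct = np.asarray(ct, dtype=float)
    out = np.power(10.0, (cfg.calib_intercept - ct) / cfg.calib_slope) / cfg.calib_divisor
    return out if out.ndim else float(out)


def copies_table(censored: CtMatrix, cfg: QpcrConfig = QpcrConfig()):
    """Copies-per-cell for every entry of a censored CT matrix (report aid)."""
    return censored.values.apply(lambda col: copies_per_cell(col.to_numpy(), cfg), axis=0)


def dct_to_log2_expression(dct: ExpressionMatrix) -> ExpressionMatrix:
    """Negate ΔCT so the matrix reads as log2 expression (larger = more).

    Range and ANOVA statistics are invariant under this negation; Pearson
    correlations against other layers flip sign, which is exactly why the
    orientation must be made explicit before the correlation stage.
    """
    if dct.orientation != "dct":
        raise ValueError("matrix is already in expression orientation")
    return ExpressionMatrix(
        layer=dct.layer, values=-dct.values, design=dct.design, orientation="expression"
    )
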