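"""miRNA–target screening by time-course Pearson correlation.

Every (miRNA, target) pair is scored by the Pearson correlation of the two
per-time-point mean profiles (n = 7 on the RNA axis, n = 6 after protein
alignment).  Pairs exceeding a strict |r| cutoff are labeled negative or
positive; negative pairs that also appear in a sequence-based prediction
table (after transcript → probe id mapping) are flagged as *direct*
targets — the anti-correlation-plus-prediction intersection.

Because a miRNA measured as ΔCT is on an inverted scale, the miRNA matrix
must be converted to expression orientation (−ΔCT) before correlating, so
that "negative correlation" means biological anti-correlation for every
layer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_model import ExpressionMatrix, IdMap, TargetPredictionTable

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["mirna", "target", "r", "n", "direction"]


def timecourse_pearson(a, b) -> float:
    """Sample Pearson correlation of two equal-length profiles (n ≥ 3).

    Returns NaN (and logs) when either profile has zero variance — such a
    pair is undefined and is skipped by the pair screen.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 time points for a correlation")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        logger.debug("zero-variance profile; correlation undefined")
        return float("nan")
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def correlate_profiles(
    a: pd.DataFrame, b: pd.DataFrame, cutoff: float
) -> pd.DataFrame:
    """All-pairs Pearson screen between two profile matrices (shared columns).

    Rows of ``a`` (miRNAs) × rows of ``b`` (targets); strict comparison
    (|r| > cutoff).  Zero-variance rows are dropped with a log entry.
    """
    shared = [c for c in a.columns if c in set(b.columns)]
    if not shared:
        raise ValueError("no shared time points between the two matrices")
    a = a[shared]
    b = b[shared]
    n = len(shared)

    def z(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(axis=1, ddof=0)
        dropped = df.index[sd == 0.0]
        if len(dropped):
            logger.info("dropping %d zero-variance profiles from the pair screen", len(dropped))
        kept = df.loc[sd > 0.0]
        return kept.sub(kept.mean(axis=1), axis=0).div(sd[kept.index], axis=0)

    za, zb = z(a), z(b)
    r = np.clip(za.to_numpy() @ zb.to_numpy().T / n, -1.0, 1.0)
    mi, ti = np.nonzero(np.abs(r) > cutoff)
    out = pd.DataFrame(
        {
            "mirna": za.index.to_numpy()[mi],
            "target": zb.index.to_numpy()[ti],
            "r": r[mi, ti],
            "n": n,
        }
    )
    out["direction"] = np.where(out["r"] < 0, "negative", "positive")
    return out


def correlate_all_pairs(
    mirnas: ExpressionMatrix, targets: ExpressionMatrix, cutoff: float = 0.9
) -> pd.DataFrame:
    """Screen all miRNA × target pairs on the shared time-point axis.

    Both matrices must be in expression orientation; per-time-point means
    are correlated (n = number of shared time points).
    """
    for em, name in ((mirnas, "miRNA"), (targets, "target")):
        if em.orientation != "expression":
            raise ValueError(
                f"{name} matrix is in {em.orientation!r} orientation; convert with "
                "dct_to_log2_expression so that negative r means anti-correlation"
            )
    pairs = correlate_profiles(mirnas.timepoint_means(), targets.timepoint_means(), cutoff)
    neg = int((pairs["direction"] == "negative").sum())
    logger.info(
        "pair screen at |r| > %g: %d negative, %d positive pairs",
        cutoff, neg, len(pairs) - neg,
    )
    return pairs


def intersect_predictions(
    pairs: pd.DataFrame,
    predictions: TargetPredictionTable,
    prediction_idmap: IdMap | None = None,
    target_idmap: IdMap | None = None,
) -> pd.DataFrame:
    """Flag negative pairs matching a predicted target as ``direct``.

    Prediction transcript ids are mapped to probe ids via
    ``prediction_idmap`` (identity when None); the pair's own target id is
    mapped via ``target_idmap`` (identity for mRNA probes, protein → probe
    for the protein layer).  A negative pair is direct iff the two probe
    sets intersect for that miRNA.  Positive pairs are never direct.
    """
    predicted: dict[str, set[str]] = {}
    for mirna, transcript in predictions.pairs:
        probes = prediction_idmap.lookup(transcript) if prediction_idmap else {transcript}
        if probes:
            predicted.setdefault(mirna, set()).update(probes)

    direct = []
    for mirna, target, direction in zip(pairs["mirna"], pairs["target"], pairs["direction"]):
        if direction != "negative":
            direct.append(False)
            continue
        target_probes = target_idmap.lookup(target) if target_idmap else {target}
        direct.append(bool(target_probes & predicted.get(mirna, set())))
    out = pairs.copy()
    out["direct"] = direct
    counts = out[out["direct"]].groupby("mirna").size()
    logger.info(
        "direct targets: %d pairs across %d miRNAs", int(out["direct"].sum()), len(counts)
    )
    return out
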