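"""Control-based normalization, plate-pattern correction, and assay QC.

Normalization follows the "neutral controls minus inhibitors" convention:
per plate, the median raw signal of the neutral (vehicle, DMSO) control wells
maps to a normalized activity of 0 and the median raw signal of the positive
(full-inhibition) control wells maps to -100.  Inhibition is therefore
*negative* activity; QC reports the positive-control level as |activity| = 100.

The pattern correction removes additive positional (row/column) bias shared
across the plates of one replicate run: for every well position it subtracts
the across-plate median of that position's compound-well activity, re-centred
on the grand median of those positional medians so plate-level medians are
preserved.  Control wells are never touched.

Assay quality is summarised by the Z'-factor,

    Z' = 1 - 3 (sd_pos + sd_neu) / |mean_pos - mean_neu|,

computed from the *raw* control signals (means/SDs, not medians); Z' > 0.5 is
conventionally regarded as robust for single-point screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ControlStats",
    "DegeneratePlateError",
    "control_stats",
    "zprime",
    "normalize_plate",
    "normalize_screen",
    "correct_pattern",
    "fold_change",
    "baseline_subtracted",
    "replicate_r2",
    "qc_table",
]

ZPRIME_ROBUST = 0.5


class DegeneratePlateError(ValueError):
    """Plate controls cannot define a normalization scale (m_n == m_p, or missing)."""


@dataclass(frozen=True)
class ControlStats:
    """Per-plate control summaries.

    Means/SDs feed the Z'-factor; medians define the normalization anchors.
    """

    mu_n: float
    sd_n: float
    mu_p: float
    sd_p: float
    m_n: float
    m_p: float
    n_neutral: int
    n_positive: int


def control_stats(plate: pd.DataFrame) -> ControlStats:
    """Compute :class:`ControlStats` from one plate's well records."""
    neu = plate.loc[plate["well_type"] == "neutral", "raw_signal"].to_numpy(float)
    pos = plate.loc[plate["well_type"] == "positive", "raw_signal"].to_numpy(float)
    if neu.size < 2 or pos.size < 2:
        raise DegeneratePlateError(
            f"plate needs >=2 neutral and >=2 positive control wells "
            f"(got {neu.size} neutral, {pos.size} positive)"
        )
    return ControlStats(
        mu_n=float(neu.mean()),
        sd_n=float(neu.std(ddof=1)),
        mu_p=float(pos.mean()),
        sd_p=float(pos.std(ddof=1)),
        m_n=float(np.median(neu)),
        m_p=float(np.median(pos)),
        n_neutral=int(neu.size),
        n_positive=int(pos.size),
    )


def zprime(cs: ControlStats) -> float:
    """Z'-factor of a plate; raises if the control means coincide."""
    if cs.mu_p == cs.mu_n:
        raise DegeneratePlateError("Z' undefined: positive and neutral control means are equal")
    return 1.0 - 3.0 * (cs.sd_p + cs.sd_n) / abs(cs.mu_p - cs.mu_n)


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Normalize one plate's raw signals to the control scale.

    activity(x) = 100 * (x - m_n) / (m_n - m_p), so the neutral-control
    median maps to 0 and the positive-control median to -100.
    """
    cs = control_stats(plate)
    if cs.m_n == cs.m_p:
        raise DegeneratePlateError("degenerate plate: neutral and positive control medians equal")
    out = plate.copy()
    x = out["raw_signal"].to_numpy(float)
    out["activity"] = 100.0 * (x - cs.m_n) / (cs.m_n - cs.m_p)
    return out


def normalize_screen(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize every (replicate, plate) group of a well table."""
    parts = [
        normalize_plate(g)
        for _, g in wells.groupby(["replicate_id", "plate_id"], sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def correct_pattern(normalized: pd.DataFrame, min_plates: int = 3) -> pd.DataFrame:
    """Subtract positional-median bias from compound wells, per replicate run.

    Requires at least ``min_plates`` plates sharing a layout within a
    replicate; with fewer, correction is skipped with a warning and
    ``corrected_activity`` equals ``activity``.
    """
    out = normalized.copy()
    out["corrected_activity"] = out["activity"]
    for rep, grp in out.groupby("replicate_id", sort=True):
        n_plates = grp["plate_id"].nunique()
        if n_plates < min_plates:
            logger.warning(
                "replicate %s: only %d plate(s), pattern correction skipped", rep, n_plates
            )
            continue
        comp = grp[grp["well_type"] == "compound"]
        pos_median = comp.groupby(["row", "col"])["activity"].median()
        offsets = pos_median - pos_median.median()
        idx = comp.set_index(["row", "col"]).index
        out.loc[comp.index, "corrected_activity"] = (
            comp["activity"].to_numpy() - offsets.loc[idx].to_numpy()
        )
    return out


def fold_change(activated: float, baseline: float) -> float:
    """Activated/baseline signal ratio (e.g. fold induction of a reporter)."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return activated / baseline


def baseline_subtracted(activated: float, baseline: float) -> float:
    """Baseline-subtracted signal, used for titration plots."""
    return activated - baseline


def replicate_r2(a1, a2) -> float:
    """Squared Pearson correlation between paired replicate activities."""
    x = np.asarray(a1, float)
    y = np.asarray(a2, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("replicate_r2 needs >=3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("replicate_r2 undefined: zero variance in a replicate")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def qc_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-(replicate, plate) QC: Z', fold inhibition, control medians.

    The positive-control activity level is reported as an absolute value
    (100 at the median by construction).
    """
    rows = []
    for (rep, plate_id), grp in wells.groupby(["replicate_id", "plate_id"], sort=True):
        cs = control_stats(grp)
        z = zprime(cs)
        rows.append(
            {
                "replicate_id": rep,
                "plate_id": plate_id,
                "zprime": z,
                "robust": z > ZPRIME_ROBUST,
                "fold_inhibition": cs.m_n / cs.m_p if cs.m_p > 0 else np.inf,
                "neutral_median": cs.m_n,
                "positive_median": cs.m_p,
                "neutral_mean": cs.mu_n,
                "neutral_sd": cs.sd_n,
                "positive_mean": cs.mu_p,
                "positive_sd": cs.sd_p,
                "positive_abs_activity": 100.0,
            }
        )
    return pd.DataFrame(rows)
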