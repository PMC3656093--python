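"""Duplicate-concordance hit calling, promiscuity filtering, and hit accounting.

A compound is a *preliminary hit* (inhibition direction) when its corrected
activity falls below ``neutral_mean - k_sd * neutral_sd`` in BOTH replicate
experiments; with ``k_sd = 2`` this is the ">2 SD from the neutral-control
mean, in both dimensions" rule.  A compound is *promiscuous* (a frequent
hitter) when its assay history shows it was tested in more than 50 assays AND
hit in more than 25% of them (both inequalities strict).  Final hits are
preliminary hits that are not promiscuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HitThresholds",
    "PROMISCUITY_MIN_ASSAYS",
    "PROMISCUITY_MIN_RATIO",
    "neutral_activity_stats",
    "compound_activities",
    "call_preliminary_hits",
    "flag_promiscuous",
    "finalize_hits",
    "excess_hit_test",
    "hit_rate",
]

PROMISCUITY_MIN_ASSAYS = 50
PROMISCUITY_MIN_RATIO = 0.25


@dataclass(frozen=True)
class HitThresholds:
    """Activity thresholds on the corrected-activity scale.

    ``k_sd`` is the SD multiplier around the neutral-control mean (default 2,
    the operational reading of a 95% confidence band); ``direction`` selects
    which tail(s) count as hits.
    """

    neutral_mean: float
    neutral_sd: float
    k_sd: float = 2.0
    direction: str = "inhibition"

    def __post_init__(self):
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.direction not in ("inhibition", "activation", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.neutral_sd < 0:
            raise ValueError("neutral_sd must be non-negative")

    @property
    def lower(self) -> float:
        return self.neutral_mean - self.k_sd * self.neutral_sd

    @property
    def upper(self) -> float:
        return self.neutral_mean + self.k_sd * self.neutral_sd


def neutral_activity_stats(corrected: pd.DataFrame) -> tuple[float, float]:
    """Pooled mean/SD of neutral-control corrected activities across plates."""
    vals = corrected.loc[
        corrected["well_type"] == "neutral", "corrected_activity"
    ].to_numpy(float)
    if vals.size < 2:
        raise ValueError("need >=2 neutral control wells to estimate thresholds")
    return float(vals.mean()), float(vals.std(ddof=1))


def compound_activities(corrected: pd.DataFrame) -> pd.DataFrame:
    """Per-compound activity table with one column per replicate.

    Returns columns ``compound_id, activity_rep1, activity_rep2, ...`` in
    sorted replicate order (a compound measured once per replicate simply
    carries that well's corrected activity).
    """
    comp = corrected[corrected["well_type"] == "compound"]
    wide = (
        comp.groupby(["compound_id", "replicate_id"])["corrected_activity"]
        .mean()
        .unstack("replicate_id")
    )
    wide.columns = [f"activity_rep{i + 1}" for i in range(wide.shape[1])]
    return wide.reset_index()


def call_preliminary_hits(acts: pd.DataFrame, thresholds: HitThresholds) -> pd.DataFrame:
    """Flag compounds outside the neutral band in both replicates.

    ``acts`` must carry ``compound_id, activity_rep1, activity_rep2``.
    Compounds with a missing replicate are excluded (and logged).  With
    ``direction='both'`` an extra ``activation_hit`` column flags the
    symmetric upper tail; ``preliminary_hit`` is always the tail named by
    the primary direction (inhibition unless direction='activation').
    """
    required = ["compound_id", "activity_rep1", "activity_rep2"]
    missing = [c for c in required if c not in acts.columns]
    if missing:
        raise ValueError(f"activity table missing column(s) {missing}")
    complete = acts["activity_rep1"].notna() & acts["activity_rep2"].notna()
    if (~complete).any():
        dropped = acts.loc[~complete, "compound_id"].tolist()
        logger.warning("excluding %d compound(s) with a missing replicate: %s",
                       len(dropped), ", ".join(map(str, dropped[:20])))
    out = acts.loc[complete, required].copy()
    a1 = out["activity_rep1"].to_numpy(float)
    a2 = out["activity_rep2"].to_numpy(float)
    low_both = (a1 < thresholds.lower) & (a2 < thresholds.lower)
    high_both = (a1 > thresholds.upper) & (a2 > thresholds.upper)
    if thresholds.direction == "inhibition":
        out["preliminary_hit"] = low_both
    elif thresholds.direction == "activation":
        out["preliminary_hit"] = high_both
    else:
        out["preliminary_hit"] = low_both
        out["activation_hit"] = high_both
    return out.reset_index(drop=True)


def flag_promiscuous(records: pd.DataFrame) -> pd.Series:
    """Frequent-hitter flags from assay-history records.

    promiscuous <=> n_assays_tested > 50 AND n_assays_hit / n_assays_tested
    > 0.25 (both strict).  Compounds with zero assays tested are never
    promiscuous (logged).
    """
    tested = records["n_assays_tested"].to_numpy(float)
    hit = records["n_assays_hit"].to_numpy(float)
    if (hit > tested).any():
        raise ValueError("n_assays_hit exceeds n_assays_tested")
    zero = tested == 0
    if zero.any():
        logger.info("%d compound(s) with zero assay history treated as non-promiscuous",
                    int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tested > 0, hit / np.where(tested > 0, tested, 1), 0.0)
    flags = (tested > PROMISCUITY_MIN_ASSAYS) & (ratio > PROMISCUITY_MIN_RATIO)
    return pd.Series(flags, index=records["compound_id"].to_numpy(), name="promiscuous")


def finalize_hits(
    hits: pd.DataFrame, promiscuous: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Combine preliminary and promiscuity flags into the final hit table.

    final_hit = preliminary_hit AND NOT promiscuous.  Compounds absent from
    the promiscuity history are treated as non-promiscuous.  Returns the
    augmented table and a summary with preliminary / promiscuous-overlap /
    final counts.
    """
    out = hits.copy()
    flagged = set(promiscuous.index[promiscuous.astype(bool)]) if len(promiscuous) else set()
    out["promiscuous"] = out["compound_id"].isin(flagged)
    out["final_hit"] = out["preliminary_hit"] & ~out["promiscuous"]
    n_prelim = int(out["preliminary_hit"].sum())
    n_overlap = int((out["preliminary_hit"] & out["promiscuous"]).sum())
    summary = {
        "n_compounds": int(len(out)),
        "n_preliminary": n_prelim,
        "n_promiscuous": int(out["promiscuous"].sum()),
        "n_promiscuous_overlap": n_overlap,
        "n_final": n_prelim - n_overlap,
    }
    assert summary["n_final"] == int(out["final_hit"].sum())
    return out, summary


def excess_hit_test(n_hits: int, n_compounds: int, null_both_replicate_tail: float) -> float:
    """One-sided exact binomial test for more hits than chance predicts.

    ``null_both_replicate_tail`` is the probability that a single inactive
    compound lands outside the threshold in both replicates (e.g. 0.025**2
    for independent replicates at a one-sided 2.5% tail).  Returns
    P(X >= n_hits) for X ~ Binomial(n_compounds, p0).
    """
    if not 0 < null_both_replicate_tail < 1:
        raise ValueError("null probability must lie strictly in (0, 1)")
    if not 0 <= n_hits <= n_compounds:
        raise ValueError("n_hits must lie in [0, n_compounds]")
    return float(stats.binom.sf(n_hits - 1, n_compounds, null_both_replicate_tail))


def hit_rate(n_hits: int, n_compounds: int) -> float:
    """Hit rate in percent (reported to one decimal place)."""
    if n_compounds <= 0:
        raise ValueError("n_compounds must be positive")
    return 100.0 * n_hits / n_compounds
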