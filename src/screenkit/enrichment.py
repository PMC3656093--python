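"""Compound-set enrichment and class enrichment among screening hits.

Two complementary questions:

* Do compounds sharing an annotation term (e.g. a pharmacological-action
  MeSH term) collectively rank toward the inhibitory end of the corrected
  activity distribution?  Tested per term with a two-sided Wilcoxon
  rank-sum (Mann-Whitney) test of members vs non-members; the enrichment
  score is the mean-rank gap (non-members minus members) scaled by the
  number of compounds, so inhibition-enriched sets score positive.
  Significance uses Bonferroni control at 0.05 / (number of sets tested).

* Is a chemical class over-represented among the hits?  Upper-tail
  hypergeometric probability P(X >= k) of drawing at least k class members
  in n hits from a library of N compounds containing K class members,
  evaluated in log space so extreme tails (p << 1e-16) survive.

Activities can also be trinarized for display: scaled by the neutral-control
SD, values in the open interval (-1, 1) are "neutral", <= -1 "decreased"
(inhibition) and >= 1 "increased".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClassEnrichment",
    "trinarize",
    "set_enrichment",
    "class_enrichment",
]

EXACT_MAX_GROUP = 20  # exact rank-sum enumeration up to this per-group size


def trinarize(activities: pd.Series, scale_sd: float) -> pd.DataFrame:
    """Classify corrected activities as increased / neutral / decreased.

    The value is activity / scale_sd, so the +/-1 band is +/-1 neutral-control
    SD; boundaries are closed on the active side (exactly -1 -> decreased).
    """
    if scale_sd <= 0:
        raise ValueError("scale_sd must be positive")
    v = activities.astype(float) / scale_sd
    cls = np.where(v <= -1, "decreased", np.where(v >= 1, "increased", "neutral"))
    return pd.DataFrame(
        {"compound_id": activities.index, "value": v.to_numpy(), "class": cls}
    ).reset_index(drop=True)


def _ranksum_p(members: np.ndarray, others: np.ndarray) -> float:
    n1, n2 = members.size, others.size
    pooled = np.concatenate([members, others])
    has_ties = np.unique(pooled).size < pooled.size
    if min(n1, n2) <= EXACT_MAX_GROUP and not has_ties:
        res = stats.mannwhitneyu(members, others, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            members, others, alternative="two-sided", method="asymptotic"
        )
    return float(res.pvalue)


def set_enrichment(
    activities: pd.Series,
    annotations: pd.DataFrame,
    min_set_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based enrichment of annotation term sets in an activity profile.

    ``activities`` is indexed by compound_id (corrected activity, inhibition
    negative); ``annotations`` is a long-format term -> compound_id table.
    Compounds are ranked ascending (most inhibitory = rank 1, mid-ranks for
    ties).  Terms with fewer than ``min_set_size`` screened members are
    excluded, as are degenerate terms covering every compound (warned).
    """
    if annotations.empty:
        raise ValueError("empty annotation table")
    vals = activities.astype(float)
    n_total = len(vals)
    ranks = pd.Series(stats.rankdata(vals.to_numpy()), index=vals.index)
    members_by_term = {
        term: [c for c in grp["compound_id"] if c in vals.index]
        for term, grp in annotations.groupby("term", sort=True)
    }
    eligible = {}
    for term, members in members_by_term.items():
        if len(members) < min_set_size:
            continue
        if len(members) >= n_total:
            logger.warning("term %r covers every compound; excluded as degenerate", term)
            continue
        eligible[term] = members
    n_tested = len(eligible)
    rows = []
    for term, members in eligible.items():
        is_member = vals.index.isin(members)
        member_vals = vals.to_numpy()[is_member]
        other_vals = vals.to_numpy()[~is_member]
        score = float(
            (ranks.to_numpy()[~is_member].mean() - ranks.to_numpy()[is_member].mean())
            / n_total
        )
        p = _ranksum_p(member_vals, other_vals)
        rows.append(
            {"term": term, "set_size": int(is_member.sum()), "score": score, "p": p}
        )
    out = pd.DataFrame(rows, columns=["term", "set_size", "score", "p"])
    if n_tested:
        out["bonferroni_significant"] = out["p"] < alpha / n_tested
    else:
        out["bonferroni_significant"] = pd.Series([], dtype=bool)
    out.attrs["n_sets_tested"] = n_tested
    return out


@dataclass(frozen=True)
class ClassEnrichment:
    """Hypergeometric enrichment of a class among hits.

    k class members among n hits, from a library of N compounds containing
    K class members; ``p`` is the upper tail P(X >= k).
    """

    k: int
    n: int
    K: int
    N: int
    p: float
    log10_p: float


def class_enrichment(k: int, n: int, K: int, N: int) -> ClassEnrichment:
    """Upper-tail hypergeometric probability of >= k class members among hits."""
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    logp = min(logp, 0.0)
    return ClassEnrichment(
        k=k, n=n, K=K, N=N, p=float(np.exp(logp)), log10_p=float(logp / np.log(10.0))
    )
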