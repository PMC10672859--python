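"""Bucket annotation and the gradual bucket-reduction biomarker funnel.

Buckets are assigned to metabolites by chemical shift (a metabolite is
assigned to a bucket iff one of its multiplet centers lies within the
bucket window inflated by a tolerance).  The reduction funnel then runs:

1. keep only buckets annotated to exactly one metabolite (avoids the
   metabolite-overlap problem in crowded spectral regions);
2. score every unique bucket with a two-sided Mann-Whitney U test and
   the AUROC (folded to max(A, 1-A), with the raw direction kept);
3. promote buckets with folded AUROC > 0.75 and p < 0.05 (strict);
4. collapse to one winning bucket per metabolite, keeping the highest
   AUROC (ties: smaller p, then lower ppm).

Stage counts are logged so the funnel (annotated -> unique -> passing
-> winners) can be reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import BucketTable
from .synth import MetaboliteSpec

__all__ = [
    "AnnotationMap",
    "FeatureRecord",
    "PromotionResult",
    "annotate_buckets",
    "unique_bucket_filter",
    "mannwhitney_test",
    "auroc",
    "score_buckets",
    "promote_biomarkers",
]

log = logging.getLogger("afnmr.biomarkers")


@dataclass
class AnnotationMap:
    """bucket index -> set of metabolite names (empty sets excluded)."""

    assignments: dict[int, set[str]]
    unannotated: list[int]
    n_buckets: int

    def unique(self) -> dict[int, str]:
        return {i: next(iter(s)) for i, s in self.assignments.items() if len(s) == 1}


@dataclass
class FeatureRecord:
    """Per-bucket univariate statistics."""

    bucket_index: int
    bucket: tuple[float, float]
    metabolite: str
    auroc: float  # folded: max(A, 1-A)
    auroc_raw: float  # P(preterm > term)
    p_value: float
    direction: str  # higher_in_preterm | lower_in_preterm
    median_term: float
    median_preterm: float
    fdr_p: float = np.nan  # informational only, not used for selection


@dataclass
class PromotionResult:
    passing: list[FeatureRecord]
    winners: dict[str, FeatureRecord]  # metabolite -> best bucket
    funnel: dict[str, int] = field(default_factory=dict)


def annotate_buckets(
    buckets: BucketTable,
    library: list[MetaboliteSpec],
    tolerance_ppm: float = 0.02,
) -> AnnotationMap:
    """Assign metabolites to buckets by multiplet-center position.

    A metabolite is assigned to a bucket iff any of its multiplet
    centers lies within [lo - tol, hi + tol).  Buckets with no
    assignment are flagged unannotated and excluded downstream.
    """
    if tolerance_ppm < 0:
        raise ValueError("tolerance_ppm must be >= 0")
    if not library:
        raise ValueError("empty metabolite library")
    assignments: dict[int, set[str]] = {}
    unannotated: list[int] = []
    for i, (lo, hi) in enumerate(buckets.buckets):
        hit = {
            met.name
            for met in library
            for mult in met.multiplets
            if lo - tolerance_ppm <= mult.center_ppm < hi + tolerance_ppm
        }
        if hit:
            assignments[i] = hit
        else:
            unannotated.append(i)
    log.info(
        "annotation: %d/%d buckets annotated (%d unique)",
        len(assignments), len(buckets.buckets),
        sum(1 for s in assignments.values() if len(s) == 1),
    )
    return AnnotationMap(assignments, unannotated, len(buckets.buckets))


def unique_bucket_filter(annotation: AnnotationMap) -> tuple[list[int], int]:
    """Buckets annotated to exactly one metabolite.

    Returns the bucket indices and the number of distinct metabolites
    they cover; warns when none qualify.
    """
    uniq = annotation.unique()
    indices = sorted(uniq)
    n_met = len(set(uniq.values()))
    if not indices:
        warnings.warn("no uniquely annotated buckets", stacklevel=2)
    return indices, n_met


def mannwhitney_test(
    values_term: np.ndarray, values_preterm: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n1 + n2 <= 12 and there are no ties, normal
    approximation with tie correction otherwise.  Degenerate input
    (all values identical) returns p = 1.
    """
    x = np.asarray(values_term, dtype=float)
    y = np.asarray(values_preterm, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def auroc(
    values_term: np.ndarray, values_preterm: np.ndarray, fold: bool = True
) -> float:
    """Area under the ROC curve for separating preterm from term.

    Computed as (wins + 0.5 ties) / (n1 * n2) over all cross-group
    pairs, i.e. the Mann-Whitney U statistic scaled by n1*n2; the raw
    orientation is P(preterm > term).  With ``fold`` the value is
    folded to max(A, 1 - A).
    """
    x = np.asarray(values_term, dtype=float)
    y = np.asarray(values_preterm, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_pre = ranks[x.size :].sum()
    u_pre = r_pre - y.size * (y.size + 1) / 2.0
    a = u_pre / (x.size * y.size)
    return float(max(a, 1.0 - a)) if fold else float(a)


def score_buckets(
    bucket_table: BucketTable, annotation: AnnotationMap
) -> list[FeatureRecord]:
    """Mann-Whitney p and AUROC for every uniquely annotated bucket."""
    uniq = annotation.unique()
    groups = np.asarray(bucket_table.groups)
    term = groups == "term"
    pre = groups == "preterm"
    records = []
    for i in sorted(uniq):
        v = bucket_table.values[:, i]
        vt, vp = v[term], v[pre]
        _, p = mannwhitney_test(vt, vp)
        a_raw = auroc(vt, vp, fold=False)
        mt, mp = float(np.median(vt)), float(np.median(vp))
        records.append(
            FeatureRecord(
                bucket_index=i,
                bucket=bucket_table.buckets[i],
                metabolite=uniq[i],
                auroc=max(a_raw, 1.0 - a_raw),
                auroc_raw=a_raw,
                p_value=p,
                direction="higher_in_preterm" if mp >= mt else "lower_in_preterm",
                median_term=mt,
                median_preterm=mp,
            )
        )
    if records:
        # informational FDR column (selection uses unadjusted p)
        ps = np.array([r.p_value for r in records])
        fdr = stats.false_discovery_control(ps, method="bh")
        for r, q in zip(records, fdr):
            r.fdr_p = float(q)
    return records


def promote_biomarkers(
    records: list[FeatureRecord],
    auroc_min: float = 0.75,
    p_max: float = 0.05,
) -> PromotionResult:
    """Two-stage biomarker promotion.

    Stage 1 keeps records with folded AUROC strictly above ``auroc_min``
    and p strictly below ``p_max``.  Stage 2 collapses to one bucket per
    metabolite, keeping the highest AUROC (ties: smaller p, then lower
    ppm).  An empty stage-1 result warns rather than raising.
    """
    passing = [r for r in records if r.auroc > auroc_min and r.p_value < p_max]
    winners: dict[str, FeatureRecord] = {}
    for r in passing:
        cur = winners.get(r.metabolite)
        if cur is None or (
            (r.auroc, -r.p_value, -r.bucket[0])
            > (cur.auroc, -cur.p_value, -cur.bucket[0])
        ):
            winners[r.metabolite] = r
    funnel = {
        "scored": len(records),
        "passing": len(passing),
        "winners": len(winners),
    }
    if not passing:
        warnings.warn("no buckets passed the AUROC/p promotion thresholds",
                      stacklevel=2)
    log.info("promotion funnel: %s", funnel)
    return PromotionResult(passing=passing, winners=winners, funnel=funnel)
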