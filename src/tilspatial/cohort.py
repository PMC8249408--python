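"""Per-patient metric registry and cohort-level statistics.

Every quantity is summarised per patient first; cohort values are means of
per-patient values, never pooled cells across patients.  Group comparisons
report the classical equal-variance two-sided Student t-test (with the
Welch variant alongside), the Mann–Whitney two-sided p, and the ROC AUC —
the probability that a random good-outcome value exceeds a random
poor-outcome value, ties counting one half.  The direction of a metric is
never flipped: an AUC below 0.5 is reported as-is.

Relapse-free-survival stratification uses a systematic threshold placing
two thirds of patients in the upper stratum and one third in the lower,
mirroring the good:poor cohort proportions; Kaplan–Meier curves per stratum
come from the standard product-limit estimator, with a log-rank test as a
conventional companion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from . import metrics as sm
from .clusters import (ClusterParams, DEFAULT_CLUSTER_PARAMS,
                       DEFAULT_TLS_PARAMS, detect_clusters, detect_tls,
                       membership_by_cell)
from .grid import (BinaryQuestion, DEFAULT_L_LADDER, InsufficientScalesError,
                   fd_difference, occupancy_auc, occupancy_curve)
from .io import PointPattern, T_LINEAGE_PHENOTYPES

__all__ = [
    "DEFAULT_QUESTIONS",
    "PatientMetrics",
    "CohortComparison",
    "SurvivalRecord",
    "patient_summary",
    "compare_groups",
    "rfs_threshold",
    "km_estimate",
]

#: Named binary questions evaluated per patient for occupancy/FD metrics.
DEFAULT_QUESTIONS: dict[str, BinaryQuestion] = {
    "B_stroma": BinaryQuestion.b_cells("stroma", name="B_stroma"),
    "T_stroma": BinaryQuestion.t_cells("stroma", name="T_stroma"),
    "B_island": BinaryQuestion.b_cells("cancer_island", name="B_island"),
    "T_island": BinaryQuestion.t_cells("cancer_island", name="T_island"),
}

_T = frozenset(T_LINEAGE_PHENOTYPES)
_B = frozenset({"B"})
_LYMPH = _B | _T

#: Density metrics: name -> (phenotype set, tissue scope, membership scope).
DENSITY_REGISTRY: dict[str, tuple[frozenset, str, str]] = {
    "density_B_any": (_B, "any", "any"),
    "density_B_island": (_B, "cancer_island", "any"),
    "density_B_stroma": (_B, "stroma", "any"),
    "density_T_any": (_T, "any", "any"),
    "density_T_island": (_T, "cancer_island", "any"),
    "density_T_stroma": (_T, "stroma", "any"),
    "density_lymph_any": (_LYMPH, "any", "any"),
    "density_lymph_island": (_LYMPH, "cancer_island", "any"),
    "density_lymph_stroma": (_LYMPH, "stroma", "any"),
    "density_isolated_lymph_island": (_LYMPH, "cancer_island", "isolated_only"),
    "density_isolated_B_island": (_B, "cancer_island", "isolated_only"),
    "density_isolated_T_island": (_T, "cancer_island", "isolated_only"),
    "density_isolated_lymph_stroma": (_LYMPH, "stroma", "isolated_only"),
    "density_isolated_B_stroma": (_B, "stroma", "isolated_only"),
    "density_isolated_T_stroma": (_T, "stroma", "isolated_only"),
}


def metric_registry(questions: dict[str, BinaryQuestion] | None = None,
                    ) -> list[str]:
    """The fixed set of per-patient metric names for a question registry."""
    questions = DEFAULT_QUESTIONS if questions is None else questions
    names = list(DENSITY_REGISTRY)
    for q in questions:
        names += [f"occupancy_auc_{q}", f"fd_small_{q}", f"fd_large_{q}",
                  f"fd_delta_{q}"]
    names += [
        "lc_count_per_cm2_heterotypic", "lc_count_per_cm2_pure_T",
        "lc_size_mean_heterotypic", "lc_size_median_heterotypic",
        "lc_size_mean_pure_T", "lc_size_median_pure_T",
        "lc_island_distance_mean_heterotypic",
        "lc_island_distance_median_heterotypic",
        "lc_island_distance_mean_pure_T",
        "lc_island_distance_median_pure_T",
        "frac_lymph_isolated", "frac_lymph_in_lc", "frac_lymph_in_tls",
        "frac_B_in_lc", "frac_island_lymph_isolated",
        "frac_stroma_lymph_isolated",
        "tls_count",
    ]
    return names


@dataclass
class PatientMetrics:
    """Named scalar metrics for one patient; absent values are flagged, not 0."""

    patient_id: str
    outcome: str
    values: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)

    def get(self, name: str) -> float | None:
        return None if name in self.missing else self.values.get(name)

    def as_row(self) -> dict:
        row: dict = {"patient_id": self.patient_id, "outcome": self.outcome}
        for k, v in self.values.items():
            row[k] = v
        for k in self.missing:
            row[k] = math.nan
        return row


def _put(pm: PatientMetrics, name: str, value: float | None) -> None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        pm.missing.add(name)
    else:
        pm.values[name] = float(value)


def patient_summary(pattern: PointPattern,
                    clusters=None,
                    isolated=None,
                    questions: dict[str, BinaryQuestion] | None = None,
                    Ls: Sequence[float] = DEFAULT_L_LADDER,
                    cluster_params: ClusterParams = DEFAULT_CLUSTER_PARAMS,
                    tls_params: ClusterParams = DEFAULT_TLS_PARAMS,
                    ) -> PatientMetrics:
    """Assemble the full metric registry for one patient.

    Runs clustering and TLS detection when not supplied.  Metrics that are
    undefined for the pattern (no LCs of a type, no cancer cells, too few
    occupied scales for an FD fit) land in ``missing``.
    """
    questions = DEFAULT_QUESTIONS if questions is None else questions
    pm = PatientMetrics(pattern.patient_id, pattern.outcome)
    if clusters is None or isolated is None:
        clusters, isolated = detect_clusters(pattern, cluster_params)
        detect_tls(pattern, clusters, tls_params)
    mem = membership_by_cell(pattern, clusters, isolated)

    for name, (phset, tscope, mscope) in DENSITY_REGISTRY.items():
        res = sm.region_density(pattern, phset, tscope, mscope, membership=mem)
        _put(pm, name, res.density)

    if pattern.n_cells:
        for qname, q in questions.items():
            try:
                curve = occupancy_curve(pattern, Ls, q, membership=mem)
                _put(pm, f"occupancy_auc_{qname}", occupancy_auc(curve))
            except ValueError:
                pm.missing.add(f"occupancy_auc_{qname}")
            try:
                dd = fd_difference(pattern, q, membership=mem)
                _put(pm, f"fd_small_{qname}", dd.s_small)
                _put(pm, f"fd_large_{qname}", dd.s_large)
                _put(pm, f"fd_delta_{qname}", dd.delta_s)
            except (InsufficientScalesError, ValueError):
                pm.missing.update({f"fd_small_{qname}", f"fd_large_{qname}",
                                   f"fd_delta_{qname}"})
    else:
        for qname in questions:
            pm.missing.update({f"occupancy_auc_{qname}", f"fd_small_{qname}",
                               f"fd_large_{qname}", f"fd_delta_{qname}"})

    area_cm2 = pattern.roi.area_mm2 / 100.0
    dists = sm.cluster_island_distances(clusters, pattern)
    for lc_type in ("heterotypic", "pure_T"):
        of_type = [cl for cl in clusters if cl.lc_type == lc_type]
        _put(pm, f"lc_count_per_cm2_{lc_type}", len(of_type) / area_cm2)
        sizes = [cl.size_s for cl in of_type]
        _put(pm, f"lc_size_mean_{lc_type}",
             float(np.mean(sizes)) if sizes else None)
        _put(pm, f"lc_size_median_{lc_type}",
             float(np.median(sizes)) if sizes else None)
        dd = [d.distance_um for cl, d in zip(clusters, dists)
              if d is not None and cl.lc_type == lc_type]
        _put(pm, f"lc_island_distance_mean_{lc_type}",
             float(np.mean(dd)) if dd else None)
        _put(pm, f"lc_island_distance_median_{lc_type}",
             float(np.median(dd)) if dd else None)

    fr = sm.membership_fractions(pattern, clusters, isolated)
    _put(pm, "frac_lymph_isolated", fr["all"]["isolated"])
    _put(pm, "frac_lymph_in_lc", fr["all"]["in_lc"])
    _put(pm, "frac_lymph_in_tls", fr["all"]["in_tls"])
    _put(pm, "frac_B_in_lc", fr["B"]["in_lc"])
    _put(pm, "frac_island_lymph_isolated", fr["cancer_island"]["isolated"])
    _put(pm, "frac_stroma_lymph_isolated", fr["stroma"]["isolated"])
    _put(pm, "tls_count", float(sum(cl.is_tls for cl in clusters)))
    return pm


@dataclass
class CohortComparison:
    metric: str
    mean_good: float
    mean_poor: float
    n_good: int
    n_poor: int
    t_p: float
    t_p_welch: float
    roc_auc: float
    mw_p: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("metric", "mean_good", "mean_poor", "n_good", "n_poor",
                 "t_p", "t_p_welch", "roc_auc", "mw_p")}


def compare_groups(values_good: Sequence[float],
                   values_poor: Sequence[float],
                   metric: str = "") -> CohortComparison:
    """Good-vs-poor comparison of one per-patient metric.

    ROC AUC is the Mann–Whitney U statistic scaled by the number of pairs:
    the probability that a random good value exceeds a random poor value,
    counting ties as one half.
    """
    g = np.asarray(values_good, dtype=float)
    p = np.asarray(values_poor, dtype=float)
    g = g[~np.isnan(g)]
    p = p[~np.isnan(p)]
    if len(g) == 0 or len(p) == 0:
        raise ValueError(f"{metric}: empty group after dropping missing values")
    if len(g) >= 2 and len(p) >= 2 and (np.ptp(g) > 0 or np.ptp(p) > 0):
        t_p = float(stats.ttest_ind(g, p, equal_var=True).pvalue)
        t_p_welch = float(stats.ttest_ind(g, p, equal_var=False).pvalue)
    else:
        t_p = t_p_welch = 1.0 if np.mean(g) == np.mean(p) else math.nan
    mw = stats.mannwhitneyu(g, p, alternative="two-sided")
    roc_auc = float(mw.statistic) / (len(g) * len(p))
    return CohortComparison(
        metric=metric, mean_good=float(g.mean()), mean_poor=float(p.mean()),
        n_good=len(g), n_poor=len(p), t_p=t_p, t_p_welch=t_p_welch,
        roc_auc=roc_auc, mw_p=float(mw.pvalue))


def rfs_threshold(values: Sequence[float]) -> float:
    """Threshold putting two thirds of patients above and one third below.

    The cut sits midway between the ceil(n/3)-th smallest value and the next
    distinct value.  If ties straddle the cut, the largest threshold keeping
    at least 2n/3 patients strictly above is chosen.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 values for a threshold")
    if np.ptp(v) == 0:
        raise ValueError("degenerate threshold: all values identical")
    k = math.ceil(n / 3)  # number intended below
    target_above = n - k
    # Candidate cuts sit midway between consecutive distinct values.  The
    # standard cut follows the k-th smallest value; when ties straddle it,
    # take the largest candidate that still keeps >= 2n/3 strictly above
    # (or, if no cut can, the one maximizing the above count).
    distinct = np.unique(v)
    cuts = 0.5 * (distinct[:-1] + distinct[1:])
    feasible = [c for c in cuts if (v > c).sum() >= target_above]
    if feasible:
        return float(max(feasible))
    return float(max(cuts, key=lambda c: (v > c).sum()))


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: int   # 1 = relapse observed, 0 = censored
    stratum: str = "all"

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def km_estimate(records: Sequence[SurvivalRecord],
                ) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier product-limit estimate per stratum.

    Returns a step table per stratum with columns ``time`` and ``survival``
    (right-continuous, starting at 1).  Censored records shrink the risk set
    without an event.
    """
    if not records:
        raise ValueError("no survival records")
    out: dict[str, pd.DataFrame] = {}
    strata = sorted({r.stratum for r in records})
    for s in strata:
        rs = [r for r in records if r.stratum == s]
        kmf = KaplanMeierFitter()
        kmf.fit([r.time for r in rs], [r.event for r in rs])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[s] = sf
    return out


def km_logrank(records: Sequence[SurvivalRecord]) -> float:
    """Two-stratum log-rank p-value (a conventional companion to the KM
    curves, not part of the core comparison battery)."""
    strata = sorted({r.stratum for r in records})
    if len(strata) != 2:
        raise ValueError("log-rank test needs exactly 2 strata")
    a = [r for r in records if r.stratum == strata[0]]
    b = [r for r in records if r.stratum == strata[1]]
    res = logrank_test([r.time for r in a], [r.time for r in b],
                       event_observed_A=[r.event for r in a],
                       event_observed_B=[r.event for r in b])
    return float(res.p_value)
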