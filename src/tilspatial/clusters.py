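"""Density-based lymphocyte clusters (LCs) and tertiary lymphoid structures.

An LC is a maximal density-connected set of lymphocytes found by DBSCAN with
eps = 20 μm and min_pts = 5 (the point itself counts): at least five
lymphocytes inside a circle of 40 μm diameter, the minimum span of five
contiguous 10 μm cells along a line.  Lymphocytes outside every LC are
*isolated*.  LCs are typed pure_T (no B members), pure_B (no T-lineage
members) or heterotypic (both); pure-B LCs are rare and excluded from the
size-distribution machinery, whose type index covers pure_T and heterotypic
only.

A TLS is an LC dense enough to hold at least 200 lymphocytes within a
circle of radius 70 μm, operationalised as a second DBSCAN pass
(eps = 70 μm, min_pts = 200) over the LC's own members producing at least
one core point.  TLS flags never alter cluster membership.

The cluster-size distribution for outcome o and type i counts P_{o,i}(s)
clusters of size s and normalises by N_{o,i}, the total lymphocytes in
clusters of that type, so that sum_{s>=5} P(s)·s / N = 1; the cumulative
fraction f(s) accumulates the same summand up to s.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .io import LYMPHOCYTE_PHENOTYPES, T_LINEAGE_PHENOTYPES, PointPattern

__all__ = [
    "ClusterParams",
    "DEFAULT_CLUSTER_PARAMS",
    "DEFAULT_TLS_PARAMS",
    "LymphocyteCluster",
    "ClusterSizeDistribution",
    "EmptyDistributionError",
    "detect_clusters",
    "classify_cluster",
    "detect_tls",
    "size_distribution",
    "composition_proportions",
    "membership_by_cell",
]

LC_TYPES = ("pure_T", "heterotypic", "pure_B")


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN neighbourhood: radius eps (μm) and minimum count min_pts,
    the centre cell included."""

    eps: float = 20.0
    min_pts: int = 5

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.min_pts < 2:
            raise ValueError(f"min_pts must be >= 2, got {self.min_pts}")


DEFAULT_CLUSTER_PARAMS = ClusterParams(eps=20.0, min_pts=5)
DEFAULT_TLS_PARAMS = ClusterParams(eps=70.0, min_pts=200)


@dataclass
class LymphocyteCluster:
    """One detected LC: members are lymphocyte cell_ids in stable pattern order."""

    cluster_id: int
    members: list[str]
    composition: dict[str, int]
    centroid: tuple[float, float]
    lc_type: str = "pure_T"
    is_tls: bool = False

    @property
    def size_s(self) -> int:
        return len(self.members)

    def lymphocyte_proportions(self) -> dict[str, float]:
        """Per-phenotype proportions over lymphocyte members (sum to 1)."""
        total = sum(self.composition.values())
        return {ph: c / total for ph, c in self.composition.items()}


class EmptyDistributionError(ValueError):
    """No clusters of the requested type/outcome."""


def detect_clusters(pattern: PointPattern,
                    params: ClusterParams = DEFAULT_CLUSTER_PARAMS,
                    ) -> tuple[list[LymphocyteCluster], set[str]]:
    """Run DBSCAN over the pattern's lymphocytes (B and T lineages pooled).

    Returns the detected clusters (classified by composition) and the set of
    isolated lymphocyte cell_ids.  Every lymphocyte lands in exactly one of
    the two.  Border cells reachable from several clusters are assigned
    deterministically by stable input order (scikit-learn's DBSCAN assigns a
    border point to the first cluster that reaches it in data order).
    """
    lmask = pattern.lymphocyte_mask
    sub = pattern.cells.loc[lmask]
    if len(sub) == 0:
        return [], set()
    xy = sub[["x", "y"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(xy)

    clusters: list[LymphocyteCluster] = []
    ids = sub["cell_id"].to_numpy()
    phen = sub["phenotype"].to_numpy()
    for lab in np.unique(labels):
        if lab < 0:
            continue
        sel = labels == lab
        comp = dict(Counter(phen[sel]))
        cl = LymphocyteCluster(
            cluster_id=int(lab),
            members=list(ids[sel]),
            composition=comp,
            centroid=(float(xy[sel, 0].mean()), float(xy[sel, 1].mean())))
        cl.lc_type = classify_cluster(cl)
        clusters.append(cl)
    isolated = set(ids[labels < 0])
    return clusters, isolated


def classify_cluster(cluster: LymphocyteCluster) -> str:
    """pure_T if no B members, pure_B if no T-lineage members, else heterotypic."""
    n_b = cluster.composition.get("B", 0)
    n_t = sum(cluster.composition.get(ph, 0) for ph in T_LINEAGE_PHENOTYPES)
    if n_b == 0 and n_t == 0:
        raise ValueError("cluster has no lymphocyte members")
    if n_b == 0:
        return "pure_T"
    if n_t == 0:
        return "pure_B"
    return "heterotypic"


def detect_tls(pattern: PointPattern,
               clusters: list[LymphocyteCluster],
               tls_params: ClusterParams = DEFAULT_TLS_PARAMS,
               ) -> list[LymphocyteCluster]:
    """Flag TLS among detected LCs; returns the flagged subset.

    A cluster qualifies when a density pass over its own members with
    eps = 70 μm and min_pts = 200 yields at least one core point, i.e. some
    member has >= 200 fellow members (itself included) within 70 μm.
    Membership is never modified, so TLS remain a subset of LCs.
    """
    id_index = pattern.cells.set_index("cell_id")
    for cl in clusters:
        cl.is_tls = False
        if cl.size_s < tls_params.min_pts:
            continue
        xy = id_index.loc[cl.members, ["x", "y"]].to_numpy(dtype=float)
        nn = NearestNeighbors(radius=tls_params.eps).fit(xy)
        counts = np.fromiter(
            (len(idx) for idx in nn.radius_neighbors(xy, return_distance=False)),
            dtype=int, count=len(xy))
        if (counts >= tls_params.min_pts).any():
            cl.is_tls = True
    return [cl for cl in clusters if cl.is_tls]


def size_distribution(clusters: list[LymphocyteCluster],
                      type_i: str,
                      outcome_o: str = "unlabeled",
                      min_size: int = 5,
                      ) -> "ClusterSizeDistribution":
    """Normalised cluster-size distribution for one LC type.

    ``type_i`` must be pure_T or heterotypic (pure-B LCs are reported by
    detection but excluded from the distribution index).
    """
    if type_i not in ("pure_T", "heterotypic"):
        raise ValueError(
            f"size distribution is defined for pure_T/heterotypic, got {type_i!r}")
    sizes = [cl.size_s for cl in clusters
             if cl.lc_type == type_i and cl.size_s >= min_size]
    if not sizes:
        raise EmptyDistributionError(
            f"no clusters of type {type_i!r} for outcome {outcome_o!r}")
    counts = Counter(sizes)
    total_N = sum(s * c for s, c in counts.items())
    normalized = {s: c / total_N for s, c in sorted(counts.items())}
    cumulative, running = {}, 0.0
    for s in sorted(counts):
        running += counts[s] * s / total_N
        cumulative[s] = running
    return ClusterSizeDistribution(
        outcome_o=outcome_o, type_i=type_i,
        counts_P=dict(sorted(counts.items())), total_N=total_N,
        normalized=normalized, cumulative_f=cumulative)


@dataclass
class ClusterSizeDistribution:
    outcome_o: str
    type_i: str
    counts_P: dict[int, int]
    total_N: int
    normalized: dict[int, float]
    cumulative_f: dict[int, float]

    def check_normalization(self) -> float:
        """Value of sum_s P(s)·s / N; exactly 1 by construction."""
        return sum(s * c for s, c in self.counts_P.items()) / self.total_N

    def to_frame(self):
        """Tabular export: columns (s, P, P_over_N, f)."""
        import pandas as pd
        return pd.DataFrame({
            "s": list(self.counts_P),
            "P": list(self.counts_P.values()),
            "P_over_N": [self.normalized[s] for s in self.counts_P],
            "f": [self.cumulative_f[s] for s in self.counts_P]})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def composition_proportions(clusters: list[LymphocyteCluster],
                            type_i: str) -> dict[str, float]:
    """Unweighted mean per-phenotype lymphocyte proportions across clusters
    of one type ("tls" selects flagged TLS of any type)."""
    if type_i == "tls":
        selected = [cl for cl in clusters if cl.is_tls]
    else:
        selected = [cl for cl in clusters if cl.lc_type == type_i]
    if not selected:
        raise EmptyDistributionError(f"no clusters of type {type_i!r}")
    acc: dict[str, float] = {ph: 0.0 for ph in LYMPHOCYTE_PHENOTYPES}
    for cl in selected:
        for ph, p in cl.lymphocyte_proportions().items():
            acc[ph] = acc.get(ph, 0.0) + p
    return {ph: v / len(selected) for ph, v in acc.items()}


def membership_by_cell(pattern: PointPattern,
                       clusters: list[LymphocyteCluster],
                       isolated: set[str]) -> dict[str, str]:
    """Map each lymphocyte cell_id to its membership class: the containing
    LC's type, or "isolated".  Non-lymphocytes are absent from the map."""
    out: dict[str, str] = {cid: "isolated" for cid in isolated}
    for cl in clusters:
        for cid in cl.members:
            out[cid] = cl.lc_type
    return out
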