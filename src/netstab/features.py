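"""Graph-theoretic features of weighted connectomes and their stability.

Univariate (graphwise) features: edge count, mean clustering coefficient,
global efficiency, modularity of the largest connected component,
degree assortativity and mean path length.  Nodewise features: weighted
degree (strength), clustering coefficient, betweenness centrality.
Edgewise features: edge weight and connection length (Euclidean distance
between node coordinates — a geometric stand-in, flagged in outputs).

Path-based measures use inverse-weight edge lengths, the standard
weighted-connectome convention.  Modularity uses greedy modularity
maximization on the largest connected component.  Kurtosis is reported
as excess kurtosis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .stability import significant_digits

__all__ = [
    "UNIVARIATE_FEATURES",
    "NODEWISE_FEATURES",
    "EDGEWISE_FEATURES",
    "MomentReport",
    "compute_features",
    "univariate_features",
    "nodewise_features",
    "edgewise_features",
    "univariate_zscore_fpr",
    "multivariate_stability",
]

UNIVARIATE_FEATURES = (
    "edge_count",
    "mean_clustering",
    "global_efficiency",
    "modularity",
    "assortativity",
    "mean_path_length",
)
NODEWISE_FEATURES = ("degree", "clustering", "betweenness")
EDGEWISE_FEATURES = ("edge_weight", "connection_length")
MOMENTS = ("sum", "mean", "variance", "skew", "kurtosis")

#: two-sided critical value for p < 0.05
_Z_CRIT = stats.norm.ppf(0.975)


def _as_graph(weights: np.ndarray) -> nx.Graph:
    w = np.asarray(weights, dtype=np.float64)
    g = nx.from_numpy_array(w)
    # inverse-weight lengths for path-based measures
    for _, _, d in g.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    return g


def _empty_sentinels() -> dict:
    return {f: float("nan") for f in UNIVARIATE_FEATURES} | {"edge_count": 0.0}


def univariate_features(weights: np.ndarray, seed: int = 0) -> dict[str, float]:
    """Graphwise summary features of a weighted adjacency matrix."""
    g = _as_graph(weights)
    if g.number_of_edges() == 0:
        return _empty_sentinels()

    out: dict[str, float] = {}
    out["edge_count"] = float(g.number_of_edges())
    out["mean_clustering"] = float(nx.average_clustering(g, weight="weight"))

    n = g.number_of_nodes()
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    eff_sum = 0.0
    path_sum = 0.0
    n_reachable = 0
    for u in g:
        for v in g:
            if u == v:
                continue
            d = lengths[u].get(v)
            if d is not None and d > 0:
                eff_sum += 1.0 / d
                path_sum += d
                n_reachable += 1
    out["global_efficiency"] = eff_sum / (n * (n - 1)) if n > 1 else float("nan")
    out["mean_path_length"] = (
        path_sum / n_reachable if n_reachable else float("nan")
    )

    lcc = g.subgraph(max(nx.connected_components(g), key=len))
    communities = nx.community.greedy_modularity_communities(lcc, weight="weight")
    out["modularity"] = float(
        nx.community.modularity(lcc, communities, weight="weight")
    )

    try:
        with warnings.catch_warnings():
            # regular graphs have zero degree variance: NaN, not an error
            warnings.simplefilter("ignore", RuntimeWarning)
            out["assortativity"] = float(
                nx.degree_assortativity_coefficient(g, weight="weight")
            )
    except (ZeroDivisionError, ValueError):
        out["assortativity"] = float("nan")
    return out


def nodewise_features(weights: np.ndarray) -> dict[str, np.ndarray]:
    """Per-node feature vectors: strength, clustering, betweenness.

    Betweenness is unnormalized (pair counts through each node), computed
    on inverse-weight shortest paths.
    """
    g = _as_graph(weights)
    n = g.number_of_nodes()
    degree = np.array([d for _, d in g.degree(weight="weight")], dtype=np.float64)
    clustering = np.array(
        [nx.clustering(g, weight="weight")[v] for v in range(n)], dtype=np.float64
    )
    betweenness = np.array(
        [
            nx.betweenness_centrality(g, weight="length", normalized=False)[v]
            for v in range(n)
        ],
        dtype=np.float64,
    )
    return {"degree": degree, "clustering": clustering, "betweenness": betweenness}


def edgewise_features(
    weights: np.ndarray, node_coords: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Per-edge feature vectors over present (nonzero) edges."""
    w = np.asarray(weights, dtype=np.float64)
    iu = np.triu_indices(w.shape[0], k=1)
    present = w[iu] > 0
    out = {"edge_weight": w[iu][present]}
    if node_coords is not None:
        coords = np.asarray(node_coords, dtype=np.float64)
        dists = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
        out["connection_length"] = dists[present]
    return out


def compute_features(
    weights: np.ndarray, node_coords: np.ndarray | None = None, seed: int = 0
) -> dict:
    """All feature families for one connectome."""
    return {
        "univariate": univariate_features(weights, seed=seed),
        "nodewise": nodewise_features(weights),
        "edgewise": edgewise_features(weights, node_coords),
    }


@dataclass
class FprResult:
    """Z-score false-positive proportion for one univariate feature."""

    feature: str
    proportion: float          # NaN when every subject was perfectly stable
    n_flagged: int             # samples with |Z| exceeding the critical value
    n_samples: int
    n_stable_subjects: int     # subjects with zero within-subject variance


def univariate_zscore_fpr(
    values_per_subject: Mapping | Sequence[Sequence[float]],
    feature: str = "feature",
) -> FprResult:
    """Proportion of classically significant Z-scores across perturbations.

    Each sample is Z-scored against its subject's perturbation
    distribution; the proportion with two-sided p < 0.05 is aggregated
    across subjects.  Deliberately uncorrected for multiple comparisons.
    Subjects with zero within-subject variance are flagged perfectly
    stable and excluded from the proportion.
    """
    if isinstance(values_per_subject, Mapping):
        groups = list(values_per_subject.values())
    else:
        groups = list(values_per_subject)
    n_flagged = 0
    n_samples = 0
    n_stable = 0
    for vals in groups:
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size < 2:
            raise ValueError("need >= 2 perturbed values per subject")
        sd = arr.std(ddof=1)
        if sd == 0.0:
            n_stable += 1
            continue
        z = (arr - arr.mean()) / sd
        n_flagged += int(np.sum(np.abs(z) > _Z_CRIT))
        n_samples += arr.size
    proportion = n_flagged / n_samples if n_samples else float("nan")
    return FprResult(
        feature=feature,
        proportion=proportion,
        n_flagged=n_flagged,
        n_samples=n_samples,
        n_stable_subjects=n_stable,
    )


def _moments(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        return {m: float("nan") for m in MOMENTS}
    return {
        "sum": float(v.sum()),
        "mean": float(v.mean()),
        "variance": float(v.var(ddof=1)) if v.size > 1 else 0.0,
        "skew": float(stats.skew(v)),
        "kurtosis": float(stats.kurtosis(v)),  # excess kurtosis
    }


@dataclass
class MomentReport:
    """Distributional stability of one multivariate feature."""

    feature: str
    moments: pd.DataFrame        # subject x sim x moment values
    moment_digits: pd.DataFrame  # per subject: significant digits per moment
    cdf_grid: np.ndarray
    cdf_mean: np.ndarray         # across-subject mean CDF on the grid
    cdf_se: np.ndarray           # across-subject standard error

    @property
    def median_digits(self) -> dict[str, float]:
        return {
            m: float(self.moment_digits[m].median()) for m in MOMENTS
        }

    def validate(self) -> None:
        if np.any(np.diff(self.cdf_mean) < -1e-12):
            raise AssertionError("CDF must be nondecreasing")
        if self.cdf_mean.min() < -1e-12 or self.cdf_mean.max() > 1 + 1e-12:
            raise AssertionError("CDF must be within [0, 1]")


def multivariate_stability(
    values_per_subject: Mapping,
    feature: str = "feature",
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> MomentReport:
    """Moment stability and CDF summary of a multivariate feature.

    ``values_per_subject`` maps subject id to an (n_sims, n_items) array
    (or list of per-sim value vectors).  Per subject, the five moments of
    each simulation's distribution are computed and their significant
    digits across simulations recorded; per-subject pooled CDFs are
    evaluated on a fixed grid and averaged across subjects with a
    standard error.  The default grid spans 0 to the 99.5th percentile of
    the pooled values.
    """
    subjects = sorted(values_per_subject)
    stacks: dict = {}
    for s in subjects:
        arr = np.asarray(values_per_subject[s], dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[0] < 2:
            raise ValueError("need >= 2 simulations per subject")
        stacks[s] = arr
    shapes = {a.shape[1] for a in stacks.values()}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent item counts across subjects: {shapes}")

    if grid is None:
        pooled = np.concatenate([a.ravel() for a in stacks.values()])
        hi = float(np.percentile(pooled, 99.5))
        if hi <= 0:
            hi = max(float(pooled.max()), 1.0)
        grid = np.linspace(0.0, hi, n_grid)
    grid = np.asarray(grid, dtype=np.float64)

    moment_rows = []
    digit_rows = []
    cdfs = []
    for s in subjects:
        arr = stacks[s]
        per_sim = [_moments(arr[i]) for i in range(arr.shape[0])]
        for i, m in enumerate(per_sim):
            moment_rows.append({"subject": s, "sim": i, **m})
        digits = {}
        for m in MOMENTS:
            vals = np.array([p[m] for p in per_sim])
            if np.all(np.isfinite(vals)):
                digits[m] = float(significant_digits(vals))
            else:
                digits[m] = float("nan")
        digit_rows.append({"subject": s, **digits})
        pooled_subj = np.sort(arr.ravel())
        cdfs.append(
            np.searchsorted(pooled_subj, grid, side="right") / pooled_subj.size
        )

    cdf_arr = np.asarray(cdfs)
    report = MomentReport(
        feature=feature,
        moments=pd.DataFrame(moment_rows),
        moment_digits=pd.DataFrame(digit_rows),
        cdf_grid=grid,
        cdf_mean=cdf_arr.mean(axis=0),
        cdf_se=(
            cdf_arr.std(axis=0, ddof=1) / math.sqrt(len(subjects))
            if len(subjects) > 1
            else np.zeros_like(grid)
        ),
    )
    report.validate()
    return report
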