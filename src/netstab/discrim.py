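"""Discriminability statistic, permutation testing and condition comparisons.

The discriminability of a labelled set of observations is the probability,
over all (anchor, within-class partner, cross-class observation) triples,
that the within-class distance is less than or equal to the cross-class
distance.  It is a rank-based reliability statistic: invariant to any
strictly increasing transform of the distance and to relabelling of
classes.

Hypotheses on the synthetic cohort:

* H1 — subjects are distinct (class = subject);
* H2 — sessions within a subject are distinct (class = session,
  evaluated per subject and aggregated);
* H3 — subsamples within a subject+session are distinct (class =
  subsample, requires perturbed executions).

Significance is assessed by permuting labels within the hypothesis's
exchangeability blocks.  Chance level is reported as one over the number
of classes (the tabulation convention), alongside the empirical
permutation-null mean, which differs from it for multi-class designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .cohort import REFERENCE_SIM, Connectome, SampleKey

__all__ = [
    "HYPOTHESES",
    "DiscriminabilityResult",
    "discriminability",
    "permutation_test",
    "run_hypothesis",
    "compare_conditions",
    "default_scaled_score",
]

HYPOTHESES = ("H1", "H2", "H3")

#: comparison settings per hypothesis; those usable on reference-only data
#: are marked reference-capable
HYPOTHESIS_COMPARISONS: dict[str, tuple[str, ...]] = {
    "H1": ("session", "subsample", "mca"),
    "H2": ("subsample", "mca"),
    "H3": ("mca",),
}


def _validate_obs(x: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(labels)
    if x.ndim != 2 or len(labels) != x.shape[0]:
        raise ValueError("observations must be (n, d) with one label per row")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("discriminability requires at least 2 classes")
    if counts.min() < 2:
        raise ValueError(
            "every class needs >= 2 observations (singleton class found)"
        )
    return x, labels


def discriminability(
    x: np.ndarray, labels: Sequence, metric: str = "euclidean"
) -> float:
    """Probability that within-class distances do not exceed cross-class ones.

    For every anchor observation, every other observation of the same
    class, and every observation of a different class, the event
    ``d(anchor, within) <= d(anchor, cross)`` is counted; ties count as
    successes.  The value is the proportion of successes over all such
    triples.
    """
    x, labels = _validate_obs(x, np.asarray(labels))
    dist = cdist(x, x, metric=metric)
    n = x.shape[0]
    hits = 0
    total = 0
    for i in range(n):
        same = (labels == labels[i])
        same[i] = False
        within = dist[i, same]
        cross = np.sort(dist[i, ~same & (np.arange(n) != i)])
        if within.size == 0 or cross.size == 0:
            continue
        # successes: cross >= within, counted via sorted search
        lt = np.searchsorted(cross, within, side="left")  # #cross < within
        hits += within.size * cross.size - int(lt.sum())
        total += within.size * cross.size
    return hits / total


def _permute_labels(
    labels: np.ndarray, blocks: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    if blocks is None:
        return rng.permutation(labels)
    out = labels.copy()
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        out[idx] = labels[idx][rng.permutation(len(idx))]
    return out


def permutation_test(
    x: np.ndarray,
    labels: Sequence,
    blocks: Sequence | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "euclidean",
    return_null: bool = False,
):
    """Permutation p-value for the discriminability statistic.

    Labels are permuted within the exchangeability ``blocks`` (or freely
    when ``blocks`` is None); the p-value is
    ``(1 + #{D_perm >= D_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    blocks_arr = None if blocks is None else np.asarray(blocks)
    if blocks_arr is not None and len(blocks_arr) != len(labels):
        raise ValueError("blocks must align with labels")
    d_obs = discriminability(x, labels, metric=metric)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = _permute_labels(labels, blocks_arr, rng)
        try:
            null[p] = discriminability(x, perm, metric=metric)
        except ValueError as exc:
            raise ValueError(
                f"exchangeability blocks incompatible with labels: {exc}"
            ) from exc
    p_value = (1 + int(np.sum(null >= d_obs))) / (1 + n_perm)
    if return_null:
        return p_value, d_obs, null
    return p_value, d_obs


def default_scaled_score(d: float, chance_empirical: float) -> float:
    """Rescale D so the empirical null maps to 0 and perfect to 1."""
    if chance_empirical >= 1.0:
        return 0.0
    return (d - chance_empirical) / (1.0 - chance_empirical)


@dataclass
class DiscriminabilityResult:
    """One hypothesis test outcome with its reporting metadata."""

    hypothesis: str
    comparison: str
    pipeline: str
    mode: str
    source: str  # observation pool: 'mca' (perturbed) or 'reference'
    statistic: float
    chance: float
    chance_empirical: float
    scaled_score: float
    p_value: float
    n_permutations: int
    n_classes: int
    n_observations: int
    n_sets: int
    notes: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "comparison": self.comparison,
            "pipeline": self.pipeline,
            "mode": self.mode if self.source == "mca" else "reference",
            "source": self.source,
            "discriminability": self.statistic,
            "chance": self.chance,
            "chance_empirical": self.chance_empirical,
            "scaled_score": self.scaled_score,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def _vectorize(c: Connectome | np.ndarray) -> np.ndarray:
    w = c.weights if isinstance(c, Connectome) else np.asarray(c)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu]


def _observation_sets(
    connectomes: Mapping[SampleKey, Connectome | np.ndarray],
    hypothesis: str,
    comparison: str,
    pipeline: str,
    mode: str,
    source: str = "mca",
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray | None]]:
    """Assemble independent (observations, labels, blocks) sets.

    ``source`` selects the observation pool: perturbed simulations
    (``mca``) or reference executions (``reference``).  Returns one set
    per independent slice of the design; statistics are computed per set
    and aggregated by the caller.
    """
    keys = [k for k in connectomes if k.pipeline == pipeline and k.mode == mode]
    use_mca = source == "mca"
    if use_mca:
        pool = [k for k in keys if k.sim != REFERENCE_SIM]
    else:
        pool = [k for k in keys if k.sim == REFERENCE_SIM]
    if not pool:
        raise ValueError(
            f"no {'perturbed' if use_mca else 'reference'} executions available "
            f"for {hypothesis}/{comparison} ({pipeline}, {mode})"
        )

    sets: list[tuple[np.ndarray, np.ndarray, np.ndarray | None]] = []

    def build(members: list[SampleKey], label_of, block_of=None):
        if not members:
            return
        x = np.stack([_vectorize(connectomes[k]) for k in members])
        labels = np.asarray([label_of(k) for k in members])
        blocks = None if block_of is None else np.asarray([block_of(k) for k in members])
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) >= 2 and counts.min() >= 2:
            sets.append((x, labels, blocks))

    if hypothesis == "H1":
        # class = subject; independent sets fix the sampled-over fields
        if comparison == "session":
            slices = sorted({k.subsample for k in pool})
            for sub in slices:
                build([k for k in pool if k.subsample == sub], lambda k: k.subject)
        elif comparison == "subsample":
            slices = sorted({k.session for k in pool})
            for ses in slices:
                build([k for k in pool if k.session == ses], lambda k: k.subject)
        else:  # mca: fixed session and subsample, observations across sims
            slices = sorted({(k.session, k.subsample) for k in pool})
            for ses, sub in slices:
                build(
                    [k for k in pool if k.session == ses and k.subsample == sub],
                    lambda k: k.subject,
                )
    elif hypothesis == "H2":
        # class = session within subject: one set per subject (and per
        # subsample for MCA observations); permute sessions within subject
        if comparison == "mca":
            slices = sorted({(k.subject, k.subsample) for k in pool})
            for subj, sub in slices:
                build(
                    [k for k in pool if k.subject == subj and k.subsample == sub],
                    lambda k: k.session,
                )
        else:  # subsample observations
            for subj in sorted({k.subject for k in pool}):
                build([k for k in pool if k.subject == subj], lambda k: k.session)
    elif hypothesis == "H3":
        if comparison != "mca":
            raise ValueError(
                "H3 requires perturbed executions; it cannot be tested on "
                "reference executions alone"
            )
        slices = sorted({(k.subject, k.session) for k in pool})
        for subj, ses in slices:
            build(
                [k for k in pool if k.subject == subj and k.session == ses],
                lambda k: k.subsample,
            )
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")

    if not sets:
        raise ValueError(
            f"cohort design does not support {hypothesis}/{comparison}: "
            "no observation set has >= 2 classes with >= 2 observations each"
        )
    return sets


def run_hypothesis(
    connectomes: Mapping[SampleKey, Connectome | np.ndarray],
    hypothesis: str,
    pipeline: str,
    mode: str,
    comparison: str | None = None,
    source: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "euclidean",
    scale_fn: Callable[[float, float], float] = default_scaled_score,
) -> DiscriminabilityResult:
    """Run one discriminability hypothesis test on a cohort's connectomes.

    The statistic is the mean discriminability over the hypothesis's
    independent observation sets; the permutation null permutes labels
    within each set's exchangeability blocks and recomputes the same
    aggregate, yielding a single p-value for the aggregated statistic.

    ``source`` selects perturbed (``'mca'``) or reference
    (``'reference'``) observations; the ``'mca'`` comparison setting has
    no reference variant (too few executions to compare).
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
    if comparison is None:
        comparison = HYPOTHESIS_COMPARISONS[hypothesis][-1]
    if comparison not in HYPOTHESIS_COMPARISONS[hypothesis]:
        raise ValueError(
            f"{hypothesis} supports comparisons {HYPOTHESIS_COMPARISONS[hypothesis]}"
        )
    if source is None:
        source = "mca"
    if source not in ("mca", "reference"):
        raise ValueError("source must be 'mca' or 'reference'")
    if comparison == "mca" and source == "reference":
        raise ValueError("the MCA comparison cannot run on reference executions")
    sets = _observation_sets(
        connectomes, hypothesis, comparison, pipeline, mode, source
    )

    d_per_set = [discriminability(x, lab, metric=metric) for x, lab, _ in sets]
    d_obs = float(np.mean(d_per_set))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        vals = []
        for x, lab, _ in sets:
            perm = _permute_labels(lab, None, rng)
            # retry degenerate block permutations are not possible here:
            # free permutation preserves class counts, so always valid
            vals.append(discriminability(x, perm, metric=metric))
        null[p] = np.mean(vals)
    p_value = (1 + int(np.sum(null >= d_obs))) / (1 + n_perm)
    chance_empirical = float(np.mean(null))

    n_classes = int(np.mean([len(np.unique(lab)) for _, lab, _ in sets]))
    chance = 1.0 / n_classes
    return DiscriminabilityResult(
        hypothesis=hypothesis,
        comparison=comparison,
        pipeline=pipeline,
        mode=mode,
        source=source,
        statistic=d_obs,
        chance=chance,
        chance_empirical=chance_empirical,
        scaled_score=scale_fn(d_obs, chance_empirical),
        p_value=p_value,
        n_permutations=n_perm,
        n_classes=n_classes,
        n_observations=int(sum(x.shape[0] for x, _, _ in sets)),
        n_sets=len(sets),
        notes={
            "chance_convention": "1/n_classes (tabulation convention); the "
            "empirical exchangeable null of the rank statistic is also reported "
            "and differs for multi-class designs",
        },
    )


def compare_conditions(
    condition_a: Sequence[float],
    condition_b: Sequence[float],
    *more_pairs: tuple[Sequence[float], Sequence[float]],
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests with multiple-comparison correction.

    Accepts one or more pairs of equal-length paired statistic lists and
    returns a table with raw and Benjamini-Hochberg-corrected p-values.
    Pairs whose differences are all zero are degenerate: their p-value is
    the NaN sentinel and they are never rejected.
    """
    pairs = [(condition_a, condition_b), *more_pairs]
    rows = []
    for i, (a, b) in enumerate(pairs):
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("conditions must be paired equal-length 1-d lists")
        diffs = b - a
        if np.all(diffs == 0.0):
            rows.append({"pair": i, "statistic": np.nan, "p_raw": np.nan,
                         "direction": 0.0, "degenerate": True})
            continue
        stat, p = wilcoxon(a, b)
        rows.append({"pair": i, "statistic": float(stat), "p_raw": float(p),
                     "direction": float(np.sign(np.median(diffs))),
                     "degenerate": False})
    df = pd.DataFrame(rows)
    valid = ~df["p_raw"].isna()
    df["p_corrected"] = np.nan
    df["reject"] = False
    if valid.any():
        reject, p_corr, *_ = multipletests(
            df.loc[valid, "p_raw"], alpha=alpha, method=method
        )
        df.loc[valid, "p_corrected"] = p_corr
        df.loc[valid, "reject"] = reject
    return df


def results_table(results: Sequence[DiscriminabilityResult]) -> pd.DataFrame:
    """Tabulate hypothesis results (hypothesis x comparison x pipeline x mode)."""
    return pd.DataFrame([r.to_row() for r in results])


def count_tests(
    hypotheses: Mapping[str, Sequence[str]] = HYPOTHESIS_COMPARISONS,
    n_pipelines: int = 2,
    n_modes: int = 2,
) -> int:
    """Number of distinct tests in a hypothesis grid.

    Every comparison setting is evaluated on perturbed (MCA) data for
    each pipeline-mode combination; comparison settings that do not need
    perturbed executions are additionally evaluated on the reference
    executions, once per pipeline (references carry no perturbation mode).
    """
    n_mca_settings = sum(len(v) for v in hypotheses.values())
    n_ref_settings = sum(1 for v in hypotheses.values() for c in v if c != "mca")
    return n_mca_settings * n_pipelines * n_modes + n_ref_settings * n_pipelines
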