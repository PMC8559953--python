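"""Direct variability quantification between connectomes.

Three metrics are computed between (or across) adjacency matrices:

* normalized percent deviation — the Frobenius norm of the difference
  between a matrix and a reference, scaled by the reference norm;
* Pearson correlation of vectorized upper-triangle edge weights;
* significant digits — ``-log10(sigma / |mu|)`` across repeated
  executions, capped at 15.7 (the double-precision bound).

:func:`group_stability` aggregates these metrics over all comparison
pairs of a cohort grouped by which design field varies (simulation,
subsample, session or subject).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import REFERENCE_SIM, Connectome, SampleKey

__all__ = [
    "DIGITS_CAP",
    "COMPARISON_LEVELS",
    "StabilityReport",
    "percent_deviation",
    "significant_digits",
    "pearson_correlation",
    "group_stability",
]

#: upper bound on significant decimal digits for 64-bit floats:
#: -log10(2**-52) rounded to three significant figures
DIGITS_CAP = 15.7

COMPARISON_LEVELS = ("mca", "subsample", "session", "subject")


class UndefinedReferenceError(ValueError):
    """Raised when percent deviation is requested against a zero reference."""


def percent_deviation(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized percent deviation of ``b`` from the reference ``a``.

    Computed as ``||a - b||_F / ||a||_F``.  Zero iff the matrices are
    equal; equals 1.0 when ``b`` is the zero matrix.  Scale invariant:
    rescaling both matrices by the same nonzero factor leaves the value
    unchanged.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = np.linalg.norm(a)
    if denom == 0.0:
        raise UndefinedReferenceError("reference matrix is all-zero")
    return float(np.linalg.norm(a - b) / denom)


def significant_digits(
    samples: np.ndarray, axis: int = 0, cap: float = DIGITS_CAP
) -> np.ndarray | float:
    """Estimated significant decimal digits across repeated samples.

    ``s' = -log10(sigma / |mu|)`` where ``mu`` and ``sigma`` are the mean
    and the n-1-denominator (unbiased-variance) standard deviation along
    ``axis``.  Values are clipped to ``[0, cap]``; ``sigma == 0`` maps to
    the cap and ``mu == 0`` with ``sigma > 0`` maps to 0.

    Raises
    ------
    ValueError
        If fewer than two samples are provided along ``axis``.
    """
    arr = np.asarray(samples, dtype=np.float64)
    if arr.shape[axis] < 2:
        raise ValueError("significant_digits requires at least 2 samples")
    mu = arr.mean(axis=axis)
    sigma = arr.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        digits = -np.log10(sigma / np.abs(mu))
    digits = np.where(sigma == 0.0, cap, digits)
    digits = np.where((sigma > 0.0) & (mu == 0.0), 0.0, digits)
    digits = np.clip(digits, 0.0, cap)
    return float(digits) if np.ndim(digits) == 0 else digits


def _upper(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of upper-triangle edge weights.

    Returns NaN (undefined-correlation sentinel) when either input has
    zero variance over the compared entries.
    """
    x, y = _upper(a), _upper(b)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class StabilityReport:
    """Pairwise metrics and per-edge digit summaries for one level."""

    level: str
    pairs: pd.DataFrame        # one row per compared pair: pdev, correlation
    edge_digits: pd.DataFrame  # one row per group: mean/median per-edge digits

    @property
    def median_pdev(self) -> float:
        return float(self.pairs["pdev"].median())

    @property
    def median_correlation(self) -> float:
        return float(self.pairs["correlation"].median())

    @property
    def mean_edge_digits(self) -> float:
        return float(self.edge_digits["mean_digits"].mean())

    def to_json_summary(self) -> dict:
        return {
            "level": self.level,
            "n_pairs": int(len(self.pairs)),
            "median_pdev": self.median_pdev,
            "median_correlation": self.median_correlation,
            "mean_edge_digits": self.mean_edge_digits,
        }


def _weights(c) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=np.float64)


def group_stability(
    connectomes: Mapping[SampleKey, Connectome | np.ndarray],
    level: str,
) -> StabilityReport:
    """Aggregate stability metrics for one comparison class.

    Pairing rules (within fixed pipeline and perturbation mode):

    ``mca``
        reference vs. each perturbed simulation of the same sample;
        per-edge digits across the perturbed simulations of the sample.
    ``subsample``
        reference executions of different subsamples, same
        subject+session.
    ``session``
        references of different sessions, same subject and subsample.
    ``subject``
        references of different subjects, same session and subsample.

    For the non-MCA levels the first element of each (unordered) pair
    acts as the reference in the percent-deviation ratio, and per-edge
    digits are evaluated across the full group of references.
    """
    if level not in COMPARISON_LEVELS:
        raise ValueError(f"level must be one of {COMPARISON_LEVELS}, got {level!r}")

    keys = list(connectomes)
    refs = [k for k in keys if k.sim == REFERENCE_SIM]
    sims = [k for k in keys if k.sim != REFERENCE_SIM]

    pair_rows: list[dict] = []
    digit_rows: list[dict] = []

    def add_digits(group_id: tuple, members: list[SampleKey]) -> None:
        if len(members) < 2:
            return
        stack = np.stack([_weights(connectomes[k]) for k in members])
        iu = np.triu_indices(stack.shape[1], k=1)
        per_edge = significant_digits(stack[:, iu[0], iu[1]], axis=0)
        digit_rows.append(
            {
                "group": repr(group_id),
                "n_members": len(members),
                "mean_digits": float(np.mean(per_edge)),
                "median_digits": float(np.median(per_edge)),
            }
        )

    def add_pair(ref_key: SampleKey, other_key: SampleKey) -> None:
        a = _weights(connectomes[ref_key])
        b = _weights(connectomes[other_key])
        pair_rows.append(
            {
                "ref": repr(tuple(ref_key)),
                "other": repr(tuple(other_key)),
                "pipeline": ref_key.pipeline,
                "mode": ref_key.mode,
                "pdev": percent_deviation(a, b),
                "correlation": pearson_correlation(a, b),
            }
        )

    if level == "mca":
        units = sorted({(k.sample_id, k.pipeline, k.mode) for k in sims})
        for sample_id, pipeline, mode in units:
            ref_key = SampleKey(*sample_id, pipeline=pipeline, mode=mode)
            if ref_key not in connectomes:
                continue
            members = sorted(
                k for k in sims
                if k.sample_id == sample_id and k.pipeline == pipeline and k.mode == mode
            )
            for k in members:
                add_pair(ref_key, k)
            add_digits((sample_id, pipeline, mode), members)
    else:
        varying = {"subsample": 2, "session": 1, "subject": 0}[level]
        fixed = [i for i in range(3) if i != varying]

        def group_of(k: SampleKey) -> tuple:
            sid = k.sample_id
            return (tuple(sid[i] for i in fixed), k.pipeline, k.mode)

        groups: dict[tuple, list[SampleKey]] = {}
        for k in refs:
            groups.setdefault(group_of(k), []).append(k)
        for gid in sorted(groups):
            members = sorted(groups[gid])
            if len(members) < 2:
                continue
            for ka, kb in combinations(members, 2):
                add_pair(ka, kb)
            add_digits(gid, members)

    if not pair_rows:
        raise ValueError(f"no valid comparison pairs for level {level!r}")
    return StabilityReport(
        level=level,
        pairs=pd.DataFrame(pair_rows),
        edge_digits=pd.DataFrame(digit_rows),
    )
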