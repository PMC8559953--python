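"""Synthetic cohort generation and perturbable connectome reconstruction.

The cohort emulates the hierarchical structure of a test-retest imaging
study: subjects carry a latent connectivity profile, sessions add a
session-specific bias, and each measurement volume adds i.i.d. noise.
Sessions can be split into odd/even subsamples that each retain all
baseline volumes.  Connectomes are reconstructed from the measurements by
a numeric chain (normal-equation model fit, outer-product accumulation,
normalization) whose floating-point steps are routed through the MCA
instrumentation layer, so perturbation noise propagates through the same
arithmetic that produces the reference result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

from .mca import (
    CORE_NUMERIC,
    DATA_LAYER,
    MCAContext,
    PerturbationProfile,
    simulation_rng,
)
from .util import stable_seed

__all__ = [
    "StudyDesign",
    "EffectSizes",
    "SampleKey",
    "SubjectModel",
    "Sample",
    "Cohort",
    "Connectome",
    "generate_cohort",
    "split_subsamples",
    "reconstruct_connectome",
    "run_sample_simulations",
    "REFERENCE_SIM",
]

#: simulation index used for the unperturbed reference execution
REFERENCE_SIM = -1

PIPELINES = ("det-like", "prob-like")
MODES = ("dense", "sparse")


class SampleKey(NamedTuple):
    """Identifies one pipeline execution within the experiment grid."""

    subject: int
    session: int
    subsample: int
    pipeline: str = "det-like"
    mode: str = "dense"
    sim: int = REFERENCE_SIM

    @property
    def is_reference(self) -> bool:
        return self.sim == REFERENCE_SIM

    @property
    def sample_id(self) -> tuple[int, int, int]:
        return (self.subject, self.session, self.subsample)


@dataclass(frozen=True)
class StudyDesign:
    """Counts defining a study layout and its perturbation grid."""

    n_subjects: int = 25
    n_sessions: int = 2
    n_subsamples: int = 2
    n_volumes: int = 128
    n_b0: int = 9
    n_sims: int = 20
    pipelines: tuple[str, ...] = PIPELINES
    modes: tuple[str, ...] = MODES
    n_nodes: int = 40
    rank: int = 6

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_subsamples", "n_volumes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_b0 < 0:
            raise ValueError("n_b0 must be >= 0")
        if self.n_sims < 0:
            raise ValueError("n_sims must be >= 0")
        if self.n_subsamples == 2 and self.n_volumes % 2:
            raise ValueError("n_volumes must be even to split into two subsamples")
        if self.n_subsamples not in (1, 2):
            raise ValueError("n_subsamples must be 1 (full session) or 2 (odd/even)")
        unknown = set(self.pipelines) - set(PIPELINES)
        if unknown:
            raise ValueError(f"unknown pipelines {sorted(unknown)}")
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes {sorted(unknown)}")
        if self.n_nodes < 2 or self.rank < 1:
            raise ValueError("need n_nodes >= 2 and rank >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_subjects * self.n_sessions * self.n_subsamples

    @property
    def total_executions(self) -> int:
        """Closed-form execution count: samples x pipelines x modes x (sims + ref)."""
        return (
            self.n_samples
            * len(self.pipelines)
            * len(self.modes)
            * (self.n_sims + 1)
        )

    @classmethod
    def repeated_measures(cls, **overrides) -> "StudyDesign":
        """25 subjects x 2 sessions x 2 subsamples, 20 simulations."""
        return cls(
            n_subjects=25, n_sessions=2, n_subsamples=2,
            n_volumes=128, n_b0=9, n_sims=20,
        ).replace(**overrides)

    @classmethod
    def cross_sectional(cls, **overrides) -> "StudyDesign":
        """100 subjects x 1 session x 1 full-resolution sample, 20 simulations."""
        return cls(
            n_subjects=100, n_sessions=1, n_subsamples=1,
            n_volumes=128, n_b0=9, n_sims=20,
        ).replace(**overrides)

    @classmethod
    def smoke(cls, **overrides) -> "StudyDesign":
        """Tiny end-to-end preset for fast checks."""
        return cls(
            n_subjects=4, n_sessions=2, n_subsamples=2,
            n_volumes=8, n_b0=1, n_sims=2, n_nodes=5, rank=2,
        ).replace(**overrides)

    def replace(self, **overrides) -> "StudyDesign":
        return replace(self, **overrides) if overrides else self


@dataclass(frozen=True)
class EffectSizes:
    """Variance components and phenotype association of the generator.

    The defaults reproduce the qualitative ordering of variability
    sources: subject differences dominate session differences, which
    dominate subsample differences.
    """

    sigma_subject: float = 1.0
    sigma_session: float = 0.3
    sigma_subsample: float = 0.1
    sigma_noise: float = 0.02
    phenotype_association: float = 0.8

    def __post_init__(self) -> None:
        for name in ("sigma_subject", "sigma_session", "sigma_subsample", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SubjectModel:
    """Latent state of one synthetic subject."""

    index: int
    factors: np.ndarray            # n_nodes x rank loading matrix
    covariate: float               # latent scalar driving the phenotype
    phenotype_label: int           # binary label, thresholded covariate
    latent_profile: np.ndarray     # symmetric, zero-diagonal, nonnegative

    def __post_init__(self) -> None:
        lp = self.latent_profile
        if not np.allclose(lp, lp.T):
            raise ValueError("latent profile must be symmetric")
        if np.any(np.diag(lp) != 0):
            raise ValueError("latent profile must have zero diagonal")
        if np.any(lp < 0):
            raise ValueError("latent profile must be nonnegative")


@dataclass
class Sample:
    """Measurement set for one (subject, session, subsample) sample."""

    sample_id: tuple[int, int, int]
    design_matrix: np.ndarray   # n_meas x (rank + 1); first column is intercept
    signals: np.ndarray         # n_meas x n_nodes


@dataclass
class Connectome:
    """Symmetric nonnegative weighted adjacency matrix with provenance."""

    weights: np.ndarray
    key: SampleKey

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class Cohort:
    """A generated cohort: subject models, node geometry and measurements."""

    design: StudyDesign
    effects: EffectSizes
    seed: int
    node_coords: np.ndarray
    subjects: list[SubjectModel]
    samples: dict[tuple[int, int, int], Sample] = field(repr=False, default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.phenotype_label for s in self.subjects], dtype=int)

    @property
    def covariates(self) -> np.ndarray:
        return np.array([s.covariate for s in self.subjects])

    def sample_ids(self) -> Iterator[tuple[int, int, int]]:
        d = self.design
        for subject in range(d.n_subjects):
            for session in range(d.n_sessions):
                for subsample in range(d.n_subsamples):
                    yield (subject, session, subsample)


def split_subsamples(
    n_volumes: int, n_b0: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split a session's volume indices into odd and even subsamples.

    Directional volumes are assigned alternately (even indices to the
    first subsample, odd to the second); every baseline (non-directional)
    volume appears in both subsamples.  Volumes are indexed with the
    directional volumes first (``0 .. n_volumes-1``) followed by the
    baselines (``n_volumes .. n_volumes+n_b0-1``).

    Returns
    -------
    (even, odd) : pair of index arrays, each of length
        ``n_volumes // 2 + n_b0``.
    """
    if n_volumes < 1 or n_volumes % 2:
        raise ValueError(f"n_volumes must be positive and even, got {n_volumes}")
    if n_b0 < 0:
        raise ValueError(f"n_b0 must be >= 0, got {n_b0}")
    directional = np.arange(n_volumes)
    b0 = np.arange(n_volumes, n_volumes + n_b0)
    even = np.concatenate([directional[0::2], b0])
    odd = np.concatenate([directional[1::2], b0])
    return even, odd


def generate_cohort(
    design: StudyDesign,
    effects: EffectSizes | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a cohort with subject/session/subsample structure.

    Each subject draws a latent factor matrix; each session adds a bias
    with scale ``sigma_session``; volumes of a given parity add a
    subsample bias (``sigma_subsample``) and i.i.d. measurement noise
    (``sigma_noise``).  The binary phenotype thresholds a latent covariate
    that is mixed into the subject factors with strength
    ``phenotype_association``.  Fully determined by ``seed``.
    """
    effects = effects or EffectSizes()
    d = design
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))

    node_coords = rng.uniform(0.0, 1.0, size=(d.n_nodes, 3))
    assoc_mix = rng.normal(size=(d.n_nodes, d.rank)) / np.sqrt(d.rank)
    base = np.abs(rng.normal(loc=1.0, scale=0.5, size=(d.n_nodes, d.rank)))

    subjects: list[SubjectModel] = []
    samples: dict[tuple[int, int, int], Sample] = {}

    for subject in range(d.n_subjects):
        z = rng.normal()
        factors = (
            base
            + effects.sigma_subject * rng.normal(size=(d.n_nodes, d.rank))
            + effects.phenotype_association * z * assoc_mix
        )
        profile = factors @ factors.T
        profile = np.maximum(profile, 0.0)
        np.fill_diagonal(profile, 0.0)
        profile = (profile + profile.T) / 2.0
        subjects.append(
            SubjectModel(
                index=subject,
                factors=factors,
                covariate=z,
                phenotype_label=int(z > 0),
                latent_profile=profile,
            )
        )

        for session in range(d.n_sessions):
            f_sess = factors + effects.sigma_session * rng.normal(
                size=(d.n_nodes, d.rank)
            )
            # parity-specific bias: the explicit subsample variance component
            parity_bias = effects.sigma_subsample * rng.normal(
                size=(2, d.n_nodes, d.rank)
            )
            directions = rng.normal(size=(d.n_volumes, d.rank))
            baseline = rng.normal(loc=1.0, scale=0.1, size=d.n_nodes)

            n_meas = d.n_volumes + d.n_b0
            dmat = np.zeros((n_meas, d.rank + 1))
            dmat[:, 0] = 1.0
            dmat[: d.n_volumes, 1:] = directions
            signals = np.empty((n_meas, d.n_nodes))
            for k in range(d.n_volumes):
                f_eff = f_sess + parity_bias[k % 2]
                signals[k] = (
                    baseline
                    + f_eff @ directions[k]
                    + effects.sigma_noise * rng.normal(size=d.n_nodes)
                )
            for k in range(d.n_b0):
                signals[d.n_volumes + k] = (
                    baseline + effects.sigma_noise * rng.normal(size=d.n_nodes)
                )

            if d.n_subsamples == 2:
                halves = split_subsamples(d.n_volumes, d.n_b0)
            else:
                halves = (np.arange(n_meas),)
            for subsample, idx in enumerate(halves):
                samples[(subject, session, subsample)] = Sample(
                    sample_id=(subject, session, subsample),
                    design_matrix=dmat[idx],
                    signals=signals[idx],
                )

    return Cohort(
        design=d,
        effects=effects,
        seed=int(seed),
        node_coords=node_coords,
        subjects=subjects,
        samples=samples,
    )


def _fit_factors(ctx: MCAContext, dmat: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """Least-squares signal-model fit via instrumented normal equations."""
    gram = ctx.matmul(dmat.T, dmat, tag=CORE_NUMERIC)
    moment = ctx.matmul(dmat.T, signals, tag=DATA_LAYER)
    # the LAPACK solve is a double-precision black box: round at its boundary
    gram64 = np.asarray(gram, dtype=np.float64)
    moment64 = np.asarray(moment, dtype=np.float64)
    try:
        coefs = np.linalg.solve(gram64, moment64)
    except np.linalg.LinAlgError:
        coefs, *_ = np.linalg.lstsq(gram64, moment64, rcond=None)
    # the solve is dispatched as a single core-numeric operation
    return ctx.mul(coefs, 1.0, tag=CORE_NUMERIC)


def _edge_accumulation(ctx: MCAContext, coefs: np.ndarray) -> np.ndarray:
    """Outer-product accumulation of fitted loadings into edge weights."""
    loadings = coefs[1:, :]  # drop the intercept row
    return ctx.matmul(loadings.T, loadings, tag=DATA_LAYER)


def reconstruct_connectome(
    sample: Sample,
    pipeline: str,
    profile: PerturbationProfile,
    rng: np.random.Generator,
    key: SampleKey | None = None,
) -> Connectome:
    """Reconstruct one connectome from a sample's measurements.

    The ``det-like`` variant performs a single model fit; the
    ``prob-like`` variant averages the edge weights over internal
    bootstrap resamples of the measurement volumes drawn from a random
    state fixed by the sample identity, so repeated reference executions
    are bit-identical.  All floating-point steps are instrumented
    operations; with ``profile.density='off'`` the result is the exact
    IEEE reference.
    """
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}")
    dmat = np.asarray(sample.design_matrix, dtype=np.float64)
    signals = np.asarray(sample.signals, dtype=np.float64)
    if not (np.all(np.isfinite(dmat)) and np.all(np.isfinite(signals))):
        raise ValueError("sample measurements must be finite")
    n_nodes = signals.shape[1]
    key = key or SampleKey(*sample.sample_id, pipeline=pipeline)

    if not np.any(signals):
        warnings.warn(
            "all-zero measurements: returning an empty connectome", RuntimeWarning
        )
        return Connectome(np.zeros((n_nodes, n_nodes)), key)

    ctx = MCAContext(profile, rng)
    if pipeline == "det-like":
        weights = _edge_accumulation(ctx, _fit_factors(ctx, dmat, signals))
    else:  # prob-like: internal resampling with a fixed random state
        n_boot = 4
        internal = np.random.default_rng(
            np.random.SeedSequence(stable_seed("prob-like", *sample.sample_id))
        )
        weights = None
        for _ in range(n_boot):
            idx = internal.integers(0, dmat.shape[0], size=dmat.shape[0])
            w_b = _edge_accumulation(ctx, _fit_factors(ctx, dmat[idx], signals[idx]))
            weights = w_b if weights is None else ctx.add(weights, w_b, tag=DATA_LAYER)
        weights = ctx.div(weights, float(n_boot), tag=DATA_LAYER)

    # normalization (data-layer): unit Frobenius norm
    sq = ctx.mul(weights, weights, tag=DATA_LAYER)
    norm = ctx.sqrt(ctx.sum(sq, tag=DATA_LAYER), tag=DATA_LAYER)
    if norm == 0.0:
        warnings.warn("degenerate sample: zero-norm edge weights", RuntimeWarning)
        return Connectome(np.zeros((n_nodes, n_nodes)), key)
    weights = ctx.div(weights, norm, tag=DATA_LAYER)

    # graph construction: clip, zero diagonal, exact symmetrization
    weights = np.maximum(np.asarray(weights), 0.0)
    upper = np.triu(weights, k=1)
    weights = upper + upper.T
    return Connectome(weights, key)


def run_sample_simulations(
    cohort: Cohort,
    sample_id: tuple[int, int, int],
    pipeline: str,
    mode: str,
    n_sims: int,
    t: int = 53,
    mca_mode: str = "rr",
    base_seed: int = 0,
) -> dict[SampleKey, Connectome]:
    """Reference plus ``n_sims`` perturbed reconstructions of one sample.

    The reference execution uses an inactive profile (density ``off``);
    perturbed executions use the requested instrumentation density with
    independent, deterministic sub-seeds per simulation index.
    """
    sample = cohort.samples[sample_id]
    out: dict[SampleKey, Connectome] = {}

    ref_profile = PerturbationProfile(t=t, mode="off", density="off", seed=base_seed)
    ref_key = SampleKey(*sample_id, pipeline=pipeline, mode=mode, sim=REFERENCE_SIM)
    rng = simulation_rng(ref_profile, base_seed, REFERENCE_SIM)
    out[ref_key] = reconstruct_connectome(sample, pipeline, ref_profile, rng, key=ref_key)

    profile = PerturbationProfile(t=t, mode=mca_mode, density=mode, seed=base_seed)
    for sim in range(n_sims):
        key = SampleKey(*sample_id, pipeline=pipeline, mode=mode, sim=sim)
        # fold the sample identity into the stream so samples are independent
        stream_seed = stable_seed(*sample_id, pipeline, mode, base_seed)
        rng = simulation_rng(profile, stream_seed, sim)
        out[key] = reconstruct_connectome(sample, pipeline, profile, rng, key=key)
    return out
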