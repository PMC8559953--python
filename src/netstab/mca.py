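"""Simulated Monte Carlo Arithmetic (MCA).

Floating-point operations are routed through an operator-dispatch layer
that injects uniform random perturbations at a configurable *virtual
precision* ``t``.  Two perturbation modes are supported:

``rr`` (random rounding)
    the IEEE result of an operation is perturbed, exposing accumulated
    round-off error;
``pb`` (precision bounding)
    each operand is perturbed before the IEEE operation, limiting the
    effective precision of the inputs.

Each instrumented operation carries a *layer tag* so that perturbations can
be applied densely (all layers) or sparsely (only ``data-layer``
operations).  The sparse set of perturbed operations is a strict subset of
the dense set.  With ``density='off'`` every operation returns the exact
IEEE result, which serves as the unperturbed reference execution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PerturbationProfile",
    "InstrumentedOp",
    "MCAContext",
    "inexact",
    "perturbed_op",
    "run_simulations",
    "CORE_NUMERIC",
    "DATA_LAYER",
]

CORE_NUMERIC = "core-numeric"
DATA_LAYER = "data-layer"

_MODES = ("rr", "pb", "off")
_DENSITIES = ("dense", "sparse", "off")
_LAYER_TAGS = (CORE_NUMERIC, DATA_LAYER)


@dataclass(frozen=True)
class PerturbationProfile:
    """Configuration of one MCA instrumentation setting.

    Parameters
    ----------
    t : int
        Virtual precision in bits; perturbations target bit ``t`` of the
        significand.  Defaults to 53, the double-precision significand
        width, so that perturbations are at unit-in-the-last-place scale.
    mode : {'rr', 'pb', 'off'}
        Where the perturbation is injected (output, inputs, or nowhere).
    density : {'dense', 'sparse', 'off'}
        Which layer tags are instrumented.  ``dense`` perturbs every
        operation, ``sparse`` only ``data-layer`` operations, ``off``
        none (reference execution).
    seed : int
        Base seed folded into every random stream derived from this
        profile.
    """

    t: int = 53
    mode: str = "rr"
    density: str = "dense"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError(f"virtual precision t must be >= 1, got {self.t}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.density not in _DENSITIES:
            raise ValueError(
                f"density must be one of {_DENSITIES}, got {self.density!r}"
            )

    @property
    def active(self) -> bool:
        """Whether any operation is perturbed under this profile."""
        return self.mode != "off" and self.density != "off"

    def applies_to(self, layer_tag: str) -> bool:
        """Return True if operations tagged ``layer_tag`` are perturbed."""
        if layer_tag not in _LAYER_TAGS:
            raise ValueError(f"unknown layer tag {layer_tag!r}")
        if not self.active:
            return False
        if self.density == "dense":
            return True
        return layer_tag == DATA_LAYER  # sparse


@dataclass(frozen=True)
class InstrumentedOp:
    """An arithmetic operation together with its instrumentation layer."""

    op: str
    layer_tag: str = CORE_NUMERIC

    def __post_init__(self) -> None:
        if self.op not in _IEEE_OPS:
            raise ValueError(f"unknown op {self.op!r}")
        if self.layer_tag not in _LAYER_TAGS:
            raise ValueError(f"unknown layer tag {self.layer_tag!r}")


def inexact(x, t: int, rng: np.random.Generator):
    """Perturb ``x`` uniformly at virtual precision ``t``.

    Returns ``x + 2**(e_x - t) * xi`` with ``xi ~ Uniform(-1/2, 1/2)``
    drawn independently per element and per call, where ``e_x`` is the
    base-2 exponent of ``x`` under the convention
    ``2**(e_x - 1) <= |x| < 2**e_x``.  Exact zeros are preserved: zero has
    no exponent, and keeping it exact avoids creating spurious edges in
    sparse adjacency structures.

    The perturbed value is returned in extended precision
    (``numpy.longdouble``).  At ``t = 53`` the perturbation is below half
    a double-precision ulp, so rounding the sum to ``float64`` would
    silently erase it; carrying extended precision between instrumented
    operations lets sub-ulp noise accumulate and propagate exactly as a
    perturbation of the infinitely-precise result before final rounding.

    Parameters
    ----------
    x : float or ndarray
        Finite value(s) to perturb.
    t : int
        Virtual precision in bits (>= 1).
    rng : numpy.random.Generator
        Source of the uniform draws.

    Raises
    ------
    FloatingPointError
        If any element of ``x`` is not finite.
    ValueError
        If ``t < 1``.
    """
    if t < 1:
        raise ValueError(f"virtual precision t must be >= 1, got {t}")
    arr = np.asarray(x, dtype=np.longdouble)
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError("inexact() requires finite operands")
    # frexp: x = m * 2**e with 0.5 <= |m| < 1, hence e == e_x.
    _, e = np.frexp(arr)
    xi = rng.random(size=arr.shape) - 0.5  # [-0.5, 0.5)
    xi = np.where(xi == -0.5, 0.0, xi)  # keep |xi| strictly below 1/2
    out = arr + np.ldexp(np.asarray(xi, dtype=np.longdouble), e - t)
    out = np.where(arr == 0.0, np.longdouble(0.0), out)
    if np.isscalar(x) or np.ndim(x) == 0:
        return out[()] if isinstance(out, np.ndarray) else out
    return out


def _dot(a, b):
    return np.dot(np.asarray(a, dtype=np.longdouble), np.asarray(b, dtype=np.longdouble))


_IEEE_OPS: dict[str, Callable] = {
    "add": np.add,
    "sub": np.subtract,
    "mul": np.multiply,
    "div": np.divide,
    "dot": _dot,
    "sum": lambda a: np.sum(np.asarray(a, dtype=np.longdouble)),
    "sqrt": np.sqrt,
    "exp": np.exp,
    "log": np.log,
}

_UNARY = frozenset({"sum", "sqrt", "exp", "log"})


def perturbed_op(
    op: InstrumentedOp,
    operands: Sequence,
    profile: PerturbationProfile,
    rng: np.random.Generator,
):
    """Execute one instrumented operation under ``profile``.

    RR mode applies :func:`inexact` to the result; PB mode applies it to
    each operand before the operation.  Operations whose layer tag is
    excluded by the profile density (or with mode/density ``off``) return
    the exact result.  Arithmetic is carried in extended precision so
    that sub-ulp perturbations survive between instrumented operations
    (callers round to ``float64`` where a chain ends).

    Domain errors (division by zero, square root of a negative operand)
    raise :class:`FloatingPointError`.
    """
    fn = _IEEE_OPS[op.op]
    n_operands = 1 if op.op in _UNARY else 2
    if len(operands) != n_operands:
        raise ValueError(
            f"op {op.op!r} takes {n_operands} operand(s), got {len(operands)}"
        )
    operands = [np.asarray(v, dtype=np.longdouble) for v in operands]
    perturb = profile.applies_to(op.layer_tag)
    if perturb and profile.mode == "pb":
        operands = [inexact(v, profile.t, rng) for v in operands]
    with np.errstate(divide="raise", invalid="raise"):
        try:
            result = fn(*operands)
        except FloatingPointError as exc:
            raise FloatingPointError(f"invalid operand for {op.op!r}: {exc}") from exc
    if not np.all(np.isfinite(result)):
        raise FloatingPointError(f"non-finite result from {op.op!r}")
    if perturb and profile.mode == "rr":
        result = inexact(result, profile.t, rng)
    return result


class MCAContext:
    """Instrumented-arithmetic dispatcher bound to one random stream.

    Pipelines route their floating-point steps through the methods of this
    class; each call is one instrumented operation whose perturbation is
    controlled by the bound :class:`PerturbationProfile`.  Array arguments
    are perturbed elementwise (one independent draw per element per call).
    """

    def __init__(self, profile: PerturbationProfile, rng: np.random.Generator):
        self.profile = profile
        self.rng = rng

    def _op(self, name: str, operands: Sequence, tag: str):
        return perturbed_op(InstrumentedOp(name, tag), operands, self.profile, self.rng)

    def add(self, a, b, tag: str = CORE_NUMERIC):
        return self._op("add", (a, b), tag)

    def sub(self, a, b, tag: str = CORE_NUMERIC):
        return self._op("sub", (a, b), tag)

    def mul(self, a, b, tag: str = CORE_NUMERIC):
        return self._op("mul", (a, b), tag)

    def div(self, a, b, tag: str = CORE_NUMERIC):
        return self._op("div", (a, b), tag)

    def sqrt(self, a, tag: str = CORE_NUMERIC):
        return self._op("sqrt", (a,), tag)

    def exp(self, a, tag: str = CORE_NUMERIC):
        return self._op("exp", (a,), tag)

    def log(self, a, tag: str = CORE_NUMERIC):
        return self._op("log", (a,), tag)

    def sum(self, a, tag: str = CORE_NUMERIC):
        return self._op("sum", (a,), tag)

    def dot(self, a, b, tag: str = CORE_NUMERIC):
        return self._op("dot", (a, b), tag)

    def matmul(self, a, b, tag: str = CORE_NUMERIC) -> np.ndarray:
        """Matrix product built from instrumented multiplies and adds.

        The elementwise products are formed with one ``mul`` and the
        contraction is a sequential chain of ``add`` operations, so
        perturbation noise accumulates per partial sum as it would in a
        scalar instrumented loop.
        """
        a = np.asarray(a, dtype=np.longdouble)
        b = np.asarray(b, dtype=np.longdouble)
        if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[0]:
            raise ValueError(f"incompatible shapes {a.shape} x {b.shape}")
        # products[k] = outer contribution of contraction index k
        products = self.mul(a[:, :, None], b[None, :, :], tag=tag)
        acc = products[:, 0, :]
        for k in range(1, a.shape[1]):
            acc = self.add(acc, products[:, k, :], tag=tag)
        return acc


def run_simulations(
    computation: Callable[[MCAContext], object],
    profile: PerturbationProfile,
    n_sims: int,
    base_seed: int = 0,
) -> list:
    """Run ``computation`` under ``n_sims`` independent perturbation streams.

    Sub-seeds are derived deterministically from ``(profile.seed,
    base_seed, simulation index)``, so repeated invocation with identical
    arguments is bit-identical per simulation while distinct simulation
    indices draw statistically independent perturbations.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    outputs = []
    for index in range(n_sims):
        rng = simulation_rng(profile, base_seed, index)
        outputs.append(computation(MCAContext(profile, rng)))
    return outputs


def simulation_rng(
    profile: PerturbationProfile, base_seed: int, index: int
) -> np.random.Generator:
    """Deterministic, stream-independent RNG for one simulation index."""
    # offset keeps the entropy tuple nonnegative for the reference index -1
    ss = np.random.SeedSequence((int(profile.seed), int(base_seed), int(index) + 1))
    return np.random.default_rng(ss)
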