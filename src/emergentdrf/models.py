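"""Single-stressor quantal dose-response functions.

The central family is the shifted Frechet (inverse-Weibull) CDF

    F_F(d) = exp(-[(d - d0)/xi]^-eta),   d > d0;   F_F(d) = 0,  d <= d0,

read as the population CDF of the critical dose D = Z*/W: if the severity
per unit dose W is Weibull(shape k, scale lam), the critical dose D = 1/W
is Frechet with eta = k, xi = 1/lam.  ``eta`` is a dimensionless shape
parameter reflecting the number and autocorrelation of first-order cause
increments; ``xi`` is a scale in dose units; ``d0`` is a threshold dose
below which no individual responds.

Background (zero-dose) risk enters one of two ways:

* dissimilar-mode background (DMB) — response mixing,
  ``c + (1 - c) * F(d)``, i.e. a background pathway independent of the
  stressor's mode of action;
* common-mode background (CMB) — an additive background stress ``d_b``
  (already on the scaled-dose axis) inside the kernel,
  ``exp(-[d_b + (d - d0)/xi]^-eta)``.

The classical multistage model ``1 - exp(-q0 - q1 d - ... - qk d^k)`` and
the lognormal (probit-in-log-dose) model are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "FrechetParams",
    "BackgroundSpec",
    "MultistageParams",
    "LognormalParams",
    "frechet_response",
    "apply_background",
    "multistage_response",
    "lognormal_response",
    "FrechetModel",
    "MultistageModel",
    "LognormalModel",
]

BACKGROUND_MODES = ("none", "DMB", "CMB")


@dataclass(frozen=True)
class FrechetParams:
    """Shifted-Frechet parameters: scale ``xi`` > 0 (dose units),
    shape ``eta`` > 0, threshold ``d0`` >= 0 (dose units)."""

    xi: float
    eta: float
    d0: float = 0.0

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ValueError(f"xi must be positive, got {self.xi}")
        if not self.eta > 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.d0 < 0:
            raise ValueError(f"d0 must be non-negative, got {self.d0}")


@dataclass(frozen=True)
class BackgroundSpec:
    """Background-risk convention.

    ``mode`` is one of ``"none"``, ``"DMB"`` (response mixing with
    fraction ``c``) or ``"CMB"`` (additive scaled background stress
    ``d_b`` inside the kernel).  Only the field matching ``mode`` is
    meaningful.
    """

    mode: str = "none"
    c: float = 0.0
    d_b: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in BACKGROUND_MODES:
            raise ValueError(
                f"background mode must be one of {BACKGROUND_MODES}, got {self.mode!r}"
            )
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"c must lie in [0, 1), got {self.c}")
        if self.d_b < 0:
            raise ValueError(f"d_b must be non-negative, got {self.d_b}")


@dataclass(frozen=True)
class MultistageParams:
    """Multistage coefficients q0..qk, all non-negative; degree k >= 1."""

    q: tuple[float, ...]

    def __post_init__(self) -> None:
        q = tuple(float(v) for v in self.q)
        object.__setattr__(self, "q", q)
        if len(q) < 2:
            raise ValueError("multistage model needs q0 and at least q1 (degree >= 1)")
        if any(v < 0 for v in q):
            raise ValueError(f"all multistage coefficients must be non-negative, got {q}")

    @property
    def degree(self) -> int:
        return len(self.q) - 1


@dataclass(frozen=True)
class LognormalParams:
    """Lognormal DRF parameters: log-dose location ``mu``, spread ``sigma`` > 0."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def _frechet_kernel(arg: np.ndarray, eta: float) -> np.ndarray:
    """exp(-arg^-eta) with the arg <= 0 -> 0 convention, overflow-safe."""
    arg = np.asarray(arg, dtype=float)
    out = np.zeros(arg.shape)
    pos = arg > 0
    if np.any(pos):
        with np.errstate(over="ignore"):
            # exp(-exp(-eta ln a)): the inner exp may overflow to +inf for
            # tiny a, which collapses cleanly to exp(-inf) = 0.
            out[pos] = np.exp(-np.exp(-eta * np.log(arg[pos])))
    return out


def _as_1d(d) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    return arr, np.ndim(d) == 0


def _maybe_scalar(out: np.ndarray, scalar: bool):
    return float(out[0]) if scalar else out


def frechet_response(d, params: FrechetParams):
    """Shifted-Frechet response probability F_F(d) = exp(-[(d-d0)/xi]^-eta).

    Doses at or below the threshold ``d0`` respond with probability 0
    (the limit of the closed form as the scaled dose tends to 0+).
    Accepts scalars or arrays of doses.
    """
    d_arr, scalar = _as_1d(d)
    if np.any(d_arr < 0):
        raise ValueError("doses must be non-negative")
    dp = (d_arr - params.d0) / params.xi
    return _maybe_scalar(_frechet_kernel(dp, params.eta), scalar)


def apply_background(
    f_base: Callable[[np.ndarray], np.ndarray] | None,
    bg: BackgroundSpec,
    params: FrechetParams | None,
    d,
):
    """Apply a background-risk convention to a base DRF at doses ``d``.

    DMB wraps the base CDF as ``c + (1-c) * F_base(d)``; CMB *replaces*
    the Frechet kernel with ``exp(-[d_b + max((d-d0)/xi, 0)]^-eta)`` and
    therefore requires ``params``; mode ``"none"`` returns ``F_base(d)``.
    """
    d_arr, scalar = _as_1d(d)
    if bg.mode == "none":
        if f_base is None:
            raise ValueError("mode 'none' requires a base response function")
        return _maybe_scalar(np.asarray(f_base(d_arr), dtype=float), scalar)
    if bg.mode == "DMB":
        if f_base is None:
            raise ValueError("DMB background requires a base response function")
        base = np.asarray(f_base(d_arr), dtype=float)
        return _maybe_scalar(bg.c + (1.0 - bg.c) * base, scalar)
    # CMB: additive background stress on the scaled-dose axis
    if params is None:
        raise ValueError("CMB background requires Frechet kernel parameters")
    dp = np.maximum((d_arr - params.d0) / params.xi, 0.0)
    return _maybe_scalar(_frechet_kernel(bg.d_b + dp, params.eta), scalar)


def multistage_response(d, params: MultistageParams):
    """Multistage response 1 - exp(-q0 - q1 d - ... - qk d^k)."""
    d_arr, scalar = _as_1d(d)
    if np.any(d_arr < 0):
        raise ValueError("doses must be non-negative")
    q = np.asarray(params.q, dtype=float)
    powers = d_arr[:, None] ** np.arange(len(q))[None, :]
    s = powers @ q
    return _maybe_scalar(-np.expm1(-s), scalar)


def lognormal_response(d, params: LognormalParams, bg: BackgroundSpec | None = None):
    """Lognormal DRF: Phi((ln d - mu)/sigma), 0 at d = 0.

    Both background variants tabulated for this family use response
    mixing with a fraction ``c`` (``c + (1-c) * Phi``); a CMB request is
    honoured with the same map, the parameter being labelled ``c``.
    """
    d_arr, scalar = _as_1d(d)
    if np.any(d_arr < 0):
        raise ValueError("doses must be non-negative")
    out = np.zeros(d_arr.shape)
    pos = d_arr > 0
    out[pos] = stats.norm.cdf((np.log(d_arr[pos]) - params.mu) / params.sigma)
    if bg is not None and bg.mode in ("DMB", "CMB"):
        out = bg.c + (1.0 - bg.c) * out
    return _maybe_scalar(out, scalar)


class FrechetModel:
    """Shifted-Frechet DRF with an optional background-risk convention."""

    n_stressors = 1

    def __init__(self, params: FrechetParams, background: BackgroundSpec | None = None):
        self.params = params
        self.background = background or BackgroundSpec()

    def response(self, d):
        if self.background.mode == "none":
            return frechet_response(d, self.params)
        base = lambda x: frechet_response(x, self.params)
        return apply_background(base, self.background, self.params, d)

    def __repr__(self) -> str:
        return f"FrechetModel({self.params}, background={self.background})"


class MultistageModel:
    """Multistage DRF; background risk is intrinsic via q0."""

    n_stressors = 1

    def __init__(self, params: MultistageParams):
        self.params = params

    def response(self, d):
        return multistage_response(d, self.params)

    def __repr__(self) -> str:
        return f"MultistageModel({self.params})"


class LognormalModel:
    """Lognormal DRF with optional background mixing fraction c."""

    n_stressors = 1

    def __init__(self, params: LognormalParams, background: BackgroundSpec | None = None):
        self.params = params
        self.background = background or BackgroundSpec()

    def response(self, d):
        return lognormal_response(d, self.params, self.background)

    def __repr__(self) -> str:
        return f"LognormalModel({self.params}, background={self.background})"
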