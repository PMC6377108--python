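"""Multi-stressor dose-response models.

Two mixture conventions are implemented:

* **Common mode** (generalized dose addition): all stressors share one
  mode of action and hence one Frechet shape ``eta``.  Toxicity-scaled
  doses, pairwise interaction "doses" and a background stress add inside
  a single kernel,

      F_CM(d) = exp(-[max(sum_j d_j/xi_j
                          + sum_{j<k} xi_{j,k} g(d_j, d_k)
                          - d0 + d_b, 0)]^-eta),

  where g is the pairwise interaction kernel — by default the geometric
  mean sqrt(d_j d_k), which keeps interaction terms of the same order as
  the individual scaled doses and vanishes whenever either dose is zero
  (the raw product d_j d_k is available via ``kernel="product"``).
  A negative xi_{j,k} expresses antagonism and can carve a J-shaped
  one-dimensional slice out of an otherwise monotonic response surface.

* **Dissimilar mode** (generalized response addition): stressors act on
  parallel, largely independent pathways, each with its own shape
  ``eta_i``, scale ``xi_i`` and threshold ``d0_i``.  Interactions adjust
  the per-pathway effective doses; the mixture response is the
  probability of the union of the independent per-pathway events,
  computed by inclusion-exclusion (which collapses to
  1 - prod_i (1 - F_F(d'_i))).

A common-mode sub-mixture can be collapsed to one scalar dose and nested
as a single coordinate of an outer dissimilar-mode model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import _frechet_kernel

__all__ = [
    "CommonModeParams",
    "DissimilarModeParams",
    "common_mode_effective_dose",
    "common_mode_response",
    "dissimilar_effective_doses",
    "independent_union_response",
    "nested_common_mode_dose",
    "CommonModeModel",
    "DissimilarModeModel",
]

INTERACTION_KERNELS = ("geometric", "product")


def _normalize_pairs(
    pairs: Mapping[tuple[int, int], float] | None, n: int, what: str
) -> dict[tuple[int, int], float]:
    """Canonicalize a symmetric pair map to keys (j, k) with j < k."""
    out: dict[tuple[int, int], float] = {}
    for (j, k), v in (pairs or {}).items():
        if j == k:
            raise ValueError(f"{what} requires two distinct stressor indices, got ({j}, {k})")
        if not (0 <= j < n and 0 <= k < n):
            raise ValueError(f"{what} indices ({j}, {k}) out of range for {n} stressors")
        key = (min(j, k), max(j, k))
        if key in out and out[key] != v:
            raise ValueError(f"{what} map is not symmetric at pair {key}")
        out[key] = float(v)
    return out


def _pair_kernel(dj: np.ndarray, dk: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "geometric":
        return np.sqrt(dj * dk)
    return dj * dk


@dataclass(frozen=True)
class CommonModeParams:
    """Common-mode mixture parameters.

    ``xi``: per-stressor scales (dose units); ``interactions``: symmetric
    map (j, k) -> xi_{j,k} (sign free, zero = none); ``eta``: shared
    shape; ``d0``: overall scaled threshold (dimensionless, on the
    summed-scaled-dose axis); ``d_b``: scaled background stress.
    """

    xi: tuple[float, ...]
    eta: float
    d0: float = 0.0
    d_b: float = 0.0
    interactions: Mapping[tuple[int, int], float] = field(default_factory=dict)
    kernel: str = "geometric"

    def __post_init__(self) -> None:
        xi = tuple(float(v) for v in self.xi)
        object.__setattr__(self, "xi", xi)
        if len(xi) < 1 or any(v <= 0 for v in xi):
            raise ValueError(f"all scale parameters must be positive, got {xi}")
        if not self.eta > 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.d0 < 0 or self.d_b < 0:
            raise ValueError("d0 and d_b must be non-negative")
        if self.kernel not in INTERACTION_KERNELS:
            raise ValueError(f"kernel must be one of {INTERACTION_KERNELS}")
        object.__setattr__(
            self,
            "interactions",
            _normalize_pairs(self.interactions, len(xi), "interaction coefficient"),
        )

    @property
    def n_stressors(self) -> int:
        return len(self.xi)


@dataclass(frozen=True)
class StressorParams:
    """Per-pathway Frechet parameters of one dissimilar-mode stressor."""

    xi: float
    eta: float
    d0: float = 0.0

    def __post_init__(self) -> None:
        if not self.xi > 0 or not self.eta > 0:
            raise ValueError("xi and eta must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


@dataclass(frozen=True)
class DissimilarModeParams:
    """Dissimilar-mode mixture parameters.

    ``per_stressor``: one (xi_i, eta_i, d0_i) record per pathway;
    ``interactions``: symmetric (i, k) -> xi_{i,k} coefficients;
    ``interaction_thresholds``: symmetric (i, k) -> d0_{i,k} thresholds
    applied to the pair kernel value before the coefficient.
    """

    per_stressor: tuple[StressorParams, ...]
    interactions: Mapping[tuple[int, int], float] = field(default_factory=dict)
    interaction_thresholds: Mapping[tuple[int, int], float] = field(default_factory=dict)
    kernel: str = "geometric"

    def __post_init__(self) -> None:
        ps = tuple(
            s if isinstance(s, StressorParams) else StressorParams(**s)
            for s in self.per_stressor
        )
        object.__setattr__(self, "per_stressor", ps)
        if len(ps) < 1:
            raise ValueError("at least one stressor is required")
        if self.kernel not in INTERACTION_KERNELS:
            raise ValueError(f"kernel must be one of {INTERACTION_KERNELS}")
        n = len(ps)
        object.__setattr__(
            self, "interactions", _normalize_pairs(self.interactions, n, "interaction coefficient")
        )
        thr = _normalize_pairs(self.interaction_thresholds, n, "interaction threshold")
        if any(v < 0 for v in thr.values()):
            raise ValueError("interaction thresholds must be non-negative")
        object.__setattr__(self, "interaction_thresholds", thr)

    @property
    def n_stressors(self) -> int:
        return len(self.per_stressor)


def _as_2d(d, n_stressors: int) -> tuple[np.ndarray, bool]:
    arr = np.asarray(d, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != n_stressors:
        raise ValueError(
            f"dose vector has {arr.shape[1]} components, model expects {n_stressors}"
        )
    if np.any(arr < 0):
        raise ValueError("doses must be non-negative")
    return arr, single


def common_mode_effective_dose(d, p: CommonModeParams):
    """Scaled effective dose of a common-mode mixture.

    max(sum_j d_j/xi_j + sum_{j<k} xi_{j,k} g(d_j,d_k) - d0 + d_b, 0);
    an interaction term is exactly zero whenever either paired dose is 0.
    """
    D, single = _as_2d(d, p.n_stressors)
    total = (D / np.asarray(p.xi)).sum(axis=1)
    for (j, k), coef in p.interactions.items():
        total = total + coef * _pair_kernel(D[:, j], D[:, k], p.kernel)
    eff = np.maximum(total - p.d0 + p.d_b, 0.0)
    return float(eff[0]) if single else eff


def common_mode_response(d, p: CommonModeParams):
    """Common-mode mixture response exp(-[effective dose]^-eta)."""
    eff = np.atleast_1d(common_mode_effective_dose(d, p))
    out = _frechet_kernel(eff, p.eta)
    return float(out[0]) if np.asarray(d).ndim == 1 else out


def dissimilar_effective_doses(d, p: DissimilarModeParams):
    """Interaction-adjusted scaled effective dose of each pathway.

    d'_i = max[max(d_i - d0_i, 0)/xi_i
               + sum_{k != i} xi_{i,k} max(h(d_i, d_k) - d0_{i,k}, 0), 0]
    """
    D, single = _as_2d(d, p.n_stressors)
    I = p.n_stressors
    out = np.zeros_like(D)
    for i, sp in enumerate(p.per_stressor):
        eff = np.maximum(D[:, i] - sp.d0, 0.0) / sp.xi
        for (j, k), coef in p.interactions.items():
            if i not in (j, k) or coef == 0.0:
                continue
            other = k if i == j else j
            thr = p.interaction_thresholds.get((j, k), 0.0)
            kern = _pair_kernel(D[:, i], D[:, other], p.kernel)
            eff = eff + coef * np.maximum(kern - thr, 0.0)
        out[:, i] = np.maximum(eff, 0.0)
    return out[0] if single else out


def independent_union_response(d_prime, etas):
    """Response of independent pathways: 1 - prod_i (1 - F_F(d'_i)).

    Each effective dose is already fully scaled, so the per-pathway
    Frechet kernel takes unit scale and zero threshold.  The form equals
    the inclusion-exclusion expansion over all non-empty pathway subsets
    under independence.
    """
    dp = np.asarray(d_prime, dtype=float)
    etas = np.asarray(etas, dtype=float)
    single = dp.ndim == 1
    dp = np.atleast_2d(dp)
    if dp.shape[1] != etas.shape[0]:
        raise ValueError("d_prime and etas must have matching lengths")
    if np.any(etas <= 0):
        raise ValueError("all shape parameters must be positive")
    # complement computed in log space: 1 - prod(1 - F_i) loses the tiny
    # union probabilities to cancellation otherwise
    log_surv = np.zeros(dp.shape[0])
    for i in range(dp.shape[1]):
        log_surv = log_surv + np.log1p(-_frechet_kernel(dp[:, i], etas[i]))
    out = -np.expm1(log_surv)
    return float(out[0]) if single else out


def nested_common_mode_dose(sub_doses, sub_params: CommonModeParams):
    """Collapse an internally common-mode sub-mixture to one scalar dose.

    The result can serve as a single coordinate d_i of an outer
    dissimilar-mode model; it is the common-mode effective dose of the
    sub-mixture (with the sub-model's own threshold d0_i).
    """
    return common_mode_effective_dose(sub_doses, sub_params)


class CommonModeModel:
    """Common-mode (dose addition) mixture DRF."""

    def __init__(self, params: CommonModeParams):
        self.params = params

    @property
    def n_stressors(self) -> int:
        return self.params.n_stressors

    def effective_dose(self, d):
        return common_mode_effective_dose(d, self.params)

    def response(self, d):
        return common_mode_response(d, self.params)

    def __repr__(self) -> str:
        return f"CommonModeModel({self.params})"


class DissimilarModeModel:
    """Dissimilar-mode (response addition) mixture DRF."""

    def __init__(self, params: DissimilarModeParams):
        self.params = params

    @property
    def n_stressors(self) -> int:
        return self.params.n_stressors

    def effective_doses(self, d):
        return dissimilar_effective_doses(d, self.params)

    def response(self, d):
        dp = np.atleast_2d(dissimilar_effective_doses(d, self.params))
        etas = [s.eta for s in self.params.per_stressor]
        out = independent_union_response(dp, etas)
        return float(np.atleast_1d(out)[0]) if np.asarray(d).ndim == 1 else out

    def __repr__(self) -> str:
        return f"DissimilarModeModel({self.params})"
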