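"""Deviance-based maximum-likelihood fitting and goodness of fit.

Quantal data (n responders of N at each dose group) are fitted by
minimizing the deviance

    Y* = 2 sum_i [ n_i ln(n_i / (N_i p_i)) + (N_i - n_i) ln((N_i - n_i)/(N_i (1 - p_i))) ],

twice the log-likelihood ratio of the saturated binomial model to the
fitted model, so deviance minimization is binomial maximum likelihood.
Counts are first moved to the plotting position

    n -> min(max(0.25, n), N - 0.25),

which keeps groups with 0 or N responders usable in the (logarithmic)
GOF computation while leaving interior counts untouched.  Goodness of
fit is the upper-tail chi-square probability P(chi2_{I-m-1} >= Y*),
where I is the number of dose groups and m the number of *free*
parameters; the extra unit of lost freedom accounts for choosing a
parametric form.  Larger p indicates better fit; p >= 0.05 is the
conventional acceptance level.

The fitting surface follows the statsmodels Model/Results idiom:
``QuantalDoseResponse(data, spec).fit(seed=...)`` returns a
``DRFResults`` carrying estimates, deviance, degrees of freedom, the
GOF p-value and optimizer diagnostics, with a ``summary()`` table.
Optimization is multi-start (scrambled Sobol points over the bounds)
bounded quasi-Newton with a Nelder-Mead fallback, strictly positive
parameters being optimized in log space; the minima of the deviance can
be sharp, so single-start local optimization is not reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import xlogy
from scipy.stats import qmc

from .models import (
    BackgroundSpec,
    FrechetModel,
    FrechetParams,
    LognormalModel,
    LognormalParams,
    MultistageModel,
    MultistageParams,
)
from .mixtures import (
    CommonModeModel,
    CommonModeParams,
    DissimilarModeModel,
    DissimilarModeParams,
    StressorParams,
)

__all__ = [
    "QuantalData",
    "adjust_counts",
    "deviance",
    "gof_pvalue",
    "ModelSpec",
    "QuantalDoseResponse",
    "DRFResults",
    "compare_models",
    "results_table",
]

PROB_EPS = 1e-12
FAMILIES = ("frechet", "lognormal", "multistage", "common_mode", "dissimilar_mode")


# ---------------------------------------------------------------------------
# data container


@dataclass(frozen=True)
class QuantalData:
    """Quantal dose-response table: I dose groups of J stressors.

    ``doses`` has shape (I, J); ``n`` are responder counts, ``N`` group
    sizes.  ``stressor_names`` labels the dose columns.
    """

    doses: np.ndarray
    n: np.ndarray
    N: np.ndarray
    stressor_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        doses = np.atleast_2d(np.asarray(self.doses, dtype=float))
        if doses.ndim != 2:
            raise ValueError("doses must be a 1-D or 2-D array")
        n = np.asarray(self.n, dtype=float)
        N = np.asarray(self.N, dtype=float)
        if not (len(n) == len(N) == doses.shape[0]):
            raise ValueError("doses, n and N must have one entry per dose group")
        if doses.shape[0] < 1:
            raise ValueError("at least one dose group is required")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(N < 1):
            raise ValueError("group sizes N must be positive")
        if np.any(n < 0) or np.any(n > N):
            raise ValueError("responder counts must satisfy 0 <= n <= N")
        names = self.stressor_names
        if names is not None:
            names = tuple(names)
            if len(names) != doses.shape[1]:
                raise ValueError("one stressor name per dose column is required")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "stressor_names", names)

    @property
    def n_groups(self) -> int:
        return self.doses.shape[0]

    @property
    def n_stressors(self) -> int:
        return self.doses.shape[1]

    def adjusted_n(self, adjust: bool = True) -> np.ndarray:
        """Responder counts at the plotting position (or raw counts)."""
        if not adjust:
            return self.n.copy()
        return np.minimum(np.maximum(0.25, self.n), self.N - 0.25)

    def to_frame(self) -> pd.DataFrame:
        names = self.stressor_names or tuple(
            f"dose_{j + 1}" for j in range(self.n_stressors)
        )
        df = pd.DataFrame(self.doses, columns=list(names))
        df["n"] = self.n
        df["N"] = self.N
        return df


def adjust_counts(n: float, N: float) -> float:
    """Plotting-position count adjustment min(max(0.25, n), N - 0.25).

    Identity for interior counts 1 <= n <= N - 1; moves 0 up to 0.25 and
    N down to N - 0.25 so that log terms of the deviance stay finite.
    """
    if N < 1:
        raise ValueError("group size N must be at least 1")
    if not 0 <= n <= N:
        raise ValueError("count n must satisfy 0 <= n <= N")
    return float(min(max(0.25, n), N - 0.25))


def _model_response(model, doses: np.ndarray) -> np.ndarray:
    """Evaluate any response model on an (I, J) dose array."""
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    n_stressors = getattr(model, "n_stressors", 1)
    if n_stressors == 1 and doses.shape[1] == 1:
        return np.asarray(model.response(doses[:, 0]), dtype=float)
    return np.asarray(model.response(doses), dtype=float)


def deviance(data: QuantalData, model, adjust: bool = True, eps: float = PROB_EPS) -> float:
    """Deviance Y* of ``model`` against ``data`` (adjusted counts).

    Model probabilities are clipped to [eps, 1 - eps] inside the
    likelihood only; Y* >= 0 with equality iff the model reproduces
    n_i / N_i at every group.
    """
    p = np.clip(_model_response(model, data.doses), eps, 1.0 - eps)
    n_adj = data.adjusted_n(adjust)
    N = data.N
    t1 = xlogy(n_adj, n_adj / (N * p))
    t2 = xlogy(N - n_adj, (N - n_adj) / (N * (1.0 - p)))
    return float(2.0 * (t1 + t2).sum())


def gof_pvalue(Y_star: float, I: int, m: int, strict: bool = True) -> float:
    """Upper-tail chi-square GOF p-value of the deviance.

    With ``strict=True`` (the reporting convention used throughout) the
    reference is chi2 with I - m - 1 degrees of freedom, one unit below
    the likelihood-ratio asymptotics to charge for the choice of
    parametric form; this makes the test deliberately conservative (the
    p-value is stochastically smaller than uniform under the true
    model).  ``strict=False`` uses the asymptotically calibrated
    likelihood-ratio reference chi2_{I-m}.
    """
    df = (I - m - 1) if strict else (I - m)
    if df < 1:
        raise ValueError(f"degrees of freedom {df} < 1; p-value undefined")
    if Y_star < 0:
        raise ValueError("deviance must be non-negative")
    return float(stats.chi2.sf(Y_star, df))


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class _ParamMeta:
    default: float
    bounds: tuple[float, float]
    log: bool = False


def _pair_name(prefix: str, j: int, k: int) -> str:
    j, k = sorted((j, k))
    return f"{prefix}_{j + 1}_{k + 1}"


class ModelSpec:
    """Declarative model family + free/fixed parameter designation.

    Parameters
    ----------
    family : one of frechet, lognormal, multistage, common_mode,
        dissimilar_mode.
    background : "none", "DMB" or "CMB" (single-stressor families only).
    params : mapping of parameter name to fixed/starting value; unnamed
        parameters take family defaults.
    free : iterable of free parameter names, or mapping name -> (lo, hi)
        bounds (None bounds = family defaults).  Only free parameters
        count towards m in the GOF degrees of freedom.
    degree : multistage polynomial degree k (default 2).
    n_stressors : number of dose columns (mixture families).
    pairs : declared interacting pairs, as 0-based index tuples.
    kernel : pairwise interaction kernel, "geometric" or "product".
    label : optional display label.

    Parameter naming: single-stressor families use ``xi, eta, d0, c,
    d_b, mu, sigma, q0..qk``; common mode uses ``xi_1..xi_J, eta, d0,
    d_b`` and ``xi_j_k`` for pair (j, k) (1-based); dissimilar mode uses
    ``xi_i, eta_i, d0_i`` per stressor plus ``xi_i_k`` and ``d0_i_k``.
    """

    def __init__(
        self,
        family: str,
        background: str = "none",
        params: Mapping[str, float] | None = None,
        free: Iterable[str] | Mapping[str, tuple[float, float] | None] | None = None,
        degree: int = 2,
        n_stressors: int = 1,
        pairs: Sequence[tuple[int, int]] = (),
        kernel: str = "geometric",
        label: str | None = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
        if background not in ("none", "DMB", "CMB"):
            raise ValueError(f"unknown background mode {background!r}")
        if family in ("common_mode", "dissimilar_mode") and background != "none":
            raise ValueError(
                "mixture families carry background via d_b; use background='none'"
            )
        if degree < 1:
            raise ValueError("multistage degree must be >= 1")
        self.family = family
        self.background = background
        self.degree = int(degree)
        self.n_stressors = int(n_stressors) if family in ("common_mode", "dissimilar_mode") else 1
        self.pairs = tuple(tuple(sorted(p)) for p in pairs)
        self.kernel = kernel
        self.params = dict(params or {})
        names = self.param_names()
        for name in self.params:
            if name not in names:
                raise ValueError(f"unknown parameter {name!r} for family {family!r}")
        if free is None:
            free_map: dict[str, tuple[float, float] | None] = {
                name: None for name in self._default_free()
            }
        elif isinstance(free, Mapping):
            free_map = {k: (tuple(v) if v is not None else None) for k, v in free.items()}
        else:
            free_map = {name: None for name in free}
        for name in free_map:
            if name not in names:
                raise ValueError(f"unknown free parameter {name!r} for family {family!r}")
        if not free_map:
            # a pure-evaluation spec (e.g. GOF of printed parameters)
            pass
        self.free = free_map
        self.label = label or self._default_label()

    # -- naming ------------------------------------------------------------

    def _default_label(self) -> str:
        base = {
            "frechet": "First-order",
            "lognormal": "Lognormal",
            "multistage": "Multistage",
            "common_mode": "First-order CM",
            "dissimilar_mode": "First-order DM",
        }[self.family]
        if self.background != "none":
            base = f"{base} {self.background}"
        return base

    def param_names(self) -> list[str]:
        if self.family == "frechet":
            names = ["xi", "eta", "d0"]
            if self.background == "DMB":
                names.append("c")
            elif self.background == "CMB":
                names.append("d_b")
            return names
        if self.family == "lognormal":
            names = ["mu", "sigma"]
            if self.background != "none":
                names.append("c")
            return names
        if self.family == "multistage":
            return [f"q{i}" for i in range(self.degree + 1)]
        if self.family == "common_mode":
            names = [f"xi_{j + 1}" for j in range(self.n_stressors)]
            names += ["eta", "d0", "d_b"]
            names += [_pair_name("xi", j, k) for j, k in self.pairs]
            return names
        names = []
        for i in range(self.n_stressors):
            names += [f"xi_{i + 1}", f"eta_{i + 1}", f"d0_{i + 1}"]
        for j, k in self.pairs:
            names += [_pair_name("xi", j, k), _pair_name("d0", j, k)]
        return names

    def _default_free(self) -> list[str]:
        if self.family == "frechet":
            free = ["xi", "eta"]
            if self.background == "DMB":
                free.append("c")
            elif self.background == "CMB":
                free.append("d_b")
            return free
        if self.family == "lognormal":
            free = ["mu", "sigma"]
            if self.background != "none":
                free.append("c")
            return free
        if self.family == "multistage":
            return [f"q{i}" for i in range(self.degree + 1)]
        if self.family == "common_mode":
            return [f"xi_{j + 1}" for j in range(self.n_stressors)] + ["eta"]
        return [
            name
            for i in range(self.n_stressors)
            for name in (f"xi_{i + 1}", f"eta_{i + 1}")
        ]

    # -- metadata ----------------------------------------------------------

    def param_meta(self, max_dose: float = 1.0) -> dict[str, _ParamMeta]:
        """Defaults, bounds and scaling per parameter.

        Strictly positive parameters (scales, shapes, sigma) are flagged
        for log-space optimization.  Threshold upper bounds adapt to the
        largest observed dose.
        """
        max_dose = max(float(max_dose), 1e-6)
        meta: dict[str, _ParamMeta] = {}
        for name in self.param_names():
            if name.startswith("xi_") and name.count("_") == 2:
                meta[name] = _ParamMeta(0.0, (-100.0, 100.0))  # interaction coefficient
            elif name.startswith("d0_") and name.count("_") == 2:
                meta[name] = _ParamMeta(0.0, (0.0, 1e6))  # interaction threshold
            elif name == "xi" or name.startswith("xi_"):
                meta[name] = _ParamMeta(1.0, (1e-6, 1e8), log=True)
            elif name == "eta" or name.startswith("eta_"):
                meta[name] = _ParamMeta(1.0, (0.05, 50.0), log=True)
            elif name == "c":
                meta[name] = _ParamMeta(0.0, (0.0, 0.999))
            elif name == "d_b":
                meta[name] = _ParamMeta(0.0, (0.0, 1e4))
            elif name == "d0":
                hi = 1e4 if self.family == "common_mode" else max_dose
                meta[name] = _ParamMeta(0.0, (0.0, hi))
            elif name.startswith("d0_"):
                meta[name] = _ParamMeta(0.0, (0.0, max_dose))
            elif name == "mu":
                lo = math.log(max_dose) - 30.0
                hi = math.log(max_dose) + 10.0
                meta[name] = _ParamMeta(0.0, (lo, hi))
            elif name == "sigma":
                meta[name] = _ParamMeta(1.0, (1e-3, 100.0), log=True)
            elif name.startswith("q"):
                i = int(name[1:])
                hi = 20.0 if i == 0 else 100.0 / max_dose**i
                meta[name] = _ParamMeta(0.0, (0.0, hi))
            else:  # pragma: no cover - names are exhaustive
                raise AssertionError(name)
        return meta

    def values_with_defaults(self, max_dose: float = 1.0) -> dict[str, float]:
        meta = self.param_meta(max_dose)
        return {name: float(self.params.get(name, meta[name].default)) for name in meta}

    # -- model construction ------------------------------------------------

    def build(self, values: Mapping[str, float]):
        """Construct the response-model object from a full value map."""
        v = dict(values)
        if self.family == "frechet":
            params = FrechetParams(v["xi"], v["eta"], v.get("d0", 0.0))
            bg = BackgroundSpec(
                self.background, c=v.get("c", 0.0), d_b=v.get("d_b", 0.0)
            )
            return FrechetModel(params, bg)
        if self.family == "lognormal":
            params = LognormalParams(v["mu"], v["sigma"])
            bg = BackgroundSpec(self.background if self.background == "none" else self.background,
                                c=v.get("c", 0.0))
            return LognormalModel(params, bg)
        if self.family == "multistage":
            q = tuple(v[f"q{i}"] for i in range(self.degree + 1))
            return MultistageModel(MultistageParams(q))
        if self.family == "common_mode":
            xi = tuple(v[f"xi_{j + 1}"] for j in range(self.n_stressors))
            inter = {(j, k): v[_pair_name("xi", j, k)] for j, k in self.pairs}
            params = CommonModeParams(
                xi=xi,
                eta=v["eta"],
                d0=v.get("d0", 0.0),
                d_b=v.get("d_b", 0.0),
                interactions=inter,
                kernel=self.kernel,
            )
            return CommonModeModel(params)
        per = tuple(
            StressorParams(v[f"xi_{i + 1}"], v[f"eta_{i + 1}"], v.get(f"d0_{i + 1}", 0.0))
            for i in range(self.n_stressors)
        )
        inter = {(j, k): v[_pair_name("xi", j, k)] for j, k in self.pairs}
        thr = {(j, k): v[_pair_name("d0", j, k)] for j, k in self.pairs}
        params = DissimilarModeParams(
            per_stressor=per,
            interactions=inter,
            interaction_thresholds=thr,
            kernel=self.kernel,
        )
        return DissimilarModeModel(params)


# ---------------------------------------------------------------------------
# Model / Results


class QuantalDoseResponse:
    """Quantal dose-response model in the statsmodels Model idiom.

    Parameters
    ----------
    data : QuantalData
        Dose groups with responder counts.
    spec : ModelSpec
        Family and free/fixed parameter designation.
    adjust_counts : bool
        Apply the plotting-position adjustment (default True; disable to
        mimic analyses performed on raw counts).
    """

    def __init__(self, data: QuantalData, spec: ModelSpec, adjust_counts: bool = True):
        if spec.family in ("common_mode", "dissimilar_mode"):
            if spec.n_stressors != data.n_stressors:
                raise ValueError(
                    f"spec expects {spec.n_stressors} stressors, data has {data.n_stressors}"
                )
        elif data.n_stressors != 1:
            raise ValueError("single-stressor families require 1-column dose data")
        self.data = data
        self.spec = spec
        self.adjust = bool(adjust_counts)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec,
        n_col: str = "n",
        N_col: str = "N",
        dose_cols: Sequence[str] | None = None,
        adjust_counts: bool = True,
    ) -> "QuantalDoseResponse":
        if dose_cols is None:
            dose_cols = [c for c in df.columns if c not in (n_col, N_col)]
        data = QuantalData(
            doses=df[list(dose_cols)].to_numpy(dtype=float),
            n=df[n_col].to_numpy(dtype=float),
            N=df[N_col].to_numpy(dtype=float),
            stressor_names=tuple(dose_cols),
        )
        return cls(data, spec, adjust_counts=adjust_counts)

    # -- evaluation ---------------------------------------------------------

    def deviance(self, values: Mapping[str, float] | None = None) -> float:
        full = self.spec.values_with_defaults(self._max_dose())
        full.update(values or {})
        return deviance(self.data, self.spec.build(full), adjust=self.adjust)

    def _max_dose(self) -> float:
        return float(self.data.doses.max()) if self.data.doses.size else 1.0

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 32,
        start: Mapping[str, float] | None = None,
    ) -> "DRFResults":
        """Minimize the deviance over the free parameters.

        Multi-start local optimization: ``n_restarts`` scrambled-Sobol
        points over the (transformed) bounds, each polished with
        bounded L-BFGS-B and, where that stalls, Nelder-Mead.
        Deterministic for a given seed.
        """
        spec = self.spec
        free_names = list(spec.free)
        if not free_names:
            return self._fixed_result(seed)
        meta = spec.param_meta(self._max_dose())
        fixed = spec.values_with_defaults(self._max_dose())

        bounds_t = []
        logs = []
        for name in free_names:
            m = meta[name]
            lo, hi = spec.free[name] or m.bounds
            if m.log:
                lo = max(lo, 1e-12)
                bounds_t.append((math.log(lo), math.log(hi)))
            else:
                bounds_t.append((lo, hi))
            logs.append(m.log)
        bounds_t = np.asarray(bounds_t, dtype=float)

        def unpack(z: np.ndarray) -> dict[str, float]:
            vals = dict(fixed)
            for name, zi, lg in zip(free_names, z, logs):
                vals[name] = float(np.exp(zi)) if lg else float(zi)
            return vals

        def objective(z: np.ndarray) -> float:
            z = np.clip(z, bounds_t[:, 0], bounds_t[:, 1])
            try:
                model = spec.build(unpack(z))
                y = deviance(self.data, model, adjust=self.adjust)
            except (ValueError, FloatingPointError):
                return 1e12
            if not np.isfinite(y):
                return 1e12
            return y

        dim = len(free_names)
        sampler = qmc.Sobol(d=dim, scramble=True, seed=int(seed))
        n_pts = max(int(n_restarts), 1)
        unit = sampler.random(n_pts)
        starts = bounds_t[:, 0] + unit * (bounds_t[:, 1] - bounds_t[:, 0])
        start_list = [starts[i] for i in range(n_pts)]
        if start is not None:
            z0 = []
            for name, lg in zip(free_names, logs):
                x = float(start.get(name, fixed[name]))
                z0.append(math.log(max(x, 1e-300)) if lg else x)
            start_list.insert(0, np.clip(np.asarray(z0), bounds_t[:, 0], bounds_t[:, 1]))

        best_z, best_y, any_success = None, np.inf, False
        for z0 in start_list:
            try:
                res = optimize.minimize(
                    objective, z0, method="L-BFGS-B",
                    bounds=[tuple(b) for b in bounds_t],
                )
            except Exception:
                continue
            z1, y1, ok = res.x, res.fun, bool(res.success)
            if not ok or not np.isfinite(y1):
                try:
                    res2 = optimize.minimize(
                        objective, z1 if np.all(np.isfinite(z1)) else z0,
                        method="Nelder-Mead",
                        options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
                    )
                    if res2.fun < y1 or not np.isfinite(y1):
                        z1, y1, ok = np.clip(res2.x, bounds_t[:, 0], bounds_t[:, 1]), res2.fun, bool(res2.success)
                except Exception:
                    pass
            if np.isfinite(y1) and y1 < best_y:
                best_y, best_z = y1, np.asarray(z1)
            any_success = any_success or ok

        message = ""
        if best_z is None:
            best_z = start_list[0]
            best_y = objective(best_z)
            any_success = False
            message = "all optimizer starts failed; returning first start"
        # final polish from the best point (also makes refitting from the
        # returned parameters a fixed point)
        try:
            res = optimize.minimize(
                objective, best_z, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-14},
            )
            if np.isfinite(res.fun) and res.fun <= best_y:
                best_z = np.clip(res.x, bounds_t[:, 0], bounds_t[:, 1])
                best_y = float(res.fun)
        except Exception:
            pass

        values = unpack(np.asarray(best_z))
        model = spec.build(values)
        Y = deviance(self.data, model, adjust=self.adjust)
        degenerate = self._degeneracy_message()
        if degenerate:
            any_success = False
            message = (message + "; " if message else "") + degenerate
        return DRFResults(
            model=model,
            params=values,
            free_names=tuple(free_names),
            Y_star=Y,
            m=len(free_names),
            I=self.data.n_groups,
            converged=bool(any_success),
            n_restarts=n_pts,
            seed=int(seed),
            message=message,
            spec=spec,
            data=self.data,
            adjusted=self.adjust,
        )

    def _fixed_result(self, seed: int) -> "DRFResults":
        values = self.spec.values_with_defaults(self._max_dose())
        model = self.spec.build(values)
        Y = deviance(self.data, model, adjust=self.adjust)
        return DRFResults(
            model=model,
            params=values,
            free_names=(),
            Y_star=Y,
            m=0,
            I=self.data.n_groups,
            converged=True,
            n_restarts=0,
            seed=int(seed),
            message="no free parameters; deviance evaluated at fixed values",
            spec=self.spec,
            data=self.data,
            adjusted=self.adjust,
        )

    def _degeneracy_message(self) -> str:
        d = self.data
        if d.n_groups > 1 and np.allclose(d.doses, d.doses[0]):
            return "degenerate data: all groups share one dose vector"
        if np.all(d.n == 0):
            return "degenerate data: no responders in any group"
        return ""


@dataclass
class DRFResults:
    """Results of a deviance-minimizing fit.

    Carries the built response model, the full parameter map (fixed and
    fitted), the deviance Y*, the free-parameter count m, degrees of
    freedom I - m - 1 and the chi-square GOF p-value (None when df < 1),
    plus optimizer diagnostics.
    """

    model: object
    params: dict[str, float]
    free_names: tuple[str, ...]
    Y_star: float
    m: int
    I: int
    converged: bool
    n_restarts: int
    seed: int
    message: str
    spec: ModelSpec
    data: QuantalData
    adjusted: bool

    @property
    def df(self) -> int:
        return self.I - self.m - 1

    @property
    def p_value(self) -> float | None:
        if self.df < 1:
            return None
        return gof_pvalue(self.Y_star, self.I, self.m)

    @property
    def p_value_lr(self) -> float | None:
        """Calibrated p-value at the likelihood-ratio df I - m (uniform
        under the true model); the headline ``p_value`` is the strict
        convention with one df fewer."""
        if self.I - self.m < 1:
            return None
        return gof_pvalue(self.Y_star, self.I, self.m, strict=False)

    @property
    def gof_available(self) -> bool:
        return self.df >= 1

    def predict(self, doses) -> np.ndarray:
        """Response probabilities on a dose grid (never clipped)."""
        return _model_response(self.model, np.atleast_2d(np.asarray(doses, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "label": self.spec.label,
            "family": self.spec.family,
            "background": self.spec.background,
            "params": {k: float(v) for k, v in self.params.items()},
            "free": list(self.free_names),
            "Y_star": float(self.Y_star),
            "m": int(self.m),
            "I": int(self.I),
            "df": int(self.df),
            "p_value": None if self.p_value is None else float(self.p_value),
            "converged": bool(self.converged),
            "n_restarts": int(self.n_restarts),
            "seed": int(self.seed),
            "count_adjusted": bool(self.adjusted),
            "message": self.message,
        }

    def summary(self) -> str:
        lines = [
            "Quantal dose-response fit",
            "=" * 58,
            f"Model:            {self.spec.label} ({self.spec.family})",
            f"Groups (I):       {self.I}",
            f"Free params (m):  {self.m}  [{', '.join(self.free_names) or 'none'}]",
            f"Deviance Y*:      {self.Y_star:.6g}",
            f"Deg. of freedom:  {self.df}",
            f"GOF p-value:      "
            + (f"{self.p_value:.4g}" if self.p_value is not None else "undefined (df < 1)"),
            f"Converged:        {self.converged}  (restarts: {self.n_restarts}, seed: {self.seed})",
            "-" * 58,
            f"{'parameter':<14}{'value':>16}  {'status':<8}",
        ]
        for name, value in self.params.items():
            status = "free" if name in self.free_names else "fixed"
            lines.append(f"{name:<14}{value:>16.6g}  {status:<8}")
        if self.message:
            lines.append("-" * 58)
            lines.append(f"Note: {self.message}")
        return "\n".join(lines)


@dataclass
class FailedFit:
    """Placeholder row for a spec whose fit raised; keeps compare tables intact."""

    spec: ModelSpec
    error: str

    @property
    def p_value(self):
        return None


def compare_models(
    data: QuantalData,
    specs: Sequence[ModelSpec],
    seed: int = 0,
    adjust_counts: bool = True,
    n_restarts: int = 32,
) -> list[DRFResults | FailedFit]:
    """Fit several specs to the same data under identical conventions.

    Per-spec failures are isolated as FailedFit rows; the table reports
    side by side, it does not rank (GOF p-values are not strictly
    comparable across families).
    """
    if not specs:
        raise ValueError("at least one model spec is required")
    out: list[DRFResults | FailedFit] = []
    for spec in specs:
        try:
            model = QuantalDoseResponse(data, spec, adjust_counts=adjust_counts)
            out.append(model.fit(seed=seed, n_restarts=n_restarts))
        except Exception as exc:
            out.append(FailedFit(spec=spec, error=str(exc)))
    return out


def results_table(results: Sequence[DRFResults | FailedFit]) -> pd.DataFrame:
    """Tabulate fit results (one row per spec, ordered as given)."""
    rows = []
    for r in results:
        if isinstance(r, FailedFit):
            rows.append({"label": r.spec.label, "error": r.error})
            continue
        row = {
            "label": r.spec.label,
            "family": r.spec.family,
            "p_value": r.p_value,
            "Y_star": r.Y_star,
            "m": r.m,
            "df": r.df,
            "converged": r.converged,
            "error": "",
        }
        row.update({k: v for k, v in r.params.items()})
        rows.append(row)
    return pd.DataFrame(rows)
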