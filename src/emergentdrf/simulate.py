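"""Synthetic-data engine: severity cause-chains and quantal sampling.

The first-order (multiplicative) illness model builds severity as

    Z = C0 * prod_{i=1..t} C_i,

where C0 is the dose and the C_i are random cause sizes along a mode of
action (fractions of toxicant passed, degrees of protective-mechanism
failure).  Cause sizes in real systems are autocorrelated, so the log
cause sizes follow a stationary lag-1 autoregressive process.  The
innovations are left-skewed by default (a mean-centred reflected
exponential): a cause modelled as a failure fraction is bounded above by
complete failure but has a long lower tail, so its log is left-skewed.
With skewed increments the accumulated log severity keeps a negative
skew — the Gumbel-minimum direction — and a Weibull fit to Z outperforms
a lognormal one; with ``innovations="gaussian"`` (or with rho = 0 and
many increments, where the CLT takes over) log Z is normal and severity
is lognormal.  This is the mechanism by which the Weibull severity
family, and hence the Frechet critical-dose DRF, emerges.

With the clinical illness cutoff Z >= Z* = 1 (arbitrary units), the
severity per unit dose is W = Z / C0 and the critical dose of each
individual is D = Z*/W = 1/W; if W ~ Weibull(k, lam) then D is Frechet
with eta = k, xi = 1/lam.

``simulate_quantal`` draws binomial responder counts from any response
model, standing in for an animal dose-group experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import QuantalData

__all__ = [
    "SeverityChainConfig",
    "SeverityDraws",
    "simulate_chain",
    "critical_dose_sample",
    "simulate_quantal",
]

_BURN_IN = 200  # AR warm-up increments discarded before the chain proper


@dataclass(frozen=True)
class SeverityChainConfig:
    """Configuration of the autocorrelated multiplicative cause chain.

    ``t``: number of multiplicative increments along the mode of action;
    ``dose_C0``: the dose (initial term of the product);
    ``cause_log_mean`` / ``cause_log_sd``: stationary mean and sd of the
    log cause sizes; ``autocorr_rho``: lag-1 autocorrelation in [0, 1);
    ``n_draws``: individuals simulated; ``innovations``: "leftskew"
    (default) or "gaussian".
    """

    t: int
    dose_C0: float
    cause_log_mean: float
    cause_log_sd: float
    autocorr_rho: float
    n_draws: int
    seed: int = 0
    innovations: str = "leftskew"

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be a positive integer")
        if not self.dose_C0 > 0:
            raise ValueError("dose_C0 must be positive")
        if not self.cause_log_sd > 0:
            raise ValueError("cause_log_sd must be positive")
        if not 0.0 <= self.autocorr_rho < 1.0:
            raise ValueError("autocorr_rho must lie in [0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be a positive integer")
        if self.innovations not in ("leftskew", "gaussian"):
            raise ValueError("innovations must be 'leftskew' or 'gaussian'")


@dataclass(frozen=True)
class SeverityDraws:
    """Simulated severities Z, severities per unit dose W = Z/C0, and
    critical doses D = Z*/W (illness cutoff Z* = 1)."""

    Z: np.ndarray
    W: np.ndarray
    D: np.ndarray
    Z_star: float = 1.0


def _ar1_log_causes(cfg: SeverityChainConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_draws, t) matrix of log cause sizes from a stationary AR(1)."""
    rho = cfg.autocorr_rho
    inn_sd = cfg.cause_log_sd * np.sqrt(1.0 - rho**2)
    total = _BURN_IN + cfg.t
    if cfg.innovations == "gaussian":
        eps = rng.standard_normal((cfg.n_draws, total))
    else:
        # reflected exponential, centred and unit-variance: skewness -2
        eps = 1.0 - rng.standard_exponential((cfg.n_draws, total))
    eps = eps * inn_sd
    x = np.zeros((cfg.n_draws, total))
    x[:, 0] = eps[:, 0] / np.sqrt(1.0 - rho**2)  # variance-matched start
    for i in range(1, total):
        x[:, i] = rho * x[:, i - 1] + eps[:, i]
    return cfg.cause_log_mean + x[:, _BURN_IN:]


def simulate_chain(cfg: SeverityChainConfig) -> SeverityDraws:
    """Draw severities from the autocorrelated multiplicative chain.

    Z = C0 * exp(sum of t log cause sizes); the log cause sizes are a
    stationary lag-1 autoregressive process with the configured mean,
    standard deviation and autocorrelation.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    logs = _ar1_log_causes(cfg, rng)
    Z = cfg.dose_C0 * np.exp(logs.sum(axis=1))
    W = Z / cfg.dose_C0
    D = 1.0 / W  # Z* = 1
    return SeverityDraws(Z=Z, W=W, D=D)


def critical_dose_sample(k: float, lam: float, n: int, seed: int = 0) -> np.ndarray:
    """Critical doses D = 1/W with W ~ Weibull(shape k, scale lam).

    The empirical CDF of D converges to the Frechet CDF with eta = k and
    xi = 1/lam (zero threshold).
    """
    if not (k > 0 and lam > 0):
        raise ValueError("Weibull shape and scale must be positive")
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    W = lam * rng.weibull(k, size=n)
    return 1.0 / W


def simulate_quantal(model, doses, N, seed: int = 0) -> QuantalData:
    """Binomial quantal dataset sampled from any response model.

    ``doses`` is a list/array of dose vectors (I, J) or doses (I,);
    ``N`` a scalar or per-group sizes.  n_i ~ Binomial(N_i, F(dose_i)).
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    if doses.shape[0] == 1 and doses.shape[1] > 1 and getattr(model, "n_stressors", 1) == 1:
        doses = doses.T  # a plain list of single-stressor doses
    I = doses.shape[0]
    N_arr = np.broadcast_to(np.asarray(N, dtype=int), (I,)).copy()
    if np.any(N_arr < 1):
        raise ValueError("group sizes must be >= 1")
    from .fitting import _model_response

    p = np.clip(_model_response(model, doses), 0.0, 1.0)
    rng = np.random.default_rng(seed)
    n = rng.binomial(N_arr, p)
    return QuantalData(doses=doses, n=n, N=N_arr)
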