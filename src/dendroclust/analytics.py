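"""Steady-state analysis of the generalized model.

The expected efficacy drift under stationary input follows from averaging
the generalized dynamics over time and realizations:

    tau_w <dw_k/dt> = phi sum_l s_kl w_l ( int gamma_kl(t) Gamma(t) dt
                                           + mu_k mu_l )
                      + rho sum_l s_kl w_l mu_l

with Gamma(t) = exp(-|t|/tau_u) / (tau_u + tau_v), mu the mean of the
event-indicator train and gamma_kl its lagged covariance.  All quantities
here use event-normalized units: time is measured in multiples of the
event duration x_dur (50 ms), so phi -> phi*x_dur, a rate of 15 per min
becomes mu = 0.0125, and tau_u + tau_v = 900 ms becomes 18.  This is the
convention under which kappa = (-rho/phi - mu)(tau_u + tau_v) evaluates to
~0.32 at nominal parameters.

For homogeneously correlated inputs at density nu the competition
boundary is c* = (kappa S - 1)/(S - 1) with the neighbourhood activity
S = sqrt(2 pi) sigma_c nu; above c* the heterosynaptic component
stabilizes instead of depressing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .params import PlasticityParams

__all__ = [
    "SteadyStateSpec", "normalized_constants", "kappa", "critical_correlation",
    "neighborhood_sum", "predicted_sign", "expected_weight_change",
    "fwhm_to_sigma", "linearized_protocol_prediction",
    "sample_parameter_perturbations",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))     # ~2.3548


def normalized_constants(params: PlasticityParams) -> dict:
    """(phi, tau_u, tau_v, rho) in event-duration units."""
    xd = params.x_dur
    return {"phi": params.phi * xd, "tau_u": params.tau_u / xd,
            "tau_v": params.tau_v / xd, "rho": params.rho}


def kappa(params: PlasticityParams, rate_per_min: float = 15.0) -> float:
    """kappa = (-rho/phi - mu)(tau_u + tau_v) in event-normalized units."""
    c = normalized_constants(params)
    mu = rate_per_min / 60e3 * params.x_dur
    return (-c["rho"] / c["phi"] - mu) * (c["tau_u"] + c["tau_v"])


def neighborhood_sum(nu: float, sigma_c: float) -> float:
    """S = sqrt(2 pi) sigma_c nu, the activity mass around a synapse."""
    return math.sqrt(2.0 * math.pi) * sigma_c * nu


def critical_correlation(nu: float, sigma_c: float, kappa_value: float) -> float:
    """c* = (kappa S - 1)/(S - 1); approaches kappa from below as S grows.

    A negative c* means no correlation level in [0, 1] produces net
    depression at that density.  S = 1 is singular.
    """
    S = neighborhood_sum(nu, sigma_c)
    if abs(S - 1.0) < 1e-12:
        raise ZeroDivisionError("S = 1 makes c* singular")
    return (kappa_value * S - 1.0) / (S - 1.0)


def predicted_sign(nu: float, c: float, sigma_c: float, kappa_value: float) -> int:
    """Sign of the expected drift from the c* algebra: 1 + (S-1)c - S kappa.

    Valid for any S including S < 1 (where the formula for c* itself flips
    branches).
    """
    S = neighborhood_sum(nu, sigma_c)
    val = 1.0 + (S - 1.0) * c - S * kappa_value
    return int(np.sign(val))


# ---------------------------------------------------------------------------
# exact expected drift (quadrature)

def _gamma_kernel_integral(tau_u: float, tau_v: float) -> float:
    """int of the boxcar-event covariance triangle against Gamma.

    The event-indicator covariance of trains sharing events at unit rate is
    the unit triangle max(0, 1-|t|) (event-normalized units); the integral
    against Gamma(t) = exp(-|t|/tau_u)/(tau_u+tau_v) is evaluated by
    adaptive quadrature.
    """
    f = lambda t: max(0.0, 1.0 - abs(t)) * math.exp(-abs(t) / tau_u) / (tau_u + tau_v)
    val, _ = integrate.quad(f, -1.0, 1.0, epsabs=1e-10, epsrel=1e-10)
    return val


@dataclass
class SteadyStateSpec:
    """Stationary-input description for the drift formula.

    Rates in events/min; ``c`` the homogeneous pairwise event correlation
    (multiple-interaction construction: shared-event rate c * rate).
    Weights and the proximity matrix are per synapse.
    """
    params: PlasticityParams
    rates_per_min: np.ndarray
    s: np.ndarray
    w: np.ndarray
    c: float = 0.0
    c_matrix: np.ndarray | None = None     # optional per-pair correlations

    def __post_init__(self):
        self.rates_per_min = np.atleast_1d(np.asarray(self.rates_per_min, float))
        self.w = np.atleast_1d(np.asarray(self.w, float))
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("correlation must lie in [0, 1]")


def expected_weight_change(spec: SteadyStateSpec) -> np.ndarray:
    """Per-synapse tau_w <dw/dt> (event-normalized units).

    The covariance between trains k != l is c_kl * min(mu_k, mu_l) times
    the unit triangle (shared events from the thinning construction);
    the autocovariance is mu_k times the triangle.
    """
    p = spec.params
    cn = normalized_constants(p)
    mu = spec.rates_per_min / 60e3 * p.x_dur
    I = _gamma_kernel_integral(cn["tau_u"], cn["tau_v"])
    n = len(mu)
    if spec.c_matrix is not None:
        C = np.asarray(spec.c_matrix, dtype=float)
    else:
        C = np.full((n, n), spec.c)
    shared = C * np.minimum.outer(mu, mu)
    np.fill_diagonal(shared, mu)
    cov_int = shared * I
    out = np.zeros(n)
    for k in range(n):
        out[k] = (cn["phi"] * np.sum(spec.s[k] * spec.w * (cov_int[k] + mu[k] * mu)) +
                  cn["rho"] * np.sum(spec.s[k] * spec.w * mu))
    return out


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM -> standard deviation: sigma = fwhm / (2 sqrt(2 ln 2))."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    return fwhm / FWHM_FACTOR


# ---------------------------------------------------------------------------
# linearized two-synapse protocol

@dataclass
class _ProtocolConstants:
    K1: float
    K2: float
    K3: float


_protocol_cache: dict = {}


def _protocol_constants(params: PlasticityParams, w: float = 0.5) -> _ProtocolConstants:
    """Fit K1..K3 of the stimulated/silent drift forms to the drift formula.

    <dw_1/dt> = K1 mu + K2 mu^2 for the stimulated synapse and
    <dw_2/dt> = K3 mu exp(-d^2/(2 sigma_c^2)) for a silent neighbour; the
    constants are obtained once by least squares over a rate grid.
    """
    key = (params.phi, params.eta, params.tau_u, params.tau_v, params.x_dur, w)
    if key in _protocol_cache:
        return _protocol_cache[key]
    rates = np.linspace(1.0, 20.0, 12)
    drift1 = []
    drift3 = []
    s = np.array([[1.0, 1.0], [1.0, 1.0]])     # d = 0 reference pair
    for r in rates:
        spec = SteadyStateSpec(params=params, rates_per_min=np.array([r, 0.0]),
                               s=s, w=np.array([w, w]), c=0.0)
        d1, d2 = expected_weight_change(spec)
        # remove the silent synapse's contribution to the stimulated one
        spec_solo = SteadyStateSpec(params=params, rates_per_min=np.array([r]),
                                    s=np.array([[1.0]]), w=np.array([w]), c=0.0)
        drift1.append(expected_weight_change(spec_solo)[0])
        drift3.append(d2)
    drift1 = np.asarray(drift1)
    drift3 = np.asarray(drift3)
    mu = rates / 60e3 * params.x_dur
    X1 = np.column_stack([mu, mu ** 2])
    (K1, K2), *_ = np.linalg.lstsq(X1, drift1, rcond=None)
    K3 = float(np.linalg.lstsq(mu[:, None], drift3, rcond=None)[0][0])
    out = _ProtocolConstants(float(K1), float(K2), K3)
    _protocol_cache[key] = out
    return out


def linearized_protocol_prediction(rate_per_min: float, distance_um: float,
                                   params: PlasticityParams,
                                   w: float = 0.5) -> tuple[float, float]:
    """(drift of stimulated synapse, drift of silent synapse at distance d).

    Units are tau_w <dw/dt> in event-normalized time, as in
    :func:`expected_weight_change`.
    """
    k = _protocol_constants(params, w)
    mu = rate_per_min / 60e3 * params.x_dur
    dw1 = k.K1 * mu + k.K2 * mu * mu
    dw2 = k.K3 * mu * math.exp(-distance_um ** 2 / (2.0 * params.sigma_c ** 2))
    return dw1, dw2


# ---------------------------------------------------------------------------
# sensitivity-analysis priors

def sample_parameter_perturbations(n: int, seed=None, *,
                                   rng: np.random.Generator | None = None):
    """Draw parameter sets from the sensitivity-analysis priors.

    tau_M, tau_v ~ N(600, 300) ms truncated at 5 ms; tau_Y, tau_u ~
    N(300, 150) ms truncated at 5 ms; tau_B, tau_P ~ exp(N(4, 1)) ms
    truncated at 1 ms; sigma_c ~ N(8, 1) um truncated at 4 um;
    phi ~ N(3/50, 3/500); eta ~ U[0.40, 0.50].  Returns a pandas
    DataFrame with one row per draw.
    """
    import pandas as pd

    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    def trunc_normal(mean, sd, low, size):
        a = (low - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                                   random_state=rng)

    def trunc_lognormal(mu, sd, low, size):
        out = np.exp(rng.normal(mu, sd, size=size))
        while np.any(out < low):
            bad = out < low
            out[bad] = np.exp(rng.normal(mu, sd, size=int(bad.sum())))
        return out

    df = pd.DataFrame({
        "tau_M": trunc_normal(600.0, 300.0, 5.0, n),
        "tau_v": trunc_normal(600.0, 300.0, 5.0, n),
        "tau_Y": trunc_normal(300.0, 150.0, 5.0, n),
        "tau_u": trunc_normal(300.0, 150.0, 5.0, n),
        "tau_B": trunc_lognormal(4.0, 1.0, 1.0, n),
        "tau_P": trunc_lognormal(4.0, 1.0, 1.0, n),
        "sigma_c": trunc_normal(8.0, 1.0, 4.0, n),
        "phi": rng.normal(3.0 / 50.0, 3.0 / 500.0, size=n),
        "eta": rng.uniform(0.40, 0.50, size=n),
    })
    return df
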