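"""Somatic accumulator and backpropagating action potentials (bAPs).

The soma integrates the postsynaptic accumulators weighted by efficacy,
``A(t) = sum_k w_k u_k`` (the bAP feedback term is excluded from u before
summing, so there is no positive feedback loop).  On each upward crossing
of the threshold ``A_th`` a bAP fires with probability ``bap_prob``; the
delivered calcium at synapse k is ``B_amp * exp(-d_k^2 / (2 sigma_bAP^2))``
with ``d_k`` the path distance to the soma.
"""

from __future__ import annotations

import numpy as np

__all__ = ["somatic_drive", "maybe_fire_bap", "bap_attenuation", "crossing_times"]


def somatic_drive(w, u, u_bap_component=None) -> float:
    """A = sum_k w_k u_k, with any bAP-fed component of u removed first."""
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    if w.shape != u.shape:
        raise ValueError("w and u must align")
    if u_bap_component is not None:
        u = u - np.asarray(u_bap_component, dtype=float)
    return float(np.dot(w, u))


def maybe_fire_bap(A: float, A_th: float, bap_prob: float,
                   rng: np.random.Generator, *, prev_above: bool = False) -> int:
    """Bernoulli bAP decision on an upward threshold crossing.

    Returns 1 when A crossed A_th from below and the coin (probability
    ``bap_prob``) lands; always 0 while A stays below threshold or when
    already above (no re-draw without a fresh crossing).
    """
    if A < A_th or prev_above:
        return 0
    return int(rng.random() < bap_prob)


def bap_attenuation(path_distance, sigma_bap: float) -> np.ndarray:
    """Gaussian attenuation s_k = exp(-d_k^2 / (2 sigma_bAP^2))."""
    d = np.asarray(path_distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("path distance must be non-negative")
    if sigma_bap <= 0:
        raise ValueError("sigma_bap must be positive")
    out = np.exp(-d * d / (2.0 * sigma_bap * sigma_bap))
    return out if out.shape else float(out)


def crossing_times(A_trace: np.ndarray, A_th: float) -> np.ndarray:
    """Indices of upward threshold crossings in a somatic-drive trace."""
    above = np.asarray(A_trace) >= A_th
    return np.where(above[1:] & ~above[:-1])[0] + 1
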