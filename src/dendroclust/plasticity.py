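"""Plasticity dynamics: full neurotrophin model and generalized reduction.

The full model tracks, per excitatory synapse k, the protease accumulator
M_k (MMP9), calcium Y_k, proBDNF P_k, BDNF B_k and the bounded efficacy
W_k:

    tau_M dM/dt = -M + phi x(t)
    tau_Y dY/dt = -Y + sum_l s_kl W_l x_l(t)  [+ s_k B_amp B(t)] [+- GABA]
    tau_P dP/dt = -P + (1-eta) Y - M P
    tau_B dB/dt = -B + eta Y + M P
    tau_W dW/dt = alpha B - beta P            (W clipped to [0, 1])

The generalized model is its quasi-steady-state linearization around M = 0:

    tau_v dv/dt = -v + phi x(t)
    tau_u du/dt = -u + g(sum_l s_kl w_l x_l(t)) [+ s_k B_amp B(t)]
    tau_w dw/dt = F(u (v + rho))              (w clipped to [0, 1])

with rho, tau_w derived from (eta, alpha, beta, tau_W), g the optional
sigmoidal dendritic nonlinearity and F the optional cooperativity gate.

:func:`step_generalized` / :func:`step_neurotrophin` are single-step
reference implementations; :class:`Simulator` drives the numba kernels for
long runs and is tested against the reference steppers step-for-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import PlasticityParams, derive_generalized_params

__all__ = [
    "NeurotrophinState", "GeneralizedState", "Simulator",
    "step_neurotrophin", "step_generalized",
    "dendritic_nonlinearity", "cooperativity_gate", "step_inhibitory_weights",
    "derive_generalized_params",
]


def dendritic_nonlinearity(I, gamma: float, c1: float = 0.5, c2: float = 35.0,
                           c3: float = 0.125):
    """Sigmoidal-linear mix g(I) = gamma*c1/(1+exp(-c2(I-c3))) + (1-gamma)*I.

    gamma = 0 is the identity; gamma = 1 saturates at c1 and passes through
    c1/2 at I = c3.  Monotone nondecreasing for gamma in [0, 1].
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    I = np.asarray(I, dtype=float)
    out = gamma * c1 / (1.0 + np.exp(-c2 * (I - c3))) + (1.0 - gamma) * I
    return out if out.shape else float(out)


def cooperativity_gate(active_flags, distances, spacing_thr: float,
                       min_count: int = 3, include_self: bool = False):
    """Per-synapse cooperativity predicate.

    ``active_flags[l]`` marks synapses active within the trailing timing
    window; synapse k passes when strictly more than ``min_count``
    neighbours within ``spacing_thr`` (path distance) are flagged.  The
    reference synapse itself is excluded unless ``include_self``.
    """
    active = np.asarray(active_flags, dtype=bool)
    d = np.asarray(distances, dtype=float)
    near = d <= spacing_thr
    counts = (near & active[None, :]).sum(axis=1)
    if not include_self:
        counts = counts - (active & np.diag(near)).astype(int)
    return counts > min_count


@dataclass
class NeurotrophinState:
    M: np.ndarray
    Y: np.ndarray
    P: np.ndarray
    B: np.ndarray
    W: np.ndarray
    s: np.ndarray                       # proximity matrix
    W_gaba: np.ndarray | None = None
    s_eg: np.ndarray | None = None      # (N_exc, N_gaba) proximity

    @classmethod
    def initial(cls, s: np.ndarray, W0: float = 0.5, n_gaba: int = 0,
                s_eg: np.ndarray | None = None):
        n = s.shape[0]
        z = lambda: np.zeros(n)
        wg = np.full(n_gaba, W0) if n_gaba else None
        return cls(M=z(), Y=z(), P=z(), B=z(), W=np.full(n, W0), s=s,
                   W_gaba=wg, s_eg=s_eg)


@dataclass
class GeneralizedState:
    v: np.ndarray
    u: np.ndarray
    w: np.ndarray
    s: np.ndarray

    @classmethod
    def initial(cls, s: np.ndarray, w0: float = 0.5):
        n = s.shape[0]
        return cls(v=np.zeros(n), u=np.zeros(n), w=np.full(n, w0), s=s)


def _check_dt(dt: float, params: PlasticityParams, taus):
    if dt <= 0:
        raise ValueError("dt must be positive")
    stiffest = min(getattr(params, name) for name in taus)
    if dt > stiffest + 1e-12:
        raise ValueError(f"dt={dt} exceeds the stiffest time constant {stiffest}")


def step_neurotrophin(state: NeurotrophinState, x, dt: float,
                      params: PlasticityParams, *, x_gaba=None, bap: float = 0.0,
                      s_soma=None, ext_drive: float = 0.0, ext_gain=None,
                      freeze_w: bool = False, gaba_sign: int = 0) -> NeurotrophinState:
    """One explicit-Euler step of the full model (in place; returns state).

    All right-hand sides use the state at step start.  The M*P conversion
    moves neurotrophin from P to B so d(P+B)/dt carries no M dependence.
    ``gaba_sign`` of -1 applies the hyperpolarizing scenario (with the
    calcium positivity floor), +1 the depolarizing one.
    """
    _check_dt(dt, params, ("tau_M", "tau_Y", "tau_P", "tau_B"))
    x = np.asarray(x, dtype=float)
    if x.shape != state.M.shape:
        raise ValueError("input train shape does not match state")
    if np.any(~np.isfinite(state.W)):
        raise FloatingPointError("NaN in state")
    M0, Y0, P0, B0 = state.M.copy(), state.Y.copy(), state.P.copy(), state.B.copy()
    drive = state.s @ (state.W * x)
    if x_gaba is not None and gaba_sign != 0:
        drive = drive + gaba_sign * state.s_eg @ (state.W_gaba * np.asarray(x_gaba, float))
    if bap and s_soma is not None:
        drive = drive + np.asarray(s_soma) * params.B_amp * bap
    if ext_gain is not None:
        drive = drive + np.asarray(ext_gain) * ext_drive
    if state.W_gaba is not None and state.W_gaba.size:
        dWg = state.s_eg.T @ (B0 - P0)
        state.W_gaba = np.clip(state.W_gaba + dt / params.tau_W * dWg, 0.0, 1.0)
    state.M = M0 + dt / params.tau_M * (-M0 + params.phi * params.x_dur * x)
    Y = Y0 + dt / params.tau_Y * (-Y0 + drive)
    if gaba_sign < 0:
        Y = np.maximum(Y, 0.0)      # scenario A: calcium stays non-negative
    state.Y = Y
    conv = M0 * P0
    state.P = P0 + dt / params.tau_P * (-P0 + (1.0 - params.eta) * Y0 - conv)
    state.B = B0 + dt / params.tau_B * (-B0 + params.eta * Y0 + conv)
    if not freeze_w:
        state.W = np.clip(state.W + dt / params.tau_W *
                          (params.alpha * B0 - params.beta * P0), 0.0, 1.0)
    return state


def step_inhibitory_weights(state: NeurotrophinState, params: PlasticityParams,
                            dt: float) -> NeurotrophinState:
    """Standalone GABA efficacy update (proximity-weighted B - P)."""
    if state.W_gaba is None or state.s_eg is None:
        raise ValueError("inhibitory update requires a neurotrophin state with GABA synapses")
    dWg = state.s_eg.T @ (state.B - state.P)
    state.W_gaba = np.clip(state.W_gaba + dt / params.tau_W * dWg, 0.0, 1.0)
    return state


def step_generalized(state: GeneralizedState, x, dt: float,
                     params: PlasticityParams, *, nonlinearity_on: bool = False,
                     cooperativity_gate_values=None, bap: float = 0.0,
                     s_soma=None, freeze_w: bool = False) -> GeneralizedState:
    """One explicit-Euler step of the generalized model (in place)."""
    _check_dt(dt, params, ("tau_v", "tau_u"))
    x = np.asarray(x, dtype=float)
    v0, u0 = state.v.copy(), state.u.copy()
    I = state.s @ (state.w * x)
    if nonlinearity_on and params.gamma > 0:
        I = dendritic_nonlinearity(I, params.gamma, params.c1, params.c2, params.c3)
    if bap and s_soma is not None:
        I = I + np.asarray(s_soma) * params.B_amp * bap
    gate = 1.0 if cooperativity_gate_values is None else \
        np.asarray(cooperativity_gate_values, dtype=float)
    dw = gate * u0 * (v0 + params.rho)
    state.v = v0 + dt / params.tau_v * (-v0 + params.phi * params.x_dur * x)
    state.u = u0 + dt / params.tau_u * (-u0 + I)
    if not freeze_w:
        state.w = np.clip(state.w + dt / params.tau_w * dw, 0.0, 1.0)
    return state


# ---------------------------------------------------------------------------
# chunked fast simulator

@dataclass
class Simulator:
    """Chunked kernel driver holding resumable state.

    Parameters mirror the reference steppers; ``model`` selects the
    dynamics.  Event chunks arrive as dense (N, steps) uint8 matrices on
    the dt grid.  ``dw_sum`` accumulates the instantaneous efficacy drive
    (u(v+rho), or alpha B - beta P) per synapse for frozen-weight
    protocols.
    """

    model: str
    params: PlasticityParams
    s: np.ndarray
    dt: float
    freeze_w: bool = False
    bap_on: bool = False
    s_soma: np.ndarray | None = None
    coop_distances: np.ndarray | None = None
    n_gaba: int = 0
    s_eg: np.ndarray | None = None
    gaba_sign: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    nonlinearity_on: bool = False

    def __post_init__(self):
        n = self.s.shape[0]
        p = self.params
        if self.model not in ("generalized", "neurotrophin"):
            raise ValueError(f"unknown model {self.model!r}")
        taus = (("tau_v", "tau_u") if self.model == "generalized"
                else ("tau_M", "tau_Y", "tau_P", "tau_B"))
        _check_dt(self.dt, p, taus)
        self.n = n
        self.steps_done = 0
        self.dw_sum = np.zeros(n)
        self.u_bap = np.zeros(n)       # bAP-fed accumulator (excluded from A)
        self.bap_state = np.zeros(6, dtype=np.int64)
        if self.s_soma is None:
            self.s_soma = np.zeros(n)
        if self.model == "generalized":
            self.state = GeneralizedState.initial(self.s)
        else:
            self.state = NeurotrophinState.initial(self.s, n_gaba=self.n_gaba,
                                                   s_eg=self.s_eg)
        if self.coop_distances is not None and p.coop_on:
            self.coop_nbr = (self.coop_distances <= p.coop_spacing).astype(np.uint8)
        else:
            self.coop_nbr = np.zeros((n, n), dtype=np.uint8)
        self.last_active = np.full(n, -1e18)

    # -- bookkeeping ------------------------------------------------------
    @property
    def time_ms(self) -> float:
        return self.steps_done * self.dt

    @property
    def efficacy(self) -> np.ndarray:
        return self.state.w if self.model == "generalized" else self.state.W

    @property
    def bap_count(self) -> int:
        return int(self.bap_state[_kernels.BAP_COUNT])

    def mean_dwdt(self) -> np.ndarray:
        """Time-averaged instantaneous dw/dt (per ms) since construction."""
        steps = max(self.steps_done, 1)
        if self.model == "generalized":
            return self.dw_sum / steps / self.params.tau_w
        return self.dw_sum / steps / self.params.tau_W

    def mean_bp(self) -> np.ndarray:
        """Time-averaged alpha*B - beta*P (neurotrophin frozen-W readout)."""
        return self.dw_sum / max(self.steps_done, 1)

    def set_proximity(self, s: np.ndarray, *, s_soma=None, s_eg=None,
                      coop_distances=None):
        self.s = s
        self.state.s = s
        if s_soma is not None:
            self.s_soma = np.asarray(s_soma, dtype=float)
        if s_eg is not None:
            self.s_eg = s_eg
            self.state.s_eg = s_eg
        if coop_distances is not None and self.params.coop_on:
            self.coop_nbr = (coop_distances <= self.params.coop_spacing).astype(np.uint8)

    def reset_synapse(self, k: int, w0: float = 0.5):
        st = self.state
        if self.model == "generalized":
            st.v[k] = st.u[k] = 0.0
            st.w[k] = w0
        else:
            st.M[k] = st.Y[k] = st.P[k] = st.B[k] = 0.0
            st.W[k] = w0
        self.u_bap[k] = 0.0
        self.dw_sum[k] = 0.0
        self.last_active[k] = -1e18

    # -- stepping ---------------------------------------------------------
    def run_chunk(self, x: np.ndarray, *, ext_drive=None, ext_gain=None,
                  x_gaba=None, record_stride: int = 0):
        """Advance over a dense (N, T) uint8 chunk; optionally record.

        Returns (w_record, a_record) when record_stride > 0, else None.
        """
        p = self.params
        x = np.ascontiguousarray(x, dtype=np.uint8)
        if x.shape[0] != self.n:
            raise ValueError("chunk synapse dimension mismatch")
        T = x.shape[1]
        refr_steps = max(1, int(round(p.bap_refractory / self.dt)))
        dur_steps = max(1, int(round(p.x_dur / self.dt)))
        n_uni = T + 2 if p.bap_per_step else T // refr_steps + 2
        uniforms = self.rng.random(n_uni) if self.bap_on else np.zeros(1)
        self.bap_state[_kernels.BAP_UPTR] = 0
        nrec = (T + record_stride - 1) // record_stride if record_stride > 0 else 0
        w_rec = np.zeros((nrec, self.n))
        a_rec = np.zeros(nrec)
        if self.model == "generalized":
            st = self.state
            _kernels.generalized_chunk(
                x, self.s, st.w, st.v, st.u, self.u_bap, self.dt,
                p.tau_v, p.tau_u, p.tau_w, p.phi * p.x_dur, p.rho,
                self.freeze_w, self.dw_sum,
                (p.gamma if self.nonlinearity_on else 0.0), p.c1, p.c2, p.c3,
                bool(p.coop_on and self.coop_distances is not None),
                self.coop_nbr, int(round(p.coop_timing / self.dt)),
                p.coop_min_count, p.coop_include_self, self.last_active,
                self.bap_on, np.asarray(self.s_soma, dtype=float),
                p.A_th, p.B_amp, p.bap_prob,
                uniforms, self.bap_state, p.bap_per_step,
                refr_steps, dur_steps, p.bap_burst_events,
                record_stride, w_rec, a_rec)
        else:
            st = self.state
            if ext_drive is None:
                ext_drive = np.zeros(T)
            if ext_gain is None:
                ext_gain = np.zeros(self.n)
            if x_gaba is None:
                x_gaba = np.zeros((self.n_gaba, T), dtype=np.uint8)
            wg = st.W_gaba if st.W_gaba is not None else np.zeros(0)
            seg = self.s_eg if self.s_eg is not None else np.zeros((self.n, 0))
            _kernels.neurotrophin_chunk(
                x, self.s, st.W, st.M, st.Y, self.u_bap, st.P, st.B, self.dt,
                p.tau_M, p.tau_Y, p.tau_P, p.tau_B, p.tau_W,
                p.phi * p.x_dur, p.eta, p.alpha, p.beta,
                self.freeze_w, self.dw_sum,
                np.ascontiguousarray(ext_drive, dtype=float),
                np.ascontiguousarray(ext_gain, dtype=float),
                self.gaba_sign, np.ascontiguousarray(x_gaba, dtype=np.uint8),
                wg, np.ascontiguousarray(seg, dtype=float),
                self.gaba_sign < 0,
                self.bap_on, np.asarray(self.s_soma, dtype=float),
                p.A_th, p.B_amp, p.bap_prob,
                uniforms, self.bap_state, p.bap_per_step,
                refr_steps, dur_steps, p.bap_burst_events,
                record_stride, w_rec)
        self.steps_done += T
        if not np.all(np.isfinite(self.efficacy)):
            raise FloatingPointError("non-finite efficacy after chunk")
        if record_stride > 0:
            return w_rec, a_rec
        return None
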