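"""Model parameters, nominal values, and species presets.

All simulation time is in milliseconds.  The plasticity model couples, per
synapse, a presynaptic protease accumulator (MMP9, ``M``/``v``), a laterally
spreading postsynaptic calcium accumulator (``Y``/``u``), the neurotrophins
proBDNF (``P``, depressing) and BDNF (``B``, potentiating), and a bounded
synaptic efficacy (``W``/``w``).  The generalized model replaces the
neurotrophin pair by the heterosynaptic offset ``rho`` and a rescaled
efficacy time constant ``tau_w`` (both derived, see
:func:`derive_generalized_params`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "PlasticityParams",
    "SpeciesPreset",
    "SPECIES",
    "derive_generalized_params",
    "nominal_params",
    "stdp_control_params",
    "load_preset",
]


def derive_generalized_params(eta: float, alpha: float = 1.0, beta: float = 1.0,
                              tau_W: float = 6000.0) -> tuple[float, float]:
    """Heterosynaptic offset ``rho`` and efficacy time constant ``tau_w``.

    rho = ((alpha+beta)*eta - beta) / ((alpha+beta)*(1-eta))
    tau_w = tau_W / ((alpha+beta)*(1-eta))

    With alpha = beta this reduces to rho = (2*eta-1)/(2*(1-eta)).  For the
    nominal constitutive BDNF fraction eta=0.45 the offset is negative
    (-1/11), which is what makes unstimulated neighbours of active synapses
    depress.

    Raises
    ------
    ValueError
        if eta is outside (0, 1) or alpha + beta <= 0.
    """
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must lie in (0, 1), got {eta}")
    if alpha + beta <= 0:
        raise ValueError("alpha + beta must be positive")
    ab = alpha + beta
    rho = (ab * eta - beta) / (ab * (1.0 - eta))
    tau_w = tau_W / (ab * (1.0 - eta))
    return rho, tau_w


@dataclass(frozen=True)
class SpeciesPreset:
    """Receptive-field geometry of a species (visual degrees)."""
    name: str
    sigma_p: float      # std of RF centre spread
    diameter: float     # Gabor RF diameter

    def __post_init__(self):
        if self.sigma_p <= 0 or self.diameter <= 0:
            raise ValueError("sigma_p and diameter must be positive")


SPECIES = {
    "ferret": SpeciesPreset("ferret", sigma_p=5.3, diameter=13.4),
    "mouse": SpeciesPreset("mouse", sigma_p=26.0, diameter=20.0),
    "macaque": SpeciesPreset("macaque", sigma_p=2.0, diameter=2.0),
}


@dataclass
class PlasticityParams:
    """Nominal parameter set of the plasticity model (times in ms).

    ``rho`` and ``tau_w`` are derived, not free: they follow from
    (eta, alpha, beta, tau_W).
    """

    # time constants
    tau_W: float = 6000.0
    tau_P: float = 5.0
    tau_B: float = 5.0
    tau_Y: float = 300.0
    tau_M: float = 600.0
    tau_u: float = 300.0
    tau_v: float = 600.0
    # core constants
    eta: float = 0.45          # constitutive BDNF fraction of released neurotrophin
    phi: float = 3.0 / 50.0    # MMP9 efficiency, per ms
    sigma_c: float = 6.0       # calcium spread std, um
    alpha: float = 1.0         # BDNF binding/plasticity gain
    beta: float = 1.0          # proBDNF binding/plasticity gain
    # structural plasticity
    W_thr: float = 0.02
    nu: float = 0.2            # synapse density, per um
    # events
    x_dur: float = 50.0        # event duration, ms
    # soma / bAP
    A_th: float = 25.0
    bap_prob: float = 0.25
    B_amp: float = 5.0
    sigma_bap: float = 75.0    # bAP attenuation factor, um
    bap_refractory: float = 200.0   # ms; per-crossing Bernoulli semantics
    bap_per_step: bool = False      # alternative: draw every step while above
    bap_burst_events: int = 10      # 50-ms pulses per somatic burst (1-s burst)
    # dendritic nonlinearity g(I) = gamma*c1/(1+exp(-c2*(I-c3))) + (1-gamma)*I
    gamma: float = 0.0
    c1: float = 0.5
    c2: float = 35.0
    c3: float = 0.125
    # cooperativity gate
    coop_on: bool = False
    coop_spacing: float = 10.0     # um
    coop_timing: float = 100.0     # ms
    coop_min_count: int = 3        # gate opens when count > min_count
    coop_include_self: bool = False
    # GABA scenarios
    gaba_mode: str = "off"         # off | inhibitory | excitatory-then-switch
    switch_day: float = 4.0
    # bookkeeping
    preset: str = "nominal"
    proximity_cutoff_sigmas: float = 5.0

    @property
    def rho(self) -> float:
        return derive_generalized_params(self.eta, self.alpha, self.beta, self.tau_W)[0]

    @property
    def tau_w(self) -> float:
        return derive_generalized_params(self.eta, self.alpha, self.beta, self.tau_W)[1]

    def validate(self) -> None:
        for name in ("tau_W", "tau_P", "tau_B", "tau_Y", "tau_M", "tau_u", "tau_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must lie in (0, 1)")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.gaba_mode not in ("off", "inhibitory", "excitatory-then-switch"):
            raise ValueError(f"unknown gaba_mode {self.gaba_mode!r}")

    def max_stable_dt(self) -> float:
        """Largest admissible Euler step (the stiffest time constant)."""
        return min(self.tau_P, self.tau_B, self.tau_Y, self.tau_M,
                   self.tau_u, self.tau_v)

    def replace(self, **kw) -> "PlasticityParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rho"] = self.rho
        d["tau_w"] = self.tau_w
        return d


def nominal_params(**overrides) -> PlasticityParams:
    p = PlasticityParams(**overrides)
    p.validate()
    return p


def stdp_control_params(**overrides) -> PlasticityParams:
    """STDP control: accumulators on spike-timing scales.

    tau_M = 60 ms, tau_Y = 1 ms, eta = 0.3, phi = 3/5 per ms; the generalized
    accumulators tau_v/tau_u mirror tau_M/tau_Y.  The short integration
    window is what prevents this rule from clustering under slow
    developmental input.
    """
    kw = dict(tau_M=60.0, tau_Y=1.0, tau_v=60.0, tau_u=1.0,
              eta=0.3, phi=3.0 / 5.0, preset="stdp-control")
    kw.update(overrides)
    p = PlasticityParams(**kw)
    p.validate()
    return p


def load_preset(name_or_path: str) -> PlasticityParams:
    """Load a parameter preset from a shipped name or a YAML file path."""
    import os

    if os.path.exists(name_or_path):
        with open(name_or_path) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        fname = name_or_path.replace("-", "_") + ".yaml"
        ref = resources.files("dendroclust.presets").joinpath(fname)
        if not ref.is_file():
            raise FileNotFoundError(f"no preset named {name_or_path!r}")
        data = yaml.safe_load(ref.read_text()) or {}
    data.pop("rho", None)
    data.pop("tau_w", None)
    p = PlasticityParams(**data)
    p.validate()
    return p
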