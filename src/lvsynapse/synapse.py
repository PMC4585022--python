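"""The complete input-output synapse: release, receptors, Mg block, currents.

The pipeline mirrors a glutamatergic synapse: a presynaptic event train
drives a facilitation/depression (FD) model of vesicle release probability;
a Bernoulli draw per event decides whether release occurs (or a
deterministic mode forces release); the release train drives the trained
AMPA and NMDA input-output receptor models; the NMDA conductance is scaled
by the magnesium-block factor; and currents follow I = nb * g * (V - Vrev).

Release dynamics follow the Dittman facilitation/depression formulation:
facilitation and recovery are driven by decaying calcium-bound indicator
variables CaX_F and CaX_D that jump at each event,

    F = F1 + (1 - F1) * CaX_F / (CaX_F + K_F),
    dD/dt = (1 - D) * k(t),  k = k0 + (kmax - k0) * CaX_D / (CaX_D + K_D),

and the release probability of an event is F * D, with D depleted by F * D
after release. The inter-event update of D has a closed form, so the
recursion is evaluated exactly (no ODE stepping).

The NMDA magnesium block uses the two-conductance logistic form

    g0   = g1 + (g2 - g1) / (1 + exp(alpha * psi_m)),
    gmax = g0 / (1 + ([Mg]0 / K0) * exp(-delta * z * F * psi_m / (R T))),
    g_NMDA(t) = gmax * O(t),

with the open-state fraction O(t) predicted by the NMDA IO model. psi_m is
a fixed dimensionless affinity parameter (default 0.8); an optional hook
maps a membrane potential to psi_m for users who want a voltage-dependent
block, but the default reproduces the fixed-parameter form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .events import BinnedSignal, EventTrain, bin_events
from .volterra import VolterraModel, predict

__all__ = [
    "ReleaseParams", "MgBlockParams", "SynapseConfig",
    "release_probabilities", "sample_release", "nmda_g0", "nmda_gmax",
    "nmda_conductance", "receptor_current", "run_io_synapse", "SynapseResult",
]

FARADAY = 9.64867e4      # C / mol
GAS_CONSTANT = 8.31434   # J / (mol K)


@dataclass(frozen=True)
class ReleaseParams:
    """Dittman facilitation/depression parameters.

    The defaults are documented placeholders in the range used for
    hippocampal Schaffer-collateral synapses; they are configuration, not
    calibrated constants.

    Attributes
    ----------
    F1 : float
        Baseline (first-event) facilitation, in [0, 1].
    tau_F : float
        Facilitation indicator decay time constant, s.
    K_F : float
        Facilitation affinity constant (dimensionless, in units of the
        indicator increment).
    delta_F : float
        Indicator increment per event (conventionally 1).
    k0, kmax : float
        Baseline and calcium-saturated recovery rates from depression, 1/s.
    tau_D : float
        Depression indicator decay time constant, s.
    K_D : float
        Recovery affinity constant.
    delta_D : float
        Depression indicator increment per event.
    """

    F1: float = 0.24
    tau_F: float = 0.100
    K_F: float = 2.0
    delta_F: float = 1.0
    k0: float = 2.0
    kmax: float = 30.0
    tau_D: float = 0.050
    K_D: float = 2.0
    delta_D: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.F1 <= 1.0):
            raise ValueError("F1 must be a probability")
        if min(self.tau_F, self.tau_D) <= 0:
            raise ValueError("time constants must be positive")
        if self.k0 < 0 or self.kmax < self.k0:
            raise ValueError("need kmax >= k0 >= 0")


@dataclass(frozen=True)
class MgBlockParams:
    """NMDA magnesium-block parameters.

    g1 and g2 are the open-channel conductances with one and two glutamate
    molecules bound (pS); alpha is the steepness of the transition between
    them; psi_m the NMDAr-magnesium affinity parameter (dimensionless);
    K0 the magnesium equilibrium constant; delta the electrical distance of
    the block site and z the ionic valence (from the block literature,
    configurable).
    """

    g1: float = 40.0
    g2: float = 247.0
    alpha: float = 0.01
    psi_m: float = 0.8
    mg0: float = 1.0
    K0: float = 3.57
    delta: float = 0.8
    z: float = 2.0
    faraday: float = FARADAY
    gas_constant: float = GAS_CONSTANT
    temperature: float = 273.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.g1 <= self.g2):
            raise ValueError("need g2 >= g1 >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.mg0 < 0:
            raise ValueError("magnesium concentration must be non-negative")


@dataclass
class SynapseConfig:
    """Configuration of the assembled IO synapse."""

    nb_ampa: int = 80
    nb_nmda: int = 20
    v_rev_ampa: float = 0.0      # mV
    v_rev_nmda: float = 0.0      # mV
    release: ReleaseParams = field(default_factory=ReleaseParams)
    mg_block: MgBlockParams = field(default_factory=MgBlockParams)
    ampa_model_path: str | None = None
    nmda_model_path: str | None = None

    def __post_init__(self) -> None:
        if self.nb_ampa < 0 or self.nb_nmda < 0:
            raise ValueError("receptor counts must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SynapseConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        release = ReleaseParams(**d.pop("release", {}))
        mg = MgBlockParams(**d.pop("mg_block", {}))
        return cls(release=release, mg_block=mg, **d)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        d = {
            "nb_ampa": self.nb_ampa, "nb_nmda": self.nb_nmda,
            "v_rev_ampa": self.v_rev_ampa, "v_rev_nmda": self.v_rev_nmda,
            "release": asdict(self.release),
            "mg_block": asdict(self.mg_block),
            "ampa_model_path": self.ampa_model_path,
            "nmda_model_path": self.nmda_model_path,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Presynaptic release
# ---------------------------------------------------------------------------

def release_probabilities(events: EventTrain,
                          params: ReleaseParams) -> np.ndarray:
    """Per-event vesicle release probability from the FD recursion.

    The first event sees the baseline F1 with full recovery (D = 1). The
    inter-event depression recovery integral has the closed form

        int_0^dt k dt = k0*dt + (kmax-k0)*tau_D *
                        ln((CaX_D + K_D) / (CaX_D e^{-dt/tau_D} + K_D)).
    """
    p = params
    times = events.times
    probs = np.empty(times.size)
    caf = 0.0   # CaX_F just before the current event
    cad = 0.0
    D = 1.0
    prev_t = None
    for i, t in enumerate(times):
        if prev_t is not None:
            dt = t - prev_t
            decay_f = math.exp(-dt / p.tau_F)
            decay_d = math.exp(-dt / p.tau_D)
            # recovery of D driven by the decaying CaX_D
            integral = p.k0 * dt + (p.kmax - p.k0) * p.tau_D * math.log(
                (cad + p.K_D) / (cad * decay_d + p.K_D)) if p.K_D > 0 else \
                p.kmax * dt
            D = 1.0 - (1.0 - D) * math.exp(-integral)
            caf *= decay_f
            cad *= decay_d
        F = p.F1 + (1.0 - p.F1) * caf / (caf + p.K_F) if caf > 0 else p.F1
        probs[i] = F * D
        # post-event updates: depletion then indicator increments
        D *= (1.0 - F)
        caf += p.delta_F
        cad += p.delta_D
        prev_t = t
    return probs


def sample_release(events: EventTrain, probs, seed: int,
                   deterministic: bool = False) -> EventTrain:
    """Bernoulli release decision per event.

    One uniform draw per event is compared with the event's probability;
    deterministic given the seed. ``deterministic=True`` forces release on
    every event (the mode used when stochastic release is disabled for
    consistency between runs).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != events.times.shape:
        raise ValueError("one probability per event is required")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if deterministic:
        mask = np.ones(probs.size, dtype=bool)
    else:
        rng = np.random.default_rng(seed)
        mask = rng.random(probs.size) < probs
    return EventTrain(times=events.times[mask], duration=events.duration)


# ---------------------------------------------------------------------------
# NMDA magnesium block
# ---------------------------------------------------------------------------

def nmda_g0(params: MgBlockParams) -> float:
    """Total NMDA conductance in the absence of magnesium (pS)."""
    arg = params.alpha * params.psi_m
    if arg > 700.0:  # logistic saturates; avoid float overflow
        return params.g1
    return params.g1 + (params.g2 - params.g1) / (1.0 + math.exp(arg))


def nmda_gmax(g0: float, params: MgBlockParams,
              psi_m: float | None = None) -> float:
    """Magnesium-blocked maximal conductance (pS).

    Monotone non-increasing in the external magnesium concentration;
    equals g0 exactly at [Mg]0 = 0. ``psi_m`` overrides the fixed affinity
    parameter (the hook for a voltage-dependent block).
    """
    psi = params.psi_m if psi_m is None else psi_m
    expo = math.exp(-params.delta * params.z * params.faraday * psi
                    / (params.gas_constant * params.temperature))
    return g0 / (1.0 + (params.mg0 / params.K0) * expo)


def nmda_conductance(open_state: BinnedSignal, gmax: float) -> BinnedSignal:
    """g_NMDA(t) = gmax * O(t); gmax in pS, output in pS."""
    o = open_state.values
    if np.any((o < -1e-12) | (o > 1.0 + 1e-12)):
        raise ValueError("open-state fraction must lie in [0, 1]")
    return BinnedSignal(dt=open_state.dt, values=gmax * o,
                        t0=open_state.t0)


# ---------------------------------------------------------------------------
# Currents
# ---------------------------------------------------------------------------

def receptor_current(nb: int, g: BinnedSignal, V, v_rev: float) -> BinnedSignal:
    """I(t) = nb * g(t) * (V(t) - Vrev); nS * mV = pA.

    ``V`` may be a scalar clamp value (mV) or an array aligned with ``g``.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim == 1 and V.size != len(g):
        raise ValueError("voltage trace must align with the conductance grid")
    return BinnedSignal(dt=g.dt, values=nb * g.values * (V - v_rev), t0=g.t0)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class SynapseResult:
    """Per-receptor and total current traces plus the release train."""

    releases: EventTrain
    release_probs: np.ndarray
    g_ampa: BinnedSignal          # nS per receptor
    o_nmda: BinnedSignal          # open-state fraction
    i_ampa: BinnedSignal          # pA
    i_nmda: BinnedSignal          # pA

    @property
    def i_total(self) -> BinnedSignal:
        return BinnedSignal(dt=self.i_ampa.dt,
                            values=self.i_ampa.values + self.i_nmda.values,
                            t0=self.i_ampa.t0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.i_ampa.times,
            "I_AMPA_pA": self.i_ampa.values,
            "I_NMDA_pA": self.i_nmda.values,
            "I_total_pA": self.i_total.values,
        })


def run_io_synapse(presyn: EventTrain, config: SynapseConfig,
                   ampa_model: VolterraModel, nmda_model: VolterraModel,
                   V, seed: int = 0, deterministic_release: bool = False,
                   duration: float | None = None,
                   clip_open_state: bool = True) -> SynapseResult:
    """Run the assembled IO synapse on a presynaptic train.

    Pipeline: FD release probabilities -> Bernoulli release sampling (or
    deterministic release) -> AMPA IO conductance and NMDA IO open state ->
    magnesium block -> currents. Fully reproducible given the seed.

    The AMPA model must have been trained on per-receptor conductance (nS);
    the NMDA model on the open-state fraction. ``V`` is a clamp value (mV)
    or a trace aligned with the output grid — the coupling is feed-forward
    (no membrane model is solved).
    """
    probs = release_probabilities(presyn, config.release)
    releases = sample_release(presyn, probs, seed,
                              deterministic=deterministic_release)
    dt = ampa_model.dt
    if duration is None:
        duration = presyn.duration
    n_bins = int(np.floor(duration / dt)) + 1
    x = bin_events(releases, dt, n_bins=n_bins)

    g_ampa = predict(ampa_model, x)
    o_nmda = predict(nmda_model, x)
    o_vals = o_nmda.values
    if clip_open_state:
        # IO predictions can ring slightly outside [0, 1]; clamp for the
        # physical conductance while keeping the raw prediction available.
        o_clamped = BinnedSignal(dt=dt, values=np.clip(o_vals, 0.0, 1.0))
    else:
        o_clamped = o_nmda

    g0 = nmda_g0(config.mg_block)
    gmax = nmda_gmax(g0, config.mg_block)
    g_nmda_ps = nmda_conductance(o_clamped, gmax)
    g_nmda_ns = BinnedSignal(dt=dt, values=g_nmda_ps.values * 1e-3)

    i_ampa = receptor_current(config.nb_ampa, g_ampa, V, config.v_rev_ampa)
    i_nmda = receptor_current(config.nb_nmda, g_nmda_ns, V,
                              config.v_rev_nmda)
    return SynapseResult(releases=releases, release_probs=probs,
                         g_ampa=g_ampa, o_nmda=o_nmda, i_ampa=i_ampa,
                         i_nmda=i_nmda)
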