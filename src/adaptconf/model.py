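"""Decision confidence computed by adaptive neurons in an attractor network.

This module implements a two-pool mean-field attractor model of perceptual
decision making (the standard NMDA-gating reduction of the recurrent cortical
decision circuit) coupled to a pool of "confidence neurons".  The confidence
pool receives the summed firing of both decision pools and is equipped with
spike-frequency adaptation (or, in a variant, short-term synaptic depression
of its recurrent synapses).  Because the adaptation current lags the input
with a slow time constant, the confidence pool effectively measures the slope
of the decision pools' ramping activity: steep ramps (easy trials) outrun the
adaptation and yield high confidence-pool rates at decision time, shallow
ramps (hard trials) let adaptation catch up and yield low rates.  The
confidence-pool rate read out just before the threshold crossing then
reproduces the canonical behavioral signatures of decision confidence.

The file is organised in the order a simulation runs:

1.  parameters, state and stimulus containers;
2.  transfer functions and synaptic currents;
3.  derivatives and the RK2 integration step (with exact Ornstein-Uhlenbeck
    noise updates);
4.  the reaction-time trial protocol: batched trial integration, decision
    detection, confidence readouts;
5.  experiments (sessions x trials) and adaptation-parameter sweeps;
6.  behavioral-signature statistics (accuracy vs. confidence, the folded-X
    pattern, confidence-split psychometric curves, coding slopes);
7.  configuration files, trial-table CSV persistence and plotting helpers.

All randomness flows through explicit integer seeds; a trial is bit-exactly
reproducible from its recorded seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "DEFAULT_COHERENCES",
    "ModelParameters",
    "NetworkState",
    "StimulusSpec",
    "TrialProtocol",
    "TrialResult",
    "ExperimentPlan",
    "SweepResult",
    "RunConfig",
    "phi_decision",
    "phi_confidence",
    "external_input",
    "decision_currents",
    "confidence_current",
    "derivatives",
    "rk2_step",
    "initial_state",
    "run_trial",
    "detect_decision",
    "readout_confidence",
    "run_experiment",
    "run_sweep",
    "derive_trial_seed",
    "accuracy_by_confidence",
    "folded_x",
    "folded_x_permutation_test",
    "psychometric_by_confidence",
    "mean_readout_by_coherence",
    "relative_rc",
    "coding_slope",
    "readout_contrast",
    "load_config",
    "save_config",
    "write_trial_table",
    "read_trial_table",
    "TRIAL_TABLE_COLUMNS",
    "READOUT_COLUMNS",
]

logger = logging.getLogger("adaptconf")

#: Coherence ladder of the random-dot-motion experiments the task emulates, in %.
DEFAULT_COHERENCES: tuple[float, ...] = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)

#: Column order of the trial-table CSV schema.
TRIAL_TABLE_COLUMNS: tuple[str, ...] = (
    "session_id",
    "trial_id",
    "coherence_pct",
    "preferred_pool",
    "choice",
    "correct",
    "decision_time_s",
    "rc",
    "rc_sum",
    "rc_absdiff",
    "rc_totalinput",
    "seed",
)

#: The four candidate confidence readouts carried in a trial table.
READOUT_COLUMNS: tuple[str, ...] = ("rc", "rc_sum", "rc_absdiff", "rc_totalinput")

_VARIANTS = ("adaptation", "std", "none")
_RATE_EQ_MODES = ("relaxation", "literal")

# Number of integration steps whose Gaussian noise increments are drawn from
# each trial's generator in one call.  Fixed so that chunk boundaries (and
# hence the exact noise sequence) do not depend on early termination.
_NOISE_CHUNK = 2000


# ---------------------------------------------------------------------------
# 1. Parameters, state and stimulus containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the circuit model.

    Defaults are the model's standard operating point: the classical
    reduced two-variable decision circuit plus the confidence pool.  Units are
    given per field.  ``adaptation_scale`` and ``std_scale`` are dimensionless
    multipliers on the adaptation conductance ``J_a`` and the release fraction
    ``U_0`` respectively; see the methods note for why these two constants
    are exposed behind scale knobs.
    """

    tau_nmda: float = 0.1      #: NMDA gating decay time constant [s]
    tau_a: float = 0.25        #: adaptation time constant [s]
    tau_r: float = 0.002       #: confidence firing-rate time constant [s]
    tau_d: float = 1.0         #: short-term-depression recovery time constant [s]
    theta: float = 25.0        #: decision threshold [Hz]
    gamma: float = 0.641       #: NMDA gain per spike [dimensionless]
    J_ii: float = 0.2609       #: recurrent self-excitation within a decision pool [nA]
    J_ij: float = 0.0497       #: cross-inhibition between decision pools [nA]
    J_C: float = 0.15          #: recurrent strength among confidence neurons [nA]
    J_fc: float = 0.0002       #: confidence -> decision feedback [nA/Hz]
    J_ext: float = 5.2e-4      #: external stimulus coupling [nA/Hz]
    J_dc: float = 0.015        #: decision -> confidence feedforward coupling [nA/Hz]
    J_a: float = 0.001         #: adaptation current gain [nA per unit of a]
    c_E: float = 270.0         #: F-I curve gain of decision neurons [Hz/nA]
    I_th: float = 108.0        #: F-I curve threshold of decision neurons [Hz]
    g_E: float = 0.154         #: F-I curve noise factor of decision neurons [s]
    I_th_C: float = 108.0      #: F-I curve threshold of confidence neurons [Hz]
    A_1: float = 0.05          #: spike-driven adaptation strength
    A_0: float = 0.03          #: subthreshold adaptation strength
    mu_0: float = 30.0         #: mean external stimulus strength [Hz]
    U_0: float = 0.0001        #: synaptic release fraction of the STD variant
    I_0: float = 0.3255        #: background current to each decision pool [nA]
    I_0c: float = 0.2          #: background current to the confidence pool [nA]
    dt: float = 5e-5           #: integration time step [s]
    noise_sigma: float = 0.01  #: stationary SD of the OU noise currents [nA]
    noise_tau: float = 0.002   #: OU noise correlation time [s]
    variant: str = "adaptation"        #: 'adaptation' | 'std' | 'none'
    rate_eq_mode: str = "relaxation"   #: 'relaxation' | 'literal'
    std_site: str = "feedforward"      #: which synapses depress: 'feedforward' | 'recurrent'
    adaptation_scale: float = 2600.0   #: multiplier on J_a (see methods note)
    std_scale: float = 1000.0          #: multiplier on U_0 (see methods note)

    def __post_init__(self) -> None:
        positive = (
            "tau_nmda", "tau_a", "tau_r", "tau_d", "dt", "gamma", "c_E",
            "theta", "noise_tau",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"ModelParameters.{name} must be strictly positive")
        if not (0.0 < self.U_0 <= 1.0):
            raise ValueError("ModelParameters.U_0 must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("ModelParameters.noise_sigma must be non-negative")
        if self.variant not in _VARIANTS:
            raise ValueError(f"ModelParameters.variant must be one of {_VARIANTS}")
        if self.rate_eq_mode not in _RATE_EQ_MODES:
            raise ValueError(
                f"ModelParameters.rate_eq_mode must be one of {_RATE_EQ_MODES}"
            )
        if self.std_site not in ("feedforward", "recurrent"):
            raise ValueError(
                "ModelParameters.std_site must be 'feedforward' or 'recurrent'"
            )

    @property
    def J_a_eff(self) -> float:
        """Effective adaptation conductance ``J_a * adaptation_scale`` [nA]."""
        return self.J_a * self.adaptation_scale

    @property
    def U_0_eff(self) -> float:
        """Effective release fraction ``U_0 * std_scale`` of the STD variant."""
        return self.U_0 * self.std_scale


@dataclass
class NetworkState:
    """Instantaneous values of every dynamical variable.

    Fields may be scalars or equally-shaped arrays (one entry per trial when
    integrating a batch).  Decision-pool rates ``r_A``/``r_B`` are algebraic
    functions of the currents — the integrator recomputes them from
    :func:`decision_currents` at every sample and stores the result here;
    they are never themselves integrated.
    """

    S_A: np.ndarray | float = 0.0   #: NMDA gating of pool A, in [0, 1]
    S_B: np.ndarray | float = 0.0   #: NMDA gating of pool B, in [0, 1]
    r_A: np.ndarray | float = 0.0   #: pool-A firing rate [Hz] (algebraic)
    r_B: np.ndarray | float = 0.0   #: pool-B firing rate [Hz] (algebraic)
    S_C: np.ndarray | float = 0.0   #: NMDA gating of the confidence pool, in [0, 1]
    r_C: np.ndarray | float = 0.0   #: confidence-pool firing rate [Hz]
    a: np.ndarray | float = 0.0     #: adaptation variable
    x: np.ndarray | float = 1.0     #: STD resource fraction, in (0, 1]
    I_noise_A: np.ndarray | float = 0.0  #: OU noise current into pool A [nA]
    I_noise_B: np.ndarray | float = 0.0  #: OU noise current into pool B [nA]
    I_noise_C: np.ndarray | float = 0.0  #: OU noise current into the C pool [nA]
    t: float = 0.0                  #: simulation time [s]


@dataclass(frozen=True)
class StimulusSpec:
    """A motion stimulus: coherence, which pool it favors, and its epoch."""

    coherence_pct: float = 0.0
    preferred_pool: str = "A"
    onset_s: float = 0.0
    offset_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coherence_pct <= 100.0):
            raise ValueError("StimulusSpec.coherence_pct must lie in [0, 100]")
        if self.preferred_pool not in ("A", "B"):
            raise ValueError("StimulusSpec.preferred_pool must be 'A' or 'B'")
        if not self.onset_s < self.offset_s:
            raise ValueError("StimulusSpec requires onset_s < offset_s")

    @property
    def preferred_sign(self) -> int:
        """+1 when pool A is preferred, -1 when pool B is."""
        return 1 if self.preferred_pool == "A" else -1


def initial_state(params: ModelParameters, n: int | None = None) -> NetworkState:
    """Quiescent initial condition of the network.

    Gating variables start at zero, the STD resource at 1, the adaptation
    variable at its zero-rate fixed point ``tau_a * A_0`` (adaptation variant
    only), and the confidence rate at ``phi_C(I_0c)``.  Noise currents start
    at zero here; the trial simulator replaces them with a draw from the OU
    stationary distribution.  With ``n`` given, every field is an ``(n,)``
    array (one batch lane per trial).
    """
    a0 = params.tau_a * params.A_0 if params.variant == "adaptation" else 0.0
    rc0 = phi_confidence(params.I_0c, params)

    def _f(v: float) -> np.ndarray | float:
        return v if n is None else np.full(n, v, dtype=float)

    return NetworkState(
        S_A=_f(0.0), S_B=_f(0.0), r_A=_f(0.0), r_B=_f(0.0),
        S_C=_f(0.0), r_C=_f(rc0), a=_f(a0), x=_f(1.0),
        I_noise_A=_f(0.0), I_noise_B=_f(0.0), I_noise_C=_f(0.0), t=0.0,
    )


# ---------------------------------------------------------------------------
# 2. Transfer functions and synaptic currents
# ---------------------------------------------------------------------------


def _require_finite(I, name: str) -> np.ndarray:
    arr = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite synaptic current passed to {name}")
    return arr


def _phi_decision_raw(I: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Vectorised decision F-I curve without input validation (hot path)."""
    x = params.c_E * I - params.I_th
    gx = params.g_E * x
    small = np.abs(gx) < 1e-8
    # x/(1 - exp(-g x)) has a removable singularity at x = 0 with limit 1/g;
    # the first-order expansion 1/g + x/2 is exact to O(x^2) there.
    safe_x = np.where(small, 1.0, x)
    expo = np.exp(-np.clip(params.g_E * safe_x, -700.0, 700.0))
    out = np.where(small, 1.0 / params.g_E + x / 2.0, safe_x / (1.0 - expo))
    return np.maximum(out, 0.0)


def phi_decision(I, params: ModelParameters):
    """Input-output (F-I) function of the decision pools.

    ``phi(I) = (c_E I - I_th) / (1 - exp(-g_E (c_E I - I_th)))`` with the
    continuous limit ``1/g_E`` at the removable singularity ``c_E I = I_th``.
    Accepts scalars or arrays of total synaptic current in nA; returns Hz.
    """
    arr = _require_finite(I, "phi_decision")
    out = _phi_decision_raw(arr, params)
    return float(out) if np.ndim(I) == 0 else out


def phi_confidence(I, params: ModelParameters):
    """Input-output function of the confidence pool: ``max(c_E I - I_th_C, 0.5)``.

    The 0.5 Hz floor is the pool's spontaneous rate.
    """
    arr = _require_finite(I, "phi_confidence")
    out = np.maximum(params.c_E * arr - params.I_th_C, 0.5)
    return float(out) if np.ndim(I) == 0 else out


def external_input(stimulus: StimulusSpec, params: ModelParameters):
    """Stimulus currents ``(I_ext_A, I_ext_B)`` in nA, ungated by the epoch.

    The preferred pool receives ``J_ext mu_0 (1 + c/100)``, the other
    ``J_ext mu_0 (1 - c/100)``; their sum is coherence-independent.  Callers
    are responsible for zeroing the current outside the stimulus epoch.
    """
    base = params.J_ext * params.mu_0
    delta = base * stimulus.coherence_pct / 100.0 * stimulus.preferred_sign
    return base + delta, base - delta


def _stimulus_amplitudes(
    coherence_pct: np.ndarray, preferred_sign: np.ndarray, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial ungated stimulus currents for a batch."""
    base = params.J_ext * params.mu_0
    delta = base * coherence_pct / 100.0 * preferred_sign
    return base + delta, base - delta


def decision_currents(
    state: NetworkState,
    stimulus: StimulusSpec | None,
    params: ModelParameters,
    *,
    stimulus_active: bool | None = None,
):
    """Total synaptic currents ``(I_syn_A, I_syn_B)`` into the decision pools.

    ``I_syn_i = J_ii S_i - J_ij S_j + I_0 + I_ext_i + J_fc r_C + I_noise_i``.
    The stimulus term is included when ``stimulus`` is given and the epoch is
    active (by default judged from ``state.t``).
    """
    I_ext_A = I_ext_B = 0.0
    if stimulus is not None:
        if stimulus_active is None:
            stimulus_active = stimulus.onset_s <= state.t < stimulus.offset_s
        if stimulus_active:
            I_ext_A, I_ext_B = external_input(stimulus, params)
    common = params.I_0 + params.J_fc * state.r_C
    I_A = params.J_ii * state.S_A - params.J_ij * state.S_B + common + I_ext_A + state.I_noise_A
    I_B = params.J_ii * state.S_B - params.J_ij * state.S_A + common + I_ext_B + state.I_noise_B
    return I_A, I_B


def confidence_current(state: NetworkState, params: ModelParameters):
    """Total synaptic current into the confidence pool, per model variant.

    adaptation: ``J_C S_C + J_dc (r_A + r_B) + I_0c - J_a_eff a + I_noise_C``
    std:        depression multiplies the decision->confidence drive
                (``J_C S_C + J_dc x (r_A + r_B) + I_0c + I_noise_C``) by
                default, or the recurrent term (``J_C S_C x + ...``) when
                ``std_site == 'recurrent'``
    none:       the adaptation formula with ``a = 0``.

    ``r_A + r_B`` comes from the state's (algebraic) decision rates.
    """
    r_in = state.r_A + state.r_B
    return _confidence_current_from(state.S_C, state.a, state.x, r_in, state.I_noise_C, params)


def _confidence_current_from(S_C, a, x, r_in, I_noise_C, params: ModelParameters):
    recurrent = params.J_C * S_C
    feedforward = params.J_dc * r_in
    adapt = 0.0
    if params.variant == "std":
        if params.std_site == "feedforward":
            feedforward = feedforward * x
        else:
            recurrent = recurrent * x
    elif params.variant == "adaptation":
        adapt = params.J_a_eff * a
    elif params.variant != "none":  # pragma: no cover - guarded by validation
        raise ValueError(f"unknown variant {params.variant!r}")
    return recurrent + feedforward + params.I_0c - adapt + I_noise_C


# ---------------------------------------------------------------------------
# 3. Derivatives and the RK2 step
# ---------------------------------------------------------------------------

# Deterministic state is carried as the tuple (S_A, S_B, S_C, r_C, a, x); the
# three OU noise currents are held frozen during a deterministic step and
# advanced once per step with the exact OU transition.


def _deriv_tuple(y, noise, I_stim_A, I_stim_B, params: ModelParameters):
    """Time derivatives of the deterministic state tuple.

    Returns ``(dy, aux)`` where ``aux = (r_A, r_B, I_A, I_B)`` are the
    instantaneous decision rates and currents used by callers for detection
    and readouts.
    """
    S_A, S_B, S_C, r_C, a, x = y
    n_A, n_B, n_C = noise
    common = params.I_0 + params.J_fc * r_C
    I_A = params.J_ii * S_A - params.J_ij * S_B + common + I_stim_A + n_A
    I_B = params.J_ii * S_B - params.J_ij * S_A + common + I_stim_B + n_B
    r_A = _phi_decision_raw(I_A, params)
    r_B = _phi_decision_raw(I_B, params)
    inv_tau = 1.0 / params.tau_nmda
    dS_A = -S_A * inv_tau + (1.0 - S_A) * params.gamma * r_A
    dS_B = -S_B * inv_tau + (1.0 - S_B) * params.gamma * r_B
    dS_C = -S_C * inv_tau + (1.0 - S_C) * params.gamma * r_C

    r_in = r_A + r_B
    I_C = _confidence_current_from(S_C, a, x, r_in, n_C, params)
    phi_C = np.maximum(params.c_E * I_C - params.I_th_C, 0.5)
    if params.rate_eq_mode == "relaxation":
        dr_C = (phi_C - r_C) / params.tau_r
    else:  # literal leaky form; fixed point tau_r * phi_C
        dr_C = -r_C / params.tau_r + phi_C

    if params.variant == "adaptation":
        da = -a / params.tau_a + params.A_1 * r_C + params.A_0
    else:
        da = np.zeros_like(np.asarray(a, dtype=float))
    if params.variant == "std":
        # depression is driven by the presynaptic rate: the summed decision
        # rates for feedforward depression, the pool's own rate otherwise
        r_pre = r_in if params.std_site == "feedforward" else r_C
        dx = (1.0 - x) / params.tau_d - params.U_0_eff * x * r_pre
    else:
        dx = np.zeros_like(np.asarray(x, dtype=float))
    return (dS_A, dS_B, dS_C, dr_C, da, dx), (r_A, r_B, I_A, I_B)


def _clamp_tuple(y):
    """Clamp gating variables to [0, 1], x to (0, 1], r_C to >= 0."""
    S_A, S_B, S_C, r_C, a, x = y
    return (
        np.clip(S_A, 0.0, 1.0),
        np.clip(S_B, 0.0, 1.0),
        np.clip(S_C, 0.0, 1.0),
        np.maximum(r_C, 0.0),
        a,
        np.clip(x, 1e-12, 1.0),
    )


def _rk2_tuple(y, noise, stim_t, stim_mid, params: ModelParameters, k1=None):
    """One midpoint (RK2) step of the deterministic state.

    ``stim_t`` / ``stim_mid`` are the ``(I_stim_A, I_stim_B)`` pairs at the
    step start and midpoint (epoch gating applied by the caller).  ``k1`` may
    carry a pre-computed derivative at the step start (the simulator reuses
    the rate evaluation of the previous sample).  Returns the clamped next
    state tuple.
    """
    if k1 is None:
        k1, _ = _deriv_tuple(y, noise, stim_t[0], stim_t[1], params)
    half = 0.5 * params.dt
    y_mid = tuple(yi + half * ki for yi, ki in zip(y, k1))
    k2, _ = _deriv_tuple(y_mid, noise, stim_mid[0], stim_mid[1], params)
    y_next = tuple(yi + params.dt * ki for yi, ki in zip(y, k2))
    return _clamp_tuple(y_next)


def _ou_update(noise, xi, params: ModelParameters):
    """Exact discrete transition of the OU noise currents over one step.

    ``I(t+dt) = I(t) e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) xi`` with
    ``xi ~ N(0,1)``; the update is distribution-exact for any dt.
    """
    decay = math.exp(-params.dt / params.noise_tau)
    amp = params.noise_sigma * math.sqrt(1.0 - decay * decay)
    return tuple(n * decay + amp * z for n, z in zip(noise, xi))


def _state_to_tuple(state: NetworkState):
    return (state.S_A, state.S_B, state.S_C, state.r_C, state.a, state.x)


def derivatives(
    state: NetworkState,
    stimulus: StimulusSpec | None,
    params: ModelParameters,
    noise_frozen: bool = True,
) -> dict[str, np.ndarray | float]:
    """Time derivatives of every state variable, as a name -> value mapping.

    The stimulus epoch is gated on ``state.t``.  With ``noise_frozen`` the OU
    currents contribute zero derivative (they are advanced separately by the
    exact update in :func:`rk2_step`); otherwise their deterministic
    mean-reversion drift ``-I/noise_tau`` is reported, which is what a
    fixed-point solver of the noise-free system needs.

    Raises a numerical-failure error naming the variable if any derivative is
    not finite.
    """
    active = (
        stimulus is not None and stimulus.onset_s <= state.t < stimulus.offset_s
    )
    stim = external_input(stimulus, params) if active else (0.0, 0.0)
    y = _state_to_tuple(state)
    noise = (state.I_noise_A, state.I_noise_B, state.I_noise_C)
    dy, _ = _deriv_tuple(y, noise, stim[0], stim[1], params)
    names = ("S_A", "S_B", "S_C", "r_C", "a", "x")
    out: dict[str, np.ndarray | float] = dict(zip(names, dy))
    if noise_frozen:
        out["I_noise_A"] = out["I_noise_B"] = out["I_noise_C"] = (
            np.zeros_like(np.asarray(state.S_A, dtype=float))
            if np.ndim(state.S_A)
            else 0.0
        )
    else:
        out["I_noise_A"] = -np.asarray(state.I_noise_A) / params.noise_tau
        out["I_noise_B"] = -np.asarray(state.I_noise_B) / params.noise_tau
        out["I_noise_C"] = -np.asarray(state.I_noise_C) / params.noise_tau
    for name, value in out.items():
        if not np.all(np.isfinite(value)):
            raise FloatingPointError(
                f"non-finite derivative of {name} at t={state.t:.6f}s"
            )
    return out


def rk2_step(
    state: NetworkState,
    stimulus: StimulusSpec | None,
    params: ModelParameters,
    noise_increments: Sequence = (0.0, 0.0, 0.0),
) -> NetworkState:
    """Advance the network one time step ``dt``.

    The deterministic part uses the midpoint second-order Runge-Kutta rule
    with the noise currents frozen at their start-of-step values; the noise
    currents are then advanced with the exact OU transition driven by the
    three supplied standard-normal increments (pools A, B, C).  Gating
    variables are clamped to their admissible ranges after the step.
    """
    t0 = state.t

    def _stim_at(t: float):
        if stimulus is not None and stimulus.onset_s <= t < stimulus.offset_s:
            return external_input(stimulus, params)
        return (0.0, 0.0)

    y = _state_to_tuple(state)
    noise = (state.I_noise_A, state.I_noise_B, state.I_noise_C)
    y_next = _rk2_tuple(y, noise, _stim_at(t0), _stim_at(t0 + 0.5 * params.dt), params)
    for name, value in zip(("S_A", "S_B", "S_C", "r_C", "a", "x"), y_next):
        if not np.all(np.isfinite(value)):
            raise FloatingPointError(f"non-finite value of {name} after step at t={t0:.6f}s")
    noise_next = _ou_update(noise, tuple(noise_increments), params)
    # refresh the algebraic decision rates at the new sample
    _, aux = _deriv_tuple(y_next, noise_next, *_stim_at(t0 + params.dt), params)
    return NetworkState(
        S_A=y_next[0], S_B=y_next[1], r_A=aux[0], r_B=aux[1],
        S_C=y_next[2], r_C=y_next[3], a=y_next[4], x=y_next[5],
        I_noise_A=noise_next[0], I_noise_B=noise_next[1], I_noise_C=noise_next[2],
        t=t0 + params.dt,
    )


# ---------------------------------------------------------------------------
# 4. Trial protocol, batched integration, decision detection, readouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialProtocol:
    """Timeline and detection rules of one reaction-time trial.

    Time zero is stimulus onset.  The network settles from its quiescent
    state during the 200 ms pre-stimulus epoch, the biased stimulus is on for
    one second, and threshold crossings are accepted until ``detect_until``
    (by default the end of the trial, since the slow NMDA dynamics can carry
    a pool over threshold shortly after stimulus offset).
    """

    t_start: float = -0.2
    stim_onset: float = 0.0
    stim_offset: float = 1.0
    t_end: float = 1.5
    theta: float = 25.0        #: decision threshold [Hz]
    rc_window: float = 0.010   #: confidence-averaging window before decision [s]
    detect_until: float | None = None  #: latest accepted decision time (None = t_end)

    def __post_init__(self) -> None:
        du = self.t_end if self.detect_until is None else self.detect_until
        if not (self.t_start < self.stim_onset < self.stim_offset <= du <= self.t_end):
            raise ValueError(
                "TrialProtocol requires t_start < stim_onset < stim_offset"
                " <= detect_until <= t_end"
            )
        if not self.rc_window > 0:
            raise ValueError("TrialProtocol.rc_window must be positive")

    @property
    def detection_deadline(self) -> float:
        return self.t_end if self.detect_until is None else self.detect_until


@dataclass
class TrialResult:
    """Outcome of a single trial."""

    session_id: int
    trial_id: int
    coherence_pct: float
    preferred_pool: str
    choice: str                    #: 'A', 'B' or 'none'
    correct: bool | None           #: None when choice == 'none'
    decision_time_s: float | None  #: seconds from stimulus onset
    rc: float | None               #: confidence readout [Hz]
    rc_sum: float | None           #: r_A + r_B readout [Hz]
    rc_absdiff: float | None       #: |r_A - r_B| readout [Hz]
    rc_totalinput: float | None    #: I_syn_A + I_syn_B readout [nA]
    seed: int
    traces: dict[str, np.ndarray] | None = None


def derive_trial_seed(
    master_seed: int,
    session_id: int,
    trial_id: int,
    namespace: tuple[int, ...] = (),
) -> int:
    """Deterministic per-trial seed.

    The counter scheme hashes ``(master_seed, *namespace, session_id,
    trial_id)`` through :class:`numpy.random.SeedSequence` and keeps 31 bits,
    so every trial (and every sweep cell, via ``namespace``) owns an
    independent, reproducible stream.
    """
    ss = np.random.SeedSequence((int(master_seed), *map(int, namespace),
                                 int(session_id), int(trial_id)))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _simulate_batch(
    params: ModelParameters,
    protocol: TrialProtocol,
    coherence_pct: np.ndarray,
    preferred_sign: np.ndarray,
    seeds: Sequence[int],
    store_traces: bool = False,
) -> dict[str, np.ndarray]:
    """Integrate many trials in lock-step and detect their decisions online.

    Every trial owns its own RNG (seeded from ``seeds``); noise is drawn in
    fixed-size chunks so the per-trial noise sequence is independent of the
    batch composition and of early termination — a batch of one reproduces
    :func:`run_trial` bit-exactly.  Integration stops once every trial has
    decided (unless traces are stored).
    """
    n = len(seeds)
    coherence_pct = np.asarray(coherence_pct, dtype=float)
    preferred_sign = np.asarray(preferred_sign, dtype=float)
    if coherence_pct.shape != (n,) or preferred_sign.shape != (n,):
        raise ValueError("coherence_pct, preferred_sign and seeds must have equal length")
    if np.any(coherence_pct < 0) or np.any(coherence_pct > 100):
        raise ValueError("coherence_pct must lie in [0, 100]")

    dt = params.dt
    n_steps = int(round((protocol.t_end - protocol.t_start) / dt))
    W = int(round(protocol.rc_window / dt))  # 0 => point sample at the decision
    buf_len = max(W, 1) + 1
    theta = protocol.theta

    rngs = [np.random.default_rng(np.random.SeedSequence(int(s))) for s in seeds]

    init = initial_state(params, n=n)
    y = _state_to_tuple(init)
    # stationary OU draw for the initial noise currents
    init_noise = np.stack([rng.standard_normal(3) for rng in rngs])  # (n, 3)
    noise = tuple(params.noise_sigma * init_noise[:, j] for j in range(3))

    amp_A, amp_B = _stimulus_amplitudes(coherence_pct, preferred_sign, params)
    zeros = np.zeros(n)

    def _stim(t: float):
        if protocol.stim_onset <= t < protocol.stim_offset:
            return amp_A, amp_B
        return zeros, zeros

    # rolling sample buffers for the windowed readouts
    buf_rc = np.zeros((buf_len, n))
    buf_rA = np.zeros((buf_len, n))
    buf_rB = np.zeros((buf_len, n))
    buf_I = np.zeros((buf_len, n))

    undecided = np.ones(n, dtype=bool)
    choice_is_A = np.zeros(n, dtype=bool)
    decision_time = np.full(n, np.nan)
    out_rc = np.full(n, np.nan)
    out_sum = np.full(n, np.nan)
    out_absdiff = np.full(n, np.nan)
    out_total = np.full(n, np.nan)
    win_rate = np.full(n, np.nan)
    win_rate_prev = np.full(n, np.nan)

    traces: dict[str, np.ndarray] | None = None
    if store_traces:
        traces = {
            "t": protocol.t_start + dt * np.arange(n_steps + 1),
            "r_A": np.zeros((n, n_steps + 1)),
            "r_B": np.zeros((n, n_steps + 1)),
            "r_C": np.zeros((n, n_steps + 1)),
            "S_A": np.zeros((n, n_steps + 1)),
            "S_B": np.zeros((n, n_steps + 1)),
            "a": np.zeros((n, n_steps + 1)),
            "x": np.zeros((n, n_steps + 1)),
        }

    def _record(sample: int, r_A, r_B):
        slot = sample % buf_len
        buf_rc[slot] = y[3]
        buf_rA[slot] = r_A
        buf_rB[slot] = r_B
        buf_I[slot] = aux_I
        if traces is not None:
            traces["r_A"][:, sample] = r_A
            traces["r_B"][:, sample] = r_B
            traces["r_C"][:, sample] = y[3]
            traces["S_A"][:, sample] = y[0]
            traces["S_B"][:, sample] = y[1]
            traces["a"][:, sample] = y[4]
            traces["x"][:, sample] = y[5]

    # derivative and rates at sample 0 (start of the pre-stimulus epoch)
    t0 = protocol.t_start
    k1, aux = _deriv_tuple(y, noise, *_stim(t0), params)
    aux_I = aux[2] + aux[3]
    _record(0, aux[0], aux[1])

    xi = None
    onset = protocol.stim_onset
    deadline = protocol.detection_deadline
    for k in range(n_steps):
        if k % _NOISE_CHUNK == 0:
            xi = np.stack([rng.standard_normal((_NOISE_CHUNK, 3)) for rng in rngs])
        t = protocol.t_start + k * dt
        y = _rk2_tuple(y, noise, _stim(t), _stim(t + 0.5 * dt), params, k1=k1)
        z = xi[:, k % _NOISE_CHUNK, :]
        noise = _ou_update(noise, (z[:, 0], z[:, 1], z[:, 2]), params)

        sample = k + 1
        t_s = protocol.t_start + sample * dt
        k1, aux = _deriv_tuple(y, noise, *_stim(t_s), params)
        r_A, r_B = aux[0], aux[1]
        aux_I = aux[2] + aux[3]
        if not np.all(np.isfinite(y[3])):
            raise FloatingPointError(f"non-finite r_C at t={t_s:.6f}s")
        _record(sample, r_A, r_B)

        if t_s > onset and t_s <= deadline + 0.5 * dt and undecided.any():
            r_max = np.maximum(r_A, r_B)
            newly = undecided & (r_max >= theta)
            if newly.any():
                idx = np.nonzero(newly)[0]
                undecided[idx] = False
                t_dec = t_s - onset
                m = min(W, int(round(t_dec / dt)))  # window clipped at onset
                slots = [(sample - j) % buf_len for j in range(m + 1)]
                for i in idx:
                    a_rate, b_rate = r_A[i], r_B[i]
                    is_A = a_rate >= b_rate  # tie broken to the larger rate, then A
                    choice_is_A[i] = is_A
                    decision_time[i] = t_dec
                    w_rc = buf_rc[slots, i]
                    w_rA = buf_rA[slots, i]
                    w_rB = buf_rB[slots, i]
                    w_I = buf_I[slots, i]
                    out_rc[i] = w_rc.mean()
                    out_sum[i] = (w_rA + w_rB).mean()
                    out_absdiff[i] = np.abs(w_rA - w_rB).mean()
                    out_total[i] = w_I.mean()
                    win_rate[i] = a_rate if is_A else b_rate
                    prev = (sample - 1) % buf_len
                    win_rate_prev[i] = buf_rA[prev, i] if is_A else buf_rB[prev, i]
        if not store_traces and not undecided.any():
            break

    choice = np.where(undecided, "none", np.where(choice_is_A, "A", "B"))
    preferred = np.where(preferred_sign > 0, "A", "B")
    out = {
        "choice": choice,
        "preferred_pool": preferred,
        "correct": np.where(undecided, np.nan, (choice == preferred).astype(float)),
        "decision_time_s": decision_time,
        "rc": out_rc,
        "rc_sum": out_sum,
        "rc_absdiff": out_absdiff,
        "rc_totalinput": out_total,
        "win_rate": win_rate,
        "win_rate_prev": win_rate_prev,
    }
    if traces is not None:
        out["traces"] = traces  # type: ignore[assignment]
    return out


def run_trial(
    params: ModelParameters,
    protocol: TrialProtocol,
    stimulus: StimulusSpec,
    seed: int,
    store_traces: bool = False,
    session_id: int = 0,
    trial_id: int = 0,
) -> TrialResult:
    """Simulate one reaction-time trial.

    The trial is bit-exactly reproducible from ``(params, protocol, stimulus,
    seed)``.  The stimulus epoch of ``stimulus`` is overridden by the
    protocol's onset/offset so that trial timing has a single source of truth.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    res = _simulate_batch(
        params,
        protocol,
        np.array([stimulus.coherence_pct]),
        np.array([float(stimulus.preferred_sign)]),
        [seed],
        store_traces=store_traces,
    )
    decided = res["choice"][0] != "none"
    trace = None
    if store_traces:
        raw = res["traces"]
        trace = {k: (v[0] if k != "t" else v) for k, v in raw.items()}
    return TrialResult(
        session_id=session_id,
        trial_id=trial_id,
        coherence_pct=stimulus.coherence_pct,
        preferred_pool=stimulus.preferred_pool,
        choice=str(res["choice"][0]),
        correct=bool(res["correct"][0]) if decided else None,
        decision_time_s=float(res["decision_time_s"][0]) if decided else None,
        rc=float(res["rc"][0]) if decided else None,
        rc_sum=float(res["rc_sum"][0]) if decided else None,
        rc_absdiff=float(res["rc_absdiff"][0]) if decided else None,
        rc_totalinput=float(res["rc_totalinput"][0]) if decided else None,
        seed=seed,
        traces=trace,
    )


def detect_decision(
    r_a: np.ndarray,
    r_b: np.ndarray,
    protocol: TrialProtocol,
    dt: float,
) -> tuple[str, float] | None:
    """Threshold-crossing decision rule applied to rate traces.

    Traces are sampled every ``dt`` starting at ``protocol.t_start``.  Returns
    ``(choice, decision_time)`` — time measured from stimulus onset — for the
    first sample strictly after onset and no later than ``detect_until`` at
    which ``max(r_A, r_B) >= theta``; ``None`` if no crossing.  A tie at the
    crossing sample is broken by the larger rate, then lexicographically (A).
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.shape != r_b.shape or r_a.ndim != 1:
        raise ValueError("r_a and r_b must be 1-D traces of equal length")
    t = protocol.t_start + dt * np.arange(len(r_a))
    eligible = (t > protocol.stim_onset) & (t <= protocol.detection_deadline + 0.5 * dt)
    crossing = eligible & (np.maximum(r_a, r_b) >= protocol.theta)
    idx = np.nonzero(crossing)[0]
    if len(idx) == 0:
        return None
    k = int(idx[0])
    choice = "A" if r_a[k] >= r_b[k] else "B"
    return choice, float(t[k] - protocol.stim_onset)


def readout_confidence(
    r_c: np.ndarray,
    decision_time: float,
    protocol: TrialProtocol,
    dt: float,
) -> float:
    """Mean confidence-pool rate over the window preceding the decision.

    The window is ``[decision_time - rc_window, decision_time]`` (times from
    stimulus onset, inclusive of both endpoint samples); for decisions earlier
    than one window length after onset it is clipped at onset.
    """
    r_c = np.asarray(r_c, dtype=float)
    t_dec_abs = protocol.stim_onset + decision_time
    k_dec = int(round((t_dec_abs - protocol.t_start) / dt))
    if k_dec < 0 or k_dec >= len(r_c) or decision_time <= 0:
        raise ValueError("decision_time outside the sampled trace")
    W = int(round(protocol.rc_window / dt))  # 0 => point sample at the decision
    m = min(W, int(round(decision_time / dt)))
    return float(r_c[k_dec - m : k_dec + 1].mean())


# ---------------------------------------------------------------------------
# 5. Experiments and parameter sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentPlan:
    """A batch of sessions: the unit the behavioral statistics are built on.

    Sessions differ only by their RNG streams; they are resampling units for
    the error bars.  Within a session, trial ``k`` is assigned coherence
    ``coherences[k % len(coherences)]`` with the preferred pool alternating
    per cycle through the coherence list, so both pools and all coherences are
    balanced.  ``variant`` (if set) overrides ``ModelParameters.variant``.
    """

    coherences: tuple[float, ...] = DEFAULT_COHERENCES
    trials_per_session: int = 500
    n_sessions: int = 10
    master_seed: int = 0
    variant: str | None = None
    sweep_a0: tuple[float, ...] | None = None
    sweep_a1: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.trials_per_session < 1 or self.n_sessions < 1:
            raise ValueError("trials_per_session and n_sessions must be >= 1")
        if len(self.coherences) == 0:
            raise ValueError("ExperimentPlan.coherences must be non-empty")
        if any(not (0.0 <= c <= 100.0) for c in self.coherences):
            raise ValueError("all coherences must lie in [0, 100]")
        if self.variant is not None and self.variant not in _VARIANTS:
            raise ValueError(f"ExperimentPlan.variant must be one of {_VARIANTS}")
        if (self.sweep_a0 is None) != (self.sweep_a1 is None):
            raise ValueError("sweep_a0 and sweep_a1 must be given together")


def _session_layout(plan: ExperimentPlan) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (coherence, preferred_sign) assignment within one session."""
    n_coh = len(plan.coherences)
    idx = np.arange(plan.trials_per_session)
    coh = np.asarray(plan.coherences, dtype=float)[idx % n_coh]
    sign = np.where((idx // n_coh) % 2 == 0, 1.0, -1.0)
    return coh, sign


def run_experiment(
    plan: ExperimentPlan,
    params: ModelParameters | None = None,
    protocol: TrialProtocol | None = None,
    store_traces: bool = False,
    seed_namespace: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Run every trial of the plan and return the flat trial table.

    One row per trial in the CSV schema (see :data:`TRIAL_TABLE_COLUMNS`).
    No-decision trials are retained with ``choice == 'none'`` and missing
    outcome fields.  Per-trial seeds come from :func:`derive_trial_seed`, so
    the table is bit-identical across runs of the same plan.
    """
    params = params or ModelParameters()
    protocol = protocol or TrialProtocol(theta=params.theta)
    if plan.variant is not None and plan.variant != params.variant:
        params = replace(params, variant=plan.variant)
    frames = []
    for session in range(plan.n_sessions):
        coh, sign = _session_layout(plan)
        seeds = [
            derive_trial_seed(plan.master_seed, session, t, namespace=seed_namespace)
            for t in range(plan.trials_per_session)
        ]
        res = _simulate_batch(params, protocol, coh, sign, seeds, store_traces=store_traces)
        n_none = int((res["choice"] == "none").sum())
        logger.info(
            "session %d/%d: %d trials, %d without decision",
            session + 1, plan.n_sessions, plan.trials_per_session, n_none,
        )
        frames.append(
            pd.DataFrame(
                {
                    "session_id": session,
                    "trial_id": np.arange(plan.trials_per_session),
                    "coherence_pct": coh,
                    "preferred_pool": res["preferred_pool"],
                    "choice": res["choice"],
                    "correct": res["correct"],
                    "decision_time_s": res["decision_time_s"],
                    "rc": res["rc"],
                    "rc_sum": res["rc_sum"],
                    "rc_absdiff": res["rc_absdiff"],
                    "rc_totalinput": res["rc_totalinput"],
                    "seed": seeds,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table[list(TRIAL_TABLE_COLUMNS)]


@dataclass
class SweepResult:
    """Coding-capacity map over the adaptation-parameter grid.

    ``slopes[i, j]`` is the OLS slope of mean relative rc against coherence at
    ``(a0_values[i], a1_values[j])``; ``cells`` holds the per-cell,
    per-coherence means.  Grid iteration is row-major over (A_0, A_1).
    """

    a0_values: tuple[float, ...]
    a1_values: tuple[float, ...]
    cells: pd.DataFrame
    slopes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV-ready view: one row per (A_0, A_1, coherence)."""
        out = self.cells.copy()
        out["slope"] = [
            self.slopes[i, j] for i, j in zip(out["a0_index"], out["a1_index"])
        ]
        return out


def run_sweep(
    plan: ExperimentPlan,
    params: ModelParameters | None = None,
    protocol: TrialProtocol | None = None,
) -> SweepResult:
    """Grid sweep of the adaptation parameters (A_0, A_1).

    Each cell runs a full experiment with seeds namespaced by the cell's grid
    indices, so cells are mutually independent and individually reproducible.
    """
    if plan.sweep_a0 is None or plan.sweep_a1 is None:
        raise ValueError("run_sweep requires plan.sweep_a0 and plan.sweep_a1")
    params = params or ModelParameters()
    protocol = protocol or TrialProtocol(theta=params.theta)
    rows = []
    slopes = np.zeros((len(plan.sweep_a0), len(plan.sweep_a1)))
    for i, a0 in enumerate(plan.sweep_a0):
        for j, a1 in enumerate(plan.sweep_a1):
            cell_params = replace(params, A_0=a0, A_1=a1)
            logger.info("sweep cell A_0=%g, A_1=%g", a0, a1)
            table = run_experiment(
                plan, cell_params, protocol, seed_namespace=(i, j)
            )
            means = mean_readout_by_coherence(table, "rc")
            rel = relative_rc(means)
            slopes[i, j] = coding_slope(rel)
            for c in rel.index:
                rows.append(
                    {
                        "a0_index": i,
                        "a1_index": j,
                        "A_0": a0,
                        "A_1": a1,
                        "coherence_pct": c,
                        "mean_rc": means.loc[c],
                        "relative_rc": rel.loc[c],
                    }
                )
    return SweepResult(
        a0_values=tuple(plan.sweep_a0),
        a1_values=tuple(plan.sweep_a1),
        cells=pd.DataFrame(rows),
        slopes=slopes,
    )


# ---------------------------------------------------------------------------
# 6. Behavioral-signature statistics
# ---------------------------------------------------------------------------


def _decided(table: pd.DataFrame, undecided: str = "exclude") -> pd.DataFrame:
    """Trials entering the statistics.

    ``undecided='exclude'`` drops no-decision trials (the default);
    ``'error'`` keeps them scored as incorrect with their readouts missing.
    """
    if undecided == "exclude":
        out = table[table["choice"] != "none"].copy()
    elif undecided == "error":
        out = table.copy()
        out.loc[out["choice"] == "none", "correct"] = 0.0
    else:
        raise ValueError("undecided must be 'exclude' or 'error'")
    out["correct"] = out["correct"].astype(float)
    return out


def _session_se(values: pd.Series) -> float:
    """Standard error across session means (NaN-skipping)."""
    v = values.dropna().to_numpy()
    if len(v) < 2:
        return float("nan")
    return float(np.std(v, ddof=1) / math.sqrt(len(v)))


def accuracy_by_confidence(
    table: pd.DataFrame,
    readout: str = "rc",
    n_bins: int = 5,
    undecided: str = "exclude",
) -> pd.DataFrame:
    """Choice accuracy per confidence bin.

    Decided trials are binned by readout quantiles pooled across coherences
    (equal-count bins); each bin reports the pooled accuracy, the standard
    error across sessions, and its trial count.  Bins that receive no trials
    (possible with heavily tied readouts) are flagged with ``n == 0`` and
    missing accuracy.
    """
    dec = _decided(table, undecided).dropna(subset=[readout])
    if len(dec) == 0:
        raise ValueError("no decided trials to bin")
    dec = dec.copy()
    dec["bin"] = pd.qcut(dec[readout].rank(method="first"), n_bins, labels=False)
    rows = []
    n_sessions = table["session_id"].nunique()
    for b in range(n_bins):
        sub = dec[dec["bin"] == b]
        if len(sub) == 0:
            rows.append({"bin": b, "lo": np.nan, "hi": np.nan,
                         "accuracy": np.nan, "se": np.nan, "n": 0})
            continue
        per_session = sub.groupby("session_id")["correct"].mean()
        rows.append(
            {
                "bin": b,
                "lo": sub[readout].min(),
                "hi": sub[readout].max(),
                "accuracy": sub["correct"].mean(),
                "se": _session_se(per_session.reindex(range(n_sessions))),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def folded_x(
    table: pd.DataFrame,
    readout: str = "rc",
    min_n: int = 5,
    undecided: str = "exclude",
) -> pd.DataFrame:
    """Mean readout versus coherence, split by correctness (the folded X).

    For confidence-like readouts the correct branch increases with evidence
    strength while the error branch decreases.  Cells with fewer than
    ``min_n`` trials (error trials vanish at high coherence) are flagged.
    """
    dec = _decided(table, undecided).dropna(subset=[readout])
    rows = []
    for (c, corr), sub in dec.groupby(["coherence_pct", "correct"]):
        per_session = sub.groupby("session_id")[readout].mean()
        rows.append(
            {
                "coherence_pct": c,
                "correct": bool(corr),
                "mean": sub[readout].mean(),
                "se": _session_se(per_session),
                "n": len(sub),
                "flagged": len(sub) < min_n,
            }
        )
    return pd.DataFrame(rows).sort_values(["correct", "coherence_pct"]).reset_index(drop=True)


def _branch_trial_spearman(coh, readout, correct) -> tuple[float, float]:
    """Trial-level Spearman rho of readout vs coherence, per branch."""
    out = []
    for want in (1.0, 0.0):
        mask = correct == want
        if mask.sum() < 3 or len(np.unique(coh[mask])) < 2:
            out.append(float("nan"))
            continue
        out.append(float(stats.spearmanr(coh[mask], readout[mask]).statistic))
    return out[0], out[1]


def folded_x_permutation_test(
    table: pd.DataFrame,
    readout: str = "rc",
    n_perm: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation test of the folded-X signature.

    The branch statistics are the trial-level Spearman correlations of the
    readout with coherence among correct trials (expected positive) and
    among error trials (expected negative).  Because any readout that merely
    tracks coherence makes *both* branches trend the same way, the
    significance test targets the fold itself: the interaction statistic
    ``rho_correct - rho_error``, under the null that correct/error labels are
    exchangeable within each coherence (labels are permuted within coherence,
    which preserves the readout-coherence relation while destroying any
    branch difference).  ``p_interaction`` is the one-sided
    ``P(diff_perm >= diff_obs)``.
    """
    dec = _decided(table).dropna(subset=[readout])
    coh = dec["coherence_pct"].to_numpy()
    val = dec[readout].to_numpy()
    lab = dec["correct"].to_numpy()
    rho_c, rho_e = _branch_trial_spearman(coh, val, lab)
    diff_obs = rho_c - rho_e
    rng = np.random.default_rng(seed)
    order = np.argsort(coh, kind="stable")
    groups = np.split(order, np.unique(coh[order], return_index=True)[1][1:])
    ge = 0
    n_valid = 0
    for _ in range(n_perm):
        perm_lab = lab.copy()
        for g in groups:
            perm_lab[g] = lab[rng.permutation(g)]
        pc, pe = _branch_trial_spearman(coh, val, perm_lab)
        if np.isnan(pc) or np.isnan(pe):
            continue
        n_valid += 1
        if pc - pe >= diff_obs:
            ge += 1
    return {
        "rho_correct": rho_c,
        "rho_error": rho_e,
        "interaction": diff_obs,
        "p_interaction": (1 + ge) / (1 + n_valid) if n_valid else float("nan"),
    }


def psychometric_by_confidence(
    table: pd.DataFrame,
    readout: str = "rc",
    split: str = "within",
    undecided: str = "exclude",
) -> pd.DataFrame:
    """Accuracy versus coherence for high- versus low-confidence trials.

    Trials are split at the median of the readout — within each coherence by
    default (``split='within'``), so the split is not confounded by the
    readout-coherence correlation; ``split='global'`` uses one pooled median.
    Trials at or below the median go to the low half (so with an odd count the
    median trial is low).  Returns accuracy, session SE and n per
    (coherence, group).
    """
    dec = _decided(table, undecided).dropna(subset=[readout]).copy()
    if split == "within":
        med = dec.groupby("coherence_pct")[readout].transform("median")
    elif split == "global":
        med = pd.Series(dec[readout].median(), index=dec.index)
    else:
        raise ValueError("split must be 'within' or 'global'")
    dec["group"] = np.where(dec[readout] > med, "high", "low")
    rows = []
    for (c, g), sub in dec.groupby(["coherence_pct", "group"]):
        per_session = sub.groupby("session_id")["correct"].mean()
        rows.append(
            {
                "coherence_pct": c,
                "group": g,
                "accuracy": sub["correct"].mean(),
                "se": _session_se(per_session),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows).sort_values(["group", "coherence_pct"]).reset_index(drop=True)


def mean_readout_by_coherence(
    table: pd.DataFrame, readout: str = "rc", undecided: str = "exclude"
) -> pd.Series:
    """Per-coherence mean of a readout over decided trials."""
    dec = _decided(table, undecided).dropna(subset=[readout])
    return dec.groupby("coherence_pct")[readout].mean()


def relative_rc(means: pd.Series) -> pd.Series:
    """Readout means re-referenced to the zero-coherence mean.

    Subtracting the chance-level (c = 0) value removes the baseline offset
    that different adaptation strengths induce, leaving the coherence
    dependence proper.  Requires c = 0 in the index.
    """
    if 0.0 not in means.index:
        raise ValueError("relative_rc requires the c = 0 coherence level")
    return means - means.loc[0.0]


def coding_slope(rel: pd.Series) -> float:
    """Coding capacity: OLS slope of mean relative readout on coherence (%).

    Units Hz per % coherence.  Zero slope means the confidence pool fires
    identically across difficulties, i.e. carries no confidence information.
    """
    if len(rel) < 2:
        raise ValueError("coding_slope requires at least two coherence levels")
    res = stats.linregress(rel.index.to_numpy(dtype=float), rel.to_numpy(dtype=float))
    return float(res.slope)


def readout_contrast(
    table: pd.DataFrame,
    readouts: Sequence[str] = READOUT_COLUMNS,
    n_perm: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Folded-X scorecard comparing the candidate confidence readouts.

    For each readout, reports the branch correlations, the interaction (fold)
    statistic and its permutation p-value, plus a boolean ``passes``: correct
    branch increasing, error branch decreasing, fold significant at p < 0.05.
    In the default regime the confidence-pool readout and |r_A - r_B| carry
    the confidence signature while r_A + r_B and the total decision input do
    not.
    """
    rows = []
    for r in readouts:
        res = folded_x_permutation_test(table, r, n_perm=n_perm, seed=seed)
        res["readout"] = r
        res["passes"] = bool(
            res["rho_correct"] > 0
            and res["rho_error"] < 0
            and res["p_interaction"] < 0.05
        )
        rows.append(res)
    return pd.DataFrame(rows)[
        ["readout", "rho_correct", "rho_error", "interaction", "p_interaction", "passes"]
    ]


# ---------------------------------------------------------------------------
# 7. Configuration, persistence, plotting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration (model + protocol + plan + output)."""

    params: ModelParameters = field(default_factory=ModelParameters)
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    plan: ExperimentPlan = field(default_factory=ExperimentPlan)
    out_dir: str = "adaptconf_out"
    store_traces: bool = False
    log_level: str = "INFO"


_CONFIG_SECTIONS: dict[str, type | None] = {
    "model": ModelParameters,
    "protocol": TrialProtocol,
    "experiment": ExperimentPlan,
    "output": None,
}
_OUTPUT_KEYS = {"directory", "store_traces", "log_level"}
_TUPLE_KEYS = {"coherences", "sweep_a0", "sweep_a1"}


def _build_section(cls, data: Mapping, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown key '{section}.{key}' in config")
        if key in _TUPLE_KEYS and value is not None:
            value = tuple(float(v) for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    The document has up to four mappings — ``model``, ``protocol``,
    ``experiment``, ``output`` — whose keys are the corresponding dataclass
    fields (``output`` takes ``directory``, ``store_traces``, ``log_level``).
    Every unspecified field keeps its default; unknown sections or keys are
    rejected naming the offender.  An empty file yields the default config.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config root must be a mapping of sections")
    for section in raw:
        if section not in _CONFIG_SECTIONS:
            raise ValueError(f"unknown section '{section}' in config")
    params = _build_section(ModelParameters, raw.get("model", {}) or {}, "model")
    protocol = _build_section(TrialProtocol, raw.get("protocol", {}) or {}, "protocol")
    plan = _build_section(ExperimentPlan, raw.get("experiment", {}) or {}, "experiment")
    out = raw.get("output", {}) or {}
    for key in out:
        if key not in _OUTPUT_KEYS:
            raise ValueError(f"unknown key 'output.{key}' in config")
    return RunConfig(
        params=params,
        protocol=protocol,
        plan=plan,
        out_dir=str(out.get("directory", RunConfig.out_dir)),
        store_traces=bool(out.get("store_traces", False)),
        log_level=str(out.get("log_level", "INFO")),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML (round-trips with
    :func:`load_config`)."""
    doc = {
        "model": dataclasses.asdict(config.params),
        "protocol": dataclasses.asdict(config.protocol),
        "experiment": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config.plan).items()
        },
        "output": {
            "directory": config.out_dir,
            "store_traces": config.store_traces,
            "log_level": config.log_level,
        },
    }
    doc["model"] = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in doc["model"].items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table to CSV in the canonical schema.

    Missing values become empty fields; ``correct`` is written as True/False.
    """
    out = table[list(TRIAL_TABLE_COLUMNS)].copy()
    out["correct"] = out["correct"].map(
        lambda v: "" if pd.isna(v) else str(bool(v))
    )
    for col in ("coherence_pct", "decision_time_s", *READOUT_COLUMNS):
        # repr() is the shortest exactly round-tripping decimal form
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep="")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read a trial-table CSV; the inverse of :func:`write_trial_table`."""
    table = pd.read_csv(
        path,
        dtype={"preferred_pool": str, "choice": str},
        converters={"correct": lambda v: np.nan if v == "" else float(v == "True")},
        float_precision="round_trip",
    )
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {', '.join(missing)}")
    return table[list(TRIAL_TABLE_COLUMNS)]


def plot_confidence_signatures(table: pd.DataFrame, readout: str = "rc", path=None):
    """Three-panel summary: accuracy vs confidence bin, the folded X, and the
    confidence-split psychometric curves.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    acc = accuracy_by_confidence(table, readout)
    axes[0].errorbar(acc["bin"], acc["accuracy"], yerr=acc["se"], marker="o")
    axes[0].set_xlabel(f"{readout} quantile bin")
    axes[0].set_ylabel("accuracy")

    fx = folded_x(table, readout)
    for corr, style in ((True, "-o"), (False, "--s")):
        sub = fx[fx["correct"] == corr]
        axes[1].errorbar(sub["coherence_pct"], sub["mean"], yerr=sub["se"],
                         fmt=style, label="correct" if corr else "error")
    axes[1].set_xlabel("coherence (%)")
    axes[1].set_ylabel(f"mean {readout}")
    axes[1].legend()

    psy = psychometric_by_confidence(table, readout)
    for g, style in (("high", "-o"), ("low", "--s")):
        sub = psy[psy["group"] == g]
        axes[2].errorbar(sub["coherence_pct"], sub["accuracy"], yerr=sub["se"],
                         fmt=style, label=g)
    axes[2].set_xlabel("coherence (%)")
    axes[2].set_ylabel("accuracy")
    axes[2].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_coding_slope_map(sweep: SweepResult, path=None):
    """Heat map of the coding slope over the (A_0, A_1) grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.8))
    im = ax.imshow(sweep.slopes, origin="lower", aspect="auto")
    ax.set_xticks(range(len(sweep.a1_values)), [f"{v:g}" for v in sweep.a1_values])
    ax.set_yticks(range(len(sweep.a0_values)), [f"{v:g}" for v in sweep.a0_values])
    ax.set_xlabel("A_1")
    ax.set_ylabel("A_0")
    fig.colorbar(im, ax=ax, label="coding slope (Hz / % coherence)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
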