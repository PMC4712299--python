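"""Point-neuron models and fixed-step integrators.

Four classic point-neuron models are provided — leaky integrate-and-fire
(LIF), adaptive exponential integrate-and-fire (aEIF), Izhikevich, and
Hodgkin-Huxley (HH) — together with Euler and classical 4th-order
Runge-Kutta steppers that advance them over the engine's fixed 1 ms grid,
optionally subdivided into finer substeps.

Conventions
-----------
Membrane potential is in mV and time in ms throughout.  The aEIF model uses
pF / nS / pA units (so gL·V is in pA and C dV/dt balances); LIF, Izhikevich
and HH use the dimensionless-current conventions of their original
formulations, and injected amplitudes are interpreted in each model's native
input units.

Each model exposes a scalar/broadcastable derivative (or update) function —
the reference form used by tests — and a vectorized ``NeuronBlock`` that
holds per-neuron state and parameter arrays and advances a whole population
at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as _dataclass_fields
from typing import Callable

import numpy as np

#: Upper clamp on the aEIF exponential argument, preventing overflow once the
#: membrane potential passes the numerical spike ceiling.
EXP_ARG_CLAMP = 20.0


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

@dataclass
class AEIFParams:
    """Adaptive exponential integrate-and-fire parameters (pF/nS/mV/ms/pA).

    Defaults are the standard regular-spiking parameter set of the model's
    original publication.  ``Vr``, ``b_adapt`` and ``Vpeak`` complete the
    reset rule: on V crossing ``Vpeak`` the potential is reset to ``Vr`` and
    the adaptation current is incremented by ``b_adapt``.
    """

    C: float = 281.0        # membrane capacitance, pF
    gL: float = 30.0        # leak conductance, nS
    EL: float = -70.6       # leak reversal potential, mV
    VT: float = -50.4       # spike threshold, mV
    DeltaT: float = 2.0     # slope factor, mV
    a: float = 4.0          # subthreshold adaptation coupling, nS
    tau_w: float = 144.0    # adaptation time constant, ms
    Vr: float = -70.6       # reset potential, mV
    b_adapt: float = 80.5   # spike-triggered adaptation increment, pA
    Vpeak: float = 0.0      # numerical spike-detection ceiling, mV

    def validate(self):
        if not (np.all(np.asarray(self.C) > 0) and np.all(np.asarray(self.gL) > 0)
                and np.all(np.asarray(self.DeltaT) > 0) and np.all(np.asarray(self.tau_w) > 0)):
            raise ValueError("aEIF requires C, gL, DeltaT, tau_w > 0")
        if not np.all(np.asarray(self.Vpeak) > np.asarray(self.VT)):
            raise ValueError("aEIF requires Vpeak > VT")


@dataclass
class IzhikevichParams:
    """Canonical two-variable quadratic model parameters.

    Defaults are the regular-spiking cortical set (a=0.02, b=0.2, c=-65,
    d=8); fast-spiking inhibitory neurons use a=0.1, d=2.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    Vpeak: float = 30.0     # spike cutoff, mV

    def validate(self):
        for f in _dataclass_fields(self):
            if not np.all(np.isfinite(np.asarray(getattr(self, f.name), dtype=float))):
                raise ValueError(f"Izhikevich parameter {f.name} must be finite")


@dataclass
class LIFParams:
    """Leaky integrate-and-fire parameters."""

    tau_m: float = 20.0     # membrane time constant, ms
    EL: float = -65.0       # resting potential, mV
    Vth: float = -50.0      # spike threshold, mV
    Vr: float = -65.0       # reset potential, mV
    R: float = 1.0          # input resistance (mV per unit input current)

    def validate(self):
        if not np.all(np.asarray(self.tau_m) > 0):
            raise ValueError("LIF requires tau_m > 0")
        if not np.all(np.asarray(self.Vth) > np.asarray(self.Vr)):
            raise ValueError("LIF requires Vth > Vr")


@dataclass
class HHParams:
    """Hodgkin-Huxley squid-axon parameters (mV, ms, mS/cm^2, uA/cm^2)."""

    Cm: float = 1.0
    gNa: float = 120.0
    gK: float = 36.0
    gLeak: float = 0.3
    ENa: float = 50.0
    EK: float = -77.0
    ELeak: float = -54.387

    def validate(self):
        if not np.all(np.asarray(self.Cm) > 0):
            raise ValueError("HH requires Cm > 0")
        for name in ("gNa", "gK", "gLeak"):
            if not np.all(np.asarray(getattr(self, name)) >= 0):
                raise ValueError(f"HH requires {name} >= 0")


# ---------------------------------------------------------------------------
# Derivative functions (reference forms; broadcast over arrays)
# ---------------------------------------------------------------------------

def deriv_aeif(state, I, p: AEIFParams):
    """(dV/dt, dw/dt) of the adaptive exponential integrate-and-fire model.

    The exponential argument is clamped at ``EXP_ARG_CLAMP`` so trajectories
    past the spike ceiling stay finite until the reset rule fires.
    """
    V, w = state
    arg = np.minimum((V - p.VT) / p.DeltaT, EXP_ARG_CLAMP)
    dV = (-p.gL * (V - p.EL) + p.gL * p.DeltaT * np.exp(arg) - w + I) / p.C
    dw = (p.a * (V - p.EL) - w) / p.tau_w
    return dV, dw


def deriv_lif(V, I, p: LIFParams):
    """dV/dt of the leaky integrate-and-fire model (reset handled separately)."""
    return (-(V - p.EL) + p.R * I) / p.tau_m


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the singularity at x=0 filled by its limit y."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / y))
    return np.where(small, y, out)


def hh_rates(V, which):
    """Voltage-dependent opening/closing rates (alpha, beta) for gate m, h or n."""
    if which == "m":
        return 0.1 * _vtrap(V + 40.0, 10.0), 4.0 * np.exp(-(V + 65.0) / 18.0)
    if which == "h":
        return 0.07 * np.exp(-(V + 65.0) / 20.0), 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    if which == "n":
        return 0.01 * _vtrap(V + 55.0, 10.0), 0.125 * np.exp(-(V + 65.0) / 80.0)
    raise ValueError(f"unknown gate {which!r}")


def hh_steady_state(V, which):
    """Steady-state activation alpha/(alpha+beta) of a gate; always in [0, 1]."""
    alpha, beta = hh_rates(V, which)
    return alpha / (alpha + beta)


def deriv_hh(state, I, p: HHParams):
    """Derivatives of the canonical Hodgkin-Huxley membrane and gating system."""
    V, m, h, n = state
    am, bm = hh_rates(V, "m")
    ah, bh = hh_rates(V, "h")
    an, bn = hh_rates(V, "n")
    INa = p.gNa * m ** 3 * h * (V - p.ENa)
    IK = p.gK * n ** 4 * (V - p.EK)
    IL = p.gLeak * (V - p.ELeak)
    dV = (I - INa - IK - IL) / p.Cm
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dV, dm, dh, dn


def step_izhikevich(state, I, p: IzhikevichParams, dt=1.0, v_substeps=2):
    """Advance the Izhikevich model by one dt, returning (v, u, fired).

    The membrane equation v' = 0.04 v^2 + 5 v + 140 - u + I is advanced in
    ``v_substeps`` Euler substeps (two 0.5 ms half-steps per 1 ms step by
    default, the original model's practice), the recovery variable
    u' = a (b v - u) once per step.  Spike detection and reset (v <- c,
    u <- u + d) are applied at the end of the step, so immediately after a
    flagged spike v equals c exactly and u equals its continuous update
    plus d.
    """
    v = np.asarray(state[0], dtype=float).copy()
    u = np.asarray(state[1], dtype=float).copy()
    h = dt / v_substeps
    for _ in range(v_substeps):
        v += h * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u += (p.a * (p.b * v - u)) * dt
    fired = v >= p.Vpeak
    if np.any(fired):
        v = np.where(fired, p.c * np.ones_like(v), v)
        u = np.where(fired, u + p.d, u)
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(np.atleast_1d(v)))[0])
        raise FloatingPointError(f"Izhikevich state diverged (neuron index {bad})")
    return v, u, fired


# ---------------------------------------------------------------------------
# Integrators
# ---------------------------------------------------------------------------

@dataclass
class IntegratorConfig:
    method: str = "rk4"     # "euler" | "rk4"
    dt_ms: float = 1.0      # outer step (the engine's grid)
    substeps: int = 1       # inner subdivisions per outer step

    def validate(self):
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")


def _advance(deriv_fn: Callable, y: tuple, I, h: float, method: str) -> tuple:
    """One substep of size h; y is a tuple of state arrays."""
    if method == "euler":
        k1 = deriv_fn(y, I)
        return tuple(s + h * k for s, k in zip(y, k1))
    # classical RK4
    k1 = deriv_fn(y, I)
    y2 = tuple(s + 0.5 * h * k for s, k in zip(y, k1))
    k2 = deriv_fn(y2, I)
    y3 = tuple(s + 0.5 * h * k for s, k in zip(y, k2))
    k3 = deriv_fn(y3, I)
    y4 = tuple(s + h * k for s, k in zip(y, k3))
    k4 = deriv_fn(y4, I)
    return tuple(
        s + (h / 6.0) * (a + 2.0 * b + 2.0 * c + d)
        for s, a, b, c, d in zip(y, k1, k2, k3, k4)
    )


def integrate_step(deriv_fn, state, I, config: IntegratorConfig):
    """Advance a smooth ODE state by one outer step of ``config.dt_ms``.

    Applies the chosen method ``config.substeps`` times with step
    dt_ms/substeps.  Threshold detection and resets are the caller's
    responsibility (the neuron blocks interleave them between substeps).
    """
    config.validate()
    h = config.dt_ms / config.substeps
    y = tuple(np.asarray(s, dtype=float) for s in state)
    for _ in range(config.substeps):
        y = _advance(deriv_fn, y, I, h, config.method)
    return y


# ---------------------------------------------------------------------------
# Vectorized population blocks
# ---------------------------------------------------------------------------

def _per_neuron(populations, name):
    return np.concatenate(
        [np.full(p.size, float(p.params[name])) for p in populations]
    )


class NeuronBlock:
    """Per-neuron state + parameters for a contiguous run of populations.

    Subclasses implement ``step(I) -> fired`` advancing all neurons by one
    1 ms step, applying spike detection and reset, and raising
    ``FloatingPointError`` (naming the first offending local index) on
    numerical blow-up.
    """

    model_id: str = ""

    def __init__(self, n: int):
        self.n = n

    @property
    def V(self) -> np.ndarray:  # membrane potential view, for recording
        raise NotImplementedError

    def step(self, I: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _check_finite(self, arr):
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise FloatingPointError(
                f"{self.model_id} state diverged at neuron index {bad}"
            )


class LIFBlock(NeuronBlock):
    model_id = "lif"

    def __init__(self, populations, integrator: IntegratorConfig | None = None):
        super().__init__(sum(p.size for p in populations))
        self.p = LIFParams(**{f.name: _per_neuron(populations, f.name)
                              for f in _dataclass_fields(LIFParams)})
        self.p.validate()
        self._V = self.p.EL.copy()
        self.cfg = integrator or IntegratorConfig("rk4", 1.0, 1)

    @property
    def V(self):
        return self._V

    def step(self, I):
        h = self.cfg.dt_ms / self.cfg.substeps
        fired = np.zeros(self.n, dtype=bool)
        deriv = lambda y, cur: (deriv_lif(y[0], cur, self.p),)
        for _ in range(self.cfg.substeps):
            (self._V,) = _advance(deriv, (self._V,), I, h, self.cfg.method)
            sub = self._V >= self.p.Vth
            if np.any(sub):
                self._V[sub] = self.p.Vr[sub]
                fired |= sub
        self._check_finite(self._V)
        return fired


class AEIFBlock(NeuronBlock):
    model_id = "aeif"

    def __init__(self, populations, integrator: IntegratorConfig | None = None):
        super().__init__(sum(p.size for p in populations))
        self.p = AEIFParams(**{f.name: _per_neuron(populations, f.name)
                               for f in _dataclass_fields(AEIFParams)})
        self.p.validate()
        self._V = self.p.EL.copy()
        self.w = np.zeros(self.n)
        self.cfg = integrator or IntegratorConfig("rk4", 1.0, 2)

    @property
    def V(self):
        return self._V

    def step(self, I):
        h = self.cfg.dt_ms / self.cfg.substeps
        fired = np.zeros(self.n, dtype=bool)
        deriv = lambda y, cur: deriv_aeif(y, cur, self.p)
        for _ in range(self.cfg.substeps):
            self._V, self.w = _advance(deriv, (self._V, self.w), I, h, self.cfg.method)
            sub = self._V >= self.p.Vpeak
            if np.any(sub):
                self._V[sub] = self.p.Vr[sub]
                self.w[sub] += self.p.b_adapt[sub]
                fired |= sub
        self._check_finite(self._V)
        self._check_finite(self.w)
        return fired


class IzhikevichBlock(NeuronBlock):
    model_id = "izhikevich"

    def __init__(self, populations, integrator: IntegratorConfig | None = None):
        super().__init__(sum(p.size for p in populations))
        self.p = IzhikevichParams(**{f.name: _per_neuron(populations, f.name)
                                     for f in _dataclass_fields(IzhikevichParams)})
        self.p.validate()
        self.v = np.full(self.n, -65.0)
        self.u = self.p.b * self.v
        cfg = integrator or IntegratorConfig("euler", 1.0, 2)
        self.dt = cfg.dt_ms
        self.v_substeps = cfg.substeps
        self._scr = np.empty(self.n)  # scratch; the step loop is allocation-lean

    @property
    def V(self):
        return self.v

    def step(self, I):
        v, u, p, s = self.v, self.u, self.p, self._scr
        h = self.dt / self.v_substeps
        for _ in range(self.v_substeps):
            # s <- h * (0.04 v^2 + 5 v + 140 - u + I), with the same floating
            # point evaluation order as the scalar reference step
            np.multiply(v, 0.04, out=s)
            s *= v
            s += 5.0 * v
            s += 140.0
            s -= u
            s += I
            s *= h
            v += s
        # u <- u + (a (b v - u)) dt, again matching the scalar reference
        np.multiply(v, p.b, out=s)
        s -= u
        s *= p.a
        s *= self.dt
        u += s
        fired = v >= p.Vpeak
        if np.any(fired):
            v[fired] = p.c[fired]
            u[fired] += p.d[fired]
        self._check_finite(v)
        return fired


class HHBlock(NeuronBlock):
    model_id = "hh"
    spike_threshold_mv = 0.0  # upward crossing of 0 mV counts as a spike

    def __init__(self, populations, integrator: IntegratorConfig | None = None):
        super().__init__(sum(p.size for p in populations))
        self.p = HHParams(**{f.name: _per_neuron(populations, f.name)
                             for f in _dataclass_fields(HHParams)})
        self.p.validate()
        self._V = np.full(self.n, -65.0)
        self.m = hh_steady_state(self._V, "m")
        self.h_gate = hh_steady_state(self._V, "h")
        self.n_gate = hh_steady_state(self._V, "n")
        self.cfg = integrator or IntegratorConfig("rk4", 1.0, 20)

    @property
    def V(self):
        return self._V

    def step(self, I):
        h = self.cfg.dt_ms / self.cfg.substeps
        fired = np.zeros(self.n, dtype=bool)
        deriv = lambda y, cur: deriv_hh(y, cur, self.p)
        thr = self.spike_threshold_mv
        for _ in range(self.cfg.substeps):
            prev = self._V
            state = _advance(deriv, (self._V, self.m, self.h_gate, self.n_gate),
                             I, h, self.cfg.method)
            self._V, m, hg, ng = state
            if (np.any(m < 0) or np.any(m > 1) or np.any(hg < 0) or np.any(hg > 1)
                    or np.any(ng < 0) or np.any(ng > 1)):
                warnings.warn("HH gating variable left [0, 1]; clipping",
                              RuntimeWarning, stacklevel=2)
                m, hg, ng = np.clip(m, 0, 1), np.clip(hg, 0, 1), np.clip(ng, 0, 1)
            self.m, self.h_gate, self.n_gate = m, hg, ng
            fired |= (prev < thr) & (self._V >= thr)
        self._check_finite(self._V)
        return fired


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

@dataclass
class ModelInfo:
    params_cls: type
    block_cls: type


MODEL_REGISTRY: dict[str, ModelInfo] = {
    "lif": ModelInfo(LIFParams, LIFBlock),
    "aeif": ModelInfo(AEIFParams, AEIFBlock),
    "izhikevich": ModelInfo(IzhikevichParams, IzhikevichBlock),
    "hh": ModelInfo(HHParams, HHBlock),
}


def model_param_names(model_id: str) -> set[str]:
    if model_id not in MODEL_REGISTRY:
        raise KeyError(f"unknown neuron model {model_id!r}")
    return {f.name for f in _dataclass_fields(MODEL_REGISTRY[model_id].params_cls)}


def default_params(model_id: str, **overrides) -> dict:
    """Complete parameter map for a model, with optional overrides."""
    if model_id not in MODEL_REGISTRY:
        raise KeyError(f"unknown neuron model {model_id!r}")
    cls = MODEL_REGISTRY[model_id].params_cls
    params = {f.name: f.default for f in _dataclass_fields(cls)}
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown parameters for {model_id}: {sorted(unknown)}")
    params.update(overrides)
    return params
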