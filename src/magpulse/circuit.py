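"""Capacitor-discharge pulse-coil circuit engine.

A magnetic pulser fires by discharging a charged capacitor bank through the
pulse coil.  During the on-phase the circuit is a series RLC loop: the coil
current obeys

    L I'' + R I' + I/C = 0,    I(0) = 0,    I'(0) = U0 / L,

whose closed-form solution is sampled here in all three damping regimes.  The
magnetic field at the (fixed) position of the bird's head is proportional to
the coil current, ``B(t) = k_field * I(t)``, and the voltage a pickup coil
sees is the Faraday term ``U(t) = -a_eff * dB/dt``.  Shut-off is modelled per
device generation: the first-generation pulser chops the current with a fast
switch (approximated as a linear ramp of configurable fall time), while the
second-generation circuit drains the coil energy through a flyback diode,
giving an exponential decay with relaxation time ``tau = L / R``.

Units: SI internally (V, F, H, ohm, s, A); magnetic fields are expressed in
mT via the current-to-field factor ``k_field`` (mT per A), because that is the
unit in which peak fields and switching thresholds are quoted in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidParameterError,
    ResolutionError,
)

# ---------------------------------------------------------------------------
# Numerical constants
# ---------------------------------------------------------------------------

#: Default sampling step (s); resolves a 0.1 ms sham pulse with 100 samples.
DEFAULT_GRID_STEP = 1e-6

#: Relative discriminant width treated as critical damping, to avoid
#: catastrophic cancellation between nearly equal exponentials.
CRITICAL_DAMPING_RTOL = 1e-9

#: Flyback tail is truncated once the current falls below this fraction of
#: the on-phase peak.
FLYBACK_TRUNCATION = 1e-4

#: Fraction of the on-phase used for the least-squares onset-rate fit.
ONSET_FIT_FRACTION = 0.05


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseCircuit:
    """Electrical parameters of one pulser generation.

    Parameters
    ----------
    u0 : float
        Initial capacitor voltage (V).
    capacitance : float
        Capacitance of the discharge bank (F).
    inductance : float
        Pulse-coil inductance (H).
    r_total : float
        Equivalent series resistance during discharge (ohm).  The coil ESR
        dominates; the milliohm on-resistance of the switch is folded in.
    k_field : float
        Current-to-field conversion at the bird position (mT per A).
    t_d : float
        Programmed pulse duration (s): the time at which the switch opens.
    shutoff_model : {"linear_ramp", "flyback_exponential"}
        How the current is brought to zero after ``t_d``.
    fall_time : float
        Ramp duration (s) of the ``linear_ramp`` shut-off.
    r_on : float
        Switch on-resistance (ohm); informational, already part of r_total.
    """

    u0: float
    capacitance: float
    inductance: float
    r_total: float
    k_field: float = 24.0
    t_d: float = 9e-3
    shutoff_model: str = "linear_ramp"
    fall_time: float = 0.69e-3
    r_on: float = 0.024

    def __post_init__(self) -> None:
        for name in ("u0", "capacitance", "inductance", "r_total",
                     "k_field", "t_d", "fall_time"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if self.u0 < 0:
            raise InvalidParameterError("u0 must be >= 0")
        if self.capacitance <= 0 or self.inductance <= 0:
            raise InvalidParameterError("capacitance and inductance must be > 0")
        if self.r_total < 0:
            raise InvalidParameterError("r_total must be >= 0")
        if self.k_field <= 0:
            raise InvalidParameterError("k_field must be > 0")
        if self.t_d <= 0:
            raise InvalidParameterError("t_d must be > 0")
        if self.shutoff_model not in ("linear_ramp", "flyback_exponential"):
            raise ConfigurationError(
                f"unknown shutoff model {self.shutoff_model!r}")
        if self.shutoff_model == "linear_ramp" and self.fall_time <= 0:
            raise InvalidParameterError("fall_time must be > 0 for linear_ramp")

    @property
    def alpha(self) -> float:
        """Damping rate R / 2L (1/s)."""
        return self.r_total / (2.0 * self.inductance)

    @property
    def omega0(self) -> float:
        """Undamped resonance frequency 1 / sqrt(LC) (rad/s)."""
        return 1.0 / math.sqrt(self.inductance * self.capacitance)

    @property
    def tau_flyback(self) -> float:
        """Flyback relaxation time L / R (s)."""
        if self.r_total == 0:
            raise InvalidParameterError("flyback time constant undefined for R=0")
        return self.inductance / self.r_total


@dataclass(frozen=True)
class PickupCoil:
    """Induction probe: effective area times turns, in V per (T/s)."""

    a_eff: float

    def __post_init__(self) -> None:
        if not (self.a_eff > 0 and math.isfinite(self.a_eff)):
            raise InvalidParameterError("a_eff must be finite and > 0")


@dataclass
class PulseWaveform:
    """Sampled pulse: time grid (s), coil current (A), field at the bird (mT).

    ``phase_marks`` records switch-on time, shut-off start and effective end.
    The field is tied to the current through the circuit's ``k_field``, so
    ``b = k_field * i`` holds pointwise by construction.
    """

    t: np.ndarray
    i: np.ndarray
    k_field: float
    phase_marks: dict = field(default_factory=dict)

    @property
    def b(self) -> np.ndarray:
        """Magnetic field at the bird position (mT)."""
        return self.k_field * self.i

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.shape != self.i.shape:
            raise InvalidParameterError("t and i must have equal shape")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise InvalidParameterError("time grid must be strictly increasing")


@dataclass(frozen=True)
class PulseMetrics:
    """Scalar summary of one pulse waveform.

    Rates are quoted per millisecond (A/ms, mT/ms) to match how pulser
    characteristics are reported.  ``provenance`` distinguishes modelled
    metrics from ones entered from bench measurements.
    """

    i_peak: float
    t_peak: float
    b_peak: float
    onset_current_rate: float
    onset_field_rate: float
    shutoff_current_rate: float
    on_duration: float
    off_duration: float
    provenance: str = "modelled"


# ---------------------------------------------------------------------------
# Closed-form on-phase solution
# ---------------------------------------------------------------------------

def _on_phase_current_fn(circuit: PulseCircuit) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form I(t) of the series RLC discharge, valid on [0, t_d].

    The damping regime is selected by comparing alpha = R/2L with
    omega0 = 1/sqrt(LC); a relative gap below ``CRITICAL_DAMPING_RTOL`` is
    treated as critically damped to avoid cancellation between the two
    nearly-equal exponentials.
    """
    u0, L = circuit.u0, circuit.inductance
    a, w0 = circuit.alpha, circuit.omega0

    if abs(a - w0) <= CRITICAL_DAMPING_RTOL * w0:
        def current(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            return (u0 / L) * t * np.exp(-a * t)
    elif a > w0:  # overdamped: two real decay rates
        beta = math.sqrt(a * a - w0 * w0)
        s_slow, s_fast = a - beta, a + beta

        def current(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            return (u0 / (2.0 * L * beta)) * (
                np.exp(-s_slow * t) - np.exp(-s_fast * t))
    else:  # underdamped (includes R = 0): damped sinusoid
        wd = math.sqrt(w0 * w0 - a * a)

        def current(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            return (u0 / (L * wd)) * np.exp(-a * t) * np.sin(wd * t)

    return current


def on_phase_peak_time(circuit: PulseCircuit) -> float:
    """Time (s) of the unconstrained on-phase current maximum."""
    a, w0 = circuit.alpha, circuit.omega0
    if abs(a - w0) <= CRITICAL_DAMPING_RTOL * w0:
        return 1.0 / a
    if a > w0:
        beta = math.sqrt(a * a - w0 * w0)
        s_slow, s_fast = a - beta, a + beta
        return math.log(s_fast / s_slow) / (s_fast - s_slow)
    wd = math.sqrt(w0 * w0 - a * a)
    # first zero of d/dt [e^{-at} sin(wd t)]
    return math.atan2(wd, a) / wd


def initial_current_rate(circuit: PulseCircuit) -> float:
    """Initial current slope U0/L, expressed in A/ms.

    At t = 0 the capacitor voltage sits fully across the inductor, so the
    current rises at U0/L regardless of R and C; this is what makes a
    truncated sham pulse share the treatment pulse's onset dB/dt.
    """
    if circuit.inductance <= 0:
        raise InvalidParameterError("inductance must be > 0")
    return circuit.u0 / circuit.inductance / 1e3


def solve_discharge(circuit: PulseCircuit,
                    grid_step: float = DEFAULT_GRID_STEP) -> PulseWaveform:
    """Sample the on-phase current on [0, t_d].

    Parameters
    ----------
    circuit : PulseCircuit
    grid_step : float
        Sampling step (s).  Must be positive and no coarser than t_d / 50.

    Returns
    -------
    PulseWaveform
        On-phase only; ``phase_marks`` has ``switch_on=0`` and
        ``shutoff_start=t_d``.
    """
    if not (grid_step > 0 and math.isfinite(grid_step)):
        raise ResolutionError("grid_step must be positive and finite")
    if grid_step > circuit.t_d / 50.0:
        raise ResolutionError(
            f"grid_step {grid_step:g} s too coarse for t_d={circuit.t_d:g} s "
            "(need at least 50 samples)")

    n = int(math.floor(circuit.t_d / grid_step))
    t = np.arange(n + 1) * grid_step
    if t[-1] < circuit.t_d - 1e-15:
        t = np.append(t, circuit.t_d)
    i = _on_phase_current_fn(circuit)(t)
    i[0] = 0.0
    return PulseWaveform(
        t=t, i=i, k_field=circuit.k_field,
        phase_marks={"switch_on": 0.0, "shutoff_start": circuit.t_d},
    )


# ---------------------------------------------------------------------------
# Shut-off phase
# ---------------------------------------------------------------------------

def apply_shutoff(waveform: PulseWaveform, circuit: PulseCircuit) -> PulseWaveform:
    """Append the generation-specific shut-off tail to an on-phase waveform.

    ``linear_ramp`` chops the current linearly to zero over
    ``circuit.fall_time``; ``flyback_exponential`` decays it with time
    constant L/R, truncated when the current drops below
    ``FLYBACK_TRUNCATION`` of the on-phase peak.
    """
    t_d = waveform.phase_marks.get("shutoff_start", waveform.t[-1])
    i_d = float(waveform.i[-1])
    i_max = float(np.max(waveform.i)) if waveform.i.size else 0.0
    step = float(waveform.t[1] - waveform.t[0]) if waveform.t.size > 1 else DEFAULT_GRID_STEP

    if circuit.shutoff_model == "linear_ramp":
        n = max(int(math.ceil(circuit.fall_time / step)), 2)
        t_tail = t_d + np.arange(1, n + 1) * (circuit.fall_time / n)
        i_tail = i_d * (1.0 - np.arange(1, n + 1) / n)
    elif circuit.shutoff_model == "flyback_exponential":
        tau = circuit.tau_flyback
        if i_d <= 0 or i_max <= 0:
            t_tail = t_d + np.array([step])
            i_tail = np.array([0.0])
        else:
            floor = max(FLYBACK_TRUNCATION * i_max, 1e-300)
            t_end = tau * math.log(i_d / floor) if i_d > floor else step
            n = max(int(math.ceil(t_end / step)), 2)
            t_tail = t_d + np.arange(1, n + 1) * (t_end / n)
            i_tail = i_d * np.exp(-(t_tail - t_d) / tau)
    else:  # pragma: no cover - blocked by PulseCircuit validation
        raise ConfigurationError(f"unknown shutoff model {circuit.shutoff_model!r}")

    marks = dict(waveform.phase_marks)
    marks["shutoff_start"] = t_d
    marks["effective_end"] = float(t_tail[-1])
    return PulseWaveform(
        t=np.concatenate([waveform.t, t_tail]),
        i=np.concatenate([waveform.i, np.maximum(i_tail, 0.0)]),
        k_field=waveform.k_field,
        phase_marks=marks,
    )


def simulate_pulse(circuit: PulseCircuit,
                   grid_step: float = DEFAULT_GRID_STEP) -> PulseWaveform:
    """Full pulse: on-phase plus shut-off tail."""
    return apply_shutoff(solve_discharge(circuit, grid_step), circuit)


# ---------------------------------------------------------------------------
# Faraday pickup and metrics
# ---------------------------------------------------------------------------

def induced_voltage(waveform: PulseWaveform, pickup: PickupCoil) -> np.ndarray:
    """Voltage trace U(t) = -a_eff * dB/dt (V) seen by a pickup coil.

    dB/dt is computed by central differences on the waveform grid
    (one-sided at the boundaries); B is converted from mT to T so the
    result is in volts when ``a_eff`` is in V per (T/s).
    """
    if waveform.t.size < 3:
        raise ResolutionError("need at least 3 samples to differentiate")
    dbdt = np.gradient(waveform.b * 1e-3, waveform.t)
    return -pickup.a_eff * dbdt


def waveform_metrics(waveform: PulseWaveform,
                     circuit: PulseCircuit | None = None,
                     onset_window: float | None = None) -> PulseMetrics:
    """Extract scalar pulse metrics from a sampled waveform.

    Onset rates come from a least-squares slope over the first
    ``ONSET_FIT_FRACTION`` of the on-phase, or over ``onset_window`` seconds
    when given.  When comparing a truncated sham against its treatment
    pulse, pass the same window (5% of the shorter on-phase) to both so the
    fitted onset rates are commensurable.  The shut-off rate magnitude is
    the mean descent slope for a ramp shut-off and the initial decay rate
    I_d / tau for a flyback shut-off (the conventionally quoted figure).
    """
    if waveform.t.size == 0:
        raise InvalidParameterError("empty waveform")
    i = waveform.i
    t = waveform.t
    ipk_idx = int(np.argmax(i))
    i_peak = float(i[ipk_idx])
    t_peak = float(t[ipk_idx]) if i_peak > 0 else 0.0

    t_off = waveform.phase_marks.get("shutoff_start", t[-1])
    on = t <= t_off + 1e-15

    # onset slope: least squares through the first 5% of the on-phase
    # (or through the caller-supplied window)
    if onset_window is not None:
        n_fit = int(np.sum(t[on] <= onset_window))
    else:
        n_fit = int(np.sum(on) * ONSET_FIT_FRACTION)
    n_fit = min(max(n_fit, 3), int(np.sum(on)))
    if n_fit >= 2 and i_peak > 0:
        slope = float(np.polyfit(t[:n_fit], i[:n_fit], 1)[0]) / 1e3  # A/ms
    else:
        slope = 0.0

    # shut-off rate magnitude
    off_mask = t > t_off + 1e-15
    if np.any(off_mask) and i_peak > 0:
        i_d = float(i[on][-1])
        t_end = waveform.phase_marks.get("effective_end", t[-1])
        if circuit is not None and circuit.shutoff_model == "flyback_exponential":
            shut_rate = i_d / circuit.tau_flyback / 1e3
        else:
            dur = t_end - t_off
            shut_rate = (i_d / dur / 1e3) if dur > 0 else 0.0
        off_duration = float(t_end - t_off)
    else:
        shut_rate = 0.0
        off_duration = 0.0

    k = waveform.k_field
    return PulseMetrics(
        i_peak=i_peak,
        t_peak=t_peak,
        b_peak=k * i_peak,
        onset_current_rate=slope,
        onset_field_rate=k * slope,
        shutoff_current_rate=abs(shut_rate),
        on_duration=float(t_off),
        off_duration=off_duration,
        provenance="modelled",
    )


def measured_metrics(b_peak: float, onset_field_rate: float,
                     k_field: float = 24.0,
                     shutoff_current_rate: float = 0.0) -> PulseMetrics:
    """Wrap bench measurements in a PulseMetrics with measured provenance."""
    return PulseMetrics(
        i_peak=b_peak / k_field,
        t_peak=float("nan"),
        b_peak=b_peak,
        onset_current_rate=onset_field_rate / k_field,
        onset_field_rate=onset_field_rate,
        shutoff_current_rate=shutoff_current_rate,
        on_duration=float("nan"),
        off_duration=float("nan"),
        provenance="measured",
    )


# ---------------------------------------------------------------------------
# Waveform CSV round trip
# ---------------------------------------------------------------------------

def write_waveform_csv(waveform: PulseWaveform, path,
                       pickup: PickupCoil | None = None) -> None:
    """Write `t_s,i_a,b_mt,u_v` rows; 9 significant digits, deterministic order."""
    u = (induced_voltage(waveform, pickup) if pickup is not None
         else np.zeros_like(waveform.t))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t_s,i_a,b_mt,u_v\n")
        for row in zip(waveform.t, waveform.i, waveform.b, u):
            fh.write(",".join(f"{v:.9g}" for v in row) + "\n")


def read_waveform_csv(path, k_field: float | None = None) -> PulseWaveform:
    """Read a waveform CSV written by :func:`write_waveform_csv`.

    ``k_field`` is recovered from the b/i ratio when not given.
    """
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = np.atleast_1d(data["t_s"])
    i = np.atleast_1d(data["i_a"])
    b = np.atleast_1d(data["b_mt"])
    if k_field is None:
        nz = np.abs(i) > 0
        k_field = float(b[nz][0] / i[nz][0]) if np.any(nz) else 24.0
    return PulseWaveform(t=t, i=i, k_field=k_field)


# ---------------------------------------------------------------------------
# Built-in device generations
# ---------------------------------------------------------------------------

def mp09_2020(mode: str = "treatment") -> PulseCircuit:
    """First-generation pulser: 270 uF bank, chopped shut-off.

    Treatment runs 9 ms with a 0.69 ms fall; the sham truncates the same
    discharge at 0.2 ms with a 0.1 ms fall.
    """
    if mode == "treatment":
        return PulseCircuit(u0=230.0, capacitance=270e-6, inductance=0.170,
                            r_total=80.0, k_field=24.0, t_d=9e-3,
                            shutoff_model="linear_ramp", fall_time=0.69e-3)
    if mode == "sham":
        return PulseCircuit(u0=230.0, capacitance=270e-6, inductance=0.170,
                            r_total=80.0, k_field=24.0, t_d=0.2e-3,
                            shutoff_model="linear_ramp", fall_time=0.1e-3)
    raise ConfigurationError(f"unknown mode {mode!r}")


def custom_2021(mode: str = "treatment") -> PulseCircuit:
    """Second-generation pulser: two 470 uF capacitors in parallel, flyback."""
    if mode == "treatment":
        return PulseCircuit(u0=230.0, capacitance=940e-6, inductance=0.170,
                            r_total=80.0, k_field=24.0, t_d=10e-3,
                            shutoff_model="flyback_exponential")
    if mode == "sham":
        return PulseCircuit(u0=230.0, capacitance=940e-6, inductance=0.170,
                            r_total=80.0, k_field=24.0, t_d=0.2e-3,
                            shutoff_model="flyback_exponential")
    raise ConfigurationError(f"unknown mode {mode!r}")


CIRCUIT_PROFILES = {"mp09_2020": mp09_2020, "custom_2021": custom_2021}
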