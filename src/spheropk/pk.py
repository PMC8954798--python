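"""Pharmacokinetic dosing profiles and perfusion hydraulics.

A dosing cycle is modelled as a piecewise curve of drug concentration
versus time: a fast linear rise to the peak concentration followed by a
stepwise exponential decay over the rest of the 24-h cycle.  The decay
rate is calibrated so that the time-averaged concentration over one
cycle equals a prescribed constant ("AUC-matched" dosing): the constant
regimen and the fluctuating regimen then deliver the same total exposure
per cycle.

The module also converts a profile into the two-pump dilution schedule
that realises it at a constant total flow rate (compound stock line plus
plain-medium line merged in a T-junction), and integrates the first-order
well-mixed compartment ODE that approximates wash-in/washout of the
medium around the spheroid.

Units: time in hours (pump grids and ODE steps are specified in minutes
and converted), concentration in µM, flow in µL/min, volume in µL.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PKProfile",
    "PumpSchedule",
    "CompartmentParams",
    "build_profile",
    "calibrate_decay_to_constant",
    "auc",
    "repeat_cycles",
    "pump_schedule",
    "compartment_response",
    "constant_profile",
    "read_profile_csv",
    "write_profile_csv",
]


@dataclass(frozen=True)
class PKProfile:
    """Piecewise concentration-vs-time curve.

    ``breakpoints`` (h) are strictly increasing and start at 0;
    ``values`` (µM) give the concentration at each breakpoint;
    ``segment_modes`` has one entry per segment: ``"step"`` holds the
    left breakpoint's value over the segment, ``"linear"`` interpolates.
    """

    breakpoints: np.ndarray
    values: np.ndarray
    segment_modes: tuple[str, ...]
    cycle_length: float = 24.0

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)
        if bp.ndim != 1 or bp.size < 2:
            raise ValueError("profile needs at least two breakpoints")
        if bp[0] != 0.0:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if vals.shape != bp.shape:
            raise ValueError("values must match breakpoints")
        if np.any(vals < 0):
            raise ValueError("concentrations must be non-negative")
        if len(self.segment_modes) != bp.size - 1:
            raise ValueError("need one segment mode per segment")
        if any(m not in ("step", "linear") for m in self.segment_modes):
            raise ValueError("segment modes must be 'step' or 'linear'")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")

    @property
    def t_end(self) -> float:
        return float(self.breakpoints[-1])

    @property
    def n_cycles(self) -> int:
        return int(round(self.t_end / self.cycle_length))

    def __call__(self, t):
        """Evaluate the concentration at time(s) ``t`` (h)."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if np.any(t < self.breakpoints[0] - 1e-12) or np.any(
            t > self.t_end + 1e-12
        ):
            raise ValueError("evaluation time outside profile domain")
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        idx = np.clip(idx, 0, self.breakpoints.size - 2)
        out = np.empty_like(t)
        modes = np.array(self.segment_modes)
        is_step = modes[idx] == "step"
        out[is_step] = self.values[idx[is_step]]
        lin = ~is_step
        if np.any(lin):
            i = idx[lin]
            t0, t1 = self.breakpoints[i], self.breakpoints[i + 1]
            v0, v1 = self.values[i], self.values[i + 1]
            out[lin] = v0 + (v1 - v0) * (t[lin] - t0) / (t1 - t0)
        return float(out[0]) if scalar else out

    def max_concentration(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class PumpSchedule:
    """Two-pump flow schedule realising a profile by dilution.

    At every grid point ``q_compound + q_medium == q_total`` (mass
    balance of the T-junction) and the mixed concentration is
    ``q_compound * c_stock / q_total``.
    """

    times: np.ndarray  # h
    q_compound: np.ndarray  # µL/min
    q_medium: np.ndarray  # µL/min
    q_total: float  # µL/min
    c_stock: float  # µM

    def __post_init__(self) -> None:
        qc = np.asarray(self.q_compound, dtype=float)
        qm = np.asarray(self.q_medium, dtype=float)
        if np.any(qc < -1e-12) or np.any(qc > self.q_total * (1 + 1e-12)):
            raise ValueError("q_compound outside [0, q_total]")
        if not np.allclose(qc + qm, self.q_total, rtol=1e-12, atol=0):
            raise ValueError("flow not conserved: q_compound + q_medium != q_total")

    def reconstructed_concentration(self) -> np.ndarray:
        return self.q_compound * self.c_stock / self.q_total


@dataclass(frozen=True)
class CompartmentParams:
    """Well-mixed compartment surrogate for the microtissue cavity.

    The default volume is set so that a concentration step reaches 90%
    of its target in ~12 min at the standard 10 µL/min perfusion rate
    (time constant V/Q = 12/ln 10 min).
    """

    volume: float = 10.0 * 12.0 / np.log(10.0)  # µL (~52.1)
    flow: float = 10.0  # µL/min
    initial_concentration: float = 0.0  # µM

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.flow < 0:
            raise ValueError("flow must be non-negative")

    @property
    def time_constant_min(self) -> float:
        return self.volume / self.flow


def build_profile(
    peak_conc: float,
    t_peak: float = 1.5,
    n_decay_steps: int = 12,
    decay_rate: float = 0.0,
    cycle_length: float = 24.0,
) -> PKProfile:
    """Build one dosing cycle: linear ramp to the peak, then a stepwise
    exponential decay.

    The ramp goes from 0 to ``peak_conc`` over ``[0, t_peak]``; the
    remaining ``cycle_length - t_peak`` is split into ``n_decay_steps``
    equal "step" segments whose held values follow
    ``peak_conc * exp(-decay_rate * (t - t_peak))`` evaluated at each
    step start.  The cycle maximum is therefore exactly ``peak_conc``.
    """
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    if not 0 < t_peak < cycle_length:
        raise ValueError("t_peak must lie strictly inside the cycle")
    if peak_conc < 0:
        raise ValueError("peak_conc must be non-negative")
    if n_decay_steps < 1:
        raise ValueError("need at least one decay step")
    if decay_rate < 0:
        raise ValueError("decay_rate must be non-negative")
    step_dur = (cycle_length - t_peak) / n_decay_steps
    starts = t_peak + step_dur * np.arange(n_decay_steps)
    held = peak_conc * np.exp(-decay_rate * (starts - t_peak))
    breakpoints = np.concatenate(([0.0], starts, [cycle_length]))
    values = np.concatenate(([0.0], held, [held[-1]]))
    modes = ("linear",) + ("step",) * n_decay_steps
    return PKProfile(breakpoints, values, modes, cycle_length=cycle_length)


def constant_profile(
    concentration: float, duration: float, cycle_length: float = 24.0
) -> PKProfile:
    """A flat profile (constant dosing or vehicle when concentration=0)."""
    return PKProfile(
        np.array([0.0, duration]),
        np.array([concentration, concentration]),
        ("step",),
        cycle_length=cycle_length,
    )


def auc(profile: PKProfile, t0: float, t1: float) -> float:
    """Exact piecewise integral of the profile over [t0, t1] (µM·h).

    Step segments contribute rectangles, linear segments trapezoids.
    """
    if t0 >= t1:
        raise ValueError("need t0 < t1")
    if t0 < profile.breakpoints[0] - 1e-12 or t1 > profile.t_end + 1e-12:
        raise ValueError("integration range outside profile domain")
    bp, vals = profile.breakpoints, profile.values
    total = 0.0
    for i, mode in enumerate(profile.segment_modes):
        a, b = bp[i], bp[i + 1]
        lo, hi = max(a, t0), min(b, t1)
        if hi <= lo:
            continue
        if mode == "step":
            total += vals[i] * (hi - lo)
        else:
            slope = (vals[i + 1] - vals[i]) / (b - a)
            v_lo = vals[i] + slope * (lo - a)
            v_hi = vals[i] + slope * (hi - a)
            total += 0.5 * (v_lo + v_hi) * (hi - lo)
    return total


def cycle_average(profile: PKProfile) -> float:
    """Time-averaged concentration over the first cycle (µM)."""
    return auc(profile, 0.0, profile.cycle_length) / profile.cycle_length


def calibrate_decay_to_constant(
    peak_conc: float,
    t_peak: float = 1.5,
    n_decay_steps: int = 12,
    target_constant: float = 9.3,
    cycle_length: float = 24.0,
    tol: float = 1e-9,
) -> float:
    """Find the decay rate whose cycle-averaged concentration equals
    ``target_constant`` (the AUC-matched constant exposure).

    The map decay_rate -> average concentration is strictly decreasing,
    so the rate is found by bisection.
    """
    if target_constant > peak_conc:
        raise ValueError("target constant cannot exceed the peak")
    if target_constant == peak_conc:
        return 0.0
    if target_constant <= 0:
        raise ValueError("target constant must be positive")

    def avg(rate: float) -> float:
        return cycle_average(
            build_profile(peak_conc, t_peak, n_decay_steps, rate, cycle_length)
        )

    # Infinite decay leaves the ramp and the first (peak-valued) step.
    step_dur = (cycle_length - t_peak) / n_decay_steps
    floor = peak_conc * (0.5 * t_peak + step_dur) / cycle_length
    if target_constant <= floor:
        raise ValueError(
            f"target {target_constant} µM unattainable: the ramp and first "
            f"step alone average {floor:.4g} µM"
        )
    lo, hi = 0.0, 1.0
    while avg(hi) > target_constant:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("bisection bracket expansion failed")
    while hi - lo > 1e-14 * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if avg(mid) > target_constant:
            lo = mid
        else:
            hi = mid
        if abs(avg(mid) - target_constant) < tol:
            return mid
    return 0.5 * (lo + hi)


def repeat_cycles(profile: PKProfile, n: int) -> PKProfile:
    """Concatenate ``n`` copies of a single-cycle profile."""
    if n < 1:
        raise ValueError("need n >= 1")
    if abs(profile.t_end - profile.cycle_length) > 1e-9:
        raise ValueError("profile must span exactly one cycle")
    if n == 1:
        return profile
    bp = [profile.breakpoints]
    vals = [profile.values]
    modes: list[str] = list(profile.segment_modes)
    for k in range(1, n):
        bp.append(profile.breakpoints[1:] + k * profile.cycle_length)
        vals.append(profile.values[1:])
        modes.extend(profile.segment_modes)
    bp_all = np.concatenate(bp)
    vals_all = np.concatenate(vals)
    # Each cycle boundary kL is a shared breakpoint carrying the previous
    # cycle's terminal value; the segment starting there must instead open
    # with the cycle-start value for periodic evaluation.
    for k in range(1, n):
        j = int(np.searchsorted(bp_all, k * profile.cycle_length))
        vals_all[j] = profile.values[0]
    return PKProfile(bp_all, vals_all, tuple(modes), cycle_length=profile.cycle_length)


def pump_schedule(
    profile: PKProfile,
    q_total: float = 10.0,
    c_stock: float | None = None,
    dt: float = 1.0,
) -> PumpSchedule:
    """Convert a profile into the two-pump dilution schedule.

    ``q_compound(t) = profile(t) / c_stock * q_total`` so that mixing the
    compound stock with plain medium at total flow ``q_total`` reproduces
    the profile exactly; ``dt`` is the grid spacing in minutes.
    """
    if q_total <= 0:
        raise ValueError("q_total must be positive")
    if c_stock is None:
        c_stock = profile.max_concentration()
    if c_stock < profile.max_concentration() - 1e-12:
        raise ValueError("profile concentration exceeds stock: unmixable")
    if c_stock <= 0:
        raise ValueError("c_stock must be positive")
    times = np.arange(0.0, profile.t_end * 60.0 + 0.5 * dt, dt) / 60.0
    conc = np.atleast_1d(profile(times))
    q_comp = conc / c_stock * q_total
    return PumpSchedule(times, q_comp, q_total - q_comp, q_total, c_stock)


def compartment_response(
    inflow: PKProfile, params: CompartmentParams, dt: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dC/dt = (Q/V)·(C_in(t) − C) with classical RK4.

    ``dt`` is the step in minutes and must satisfy dt <= (V/Q)/10 (a
    stability/accuracy guard well below the RK4 stability limit).
    Returns (times in h, concentration in µM).
    """
    if params.volume <= 0:
        raise ValueError("zero or negative compartment volume")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.flow > 0 and dt > params.time_constant_min / 10.0:
        raise ValueError("dt too large for the compartment time constant")
    k = params.flow / params.volume  # 1/min
    t_end_min = inflow.t_end * 60.0
    n = int(round(t_end_min / dt))
    times_min = np.linspace(0.0, n * dt, n + 1)
    if times_min[-1] > t_end_min + 1e-9:
        times_min = times_min[times_min <= t_end_min + 1e-9]
        n = times_min.size - 1
    conc = np.empty(n + 1)
    conc[0] = params.initial_concentration
    bp_min = inflow.breakpoints * 60.0

    def f(t_min: float, c: float, t_clamp: float) -> float:
        # clamp to just inside the current smooth segment so evaluations
        # at a segment end never read the value across a discontinuity
        u = min(t_min, t_clamp, t_end_min) / 60.0
        return k * (float(inflow(u)) - c)

    def rk4(t: float, c: float, h: float, t_clamp: float) -> float:
        k1 = f(t, c, t_clamp)
        k2 = f(t + h / 2, c + h / 2 * k1, t_clamp)
        k3 = f(t + h / 2, c + h / 2 * k2, t_clamp)
        k4 = f(t + h, c + h * k3, t_clamp)
        return c + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    for i in range(n):
        t0, t1 = times_min[i], times_min[i + 1]
        c = conc[i]
        # the inflow is discontinuous at profile breakpoints: split the
        # step there so RK4 only ever sees a smooth right-hand side
        inner = bp_min[(bp_min > t0 + 1e-12) & (bp_min < t1 - 1e-12)]
        t = t0
        for tb in inner:
            c = rk4(t, c, tb - t, np.nextafter(tb, -np.inf))
            t = tb
        conc[i + 1] = rk4(t, c, t1 - t, np.nextafter(t1, -np.inf))
    return times_min / 60.0, conc


def write_profile_csv(profile: PKProfile, path: str | Path, dt_min: float = 6.0) -> None:
    """Export the profile sampled on a regular grid (columns time_h, conc_uM)."""
    times = np.arange(0.0, profile.t_end * 60.0 + 0.5 * dt_min, dt_min) / 60.0
    pd.DataFrame(
        {"time_h": times, "conc_uM": np.atleast_1d(profile(times))}
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path, cycle_length: float = 24.0) -> PKProfile:
    """Read a sampled profile back as a piecewise-linear curve."""
    df = pd.read_csv(path)
    bp = df["time_h"].to_numpy(dtype=float)
    vals = df["conc_uM"].to_numpy(dtype=float)
    return PKProfile(bp, vals, ("linear",) * (bp.size - 1), cycle_length=cycle_length)


def write_schedule_csv(schedule: PumpSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_h": schedule.times,
            "q_compound_ul_min": schedule.q_compound,
            "q_medium_ul_min": schedule.q_medium,
        }
    ).to_csv(path, index=False)
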