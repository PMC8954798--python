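"""Growth dynamics: relative size change, smoothing and shrink↔grow
transition detection against the applied dosing profile.

The frame-to-frame relative size change
``rel_change_k = area_k / area_{k-1} − 1`` (assigned to the midpoint of
the frame pair) is smoothed with LOWESS (locally weighted linear
regression, tricube weights, 10-point windows by default).  Zero
crossings of the smoothed series are the shrink↔grow transitions; the
drug concentration read off the dosing profile at each negative→positive
crossing, averaged, is the empirical efficacy-threshold estimate: the
concentration below which the spheroid resumes growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .pk import PKProfile

__all__ = [
    "ChangeSeries",
    "TransitionSet",
    "relative_change",
    "lowess_smooth",
    "detect_transitions",
    "transition_concentration",
    "periodicity_check",
]


@dataclass
class ChangeSeries:
    """Relative size change on frame-pair midpoints."""

    times: np.ndarray  # h
    rel_change: np.ndarray  # dimensionless, ratio − 1
    smoothed: np.ndarray | None = None

    def values(self) -> np.ndarray:
        return self.rel_change if self.smoothed is None else self.smoothed


@dataclass
class TransitionSet:
    """Zero crossings of a (smoothed) change series."""

    times: np.ndarray  # h, sorted
    directions: list[str]  # "neg_to_pos" | "pos_to_neg", alternating
    concentrations: np.ndarray | None = None  # µM at each crossing
    threshold_estimate: float | None = None  # mean over neg_to_pos

    @property
    def n_crossings(self) -> int:
        return self.times.size

    def neg_to_pos_times(self) -> np.ndarray:
        return self.times[[d == "neg_to_pos" for d in self.directions]]


def relative_change(times_h: np.ndarray, areas: np.ndarray) -> ChangeSeries:
    """Frame-to-frame relative change, area_k/area_{k−1} − 1, at the
    midpoint of each consecutive frame pair."""
    times_h = np.asarray(times_h, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if times_h.size < 2:
        raise ValueError("need at least two frames")
    if np.any(~np.isfinite(areas)) or np.any(areas <= 0):
        raise ValueError("areas must be finite and positive")
    rel = areas[1:] / areas[:-1] - 1.0
    mid = 0.5 * (times_h[1:] + times_h[:-1])
    return ChangeSeries(mid, rel)


def lowess_smooth(series: ChangeSeries, window_points: int = 10) -> ChangeSeries:
    """LOWESS with tricube weights over each point's ``window_points``
    nearest neighbours (classic locally weighted linear regression)."""
    n = series.times.size
    if window_points < 3:
        raise ValueError("window must cover at least 3 points")
    if window_points > n:
        raise ValueError("window larger than the series")
    frac = min(1.0, (window_points + 0.5) / n)  # int(frac·n) == window_points
    sm = _sm_lowess(series.rel_change, series.times, frac=frac, it=3, return_sorted=False)
    return ChangeSeries(series.times, series.rel_change, smoothed=sm)


def detect_transitions(series: ChangeSeries) -> TransitionSet:
    """Locate sign changes of the (smoothed) series; crossing times by
    linear interpolation between the bracketing points."""
    t = series.times
    v = series.values()
    times: list[float] = []
    dirs: list[str] = []
    # walk over consecutive non-zero samples; an exact zero is itself
    # the crossing point
    idx = np.flatnonzero(v != 0.0)
    for a, b in zip(idx[:-1], idx[1:]):
        if v[a] * v[b] < 0:
            if b - a == 1:
                tc = t[a] + (t[b] - t[a]) * (-v[a]) / (v[b] - v[a])
            else:  # zeros in between: crossing at the first exact zero
                tc = float(t[a + 1])
            times.append(float(tc))
            dirs.append("neg_to_pos" if v[a] < 0 else "pos_to_neg")
    return TransitionSet(np.asarray(times), dirs)


def transition_concentration(
    transitions: TransitionSet, profile: PKProfile
) -> TransitionSet:
    """Read the profile concentration at each crossing; the mean over
    negative→positive crossings is the threshold estimate."""
    if transitions.n_crossings == 0:
        return TransitionSet(transitions.times, transitions.directions, np.array([]), None)
    if transitions.times.min() < -1e-9 or transitions.times.max() > profile.t_end + 1e-9:
        raise ValueError("crossing time outside the profile domain")
    conc = np.atleast_1d(profile(transitions.times))
    n2p = np.array([d == "neg_to_pos" for d in transitions.directions])
    est = float(conc[n2p].mean()) if n2p.any() else None
    return TransitionSet(transitions.times, transitions.directions, conc, est)


def periodicity_check(
    transitions: TransitionSet, cycle_length: float = 24.0
) -> pd.DataFrame:
    """Per-cycle crossing summary: cycle index, direction, time and
    phase (time within the cycle) of each crossing."""
    rows = []
    for t, d in zip(transitions.times, transitions.directions):
        cyc = int(np.floor(t / cycle_length))
        rows.append(
            {
                "cycle": cyc,
                "direction": d,
                "time_h": float(t),
                "phase_h": float(t - cyc * cycle_length),
            }
        )
    return pd.DataFrame(rows, columns=["cycle", "direction", "time_h", "phase_h"])


def crossings_per_cycle(
    transitions: TransitionSet, cycle_length: float, n_cycles: int
) -> pd.DataFrame:
    """Count neg→pos and pos→neg crossings in each complete cycle."""
    table = periodicity_check(transitions, cycle_length)
    rows = []
    for cyc in range(n_cycles):
        sub = table[table["cycle"] == cyc]
        rows.append(
            {
                "cycle": cyc,
                "neg_to_pos": int((sub["direction"] == "neg_to_pos").sum()),
                "pos_to_neg": int((sub["direction"] == "pos_to_neg").sum()),
            }
        )
    return pd.DataFrame(rows)
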