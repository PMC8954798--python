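"""Quality control for spheroid size series.

A frame is flagged *empty* when segmentation found nothing or the
retained object is implausibly small (default < 1,000 µm²), and flagged
*moved out* when the mask touches the image border.  A series is
excluded when its first usable frame comes too late (default index > 4,
the normalisation fallback limit) or when more than a configurable
fraction of frames (default 10%) is empty.  Excluded series are dropped
from group averages but kept in raw outputs; every exclusion cites its
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCThresholds

__all__ = ["SeriesQC", "QCReport", "apply_qc"]


@dataclass
class SeriesQC:
    spheroid_id: str
    empty_frames: list[int]
    border_frames: list[int]
    included: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    series: list[SeriesQC]

    def included_ids(self) -> list[str]:
        return [s.spheroid_id for s in self.series if s.included]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spheroid_id": [s.spheroid_id for s in self.series],
                "n_empty": [len(s.empty_frames) for s in self.series],
                "n_border": [len(s.border_frames) for s in self.series],
                "included": [s.included for s in self.series],
                "reasons": [";".join(s.reasons) for s in self.series],
            }
        )


def apply_qc(area_table: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Evaluate per-frame flags and per-series inclusion.

    ``area_table`` is the tidy output of the 2D chain (spheroid_id,
    frame, area_um2, qc_empty, qc_border per row).  A frame is treated
    as empty if flagged by segmentation or if its area falls below the
    minimum-area threshold.
    """
    out = []
    for sid, sub in area_table.groupby("spheroid_id", sort=True):
        sub = sub.sort_values("frame")
        area = sub["area_um2"].to_numpy(dtype=float)
        empty = (
            sub["qc_empty"].to_numpy(dtype=bool)
            | ~np.isfinite(area)
            | (area < thresholds.min_area_um2)
        )
        border = sub["qc_border"].to_numpy(dtype=bool)
        frames = sub["frame"].to_numpy()
        reasons = []
        usable = frames[~empty]
        if usable.size == 0:
            reasons.append("all_frames_empty")
        elif int(usable[0]) > thresholds.max_first_frame:
            reasons.append("late_start")
        if empty.mean() > thresholds.max_empty_fraction:
            reasons.append("empty_frames")
        out.append(
            SeriesQC(
                spheroid_id=str(sid),
                empty_frames=[int(f) for f in frames[empty]],
                border_frames=[int(f) for f in frames[border]],
                included=not reasons,
                reasons=reasons,
            )
        )
    return QCReport(out)
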