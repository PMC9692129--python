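"""Calcium-trace quantification.

Normalizes each cell's fluorescence against the mean of its four
background domains, F_IN = (F_IC - F_IB)/F_IB, calls bursts by a
sustained-threshold rule, and summarizes cohorts: burst ratio, delay
times, and Pearson correlations with wall shear stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calcium_sim import FPS, CalciumCohort

__all__ = [
    "DetectionParams",
    "BurstCall",
    "normalize_trace",
    "normalize_cohort",
    "detect_burst",
    "detect_bursts",
    "burst_ratio",
    "cohort_summary",
    "correlate_with_wss",
]


@dataclass(frozen=True)
class DetectionParams:
    """Burst-call rule: F_IN above ``threshold`` for ``sustain_s`` seconds.

    The onset (used as the delay time) is the last sample still below the
    low ``onset_floor`` before the first sustained crossing, which tracks
    the foot of the pulse rather than its mid-rise; ``onset="peak"``
    reports the pulse peak instead.
    """

    threshold: float = 0.5
    sustain_s: float = 5.0
    onset_floor: float = 0.1
    onset: str = "floor"  # or "peak"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.sustain_s <= 0:
            raise ValueError("sustain_s must be positive")
        if not 0 < self.onset_floor <= self.threshold:
            raise ValueError("onset_floor must lie in (0, threshold]")
        if self.onset not in ("floor", "peak"):
            raise ValueError("onset must be 'floor' or 'peak'")


@dataclass(frozen=True)
class BurstCall:
    cell_id: int
    is_burst: bool
    delay: float      # s from trace start (firm adhesion); NaN if no burst
    peak_f_in: float


def normalize_trace(fi_cell: np.ndarray, fi_bg: np.ndarray) -> np.ndarray:
    """F_IN = (F_IC - F_IB)/F_IB with F_IB the per-frame mean of 4 domains."""
    fi_cell = np.asarray(fi_cell, dtype=float)
    fi_bg = np.asarray(fi_bg, dtype=float)
    if fi_bg.shape != (4, fi_cell.size):
        raise ValueError("expected four background series matching the cell series")
    f_ib = fi_bg.mean(axis=0)
    bad = np.nonzero(f_ib <= 0)[0]
    if bad.size:
        raise ValueError(f"nonpositive background at frame {int(bad[0])}")
    return (fi_cell - f_ib) / f_ib


def normalize_cohort(cohort: CalciumCohort) -> np.ndarray:
    """Stacked F_IN series, one row per cell."""
    f_ib = cohort.fi_bg.mean(axis=1)
    if np.any(f_ib <= 0):
        raise ValueError("nonpositive background in cohort")
    return (cohort.fi_cell - f_ib) / f_ib


def detect_burst(
    f_in: np.ndarray, time: np.ndarray, det: DetectionParams | None = None, cell_id: int = 0
) -> BurstCall:
    """Call a burst on one normalized trace sampled uniformly at 20 fps."""
    det = det or DetectionParams()
    f_in = np.asarray(f_in, dtype=float)
    window = int(round(det.sustain_s * FPS))
    if f_in.size < window:
        raise ValueError("trace shorter than the sustain window")
    above = f_in >= det.threshold
    runs = np.convolve(above.astype(int), np.ones(window, dtype=int), mode="valid")
    hits = np.nonzero(runs == window)[0]
    if hits.size == 0:
        return BurstCall(cell_id, False, float("nan"), float(np.max(f_in)))
    start = int(hits[0])
    if det.onset == "peak":
        onset_idx = int(np.argmax(f_in))
    else:
        below = np.nonzero(f_in[:start] < det.onset_floor)[0]
        onset_idx = int(below[-1]) if below.size else 0
    delay = float(time[onset_idx] - time[0])
    return BurstCall(cell_id, True, delay, float(np.max(f_in)))


def detect_bursts(cohort: CalciumCohort, det: DetectionParams | None = None) -> pd.DataFrame:
    """Burst calls for a whole cohort; one row per cell."""
    f_in = normalize_cohort(cohort)
    calls = [
        detect_burst(f_in[i], cohort.time, det, cell_id=int(cid))
        for i, cid in enumerate(cohort.meta["cell_id"])
    ]
    return pd.DataFrame(
        [(c.cell_id, c.is_burst, c.delay, c.peak_f_in) for c in calls],
        columns=["cell_id", "is_burst", "delay", "peak_f_in"],
    )


def burst_ratio(calls: pd.DataFrame) -> float:
    """Fraction of firmly adherent cells that burst within the window."""
    if len(calls) == 0:
        raise ValueError("no burst calls")
    return float(calls["is_burst"].mean())


def cohort_summary(calls: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, wss, treatment) burst ratio and delay mean +- SEM.

    Burst-negative cells are excluded from delay statistics; an empty
    burst subset reports NaN delays rather than zero.
    """
    orphans = set(calls["cell_id"]) - set(meta["cell_id"])
    if orphans:
        raise ValueError(f"burst calls with no metadata: {sorted(orphans)[:10]}")
    df = calls.merge(meta, on="cell_id", how="left")
    rows = []
    for (condition, wss, treatment), g in df.groupby(
        ["condition", "wss", "treatment"], sort=True
    ):
        delays = g.loc[g["is_burst"], "delay"]
        rows.append(
            (
                condition, wss, treatment, len(g), float(g["is_burst"].mean()),
                float(delays.mean()) if len(delays) else float("nan"),
                float(delays.sem()) if len(delays) > 1 else float("nan"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["condition", "wss", "treatment", "n_cells", "burst_ratio",
                 "delay_mean_s", "delay_sem_s"],
    )


def correlate_with_wss(
    calls: pd.DataFrame, meta: pd.DataFrame, unit: str = "cell"
) -> pd.DataFrame:
    """Pearson correlation of burst behaviour with wall shear stress.

    ``unit="cell"`` correlates the per-cell burst indicator (and, over
    burst-positive cells, the delay) with WSS; ``unit="ratio"``
    correlates per-(condition, WSS) burst ratios and mean delays, the
    replicate-mean convention used for reported correlation coefficients.
    Needs >= 3 WSS levels; zero-variance inputs report NaN.
    """
    if unit not in ("cell", "ratio"):
        raise ValueError("unit must be 'cell' or 'ratio'")
    df = calls.merge(meta, on="cell_id", how="left")
    out = []
    for condition, g in df.groupby("condition", sort=True):
        if g["wss"].nunique() < 3:
            raise ValueError(f"condition {condition!r} has < 3 WSS levels")
        if unit == "cell":
            x_b, y_b = g["wss"].to_numpy(float), g["is_burst"].to_numpy(float)
            gb = g[g["is_burst"]]
            x_d, y_d = gb["wss"].to_numpy(float), gb["delay"].to_numpy(float)
        else:
            s = g.groupby("wss").agg(
                ratio=("is_burst", "mean"),
                delay=("delay", lambda v: v.dropna().mean()),
            ).reset_index()
            x_b = x_d = s["wss"].to_numpy(float)
            y_b, y_d = s["ratio"].to_numpy(float), s["delay"].to_numpy(float)
        out.append((condition, *_pearson(x_b, y_b), *_pearson(x_d, y_d)))
    return pd.DataFrame(
        out, columns=["condition", "r_burst", "p_burst", "r_delay", "p_delay"]
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
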