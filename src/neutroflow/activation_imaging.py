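"""Whole-cell integrin-activation imaging metrics and their generator.

Fixed-cell endpoint assay: after a flow stimulus of given duration, cells
are stained with an antibody reporting the extended beta2-integrin
conformation, and each cell contributes one intensity pair (cell
fluorescence density FI_C, local background FI_B).  The metrics are the
relative extended-integrin density FI_C/FI_B - 1, the activation call
(density above a threshold), the cohort activation ratio normalized by
the static (no-flow) cohort, and a four-parameter logistic fit of the
activation time course whose inflection is the stimulus-time threshold.

Also hosts the firm-adhesion track filter (net displacement < 10 um per
minute) that defines which cells enter these cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "IMAGING_CONDITIONS",
    "ImagingCondParams",
    "ImagingParams",
    "DEFAULT_IMAGING_PARAMS",
    "DEFAULT_STIMULUS_TIMES_MIN",
    "TimecourseFit",
    "relative_extended_density",
    "classify_activated",
    "activation_ratio",
    "normalize_by_static",
    "fit_timecourse",
    "threshold_time_ratio",
    "generate_imaging_cohort",
    "firm_adhesion_filter",
]

logger = logging.getLogger(__name__)

IMAGING_CONDITIONS = ("P-selectin", "P-selectin+ICAM1", "P-selectin+GPIbalpha")

#: stimulus durations probed in the endpoint assay, min
DEFAULT_STIMULUS_TIMES_MIN = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class ImagingCondParams:
    """Logistic time courses of one condition.

    ``frac0 -> frac_inf`` is the activated-cell fraction (static baseline
    to plateau), ``dens0 -> dens_inf`` the mean relative density of
    activated cells, ``t50_min`` the stimulus-time threshold (logistic
    inflection) and ``slope_min`` its width.
    """

    frac0: float
    frac_inf: float
    dens0: float
    dens_inf: float
    t50_min: float
    slope_min: float = 0.25


@dataclass(frozen=True)
class ImagingParams:
    """Generator defaults for the endpoint imaging assay.

    Cells held by P-selectin alone switch phase at 1.5 min and plateau at
    2.1x the static activation ratio with activated-cell density rising
    16 -> 24; ligand engagement halves the threshold and raises the
    plateaus.  Inactive cells carry a low residual reporter density.
    """

    conditions: dict = field(
        default_factory=lambda: {
            "P-selectin": ImagingCondParams(0.20, 0.42, 16.0, 24.0, 1.50),
            "P-selectin+ICAM1": ImagingCondParams(0.20, 0.60, 16.0, 30.0, 0.75),
            "P-selectin+GPIbalpha": ImagingCondParams(0.20, 0.60, 16.0, 30.0, 0.75),
        }
    )
    inactive_density: float = 3.0
    intensity_sigma: float = 0.25   # lognormal sigma of per-cell densities
    background_au: float = 100.0    # a.u. per unit area
    background_sigma: float = 0.05
    blocker_rise_keep: float = 0.3  # fraction of the rise kept under blockade

    def blocked(self, condition: str) -> "ImagingParams":
        """Scale a condition's plateaus toward baseline (channel blocked)."""
        c = self.conditions[condition]
        k = self.blocker_rise_keep
        newc = replace(
            c,
            frac_inf=c.frac0 + k * (c.frac_inf - c.frac0),
            dens_inf=c.dens0 + k * (c.dens_inf - c.dens0),
        )
        return replace(self, conditions={**self.conditions, condition: newc})


DEFAULT_IMAGING_PARAMS = ImagingParams()


def relative_extended_density(fi_c, fi_b):
    """Relative extended-integrin density FI_C/FI_B - 1 (dimensionless)."""
    fi_b = np.asarray(fi_b, dtype=float)
    if np.any(fi_b <= 0):
        raise ValueError("background density must be positive")
    out = np.asarray(fi_c, dtype=float) / fi_b - 1.0
    return float(out) if out.ndim == 0 else out


def classify_activated(density, rho: float = 5.0):
    """Extension-positive iff relative density >= ``rho``."""
    if rho <= 0:
        raise ValueError("threshold rho must be positive")
    out = np.asarray(density, dtype=float) >= rho
    return bool(out) if out.ndim == 0 else out


def activation_ratio(records: pd.DataFrame, rho: float = 5.0) -> float:
    """Fraction of extension-positive cells among firmly adherent cells."""
    if len(records) == 0:
        raise ValueError("no cells")
    dens = relative_extended_density(records["fi_c"], records["fi_b"])
    return float(np.mean(classify_activated(dens, rho)))


def normalize_by_static(series: pd.DataFrame) -> pd.DataFrame:
    """Divide raw activation ratios by the no-load (stimulus 0) value.

    ``series`` has columns ``stimulus_min`` and ``ratio``; the static row
    must be present.  A zero static ratio leaves the normalization
    undefined (NaN) and is reported via a warning.
    """
    if 0.0 not in set(series["stimulus_min"]):
        raise ValueError("static (stimulus_min == 0) group required for normalization")
    static = float(series.loc[series["stimulus_min"] == 0.0, "ratio"].iloc[0])
    out = series.copy()
    if static == 0:
        logger.warning("static activation ratio is 0; normalization undefined")
        out["normalized"] = np.nan
    else:
        out["normalized"] = out["ratio"] / static
    return out


@dataclass(frozen=True)
class TimecourseFit:
    baseline: float
    plateau: float
    t50: float      # stimulus-time threshold, min
    slope: float    # min
    residuals: np.ndarray

    def predict(self, t):
        return _logistic4(np.asarray(t, float), self.baseline, self.plateau,
                          self.t50, self.slope)


def _logistic4(t, base, plateau, t50, slope):
    return base + (plateau - base) / (1.0 + np.exp(-(t - t50) / slope))


def fit_timecourse(times, values) -> TimecourseFit:
    """Fit a 4-parameter logistic to an activation time course.

    Needs >= 4 stimulus times including 0.  The reported threshold is the
    inflection time of the fitted curve.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4 or 0.0 not in t:
        raise ValueError("need >= 4 stimulus times including the static point")
    p0 = [float(y.min()), float(y.max()), float(np.median(t)), 0.3]
    try:
        popt, _ = curve_fit(
            _logistic4, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-3, 1e-3], [np.inf, np.inf, t.max() * 2, t.max()]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = y - _logistic4(t, *p0)
        raise RuntimeError(f"time-course fit did not converge (residuals {resid})") from err
    resid = y - _logistic4(t, *popt)
    return TimecourseFit(float(popt[0]), float(popt[1]), float(popt[2]),
                         float(popt[3]), resid)


def threshold_time_ratio(fit_a: TimecourseFit, fit_b: TimecourseFit) -> float:
    """Ratio of stimulus-time thresholds between two fitted conditions."""
    return fit_a.t50 / fit_b.t50


def generate_imaging_cohort(
    conditions: Sequence[str],
    stimulus_times_min: Iterable[float],
    n_cells: int,
    seed,
    params: ImagingParams = DEFAULT_IMAGING_PARAMS,
    treatment: str = "none",
) -> pd.DataFrame:
    """Simulate a fixed-cell intensity table.

    Per cell: activation is Bernoulli in the condition's logistic
    fraction-curve at the stimulus time; activated cells draw a lognormal
    relative density around the condition's density curve, inactive cells
    around the low residual level.  2-APB blocks the rise for cells on
    P-selectin alone, LaCl3 for ligand-engaged conditions.
    """
    conditions = list(conditions)
    times = [float(x) for x in stimulus_times_min]
    if not conditions or not times or n_cells < 1:
        raise ValueError("empty generation plan")
    if treatment not in ("none", "2-APB", "LaCl3", "both"):
        raise ValueError(f"unknown treatment {treatment!r}")
    gen = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sig = params.intensity_sigma
    rows = []
    cid = 0
    for condition in conditions:
        if condition not in params.conditions:
            raise ValueError(f"unknown imaging condition {condition!r}")
        ligand_engaged = condition != "P-selectin"
        blocked = {"2-APB": not ligand_engaged, "LaCl3": ligand_engaged,
                   "both": True, "none": False}[treatment]
        p = params.blocked(condition) if blocked else params
        c = p.conditions[condition]
        for t in times:
            frac = _logistic4(t, c.frac0, c.frac_inf, c.t50_min, c.slope_min)
            dens_mean = _logistic4(t, c.dens0, c.dens_inf, c.t50_min, c.slope_min)
            active = gen.random(n_cells) < frac
            mean_d = np.where(active, dens_mean, p.inactive_density)
            # mean-preserving lognormal spread around the target density
            d = mean_d * np.exp(gen.normal(-0.5 * sig**2, sig, n_cells))
            fi_b = p.background_au * np.exp(
                gen.normal(-0.5 * p.background_sigma**2, p.background_sigma, n_cells)
            )
            fi_c = p.background_au * (1.0 + d)
            for i in range(n_cells):
                rows.append((cid, condition, treatment, t, fi_c[i], fi_b[i], bool(active[i])))
                cid += 1
    return pd.DataFrame(
        rows,
        columns=["cell_id", "condition", "treatment", "stimulus_min",
                 "fi_c", "fi_b", "activated_truth"],
    )


def firm_adhesion_filter(tracks: pd.DataFrame, max_um: float = 10.0,
                         window_s: float = 60.0) -> dict:
    """Split tracks into firm and moving cells.

    A cell adheres firmly iff its net displacement within every
    ``window_s`` window stays strictly below ``max_um``.  Tracks shorter
    than one window are excluded (logged), not counted in the ratio.
    Expects columns ``cell_id, t_s, x_um, y_um``.
    """
    firm, moving, excluded = [], [], []
    for cid, g in tracks.groupby("cell_id", sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy(float)
        if t[-1] - t[0] < window_s:
            excluded.append(cid)
            logger.warning("track %s spans %.1f s < %.0f s; excluded", cid, t[-1] - t[0], window_s)
            continue
        xy = g[["x_um", "y_um"]].to_numpy(float)
        j = np.searchsorted(t, t + window_s, side="left")
        ok = j < len(t)
        disp = np.linalg.norm(xy[j[ok]] - xy[ok], axis=1)
        # also check the trailing partial window against the track end
        tail = np.linalg.norm(xy[-1] - xy[~ok], axis=1) if (~ok).any() else np.array([])
        if np.all(disp < max_um) and np.all(tail < max_um):
            firm.append(cid)
        else:
            moving.append(cid)
    total = len(firm) + len(moving)
    return {
        "firm_ids": firm,
        "moving_ids": moving,
        "excluded_ids": excluded,
        "firm_ratio": len(firm) / total if total else float("nan"),
    }
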