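"""Tether-lifetime statistics.

Everything downstream of a tether-event table: the empirical survival
ratio S(t) = N(>=t)/N_T, the integrin-involved fraction
IIF(t) = (P_E - P)/P_E comparing arms with and without an integrin
ligand, threshold-crossing times of the IIF, the biphasic
mean-lifetime-versus-WSS curve with its quadratic fit, a two-component
Gaussian lifetime mixture, and the small exact conversions (wall shear
stress to tether force, tethering adhesion ratio).

All lifetimes here are fully observed stop times - there is no censoring,
so no Kaplan-Meier machinery is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.mixture import GaussianMixture

from .tether_sim import FRAME_S, PN_PER_DYNE_CM2

__all__ = [
    "DEFAULT_GRID",
    "SurvivalCurve",
    "IIFCurve",
    "LifetimeMixture",
    "survival_curve",
    "iif_curve",
    "iif_crossing_time",
    "mean_lifetime_vs_wss",
    "lifetime_mixture_fit",
    "wss_to_force",
    "tethering_adhesion_ratio",
    "bootstrap_mean_ci",
]

logger = logging.getLogger(__name__)

#: default evaluation grid: 0-5 s in 0.01 s steps (the 100 fps quantum)
DEFAULT_GRID = np.round(np.arange(0.0, 5.0 + FRAME_S / 2, FRAME_S), 2)


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival ratio of tether events on a time grid."""

    grid: np.ndarray
    S: np.ndarray
    n_total: int

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.grid, t + 1e-12) - 1)
        return float(self.S[max(i, 0)])


@dataclass(frozen=True)
class IIFCurve:
    """Integrin-involved fraction (P_E - P)/P_E on a time grid.

    ``raw`` keeps the pointwise ratio (NaN where the with-ligand survival
    has fallen below the floor); ``iif`` is the adjusted curve - clipped
    to [0, 1] and made non-decreasing by isotonic regression - on which
    crossing times are read off.
    """

    grid: np.ndarray
    raw: np.ndarray
    iif: np.ndarray
    adjusted: bool = True


@dataclass(frozen=True)
class LifetimeMixture:
    """Two-component Gaussian mixture of a lifetime distribution."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    converged: bool


def survival_curve(lifetimes, grid=None) -> SurvivalCurve:
    """Empirical survival ratio S(t) = #{lifetime >= t} / N_T.

    ``grid`` must be sorted and start at 0 (where S = 1 because all
    lifetimes are positive).
    """
    life = np.asarray(lifetimes, dtype=float)
    if life.size == 0:
        raise ValueError("need at least one lifetime")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing and start at 0")
    srt = np.sort(life)
    n_ge = life.size - np.searchsorted(srt, grid - 1e-9, side="left")
    return SurvivalCurve(grid=grid, S=n_ge / life.size, n_total=int(life.size))


def iif_curve(
    s_with: SurvivalCurve,
    s_without: SurvivalCurve,
    pe_floor: float = 0.02,
    min_n: int = 100,
) -> IIFCurve:
    """Integrin-involved fraction from a paired pair of survival curves.

    ``s_with`` is the arm whose floor carries the integrin ligand (P_E),
    ``s_without`` the selectin-only arm (P).  Points where P_E has decayed
    below ``pe_floor`` are left undefined in the raw curve; the adjusted
    curve clips to [0, 1] and applies isotonic regression so that
    threshold crossings are well defined despite sampling noise.
    """
    if s_with.grid.shape != s_without.grid.shape or np.any(s_with.grid != s_without.grid):
        raise ValueError("survival curves must share an identical time grid")
    for name, c in (("with-ligand", s_with), ("without-ligand", s_without)):
        if c.n_total < min_n:
            raise ValueError(f"{name} cohort has {c.n_total} events; need >= {min_n}")
    ok = s_with.S >= pe_floor
    raw = np.full_like(s_with.S, np.nan, dtype=float)
    raw[ok] = (s_with.S[ok] - s_without.S[ok]) / s_with.S[ok]
    adj = np.full_like(raw, np.nan)
    if ok.any():
        clipped = np.clip(raw[ok], 0.0, 1.0)
        x = s_with.grid[ok]
        adj[ok] = IsotonicRegression(y_min=0.0, y_max=1.0).fit_transform(x, clipped)
    return IIFCurve(grid=s_with.grid, raw=raw, iif=adj, adjusted=True)


def iif_crossing_time(curve: IIFCurve, threshold: float) -> float:
    """First time the adjusted IIF reaches ``threshold``, interpolated.

    Returns NaN when the curve never reaches the threshold within its
    defined range (reported as undefined, never extrapolated).
    """
    if not curve.adjusted:
        raise ValueError("crossing times are defined on the adjusted curve only")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    y = curve.iif
    defined = ~np.isnan(y)
    idx = np.nonzero(defined & (y >= threshold))[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    prev = np.nonzero(defined[:i])[0]
    if prev.size == 0:
        return float(curve.grid[i])  # already above threshold at first defined point
    j = prev[-1]
    y0, y1 = y[j], y[i]
    if y1 == y0:
        return float(curve.grid[i])
    frac = (threshold - y0) / (y1 - y0)
    return float(curve.grid[j] + frac * (curve.grid[i] - curve.grid[j]))


def mean_lifetime_vs_wss(events: pd.DataFrame, min_events: int = 30) -> dict:
    """Per-WSS mean lifetime +- SEM with a quadratic (degree-2) fit.

    Expects columns ``wss_dyn_cm2`` and ``lifetime_s``.  Levels with
    fewer than 2 events are excluded with a warning; the fit needs at
    least 3 surviving levels.  Returns a dict with the tidy ``table``,
    the polynomial ``coeffs`` (highest degree first) and the fitted-apex
    WSS (NaN for a non-concave fit).
    """
    if events.empty:
        raise ValueError("empty event table")
    groups = []
    for wss, g in events.groupby("wss_dyn_cm2"):
        n = len(g)
        if n < 2:
            logger.warning("excluding WSS level %.3g with %d event(s)", wss, n)
            continue
        if n < min_events:
            logger.warning("WSS level %.3g has only %d events (< %d)", wss, n, min_events)
        life = g["lifetime_s"].to_numpy()
        groups.append((float(wss), life.mean(), life.std(ddof=1) / np.sqrt(n), n))
    if len(groups) < 2:
        raise ValueError("need >= 2 usable WSS levels")
    table = pd.DataFrame(groups, columns=["wss_dyn_cm2", "mean_s", "sem_s", "n"])
    coeffs = np.polyfit(table["wss_dyn_cm2"], table["mean_s"], deg=2)
    apex = -coeffs[1] / (2 * coeffs[0]) if coeffs[0] < 0 else float("nan")
    return {"table": table, "coeffs": coeffs, "apex_wss": float(apex)}


def lifetime_mixture_fit(
    lifetimes, k: int = 2, n_restarts: int = 10, seed: int = 0, min_n: int = 200
) -> LifetimeMixture:
    """EM fit of a k-component Gaussian mixture on raw lifetimes.

    Multiple random restarts, best log-likelihood kept, components
    reported in ascending order of mean.  Input order is irrelevant (the
    sample is sorted before fitting).
    """
    life = np.sort(np.asarray(lifetimes, dtype=float)).reshape(-1, 1)
    if life.shape[0] < min_n:
        raise ValueError(f"need >= {min_n} lifetimes for a stable mixture fit")
    gm = GaussianMixture(
        n_components=k, n_init=n_restarts, random_state=seed, covariance_type="full"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(life)
    if not gm.converged_:
        raise RuntimeError("EM did not converge after restarts")
    order = np.argsort(gm.means_.ravel())
    return LifetimeMixture(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(k)[order]),
        log_likelihood=float(gm.score(life) * life.shape[0]),
        converged=True,
    )


def wss_to_force(wss: float) -> float:
    """Tether force (pN) at wall shear stress ``wss`` (dyne/cm^2)."""
    if wss < 0:
        raise ValueError("wall shear stress must be >= 0")
    return PN_PER_DYNE_CM2 * wss


def tethering_adhesion_ratio(n_tethered: int, n_total: int) -> float:
    """Fraction of observed cells that tethered (per 1 min of observation)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_tethered <= n_total:
        raise ValueError("n_tethered must lie in [0, n_total]")
    return n_tethered / n_total


def bootstrap_mean_ci(
    values, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for a mean (used for lifetime summaries)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [a, 1.0 - a])
    return float(lo), float(hi)
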