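"""Synthetic calcium-fluorescence cohorts.

Each simulated cell contributes a 7-minute fluorescence recording at
20 fps: the cell-averaged Fluo-4 intensity plus four background domains
sampled around the cell.  Whether a cell bursts is Bernoulli in a
WSS-dependent probability (steep rise, then saturation); if it bursts,
the burst onset lags firm adhesion by a Gamma-distributed delay whose
mean decreases with WSS and is shorter when integrin ligands are engaged.
The burst itself is a smooth pulse (exponential rise times exponential
decay) on top of a constant baseline with white measurement noise.

Channel-blocker semantics separate the two calcium sources: 2-APB (IP3
receptor block) suppresses bursts of cells held by P-selectin alone,
LaCl3 (membrane channel block) suppresses bursts of integrin-engaged
cells, and each is inert for the other geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FPS",
    "DURATION_S",
    "CONDITIONS",
    "LIGAND_ENGAGED",
    "TREATMENTS",
    "DEFAULT_CALCIUM_WSS_GRID",
    "CalciumTraceParams",
    "CalciumCohort",
    "burst_prob",
    "delay_mean",
    "sample_delay_time",
    "generate_trace",
    "apply_channel_blockers",
    "generate_calcium_cohort",
]

#: acquisition rate of the calcium recordings, frames/s
FPS = 20.0
#: observation window, s (7 min)
DURATION_S = 420.0

#: substrate/pre-treatment arms of the calcium experiments
CONDITIONS = (
    "P-selectin",
    "P-selectin+ICAM1",
    "P-selectin+GPIbalpha",
    "Mg/ICAM1",
    "Mg/GPIbalpha",
)
#: arms in which the burst is driven through engaged integrins
LIGAND_ENGAGED = frozenset(CONDITIONS[1:])

TREATMENTS = ("none", "2-APB", "LaCl3", "both")

#: wall shear stresses probed in the calcium experiments, dyne/cm^2
DEFAULT_CALCIUM_WSS_GRID = (0.0, 0.1, 0.2, 0.6, 1.0, 2.0)


@dataclass(frozen=True)
class CalciumTraceParams:
    """Knobs of the calcium generator.

    Burst probability is logistic in log-WSS between ``burst_floor``
    (static cells burst rarely but not never) and ``burst_sat``; the mean
    delay decays exponentially in WSS to a condition-specific plateau
    reached by ~0.2 dyne/cm^2 (84 s for cells held by P-selectin alone,
    60 s whenever integrin ligands are engaged).
    """

    burst_floor: float = 0.1
    burst_sat: float = 0.8
    burst_wss_half: float = 0.15   # dyne/cm^2 at the logistic midpoint
    burst_log_slope: float = 0.6   # slope in ln(WSS)
    delay_at_ref: dict = field(
        default_factory=lambda: {"P-selectin": 84.0, "ligand": 60.0}
    )
    delay_ref_wss: float = 0.2     # dyne/cm^2 where delay_at_ref applies
    delay_wss_tau: float = 0.06    # dyne/cm^2 scale of the low-WSS rise
    delay_rise_frac: float = 1.0   # delay excess at WSS -> 0, as fraction of plateau
    delay_cv: float = 0.3
    amplitude: float = 3.0         # peak normalized intensity
    rise_tau: float = 2.0          # s
    decay_tau: float = 40.0        # s
    baseline: float = 100.0        # a.u.
    noise_sd: float = 5.0          # a.u.
    burst_scale: float = 1.0       # blocker multipliers
    delay_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.burst_floor <= self.burst_sat <= 1.0:
            raise ValueError("need 0 <= burst_floor <= burst_sat <= 1")
        if self.amplitude <= 0 or self.baseline <= 0:
            raise ValueError("amplitude and baseline must be positive")
        if self.delay_cv < 0 or self.noise_sd < 0:
            raise ValueError("delay_cv and noise_sd must be >= 0")


def burst_prob(wss: float, params: CalciumTraceParams) -> float:
    """Probability that a firmly adherent cell bursts within the window."""
    if wss < 0:
        raise ValueError("wall shear stress must be >= 0")
    if wss == 0:
        p = params.burst_floor
    else:
        z = (np.log(wss) - np.log(params.burst_wss_half)) / params.burst_log_slope
        p = params.burst_floor + (params.burst_sat - params.burst_floor) / (1 + np.exp(-z))
    return float(np.clip(p * params.burst_scale, 0.0, 1.0))


def delay_mean(wss: float, condition: str, params: CalciumTraceParams) -> float:
    """Expected burst delay (s): fast low-WSS decrease to a plateau."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    key = "ligand" if condition in LIGAND_ENGAGED else "P-selectin"
    ref = params.delay_at_ref[key]
    base = ref / (1.0 + params.delay_rise_frac * np.exp(-params.delay_ref_wss / params.delay_wss_tau))
    d = base * (1.0 + params.delay_rise_frac * np.exp(-wss / params.delay_wss_tau))
    return float(d * params.delay_scale)


def sample_delay_time(wss: float, condition: str, params: CalciumTraceParams, rng, n: int = 1):
    """Gamma-distributed burst delays with the configured mean and CV."""
    mean = delay_mean(wss, condition, params)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if params.delay_cv == 0:
        out = np.full(n, mean)
    else:
        shape = 1.0 / params.delay_cv**2
        out = gen.gamma(shape, mean / shape, size=n)
    out = np.minimum(out, DURATION_S - 1.0)  # keep onsets inside the window
    return float(out[0]) if n == 1 else out


def _pulse(t: np.ndarray, params: CalciumTraceParams) -> np.ndarray:
    """Peak-normalized burst pulse starting at t=0 (zero for t < 0)."""
    r, d = params.rise_tau, params.decay_tau
    tp = r * np.log1p(d / r)  # argmax of (1-e^(-t/r)) e^(-t/d)
    peak = (1 - np.exp(-tp / r)) * np.exp(-tp / d)
    x = np.clip(t, 0.0, None)
    return np.where(t >= 0, (1 - np.exp(-x / r)) * np.exp(-x / d) / peak, 0.0) * params.amplitude


def generate_trace(
    burst: bool, delay: float, params: CalciumTraceParams, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One cell's recording: ``(time, fi_cell, fi_bg[4, T])``.

    ``fi_cell(t) = baseline * (1 + F(t)) + noise`` where the pulse F is
    zero before the onset delay; background domains are baseline plus
    independent noise.  Non-burst traces are flat.
    """
    if burst and not 0.0 <= delay < DURATION_S:
        raise ValueError("burst onset must fall inside the observation window")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = np.arange(0.0, DURATION_S + 1e-9, 1.0 / FPS)
    f_model = _pulse(t - delay, params) if burst else np.zeros_like(t)
    fi_cell = params.baseline * (1.0 + f_model) + gen.normal(0, params.noise_sd, t.size)
    fi_bg = params.baseline + gen.normal(0, params.noise_sd, (4, t.size))
    return t, fi_cell, fi_bg


def apply_channel_blockers(
    params: CalciumTraceParams,
    treatment: str,
    condition: str,
    suppression: float = 0.2,
    delay_extension: float = 1.5,
) -> CalciumTraceParams:
    """Rewrite burst statistics for a channel-blocker pre-treatment.

    For cells held by P-selectin alone the burst rides on IP3-gated store
    release, so 2-APB suppresses it and LaCl3 is inert; for
    integrin-engaged cells the dependence is inverted.  ``both`` composes.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    engaged = condition in LIGAND_ENGAGED
    active = {"2-APB": not engaged, "LaCl3": engaged, "both": True, "none": False}[treatment]
    if not active:
        return params
    return replace(
        params,
        burst_scale=params.burst_scale * suppression,
        delay_scale=params.delay_scale * delay_extension,
    )


@dataclass
class CalciumCohort:
    """In-memory cohort: stacked traces plus metadata and hidden truth."""

    time: np.ndarray          # (T,)
    fi_cell: np.ndarray       # (n_cells, T)
    fi_bg: np.ndarray         # (n_cells, 4, T)
    meta: pd.DataFrame        # cell_id, condition, wss, treatment
    truth: pd.DataFrame       # cell_id, truth_burst, truth_delay

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (cell_id, t_s, fi_cell, fi_bg1..fi_bg4)."""
        n, T = self.fi_cell.shape
        frames = {
            "cell_id": np.repeat(self.meta["cell_id"].to_numpy(), T),
            "t_s": np.tile(self.time, n),
            "fi_cell": self.fi_cell.ravel(),
        }
        for k in range(4):
            frames[f"fi_bg{k + 1}"] = self.fi_bg[:, k, :].ravel()
        return pd.DataFrame(frames)


def generate_calcium_cohort(
    conditions: Sequence[str],
    wss_grid: Iterable[float],
    n_cells: int,
    seed,
    params: CalciumTraceParams | None = None,
    treatment: str = "none",
) -> CalciumCohort:
    """Simulate a conditions x WSS cohort of calcium recordings.

    Per cell: Bernoulli(burst_prob) decides the burst, burst-positive
    cells get a Gamma delay and a pulse trace, the rest stay flat.
    Deterministic in (arguments, seed).
    """
    conditions = list(conditions)
    wss_grid = [float(w) for w in wss_grid]
    if not conditions or not wss_grid:
        raise ValueError("empty generation plan")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    base = params or CalciumTraceParams()
    gen = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t = np.arange(0.0, DURATION_S + 1e-9, 1.0 / FPS)
    cells, bgs, meta_rows, truth_rows = [], [], [], []
    cid = 0
    for condition in conditions:
        p = apply_channel_blockers(base, treatment, condition)
        for wss in wss_grid:
            pb = burst_prob(wss, p)
            is_burst = gen.random(n_cells) < pb
            delays = np.atleast_1d(sample_delay_time(wss, condition, p, gen, n=n_cells))
            f_model = np.zeros((n_cells, t.size))
            for i in np.nonzero(is_burst)[0]:
                f_model[i] = _pulse(t - delays[i], p)
            fi_cell = p.baseline * (1.0 + f_model) + gen.normal(0, p.noise_sd, (n_cells, t.size))
            fi_bg = p.baseline + gen.normal(0, p.noise_sd, (n_cells, 4, t.size))
            cells.append(fi_cell)
            bgs.append(fi_bg)
            for i in range(n_cells):
                meta_rows.append((cid, condition, wss, treatment))
                truth_rows.append(
                    (cid, bool(is_burst[i]), float(delays[i]) if is_burst[i] else np.nan)
                )
                cid += 1
    return CalciumCohort(
        time=t,
        fi_cell=np.vstack(cells),
        fi_bg=np.concatenate(bgs, axis=0),
        meta=pd.DataFrame(meta_rows, columns=["cell_id", "condition", "wss", "treatment"]),
        truth=pd.DataFrame(truth_rows, columns=["cell_id", "truth_burst", "truth_delay"]),
    )
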