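"""Shared infrastructure: tables, configs, seeds, reports, orchestration.

All tables are RFC-4180 CSV (UTF-8, '.' decimal); summaries are JSON;
run configuration is YAML with a mandatory integer seed that fans out
deterministically to per-module child seeds.  Ground-truth columns are
written only on request, so analysis code can never peek at them by
accident.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import activation_imaging as ai
from . import calcium_analysis as ca
from . import calcium_sim as cs
from . import tether_analysis as ta
from . import tether_sim as ts

__all__ = [
    "TETHER_SCHEMA",
    "IMAGING_SCHEMA",
    "RunConfig",
    "load_config",
    "spawn_seeds",
    "read_table",
    "write_table",
    "compare_groups",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)

TETHER_SCHEMA = ["event_id", "condition", "ligand", "inhibitors", "wss_dyn_cm2", "lifetime_s"]
TETHER_TRUTH_COLS = ["engaged_truth"]
IMAGING_SCHEMA = ["cell_id", "condition", "treatment", "stimulus_min", "fi_c", "fi_b"]
IMAGING_TRUTH_COLS = ["activated_truth"]

@dataclass
class RunConfig:
    """Validated run plan for the end-to-end pipeline."""

    seed: int
    out_dir: str = "neutroflow_out"
    tether_conditions: list = field(
        default_factory=lambda: ["none", "ICAM1", "GPIbalpha"]
    )  # ligand per arm
    tether_wss_grid: list = field(default_factory=lambda: list(ts.DEFAULT_WSS_GRID))
    tether_n_events: int = 2000
    calcium_conditions: list = field(default_factory=lambda: list(cs.CONDITIONS))
    calcium_wss_grid: list = field(default_factory=lambda: list(cs.DEFAULT_CALCIUM_WSS_GRID))
    calcium_n_cells: int = 20
    imaging_conditions: list = field(default_factory=lambda: list(ai.IMAGING_CONDITIONS))
    imaging_times_min: list = field(default_factory=lambda: list(ai.DEFAULT_STIMULUS_TIMES_MIN))
    imaging_n_cells: int = 300
    write_truth: bool = False

    _KNOWN = None  # filled below

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if any(w < 0 for w in list(self.tether_wss_grid) + list(self.calcium_wss_grid)):
            raise ValueError("wss values must be >= 0")


RunConfig._KNOWN = frozenset(
    k for k in RunConfig.__dataclass_fields__ if not k.startswith("_")
)


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - RunConfig._KNOWN
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("seed is mandatory")
    return RunConfig(**raw)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (below 2**31) from one global seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(n)]


def write_table(df: pd.DataFrame, path, schema: list[str], truth_cols: list[str] | None = None,
                truth: bool = False) -> None:
    """Write a CSV with a fixed column order; truth columns only on request."""
    cols = list(schema) + (list(truth_cols) if truth and truth_cols else [])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    df[cols].to_csv(path, index=False)


def read_table(path, schema: list[str], truth_cols: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV whose header must match the schema (truth columns optional)."""
    df = pd.read_csv(path)
    allowed = set(schema) | set(truth_cols or [])
    missing = [c for c in schema if c not in df.columns]
    extra = [c for c in df.columns if c not in allowed]
    if missing or extra:
        raise ValueError(f"schema mismatch: missing {missing}, unexpected {extra}")
    return df


def compare_groups(df: pd.DataFrame, value: str, group: str,
                   factor2: str | None = None) -> dict:
    """Group comparison report: ANOVA plus Bonferroni-adjusted pairwise tests.

    One-way ANOVA on ``group`` (two-way with interaction if ``factor2``
    is given), then all pairwise Welch t-tests with p-values adjusted by
    Bonferroni (p_adj = min(1, m * p)).  Needs >= 2 groups with >= 3
    observations each.
    """
    groups = {k: g[value].to_numpy(float) for k, g in df.groupby(group)}
    if len(groups) < 2 or any(len(v) < 3 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 3 replicates each")
    if factor2 is None:
        f_stat, f_p = sps.f_oneway(*groups.values())
        anova = {"test": "one-way ANOVA", "F": float(f_stat), "p": float(f_p)}
    else:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        d = df.rename(columns={value: "y", group: "g1", factor2: "g2"})
        model = ols("y ~ C(g1) * C(g2)", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
        anova = {
            "test": "two-way ANOVA",
            "F": float(table.loc["C(g1)", "F"]),
            "p": float(table.loc["C(g1)", "PR(>F)"]),
        }
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t_stat, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({
            "group_a": a, "group_b": b,
            "effect": float(np.mean(groups[a]) - np.mean(groups[b])),
            "statistic": float(t_stat), "p_raw": float(p),
            "p_adj": float(min(1.0, m * p)),
        })
    return {"anova": anova, "pairwise": rows, "adjustment": "bonferroni", "m": m}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Simulate all three assays, analyze them, and write a report bundle.

    Outputs (CSV/JSON) land in ``config.out_dir`` together with a
    manifest recording the config, the seed and a hash of every file;
    rerunning with the same config and seed reproduces every byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(config.seed, 3)
    stage = "simulate-tethers"
    try:
        conditions = [ts.SubstrateCondition(ligand=l) for l in config.tether_conditions]
        events = ts.generate_tether_dataset(
            conditions, config.tether_wss_grid, config.tether_n_events, seeds[0]
        )
        write_table(events, out / "tether_events.csv", TETHER_SCHEMA,
                    TETHER_TRUTH_COLS, truth=config.write_truth)

        stage = "analyze-tethers"
        tether_summary = {}
        for cond, g in events.groupby("condition"):
            res = ta.mean_lifetime_vs_wss(g)
            tether_summary[cond] = {
                "mean_by_wss": res["table"].to_dict(orient="records"),
                "apex_wss": res["apex_wss"],
            }
        ref = min(config.tether_wss_grid, key=lambda w: abs(w - 0.2))
        crossings = {}
        for lig in ("ICAM1", "GPIbalpha"):
            if lig not in config.tether_conditions or "none" not in config.tether_conditions:
                continue
            lab_e = ts.SubstrateCondition(ligand=lig).label
            lab_0 = ts.SubstrateCondition().label
            ge = events.query("condition == @lab_e and wss_dyn_cm2 == @ref")["lifetime_s"]
            g0 = events.query("condition == @lab_0 and wss_dyn_cm2 == @ref")["lifetime_s"]
            if len(ge) < 100 or len(g0) < 100:
                continue
            curve = ta.iif_curve(ta.survival_curve(ge), ta.survival_curve(g0))
            crossings[lig] = {
                str(th): ta.iif_crossing_time(curve, th) for th in (0.10, 0.50, 0.95)
            }
        (out / "tether_summary.json").write_text(
            json.dumps({"mean_lifetime": tether_summary,
                        "iif_crossings_at_wss": {"wss": ref, "by_ligand": crossings}},
                       indent=2, allow_nan=True, default=float)
        )

        stage = "simulate-calcium"
        cohort = cs.generate_calcium_cohort(
            config.calcium_conditions, config.calcium_wss_grid,
            config.calcium_n_cells, seeds[1],
        )
        stage = "analyze-calcium"
        calls = ca.detect_bursts(cohort)
        summary = ca.cohort_summary(calls, cohort.meta)
        summary.to_csv(out / "calcium_summary.csv", index=False)
        corr = ca.correlate_with_wss(calls, cohort.meta, unit="ratio")
        corr.to_csv(out / "calcium_wss_correlation.csv", index=False)

        stage = "simulate-imaging"
        records = ai.generate_imaging_cohort(
            config.imaging_conditions, config.imaging_times_min,
            config.imaging_n_cells, seeds[2],
        )
        write_table(records, out / "imaging_cells.csv", IMAGING_SCHEMA,
                    IMAGING_TRUTH_COLS, truth=config.write_truth)
        stage = "analyze-imaging"
        imaging = {}
        for cond, g in records.groupby("condition"):
            series = pd.DataFrame(
                [(t, ai.activation_ratio(gt)) for t, gt in g.groupby("stimulus_min")],
                columns=["stimulus_min", "ratio"],
            )
            series = ai.normalize_by_static(series)
            fit = ai.fit_timecourse(series["stimulus_min"], series["normalized"])
            imaging[cond] = {
                "series": series.to_dict(orient="records"),
                "threshold_min": fit.t50,
                "plateau_normalized": fit.plateau,
            }
        (out / "imaging_summary.json").write_text(
            json.dumps(imaging, indent=2, default=float)
        )
    except Exception as err:  # noqa: BLE001 - annotate failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps({k: getattr(config, k) for k in sorted(RunConfig._KNOWN)},
                       sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
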