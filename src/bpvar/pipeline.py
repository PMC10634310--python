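"""Config-driven orchestration of the full estimation grid.

A single :class:`RunConfig` describes the data source (a supplied panel file
or the built-in synthetic study fixture), the variable roles, the prior and
MCMC settings, and the experiment grid: one model per health indicator, with
optional alternative lag lengths, a sixth augmentation variable, and
subsample runs by market class or income tier.  Each model run writes
impulse-response tables, posterior draws, and a convergence report under the
output directory, and everything is tied together in a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as dm
from . import estimator as est
from . import simulate as sim
from . import structural as st

logger = logging.getLogger(__name__)

GIBBS_PROFILES = {
    "desk": (2_000, 1_000),
    "reference": (55_000, 45_000),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce an estimation grid.

    Exactly one health indicator enters each model; the optional
    ``augmentation`` variable makes a 6-variate system, placed after
    healthcare expenditure and before the health indicator so that
    uncertainty stays first and health last in the recursive ordering.
    """

    # data source: a panel file, or the synthetic study fixture
    panel_path: str | None = None
    groups_path: str | None = None
    use_fixture: bool = True
    fixture_countries: int = 103
    fixture_years: int = 25

    # variable roles (names of columns in the panel)
    uncertainty: str = "uncertainty"
    gdp: str = "gdp"
    co2: str = "co2"
    health_exp: str = "health_exp"
    health_indicators: list[str] = field(default_factory=lambda: ["health_indicator"])
    augmentation: str | None = None
    log_variables: list[str] = field(default_factory=list)

    # model and prior
    lag_orders: list[int] = field(default_factory=lambda: [1])
    gamma: float = 1.0
    tau: float = 1.0
    c: float = 0.001
    lam: float = 10.0

    # MCMC schedule: profile presets, overridable explicitly
    profile: str = "desk"
    n_total: int | None = None
    n_burn: int | None = None
    thin: int = 1

    # structural analysis
    shock_variables: list[str] | None = None  # default: all non-health variables
    shock_size: float = 0.01
    horizons: int = 10

    # subsampling
    subsample_key: str | None = None
    subsample_labels: list[str] | None = None

    seed: int = 0
    output_dir: str = "bpvar_output"

    def gibbs_schedule(self) -> tuple[int, int]:
        if self.n_total is not None and self.n_burn is not None:
            return self.n_total, self.n_burn
        if self.profile not in GIBBS_PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; known: {sorted(GIBBS_PROFILES)}")
        return GIBBS_PROFILES[self.profile]

    def ordering(self, health_indicator: str) -> tuple[str, ...]:
        order = [self.uncertainty, self.gdp, self.co2, self.health_exp]
        if self.augmentation:
            order.append(self.augmentation)
        order.append(health_indicator)
        return tuple(order)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_input_panel(config: RunConfig) -> dm.PanelDataset:
    """Load the user panel or generate the synthetic study fixture."""
    if config.panel_path is not None:
        panel = dm.read_panel(config.panel_path, groups_path=config.groups_path)
        if config.log_variables:
            prep = dm.PrepConfig(frozenset(config.log_variables), config.uncertainty)
            panel = dm.apply_logs(panel, prep)
        return panel
    if not config.use_fixture:
        raise ValueError("no panel_path given and use_fixture is false")
    panel, _ = sim.make_study_fixture(
        seed=config.seed, n_countries=config.fixture_countries, n_years=config.fixture_years
    )
    return panel


def run_model(
    config: RunConfig,
    health_indicator: str,
    panel: dm.PanelDataset | None = None,
    lag_order: int | None = None,
    subsample: tuple[str, str] | None = None,
    seed: int | None = None,
    model_id: str | None = None,
) -> dict:
    """Fit one model (one health indicator) end to end and write its artifacts.

    Stages: variable selection → design → prior dummies → Gibbs →
    identification → IRF summaries → convergence report.  Returns the
    manifest entry; on failure the entry records the failing stage instead
    of raising, so grid runs continue.
    """
    lag_order = lag_order if lag_order is not None else config.lag_orders[0]
    seed = seed if seed is not None else config.seed
    if model_id is None:
        model_id = f"{health_indicator}_p{lag_order}"
        if subsample:
            model_id += f"_{subsample[0]}-{subsample[1]}"
    out_dir = Path(config.output_dir) / model_id
    entry: dict = {
        "model_id": model_id,
        "health_indicator": health_indicator,
        "lag_order": lag_order,
        "subsample": list(subsample) if subsample else None,
        "seed": seed,
        "status": "ok",
        "outputs": {},
    }
    stage = "load"
    t0 = time.perf_counter()
    try:
        if panel is None:
            panel = load_input_panel(config)
        if subsample is not None:
            stage = "subset"
            panel = dm.subset_by_group(panel, *subsample)
        stage = "select"
        order = config.ordering(health_indicator)
        missing = [v for v in order if v not in panel.frame.columns]
        if missing:
            raise ValueError(f"panel lacks variables {missing}")
        frame = panel.frame[list(dm.ID_COLUMNS) + list(order)]
        model_panel = dm.PanelDataset(frame.copy(), list(order), panel.group_labels)
        spec = est.VARSpec(order, lag_order)

        stage = "design"
        design = est.build_design(model_panel, spec)
        stage = "prior"
        hyper = est.default_hyperparams(
            model_panel, spec, gamma=config.gamma, tau=config.tau, c=config.c, lam=config.lam
        )
        dummies = est.build_dummies(spec, hyper, model_panel.n_countries)
        stage = "gibbs"
        n_total, n_burn = config.gibbs_schedule()
        gcfg = est.GibbsConfig(n_total=n_total, n_burn=n_burn, thin=config.thin, seed=seed)
        draws = est.run_gibbs(design, dummies, gcfg, spec=spec)

        out_dir.mkdir(parents=True, exist_ok=True)
        draws.save(out_dir / "draws")
        entry["outputs"]["draws"] = str(out_dir / "draws.npz")

        stage = "structural"
        shocks = config.shock_variables or [v for v in order if v != health_indicator]
        tables = []
        for shock in shocks:
            irfs = st.compute_irfs(draws, shock, config.shock_size, config.horizons)
            tables.append(st.summarize_irf(irfs).table)
        irf_table = pd.concat(tables, ignore_index=True)
        irf_path = out_dir / "irf.csv"
        irf_table.to_csv(irf_path, index=False, float_format="%.10g")
        entry["outputs"]["irf"] = str(irf_path)

        stage = "diagnostics"
        report = st.convergence_report(draws)
        b_median = np.median(draws.B_draws, axis=0)
        report["spectral_radius_posterior_median"] = st.stationarity_check(
            b_median, spec.n_vars, lag_order
        )
        report["n_obs"] = design.n_obs
        report["K"] = design.K
        report["TD"] = dummies.TD
        (out_dir / "convergence.json").write_text(json.dumps(report, indent=1))
        entry["outputs"]["convergence"] = str(out_dir / "convergence.json")
        entry["convergence"] = report
        entry["runtime_s"] = round(time.perf_counter() - t0, 3)
        logger.info("model %s done in %.1fs (K=%d, TD=%d)", model_id, entry["runtime_s"], design.K, dummies.TD)
    except Exception as err:  # noqa: BLE001 — grid runs must keep going
        entry["status"] = "failed"
        entry["stage"] = stage
        entry["error"] = f"{type(err).__name__}: {err}"
        logger.warning("model %s failed at stage %s: %s", model_id, stage, err)
    return entry


def run_grid(config: RunConfig) -> dict:
    """Run the full experiment grid and write the manifest.

    Grid = health indicators × lag orders × (full sample + any subsample
    labels).  Each run gets its own derived seed so runs are independent yet
    jointly reproducible.
    """
    panel = load_input_panel(config)
    subsamples: list[tuple[str, str] | None] = [None]
    if config.subsample_key:
        labels = config.subsample_labels
        if labels is None:
            if panel.group_labels is None:
                raise ValueError("subsample requested but panel has no group labels")
            labels = sorted({g[config.subsample_key] for g in panel.group_labels.values()})
        subsamples += [(config.subsample_key, lab) for lab in labels]

    entries = []
    run_index = 0
    for indicator in config.health_indicators:
        for lag in config.lag_orders:
            for sub in subsamples:
                seed = (config.seed + 1009 * run_index) % (2**31 - 1)
                entries.append(
                    run_model(config, indicator, panel=panel, lag_order=lag,
                              subsample=sub, seed=seed)
                )
                run_index += 1
    manifest = {
        "config": config.to_dict(),
        "n_models": len(entries),
        "n_failed": sum(e["status"] != "ok" for e in entries),
        "models": entries,
    }
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def compare_groups(summaries: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Overlay IRF summary tables from different groups into one long table.

    All tables must share the same (shock, response, horizon) grid; the
    result adds a ``group`` column for side-by-side plotting.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups to compare")
    keys = ["shock", "response", "horizon"]
    grids = {
        g: set(map(tuple, t[keys].itertuples(index=False))) for g, t in summaries.items()
    }
    reference = next(iter(grids.values()))
    for g, grid in grids.items():
        if grid != reference:
            raise ValueError(f"group {g!r} has a mismatched (shock, response, horizon) grid")
    parts = []
    for g, t in summaries.items():
        part = t.copy()
        part.insert(0, "group", g)
        parts.append(part)
    return pd.concat(parts, ignore_index=True).sort_values(
        keys + ["group"], kind="mergesort"
    ).reset_index(drop=True)
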