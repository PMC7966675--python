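"""End-to-end indicator pipeline: synth → heat → labour → burden → events →
economics → indices, with a JSON run manifest for provenance.

The pipeline is deterministic: identical configuration (including the seed)
produces bit-identical output CSVs.  Each stage failure aborts the run with
the stage name and a machine-readable error code.
"""

from __future__ import annotations

import json
import logging

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    heatwave_attributable_deaths,
    prevented_fraction,
    apply_prevention,
    vectorial_capacity,
    vc_percent_change,
)
from .economics import VSLConfig, io_losses, monetise_mortality
from .events import cyclone_trend, period_change, wildfire_exposure
from .heat import (
    compute_threshold,
    detect_heatwaves,
    exposure_person_days,
    heatwave_days_per_year,
)
from .indices import IndexComponent, composite_index
from .labour import INDUSTRY_DEFAULTS, annual_hours_lost, vapour_pressure, wbgt, work_capacity
from .synth import (
    ClimateScenarioSpec,
    EconomySpec,
    EventSpec,
    PopulationSpec,
    generate_climate,
    generate_events,
    generate_io_table,
    generate_population,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "default_config", "run_pipeline"]

STAGES = ("synth", "heat", "labour", "burden", "events", "economics", "indices")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


def default_config(seed: int = 0) -> dict:
    """Demo configuration exercising every stage on a small grid."""
    return {
        "seed": seed,
        "climate": {
            "shape": [4, 4],
            "baseline_years": [1986, 2005],
            "analysis_years": [2006, 2019],
            "base_temp_mean": 24.0,
            "seasonal_amplitude": 8.0,
            "trend_per_decade": 0.5,
            "noise_sd": 2.0,
        },
        "population": {"shape": [4, 4], "total": 1_000_000, "elderly_fraction": 0.12},
        "economy": {"n_sectors": 5, "interdependence": 0.5},
        "events": {"shape": [4, 4], "n_years": 20, "wildfire_rate": 1.0},
        "heatwave": {"percentile": 92.5, "min_run": 3, "summer_months": [6, 7, 8]},
        "burden": {"rr": 1.104, "baseline_daily_deaths": 100.0, "ac_prevalence": 0.6, "ac_efficacy": 0.75},
        "labour": {"workers": {"primary": 10_000, "secondary": 20_000, "tertiary": 30_000}},
        "economics": {"labour_share_shock": 0.02, "vsl": 3.2e6},
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, outdir: str | Path = "climhealth_run") -> dict:
    """Execute all pipeline stages, writing one CSV per indicator plus a
    run manifest.  Returns the manifest dict."""
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": [],
        "outputs": {},
    }

    def _stage(name):
        def deco(fn):
            try:
                fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, "stage_failure", str(exc)) from exc
            manifest["stages"].append({"name": name, "status": "completed"})

        return deco

    state: dict = {}

    @_stage("synth")
    def _synth():
        ccfg = cfg.get("climate", {})
        state["climate"] = generate_climate(
            ClimateScenarioSpec(
                shape=tuple(ccfg.get("shape", (4, 4))),
                baseline_years=tuple(ccfg.get("baseline_years", (1986, 2005))),
                analysis_years=tuple(ccfg.get("analysis_years", (2006, 2019))),
                base_temp_mean=ccfg.get("base_temp_mean", 24.0),
                seasonal_amplitude=ccfg.get("seasonal_amplitude", 8.0),
                trend_per_decade=ccfg.get("trend_per_decade", 0.5),
                noise_sd=ccfg.get("noise_sd", 2.0),
                seed=seed,
            )
        )
        pcfg = cfg.get("population", {})
        state["population"] = generate_population(
            PopulationSpec(
                shape=tuple(pcfg.get("shape", (4, 4))),
                total=pcfg.get("total", 1_000_000),
                elderly_fraction=pcfg.get("elderly_fraction", 0.12),
                seed=seed + 1,
            )
        )
        ecfg = cfg.get("economy", {})
        state["io_table"] = generate_io_table(
            EconomySpec(
                n_sectors=ecfg.get("n_sectors", 5),
                interdependence=ecfg.get("interdependence", 0.5),
                seed=seed + 2,
            )
        )
        vcfg = cfg.get("events", {})
        state["wildfire"], state["cyclones"] = generate_events(
            EventSpec(
                shape=tuple(vcfg.get("shape", (4, 4))),
                n_years=vcfg.get("n_years", 20),
                wildfire_rate=vcfg.get("wildfire_rate", 1.0),
                seed=seed + 3,
            )
        )

    @_stage("heat")
    def _heat():
        hcfg = cfg.get("heatwave", {})
        climate = state["climate"]
        baseline_years = tuple(cfg.get("climate", {}).get("baseline_years", (1986, 2005)))
        analysis_years = tuple(cfg.get("climate", {}).get("analysis_years", (2006, 2019)))
        thr = compute_threshold(
            climate,
            percentile=hcfg.get("percentile", 92.5),
            summer_months=tuple(hcfg.get("summer_months", (6, 7, 8))),
            baseline_years=baseline_years,
        )
        hw = detect_heatwaves(climate, thr, min_run=hcfg.get("min_run", 3))
        days = heatwave_days_per_year(hw)
        base_days = days.sel(
            year=(days["year"] >= baseline_years[0]) & (days["year"] <= baseline_years[1])
        ).mean("year")
        analysis_days = days.sel(
            year=(days["year"] >= analysis_years[0]) & (days["year"] <= analysis_years[1])
        )
        exposure = exposure_person_days(
            analysis_days, base_days, state["population"]["elderly"]
        )
        state["heatwave_days"] = analysis_days
        state["exposure"] = exposure
        path = out / "heatwave_exposure.csv"
        exposure.table.to_csv(path, index=False)
        manifest["outputs"]["heatwave_exposure"] = str(path)

    @_stage("labour")
    def _labour():
        climate = state["climate"]
        # regional mean daily series over the analysis span
        ay = tuple(cfg.get("climate", {}).get("analysis_years", (2006, 2019)))
        sel = climate.sel(time=(climate["year"] >= ay[0]) & (climate["year"] <= ay[1]))
        ta = sel["tmax"].mean(("lat", "lon")).values
        rh = sel["rh"].mean(("lat", "lon")).values
        w = wbgt(ta, vapour_pressure(ta, rh))
        workers = cfg.get("labour", {}).get("workers", {"primary": 10_000})
        frames = []
        for industry, n_workers in workers.items():
            cap = work_capacity(w, industry)
            res = annual_hours_lost(cap, INDUSTRY_DEFAULTS[industry], workers=n_workers)
            frames.append(res.table)
        table = pd.concat(frames, ignore_index=True)
        state["labour"] = table
        path = out / "labour_loss.csv"
        table.to_csv(path, index=False)
        manifest["outputs"]["labour_loss"] = str(path)

    @_stage("burden")
    def _burden():
        bcfg = cfg.get("burden", {})
        days = state["heatwave_days"]
        per_year_days = days.sum(("lat", "lon")) / (days.sizes["lat"] * days.sizes["lon"])
        rows = []
        for year, n_days in zip(days["year"].values, per_year_days.values):
            res = heatwave_attributable_deaths(
                bcfg.get("baseline_daily_deaths", 100.0), float(n_days), bcfg.get("rr", 1.104)
            )
            deaths = res.total_deaths
            pf = prevented_fraction(bcfg.get("ac_prevalence", 0.6), bcfg.get("ac_efficacy", 0.75))
            rows.append(
                {
                    "year": int(year),
                    "heatwave_days": float(n_days),
                    "attributable_deaths": deaths,
                    "prevented_fraction": pf,
                    "residual_deaths": apply_prevention(deaths, pf),
                }
            )
        table = pd.DataFrame(rows)
        state["burden"] = table
        # vectorial capacity on era means
        climate = state["climate"]
        by = tuple(cfg.get("climate", {}).get("baseline_years", (1986, 2005)))
        ay = tuple(cfg.get("climate", {}).get("analysis_years", (2006, 2019)))
        t_base = climate["tmax"].sel(time=(climate["year"] >= by[0]) & (climate["year"] <= by[1]))
        t_ana = climate["tmax"].sel(time=(climate["year"] >= ay[0]) & (climate["year"] <= ay[1]))
        _, vc_base = vectorial_capacity(t_base.mean(("lat", "lon")).values)
        _, vc_ana = vectorial_capacity(t_ana.mean(("lat", "lon")).values)
        state["vc_change_pct"] = vc_percent_change(vc_base, vc_ana)
        path = out / "heat_mortality.csv"
        table.to_csv(path, index=False)
        manifest["outputs"]["heat_mortality"] = str(path)

    @_stage("events")
    def _events():
        exposure = wildfire_exposure(
            state["wildfire"],
            state["population"]["population"],
            state["population"]["urban_mask"],
        )
        n = state["wildfire"].sizes["year"]
        half = n // 2
        years = state["wildfire"]["year"].values
        change = period_change(
            exposure.per_year, (int(years[0]), int(years[half - 1])), (int(years[half]), int(years[-1]))
        )
        trend = cyclone_trend(state["cyclones"], (1980, 1999), (2000, 2019))
        state["wildfire_exposure"] = exposure
        state["wildfire_change"] = change
        state["cyclone_trend"] = trend
        p1 = out / "wildfire_exposure.csv"
        exposure.per_year.to_csv(p1, index=False)
        p2 = out / "cyclone_trend.csv"
        trend.table.to_csv(p2, index=False)
        manifest["outputs"]["wildfire_exposure"] = str(p1)
        manifest["outputs"]["cyclone_trend"] = str(p2)

    @_stage("economics")
    def _economics():
        ecfg = cfg.get("economics", {})
        io = state["io_table"]
        shock = np.full(io.n_sectors, ecfg.get("labour_share_shock", 0.02))
        losses = io_losses(shock, io, shock_kind="labour-share")
        deaths = float(state["burden"]["attributable_deaths"].sum())
        cost = monetise_mortality(deaths, VSLConfig(ecfg.get("vsl", 3.2e6)))
        state["losses"] = losses
        state["mortality_cost"] = cost
        table = losses.to_frame()
        path = out / "economic_losses.csv"
        table.to_csv(path, index=False)
        manifest["outputs"]["economic_losses"] = str(path)
        manifest["outputs"]["mortality_cost_usd2015"] = cost

    @_stage("indices")
    def _indices():
        heat_pd = float(state["exposure"].table["excess_person_days"].iloc[-1])
        losses = state["losses"]
        components = [
            IndexComponent("excess_exposure", heat_pd, 1 / 3, (0, max(heat_pd, 1.0) * 2), "higher-is-worse"),
            IndexComponent(
                "economic_loss_gdp_share",
                losses.gdp_share_pct,
                1 / 3,
                (0, max(losses.gdp_share_pct, 1.0) * 2),
                "higher-is-worse",
            ),
            IndexComponent(
                "prevented_fraction",
                float(state["burden"]["prevented_fraction"].iloc[-1]),
                1 / 3,
                (0, 1),
                "higher-is-better",
            ),
        ]
        score = composite_index(components)
        table = pd.DataFrame(
            [{"index": "demo_preparedness", "score": score, "vc_change_pct": state["vc_change_pct"]}]
        )
        path = out / "indices.csv"
        table.to_csv(path, index=False)
        manifest["outputs"]["indices"] = str(path)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["manifest_path"] = str(manifest_path)
    state["manifest"] = manifest
    run_pipeline.last_state = state  # exposed for tests / acceptance
    return manifest
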