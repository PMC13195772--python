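"""End-to-end pipeline: survey + mortality + benchmark -> AAFs, rates, CIs.

Stages are runnable standalone on each other's CSV artifacts (see
:mod:`aafengine.cli`) or chained in memory with :func:`run_pipeline`; the
two paths produce identical numbers.  Surveys are biennial while mortality
is annual, so each mortality year is assigned the nearest survey year's
exposure (ties broken toward the earlier survey).  A YAML manifest records
the configuration hash, seed, calibration factors and warnings so any run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aaf import DEFAULT_GRID_SIZE, compute_all_aafs
from .attribution import attributable_deaths, build_death_table, rate_table
from .constants import AGE_GROUPS, who_standard_weights
from .exposure import (
    carry_forward_oldest,
    estimate_exposures,
    exposures_to_frame,
    frame_to_exposures,
)
from .rr import RRRegistry, illustrative_registry, load_registry
from .uncertainty import (
    SimulationSpec,
    attributable_draws,
    percentile_ci,
    simulate_aafs,
    summarize_aaf_draws,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    survey: str
    mortality: str
    benchmark: str
    population: str
    outdir: str
    registry: str | None = None  # None -> shipped illustrative registry
    seed: int = 0
    coverage: float = 1.0
    grams_per_drink: float = 14.0
    cap: float = 150.0
    grid_size: int = DEFAULT_GRID_SIZE
    n_iterations: int = 2000
    perturb_prevalence: bool = True
    perturb_consumption: bool = True
    perturb_rr: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        for name in ("survey", "mortality", "benchmark", "population"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.registry is not None and not Path(self.registry).exists():
            raise FileNotFoundError(f"registry file not found: {self.registry}")

    def load_registry(self) -> RRRegistry:
        if self.registry is None:
            return illustrative_registry()
        return load_registry(self.registry)

    def simulation_spec(self) -> SimulationSpec:
        return SimulationSpec(
            n_iterations=self.n_iterations, seed=self.seed,
            perturb_prevalence=self.perturb_prevalence,
            perturb_consumption=self.perturb_consumption,
            perturb_rr=self.perturb_rr, grid_size=self.grid_size,
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()


def nearest_survey_year(year: int, survey_years: list[int]) -> int:
    """Nearest survey year; ties broken toward the earlier survey."""
    return min(survey_years, key=lambda s: (abs(s - year), s))


# --- stages ------------------------------------------------------------------


def stage_exposure(survey: pd.DataFrame, benchmark: pd.DataFrame,
                   config: RunConfig) -> pd.DataFrame:
    """Per-survey-wave exposure estimation + oldest-group carry-forward."""
    bench = benchmark.set_index("year")["pcc_litres"]
    frames = []
    for year in sorted(survey["year"].unique()):
        wave = survey[survey["year"] == year]
        exposures = estimate_exposures(
            wave, float(bench.loc[year]), coverage=config.coverage,
            grams_per_drink=config.grams_per_drink, cap=config.cap,
            year=int(year))
        exposures = carry_forward_oldest(exposures)
        frames.append(exposures_to_frame(exposures))
    return pd.concat(frames, ignore_index=True)


def stage_aaf(exposure_frame: pd.DataFrame, registry: RRRegistry,
              mortality_years: list[int],
              grid_size: int = DEFAULT_GRID_SIZE) -> pd.DataFrame:
    """AAF table per mortality year via nearest-survey-year exposure."""
    survey_years = sorted(exposure_frame["year"].dropna().unique())
    frames = []
    for year in mortality_years:
        sy = nearest_survey_year(int(year), [int(y) for y in survey_years])
        exposures = frame_to_exposures(
            exposure_frame[exposure_frame["year"] == sy])
        aafs = compute_all_aafs(exposures, registry, grid_size)
        aafs["survey_year"] = sy
        aafs["year"] = int(year)
        frames.append(aafs)
    return pd.concat(frames, ignore_index=True)


def stage_attribute(mortality: pd.DataFrame, aaf_table: pd.DataFrame,
                    population: pd.DataFrame,
                    registry: RRRegistry) -> dict[str, pd.DataFrame]:
    """Death aggregation, AAF application, crude + standardized rates."""
    table = build_death_table(mortality, registry)
    att = attributable_deaths(table, aaf_table, registry)
    rates = rate_table(att, table.totals, population)
    return {"deaths": table.counts, "totals": table.totals,
            "unmapped": table.unmapped, "attributable": att, "rates": rates}


def stage_ci(exposure_frame: pd.DataFrame, registry: RRRegistry,
             attributable: pd.DataFrame, totals: pd.DataFrame,
             population: pd.DataFrame, config: RunConfig
             ) -> dict[str, pd.DataFrame]:
    """Monte Carlo CIs for AAFs and for attributable counts/rates.

    AAF draws are simulated once per survey wave and reused for every
    mortality year mapped to that wave, so derived intervals are transforms
    of one draw matrix.
    """
    spec = config.simulation_spec()
    survey_years = sorted(int(y) for y in exposure_frame["year"].dropna().unique())
    draws_by_wave = {}
    aaf_ci_frames = []
    for sy in survey_years:
        exposures = frame_to_exposures(
            exposure_frame[exposure_frame["year"] == sy])
        draws = simulate_aafs(exposures, registry, spec)
        draws_by_wave[sy] = draws
        aaf_ci_frames.append(summarize_aaf_draws(draws, exposures, registry,
                                                 spec))
    aaf_ci = pd.concat(aaf_ci_frames, ignore_index=True)

    weights = who_standard_weights()
    rows = []
    years = sorted(attributable["year"].unique())
    for year in years:
        sy = nearest_survey_year(int(year), survey_years)
        draws = {(s, a, int(year), c): d
                 for (s, a, _, c), d in draws_by_wave[sy].items()}
        att_y = attributable[attributable["year"] == year]
        cell_draws = attributable_draws(draws, att_y, registry)
        tot_y = totals[totals["year"] == year]
        pop_y = population[population["year"] == year]
        sexes = sorted(att_y["sex"].unique())
        for sex in sexes + ["all"]:
            keys = [k for k in cell_draws
                    if sex in ("all", k[0])]
            if not keys:
                continue
            att_draws = np.sum([cell_draws[k] for k in keys], axis=0)
            pop_sel = pop_y if sex == "all" else pop_y[pop_y["sex"] == sex]
            tot_sel = tot_y if sex == "all" else tot_y[tot_y["sex"] == sex]
            pops_g = pop_sel.groupby("age_group", observed=True)[
                "population"].sum().to_dict()
            pop_total = sum(pops_g.values())
            total_deaths = float(tot_sel["deaths"].sum())
            asr_draws = np.zeros_like(att_draws)
            for g in AGE_GROUPS:
                g_keys = [k for k in keys if k[1] == g]
                if g_keys:
                    g_draws = np.sum([cell_draws[k] for k in g_keys], axis=0)
                    asr_draws = asr_draws + weights[g] * g_draws / pops_g[g] * 1e5
            att_lo, att_hi = percentile_ci(att_draws)
            asr_lo, asr_hi = percentile_ci(asr_draws)
            pct = 100.0 * att_draws / total_deaths if total_deaths else att_draws * np.nan
            pct_lo, pct_hi = percentile_ci(pct) if total_deaths else (np.nan, np.nan)
            rows.append({
                "year": int(year), "sex": sex,
                "attributable_lo95": att_lo, "attributable_hi95": att_hi,
                "age_standardized_rate_lo95": asr_lo,
                "age_standardized_rate_hi95": asr_hi,
                "percent_of_total_lo95": pct_lo,
                "percent_of_total_hi95": pct_hi,
                "n_iter": spec.n_iterations, "seed": spec.seed,
            })
    return {"aaf_ci": aaf_ci, "rate_ci": pd.DataFrame(rows)}


def stage_report(attributable: pd.DataFrame, rates: pd.DataFrame,
                 population: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Trend tables mirroring the study's figure groupings.

    proportion_by_sex: percent of total deaths attributable, by sex/year;
    standardized_rates: age-standardized rates by sex/year; rates_by_age:
    crude rates per sex x age group; cause composition per sex x age x year.
    """
    proportion = rates[["year", "sex", "percent_of_total"]]
    standardized = rates[["year", "sex", "age_standardized_rate"]]
    by_age = (attributable.groupby(["year", "sex", "age_group"],
                                   observed=True)["attributable"]
              .sum().reset_index()
              .merge(population.groupby(["year", "sex", "age_group"],
                                        observed=True)["population"]
                     .sum().reset_index(),
                     on=["year", "sex", "age_group"]))
    by_age["rate"] = by_age["attributable"] / by_age["population"] * 1e5
    comp = (attributable.groupby(["year", "sex", "age_group", "cause"],
                                 observed=True)["attributable"]
            .sum().reset_index())
    return {
        "proportion_by_sex": proportion,
        "standardized_rates": standardized,
        "rates_by_age": by_age,
        "causes_female": comp[comp["sex"] == "female"].reset_index(drop=True),
        "causes_male": comp[comp["sex"] == "male"].reset_index(drop=True),
    }


def plot_trends(report: dict[str, pd.DataFrame], outdir) -> list[str]:
    """Optional PNG trend figures (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for name, (frame, ycol) in {
        "proportion_by_sex": (report["proportion_by_sex"], "percent_of_total"),
        "standardized_rates": (report["standardized_rates"],
                               "age_standardized_rate"),
    }.items():
        fig, ax = plt.subplots(figsize=(7, 4))
        for sex, sub in frame.groupby("sex"):
            ax.plot(sub["year"], sub[ycol], marker="o", label=sex)
        ax.set_xlabel("year")
        ax.set_ylabel(ycol.replace("_", " "))
        ax.legend()
        path = Path(outdir) / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written


# --- orchestration -----------------------------------------------------------


def run_pipeline(config: RunConfig, make_plots: bool = False) -> dict:
    """Run every stage and write all artifacts under ``config.outdir``.

    Returns the artifact dict (DataFrames keyed by name).  Reruns with an
    identical config and seed produce byte-identical CSVs.
    """
    config.validate()
    registry = config.load_registry()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    survey = pd.read_csv(config.survey)
    mortality = pd.read_csv(config.mortality)
    benchmark = pd.read_csv(config.benchmark)
    population = pd.read_csv(config.population)

    exposure_frame = stage_exposure(survey, benchmark, config)
    mortality_years = sorted(int(y) for y in mortality["year"].unique())
    aaf_table = stage_aaf(exposure_frame, registry, mortality_years,
                          config.grid_size)
    tables = stage_attribute(mortality, aaf_table, population, registry)
    ci = stage_ci(exposure_frame, registry, tables["attributable"],
                  tables["totals"], population, config)
    report = stage_report(tables["attributable"], tables["rates"], population)

    artifacts = {"exposure": exposure_frame, "aaf": aaf_table, **tables,
                 **ci, **report}
    for name, frame in artifacts.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    if make_plots:
        plot_trends(report, outdir)

    manifest = {
        "config": asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "aafengine_version": __version__,
        "calibration_factors": {
            int(y): float(exposure_frame[exposure_frame["year"] == y]
                          ["calibration_factor"].iloc[0])
            for y in sorted(exposure_frame["year"].dropna().unique())
        },
        "imputed_strata": int(exposure_frame["imputed"].sum()),
        "artifacts": sorted(f"{k}.csv" for k in artifacts),
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True))
    return artifacts
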