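"""Annual loop, scenario x replicate experiments, and sensitivity analysis.

Each simulated year runs, in order: ageing and growth -> spawning -> larval
mortality -> larval dispersal -> Beverton-Holt recruitment -> adult natural
mortality -> adult migration -> carrying-capacity enforcement -> survey ->
moratorium check -> quota -> distance-greedy harvest -> economics. Natural
mortality precedes harvest within the year (switchable for exploration).

Experiments run every scenario against the same per-replicate random stream,
so scenario comparisons are paired — required by the paired error statistics
and the paired NPV tests. Scenario placement is re-drawn per replicate by
default (a fixed-scenario mode is available), while the domain itself is
fixed for the whole experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .domain import GridDomain, build_synthetic_domain
from .dispersal import disperse_larvae, kernel_matrix, move_adults
from .economics import error_stats, npv, operating_cost, revenue
from .harvest import CatchRecord, allocate_catch, check_moratorium, set_quota, survey_biomass
from .params import (DispersalParams, EconParams, FisheryParams,
                     LifeHistoryParams, MortalityParams)
from .population import (Population, age_and_grow, beverton_holt_recruits,
                         draw_adult_mortality, draw_larval_mortality,
                         enforce_carrying_capacity, initialize_population, spawn)
from .scenarios import SCENARIO_NAMES, MPAScenario, MPASizeDistribution, build_scenario

__all__ = [
    "SimulationConfig",
    "YearRecord",
    "RunResult",
    "ExperimentResult",
    "run_year",
    "run_simulation",
    "run_experiment",
    "sensitivity_analysis",
    "SENSITIVITY_TABLE",
]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce an experiment from a master seed."""

    life: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    mort: MortalityParams = field(default_factory=MortalityParams)
    disp: DispersalParams = field(default_factory=DispersalParams)
    fish: FisheryParams = field(default_factory=FisheryParams)
    econ: EconParams = field(default_factory=EconParams)
    # synthetic domain: a cross-shelf transect, land along one short edge,
    # deep enough offshore that the fleet's range stays well inside the EEZ
    domain_n_x: int = 80
    domain_n_y: int = 7
    cell_area: float = 400.0
    coast_profile: dict | None = None
    domain_seed: int | None = None       # derived from master_seed when None
    breeding_fraction: float = 0.05
    shore_bias: float = 2.0
    # scenarios
    mpa_fraction: float = 0.10
    mpa_spacing: float = 75.0
    suitability_threshold: float = 0.5
    size_dist: MPASizeDistribution = field(default_factory=MPASizeDistribution)
    redraw_scenarios: bool = True
    # experiment
    n_years: int = 51
    start_year: int = 2000
    n_replicates: int = 10
    master_seed: int = 0
    npv_start_t: int = 1
    npv_horizon: int = 50
    stochastic_dispersal: bool = False
    moratorium_on_estimate: bool = False
    mortality_before_harvest: bool = True

    def build_domain(self) -> GridDomain:
        seed = self.domain_seed
        if seed is None:
            seed = int(np.random.SeedSequence(self.master_seed).generate_state(1)[0] % 2**31)
        return build_synthetic_domain(
            self.domain_n_x, self.domain_n_y, self.cell_area,
            coast_profile=self.coast_profile, seed=seed,
            suitability_threshold=self.suitability_threshold,
            breeding_fraction=self.breeding_fraction,
            shore_bias=self.shore_bias,
            k_mean=self.mort.K_mean, k_sd=self.mort.K_sd,
        )

    def replicate_seeds(self) -> list[tuple[int, int]]:
        """(simulation, scenario) integer seed pair per replicate."""
        out = []
        for child in np.random.SeedSequence(self.master_seed).spawn(self.n_replicates):
            sim_ss, scen_ss = child.spawn(2)
            out.append((
                int(sim_ss.generate_state(1)[0] % 2**31),
                int(scen_ss.generate_state(1)[0] % 2**31),
            ))
        return out

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v):
                return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, tuple):
                return list(v)
            return v
        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class YearRecord:
    year: int
    total_biomass: float                 # t, end of year (post-harvest)
    catch: float                         # t
    mean_distance: float | None         # km, catch-weighted; None if no catch
    moratorium: bool
    revenue: float                       # CAD
    cost: float                          # CAD (NaN until a baseline is known)


@dataclass
class RunResult:
    scenario: str
    replicate: int
    records: list[YearRecord]
    npv: dict[float, float]
    catch_records: list[list[CatchRecord]] = field(default_factory=list)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


def run_year(
    pop: Population,
    scenario: MPAScenario,
    domain: GridDomain,
    config: SimulationConfig,
    rng: np.random.Generator,
    year: int,
    kernels: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[Population, YearRecord, list[CatchRecord]]:
    """Advance the population and fishery by one year."""
    life, mort, disp, fishp = config.life, config.mort, config.disp, config.fish
    if kernels is None:
        kernels = (kernel_matrix(domain, disp.e_fold_larvae),
                   kernel_matrix(domain, disp.e_fold_adult))
    k_larvae, k_adult = kernels

    # growth, reproduction, recruitment
    pop = age_and_grow(pop, life)
    eggs = spawn(pop, life)
    m_larv = draw_larval_mortality(domain.n_cells, mort, rng)
    larvae = eggs * (1.0 - m_larv)
    settlers = disperse_larvae(
        larvae, domain, disp, seed=rng,
        stochastic=config.stochastic_dispersal, kernel=k_larvae,
    )
    recruits = beverton_holt_recruits(settlers, domain.K * domain.cell_area, life, mort)

    # adult natural mortality, then recruits join as age-1 fish: the
    # egg -> age-1 transition is the larval mortality + Beverton-Holt step,
    # so first-year mortality is not double counted
    m_adult = draw_adult_mortality(domain.n_cells, mort, rng)
    pop.counts[:, 1:, :] *= (1.0 - m_adult)[:, None, None]
    pop.counts[:, 1, 0] += recruits
    pop = move_adults(pop, domain, disp, kernel=k_adult)
    pop = enforce_carrying_capacity(pop, domain)

    # management and harvest
    pre_harvest_biomass = pop.total_biomass()
    estimate = survey_biomass(pop, domain, fishp, rng)
    trigger = estimate if config.moratorium_on_estimate else pre_harvest_biomass
    moratorium = check_moratorium(trigger, fishp)
    quota = 0.0 if moratorium else set_quota(estimate, fishp)
    records, pop, mean_dist = allocate_catch(pop, quota, scenario, domain, fishp)
    catch = sum(r.weight_t for r in records)

    rev = revenue(catch, fishp.price)
    if config.econ.baseline_distance is not None:
        cost = operating_cost(rev, mean_dist, config.econ)
    else:
        cost = float("nan")
    record = YearRecord(
        year=year, total_biomass=pop.total_biomass(), catch=catch,
        mean_distance=mean_dist, moratorium=moratorium, revenue=rev, cost=cost,
    )
    return pop, record, records


def _npvs_from_records(records: list[YearRecord], econ: EconParams,
                       start_t: int, horizon: int) -> dict[float, float]:
    """Final NPV per social discount rate from a run's yearly records."""
    t_idx = range(start_t, min(start_t + horizon, len(records)))
    net = [records[t].revenue - records[t].cost for t in t_idx]
    if not net:  # run shorter than the evaluation window
        return {sdr: 0.0 for sdr in econ.sdr_set}
    return {sdr: npv(net, sdr, t_start=start_t) for sdr in econ.sdr_set}


def _catch_weighted_distance(records: list[YearRecord]) -> float | None:
    num = sum(r.catch * r.mean_distance for r in records if r.mean_distance is not None)
    den = sum(r.catch for r in records if r.mean_distance is not None)
    return num / den if den > 0 else None


def run_simulation(
    domain: GridDomain,
    scenario: MPAScenario,
    config: SimulationConfig,
    seed: int,
    replicate: int = 0,
) -> RunResult:
    """Run one replicate of one scenario over ``n_years``.

    If no Status-Quo baseline distance is configured, the run's own
    catch-weighted mean distance is used when computing costs (adequate for a
    single run; experiments pin a common Status-Quo baseline instead).
    """
    rng = np.random.default_rng(seed)
    kernels = (kernel_matrix(domain, config.disp.e_fold_larvae),
               kernel_matrix(domain, config.disp.e_fold_adult))
    pop = initialize_population(domain, config.life, config.mort)
    records: list[YearRecord] = []
    all_catches: list[list[CatchRecord]] = []
    for t in range(config.n_years):
        pop, rec, catches = run_year(
            pop, scenario, domain, config, rng, config.start_year + t, kernels
        )
        records.append(rec)
        all_catches.append(catches)

    econ = config.econ
    if econ.baseline_distance is None:
        baseline = _catch_weighted_distance(records)
        econ = replace(econ, baseline_distance=baseline or 1.0)
        for rec in records:
            rec.cost = operating_cost(rec.revenue, rec.mean_distance, econ)
    npvs = _npvs_from_records(records, econ, config.npv_start_t, config.npv_horizon)
    return RunResult(scenario.name, replicate, records, npvs, all_catches)


@dataclass
class ExperimentResult:
    """Tidy outputs of a scenario x replicate experiment."""

    yearly: pd.DataFrame       # scenario, replicate, year, biomass, catch, ...
    npv: pd.DataFrame          # scenario, replicate, sdr, npv
    table1: pd.DataFrame       # Mean +/- SE summary per scenario
    table2: pd.DataFrame       # error stats vs status quo per sdr
    scenarios: dict            # {(scenario, replicate): MPAScenario}
    baseline_distance: float
    config: SimulationConfig

    def save(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.yearly.to_csv(out / "yearly.csv", index=False)
        self.npv.to_csv(out / "npv.csv", index=False)
        self.table1.to_csv(out / "summary_table1.csv", index=False)
        self.table2.to_csv(out / "error_table2.csv", index=False)


def _summary_table(yearly: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name, g in yearly.groupby("scenario", sort=False):
        n = len(g)
        dist = g["mean_distance"].dropna()
        rows.append({
            "scenario": name,
            "biomass_mean": g["total_biomass"].mean(),
            "biomass_se": g["total_biomass"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "catch_mean": g["catch"].mean(),
            "catch_se": g["catch"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "distance_mean": dist.mean() if len(dist) else np.nan,
            "distance_se": dist.std(ddof=1) / np.sqrt(len(dist)) if len(dist) > 1 else 0.0,
            "moratorium_pct": 100.0 * g["moratorium"].mean(),
            "n": n,
        })
    return pd.DataFrame(rows)


def _error_table(npv_df: pd.DataFrame, reference: str = "status_quo") -> pd.DataFrame:
    rows = []
    if reference not in set(npv_df["scenario"]):
        return pd.DataFrame(columns=["sdr", "comparison", "mae", "rmse", "mape"])
    for sdr, g in npv_df.groupby("sdr"):
        ref = g[g["scenario"] == reference].sort_values("replicate")["npv"].to_numpy()
        for name in g["scenario"].unique():
            if name == reference:
                continue
            alt = g[g["scenario"] == name].sort_values("replicate")["npv"].to_numpy()
            mae, rmse, mape = error_stats(ref, alt)
            rows.append({"sdr": sdr, "comparison": f"{reference} vs {name}",
                         "mae": mae, "rmse": rmse, "mape": mape})
    return pd.DataFrame(rows)


def run_experiment(
    config: SimulationConfig,
    domain: GridDomain | None = None,
    scenario_names: tuple[str, ...] = SCENARIO_NAMES,
    existing_mpas=None,
) -> ExperimentResult:
    """Run all scenarios x replicates with paired seeds and summarize.

    The Status-Quo catch-weighted mean distance (pooled over its replicates)
    is the cost baseline for every scenario unless one is pinned in the
    config. Replicate seeds are shared across scenarios so that comparisons
    and error statistics are paired.
    """
    domain = domain if domain is not None else config.build_domain()
    seeds = config.replicate_seeds()

    runs: dict[tuple[str, int], RunResult] = {}
    scen_objs: dict[tuple[str, int], MPAScenario] = {}
    raw_config = replace(config, econ=replace(config.econ, baseline_distance=None))
    for name in scenario_names:
        for rep, (sim_seed, scen_seed) in enumerate(seeds):
            s_seed = scen_seed if config.redraw_scenarios else seeds[0][1]
            scen = build_scenario(
                name, domain, seed=s_seed, fraction=config.mpa_fraction,
                spacing=config.mpa_spacing,
                suitability_threshold=config.suitability_threshold,
                dist=config.size_dist, existing_mpas=existing_mpas,
            )
            scen_objs[(name, rep)] = scen
            runs[(name, rep)] = run_simulation(domain, scen, raw_config, sim_seed, rep)

    # pin the cost baseline to the Status-Quo mean distance (or config value)
    baseline = config.econ.baseline_distance
    if baseline is None:
        sq_records = [r for (n, _), run in runs.items() if n == "status_quo"
                      for r in run.records]
        baseline = _catch_weighted_distance(sq_records)
    if baseline is None:  # no status quo scenario or no catch at all
        pooled = [r for run in runs.values() for r in run.records]
        baseline = _catch_weighted_distance(pooled) or 1.0
    econ = replace(config.econ, baseline_distance=float(baseline))

    yearly_rows, npv_rows = [], []
    for (name, rep), run in runs.items():
        for t, rec in enumerate(run.records):
            rec.cost = operating_cost(rec.revenue, rec.mean_distance, econ)
            yearly_rows.append({
                "scenario": name, "replicate": rep, "year": rec.year, "t": t,
                "total_biomass": rec.total_biomass, "catch": rec.catch,
                "mean_distance": rec.mean_distance, "moratorium": rec.moratorium,
                "revenue": rec.revenue, "cost": rec.cost,
            })
        run.npv = _npvs_from_records(run.records, econ, config.npv_start_t,
                                     config.npv_horizon)
        for sdr, value in run.npv.items():
            npv_rows.append({"scenario": name, "replicate": rep,
                             "sdr": sdr, "npv": value})

    yearly = pd.DataFrame(yearly_rows)
    npv_df = pd.DataFrame(npv_rows)
    return ExperimentResult(
        yearly=yearly, npv=npv_df,
        table1=_summary_table(yearly),
        table2=_error_table(npv_df),
        scenarios=scen_objs, baseline_distance=float(baseline), config=config,
    )


# Sensitivity table: parameter -> (targets, low, high). Integer-valued
# parameters move by +/- 1 year instead of +/- 10%.
SENSITIVITY_TABLE: dict[str, tuple[list[tuple[str, str]], float, float]] = {
    "age_mat_sigm": ([("life", "age_mat_mid")], 3.6, 4.4),
    "e_fold_adult": ([("disp", "e_fold_adult")], 245.0, 300.0),
    "e_fold_larvae": ([("disp", "e_fold_larvae")], 140.0, 171.0),
    "fecundity": ([("life", "fecundity")], 450_000.0, 550_000.0),
    "FMSY": ([("fish", "fmsy")], 0.25, 0.31),
    "initial_abun": ([("life", "initial_abun")], 2.25e8, 2.75e8),
    "k_mean": ([("life", "k_mean")], 0.12, 0.14),
    "min_age_catch": ([("fish", "min_age_catch")], 3, 5),
    "min_age_migration": ([("life", "min_age_migration"),
                           ("disp", "min_age_migration")], 5, 7),
}


def _perturbed_config(config: SimulationConfig, targets, value) -> SimulationConfig:
    out = config
    for block, attr in targets:
        out = replace(out, **{block: replace(getattr(out, block), **{attr: value})})
    return out


def sensitivity_analysis(
    config: SimulationConfig,
    parameters: list[str] | None = None,
    n_replicates: int = 25,
    scenario_names: tuple[str, ...] = ("status_quo", "targeted"),
    sdr: float = 0.015,
    domain: GridDomain | None = None,
) -> pd.DataFrame:
    """Mean final NPV per (parameter, direction) at one discount rate.

    Each named parameter is set to its low/high value (+/- 10%, or +/- 1 y
    for integer parameters) and ``n_replicates`` paired replicates of each
    scenario are run; the unaltered configuration is reported as the
    ``baseline`` row. Unknown names raise a configuration error listing the
    valid parameters.
    """
    parameters = list(SENSITIVITY_TABLE) if parameters is None else list(parameters)
    unknown = [p for p in parameters if p not in SENSITIVITY_TABLE]
    if unknown:
        raise ValueError(
            f"unknown sensitivity parameter(s) {unknown}; "
            f"valid names: {sorted(SENSITIVITY_TABLE)}"
        )
    base = replace(config, n_replicates=n_replicates,
                   econ=replace(config.econ, sdr_set=(sdr,)))
    domain = domain if domain is not None else base.build_domain()

    def mean_npvs(cfg) -> dict[str, float]:
        res = run_experiment(cfg, domain=domain, scenario_names=scenario_names)
        g = res.npv[res.npv["sdr"] == sdr].groupby("scenario")["npv"].mean()
        return g.to_dict()

    rows = []
    for scen, value in mean_npvs(base).items():
        rows.append({"parameter": "baseline", "direction": "normal",
                     "value": np.nan, "scenario": scen, "mean_final_npv": value})
    for name in parameters:
        targets, low, high = SENSITIVITY_TABLE[name]
        for direction, value in (("low", low), ("high", high)):
            cfg = _perturbed_config(base, targets, value)
            for scen, v in mean_npvs(cfg).items():
                rows.append({"parameter": name, "direction": direction,
                             "value": value, "scenario": scen,
                             "mean_final_npv": v})
    return pd.DataFrame(rows)
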