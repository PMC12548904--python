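"""End-to-end orchestration: generate -> project -> simulate -> decompose ->
score -> intervals.

A run executes four scenarios (status quo plus tax doubling in each
configured implementation year) over one shared synthetic world: identical
individuals, calibrated weights, mortality schedule, and parameter draws;
only the population intake trajectory differs between scenarios. Outputs are
delimited text tables plus a JSON summary and a run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import config_hash, load_config, make_config
from . import synthetic, intake, hall, mortality, outcomes, uncertainty

__all__ = ["ScenarioSpec", "World", "RunResult", "build_world", "run",
           "validate_inputs"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario of a run."""

    label: str
    mode: str = "nordpred"
    impl_year: int | None = None
    horizon: int = 2040

    def __post_init__(self):
        if (self.impl_year is None) != (self.label == "status_quo"):
            raise ValueError("impl_year is None exactly for the status_quo label")
        if self.impl_year is not None and self.horizon < self.impl_year:
            raise ValueError("horizon precedes the implementation year")


# ---------------------------------------------------------------------------
# input validation (anthropometric exclusion rules)
# ---------------------------------------------------------------------------

EXCLUSION_RULES = (
    ("missing_weight_or_height", lambda t: t["weight"].isna() | t["height"].isna()),
    ("height_outside_130_200", lambda t: (t["height"] < 130) | (t["height"] > 200)),
    ("bmi_outside_10_59",
     lambda t: (t["weight"] / (t["height"] / 100.0) ** 2 < 10)
     | (t["weight"] / (t["height"] / 100.0) ** 2 > 59)),
    ("pregnant_or_lactating",
     lambda t: t["pregnant_or_lactating"].fillna(False).astype(bool)
     if "pregnant_or_lactating" in t.columns
     else pd.Series(False, index=t.index)),
)


def validate_inputs(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the anthropometric exclusion filters and count each rule.

    Returns ``(clean_table, report)`` where the report has one row per rule
    with the number of rows it excluded (rules are applied in order, so each
    row is counted once, under the first rule that catches it).
    """
    remaining = cohort.copy()
    counts = []
    for name, rule in EXCLUSION_RULES:
        mask = rule(remaining).fillna(True) if name == "missing_weight_or_height" \
            else rule(remaining).fillna(False)
        counts.append({"rule": name, "excluded": int(mask.sum())})
        remaining = remaining[~mask]
    report = pd.DataFrame(counts)
    return remaining.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# world construction
# ---------------------------------------------------------------------------

@dataclass
class World:
    """The shared synthetic inputs of one run."""

    cfg: dict
    cohort: pd.DataFrame            # includes calibrated 'weight_raked'
    exclusions: pd.DataFrame
    diet: pd.DataFrame
    tei_series: pd.DataFrame
    projection: synthetic.PopulationProjection
    pd_grid: mortality.PDGrid
    hr_table: mortality.HazardRatioTable
    hall_params: hall.HallParameters
    baseline_intake: np.ndarray
    trend: intake.TrendFit
    tax_effect: intake.TaxEffect


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def build_world(cfg: dict) -> World:
    """Generate and calibrate every shared input of a run."""
    (seed_cohort, seed_diet, seed_tei, _seed_boot, _seed_mc) = _child_seeds(
        cfg["seed"], 5)
    ccfg = cfg["cohort"]
    cohort = synthetic.generate_cohort(int(ccfg["n"]), seed_cohort, ccfg)
    cohort, exclusions = validate_inputs(cohort)

    # age density used for both the raking margins and the projection totals
    ages = np.arange(20, 101)
    age_p = np.exp(-ccfg["age"]["decay"] * (ages - 20.0))
    age_p /= age_p.sum()
    total = ccfg["population_total"]

    edges = list(cfg["raking"]["age_band_edges"])
    band_of_age = np.digitize(ages, edges[1:], right=False)
    band_targets = {
        int(b): float(total * age_p[band_of_age == b].sum())
        for b in np.unique(band_of_age)
    }
    sex_targets = {"female": total * ccfg["female_share"],
                   "male": total * (1.0 - ccfg["female_share"])}
    member_band = np.digitize(cohort["age"].to_numpy(), edges[1:], right=False)
    raked = synthetic.rake_weights(
        cohort["base_weight_sampling"].to_numpy(),
        [(member_band, band_targets),
         (cohort["sex"].to_numpy(), sex_targets)],
        max_iter=int(cfg["raking"]["max_iter"]),
        tol=float(cfg["raking"]["tol"]),
    )
    cohort = cohort.assign(weight_raked=raked)

    diet = synthetic.generate_diet_subsample(
        cohort, cfg["diet"]["fraction"], seed_diet, cfg["diet"])
    tei_series = synthetic.generate_tei_series(
        cfg["tei_series"]["slope"], cfg["tei_series"]["intercept_2000"],
        cfg["tei_series"]["noise_sd"], seed_tei)
    trend = intake.fit_linear_trend(tei_series)

    mcfg = cfg["mortality"]
    q = synthetic.gompertz_q(ages, mcfg["gompertz_a"], mcfg["gompertz_b"],
                             mcfg["q_cap"])
    projection = synthetic.generate_projection(
        total * age_p, q, horizon=cfg["years"]["end"] + 1,
        ages=ages, start_year=cfg["years"]["start"])
    pd_grid = mortality.estimate_pd(projection)

    tax_cfg = cfg["tax"]
    if tax_cfg["tei_reduction"] is None:
        merged = diet.merge(cohort[["id", "weight_raked"]], on="id")
        tei_reduction = intake.mean_tei_reduction(
            merged, merged["weight_raked"],
            tax_cfg["ssb_cut"], tax_cfg["nedf_cut"])
    else:
        tei_reduction = float(tax_cfg["tei_reduction"])
    tax_effect = intake.TaxEffect(
        ssb_reduction=tax_cfg["ssb_cut"],
        nedf_reduction=tax_cfg["nedf_cut"],
        tei_reduction=tei_reduction,
        tei_reduction_ui=tuple(tax_cfg["tei_reduction_ui"]),
        phase_in_years=int(tax_cfg["phase_in_years"]),
    )

    params = hall.HallParameters.from_dict(cfg["hall"])
    baseline = hall.baseline_intakes(cohort, params)
    return World(cfg=cfg, cohort=cohort, exclusions=exclusions, diet=diet,
                 tei_series=tei_series, projection=projection, pd_grid=pd_grid,
                 hr_table=mortality.HazardRatioTable.meta_analytic(),
                 hall_params=params, baseline_intake=baseline, trend=trend,
                 tax_effect=tax_effect)


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------

def scenario_specs(cfg: dict) -> list[ScenarioSpec]:
    mode = cfg["scenarios"]["mode"]
    horizon = cfg["years"]["end"]
    specs = [ScenarioSpec("status_quo", mode, None, horizon)]
    for y in cfg["scenarios"]["impl_years"]:
        specs.append(ScenarioSpec(f"tax_{y}", mode, int(y), horizon))
    return specs


def _trajectories(world: World, specs, *, slope=None, tei_reduction=None):
    cfg = world.cfg
    years = range(cfg["years"]["start"], cfg["years"]["end"] + 1)
    sq = intake.project_status_quo(world.trend, cfg["scenarios"]["mode"],
                                   years, slope=slope)
    out = []
    for spec in specs:
        if spec.impl_year is None:
            out.append(sq)
        else:
            out.append(intake.apply_tax(sq, world.tax_effect, spec.impl_year,
                                        tei_reduction=tei_reduction,
                                        label=spec.label))
    return out


def _simulate_bmi(world: World, mult: np.ndarray) -> np.ndarray:
    years = np.arange(world.cfg["years"]["start"], world.cfg["years"]["end"] + 1)
    res = hall.simulate_cohort(world.cohort, world.baseline_intake, mult,
                               world.hall_params, years=years)
    return res["bmi"]


def _schedule_for(world: World, weights, sq_bmi, hr_per_5=None):
    cfg = world.cfg
    years = np.arange(cfg["years"]["start"], cfg["years"]["end"] + 1)
    pi = outcomes.category_prevalence_grid(
        world.cohort["age"].to_numpy(), weights, sq_bmi,
        world.pd_grid.values, world.pd_grid.ages, years)
    return mortality.build_schedule(
        world.pd_grid, world.hr_table, pi,
        decompose_start=cfg["years"]["decompose_start"],
        hr_per_5=hr_per_5, method=cfg["mortality"]["decompose_method"])


def _score(world: World, weights, bmi, schedule) -> dict:
    cfg = world.cfg
    years = np.arange(cfg["years"]["start"], cfg["years"]["end"] + 1)
    return outcomes.cohort_accounting(
        world.cohort["age"].to_numpy(), weights, bmi, schedule, years,
        a_frac=cfg["outcomes"]["a_frac"],
        l_convention=cfg["outcomes"]["l_convention"])


def _overall_prevalence(acc: dict) -> np.ndarray:
    """Population obesity prevalence by year from a scored accounting."""
    l = acc["l"]
    return (l * acc["prevalence"]).sum(axis=0) / l.sum(axis=0)


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    outdir: Path
    world: World
    scenarios: list
    outcome_tables: dict
    prevalence: pd.DataFrame
    comparison: pd.DataFrame | None
    summary: dict


def run(config: dict | str | Path | None = None,
        outdir: str | Path = "runs/latest") -> RunResult:
    """Execute a full run and write its artifacts under *outdir*."""
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = make_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    world = build_world(cfg)
    specs = scenario_specs(cfg)
    years = np.arange(cfg["years"]["start"], cfg["years"]["end"] + 1)
    w_point = world.cohort["weight_raked"].to_numpy()

    # --- point estimates: all scenarios in one vectorized simulation
    trajs = _trajectories(world, specs)
    mult = np.vstack([t.multipliers() for t in trajs])
    bmi = _simulate_bmi(world, mult)               # (S, n, Y)
    schedule = _schedule_for(world, w_point, bmi[0])
    accs = [_score(world, w_point, bmi[s], schedule)
            for s in range(len(specs))]

    outcome_tables = {
        spec.label: outcomes.accounting_to_frame(acc, spec.label)
        for spec, acc in zip(specs, accs)
    }
    prev_frames = []
    for spec, acc in zip(specs, accs):
        prev_frames.append(pd.DataFrame({
            "scenario": spec.label, "year": years,
            "obesity_prevalence": _overall_prevalence(acc),
        }))
    prevalence = pd.concat(prev_frames, ignore_index=True)

    point_metrics = {}
    for spec, acc in zip(specs[1:], accs[1:]):
        point_metrics[spec.label] = {
            "deaths_averted": float((accs[0]["d"] - acc["d"]).sum()),
            "ylwo_saved": float((acc["ylwo"] - accs[0]["ylwo"]).sum()),
        }

    # --- uncertainty propagation
    R = int(cfg["uncertainty"]["replicates"])
    intervals: dict = {}
    if R > 0:
        (_, _, _, seed_boot, seed_mc) = _child_seeds(cfg["seed"], 5)
        rep_w = uncertainty.make_replicate_weights(
            world.cohort, R, seed_boot, weight_col="weight_raked")
        draws = uncertainty.draw_parameters(
            R, seed_mc,
            tax_mean=world.tax_effect.tei_reduction,
            tax_ui=world.tax_effect.tei_reduction_ui,
            hr_table=world.hr_table,
            slope=world.trend.slope, slope_se=world.trend.slope_se)

        rep_bmi = []
        for si, spec in enumerate(specs):
            m = np.empty((R, years.size))
            for r in range(R):
                t = _trajectories(world, [spec], slope=draws["slope"][r],
                                  tei_reduction=draws["tax"][r])[0]
                m[r] = t.multipliers()
            rep_bmi.append(_simulate_bmi(world, m))   # (R, n, Y)

        samples = {spec.label: {"deaths_averted": np.empty(R),
                                "ylwo_saved": np.empty(R)}
                   for spec in specs[1:]}
        prev_samples = {spec.label: np.empty(R) for spec in specs}
        for r in range(R):
            sched_r = _schedule_for(world, rep_w[r], rep_bmi[0][r],
                                    hr_per_5=draws["hr_per_5"][r])
            acc_sq = _score(world, rep_w[r], rep_bmi[0][r], sched_r)
            prev_samples["status_quo"][r] = _overall_prevalence(acc_sq)[-1]
            for si, spec in enumerate(specs[1:], start=1):
                acc_s = _score(world, rep_w[r], rep_bmi[si][r], sched_r)
                samples[spec.label]["deaths_averted"][r] = \
                    (acc_sq["d"] - acc_s["d"]).sum()
                samples[spec.label]["ylwo_saved"][r] = \
                    (acc_s["ylwo"] - acc_sq["ylwo"]).sum()
                prev_samples[spec.label][r] = _overall_prevalence(acc_s)[-1]

        for spec in specs[1:]:
            for metric in ("deaths_averted", "ylwo_saved"):
                est = uncertainty.interval(
                    samples[spec.label][metric],
                    point=point_metrics[spec.label][metric])
                intervals.setdefault(spec.label, {})[metric] = est
        for si, spec in enumerate(specs):
            est = uncertainty.interval(
                prev_samples[spec.label],
                point=float(_overall_prevalence(accs[si])[-1]))
            intervals.setdefault(spec.label, {})["final_prevalence"] = est

    # --- comparison table
    comparison = None
    if len(specs) > 1:
        rows = []
        for spec in specs[1:]:
            row = {"scenario": spec.label, "impl_year": spec.impl_year}
            for metric in ("deaths_averted", "ylwo_saved"):
                row[metric] = point_metrics[spec.label][metric]
                if spec.label in intervals and metric in intervals[spec.label]:
                    est = intervals[spec.label][metric]
                    row[f"{metric}_lower"] = est.lower
                    row[f"{metric}_upper"] = est.upper
            rows.append(row)
        comparison = pd.DataFrame(rows)

    summary = _summarize(cfg, world, specs, accs, point_metrics, intervals,
                         prevalence)
    _write_artifacts(outdir, cfg, world, trajs, outcome_tables, prevalence,
                     comparison, summary)
    return RunResult(outdir=outdir, world=world, scenarios=specs,
                     outcome_tables=outcome_tables, prevalence=prevalence,
                     comparison=comparison, summary=summary)


def _summarize(cfg, world, specs, accs, point_metrics, intervals, prevalence):
    final_year = int(cfg["years"]["end"])
    summary = {
        "seed": cfg["seed"],
        "profile": cfg["profile"],
        "n_individuals": int(len(world.cohort)),
        "replicates": int(cfg["uncertainty"]["replicates"]),
        "tei_reduction_point": world.tax_effect.tei_reduction,
        "trend_slope": world.trend.slope,
        "trend_adjusted_r2": world.trend.adjusted_r2,
        "final_year": final_year,
        "scenarios": {},
    }
    for spec, acc in zip(specs, accs):
        prev = float(_overall_prevalence(acc)[-1])
        entry: dict = {"final_obesity_prevalence": prev}
        if spec.label in point_metrics:
            entry.update(point_metrics[spec.label])
        if spec.label in intervals:
            for metric, est in intervals[spec.label].items():
                entry[f"{metric}_ui"] = [est.lower, est.upper]
        summary["scenarios"][spec.label] = entry
    labels = [s.label for s in specs[1:]]
    if len(labels) >= 2:
        first, last = labels[0], labels[-1]
        summary["delay_ratios"] = {
            "deaths_pct_more_first_vs_last": outcomes.percent_excess(
                point_metrics[first]["deaths_averted"],
                point_metrics[last]["deaths_averted"]),
            "ylwo_pct_more_first_vs_last": outcomes.percent_excess(
                point_metrics[first]["ylwo_saved"],
                point_metrics[last]["ylwo_saved"]),
        }
    return summary


def _write_artifacts(outdir, cfg, world, trajs, outcome_tables, prevalence,
                     comparison, summary):
    def write(df: pd.DataFrame, name: str):
        df.to_csv(outdir / name, index=False, float_format=_FLOAT_FMT)

    write(world.cohort, "cohort.csv")
    write(world.exclusions, "exclusions.csv")
    write(world.diet, "diet.csv")
    write(world.tei_series, "tei_series.csv")
    write(world.projection.to_frame(), "projection.csv")
    write(world.hr_table.to_frame(), "hr_table.csv")
    write(pd.concat([t.to_frame() for t in trajs], ignore_index=True),
          "trajectories.csv")
    for label, table in outcome_tables.items():
        write(table, f"outcomes_{label}.csv")
    write(prevalence, "prevalence.csv")
    if comparison is not None:
        write(comparison, "comparison.csv")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config_sha256": config_hash(cfg),
        "seed": cfg["seed"],
        "profile": cfg["profile"],
        "rows": {"cohort": int(len(world.cohort)),
                 "diet": int(len(world.diet))},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(_report_text(summary))


def _report_text(summary: dict) -> str:
    lines = [
        "Cost-of-delay simulation report",
        "===============================",
        f"profile={summary['profile']}  n={summary['n_individuals']}  "
        f"replicates={summary['replicates']}  seed={summary['seed']}",
        f"TEI trend slope {summary['trend_slope']:.2f} kcal/day/year "
        f"(adjusted R2 {summary['trend_adjusted_r2']:.3f}); "
        f"tax effect {100 * summary['tei_reduction_point']:.2f}% of TEI",
        "",
    ]
    for label, entry in summary["scenarios"].items():
        lines.append(f"[{label}]")
        lines.append(
            f"  obesity prevalence {summary['final_year']}: "
            f"{100 * entry['final_obesity_prevalence']:.1f}%")
        if "deaths_averted" in entry:
            lines.append(f"  deaths averted: {entry['deaths_averted']:,.0f}")
            lines.append(f"  YLWO saved:     {entry['ylwo_saved']:,.0f}")
        lines.append("")
    if "delay_ratios" in summary:
        r = summary["delay_ratios"]
        lines.append(
            "Earliest vs latest implementation: "
            f"{r['deaths_pct_more_first_vs_last']:.1f}% more deaths averted, "
            f"{r['ylwo_pct_more_first_vs_last']:.1f}% more YLWO gained.")
    return "\n".join(lines) + "\n"
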