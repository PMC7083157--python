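"""End-to-end orchestration: catches -> AA -> covariates -> model selection.

``run_full_analysis`` executes the whole workflow from one declarative
config and returns an artifact bundle; ``render_reports`` writes the bundle
as delimiter-separated text tables (and optional figures).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import anomaly, catch_records, climate, modeling, synthetic
from .errors import PhenoanomalyError

log = logging.getLogger("phenoanomaly")


@dataclasses.dataclass
class RunConfig:
    """Inputs and knobs for one full analysis run.

    Exactly one of (``catches_path``, ``synthetic_config``) must be set.
    """

    catches_path: str | None = None
    index_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    temperature_path: str | None = None
    synthetic_config: synthetic.SimulationConfig | None = None
    baseline_method: str = "pooled"
    min_total: int = 31
    half_window_years: int = 6
    max_lag: int = 10
    selection_methods: tuple[str, ...] = ("all_subsets", "stepwise_backward")
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> None:
        real = self.catches_path is not None
        synth = self.synthetic_config is not None
        if real == synth:
            raise PhenoanomalyError(
                "exactly one of catches_path / synthetic_config must be given"
            )
        if real:
            for p in [self.catches_path, self.temperature_path,
                      *self.index_paths.values()]:
                if p is not None and not Path(p).exists():
                    raise PhenoanomalyError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic_config", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in _FIELD_NAMES})
        if synth is not None:
            cfg.synthetic_config = synthetic.SimulationConfig(**synth)
        if "selection_methods" in raw:
            cfg.selection_methods = tuple(raw["selection_methods"])
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _load_inputs(config: RunConfig):
    if config.synthetic_config is not None:
        archive, truth, clim = synthetic.simulate_catch_archive(
            config.synthetic_config
        )
        return archive, clim.indices, clim.temperature, truth
    archive = catch_records.read_daily_catches(config.catches_path)
    indices = {
        name: climate.read_noaa_monthly(path, name)
        for name, path in config.index_paths.items()
    }
    temperature = (
        climate.read_ecad_daily_temperature(config.temperature_path)
        if config.temperature_path
        else None
    )
    return archive, indices, temperature, None


def regression_inputs(config: RunConfig) -> dict[str, Any]:
    """Run the data stages only: archive -> AA -> standardized design.

    Returns a dict with the filtered archive, season table, raw covariates,
    standardized design ``z``, standardized response ``y``, the input
    sources and (for synthetic runs) the ground truth.
    """
    archive, indices, temperature, truth = _load_inputs(config)
    archive = catch_records.impute_missing_days(archive, config.half_window_years)
    n_imputed = sum(len(s.imputed_days) for s in archive.series.values())
    archive = catch_records.filter_low_count_years(archive, config.min_total)
    log.info(
        "stage=filter years_kept=%d excluded=%s imputed_days=%d",
        len(archive.series), archive.excluded_years, n_imputed,
    )
    seasons = anomaly.season_table(archive, config.baseline_method)
    covariates = climate.build_covariate_table(
        indices, temperature, sorted(seasons["year"])
    )
    z = climate.standardize_table(covariates)
    y = climate.standardize(seasons["aa"]).to_numpy()
    return dict(
        archive=archive, seasons=seasons, covariates=covariates, z=z, y=y,
        indices=indices, temperature=temperature, truth=truth,
        n_imputed_days=n_imputed,
    )


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return the artifact bundle as a dict."""
    config.validate()
    bundle: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    stage = regression_inputs(config)
    archive = stage["archive"]
    indices, temperature = stage["indices"], stage["temperature"]
    bundle["archive_summary"] = archive.summary()
    bundle["excluded_years"] = list(archive.excluded_years)
    bundle["ground_truth"] = stage["truth"]

    seasons = stage["seasons"]
    span = max(seasons["year"]) - min(seasons["year"])
    trends = anomaly.trend_table(seasons, span_years=span + 1)
    bundle["seasons"] = seasons
    bundle["trends"] = trends
    bundle["baseline"] = anomaly.baseline_curve(archive, config.baseline_method)

    aa = anomaly.AnomalySeries(dict(zip(seasons["year"], seasons["aa"])))
    aa_fit = anomaly.trend_regression(aa.values)
    bundle["aa_trend"] = aa_fit
    resid = {
        y: aa.values[y] - aa_fit.predict(y) for y in aa.values
    }
    extreme_year = max(resid, key=lambda y: abs(resid[y]))
    bundle["aa_extreme_residual"] = (extreme_year, resid[extreme_year])

    covariates = stage["covariates"]
    bundle["covariates"] = covariates

    # Ljung-Box screen uses the gapless AA (excluded springs filled from trend)
    all_years = range(min(archive.series), max(archive.series) + 1)
    aa_gapless = anomaly.impute_missing_anomalies(aa, all_years).as_series()
    covariates_allyears = climate.build_covariate_table(
        indices, temperature, sorted(aa_gapless.index)
    )
    bundle["screen"] = climate.screening_table(
        covariates_allyears.drop(columns=[climate.YEAR_COLUMN]),
        aa_gapless.to_numpy(),
        config.max_lag,
    )

    z = stage["z"]
    y = stage["y"]
    bundle["design"] = z
    bundle["response"] = y

    lq_rows = []
    for c in z.columns:
        if c == climate.YEAR_COLUMN:
            continue
        cmp_ = modeling.compare_linear_quadratic(y, z[c].to_numpy(), c)
        lq_rows.append(dataclasses.asdict(cmp_) | {"delta_aicc": cmp_.delta_aicc})
    bundle["linear_vs_quadratic"] = pd.DataFrame(lq_rows)

    selections: dict[str, modeling.ModelSelectionResult] = {}
    if "all_subsets" in config.selection_methods:
        selections["all_subsets"] = modeling.all_subsets_selection(y, z)
    if "stepwise_backward" in config.selection_methods:
        selections["stepwise_backward"] = modeling.stepwise_backward(y, z)
    bundle["selection"] = selections
    if len(selections) == 2:
        bundle["methods_agree"] = (
            set(selections["all_subsets"].best.terms)
            == set(selections["stepwise_backward"].best.terms)
        )

    primary = selections.get("all_subsets") or next(iter(selections.values()))
    best = primary.best
    bundle["best_model"] = best
    bundle["full_model"] = modeling.fit_ols(y, z)
    bundle["vif_full"] = modeling.vif(z)
    bundle["model_report"] = modeling.model_report(best, z, y, full_design=z)
    bundle["diagnostics"] = modeling.residual_diagnostics(best)
    if len(best.terms) >= 2:
        bundle["leave_one_out"] = modeling.leave_one_covariate_residual_check(
            y, z, best.terms
        )

    bundle["summary"] = {
        "seed": config.seed,
        "config_hash": bundle["config_hash"],
        "n_years": len(seasons),
        "excluded_years": [list(e) for e in archive.excluded_years],
        "aa_slope_days_per_year": aa_fit.slope,
        "aa_total_change_days": aa_fit.total_change(span + 1),
        "selected_terms": list(best.terms),
        "adj_r_squared": best.adj_r_squared,
        "methods_agree": bundle.get("methods_agree"),
    }
    return bundle


def render_reports(bundle: dict[str, Any], outdir, plots: bool = False) -> list[Path]:
    """Write the bundle as text tables (and optional figures); return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# seed={bundle['seed']} config={bundle['config_hash']}\n")
            df.to_csv(fh, sep="\t", index=False)
        written.append(path)

    _write(bundle["archive_summary"], "archive_summary.tsv")
    _write(bundle["seasons"], "season_table.tsv")
    _write(bundle["trends"], "trend_table.tsv")
    _write(bundle["screen"], "ljung_box_screen.tsv")
    _write(bundle["linear_vs_quadratic"], "linear_vs_quadratic.tsv")
    _write(bundle["model_report"], "best_model_report.tsv")
    ledger = bundle["selection"]["all_subsets"].ledger.head(50).copy() \
        if "all_subsets" in bundle["selection"] else None
    if ledger is not None:
        ledger["terms"] = ledger["terms"].map(lambda t: "+".join(t) or "<intercept>")
        _write(ledger, "aicc_ledger_top50.tsv")

    summary = dict(bundle["summary"])
    if not bundle["excluded_years"]:
        summary["excluded_years"] = "none"
    path = outdir / "summary.json"
    path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    written.append(path)

    if plots:
        written.extend(_render_plots(bundle, outdir))
    return written


def _render_plots(bundle: dict[str, Any], outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    seasons = bundle["seasons"]

    fig, axes = plt.subplots(2, 1, figsize=(7, 8), sharex=True)
    for metric, ax in (("d10", axes[0]), ("aa", axes[1])):
        ax.plot(seasons["year"], seasons[metric], "ko-", ms=3)
        ax.set_ylabel(metric)
    axes[1].set_xlabel("year")
    p = outdir / "trend_panels.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    base = bundle["baseline"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, len(base) + 1), base.fractions, "k-", label=base.label)
    ax.set_xlabel("day of spring window")
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    p = outdir / "baseline_curve.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)
    return written
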