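"""End-to-end analysis: classify, sample, assemble, fit, report.

Mirrors the study design: used (bear foraging) and available (random) berry
plots are compared with species-specific hurdle mixed models; a seasonal-shift
model asks whether the two species' abundance trends diverge at foraging
locations; linear mixed models explain sugar content.  Every stage is
deterministic given the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import trajectory as traj
from .io import RunConfig
from .models import (
    ContrastResult,
    FormulaSpec,
    GlmmFit,
    SelectionTrace,
    backward_select,
    pairwise_contrasts,
    pearson_cor,
    predict_population,
    vif_screen,
    welch_t,
)
from .plots import assemble_dataset
from .synthetic import Scenario

__all__ = [
    "SpeciesSelectionResult",
    "run_berry_selection",
    "average_plottype_effect",
    "run_seasonal_shift",
    "run_sugar_analysis",
    "descriptive_summaries",
    "classify_scenario",
    "run_full_analysis",
    "run_report",
]

NUMERIC_COVARIATES = ["elevation", "ndvi", "slope", "ordinal_day"]


@dataclass
class SpeciesSelectionResult:
    """Hurdle selection analysis for one species."""

    species: str
    occurrence: GlmmFit
    occurrence_trace: SelectionTrace
    abundance: GlmmFit
    abundance_trace: SelectionTrace
    vif: object
    contrasts: dict[str, list[ContrastResult]]
    predictions: pd.DataFrame


def _full_terms(numeric_retained: list[str], data: pd.DataFrame) -> tuple[str, ...]:
    """The full fixed-effect structure: plot type, landscape characteristics,
    habitat and sampling date, plus habitat x plot type and date x plot type."""
    terms = ["plottype", "habitat"]
    terms += [c for c in numeric_retained if c != "ordinal_day"]
    if "aspect" in data.columns:
        terms.append("aspect")
    if "ordinal_day" in numeric_retained:
        terms.append("ordinal_day")
        terms.append("plottype:ordinal_day")
    terms.append("plottype:habitat")
    return tuple(terms)


def _posthoc(fit: GlmmFit, data: pd.DataFrame, rng, n_draws: int) -> dict[str, list[ContrastResult]]:
    """Pairwise contrasts for surviving multilevel factors / interactions."""
    out: dict[str, list[ContrastResult]] = {}
    terms = fit.spec.terms if fit.spec is not None else ()
    if "plottype:habitat" in terms:
        out["plottype:habitat"] = pairwise_contrasts(
            fit, "plottype:habitat", data, rng=rng, n_draws=n_draws
        )
    elif "habitat" in terms:
        out["habitat"] = pairwise_contrasts(fit, "habitat", data, rng=rng, n_draws=n_draws)
    return out


def average_plottype_effect(fit: GlmmFit, data: pd.DataFrame) -> float | None:
    """Marginal used-vs-available effect on the link scale.

    The (bear - random) linear-predictor difference averaged over the habitat
    classes, at the mean of the numeric covariates; equals the plain plot-type
    coefficient when no plot-type interaction survived selection, and the
    habitat-averaged selection effect when one did.  ``None`` when plot type
    was eliminated.
    """
    import patsy

    terms = fit.spec.terms if fit.spec is not None else ()
    if not any(t == "plottype" or "plottype" in t.split(":") for t in terms):
        return None
    habs = sorted(data["habitat"].unique())
    base = {
        c: float(data[c].mean())
        for c in NUMERIC_COVARIATES
        if c in data.columns
    }
    rows = [
        dict(base, plottype=pt, habitat=h, aspect="N")
        for pt in (0, 1)
        for h in habs
    ]
    (X,) = patsy.build_design_matrices([fit.design_info], pd.DataFrame(rows))
    X = np.asarray(X)
    eta = X @ fit.beta
    k = len(habs)
    return float(np.mean(eta[k:] - eta[:k]))


def _prediction_frame(data: pd.DataFrame, habitat: str = "mature_forest") -> pd.DataFrame:
    """Date-gradient prediction grid at mean elevation, both plot types."""
    days = np.arange(int(data["ordinal_day"].min()), int(data["ordinal_day"].max()) + 1)
    base = {
        c: float(data[c].mean()) for c in NUMERIC_COVARIATES if c in data and c != "ordinal_day"
    }
    rows = []
    for pt in (0, 1):
        for d in days:
            rows.append(
                dict(
                    base,
                    plottype=pt,
                    ordinal_day=int(d),
                    habitat=habitat,
                    aspect="N",
                )
            )
    return pd.DataFrame(rows)


def run_berry_selection(
    data: pd.DataFrame,
    species: str,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SpeciesSelectionResult:
    """Hurdle used-available analysis for one berry species.

    Numeric covariates are VIF-screened first; both hurdle parts then start
    from the full model (plot type, landscape characteristics, habitat and
    date main effects plus the habitat x plot type and date x plot type
    interactions) and are reduced by backward LR selection.  Post hoc
    single-step contrasts are computed for surviving factor structure, and a
    population-level prediction curve over the date window (at mean elevation,
    mature forest) is attached for both plot types.
    """
    cfg = config or RunConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    count = f"count_{species}"
    if count not in data.columns:
        raise ValueError(f"no column {count!r} in the assembled table")

    numeric = [c for c in NUMERIC_COVARIATES if c in data.columns]
    vif = vif_screen(data[numeric], cutoff=cfg.vif_cutoff)
    terms = _full_terms(list(vif.retained), data)
    refs = {"habitat": "bog", "aspect": "N"}

    work = data.copy()
    work["_occ"] = (work[count] >= 1).astype(float)
    spec_occ = FormulaSpec("_occ", terms, group="bear_id", reference=refs)
    occ_fit, occ_trace = backward_select(
        work, spec_occ, "binomial", alpha=cfg.alpha, nodes=cfg.selection_nodes
    )

    positive = work[work[count] >= 1]
    spec_abn = FormulaSpec(count, terms, group="bear_id", reference=refs)
    abn_fit, abn_trace = backward_select(
        positive, spec_abn, "truncnegbin", alpha=cfg.alpha, nodes=cfg.selection_nodes
    )

    contrasts = {}
    for label, fit, frame in (("occurrence", occ_fit, work), ("abundance", abn_fit, positive)):
        for key, res in _posthoc(fit, frame, rng, cfg.mc_draws).items():
            contrasts[f"{label}:{key}"] = res

    grid = _prediction_frame(work)
    pred_occ = predict_population(occ_fit, grid)
    pred_abn = predict_population(abn_fit, grid)
    predictions = grid.assign(
        occurrence=pred_occ["fit"].to_numpy(),
        occurrence_lower=pred_occ["lower"].to_numpy(),
        occurrence_upper=pred_occ["upper"].to_numpy(),
        abundance=pred_abn["fit"].to_numpy(),
        abundance_lower=pred_abn["lower"].to_numpy(),
        abundance_upper=pred_abn["upper"].to_numpy(),
    )
    return SpeciesSelectionResult(
        species=species,
        occurrence=occ_fit,
        occurrence_trace=occ_trace,
        abundance=abn_fit,
        abundance_trace=abn_trace,
        vif=vif,
        contrasts=contrasts,
        predictions=predictions,
    )


def run_seasonal_shift(
    foraging_plots: pd.DataFrame, config: RunConfig | None = None
) -> tuple[GlmmFit, SelectionTrace, pd.DataFrame]:
    """Species x date x habitat count model at foraging locations.

    Restricted to the two productive berry habitats (clearcut, mature forest)
    and to foraging plots; the table is stacked long (two rows per plot, one
    per species) with a plot-id random intercept because both species were
    counted in the same quadrats.  Starts from the full three-way interaction
    and reduces backward.
    """
    cfg = config or RunConfig()
    sub = foraging_plots[
        foraging_plots["habitat"].isin(["clearcut", "mature_forest"])
    ].reset_index(drop=True)
    if "plottype" in sub.columns:
        sub = sub[sub["plottype"] == 1].reset_index(drop=True)
    if sub.empty:
        raise ValueError("no foraging plots in clearcut / mature forest")
    if "plot_id" not in sub.columns:
        sub = sub.assign(plot_id=[f"P{i:04d}" for i in range(len(sub))])
    long = pd.concat(
        [
            sub.assign(species="bilberry", count=sub["count_bilberry"]),
            sub.assign(species="lingonberry", count=sub["count_lingonberry"]),
        ],
        ignore_index=True,
    )
    if cfg.seasonal_family == "truncnegbin":
        long = long[long["count"] >= 1].reset_index(drop=True)
    spec = FormulaSpec(
        "count",
        (
            "species",
            "ordinal_day",
            "habitat",
            "species:ordinal_day",
            "species:habitat",
            "ordinal_day:habitat",
            "species:ordinal_day:habitat",
        ),
        group="plot_id",
        reference={"species": "bilberry", "habitat": "clearcut"},
    )
    fit, trace = backward_select(
        long, spec, cfg.seasonal_family, alpha=cfg.alpha, nodes=cfg.selection_nodes
    )
    return fit, trace, long


@dataclass
class SugarResult:
    fits: dict[str, GlmmFit]
    traces: dict[str, SelectionTrace]
    t_test: tuple[float, float]  # bilberry vs lingonberry TSS


def run_sugar_analysis(
    data: pd.DataFrame, config: RunConfig | None = None
) -> SugarResult:
    """Per-species linear mixed models for sugar content plus the species test.

    TSS is only defined where the species occurred; each species' model starts
    from the full predictor set (plot type, habitat, aspect, screened numeric
    terrain variables, date) with a bear-id random intercept and is reduced
    backward.  A Welch t test compares the two species' mean TSS.
    """
    cfg = config or RunConfig()
    fits: dict[str, GlmmFit] = {}
    traces: dict[str, SelectionTrace] = {}
    for species in ("bilberry", "lingonberry"):
        col = f"tss_{species}"
        sub = data[data[col].notna()].reset_index(drop=True)
        if len(sub) < 30:
            raise ValueError(f"only {len(sub)} plots with {species} TSS; need >= 30")
        numeric = [c for c in NUMERIC_COVARIATES if c in sub.columns]
        vif = vif_screen(sub[numeric], cutoff=cfg.vif_cutoff)
        terms = ["plottype", "habitat"]
        if "aspect" in sub.columns:
            terms.append("aspect")
        terms += list(vif.retained)
        spec = FormulaSpec(
            col,
            tuple(terms),
            group="bear_id",
            reference={"habitat": "clearcut", "aspect": "N"},
        )
        fits[species], traces[species] = backward_select(
            sub, spec, "gaussian", alpha=cfg.alpha, nodes=cfg.selection_nodes
        )
    t_stat = welch_t(
        data["tss_bilberry"].dropna(), data["tss_lingonberry"].dropna()
    )
    return SugarResult(fits=fits, traces=traces, t_test=t_stat)


def classify_scenario(scn: Scenario) -> tuple[list, dict]:
    """Re-run the trajectory classifier on a scenario's tracks.

    Returns the per-track segment lists (after buffer exclusion) and a small
    summary (counts, fix success), as the reporting stage uses them.
    """
    cfg = scn.config
    all_segments = []
    success = {}
    for track in scn.tracks:
        segs = traj.find_foraging_segments(track, cfg.d_min, cfg.d_max, cfg.min_fixes)
        segs = traj.exclude_near_sites(segs, track, scn.exclusion_sites, cfg.buffer_radius)
        all_segments.append(segs)
        success[track.bear_id] = traj.fix_success_rate(track)
    return all_segments, success


def descriptive_summaries(
    scn: Scenario, assembled: pd.DataFrame, segments: list | None = None
) -> dict:
    """The report's descriptive block: segments, fix success, occupancy, TSS."""
    if segments is None:
        segments, success = classify_scenario(scn)
    else:
        success = {t.bear_id: traj.fix_success_rate(t) for t in scn.tracks}
    flat = [s for per_track in segments for s in per_track]
    forage = assembled[assembled["plottype"] == 1]
    out = {
        "n_segments": len(flat),
        "mean_fixes_per_segment": float(np.mean([s.n_fixes for s in flat])) if flat else float("nan"),
        "fix_success_mean": float(np.mean(list(success.values()))),
        "n_foraging_plots": int(len(forage)),
        "n_random_plots": int((assembled["plottype"] == 0).sum()),
    }
    for sp in ("bilberry", "lingonberry", "crowberry"):
        col = f"count_{sp}"
        if col not in assembled:
            continue
        occupied = assembled[assembled[col] >= 1]
        out[f"pct_foraging_with_{sp}"] = float(100.0 * (forage[col] >= 1).mean())
        out[f"density_occupied_{sp}"] = float(occupied[col].mean()) if len(occupied) else float("nan")
    out["pct_foraging_with_neither"] = float(
        100.0
        * ((forage["count_bilberry"] == 0) & (forage["count_lingonberry"] == 0)).mean()
    )
    for sp in ("bilberry", "lingonberry"):
        col = f"tss_{sp}"
        if col in assembled:
            vals = assembled[col].dropna()
            out[f"tss_mean_{sp}"] = float(vals.mean())
            out[f"tss_sd_{sp}"] = float(vals.std(ddof=1))
    r, p = pearson_cor(forage["count_bilberry"], forage["count_lingonberry"])
    out["count_correlation_r"] = r
    out["count_correlation_p"] = p
    return out


@dataclass
class AnalysisReport:
    """Everything one full run produces, in memory."""

    config: RunConfig
    assembled: pd.DataFrame
    selection: dict[str, SpeciesSelectionResult]
    seasonal_fit: GlmmFit
    seasonal_trace: SelectionTrace
    sugar: SugarResult
    summaries: dict


def run_full_analysis(scn: Scenario, config: RunConfig | None = None) -> AnalysisReport:
    """Classify, assemble and fit everything for one scenario."""
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    assembled = assemble_dataset(scn.foraging_plots, scn.random_plots, rng)
    selection = {
        sp: run_berry_selection(assembled, sp, cfg, rng)
        for sp in ("bilberry", "lingonberry")
    }
    seasonal_fit, seasonal_trace, _ = run_seasonal_shift(
        assembled[assembled["plottype"] == 1], cfg
    )
    sugar = run_sugar_analysis(assembled, cfg)
    summaries = descriptive_summaries(scn, assembled)
    return AnalysisReport(
        config=cfg,
        assembled=assembled,
        selection=selection,
        seasonal_fit=seasonal_fit,
        seasonal_trace=seasonal_trace,
        sugar=sugar,
        summaries=summaries,
    )


def _contrast_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"contrast": c.label, "estimate": c.estimate, "se": c.se,
             "z": c.z, "p_raw": c.p_raw, "p_adj": c.p_adj}
            for c in results
        ]
    )


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    """Export a report as CSV coefficient / contrast / prediction tables.

    File contents are a pure function of the report, so two runs from the
    same seed and config produce byte-identical directories.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"
    for sp, res in report.selection.items():
        for part, fit, trace in (
            ("occurrence", res.occurrence, res.occurrence_trace),
            ("abundance", res.abundance, res.abundance_trace),
        ):
            tab = fit.coef_table().reset_index(names="term")
            tab.to_csv(outdir / f"coefficients_{sp}_{part}.csv", index=False, float_format=float_fmt)
        res.predictions.to_csv(outdir / f"predictions_{sp}.csv", index=False, float_format=float_fmt)
        for key, contrasts in res.contrasts.items():
            safe = key.replace(":", "_")
            _contrast_frame(contrasts).to_csv(
                outdir / f"contrasts_{sp}_{safe}.csv", index=False, float_format=float_fmt
            )
    report.seasonal_fit.coef_table().reset_index(names="term").to_csv(
        outdir / "coefficients_seasonal.csv", index=False, float_format=float_fmt
    )
    for sp, fit in report.sugar.fits.items():
        fit.coef_table().reset_index(names="term").to_csv(
            outdir / f"coefficients_sugar_{sp}.csv", index=False, float_format=float_fmt
        )
    summary = dict(report.summaries)
    summary["sugar_t_statistic"], summary["sugar_t_p"] = report.sugar.t_test
    summary["seed"] = report.config.seed
    summary["config_hash"] = report.config.digest()
    summary["selection_final_terms"] = {
        sp: {
            "occurrence": list(res.occurrence.spec.terms),
            "abundance": list(res.abundance.spec.terms),
        }
        for sp, res in report.selection.items()
    }
    summary["seasonal_final_terms"] = list(report.seasonal_fit.spec.terms)
    summary["sugar_final_terms"] = {
        sp: list(fit.spec.terms) for sp, fit in report.sugar.fits.items()
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"seed: {report.config.seed}\n")
        fh.write(f"config_hash: {report.config.digest()}\n")
        fh.write(f"n_rows_assembled: {len(report.assembled)}\n")
        flagged = [
            f"{sp}:{part}"
            for sp, res in report.selection.items()
            for part, fit in (("occurrence", res.occurrence), ("abundance", res.abundance))
            if not fit.converged
        ]
        fh.write(f"nonconverged_fits: {','.join(flagged) if flagged else 'none'}\n")


def run_report(
    scn: Scenario, config: RunConfig | None = None, outdir: str | Path = "report"
) -> AnalysisReport:
    """Full analysis plus on-disk report directory."""
    report = run_full_analysis(scn, config)
    write_report(report, outdir)
    return report
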