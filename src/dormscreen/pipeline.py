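"""End-to-end driver: simulate -> classify -> measure -> QC -> ordinate -> model.

The pipeline chains every stage of the dormancy phenotyping workflow on a
synthetic variety panel (or user-supplied tables) and emits the standard
report bundle: dormancy category counts, a trait-by-category means/ranges
table, a seed-coat-color by category contingency table, four FAMD
ordinations over the configured variable sets, and three proportional-odds
regressions of dormancy category on trait predictors.

Every stage logs rows in/out and the bundle carries an accounting frame, so
no sample is lost silently: rows excluded by spectral QC are enumerated
with reasons, and ordinations report how many incomplete rows they dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as _clf
from .famd import famd as _famd_fit
from .famd import plot_factor_map as _famd_plot
from .famd import support_check as _famd_support
from . import morphometrics as _morph
from . import nirqc as _nirqc
from . import olr as _olr
from . import synthetic as _synth
from .germination import arcsine_transform, anova_tukey

log = logging.getLogger("dormscreen")

__all__ = ["RunConfig", "run_pipeline", "make_report", "FAMD_VARIABLE_SETS",
           "OLR_MODELS"]

QUANT_TRAITS = ["area", "thickness", "protein", "moisture", "eccentricity",
                "major_axis", "minor_axis", "perimeter", "solidity"]

#: The four ordination variable sets: everything; coat traits only; shape
#: traits only; composition only.  Dormancy category is always an active
#: categorical variable.
FAMD_VARIABLE_SETS = {
    "all_traits": {
        "quantitative": ["area", "thickness", "protein", "eccentricity",
                         "major_axis", "minor_axis", "moisture", "perimeter",
                         "solidity"],
        "categorical": ["coat_color", "dormancy"],
    },
    "coat": {
        "quantitative": ["thickness"],
        "categorical": ["coat_color", "dormancy"],
    },
    "shape": {
        "quantitative": ["area", "eccentricity", "major_axis", "minor_axis",
                         "perimeter", "solidity"],
        "categorical": ["dormancy"],
    },
    "composition": {
        "quantitative": ["protein", "moisture"],
        "categorical": ["dormancy"],
    },
}

#: The three regression models: coat thickness + color; composition; shape.
OLR_MODELS = {
    "thickness_color": {
        "continuous": ["thickness"],
        "categorical": {"coat_color": "beige"},
    },
    "composition": {
        "continuous": ["protein", "moisture"],
        "categorical": {},
    },
    "shape": {
        "continuous": ["area", "solidity", "perimeter", "eccentricity",
                       "major_axis", "minor_axis"],
        "categorical": {},
    },
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; defaults run out of the box."""

    seed: int = 42
    n_varieties: int = 189
    classify: bool = True
    classifier: _clf.ClassifierConfig = field(default_factory=_clf.ClassifierConfig)
    # NIR QC
    nir_alpha: float = 0.001
    nir_n_calibration: int = 400
    nir_outlier_fraction: float = 0.04
    calibration_ranges: dict = field(default_factory=lambda: {
        "protein": (12.0, 19.5), "moisture": (7.4, 9.0)})
    # morphometrics demonstration scans
    n_sample_images: int = 2
    seeds_per_image: int = 24
    dpi: int = 1200
    image_size: tuple = (1500, 1500)
    # analyses
    famd_sets: dict = field(default_factory=lambda: dict(FAMD_VARIABLE_SETS))
    olr_models: dict = field(default_factory=lambda: dict(OLR_MODELS))
    olr_min_level_count: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "n_varieties", "classify", "nir_alpha",
                    "nir_n_calibration", "nir_outlier_fraction",
                    "n_sample_images", "seeds_per_image", "dpi",
                    "olr_min_level_count"):
            if key in raw:
                kwargs[key] = raw[key]
        if "calibration_ranges" in raw:
            kwargs["calibration_ranges"] = {
                k: tuple(v) for k, v in raw["calibration_ranges"].items()}
        if "image_size" in raw:
            kwargs["image_size"] = tuple(raw["image_size"])
        if "classifier" in raw:
            kwargs["classifier"] = _clf.ClassifierConfig(**raw["classifier"])
        for key in ("famd_sets", "olr_models"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _panel_config(config: RunConfig) -> _synth.PanelConfig:
    if config.n_varieties == 189:
        return _synth.PanelConfig(rng_seed=config.seed)
    return _synth.PanelConfig(n_varieties=config.n_varieties,
                              rng_seed=config.seed)


def germination_summary(germination: pd.DataFrame) -> pd.DataFrame:
    """Mean germination fraction per variety x round x treatment."""
    df = germination.copy()
    df["fraction"] = df["germinated"] / df["sown"]
    out = (
        df.groupby(["variety_id", "round", "treatment"], sort=True)
        .agg(n_reps=("fraction", "size"), mean_fraction=("fraction", "mean"))
        .reset_index()
    )
    return out


def refined_tukey_letters(germination: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Tukey compact letters across the refined NT/ABA/GA arms per variety."""
    rows = []
    refined = germination[germination["round"] == "refined"]
    for vid, sub in refined.groupby("variety_id", sort=True):
        groups = {}
        for code, arm in sub.groupby("treatment"):
            fracs = (arm["germinated"] / arm["sown"]).to_numpy()
            groups[code] = arcsine_transform(fracs)
        if len(groups) < 2:
            continue
        res = anova_tukey(groups, alpha=alpha)
        for code, letter in res.letters.items():
            rows.append({"variety_id": vid, "treatment": code,
                         "letters": letter, "f_pvalue": res.f_pvalue,
                         "zero_variance": res.zero_variance})
    return pd.DataFrame(rows)


def _nir_stage(config: RunConfig, traits: pd.DataFrame):
    spectra, calibration, outlier_idx = _synth.generate_spectra(
        n_experimental=len(traits),
        n_calibration=config.nir_n_calibration,
        outlier_fraction=config.nir_outlier_fraction,
        seed=config.seed,
    )
    spectra.index = traits.index
    predicted = traits[["protein", "moisture"]].copy()
    qc = _nirqc.apply_qc(spectra, calibration, predicted,
                         config.calibration_ranges, alpha=config.nir_alpha)
    return qc, outlier_idx


def _morph_stage(config: RunConfig, truths, outdir: Path | None):
    summaries = []
    for i, truth in enumerate(truths[: config.n_sample_images]):
        layout = _synth.random_seed_layout(
            config.seeds_per_image, truth.major_axis, truth.minor_axis,
            config.image_size, dpi=config.dpi,
            seed=config.seed * 1000 + i,
        )
        image, _ = _synth.render_seed_image(layout, config.image_size,
                                            dpi=config.dpi)
        labels, shapes = _morph.measure_image(image, dpi=config.dpi)
        summary = _morph.sample_summary(shapes)
        summaries.append({
            "variety_id": truth.variety_id,
            "n_seeds": summary.n_seeds if summary else 0,
            "mean_area": summary.mean_area if summary else np.nan,
            "mean_perimeter": summary.mean_perimeter if summary else np.nan,
            "mean_major_axis": summary.mean_major_axis if summary else np.nan,
            "mean_minor_axis": summary.mean_minor_axis if summary else np.nan,
            "mean_eccentricity": summary.mean_eccentricity if summary else np.nan,
            "mean_solidity": summary.mean_solidity if summary else np.nan,
        })
        if outdir is not None:
            _morph.shapes_to_frame(shapes).to_csv(
                outdir / f"morph_seeds_{truth.variety_id}.csv", index=False)
            _morph.save_overlay(image, labels,
                                outdir / f"morph_mask_{truth.variety_id}.png")
    return pd.DataFrame(summaries)


def make_report(calls: pd.DataFrame | None, analysis_table: pd.DataFrame,
                famd_results: dict, olr_tables: dict) -> dict:
    """Assemble the report tables from stage outputs.

    ``analysis_table`` is the per-variety trait table carrying a
    ``dormancy`` label column.  Returns a dict with category counts (when
    classification ran), the trait-by-category means/ranges table, the
    color x category contingency table, FAMD inertia summaries with the
    50%-support verdict, and the regression coefficient tables.
    """
    report: dict = {}
    order = [c.label for c in _clf.Category]
    if calls is not None:
        counts, crosstab = _clf.summarize_panel(
            calls, analysis_table["coat_color"])
        counts_df = counts.rename_axis("category").reset_index()
        counts_df["denominator"] = int(counts.sum())
        report["category_counts"] = counts_df
        report["color_by_category"] = crosstab

    rows = []
    traits = [c for c in QUANT_TRAITS if c in analysis_table.columns]
    for trait in traits:
        for cat in order:
            sub = analysis_table.loc[analysis_table["dormancy"] == cat, trait]
            sub = sub.dropna()
            rows.append({
                "trait": trait, "category": cat, "n": len(sub),
                "mean": sub.mean() if len(sub) else np.nan,
                "min": sub.min() if len(sub) else np.nan,
                "max": sub.max() if len(sub) else np.nan,
            })
    report["trait_by_category"] = pd.DataFrame(rows)

    famd_rows = []
    for name, result in famd_results.items():
        ok, line = _famd_support(result)
        famd_rows.append({
            "analysis": name,
            "n_rows": result.n_rows,
            "n_dropped": result.n_dropped,
            "dim1_pct": result.percent_inertia[0],
            "dim2_pct": result.percent_inertia[1]
            if len(result.percent_inertia) > 1 else np.nan,
            "cumulative_2d_pct": result.cumulative_inertia[
                min(1, len(result.cumulative_inertia) - 1)],
            "supported": ok,
            "verdict": line,
        })
    report["famd_summary"] = pd.DataFrame(famd_rows)
    for name, table in olr_tables.items():
        report[f"olr_{name}"] = table
    return report


def run_pipeline(config: RunConfig | None = None,
                 outdir=None) -> dict:
    """Execute the full chain and return the report bundle.

    The bundle maps stage names to data frames; when ``outdir`` is given
    every table is also written as CSV (floats at 6 significant digits,
    regression estimates at 8 decimals) plus factor-map and mask PNGs.
    Identical config and seed give byte-identical CSV output.
    """
    config = config or RunConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    accounting = []

    def account(stage, n_in, n_out, reason=""):
        accounting.append({"stage": stage, "rows_in": int(n_in),
                           "rows_out": int(n_out), "excluded_reason": reason})
        log.info("%s: %d rows in, %d rows out %s", stage, n_in, n_out, reason)

    # 1. synthetic panel
    panel_cfg = _panel_config(config)
    truths, traits = _synth.generate_panel(panel_cfg)
    bundle["traits"] = traits
    account("generate_panel", 0, len(traits))

    # 2. germination assays + summary statistics
    germination = _synth.simulate_panel_assays(truths, panel_cfg)
    bundle["germination"] = germination
    bundle["germination_summary"] = germination_summary(germination)
    bundle["tukey_letters"] = refined_tukey_letters(
        germination, config.classifier.alpha)
    account("simulate_assays", len(traits), len(germination))

    # 3. dormancy classification
    calls = None
    if config.classify:
        calls = _clf.classify_panel(germination, config.classifier)
        bundle["calls"] = calls
        account("classify", germination["variety_id"].nunique(), len(calls))

    # 4. morphometrics demonstration scans
    bundle["morph_samples"] = _morph_stage(config, truths, outdir)
    account("morphometrics", config.n_sample_images,
            len(bundle["morph_samples"]))

    # 5. NIR QC
    qc, outlier_idx = _nir_stage(config, traits)
    bundle["nir_qc"] = qc
    n_kept = int((qc["qc_status"] == "kept").sum())
    account("nir_qc", len(qc), n_kept,
            reason="; ".join(f"{k}={v}" for k, v in
                             qc["qc_status"].value_counts().items()
                             if k != "kept"))

    # 6. analysis table: traits + dormancy label, QC-kept complete cases
    analysis = traits.copy()
    if calls is not None:
        dorm = calls.set_index("variety_id")["category_label"]
        analysis["dormancy"] = dorm.reindex(analysis.index)
    else:
        analysis["dormancy"] = analysis["true_class"]
    analysis["protein"] = qc["protein_dry"]
    analysis["moisture"] = qc["moisture"].where(qc["qc_status"] == "kept")
    analysis_complete = analysis.dropna(subset=["protein", "moisture"])
    bundle["analysis_table"] = analysis_complete
    account("trait_assembly", len(analysis), len(analysis_complete),
            reason="NIR QC exclusions")

    # 7. FAMD ordinations
    famd_results = {}
    for name, spec in config.famd_sets.items():
        result = _famd_fit(analysis_complete, spec["quantitative"],
                            spec["categorical"], n_dims=2)
        famd_results[name] = result
        if outdir is not None:
            eig = pd.DataFrame({
                "eigenvalue": result.eigenvalues,
                "percent_inertia": result.percent_inertia,
                "cumulative_inertia": result.cumulative_inertia,
            })
            eig.to_csv(outdir / f"famd_{name}_inertia.csv", index=False,
                       float_format="%.6g")
            result.row_coords.to_csv(outdir / f"famd_{name}_coords.csv",
                                     float_format="%.6g")
            result.contributions.to_csv(
                outdir / f"famd_{name}_contributions.csv", float_format="%.6g")
            _famd_plot(
                result, analysis_complete["dormancy"],
                outdir / f"famd_{name}_map.png")
    bundle["famd_results"] = famd_results

    # 8. proportional-odds regressions
    olr_tables = {}
    cat_codes = {c.label: int(c) for c in _clf.Category}
    y = analysis_complete["dormancy"].map(cat_codes).to_numpy()
    for name, spec in config.olr_models.items():
        try:
            X, names = _olr.design_matrix(
                analysis_complete, spec["continuous"],
                spec.get("categorical") or None,
                min_level_count=config.olr_min_level_count)
            fit = _olr.fit_proportional_odds(X, y, names=names)
            olr_tables[name] = _olr.coefficient_table(fit)
        except (_olr.ConvergenceError, ValueError) as exc:
            raise RuntimeError(f"stage olr[{name}]: {exc}") from exc
    bundle["olr_tables"] = olr_tables

    # 9. report
    report = make_report(calls, analysis_complete, famd_results, olr_tables)
    bundle["report"] = report
    bundle["accounting"] = pd.DataFrame(accounting)

    if outdir is not None:
        traits.to_csv(outdir / "traits.csv", float_format="%.6g")
        germination.to_csv(outdir / "germination.csv", index=False)
        bundle["germination_summary"].to_csv(
            outdir / "germination_summary.csv", index=False,
            float_format="%.6g")
        bundle["tukey_letters"].to_csv(outdir / "tukey_letters.csv",
                                       index=False, float_format="%.6g")
        if calls is not None:
            calls.to_csv(outdir / "dormancy_calls.csv", index=False)
            report["category_counts"].to_csv(outdir / "category_counts.csv",
                                             index=False)
            report["color_by_category"].to_csv(outdir / "color_by_category.csv")
        qc.to_csv(outdir / "nir_qc.csv", float_format="%.6g")
        bundle["morph_samples"].to_csv(outdir / "morph_samples.csv",
                                       index=False, float_format="%.6g")
        analysis_complete.to_csv(outdir / "analysis_table.csv",
                                 float_format="%.6g")
        report["trait_by_category"].to_csv(outdir / "trait_by_category.csv",
                                           index=False, float_format="%.6g")
        report["famd_summary"].to_csv(outdir / "famd_summary.csv", index=False,
                                      float_format="%.6g")
        for name, table in olr_tables.items():
            table.to_csv(outdir / f"olr_{name}.csv", index=False,
                         float_format="%.8f")
        bundle["accounting"].to_csv(outdir / "accounting.csv", index=False)
    return bundle
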