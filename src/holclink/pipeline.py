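"""End-to-end pipeline: coverages -> schemes -> CV -> selection -> validation.

The runner sequences the whole analysis and writes every intermediate
table as CSV plus a machine-readable JSON summary. Inputs come from a
:class:`PipelineConfig`: polygon layers (optional; run the overlay), a
coverage table, or neither (simulate a synthetic universe from the seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .collapse import class_profile, collapse_labels, composite_outcome, cronbach_alpha
from .compare import coefficient_table, performance_ratio, predictor_labels, r2_table
from .crossval import DEFAULT_THRESHOLDS, run_grid, standardize
from .meta import (
    plot_mse_vs_df,
    select_optimal,
    select_parsimonious,
    summarize_schemes,
    table3_columns,
)
from .overlay import centroid_grade, compute_coverage, filter_by_threshold
from .schemes import Scheme, enumerate_schemes, label_table
from .synthetic import SyntheticConfig, generate_coverages, generate_outcomes


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one source of coverages is used: ``tracts_path`` +
    ``holc_path`` (polygon overlay), ``coverages_path`` (precomputed
    table), or neither (synthetic simulation of ``n_tracts`` tracts).
    ``cv_outcomes`` are used for the cross-validation experiments and the
    composite profiles; ``validation_outcomes`` (disjoint) for the
    held-out comparisons. ``sign_flips`` lists 0-based positions within
    ``cv_outcomes`` whose sign is inverted when building the composite.
    """

    out_dir: str = "holclink_out"
    coverages_path: str | None = None
    outcomes_path: str | None = None
    tracts_path: str | None = None
    holc_path: str | None = None
    mask_path: str | None = None
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    cv_outcomes: Sequence[str] | None = None
    validation_outcomes: Sequence[str] | None = None
    sign_flips: Sequence[int] = ()
    seed: int = 0
    tolerance: float = 0.005
    profile_threshold: float = 5.0
    n_tracts: int = 1500
    n_outcomes: int = 8

    def __post_init__(self) -> None:
        if self.cv_outcomes and self.validation_outcomes:
            overlap = set(self.cv_outcomes) & set(self.validation_outcomes)
            if overlap:
                raise ValueError(
                    f"cv and validation outcomes must be disjoint; "
                    f"shared: {sorted(overlap)}"
                )
        bad = [t for t in self.thresholds if not 0 <= t <= 100]
        if bad:
            raise ValueError(f"thresholds outside [0, 100]: {bad}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the JSON-ready summary dict (also written to
    ``summary.json``). Any stage error aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    import holclink

    _log(log, f"holclink {holclink.__version__}; seed={config.seed}")
    summary: dict = {"seed": config.seed}

    # ---- stage: coverages -------------------------------------------------
    stage = "coverage"
    try:
        centroid_map = None
        if config.tracts_path and config.holc_path:
            coverages = compute_coverage(
                config.tracts_path, config.holc_path, config.mask_path
            )
            centroid_map = centroid_grade(config.tracts_path, config.holc_path)
            _log(log, f"overlay: {len(coverages)} tracts")
        elif config.coverages_path:
            coverages = hio.read_coverage_csv(config.coverages_path)
            _log(log, f"coverages read: {len(coverages)} tracts")
        else:
            syn = SyntheticConfig(
                n_tracts=config.n_tracts,
                n_outcomes=config.n_outcomes,
                sign_flips=frozenset(config.sign_flips),
                seed=config.seed,
            )
            coverages = generate_coverages(syn)
            _log(log, f"simulated: {len(coverages)} tracts")
        hio.write_coverage_csv(coverages, out / "coverages.csv")

        if config.outcomes_path:
            outcomes = hio.read_outcomes_csv(config.outcomes_path)
        elif config.coverages_path or config.tracts_path:
            raise ValueError("outcomes_path required when coverages are not simulated")
        else:
            outcomes = generate_outcomes(coverages, syn)
        hio.write_outcomes_csv(outcomes, out / "outcomes.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    all_outcomes = [c for c in outcomes.columns if c != "tract_id"]
    cv_cols = list(config.cv_outcomes or all_outcomes[: min(6, len(all_outcomes))])
    val_cols = list(
        config.validation_outcomes
        or [c for c in all_outcomes if c not in cv_cols]
    )
    if set(cv_cols) & set(val_cols):
        raise RuntimeError(
            "pipeline stage 'outcomes' failed: cv and validation outcomes overlap"
        )
    _log(log, f"cv outcomes: {cv_cols}; validation outcomes: {val_cols}")

    # ---- stage: cross-validation grid ------------------------------------
    stage = "cv_grid"
    try:
        schemes = enumerate_schemes()
        cv_results = run_grid(
            coverages, outcomes, schemes,
            thresholds=config.thresholds, seed=config.seed,
            outcome_columns=cv_cols,
        )
        cv_results.to_csv(out / "cv_results.csv", index=False)
        summary["n_schemes"] = len(schemes)
        summary["n_cv_rows"] = len(cv_results)
        cells = cv_results.groupby("scheme_id").size()
        summary["cells_per_scheme"] = int(cells.iloc[0]) if cells.nunique() == 1 \
            else cells.to_dict()
        _log(log, f"cv grid: {len(cv_results)} cells "
                  f"({len(schemes)} schemes x {len(cv_cols)} outcomes x "
                  f"{len(list(config.thresholds))} thresholds)")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage: meta-analysis + selection --------------------------------
    stage = "meta_select"
    try:
        tables = table3_columns(cv_results)
        for name, tab in tables.items():
            tab.to_csv(out / f"meta_regression_{name}.csv")
        summaries = summarize_schemes(cv_results)
        summaries.to_csv(out / "scheme_summary.csv", index=False)
        optimal = select_optimal(summaries)
        parsimonious = select_parsimonious(summaries, config.tolerance)
        plot_mse_vs_df(summaries, out / "mse_vs_df.png")
        summary["optimal_scheme"] = optimal
        summary["parsimonious_scheme"] = parsimonious
        _log(log, f"selected optimal={optimal} parsimonious={parsimonious}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage: collapse + profiles --------------------------------------
    stage = "collapse_profile"
    try:
        prof_data = filter_by_threshold(
            coverages.merge(outcomes, on="tract_id"), config.profile_threshold
        )
        detailed = label_table(prof_data, Scheme(6, 2, False))
        collapsed = collapse_labels(detailed)
        pd.DataFrame({
            "tract_id": prof_data["tract_id"].to_numpy(),
            "detailed": detailed.to_numpy(),
            "collapsed": collapsed.to_numpy(),
        }).to_csv(out / "labels_two_rating.csv", index=False)
        z = pd.DataFrame({c: standardize(prof_data[c]) for c in cv_cols},
                         index=prof_data.index)
        comp = composite_outcome(z, config.sign_flips)
        alpha = cronbach_alpha(
            z * np.array([-1.0 if j in set(config.sign_flips) else 1.0
                          for j in range(len(cv_cols))])
        )
        prof16 = class_profile(detailed, comp["composite"])
        prof10 = class_profile(collapsed, comp["composite"])
        prof16.to_csv(out / "profile_detailed.csv", index=False)
        prof10.to_csv(out / "profile_collapsed.csv", index=False)
        summary["n_detailed_classes"] = int(prof16.shape[0])
        summary["n_collapsed_classes"] = int(prof10.shape[0])
        summary["cronbach_alpha"] = alpha
        _log(log, f"collapse: {prof16.shape[0]} -> {prof10.shape[0]} classes; "
                  f"alpha={alpha:.3f}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage: validation comparisons -----------------------------------
    stage = "compare_validate"
    try:
        if val_cols:
            val_data = filter_by_threshold(
                coverages.merge(outcomes, on="tract_id"),
                config.profile_threshold,
            )
            kinds = ["proportions", "one_rating", "collapsed10",
                     "detailed16", "optimal40"]
            if centroid_map is not None:
                kinds.append("centroid")
            r2 = r2_table(
                outcomes[["tract_id"] + val_cols],
                filter_by_threshold(coverages, config.profile_threshold),
                kinds,
                centroid_grades=centroid_map,
            )
            r2.to_csv(out / "validation_r2.csv")
            ratio = performance_ratio(
                float(r2.loc[val_cols, "collapsed10"].mean()),
                float(r2.loc[val_cols, "optimal40"].mean()),
            )
            summary["collapsed_vs_optimal_pct"] = ratio.percent
            summary["collapsed_vs_optimal_pct_rounded"] = ratio.rounded
            oc = val_cols[0]
            keep = val_data[oc].notna()
            for kind in ("one_rating", "collapsed10"):
                labels = predictor_labels(val_data.loc[keep], kind)
                ref = "A" if kind == "one_rating" else "Only or mainly A"
                if ref in set(labels):
                    ct = coefficient_table(
                        standardize(val_data.loc[keep, oc]), labels, ref
                    )
                    ct.to_csv(out / f"coefficients_{kind}_{oc}.csv")
            _log(log, f"validation: collapsed10 achieves "
                      f"{ratio.rounded}% of optimal40's average R²")
        else:
            _log(log, "validation skipped: no validation outcomes")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return summary
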