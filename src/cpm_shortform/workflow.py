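"""Configuration, orchestration and reporting.

A flat key-value config (YAML) drives the whole pipeline; every default
equals the study design's stated value (70/30 split halved into 35/35,
alpha in [.4, 1], lambda in [1, 3], 1% gain threshold, 100 stability and
baseline runs). One master seed governs all stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde

from . import __version__
from .io import (
    read_covariates_csv,
    read_response_csv,
    write_covariates_csv,
    write_item_metadata_csv,
    write_response_csv,
)
from .items import SCORED_ITEMS
from .pipeline import SplitPlan, StoppingPolicy, develop_short_form, split_data
from .simulator import CohortSpec, make_cohort
from .validation import ValidationReport, score_form, total_score, validate_short_form

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "render_report"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults mirror the study design."""

    seed: int = 0
    simulate: bool = True
    n_persons: int = 336
    target_alpha: float = 0.86
    responses_csv: str | None = None
    covariates_csv: str | None = None
    development_fraction: float = 0.70
    validation_fraction: float = 0.30
    alpha_min: float = 0.40
    alpha_max: float = 1.00
    alpha_step: float = 0.05
    lambda_min: float = 1.00
    lambda_max: float = 3.00
    lambda_step: float = 0.05
    policy: str = "all_subsequent_below"
    threshold: float = 0.01
    runs: int = 100
    bootstrap_B: int = 2000
    run_stability: bool = True
    out_dir: str = "cpm_shortform_output"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def alpha_grid(self) -> tuple[float, ...]:
        return tuple(
            np.round(
                np.arange(self.alpha_min, self.alpha_max + 1e-9, self.alpha_step), 10
            )
        )

    def lambda_grid(self) -> tuple[float, ...]:
        return tuple(
            np.round(
                np.arange(self.lambda_min, self.lambda_max + 1e-9, self.lambda_step), 10
            )
        )


def _density_table(full_scores, short_scores) -> pd.DataFrame:
    """Score-density data for the full form and short form (for plotting)."""
    grid = np.linspace(
        0, max(float(np.max(full_scores)), float(np.max(short_scores))), 201
    )
    return pd.DataFrame(
        {
            "score": grid,
            "full_density": gaussian_kde(full_scores)(grid),
            "short_density": gaussian_kde(short_scores)(grid),
        }
    )


def run_all(config: PipelineConfig) -> dict:
    """simulate (optional) -> develop -> validate -> report.

    Writes all declared artifacts under ``config.out_dir`` and returns the
    aggregated report dictionary. Deterministic given the config.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        logger.info("stage simulate: n=%d", config.n_persons)
        cohort = make_cohort(
            CohortSpec(
                n_persons=config.n_persons,
                target_alpha=config.target_alpha,
                seed=config.seed,
            )
        )
        responses = cohort.responses[list(SCORED_ITEMS)]
        covariates = cohort.covariates
        write_response_csv(cohort.responses, out / "responses.csv")
        write_covariates_csv(covariates, out / "covariates.csv")
        write_item_metadata_csv(cohort.item_params, out / "items.csv")
    else:
        if not config.responses_csv:
            raise FileNotFoundError("simulation off and no responses_csv given")
        responses = read_response_csv(config.responses_csv)
        covariates = (
            read_covariates_csv(config.covariates_csv)
            if config.covariates_csv
            else None
        )

    logger.info("stage develop: grid %dx%d",
                len(config.alpha_grid()), len(config.lambda_grid()))
    plan = SplitPlan(
        development_fraction=config.development_fraction,
        validation_fraction=config.validation_fraction,
        train_fraction=config.development_fraction / 2,
        test_fraction=config.development_fraction / 2,
        seed=config.seed,
    )
    policy = StoppingPolicy(name=config.policy, threshold=config.threshold)
    selected, grid, audit = develop_short_form(
        responses, plan, config.alpha_grid(), config.lambda_grid(), policy
    )
    grid.candidate_table().to_csv(out / "candidates.csv", index=False)
    (out / "selected_form.json").write_text(json.dumps(selected.to_dict(), indent=2))

    logger.info("stage validate: %d runs, B=%d", config.runs, config.bootstrap_B)
    idx = split_data(len(responses), plan)
    dev = responses.iloc[np.concatenate([idx["train"], idx["test"]])]
    val = responses.iloc[idx["validation"]]
    report = validate_short_form(
        val,
        selected.items,
        development_responses=dev if config.run_stability else None,
        covariates=covariates,
        runs=config.runs,
        B=config.bootstrap_B,
        seed=config.seed,
        alpha_grid=config.alpha_grid(),
        lambda_grid=config.lambda_grid(),
        run_stability=config.run_stability,
    )
    report.stability and report.stability.to_frame().to_csv(
        out / "stability.csv", index=False
    )
    report.baseline.to_frame().to_csv(out / "baseline.csv", index=False)
    report.content.to_csv(out / "content.csv", index=False)
    if report.concurrent is not None:
        report.concurrent.to_csv(out / "concurrent.csv", index=False)
    _density_table(
        total_score(val).to_numpy(float),
        score_form(val, selected.items).to_numpy(float),
    ).to_csv(out / "density.csv", index=False)

    payload = {
        "version": __version__,
        "config": asdict(config),
        "audit": audit,
        "report": report.to_dict(),
    }
    (out / "audit.json").write_text(json.dumps(
        {"version": __version__, "config": asdict(config), "audit": audit},
        indent=2,
    ))
    (out / "report.json").write_text(json.dumps(payload["report"], indent=2))
    (out / "report.md").write_text(render_report(report))
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return payload


def render_report(report: ValidationReport) -> str:
    """Human-readable markdown summary of a validation report."""
    lines = ["# Short-form validation report", ""]
    lines.append(f"Selected form ({len(report.selected_items)} items): "
                 + " ".join(report.selected_items))
    lines.append("")
    lines.append("## Agreement and reliability")
    lines.append("")
    lines.append(
        f"- r with full-form total: {report.r_with_full:.2f} "
        f"[{report.r_with_full_ci[0]:.2f}, {report.r_with_full_ci[1]:.2f}]"
    )
    lines.append(
        f"- Cronbach's alpha (short form): {report.alpha_short:.2f} "
        f"[{report.alpha_short_ci[0]:.2f}, {report.alpha_short_ci[1]:.2f}]"
    )
    lines.append(
        f"- Cronbach's alpha (full form): {report.alpha_full:.2f} "
        f"[{report.alpha_full_ci[0]:.2f}, {report.alpha_full_ci[1]:.2f}]"
    )
    lines.append("")
    lines.append("## Item stability")
    lines.append("")
    if report.stability is None:
        lines.append("not run")
    else:
        st = report.stability
        lines.append(
            f"{st.effective_runs} effective runs at target length "
            f"{st.target_length}; inclusion frequency of selected items:"
        )
        lines.append("")
        lines.append("| item | frequency |")
        lines.append("| --- | --- |")
        for item in report.selected_items:
            lines.append(f"| {item} | {st.inclusion_frequency[item]:.2f} |")
    lines.append("")
    lines.append("## Random-subset baseline")
    lines.append("")
    if report.baseline is None:
        lines.append("not run")
    else:
        bl = report.baseline
        lines.append(
            f"- {bl.runs} random {bl.length}-item forms: mean r = "
            f"{bl.r_distribution.mean():.2f} "
            f"(range {bl.r_distribution.min():.2f}-{bl.r_distribution.max():.2f}), "
            f"mean alpha = {bl.alpha_distribution.mean():.2f} "
            f"(range {bl.alpha_distribution.min():.2f}-"
            f"{bl.alpha_distribution.max():.2f})"
        )
        if bl.exceedance is not None:
            lines.append(
                f"- selected form (r = {bl.selected_r:.2f}) outperformed "
                f"{100 * bl.exceedance:.0f}% of random forms"
            )
    lines.append("")
    lines.append("## Content coverage")
    lines.append("")
    lines.append("| domain | full form | short form |")
    lines.append("| --- | --- | --- |")
    for _, row in report.content.iterrows():
        lines.append(
            f"| {row['domain']} | {row['full_count']} | {row['short_count']} |"
        )
    lines.append("")
    lines.append("## Concurrent validity")
    lines.append("")
    if report.concurrent is None or report.concurrent.empty:
        lines.append("not run")
    else:
        lines.append("| measure | r | n | 95% BCa CI |")
        lines.append("| --- | --- | --- | --- |")
        for _, row in report.concurrent.iterrows():
            lines.append(
                f"| {row['covariate']} | {row['r']:.2f} | {row['n_pairs']} | "
                f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}] |"
            )
    lines.append("")
    return "\n".join(lines)
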