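"""Validation battery for a developed short form.

Covers the five lines of evidence a short form needs: agreement with the
full-form total score (Pearson r with a BCa bootstrap interval), internal
consistency (Cronbach's alpha with a BCa interval), item stability under
re-randomised train/test halves (Monte Carlo inclusion frequencies),
performance against same-length random item subsets (baseline r and alpha
distributions with a strict exceedance proportion), content coverage across
the manual's cognitive-demand domains, and concurrent validity against
related measures with pairwise-complete ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .items import DOMAIN_MAP, canonical_sort
from .pipeline import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_LAMBDA_GRID,
    grid_search,
    score_form,
    total_score,
)

__all__ = [
    "pearson_r",
    "cronbach_alpha",
    "bca_ci",
    "StabilityResult",
    "monte_carlo_stability",
    "BaselineResult",
    "random_form_baseline",
    "content_distribution",
    "concurrent_validity",
    "inverse_efficiency",
    "evaluate_fixed_form",
    "ValidationReport",
    "validate_short_form",
]


def pearson_r(x, y) -> tuple[float, int]:
    """Product-moment correlation over pairwise-complete cases.

    Returns (r, number of complete pairs). Raises on fewer than 3 pairs or
    a zero-variance margin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(xs, ys).statistic), n


def cronbach_alpha(responses: pd.DataFrame, items=None) -> float:
    """Cronbach's alpha (k/(k-1)) * (1 - sum item variances / variance of sum).

    Computed on complete cases over the item subset; sample variances
    (ddof = 1). Alpha <= 1 always; negative values are returned as-is.
    """
    sub = responses if items is None else responses[list(items)]
    sub = sub.dropna(axis=0, how="any")
    k = sub.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if sub.shape[0] < 3:
        raise ValueError("alpha needs at least 3 complete persons")
    values = sub.to_numpy(dtype=float)
    item_vars = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def bca_ci(
    statistic,
    data,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    paired: bool = True,
) -> tuple[float, float]:
    """Bias-corrected and accelerated (BCa) bootstrap confidence interval.

    ``data`` is a sequence of equal-length sample arrays resampled jointly
    (paired) by default; ``statistic`` takes the resampled arrays as
    positional arguments. Deterministic given the seed. A degenerate
    bootstrap distribution collapses to the point estimate with a warning.
    """
    if B < 999:
        raise ValueError("need B >= 999 bootstrap replicates")
    data = tuple(np.asarray(d, dtype=float) for d in data)
    point = float(statistic(*data))
    rng = np.random.default_rng(seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns on near-degenerate z0
            res = stats.bootstrap(
                data,
                statistic,
                n_resamples=B,
                confidence_level=level,
                method="BCa",
                paired=paired and len(data) > 1,
                vectorized=False,
                rng=rng,
            )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    except Exception:
        lo = hi = np.nan
    if not (np.isfinite(lo) and np.isfinite(hi)):
        warnings.warn(
            "degenerate bootstrap distribution; interval collapsed to the "
            "point estimate",
            stacklevel=2,
        )
        return point, point
    return lo, hi


@dataclass
class StabilityResult:
    """Item inclusion frequencies over re-randomised selection runs."""

    runs: int
    target_length: int
    inclusion_frequency: dict[str, float]
    effective_runs: int
    fallback_lengths: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": list(self.inclusion_frequency),
             "frequency": list(self.inclusion_frequency.values())}
        )


def monte_carlo_stability(
    development_responses: pd.DataFrame,
    target_length: int,
    runs: int = 100,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> StabilityResult:
    """Re-run the selection algorithm on random train/test halves.

    Each run halves the development set at random, repeats the grid search,
    and keeps the best candidate of the target length (falling back to the
    nearest available length, preferring longer, when the exact length never
    appears — recorded in ``fallback_lengths``). Frequencies are tallied
    over runs that produced any candidate.
    """
    n = len(development_responses)
    if n < 20:
        raise ValueError("development set too small for stability analysis")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {c: 0 for c in development_responses.columns}
    effective = 0
    fallbacks: dict[int, int] = {}
    for _ in range(runs):
        perm = rng.permutation(n)
        half = n // 2
        train = development_responses.iloc[perm[:half]]
        test = development_responses.iloc[perm[half:]]
        grid = grid_search(train, test, alpha_grid, lambda_grid)
        if not grid.best_per_length:
            continue
        lengths = np.array(sorted(grid.best_per_length))
        if target_length in grid.best_per_length:
            chosen_len = target_length
        else:
            # nearest available length, preferring longer on ties
            chosen_len = int(
                min(lengths, key=lambda L: (abs(L - target_length), -L))
            )
            fallbacks[chosen_len] = fallbacks.get(chosen_len, 0) + 1
        for item in grid.best_per_length[chosen_len].items:
            counts[item] += 1
        effective += 1
    if effective == 0:
        raise RuntimeError("no stability run produced a candidate form")
    return StabilityResult(
        runs=runs,
        target_length=target_length,
        inclusion_frequency={c: counts[c] / effective for c in counts},
        effective_runs=effective,
        fallback_lengths=fallbacks,
    )


@dataclass
class BaselineResult:
    """Random same-length item subsets as a performance baseline."""

    runs: int
    length: int
    r_distribution: np.ndarray
    alpha_distribution: np.ndarray
    exceedance: float | None
    selected_r: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"run": np.arange(1, self.runs + 1),
             "r": self.r_distribution,
             "alpha": self.alpha_distribution}
        )


def random_form_baseline(
    validation_responses: pd.DataFrame,
    length: int,
    runs: int = 100,
    seed: int = 0,
    selected_form=None,
) -> BaselineResult:
    """Correlations and alphas of uniform random item subsets.

    Each run draws ``length`` items without replacement, scores the subset
    on the validation set, and records its correlation with the total score
    and its Cronbach's alpha. Exceedance is the strict fraction of random
    forms whose r falls below the selected form's r (ties do not count as
    outperformed).
    """
    columns = list(validation_responses.columns)
    if length >= len(columns) + 1:
        raise ValueError("subset length exceeds item count")
    rng = np.random.default_rng(seed)
    totals = total_score(validation_responses)
    rs = np.empty(runs)
    alphas = np.empty(runs)
    for k in range(runs):
        subset = list(rng.choice(columns, size=length, replace=False))
        scores = score_form(validation_responses, subset)
        rs[k], _ = pearson_r(scores, totals)
        # alpha is undefined for single-item forms
        alphas[k] = (
            cronbach_alpha(validation_responses, subset) if length >= 2
            else np.nan
        )
    exceedance = None
    selected_r = None
    if selected_form is not None:
        selected_r, _ = pearson_r(
            score_form(validation_responses, list(selected_form)), totals
        )
        exceedance = float(np.sum(rs < selected_r)) / runs
    return BaselineResult(
        runs=runs,
        length=length,
        r_distribution=rs,
        alpha_distribution=alphas,
        exceedance=exceedance,
        selected_r=selected_r,
    )


def content_distribution(items, content_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Counts of full-form and subset items per cognitive-demand domain.

    Every subset item must be mapped; domains are reported in manual order
    with both the full-form and short-form counts.
    """
    content_map = content_map or DOMAIN_MAP
    items = canonical_sort(items)
    unmapped = [i for i in items if i not in content_map]
    if unmapped:
        raise KeyError(f"item(s) without a domain mapping: {unmapped}")
    domains = list(dict.fromkeys(content_map.values()))
    full_counts = {d: 0 for d in domains}
    for item, d in content_map.items():
        full_counts[d] += 1
    short_counts = {d: 0 for d in domains}
    for item in items:
        short_counts[content_map[item]] += 1
    return pd.DataFrame(
        {
            "domain": domains,
            "full_count": [full_counts[d] for d in domains],
            "short_count": [short_counts[d] for d in domains],
        }
    )


def content_set_counts(items) -> dict[str, int]:
    """Short-form item counts per CPM set (A / Ab / B)."""
    from .items import set_of

    counts = {"A": 0, "Ab": 0, "B": 0}
    for item in canonical_sort(items):
        counts[set_of(item)] += 1
    return counts


def concurrent_validity(
    short_scores: pd.Series,
    covariates: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise-complete correlations of the short form with each covariate.

    Returns one row per covariate: r, number of complete pairs, and a 95%
    BCa interval. Covariates with fewer than 3 complete pairs are skipped
    with a warning.
    """
    scores = short_scores.to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(covariates.columns):
        cov = covariates[name].to_numpy(dtype=float)
        mask = ~(np.isnan(scores) | np.isnan(cov))
        if mask.sum() < 3:
            warnings.warn(f"covariate {name!r} skipped: fewer than 3 pairs")
            continue
        r, n_pairs = pearson_r(scores, cov)

        def _r(x, y):
            if np.std(x) == 0 or np.std(y) == 0:
                return np.nan
            return stats.pearsonr(x, y).statistic

        lo, hi = bca_ci(
            _r, (scores[mask], cov[mask]), B=B, seed=seed + j, paired=True
        )
        rows.append(
            {"covariate": name, "r": r, "n_pairs": n_pairs,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def inverse_efficiency(
    time_seconds: float, n_correct: int, n_total: int
) -> float:
    """Inverse efficiency score: time divided by proportion correct.

    Lower is better. Undefined at zero accuracy.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must be in [0, n_total]")
    if time_seconds <= 0:
        raise ValueError("time must be > 0")
    if n_correct == 0:
        raise ZeroDivisionError("inverse efficiency undefined at 0 accuracy")
    return float(time_seconds / (n_correct / n_total))


def evaluate_fixed_form(
    responses: pd.DataFrame, items
) -> tuple[float, float]:
    """(r with the total score, Cronbach's alpha) for any fixed item subset.

    The generic mechanism for benchmarking published subsets against the
    developed form on the same data.
    """
    items = list(items)
    if not items:
        raise ValueError("empty item subset")
    scores = score_form(responses, items)
    r, _ = pearson_r(scores, total_score(responses))
    alpha = cronbach_alpha(responses, items)
    return r, alpha


@dataclass
class ValidationReport:
    """Aggregated validation evidence for a selected short form."""

    selected_items: tuple[str, ...]
    r_with_full: float
    r_with_full_ci: tuple[float, float]
    alpha_short: float
    alpha_short_ci: tuple[float, float]
    alpha_full: float
    alpha_full_ci: tuple[float, float]
    stability: StabilityResult | None
    baseline: BaselineResult | None
    content: pd.DataFrame
    concurrent: pd.DataFrame | None

    def to_dict(self) -> dict:
        out = {
            "selected_items": list(self.selected_items),
            "r_with_full": self.r_with_full,
            "r_with_full_ci": list(self.r_with_full_ci),
            "alpha_short": self.alpha_short,
            "alpha_short_ci": list(self.alpha_short_ci),
            "alpha_full": self.alpha_full,
            "alpha_full_ci": list(self.alpha_full_ci),
            "content": self.content.to_dict(orient="records"),
        }
        if self.stability is not None:
            out["stability"] = {
                "runs": self.stability.runs,
                "effective_runs": self.stability.effective_runs,
                "target_length": self.stability.target_length,
                "inclusion_frequency": self.stability.inclusion_frequency,
                "fallback_lengths": {
                    str(k): v for k, v in self.stability.fallback_lengths.items()
                },
            }
        if self.baseline is not None:
            out["baseline"] = {
                "runs": self.baseline.runs,
                "length": self.baseline.length,
                "mean_r": float(self.baseline.r_distribution.mean()),
                "mean_alpha": float(self.baseline.alpha_distribution.mean()),
                "exceedance": self.baseline.exceedance,
                "selected_r": self.baseline.selected_r,
            }
        if self.concurrent is not None:
            out["concurrent"] = self.concurrent.to_dict(orient="records")
        return out


def _alpha_stat(items):
    def stat(*cols):
        values = np.column_stack(cols)
        k = values.shape[1]
        total_var = values.sum(axis=1).var(ddof=1)
        if total_var == 0:
            return np.nan
        return k / (k - 1) * (1 - values.var(axis=0, ddof=1).sum() / total_var)

    return stat


def validate_short_form(
    validation_responses: pd.DataFrame,
    selected_items,
    development_responses: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    runs: int = 100,
    B: int = 2000,
    seed: int = 0,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    run_stability: bool = True,
) -> ValidationReport:
    """Run the full validation battery on a held-out validation set."""
    selected_items = canonical_sort(selected_items)
    totals = total_score(validation_responses)
    short = score_form(validation_responses, selected_items)
    r_full, _ = pearson_r(short, totals)

    def _r(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return stats.pearsonr(x, y).statistic

    r_ci = bca_ci(
        _r,
        (short.to_numpy(float), totals.to_numpy(float)),
        B=B, seed=seed + 1, paired=True,
    )
    alpha_short = cronbach_alpha(validation_responses, selected_items)
    alpha_short_ci = bca_ci(
        _alpha_stat(selected_items),
        tuple(
            validation_responses[i].to_numpy(float) for i in selected_items
        ),
        B=B, seed=seed + 2, paired=True,
    )
    all_items = list(validation_responses.columns)
    alpha_full = cronbach_alpha(validation_responses, all_items)
    alpha_full_ci = bca_ci(
        _alpha_stat(all_items),
        tuple(validation_responses[i].to_numpy(float) for i in all_items),
        B=B, seed=seed + 3, paired=True,
    )
    stability = None
    if run_stability and development_responses is not None:
        stability = monte_carlo_stability(
            development_responses,
            target_length=len(selected_items),
            runs=runs,
            alpha_grid=alpha_grid,
            lambda_grid=lambda_grid,
            seed=seed + 4,
        )
    baseline = random_form_baseline(
        validation_responses,
        length=len(selected_items),
        runs=runs,
        seed=seed + 5,
        selected_form=selected_items,
    )
    concurrent = None
    if covariates is not None:
        concurrent = concurrent_validity(
            short, covariates.loc[validation_responses.index], B=B, seed=seed + 6
        )
    content = content_distribution(selected_items)
    return ValidationReport(
        selected_items=selected_items,
        r_with_full=r_full,
        r_with_full_ci=r_ci,
        alpha_short=alpha_short,
        alpha_short_ci=alpha_short_ci,
        alpha_full=alpha_full,
        alpha_full_ci=alpha_full_ci,
        stability=stability,
        baseline=baseline,
        content=content,
        concurrent=concurrent,
    )
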