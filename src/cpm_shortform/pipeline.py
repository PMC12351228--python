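"""Short-form development: splitting, grid search, stopping rule.

The procedure mirrors standard machine-learning scale abbreviation: the
cohort is split into a development set (70%, itself halved into train and
test) and a held-out validation set (30%). On the train half, the total
score is regressed on the individual items with the elastic net over a grid
of (mixing alpha, penalty lambda); each grid point's surviving items form a
candidate short form whose unit-weighted sum score is correlated with the
total score on the test half. Among candidates of equal length the highest
test-set correlation wins, and an a-priori rule on the percent gain in that
correlation between consecutive available lengths fixes the final length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import elastic_net as enet

__all__ = [
    "SplitPlan",
    "CandidateForm",
    "GridResult",
    "StoppingPolicy",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_LAMBDA_GRID",
    "split_data",
    "total_score",
    "score_form",
    "grid_search",
    "apply_stopping_rule",
    "develop_short_form",
]

#: Default search grids; every published candidate's (alpha, lambda) pair is
#: a multiple of .05 inside alpha in [.4, 1], lambda in [1, 3].
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.40, 1.0001, 0.05), 2)
)
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(1.00, 3.0001, 0.05), 2)
)


@dataclass(frozen=True)
class SplitPlan:
    """Cohort partition fractions: 70% development (split equally into
    train and test) and 30% held-out validation."""

    development_fraction: float = 0.70
    validation_fraction: float = 0.30
    train_fraction: float = 0.35
    test_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.development_fraction + self.validation_fraction, 1.0):
            raise ValueError("development + validation fractions must sum to 1")
        if not np.isclose(
            self.train_fraction + self.test_fraction, self.development_fraction
        ):
            raise ValueError("train + test fractions must equal development fraction")


def split_data(n_persons: int, plan: SplitPlan) -> dict[str, np.ndarray]:
    """Random disjoint train/test/validation index sets.

    Sizes are floor allocations of the fractions; leftover persons go to
    validation first, then test. At n = 336 with the default plan this gives
    117 / 118 / 101 (development total 235).
    """
    if n_persons < 4:
        raise ValueError("need at least 4 persons to split")
    n_train = int(np.floor(plan.train_fraction * n_persons))
    n_test = int(np.floor(plan.test_fraction * n_persons))
    n_val = int(np.floor(plan.validation_fraction * n_persons))
    remainder = n_persons - n_train - n_test - n_val
    if remainder >= 1:
        n_val += 1
    if remainder == 2:
        n_test += 1
    if remainder > 2:  # only possible with non-default fraction rounding
        n_train += remainder - 2
    if min(n_train, n_test, n_val) < 2:
        raise ValueError(
            f"n = {n_persons} too small: every subset needs >= 2 persons"
        )
    perm = np.random.default_rng(plan.seed).permutation(n_persons)
    return {
        "train": np.sort(perm[:n_train]),
        "test": np.sort(perm[n_train:n_train + n_test]),
        "validation": np.sort(perm[n_train + n_test:]),
    }


def total_score(responses: pd.DataFrame) -> pd.Series:
    """Per-person sum over all (scored) items; missing responses score 0."""
    return responses.fillna(0).sum(axis=1)


def score_form(responses: pd.DataFrame, items) -> pd.Series:
    """Unit-weighted sum score over an item subset; missing responses score 0."""
    items = list(items)
    unknown = [i for i in items if i not in responses.columns]
    if unknown:
        raise KeyError(f"unknown item id(s): {unknown}")
    if not items:
        return pd.Series(0.0, index=responses.index)
    return responses[items].fillna(0).sum(axis=1)


@dataclass(frozen=True)
class CandidateForm:
    """An item subset found at one grid point, with its test-set merit."""

    items: tuple[str, ...]
    mixing: float
    penalty: float
    test_r: float

    @property
    def length(self) -> int:
        return len(self.items)

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "items": list(self.items),
            "mixing": self.mixing,
            "penalty": self.penalty,
            "test_r": self.test_r,
        }


@dataclass
class GridResult:
    """All candidate forms from a grid search plus per-length summaries."""

    candidates: list[CandidateForm]
    best_per_length: dict[int, CandidateForm]
    #: (length, fractional gain in r over the previous available length);
    #: the shortest length carries None.
    gain_sequence: list[tuple[int, float | None]]
    #: item set -> number of grid points that produced it
    support_counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    skipped_grid_points: int = 0

    def candidate_table(self) -> pd.DataFrame:
        """Best-per-length table with percent gains, in display schema."""
        gains = dict(self.gain_sequence)
        rows = []
        for length in sorted(self.best_per_length):
            c = self.best_per_length[length]
            g = gains.get(length)
            rows.append(
                {
                    "length": length,
                    "items": " ".join(c.items),
                    "mixing": c.mixing,
                    "penalty": c.penalty,
                    "r": c.test_r,
                    "pct_change": None if g is None else 100.0 * g,
                }
            )
        return pd.DataFrame(rows)


def _preferred(a: CandidateForm, b: CandidateForm) -> CandidateForm:
    """Tie-break equal-length candidates: higher r, then larger lambda,
    then smaller alpha, then lexicographic item order."""
    ka = (a.test_r, a.penalty, -a.mixing)
    kb = (b.test_r, b.penalty, -b.mixing)
    if ka != kb:
        return a if ka > kb else b
    return a if a.items <= b.items else b


def gain_sequence_from_rs(
    rs_by_length: dict[int, float],
) -> list[tuple[int, float | None]]:
    """Fractional gains in r between consecutive *available* lengths."""
    lengths = sorted(rs_by_length)
    out: list[tuple[int, float | None]] = []
    prev_r: float | None = None
    for length in lengths:
        r = rs_by_length[length]
        out.append((length, None if prev_r is None else (r - prev_r) / prev_r))
        prev_r = r
    return out


def grid_search(
    train_responses: pd.DataFrame,
    test_responses: pd.DataFrame,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    enet_tolerance: float = 1e-7,
) -> GridResult:
    """Enumerate candidate short forms over the (alpha, lambda) grid.

    For each grid point the elastic net regresses the train-set total score
    on the individual item responses; the surviving items (non-zero
    coefficients) form a candidate whose unit-weighted sum score is
    correlated with the total score on the test set. Identical supports
    arising at several grid points are deduplicated (counts retained), with
    the representative (alpha, lambda) chosen by the tie-break preference.
    Grid points with empty supports are skipped and counted.
    """
    alpha_grid, lambda_grid = list(alpha_grid), list(lambda_grid)
    if not alpha_grid or not lambda_grid:
        raise ValueError("alpha and lambda grids must be non-empty")
    item_names = tuple(train_responses.columns)
    X_train = train_responses.fillna(0).to_numpy(dtype=float)
    y_train = total_score(train_responses).to_numpy(dtype=float)
    X_test = test_responses.fillna(0).to_numpy(dtype=float)
    y_test = total_score(test_responses).to_numpy(dtype=float)

    col_index = {name: j for j, name in enumerate(item_names)}
    support_counts: dict[tuple[str, ...], int] = {}
    support_meta: dict[tuple[str, ...], tuple[float, float]] = {}
    skipped = 0
    for alpha in alpha_grid:
        beta_warm = None
        # descend lambda within each alpha so warm starts track the path
        for lam in sorted(lambda_grid, reverse=True):
            fit = enet.fit(
                X_train,
                y_train,
                enet.ElasticNetSpec(
                    mixing=float(alpha), penalty=float(lam),
                    tolerance=enet_tolerance,
                ),
                feature_names=item_names,
                beta_init=beta_warm,
            )
            beta_warm = fit.beta_standardized
            # select_support preserves the column order of the input
            # matrix, which for CPM data is the canonical A -> Ab -> B order
            support = enet.select_support(fit)
            if not support:
                skipped += 1
                continue
            support_counts[support] = support_counts.get(support, 0) + 1
            prev = support_meta.get(support)
            cand = (float(lam), -float(alpha))
            if prev is None or cand > prev:
                support_meta[support] = cand

    candidates: list[CandidateForm] = []
    for support, (lam, neg_alpha) in support_meta.items():
        idx = [col_index[i] for i in support]
        form_scores = X_test[:, idx].sum(axis=1)
        if np.std(form_scores) == 0 or np.std(y_test) == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(form_scores, y_test)[0, 1])
        candidates.append(
            CandidateForm(
                items=support, mixing=-neg_alpha, penalty=lam, test_r=r
            )
        )

    best: dict[int, CandidateForm] = {}
    for cand in candidates:
        cur = best.get(cand.length)
        best[cand.length] = cand if cur is None else _preferred(cur, cand)
    gains = gain_sequence_from_rs({L: c.test_r for L, c in best.items()})
    return GridResult(
        candidates=candidates,
        best_per_length=best,
        gain_sequence=gains,
        support_counts=support_counts,
        skipped_grid_points=skipped,
    )


@dataclass(frozen=True)
class StoppingPolicy:
    """A rule mapping the per-length gain sequence to a final length.

    ``first_below``: stop at the first length whose gain to the next
    available length falls below the threshold. ``first_below_skip_negative``:
    the same, but an isolated negative gain (one followed by an
    above-threshold gain) is treated as an anomaly and skipped.
    ``all_subsequent_below``: the smallest length beyond which every gain
    stays below the threshold — the stability-oriented reading.
    """

    name: str = "all_subsequent_below"
    threshold: float = 0.01

    _NAMES = ("first_below", "first_below_skip_negative", "all_subsequent_below")

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ValueError(f"unknown policy {self.name!r}; choose from {self._NAMES}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def apply_stopping_rule(
    gain_sequence: list[tuple[int, float | None]], policy: StoppingPolicy
) -> int:
    """Select the short-form length from a per-length gain sequence.

    ``gain_sequence`` is ordered by length; each entry is (length,
    fractional gain in r over the previous available length), with the
    first gain None.
    """
    if len(gain_sequence) < 2:
        raise ValueError("gain sequence needs at least two lengths")
    lengths = [L for L, _ in gain_sequence]
    # pairs: (previous available length, gain attached to the next length)
    pairs = [
        (lengths[k - 1], g)
        for k, (_, g) in enumerate(gain_sequence)
        if k >= 1 and g is not None
    ]
    if not pairs:
        raise ValueError("gain sequence carries no gains")
    thr = policy.threshold

    if policy.name == "first_below":
        for prev_len, g in pairs:
            if g < thr:
                return prev_len
        return lengths[-1]

    if policy.name == "first_below_skip_negative":
        for k, (prev_len, g) in enumerate(pairs):
            if g < 0 and k + 1 < len(pairs) and pairs[k + 1][1] >= thr:
                continue  # isolated dip, treated as an anomaly
            if g < thr:
                return prev_len
        return lengths[-1]

    # all_subsequent_below: gains are attached to the *following* length,
    # so length L qualifies when every gain at lengths > L is below thr.
    gains_at = {
        lengths[k]: g
        for k, (_, g) in enumerate(gain_sequence)
        if g is not None
    }
    for L in lengths:
        later = [g for Lg, g in gains_at.items() if Lg > L]
        if all(g < thr for g in later):
            return L
    return lengths[-1]


def develop_short_form(
    responses: pd.DataFrame,
    plan: SplitPlan | None = None,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    policy: StoppingPolicy | None = None,
) -> tuple[CandidateForm, GridResult, dict]:
    """End-to-end development: split, grid search, stopping rule.

    ``responses`` must contain only the scored items (practice excluded).
    Returns the selected candidate, the full grid result, and an audit
    dictionary sufficient to re-run every stage.
    """
    plan = plan or SplitPlan()
    policy = policy or StoppingPolicy()
    idx = split_data(len(responses), plan)
    train = responses.iloc[idx["train"]]
    test = responses.iloc[idx["test"]]
    grid = grid_search(train, test, alpha_grid, lambda_grid)
    if not grid.best_per_length:
        raise RuntimeError("grid search produced no candidate forms")
    if len(grid.gain_sequence) < 2:
        warnings.warn("only one candidate length; stopping rule degenerate")
        selected_length = next(iter(grid.best_per_length))
    else:
        selected_length = apply_stopping_rule(grid.gain_sequence, policy)
    selected = grid.best_per_length[selected_length]
    audit = {
        "plan": {
            "development_fraction": plan.development_fraction,
            "validation_fraction": plan.validation_fraction,
            "train_fraction": plan.train_fraction,
            "test_fraction": plan.test_fraction,
            "seed": plan.seed,
        },
        "split_sizes": {k: int(len(v)) for k, v in idx.items()},
        "split_indices": {k: v.tolist() for k, v in idx.items()},
        "alpha_grid": [float(a) for a in alpha_grid],
        "lambda_grid": [float(l) for l in lambda_grid],
        "policy": {"name": policy.name, "threshold": policy.threshold},
        "n_grid_points": len(list(alpha_grid)) * len(list(lambda_grid)),
        "skipped_grid_points": grid.skipped_grid_points,
        "n_unique_supports": len(grid.support_counts),
        # JSON-safe: the undefined gain of the shortest length stays None
        "candidate_table": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in row.items()}
            for row in grid.candidate_table().to_dict(orient="records")
        ],
        "selected_length": selected.length,
        "selected_form": selected.to_dict(),
    }
    return selected, grid, audit
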