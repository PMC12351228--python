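"""Synthetic cohorts of CPM item responses and concurrent measures.

Responses follow a unidimensional two-parameter logistic (2PL) item-response
model: a child with latent ability theta ~ N(0, 1) answers item j correctly
with probability

    P(correct | theta) = 1 / (1 + exp(-a_j * (theta - b_j)))

where a_j > 0 is the item's discrimination and b_j its difficulty on the
logit scale. Difficulties are calibrated so that each item's marginal
proportion correct matches its published value; discriminations are drawn
log-normally for heterogeneity and then scaled by a common factor until the
full-form Cronbach's alpha on a large probe sample matches a target (0.86 by
default, the published validation-set value). Concurrent measures (backwards
digit span, HTKS, receptive vocabulary, RAN inverse-efficiency) are built
from the same latent ability with declared target correlations, mapped into
their instrument ranges, and thinned completely at random to reproduce the
published pairwise sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit

from .items import ITEM_IDS, ITEM_PROPORTIONS, PRACTICE_ITEMS, item_metadata

__all__ = [
    "ItemParams",
    "CohortSpec",
    "SyntheticCohort",
    "calibrate_difficulties",
    "default_item_bank",
    "generate_responses",
    "generate_covariates",
    "tune_discriminations",
    "make_cohort",
]

# fixed sub-stream labels so each stage is independently reproducible
_STREAMS = {
    "discriminations": 11,
    "responses": 12,
    "covariates": 13,
    "probe": 14,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stage]]))


@dataclass
class ItemParams:
    """2PL parameters and metadata for one item."""

    item_id: str
    set_label: str
    domain_label: str
    difficulty: float
    discrimination: float
    target_p: float
    is_practice: bool = False

    def __post_init__(self) -> None:
        if self.discrimination <= 0:
            raise ValueError(
                f"{self.item_id}: discrimination must be > 0, "
                f"got {self.discrimination}"
            )
        if not 0.0 < self.target_p < 1.0:
            raise ValueError(
                f"{self.item_id}: target_p must be inside (0, 1), "
                f"got {self.target_p}"
            )


#: Covariate targets: correlation with latent ability, instrument range
#: (min, max, integer-valued), and MCAR missing rate. Rates reproduce the
#: published pairwise ns (101/92/75/72) on a 101-person validation split.
DEFAULT_COVARIATE_TARGETS = {
    "bds": 0.44, "htks": 0.41, "crvt": 0.50, "ran_ies": -0.14,
}
DEFAULT_COVARIATE_RANGES = {
    "bds": (0.0, 14.0, True),
    "htks": (0.0, 40.0, True),
    "crvt": (0.0, 65.0, True),
    "ran_ies": (10.0, math.inf, False),
}
DEFAULT_MISSING_RATES = {"bds": 0.0, "htks": 0.09, "crvt": 0.26, "ran_ies": 0.29}


@dataclass
class CohortSpec:
    """Study-level description of a synthetic cohort."""

    n_persons: int = 336
    covariate_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_TARGETS)
    )
    covariate_ranges: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES)
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    target_alpha: float = 0.86
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rho in self.covariate_targets.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"{name}: target correlation must be in (-1, 1)")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name}: missing rate must be in [0, 1)")
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")


@dataclass
class SyntheticCohort:
    """A generated cohort: responses, covariates and the latent truth."""

    responses: pd.DataFrame
    covariates: pd.DataFrame
    true_ability: np.ndarray
    item_params: list[ItemParams]
    spec: CohortSpec


_QUAD_NODES, _QUAD_WEIGHTS = hermegauss(61)
_QUAD_WEIGHTS = _QUAD_WEIGHTS / _QUAD_WEIGHTS.sum()  # N(0,1) probabilities


def marginal_proportion(difficulty: float, discrimination: float) -> float:
    """Marginal P(correct) = E_theta[logistic(a(theta - b))], theta ~ N(0,1).

    Evaluated by 61-node Gauss-Hermite quadrature.
    """
    return float(
        _QUAD_WEIGHTS @ expit(discrimination * (_QUAD_NODES - difficulty))
    )


def calibrate_difficulties(target_ps, discrimination) -> np.ndarray:
    """Difficulties b_j solving E_theta[logistic(a_j(theta - b_j))] = p_j.

    The marginal proportion is strictly decreasing in b, so each root is
    found by bracketed root-finding; larger target p gives smaller b.

    Parameters
    ----------
    target_ps
        Marginal proportions, each strictly inside (0, 1).
    discrimination
        Scalar or per-item vector of positive discriminations.
    """
    ps = np.atleast_1d(np.asarray(target_ps, dtype=float))
    a = np.broadcast_to(
        np.atleast_1d(np.asarray(discrimination, dtype=float)), ps.shape
    )
    if np.any(a <= 0):
        raise ValueError("discrimination must be strictly positive")
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        raise ValueError("target proportions must lie strictly inside (0, 1)")
    out = np.empty_like(ps)
    for j, (p, aj) in enumerate(zip(ps, a)):
        # bracket widens as 1/a: low discriminations flatten the marginal
        span = 15.0 + 20.0 / aj
        out[j] = brentq(
            lambda b: marginal_proportion(b, aj) - p, -span, span, xtol=1e-10
        )
    return out


def default_item_bank(
    seed: int = 0, discrimination_sd: float = 0.25
) -> list[ItemParams]:
    """The 36-item bank with published target proportions.

    Discriminations are log-normal(0, ``discrimination_sd``) draws — item
    heterogeneity gives the selection procedure real signal to discriminate
    among items — and difficulties are calibrated to the published marginal
    proportions. Practice items A1/A2 are generated for format fidelity but
    flagged for exclusion from scoring.
    """
    rng = _rng(seed, "discriminations")
    a = np.exp(rng.normal(0.0, discrimination_sd, size=len(ITEM_IDS)))
    ps = np.array([ITEM_PROPORTIONS[i] for i in ITEM_IDS])
    bs = calibrate_difficulties(ps, a)
    meta = item_metadata()
    return [
        ItemParams(
            item_id=item,
            set_label=meta.loc[item, "set_label"],
            domain_label=meta.loc[item, "domain_label"],
            difficulty=float(bs[j]),
            discrimination=float(a[j]),
            target_p=float(ps[j]),
            is_practice=item in PRACTICE_ITEMS,
        )
        for j, item in enumerate(ITEM_IDS)
    ]


def generate_responses(
    item_params: list[ItemParams], n: int, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw an n-person binary response matrix and its latent abilities.

    theta_i ~ N(0,1); responses independent Bernoulli given theta.
    Deterministic for a given seed.
    """
    if n < 2:
        raise ValueError("need n >= 2 persons")
    rng = _rng(seed, "responses")
    theta = rng.standard_normal(n)
    a = np.array([ip.discrimination for ip in item_params])
    b = np.array([ip.difficulty for ip in item_params])
    probs = expit(a[None, :] * (theta[:, None] - b[None, :]))
    resp = (rng.random(probs.shape) < probs).astype(np.int8)
    df = pd.DataFrame(
        resp,
        columns=[ip.item_id for ip in item_params],
        index=pd.RangeIndex(n, name="person_id"),
    )
    return df, theta


def generate_covariates(true_ability: np.ndarray, spec: CohortSpec) -> pd.DataFrame:
    """Concurrent measures correlated with ability, with MCAR missingness.

    Each covariate starts as rho * theta + sqrt(1 - rho^2) * noise. Bounded
    integer instruments (digit span, HTKS, vocabulary) are mapped affinely
    to their score range (centre at the midpoint, sd = range / 6), rounded
    and clipped. The RAN inverse-efficiency score — time divided by
    proportion correct, so positive with a long right tail — gets a shifted
    log-normal shape. Missing entries are NaN.
    """
    theta = np.asarray(true_ability, dtype=float)
    rng = _rng(spec.seed, "covariates")
    n = theta.shape[0]
    cols: dict[str, np.ndarray] = {}
    for name, rho in spec.covariate_targets.items():
        z = rho * theta + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        lo, hi, integer = spec.covariate_ranges[name]
        if math.isinf(hi):
            # positive, right-skewed: shifted log-normal above the floor
            values = lo + np.exp(math.log(30.0) + 0.35 * z)
        else:
            mid, scale = (lo + hi) / 2.0, (hi - lo) / 6.0
            values = np.clip(mid + scale * z, lo, hi)
            if integer:
                values = np.round(values)
        rate = spec.missing_rates.get(name, 0.0)
        if rate > 0.0:
            values = np.where(rng.random(n) < rate, np.nan, values)
        cols[name] = values
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="person_id"))


def tune_discriminations(
    item_params: list[ItemParams],
    target_alpha: float = 0.86,
    n_probe: int = 20_000,
    seed: int = 0,
    tolerance: float = 0.02,
    factor_bounds: tuple[float, float] = (0.05, 8.0),
    max_iter: int = 40,
) -> list[ItemParams]:
    """Scale all discriminations by a common factor to hit a target alpha.

    Cronbach's alpha of the 34 scored items, measured on a fixed-seed probe
    sample of ``n_probe`` persons, increases monotonically with the common
    factor; bisection finds the factor whose probe alpha is within
    ``tolerance`` of ``target_alpha``. Difficulties are re-calibrated at
    every factor so the marginal proportions stay on target.
    """
    if not 0.0 < target_alpha < 1.0:
        raise ValueError("target_alpha must be inside (0, 1)")
    from .validation import cronbach_alpha  # local import to avoid a cycle

    base_a = np.array([ip.discrimination for ip in item_params])
    ps = np.array([ip.target_p for ip in item_params])
    scored = [ip.item_id for ip in item_params if not ip.is_practice]
    probe_seed = int(_rng(seed, "probe").integers(2**31 - 1))

    def rescaled(factor: float) -> list[ItemParams]:
        a = base_a * factor
        b = calibrate_difficulties(ps, a)
        return [
            ItemParams(
                item_id=ip.item_id, set_label=ip.set_label,
                domain_label=ip.domain_label, difficulty=float(b[j]),
                discrimination=float(a[j]), target_p=ip.target_p,
                is_practice=ip.is_practice,
            )
            for j, ip in enumerate(item_params)
        ]

    def probe_alpha(factor: float) -> float:
        resp, _ = generate_responses(rescaled(factor), n_probe, probe_seed)
        return cronbach_alpha(resp, scored)

    lo, hi = factor_bounds
    a_lo, a_hi = probe_alpha(lo), probe_alpha(hi)
    if not a_lo <= target_alpha <= a_hi:
        raise RuntimeError(
            f"target alpha {target_alpha} unattainable within factor bounds "
            f"{factor_bounds}: probe alpha range [{a_lo:.3f}, {a_hi:.3f}]"
        )
    factor, alpha = hi, a_hi
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric bisection on a scale factor
        alpha = probe_alpha(mid)
        factor = mid
        if abs(alpha - target_alpha) <= tolerance:
            break
        if alpha < target_alpha:
            lo = mid
        else:
            hi = mid
    else:
        raise RuntimeError(
            f"alpha tuning did not converge: last factor {factor:.4f}, "
            f"probe alpha {alpha:.4f}, target {target_alpha}"
        )
    return rescaled(factor)


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Full generation pipeline: bank -> alpha tuning -> responses -> covariates."""
    bank = default_item_bank(seed=spec.seed)
    bank = tune_discriminations(
        bank, target_alpha=spec.target_alpha, seed=spec.seed
    )
    responses, theta = generate_responses(bank, spec.n_persons, spec.seed)
    covariates = generate_covariates(theta, spec)
    return SyntheticCohort(
        responses=responses,
        covariates=covariates,
        true_ability=theta,
        item_params=bank,
        spec=spec,
    )
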