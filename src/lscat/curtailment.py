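"""Stochastic curtailment (SC): fixed-order early stopping on the cumulative score.

SC administers items in a fixed order and stops as soon as the cumulative
score makes the final classification sufficiently certain.  Calibration
fits, for each step k, a logistic regression of the true status (complete
sum >= cutoff) on the cumulative score after k items, and converts the
fitted curve into integer stop thresholds: the smallest cumulative score
whose fitted eligibility probability reaches gamma (stop 'eligible') and
the largest whose probability falls to 1 - gamma (stop 'not eligible').
Deterministic curtailment bounds always dominate: a cumulative score
already at the cutoff stops 'eligible' regardless of gamma, and one that
cannot reach the cutoff even with maximal remaining scores stops 'not
eligible'.  The result is a per-step look-up table; administration is a
plain walk down it, with no dynamic item selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .engine import AdministrationRecord, EfficiencySummary
from .io import ResponseMatrix

__all__ = [
    "SCStepRule",
    "SCLookupTable",
    "SCStepFits",
    "fit_sc",
    "fit_sc_steps",
    "sc_table_from_steps",
    "sc_item_counts",
    "administer_sc",
    "administer_sc_all",
]


@dataclass(frozen=True)
class SCStepRule:
    """Stop thresholds after step k (1-based), on the cumulative score s_k.

    ``stop_high``: minimal s_k triggering 'eligible' (always defined —
    at worst the deterministic bound s_k >= cutoff).  ``stop_low``:
    maximal s_k triggering 'not eligible', or None when no cumulative
    score is low enough to stop at this step.  ``coef`` holds the fitted
    logistic (intercept, slope) or None when the fit fell back to the
    deterministic bounds.
    """

    step: int
    stop_high: int
    stop_low: int | None
    coef: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.stop_low is not None and not (self.stop_low < self.stop_high):
            raise ValueError("stop_low must be strictly below stop_high")


@dataclass(frozen=True)
class SCLookupTable:
    item_order: tuple[int, ...]
    steps: tuple[SCStepRule, ...]  # steps 1..J-1; step J decides by sum vs cutoff
    cutoff: int
    gamma: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "step": r.step,
                    "item": self.item_order[r.step - 1],
                    "stop_eligible_at": r.stop_high,
                    "stop_not_eligible_at": r.stop_low,
                    "logistic": r.coef is not None,
                }
                for r in self.steps
            ]
        )


def _fit_step_logistic(s_k: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Status-on-cumulative-score logistic fit; None on separation/degeneracy."""
    if y.min() == y.max() or s_k.min() == s_k.max():
        return None
    X = sm.add_constant(s_k.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
        b0, b1 = float(res.params[0]), float(res.params[1])
    except Exception:
        return None
    if not (np.isfinite(b0) and np.isfinite(b1)) or b1 <= 0 or abs(b1) > 50:
        return None  # separation or a non-increasing curve: use deterministic bounds
    return b0, b1


def fit_sc_steps(
    calibration: ResponseMatrix,
    cutoff: int,
    item_order: Sequence[int] | None = None,
) -> "SCStepFits":
    """Fit the per-step status-on-cumulative-score logistic regressions once.

    The regressions do not depend on gamma, so a whole gamma grid (as in
    efficiency matching) can be thresholded from one set of fits via
    :func:`sc_table_from_steps`.
    """
    J = calibration.n_items
    order = tuple(int(j) for j in (item_order if item_order is not None else range(J)))
    if sorted(order) != list(range(J)):
        raise ValueError("item_order must be a permutation of all items")
    cutoff = int(cutoff)
    if not (1 <= cutoff <= calibration.max_sum):
        raise ValueError("cutoff outside achievable sum range")
    y = calibration.status(cutoff).astype(int)
    cum = np.cumsum(calibration.scores[:, list(order)], axis=1)
    max_step_sum = tuple(
        int(v) for v in np.cumsum([calibration.categories[j] - 1 for j in order])
    )
    coefs = []
    for k in range(1, J):
        coef = _fit_step_logistic(cum[:, k - 1], y)
        if coef is None:
            warnings.warn(
                f"step {k}: logistic fit degenerate/separated; "
                "using deterministic curtailment bounds",
                stacklevel=2,
            )
        coefs.append(coef)
    return SCStepFits(order, tuple(coefs), max_step_sum, cutoff)


@dataclass(frozen=True)
class SCStepFits:
    """Gamma-independent part of SC calibration: fitted per-step logistics."""

    item_order: tuple[int, ...]
    coefs: tuple[tuple[float, float] | None, ...]
    max_step_sum: tuple[int, ...]
    cutoff: int


def sc_table_from_steps(fits: SCStepFits, gamma: float) -> SCLookupTable:
    """Convert fitted step logistics into stop thresholds at a given gamma."""
    if not (0.5 < gamma < 1.0):
        raise ValueError(f"gamma must lie in (0.5, 1), got {gamma}")
    cutoff = fits.cutoff
    steps = []
    for k, coef in enumerate(fits.coefs, start=1):
        max_rem = fits.max_step_sum[-1] - fits.max_step_sum[k - 1]
        det_low = cutoff - max_rem - 1          # cannot reach cutoff even maxing out
        stop_high = cutoff                       # s_k >= cutoff is certain-eligible
        stop_low = det_low if det_low >= 0 else None
        if coef is not None:
            b0, b1 = coef
            grid = np.arange(0, fits.max_step_sum[k - 1] + 1)
            p = 1.0 / (1.0 + np.exp(-(b0 + b1 * grid)))
            hi = grid[p >= gamma]
            if hi.size:
                stop_high = min(stop_high, int(hi[0]))
            lo = grid[p <= 1.0 - gamma]
            if lo.size:
                cand = int(lo[-1])
                stop_low = cand if stop_low is None else max(stop_low, cand)
        if stop_low is not None and stop_low >= stop_high:
            stop_low = stop_high - 1 if stop_high >= 1 else None
        steps.append(SCStepRule(k, stop_high, stop_low, coef))
    return SCLookupTable(fits.item_order, tuple(steps), cutoff, float(gamma))


def fit_sc(
    calibration: ResponseMatrix,
    cutoff: int,
    gamma: float = 0.95,
    item_order: Sequence[int] | None = None,
) -> SCLookupTable:
    """Calibrate the SC look-up table on complete data.

    One logistic regression per step k = 1..J-1 with the cumulative score
    as sole predictor; a step whose regression separates (or degenerates)
    falls back to the deterministic curtailment bounds with a warning.
    As gamma -> 1 the logistic thresholds become unreachable and the
    table reduces to purely deterministic curtailment.
    """
    return sc_table_from_steps(fit_sc_steps(calibration, cutoff, item_order), gamma)


def sc_item_counts(table: SCLookupTable, data: ResponseMatrix) -> np.ndarray:
    """Vectorized number of administered items per respondent (no records)."""
    J = len(table.item_order)
    cum = np.cumsum(data.scores[:, list(table.item_order)], axis=1)
    stopped = np.zeros((data.n_respondents, J - 1), dtype=bool)
    for k, rule in enumerate(table.steps, start=1):
        s = cum[:, k - 1]
        hit = s >= rule.stop_high
        if rule.stop_low is not None:
            hit |= s <= rule.stop_low
        stopped[:, k - 1] = hit
    any_stop = stopped.any(axis=1)
    first = np.argmax(stopped, axis=1) + 1
    return np.where(any_stop, first, J)


def administer_sc(
    table: SCLookupTable, respondent_row: np.ndarray, respondent: int = 0
) -> AdministrationRecord:
    """Walk the fixed item order accumulating the score until a rule fires."""
    row = np.asarray(respondent_row, dtype=np.int64).ravel()
    J = len(table.item_order)
    s = 0
    items: list[int] = []
    scores: list[int] = []
    for k, j in enumerate(table.item_order, start=1):
        x = int(row[j])
        items.append(j)
        scores.append(x)
        s += x
        if k < J:
            rule = table.steps[k - 1]
            if s >= rule.stop_high:
                return AdministrationRecord(
                    respondent, tuple(items), tuple(scores),
                    _rule_prob(rule, s, True), True, True,
                )
            if rule.stop_low is not None and s <= rule.stop_low:
                return AdministrationRecord(
                    respondent, tuple(items), tuple(scores),
                    _rule_prob(rule, s, False), False, True,
                )
    status = s >= table.cutoff
    return AdministrationRecord(
        respondent, tuple(items), tuple(scores), 1.0 if status else 0.0, status, False
    )


def _rule_prob(rule: SCStepRule, s: int, eligible: bool) -> float:
    """Fitted eligibility probability at the stop, exact 0/1 on deterministic stops."""
    if rule.coef is not None:
        b0, b1 = rule.coef
        return float(1.0 / (1.0 + np.exp(-(b0 + b1 * s))))
    return 1.0 if eligible else 0.0


def administer_sc_all(
    table: SCLookupTable, data: ResponseMatrix
) -> tuple[list[AdministrationRecord], EfficiencySummary]:
    records = [administer_sc(table, row, i) for i, row in enumerate(data.scores)]
    return records, EfficiencySummary.from_records(records)
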