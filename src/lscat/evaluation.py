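"""Post-hoc simulation harness: efficiency matching, validity metrics, reports.

The comparative experiment replays each adaptive method against complete
observed responses (post-hoc simulation), treating the observed sum score
as truth.  The design crosses screening cutoffs with stopping criteria
and methods.  Within each (cutoff, c) cell, LSCAT's average number of
administered items on the *calibration* sample sets the efficiency
target; the stopping knobs of the benchmarks (gamma for stochastic
curtailment, the pruning parameter for the decision tree) are then tuned
a priori — on calibration data only, never on validation data — to match
that average as closely as their grids allow.  All methods are finally
administered on the validation sample and compared on Type I/II error
rate, accuracy and Cohen's kappa, alongside a base-rate benchmark that
assigns status at random with the calibration prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .curtailment import (
    SCLookupTable,
    administer_sc_all,
    fit_sc,
    fit_sc_steps,
    sc_item_counts,
    sc_table_from_steps,
)
from .dtcat import DecisionTree, administer_dtcat_all, dtcat_item_counts, fit_tree
from .engine import AdministrationRecord, EfficiencySummary, administer_all
from .io import ResponseMatrix, ScreeningConfig, split_calibration_validation
from .ulcm import ULCMParams, fit_em, select_n_classes

__all__ = [
    "ValidityReport",
    "compute_metrics",
    "base_rate_benchmark",
    "match_efficiency",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "kappa_label",
]

_KAPPA_BANDS = [
    (0.20, "none to slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


def kappa_label(kappa: float) -> str:
    """Rule-of-thumb agreement band for a kappa value (reporting only)."""
    if not np.isfinite(kappa):
        return "undefined"
    for hi, lab in _KAPPA_BANDS:
        if kappa <= hi:
            return lab
    return "almost perfect"


@dataclass(frozen=True)
class ValidityReport:
    """Confusion counts and predictive-validity metrics for one method/cell.

    Undefined ratios (no actual positives or negatives, or chance
    agreement of 1) are NaN with the offending metric named in
    ``undefined`` — never silently zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    type_i_error: float
    type_ii_error: float
    accuracy: float
    kappa: float
    undefined: tuple[str, ...] = ()
    efficiency: EfficiencySummary | None = None
    method: str = ""
    cutoff: int | None = None
    stopping_criterion: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(
    true_status: np.ndarray, predicted_status: np.ndarray
) -> ValidityReport:
    """Confusion counts and Type I/II error, accuracy and Cohen's kappa.

    Type I error = FP / (TN + FP): false alarms among actual negatives.
    Type II error = FN / (TP + FN): misses among actual positives.
    Accuracy = (TP + TN) / N.  Kappa = (p_o - p_e) / (1 - p_e) with the
    chance agreement p_e from the marginal products.
    """
    t = np.asarray(true_status).astype(bool).ravel()
    p = np.asarray(predicted_status).astype(bool).ravel()
    if t.size != p.size:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    if t.size == 0:
        raise ValueError("need at least one respondent")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    n = t.size
    undefined: list[str] = []

    if tn + fp > 0:
        type_i = fp / (tn + fp)
    else:
        type_i = math.nan
        undefined.append("type_i_error")
    if tp + fn > 0:
        type_ii = fn / (tp + fn)
    else:
        type_ii = math.nan
        undefined.append("type_ii_error")
    accuracy = (tp + tn) / n
    p_o = accuracy
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    if p_e < 1.0:
        kappa = (p_o - p_e) / (1.0 - p_e)
    else:
        kappa = math.nan
        undefined.append("kappa")
    return ValidityReport(tp, fp, tn, fn, type_i, type_ii, accuracy, kappa,
                          tuple(undefined))


def base_rate_benchmark(
    base_rate: float, true_status: np.ndarray, seed: int = 0
) -> ValidityReport:
    """Lower benchmark: assign 'eligible' at random with the calibration prevalence."""
    if not (0.0 <= base_rate <= 1.0):
        raise ValueError("base rate must lie in [0, 1]")
    t = np.asarray(true_status).astype(bool).ravel()
    rng = np.random.default_rng(seed)
    pred = rng.random(t.size) < base_rate
    rep = compute_metrics(t, pred)
    return replace(rep, method="base rate")


def _avg_items(records: Sequence[AdministrationRecord]) -> float:
    return float(np.mean([r.n_items for r in records]))


def match_efficiency(
    target_avg_items: float,
    engine: str,
    calibration: ResponseMatrix,
    cutoff: int,
    grid: Sequence[float],
    item_order: Sequence[int] | None = None,
    min_leaf: int = 50,
) -> tuple[SCLookupTable | DecisionTree, float, float, pd.DataFrame]:
    """Tune a benchmark's stopping knob to match a target average item count.

    ``engine`` is 'SC' (grid of gamma values) or 'DTCAT' (grid of pruning
    parameters).  Each grid point is calibrated and administered on the
    calibration sample; the point whose average administered items is
    closest to the target wins, ties going to the cheaper (fewer-items)
    point.  Returns (tuned engine, achieved average, gap, tuning trace);
    the gap is reported, never hidden — exact equality is generally
    unattainable on discrete data.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("tuning grid must be non-empty")
    kind = engine.upper()
    if kind == "SC":
        step_fits = fit_sc_steps(calibration, cutoff, item_order=item_order)
    elif kind != "DTCAT":
        raise ValueError(f"unknown engine {engine!r}")
    rows = []
    fitted = []
    for g in grid:
        if kind == "SC":
            eng = sc_table_from_steps(step_fits, float(g))
            avg = float(sc_item_counts(eng, calibration).mean())
        else:
            eng = fit_tree(calibration, cutoff, complexity=float(g), min_leaf=min_leaf)
            avg = float(dtcat_item_counts(eng, calibration).mean())
        fitted.append(eng)
        rows.append({"knob": float(g), "avg_items": avg,
                     "gap": abs(avg - target_avg_items)})
    trace = pd.DataFrame(rows)
    best_gap = trace["gap"].min()
    candidates = trace.index[trace["gap"] <= best_gap + 1e-12]
    # tie rule: fewer items wins
    best_idx = int(min(candidates, key=lambda i: (trace.loc[i, "avg_items"], i)))
    achieved = float(trace.loc[best_idx, "avg_items"])
    return fitted[best_idx], achieved, achieved - target_avg_items, trace


@dataclass(frozen=True)
class ExperimentConfig:
    """Full factorial post-hoc simulation: cutoffs x stopping criteria x methods."""

    cutoffs: tuple[int, ...] = (5, 10)
    criteria: tuple[float, ...] = (0.95, 0.99)
    methods: tuple[str, ...] = ("LSCAT", "SC", "DTCAT")
    split_fraction: float = 0.5
    seed: int = 0
    stratified: bool = False
    n_classes: int | None = None  # None: select by BIC up to max_classes
    max_classes: int = 6
    n_starts: int = 10
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    # gamma grid densifies toward 1: high-cutoff cells need very
    # conservative stopping to match LSCAT's average item count
    gamma_grid: tuple[float, ...] = tuple(np.round(np.arange(0.55, 0.99, 0.01), 3)) + (
        0.99, 0.993, 0.995, 0.997, 0.998, 0.999, 0.9995, 0.9998, 0.9999,
        0.99995, 0.99999,
    )
    complexity_grid: tuple[float, ...] = (0.0,) + tuple(
        float(a) for a in np.geomspace(1e-5, 0.2, 40)
    )
    min_leaf: int = 50
    item_order: tuple[int, ...] | None = None


@dataclass
class ExperimentResult:
    engine_params: ULCMParams
    bic_table: pd.DataFrame | None
    efficiency_table: pd.DataFrame
    validity_table: pd.DataFrame
    traces: pd.DataFrame
    fig_data: pd.DataFrame
    tuning_log: list[dict] = field(default_factory=list)


def _stratified_split(
    data: ResponseMatrix, cutoff: int, fraction: float, seed: int
) -> tuple[ResponseMatrix, ResponseMatrix]:
    status = data.status(cutoff)
    rng = np.random.default_rng(seed)
    cal_rows = []
    for val in (False, True):
        idx = np.nonzero(status == val)[0]
        k = int(np.ceil(fraction * idx.size))
        cal_rows.append(rng.permutation(idx)[:k])
    cal = np.sort(np.concatenate(cal_rows))
    val_rows = np.setdiff1d(np.arange(data.n_respondents), cal)
    return data.subset(cal), data.subset(val_rows)


def _records_frame(
    records: Sequence[AdministrationRecord], method: str, cutoff: int, crit: float,
    true_status: np.ndarray, full_sums: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": method,
            "cutoff": cutoff,
            "stopping_criterion": crit,
            "respondent": [r.respondent for r in records],
            "n_items": [r.n_items for r in records],
            "item_sequence": ["|".join(str(j + 1) for j in r.item_sequence)
                              for r in records],
            "final_probability": [r.final_probability for r in records],
            "predicted_status": [r.predicted_status for r in records],
            "true_status": true_status.astype(bool),
            "full_sum": full_sums,
            "stopped_early": [r.stopped_early for r in records],
        }
    )


def run_experiment(data: ResponseMatrix, config: ExperimentConfig) -> ExperimentResult:
    """Run the full cross-factorial post-hoc simulation on one dataset.

    Steps: split into calibration/validation; fit the latent class engine
    on calibration (BIC-selected K unless fixed); per (cutoff, criterion)
    cell, measure LSCAT's calibration-sample efficiency, tune SC/DTCAT to
    match it, administer every method on validation; emit an efficiency
    table, a validity table (with base-rate rows per cutoff), full
    per-respondent traces, and misclassification-by-sum-score data.

    A failed cell is recorded in the tables with an ``error`` column and
    the run continues.
    """
    if config.stratified:
        cal, val = _stratified_split(
            data, config.cutoffs[0], config.split_fraction, config.seed
        )
    else:
        cal, val = split_calibration_validation(data, config.split_fraction, config.seed)

    if config.n_classes is not None:
        engine_params = fit_em(cal, config.n_classes, n_starts=config.n_starts,
                               tol=config.em_tol, max_iter=config.em_max_iter,
                               seed=config.seed)
        bic_table = None
    else:
        engine_params, bic_table = select_n_classes(
            cal, config.max_classes, n_starts=config.n_starts, tol=config.em_tol,
            max_iter=config.em_max_iter, seed=config.seed,
        )

    val_sums = val.sum_scores()
    eff_rows, val_rows, trace_frames, tuning_log = [], [], [], []

    for cutoff in config.cutoffs:
        true_val = val.status(cutoff)
        base_rate = float(cal.status(cutoff).mean())
        rep = base_rate_benchmark(base_rate, true_val, seed=config.seed + cutoff)
        val_rows.append(_validity_row(rep, "base rate", cutoff, None))

        for crit in config.criteria:
            scfg = ScreeningConfig(cutoff, crit, seed=config.seed)
            # a priori efficiency target: LSCAT's average on calibration
            cal_records, cal_eff = administer_all(engine_params, cal, scfg)
            target = cal_eff.mean

            for method in config.methods:
                try:
                    if method == "LSCAT":
                        records, eff = administer_all(engine_params, val, scfg)
                        knob = crit
                    elif method == "SC":
                        eng, achieved, gap, _ = match_efficiency(
                            target, "SC", cal, cutoff, config.gamma_grid,
                            item_order=config.item_order,
                        )
                        records, eff = administer_sc_all(eng, val)
                        knob = eng.gamma
                        tuning_log.append(
                            {"cutoff": cutoff, "criterion": crit, "method": "SC",
                             "knob": knob, "target_avg_items": target,
                             "achieved_calibration_avg": achieved, "gap": gap}
                        )
                    elif method == "DTCAT":
                        eng, achieved, gap, _ = match_efficiency(
                            target, "DTCAT", cal, cutoff, config.complexity_grid,
                            min_leaf=config.min_leaf,
                        )
                        records, eff = administer_dtcat_all(eng, val)
                        knob = eng.complexity
                        tuning_log.append(
                            {"cutoff": cutoff, "criterion": crit, "method": "DTCAT",
                             "knob": knob, "target_avg_items": target,
                             "achieved_calibration_avg": achieved, "gap": gap}
                        )
                    else:
                        raise ValueError(f"unknown method {method!r}")
                except Exception as exc:
                    eff_rows.append({"cutoff": cutoff, "stopping_criterion": crit,
                                     "method": method, "error": str(exc)})
                    val_rows.append({"cutoff": cutoff, "stopping_criterion": crit,
                                     "method": method, "error": str(exc)})
                    continue

                pred = np.array([r.predicted_status for r in records])
                rep = replace(
                    compute_metrics(true_val, pred),
                    efficiency=eff, method=method, cutoff=cutoff,
                    stopping_criterion=crit,
                )
                eff_rows.append(
                    {"cutoff": cutoff, "stopping_criterion": crit, "method": method,
                     "mean_items": eff.mean, "sd_items": eff.sd,
                     "min_items": eff.min, "max_items": eff.max, "error": ""}
                )
                val_rows.append(_validity_row(rep, method, cutoff, crit))
                trace_frames.append(
                    _records_frame(records, method, cutoff, crit, true_val, val_sums)
                )

    traces = pd.concat(trace_frames, ignore_index=True) if trace_frames else pd.DataFrame()
    fig_data = _fig_data(traces)
    return ExperimentResult(
        engine_params, bic_table, pd.DataFrame(eff_rows), pd.DataFrame(val_rows),
        traces, fig_data, tuning_log,
    )


def _validity_row(rep: ValidityReport, method: str, cutoff: int, crit) -> dict:
    return {
        "cutoff": cutoff,
        "stopping_criterion": crit if crit is not None else "",
        "method": method,
        "tp": rep.tp, "fp": rep.fp, "tn": rep.tn, "fn": rep.fn,
        "type_i_error": rep.type_i_error,
        "type_ii_error": rep.type_ii_error,
        "accuracy": rep.accuracy,
        "kappa": rep.kappa,
        "kappa_band": kappa_label(rep.kappa),
        "error": "",
    }


def _fig_data(traces: pd.DataFrame) -> pd.DataFrame:
    """Items administered and misclassification by complete-test sum score."""
    if traces.empty:
        return pd.DataFrame()
    df = traces.copy()
    df["misclassified"] = df["predicted_status"] != df["true_status"]
    out = (
        df.groupby(["method", "cutoff", "stopping_criterion", "full_sum"])
        .agg(n=("respondent", "size"), mean_items=("n_items", "mean"),
             max_items=("n_items", "max"),
             n_misclassified=("misclassified", "sum"))
        .reset_index()
    )
    return out
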