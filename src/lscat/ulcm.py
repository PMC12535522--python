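"""Unrestricted latent class model (ULCM) for polytomous items.

The ULCM is a finite mixture over K latent classes.  Within class k the
J item scores are independent categoricals:

    P(X = x) = sum_k pi_k * prod_j rho[k][j][x_j]

It is the most flexible measurement model for categorical item data and
serves here as the engine behind latent-class adaptive screening: from a
fitted ULCM every response-pattern probability, and hence the eligibility
probability P(sum >= cutoff | responses so far), can be derived.

Estimation is by EM with multiple random starts; the number of classes is
chosen by BIC.  Class labels are arbitrary (label switching): nothing
downstream depends on class order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import ResponseMatrix

__all__ = ["ULCMParams", "log_likelihood", "fit_em", "select_n_classes", "bic"]

# floor on conditional response probabilities during M-steps; guards
# log(0) on categories unobserved within a class
RHO_FLOOR = 1e-10


@dataclass(frozen=True)
class ULCMParams:
    """Parameters of a fitted (or specified) unrestricted latent class model.

    Attributes
    ----------
    class_weights
        Mixing proportions pi, length K, summing to 1.
    conditionals
        One array per item; ``conditionals[j][k, x]`` is the probability
        of score x on item j within class k.  Rows sum to 1.
    log_likelihood_
        Log-likelihood on the data the model was fitted to (None for a
        specified model).
    ll_trace
        Per-iteration log-likelihood of the winning EM start.
    """

    class_weights: np.ndarray
    conditionals: tuple[np.ndarray, ...]
    log_likelihood_: float | None = None
    ll_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        pi = np.asarray(self.class_weights, dtype=float)
        if pi.ndim != 1 or pi.size < 1:
            raise ValueError("class_weights must be a non-empty vector")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("class weights must be non-negative and sum to 1")
        object.__setattr__(self, "class_weights", pi)
        k = pi.size
        conds = tuple(np.asarray(r, dtype=float) for r in self.conditionals)
        if not conds:
            raise ValueError("need at least one item")
        for j, r in enumerate(conds):
            if r.ndim != 2 or r.shape[0] != k or r.shape[1] < 2:
                raise ValueError(f"conditionals[{j}] must be K x m_j with m_j >= 2")
            if np.any(r < 0) or np.max(np.abs(r.sum(axis=1) - 1.0)) > 1e-8:
                raise ValueError(f"conditionals[{j}] rows must be probability vectors")
        object.__setattr__(self, "conditionals", conds)

    @property
    def n_classes(self) -> int:
        return int(self.class_weights.size)

    @property
    def n_items(self) -> int:
        return len(self.conditionals)

    @property
    def categories(self) -> tuple[int, ...]:
        return tuple(r.shape[1] for r in self.conditionals)

    @property
    def max_sum(self) -> int:
        return int(sum(m - 1 for m in self.categories))

    @property
    def n_params(self) -> int:
        """Free parameters: (K-1) weights + K * sum_j (m_j - 1) conditionals."""
        k = self.n_classes
        return (k - 1) + k * sum(m - 1 for m in self.categories)

    def check_data(self, data: ResponseMatrix) -> None:
        if data.n_items != self.n_items or tuple(data.categories) != self.categories:
            raise ValueError(
                f"model dimensioned for items {self.categories}, "
                f"data has {tuple(data.categories)}"
            )

    def pattern_log_prob(self, scores: np.ndarray) -> np.ndarray:
        """Log P(X = x_i) for each row of an n x J score matrix."""
        return logsumexp(self._class_pattern_log_prob(scores), axis=0)

    def _class_pattern_log_prob(self, scores: np.ndarray) -> np.ndarray:
        """K x n matrix of log pi_k + sum_j log rho[k][j][x_ij]."""
        scores = np.atleast_2d(np.asarray(scores))
        out = np.repeat(
            np.log(self.class_weights)[:, None], scores.shape[0], axis=1
        )
        for j, rho_j in enumerate(self.conditionals):
            with np.errstate(divide="ignore"):
                out += np.log(rho_j)[:, scores[:, j]]
        return out

    # ---- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None, **extra) -> str:
        payload = {
            "n_classes": self.n_classes,
            "class_weights": self.class_weights.tolist(),
            "conditionals": [r.tolist() for r in self.conditionals],
            "log_likelihood": self.log_likelihood_,
            "n_params": self.n_params,
            **extra,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ULCMParams":
        try:
            is_file = Path(str(source)).is_file()
        except OSError:
            is_file = False
        text = Path(str(source)).read_text() if is_file else str(source)
        d = json.loads(text)
        return cls(
            np.asarray(d["class_weights"]),
            tuple(np.asarray(r) for r in d["conditionals"]),
            d.get("log_likelihood"),
        )


def log_likelihood(params: ULCMParams, data: ResponseMatrix) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_k prod_j rho[k][j][x_ij]."""
    params.check_data(data)
    return float(params.pattern_log_prob(data.scores).sum())


def bic(ll: float, n_params: int, n: int) -> float:
    """Bayesian information criterion, -2 logL + p ln N (smaller is better)."""
    return -2.0 * ll + n_params * np.log(n)


def _random_init(
    rng: np.random.Generator, n_classes: int, categories: tuple[int, ...]
) -> tuple[np.ndarray, list[np.ndarray]]:
    pi = rng.dirichlet(np.full(n_classes, 5.0))
    conds = [rng.dirichlet(np.full(m, 2.0), size=n_classes) for m in categories]
    return pi, conds


def fit_em(
    data: ResponseMatrix,
    n_classes: int,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> ULCMParams:
    """Fit a K-class ULCM by EM; return the best of ``n_starts`` random starts.

    The log-likelihood is non-decreasing within every start (EM guarantee;
    the winning start's trace is kept on the result).  Convergence is an
    absolute log-likelihood gain below ``tol``.  K = 1 is the closed-form
    marginal model and uses a single start.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    n, n_items = data.scores.shape
    cats = tuple(data.categories)

    # collapse to unique response patterns: EM cost scales with patterns,
    # not respondents
    patterns, counts = np.unique(data.scores, axis=0, return_counts=True)
    n_pat = patterns.shape[0]
    w = counts.astype(float)

    if n_classes > n_pat:
        warnings.warn(
            f"{n_classes} classes exceed the {n_pat} distinct response patterns; "
            "the model is not identified",
            stacklevel=2,
        )

    if n_classes == 1:
        conds = []
        for j, m in enumerate(cats):
            freq = np.bincount(data.scores[:, j], minlength=m).astype(float) / n
            conds.append(np.clip(freq, RHO_FLOOR, None)[None, :])
        conds = [c / c.sum(axis=1, keepdims=True) for c in conds]
        params = ULCMParams(np.array([1.0]), tuple(conds))
        ll = log_likelihood(params, data)
        return ULCMParams(params.class_weights, params.conditionals, ll, (ll,))

    # per-item one-hot indicator matrices over unique patterns (pattern x m_j)
    onehot = [
        (patterns[:, j][:, None] == np.arange(m)[None, :]).astype(float)
        for j, m in enumerate(cats)
    ]

    rng = np.random.default_rng(seed)
    start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)
    best: tuple[float, np.ndarray, list[np.ndarray], list[float]] | None = None

    for s in start_seeds:
        pi, conds = _random_init(np.random.default_rng(int(s)), n_classes, cats)
        trace: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            # E-step in log space
            logp = np.repeat(np.log(pi)[:, None], n_pat, axis=1)
            for j in range(n_items):
                logp += np.log(conds[j])[:, patterns[:, j]]
            pat_ll = logsumexp(logp, axis=0)
            ll = float(np.dot(w, pat_ll))
            trace.append(ll)
            resp = np.exp(logp - pat_ll[None, :])  # K x n_pat responsibilities

            # M-step
            wr = resp * w[None, :]
            class_mass = wr.sum(axis=1)
            pi = class_mass / n
            for j in range(n_items):
                num = wr @ onehot[j]
                num = np.clip(num / class_mass[:, None], RHO_FLOOR, None)
                conds[j] = num / num.sum(axis=1, keepdims=True)

            if ll - prev < tol and np.isfinite(prev):
                break
            prev = ll

        if best is None or trace[-1] > best[0]:
            best = (trace[-1], pi, [c.copy() for c in conds], trace)

    ll_best, pi, conds, trace = best
    return ULCMParams(pi / pi.sum(), tuple(conds), ll_best, tuple(trace))


def select_n_classes(
    data: ResponseMatrix,
    max_classes: int = 10,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[ULCMParams, pd.DataFrame]:
    """Fit K = 1..max_classes and return the BIC-minimizing model plus a BIC table.

    A K whose fit fails is recorded in the table with NaN and skipped.
    """
    if max_classes < 1:
        raise ValueError("max_classes must be >= 1")
    rows = []
    fits: dict[int, ULCMParams] = {}
    for k in range(1, max_classes + 1):
        try:
            fit = fit_em(data, k, n_starts=n_starts, tol=tol, max_iter=max_iter,
                         seed=seed + k)
            fits[k] = fit
            rows.append(
                {
                    "n_classes": k,
                    "log_likelihood": fit.log_likelihood_,
                    "n_params": fit.n_params,
                    "bic": bic(fit.log_likelihood_, fit.n_params, data.n_respondents),
                    "error": "",
                }
            )
        except Exception as exc:  # a failed K is recorded, not fatal
            rows.append(
                {"n_classes": k, "log_likelihood": np.nan, "n_params": np.nan,
                 "bic": np.nan, "error": str(exc)}
            )
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("every candidate K failed to fit")
    k_best = int(table.loc[table["bic"].idxmin(), "n_classes"])
    return fits[k_best], table
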