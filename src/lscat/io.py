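"""Item-response matrices, screening configurations, and their file formats.

The whole package operates on *complete* polytomous item-response data:
an N x J integer matrix where respondent i scored ``scores[i, j]`` on item
j, with item j offering categories ``0 .. categories[j] - 1``.  The PHQ-9
is the canonical case: J = 9 items, four categories each (0-3), sum score
0-27.  Post-hoc simulation replays adaptive algorithms against these
observed scores, so missing data are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "ScreeningConfig",
    "read_responses",
    "write_responses",
    "split_calibration_validation",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Complete integer scores for N respondents on J polytomous items.

    Parameters
    ----------
    scores
        N x J integer array; entry (i, j) in ``0 .. categories[j] - 1``.
    categories
        Number of response categories per item (``m_j``).
    item_labels
        Column names; defaults to ``item1 .. itemJ``.
    """

    scores: np.ndarray
    categories: tuple[int, ...]
    item_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.floor(scores)):
                raise ValueError("scores must be integers")
            scores = scores.astype(np.int64)
        object.__setattr__(self, "scores", np.ascontiguousarray(scores, dtype=np.int64))
        n, j = scores.shape
        if n < 1 or j < 2:
            raise ValueError(f"need N >= 1 respondents and J >= 2 items, got N={n}, J={j}")
        cats = tuple(int(m) for m in self.categories)
        if len(cats) != j:
            raise ValueError(f"categories has length {len(cats)}, expected J={j}")
        if any(m < 2 for m in cats):
            raise ValueError("every item needs at least 2 categories")
        object.__setattr__(self, "categories", cats)
        labels = tuple(self.item_labels) or tuple(f"item{k + 1}" for k in range(j))
        if len(labels) != j:
            raise ValueError("item_labels length mismatch")
        object.__setattr__(self, "item_labels", labels)
        lo = scores.min(axis=0)
        hi = scores.max(axis=0)
        for col, (m, a, b) in enumerate(zip(cats, lo, hi)):
            if a < 0 or b > m - 1:
                raise ValueError(
                    f"item {labels[col]!r}: observed scores [{a}, {b}] outside 0..{m - 1}"
                )

    @property
    def n_respondents(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def max_sum(self) -> int:
        """Largest achievable sum score, sum_j (m_j - 1)."""
        return int(sum(m - 1 for m in self.categories))

    def sum_scores(self) -> np.ndarray:
        return self.scores.sum(axis=1)

    def status(self, cutoff: int) -> np.ndarray:
        """True eligibility per respondent: complete-data sum >= cutoff."""
        return self.sum_scores() >= int(cutoff)

    def subset(self, rows: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(self.scores[rows], self.categories, self.item_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=list(self.item_labels))


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening rule: sum-score cutoff t and stopping criterion c.

    The adaptive test halts once the probability of either status
    ('eligible': final sum >= ``cutoff``; 'not eligible': otherwise)
    reaches ``stopping_criterion``.  c must exceed 0.5, else both
    statuses could qualify simultaneously.
    """

    cutoff: int
    stopping_criterion: float = 0.95
    seed: int = 0
    max_classes: int = 10

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ValueError(f"cutoff must be >= 1, got {self.cutoff}")
        if not (0.5 < self.stopping_criterion <= 1.0):
            raise ValueError(
                f"stopping criterion must lie in (0.5, 1.0], got {self.stopping_criterion}"
            )
        if self.max_classes < 1:
            raise ValueError("max_classes must be >= 1")

    def validate_for(self, data: ResponseMatrix) -> None:
        if self.cutoff > data.max_sum:
            raise ValueError(
                f"cutoff {self.cutoff} exceeds maximum achievable sum {data.max_sum}"
            )


def read_responses(
    path: str | Path,
    categories: Sequence[int] | None = None,
    sep: str | None = None,
) -> ResponseMatrix:
    """Read a delimited item-response matrix with a header row.

    Category counts are taken from ``categories`` when given; otherwise
    each item's count is inferred as ``max observed score + 1`` (a caveat
    when a column never attains its top category).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise ValueError(
            f"missing value at row {rows[0] + 1}, column {df.columns[cols[0]]!r}: "
            "complete data are required"
        )
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(vals == np.floor(vals)):
            bad = np.nonzero(vals != np.floor(vals))[0] if np.issubdtype(vals.dtype, np.number) else [0]
            raise ValueError(f"non-integer cell at row {bad[0] + 1}, column {col!r}")
    scores = df.to_numpy(dtype=np.int64)
    if categories is None:
        categories = tuple(int(scores[:, j].max()) + 1 for j in range(scores.shape[1]))
    return ResponseMatrix(scores, tuple(int(m) for m in categories), tuple(df.columns))


def write_responses(data: ResponseMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    data.to_frame().to_csv(path, sep=sep, index=False)


def split_calibration_validation(
    data: ResponseMatrix, fraction: float = 0.5, seed: int = 0
) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Randomly partition respondents into calibration and validation sets.

    The calibration set receives ``ceil(fraction * N)`` rows drawn by a
    uniform random permutation; the remainder form the validation set.
    Reproducible for a given seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = data.n_respondents
    n_cal = int(np.ceil(fraction * n))
    if n_cal >= n:
        raise ValueError(
            f"fraction {fraction} leaves no validation respondents at N={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    cal_rows = np.sort(perm[:n_cal])
    val_rows = np.sort(perm[n_cal:])
    return data.subset(cal_rows), data.subset(val_rows)
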