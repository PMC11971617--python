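"""Score-pattern data structures, dummy coding, and table readers.

The sufficient data for the pattern-frequency likelihood are the distinct
observed score patterns with their frequencies, so everything downstream
works on :class:`PatternCounts` rather than person-level tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TestDesign",
    "PatternCounts",
    "DummyCoding",
    "parse_pattern",
    "format_pattern",
    "dummy_code",
    "decode_dummy",
    "dummy_matrices",
    "load_responses",
    "load_pattern_counts",
    "save_pattern_counts",
    "all_patterns",
]


@dataclass(frozen=True)
class TestDesign:
    """A test of ``k`` polytomous items.

    Item ``i`` has ``m[i] + 1`` ordered response categories scored
    ``0..m[i]``; category counts need not be equal across items.
    """

    m: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.m) < 1:
            raise ValueError("design needs at least one item")
        if any(int(mi) < 1 for mi in self.m):
            raise ValueError("every item needs at least two categories (m_i >= 1)")
        object.__setattr__(self, "m", tuple(int(mi) for mi in self.m))

    @property
    def k(self) -> int:
        return len(self.m)

    @property
    def n_beta(self) -> int:
        """Length of the stacked item-category parameter vector."""
        return int(sum(self.m))

    @property
    def n_patterns(self) -> int:
        """Size of the full product pattern space."""
        return int(np.prod([mi + 1 for mi in self.m]))

    def slot_index(self, item: int, s: int) -> int:
        """Position of category ``s`` of ``item`` in the stacked coding."""
        if not (0 <= item < self.k) or not (1 <= s <= self.m[item]):
            raise ValueError(f"no slot (item={item}, s={s}) in design {self.m}")
        return int(sum(self.m[:item])) + s - 1

    def validate_pattern(self, y: Sequence[int], *, where: str = "pattern") -> tuple[int, ...]:
        y = tuple(int(v) for v in y)
        if len(y) != self.k:
            raise ValueError(f"{where}: expected {self.k} item scores, got {len(y)}")
        for i, (yi, mi) in enumerate(zip(y, self.m)):
            if not 0 <= yi <= mi:
                raise ValueError(
                    f"{where}: score {yi} out of range 0..{mi} for item {i + 1}"
                )
        return y


def parse_pattern(text: str) -> tuple[int, ...]:
    """Parse a pattern string like ``"(0,1,0,2,0)"`` into a tuple of scores."""
    body = text.strip().strip("()")
    if not body:
        raise ValueError(f"empty pattern string: {text!r}")
    try:
        return tuple(int(tok) for tok in body.split(","))
    except ValueError as exc:
        raise ValueError(f"malformed pattern string: {text!r}") from exc


def format_pattern(y: Sequence[int]) -> str:
    return "(" + ",".join(str(int(v)) for v in y) + ")"


@dataclass(frozen=True)
class DummyCoding:
    """Dummy scores of a pattern relative to a reference pattern.

    ``x_tilde`` stacks, item by item, the indicator of each non-zero
    category minus the same indicator for the reference pattern, so its
    entries lie in {-1, 0, 1} with at most one +1 and one -1 per item.
    ``y_tilde`` holds the shifted scores ``y_i - y0_i``.
    """

    x_tilde: np.ndarray
    y_tilde: np.ndarray
    y0: tuple[int, ...]


def dummy_code(y: Sequence[int], y0: Sequence[int], design: TestDesign) -> DummyCoding:
    y = design.validate_pattern(y, where="y")
    y0 = design.validate_pattern(y0, where="y0")
    x = np.zeros(design.n_beta, dtype=np.int64)
    for i in range(design.k):
        if y[i] > 0:
            x[design.slot_index(i, y[i])] += 1
        if y0[i] > 0:
            x[design.slot_index(i, y0[i])] -= 1
    y_tilde = np.asarray(y, dtype=np.int64) - np.asarray(y0, dtype=np.int64)
    return DummyCoding(x_tilde=x, y_tilde=y_tilde, y0=y0)


def decode_dummy(coding: DummyCoding, design: TestDesign) -> tuple[int, ...]:
    """Invert :func:`dummy_code`: recover ``y`` from ``(x_tilde, y0)``."""
    y = list(coding.y0)
    offset = 0
    for i, mi in enumerate(design.m):
        block = coding.x_tilde[offset : offset + mi]
        pos = np.flatnonzero(block == 1)
        neg = np.flatnonzero(block == -1)
        if len(pos) > 1 or len(neg) > 1:
            raise ValueError("invalid dummy coding block")
        if len(pos) == 1:
            y[i] = int(pos[0]) + 1
        elif len(neg) == 1:
            # reference category was left; y_i must be 0 or the +1 slot
            y[i] = 0
        offset += mi
    return tuple(y)


def dummy_matrices(
    patterns: np.ndarray, y0: Sequence[int], design: TestDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked codings for an array of patterns (rows).

    Returns ``(X, Yt)`` with ``X`` of shape ``(P, sum m_i)`` holding the
    x-tilde rows and ``Yt`` of shape ``(P, k)`` the shifted scores.
    """
    patterns = np.asarray(patterns, dtype=np.int64)
    y0 = design.validate_pattern(y0, where="y0")
    P = patterns.shape[0]
    X = np.zeros((P, design.n_beta), dtype=np.float64)
    offset = 0
    for i, mi in enumerate(design.m):
        col = patterns[:, i]
        for s in range(1, mi + 1):
            X[:, offset + s - 1] = (col == s).astype(np.float64)
            if y0[i] == s:
                X[:, offset + s - 1] -= 1.0
        offset += mi
    Yt = patterns.astype(np.float64) - np.asarray(y0, dtype=np.float64)
    return X, Yt


@dataclass
class PatternCounts:
    """Distinct observed score patterns with frequencies.

    ``partition``, when present, assigns each pattern to one of two
    disjoint halves (labels 1 and 2) for the split-sample fit test.
    Patterns are kept in lexicographic order for reproducible sums.
    """

    design: TestDesign
    patterns: np.ndarray  # (P, k) int
    counts: np.ndarray  # (P,) int
    partition: np.ndarray | None = None  # (P,) int in {1, 2}
    _index: dict[tuple[int, ...], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.patterns.ndim != 2 or self.patterns.shape[1] != self.design.k:
            raise ValueError("patterns must be a (P, k) array")
        if self.counts.shape != (self.patterns.shape[0],):
            raise ValueError("counts must align with patterns")
        if np.any(self.counts <= 0):
            raise ValueError("pattern counts must be positive")
        for row in self.patterns:
            self.design.validate_pattern(row)
        order = np.lexsort(self.patterns.T[::-1])
        self.patterns = self.patterns[order]
        self.counts = self.counts[order]
        if self.partition is not None:
            self.partition = np.asarray(self.partition, dtype=np.int64)[order]
            if not set(np.unique(self.partition)) <= {1, 2}:
                raise ValueError("partition labels must be 1 or 2")
        self._index = {tuple(int(v) for v in row): i for i, row in enumerate(self.patterns)}
        if len(self._index) != len(self.patterns):
            raise ValueError("patterns must be unique")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_patterns(self) -> int:
        return len(self.counts)

    def __contains__(self, y: Sequence[int]) -> bool:
        return tuple(int(v) for v in y) in self._index

    def index_of(self, y: Sequence[int]) -> int:
        return self._index[tuple(int(v) for v in y)]

    def most_frequent(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.patterns[int(np.argmax(self.counts))])

    def pattern_strings(self) -> list[str]:
        return [format_pattern(row) for row in self.patterns]

    def subset(self, mask: np.ndarray) -> "PatternCounts":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("subset would contain no patterns")
        part = self.partition[mask] if self.partition is not None else None
        return PatternCounts(self.design, self.patterns[mask], self.counts[mask], part)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"pattern": self.pattern_strings(), "count": self.counts})
        if self.partition is not None:
            out["partition"] = self.partition
        return out


def load_responses(table, design: TestDesign) -> PatternCounts:
    """Collapse a person-by-item score table into pattern frequencies.

    ``table`` may be a DataFrame, a 2-D array, or a path to a wide CSV
    with one integer column per item. Missing values are rejected.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    if isinstance(table, pd.DataFrame):
        if table.isna().any().any():
            bad = int(np.flatnonzero(table.isna().any(axis=1).to_numpy())[0])
            raise ValueError(f"missing score in row {bad}; complete patterns required")
        arr = table.to_numpy()
    else:
        arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[1] != design.k:
        raise ValueError(f"expected {design.k} item columns, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("scores must be numeric integers")
    if np.any(arr != np.floor(arr)):
        raise ValueError("scores must be integers")
    arr = arr.astype(np.int64)
    for r, row in enumerate(arr):
        for i, (v, mi) in enumerate(zip(row, design.m)):
            if not 0 <= v <= mi:
                raise ValueError(
                    f"row {r}, item {i + 1}: score {v} out of range 0..{mi}"
                )
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    return PatternCounts(design, uniq, counts)


def load_pattern_counts(path, design: TestDesign) -> PatternCounts:
    """Read a pattern-frequency CSV with columns ``pattern,count[,partition]``."""
    df = pd.read_csv(path)
    required = {"pattern", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"pattern table needs columns {sorted(required)}")
    patterns = np.array([parse_pattern(p) for p in df["pattern"]], dtype=np.int64)
    partition = df["partition"].to_numpy() if "partition" in df.columns else None
    return PatternCounts(design, patterns, df["count"].to_numpy(), partition)


def save_pattern_counts(data: PatternCounts, path) -> None:
    data.to_frame().to_csv(path, index=False)


def all_patterns(design: TestDesign) -> np.ndarray:
    """Enumerate the full product pattern space in lexicographic order."""
    grids = np.meshgrid(*[np.arange(mi + 1) for mi in design.m], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
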