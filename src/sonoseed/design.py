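"""Construction, decoding and validation of the 16-run, four-level orthogonal design.

The study design assigns three quantitative ultrasound factors (sonication
time A, bath temperature B, output power C) to columns of a 16-run orthogonal
array; a fourth, unassigned column D ("vacancy") is carried along so that its
apparent effect estimates experimental error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "N_LEVELS",
    "Factor",
    "DesignTable",
    "ValidationReport",
    "default_factors",
    "build_l16",
    "decode",
    "validate",
]

COLUMNS: tuple[str, ...] = ("A", "B", "C", "D")
N_LEVELS = 4

#: physical column names used for decoded condition tables
PHYSICAL_NAMES = {"A": "time_min", "B": "temperature_c", "C": "power_w"}


@dataclass(frozen=True)
class Factor:
    """One design factor: a name, a unit, and its four physical level values.

    The vacancy column carries ``levels=None`` — it has no physical meaning.
    """

    name: str
    unit: str
    levels: tuple[float, ...] | None

    def __post_init__(self) -> None:
        if self.levels is not None:
            if len(self.levels) != N_LEVELS:
                raise ValueError(
                    f"factor {self.name!r} must have exactly {N_LEVELS} levels, "
                    f"got {len(self.levels)}"
                )
            if not all(a < b for a, b in zip(self.levels, self.levels[1:])):
                raise ValueError(f"factor {self.name!r} levels must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        """(lowest, highest) physical level — the experimental range."""
        if self.levels is None:
            raise ValueError(f"factor {self.name!r} has no physical levels")
        return (self.levels[0], self.levels[-1])


def default_factors() -> list[Factor]:
    """The study's factor/level assignment (three active factors + vacancy)."""
    return [
        Factor("A", "min", (5.0, 15.0, 25.0, 35.0)),
        Factor("B", "°C", (25.0, 35.0, 45.0, 55.0)),
        Factor("C", "W", (200.0, 300.0, 400.0, 500.0)),
        Factor("D", "", None),
    ]


# The 16x4 level-index assignment used by the study (columns A, B, C, D).
_L16 = np.array(
    [
        [1, 1, 4, 3],
        [2, 1, 1, 1],
        [3, 1, 3, 4],
        [4, 1, 2, 2],
        [1, 2, 3, 2],
        [2, 2, 2, 4],
        [3, 2, 4, 1],
        [4, 2, 1, 3],
        [1, 3, 1, 4],
        [2, 3, 4, 2],
        [3, 3, 2, 3],
        [4, 3, 3, 1],
        [1, 4, 2, 1],
        [2, 4, 3, 3],
        [3, 4, 1, 2],
        [4, 4, 4, 4],
    ],
    dtype=int,
)


@dataclass
class DesignTable:
    """A treatments-by-columns table of level indices (1-based)."""

    levels: np.ndarray
    columns: tuple[str, ...] = COLUMNS
    treatments: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.ndim != 2 or self.levels.shape[1] != len(self.columns):
            raise ValueError(
                f"levels must be 2-D with {len(self.columns)} columns, got shape "
                f"{self.levels.shape}"
            )
        if self.treatments is None:
            self.treatments = np.arange(1, len(self.levels) + 1)
        else:
            self.treatments = np.asarray(self.treatments, dtype=int)
            if len(self.treatments) != len(self.levels):
                raise ValueError("treatments and levels length mismatch")

    @property
    def n_treatments(self) -> int:
        return len(self.levels)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(f"no design column named {name!r}") from None
        return self.levels[:, j]

    def row(self, treatment: int) -> dict[str, int]:
        idx = np.flatnonzero(self.treatments == treatment)
        if len(idx) != 1:
            raise KeyError(f"treatment {treatment} not found (or duplicated)")
        return dict(zip(self.columns, self.levels[idx[0]]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=list(self.columns))
        df.insert(0, "treatment", self.treatments)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DesignTable":
        cols = [c for c in df.columns if c != "treatment"]
        return cls(
            levels=df[cols].to_numpy(dtype=int),
            columns=tuple(cols),
            treatments=df["treatment"].to_numpy(dtype=int)
            if "treatment" in df.columns
            else None,
        )

    @classmethod
    def from_csv(cls, path) -> "DesignTable":
        return cls.from_frame(pd.read_csv(path))


def build_l16() -> DesignTable:
    """Return the canonical 16-run orthogonal array (columns A, B, C, D)."""
    return DesignTable(levels=_L16.copy())


def decode(design: DesignTable, factors: Sequence[Factor] | None = None) -> pd.DataFrame:
    """Map level indices to physical conditions (time min, temperature °C, power W).

    Only columns with physical levels are decoded; the vacancy column is
    carried through as its level index.
    """
    if factors is None:
        factors = default_factors()
    by_name = {f.name: f for f in factors}
    missing = [c for c in ("A", "B", "C") if c not in by_name or by_name[c].levels is None]
    if missing:
        raise ValueError(f"factors must cover columns A, B, C with levels; missing {missing}")

    out = pd.DataFrame({"treatment": design.treatments})
    for name in design.columns:
        idx = design.column(name)
        bad = (idx < 1) | (idx > N_LEVELS)
        if bad.any():
            t = design.treatments[bad][0]
            raise ValueError(
                f"level index {idx[bad][0]} out of range 1..{N_LEVELS} "
                f"at treatment {t}, column {name}"
            )
        fac = by_name.get(name)
        if fac is not None and fac.levels is not None:
            out[PHYSICAL_NAMES.get(name, name)] = np.asarray(fac.levels)[idx - 1]
        else:
            out[name] = idx
    return out


@dataclass(frozen=True)
class ValidationReport:
    balanced: bool
    orthogonal: bool
    offending: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.balanced and self.orthogonal


def validate(design: DesignTable) -> ValidationReport:
    """Check level balance per column and pairwise orthogonality.

    Balance: each level index appears equally often in every column.
    Orthogonality: over any two columns, every ordered level pair occurs
    equally often (exactly once for a 16-run, 4-level array).
    """
    if design.n_treatments == 0:
        raise ValueError("design has no rows")
    lv = design.levels
    n, k = lv.shape
    per_level = n // N_LEVELS

    balanced = True
    offending: list[str] = []
    for j, name in enumerate(design.columns):
        counts = np.bincount(lv[:, j], minlength=N_LEVELS + 1)[1:]
        if not np.all(counts == per_level):
            balanced = False
            offending.append(f"column {name}: level counts {counts.tolist()}")

    orthogonal = True
    expect = n // (N_LEVELS * N_LEVELS)
    for (i, a), (j, b) in combinations(enumerate(design.columns), 2):
        census: dict[tuple[int, int], int] = {p: 0 for p in product(range(1, 5), repeat=2)}
        for r in range(n):
            key = (int(lv[r, i]), int(lv[r, j]))
            if key in census:
                census[key] += 1
        bad = {p: c for p, c in census.items() if c != expect}
        if bad:
            orthogonal = False
            offending.append(f"columns {a}x{b}: non-uniform pair counts {bad}")

    return ValidationReport(balanced=balanced, orthogonal=orthogonal, offending=tuple(offending))
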