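"""Pairwise binary quadratic response surfaces and peak extraction.

For each response and each pair of quantitative factors, fit

    Y = b0 + bi*Xi + bj*Xj + bii*Xi^2 + bjj*Xj^2 + bij*Xi*Xj

by ordinary least squares on physical units (min, °C, W), defaulting to the
16 treatment means (the third factor is marginalized by averaging, which the
balanced design makes unbiased for main and own-quadratic terms).  Stationary
points come from the 2x2 gradient system and are classified by the Hessian;
in-bounds maxima are harvested per factor into a peak collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable, Factor, decode, default_factors
from .synthetic_data import ResponseDataset, response_column

__all__ = [
    "PAIRS",
    "QuadraticFit",
    "StationaryPoint",
    "PeakValue",
    "PeakCollection",
    "fit_quadratic_pair",
    "fit_all_pairs",
    "stationary_point",
    "collect_peaks",
    "surface_grid",
    "default_bounds",
]

#: the three factor pairs fitted per response
PAIRS: tuple[tuple[str, str], ...] = (("A", "B"), ("A", "C"), ("B", "C"))

_COORD = {"A": "time_min", "B": "temperature_c", "C": "power_w"}


def default_bounds(factors: Sequence[Factor] | None = None) -> dict[str, tuple[float, float]]:
    """Experimental spans per factor (level 1 .. level 4 physical values)."""
    factors = factors or default_factors()
    return {f.name: f.span for f in factors if f.levels is not None}


@dataclass
class QuadraticFit:
    response: str
    pair: tuple[str, str]
    beta: np.ndarray  # (b0, bi, bj, bii, bjj, bij)
    r2: float
    n: int
    basis: str  # "treatment-means" | "raw"

    def predict(self, xi, xj) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        xj = np.asarray(xj, dtype=float)
        b = self.beta
        return b[0] + b[1] * xi + b[2] * xj + b[3] * xi**2 + b[4] * xj**2 + b[5] * xi * xj

    @property
    def hessian(self) -> np.ndarray:
        b = self.beta
        return np.array([[2 * b[3], b[5]], [b[5], 2 * b[4]]])

    def gradient(self, xi: float, xj: float) -> np.ndarray:
        b = self.beta
        return np.array(
            [b[1] + 2 * b[3] * xi + b[5] * xj, b[2] + 2 * b[4] * xj + b[5] * xi]
        )


def _design_points(
    data,
    design: DesignTable,
    response: str,
    factors: Sequence[Factor] | None,
) -> tuple[np.ndarray, np.ndarray, str]:
    """(X physical coords per observation, y, basis)."""
    cond = decode(design, factors).set_index("treatment")
    if isinstance(data, ResponseDataset):
        col = response_column(response)
        if col not in data.frame.columns:
            raise ValueError(f"dataset lacks response {response}")
        y = data.frame[col].to_numpy(dtype=float)
        coords = cond.loc[data.frame["treatment"], [_COORD["A"], _COORD["B"], _COORD["C"]]]
        return coords.to_numpy(), y, "raw"
    if isinstance(data, pd.DataFrame) and f"{response.lower()}_mean" in data.columns:
        y = pd.Series(
            data[f"{response.lower()}_mean"].to_numpy(), index=data["treatment"].to_numpy()
        )
    else:
        y = pd.Series(np.asarray(data, dtype=float), index=design.treatments)
    y = y.loc[design.treatments]
    coords = cond.loc[design.treatments, [_COORD["A"], _COORD["B"], _COORD["C"]]]
    return coords.to_numpy(), y.to_numpy(), "treatment-means"


def fit_quadratic_pair(
    data,
    design: DesignTable,
    response: str,
    pair: tuple[str, str],
    factors: Sequence[Factor] | None = None,
) -> QuadraticFit:
    """OLS fit of the binary quadratic for one factor pair.

    ``data`` may be a length-16 vector of treatment means, a per-treatment
    mean table, or a raw :class:`ResponseDataset` (one row per observation).
    """
    if tuple(pair) not in PAIRS and tuple(pair[::-1]) not in PAIRS:
        raise ValueError(f"unknown factor pair {pair}")
    coords, y, basis = _design_points(data, design, response, factors)
    idx = {"A": 0, "B": 1, "C": 2}
    xi = coords[:, idx[pair[0]]]
    xj = coords[:, idx[pair[1]]]
    X = np.column_stack([np.ones_like(xi), xi, xj, xi**2, xj**2, xi * xj])
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        raise ValueError(
            f"rank-deficient design for pair {pair}: rank {rank} < 6 distinct basis directions"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    return QuadraticFit(
        response=response, pair=tuple(pair), beta=beta, r2=r2, n=len(y), basis=basis
    )


def fit_all_pairs(
    data,
    design: DesignTable,
    responses: Sequence[str] = ("GP", "PL", "RL"),
    factors: Sequence[Factor] | None = None,
) -> list[QuadraticFit]:
    """All response x pair fits (9 for the three responses)."""
    if isinstance(data, pd.DataFrame) and "gp_mean" in data.columns:
        streams = {r: data for r in responses}
    elif isinstance(data, ResponseDataset):
        streams = {r: data for r in responses}
    else:
        raise TypeError("data must be a per-treatment mean table or a ResponseDataset")
    return [
        fit_quadratic_pair(streams[r], design, r, pair, factors)
        for r in responses
        for pair in PAIRS
    ]


@dataclass
class StationaryPoint:
    fit: QuadraticFit
    coords: tuple[float, float] | None
    kind: str  # "maximum" | "minimum" | "saddle" | "degenerate"
    in_bounds: bool
    value: float | None

    @property
    def pair(self) -> tuple[str, str]:
        return self.fit.pair


def stationary_point(
    fit: QuadraticFit, bounds: Mapping[str, tuple[float, float]] | None = None
) -> StationaryPoint:
    """Solve the gradient system, classify via the Hessian, check bounds."""
    bounds = bounds or default_bounds()
    H = fit.hessian
    det = np.linalg.det(H)
    if abs(det) < 1e-12 * (1 + np.abs(H).max()) ** 2:
        return StationaryPoint(fit=fit, coords=None, kind="degenerate", in_bounds=False, value=None)
    x = np.linalg.solve(H, -np.array([fit.beta[1], fit.beta[2]]))
    ev = np.linalg.eigvalsh(H)
    if ev[1] < 0:
        kind = "maximum"
    elif ev[0] > 0:
        kind = "minimum"
    else:
        kind = "saddle"
    lo_i, hi_i = bounds[fit.pair[0]]
    lo_j, hi_j = bounds[fit.pair[1]]
    in_bounds = bool(lo_i <= x[0] <= hi_i and lo_j <= x[1] <= hi_j)
    return StationaryPoint(
        fit=fit,
        coords=(float(x[0]), float(x[1])),
        kind=kind,
        in_bounds=in_bounds,
        value=float(fit.predict(x[0], x[1])),
    )


@dataclass(frozen=True)
class PeakValue:
    value: float
    response: str
    pair: tuple[str, str]


@dataclass
class PeakCollection:
    """Per factor: the coordinate of every in-bounds maximum involving it."""

    peaks: dict[str, list[PeakValue]]
    excluded: list[str] = field(default_factory=list)

    def values(self, factor: str) -> list[float]:
        return [p.value for p in self.peaks.get(factor, [])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f, p.response, "x".join(p.pair), p.value)
            for f, plist in self.peaks.items()
            for p in plist
        ]
        return pd.DataFrame(rows, columns=["factor", "response", "pair", "value"])


def collect_peaks(
    fits: Sequence[QuadraticFit],
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> PeakCollection:
    """Harvest per-factor peak coordinates from in-bounds maxima.

    Saddles, minima, degenerate fits and out-of-bounds points are excluded
    with a logged reason; a full three-response run yields six values per
    factor (two pairs x three responses).
    """
    bounds = bounds or default_bounds()
    peaks: dict[str, list[PeakValue]] = {}
    excluded: list[str] = []
    for fit in fits:
        sp = stationary_point(fit, bounds)
        tag = f"{fit.response} {fit.pair[0]}x{fit.pair[1]}"
        if sp.kind != "maximum":
            excluded.append(f"{tag}: {sp.kind}, not a maximum")
            continue
        if not sp.in_bounds:
            excluded.append(f"{tag}: maximum at {sp.coords} outside bounds")
            continue
        for axis, coord in zip(fit.pair, sp.coords):
            peaks.setdefault(axis, []).append(PeakValue(coord, fit.response, fit.pair))
    return PeakCollection(peaks=peaks, excluded=excluded)


def surface_grid(
    fit: QuadraticFit,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    resolution: int = 50,
) -> pd.DataFrame:
    """Long-format grid of predictions (xi, xj, yhat) for contour plotting."""
    bounds = bounds or default_bounds()
    lo_i, hi_i = bounds[fit.pair[0]]
    lo_j, hi_j = bounds[fit.pair[1]]
    xi = np.linspace(lo_i, hi_i, resolution)
    xj = np.linspace(lo_j, hi_j, resolution)
    gi, gj = np.meshgrid(xi, xj, indexing="ij")
    yhat = fit.predict(gi, gj)
    return pd.DataFrame(
        {"xi": gi.ravel(), "xj": gj.ravel(), "yhat": yhat.ravel()}
    )
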