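"""Grouped-frequency mode aggregation of response-surface peaks.

Six peak coordinates per factor (two pairs x three responses) are binned into
half-open intervals and the mode is interpolated inside the modal bin:

    M = L + d * D1 / (D1 + D2)        (lower-limit form)
    M = U - d * D2 / (D1 + D2)        (upper-limit form, identical since U=L+d)

where L/U bound the modal bin, d is the bin width, and D1/D2 are the count
drops to the lower/upper adjacent bins.  Bin widths and origins are not
dictated by the estimator; the defaults are calibrated per factor and every
result carries the binning used plus a sensitivity flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .response_surface import PeakCollection

__all__ = [
    "BinningConfig",
    "Bins",
    "ModeResult",
    "FactorOptimum",
    "FinalConditions",
    "DEFAULT_BINNING",
    "bin_frequencies",
    "grouped_mode",
    "grouped_mode_of",
    "final_conditions",
]


@dataclass(frozen=True)
class BinningConfig:
    """Half-open binning spec: edges at ``origin + k*width``.

    ``value_digits`` rounds input values to reporting precision before
    tallying (peak coordinates are quoted at 0.1 resolution); ``mode_digits``
    rounds the reported mode.
    """

    width: float
    origin: float = 0.0
    value_digits: int | None = 1
    mode_digits: int = 1

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("bin width must be positive")

    def bin_index(self, value: float) -> int:
        # half-open [edge, edge+width): a value exactly on an edge goes up
        return math.floor((value - self.origin) / self.width + 1e-12)

    def lower_edge(self, index: int) -> float:
        return self.origin + index * self.width


@dataclass
class Bins:
    config: BinningConfig
    first_index: int
    counts: np.ndarray  # contiguous counts from first_index upward

    @property
    def lower_edges(self) -> np.ndarray:
        return self.config.lower_edge(self.first_index) + self.config.width * np.arange(
            len(self.counts)
        )

    def count_at(self, index: int) -> int:
        off = index - self.first_index
        if 0 <= off < len(self.counts):
            return int(self.counts[off])
        return 0


def bin_frequencies(values: Sequence[float], config: BinningConfig) -> Bins:
    """Tally values into half-open bins; flanking bins count as zero."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("at least one value is required")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if config.value_digits is not None:
        values = np.round(values, config.value_digits)
    idx = np.array([config.bin_index(v) for v in values])
    first, last = int(idx.min()), int(idx.max())
    counts = np.zeros(last - first + 1, dtype=int)
    for i in idx:
        counts[i - first] += 1
    return Bins(config=config, first_index=first, counts=counts)


@dataclass
class ModeResult:
    """Interpolated mode with full binning provenance."""

    lower: float  # L
    upper: float  # U
    width: float  # d
    delta1: int
    delta2: int
    mode: float
    mode_upper_form: float
    bins: Bins

    @property
    def rounded(self) -> float:
        return round(self.mode, self.bins.config.mode_digits)


def grouped_mode(bins: Bins) -> ModeResult:
    """Interpolated mode of binned counts.

    Requires a unique modal bin; ties are refused (the "thickest" bin is
    undefined there) with the tied bins listed so the caller can rebin.  The
    one exception is a tie between two *adjacent* bins: the interpolation
    formula remains continuous there (D2=0 gives M=U, the shared boundary),
    so the lower bin is taken as modal.
    """
    counts = bins.counts
    peak = counts.max()
    tied = np.flatnonzero(counts == peak)
    if len(tied) > 1 and not (len(tied) == 2 and tied[1] - tied[0] == 1):
        edges = [bins.lower_edges[i] for i in tied]
        raise ValueError(
            f"tied modal bins at lower edges {edges} (count {peak}); rebin to break the tie"
        )
    i = int(tied[0])
    d = bins.config.width
    L = float(bins.lower_edges[i])
    U = L + d
    f_mode = int(counts[i])
    f_lo = bins.count_at(bins.first_index + i - 1)
    f_hi = bins.count_at(bins.first_index + i + 1)
    d1 = f_mode - f_lo
    d2 = f_mode - f_hi
    mode = L + d * d1 / (d1 + d2)
    mode_upper = U - d * d2 / (d1 + d2)
    return ModeResult(
        lower=L,
        upper=U,
        width=d,
        delta1=d1,
        delta2=d2,
        mode=float(mode),
        mode_upper_form=float(mode_upper),
        bins=bins,
    )


def grouped_mode_of(values: Sequence[float], config: BinningConfig) -> ModeResult:
    return grouped_mode(bin_frequencies(values, config))


#: calibrated defaults: temperature bins of 2 °C with edges on odd integers
#: and power bins of 5 W on multiples of 5 reproduce the published modes from
#: the published peak lists; the time binning (2 min, odd-integer edges) is a
#: choice — no simple binning reproduces the published time mode.
DEFAULT_BINNING: dict[str, BinningConfig] = {
    "A": BinningConfig(width=2.0, origin=1.0, value_digits=1, mode_digits=1),
    "B": BinningConfig(width=2.0, origin=1.0, value_digits=1, mode_digits=1),
    "C": BinningConfig(width=5.0, origin=0.0, value_digits=1, mode_digits=0),
}


@dataclass
class FactorOptimum:
    factor: str
    peaks: list[float]
    result: ModeResult
    rounded: float
    binning_sensitive: bool
    notes: str = ""


@dataclass
class FinalConditions:
    """Recommended condition per factor, with provenance and fidelity flags."""

    per_factor: dict[str, FactorOptimum]
    excluded: list[str] = field(default_factory=list)

    def condition(self) -> dict[str, float]:
        return {f: opt.rounded for f, opt in self.per_factor.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, opt in self.per_factor.items():
            r = opt.result
            rows.append(
                (
                    f,
                    ";".join(f"{v:g}" for v in opt.peaks),
                    r.width,
                    r.bins.config.origin,
                    r.lower,
                    r.upper,
                    r.delta1,
                    r.delta2,
                    r.mode,
                    opt.rounded,
                    opt.binning_sensitive,
                    opt.notes,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "factor",
                "peaks",
                "bin_width",
                "bin_origin",
                "L",
                "U",
                "delta1",
                "delta2",
                "mode",
                "rounded_mode",
                "binning_sensitive",
                "notes",
            ],
        )


def _sensitivity(values: Sequence[float], config: BinningConfig, mode: float) -> bool:
    """Flag when a half-width origin shift ties or moves the mode > width/2."""
    shifted = BinningConfig(
        width=config.width,
        origin=config.origin + config.width / 2.0,
        value_digits=config.value_digits,
        mode_digits=config.mode_digits,
    )
    try:
        alt = grouped_mode_of(values, shifted)
    except ValueError:
        return True
    return abs(alt.mode - mode) >= config.width / 2.0


def final_conditions(
    peaks: PeakCollection | Mapping[str, Sequence[float]],
    binning: Mapping[str, BinningConfig] | None = None,
) -> FinalConditions:
    """Grouped-mode optimum per factor from its collected peak values."""
    binning = dict(binning or DEFAULT_BINNING)
    if isinstance(peaks, PeakCollection):
        factor_values = {f: peaks.values(f) for f in peaks.peaks}
        excluded = list(peaks.excluded)
    else:
        factor_values = {f: list(v) for f, v in peaks.items()}
        excluded = []

    per_factor: dict[str, FactorOptimum] = {}
    for f, values in factor_values.items():
        if not values:
            raise ValueError(f"no peak values for factor {f}")
        cfg = binning.get(f)
        if cfg is None:
            raise ValueError(f"no binning config for factor {f}")
        result = grouped_mode_of(values, cfg)
        sensitive = _sensitivity(values, cfg, result.mode)
        notes = ""
        if len(values) < 6:
            notes = f"only {len(values)} peak values (expected 6); see exclusions"
        if sensitive:
            notes = (notes + "; " if notes else "") + (
                "mode estimate is sensitive to bin placement"
            )
        per_factor[f] = FactorOptimum(
            factor=f,
            peaks=[float(v) for v in values],
            result=result,
            rounded=result.rounded,
            binning_sensitive=sensitive,
            notes=notes,
        )
    return FinalConditions(per_factor=per_factor, excluded=excluded)
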