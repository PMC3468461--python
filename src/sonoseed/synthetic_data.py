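"""Synthetic germination / seedling / conductivity data with the study's layout.

The generator mirrors the replicate structure of the germination experiments:
16 treatments, three experiment blocks (4 + 6 + 6 dishes per treatment), 100
seeds per dish, and 10 measured seedlings per dish — so 256 dish records and
2,560 seedling records at the defaults.  Germinated counts are beta-binomial
(dish-level overdispersion calibrated to the published per-treatment SDs);
seedling lengths are correlated normals truncated at zero; conductivity series
follow ``y = a + b*ln(t)`` plus noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable, Factor, build_l16, decode, default_factors

__all__ = [
    "LayoutConfig",
    "EffectConfig",
    "ResponseDataset",
    "ConductivityConfig",
    "gen_germination",
    "gen_seedling_lengths",
    "gen_conductivity",
    "load_fixture_means",
    "fixture_effects",
    "effects_from_surfaces",
    "write_long_csv",
    "read_long_csv",
]

RESPONSES = ("GP", "PL", "RL")

_RESPONSE_COLUMNS = {"GP": "gp_pct", "PL": "pl_mm", "RL": "rl_mm"}


def response_column(response: str) -> str:
    try:
        return _RESPONSE_COLUMNS[response]
    except KeyError:
        raise ValueError(f"unknown response {response!r}; expected one of {RESPONSES}") from None


@dataclass(frozen=True)
class LayoutConfig:
    """Replicate structure of the germination experiments."""

    n_seeds_per_dish: int = 100
    dishes_per_experiment: tuple[int, ...] = (4, 6, 6)
    seedlings_measured_per_dish: int = 10

    def __post_init__(self) -> None:
        if self.n_seeds_per_dish <= 0:
            raise ValueError("n_seeds_per_dish must be positive")
        if not self.dishes_per_experiment or any(d <= 0 for d in self.dishes_per_experiment):
            raise ValueError("dishes_per_experiment must be positive counts")
        if self.seedlings_measured_per_dish <= 0:
            raise ValueError("seedlings_measured_per_dish must be positive")

    @property
    def n_experiments(self) -> int:
        return len(self.dishes_per_experiment)

    @property
    def dishes_per_treatment(self) -> int:
        return sum(self.dishes_per_experiment)

    @property
    def seedlings_per_treatment(self) -> int:
        return self.dishes_per_treatment * self.seedlings_measured_per_dish


@dataclass(frozen=True)
class EffectConfig:
    """True per-treatment response means and dispersion knobs.

    ``gp_mean`` is on the percentage scale.  ``gp_overdispersion`` is the
    beta-binomial intra-dish correlation rho (0 = plain binomial); scalar or
    one value per treatment.  ``block_sd`` adds an experiment-block shift
    (logit scale for GP, additive mm for lengths).
    """

    gp_mean: np.ndarray
    pl_mean: np.ndarray
    pl_sd: np.ndarray
    rl_mean: np.ndarray
    rl_sd: np.ndarray
    gp_overdispersion: np.ndarray | float = 0.0
    block_sd: float = 0.0
    pl_rl_corr: float = 0.5

    def __post_init__(self) -> None:
        for name in ("gp_mean", "pl_mean", "pl_sd", "rl_mean", "rl_sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any((self.gp_mean < 0) | (self.gp_mean > 100)):
            raise ValueError("gp_mean values must lie in [0, 100]")
        if np.any(self.pl_mean < 0) or np.any(self.rl_mean < 0):
            raise ValueError("length means must be non-negative")
        if np.any(self.pl_sd < 0) or np.any(self.rl_sd < 0):
            raise ValueError("length SDs must be non-negative")
        rho = np.asarray(self.gp_overdispersion, dtype=float)
        if np.any((rho < 0) | (rho >= 1)):
            raise ValueError("gp_overdispersion must lie in [0, 1)")
        if not -1 < self.pl_rl_corr < 1:
            raise ValueError("pl_rl_corr must lie in (-1, 1)")

    @property
    def n_treatments(self) -> int:
        return len(self.gp_mean)

    def rho_per_treatment(self) -> np.ndarray:
        rho = np.asarray(self.gp_overdispersion, dtype=float)
        if rho.ndim == 0:
            return np.full(self.n_treatments, float(rho))
        return rho


@dataclass
class ResponseDataset:
    """Long-format observations, at dish or seed granularity."""

    frame: pd.DataFrame
    granularity: str  # "dish" | "seed"
    layout: LayoutConfig = field(default_factory=LayoutConfig)

    def __post_init__(self) -> None:
        if self.granularity not in ("dish", "seed"):
            raise ValueError("granularity must be 'dish' or 'seed'")

    def treatment_means(self, response: str) -> pd.Series:
        col = response_column(response)
        if col not in self.frame.columns:
            raise ValueError(f"dataset has no column {col!r} for response {response}")
        return self.frame.groupby("treatment")[col].mean()


@dataclass(frozen=True)
class ConductivityConfig:
    """Per-group logarithmic leakage model y = a + b*ln(t) plus noise."""

    groups: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (2.0, 1.2),
            "water": (2.1, 1.4),
            "ultrasonic": (2.0, 1.6),
        }
    )
    noise_sd: float = 0.1
    times_h: tuple[float, ...] = (4.0, 8.0, 12.0, 24.0)
    replicates: int = 3

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.times_h):
            raise ValueError("sampling times must be positive")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("sampling times must be increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# fixtures


def _fixture_path(name: str):
    return importlib.resources.files("sonoseed.data").joinpath(name)


def load_fixture_means() -> pd.DataFrame:
    """Published per-treatment mean +/- SD table for GP, PL and RL."""
    with importlib.resources.as_file(_fixture_path("treatment_response_means.csv")) as p:
        return pd.read_csv(p)


def calibrate_overdispersion(gp_mean_pct: np.ndarray, gp_sd_pct: np.ndarray, n_seeds: int) -> np.ndarray:
    """Beta-binomial rho such that the count SD matches the target SD.

    With 100 seeds/dish the count and percentage scales coincide.  Var of a
    beta-binomial count is n*p*q*(1 + (n-1)*rho); solve for rho and clip into
    [0, 1).  Published germination SDs (11-25%) far exceed the binomial SE at
    n=100, hence the need for rho > 0.
    """
    p = np.asarray(gp_mean_pct, dtype=float) / 100.0
    scale = n_seeds / 100.0
    target_var = (np.asarray(gp_sd_pct, dtype=float) * scale) ** 2
    npq = n_seeds * p * (1 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (target_var / npq - 1.0) / (n_seeds - 1.0)
    rho = np.where(npq > 0, rho, 0.0)
    return np.clip(rho, 0.0, 0.999)


def fixture_effects(layout: LayoutConfig | None = None) -> EffectConfig:
    """EffectConfig whose means/SDs replicate the published treatment table."""
    layout = layout or LayoutConfig()
    tab = load_fixture_means()
    return EffectConfig(
        gp_mean=tab["gp_mean"].to_numpy(),
        pl_mean=tab["pl_mean"].to_numpy(),
        pl_sd=tab["pl_sd"].to_numpy(),
        rl_mean=tab["rl_mean"].to_numpy(),
        rl_sd=tab["rl_sd"].to_numpy(),
        gp_overdispersion=calibrate_overdispersion(
            tab["gp_mean"].to_numpy(), tab["gp_sd"].to_numpy(), layout.n_seeds_per_dish
        ),
    )


def effects_from_surfaces(
    design: DesignTable,
    gp: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    pl: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None,
    rl: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None,
    pl_sd: float = 9.0,
    rl_sd: float = 6.0,
    factors: Sequence[Factor] | None = None,
    **kwargs,
) -> EffectConfig:
    """Build an EffectConfig from true response surfaces over physical units.

    Each surface is a function of (time_min, temperature_c, power_w) arrays,
    evaluated at the design's decoded conditions.
    """
    cond = decode(design, factors)
    t, c, w = (
        cond["time_min"].to_numpy(),
        cond["temperature_c"].to_numpy(),
        cond["power_w"].to_numpy(),
    )
    gp_mean = np.clip(np.asarray(gp(t, c, w), dtype=float), 0.0, 100.0)
    pl_mean = np.asarray(pl(t, c, w), dtype=float) if pl else np.full_like(gp_mean, 38.0)
    rl_mean = np.asarray(rl(t, c, w), dtype=float) if rl else np.full_like(gp_mean, 14.0)
    return EffectConfig(
        gp_mean=gp_mean,
        pl_mean=pl_mean,
        pl_sd=np.full_like(gp_mean, pl_sd),
        rl_mean=rl_mean,
        rl_sd=np.full_like(gp_mean, rl_sd),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# generators


def gen_germination(
    design: DesignTable,
    layout: LayoutConfig,
    effects: EffectConfig,
    seed: int | np.random.Generator,
) -> ResponseDataset:
    """Dish-level germinated counts, beta-binomial across dishes.

    Deterministic given ``seed``.  A per-experiment block shift (logit scale,
    SD ``effects.block_sd``) is shared by all treatments within a block.
    """
    if effects.n_treatments != design.n_treatments:
        raise ValueError(
            f"effects cover {effects.n_treatments} treatments but design has "
            f"{design.n_treatments}"
        )
    rng = np.random.default_rng(seed)
    rho = effects.rho_per_treatment()
    n = layout.n_seeds_per_dish

    block_shift = (
        rng.normal(0.0, effects.block_sd, size=layout.n_experiments)
        if effects.block_sd > 0
        else np.zeros(layout.n_experiments)
    )

    rows = []
    for ti, treatment in enumerate(design.treatments):
        p0 = effects.gp_mean[ti] / 100.0
        for ei, n_dishes in enumerate(layout.dishes_per_experiment):
            p = _shift_logit(p0, block_shift[ei])
            for dish in range(1, n_dishes + 1):
                if rho[ti] > 0 and 0 < p < 1:
                    s = (1.0 - rho[ti]) / rho[ti]
                    p_dish = rng.beta(p * s, (1 - p) * s)
                else:
                    p_dish = p
                count = int(rng.binomial(n, p_dish))
                rows.append((int(treatment), ei + 1, dish, count, 100.0 * count / n))

    frame = pd.DataFrame(rows, columns=["treatment", "experiment", "dish", "gp_count", "gp_pct"])
    return ResponseDataset(frame=frame, granularity="dish", layout=layout)


def _shift_logit(p: float, delta: float) -> float:
    if delta == 0.0 or p <= 0.0 or p >= 1.0:
        return min(max(p, 0.0), 1.0)
    logit = np.log(p / (1 - p)) + delta
    return float(1.0 / (1.0 + np.exp(-logit)))


def gen_seedling_lengths(
    dataset: ResponseDataset,
    effects: EffectConfig,
    seed: int | np.random.Generator,
) -> ResponseDataset:
    """Per-seedling plumular/radicular lengths, correlated and truncated at 0.

    Samples ``layout.seedlings_measured_per_dish`` seedlings per dish record
    of ``dataset``; negative draws are rejected and resampled.
    """
    if dataset.granularity != "dish":
        raise ValueError("seedling lengths are generated from a dish-level dataset")
    if np.any(effects.pl_sd < 0) or np.any(effects.rl_sd < 0):
        raise ValueError("length SDs must be non-negative")
    rng = np.random.default_rng(seed)
    m = dataset.layout.seedlings_measured_per_dish
    corr = effects.pl_rl_corr
    treatments = dataset.frame["treatment"].to_numpy()
    t_index = {t: i for i, t in enumerate(np.unique(treatments), 0)}
    # map treatment id -> row in effects arrays (effects are in design row order)
    order = sorted(t_index)
    if len(order) != effects.n_treatments:
        raise ValueError("dataset treatments do not match effects table")

    block_shift = (
        rng.normal(0.0, effects.block_sd, size=(int(dataset.frame["experiment"].max()), 2))
        if effects.block_sd > 0
        else None
    )

    rows = []
    for rec in dataset.frame.itertuples(index=False):
        i = order.index(rec.treatment)
        mu = np.array([effects.pl_mean[i], effects.rl_mean[i]])
        sd = np.array([effects.pl_sd[i], effects.rl_sd[i]])
        if block_shift is not None:
            mu = np.maximum(mu + block_shift[rec.experiment - 1], 0.0)
        draws = _truncated_bivariate(rng, mu, sd, corr, m)
        for s in range(m):
            rows.append(
                (rec.treatment, rec.experiment, rec.dish, s + 1, draws[s, 0], draws[s, 1])
            )
    frame = pd.DataFrame(
        rows, columns=["treatment", "experiment", "dish", "seed", "pl_mm", "rl_mm"]
    )
    return ResponseDataset(frame=frame, granularity="seed", layout=dataset.layout)


def _truncated_bivariate(
    rng: np.random.Generator, mu: np.ndarray, sd: np.ndarray, corr: float, m: int
) -> np.ndarray:
    """m draws from N(mu, diag(sd) R diag(sd)) truncated to the positive orthant."""
    if np.all(sd == 0):
        return np.tile(mu, (m, 1))
    cov = np.array(
        [
            [sd[0] ** 2, corr * sd[0] * sd[1]],
            [corr * sd[0] * sd[1], sd[1] ** 2],
        ]
    )
    out = np.empty((m, 2))
    need = np.arange(m)
    # rejection sampling; means sit well above zero so acceptance is high
    for _ in range(1000):
        draws = rng.multivariate_normal(mu, cov, size=len(need), method="cholesky")
        ok = np.all(draws >= 0, axis=1)
        out[need[ok]] = draws[ok]
        need = need[~ok]
        if len(need) == 0:
            return out
    raise RuntimeError("truncated sampling failed to converge (means too close to 0?)")


def gen_conductivity(
    config: ConductivityConfig, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Replicate conductivity readings per group/time: a + b*ln(t) + noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, (a, b) in config.groups.items():
        for t in config.times_h:
            if t <= 0:
                raise ValueError("sampling times must be positive")
            mean = a + b * np.log(t)
            for rep in range(1, config.replicates + 1):
                val = mean + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
                rows.append((group, float(t), rep, float(val)))
    return pd.DataFrame(rows, columns=["group", "time_h", "replicate", "conductivity"])


# ---------------------------------------------------------------------------
# long-format CSV interchange


def write_long_csv(dataset: ResponseDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


def read_long_csv(path, layout: LayoutConfig | None = None) -> ResponseDataset:
    frame = pd.read_csv(path)
    granularity = "seed" if "seed" in frame.columns else "dish"
    return ResponseDataset(frame=frame, granularity=granularity, layout=layout or LayoutConfig())
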