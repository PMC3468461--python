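"""Factorial ANOVA, Student-Newman-Keuls letter display, and MANOVA statistics.

The orthogonal design is balanced, so main-effect sums of squares are
order-invariant; the vacancy column D enters as a pseudo-term whose
non-significance is an internal error check.  SNK letters use studentized-
range quantiles; MANOVA statistics are the four standard functions of the
eigenvalues of H·E^{-1} with their F approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .design import DesignTable
from .synthetic_data import ResponseDataset, response_column

__all__ = [
    "AnovaTable",
    "LetterGrouping",
    "ManovaResult",
    "anova_table",
    "factorial_anova",
    "snk_letters",
    "manova_tests",
    "group_sscp",
]


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaTable:
    response: str
    table: pd.DataFrame  # columns: term, df, sum_sq, mean_sq, F, p

    def term(self, name: str) -> pd.Series:
        hit = self.table.loc[self.table["term"] == name]
        if hit.empty:
            raise KeyError(f"no ANOVA term {name!r}")
        return hit.iloc[0]

    @property
    def residual(self) -> pd.Series:
        return self.term("Residual")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def anova_table(df: pd.DataFrame, response: str, terms: Sequence[str]) -> AnovaTable:
    """Type-II ANOVA of ``response`` on categorical ``terms`` in a dataframe.

    Balanced data makes type II equal to the sequential decomposition.  Raises
    if a requested term leaves no residual degrees of freedom.
    """
    parts: list[str] = []
    for term in terms:
        for part in term.split(":"):
            if part not in df.columns:
                raise ValueError(f"term {term!r}: column {part!r} not in data")
            if part not in parts:
                parts.append(part)
    # a design column named "C" would shadow patsy's C() builtin; work on
    # prefixed copies and map the term names back afterwards
    safe = {p: f"fac_{p}" for p in parts}
    work = df[[response, *parts]].rename(columns=safe)
    formula = f"{response} ~ " + " + ".join(
        ":".join(f"C({safe[p]})" for p in t.split(":")) for t in terms
    )
    fit = smf.ols(formula, data=work).fit()
    if fit.df_resid < 1:
        interactions = [t for t in terms if ":" in t] or list(terms)
        raise ValueError(
            f"no residual degrees of freedom for model with terms {list(terms)}; "
            f"replication is required for {interactions}"
        )
    raw = anova_lm(fit, typ=2)
    out = raw.reset_index().rename(
        columns={"index": "term", "sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    )
    out["term"] = [t.replace("C(fac_", "").replace(")", "") for t in out["term"]]
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out = out[["term", "df", "sum_sq", "mean_sq", "F", "p"]]
    return AnovaTable(response=response, table=out)


def factorial_anova(
    data: ResponseDataset | pd.DataFrame,
    design: DesignTable,
    response: str,
    terms: Sequence[str] = ("A", "B", "C", "D"),
) -> AnovaTable:
    """ANOVA of an observed response with design columns attached as factors.

    ``terms`` may include design columns (``"A"``...), pairwise interactions
    (``"A:B"``), and the block column ``"experiment"`` when present in the
    data.  Each design main effect has 3 df; pairwise interactions 9 df.
    """
    frame = data.frame if isinstance(data, ResponseDataset) else data
    col = response_column(response)
    if col not in frame.columns:
        raise ValueError(f"data has no column {col!r} for response {response}")
    levels = design.to_frame()
    merged = frame.merge(levels, on="treatment", how="left", validate="many_to_one")
    if merged[list(design.columns)].isna().any().any():
        raise ValueError("data contains treatments absent from the design")
    merged = merged.rename(columns={col: "_y"})
    fitted = anova_table(merged, "_y", terms)
    return AnovaTable(response=response, table=fitted.table)


# ---------------------------------------------------------------------------
# Student-Newman-Keuls letters


@dataclass
class LetterGrouping:
    labels: list
    means: np.ndarray  # in the order of ``labels``
    letters: list[str]
    alpha: float

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.letters))


def snk_letters(
    means: Sequence[float],
    mse: float,
    df_error: float,
    n_per_group: int,
    alpha: float = 0.05,
    labels: Sequence | None = None,
) -> LetterGrouping:
    """Stepwise studentized-range comparison with a compact letter display.

    Means are ordered descending; a stretch of p ordered means is declared
    homogeneous when its range falls below q(1-alpha, p, df)·sqrt(MSE/n), and
    significant stretches are split recursively (the SNK protection rule:
    sub-stretches of a homogeneous stretch are never tested).  Letters follow
    descending means, one letter per maximal homogeneous stretch.
    """
    means = np.asarray(means, dtype=float)
    k = len(means)
    if labels is None:
        labels = list(range(k))
    elif len(labels) != k:
        raise ValueError("labels/means length mismatch")
    if df_error < 1:
        raise ValueError("error df must be >= 1")
    if n_per_group < 1:
        raise ValueError("n per group must be >= 1")
    if mse < 0:
        raise ValueError("error mean square must be non-negative")

    order = np.argsort(-means, kind="stable")
    m = means[order]
    se = np.sqrt(mse / n_per_group)

    homogeneous: list[tuple[int, int]] = []

    def test(lo: int, hi: int) -> None:
        if lo >= hi:
            homogeneous.append((lo, hi))
            return
        p = hi - lo + 1
        crit = stats.studentized_range.ppf(1 - alpha, p, df_error) * se
        if (m[lo] - m[hi]) < crit or np.isclose(m[lo] - m[hi], 0.0):
            homogeneous.append((lo, hi))
        else:
            test(lo, hi - 1)
            test(lo + 1, hi)

    test(0, k - 1)

    # keep maximal stretches only
    maximal = [
        (lo, hi)
        for lo, hi in set(homogeneous)
        if not any((a <= lo and hi <= b) and (a, b) != (lo, hi) for a, b in set(homogeneous))
    ]
    maximal.sort()

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters_sorted = ["" for _ in range(k)]
    for gi, (lo, hi) in enumerate(maximal):
        ch = alphabet[gi % len(alphabet)] * (gi // len(alphabet) + 1)
        for i in range(lo, hi + 1):
            letters_sorted[i] += ch

    letters = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        letters[orig] = letters_sorted[pos]
    return LetterGrouping(labels=list(labels), means=means, letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# MANOVA


@dataclass
class ManovaResult:
    """The four standard MANOVA criteria with F approximations.

    ``s``, ``m``, ``n`` are the usual auxiliary parameters; Roy's F is an
    upper bound, as conventionally reported.
    """

    wilks: float
    pillai: float
    hotelling_lawley: float
    roy: float
    tests: pd.DataFrame  # statistic, value, F, num_df, den_df, p, note
    s: float
    m: float
    n: float
    eigenvalues: np.ndarray

    def to_csv(self, path) -> None:
        self.tests.to_csv(path, index=False)


def manova_tests(H: np.ndarray, E: np.ndarray, df_hypothesis: int, df_error: int) -> ManovaResult:
    """MANOVA criteria from hypothesis and error SSCP matrices.

    Wilks = det(E)/det(H+E); Pillai = tr(H(H+E)^{-1}); Hotelling-Lawley =
    tr(HE^{-1}); Roy = max eigenvalue of HE^{-1}.
    """
    H = np.asarray(H, dtype=float)
    E = np.asarray(E, dtype=float)
    if H.shape != E.shape or H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("H and E must be square matrices of equal shape")
    if not np.allclose(H, H.T, atol=1e-8 * (1 + np.abs(H).max())):
        raise ValueError("H must be symmetric")
    try:
        np.linalg.cholesky(E)
    except np.linalg.LinAlgError:
        raise ValueError("E must be positive definite") from None

    p = H.shape[0]
    q = float(df_hypothesis)
    v = float(df_error)

    lam = np.linalg.eigvals(np.linalg.solve(E, H))
    lam = np.sort(np.real(lam))[::-1]
    lam = np.clip(lam, 0.0, None)  # H psd => eigenvalues >= 0 up to roundoff

    wilks = float(np.prod(1.0 / (1.0 + lam)))
    pillai = float(np.sum(lam / (1.0 + lam)))
    hotelling = float(np.sum(lam))
    roy = float(lam[0]) if len(lam) else 0.0

    s = min(p, q)
    m = (abs(p - q) - 1.0) / 2.0
    n = (v - p - 1.0) / 2.0

    rows = []

    # Wilks (Rao's F; exact when min(p, q) <= 2)
    pq = p * q
    t = (
        np.sqrt((p**2 * q**2 - 4.0) / (p**2 + q**2 - 5.0))
        if (p**2 + q**2 - 5.0) > 0
        else 1.0
    )
    r = v - (p - q + 1.0) / 2.0
    u = (pq - 2.0) / 4.0
    df2_w = r * t - 2.0 * u
    lam_t = wilks ** (1.0 / t)
    f_w = np.inf if lam_t == 0 else (1.0 - lam_t) / lam_t * df2_w / pq
    rows.append(("wilks", wilks, f_w, pq, df2_w, _fp(f_w, pq, df2_w), "exact for s<=2"))

    # Pillai
    df1_p = s * (2.0 * m + s + 1.0)
    df2_p = s * (2.0 * n + s + 1.0)
    f_p = np.inf if pillai >= s else (df2_p / df1_p) * pillai / (s - pillai)
    rows.append(("pillai", pillai, f_p, df1_p, df2_p, _fp(f_p, df1_p, df2_p), ""))

    # Hotelling-Lawley
    df1_h = s * (2.0 * m + s + 1.0)
    df2_h = 2.0 * (s * n + 1.0)
    f_h = df2_h * hotelling / (s**2 * (2.0 * m + s + 1.0))
    rows.append(("hotelling_lawley", hotelling, f_h, df1_h, df2_h, _fp(f_h, df1_h, df2_h), ""))

    # Roy (upper bound)
    rr = max(p, q)
    df1_r = rr
    df2_r = v - rr + q
    f_r = roy * df2_r / rr
    rows.append(("roy", roy, f_r, df1_r, df2_r, _fp(f_r, df1_r, df2_r), "upper bound"))

    tests = pd.DataFrame(rows, columns=["statistic", "value", "F", "num_df", "den_df", "p", "note"])
    return ManovaResult(
        wilks=wilks,
        pillai=pillai,
        hotelling_lawley=hotelling,
        roy=roy,
        tests=tests,
        s=s,
        m=m,
        n=n,
        eigenvalues=lam,
    )


def _fp(f: float, df1: float, df2: float) -> float:
    if not np.isfinite(f):
        return 0.0
    if df1 <= 0 or df2 <= 0:
        return np.nan
    return float(stats.f.sf(f, df1, df2))


def group_sscp(Y: np.ndarray, groups: Sequence) -> tuple[np.ndarray, np.ndarray, int, int]:
    """One-way hypothesis and error SSCP matrices for multivariate responses.

    Returns (H, E, df_hypothesis, df_error) for observations ``Y`` (n x p)
    grouped by ``groups``.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    grand = Y.mean(axis=0)
    H = np.zeros((Y.shape[1], Y.shape[1]))
    E = np.zeros_like(H)
    uniq = pd.unique(groups)
    for g in uniq:
        sub = Y[groups == g]
        d = sub.mean(axis=0) - grand
        H += len(sub) * np.outer(d, d)
        resid = sub - sub.mean(axis=0)
        E += resid.T @ resid
    return H, E, len(uniq) - 1, len(Y) - len(uniq)
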