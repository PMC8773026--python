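"""Stress-induced-hyperthermia statistics.

Quantifies SIH from tidy trial tables: per-timepoint grand means with
t-based confidence intervals, per-animal temperature deltas (last minus
first scheduled second; positive = hyperthermia), a within-subject
repeated-measures ANOVA on time with Greenhouse-Geisser correction and
Mauchly's sphericity test, factorial between-animal ANOVAs on per-animal
summaries, Sidak-adjusted pairwise contrasts, and the within-cage
testing-order contrast.

The full mixed design (time x several between factors) is decomposed into
(a) the within-subject time test and (b) factorial ANOVA on per-animal
baselines or deltas — the same scientific contrasts, estimable on any
complete-case table.  Sphericity quantities use normalized polynomial
contrasts, which are deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


class StatsError(ValueError):
    """Insufficient or degenerate data for the requested statistic."""


# --------------------------------------------------------------------------
# Elementary summaries
# --------------------------------------------------------------------------


def mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a t-based confidence interval.

    Returns ``(mean, lower, upper)`` where the half-width is
    ``t(1 - alpha/2, n-1) * sd / sqrt(n)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if np.isnan(v).any():
        raise StatsError("mean_ci requires complete data")
    n = v.size
    if n < 2:
        raise StatsError("mean_ci needs at least two values")
    m = float(v.mean())
    half = float(sps.t.ppf(0.5 + level / 2, n - 1) * v.std(ddof=1) / np.sqrt(n))
    return m, m - half, m + half


def delta_t(series, measure: str) -> float:
    """Temperature change, last minus first scheduled second.

    Positive values indicate hyperthermia; for the tail the sign is
    typically negative (peripheral vasoconstriction).  ``series`` is either
    a :class:`~thermosih.measurement.TrialRecord` or a mapping
    ``timepoint -> value``.
    """
    attr = {"T_sc": "t_sc_c", "T_body": "t_body_c", "T_tail": "t_tail_c"}
    if hasattr(series, "series"):
        values = {
            m.timepoint_s: getattr(m, attr[measure])
            for m in series.series
            if getattr(m, attr[measure]) is not None
        }
    else:
        values = {int(t): v for t, v in dict(series).items() if v is not None and not np.isnan(v)}
    if len(values) < 2:
        raise StatsError(f"need first and last timepoints for {measure}")
    first, last = min(values), max(values)
    return float(values[last] - values[first])


def sidak(p_raw: float, m: int) -> float:
    """Sidak multiplicity adjustment ``1 - (1 - p)^m``, capped at 1."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if p_raw == 1.0:
        return 1.0
    # -expm1(m*log1p(-p)) == 1-(1-p)^m without cancellation for tiny p
    return float(min(1.0, -np.expm1(m * np.log1p(-p_raw))))


# --------------------------------------------------------------------------
# Sphericity machinery
# --------------------------------------------------------------------------


def _polynomial_contrasts(k: int) -> np.ndarray:
    """Orthonormal polynomial contrast matrix C (k x (k-1)), C'C = I, C'1 = 0."""
    t = np.arange(k, dtype=float)
    basis = np.vander(t, k, increasing=True)  # [1, t, t^2, ...]
    q, _ = np.linalg.qr(basis)
    c = q[:, 1:]
    # fix signs for determinism: leading nonzero element positive
    for j in range(c.shape[1]):
        lead = c[np.argmax(np.abs(c[:, j]) > 1e-12), j]
        if lead < 0:
            c[:, j] = -c[:, j]
    return c


def _as_complete_matrix(data: np.ndarray) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise StatsError("expected an animals x timepoints matrix")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise StatsError("need >= 2 complete rows and >= 2 timepoints")
    return x


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast covariance eigenvalues.

    ``eps = (sum lam)^2 / ((k-1) * sum lam^2)`` with ``lam`` the eigenvalues
    of ``C' S C`` for an orthonormal within-subject contrast basis C and
    sample covariance S; bounded to ``[1/(k-1), 1]``.  With k = 2 there is a
    single contrast and epsilon is exactly 1.
    """
    x = _as_complete_matrix(data)
    n, k = x.shape
    if k == 2:
        return 1.0
    c = _polynomial_contrasts(k)
    s = np.cov(x, rowvar=False)
    sc = c.T @ s @ c
    lam = np.linalg.eigvalsh(sc)
    total = lam.sum()
    if not np.isfinite(total) or total <= 0:
        raise StatsError("singular covariance: epsilon undefined")
    eps = total**2 / ((k - 1) * np.sum(lam**2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_w(data: np.ndarray) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on the contrast covariance.

    ``W = det(S_c) / (tr(S_c) / (k-1))^(k-1)``, chi-square approximated with
    ``df = k(k-1)/2 - 1``.  With k = 2 the test is vacuous and
    ``(1, 0, 0, 1)`` is returned.
    """
    x = _as_complete_matrix(data)
    n, k = x.shape
    if k == 2:
        return 1.0, 0.0, 0, 1.0
    if n <= k - 1:
        raise StatsError("need more complete rows than contrasts for Mauchly's test")
    p = k - 1
    c = _polynomial_contrasts(k)
    sc = c.T @ np.cov(x, rowvar=False) @ c
    det = float(np.linalg.det(sc))
    tr = float(np.trace(sc))
    if det <= 0 or tr <= 0:
        raise StatsError("singular contrast covariance")
    w = det / (tr / p) ** p
    d = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1))
    chi2 = float(-(n - 1) * d * np.log(w))
    df = p * (p + 1) // 2 - 1
    pval = float(sps.chi2.sf(chi2, df))
    return float(w), chi2, df, pval


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way repeated-measures ANOVA on time, with and without GG adjustment."""

    f: float
    df1: float
    df2: float
    p_uncorrected: float
    epsilon_gg: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    n: int
    k: int


def rm_time_anova(data: np.ndarray) -> RmAnovaResult:
    """Within-subject F test of the time effect.

    ``F = MS_time / MS_(time x subject)`` on a complete-case animals x
    timepoints matrix; the Greenhouse-Geisser adjusted p uses
    ``eps*(k-1)`` and ``eps*(k-1)(n-1)`` degrees of freedom.
    """
    x = _as_complete_matrix(data)
    n, k = x.shape
    if n < 3:
        raise StatsError("need at least 3 complete subjects")
    grand = x.mean()
    col = x.mean(axis=0)
    row = x.mean(axis=1)
    ss_time = n * np.sum((col - grand) ** 2)
    ss_subj = k * np.sum((row - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_time - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_time = ss_time / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        raise StatsError("zero within-subject error variance")
    f = float(ms_time / ms_err)
    eps = gg_epsilon(x)
    return RmAnovaResult(
        f=f,
        df1=float(df1),
        df2=float(df2),
        p_uncorrected=float(sps.f.sf(f, df1, df2)),
        epsilon_gg=eps,
        df1_gg=eps * df1,
        df2_gg=eps * df2,
        p_gg=float(sps.f.sf(f, eps * df1, eps * df2)),
        n=n,
        k=k,
    )


# --------------------------------------------------------------------------
# Between-animal factorial ANOVA on per-animal summaries
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    """A labelled two-group mean difference with CI and adjusted p."""

    label: str
    estimate: float
    ci_lower: float
    ci_upper: float
    p_raw: float
    p_sidak: float
    n_minus: int
    n_plus: int


def _two_group_contrast(
    minus: np.ndarray, plus: np.ndarray, label: str, m_comparisons: int = 1, level: float = 0.95
) -> ContrastResult:
    minus = np.asarray(minus, dtype=float)
    plus = np.asarray(plus, dtype=float)
    if minus.size < 2 or plus.size < 2:
        raise StatsError(f"contrast {label!r}: need >= 2 observations per level")
    est = float(plus.mean() - minus.mean())
    res = sps.ttest_ind(plus, minus, equal_var=False)
    ci = res.confidence_interval(confidence_level=level)
    p_raw = float(res.pvalue)
    return ContrastResult(
        label=label,
        estimate=est,
        ci_lower=float(ci.low),
        ci_upper=float(ci.high),
        p_raw=p_raw,
        p_sidak=sidak(p_raw, m_comparisons),
        n_minus=int(minus.size),
        n_plus=int(plus.size),
    )


@dataclass
class BetweenAnovaResult:
    """Factorial fixed-effects ANOVA on a per-animal scalar summary."""

    table: pd.DataFrame  # term, F, p, note
    estimates: dict[str, ContrastResult]  # two-level factor -> level difference
    aliased: list[str]  # interaction terms dropped for empty cells


def between_anova(
    summary: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    include_interactions: bool = True,
) -> BetweenAnovaResult:
    """Factorial ANOVA (main effects + two-way interactions, sum coding).

    ``summary`` holds one row per animal with the scalar ``response`` and
    the factor columns.  Interactions whose cell table has empty cells are
    reported as aliased rather than silently dropped.  For every factor with
    exactly two observed levels the level difference (in the canonical
    direction used by the simulator, e.g. dark minus light) is estimated
    with a Welch CI.
    """
    from thermosih.synthetic import EFFECT_LEVELS

    data = summary.dropna(subset=[response]).copy()
    terms: list[str] = []
    aliased: list[str] = []
    usable_factors: list[str] = []
    for f in factors:
        levels = data[f].unique()
        if len(levels) < 2:
            aliased.append(f)
            continue
        usable_factors.append(f)
        terms.append(f"C({f}, Sum)")
    if not usable_factors:
        raise StatsError("no factor with >= 2 observed levels")
    n_params = 1 + sum(data[f].nunique() - 1 for f in usable_factors)
    if include_interactions:
        inter_params = sum(
            (data[a].nunique() - 1) * (data[b].nunique() - 1)
            for i, a in enumerate(usable_factors)
            for b in usable_factors[i + 1 :]
        )
        if len(data) - (n_params + inter_params) < 2:
            # saturated design: fall back to main effects only
            include_interactions = False
            aliased.append("two-way interactions (insufficient residual df)")
    if include_interactions:
        for i, a in enumerate(usable_factors):
            for b in usable_factors[i + 1 :]:
                cells = pd.crosstab(data[a], data[b])
                if (cells.values == 0).any():
                    aliased.append(f"{a}:{b}")
                else:
                    terms.append(f"C({a}, Sum):C({b}, Sum)")
    if len(data) - n_params < 2:
        raise StatsError("too few animals for a factorial ANOVA on this summary")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    aov = anova_lm(model, typ=2)
    rows = []
    for term, row in aov.iterrows():
        if term == "Residual":
            continue
        clean = term.replace("C(", "").replace(", Sum)", "")
        rows.append({"term": clean, "F": row["F"], "p": row["PR(>F)"], "note": ""})
    for term in aliased:
        rows.append({"term": term, "F": np.nan, "p": np.nan, "note": "aliased/empty cells"})
    table = pd.DataFrame(rows, columns=["term", "F", "p", "note"])

    estimates: dict[str, ContrastResult] = {}
    for f in usable_factors:
        levels = set(data[f].unique())
        if len(levels) != 2:
            continue
        canon = EFFECT_LEVELS.get(f)
        if canon and levels == set(canon):
            lo, hi = canon
        else:
            lo, hi = sorted(levels, key=str)
        estimates[f] = _two_group_contrast(
            data.loc[data[f] == lo, response].to_numpy(),
            data.loc[data[f] == hi, response].to_numpy(),
            label=f"{f}: {hi} - {lo}",
        )
    return BetweenAnovaResult(table=table, estimates=estimates, aliased=aliased)


# --------------------------------------------------------------------------
# Trial-table summaries
# --------------------------------------------------------------------------

_MEASURE_COLUMN = {"T_sc": "t_sc_c", "T_body": "t_body_c", "T_tail": "t_tail_c"}


def measure_matrix(table: pd.DataFrame, measure: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Wide complete-case matrix (animals x scheduled timepoints) for a measure."""
    col = _MEASURE_COLUMN[measure]
    wide = table.pivot_table(
        index=["animal_id", "trial_index"], columns="timepoint_s", values=col, aggfunc="first"
    )
    wide = wide.dropna(axis=1, how="all").dropna(axis=0, how="any")
    return wide, wide.to_numpy(dtype=float)


@dataclass
class SihSummary:
    """Per-measure SIH summary: grand means, delta, time test, sphericity."""

    measure: str
    timepoints: tuple[int, ...]
    means: dict[int, tuple[float, float, float]]  # t -> (mean, lo, hi)
    delta: tuple[float, float, float]  # mean change last - first, with CI
    anova: RmAnovaResult
    mauchly: tuple[float, float, int, float]  # (W, chi2, df, p)
    n_animals: int


def sih_summary(table: pd.DataFrame, measure: str, level: float = 0.95) -> SihSummary:
    """Summarize one measure over a tidy trial table (complete cases)."""
    wide, x = measure_matrix(table, measure)
    tps = tuple(int(t) for t in wide.columns)
    means = {t: mean_ci(x[:, i], level) for i, t in enumerate(tps)}
    deltas = x[:, -1] - x[:, 0]
    try:
        mauchly = mauchly_w(x)
    except StatsError:
        # fewer complete animals than within-subject contrasts: W undefined
        mauchly = (float("nan"), float("nan"), 0, float("nan"))
    return SihSummary(
        measure=measure,
        timepoints=tps,
        means=means,
        delta=mean_ci(deltas, level),
        anova=rm_time_anova(x),
        mauchly=mauchly,
        n_animals=x.shape[0],
    )


def testing_order_contrast(
    table: pd.DataFrame,
    measure: str,
    timepoint_s: int,
    m_comparisons: Optional[int] = None,
) -> ContrastResult:
    """Second-tested minus first-tested cage-mate contrast at one second.

    The Sidak adjustment defaults to the number of scheduled timepoints of
    the measure (each tested in the same family of comparisons).
    """
    col = _MEASURE_COLUMN[measure]
    at = table[(table["timepoint_s"] == timepoint_s) & table[col].notna()]
    first = at.loc[at["testing_order"] == 1, col].to_numpy(dtype=float)
    second = at.loc[at["testing_order"] == 2, col].to_numpy(dtype=float)
    if first.size < 2 or second.size < 2:
        raise StatsError("need >= 2 animals per testing-order level at this timepoint")
    if m_comparisons is None:
        m_comparisons = int(table.loc[table[col].notna(), "timepoint_s"].nunique())
    return _two_group_contrast(
        first,
        second,
        label=f"{measure} order 2 - order 1 at {timepoint_s} s",
        m_comparisons=max(1, m_comparisons),
    )
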