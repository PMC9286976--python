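"""Group statistics for climbing metrics and flight proportions.

Climbing metrics are compared with two-way ANOVA (Type II sums of squares
by default, configurable to Type III) followed by Tukey's HSD. Flight
proportions use Fisher's exact test for two groups and the Marascuilo
multiple-proportion procedure with a Bonferroni correction when more than
two groups are compared. The delayed-treatment "window" analysis runs a
per-start-day Fisher test against the matched untreated baseline and
reports the last start day of an unbroken run of significant benefit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .monitor_io import FlightRecord

__all__ = [
    "AnovaResult",
    "ProportionComparison",
    "WindowResult",
    "fisher_exact",
    "marascuilo",
    "two_way_anova_tukey",
    "window_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus Tukey HSD post-hoc comparisons."""

    anova_table: pd.DataFrame  # rows: factor_a, factor_b, interaction, Residual
    tukey_table: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    response: str
    factor_a: str
    factor_b: str
    n_used: int
    n_dropped: int


@dataclass
class ProportionComparison:
    """Omnibus chi-square plus Marascuilo pairwise critical ranges."""

    groups: pd.DataFrame  # label, n, k_flew, proportion
    chi2: float
    chi2_p: float
    pairwise: pd.DataFrame  # group_i, group_j, abs_diff, critical_range, significant
    alpha: float
    bonferroni_m: int
    fisher_p: float | None = None  # two-group designs only


@dataclass
class WindowResult:
    """Per-start-day treated-vs-untreated comparisons and the window edge."""

    table: pd.DataFrame
    window_edges: dict[str, int | None]  # genotype -> last day of benefit
    alpha: float


def two_way_anova_tukey(
    metrics: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    *,
    ss_type: int = 2,
    tukey_on: str = "cells",
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way factorial ANOVA with interaction, then Tukey HSD.

    Rows with an undefined (NaN) response are dropped with a logged count.
    ``tukey_on`` is ``"cells"`` (all factor-level combinations) or the name
    of one factor for marginal comparisons.
    """
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    for col in (response, factor_a, factor_b):
        if col not in metrics.columns:
            raise ValueError(f"column {col!r} not in metrics table")
    df = metrics[[response, factor_a, factor_b]].copy()
    n_total = len(df)
    df = df.dropna(subset=[response])
    n_dropped = n_total - len(df)
    if n_dropped:
        logger.info(
            "two_way_anova_tukey: dropped %d rows with undefined %r",
            n_dropped,
            response,
        )
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[factor_a].unique(), df[factor_b].unique()]
    )
    empty = full.difference(counts.index)
    if len(empty):
        raise ValueError(f"empty design cell(s): {list(empty)}")
    if len(df) - df[factor_a].nunique() * df[factor_b].nunique() <= 0:
        raise ValueError("zero residual degrees of freedom")
    if np.allclose(df[response].var(ddof=0), 0.0):
        raise ValueError(f"response {response!r} is constant")

    work = df.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    table = table.rename(
        index={
            "C(_a)": factor_a,
            "C(_b)": factor_b,
            "C(_a):C(_b)": f"{factor_a}:{factor_b}",
        }
    )

    if tukey_on == "cells":
        labels = (
            work["_a"].astype(str) + ":" + work["_b"].astype(str)
        ).to_numpy()
    elif tukey_on in (factor_a, factor_b):
        col = "_a" if tukey_on == factor_a else "_b"
        labels = work[col].astype(str).to_numpy()
    else:
        raise ValueError("tukey_on must be 'cells' or one of the factor names")
    tk = pairwise_tukeyhsd(work["_y"].to_numpy(), labels, alpha=alpha)
    tukey_table = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )

    return AnovaResult(
        anova_table=table,
        tukey_table=tukey_table,
        response=response,
        factor_a=factor_a,
        factor_b=factor_b,
        n_used=len(df),
        n_dropped=n_dropped,
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (at the observed
    margins) no more probable than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table must hold nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


def marascuilo(
    groups: Sequence[tuple[int, int]],
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    *,
    labels: Sequence[str] | None = None,
    control: str | int | None = None,
) -> ProportionComparison:
    """Marascuilo multiple-proportion comparison with Bonferroni correction.

    ``groups`` are (k_flew, n) pairs. If ``control`` designates a group
    (label or index), only control-vs-treatment pairs are compared and the
    Bonferroni m defaults to the number of those comparisons; otherwise all
    pairs are compared. Pair (i, j) is significant when
    |p_i - p_j| > sqrt(chi2[1 - alpha/m; g-1]) * sqrt(p_i q_i/n_i + p_j q_j/n_j).
    """
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    for k, n in groups:
        if n < 1 or not (0 <= k <= n):
            raise ValueError(f"invalid group counts (k={k}, n={n})")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(g)]
    if len(labels) != g:
        raise ValueError("labels length must match groups")

    k_arr = np.array([k for k, _ in groups], dtype=float)
    n_arr = np.array([n for _, n in groups], dtype=float)
    p_arr = k_arr / n_arr

    obs = np.vstack([k_arr, n_arr - k_arr])
    if np.any(obs.sum(axis=1) == 0):
        # degenerate omnibus (all successes or all failures); chi2 undefined
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = scipy.stats.chi2_contingency(obs)

    if control is not None:
        ci = labels.index(control) if isinstance(control, str) else int(control)
        pairs = [(ci, j) for j in range(g) if j != ci]
    else:
        pairs = list(combinations(range(g), 2))
    m = bonferroni_m if bonferroni_m is not None else len(pairs)
    if m < 1:
        raise ValueError("bonferroni_m must be >= 1")

    crit_chi2 = scipy.stats.chi2.ppf(1.0 - alpha / m, df=g - 1)
    rows = []
    for i, j in pairs:
        se = math.sqrt(
            p_arr[i] * (1 - p_arr[i]) / n_arr[i]
            + p_arr[j] * (1 - p_arr[j]) / n_arr[j]
        )
        r = math.sqrt(crit_chi2) * se
        diff = abs(p_arr[i] - p_arr[j])
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "abs_diff": diff,
                "critical_range": r,
                "significant": bool(diff > r),
            }
        )

    fisher_p = None
    if g == 2:
        fisher_p = fisher_exact(
            [
                [int(k_arr[0]), int(n_arr[0] - k_arr[0])],
                [int(k_arr[1]), int(n_arr[1] - k_arr[1])],
            ]
        )

    return ProportionComparison(
        groups=pd.DataFrame(
            {
                "label": labels,
                "n": n_arr.astype(int),
                "k_flew": k_arr.astype(int),
                "proportion": p_arr,
            }
        ),
        chi2=float(chi2_stat),
        chi2_p=float(chi2_p),
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
        bonferroni_m=m,
        fisher_p=fisher_p,
    )


def _flight_counts(records: Sequence[FlightRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "dose_ug_per_ml": [r.dose_ug_per_ml for r in records],
            "start_day": [r.start_day for r in records],
            "flew": [r.flew for r in records],
        }
    )


def window_analysis(
    flight: Sequence[FlightRecord],
    alpha: float = 0.05,
) -> WindowResult:
    """Per-start-day Fisher tests of treated vs matched untreated flies.

    Within each genotype, every treated start-day group (dose > 0) is
    compared against that genotype's untreated flies (dose == 0) with a
    two-sided Fisher exact test. The window edge is the largest start day d
    such that days 0..d are all significant (an unbroken run of benefit
    from day 0); None when day 0 itself shows no effect.
    """
    df = _flight_counts(flight)
    treated = df[(df["dose_ug_per_ml"] > 0) & df["start_day"].notna()]
    if treated["start_day"].nunique() < 2:
        raise ValueError("window analysis needs records spanning >= 2 start days")

    rows = []
    edges: dict[str, int | None] = {}
    for genotype, sub in treated.groupby("genotype"):
        base = df[(df["genotype"] == genotype) & (df["dose_ug_per_ml"] == 0)]
        if base.empty:
            logger.warning(
                "window_analysis: no untreated baseline for genotype %r; skipped",
                genotype,
            )
            continue
        kb, nb = int(base["flew"].sum()), len(base)
        sig_by_day: dict[int, bool] = {}
        for day, day_sub in sub.groupby("start_day"):
            kt, nt = int(day_sub["flew"].sum()), len(day_sub)
            if kt + kb == 0 or (nt - kt) + (nb - kb) == 0:
                p = 1.0  # degenerate table: identical outcomes, no evidence
            else:
                p = fisher_exact([[kt, nt - kt], [kb, nb - kb]])
            sig = p < alpha
            sig_by_day[int(day)] = sig
            rows.append(
                {
                    "genotype": genotype,
                    "start_day": int(day),
                    "n_treated": nt,
                    "k_treated": kt,
                    "prop_treated": kt / nt,
                    "n_untreated": nb,
                    "k_untreated": kb,
                    "prop_untreated": kb / nb,
                    "fisher_p": p,
                    "significant": sig,
                }
            )
        edge: int | None = None
        for day in sorted(sig_by_day):
            if sig_by_day[day]:
                edge = day
            else:
                break
        edges[genotype] = edge

    table = pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "start_day",
            "n_treated",
            "k_treated",
            "prop_treated",
            "n_untreated",
            "k_untreated",
            "prop_untreated",
            "fisher_p",
            "significant",
        ],
    ).sort_values(["genotype", "start_day"], ignore_index=True)
    return WindowResult(table=table, window_edges=edges, alpha=alpha)
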