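"""Group summaries, hypothesis tests, and the normalized relative difference.

Environment comparisons follow the classical parametric toolkit: optional
log transform of strictly positive values (a variance stabilizer for
right-skewed intensity data), pooled-variance independent-samples t-test
paired with a two-sample F-test for equal variances, paired t-tests, and a
one-way ANOVA with Tukey-Kramer post-tests honoring unequal group sizes.
Summaries are reported as median and interquartile range with
linear-interpolation quantiles.

The normalized relative difference (NRD) compares human-made against
natural scene means across illuminants on a common unitless scale: the
relative difference (HM - Nat) / Nat per illuminant, divided by its maximum
over illuminants for that metric (so the most differentiating illuminant
scores exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, TransformError


@dataclass
class GroupComparison:
    """One test result: kind, statistic, p-value, degrees of freedom, transform."""

    metric: str
    statistic_kind: str  # t_independent | t_paired | F_variance | anova_oneway | tukey_kramer | pearson
    statistic: float
    p_value: float
    df: tuple[float, ...]
    transform: str = "none"
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DegenerateDataError(f"p-value {self.p_value} outside [0, 1]")


def summarize(values: np.ndarray | list[float]) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateDataError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)


def _apply_transform(values: np.ndarray, transform: str, label: str) -> np.ndarray:
    if transform == "none":
        return values
    if transform == "log":
        n_bad = int((values <= 0).sum())
        if n_bad:
            raise TransformError(
                f"log transform undefined for {n_bad} non-positive value(s) in {label}"
            )
        return np.log(values)
    raise TransformError(f"unknown transform {transform!r}")


def compare_groups(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    transform: str = "none",
    metric: str = "",
    paired: bool = False,
    welch: bool = False,
) -> list[GroupComparison]:
    """Two-group comparison: t-test on means plus F-test on variances.

    The optional log transform is applied to both groups first. The default
    t-test pools variances (the classical procedure alongside a separate
    equal-variance F-test); ``welch=True`` switches to the Welch t. The
    paired variant requires equal lengths and skips the F-test's pooling
    assumption but still reports it.
    """
    x = _apply_transform(np.asarray(a, dtype=float), transform, "group a")
    y = _apply_transform(np.asarray(b, dtype=float), transform, "group b")
    if x.size < 3 or y.size < 3:
        raise DegenerateDataError(
            f"each group needs n >= 3, got {x.size} and {y.size}"
        )
    out: list[GroupComparison] = []
    if paired:
        if x.size != y.size:
            raise DegenerateDataError(
                f"paired test needs equal lengths, got {x.size} and {y.size}"
            )
        t_res = sps.ttest_rel(x, y)
        out.append(
            GroupComparison(
                metric, "t_paired", float(t_res.statistic), float(t_res.pvalue),
                (float(x.size - 1),), transform,
            )
        )
    else:
        t_res = sps.ttest_ind(x, y, equal_var=not welch)
        df_t = (
            float(t_res.df) if hasattr(t_res, "df") else float(x.size + y.size - 2)
        )
        out.append(
            GroupComparison(
                metric, "t_independent", float(t_res.statistic), float(t_res.pvalue),
                (df_t,), transform,
            )
        )
    var_x = float(np.var(x, ddof=1))
    var_y = float(np.var(y, ddof=1))
    if var_x == 0.0 and var_y == 0.0:
        raise DegenerateDataError("both groups have zero variance; F-test undefined")
    f_stat = var_x / var_y if var_y > 0 else np.inf
    df1, df2 = float(x.size - 1), float(y.size - 1)
    if np.isfinite(f_stat):
        cdf = sps.f.cdf(f_stat, df1, df2)
        p_f = float(2.0 * min(cdf, 1.0 - cdf))
        p_f = min(p_f, 1.0)
    else:
        p_f = 0.0
    out.append(
        GroupComparison(metric, "F_variance", f_stat, p_f, (df1, df2), transform)
    )
    return out


def anova_tukey(
    groups: list[np.ndarray | list[float]],
    transform: str = "none",
    metric: str = "",
    labels: list[str] | None = None,
) -> list[GroupComparison]:
    """One-way ANOVA plus Tukey-Kramer pairwise post-tests (unequal n honored)."""
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA needs >= 2 groups")
    gs = [
        _apply_transform(np.asarray(g, dtype=float), transform, f"group {i}")
        for i, g in enumerate(groups)
    ]
    for i, g in enumerate(gs):
        if g.size < 2:
            raise DegenerateDataError(f"group {i} has n < 2")
    if all(np.ptp(g) == 0 for g in gs):
        if len({float(g[0]) for g in gs}) == 1:
            # identical constant groups: F is 0/0 by the sums of squares; report 0
            k = len(gs)
            n_total = sum(g.size for g in gs)
            return [
                GroupComparison(
                    metric, "anova_oneway", 0.0, 1.0,
                    (float(k - 1), float(n_total - k)), transform,
                )
            ]
        raise DegenerateDataError("within-group variance is zero; F undefined")
    names = labels or [f"group{i}" for i in range(len(gs))]
    f_stat, p = sps.f_oneway(*gs)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    out = [
        GroupComparison(
            metric, "anova_oneway", float(f_stat), float(p),
            (float(k - 1), float(n_total - k)), transform,
        )
    ]
    tk = sps.tukey_hsd(*gs)
    for i in range(k):
        for j in range(i + 1, k):
            out.append(
                GroupComparison(
                    metric, "tukey_kramer", float(tk.statistic[i, j]),
                    float(tk.pvalue[i, j]), (float(k), float(n_total - k)),
                    transform, label=f"{names[i]} vs {names[j]}",
                )
            )
    return out


def nrd(means_by_illuminant: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Normalized relative difference across illuminants for one metric.

    ``means_by_illuminant`` maps illuminant name -> (human_made_mean,
    natural_mean). Per illuminant k the relative difference
    (HM_k - Nat_k) / Nat_k is divided by the maximum relative difference
    over all illuminants, so max_k NRD_k = 1.
    """
    if not means_by_illuminant:
        raise DegenerateDataError("NRD needs at least one illuminant")
    rel = {}
    for k, (hm, nat) in means_by_illuminant.items():
        if nat == 0:
            raise DegenerateDataError(f"natural mean is zero for illuminant {k!r}")
        rel[k] = (hm - nat) / nat
    peak = max(rel.values())
    if peak <= 0:
        raise DegenerateDataError(
            "maximum relative difference is non-positive; NRD normalization undefined"
        )
    return {k: v / peak for k, v in rel.items()}
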