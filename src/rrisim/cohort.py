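"""Cohort-level statistics for similarity coefficients.

Two designs are supported, matching the two study questions:

* ``development`` — does each similarity coefficient (CC1, CC2, CLF, CHF)
  increase with embryonic day? Normality-gated correlation (Pearson when
  both variables pass a Shapiro-Wilk test at alpha = 0.05, Spearman
  otherwise) plus an omnibus comparison across stages with all pairwise
  contrasts.
* ``asd`` — do VPA-exposed fetuses differ from saline controls at each
  recorded stage? Normality-gated two-group comparison per embryonic day
  (one-way ANOVA when every group passes the gate, two-sample rank-sum
  otherwise).

The entry point is :class:`CohortModel`, built from a scores table with
one row per (mother, fetus, epoch); ``fit()`` returns a
:class:`CohortResults` carrying trend and comparison tables and a
``summary()``.

Caveat baked into the default design: fetuses sharing a mother and the
two epochs per fetus are treated as independent observations; an
``aggregate`` option averages within fetus or mother first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COEFFICIENTS = ("cc1", "cc2", "clf", "chf")
ALPHA = 0.05


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class GateResult:
    classification: str  # "normal" | "non_normal"
    w: float
    p: float


@dataclass(frozen=True)
class TrendResult:
    coefficient: str
    r: float
    p: float
    method: str  # "pearson" | "spearman"
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    coefficient: str
    groups: tuple
    statistic: float
    p: float
    method: str  # "anova" | "rank_sum" | "kruskal"
    n_per_group: tuple


def normality_gate(values, alpha: float = ALPHA) -> GateResult:
    """Shapiro-Wilk normality classification of one score sample."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise CohortError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise CohortError("insufficient variance: constant sample")
    w, p = stats.shapiro(x)
    return GateResult("normal" if p >= alpha else "non_normal",
                      float(w), float(p))


def _aggregate(table: pd.DataFrame, how: str) -> pd.DataFrame:
    if how == "none":
        return table
    if how == "epoch_mean":
        keys = ["mother_id", "fetus_id", "ed", "group"]
    elif how == "fetus_mean":
        keys = ["mother_id", "ed", "group"]
    else:
        raise CohortError(f"unknown aggregate mode {how!r}")
    return (table.groupby(keys, as_index=False)[list(COEFFICIENTS)]
            .mean())


def trend_with_age(table: pd.DataFrame, coefficient: str,
                   method: str | None = None, alpha: float = ALPHA,
                   aggregate: str = "none") -> TrendResult:
    """Correlation of one coefficient with embryonic day (numeric days).

    The parametric/nonparametric choice follows Shapiro-Wilk gates on both
    variables unless ``method`` forces one.
    """
    table = _aggregate(table, aggregate)
    if table["ed"].nunique() < 2:
        raise CohortError("degenerate design: a trend needs >= 2 ED levels")
    x = table["ed"].to_numpy(dtype=float)
    y = table[coefficient].to_numpy(dtype=float)
    if method is None:
        both_normal = all(
            normality_gate(v, alpha).classification == "normal"
            for v in (x, y))
        method = "pearson" if both_normal else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise CohortError(f"unknown method {method!r}")
    return TrendResult(coefficient, float(r), float(p), method, x.size)


def _gate_all_normal(samples, alpha: float) -> bool:
    try:
        return all(normality_gate(s, alpha).classification == "normal"
                   for s in samples)
    except CohortError:
        return False


def _two_group(a, b, parametric: bool):
    if parametric:
        stat, p = stats.f_oneway(a, b)
        return float(stat), float(p), "anova"
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p), "rank_sum"


def compare_groups(table: pd.DataFrame, coefficient: str,
                   design: str = "stagewise", alpha: float = ALPHA,
                   adjust: str | None = None,
                   aggregate: str = "none") -> list[ComparisonResult]:
    """Normality-gated group comparisons for one coefficient.

    ``stagewise``: omnibus over the ED levels plus all pairwise stage
    contrasts. ``saline_vs_vpa``: one saline-vs-VPA contrast per ED. If any
    group in a comparison fails the normality gate the nonparametric branch
    (rank-sum / Kruskal-Wallis) is used for that comparison. ``adjust``:
    None (default, mirrors unadjusted reporting) or "holm" on the pairwise
    contrasts.
    """
    table = _aggregate(table, aggregate)
    results: list[ComparisonResult] = []
    if design == "stagewise":
        eds = sorted(table["ed"].unique())
        samples = {ed: table.loc[table["ed"] == ed, coefficient].to_numpy()
                   for ed in eds}
        for ed, s in samples.items():
            if s.size < 3:
                raise CohortError(f"group ED{ed} has n={s.size} < 3")
        parametric = _gate_all_normal(samples.values(), alpha)
        if len(eds) > 2:
            if parametric:
                stat, p = stats.f_oneway(*samples.values())
                method = "anova"
            else:
                stat, p = stats.kruskal(*samples.values())
                method = "kruskal"
            results.append(ComparisonResult(
                coefficient, tuple(f"ED{e}" for e in eds), float(stat),
                float(p), method, tuple(s.size for s in samples.values())))
        pairwise = []
        for e1, e2 in itertools.combinations(eds, 2):
            par = _gate_all_normal((samples[e1], samples[e2]), alpha)
            stat, p, method = _two_group(samples[e1], samples[e2], par)
            pairwise.append(ComparisonResult(
                coefficient, (f"ED{e1}", f"ED{e2}"), stat, p, method,
                (samples[e1].size, samples[e2].size)))
        if adjust == "holm" and pairwise:
            order = np.argsort([c.p for c in pairwise])
            m = len(pairwise)
            adj = {}
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, min(1.0, (m - rank) * pairwise[i].p))
                adj[i] = running
            pairwise = [ComparisonResult(c.coefficient, c.groups, c.statistic,
                                         adj[i], c.method, c.n_per_group)
                        for i, c in enumerate(pairwise)]
        results.extend(pairwise)
    elif design == "saline_vs_vpa":
        for grp in ("saline", "vpa"):
            if grp not in set(table["group"]):
                raise CohortError(
                    f"group {grp!r} missing; present: {sorted(set(table['group']))}")
        for ed in sorted(table["ed"].unique()):
            sub = table[table["ed"] == ed]
            a = sub.loc[sub["group"] == "saline", coefficient].to_numpy()
            b = sub.loc[sub["group"] == "vpa", coefficient].to_numpy()
            if a.size < 3 or b.size < 3:
                raise CohortError(f"ED{ed}: each arm needs n >= 3")
            par = _gate_all_normal((a, b), alpha)
            stat, p, method = _two_group(a, b, par)
            results.append(ComparisonResult(
                coefficient, (f"saline_ED{ed}", f"vpa_ED{ed}"), stat, p,
                method, (a.size, b.size)))
    else:
        raise CohortError(f"unknown design {design!r}")
    return results


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"mother_id", "fetus_id", "epoch_index", "ed", "group",
                *COEFFICIENTS}
    missing = required - set(table.columns)
    if missing:
        raise CohortError(f"scores table missing columns: {sorted(missing)}")
    keys = table[["mother_id", "fetus_id", "epoch_index"]]
    if keys.duplicated().any():
        raise CohortError("duplicated (mother, fetus, epoch) keys")
    return table


class CohortModel:
    """Statistical model of similarity scores across a cohort.

    Parameters
    ----------
    table : DataFrame
        One row per (mother, fetus, epoch) with columns ``mother_id,
        fetus_id, epoch_index, ed, group, cc1, cc2, clf, chf``.
    aggregate : {"none", "epoch_mean", "fetus_mean"}
        Observation unit. Default treats every epoch row as independent.
    """

    def __init__(self, table: pd.DataFrame, aggregate: str = "none",
                 alpha: float = ALPHA):
        self.table = _validate_table(table.copy())
        self.aggregate = aggregate
        self.alpha = alpha

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CohortModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, design: str = "development") -> "CohortResults":
        """Run the full battery for one design.

        ``development``: per-coefficient trend with ED plus stagewise
        comparisons. ``asd``: per-coefficient saline-vs-VPA contrast at
        each ED.
        """
        trends, comparisons = [], []
        if design == "development":
            for coef in COEFFICIENTS:
                trends.append(trend_with_age(self.table, coef,
                                             alpha=self.alpha,
                                             aggregate=self.aggregate))
                comparisons.extend(compare_groups(
                    self.table, coef, design="stagewise", alpha=self.alpha,
                    aggregate=self.aggregate))
        elif design == "asd":
            for coef in COEFFICIENTS:
                comparisons.extend(compare_groups(
                    self.table, coef, design="saline_vs_vpa",
                    alpha=self.alpha, aggregate=self.aggregate))
        else:
            raise CohortError(f"unknown design {design!r}")
        return CohortResults(self, design, trends, comparisons)


class CohortResults:
    """Fitted trend and comparison tables with a text summary."""

    def __init__(self, model: CohortModel, design: str,
                 trends: list[TrendResult],
                 comparisons: list[ComparisonResult]):
        self.model = model
        self.design = design
        self._trends = trends
        self._comparisons = comparisons

    @property
    def trends(self) -> pd.DataFrame:
        return pd.DataFrame([{"coefficient": t.coefficient, "r": t.r,
                              "p": t.p, "method": t.method, "n": t.n}
                             for t in self._trends])

    @property
    def comparisons(self) -> pd.DataFrame:
        return pd.DataFrame([{"coefficient": c.coefficient,
                              "groups": " vs ".join(c.groups),
                              "statistic": c.statistic, "p": c.p,
                              "method": c.method,
                              "n": "/".join(map(str, c.n_per_group))}
                             for c in self._comparisons])

    def to_csv(self, path) -> None:
        frames = []
        if self._trends:
            t = self.trends.copy()
            t.insert(0, "test", "trend_with_age")
            t["groups"] = ""
            frames.append(t.rename(columns={"r": "statistic"}))
        if self._comparisons:
            c = self.comparisons.copy()
            c.insert(0, "test", "group_comparison")
            c.rename(columns={"n": "n_per_group"}, inplace=True)
            frames.append(c)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"Cohort similarity analysis — design: {self.design}",
                 f"observation unit: {self.model.aggregate}",
                 f"alpha: {self.model.alpha}", ""]
        if self._trends:
            lines.append("Trend with embryonic day")
            lines.append("-" * 52)
            lines.append(f"{'coef':<6}{'method':<10}{'r':>8}{'p':>12}{'n':>6}")
            for t in self._trends:
                lines.append(f"{t.coefficient:<6}{t.method:<10}"
                             f"{t.r:>8.3f}{t.p:>12.3g}{t.n:>6d}")
            lines.append("")
        if self._comparisons:
            width = max(20, max(len(" vs ".join(c.groups))
                                for c in self._comparisons) + 2)
            lines.append("Group comparisons")
            lines.append("-" * (width + 37))
            lines.append(f"{'coef':<6}{'groups':<{width}}{'method':<10}"
                         f"{'stat':>9}{'p':>12}")
            for c in self._comparisons:
                lines.append(f"{c.coefficient:<6}"
                             f"{' vs '.join(c.groups):<{width}}{c.method:<10}"
                             f"{c.statistic:>9.3f}{c.p:>12.3g}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<CohortResults design={self.design!r} "
                f"trends={len(self._trends)} "
                f"comparisons={len(self._comparisons)}>")
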