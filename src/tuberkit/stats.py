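"""Group statistics for tubercle morphometry.

Per-species summaries (mean, coefficient of variation, min, max per
variable), classical one-way ANOVA computed from sums of squares, Tukey
honest-significant-difference pairwise tests on the studentized-range
distribution (Tukey-Kramer for unbalanced designs), and a compact letter
display summarising the pairwise decisions.  The coefficient of variation
uses the sample (n-1) standard deviation, matching published summary
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measurement import MEASUREMENT_VARIABLES

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "GroupComparisonResults",
    "GroupComparison",
    "summarize_species",
    "anova_oneway",
    "tukey_hsd",
    "compact_letter_display",
    "pooled_group_stats",
    "pooled_mean_from_summaries",
    "cv_percent",
]


def cv_percent(values) -> float:
    """Coefficient of variation in percent (sample SD / mean * 100)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("CV requires at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m * 100.0)


def summarize_species(df: pd.DataFrame, variables=MEASUREMENT_VARIABLES) -> pd.DataFrame:
    """Per-species N, mean, CV%, min and max for each measured variable.

    ``df`` is a per-tubercle table with a ``species`` column; every species
    needs at least 2 tubercles for the CV.  The output has one row per
    species (input order preserved) with ``{var}_mean``/``_cv``/``_min``/
    ``_max`` columns, the shape of published species summary tables.
    """
    if "species" not in df.columns:
        raise ValueError("per-tubercle table needs a 'species' column")
    if df.empty:
        raise ValueError("empty per-tubercle table")
    rows = []
    for species, g in df.groupby("species", sort=False):
        if len(g) < 2:
            raise ValueError(f"species {species!r} has fewer than 2 tubercles")
        row = {"species": species, "n_tubercles": len(g)}
        if "seed_id" in g.columns:
            row["n_seeds"] = g["seed_id"].nunique()
        for lbl in ("type_label", "subgenus"):
            if lbl in g.columns and g[lbl].notna().any():
                row["type" if lbl == "type_label" else lbl] = g[lbl].dropna().iloc[0]
        for v in variables:
            vals = g[v].to_numpy(dtype=float)
            row[f"{v}_mean"] = vals.mean()
            row[f"{v}_cv"] = cv_percent(vals)
            row[f"{v}_min"] = vals.min()
            row[f"{v}_max"] = vals.max()
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


def _as_groups(groups) -> list[np.ndarray]:
    if isinstance(groups, dict):
        groups = list(groups.values())
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g in out:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 values")
    return out


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from explicit sums of squares.

    Degenerate case: when both the between- and within-group sums of squares
    vanish (all values identical) the convention F = 0, p = 1 is used.
    """
    gs = _as_groups(groups)
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = len(all_vals) - len(gs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w, 0.0, 0.0)
        return AnovaResult(np.inf, 0.0, df_b, df_w, float(ss_between), 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, float(ss_between), float(ss_within))


def anova_welch(groups) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA (optional alternative)."""
    gs = _as_groups(groups)
    k = len(gs)
    n = np.array([len(g) for g in gs])
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    w = n / v
    mw = (w * m).sum() / w.sum()
    F = ((w * (m - mw) ** 2).sum() / (k - 1)) / (
        1 + 2 * (k - 2) / (k**2 - 1) * ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    )
    df2 = (k**2 - 1) / (3 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum())
    p = float(sps.f.sf(F, k - 1, df2))
    return AnovaResult(float(F), p, k - 1, int(round(df2)), np.nan, np.nan)


@dataclass(frozen=True)
class TukeyResult:
    labels: tuple
    p_values: np.ndarray  # symmetric matrix
    significant: np.ndarray  # symmetric boolean matrix
    alpha: float

    def pairs(self):
        for i, j in combinations(range(len(self.labels)), 2):
            yield self.labels[i], self.labels[j], self.p_values[i, j], bool(self.significant[i, j])


def tukey_hsd(groups, alpha: float = 0.05, labels=None) -> TukeyResult:
    """All-pairs Tukey HSD using the studentized-range distribution.

    Unbalanced designs use the Tukey-Kramer standard error
    sqrt(MSW/2 * (1/n_i + 1/n_j)).
    """
    if isinstance(groups, dict) and labels is None:
        labels = tuple(groups.keys())
    gs = _as_groups(groups)
    if labels is None:
        labels = tuple(range(len(gs)))
    an = anova_oneway(gs)
    k = len(gs)
    p = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        if an.ms_within == 0.0:
            pij = 1.0 if gs[i].mean() == gs[j].mean() else 0.0
        else:
            se = np.sqrt(an.ms_within / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            q = abs(gs[i].mean() - gs[j].mean()) / se
            pij = float(sps.studentized_range.sf(q, k, an.df_within))
        p[i, j] = p[j, i] = pij
    np.fill_diagonal(p, 1.0)
    return TukeyResult(tuple(labels), p, p < alpha, alpha)


def compact_letter_display(significant: np.ndarray, means, labels=None) -> dict:
    """Minimal letter codes: two groups share a letter iff not significantly
    different (insertion-absorption algorithm).

    Letters are assigned in group-mean order: the letter containing the
    smallest mean is "a".  Returns ``{label: letters}``.
    """
    sig = np.asarray(significant, dtype=bool)
    k = sig.shape[0]
    if sig.shape != (k, k) or not np.array_equal(sig, sig.T):
        raise ValueError("significant must be a symmetric square matrix")
    means = np.asarray(means, dtype=float)
    if labels is None:
        labels = tuple(range(k))
    letters: list[set] = [set(range(k))]
    for i, j in combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for L in [L for L in letters if i in L and j in L]:
            letters.remove(L)
            letters.extend([L - {i}, L - {j}])
        # absorption: drop letters that are subsets of another
        letters = [L for L in letters if L and not any(L < M for M in letters if M is not L)]
    # deduplicate while preserving content
    uniq = []
    for L in letters:
        if L not in uniq:
            uniq.append(L)
    uniq.sort(key=lambda L: (min(means[list(L)]), sorted(L)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned = {lab: "" for lab in labels}
    for letter, L in zip(alphabet, uniq):
        for idx in sorted(L):
            assigned[labels[idx]] += letter
    # groups keep their letters sorted in display order
    return {lab: "".join(sorted(v)) for lab, v in assigned.items()}


@dataclass
class GroupComparisonResults:
    """Pooled per-group statistics plus ANOVA/Tukey decisions per variable."""

    grouping: str
    group_stats: pd.DataFrame  # one row per group: N + mean/cv/min/max per variable
    anova_table: pd.DataFrame  # one row per variable: F, p
    letters: pd.DataFrame  # groups x variables letter codes
    alpha: float

    def summary(self) -> str:
        lines = [
            f"Group comparison by {self.grouping!r} (alpha = {self.alpha})",
            "=" * 58,
        ]
        for v in self.anova_table.index:
            F, p = self.anova_table.loc[v, ["F", "p"]]
            lines.append(f"\n{v}: F = {F:.2f}, p = {p:.3g}")
            for g in self.group_stats.index:
                m = self.group_stats.loc[g, f"{v}_mean"]
                cv = self.group_stats.loc[g, f"{v}_cv"]
                lo = self.group_stats.loc[g, f"{v}_min"]
                hi = self.group_stats.loc[g, f"{v}_max"]
                let = self.letters.loc[g, v]
                lines.append(f"  {g:<28} {m:8.1f} {let:<4} ({cv:.1f})  {lo:.1f}/{hi:.1f}")
        return "\n".join(lines)

    def to_markdown(self) -> str:
        rows = ["| group | N | " + " | ".join(self.anova_table.index) + " |",
                "|---" * (2 + len(self.anova_table.index)) + "|"]
        for g in self.group_stats.index:
            cells = [str(g), str(int(self.group_stats.loc[g, "N"]))]
            for v in self.anova_table.index:
                m = self.group_stats.loc[g, f"{v}_mean"]
                cv = self.group_stats.loc[g, f"{v}_cv"]
                lo = self.group_stats.loc[g, f"{v}_min"]
                hi = self.group_stats.loc[g, f"{v}_max"]
                cells.append(f"{m:.1f} ^{self.letters.loc[g, v]}^ ({cv:.1f}) {lo:.1f}/{hi:.1f}")
            rows.append("| " + " | ".join(cells) + " |")
        return "\n".join(rows)


class GroupComparison:
    """Pooled comparison of measured variables between labelled groups.

    Statsmodels-style model object: construct from a per-tubercle table and a
    grouping column (for example seed type or subgenus), then ``fit()``.

    Parameters
    ----------
    data : DataFrame
        Per-tubercle table with the measurement variables and the grouping
        column; every record must be labelled.
    by : str
        Grouping column name.
    variables : sequence of str
        Variables to compare (defaults to the six standard measurements).
    alpha : float
    welch : bool
        Use Welch's heteroscedastic ANOVA instead of the classical one.
    """

    def __init__(self, data: pd.DataFrame, by: str, variables=MEASUREMENT_VARIABLES,
                 alpha: float = 0.05, welch: bool = False):
        if by not in data.columns:
            raise ValueError(f"grouping column {by!r} not in table")
        if data[by].isna().any():
            raise ValueError("unlabelled records in grouping column")
        missing = [v for v in variables if v not in data.columns]
        if missing:
            raise ValueError(f"missing variables: {missing}")
        self.data = data
        self.by = by
        self.variables = tuple(variables)
        self.alpha = float(alpha)
        self.welch = bool(welch)

    def fit(self) -> GroupComparisonResults:
        grouped = list(self.data.groupby(self.by, sort=False))
        names = [g for g, _ in grouped]
        stats_rows, anova_rows = [], []
        letters = pd.DataFrame(index=pd.Index(names, name=self.by), columns=self.variables, dtype=object)
        for g, sub in grouped:
            row = {"N": len(sub)}
            for v in self.variables:
                vals = sub[v].to_numpy(dtype=float)
                row[f"{v}_mean"] = vals.mean()
                row[f"{v}_cv"] = cv_percent(vals) if len(vals) > 1 else np.nan
                row[f"{v}_min"] = vals.min()
                row[f"{v}_max"] = vals.max()
            stats_rows.append(row)
        group_stats = pd.DataFrame(stats_rows, index=pd.Index(names, name=self.by))
        for v in self.variables:
            gs = [sub[v].to_numpy(dtype=float) for _, sub in grouped]
            if len(gs) >= 2:
                an = anova_welch(gs) if self.welch else anova_oneway(gs)
                anova_rows.append({"variable": v, "F": an.F, "p": an.p})
                tk = tukey_hsd(gs, alpha=self.alpha, labels=names)
                means = [g.mean() for g in gs]
                cld = compact_letter_display(tk.significant, means, labels=tuple(names))
                for g in names:
                    letters.loc[g, v] = cld[g]
            else:
                anova_rows.append({"variable": v, "F": np.nan, "p": np.nan})
                letters.loc[names[0], v] = ""
        anova_table = pd.DataFrame(anova_rows).set_index("variable")
        return GroupComparisonResults(self.by, group_stats, anova_table, letters, self.alpha)


def pooled_group_stats(records: pd.DataFrame, grouping: str, **kwargs) -> GroupComparisonResults:
    """Functional wrapper over :class:`GroupComparison`."""
    return GroupComparison(records, by=grouping, **kwargs).fit()


def pooled_mean_from_summaries(summary: pd.DataFrame, variable: str,
                               n_col: str = "n_tubercles") -> float:
    """Tubercle-count-weighted pooled mean from per-species (mean, N) rows.

    Equals the mean over raw records exactly when the summary means come from
    those records.
    """
    return float(np.average(summary[f"{variable}_mean"], weights=summary[n_col]))
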