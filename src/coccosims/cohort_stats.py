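"""Sample-level statistics for per-coccolith El/Ca tables.

Covers the cohort-level questions asked of single-coccolith data:

* how much of the spread is measurement (within-lith residual depth CV)
  versus real heterogeneity among coccoliths of one sample;
* which samples differ (one-way ANOVA on log-ratios with Tukey HSD
  post-hoc tests and a compact letter display);
* whether log-ratios track environmental covariates (Pearson correlations);
* culture growth rates from log-transformed cell densities.

Ion-count ratios are right-skewed, so all inferential statistics use the
natural log of the ratio (the base cancels in F, r and CV; natural log keeps
growth rates in d^-1).  Per-lith values enter unweighted by their precision.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


class CohortStatsError(Exception):
    pass


def ratio_column(element: str) -> str:
    return f"ratio_{element.lower()}"


def precision_column(element: str) -> str:
    return f"precision_cv_{element.lower()}"


def _log_ratios(table: pd.DataFrame, element: str) -> pd.DataFrame:
    """Rows with positive ratios, plus their natural logs; zeros are dropped."""
    col = ratio_column(element)
    if col not in table.columns:
        raise CohortStatsError(f"table lacks column {col}")
    sub = table[np.isfinite(table[col]) & (table[col] > 0)].copy()
    sub["_log_ratio"] = np.log(sub[col])
    return sub


# ---------------------------------------------------------------------------
# CV decomposition


def cv_decomposition(table: pd.DataFrame, element: str, group: str,
                     group_col: str = "sample_id") -> dict:
    """Within-lith vs among-lith variability for one sample.

    ``within_lith_cvs`` are the per-coccolith residual depth CVs (precision,
    passed through from depth QC); ``among_lith_cv`` is the n-1 CV of the
    per-coccolith ratios in the group.  ``among_exceeds_one`` flags samples
    whose among-lith CV exceeds 1 (conventionally not displayed).
    """
    sub = table[table[group_col] == group]
    if len(sub) < 2:
        raise CohortStatsError(f"group {group!r} has fewer than 2 coccoliths")
    ratios = sub[ratio_column(element)].to_numpy(dtype=float)
    mean = ratios.mean()
    among = float(ratios.std(ddof=1) / mean) if mean > 0 else float("inf")
    pcol = precision_column(element)
    within = sub[pcol].to_numpy(dtype=float) if pcol in sub.columns else np.array([])
    return {
        "within_lith_cvs": within,
        "among_lith_cv": among,
        "among_exceeds_one": among > 1.0,
        "n": len(sub),
    }


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD + compact letter display


@dataclass
class TukeyGrouping:
    """ANOVA/Tukey verdict: group means, all pairwise adjusted p, letters."""

    element: str
    alpha: float
    groups: list[str]
    n: dict[str, int]
    log_means: dict[str, float]
    anova_f: float
    anova_p: float
    pairs: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, significant
    letters: dict[str, str]
    warning: str = ""
    n_zero_excluded: int = 0

    def share_letter(self, g1: str, g2: str) -> bool:
        return bool(set(self.letters[g1]) & set(self.letters[g2]))


def _compact_letter_display(groups: list[str], sig_pairs: set[tuple[str, str]],
                            order: list[str]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; the letter count
    is kept minimal by absorbing subset columns.  ``order`` fixes letter
    assignment (first group of a column by that order gets the earlier
    letter), making the partition independent of input ordering.
    """
    columns: list[set[str]] = [set(groups)]
    for g1, g2 in sorted(sig_pairs):
        new_columns: list[set[str]] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop duplicates and strict subsets
        absorbed: list[set[str]] = []
        for col in new_columns:
            if any(col < other for other in new_columns):
                continue
            if col and col not in absorbed:
                absorbed.append(col)
        columns = absorbed
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = string.ascii_lowercase
    letters: dict[str, str] = {g: "" for g in groups}
    for i, col in enumerate(columns):
        sym = alphabet[i] if i < len(alphabet) else f"z{i}"
        for g in col:
            letters[g] += sym
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def tukey_pairwise_p(mean_diff: float, mse: float, n1: int, n2: int,
                     k: int, df: int) -> float:
    """Tukey(-Kramer) adjusted p for one pair from the studentized range.

    ``q = |diff| / sqrt((MSE / 2) (1/n1 + 1/n2))`` referred to the
    studentized-range distribution with ``k`` groups and ``df`` error
    degrees of freedom.
    """
    se = np.sqrt((mse / 2.0) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 1.0 if mean_diff == 0 else 0.0
    q = abs(mean_diff) / se
    return float(stats.studentized_range.sf(q, k, df))


def anova_tukey(table: pd.DataFrame, element: str, alpha: float = DEFAULT_ALPHA,
                group_col: str = "sample_id") -> TukeyGrouping:
    """One-way ANOVA on log-ratios with Tukey HSD letters.

    Unequal group sizes use the Tukey-Kramer standard error.  A degenerate
    table (zero within-group variance everywhere) yields exact-separation
    letters with a warning instead of failing.
    """
    sub = _log_ratios(table, element)
    n_zero = len(table) - len(sub)
    groups = sorted(sub[group_col].unique())
    if len(groups) < 2:
        raise CohortStatsError("need at least 2 groups")
    samples = {g: sub.loc[sub[group_col] == g, "_log_ratio"].to_numpy() for g in groups}
    if any(len(v) < 2 for v in samples.values()):
        raise CohortStatsError("every group needs at least 2 coccoliths")

    k = len(groups)
    n = {g: len(samples[g]) for g in groups}
    log_means = {g: float(samples[g].mean()) for g in groups}
    n_total = sum(n.values())
    df_err = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in samples.values())
    mse = sse / df_err
    grand = sum(v.sum() for v in samples.values()) / n_total
    ssb = sum(n[g] * (log_means[g] - grand) ** 2 for g in groups)

    warning = ""
    if mse == 0:
        warning = "zero within-group variance; exact-separation letters"
        anova_f, anova_p = float("inf"), 0.0
    else:
        anova_f = (ssb / (k - 1)) / mse
        anova_p = float(stats.f.sf(anova_f, k - 1, df_err))

    rows = []
    sig_pairs: set[tuple[str, str]] = set()
    for g1, g2 in combinations(groups, 2):
        diff = log_means[g1] - log_means[g2]
        p = tukey_pairwise_p(diff, mse, n[g1], n[g2], k, df_err)
        sig = p < alpha
        if sig:
            sig_pairs.add((g1, g2))
        rows.append({"group1": g1, "group2": g2, "mean_diff": diff,
                     "p_adj": p, "significant": sig})
    order = sorted(groups, key=lambda g: -log_means[g])
    letters = _compact_letter_display(groups, sig_pairs, order)
    return TukeyGrouping(
        element=element, alpha=alpha, groups=groups, n=n, log_means=log_means,
        anova_f=float(anova_f), anova_p=float(anova_p),
        pairs=pd.DataFrame(rows), letters=letters, warning=warning,
        n_zero_excluded=n_zero,
    )


# ---------------------------------------------------------------------------
# correlations


def correlation_matrix(
    table: pd.DataFrame,
    elements: list[str],
    covariate_table: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    group_col: str = "sample_id",
) -> pd.DataFrame:
    """Pearson correlations of log-ratios against per-sample covariates.

    Covariates are constant within a sample and are mapped onto individual
    coccoliths through ``group_col``, so the effective replication is at the
    coccolith level (as in per-lith scatter plots); interpret p-values with
    that caveat.  No multiple-testing adjustment is applied.  Returns a
    long-form frame with one row per (element, covariate) cell.
    """
    if covariates is None:
        covariates = [c for c in covariate_table.columns if c != group_col]
    cov = covariate_table.set_index(group_col) if group_col in covariate_table.columns else covariate_table
    rows = []
    for element in elements:
        sub = _log_ratios(table, element)
        missing = set(sub[group_col]) - set(cov.index)
        if missing:
            raise CohortStatsError(f"covariate table lacks groups: {sorted(missing)}")
        for covariate in covariates:
            x = sub["_log_ratio"].to_numpy()
            y = cov.loc[sub[group_col], covariate].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3:
                raise CohortStatsError(
                    f"fewer than 3 complete pairs for {element} vs {covariate}"
                )
            r, p = stats.pearsonr(x[keep], y[keep])
            rows.append({
                "element": element, "covariate": covariate,
                "r": float(r), "p": float(p), "n": int(keep.sum()),
                "significant": bool(p < alpha),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# culture growth rates


@dataclass
class GrowthRate:
    """Exponential-phase specific growth rate from a cell-density series."""

    mu_per_day: float
    r_squared: float
    stderr: float
    intercept: float


def growth_rate(times_days, cell_densities) -> GrowthRate:
    """OLS slope of ln(cell density) on time: the specific growth rate (d^-1)."""
    t = np.asarray(times_days, dtype=float)
    d = np.asarray(cell_densities, dtype=float)
    if t.size < 3:
        raise CohortStatsError("need at least 3 time points")
    if np.any(d <= 0):
        raise CohortStatsError("cell densities must be > 0")
    fit = stats.linregress(t, np.log(d))
    return GrowthRate(
        mu_per_day=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
    )


# ---------------------------------------------------------------------------
# per-sample summary (publication-style layout)


def summarize_samples(
    table: pd.DataFrame,
    elements: list[str],
    alpha: float = DEFAULT_ALPHA,
    group_col: str = "sample_id",
) -> pd.DataFrame:
    """Per-sample mean +/- SE of raw ion-count ratios with Tukey letters.

    One row per sample; per element: mean, SE (raw scale), and the compact
    letter from the log-scale Tukey test when >= 2 groups are present.
    """
    groups = sorted(table[group_col].unique())
    out = pd.DataFrame({group_col: groups}).set_index(group_col)
    out["n"] = table.groupby(group_col).size()
    for element in elements:
        col = ratio_column(element)
        if col not in table.columns:
            continue
        grp = table.groupby(group_col)[col]
        out[f"{element.lower()}_mean"] = grp.mean()
        out[f"{element.lower()}_se"] = grp.std(ddof=1) / np.sqrt(grp.size())
        if len(groups) >= 2 and all(table.groupby(group_col).size() >= 2):
            try:
                tukey = anova_tukey(table, element, alpha=alpha, group_col=group_col)
                out[f"{element.lower()}_letters"] = pd.Series(tukey.letters)
            except CohortStatsError:
                pass
    return out.reset_index()
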