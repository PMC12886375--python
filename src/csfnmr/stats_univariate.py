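"""Normalization, scaling and the univariate test battery.

The metabolite table is normalized to total area per sample, then
Pareto-scaled (centre each metabolite, divide by the square root of its
standard deviation) to temper the dominance of high-abundance signals
without fully flattening the variance structure.

Each metabolite is then assessed with both the non-parametric family
(Kruskal-Wallis across groups, pairwise two-sided Wilcoxon rank-sum)
and the parametric one (one-way ANOVA with Tukey HSD post hoc), with
Benjamini-Hochberg FDR correction applied across metabolites within
each test family.  Shapiro-Wilk normality p-values are reported but do
not gate which family runs: both always do.  Effect directions (up /
down arrows) are assigned from the sign of the pairwise difference when
the pair's adjusted p-value clears the declared alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binning import MetaboliteTable
from .errors import DegenerateSampleError, InvalidParameterError, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ProcessedMatrix:
    """Samples x metabolites values after declared transforms."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    normalized: bool = False
    pareto_scaled: bool = False


def normalize_total_area(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample row by its total area (row sum)."""
    sums = table.values.sum(axis=1)
    bad = sums[sums <= 0]
    if len(bad):
        raise DegenerateSampleError(
            f"non-positive total area for sample(s) {list(bad.index)}")
    values = table.values.div(sums, axis=0)
    return MetaboliteTable(values=values, provenance=dict(table.provenance),
                           sample_meta=table.sample_meta.copy())


def pareto_scale(values: pd.DataFrame,
                 sample_meta: pd.DataFrame | None = None,
                 normalized: bool = False) -> ProcessedMatrix:
    """Centre each column and divide by sqrt(sample SD, n-1 denominator).

    Zero-variance columns are mapped to all-zero with a warning.
    """
    if values.shape[0] < 2:
        raise ValidationError("Pareto scaling needs >= 2 samples")
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        log.warning("zero-variance columns mapped to zero: %s",
                    list(values.columns[zero]))
    denom = np.where(zero, 1.0, np.sqrt(sd))
    scaled = (x - mean) / denom
    scaled[:, zero] = 0.0
    out = pd.DataFrame(scaled, index=values.index, columns=values.columns)
    meta = sample_meta.copy() if sample_meta is not None else pd.DataFrame(
        {"sample_id": values.index})
    return ProcessedMatrix(values=out, sample_meta=meta,
                           normalized=normalized, pareto_scaled=True)


def preprocess(table: MetaboliteTable) -> ProcessedMatrix:
    """Total-area normalization followed by Pareto scaling."""
    norm = normalize_total_area(table)
    return pareto_scale(norm.values, norm.sample_meta, normalized=True)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q(i) = min_{j>=i} p(j) * m / j over the ascending-sorted p-values,
    clipped to 1 and mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InvalidParameterError("p-values must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# test battery
# ---------------------------------------------------------------------------

@dataclass
class UnivariateResults:
    """Per-metabolite omnibus tests and per-pair post hoc results.

    ``table``: shapiro_p, kruskal_h/p/fdr, anova_f/p/fdr per metabolite.
    ``pairwise``: (group_a, group_b) -> DataFrame with Wilcoxon rank-sum
    (u_statistic, p, fdr, direction) and Tukey HSD (tukey_diff, tukey_p,
    tukey_direction) columns; directions describe group_b relative to
    group_a ("up" = elevated in group_b).
    """

    table: pd.DataFrame
    pairwise: dict = field(default_factory=dict)
    alpha: float = 0.05

    def significant(self, family: str = "kruskal", alpha: float | None = None):
        a = self.alpha if alpha is None else alpha
        col = {"kruskal": "kruskal_fdr", "anova": "anova_fdr"}[family]
        return list(self.table.loc[self.table[col] < a, "metabolite"])

    def to_files(self, csv_path, json_path=None) -> None:
        wide = self.table.copy()
        for (a, b), df in self.pairwise.items():
            tag = f"{a}_vs_{b}"
            sub = df.rename(columns={
                "u_statistic": f"u_{tag}", "p": f"wilcoxon_p_{tag}",
                "fdr": f"wilcoxon_fdr_{tag}", "direction": f"direction_{tag}",
                "tukey_diff": f"tukey_diff_{tag}", "tukey_p": f"tukey_p_{tag}",
                "tukey_direction": f"tukey_direction_{tag}"})
            wide = wide.merge(sub, on="metabolite")
        with open(csv_path, "w") as fh:
            fh.write("# csfnmr univariate results; dialect: csv\n")
            wide.to_csv(fh, index=False)
        if json_path is not None:
            import json
            payload = {
                "alpha": self.alpha,
                "table": self.table.to_dict(orient="records"),
                "pairwise": {f"{a}|{b}": df.to_dict(orient="records")
                             for (a, b), df in self.pairwise.items()},
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def _kruskal(groups: list[np.ndarray]) -> tuple[float, float]:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0   # no separation at all; tie correction degenerate
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact when small and tie-free."""
    tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
    if tie_free and max(x.size, y.size) <= 10:
        method = "exact"
    else:
        method = "asymptotic"  # normal approximation, tie + continuity corr.
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def univariate_battery(matrix: ProcessedMatrix, alpha: float = 0.05,
                       groups: pd.Series | None = None) -> UnivariateResults:
    """Run the full univariate battery over every metabolite column.

    ``groups`` defaults to the ``group`` column of the matrix metadata.
    BH-FDR is applied within each test family across metabolites (and,
    for pairwise tests, within each comparison).
    """
    values = matrix.values
    if groups is None:
        groups = matrix.sample_meta.set_index("sample_id")["group"]
    groups = groups.loc[values.index]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    counts = groups.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"groups with < 2 samples: {dict(small)}")

    idx = {g: (groups == g).to_numpy() for g in labels}
    mets = list(values.columns)
    x = values.to_numpy(dtype=float)

    shapiro_p, kw_h, kw_p, an_f, an_p = [], [], [], [], []
    tukey_res = []
    for j in range(x.shape[1]):
        col = x[:, j]
        per_group = [col[idx[g]] for g in labels]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                shapiro_p.append(float(stats.shapiro(col).pvalue))
            except ValueError:
                shapiro_p.append(np.nan)
            h, p = _kruskal(per_group)
            kw_h.append(h)
            kw_p.append(p)
            if np.all(col == col[0]):
                an_f.append(0.0)
                an_p.append(1.0)
                tukey_res.append(None)
            else:
                f, pa = stats.f_oneway(*per_group)
                an_f.append(float(f) if np.isfinite(f) else np.inf)
                an_p.append(float(pa) if np.isfinite(pa) else 0.0)
                tukey_res.append(stats.tukey_hsd(*per_group))

    table = pd.DataFrame({
        "metabolite": mets,
        "shapiro_p": shapiro_p,
        "kruskal_h": kw_h,
        "kruskal_p": kw_p,
        "kruskal_fdr": bh_fdr(kw_p),
        "anova_f": an_f,
        "anova_p": an_p,
        "anova_fdr": bh_fdr(an_p),
    })

    pairwise = {}
    pairs = [(labels[i], labels[j]) for i in range(len(labels))
             for j in range(i + 1, len(labels))]
    for a, b in pairs:
        ia, ib = labels.index(a), labels.index(b)
        u_stat, wp, tk_diff, tk_p = [], [], [], []
        for j in range(x.shape[1]):
            xa, xb = x[idx[a], j], x[idx[b], j]
            u, p = _mannwhitney(xa, xb)
            u_stat.append(u)
            wp.append(p)
            res = tukey_res[j]
            if res is None:
                tk_diff.append(0.0)
                tk_p.append(1.0)
            else:
                # statistic[i, j] = mean_i - mean_j
                tk_diff.append(float(res.statistic[ib, ia]))  # b minus a
                tk_p.append(float(res.pvalue[ib, ia]))
        wq = bh_fdr(wp)
        direction = []
        for j in range(x.shape[1]):
            med_diff = np.median(x[idx[b], j]) - np.median(x[idx[a], j])
            if wq[j] < alpha and med_diff != 0:
                direction.append("up" if med_diff > 0 else "down")
            else:
                direction.append("ns")
        tukey_dir = ["up" if (p < alpha and d > 0)
                     else "down" if (p < alpha and d < 0) else "ns"
                     for d, p in zip(tk_diff, tk_p)]
        pairwise[(a, b)] = pd.DataFrame({
            "metabolite": mets,
            "u_statistic": u_stat,
            "p": wp,
            "fdr": wq,
            "direction": direction,
            "tukey_diff": tk_diff,
            "tukey_p": tk_p,
            "tukey_direction": tukey_dir,
        })
    return UnivariateResults(table=table, pairwise=pairwise, alpha=alpha)
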