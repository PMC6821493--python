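"""Statistical layer for pattern time courses and group comparisons.

Pattern occurrence frequencies are compared pairwise between conditions with
a pooled two-proportion z-test at each time point; study design is assessed
with the analytic power of that test. Scalar readouts (e.g. relative IL-2
mRNA) are log-transformed before ANOVA, after single-pass Chauvenet outlier
rejection. Sensor-by-(pattern, time) frequency matrices are compared across
sensors with hierarchical clustering on correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ProportionComparison",
    "ClusterResult",
    "proportion_z_test",
    "power_two_proportions",
    "chauvenet_outliers",
    "log_group_compare",
    "log_group_compare_twoway",
    "cluster_sensors",
]


@dataclass
class ProportionComparison:
    x1: int
    n1: int
    x2: int
    n2: int
    z: float
    p: float


def proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> ProportionComparison:
    """Pooled two-proportion z-test, two-sided.

    The statistic is (p̂1 − p̂2) / sqrt(p̄(1 − p̄)(1/n1 + 1/n2)) with p̄ the
    pooled proportion. A degenerate pooled proportion of 0 or 1 carries no
    information about a difference; z is defined as 0 and p as 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n, n >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return ProportionComparison(x1, n1, x2, n2, z=0.0, p=1.0)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ProportionComparison(x1, n1, x2, n2, z=float(z), p=float(min(p, 1.0)))


def power_two_proportions(
    p1: float,
    p2: float,
    n_per_group: int,
    alpha: float = 0.05,
    method: str = "analytic",
    n_reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Power of the two-sided pooled two-proportion z-test.

    ``method='analytic'`` uses the normal approximation: the null rejection
    boundary uses the pooled standard error, the alternative distribution the
    unpooled one. ``method='simulation'`` estimates power by Monte-Carlo with
    ``n_reps`` binomial replicates.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    n = n_per_group
    if method == "analytic":
        pbar = 0.5 * (p1 + p2)
        se0 = np.sqrt(2.0 * pbar * (1.0 - pbar) / n)
        se1 = np.sqrt(p1 * (1.0 - p1) / n + p2 * (1.0 - p2) / n)
        zcrit = sps.norm.isf(alpha / 2.0)
        delta = abs(p1 - p2)
        power = sps.norm.cdf((delta - zcrit * se0) / se1) + sps.norm.cdf(
            (-delta - zcrit * se0) / se1
        )
        return float(power)
    if method == "simulation":
        rng = np.random.default_rng(seed)
        x1 = rng.binomial(n, p1, size=n_reps)
        x2 = rng.binomial(n, p2, size=n_reps)
        pooled = (x1 + x2) / (2.0 * n)
        se = np.sqrt(pooled * (1.0 - pooled) * (2.0 / n))
        ok = (pooled > 0) & (pooled < 1)
        z = np.zeros(n_reps)
        z[ok] = (x1[ok] - x2[ok]) / n / se[ok]
        pvals = 2.0 * sps.norm.sf(np.abs(z))
        return float(np.mean(pvals < alpha))
    raise ValueError(f"unknown method {method!r}")


def chauvenet_outliers(values) -> np.ndarray:
    """Indices rejected by Chauvenet's criterion (single pass, normal model).

    Value i is rejected iff n · P(|Z| ≥ |vᵢ − mean| / sd) < 0.5, with mean
    and sample standard deviation computed once from all values. A zero
    standard deviation rejects nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    z = np.abs(v - v.mean()) / sd
    tail = 2.0 * sps.norm.sf(z)
    return np.flatnonzero(v.size * tail < 0.5)


@dataclass
class GroupComparison:
    F: float
    p: float
    posthoc: pd.DataFrame
    anova_table: pd.DataFrame | None = None


def _check_positive(groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        if np.any(a <= 0):
            raise ValueError("all values must be positive for log transform")
        out.append(a)
    return out


def log_group_compare(groups, labels=None) -> GroupComparison:
    """Natural-log transform then one-way ANOVA with Tukey HSD post-hoc.

    ``groups`` is a sequence of 1-D arrays of positive values. Returns the
    ANOVA F and p plus the Tukey pairwise table on the log scale.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    arrays = _check_positive(groups)
    logs = [np.log(a) for a in arrays]
    F, p = sps.f_oneway(*logs)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    values = np.concatenate(logs)
    codes = np.concatenate([[lab] * len(a) for lab, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, codes)
    posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return GroupComparison(F=float(F), p=float(p), posthoc=posthoc)


def log_group_compare_twoway(table: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> GroupComparison:
    """Natural-log transform then two-way ANOVA with Sidak-adjusted pairwise tests.

    ``table`` is long-format with one positive measurement per row. The ANOVA
    is type-II with interaction; pairwise comparisons between levels of
    ``factor_a`` are run within each level of ``factor_b`` (Welch t-tests) and
    Sidak-adjusted.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multitest import multipletests

    df = table.copy()
    if np.any(df[value].to_numpy(dtype=float) <= 0):
        raise ValueError("all values must be positive for log transform")
    df["_logv"] = np.log(df[value].astype(float))
    df = df.rename(columns={factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_logv ~ C(_fa) * C(_fb)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = []
    for bl, sub in df.groupby("_fb", sort=True):
        levels = sorted(sub["_fa"].unique())
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                g1 = sub.loc[sub["_fa"] == levels[i], "_logv"]
                g2 = sub.loc[sub["_fa"] == levels[j], "_logv"]
                t, pr = sps.ttest_ind(g1, g2, equal_var=False)
                rows.append({"within": bl, "level1": levels[i], "level2": levels[j], "t": t, "p_raw": pr})
    posthoc = pd.DataFrame(rows)
    if len(posthoc):
        posthoc["p_sidak"] = multipletests(posthoc["p_raw"], method="sidak")[1]
    f_row = anova.loc["C(_fa)"]
    return GroupComparison(
        F=float(f_row["F"]), p=float(f_row["PR(>F)"]), posthoc=posthoc, anova_table=anova
    )


@dataclass
class ClusterResult:
    """Hierarchical clustering of sensors by their pattern-frequency profiles."""

    distance: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    flagged_constant: list[str] = field(default_factory=list)
    flagged_missing: bool = False

    def newick(self) -> str:
        """Newick string of the (ultrametric) average-linkage tree."""
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.distance.index)

        def rec(node, parent_height):
            blen = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{blen / 2:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{blen / 2:.6g}"

        return rec(tree, tree.dist) + ";"


def cluster_sensors(freq_matrix: pd.DataFrame) -> ClusterResult:
    """Cluster sensors (rows) on 1 − Pearson correlation, average linkage.

    Missing cells are imputed as 0 and flagged. A constant row has no defined
    correlation; its distance to every other row is set to the maximum (1)
    and the row is flagged. Leaf order is deterministic (scipy's ordering;
    ties resolved by input row order).
    """
    if freq_matrix.shape[0] < 2:
        raise ValueError("need at least 2 sensors to cluster")
    mat = freq_matrix.astype(float)
    flagged_missing = bool(mat.isna().any().any())
    mat = mat.fillna(0.0)
    x = mat.to_numpy()
    sd = x.std(axis=1)
    constant = sd == 0
    corr = np.ones((len(x), len(x)))
    ok = ~constant
    if ok.sum() >= 2:
        corr_ok = np.corrcoef(x[ok])
        corr[np.ix_(ok, ok)] = corr_ok
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    names = list(mat.index)
    return ClusterResult(
        distance=pd.DataFrame(dist, index=names, columns=names),
        linkage=Z,
        leaf_order=[names[i] for i in order],
        flagged_constant=[names[i] for i in np.flatnonzero(constant)],
        flagged_missing=flagged_missing,
    )
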