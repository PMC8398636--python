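"""Differential node and edge statistics for two-group comparisons.

Node-level: per-lipid log fold changes (difference of group means on the
stored, typically log-transformed, scale), two-sided hypothesis tests
(Welch's t-test or a rank test) and Benjamini–Hochberg false discovery
rates.

Edge-level: per-group (partial) correlations with BH-adjusted
significance, and a discrete classification of how each edge's
correlation changed between the two groups:

==========================  =================================================
category                    meaning (sig := FDR < alpha)
==========================  =================================================
UNCHANGED_INSIGNIFICANT     not significant in either group
UNCHANGED_SIGNIFICANT       significant in both groups, same sign
TURNED_SIGNIFICANT          significant only in the second group
TURNED_INSIGNIFICANT        significant only in the first group
SIGN_CHANGE                 significant in both groups, opposite signs
==========================  =================================================

The five categories are exhaustive and mutually exclusive over all
(significance in group 1, significance in group 2, sign agreement)
outcomes: the sign of an insignificant correlation is treated as noise,
so a sign flip with one side insignificant falls into the turned
categories.

Partial correlations condition each pair on all other lipids.  Because
the number of lipids typically exceeds the number of samples, the
covariance matrix is shrunk (Ledoit–Wolf) before inversion and the
significance is an approximation (Fisher z with a reduced effective
sample size); results carry an ``approximate`` flag.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

from .network_builder import LipidNetwork, topology_metrics

__all__ = [
    "AbundanceTable",
    "TestMethod",
    "CorrelationMethod",
    "ChangeCategory",
    "log_fold_change",
    "differential_test",
    "group_correlations",
    "classify_edge_change",
    "annotate_network",
]


class TestMethod(enum.Enum):
    T_TEST = "ttest"
    RANK_TEST = "rank"


class CorrelationMethod(enum.Enum):
    PEARSON = "pearson"
    SPEARMAN = "spearman"


class ChangeCategory(enum.Enum):
    UNCHANGED_INSIGNIFICANT = "unchanged_insignificant"
    UNCHANGED_SIGNIFICANT = "unchanged_significant"
    TURNED_SIGNIFICANT = "turned_significant"
    TURNED_INSIGNIFICANT = "turned_insignificant"
    SIGN_CHANGE = "sign_change"


@dataclass
class AbundanceTable:
    """Samples × lipids abundance matrix with group labels.

    ``data`` has samples as rows (index = sample ids) and canonical
    lipid names as columns.  Values are assumed pre-processed (sample
    normalization, transformation); no pre-processing happens here.
    Missing values are permitted and excluded pairwise downstream.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate lipid names: {dup}")
        self.groups = pd.Series(self.groups)
        missing = self.data.index.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without group label: {missing.tolist()}")
        self.groups = self.groups.loc[self.data.index]

    @property
    def sample_ids(self) -> List[str]:
        return self.data.index.tolist()

    @property
    def lipid_names(self) -> List[str]:
        return self.data.columns.tolist()

    @property
    def group_labels(self) -> List[str]:
        return sorted(map(str, self.groups.unique()))

    def group_data(self, group: str) -> pd.DataFrame:
        mask = self.groups.astype(str) == str(group)
        if not mask.any():
            raise ValueError(
                f"unknown group {group!r}; valid groups: {self.group_labels}"
            )
        return self.data.loc[mask]


def log_fold_change(
    table: AbundanceTable, group_a: str, group_b: str
) -> pd.Series:
    """Per-lipid difference of group means, ``mean(a) − mean(b)``.

    On log-transformed input this is the log fold change.  Missing
    values are excluded per lipid; a lipid with no observations in
    either group gets NaN.  Antisymmetric under swapping the groups.
    """
    a = table.group_data(group_a)
    b = table.group_data(group_b)
    if a.empty or b.empty:
        raise ValueError("both groups need at least one sample")
    return a.mean(axis=0, skipna=True) - b.mean(axis=0, skipna=True)


def _bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini–Hochberg adjustment; NaN p-values are excluded from the
    family and stay NaN."""
    fdr = pd.Series(np.nan, index=p.index, dtype=float)
    mask = p.notna()
    if mask.any():
        fdr.loc[mask] = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
    return fdr


def differential_test(
    table: AbundanceTable,
    group_a: str,
    group_b: str,
    method: TestMethod = TestMethod.T_TEST,
    paired: bool = False,
) -> pd.DataFrame:
    """Two-sided per-lipid test between two groups, with BH-FDR.

    ``T_TEST`` is Welch's unequal-variance t-test.  ``RANK_TEST`` is the
    Mann–Whitney rank-sum test for independent groups, or the Wilcoxon
    signed-rank test when ``paired=True`` (requires equal group sizes in
    matching sample order).  Lipids with zero variance in both groups
    under the t-test get a missing p-value and are excluded from the
    BH family.

    Returns a DataFrame indexed by lipid with columns ``p_value`` and
    ``fdr``.
    """
    a = table.group_data(group_a)
    b = table.group_data(group_b)
    if method is TestMethod.T_TEST and (len(a) < 2 or len(b) < 2):
        raise ValueError("t-test requires at least two samples per group")

    p_values = pd.Series(np.nan, index=table.data.columns, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for lipid in table.data.columns:
            xa = a[lipid].dropna().to_numpy()
            xb = b[lipid].dropna().to_numpy()
            if len(xa) == 0 or len(xb) == 0:
                continue
            if method is TestMethod.T_TEST:
                if np.var(xa) == 0 and np.var(xb) == 0:
                    continue  # flagged missing, excluded from BH
                p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
            elif paired:
                if len(xa) != len(xb):
                    raise ValueError("paired test requires equal group sizes")
                diff = xa - xb
                if np.all(diff == 0):
                    continue
                p = stats.wilcoxon(xa, xb).pvalue
            else:
                p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            p_values[lipid] = p

    return pd.DataFrame({"p_value": p_values, "fdr": _bh_adjust(p_values)})


def _pairwise_correlation(
    data: pd.DataFrame, method: CorrelationMethod
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full correlation matrix with t-distributed p-values (df = n−2).

    Pairwise-complete observations; pairs with fewer than three complete
    observations (or a constant lipid) get NaN.
    """
    r = data.corr(method=method.value, min_periods=3)
    notna = data.notna().astype(float)
    n_pair = notna.T @ notna
    df = n_pair - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r_clipped = r.clip(-0.9999999, 0.9999999)
        t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
    p = pd.DataFrame(
        2.0 * stats.t.sf(np.abs(t.to_numpy()), df=np.maximum(df.to_numpy(), 1)),
        index=r.index,
        columns=r.columns,
    )
    p[df < 1] = np.nan
    p[r.isna()] = np.nan
    return r, p


def _partial_correlation(
    data: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Shrinkage-based partial correlations with approximate p-values.

    The covariance is regularized with Ledoit–Wolf shrinkage (the lipid
    count typically exceeds the sample count, making the sample
    covariance singular) and inverted; the partial correlation is the
    scaled negative precision, clipped to [−1, 1].  Significance uses a
    Fisher z statistic with effective degrees of freedom
    ``n − 2 − (k − 2)`` floored at 3, where k is the number of lipids —
    an acknowledged approximation.
    """
    complete = data.dropna(axis=0, how="any")
    constant = data.columns[data.std(skipna=True).fillna(0.0) == 0.0]
    n, k = complete.shape
    if n < 3:
        raise ValueError("partial correlations require >=3 complete samples")
    lw = LedoitWolf().fit(complete.to_numpy())
    precision = np.linalg.pinv(lw.covariance_)
    d = np.sqrt(np.diag(precision))
    with np.errstate(divide="ignore", invalid="ignore"):
        partial = -precision / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    partial = np.clip(partial, -1.0, 1.0)
    r = pd.DataFrame(partial, index=data.columns, columns=data.columns)
    df_eff = max(n - 2 - (k - 2), 3)
    z = np.arctanh(np.clip(partial, -0.9999999, 0.9999999))
    p = pd.DataFrame(
        2.0 * stats.norm.sf(np.abs(z) * math.sqrt(df_eff)),
        index=data.columns,
        columns=data.columns,
    )
    r.loc[:, constant] = np.nan
    r.loc[constant, :] = np.nan
    p.loc[:, constant] = np.nan
    p.loc[constant, :] = np.nan
    return r, p


def group_correlations(
    table: AbundanceTable,
    group: str,
    method: CorrelationMethod = CorrelationMethod.PEARSON,
    partial: bool = False,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Per-pair correlation and BH-FDR within one sample group.

    ``pairs`` restricts the output (and the BH family) to the given
    lipid pairs — typically the network's edges; by default all pairs
    are returned.  Returns a DataFrame indexed by (lipid_a, lipid_b)
    with columns ``r``, ``p_value``, ``fdr``; ``.attrs["approximate"]``
    is True for partial correlations.
    """
    data = table.group_data(group)
    if len(data) < 3:
        raise ValueError("correlations require at least three samples per group")
    if partial:
        if method is not CorrelationMethod.PEARSON:
            raise ValueError("partial correlations are Pearson-based")
        r_mat, p_mat = _partial_correlation(data)
    else:
        r_mat, p_mat = _pairwise_correlation(data, method)

    if pairs is None:
        names = list(data.columns)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    index = pd.MultiIndex.from_tuples(pairs, names=["lipid_a", "lipid_b"])
    r = pd.Series([r_mat.at[a, b] for a, b in pairs], index=index, dtype=float)
    p = pd.Series([p_mat.at[a, b] for a, b in pairs], index=index, dtype=float)
    out = pd.DataFrame({"r": r, "p_value": p, "fdr": _bh_adjust(p)})
    out.attrs["approximate"] = bool(partial)
    out.attrs["group"] = str(group)
    return out


def classify_edge_change(
    r1: float, fdr1: float, r2: float, fdr2: float, alpha: float = 0.05
) -> Optional[ChangeCategory]:
    """Sort a correlation change between two groups into five categories.

    Significance is the strict inequality ``fdr < alpha`` (an FDR equal
    to alpha is not significant).  Missing inputs yield ``None``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    values = (r1, fdr1, r2, fdr2)
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
        return None
    sig1, sig2 = fdr1 < alpha, fdr2 < alpha
    if not sig1 and not sig2:
        return ChangeCategory.UNCHANGED_INSIGNIFICANT
    if not sig1 and sig2:
        return ChangeCategory.TURNED_SIGNIFICANT
    if sig1 and not sig2:
        return ChangeCategory.TURNED_INSIGNIFICANT
    if r1 * r2 < 0:
        return ChangeCategory.SIGN_CHANGE
    return ChangeCategory.UNCHANGED_SIGNIFICANT


def annotate_network(
    net: LipidNetwork,
    table: AbundanceTable,
    comparisons: Sequence[Tuple[str, str]],
    test_method: TestMethod = TestMethod.T_TEST,
    paired: bool = False,
    correlation_method: CorrelationMethod = CorrelationMethod.PEARSON,
    partial: bool = False,
    alpha: float = 0.05,
) -> LipidNetwork:
    """Overlay differential statistics onto the network (in place).

    For every comparison ``(a, b)`` nodes get
    ``log_fold_change_{a}_vs_{b}``, ``p_value_...`` and ``fdr_...``;
    edges get per-group ``r_{g}`` / ``fdr_{g}`` and the change category
    ``change_{a}_vs_{b}``.  Group-independent topology metrics (degree,
    betweenness, closeness) are attached once.  Nodes absent from the
    abundance table are warned about and left without statistical
    attributes.  Re-annotation overwrites previous values.
    """
    valid = set(table.group_labels)
    for a, b in comparisons:
        for g in (a, b):
            if str(g) not in valid:
                raise ValueError(
                    f"unknown group {g!r}; valid groups: {sorted(valid)}"
                )

    for node, metrics in topology_metrics(net).items():
        net.nodes[node].update(metrics)

    measured = set(table.lipid_names)
    absent = [n for n in net.nodes if n not in measured]
    if absent:
        warnings.warn(
            f"{len(absent)} network node(s) not in the abundance table: "
            + ", ".join(sorted(absent)[:10]),
            stacklevel=2,
        )

    edges = [
        (u, v)
        for u, v in net.edges
        if u in measured and v in measured
    ]
    groups_needed = sorted({str(g) for pair in comparisons for g in pair})
    corr: Dict[str, pd.DataFrame] = {}
    for g in groups_needed:
        corr[g] = group_correlations(
            table, g, method=correlation_method, partial=partial, pairs=edges
        )
        for (u, v), row in corr[g].iterrows():
            net.edges[u, v][f"r_{g}"] = float(row["r"])
            net.edges[u, v][f"fdr_{g}"] = float(row["fdr"])
        if corr[g].attrs.get("approximate"):
            net.graph["partial_correlations_approximate"] = True

    for a, b in comparisons:
        a, b = str(a), str(b)
        tag = f"{a}_vs_{b}"
        lfc = log_fold_change(table, a, b)
        tests = differential_test(table, a, b, method=test_method, paired=paired)
        for node in net.nodes:
            if node not in measured:
                continue
            net.nodes[node][f"log_fold_change_{tag}"] = float(lfc[node])
            net.nodes[node][f"p_value_{tag}"] = float(tests.at[node, "p_value"])
            net.nodes[node][f"fdr_{tag}"] = float(tests.at[node, "fdr"])
        for u, v in edges:
            category = classify_edge_change(
                net.edges[u, v].get(f"r_{a}", float("nan")),
                net.edges[u, v].get(f"fdr_{a}", float("nan")),
                net.edges[u, v].get(f"r_{b}", float("nan")),
                net.edges[u, v].get(f"fdr_{b}", float("nan")),
                alpha=alpha,
            )
            net.edges[u, v][f"change_{tag}"] = (
                category.value if category is not None else ""
            )
    net.graph["alpha"] = alpha
    return net
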