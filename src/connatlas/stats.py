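"""Group-level comparison of connectivity profiles.

Samples (e.g. four tracing experiments per neuron group, four groups) are
rows of a proportion matrix over analysis regions.  The module provides the
comparisons used for such designs: pairwise Pearson correlation of profiles,
per-region one-way ANOVA with Tukey HSD multiple comparisons
(Tukey–Kramer standard errors for unbalanced designs), agglomerative
hierarchical clustering under correlation distance, and multiscale bootstrap
support for dendrogram nodes — bootstrap probability (BP) at unit scale and
an approximately-unbiased (AU) p-value from the probit regression of BP
across resample scales.  The AU fit follows the multiscale-bootstrap recipe
(z(r) = v*sqrt(r) + c/sqrt(r), AU = 1 - Phi(v - c)) and is flagged
experimental.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError
from .quantify import ConnectivityProfile

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


@dataclass
class GroupMatrix:
    """Samples × regions proportion matrix with group labels per sample."""

    data: pd.DataFrame  # index: sample ids; columns: region ids
    groups: pd.Series  # index: sample ids; values: group label

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise InputError("every sample needs a group label")

    @classmethod
    def from_profiles(cls, profiles: Sequence[ConnectivityProfile]) -> "GroupMatrix":
        regions = sorted({r for p in profiles for r in p.regions})
        data = pd.DataFrame(
            [p.vector(regions) for p in profiles],
            index=[p.sample for p in profiles],
            columns=regions,
        )
        groups = pd.Series([p.group for p in profiles], index=data.index)
        return cls(data, groups)

    @property
    def n_samples(self) -> int:
        return len(self.data)


def correlation_matrix(M: GroupMatrix) -> pd.DataFrame:
    """Pearson r between all sample rows; unit diagonal.

    Zero-variance rows yield NaN off-diagonal entries (undefined correlation).
    """
    X = M.data.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise InputError("need at least 3 regions")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.asarray(R, dtype=float)
    bad = sd == 0
    R[bad, :] = np.nan
    R[:, bad] = np.nan
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=M.data.index, columns=M.data.index)


@dataclass
class RegionTestResult:
    region: Union[int, str]
    group_means: Dict[str, float]
    group_sems: Dict[str, float]
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, mean_diff, p_adj, significant


def anova_tukey(
    M: GroupMatrix, region: Union[int, str], alpha: float = 0.05
) -> RegionTestResult:
    """One-way ANOVA across groups for one region, with Tukey HSD pairs.

    F = MS_between / MS_within on (k-1, N-k) degrees of freedom; adjusted
    pairwise p-values come from the studentized range distribution with
    Tukey–Kramer standard errors.  A fully degenerate region (no between- or
    within-group variance) returns F = 0, p = 1.
    """
    y = M.data[region].to_numpy(dtype=float)
    labels = M.groups.to_numpy()
    group_names = list(pd.unique(labels))
    samples = [y[labels == g] for g in group_names]
    k = len(samples)
    if k < 2 or any(len(s) < 2 for s in samples):
        raise InputError("need >=2 groups with >=2 samples each")
    N = len(y)
    grand = y.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, N - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        if ms_b == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(sstats.f.sf(f_stat, df_b, df_w))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            diff = b.mean() - a.mean()
            if ms_w == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(ms_w / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
                q = abs(diff) / se
                p_adj = float(sstats.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group1": group_names[i],
                    "group2": group_names[j],
                    "mean_diff": diff,
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                    "significant": p_adj < alpha,
                }
            )
    return RegionTestResult(
        region=region,
        group_means={g: float(s.mean()) for g, s in zip(group_names, samples)},
        group_sems={
            g: float(s.std(ddof=1) / np.sqrt(len(s)))
            for g, s in zip(group_names, samples)
        },
        f_statistic=float(f_stat),
        p_value=float(min(max(p, 0.0), 1.0)),
        tukey=pd.DataFrame(rows),
    )


def anova_tukey_all(M: GroupMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region ANOVA summary table over all regions in the matrix."""
    rows = []
    for region in M.data.columns:
        res = anova_tukey(M, region, alpha)
        rows.append(
            {
                "region": region,
                "F": res.f_statistic,
                "p": res.p_value,
                "any_significant_pair": bool(res.tukey["significant"].any()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hierarchical clustering with multiscale bootstrap


@dataclass
class ClusterTree:
    linkage: np.ndarray  # scipy linkage matrix
    items: List[str]
    node_sets: List[FrozenSet[int]]  # leaf-index set per internal node
    heights: List[float]
    bp: Dict[FrozenSet[int], float] = field(default_factory=dict)
    au: Dict[FrozenSet[int], float] = field(default_factory=dict)
    au_flag: Dict[FrozenSet[int], str] = field(default_factory=dict)

    def support_table(self) -> pd.DataFrame:
        rows = []
        for s, h in zip(self.node_sets, self.heights):
            rows.append(
                {
                    "members": ",".join(self.items[i] for i in sorted(s)),
                    "height": h,
                    "bp": self.bp.get(s, float("nan")),
                    "au": self.au.get(s, float("nan")),
                    "au_flag": self.au_flag.get(s, ""),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "items": self.items,
                    "linkage": self.linkage.tolist(),
                    "nodes": [
                        {
                            "members": sorted(s),
                            "height": h,
                            "bp": self.bp.get(s),
                            "au": self.au.get(s),
                            "flag": self.au_flag.get(s, ""),
                        }
                        for s, h in zip(self.node_sets, self.heights)
                    ],
                },
                indent=2,
            )
        )


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distance between rows; NaN r counts as 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.nan_to_num(np.asarray(R, dtype=float), nan=0.0)
    np.fill_diagonal(R, 1.0)
    D = 1.0 - R
    D[D < 0] = 0.0
    return squareform(D, checks=False)


def _node_sets(Z: np.ndarray, n: int) -> List[FrozenSet[int]]:
    sets: List[FrozenSet[int]] = []
    lookup: Dict[int, FrozenSet[int]] = {i: frozenset([i]) for i in range(n)}
    for row_idx, (a, b, _h, _cnt) in enumerate(Z):
        merged = lookup[int(a)] | lookup[int(b)]
        lookup[n + row_idx] = merged
        sets.append(merged)
    return sets


def hcluster(
    M: GroupMatrix, distance: str = "correlation", linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of sample profiles.

    Default is pvclust-style: d = 1 - Pearson r, average linkage.
    """
    X = M.data.to_numpy(dtype=float)
    if len(X) < 3:
        raise InputError("need at least 3 items to cluster")
    if distance == "correlation":
        if np.any(X.std(axis=1) == 0):
            raise InputError("zero-variance item: correlation distance undefined")
        d = _correlation_distance(X)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        d = pdist(X)
    else:
        raise InputError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(d, method=linkage)
    sets = _node_sets(Z, len(X))
    return ClusterTree(
        linkage=Z,
        items=[str(i) for i in M.data.index],
        node_sets=sets,
        heights=[float(r[2]) for r in Z],
    )


def bootstrap_support(
    M: GroupMatrix,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterTree:
    """Multiscale bootstrap support for the cluster tree of ``M``.

    For every scale r, ``n_boot`` column resamples of size ``round(r*p)``
    are drawn with replacement and reclustered; BP(node, r) is the fraction
    of replicate trees containing the node's item set.  The reported BP is
    the one at r = 1; AU comes from the least-squares probit fit
    ``z(r) = v*sqrt(r) + c/sqrt(r)`` with ``z = Phi^{-1}(1 - BP)`` and
    ``AU = 1 - Phi(v - c)``.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise InputError("n_boot must be >= 100")
    scales = [float(s) for s in scales]
    if not any(abs(s - 1.0) < 1e-9 for s in scales):
        raise InputError("scales must include 1.0")
    tree = hcluster(M, distance=distance, linkage=linkage)
    X = M.data.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    counts = {s: np.zeros(len(scales)) for s in tree.node_sets}
    for si, scale in enumerate(scales):
        p_r = max(3, int(round(scale * p)))
        for _ in range(n_boot):
            cols = rng.integers(0, p, size=p_r)
            Xb = X[:, cols]
            d = _correlation_distance(Xb)
            Zb = hierarchy.linkage(d, method=linkage)
            for s in _node_sets(Zb, n):
                if s in counts:
                    counts[s][si] += 1
    unit = scales.index(1.0)
    sqrt_r = np.sqrt(np.array(scales))
    for s in tree.node_sets:
        cnt = counts[s]
        bp_scales = cnt / n_boot
        tree.bp[s] = float(bp_scales[unit])
        if np.all(cnt == 0):
            tree.au[s] = 0.0
            tree.au_flag[s] = "never-observed"
            continue
        if len(s) in (1, n):  # leaves / root are trivially certain
            tree.au[s] = 1.0
            tree.au_flag[s] = "trivial" if len(s) == n else ""
            continue
        # probit fit over scales where BP is informative (not pinned at 0/1);
        # a node observed in (essentially) every replicate at every scale is
        # saturated and its AU is taken as its BP
        informative = (cnt > 0) & (cnt < n_boot)
        if informative.sum() < 2:
            tree.au[s] = float(bp_scales[unit])
            tree.au_flag[s] = "saturated"
            continue
        bp_i = bp_scales[informative]
        z = sstats.norm.ppf(1.0 - bp_i)
        # weighted least squares with binomial variance on the probit scale
        w = n_boot * sstats.norm.pdf(z) ** 2 / (bp_i * (1.0 - bp_i))
        A = np.column_stack([sqrt_r[informative], 1.0 / sqrt_r[informative]])
        Aw = A * w[:, None]
        coef = np.linalg.solve(A.T @ Aw, Aw.T @ z)
        v, c = coef
        tree.au[s] = float(sstats.norm.sf(v - c))
        tree.au_flag[s] = "experimental"
    return tree
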