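"""Beta-diversity ordination and the statistical battery.

Bray-Curtis distances, classical PCoA, distance-based PERMANOVA, species
richness, two-group tests, one-way ANOVA with Tukey HSD post-hocs,
Benjamini-Hochberg FDR, and a simple per-feature linear association model
for proportion data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    GroupSizeError,
    ParameterError,
    RankDeficiencyError,
    UndefinedStatisticError,
    ValidationError,
)
from .cst_core import DistanceMatrix
from .profiles_io import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix."""

    ids: list[str]
    coordinates: np.ndarray  # n x m, columns ordered by eigenvalue
    eigenvalues: np.ndarray  # kept (positive) eigenvalues, descending
    proportion_explained: np.ndarray
    all_eigenvalues: np.ndarray = field(default=None)  # full spectrum incl. negatives

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValidationError("PERMANOVA p-value outside (0, 1]")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    groups: list[str]
    effect: dict

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# distances & ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity; a pair of all-zero samples scores 0."""
    x = table.values
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    # |xi - xj| and (xi + xj) summed over taxa, all pairs at once
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(table.sample_ids), values=d)


def pcoa(dist: DistanceMatrix, n_axes: int = 3, correction: str | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Negative eigenvalues are reported in ``all_eigenvalues`` but not
    corrected unless ``correction="lingoes"`` is requested.
    """
    n = dist.n
    if n_axes > n - 1:
        raise ParameterError(f"n_axes={n_axes} exceeds n-1={n - 1}")
    d2 = dist.values ** 2
    if correction == "lingoes":
        b = _double_center(d2)
        lam_min = np.linalg.eigvalsh(b).min()
        if lam_min < 0:
            c = -lam_min
            d2 = d2 + 2 * c
            np.fill_diagonal(d2, 0.0)
    elif correction is not None:
        raise ParameterError(f"unknown correction {correction!r}")
    b = _double_center(d2)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(1.0, abs(eigvals[0]))
    n_pos = int((eigvals > tol).sum())
    m = min(n_axes, n_pos)
    if m < n_axes:
        logger.warning("only %d positive eigenvalues; truncating from %d axes", n_pos, n_axes)
    kept = eigvals[:m]
    coords = eigvecs[:, :m] * np.sqrt(kept)
    pos_sum = eigvals[eigvals > tol].sum()
    prop = kept / pos_sum if pos_sum > 0 else np.zeros(m)
    return OrdinationResult(
        ids=list(dist.ids),
        coordinates=coords,
        eigenvalues=kept,
        proportion_explained=prop,
        all_eigenvalues=eigvals,
    )


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, labels: np.ndarray, k: int) -> float:
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(k):
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based one-way PERMANOVA with a seeded permutation null.

    p = (#{permuted F >= observed F} + 1) / (n_permutations + 1).
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    raw = [groups[s] for s in dist.ids]
    levels = sorted(set(raw))
    if len(levels) < 2:
        raise GroupSizeError("PERMANOVA needs at least 2 groups")
    labels = np.array([levels.index(g) for g in raw])
    counts = np.bincount(labels)
    if counts.min() < 2:
        small = levels[int(np.argmin(counts))]
        raise GroupSizeError(f"group {small!r} has fewer than 2 members")
    k = len(levels)
    d2 = dist.values ** 2
    f_obs = _pseudo_f(d2, labels, k)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, k) >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs), p_value=p, n_permutations=n_permutations, seed=seed
    )


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------

def richness(table: AbundanceTable, threshold: float = 0.0) -> pd.Series:
    """Per-sample count of taxa with abundance strictly above ``threshold``."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    counts = (table.values > threshold).sum(axis=1)
    return pd.Series(counts, index=table.sample_ids, name="richness")


def two_group_test(
    values_a,
    values_b,
    method: str = "mann_whitney",
    equal_var: bool = False,
) -> TestResult:
    """Welch t-test or two-sided Mann-Whitney U (normal approx., tie-corrected)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise GroupSizeError("each group needs at least 2 values")
    effect = {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
    if method == "t_test":
        if a.std() == 0 and b.std() == 0:
            raise UndefinedStatisticError("t statistic undefined for two constant groups")
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
        name = "t_test" if equal_var else "welch_t_test"
    elif method == "mann_whitney":
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        name = "mann_whitney"
    else:
        raise ParameterError(f"unknown method {method!r}")
    return TestResult(
        statistic=float(stat), p_value=float(min(p, 1.0)), method=name,
        groups=["a", "b"], effect=effect,
    )


def anova_tukey(
    values: pd.Series,
    groups: pd.Series,
    alpha: float = 0.05,
) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA plus Tukey-Kramer HSD pairwise comparisons.

    Convention: when every observation is identical the F statistic is
    undefined and reported as 0 with p = 1.
    """
    groups = groups.loc[values.index]
    levels = sorted(groups.unique())
    if len(levels) < 3:
        raise GroupSizeError("anova_tukey needs >= 3 groups; use two_group_test")
    arrays = [values[groups == g].to_numpy(dtype=float) for g in levels]
    for g, arr in zip(levels, arrays):
        if len(arr) < 2:
            raise GroupSizeError(f"group {g!r} has fewer than 2 members")
    pooled = np.concatenate(arrays)
    effect = {str(g): float(arr.mean()) for g, arr in zip(levels, arrays)}
    if np.ptp(pooled) == 0:
        anova = TestResult(0.0, 1.0, "anova", [str(g) for g in levels], effect)
        pairs = pd.DataFrame(
            [(str(x), str(y), 0.0, 1.0, False)
             for i, x in enumerate(levels) for y in levels[i + 1:]],
            columns=["group_a", "group_b", "diff", "p_value", "significant"],
        )
        return anova, pairs
    f_stat, f_p = scipy.stats.f_oneway(*arrays)
    anova = TestResult(float(f_stat), float(f_p), "anova", [str(g) for g in levels], effect)
    hsd = scipy.stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p = float(hsd.pvalue[i, j])
            rows.append((
                str(levels[i]), str(levels[j]),
                float(arrays[i].mean() - arrays[j].mean()), p, p < alpha,
            ))
    pairs = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p_value", "significant"])
    return anova, pairs


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-feature association model
# ---------------------------------------------------------------------------

def associate_features(table, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-feature linear model of arcsin-sqrt abundance on dummy-coded covariates.

    ``table`` is an AbundanceTable or ECTable; ``covariates`` a frame indexed
    by sample id with one categorical column per covariate. Returns one row
    per (feature, covariate, non-reference level) with the least-squares
    coefficient, its Wald p-value, and BH-FDR q across all rows.

    This is deliberately simple plumbing for screening associations, not a
    reimplementation of any published multivariate tool.
    """
    feats = getattr(table, "taxon_ids", None) or getattr(table, "ec_numbers")
    cov = covariates.loc[table.sample_ids]
    design_cols: list[tuple[str, str]] = []
    blocks = []
    for name in cov.columns:
        col = cov[name].astype(str)
        levels = sorted(col.unique())
        if len(levels) < 2:
            raise ParameterError(f"covariate {name!r} has fewer than 2 levels")
        for lvl in levels[1:]:  # first level is the reference
            design_cols.append((name, lvl))
            blocks.append((col == lvl).to_numpy(dtype=float))
    x = np.column_stack([np.ones(len(cov))] + blocks)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficiencyError(
            "collinear covariates among " + ", ".join(covariates.columns)
        )
    y_all = np.arcsin(np.sqrt(np.clip(table.values, 0.0, 1.0)))
    rows = []
    for fi, feat in enumerate(feats):
        fit = sm.OLS(y_all[:, fi], x).fit()
        for ci, (name, lvl) in enumerate(design_cols, start=1):
            rows.append((feat, name, lvl, float(fit.params[ci]), float(fit.pvalues[ci])))
    out = pd.DataFrame(rows, columns=["feature", "covariate", "level", "coef", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out
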