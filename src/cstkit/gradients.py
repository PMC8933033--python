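"""Compartment-level reporting: CST prevalence tables, shared-species sets,
and detection of distance-ordered abundance gradients."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GroupSizeError, ParameterError, UnknownTaxonError, VocabularyError
from .cst_core import CSTCatalog
from .profiles_io import COMPARTMENTS, AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class PrevalenceTable:
    """CST x group prevalence fractions plus the per-group unassigned share."""

    table: pd.DataFrame  # rows: CST labels, columns: group labels
    unassigned: pd.Series  # per-group fraction of unassigned samples
    highlight_threshold: float = 0.15

    @property
    def highlights(self) -> pd.DataFrame:
        return self.table > self.highlight_threshold

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.loc["unassigned"] = self.unassigned
        return out


@dataclass
class GradientReport:
    taxon: str
    group_order: list[str]
    group_means: list[float]
    direction: str  # "increasing" | "decreasing" | "none"
    monotone: bool
    p_value: float
    statistic: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "group_order": list(self.group_order),
            "group_means": [float(m) for m in self.group_means],
            "direction": self.direction,
            "monotone": self.monotone,
            "p_value": self.p_value,
            "statistic": self.statistic,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def cst_prevalence_by_group(
    catalog: CSTCatalog,
    meta: pd.DataFrame,
    group_key: str = "compartment",
    highlight_threshold: float = 0.15,
) -> PrevalenceTable:
    """Fraction of each group's samples falling in each CST.

    Unassigned samples count in the denominators but in no CST row, so each
    column plus its unassigned share sums to exactly 1.
    """
    if group_key not in ("sampling_method", "compartment", "health_status"):
        raise VocabularyError(f"unsupported group key {group_key!r}")
    label_of = catalog.label_of()
    samples = [s for s in catalog.all_samples() if s in meta.index]
    if len(samples) < len(catalog.all_samples()):
        raise GroupSizeError("catalog contains samples missing from metadata")
    groups = meta.loc[samples, group_key]
    levels = [g for g in groups.unique() if (groups == g).sum() > 0]
    cst_labels = [c.label for c in catalog.csts]
    data = pd.DataFrame(0.0, index=cst_labels, columns=levels)
    unassigned = pd.Series(0.0, index=levels)
    for g in levels:
        members = [s for s in samples if groups[s] == g]
        n = len(members)
        if n == 0:
            logger.warning("group %r is empty; dropped", g)
            continue
        counts: dict[str, int] = {}
        for s in members:
            counts[label_of[s]] = counts.get(label_of[s], 0) + 1
        for lbl in cst_labels:
            data.loc[lbl, g] = counts.get(lbl, 0) / n
        unassigned[g] = counts.get("unassigned", 0) / n
    return PrevalenceTable(table=data, unassigned=unassigned,
                           highlight_threshold=highlight_threshold)


def shared_species(
    table: AbundanceTable,
    meta: pd.DataFrame,
    abundance_cut: float = 0.01,
    groups: tuple[str, ...] = ("nasal", "throat", "sputum", "lung"),
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Per-group species sets by mean abundance, their union and intersection.

    A species enters a group's set when its mean relative abundance over the
    group's samples exceeds ``abundance_cut``. Returns
    ``(per_group_sets, union, intersection)``.
    """
    for g in groups:
        if g not in COMPARTMENTS:
            raise VocabularyError(
                f"unknown compartment {g!r}; accepted: {', '.join(COMPARTMENTS)}"
            )
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    per_group: dict[str, set[str]] = {}
    for g in groups:
        members = [s for s in table.sample_ids if meta.loc[s, "compartment"] == g]
        if not members:
            per_group[g] = set()
            continue
        means = table.values[[pos[s] for s in members], :].mean(axis=0)
        per_group[g] = {t for t, m in zip(table.taxon_ids, means) if m > abundance_cut}
    union: set[str] = set().union(*per_group.values())
    inter = set(table.taxon_ids)
    for g in groups:
        inter &= per_group[g]
    return per_group, union, inter


def _jt_statistic(values: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    """Jonckheere-Terpstra statistic with ties counted as 1/2."""
    jt = 0.0
    arrays = [values[group_idx == g] for g in range(n_groups)]
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            a, b = arrays[i], arrays[j]
            lt = (a[:, None] < b[None, :]).sum()
            eq = (a[:, None] == b[None, :]).sum()
            jt += lt + 0.5 * eq
    return float(jt)


def detect_gradient(
    table: AbundanceTable,
    meta: pd.DataFrame,
    taxon: str,
    group_order: tuple[str, ...],
    n_permutations: int = 1000,
    seed: int = 0,
) -> GradientReport:
    """Test a taxon for an ordered abundance trend along ``group_order``.

    The trend statistic is Jonckheere-Terpstra with a two-sided permutation
    p-value centered on the exact null mean, so reversing the group order
    flips the direction but leaves p unchanged.
    """
    if len(group_order) < 2:
        raise ParameterError("need at least 2 ordered groups")
    ti = table.taxon_index(taxon)  # raises UnknownTaxonError
    comp = meta.loc[table.sample_ids, "compartment"]
    group_idx_map = {g: i for i, g in enumerate(group_order)}
    keep, gidx = [], []
    for i, s in enumerate(table.sample_ids):
        g = comp[s]
        if g in group_idx_map:
            keep.append(i)
            gidx.append(group_idx_map[g])
    gidx = np.array(gidx, dtype=int)
    for g, i in group_idx_map.items():
        if (gidx == i).sum() == 0:
            raise GroupSizeError(f"group {g!r} has no samples")
    values = table.values[keep, ti]
    n_groups = len(group_order)
    counts = np.bincount(gidx, minlength=n_groups)
    mu0 = sum(
        counts[i] * counts[j]
        for i in range(n_groups)
        for j in range(i + 1, n_groups)
    ) / 2.0

    jt_obs = _jt_statistic(values, gidx, n_groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    dev_obs = abs(jt_obs - mu0)
    for _ in range(n_permutations):
        perm = rng.permutation(gidx)
        if abs(_jt_statistic(values, perm, n_groups) - mu0) >= dev_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)

    means = [float(values[gidx == i].mean()) for i in range(n_groups)]
    diffs = np.diff(means)
    if len(diffs) and (diffs > 0).all():
        direction, monotone = "increasing", True
    elif len(diffs) and (diffs < 0).all():
        direction, monotone = "decreasing", True
    else:
        direction, monotone = "none", False
    return GradientReport(
        taxon=taxon,
        group_order=list(group_order),
        group_means=means,
        direction=direction,
        monotone=monotone,
        p_value=p,
        statistic=jt_obs,
        n_permutations=n_permutations,
        seed=seed,
    )
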