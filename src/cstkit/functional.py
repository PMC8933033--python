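"""Enzyme-class functional profiling.

EC numbers collapse to their top-level class (1 oxidoreductases ...
7 translocases); class profiles are compared across groups and pathway
tables are screened for compartment-unique pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError, TableParseError, ValidationError, VocabularyError
from .ordination_stats import anova_tukey, bh_fdr
from .profiles_io import ECTable, PathwayTable

EC_CLASS_NAMES = {
    1: "oxidoreductases",
    2: "transferases",
    3: "hydrolases",
    4: "lyases",
    5: "isomerases",
    6: "ligases",
    7: "translocases",
}


@dataclass
class ECClassProfile:
    """Per-sample relative abundance of the seven top-level EC classes.

    Rows are renormalized over annotated reads and sum to 1.
    """

    sample_ids: list[str]
    classes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.classes) != 7:
            raise ValidationError("EC class profile must have exactly 7 classes")
        sums = self.values.sum(axis=1)
        if np.abs(sums - 1).max(initial=0.0) > 1e-9:
            raise ValidationError("EC class profile rows must sum to 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.classes)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.12g")


@dataclass
class UniquePathwayReport:
    """Per-compartment pathway presence sets and the unique subsets."""

    compartment_sets: dict[str, set[str]]
    unique_sets: dict[str, set[str]]
    presence_min_prevalence: float

    @property
    def unique_counts(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.unique_sets.items()}

    def to_dict(self) -> dict:
        return {
            "presence_min_prevalence": self.presence_min_prevalence,
            "unique_counts": self.unique_counts,
            "present_counts": {g: len(s) for g, s in self.compartment_sets.items()},
        }


def ec_class_of(ec_number: str) -> int:
    head = ec_number.split(".", 1)[0]
    try:
        cls = int(head)
    except ValueError:
        raise TableParseError(f"malformed EC number {ec_number!r}") from None
    if cls not in EC_CLASS_NAMES:
        raise TableParseError(f"EC number {ec_number!r} has top-level class {cls}, expected 1-7")
    return cls


def ec_class_profile(ec: ECTable) -> ECClassProfile:
    """Collapse an EC table to the seven top-level classes and renormalize."""
    class_idx = np.array([ec_class_of(e) - 1 for e in ec.ec_numbers])
    agg = np.zeros((len(ec.sample_ids), 7))
    for c in range(7):
        cols = class_idx == c
        if cols.any():
            agg[:, c] = ec.values[:, cols].sum(axis=1)
    totals = agg.sum(axis=1)
    empty = np.nonzero(totals == 0)[0]
    if empty.size:
        raise ValidationError(
            f"sample {ec.sample_ids[empty[0]]!r} has no annotated EC abundance; "
            "cannot renormalize"
        )
    return ECClassProfile(
        sample_ids=list(ec.sample_ids),
        classes=[EC_CLASS_NAMES[c] for c in range(1, 8)],
        values=agg / totals[:, None],
    )


def compare_ec_classes(
    profile: ECClassProfile,
    meta: pd.DataFrame,
    group_key: str = "compartment",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-class one-way ANOVA + Tukey HSD across groups, BH-FDR across classes.

    Returns a summary frame (class, F, p, q) and the per-class pairwise
    Tukey tables. With fewer than 3 groups the underlying ANOVA raises and
    directs callers to ``two_group_test``.
    """
    if group_key not in meta.columns:
        raise VocabularyError(f"metadata has no column {group_key!r}")
    groups = meta.loc[profile.sample_ids, group_key]
    rows, pairwise = [], {}
    for ci, cls in enumerate(profile.classes):
        vals = pd.Series(profile.values[:, ci], index=profile.sample_ids)
        res, pairs = anova_tukey(vals, groups, alpha=alpha)
        rows.append((cls, res.statistic, res.p_value))
        pairwise[cls] = pairs
    out = pd.DataFrame(rows, columns=["ec_class", "f_statistic", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out, pairwise


def unique_pathways(
    pw: PathwayTable,
    meta: pd.DataFrame,
    presence_min_prevalence: float = 0.25,
    groups: tuple[str, ...] = ("nasal", "throat", "sputum", "lung"),
) -> UniquePathwayReport:
    """Count pathways present in exactly one compartment.

    A pathway is "present" in a compartment when it is detected
    (abundance > 0) in at least ``presence_min_prevalence`` of the
    compartment's samples.
    """
    if not 0 <= presence_min_prevalence <= 1:
        raise ParameterError("presence_min_prevalence must lie in [0, 1]")
    pos = {s: i for i, s in enumerate(pw.sample_ids)}
    comp_sets: dict[str, set[str]] = {}
    for g in groups:
        members = [s for s in pw.sample_ids if meta.loc[s, "compartment"] == g]
        if not members:
            comp_sets[g] = set()
            continue
        prev = (pw.values[[pos[s] for s in members], :] > 0).mean(axis=0)
        comp_sets[g] = {
            p for p, f in zip(pw.pathway_ids, prev) if f >= presence_min_prevalence
        }
    unique_sets = {
        g: {
            p for p in comp_sets[g]
            if all(p not in comp_sets[o] for o in groups if o != g)
        }
        for g in groups
    }
    return UniquePathwayReport(
        compartment_sets=comp_sets,
        unique_sets=unique_sets,
        presence_min_prevalence=presence_min_prevalence,
    )
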