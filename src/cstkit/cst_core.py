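"""Community state type (CST) calling.

The procedure: correlation-based sample distances -> average-linkage
hierarchical clustering -> silhouette-guided choice of the number of
clusters -> retention filters (minimum size, minimum number of source
datasets) -> per-cluster core-taxon characterization and labelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .exceptions import (
    AlignmentError,
    DegenerateSampleError,
    NoCSTError,
    ParameterError,
    UndefinedScoreError,
    ValidationError,
)
from .profiles_io import AbundanceTable

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Square, symmetric, zero-diagonal dissimilarity matrix."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0):
            raise ValidationError("distance matrix is not symmetric")
        if (self.values < 0).any():
            raise ValidationError("distance matrix has negative entries")
        if np.abs(np.diag(self.values)).max(initial=0.0) > _SYM_TOL:
            raise ValidationError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        sym = (self.values + self.values.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        return squareform(sym, checks=False)


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage form plus leaf ids.

    ``linkage[i] = (left, right, height, size)`` with cluster index
    ``n + i`` created by merge ``i``; heights are non-decreasing.
    """

    leaf_ids: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValidationError(f"expected {n - 1} merges, got {self.linkage.shape}")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValidationError("merge heights are not monotone non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(l), int(r), float(h), int(s)) for l, r, h, s in self.linkage
        ]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_ids[i] for i in range(n)}
        for i, (l, r, h, _s) in enumerate(self.merges):
            bl_l = h - height[l]
            bl_r = h - height[r]
            node[n + i] = f"({node[l]}:{bl_l:.10g},{node[r]}:{bl_r:.10g})"
            height[n + i] = h
        return node[n + len(self.merges) - 1] + ";"


@dataclass
class ClusterAssignment:
    """Flat clustering: sample id -> integer label in 1..k, no empty cluster."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        used = set(self.labels.values())
        if used != set(range(1, self.k + 1)):
            raise ValidationError(
                f"labels must cover 1..{self.k} with no empty cluster; got {sorted(used)}"
            )

    def label_array(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in ids], dtype=int)

    def members(self, label: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == label]


@dataclass
class CSTDefinition:
    """One called community state type (or an excluded putative cluster)."""

    label: str
    member_samples: list[str]
    prevalence_over_total: float
    core_taxa: list[tuple[str, float, float]]  # (taxon, mean abundance, prevalence)
    defining_taxon: str | None
    accessory_taxa: list[tuple[str, float, float]]
    status: str  # "cst" | "putative_excluded"
    mean_abundance: np.ndarray | None = None  # centroid over member samples

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "status": self.status,
            "n_members": len(self.member_samples),
            "prevalence_over_total": self.prevalence_over_total,
            "defining_taxon": self.defining_taxon,
            "core_taxa": [
                {"taxon": t, "mean_abundance": a, "prevalence": p}
                for t, a, p in self.core_taxa
            ],
            "member_samples": list(self.member_samples),
        }


@dataclass
class CSTCatalog:
    """The full set of called CSTs plus unassigned samples and parameters."""

    csts: list[CSTDefinition]
    unassigned_samples: list[str]
    taxon_ids: list[str]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.csts:
            overlap = seen.intersection(c.member_samples)
            if overlap:
                raise ValidationError(f"CST member sets overlap on {sorted(overlap)[:3]}")
            seen.update(c.member_samples)
        overlap = seen.intersection(self.unassigned_samples)
        if overlap:
            raise ValidationError("unassigned samples overlap CST members")

    @property
    def called(self) -> list[CSTDefinition]:
        return [c for c in self.csts if c.status == "cst"]

    def all_samples(self) -> set[str]:
        out = set(self.unassigned_samples)
        for c in self.csts:
            out.update(c.member_samples)
        return out

    def label_of(self) -> dict[str, str]:
        """sample id -> CST label ('unassigned' for leftovers)."""
        out = {s: "unassigned" for s in self.unassigned_samples}
        for c in self.csts:
            for s in c.member_samples:
                out[s] = c.label
        return out

    def to_json(self) -> str:
        payload = {
            "parameters": self.parameters,
            "csts": [c.to_dict() for c in self.csts],
            "unassigned_samples": list(self.unassigned_samples),
        }
        return json.dumps(payload, indent=2)

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    def assignment_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.csts:
            for s in c.member_samples:
                rows.append((s, c.label, c.status))
        for s in self.unassigned_samples:
            rows.append((s, "unassigned", "unassigned"))
        return pd.DataFrame(rows, columns=["sample_id", "cst_label", "status"]).set_index(
            "sample_id"
        )


# ---------------------------------------------------------------------------
# distances and clustering
# ---------------------------------------------------------------------------

def pearson_distance(table: AbundanceTable) -> DistanceMatrix:
    """d(i, j) = 1 - Pearson r between the two samples' abundance vectors."""
    x = table.values
    if x.shape[0] < 2:
        raise ParameterError("need at least 2 samples for a distance matrix")
    sd = x.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise DegenerateSampleError(
            f"sample {table.sample_ids[flat[0]]!r} has zero variance across taxa; "
            "Pearson correlation is undefined"
        )
    r = np.corrcoef(x)
    d = 1.0 - r
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(table.sample_ids), values=d)


def upgma_linkage(dist: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Agglomerate a distance matrix; UPGMA (average linkage) by default.

    ``method`` may also be ``"complete"`` or ``"ward"`` (Ward-on-distances).
    """
    if dist.n < 2:
        raise ParameterError("need at least 2 samples to build a dendrogram")
    if method not in ("average", "complete", "ward"):
        raise ParameterError(f"unsupported linkage method {method!r}")
    z = sch.linkage(dist.condensed(), method=method)
    return Dendrogram(leaf_ids=list(dist.ids), linkage=z)


def cut_dendrogram(tree: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into k clusters by removing the k-1 highest (latest) merges.

    Equal-height merges are broken by merge order: later merges are removed
    first, so the cut always yields exactly k connected components.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} out of range 1..{n}")
    parent = list(range(n + max(0, n - k)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    # keep the first n-k merges, i.e. drop the k-1 highest ones
    for i, (l, r, _h, _s) in enumerate(tree.merges[: n - k]):
        parent[find(l)] = parent[find(r)] = n + i

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in roots:
            roots[root] = len(roots) + 1
        labels[tree.leaf_ids[leaf]] = roots[root]
    return ClusterAssignment(labels=labels, k=k)


def silhouette_mean(dist: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """Mean silhouette width over all samples.

    Conventions: singleton clusters score 0; when a(i) = b(i) = 0 (duplicate
    points) the sample scores 0.
    """
    if assignment.k < 2:
        raise UndefinedScoreError("silhouette undefined for a single cluster")
    labels = assignment.label_array(dist.ids)
    d = dist.values
    n = len(labels)
    scores = np.zeros(n)
    masks = {c: labels == c for c in range(1, assignment.k + 1)}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue  # singleton -> 0
        a = d[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(
            d[i, masks[o]].mean() for o in masks if o != c and sizes[o] > 0
        )
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def select_k(
    dist: DistanceMatrix,
    tree: Dendrogram,
    k_min: int = 2,
    k_max: int = 20,
) -> tuple[int, dict[int, float]]:
    """Pick the cluster number maximizing mean silhouette along the dendrogram.

    Ties go to the smallest k. ``k_max`` is clipped to n - 1.
    """
    n = dist.n
    k_max = min(k_max, n - 1)
    if not 2 <= k_min <= k_max:
        raise ParameterError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        scores[k] = silhouette_mean(dist, cut_dendrogram(tree, k))
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


# ---------------------------------------------------------------------------
# CST characterization
# ---------------------------------------------------------------------------

def _taxon_initials(taxon: str) -> str:
    parts = [p for p in taxon.replace("_", " ").split() if p]
    initials = "".join(p[0] for p in parts[:2])
    return initials[:1].upper() + initials[1:].lower()


def call_csts(
    table: AbundanceTable,
    meta: pd.DataFrame,
    assignment: ClusterAssignment,
    min_fraction: float = 0.01,
    min_datasets: int = 2,
    core_prevalence: float = 0.85,
    single_project_exclude: bool = True,
    presence_threshold: float = 0.0,
) -> CSTCatalog:
    """Turn a flat clustering into a catalog of community state types.

    Clusters are retained when they hold at least ``max(2,
    round(min_fraction * n))`` samples drawn from at least ``min_datasets``
    bioprojects; the rest go to the unassigned pool. A retained cluster's
    core taxa are those detected (abundance > ``presence_threshold``) in
    more than ``core_prevalence`` of its members; the most abundant core
    taxon names the CST. Clusters defined by a taxon not resolved to
    species level — or, when ``single_project_exclude``, drawn from a single
    bioproject — are kept in the catalog but flagged ``putative_excluded``.
    """
    n_total = table.n_samples
    min_size = max(2, round(min_fraction * n_total))
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}

    csts: list[CSTDefinition] = []
    unassigned: list[str] = []
    label_counts: dict[str, int] = {}

    for c in range(1, assignment.k + 1):
        members = [s for s in table.sample_ids if assignment.labels[s] == c]
        projects = set(meta.loc[members, "bioproject"])
        if len(members) < min_size or len(projects) < min_datasets:
            unassigned.extend(members)
            continue

        sub = table.values[[sample_pos[s] for s in members], :]
        mean_ab = sub.mean(axis=0)
        prev = (sub > presence_threshold).mean(axis=0)

        core, accessory = [], []
        for j, taxon in enumerate(table.taxon_ids):
            entry = (taxon, float(mean_ab[j]), float(prev[j]))
            (core if prev[j] > core_prevalence else accessory).append(entry)

        status = "cst"
        if core:
            # argmax mean abundance, lexicographic tie-break
            defining = min(core, key=lambda e: (-e[1], e[0]))[0]
            j = table.taxon_ids.index(defining)
            if not table.species_resolved[j]:
                status = "putative_excluded"
        else:
            defining = None
            status = "putative_excluded"
        if single_project_exclude and len(projects) == 1:
            status = "putative_excluded"

        prefix = "CST-" if status == "cst" else "Cluster-"
        base = prefix + (_taxon_initials(defining) if defining else str(c))
        label_counts[base] = label_counts.get(base, 0) + 1
        label = base if label_counts[base] == 1 else f"{base}{label_counts[base]}"

        csts.append(
            CSTDefinition(
                label=label,
                member_samples=members,
                prevalence_over_total=len(members) / n_total,
                core_taxa=sorted(core, key=lambda e: -e[1]),
                defining_taxon=defining,
                accessory_taxa=sorted(accessory, key=lambda e: -e[1]),
                status=status,
                mean_abundance=mean_ab,
            )
        )

    if not any(c.status == "cst" for c in csts):
        raise NoCSTError(
            "no cluster survived the retention filters; review min_fraction/"
            "min_datasets or the clustering granularity"
        )

    return CSTCatalog(
        csts=csts,
        unassigned_samples=unassigned,
        taxon_ids=list(table.taxon_ids),
        parameters={
            "k": assignment.k,
            "min_fraction": min_fraction,
            "min_size": min_size,
            "min_datasets": min_datasets,
            "core_prevalence": core_prevalence,
            "presence_threshold": presence_threshold,
            "single_project_exclude": single_project_exclude,
        },
    )


def characterize_cst_from_summary(
    avg_abundances: Mapping[str, float],
    prevalences: Mapping[str, float],
    core_prevalence: float = 0.85,
) -> tuple[str | None, float | None]:
    """Apply the core-taxon rule to a printed summary row.

    Both mappings are in percent. Core taxa are those with prevalence
    strictly above ``core_prevalence * 100``; among them the taxon with the
    highest average abundance is returned with its abundance. Returns
    ``(None, None)`` when no taxon passes the prevalence cut.
    """
    if set(avg_abundances) != set(prevalences):
        raise AlignmentError("abundance and prevalence mappings differ in taxa")
    cut = core_prevalence * 100.0
    core = [t for t in avg_abundances if prevalences[t] > cut]
    if not core:
        return None, None
    defining = min(core, key=lambda t: (-avg_abundances[t], t))
    return defining, float(avg_abundances[defining])


def assign_to_cst(
    catalog: CSTCatalog, table: AbundanceTable, sample_id: str
) -> tuple[str, float]:
    """Nearest CST (status=cst only) by Pearson correlation with centroids."""
    called = catalog.called
    if not called:
        raise NoCSTError("catalog holds no called CSTs")
    if catalog.taxon_ids != table.taxon_ids:
        raise AlignmentError("catalog and table taxon sets differ")
    x = table.values[table.sample_index(sample_id), :]
    if x.std() == 0:
        raise DegenerateSampleError(
            f"sample {sample_id!r} has zero variance; correlation undefined"
        )
    best_label, best_r = None, -np.inf
    for c in called:
        centroid = c.mean_abundance
        if centroid is None or np.std(centroid) == 0:
            continue
        r = float(np.corrcoef(x, centroid)[0, 1])
        if r > best_r:
            best_label, best_r = c.label, r
    if best_label is None:
        raise NoCSTError("no CST centroid with nonzero variance")
    return best_label, best_r
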