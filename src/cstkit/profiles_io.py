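"""Reading, validation and alignment of abundance / metadata / EC / pathway tables.

All tables travel as TSV (UTF-8, ``.`` decimal). Abundance-like tables are
samples x features with the first column holding sample ids and the header
holding feature ids. Metadata is one row per sample with the fixed columns
``sample_id, bioproject, country, sampling_method, health_status``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyDatasetError,
    IdentifierError,
    TableParseError,
    ValidationError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

#: accepted sampling-method tokens and the anatomical compartment each maps to
COMPARTMENT_MAP: dict[str, str] = {
    "nasal_lavage": "nasal",
    "nasopharynx_swab": "nasal",
    "oropharynx_swab": "throat",
    "cough_swab": "throat",
    "sputum": "sputum",
    "lung_lavage": "lung",
    "biopsy": "other",
    "undefined_swab": "other",
}

COMPARTMENTS = ("nasal", "throat", "sputum", "lung", "other")
HEALTH_STATUSES = ("healthy", "diseased", "unknown")

METADATA_COLUMNS = ("sample_id", "bioproject", "country", "sampling_method", "health_status")

#: taxa matching this are not resolved to species level
_UNRESOLVED_RE = re.compile(r"(\ssp\.)|(\bunclassified\b)", re.IGNORECASE)

_EC_RE = re.compile(r"^\d+(\.\d+){0,3}$")

_ROW_SUM_TOL = 1e-9


def is_species_resolved(taxon: str) -> bool:
    """False for names like ``"Pasteurella sp."`` or ``"... unclassified"``."""
    return _UNRESOLVED_RE.search(taxon) is None


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of relative abundances (fractions in [0, 1]).

    Row sums may fall below 1: the residual is the fraction of reads not
    classified at species level. ``species_resolved`` flags, per taxon,
    whether the name resolves to species level.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    species_resolved: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.species_resolved is None:
            self.species_resolved = np.array(
                [is_species_resolved(t) for t in self.taxon_ids], dtype=bool
            )
        else:
            self.species_resolved = np.asarray(self.species_resolved, dtype=bool)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierError("duplicate sample ids in abundance table")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise IdentifierError("duplicate taxon ids in abundance table")
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("abundance table contains missing or non-finite values")
        if (self.values < 0).any():
            raise ValidationError("abundance table contains negative values")
        sums = self.values.sum(axis=1)
        bad = np.nonzero(sums > 1 + _ROW_SUM_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"sample {self.sample_ids[bad[0]]!r} has abundance sum {sums[bad[0]]:.6g} > 1"
            )

    # -- conversions -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise IdentifierError(f"unknown sample id {sample_id!r}") from None

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxon_ids.index(taxon)
        except ValueError:
            from .exceptions import UnknownTaxonError

            raise UnknownTaxonError(f"unknown taxon {taxon!r}") from None

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return AbundanceTable(
            sample_ids=list(sample_ids),
            taxon_ids=list(self.taxon_ids),
            values=self.values[idx, :],
            species_resolved=self.species_resolved.copy(),
        )

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.12g")


@dataclass
class ECTable:
    """Samples x EC-number matrix of relative abundances."""

    sample_ids: list[str]
    ec_numbers: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierError("duplicate sample ids in EC table")
        if len(set(self.ec_numbers)) != len(self.ec_numbers):
            raise IdentifierError("duplicate EC numbers in EC table")
        for ec in self.ec_numbers:
            if not _EC_RE.match(ec):
                raise TableParseError(f"malformed EC number {ec!r}")
        if (self.values < 0).any():
            raise ValidationError("EC table contains negative values")
        sums = self.values.sum(axis=1)
        bad = np.nonzero(sums > 1 + _ROW_SUM_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"sample {self.sample_ids[bad[0]]!r} has EC abundance sum > 1"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.ec_numbers)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.12g")


@dataclass
class PathwayTable:
    """Samples x pathway matrix of relative abundances (non-negative)."""

    sample_ids: list[str]
    pathway_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierError("duplicate sample ids in pathway table")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise IdentifierError("duplicate pathway ids in pathway table")
        if (self.values < 0).any():
            raise ValidationError("pathway table contains negative values")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.pathway_ids)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _read_matrix(path, delimiter: str) -> tuple[list[str], list[str], np.ndarray]:
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough
        raise TableParseError(f"could not read table {path}: {exc}") from exc
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise TableParseError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        raise ValidationError(f"missing values in {path}; tables must be complete")
    return sample_ids, feature_ids, values


def load_abundance_table(path, delimiter: str = "\t", percent: bool | None = None) -> AbundanceTable:
    """Load a samples x taxa TSV into a validated :class:`AbundanceTable`.

    ``percent=None`` autodetects the convention: any value above 1.5 means
    the table is in percentages and gets rescaled to fractions. Pass
    ``percent=True``/``False`` to override the autodetection.
    """
    sample_ids, taxon_ids, values = _read_matrix(path, delimiter)
    if (values < 0).any():
        raise ValidationError(f"negative abundance in {path}")
    if percent is None:
        percent = bool((values > 1.5).any())
    if percent:
        values = values / 100.0
    return AbundanceTable(sample_ids=sample_ids, taxon_ids=taxon_ids, values=values)


def load_ec_table(path, delimiter: str = "\t", percent: bool | None = None) -> ECTable:
    sample_ids, ec_numbers, values = _read_matrix(path, delimiter)
    if percent is None:
        percent = bool((values > 1.5).any())
    if percent:
        values = values / 100.0
    return ECTable(sample_ids=sample_ids, ec_numbers=ec_numbers, values=values)


def load_pathway_table(path, delimiter: str = "\t") -> PathwayTable:
    sample_ids, pathway_ids, values = _read_matrix(path, delimiter)
    return PathwayTable(sample_ids=sample_ids, pathway_ids=pathway_ids, values=values)


def derive_compartment(sampling_method: str) -> str:
    try:
        return COMPARTMENT_MAP[sampling_method]
    except KeyError:
        raise VocabularyError(
            f"unknown sampling_method {sampling_method!r}; accepted: "
            + ", ".join(sorted(COMPARTMENT_MAP))
        ) from None


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a metadata frame (indexed by sample_id).

    Adds the derived ``compartment`` column and fills missing
    ``health_status`` with ``"unknown"``.
    """
    df = df.copy()
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise IdentifierError(f"duplicate sample ids in metadata: {dupes[:5]}")
    for col in ("bioproject", "sampling_method"):
        if col not in df.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    if "country" not in df.columns:
        df["country"] = "unknown"
    if "health_status" not in df.columns:
        df["health_status"] = "unknown"
    df["health_status"] = df["health_status"].fillna("unknown")
    bad_status = set(df["health_status"]) - set(HEALTH_STATUSES)
    if bad_status:
        raise VocabularyError(
            f"unknown health_status value(s) {sorted(bad_status)}; accepted: "
            + ", ".join(HEALTH_STATUSES)
        )
    df["compartment"] = [derive_compartment(m) for m in df["sampling_method"]]
    return df[["bioproject", "country", "sampling_method", "compartment", "health_status"]]


def load_metadata(path, delimiter: str = "\t") -> pd.DataFrame:
    """Load per-sample metadata; returns a frame indexed by sample_id.

    Columns after loading: bioproject, country, sampling_method,
    compartment (derived), health_status.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError("metadata is missing required column 'sample_id'")
    df = df.set_index("sample_id")
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.drop(columns=["compartment"], errors="ignore")
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def align_dataset(
    table: AbundanceTable,
    meta: pd.DataFrame,
    drop_groups: set[str] = frozenset({"other"}),
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Intersect table and metadata sample sets and drop excluded compartments.

    Samples present in only one of the two inputs are dropped with a logged
    warning; samples whose compartment is in ``drop_groups`` are removed.
    The two outputs share one identical sample ordering (table order).
    """
    meta_ids = set(meta.index)
    keep = [s for s in table.sample_ids if s in meta_ids]
    missing_meta = [s for s in table.sample_ids if s not in meta_ids]
    if missing_meta:
        logger.warning("%d sample(s) missing from metadata, dropped: %s...",
                       len(missing_meta), missing_meta[:5])
    extra_meta = meta_ids - set(table.sample_ids)
    if extra_meta:
        logger.warning("%d metadata sample(s) absent from abundance table, dropped",
                       len(extra_meta))
    drop_groups = set(drop_groups)
    keep = [s for s in keep if meta.loc[s, "compartment"] not in drop_groups]
    if not keep:
        raise EmptyDatasetError("no samples remain after aligning table and metadata")
    return table.select_samples(keep), meta.loc[keep]
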