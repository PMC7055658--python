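"""Tabular I/O for fractionation-proteomics signal tables, annotations and call sheets.

The pipeline consumes one reporter-ion signal matrix per biological replicate
(proteins x channels, where the channels are the ten sucrose gradient fractions
f02..f11 plus the unfractionated "total" membrane reference), a protein
annotation table with STEPdb-style localization categories, and emits a
per-protein localization call table.

All tables are delimited text (tab by default, comma auto-detected), UTF-8,
with a header row. A raw signal of 0 or an empty cell marks a missing
measurement and is represented internally as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

log = logging.getLogger(__name__)

#: Quantified sucrose gradient fractions, low density to high density.
FRACTIONS: tuple[str, ...] = tuple(f"f{i:02d}" for i in range(2, 12))
#: The unfractionated total-membrane reference channel.
TOTAL_CHANNEL = "total"
#: Full channel vocabulary in canonical order.
CHANNELS: tuple[str, ...] = FRACTIONS + (TOTAL_CHANNEL,)

#: Low- and high-density fraction triplets entering the sucrose gradient ratio.
LOW_DENSITY_FRACTIONS: tuple[str, ...] = ("f02", "f03", "f04")
HIGH_DENSITY_FRACTIONS: tuple[str, ...] = ("f08", "f09", "f10")

#: STEPdb-style localization category vocabulary.
CATEGORIES: tuple[str, ...] = (
    "cytoplasmic",
    "periplasmic",
    "IM-integral",
    "IM-peri",
    "IMLP",
    "IM-cyto",
    "OMP",
    "OMLP",
    "other",
)

#: Localization classes the pipeline assigns.
LOCALIZATION_CLASSES: tuple[str, ...] = ("IM", "OM", "soluble")

_PROTEIN_ID_COLUMNS = ("protein_id", "protein", "uniprot_id", "id")
_PEPTIDE_COLUMN = "unique_peptides"

_CALL_COLUMNS = [
    "sucrose_ratio",
    "ratio_call",
    "cluster_rep1",
    "cluster_rep2",
    "cluster_avg",
    "cluster_call",
    "replicate_consistent",
    "consensus_call",
    "high_confidence",
    "exclusion_reason",
    "annotation_category",
    "annotation_match",
]


@dataclass
class SignalMatrix:
    """Protein x channel reporter-ion signals for one biological replicate.

    ``values`` is indexed by protein accession with one column per channel in
    canonical order (f02..f11, total). On the raw scale all observed values are
    finite and > 0; missing measurements are NaN. After normalization the
    matrix lives on a log-like scale recorded in ``scale``.
    """

    replicate_id: str
    values: pd.DataFrame
    unique_peptides: pd.Series | None = None
    scale: str = "raw"  # raw | glog2 | log2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cols = list(self.values.columns)
        if sorted(cols) != sorted(CHANNELS):
            missing = sorted(set(CHANNELS) - set(cols))
            extra = sorted(set(cols) - set(CHANNELS))
            raise FormatError(
                f"replicate {self.replicate_id!r}: channel columns must be exactly "
                f"{list(CHANNELS)}; missing {missing}, unexpected {extra}"
            )
        if cols != list(CHANNELS):
            self.values = self.values.loc[:, list(CHANNELS)]
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(
                f"replicate {self.replicate_id!r}: duplicate protein ids {dupes[:5]}"
            )
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError(f"replicate {self.replicate_id!r}: non-finite signal values")
        if self.scale == "raw" and np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError(f"replicate {self.replicate_id!r}: negative signal values")
        if self.unique_peptides is not None:
            self.unique_peptides = self.unique_peptides.reindex(self.values.index)

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_proteins(self) -> int:
        return len(self.values)

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(
            replicate_id=self.replicate_id,
            values=self.values.copy(),
            unique_peptides=None if self.unique_peptides is None else self.unique_peptides.copy(),
            scale=self.scale,
        )


@dataclass
class AnnotationTable:
    """Protein -> STEPdb-style localization category, one category per protein.

    ``benchmark_group`` collapses categories to the coarse classes used for
    calibration and compatibility checks: IM-integral and IM-peri (and, by
    default, IM lipoproteins) are IM; beta-barrel OMPs and OM lipoproteins are
    OM; cytoplasmic and periplasmic proteins are soluble; peripheral-IM
    ("IM-cyto") proteins keep their own ambiguous group; everything else is
    "other". An optional secondary category records dual prior annotations
    (e.g. a protein listed as both IM-peri and periplasmic).
    """

    categories: pd.Series
    secondary: pd.Series | None = None
    imlp_group: str = "IM"

    def __post_init__(self) -> None:
        bad = set(self.categories.unique()) - set(CATEGORIES)
        if bad:
            raise FormatError(f"unknown localization categories: {sorted(bad)}")
        if self.categories.index.has_duplicates:
            raise FormatError("annotation table lists a protein more than once")
        if self.imlp_group not in ("IM", "other"):
            raise ConfigurationError("imlp_group must be 'IM' or 'other'")

    def group_of(self, category: str) -> str:
        mapping = {
            "IM-integral": "IM",
            "IM-peri": "IM",
            "IMLP": self.imlp_group,
            "OMP": "OM",
            "OMLP": "OM",
            "cytoplasmic": "soluble",
            "periplasmic": "soluble",
            "IM-cyto": "IM-cyto",
            "other": "other",
        }
        return mapping[category]

    def benchmark_group(self) -> pd.Series:
        return self.categories.map(self.group_of).rename("benchmark_group")

    def category_for(self, protein_id: str) -> str | None:
        if protein_id in self.categories.index:
            return self.categories.loc[protein_id]
        return None


@dataclass
class LocalizationCalls:
    """Per-protein localization calls from both methods and their consensus."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CALL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"calls table missing columns: {missing}")
        self.frame = self.frame.loc[:, _CALL_COLUMNS]
        for col in ("ratio_call", "cluster_call", "consensus_call", "exclusion_reason",
                    "annotation_category", "annotation_match"):
            s = self.frame[col].astype(object)
            self.frame[col] = s.where(s.notna(), None)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        both = f["ratio_call"].notna() & f["cluster_call"].notna()
        agree = both & (f["ratio_call"] == f["cluster_call"])
        expected_hc = agree & f["replicate_consistent"].fillna(False).astype(bool)
        if not (f["high_confidence"].fillna(False).astype(bool) == expected_hc).all():
            raise ValidationError(
                "high_confidence must hold exactly when replicates are consistent "
                "and the two methods agree"
            )
        hc = f["high_confidence"].fillna(False).astype(bool)
        if not (f.loc[hc, "consensus_call"] == f.loc[hc, "ratio_call"]).all():
            raise ValidationError("high-confidence consensus must equal the shared call")
        if not (f.loc[~hc, "consensus_call"] == "excluded").all():
            raise ValidationError("non-high-confidence proteins must be 'excluded'")

    @property
    def protein_ids(self) -> pd.Index:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)


def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _find_protein_column(columns) -> str:
    for cand in _PROTEIN_ID_COLUMNS:
        if cand in columns:
            return cand
    raise FormatError(
        f"no protein identifier column found (expected one of {_PROTEIN_ID_COLUMNS}); "
        f"got columns {list(columns)[:6]}"
    )


def read_signal_matrix(path: str, replicate_id: str) -> SignalMatrix:
    """Read a delimited signal table into a validated :class:`SignalMatrix`.

    The file must contain a protein identifier column and one column per
    channel (f02..f11 and total). An f01 column, if present, is ignored with a
    warning (the first gradient fraction is not quantified). Zero or empty
    cells are parsed as missing.
    """
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    pid_col = _find_protein_column(raw.columns)
    missing = [c for c in CHANNELS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s) {missing}")
    if "f01" in raw.columns:
        log.warning("%s: ignoring f01 column (fraction 1 is not a pipeline input)", path)
    ids = raw[pid_col].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate protein id(s) {dupes[:5]}")
    values = raw[list(CHANNELS)].apply(pd.to_numeric, errors="coerce").astype(float)
    values.index = pd.Index(ids, name="protein_id")
    arr = values.to_numpy()
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValidationError(f"{path}: negative signal values are not allowed")
    # zero signal == undetected
    values = values.mask(values == 0.0)
    peptides = None
    if _PEPTIDE_COLUMN in raw.columns:
        peptides = pd.to_numeric(raw[_PEPTIDE_COLUMN], errors="coerce")
        peptides.index = values.index
    return SignalMatrix(replicate_id=replicate_id, values=values, unique_peptides=peptides)


def write_signal_matrix(m: SignalMatrix, path: str) -> None:
    """Write a signal matrix as a TSV (missing values as empty cells)."""
    out = m.values.copy()
    out.insert(0, "protein_id", out.index)
    if m.unique_peptides is not None:
        out.insert(1, _PEPTIDE_COLUMN, m.unique_peptides.values)
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path: str, imlp_group: str = "IM") -> AnnotationTable:
    """Read a protein -> category annotation TSV/CSV.

    Expected columns: protein identifier, ``category``; an optional
    ``secondary_category`` column records dual prior annotations.
    """
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    pid_col = _find_protein_column(raw.columns)
    if "category" not in raw.columns:
        raise FormatError(f"{path}: missing 'category' column")
    cats = pd.Series(raw["category"].values, index=pd.Index(raw[pid_col], name="protein_id"))
    secondary = None
    if "secondary_category" in raw.columns:
        secondary = pd.Series(
            raw["secondary_category"].values, index=cats.index
        ).replace("", np.nan).dropna()
    return AnnotationTable(categories=cats, secondary=secondary, imlp_group=imlp_group)


def write_annotation(ann: AnnotationTable, path: str) -> None:
    out = pd.DataFrame({"protein_id": ann.categories.index, "category": ann.categories.values})
    if ann.secondary is not None:
        out["secondary_category"] = (
            ann.secondary.reindex(ann.categories.index).fillna("").values
        )
    out.to_csv(path, sep="\t", index=False)


def filter_min_peptides(m: SignalMatrix, min_peptides: int = 2) -> SignalMatrix:
    """Restrict to proteins quantified with at least ``min_peptides`` unique peptides.

    The standard quality criterion keeps proteins with >= 2 unique peptides.
    """
    if min_peptides < 1:
        raise ConfigurationError("min_peptides must be >= 1")
    if m.unique_peptides is None:
        raise ConfigurationError(
            "signal matrix has no unique_peptides column; omit the peptide filter "
            "for tables without peptide counts"
        )
    keep = m.unique_peptides.fillna(0) >= min_peptides
    if not keep.any():
        log.warning(
            "replicate %s: no protein passes the >=%d unique-peptide filter",
            m.replicate_id, min_peptides,
        )
    return SignalMatrix(
        replicate_id=m.replicate_id,
        values=m.values.loc[keep],
        unique_peptides=m.unique_peptides.loc[keep],
        scale=m.scale,
    )


def intersect_replicates(a: SignalMatrix, b: SignalMatrix) -> tuple[SignalMatrix, SignalMatrix]:
    """Restrict both replicates to their common protein set, identical row order."""
    if list(a.values.columns) != list(b.values.columns):
        raise ValidationError("replicates have different channel vocabularies")
    shared = a.protein_ids.intersection(b.protein_ids)
    if len(shared) == 0:
        raise ValidationError("replicates share no proteins")
    # preserve replicate A's ordering for both
    order = [p for p in a.protein_ids if p in set(shared)]

    def _take(m: SignalMatrix) -> SignalMatrix:
        return SignalMatrix(
            replicate_id=m.replicate_id,
            values=m.values.loc[order],
            unique_peptides=None if m.unique_peptides is None else m.unique_peptides.loc[order],
            scale=m.scale,
        )

    return _take(a), _take(b)


def write_calls(calls: LocalizationCalls, path: str) -> None:
    """Write the calls table as TSV; re-reading reproduces it bit-exactly."""
    if len(calls) == 0:
        raise ValidationError("refusing to write an empty calls table")
    out = calls.frame.copy()
    out.insert(0, "protein_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> LocalizationCalls:
    """Read a calls table written by :func:`write_calls`."""
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    pid_col = _find_protein_column(raw.columns)
    raw = raw.set_index(pid_col)
    raw.index = raw.index.astype(str)
    raw.index.name = "protein_id"
    for col in ("replicate_consistent", "high_confidence"):
        raw[col] = raw[col].map({True: True, False: False, "True": True, "False": False})
    for col in ("cluster_rep1", "cluster_rep2", "cluster_avg"):
        raw[col] = raw[col].astype("Int64")
    for col in ("ratio_call", "cluster_call", "consensus_call", "exclusion_reason",
                "annotation_category", "annotation_match"):
        raw[col] = raw[col].astype(object).where(raw[col].notna(), None)
    return LocalizationCalls(frame=raw)
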