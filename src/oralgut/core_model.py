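"""Shared domain types and tabular I/O for the oral-to-gut invasion pipeline.

The pipeline works at the level of *gene abundance tables* (genes x samples
read counts obtained by mapping shotgun reads against a gut and an oral gene
catalogue) and *MSP abundance tables* (metagenomic species pangenomes x
samples).  This module holds the containers shared by all stages plus
readers/writers for the plain TSV formats the pipeline exchanges.

TSV dialect: tab-separated, UTF-8, ``.`` decimal separator; lines starting
with ``#`` are comments / metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PipelineError",
    "FormatError",
    "InputError",
    "ConfigError",
    "SAMPLE_TYPES",
    "NICHE_LABELS",
    "UNASSIGNED_ROW",
    "SampleMeta",
    "GeneCatalogue",
    "GeneAbundanceTable",
    "MSPAbundanceTable",
    "read_gene_table",
    "write_gene_table",
    "read_msp_table",
    "write_msp_table",
    "read_catalogue",
    "write_catalogue",
    "read_sample_meta",
    "write_sample_meta",
    "read_taxonomy",
    "write_taxonomy",
    "validate_catalogue",
]


class PipelineError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PipelineError):
    """A file does not conform to the expected tabular format."""


class InputError(PipelineError):
    """Structurally valid inputs that violate an operation's precondition."""


class ConfigError(PipelineError):
    """An out-of-range or inconsistent configuration value."""


SAMPLE_TYPES = ("stool", "raw_saliva", "enriched_saliva", "luminal", "mucosal")
NICHE_LABELS = ("gut", "oral", "ND")
CATALOGUE_NAMES = ("gut", "oral")

#: sentinel row name holding reads mapped to no catalogue gene (host / unknown)
UNASSIGNED_ROW = "__unassigned__"


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample.

    ``day`` is the fermentation day (0 = inoculum); it may be ``None`` for
    baseline stool / raw saliva samples whose collection day is irrelevant
    to the analysis.  Exactly one baseline stool and one baseline raw-saliva
    sample per donor must carry ``is_baseline=True``: these two samples
    define the ecological-niche reference for that donor.
    """

    sample_id: str
    donor: str
    sample_type: str
    day: int | None = None
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise InputError(
                f"unknown sample_type {self.sample_type!r} for sample "
                f"{self.sample_id!r}; expected one of {SAMPLE_TYPES}"
            )
        if self.day is not None and self.day < 0:
            raise InputError(f"negative day for sample {self.sample_id!r}")

    @property
    def is_bioreactor(self) -> bool:
        return self.sample_type in ("luminal", "mucosal")


def meta_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Tabulate a list of :class:`SampleMeta`, indexed by sample id."""
    df = pd.DataFrame([dataclasses.asdict(m) for m in meta])
    if df.empty:
        raise InputError("empty sample metadata")
    return df.set_index("sample_id")


def check_baselines(meta: Sequence[SampleMeta]) -> None:
    """Ensure each donor has exactly one baseline stool and raw-saliva sample."""
    df = meta_frame(meta)
    for donor, sub in df.groupby("donor"):
        for stype in ("stool", "raw_saliva"):
            n = int(((sub.sample_type == stype) & sub.is_baseline).sum())
            if n != 1:
                raise InputError(
                    f"donor {donor!r}: expected exactly one baseline {stype} "
                    f"sample, found {n}"
                )


# ---------------------------------------------------------------------------
# gene catalogue
# ---------------------------------------------------------------------------


@dataclass
class GeneCatalogue:
    """Gene-to-MSP membership for a paired gut + oral catalogue.

    ``genes`` is indexed by gene id with columns ``msp_id`` (str),
    ``is_marker`` (bool), ``length_weight`` (positive float) and
    ``catalogue`` ('gut' or 'oral').  ``overlap_pairs`` declares which
    gut-catalogue MSP and oral-catalogue MSP represent the same species;
    each MSP may appear in at most one pair.
    """

    genes: pd.DataFrame
    overlap_pairs: list[tuple[str, str]] = field(default_factory=list)
    markers_per_msp: int = 100

    def msp_ids(self, catalogue: str | None = None) -> pd.Index:
        sub = self.genes if catalogue is None else self.genes[self.genes["catalogue"] == catalogue]
        return pd.Index(pd.unique(sub["msp_id"]))

    def marker_genes(self, catalogue: str) -> pd.DataFrame:
        sub = self.genes
        mask = (sub["catalogue"] == catalogue) & sub["is_marker"]
        return sub[mask]

    def catalogue_of_msp(self) -> pd.Series:
        return self.genes.groupby("msp_id")["catalogue"].first()


def validate_catalogue(cat: GeneCatalogue) -> list[str]:
    """Check every catalogue invariant; return a list of violations.

    The empty list means the catalogue is well formed.  Never mutates.
    """
    problems: list[str] = []
    genes = cat.genes

    dup = genes.index[genes.index.duplicated()]
    for g in pd.unique(dup):
        problems.append(f"duplicate gene_id {g!r}")

    bad_cat = genes.loc[~genes["catalogue"].isin(CATALOGUE_NAMES), "catalogue"]
    for value in pd.unique(bad_cat):
        problems.append(f"unknown catalogue value {value!r}")

    if (genes["length_weight"] <= 0).any():
        bad = genes.index[genes["length_weight"] <= 0]
        problems.append(f"non-positive length_weight for genes {list(bad[:5])}")

    grouped = genes.groupby("msp_id")
    marker_counts = grouped["is_marker"].sum()
    for msp, n_markers in marker_counts.items():
        if int(n_markers) != cat.markers_per_msp:
            problems.append(
                f"MSP {msp!r} has {int(n_markers)} marker genes, "
                f"expected {cat.markers_per_msp}"
            )
    n_catalogues = grouped["catalogue"].nunique()
    for msp in n_catalogues.index[n_catalogues > 1]:
        problems.append(f"MSP {msp!r} spans both catalogues")

    cat_of = genes.drop_duplicates().groupby("msp_id")["catalogue"].first()
    seen: dict[str, int] = {}
    for i, (gut_msp, oral_msp) in enumerate(cat.overlap_pairs):
        for msp, side in ((gut_msp, "gut"), (oral_msp, "oral")):
            if msp not in cat_of.index:
                problems.append(f"overlap pair {i} references unknown MSP {msp!r}")
            elif cat_of[msp] != side:
                problems.append(
                    f"overlap pair {i}: MSP {msp!r} is from the "
                    f"{cat_of[msp]} catalogue, expected {side}"
                )
            if msp in seen:
                problems.append(
                    f"MSP {msp!r} appears in overlap pairs {seen[msp]} and {i}"
                )
            else:
                seen[msp] = i
    return problems


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------


@dataclass
class GeneAbundanceTable:
    """Genes x samples non-negative count matrix, the pipeline entry format.

    ``unassigned`` optionally holds, per sample, the number of reads mapped
    to no catalogue gene (host or unknown origin); it lets mapping-rate
    summaries be computed downstream.
    """

    counts: pd.DataFrame
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise FormatError("gene counts must be finite and non-negative")
        if self.unassigned is not None:
            self.unassigned = self.unassigned.reindex(self.counts.columns)
            if self.unassigned.isna().any() or (self.unassigned < 0).any():
                raise FormatError("unassigned counts must cover every sample and be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> pd.Series:
        """Assigned + unassigned reads per sample."""
        tot = self.counts.sum(axis=0)
        if self.unassigned is not None:
            tot = tot + self.unassigned
        return tot


@dataclass
class MSPAbundanceTable:
    """MSPs x samples abundance matrix, raw or per-sample normalized.

    An abundance of 0 means the MSP failed the marker-detection rule in
    that sample.  ``provenance`` records each MSP's catalogue of origin
    after merging ('gut', 'oral', or 'both' for overlap-merged species).
    """

    abundance: pd.DataFrame
    normalized: bool = False
    provenance: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.abundance.to_numpy()
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            raise FormatError("MSP abundances must be finite and non-negative")
        if self.normalized and values.size:
            sums = values.sum(axis=0)
            live = sums > 0
            if np.abs(sums[live] - 1.0).max(initial=0.0) > 1e-9:
                raise FormatError("normalized table has sample sums != 1")

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def msps(self) -> list[str]:
        return list(self.abundance.index)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: {exc}") from exc


def read_gene_table(path: str | Path) -> GeneAbundanceTable:
    """Parse a gene abundance TSV (header of sample ids, first column gene_id).

    An optional ``__unassigned__`` row is moved to the ``unassigned`` field.
    Row order of the file is preserved.
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene_id {dup[0]!r}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing or ragged cells")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative abundance cell")
    unassigned = None
    if UNASSIGNED_ROW in df.index:
        unassigned = df.loc[UNASSIGNED_ROW]
        df = df.drop(index=UNASSIGNED_ROW)
    df.columns = df.columns.astype(str)
    return GeneAbundanceTable(counts=df, unassigned=unassigned)


def write_gene_table(table: GeneAbundanceTable, path: str | Path) -> None:
    df = table.counts
    if table.unassigned is not None:
        df = pd.concat([df, table.unassigned.rename(UNASSIGNED_ROW).to_frame().T])
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_msp_table(path: str | Path) -> MSPAbundanceTable:
    """Read an MSP abundance TSV written by :func:`write_msp_table`."""
    normalized = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "normalized":
                normalized = value.strip().lower() == "true"
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MSPAbundanceTable(abundance=df.astype(float), normalized=normalized)


def write_msp_table(table: MSPAbundanceTable, path: str | Path) -> None:
    """Write an MSP abundance table; round-trips to 1e-12 per cell."""
    if not table.samples:
        raise InputError("empty table")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# normalized={'true' if table.normalized else 'false'}\n")
        out = table.abundance.copy()
        out.index.name = "msp_id"
        out.to_csv(fh, sep="\t", float_format="%.17g")


def read_catalogue(
    genes_path: str | Path,
    overlaps_path: str | Path | None = None,
    markers_per_msp: int = 100,
) -> GeneCatalogue:
    df = _read_tsv(genes_path, dtype={"gene_id": str, "msp_id": str, "catalogue": str})
    expected = ["gene_id", "msp_id", "is_marker", "length_weight", "catalogue"]
    if list(df.columns) != expected:
        raise FormatError(f"{genes_path}: expected columns {expected}, got {list(df.columns)}")
    df["is_marker"] = df["is_marker"].astype(int).astype(bool)
    df = df.set_index("gene_id")
    pairs: list[tuple[str, str]] = []
    if overlaps_path is not None:
        ov = _read_tsv(overlaps_path, dtype=str)
        if list(ov.columns) != ["gut_msp_id", "oral_msp_id"]:
            raise FormatError(f"{overlaps_path}: expected columns gut_msp_id, oral_msp_id")
        pairs = list(ov.itertuples(index=False, name=None))
    return GeneCatalogue(genes=df, overlap_pairs=pairs, markers_per_msp=markers_per_msp)


def write_catalogue(
    cat: GeneCatalogue, genes_path: str | Path, overlaps_path: str | Path | None = None
) -> None:
    out = cat.genes.copy()
    out["is_marker"] = out["is_marker"].astype(int)
    out.index.name = "gene_id"
    out.to_csv(genes_path, sep="\t", float_format="%.17g")
    if overlaps_path is not None:
        pd.DataFrame(cat.overlap_pairs, columns=["gut_msp_id", "oral_msp_id"]).to_csv(
            overlaps_path, sep="\t", index=False
        )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path, dtype={"sample_id": str, "donor": str, "sample_type": str})
    metas = []
    for row in df.itertuples(index=False):
        day = None if pd.isna(row.day) else int(row.day)
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                donor=row.donor,
                sample_type=row.sample_type,
                day=day,
                is_baseline=bool(int(row.is_baseline)),
            )
        )
    return metas


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    df = meta_frame(meta).reset_index()
    df["is_baseline"] = df["is_baseline"].astype(int)
    df["day"] = df["day"].astype("Int64")
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV: msp_id, species, genus, family, phylum (ranks may be empty)."""
    df = _read_tsv(path, dtype=str).fillna("")
    expected = ["msp_id", "species", "genus", "family", "phylum"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df["msp_id"].duplicated().any():
        dup = df.loc[df["msp_id"].duplicated(), "msp_id"].iloc[0]
        raise FormatError(f"{path}: duplicate msp_id {dup!r}")
    return df.set_index("msp_id")


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    out = tax.copy()
    out.index.name = "msp_id"
    out.to_csv(path, sep="\t")
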