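"""MSP quantification: gene counts -> merged, normalized species abundances.

The estimator is the field's standard marker-gene rule: the abundance of a
metagenomic species pangenome (MSP) in a sample is the arithmetic mean over
all of its marker genes (zeros included), reported only when at least a
fraction ``min_marker_fraction`` (default 10%) of the markers have strictly
positive abundance; otherwise the species counts as undetected (0).

Gut- and oral-catalogue tables are then merged into a single species table:
for each declared overlap pair the oral member is dropped and the retained
gut identifier carries, per sample, the elementwise maximum of the pair
(configurable), so the same biological species is never double counted.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    CATALOGUE_NAMES,
    GeneAbundanceTable,
    GeneCatalogue,
    InputError,
    MSPAbundanceTable,
)

__all__ = [
    "quantify_msp",
    "merge_tables",
    "normalize",
    "richness",
    "downsample",
    "mapping_rate",
]


def quantify_msp(
    genes: GeneAbundanceTable,
    cat: GeneCatalogue,
    min_marker_fraction: float = 0.10,
    length_normalize: bool = False,
) -> dict[str, MSPAbundanceTable]:
    """Estimate MSP abundances per catalogue from a gene abundance table.

    Parameters
    ----------
    genes
        Gene x sample counts; must contain a row for every marker gene of
        the catalogue (non-marker genes are ignored and may be absent).
    cat
        Paired gut/oral catalogue.
    min_marker_fraction
        Detection threshold: an MSP is detected in a sample when at least
        ``ceil(min_marker_fraction * n_markers)`` of its marker genes have
        strictly positive abundance ("at least 10%" is inclusive).
    length_normalize
        Divide each marker count by its catalogue ``length_weight`` before
        averaging.  Off by default: abundances are treated as plain read
        counts.

    Returns
    -------
    dict mapping 'gut' / 'oral' to an (unnormalized) MSP table.
    """
    if not 0.0 < min_marker_fraction <= 1.0:
        raise InputError("min_marker_fraction must be in (0, 1]")
    out: dict[str, MSPAbundanceTable] = {}
    for catalogue in CATALOGUE_NAMES:
        markers = cat.marker_genes(catalogue)
        missing = markers.index.difference(genes.counts.index)
        if len(missing):
            raise InputError(
                f"marker gene {missing[0]!r} of the {catalogue} catalogue is "
                f"missing from the gene abundance table"
            )
        if markers.empty:
            out[catalogue] = MSPAbundanceTable(
                abundance=pd.DataFrame(index=pd.Index([], name="msp_id"),
                                       columns=genes.counts.columns, dtype=float)
            )
            continue
        mat = genes.counts.loc[markers.index].to_numpy(dtype=float)
        if length_normalize:
            mat = mat / markers["length_weight"].to_numpy()[:, None]
        codes, msps = pd.factorize(markers["msp_id"])
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
        starts = np.concatenate([[0], boundaries])
        n_markers = np.diff(np.concatenate([starts, [len(sorted_codes)]]))

        sums = np.add.reduceat(mat[order], starts, axis=0)
        detected = np.add.reduceat((mat[order] > 0).astype(np.int64), starts, axis=0)
        thresholds = np.array(
            [math.ceil(min_marker_fraction * n) for n in n_markers]
        )[:, None]
        abundance = np.where(detected >= thresholds, sums / n_markers[:, None], 0.0)
        out[catalogue] = MSPAbundanceTable(
            abundance=pd.DataFrame(
                abundance, index=pd.Index(msps, name="msp_id"),
                columns=genes.counts.columns,
            ),
            provenance=pd.Series(catalogue, index=pd.Index(msps, name="msp_id")),
        )
    return out


def merge_tables(
    gut: MSPAbundanceTable,
    oral: MSPAbundanceTable,
    overlaps: Sequence[tuple[str, str]],
    strategy: str = "max",
) -> MSPAbundanceTable:
    """Merge the per-catalogue tables into one species-level table.

    For every overlap pair the oral member is dropped; the retained gut
    identifier holds, per sample, the elementwise ``max`` of the pair
    (default), the gut value (``'gut'``) or the sum (``'sum'``).
    """
    if strategy not in ("max", "gut", "sum"):
        raise InputError(f"unknown merge strategy {strategy!r}")
    if list(gut.samples) != list(oral.samples):
        raise InputError("gut and oral tables have different sample lists")
    gut_df = gut.abundance.copy()
    oral_df = oral.abundance.copy()
    drop: list[str] = []
    for gut_msp, oral_msp in overlaps:
        if gut_msp not in gut_df.index:
            raise InputError(f"overlap pair references unknown gut MSP {gut_msp!r}")
        if oral_msp not in oral_df.index:
            raise InputError(f"overlap pair references unknown oral MSP {oral_msp!r}")
        if strategy == "max":
            gut_df.loc[gut_msp] = np.maximum(
                gut_df.loc[gut_msp].to_numpy(), oral_df.loc[oral_msp].to_numpy()
            )
        elif strategy == "sum":
            gut_df.loc[gut_msp] = (
                gut_df.loc[gut_msp].to_numpy() + oral_df.loc[oral_msp].to_numpy()
            )
        drop.append(oral_msp)
    oral_df = oral_df.drop(index=drop)
    merged = pd.concat([gut_df, oral_df])
    paired_gut = {g for g, _ in overlaps}
    provenance = pd.Series(
        ["both" if m in paired_gut else "gut" for m in gut_df.index]
        + ["oral"] * len(oral_df.index),
        index=merged.index,
    )
    return MSPAbundanceTable(abundance=merged, normalized=False, provenance=provenance)


def normalize(table: MSPAbundanceTable) -> MSPAbundanceTable:
    """Per-sample relative abundances: each column divided by its own sum."""
    if table.normalized:
        raise InputError("table is already normalized")
    sums = table.abundance.sum(axis=0)
    dead = sums.index[sums <= 0]
    if len(dead):
        raise InputError(f"no detected MSP in sample {dead[0]!r}")
    return MSPAbundanceTable(
        abundance=table.abundance / sums,
        normalized=True,
        provenance=table.provenance,
    )


def richness(table: MSPAbundanceTable) -> pd.Series:
    """Number of detected (abundance > 0) MSPs per sample."""
    return (table.abundance > 0).sum(axis=0).rename("richness")


def downsample(
    genes: GeneAbundanceTable,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> GeneAbundanceTable:
    """Subsample every sample to a fixed read depth, without replacement.

    Draws from a multivariate hypergeometric distribution over the sample's
    gene rows plus its unassigned pool, mirroring read-level downsizing to
    equalize sequencing effort.  Column totals equal ``depth`` exactly.
    """
    if depth < 1:
        raise InputError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = genes.counts.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise InputError("downsampling requires integer counts")
    counts = np.round(counts).astype(np.int64)
    unassigned = (
        np.round(genes.unassigned.to_numpy()).astype(np.int64)
        if genes.unassigned is not None
        else np.zeros(counts.shape[1], dtype=np.int64)
    )
    totals = counts.sum(axis=0) + unassigned
    short = [s for s, t in zip(genes.samples, totals) if t < depth]
    if short:
        raise InputError(
            f"samples with fewer than {depth} total reads: {short}"
        )
    new_counts = np.empty_like(counts)
    new_unassigned = np.empty_like(unassigned)
    for j in range(counts.shape[1]):
        colors = np.concatenate([counts[:, j], [unassigned[j]]])
        draw = rng.multivariate_hypergeometric(colors, depth)
        new_counts[:, j] = draw[:-1]
        new_unassigned[j] = draw[-1]
    out = GeneAbundanceTable(
        counts=pd.DataFrame(
            new_counts.astype(float), index=genes.counts.index, columns=genes.counts.columns
        ),
        unassigned=(
            pd.Series(new_unassigned.astype(float), index=genes.counts.columns)
            if genes.unassigned is not None
            else None
        ),
    )
    return out


def mapping_rate(genes: GeneAbundanceTable, cat: GeneCatalogue) -> pd.DataFrame:
    """Fraction of each sample's reads assigned to each catalogue.

    Returns a samples x ('gut', 'oral', 'unassigned') frame whose rows sum
    to 1.  Requires the unassigned field (it is part of the denominator).
    """
    if genes.unassigned is None:
        raise InputError("mapping_rate requires the unassigned read counts")
    membership = cat.genes["catalogue"].reindex(genes.counts.index)
    if membership.isna().any():
        missing = genes.counts.index[membership.isna()][0]
        raise InputError(f"gene {missing!r} not present in the catalogue")
    rates = {}
    for catalogue in CATALOGUE_NAMES:
        rates[catalogue] = genes.counts[(membership == catalogue).to_numpy()].sum(axis=0)
    rates["unassigned"] = genes.unassigned
    df = pd.DataFrame(rates)
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        raise InputError("sample with zero total reads")
    return df.div(totals, axis=0)
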