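"""Ecological-niche assignment and oral-invasion analytics.

Every merged MSP gets a niche label from its strict occurrence in the two
baseline samples of its donor: detected only in the baseline stool -> gut;
only in the baseline raw saliva -> oral; in both or in neither -> not
determined (ND).  Oral invaders are then the oral-niche species detected in
any luminal or mucosal bioreactor sample; the module tracks them per
compartment and day, computes niche-split richness/abundance series,
Bray-Curtis dissimilarities, taxonomic rank compositions, and the Spearman
correlation between the invaders' abundance in enriched saliva and in the
mucosa.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr, rankdata

from .core_model import (
    InputError,
    MSPAbundanceTable,
    NICHE_LABELS,
    SampleMeta,
    check_baselines,
    meta_frame,
)

__all__ = [
    "InvasionReport",
    "CorrelationResult",
    "assign_niches",
    "niche_series",
    "detect_oral_invaders",
    "bray_curtis_matrix",
    "aggregate_by_rank",
    "invader_correlation",
    "build_invasion_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    source_sample: str
    target_sample: str
    rho: float
    p_value: float
    n: int


@dataclass
class InvasionReport:
    """Per-sample niche analytics plus the oral-invader detection matrix."""

    niche_richness: pd.DataFrame        # samples x (gut, oral, ND) counts
    niche_abundance: pd.DataFrame       # samples x (gut, oral, ND) rel. abundance
    invader_matrix: pd.DataFrame        # oral MSPs x bioreactor samples (normalized)
    pre_existing: pd.Series             # per invader MSP: detected before invasion?
    invader_summary: pd.DataFrame       # compartment, day, n_oral, phase
    correlations: list[CorrelationResult] = field(default_factory=list)


def _single_donor(meta: Sequence[SampleMeta], donor: str | None) -> list[SampleMeta]:
    donors = sorted({m.donor for m in meta})
    if donor is None:
        if len(donors) > 1:
            raise InputError(
                f"multiple donors present ({donors}); pass donor= to process one at a time"
            )
        return list(meta)
    return [m for m in meta if m.donor == donor]


def assign_niches(
    merged: MSPAbundanceTable,
    meta: Sequence[SampleMeta],
    detection_floor: float = 0.0,
    donor: str | None = None,
) -> pd.Series:
    """Label every merged MSP as gut, oral or ND from the donor baselines.

    Detection is abundance strictly greater than ``detection_floor``
    (default 0, the same rule quantification uses).  The map is total:
    species undetected in both baselines are ND, as are species detected in
    both.
    """
    meta = _single_donor(meta, donor)
    check_baselines(meta)
    stool = next(m for m in meta if m.sample_type == "stool" and m.is_baseline)
    saliva = next(m for m in meta if m.sample_type == "raw_saliva" and m.is_baseline)
    for m in (stool, saliva):
        if m.sample_id not in merged.abundance.columns:
            raise InputError(f"baseline sample {m.sample_id!r} missing from the table")
    in_stool = merged.abundance[stool.sample_id] > detection_floor
    in_saliva = merged.abundance[saliva.sample_id] > detection_floor
    labels = np.where(
        in_stool & ~in_saliva, "gut", np.where(in_saliva & ~in_stool, "oral", "ND")
    )
    return pd.Series(labels, index=merged.abundance.index, name="niche")


def niche_series(
    merged: MSPAbundanceTable,
    niches: pd.Series,
    meta: Sequence[SampleMeta],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample niche-split richness and summed relative abundance.

    Returns ``(richness, abundance)`` frames with columns (gut, oral, ND).
    The abundance triplet requires a normalized table; richness works on
    raw or normalized tables alike.
    """
    missing = merged.abundance.index.difference(niches.index)
    if len(missing):
        raise InputError(f"niche assignment does not cover MSP {missing[0]!r}")
    if not merged.normalized:
        raise InputError("niche abundance series requires a normalized table")
    sample_ids = [m.sample_id for m in meta if m.sample_id in merged.abundance.columns]
    ab = merged.abundance[sample_ids]
    labels = niches.reindex(ab.index)
    richness_df = pd.DataFrame(
        {label: (ab.loc[(labels == label).to_numpy()] > 0).sum(axis=0)
         for label in NICHE_LABELS}
    )
    abundance_df = pd.DataFrame(
        {label: ab.loc[(labels == label).to_numpy()].sum(axis=0) for label in NICHE_LABELS}
    )
    return richness_df[list(NICHE_LABELS)], abundance_df[list(NICHE_LABELS)]


def detect_oral_invaders(
    merged: MSPAbundanceTable,
    niches: pd.Series,
    meta: Sequence[SampleMeta],
    first_injection_day: int = 9,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Track oral-niche MSPs across the bioreactor compartments.

    Returns ``(invader_matrix, pre_existing, summary)``:

    * ``invader_matrix`` — every oral-niche MSP detected in at least one
      luminal or mucosal sample, with its per-sample abundance;
    * ``pre_existing`` — flag per invader: already detected in a bioreactor
      sample before ``first_injection_day`` (day < threshold = pre-invasion);
    * ``summary`` — per compartment and day, the count of detected oral
      MSPs and the invasion phase ('pre' or 'post').
    """
    bio = [m for m in meta if m.is_bioreactor and m.sample_id in merged.abundance.columns]
    if not bio:
        raise InputError("no luminal or mucosal samples in the metadata")
    oral_msps = niches.index[niches == "oral"].intersection(merged.abundance.index)
    bio_ids = [m.sample_id for m in bio]
    sub = merged.abundance.loc[oral_msps, bio_ids]
    detected_any = (sub > 0).any(axis=1)
    invaders = sub.index[detected_any]
    invader_matrix = sub.loc[invaders]

    pre_ids = [m.sample_id for m in bio if m.day is not None and m.day < first_injection_day]
    pre_existing = (invader_matrix[pre_ids] > 0).any(axis=1).rename("pre_existing")

    rows = []
    for m in sorted(bio, key=lambda m: (m.sample_type, m.day)):
        n_oral = int((invader_matrix[m.sample_id] > 0).sum())
        phase = "pre" if (m.day is not None and m.day < first_injection_day) else "post"
        rows.append((m.sample_type, m.day, n_oral, phase))
    summary = pd.DataFrame(rows, columns=["compartment", "day", "n_oral", "phase"])
    return invader_matrix, pre_existing, summary


def bray_curtis_matrix(table: MSPAbundanceTable) -> pd.DataFrame:
    """All-pairs Bray-Curtis dissimilarity, 1 - 2 sum(min) / (sum x + sum y).

    Requires a normalized table; the result is symmetric with a zero
    diagonal and values in [0, 1].
    """
    if not table.normalized:
        raise InputError("Bray-Curtis requires a normalized table")
    data = table.abundance.to_numpy().T
    dm = squareform(pdist(data, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.samples, columns=table.samples)


def aggregate_by_rank(
    table: MSPAbundanceTable,
    tax: pd.DataFrame,
    rank: str,
) -> pd.DataFrame:
    """Sum normalized abundances within each value of a taxonomic rank.

    MSPs with an empty rank value, or missing from the taxonomy altogether
    (warned about, not fatal), are pooled under ``'unclassified'``.  Column
    sums are preserved.
    """
    if rank not in ("phylum", "family", "genus"):
        raise InputError(f"unsupported rank {rank!r}")
    if not table.normalized:
        raise InputError("rank aggregation requires a normalized table")
    labels = tax[rank].reindex(table.abundance.index)
    n_missing = int(labels.isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} MSPs missing from the taxonomy; pooled as 'unclassified'",
            stacklevel=2,
        )
    labels = labels.fillna("").replace("", "unclassified")
    return table.abundance.groupby(labels.to_numpy()).sum()


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n <= 10)."""
    n = len(x_ranks)
    xs = (x_ranks - x_ranks.mean()) / x_ranks.std()
    ys = (y_ranks - y_ranks.mean()) / y_ranks.std()
    count = 0
    total = 0
    batch: list[tuple[int, ...]] = []

    def flush(batch: list[tuple[int, ...]]) -> int:
        perm = np.array(batch)
        rhos = (xs[perm] * ys).mean(axis=1)
        return int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())

    for p in itertools.permutations(range(n)):
        batch.append(p)
        total += 1
        if len(batch) == 100_000:
            count += flush(batch)
            batch = []
    if batch:
        count += flush(batch)
    return count / total


def invader_correlation(
    source_sample: str,
    target_sample: str,
    invaders: Iterable[str],
    table: MSPAbundanceTable,
    exact: bool = False,
) -> CorrelationResult:
    """Spearman correlation of the invaders' abundance in two samples.

    Average ranks for ties; two-sided p-value from the t-approximation, or
    an exact permutation p-value when ``exact=True`` (only for n <= 10).
    Typical use: enriched saliva (source) vs a mucosal sample (target).
    """
    invaders = sorted(set(invaders))
    missing = [m for m in invaders if m not in table.abundance.index]
    if missing:
        raise InputError(f"invader MSP {missing[0]!r} missing from the table")
    for s in (source_sample, target_sample):
        if s not in table.abundance.columns:
            raise InputError(f"sample {s!r} missing from the table")
    if len(invaders) < 3:
        raise InputError("correlation undefined: fewer than 3 invader MSPs")
    x = table.abundance.loc[invaders, source_sample].to_numpy()
    y = table.abundance.loc[invaders, target_sample].to_numpy()
    res = spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    if exact:
        if len(invaders) > 10:
            raise InputError("exact permutation p-value limited to n <= 10")
        p = _exact_spearman_p(rankdata(x), rankdata(y), rho)
    return CorrelationResult(source_sample, target_sample, rho, p, len(invaders))


def build_invasion_report(
    merged_normalized: MSPAbundanceTable,
    meta: Sequence[SampleMeta],
    first_injection_day: int = 9,
    detection_floor: float = 0.0,
    donor: str | None = None,
    correlate: bool = True,
) -> InvasionReport:
    """Assemble the full invasion report for one donor.

    Computes niche labels, niche-split series, the invader matrix, and (when
    possible) the Spearman correlation between each enriched-saliva sample
    and the latest mucosal sample over the detected invaders.
    """
    meta = _single_donor(meta, donor)
    niches = assign_niches(merged_normalized, meta, detection_floor=detection_floor)
    richness_df, abundance_df = niche_series(merged_normalized, niches, meta)
    invader_matrix, pre_existing, summary = detect_oral_invaders(
        merged_normalized, niches, meta, first_injection_day=first_injection_day
    )
    correlations: list[CorrelationResult] = []
    if correlate and len(invader_matrix.index) >= 3:
        mucosal = [m for m in meta if m.sample_type == "mucosal"
                   and m.sample_id in merged_normalized.abundance.columns]
        enriched = [m for m in meta if m.sample_type == "enriched_saliva"
                    and m.sample_id in merged_normalized.abundance.columns]
        if mucosal:
            target = max(mucosal, key=lambda m: m.day)
            for src in sorted(enriched, key=lambda m: m.day):
                correlations.append(
                    invader_correlation(
                        src.sample_id, target.sample_id,
                        invader_matrix.index, merged_normalized,
                    )
                )
    return InvasionReport(
        niche_richness=richness_df,
        niche_abundance=abundance_df,
        invader_matrix=invader_matrix,
        pre_existing=pre_existing,
        invader_summary=summary,
        correlations=correlations,
    )
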