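"""Marker-mean MSP quantification, merge, normalization, downsampling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from oralgut import (
    GeneAbundanceTable,
    GeneCatalogue,
    InputError,
    MSPAbundanceTable,
    downsample,
    mapping_rate,
    merge_tables,
    normalize,
    quantify_msp,
    richness,
)


def micro_catalogue(n_msps=3, n_markers=100, n_extra=20, catalogue="gut", prefix="m"):
    """A catalogue with n_msps MSPs of n_markers markers + n_extra other genes."""
    rows = []
    for i in range(n_msps):
        msp = f"{prefix}{i:02d}"
        for k in range(n_markers + n_extra):
            rows.append((f"{msp}.g{k:03d}", msp, k < n_markers, 1.0, catalogue))
    df = pd.DataFrame(
        rows, columns=["gene_id", "msp_id", "is_marker", "length_weight", "catalogue"]
    ).set_index("gene_id")
    return GeneCatalogue(genes=df, overlap_pairs=[], markers_per_msp=n_markers)


def gene_table_for(cat, fill):
    """Gene table whose marker values come from fill(msp_index, marker_index)."""
    values = {}
    for gene, row in cat.genes.iterrows():
        i = int(row["msp_id"][-2:])
        k = int(gene.split(".g")[-1])
        values[gene] = fill(i, k) if row["is_marker"] else 0.0
    return GeneAbundanceTable(
        counts=pd.DataFrame({"s0": pd.Series(values, dtype=float)})
    )


def brute_force_quantify(genes, cat, min_marker_fraction=0.10):
    """Independent per-MSP loop oracle for the marker mean / threshold rule."""
    out = {}
    for catalogue in ("gut", "oral"):
        markers = cat.genes[(cat.genes["catalogue"] == catalogue) & cat.genes["is_marker"]]
        result = {}
        for msp in pd.unique(markers["msp_id"]):
            ids = markers.index[markers["msp_id"] == msp]
            per_sample = {}
            for s in genes.samples:
                vals = [genes.counts.at[g, s] for g in ids]
                d = sum(v > 0 for v in vals)
                per_sample[s] = (
                    sum(vals) / len(vals)
                    if d >= math.ceil(min_marker_fraction * len(vals))
                    else 0.0
                )
            result[msp] = per_sample
        out[catalogue] = pd.DataFrame(result).T
    return out


class TestQuantify:
    def test_uniform_markers_give_their_value(self):
        cat = micro_catalogue(1)
        t = gene_table_for(cat, lambda i, k: 5.0)
        assert quantify_msp(t, cat)["gut"].abundance.at["m00", "s0"] == 5.0

    def test_nine_percent_detection_is_below_threshold(self):
        cat = micro_catalogue(1)
        t = gene_table_for(cat, lambda i, k: 3.0 if k < 9 else 0.0)
        assert quantify_msp(t, cat)["gut"].abundance.at["m00", "s0"] == 0.0

    def test_inclusive_ten_percent_boundary(self):
        # exactly 10 of 100 markers at 3.0 -> detected, mean = 30/100 = 0.30
        cat = micro_catalogue(1)
        t = gene_table_for(cat, lambda i, k: 3.0 if k < 10 else 0.0)
        assert quantify_msp(t, cat)["gut"].abundance.at["m00", "s0"] == pytest.approx(0.30)

    def test_non_marker_genes_are_ignored(self):
        cat = micro_catalogue(1)
        t = gene_table_for(cat, lambda i, k: 2.0)
        t.counts.loc[t.counts.index.str.endswith("g115")] = 1e6  # a non-marker gene
        assert quantify_msp(t, cat)["gut"].abundance.at["m00", "s0"] == 2.0

    def test_missing_marker_gene_is_named(self):
        cat = micro_catalogue(1)
        t = gene_table_for(cat, lambda i, k: 1.0)
        t.counts.drop(index="m00.g000", inplace=True)
        with pytest.raises(InputError, match="m00.g000"):
            quantify_msp(t, cat)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        cat = micro_catalogue(n_msps=10, n_markers=20, n_extra=5)
        counts = rng.integers(0, 3, size=(len(cat.genes), 4)).astype(float)
        counts[rng.random(counts.shape) < 0.7] = 0.0
        genes = GeneAbundanceTable(
            counts=pd.DataFrame(counts, index=cat.genes.index,
                                columns=[f"s{j}" for j in range(4)])
        )
        got = quantify_msp(genes, cat)["gut"].abundance
        expected = brute_force_quantify(genes, cat)["gut"]
        pd.testing.assert_frame_equal(
            got.sort_index(), expected.sort_index(), check_names=False
        )

    def test_scaling_equivariance(self, rng):
        cat = micro_catalogue(n_msps=5, n_markers=20, n_extra=0)
        counts = rng.integers(0, 4, size=(len(cat.genes), 2)).astype(float)
        genes = GeneAbundanceTable(
            counts=pd.DataFrame(counts, index=cat.genes.index, columns=["s0", "s1"])
        )
        base = quantify_msp(genes, cat)["gut"]
        scaled_genes = GeneAbundanceTable(counts=genes.counts * [7.0, 1.0])
        scaled = quantify_msp(scaled_genes, cat)["gut"]
        assert np.allclose(scaled.abundance["s0"], base.abundance["s0"] * 7.0)
        assert np.allclose(scaled.abundance["s1"], base.abundance["s1"])
        assert richness(scaled).equals(richness(base))
        if (base.abundance.sum(axis=0) > 0).all():
            pd.testing.assert_frame_equal(
                normalize(scaled).abundance, normalize(base).abundance
            )


def random_pair(rng, n_gut=4, n_oral=4, n_samples=3, n_overlap=2):
    samples = [f"s{j}" for j in range(n_samples)]
    gut = MSPAbundanceTable(abundance=pd.DataFrame(
        rng.gamma(1.0, 1.0, size=(n_gut, n_samples)),
        index=[f"g{i}" for i in range(n_gut)], columns=samples))
    oral = MSPAbundanceTable(abundance=pd.DataFrame(
        rng.gamma(1.0, 1.0, size=(n_oral, n_samples)),
        index=[f"o{i}" for i in range(n_oral)], columns=samples))
    overlaps = [(f"g{i}", f"o{i}") for i in range(n_overlap)]
    return gut, oral, overlaps


class TestMerge:
    def test_disjoint_union(self, rng):
        gut, oral, _ = random_pair(rng, n_gut=3, n_oral=3, n_overlap=0)
        merged = merge_tables(gut, oral, [])
        assert len(merged.msps) == 6

    def test_overlap_takes_elementwise_max_under_gut_id(self):
        gut = MSPAbundanceTable(abundance=pd.DataFrame({"s0": [2.0]}, index=["g0"]))
        oral = MSPAbundanceTable(abundance=pd.DataFrame({"s0": [5.0]}, index=["o0"]))
        merged = merge_tables(gut, oral, [("g0", "o0")])
        assert merged.msps == ["g0"]
        assert merged.abundance.at["g0", "s0"] == 5.0
        assert merged.provenance["g0"] == "both"

    @pytest.mark.parametrize("strategy, expected", [("gut", 2.0), ("max", 5.0), ("sum", 7.0)])
    def test_merge_strategies(self, strategy, expected):
        gut = MSPAbundanceTable(abundance=pd.DataFrame({"s0": [2.0]}, index=["g0"]))
        oral = MSPAbundanceTable(abundance=pd.DataFrame({"s0": [5.0]}, index=["o0"]))
        merged = merge_tables(gut, oral, [("g0", "o0")], strategy=strategy)
        assert merged.abundance.at["g0", "s0"] == expected

    def test_sample_mismatch_rejected(self, rng):
        gut, oral, _ = random_pair(rng)
        oral.abundance.columns = ["x0", "x1", "x2"]
        with pytest.raises(InputError, match="sample lists"):
            merge_tables(gut, oral, [])

    def test_unknown_overlap_msp_rejected(self, rng):
        gut, oral, _ = random_pair(rng)
        with pytest.raises(InputError, match="ghost"):
            merge_tables(gut, oral, [("ghost", "o0")])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_drop_then_max_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_overlap = int(rng.integers(0, 4))
        gut, oral, overlaps = random_pair(
            rng, n_gut=5, n_oral=5, n_overlap=n_overlap
        )
        merged = merge_tables(gut, oral, overlaps)
        assert len(merged.msps) == 10 - n_overlap
        # independent row-by-row reconstruction
        for msp in merged.msps:
            paired = dict(overlaps)
            if msp in paired:
                expect = np.maximum(
                    gut.abundance.loc[msp].to_numpy(),
                    oral.abundance.loc[paired[msp]].to_numpy(),
                )
            elif msp.startswith("g"):
                expect = gut.abundance.loc[msp].to_numpy()
            else:
                expect = oral.abundance.loc[msp].to_numpy()
            assert np.allclose(merged.abundance.loc[msp].to_numpy(), expect)


class TestNormalizeAndRichness:
    def test_simple_column(self):
        t = MSPAbundanceTable(abundance=pd.DataFrame({"s0": [2.0, 3.0, 5.0]},
                                                     index=["a", "b", "c"]))
        assert normalize(t).abundance["s0"].tolist() == [0.2, 0.3, 0.5]

    def test_single_msp_column_is_one(self):
        t = MSPAbundanceTable(abundance=pd.DataFrame({"s0": [7.0]}, index=["a"]))
        assert normalize(t).abundance["s0"].tolist() == [1.0]

    def test_zero_column_names_the_sample(self):
        t = MSPAbundanceTable(abundance=pd.DataFrame({"s0": [1.0], "bad": [0.0]},
                                                     index=["a"]))
        with pytest.raises(InputError, match="bad"):
            normalize(t)

    def test_double_normalization_rejected(self, rng):
        from conftest import random_msp_table

        t = random_msp_table(rng, normalized=True)
        with pytest.raises(InputError, match="already"):
            normalize(t)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_random_columns_sum_to_one(self, seed):
        from conftest import random_msp_table

        t = random_msp_table(np.random.default_rng(seed))
        sums = normalize(t).abundance.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_richness_counts_positive_rows(self):
        t = MSPAbundanceTable(abundance=pd.DataFrame(
            {"s0": [0.0, 0.1, 0.3], "s1": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]))
        assert richness(t).tolist() == [2, 0]

    def test_richness_matches_positional_scan(self, rng):
        from conftest import random_msp_table

        t = random_msp_table(rng, n_msps=12, n_samples=6)
        expected = [int(sum(v > 0 for v in t.abundance[s])) for s in t.samples]
        assert richness(t).tolist() == expected


class TestDownsample:
    def test_exact_depth_is_identity(self, rng):
        from conftest import random_gene_table

        t = random_gene_table(rng)
        depth = int(t.total_reads().min())
        out = downsample(t, depth, seed=1)
        j = int(np.argmin(t.total_reads().to_numpy()))
        s = t.samples[j]
        pd.testing.assert_series_equal(out.counts[s], t.counts[s])

    def test_insufficient_depth_lists_samples(self, rng):
        from conftest import random_gene_table

        t = random_gene_table(rng)
        with pytest.raises(InputError, match="s0"):
            downsample(t, int(t.total_reads().max()) + 1, seed=1)

    def test_non_integer_counts_rejected(self):
        t = GeneAbundanceTable(counts=pd.DataFrame({"s0": [1.5, 2.0]}, index=["a", "b"]))
        with pytest.raises(InputError, match="integer"):
            downsample(t, 1, seed=0)

    def test_column_totals_equal_requested_depth(self, rng):
        from conftest import random_gene_table

        t = random_gene_table(rng, n_genes=30)
        depth = int(t.total_reads().min()) // 2
        out = downsample(t, depth, seed=3)
        totals = out.counts.sum(axis=0) + out.unassigned
        assert (totals == depth).all()

    def test_hypergeometric_expectation(self):
        # gene holding half a sample's reads keeps ~half after halving the depth
        counts = pd.DataFrame({"s0": [500.0, 300.0, 200.0]}, index=["a", "b", "c"])
        t = GeneAbundanceTable(counts=counts)
        rng = np.random.default_rng(8)
        draws = [
            downsample(t, 500, seed=rng).counts.at["a", "s0"] for _ in range(1000)
        ]
        # variance of the hypergeometric: n p q (N-n)/(N-1)
        var = 500 * 0.5 * 0.5 * (1000 - 500) / 999
        se = math.sqrt(var / 1000)
        assert abs(np.mean(draws) - 250.0) <= 3 * se


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_normalized_abundances_track_planted_compositions(self, seed):
        """At default depth the quantified relative abundances rank-correlate
        with the planted compositions for species above 1e-3; samples with few
        such species are rank-noise limited, so the per-sample bound applies
        where n >= 30 and the median applies everywhere."""
        from scipy.stats import spearmanr

        from oralgut import SimulationConfig, simulate_dataset

        ds = simulate_dataset(SimulationConfig(seed=seed))
        tables = quantify_msp(ds.gene_table, ds.catalogue)
        norm = normalize(
            merge_tables(tables["gut"], tables["oral"], ds.catalogue.overlap_pairs)
        )
        merged_ids = np.array(ds.truth.species["merged_msp_id"].tolist())
        rhos = []
        for m in ds.meta:
            planted = ds.truth.sample_compositions[m.sample_id]
            mask = planted >= 1e-3
            got = norm.abundance.loc[merged_ids[mask], m.sample_id].to_numpy()
            rho = spearmanr(planted[mask], got).statistic
            rhos.append(rho)
            if mask.sum() >= 30:
                assert rho >= 0.9, m.sample_id
        assert np.median(rhos) >= 0.9


class TestMappingRate:
    def test_all_gut_no_unassigned(self, small_catalogue):
        genes = GeneAbundanceTable(
            counts=pd.DataFrame(
                {"s0": (small_catalogue.genes["catalogue"] == "gut").astype(float)},
                index=small_catalogue.genes.index,
            ),
            unassigned=pd.Series({"s0": 0.0}),
        )
        rates = mapping_rate(genes, small_catalogue)
        assert rates.at["s0", "gut"] == 1.0
        assert rates.at["s0", "oral"] == 0.0

    def test_arithmetic_split(self, small_catalogue):
        gut_gene = small_catalogue.genes.index[small_catalogue.genes["catalogue"] == "gut"][0]
        oral_gene = small_catalogue.genes.index[small_catalogue.genes["catalogue"] == "oral"][0]
        counts = pd.DataFrame({"s0": 0.0}, index=small_catalogue.genes.index)
        counts.loc[gut_gene] = 50.0
        counts.loc[oral_gene] = 30.0
        genes = GeneAbundanceTable(counts=counts, unassigned=pd.Series({"s0": 20.0}))
        rates = mapping_rate(genes, small_catalogue)
        assert rates.loc["s0"].tolist() == [0.5, 0.3, 0.2]

    def test_rates_sum_to_one(self, small_catalogue, rng):
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(len(small_catalogue.genes), 4)).astype(float),
            index=small_catalogue.genes.index, columns=list("abcd"),
        )
        genes = GeneAbundanceTable(
            counts=counts,
            unassigned=pd.Series(rng.integers(1, 50, size=4).astype(float),
                                 index=list("abcd")),
        )
        assert np.allclose(mapping_rate(genes, small_catalogue).sum(axis=1), 1.0, atol=1e-12)

    def test_requires_unassigned(self, small_catalogue, rng):
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(len(small_catalogue.genes), 1)).astype(float),
            index=small_catalogue.genes.index, columns=["s0"],
        )
        with pytest.raises(InputError, match="unassigned"):
            mapping_rate(GeneAbundanceTable(counts=counts), small_catalogue)
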