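"""Windowed counts, exon-density enrichment, distances, hotspots."""

from functools import lru_cache
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import insmap as im
from insmap.controls import ControlCollection
from insmap.distribution import exon_density_bins, window_counts
from insmap.tracks import GeneModel

from conftest import random_genome


def identity_controls(iset, genome, n_sets=1):
    """A ControlCollection whose every set is the observed set itself."""
    names = genome.names
    idx = {c: i for i, c in enumerate(names)}
    ci = np.array([idx[c] for c in iset.df["chrom"]], dtype=np.int16)
    pos = iset.df["position"].to_numpy()
    frag = np.nan_to_num(iset.df["fragment_length"].to_numpy())
    return ControlCollection(
        iset,
        names,
        np.tile(ci, (n_sets, 1)),
        np.tile(pos, (n_sets, 1)),
        np.tile(frag, (n_sets, 1)),
        np.ones((n_sets, len(iset)), dtype=bool),
    )


def brute_force_max_loci(pos, W, m):
    """Exhaustive search over all disjoint qualifying site subsets,
    maximising the locus count (bitmask recursion, n <= 12)."""
    pos = sorted(pos)
    n = len(pos)

    @lru_cache(maxsize=None)
    def rec(mask):
        if not mask:
            return 0
        i = (mask & -mask).bit_length() - 1
        best = rec(mask & ~(1 << i))  # leave site i unused
        avail = [
            j for j in range(i + 1, n) if (mask >> j) & 1 and pos[j] - pos[i] <= W
        ]
        for combo in combinations(avail, m - 1):
            newmask = mask & ~(1 << i)
            for j in combo:
                newmask &= ~(1 << j)
            best = max(best, 1 + rec(newmask))
        return best

    return rec((1 << n) - 1)


def make_sites(genome, positions, chrom="chr1", replicates=None, **extra):
    n = len(positions)
    return im.InsertionSet.from_arrays(
        [chrom] * n,
        positions,
        ["+"] * n,
        genome=genome,
        vector="PB",
        replicate=replicates if replicates is not None else ["1"] * n,
        **extra,
    )


class TestWindowCounts:
    def test_exact_counts_conserve_total(self):
        genome = im.GenomeIndex({"chr1": "A" * 2_000_000})
        sites = make_sites(genome, [10, 20, 999_999, 1_000_000, 1_500_000,
                                    1_700_000, 42, 77, 1_234_567, 3])
        prof = window_counts(sites, genome, reps=0)
        assert prof.counts["chr1"].tolist() == [6, 4]
        assert prof.total() == 10

    def test_full_sample_equals_exact_for_any_reps(self, toy_genome):
        rng = np.random.default_rng(0)
        sites = make_sites(toy_genome, np.sort(rng.integers(0, 49_000, 60)))
        exact = window_counts(sites, toy_genome, window_size=10_000, reps=0)
        sampled = window_counts(
            sites, toy_genome, window_size=10_000, sample_size=60, reps=50, seed=1
        )
        assert np.allclose(exact.counts["chr1"], sampled.counts["chr1"])

    def test_half_sample_means_within_hypergeometric_se(self, toy_genome):
        rng = np.random.default_rng(1)
        sites = make_sites(toy_genome, np.sort(rng.integers(0, 49_000, 40)))
        exact = window_counts(sites, toy_genome, window_size=10_000, reps=0)
        reps = 400
        sampled = window_counts(
            sites, toy_genome, window_size=10_000, sample_size=20, reps=reps, seed=2
        )
        n, s = 40, 20
        for w, K in enumerate(exact.counts["chr1"]):
            mean = K * s / n
            var = s * (K / n) * (1 - K / n) * (n - s) / (n - 1)
            se = np.sqrt(var / reps)
            assert abs(sampled.counts["chr1"][w] - mean) <= 4 * se + 1e-9

    def test_window_size_validation(self, toy_genome):
        sites = make_sites(toy_genome, [10])
        with pytest.raises(ValueError):
            window_counts(sites, toy_genome, window_size=0)


class TestExonDensityBins:
    def make_genome_with_exon_ladder(self, bin_size=1_000, n_bins=10):
        genome = im.GenomeIndex({"chr1": "A" * (bin_size * n_bins)})
        genes = []
        for b in range(n_bins):
            start = b * bin_size
            size = b + 1  # exon bp 1..10 across the bins
            genes.append(
                GeneModel(
                    f"g{b}", "chr1", "+", start, start + size, [(start, start + size)]
                )
            )
        return genome, genes

    def test_rank_split_into_quintiles(self):
        genome, genes = self.make_genome_with_exon_ladder()
        bins = exon_density_bins(genes, genome, bin_size=1_000)
        assert bins.exon_bp.tolist() == list(range(1, 11))
        assert np.bincount(bins.quintile, minlength=5).tolist() == [2] * 5
        assert bins.quintile[-2:].tolist() == [4, 4]  # exon bp {9,10} = highest

    def test_tie_break_is_deterministic_stable(self):
        genome = im.GenomeIndex({"chr1": "A" * 10_000})
        genes = []  # identical (zero) density everywhere
        bins = exon_density_bins(genes, genome, bin_size=1_000)
        # stable sort: coordinate order decides the labels
        assert bins.quintile.tolist() == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_exon_split_pro_rata_across_boundary(self):
        genome = im.GenomeIndex({"chr1": "A" * 2_000})
        gene = GeneModel("g", "chr1", "+", 400, 1_400, [(400, 1_400)])
        bins = exon_density_bins([gene], genome, bin_size=1_000)
        assert bins.exon_bp.tolist() == [600.0, 400.0]


class TestQuintileEnrichment:
    def test_fractions_sum_to_one_and_identity(self, toy_genome):
        rng = np.random.default_rng(2)
        genes = [
            GeneModel(f"g{i}", "chr1", "+", int(s), int(s) + 400, [(int(s), int(s) + 400)])
            for i, s in enumerate(range(0, 40_000, 4_000))
        ]
        bins = exon_density_bins(genes, toy_genome, bin_size=5_000)
        sites = make_sites(toy_genome, np.sort(rng.integers(0, 49_000, 200)))
        controls = identity_controls(sites, toy_genome, n_sets=3)
        table = im.quintile_enrichment(sites, bins, controls)
        assert table["observed_fraction"].sum() == pytest.approx(1.0)
        assert table["control_fraction"].sum() == pytest.approx(1.0)
        assert np.allclose(table["observed_fraction"], table["control_fraction"])

    def test_all_sites_in_highest_bins(self, toy_genome):
        genes = [
            GeneModel("g", "chr1", "+", 0, 4_000, [(0, 4_000)]),
        ]
        bins = exon_density_bins(genes, toy_genome, bin_size=5_000)
        sites = make_sites(toy_genome, [100, 200, 300])
        table = im.quintile_enrichment(sites, bins)
        assert table["observed_fraction"].tolist() == [0, 0, 0, 0, 1]

    def test_site_outside_bins_is_error(self, toy_genome):
        bins = exon_density_bins([], toy_genome, bin_size=5_000)
        other = im.GenomeIndex({"chrZ": "A" * 100})
        sites = make_sites(other, [5], chrom="chrZ")
        with pytest.raises(ValueError, match="outside"):
            im.quintile_enrichment(sites, bins)


class TestExonInsertionCorrelation:
    def test_perfect_linearity(self):
        genome, genes = TestExonDensityBins().make_genome_with_exon_ladder()
        bins = exon_density_bins(genes, genome, bin_size=1_000)
        # insertion counts proportional to exon bp: b+1 sites in bin b
        positions = [b * 1_000 + 10 * i for b in range(10) for i in range(b + 1)]
        sites = make_sites(genome, positions)
        assert im.exon_insertion_correlation(sites, bins).r == pytest.approx(1.0)
        # anti-proportional
        positions = [b * 1_000 + 10 * i for b in range(10) for i in range(10 - b)]
        sites = make_sites(genome, positions)
        assert im.exon_insertion_correlation(sites, bins).r == pytest.approx(-1.0)

    def test_permuted_counts_give_near_zero_r(self):
        genome, genes = TestExonDensityBins().make_genome_with_exon_ladder(n_bins=64)
        bins = exon_density_bins(genes, genome, bin_size=1_000)
        rng = np.random.default_rng(3)
        perm = rng.permutation(64)
        positions = [int(b) * 1_000 + 10 * i for b in perm[:32] for i in range(3)]
        sites = make_sites(genome, positions)
        assert abs(im.exon_insertion_correlation(sites, bins).r) < 4 / np.sqrt(64)

    def test_zero_variance_flagged(self):
        genome, genes = TestExonDensityBins().make_genome_with_exon_ladder()
        bins = exon_density_bins(genes, genome, bin_size=1_000)
        sites = make_sites(genome, [b * 1_000 + 5 for b in range(10)])
        res = im.exon_insertion_correlation(sites, bins)
        assert "zero_variance" in res.flags and np.isnan(res.r)


class TestInterInsertionDistances:
    def test_direct_arithmetic_example(self):
        genome = im.GenomeIndex({"chr1": "A" * 50_000})
        sites = make_sites(genome, [100, 1_100, 21_100])
        summ = im.inter_insertion_distances(sites, reps=0)
        assert summ.distances.tolist() == [1_000, 20_000]
        assert summ.mean_log10 == pytest.approx(np.mean([3.0, np.log10(20_000)]))
        assert summ.fraction_below == pytest.approx(0.5)
        assert summ.mean_count_below == 1

    def test_one_site_per_chromosome_gives_no_distances(self, toy_genome):
        sites = im.InsertionSet.from_arrays(
            ["chr1", "chr2"], [100, 100], ["+", "+"], genome=toy_genome, vector="PB"
        )
        summ = im.inter_insertion_distances(sites, reps=0)
        assert len(summ.distances) == 0

    def test_zero_distances_excluded_and_counted(self, toy_genome):
        sites = make_sites(toy_genome, [100, 100, 5_000])
        summ = im.inter_insertion_distances(sites, reps=0)
        assert summ.n_zero_excluded == 1
        assert summ.distances.tolist() == [4_900]

    def test_null_fold_enrichment_near_one(self, toy_genome):
        motif = im.scan_motif_positions(toy_genome, "TTAA")
        pool = np.concatenate([motif.positions["chr1"]])
        rng = np.random.default_rng(4)
        obs_pos = np.sort(rng.choice(pool, 300, replace=True))
        sites = make_sites(toy_genome, obs_pos)
        controls = im.generate_shear_controls(
            sites, toy_genome, motif=motif, n_sets=100, seed=5, mappability_k=None
        )
        summ = im.inter_insertion_distances(
            sites, sample_size=150, reps=100, seed=6, controls=controls
        )
        sd = summ.control_counts_per_set.std(ddof=1)
        assert abs(summ.mean_count_below - summ.control_mean_count_below) < 3 * sd


class TestHotspots:
    @pytest.fixture()
    def flat_genome(self):
        return im.GenomeIndex({"chr1": "A" * 1_000_000})

    def test_worked_examples(self, flat_genome):
        sites = make_sites(flat_genome, [0, 10_000, 40_000])
        report = im.count_hotspots(sites, rules=((2, 30_000),), reps=0)
        assert report.mean_counts[(2, 30_000)] == 1
        assert brute_force_max_loci([0, 10_000, 40_000], 30_000, 2) == 1

    def test_empty_set(self, flat_genome):
        sites = im.InsertionSet.from_arrays([], [], [], genome=flat_genome)
        report = im.count_hotspots(sites, reps=0)
        assert all(v == 0 for v in report.mean_counts.values())

    def test_four_sites_within_90kb(self, flat_genome):
        sites = make_sites(flat_genome, [0, 30_000, 60_000, 90_000])
        report = im.count_hotspots(sites, rules=((4, 100_000),), reps=0)
        assert report.mean_counts[(4, 100_000)] == 1

    def test_cluster_vs_max_disjoint_semantics(self, flat_genome):
        # a 30-kb run of 4 sites: one hotspot locus, but two disjoint pairs
        sites = make_sites(flat_genome, [0, 10_000, 20_000, 30_000])
        rule = ((2, 30_000),)
        as_cluster = im.count_hotspots(sites, rules=rule, reps=0, method="cluster")
        as_disjoint = im.count_hotspots(sites, rules=rule, reps=0, method="max-disjoint")
        assert as_cluster.mean_counts[(2, 30_000)] == 1
        assert as_disjoint.mean_counts[(2, 30_000)] == 2
        assert brute_force_max_loci([0, 10_000, 20_000, 30_000], 30_000, 2) == 2

    def test_max_disjoint_equals_brute_force_on_random_instances(self, flat_genome):
        rng = np.random.default_rng(7)
        for _ in range(120):
            n = int(rng.integers(2, 13))
            span = int(rng.choice([50_000, 150_000, 400_000]))
            pos = np.sort(rng.choice(span, n, replace=False))
            m, W = [(2, 30_000), (3, 50_000), (4, 100_000)][int(rng.integers(3))]
            sites = make_sites(flat_genome, pos)
            got = im.count_hotspots(
                sites, rules=((m, W),), reps=0, method="max-disjoint"
            ).mean_counts[(m, W)]
            assert got == brute_force_max_loci(pos.tolist(), W, m)

    def test_rule_validation(self, flat_genome):
        sites = make_sites(flat_genome, [0])
        with pytest.raises(ValueError):
            im.count_hotspots(sites, rules=((1, 30_000),), reps=0)
        with pytest.raises(ValueError):
            im.count_hotspots(sites, rules=((2, 0),), reps=0)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 500_000), min_size=2, max_size=25, unique=True),
        st.integers(0, 500_000),
    )
    def test_adding_a_site_never_decreases_cluster_counts(self, positions, extra):
        if extra in positions:
            return
        genome = im.GenomeIndex({"chr1": "A" * 600_000})
        base = im.count_hotspots(
            make_sites(genome, sorted(positions)), reps=0, method="cluster"
        )
        more = im.count_hotspots(
            make_sites(genome, sorted(positions + [extra])), reps=0, method="cluster"
        )
        for rule in base.rules:
            assert more.mean_counts[rule] >= base.mean_counts[rule]

    def test_nonexclusive_rules_count_independently(self, flat_genome):
        # 3 sites within 30 kb: a 2-hit locus AND a 3-hit locus
        sites = make_sites(flat_genome, [0, 10_000, 20_000])
        report = im.count_hotspots(sites, reps=0)
        assert report.mean_counts[(2, 30_000)] == 1
        assert report.mean_counts[(3, 50_000)] == 1
        excl = im.count_hotspots(sites, reps=0, exclusive=True)
        assert excl.mean_counts[(3, 50_000)] == 1
        assert excl.mean_counts[(2, 30_000)] == 0  # consumed by the 3-hit locus

    def test_replicate_provenance(self, flat_genome):
        sites = make_sites(
            flat_genome,
            [0, 1_000, 100_000, 101_000, 300_000, 301_000],
            replicates=["1", "2", "1", "1", "2", "3"],
        )
        report = im.count_hotspots(sites, rules=((2, 30_000),), reps=0)
        prov = im.hotspot_replicate_provenance(report)[(2, 30_000)]
        assert prov["fraction_multi_replicate"] == pytest.approx(2 / 3)

    def test_sampled_mean_with_controls(self, toy_genome):
        rng = np.random.default_rng(9)
        sites = make_sites(toy_genome, np.sort(rng.integers(0, 49_000, 100)))
        controls = identity_controls(sites, toy_genome, n_sets=20)
        report = im.count_hotspots(
            sites, sample_size=50, reps=20, seed=1, controls=controls
        )
        for rule in report.rules:
            assert report.tests[rule].p >= 0.0
            # identical generator: observed mean close to control mean
            sd = max(np.std([report.control_mean_counts[rule]]), 1.0)
            assert abs(
                report.mean_counts[rule] - report.control_mean_counts[rule]
            ) < 5 * sd
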