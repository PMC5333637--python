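"""Matched in-silico control generation: contracts and oracle equivalence."""

import numpy as np
import pytest
from scipy import stats as sps

import insmap as im
from insmap.controls import enumerate_flx_candidates

from conftest import random_genome


def brute_force_admissible(genome, strand, frag, constraints):
    """Enumerate every admissible (chrom, position, control_fragment) by
    direct looping -- the independent oracle for the vectorised path."""
    d = constraints.max_fragment_diff
    uniq = (
        genome.kmer_uniqueness(constraints.mappability_k)
        if constraints.mappability_k
        else None
    )
    out = set()
    for chrom, L in genome.chromosomes:
        cuts = constraints.primary.cuts[chrom]
        secs = [s.cuts.get(chrom, np.empty(0, int)) for s in constraints.secondary]
        if constraints.motif is not None:
            cands = constraints.motif.positions[chrom]
        else:
            cands = None
        for C in cuts:
            if cands is None:
                Ps = [C - frag] if strand == "+" else [C + frag]
                Ps = [P for P in Ps if 0 <= P < L]
            else:
                if strand == "+":
                    Ps = [P for P in cands if 0 < C - P and abs((C - P) - frag) < d]
                else:
                    Ps = [P for P in cands if 0 < P - C and abs((P - C) - frag) < d]
            for P in Ps:
                lo, hi = min(P, C), max(P, C)
                if any(((s > lo) & (s < hi)).any() for s in secs if len(s)):
                    continue
                if uniq is not None and not uniq[chrom][P]:
                    continue
                out.add((chrom, int(P), int(abs(C - P))))
    return out


@pytest.fixture(scope="module")
def flx_setup():
    genome = random_genome(21, lengths=(30_000, 20_000))
    motif = im.scan_motif_positions(genome, "TTAA")
    constraints = im.ControlConstraints(
        primary=im.index_restriction_sites(genome),  # HaeIII
        secondary=[im.index_restriction_sites(genome, "TCTAGA", 1)],  # XbaI
        motif=motif,
        n_sets=200,
        seed=17,
        mappability_k=36,
    )
    rng = np.random.default_rng(2)
    n = 40
    observed = im.InsertionSet.from_arrays(
        np.where(rng.random(n) < 0.5, "chr1", "chr2"),
        rng.integers(100, 19_000, n),
        np.where(rng.random(n) < 0.5, "+", "-"),
        genome=genome,
        vector="PB",
        platform="restriction",
        fragment_length=rng.integers(80, 600, n).astype(float),
    )
    return genome, constraints, observed


class TestFlxControls:
    def test_support_equals_brute_force_admissible_set(self, flx_setup):
        genome, constraints, observed = flx_setup
        names, cchrom, cpos, cfrag, offsets = enumerate_flx_candidates(
            observed, genome, constraints
        )
        df = observed.df
        for i in range(len(observed)):
            want = brute_force_admissible(
                genome,
                df["strand"].iloc[i],
                int(df["fragment_length"].iloc[i]),
                constraints,
            )
            got = {
                (names[cchrom[j]], int(cpos[j]), int(cfrag[j]))
                for j in range(offsets[i], offsets[i + 1])
            }
            assert got == want

    def test_full_contract_over_all_sets(self, flx_setup):
        genome, constraints, observed = flx_setup
        coll = im.generate_flx_controls(observed, genome, constraints)
        obs_frag = observed.df["fragment_length"].to_numpy()
        obs_strand = observed.df["strand"].to_numpy()
        motif_pos = {
            c: set(constraints.motif.positions[c].tolist()) for c in genome.names
        }
        sec = constraints.secondary[0].cuts
        uniq = genome.kmer_uniqueness(36)
        assert coll.n_sets == 200
        for j in range(coll.n_sets):
            mask = coll.valid[j]
            # cardinality = |observed| - attrition
            assert mask.sum() == len(observed) - coll.attrition[j]
            assert (np.abs(coll.fragments[j, mask] - obs_frag[mask]) < 20).all()
            assert (coll.strands[mask] == obs_strand[mask]).all()
            for ci, p, f, s in zip(
                coll.chrom_idx[j, mask],
                coll.positions[j, mask],
                coll.fragments[j, mask],
                obs_strand[mask],
            ):
                chrom = coll.chrom_names[ci]
                assert p in motif_pos[chrom]
                assert uniq[chrom][p]
                cut = p + int(f) if s == "+" else p - int(f)
                lo, hi = min(p, cut), max(p, cut)
                inside = sec[chrom][(sec[chrom] > lo) & (sec[chrom] < hi)]
                assert len(inside) == 0

    def test_deterministic_under_seed(self, flx_setup):
        genome, constraints, observed = flx_setup
        a = im.generate_flx_controls(observed, genome, constraints)
        b = im.generate_flx_controls(observed, genome, constraints)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.chrom_idx, b.chrom_idx)

    def test_requires_fragment_lengths(self, flx_setup):
        genome, constraints, _ = flx_setup
        no_frag = im.InsertionSet.from_arrays(
            ["chr1"], [500], ["+"], genome=genome, vector="PB"
        )
        with pytest.raises(ValueError, match="fragment_length"):
            im.generate_flx_controls(no_frag, genome, constraints)

    def test_motif_without_occurrences_is_an_error(self, flx_setup):
        genome, constraints, observed = flx_setup
        bad = im.ControlConstraints(
            primary=constraints.primary,
            motif=im.MotifIndex("TTAA", {c: np.empty(0, np.int64) for c in genome.names}),
            n_sets=2,
            seed=0,
        )
        with pytest.raises(ValueError, match="zero occurrences"):
            im.generate_flx_controls(observed, genome, bad)

    def test_attrition_reported_for_impossible_sites(self, flx_setup, caplog):
        genome, constraints, _ = flx_setup
        # a fragment longer than any chromosome admits no candidate
        observed = im.InsertionSet.from_arrays(
            ["chr1", "chr1"],
            [500, 600],
            ["+", "+"],
            genome=genome,
            vector="PB",
            fragment_length=[200.0, 1e7],
        )
        cons = im.ControlConstraints(
            primary=constraints.primary, motif=constraints.motif, n_sets=5, seed=1
        )
        with caplog.at_level("WARNING"):
            coll = im.generate_flx_controls(observed, genome, cons)
        assert coll.attrition.tolist() == [1] * 5
        assert "attrition" in caplog.text

    def test_secondary_cut_inside_fragment_rejected(self):
        # hand-built chromosome: TTAA at 10, HaeIII cut at 112, XbaI at 60
        seq = ["A"] * 200
        seq[10:14] = list("TTAA")
        seq[110:114] = list("GGCC")
        seq[60:66] = list("TCTAGA")
        genome = im.GenomeIndex({"c": "".join(seq)})
        observed = im.InsertionSet.from_arrays(
            ["c"], [10], ["+"], genome=genome, vector="PB",
            fragment_length=[100.0],
        )
        base = dict(
            primary=im.index_restriction_sites(genome),
            motif=im.scan_motif_positions(genome, "TTAA"),
            n_sets=3,
            seed=0,
            mappability_k=None,
        )
        with_sec = im.ControlConstraints(
            secondary=[im.index_restriction_sites(genome, "TCTAGA", 1)], **base
        )
        coll = im.generate_flx_controls(observed, genome, with_sec)
        assert coll.attrition.tolist() == [1, 1, 1]  # only candidate rejected
        without = im.ControlConstraints(**base)
        coll2 = im.generate_flx_controls(observed, genome, without)
        assert coll2.attrition.tolist() == [0, 0, 0]
        assert (coll2.positions[coll2.valid] == 10).all()


class TestShearControls:
    def test_pb_controls_all_on_motif(self, toy_genome):
        motif = im.scan_motif_positions(toy_genome, "TTAA")
        observed = im.InsertionSet.from_arrays(
            ["chr1"] * 50,
            np.linspace(100, 40_000, 50).astype(int),
            ["+"] * 50,
            genome=toy_genome,
            vector="PB",
        )
        coll = im.generate_shear_controls(
            observed, toy_genome, motif=motif, n_sets=50, seed=3
        )
        pos_sets = {c: set(motif.positions[c].tolist()) for c in toy_genome.names}
        for j in range(coll.n_sets):
            chroms, pos, strands, _ = coll.set_arrays(j)
            assert all(p in pos_sets[c] for c, p in zip(chroms, pos))
            assert (strands == "+").all()

    def test_chromosome_usage_proportional_to_length(self):
        genome = random_genome(31, lengths=(30_000, 10_000))
        observed = im.InsertionSet.from_arrays(
            ["chr1"] * 100,
            np.arange(100) * 250 + 10,
            ["+"] * 100,
            genome=genome,
            vector="Tol2",
        )
        coll = im.generate_shear_controls(
            observed, genome, motif=None, n_sets=100, seed=5, mappability_k=None
        )
        n1 = int((coll.chrom_idx == 0).sum())
        n2 = int((coll.chrom_idx == 1).sum())
        # 3:1 length ratio within binomial error (n = 10,000 draws)
        p = n1 / (n1 + n2)
        se = np.sqrt(0.75 * 0.25 / (n1 + n2))
        assert abs(p - 0.75) < 4 * se

    def test_single_set_reproducible(self, toy_genome):
        motif = im.scan_motif_positions(toy_genome, "TTAA")
        observed = im.InsertionSet.from_arrays(
            ["chr1"] * 10, np.arange(10) * 1_000 + 50, ["+"] * 10,
            genome=toy_genome, vector="PB",
        )
        a = im.generate_shear_controls(observed, toy_genome, motif=motif, n_sets=1, seed=42)
        b = im.generate_shear_controls(observed, toy_genome, motif=motif, n_sets=1, seed=42)
        assert np.array_equal(a.positions, b.positions)

    def test_pooled_positions_uniform_over_admissible(self, toy_genome):
        """Chi-square goodness of fit over deciles of the admissible pool."""
        motif = im.scan_motif_positions(toy_genome, "TTAA")
        uniq = toy_genome.kmer_uniqueness(36)
        pool = {
            c: motif.positions[c][uniq[c][motif.positions[c]]]
            for c in toy_genome.names
        }
        observed = im.InsertionSet.from_arrays(
            ["chr1"] * 500,
            np.linspace(50, 45_000, 500).astype(int),
            ["+"] * 500,
            genome=toy_genome,
            vector="PB",
        )
        coll = im.generate_shear_controls(
            observed, toy_genome, motif=motif, n_sets=25, seed=7
        )
        ranks = []
        pool_sorted = {c: np.sort(p) for c, p in pool.items()}
        offsets = {"chr1": 0, "chr2": len(pool_sorted["chr1"])}
        total = sum(len(p) for p in pool_sorted.values())
        for j in range(coll.n_sets):
            chroms, pos, _, _ = coll.set_arrays(j)
            for c, p in zip(chroms, pos):
                ranks.append(offsets[c] + np.searchsorted(pool_sorted[c], p))
        ranks = np.asarray(ranks)
        assert len(ranks) >= 10_000
        deciles = np.minimum(ranks * 10 // total, 9)
        counts = np.bincount(deciles, minlength=10)
        p = sps.chisquare(counts).pvalue
        assert p > 0.01


class TestMappabilityFilter:
    def test_duplicated_block_candidates_rejected(self):
        rng = np.random.default_rng(8)
        block = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5_000)])
        mid = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        genome = im.GenomeIndex({"c": block + mid + block})
        cands = im.InsertionSet.from_arrays(
            ["c"] * 3, [1_000, 7_000, 16_000], ["+"] * 3, genome=genome, vector="Tol2"
        )
        out = im.mappability_filter(cands, genome, k=36)
        assert out.df["position"].tolist() == [7_000]

    def test_k_validation(self, toy_genome):
        cands = im.InsertionSet.from_arrays(
            ["chr1"], [100], ["+"], genome=toy_genome, vector="Tol2"
        )
        with pytest.raises(ValueError):
            im.mappability_filter(cands, toy_genome, k=0)
        with pytest.raises(ValueError):
            im.mappability_filter(cands, toy_genome, k=100_000)


def test_control_bed_export(tmp_path, toy_genome):
    motif = im.scan_motif_positions(toy_genome, "TTAA")
    observed = im.InsertionSet.from_arrays(
        ["chr1"] * 5, np.arange(5) * 2_000 + 100, ["+"] * 5,
        genome=toy_genome, vector="PB",
    )
    coll = im.generate_shear_controls(observed, toy_genome, motif=motif, n_sets=3, seed=1)
    coll.to_bed(tmp_path)
    assert (tmp_path / "controls_0001.bed").exists()
    manifest = (tmp_path / "manifest.tsv").read_text().splitlines()
    assert manifest[0] == "set\tattrition\tseed"
    assert len(manifest) == 4
    track = im.load_interval_track(tmp_path / "controls_0001.bed")
    assert len(track) == 5
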