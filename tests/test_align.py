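"""Fragmenting, local alignment, MEM/MUM anchoring, ANI estimators."""

import numpy as np
import pytest
from Bio import Align

from evani.errors import ConfigError
from evani import align as al
from evani.simulate import SimConfig, evolve, sample_species_tree

from conftest import random_seq


def mutate(rng, seq, n_subs):
    out = list(seq)
    for p in rng.choice(len(seq), n_subs, replace=False):
        cur = "ACGT".index(out[p])
        out[p] = "ACGT"[(cur + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestFragmentGenome:
    def test_exact_tiling(self):
        frags = al.fragment_genome("A" * 5100, 1020)
        assert [f.offset for f in frags] == [0, 1020, 2040, 3060, 4080]
        assert all(len(f.sequence) == 1020 for f in frags)

    def test_trailing_fragment_kept(self):
        frags = al.fragment_genome("A" * 2500, 1020)
        assert len(frags) == 3
        assert len(frags[-1].sequence) == 460

    def test_concatenation_reconstructs_genome(self, rng):
        g = random_seq(rng, 3333)
        frags = al.fragment_genome(g, 1020)
        assert "".join(f.sequence for f in frags) == g

    def test_empty_genome(self):
        assert al.fragment_genome("", 1020) == []

    def test_bad_length_raises(self):
        with pytest.raises(ConfigError):
            al.fragment_genome("ACGT", 0)


class TestBestLocalHit:
    def test_exact_substring(self, rng):
        target = random_seq(rng, 8000)
        hit = al.best_local_hit(target[2000:3020], target)
        assert hit.identity == 1.0
        assert hit.coverage == 1.0
        assert hit.strand == "+"
        assert hit.target_start == 2000

    def test_reverse_complement_hit(self, rng):
        target = random_seq(rng, 8000)
        hit = al.best_local_hit(al.revcomp(target[2000:3020]), target)
        assert hit.identity == 1.0
        assert hit.strand == "-"

    def test_no_shared_seed_returns_none(self):
        assert al.best_local_hit("A" * 200, "C" * 5000) is None

    def test_identity_matches_smith_waterman_oracle(self, rng):
        """Banded alignment vs full Smith-Waterman on a mutated fragment."""
        aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-1,
            open_gap_score=-7, extend_gap_score=-2,
        )
        target = random_seq(rng, 6000)
        for n_subs in (51, 150):
            frag = mutate(rng, target[2000:3020], n_subs)
            hit = al.best_local_hit(frag, target)
            aln = aligner.align(frag, target)[0]
            counts = aln.counts()
            oracle_identity = counts.identities / (
                counts.identities + counts.mismatches + counts.gaps
            )
            assert hit.identity == pytest.approx(oracle_identity, abs=0.01)


class TestAnib:
    def test_self_comparison(self, rng):
        g = random_seq(rng, 5100)
        r = al.anib(g, g)
        assert r.ani == 1.0
        assert r.af_query == 1.0

    def test_reverse_complement_strand_handling(self, rng):
        g = random_seq(rng, 5100)
        r = al.anib(g, al.revcomp(g))
        assert r.ani == pytest.approx(1.0)

    def test_recovers_true_identity_on_simulated_pair(self):
        """Substitution-only pair: ANIb tracks the truth from the site map."""
        cfg = SimConfig(
            n_leaves=2, mutation_rate=2.6, n_genes=10, gene_len=1500,
            indel_rate=0.0, seed=5,
        )
        tree = sample_species_tree(cfg)
        genomes, _ = evolve(tree, cfg)
        a, b = [g.sequence for g in genomes.values()]
        true_identity = np.mean([x == y for x, y in zip(a, b)])
        r = al.anib(a, b)
        assert r.ani == pytest.approx(true_identity, abs=0.005)

    def test_no_hit_is_undefined(self):
        r = al.anib("A" * 2000, "C" * 2000)
        assert not r.defined


class TestOrthoani:
    def test_self_comparison_fully_reciprocal(self, rng):
        g = random_seq(rng, 5100)
        r = al.orthoani(g, g)
        assert r.ani == 1.0
        assert r.n_units == 5

    def test_no_shared_kmers_undefined(self):
        r = al.orthoani("A" * 3000, "C" * 3000)
        assert not r.defined

    def test_agrees_with_anib_without_duplication(self):
        cfg = SimConfig(
            n_leaves=2, mutation_rate=4.0, n_genes=10, gene_len=1000,
            indel_rate=0.0, seed=8,
        )
        tree = sample_species_tree(cfg)
        genomes, _ = evolve(tree, cfg)
        a, b = [g.sequence for g in genomes.values()]
        r_ortho = al.orthoani(a, b)
        r_anib = al.anib(a, b)
        assert r_ortho.ani == pytest.approx(r_anib.ani, abs=0.01)


def brute_force_mems(a, b, min_len):
    """O(n^2) oracle: extend every start pair, keep maximal runs, both strands."""
    out = set()
    for bx, strand in ((b, "+"), (al.revcomp(b), "-")):
        for i in range(len(a)):
            for j in range(len(bx)):
                if a[i] != bx[j]:
                    continue
                if i > 0 and j > 0 and a[i - 1] == bx[j - 1]:
                    continue  # not left-maximal
                length = 0
                while (
                    i + length < len(a)
                    and j + length < len(bx)
                    and a[i + length] == bx[j + length]
                ):
                    length += 1
                if length >= min_len:
                    pos_b = j if strand == "+" else len(b) - (j + length)
                    out.add((i, pos_b, length, strand))
    return out


class TestFindMems:
    def test_self_match_is_single_full_length_mum(self, rng):
        a = random_seq(rng, 200)
        mems = al.find_mems(a, a, min_len=8, unique_mode=True)
        full = [m for m in mems if m.length == 200]
        assert len(full) == 1
        assert (full[0].pos_a, full[0].pos_b, full[0].strand) == (0, 0, "+")

    def test_disjoint_alphabet_layouts_yield_nothing(self):
        # no shared 8-mer on either strand
        assert al.find_mems("AG" * 100, "AC" * 100, min_len=8) == []

    def test_min_len_guard(self):
        with pytest.raises(ConfigError):
            al.find_mems("ACGTACGT", "ACGTACGT", min_len=4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 300)
        b = mutate(rng, a, 40) if seed % 2 else random_seq(rng, 300)
        mems = al.find_mems(a, b, min_len=8, unique_mode=False)
        got = {(m.pos_a, m.pos_b, m.length, m.strand) for m in mems}
        assert got == brute_force_mems(a, b, 8)

    def test_unique_mode_drops_repeated_substrings(self, rng):
        core = random_seq(rng, 60)
        a = random_seq(rng, 50) + core + random_seq(rng, 40) + core
        b = random_seq(rng, 30) + core + random_seq(rng, 30)
        all_mems = al.find_mems(a, b, min_len=10, unique_mode=False)
        mums = al.find_mems(a, b, min_len=10, unique_mode=True)
        assert any(not m.unique_a for m in all_mems)
        assert all(m.unique_a and m.unique_b for m in mums)
        assert len(mums) < len(all_mems)


class TestChainAndFilter:
    def test_single_anchor_passes_through(self):
        anchor = al.AnchorMatch(pos_a=10, pos_b=20, length=80, strand="+")
        chains = al.chain_and_filter([anchor], "one_to_one", len_a=200, len_b=200)
        assert len(chains) == 1
        assert chains[0].a_start == 10
        assert chains[0].b_start == 20
        assert chains[0].anchor_bases == 80

    def test_crossing_anchors_keep_only_longer(self):
        a1 = al.AnchorMatch(pos_a=0, pos_b=500, length=100, strand="+")
        a2 = al.AnchorMatch(pos_a=300, pos_b=100, length=50, strand="+")
        chains = al.chain_and_filter([a1, a2], "one_to_one", len_a=1000, len_b=1000)
        assert len(chains) == 1
        assert chains[0].anchor_bases == 100

    def test_tandem_duplication_coverage(self, rng):
        """maxmatch covers both copies; one_to_one covers exactly one."""
        core = random_seq(rng, 400)
        a = random_seq(rng, 200) + core + core + random_seq(rng, 200)
        b = random_seq(rng, 150) + core + random_seq(rng, 250)
        anchors = al.find_mems(a, b, min_len=20, unique_mode=False)
        both = al.chain_and_filter(anchors, "all", a=a, b=b)
        one = al.chain_and_filter(anchors, "one_to_one", a=a, b=b)
        cover_both = sum(c.a_aligned for c in both)
        cover_one = sum(c.a_aligned for c in one)
        assert cover_both >= 2 * 390  # both copies
        assert 390 <= cover_one <= 410  # exactly one copy


class TestAnim:
    def test_self_comparison(self, rng):
        g = random_seq(rng, 4000)
        r = al.anim(g, g)
        assert r.ani == 1.0
        assert r.af_query == 1.0
        assert r.af_ref == 1.0

    def test_single_mismatch_chained_across(self, rng):
        s = random_seq(rng, 101)
        s2 = list(s)
        s2[50] = "ACGT"[("ACGT".index(s[50]) + 1) % 4]
        r = al.anim(s, "".join(s2), min_len=10, min_chain_length=1)
        assert r.ani == pytest.approx(100 / 101)

    def test_divergent_pair_undefined(self):
        r = al.anim("AG" * 2000, "AC" * 2000, min_len=20)
        assert not r.defined

    def test_symmetry_on_simulated_pair(self, small_sim):
        _, _, genomes, _, _ = small_sim
        labels = sorted(genomes)
        a = genomes[labels[0]].sequence
        b = genomes[labels[1]].sequence
        r_ab = al.anim(a, b, min_len=15)
        r_ba = al.anim(b, a, min_len=15)
        assert r_ab.defined and r_ba.defined
        assert abs(r_ab.ani - r_ba.ani) <= 0.002

    def test_lower_min_len_never_loses_defined_pairs(self, small_sim):
        _, _, genomes, _, _ = small_sim
        labels = sorted(genomes)
        pairs = [(labels[i], labels[j]) for i in range(4) for j in range(i + 1, 4)]
        defined = {}
        for min_len in (24, 16, 10):
            defined[min_len] = sum(
                al.anim(genomes[x].sequence, genomes[y].sequence,
                        min_len=min_len).defined
                for x, y in pairs
            )
        assert defined[10] >= defined[16] >= defined[24]

    def test_monotone_in_divergence(self):
        """Estimator ANI is non-increasing as true divergence grows."""
        rng = np.random.default_rng(0)
        base = random_seq(rng, 20_000)
        anis = []
        for div in (0.01, 0.05, 0.10, 0.15):
            other = mutate(rng, base, int(div * len(base)))
            r = al.anim(base, other, min_len=15)
            anis.append(r.ani if r.defined else 0.0)
        assert all(b <= a + 1e-9 for a, b in zip(anis, anis[1:]))


class TestAfWeightedAndDdh:
    def test_perfect_alignment(self):
        r = al.ANIResult(ani=1.0, af_query=1.0, af_ref=1.0, aligned_bases=10,
                         n_units=1)
        assert al.af_weighted(r) == 1.0

    def test_zero_af(self):
        r = al.ANIResult(ani=0.9, af_query=0.0, af_ref=0.0, aligned_bases=0,
                         n_units=0)
        assert al.af_weighted(r) == 0.0

    def test_ninety_percent_over_seventy_percent(self):
        # the classic thought experiment: 90% ANI over a 70% aligned region
        r = al.ANIResult(ani=0.90, af_query=0.70, af_ref=0.70, aligned_bases=1,
                         n_units=1)
        assert al.af_weighted(r) == pytest.approx(0.63)

    def test_undefined_maps_to_zero(self):
        r = al.ANIResult(ani=None, af_query=0.0, af_ref=0.0, aligned_bases=0,
                         n_units=0)
        assert al.af_weighted(r) == 0.0

    def _block(self, cols, matches):
        return al.Chain(
            anchors=[], strand="+", a_start=0, a_end=cols, b_start=0,
            b_end=cols, anchor_bases=cols, matches=matches, aligned_cols=cols,
            a_aligned=cols, b_aligned=cols,
        )

    def test_ddh_identical_genomes(self):
        blocks = [self._block(1000, 1000)]
        d1, d2, d3 = al.ddh_distances(blocks, blocks, 1000, 1000)
        assert (d1, d2, d3) == (0.0, 0.0, 0.0)

    def test_ddh_hand_case(self):
        blocks = [self._block(500, 450)]
        d1, d2, d3 = al.ddh_distances(blocks, blocks, 1000, 1000)
        assert d1 == pytest.approx(0.5)
        assert d2 == pytest.approx(0.1)
        assert d3 == pytest.approx(0.55)

    def test_ddh_no_alignment(self):
        d1, d2, d3 = al.ddh_distances([], [], 1000, 1000)
        assert d1 == 1.0
        assert d2 is None
        assert d3 == 1.0
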