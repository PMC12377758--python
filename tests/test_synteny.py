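"""Collinear chaining, block merging, Ks dating and tandem detection."""
import numpy as np
import pandas as pd
import pytest

from oracles import kde_mode_gaussian, max_collinear_chain, tandem_groups_exhaustive
from syndel.models import as_anchor_frame
from syndel.synteny import (
    KS_GRID,
    ChainParams,
    block_stats,
    chain_anchors,
    classify_age,
    conservation_rate,
    date_blocks,
    find_tandem_duplicates,
    ks_mode,
    merge_blocks,
)


def make_anchors(pairs, chrom_a="1", chrom_b="2"):
    return as_anchor_frame([
        (f"a{ra}", f"b{rb}", chrom_a, chrom_b, ra, rb, 1.0) for ra, rb in pairs
    ])


def test_empty_input_yields_no_blocks():
    assert chain_anchors(pd.DataFrame(columns=as_anchor_frame([]).columns)) == []


def test_perfect_collinear_run_is_one_block():
    anchors = make_anchors([(i, i + 100) for i in range(7)])
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert blocks[0].n_anchors == 7
    assert blocks[0].orientation == 1
    assert blocks[0].n_anchors == max_collinear_chain(
        anchors["rank_a"], anchors["rank_b"], 20)


def test_run_below_min_anchors_is_rejected():
    anchors = make_anchors([(i, i) for i in range(4)])
    assert chain_anchors(anchors, ChainParams(min_anchors=5)) == []


def test_inverted_block_is_detected_with_negative_orientation():
    anchors = make_anchors([(i, 50 - i) for i in range(6)])
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert blocks[0].orientation == -1
    assert blocks[0].n_anchors == 6


def test_chaining_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(42)
    params = ChainParams(max_gap_genes=6, min_anchors=3)
    for _ in range(40):
        n = int(rng.integers(3, 12))
        ra = np.sort(rng.choice(60, size=n, replace=False))
        rb = rng.choice(60, size=n, replace=False)
        anchors = make_anchors(list(zip(ra, rb)))
        blocks = chain_anchors(anchors, params)
        best = max_collinear_chain(ra, rb, params.max_gap_genes)
        if best >= params.min_anchors:
            assert blocks and blocks[0].n_anchors == best
            # chain validity: strict monotone with bounded gaps on both sides
            a = blocks[0].anchors
            da = np.diff(a["rank_a"])
            db = np.diff(a["rank_b"]) * blocks[0].orientation
            assert (da > 0).all() and (da <= params.max_gap_genes).all()
            assert (db > 0).all() and (db <= params.max_gap_genes).all()
        else:
            assert blocks == []


def test_chaining_is_input_order_invariant():
    rng = np.random.default_rng(1)
    pairs = [(i, i + 3) for i in range(10)] + [(i + 30, 90 - i) for i in range(8)]
    anchors = make_anchors(pairs)
    shuffled = anchors.sample(frac=1.0, random_state=7).reset_index(drop=True)
    b1, b2 = chain_anchors(anchors), chain_anchors(shuffled)
    assert [(b.block_id, b.n_anchors, b.orientation) for b in b1] == \
           [(b.block_id, b.n_anchors, b.orientation) for b in b2]


def test_inconsistent_ranks_raise():
    anchors = as_anchor_frame([
        ("g1", "h1", "1", "2", 0, 0, 1.0),
        ("g1", "h2", "1", "2", 5, 1, 1.0),  # same gene, two ranks
    ])
    with pytest.raises(ValueError, match="inconsistent"):
        chain_anchors(anchors)


def test_antiparallel_symmetry(medium_genome):
    """Reversing genome B's gene order flips orientations, not anchor sets."""
    anchors = medium_genome.anchors
    blocks = chain_anchors(anchors)
    flipped = anchors.copy()
    max_rank = anchors["rank_b"].max()
    flipped["rank_b"] = max_rank - flipped["rank_b"]
    blocks_f = chain_anchors(flipped)
    key = lambda bs: sorted(frozenset(zip(b.anchors["gene_a"], b.anchors["gene_b"]))
                            for b in bs)
    assert key(blocks) == key(blocks_f)
    orients = {frozenset(zip(b.anchors["gene_a"], b.anchors["gene_b"])): b.orientation
               for b in blocks}
    for b in blocks_f:
        assert b.orientation == -orients[frozenset(zip(b.anchors["gene_a"], b.anchors["gene_b"]))]


class TestMerge:
    def test_adjacent_blocks_merge_with_provenance(self):
        b1 = chain_anchors(make_anchors([(i, i) for i in range(5)]))[0]
        b2 = chain_anchors(make_anchors([(i, i) for i in range(8, 13)]))[0]
        b2.block_id = "SB0002"
        merged = merge_blocks([b1, b2], merge_gap_genes=10)
        assert len(merged) == 1
        assert merged[0].n_anchors == 10
        assert merged[0].merged_from == ["SB0001", "SB0002"]

    def test_different_chromosome_pairs_do_not_merge(self):
        b1 = chain_anchors(make_anchors([(i, i) for i in range(5)]))[0]
        b2 = chain_anchors(make_anchors([(i, i) for i in range(8, 13)],
                                        chrom_b="3"))[0]
        assert len(merge_blocks([b1, b2], merge_gap_genes=10)) == 2

    def test_merge_is_idempotent_and_a_fixpoint(self):
        blocks = [chain_anchors(make_anchors([(i + off, i + off) for i in range(5)]))[0]
                  for off in (0, 8, 16)]
        for i, b in enumerate(blocks):
            b.block_id = f"SB{i + 1:04d}"
        once = merge_blocks(blocks, merge_gap_genes=5)
        twice = merge_blocks(once, merge_gap_genes=5)
        assert len(once) == 1 and len(twice) == 1  # transitive closure
        assert once[0].merged_from == ["SB0001", "SB0002", "SB0003"]
        pd.testing.assert_frame_equal(once[0].anchors, twice[0].anchors)

    def test_single_block_unchanged(self):
        b = chain_anchors(make_anchors([(i, i) for i in range(6)]))[0]
        assert merge_blocks([b])[0].n_anchors == 6


class TestKsMode:
    def test_point_mass_returns_the_value(self):
        assert ks_mode([0.8, 0.8, 0.8]) == 0.8
        assert ks_mode([1.3]) == 1.3

    def test_no_values_returns_nan(self):
        assert np.isnan(ks_mode([]))

    def test_lognormal_sample_mode_recovered(self):
        rng = np.random.default_rng(0)
        sd = 0.25
        sample = rng.lognormal(np.log(0.8) + sd ** 2, sd, size=500)
        est = ks_mode(sample)
        assert abs(est - 0.8) < 0.1
        assert abs(est - kde_mode_gaussian(sample, KS_GRID)) < 0.05


class TestAgeClass:
    def test_threshold_is_inclusive(self):
        assert classify_age(0.5, 1.2) == "alpha_beta"
        assert classify_age(1.2, 1.2) == "alpha_beta"
        assert classify_age(1.2000001, 1.2) == "gamma"

    def test_negative_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_age(-0.1, 1.2)

    def test_two_event_genome_labels_recovered(self, medium_genome):
        blocks = date_blocks(chain_anchors(medium_genome.anchors), alpha_beta_max=1.3)
        anchors = medium_genome.anchors
        truth_of_pair = dict(zip(zip(anchors["gene_a"], anchors["gene_b"]),
                                 anchors["event"]))
        n_ok = n_tot = 0
        for b in blocks:
            events = {truth_of_pair[p] for p in zip(b.anchors["gene_a"], b.anchors["gene_b"])}
            if len(events) != 1:
                continue  # chimeric chain; only well-separated blocks are scored
            n_tot += 1
            want = "alpha_beta" if events == {"alpha_beta"} else "gamma"
            n_ok += b.age_class == want
        assert n_tot >= 10
        assert n_ok / n_tot >= 0.9


class TestTandem:
    def test_adjacent_same_group_pair(self, small_genome):
        genes = pd.DataFrame({
            "feature_id": ["g1", "g2", "g3"], "chrom": ["1", "1", "1"],
            "rank": [0, 1, 50],
        })
        groups = pd.Series({"g1": "F", "g2": "F", "g3": "F"})
        sets = find_tandem_duplicates(genes, groups, max_rank_gap=10)
        assert sets == [{"g1", "g2"}]

    def test_cross_chromosome_pairs_are_not_tandem(self):
        genes = pd.DataFrame({
            "feature_id": ["g1", "g2"], "chrom": ["1", "2"], "rank": [0, 0],
        })
        groups = pd.Series({"g1": "F", "g2": "F"})
        assert find_tandem_duplicates(genes, groups) == []

    def test_transitive_closure_matches_exhaustive_grouping(self):
        genes = pd.DataFrame({
            "feature_id": ["a", "b", "c"], "chrom": ["1"] * 3, "rank": [1, 3, 9],
        })
        groups = pd.Series({"a": "F", "b": "F", "c": "F"})
        sets = find_tandem_duplicates(genes, groups, max_rank_gap=5)
        assert sets == [{"a", "b", "c"}]
        oracle = tandem_groups_exhaustive({"a": 1, "b": 3, "c": 9}, 5)
        assert sets == oracle

    def test_random_instance_matches_oracle(self):
        rng = np.random.default_rng(3)
        ranks = sorted(rng.choice(100, size=12, replace=False))
        names = [f"g{i}" for i in range(12)]
        genes = pd.DataFrame({"feature_id": names, "chrom": ["1"] * 12, "rank": ranks})
        groups = pd.Series({n: "F" for n in names})
        got = find_tandem_duplicates(genes, groups, max_rank_gap=7)
        want = tandem_groups_exhaustive(dict(zip(names, ranks)), 7)
        assert sorted(map(sorted, got)) == sorted(map(sorted, want))


class TestStats:
    def test_direct_conservation_ratio(self, small_genome):
        blocks = chain_anchors(small_genome.anchors)
        b = blocks[0]
        lo, hi = b.rank_span_a
        n_genes = hi - lo + 1  # synthetic chromosomes have a gene at every rank
        assert conservation_rate(b, small_genome.annotation) == pytest.approx(
            b.n_anchors / n_genes)

    def test_identical_blocks_have_zero_sd(self, small_genome):
        blocks = chain_anchors(small_genome.anchors)[:1] * 3
        date_blocks(blocks, alpha_beta_max=1.3)
        stats = block_stats(blocks, small_genome.annotation)
        assert (stats["sd_length_bp"] == 0).all()

    def test_mean_conservation_tracks_retention(self, medium_genome):
        cfg = medium_genome.config
        blocks = date_blocks(chain_anchors(medium_genome.anchors), alpha_beta_max=1.3)
        stats = block_stats(blocks, medium_genome.annotation)
        overall = np.average(stats["mean_conservation"], weights=stats["n_blocks"])
        assert abs(overall - (1 - cfg.fractionation_rate)) < 0.1

    def test_empty_block_list_gives_empty_table(self, small_genome):
        assert block_stats([], small_genome.annotation).empty
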