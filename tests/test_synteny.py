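import random
from itertools import combinations

import pytest

from conftest import make_genome, make_table
from wgdating.synteny import (
    GAP_PENALTY,
    MATCH_SCORE,
    block_summary,
    CollinearBlock,
    Anchor,
    detect_blocks,
    self_synteny,
)


def _two_chrom_setup(n, order_b=None):
    """Genome A: a1..an on cA; genome B: b1..bn on cB (optionally reordered)."""
    ids_a = [f"a{i}" for i in range(n)]
    ids_b = [f"b{i}" for i in range(n)]
    order_b = order_b if order_b is not None else list(range(n))
    ga = make_genome({"cA": ids_a})
    gb = make_genome({"cB": [ids_b[i] for i in order_b]})
    table = make_table([(f"a{i}", f"b{i}") for i in range(n)])
    return ga, gb, table


def _brute_best_score(coords, max_gaps=50):
    """Optimal single chain by exhaustive enumeration over anchor subsets."""
    best = 0.0
    idx = sorted(range(len(coords)), key=lambda i: coords[i])
    for r in range(1, len(coords) + 1):
        for subset in combinations(idx, r):
            xs = [coords[i][0] for i in subset]
            ys = [coords[i][1] for i in subset]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                continue
            up = all(b > a for a, b in zip(ys, ys[1:]))
            down = all(b < a for a, b in zip(ys, ys[1:]))
            if r > 1 and not (up or down):
                continue
            gaps = sum(b - a - 1 for a, b in zip(xs, xs[1:]))
            gaps += sum(abs(b - a) - 1 for a, b in zip(ys, ys[1:]))
            if any(b - a - 1 > max_gaps for a, b in zip(xs, xs[1:])):
                continue
            if any(abs(b - a) - 1 > max_gaps for a, b in zip(ys, ys[1:])):
                continue
            best = max(best, MATCH_SCORE * r - GAP_PENALTY * gaps)
    return best


class TestDetectBlocks:
    def test_perfect_collinearity_single_plus_block(self):
        ga, gb, table = _two_chrom_setup(10)
        blocks = detect_blocks(table, ga, gb)
        assert len(blocks) == 1
        assert blocks[0].orientation == "plus"
        assert len(blocks[0]) == 10

    def test_reversed_copy_gives_minus_block(self):
        ga, gb, table = _two_chrom_setup(10, order_b=list(range(9, -1, -1)))
        blocks = detect_blocks(table, ga, gb)
        assert len(blocks) == 1
        assert blocks[0].orientation == "minus"
        assert len(blocks[0]) == 10

    def test_chain_score_matches_brute_force_with_decoys(self):
        # 7 collinear anchors plus 2 off-diagonal decoys
        coords = [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5), (6, 6), (2, 6), (5, 0)]
        ga = make_genome({"cA": [f"a{i}" for i in range(7)]})
        gb = make_genome({"cB": [f"b{i}" for i in range(7)]})
        table = make_table([(f"a{x}", f"b{y}") for x, y in coords])
        blocks = detect_blocks(table, ga, gb, min_block=2, overlap_window=100)
        assert blocks[0].score == _brute_best_score(coords)
        assert len(blocks[0]) == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_optimal_chain_on_random_small_instances(self, seed):
        rng = random.Random(seed)
        n = 10
        coords = sorted({(rng.randrange(12), rng.randrange(12)) for _ in range(n)})
        ga = make_genome({"cA": [f"a{i}" for i in range(12)]})
        gb = make_genome({"cB": [f"b{i}" for i in range(12)]})
        table = make_table([(f"a{x}", f"b{y}") for x, y in coords])
        blocks = detect_blocks(table, ga, gb, min_block=1, overlap_window=1000)
        got = max(b.score for b in blocks)
        assert got == _brute_best_score(coords)

    def test_every_block_satisfies_chain_invariants(self):
        rng = random.Random(99)
        coords = sorted({(rng.randrange(40), rng.randrange(40)) for _ in range(60)})
        ga = make_genome({"cA": [f"a{i}" for i in range(40)]})
        gb = make_genome({"cB": [f"b{i}" for i in range(40)]})
        table = make_table([(f"a{x}", f"b{y}") for x, y in coords])
        for blk in detect_blocks(table, ga, gb, min_block=2, max_gaps=10):
            blk.validate(max_gaps=10)

    def test_output_invariant_to_anchor_order(self):
        rng = random.Random(4)
        coords = sorted({(rng.randrange(20), rng.randrange(20)) for _ in range(25)})
        ga = make_genome({"cA": [f"a{i}" for i in range(20)]})
        gb = make_genome({"cB": [f"b{i}" for i in range(20)]})
        pairs = [(f"a{x}", f"b{y}") for x, y in coords]
        blocks1 = detect_blocks(make_table(pairs), ga, gb, min_block=2)
        rng.shuffle(pairs)
        blocks2 = detect_blocks(make_table(pairs), ga, gb, min_block=2)
        key = lambda bs: [(b.chrom_a, b.chrom_b, b.orientation,
                           [(a.xa, a.xb) for a in b.anchors]) for b in bs]
        assert key(blocks1) == key(blocks2)

    def test_swapping_genomes_transposes_blocks(self):
        ga, gb, table = _two_chrom_setup(8, order_b=[2, 0, 1, 3, 4, 5, 7, 6])
        fwd = detect_blocks(table, ga, gb, min_block=2)
        rev_table = make_table([(s, q) for q, s in table.hits])
        rev = detect_blocks(rev_table, gb, ga, min_block=2)
        fwd_pairs = sorted((a.xa, a.xb) for b in fwd for a in b.anchors)
        rev_pairs = sorted((a.xb, a.xa) for b in rev for a in b.anchors)
        assert fwd_pairs == rev_pairs

    def test_unknown_genes_rejected(self):
        ga, gb, table = _two_chrom_setup(5)
        table.add(next(iter(make_table([("ghost", "b0")]))))
        with pytest.raises(ValueError, match="ghost"):
            detect_blocks(table, ga, gb)


class TestSelfSynteny:
    def test_exact_wgd_recovers_all_pairs(self):
        n = 20
        genome = make_genome({"cA": [f"a{i}" for i in range(n)],
                              "cB": [f"b{i}" for i in range(n)]})
        table = make_table([(f"a{i}", f"b{i}") for i in range(n)]
                           + [(f"b{i}", f"a{i}") for i in range(n)])
        blocks = self_synteny(table, genome)
        pairs = {frozenset((a.gene_a, a.gene_b)) for b in blocks for a in b.anchors}
        assert pairs == {frozenset((f"a{i}", f"b{i}")) for i in range(n)}

    def test_tandem_array_not_a_block(self):
        genome = make_genome({"cA": [f"g{i}" for i in range(10)]})
        members = ["g2", "g3", "g4", "g5"]
        pairs = [(x, y) for x in members for y in members if x != y]
        assert self_synteny(make_table(pairs), genome) == []

    def test_block_recall_on_simulated_wgd(self, wgd60_sim):
        from wgdating.homology import all_vs_all, filter_families

        _, genome, truth = wgd60_sim
        table = filter_families(all_vs_all(genome))
        blocks = self_synteny(table, genome)
        found = {frozenset((a.gene_a, a.gene_b)) for b in blocks for a in b.anchors}
        truth_pairs = [frozenset((a, b)) for a, b in
                       zip(truth.wgd_pairs.gene_a, truth.wgd_pairs.gene_b)]
        recall = sum(p in found for p in truth_pairs) / len(truth_pairs)
        assert recall >= 0.9


class TestBlockSummary:
    def _blocks(self, spec):
        out = []
        bid = 0
        for event, n_blocks, n_pairs in spec:
            base, extra = divmod(n_pairs, n_blocks)
            for i in range(n_blocks):
                k = base + (1 if i < extra else 0)
                anchors = [Anchor(f"x{bid}_{j}", f"y{bid}_{j}", j, j, 50.0) for j in range(k)]
                out.append(CollinearBlock("c1", "c2", "plus", anchors, 50.0 * k,
                                          block_id=bid, event_class=event))
                bid += 1
        return out

    def test_published_style_breakdown(self):
        blocks = self._blocks([("ECH", 177, 2152), ("CRT", 77, 2596)])
        s = block_summary(blocks)
        assert s["n_blocks"] == 254 and s["n_pairs"] == 4748
        assert s["by_class"]["CRT"]["pairs_per_block"] == 33.7
        assert s["by_class"]["ECH"]["pairs_per_block"] == 12.2
        assert s["by_class"]["ECH"]["pct_pairs"] == 45.3
        assert s["by_class"]["CRT"]["pct_pairs"] == 54.7

    def test_single_block(self):
        s = block_summary(self._blocks([("CRT", 1, 4)]))
        assert s["pairs_per_block"] == 4.0
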