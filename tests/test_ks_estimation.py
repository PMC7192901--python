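"""NG86 estimator checked against an independently written counting oracle."""

import math

import numpy as np
import pytest

from wgdating.ks_estimation import (
    MIN_CODONS,
    align_codons,
    annotate_blocks_with_ks,
    ng86,
    pathway_differences,
    syn_sites,
)
from wgdating.synteny import Anchor, CollinearBlock

# --- independent oracle -----------------------------------------------------
# Genetic code entered as the classic 64-letter string over TCAG ordering,
# deliberately not sharing data structures with the implementation.
_ORDER = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_ORDER)
    for j, b in enumerate(_ORDER)
    for k, c in enumerate(_ORDER)
}
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")


def oracle_syn_sites(codon):
    total = 0.0
    for pos in range(3):
        syn = nonsyn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODE[alt] == "*":
                continue
            if CODE[alt] == CODE[codon]:
                syn += 1
            else:
                nonsyn += 1
        if syn + nonsyn:
            total += syn / (syn + nonsyn)
    return total


def oracle_pathways(c1, c2):
    """All orderings of the differing positions, walked recursively."""
    diff = [i for i in range(3) if c1[i] != c2[i]]

    def walk(cur, remaining):
        if not remaining:
            return [(0.0, 0.0, False)]
        results = []
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            step_stop = CODE[nxt] == "*" or CODE[cur] == "*"
            syn = (not step_stop) and CODE[cur] == CODE[nxt]
            for sd, nd, stopped in walk(nxt, [p for p in remaining if p != pos]):
                results.append((sd + (1.0 if syn else 0.0),
                                nd + (0.0 if syn else 1.0),
                                stopped or step_stop))
        return results

    paths = walk(c1, diff)
    clean = [(sd, nd) for sd, nd, stopped in paths if not stopped]
    if not clean:
        clean = [(sd, nd) for sd, nd, _ in paths]
    return (sum(p[0] for p in clean) / len(clean), sum(p[1] for p in clean) / len(clean))


# --- unit tests -------------------------------------------------------------


class TestSitesAndPathways:
    def test_sites_match_oracle_for_all_sense_codons(self):
        for codon in SENSE:
            assert syn_sites(codon) == pytest.approx(oracle_syn_sites(codon), abs=1e-12)

    def test_pathways_match_oracle_for_all_codon_pairs(self):
        for c1 in SENSE:
            for c2 in SENSE:
                got = pathway_differences(c1, c2)
                want = oracle_pathways(c1, c2)
                assert got == pytest.approx(want, abs=1e-12), (c1, c2)

    def test_textbook_two_step_example(self):
        # Phe TTT -> Val GTA: via GTT (nonsyn, then syn) or TTA (twice nonsyn)
        assert pathway_differences("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_differences_sum_to_number_of_changed_positions(self):
        for c1 in SENSE[::7]:
            for c2 in SENSE[::5]:
                sd, nd = pathway_differences(c1, c2)
                n_diff = sum(a != b for a, b in zip(c1, c2))
                assert sd + nd == pytest.approx(n_diff)


class TestAlignCodons:
    def test_identical_cds_keeps_all_columns(self):
        cds = "ATG" + "GCT" * 59
        aln = align_codons(cds, cds)
        assert aln.n_codons == 60

    def test_inserted_codon_column_dropped(self):
        a = "ATG" + "GCT" * 20 + "TGG" * 20
        b = "ATG" + "GCT" * 20 + "CCA" + "TGG" * 20
        aln = align_codons(a, b)
        assert aln.n_codons == 41

    def test_ambiguous_base_column_dropped(self):
        a = "ATG" + "GCT" * 40
        b = "ATG" + "GCT" * 20 + "GNT" + "GCT" * 19
        aln = align_codons(a, b)
        assert aln.n_codons == 40


class TestNg86:
    def test_identical_sequences_give_zero(self):
        cds = "ATG" + "TCT" * 49
        est = ng86(align_codons(cds, cds))
        assert est.status == "ok"
        assert est.pS == 0.0 and est.ks == 0.0
        assert est.S + est.N == pytest.approx(3 * est.n_codons)

    def test_single_synonymous_codon_difference(self):
        aln = align_codons("TTT" * 40, "TTT" * 39 + "TTC")
        est = ng86(aln)
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)
        # S per TTT codon is 1/3; JC correction of pS = 1/S_total
        S = 40 / 3
        assert est.ks == pytest.approx(-0.75 * math.log(1 - 4 / 3 * (1 / S)))

    def test_symmetry(self):
        a = "ATGTTTGCTCAA" * 12
        b = "ATGTTCGCACAG" * 12
        ea = ng86(align_codons(a, b))
        eb = ng86(align_codons(b, a))
        assert ea.ks == pytest.approx(eb.ks)
        assert ea.ka == pytest.approx(eb.ka)

    def test_saturation_status(self):
        # every codon differs synonymously: pS = 1/(1/3) = 3 >= 3/4
        aln = align_codons("TTT" * 40, "TTC" * 40)
        est = ng86(aln)
        assert est.status == "saturated"
        assert est.ks is None

    def test_short_alignment_flagged(self):
        aln = align_codons("ATG" + "GCT" * 10, "ATG" + "GCT" * 10)
        est = ng86(aln)
        assert est.n_codons < MIN_CODONS
        assert est.status == "too_short"


class TestBlockAnnotation:
    def _block(self, ks_values):
        anchors = [Anchor(f"a{i}", f"b{i}", i, i, 50.0) for i in range(len(ks_values))]
        return CollinearBlock("c1", "c2", "plus", anchors, 50.0 * len(anchors), block_id=0)

    def _estimates(self, block, ks_values, status="ok"):
        from wgdating.ks_estimation import KsEstimate

        return {
            (a.gene_a, a.gene_b): KsEstimate(a.gene_a, a.gene_b, 100.0, 200.0, 1.0, 1.0,
                                             0.01, 0.005, ks, ks / 2 if ks is not None else None,
                                             100, status if ks is not None else "saturated")
            for a, ks in zip(block.anchors, ks_values)
        }

    def test_odd_count_median(self):
        blk = self._block([0.3, 0.5, 0.4])
        annotate_blocks_with_ks([blk], self._estimates(blk, [0.3, 0.5, 0.4]))
        assert blk.median_ks == pytest.approx(0.4)

    def test_even_count_median_averages(self):
        blk = self._block([0.2, 0.6])
        annotate_blocks_with_ks([blk], self._estimates(blk, [0.2, 0.6]))
        assert blk.median_ks == pytest.approx(0.4)

    def test_low_support_flagged(self):
        blk = self._block([0.2, None, None])
        annotate_blocks_with_ks([blk], self._estimates(blk, [0.2, None, None]))
        assert blk.median_ks == pytest.approx(0.2)
        assert blk.low_ks_support


def test_block_medians_cluster_near_clock_expectation(wgd60_sim):
    """Simulated 60-Mya WGD: per-block median Ks within 0.1 of 2rt = 0.4068."""
    from wgdating.homology import all_vs_all, filter_families
    from wgdating.ks_estimation import ks_for_pairs
    from wgdating.synteny import self_synteny

    _, genome, truth = wgd60_sim
    blocks = self_synteny(filter_families(all_vs_all(genome)), genome)
    pairs = [(a.gene_a, a.gene_b) for b in blocks for a in b.anchors]
    annotate_blocks_with_ks(blocks, ks_for_pairs(genome, pairs))
    medians = [b.median_ks for b in blocks if b.median_ks is not None]
    assert medians, "no blocks with a defined median"
    assert np.all(np.abs(np.array(medians) - 0.4068) < 0.1)
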