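"""Collinear-block detection by dynamic-programming chaining in gene-order space.

Anchors (homologous gene pairs addressed by order indices) are chained per
chromosome pair and orientation under the MCScanX-style parameterization:
minimum block size 4 anchors (-s), maximum gap 50 genes between consecutive
anchors on either axis (-m), and an overlap window of 5 genes (-w) beyond
which the lower-scoring of two overlapping blocks is dropped.  Scoring is
the MCScanX default: 50 per anchor minus 1 per skipped gene.

Chains are extracted greedily: the highest-scoring chain over the remaining
anchors of a cell is taken, its anchors removed, and the search repeated, so
each anchor belongs to at most one block.  Ties break deterministically by
(chromA, chromB, orientation, starting xa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from wgdating.genome_io import Genome
from wgdating.homology import HomologyTable

__all__ = ["Anchor", "CollinearBlock", "detect_blocks", "self_synteny", "block_summary",
           "write_blocks_tsv", "write_collinearity"]

MATCH_SCORE = 50.0
GAP_PENALTY = 1.0


@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair located by gene-order indices (xa, xb)."""

    gene_a: str
    gene_b: str
    xa: int
    xb: int
    pair_score: float


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "plus" | "minus"
    anchors: list[Anchor]
    score: float
    block_id: int = -1
    median_ks: float | None = None
    event_class: str = "unassigned"  # {ECH, CRT, unassigned}
    low_ks_support: bool = False

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out

    def validate(self, max_gaps: int) -> None:
        xs = [a.xa for a in self.anchors]
        ys = [a.xb for a in self.anchors]
        assert all(b > a for a, b in zip(xs, xs[1:])), "xa not strictly increasing"
        if self.orientation == "plus":
            assert all(b > a for a, b in zip(ys, ys[1:])), "xb not increasing on plus block"
        else:
            assert all(b < a for a, b in zip(ys, ys[1:])), "xb not decreasing on minus block"
        for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
            assert x1 - x0 - 1 <= max_gaps, "gap bound violated on A axis"
            assert abs(y1 - y0) - 1 <= max_gaps, "gap bound violated on B axis"


def _chain_score(n_anchors: int, gaps: int) -> float:
    return MATCH_SCORE * n_anchors - GAP_PENALTY * gaps


def _best_chain(anchors: list[Anchor], orientation: str, max_gaps: int) -> tuple[list[int], float]:
    """Best single chain (indices into ``anchors``) for one orientation.

    Sparse DP over anchors sorted by (xa, xb); O(n^2) per cell, which is
    ample at gene-order scale.
    """
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].xa, anchors[i].xb))
    sign = 1 if orientation == "plus" else -1
    best: list[float] = [0.0] * len(order)
    prev: list[int] = [-1] * len(order)
    for ii, i in enumerate(order):
        ai = anchors[i]
        best[ii] = MATCH_SCORE
        for jj in range(ii):
            j = order[jj]
            aj = anchors[j]
            dx = ai.xa - aj.xa
            dy = sign * (ai.xb - aj.xb)
            if dx <= 0 or dy <= 0:
                continue
            if dx - 1 > max_gaps or dy - 1 > max_gaps:
                continue
            cand = best[jj] + MATCH_SCORE - GAP_PENALTY * ((dx - 1) + (dy - 1))
            if cand > best[ii]:
                best[ii] = cand
                prev[ii] = jj
    if not order:
        return [], 0.0
    end = max(range(len(order)), key=lambda ii: (best[ii], -anchors[order[ii]].xa))
    chain: list[int] = []
    ii = end
    while ii != -1:
        chain.append(order[ii])
        ii = prev[ii]
    chain.reverse()
    return chain, best[end]


def _chains_for_cell(
    anchors: list[Anchor], chrom_a: str, chrom_b: str, min_block: int, max_gaps: int
) -> list[CollinearBlock]:
    remaining = list(anchors)
    blocks: list[CollinearBlock] = []
    while len(remaining) >= min_block:
        candidates = []
        for orientation in ("plus", "minus"):
            idx, score = _best_chain(remaining, orientation, max_gaps)
            if len(idx) >= min_block:
                # deterministic tie-break: higher score, then plus first, then smaller xa
                candidates.append((-score, orientation != "plus", remaining[idx[0]].xa, orientation, idx, score))
        if not candidates:
            break
        _, _, _, orientation, idx, score = min(candidates)
        chain = [remaining[i] for i in idx]
        blocks.append(CollinearBlock(chrom_a, chrom_b, orientation, chain, score))
        taken = set(idx)
        remaining = [a for i, a in enumerate(remaining) if i not in taken]
    return blocks


def _resolve_overlaps(blocks: list[CollinearBlock], overlap_window: int) -> list[CollinearBlock]:
    """Drop the lower-scoring of any two blocks sharing > overlap_window genes."""
    ranked = sorted(
        blocks,
        key=lambda b: (-b.score, b.chrom_a, b.chrom_b, b.anchors[0].xa, b.orientation),
    )
    kept: list[CollinearBlock] = []
    for blk in ranked:
        genes = blk.genes
        if all(len(genes & k.genes) <= overlap_window for k in kept
               if (k.chrom_a, k.chrom_b) == (blk.chrom_a, blk.chrom_b)):
            kept.append(blk)
    kept.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.anchors[0].xa, b.orientation))
    for i, blk in enumerate(kept):
        blk.block_id = i
    return kept


def _build_anchors(
    table: HomologyTable, genome_a: Genome, genome_b: Genome
) -> dict[tuple[str, str], list[Anchor]]:
    missing = sorted(
        {g for h in table.cross_gene() for g in (h.query, h.subject)}
        - (set(genome_a.by_id) | set(genome_b.by_id))
    )
    cells: dict[tuple[str, str], list[Anchor]] = {}
    bad = [g for g in missing]
    if bad:
        raise ValueError(f"homology table references genes absent from the genomes: {bad[:10]}")
    for h in table.cross_gene():
        if h.query not in genome_a.by_id or h.subject not in genome_b.by_id:
            continue
        ga = genome_a.gene(h.query)
        gb = genome_b.gene(h.subject)
        cells.setdefault((ga.chrom, gb.chrom), []).append(
            Anchor(h.query, h.subject, ga.order_index, gb.order_index, h.bitscore)
        )
    return cells


def detect_blocks(
    table: HomologyTable,
    genome_a: Genome,
    genome_b: Genome,
    min_block: int = 4,
    max_gaps: int = 50,
    overlap_window: int = 5,
) -> list[CollinearBlock]:
    """Detect collinear blocks between two genomes from a family-filtered table."""
    cells = _build_anchors(table, genome_a, genome_b)
    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(cells):
        anchors = sorted(set(cells[(ca, cb)]), key=lambda a: (a.xa, a.xb, a.gene_a, a.gene_b))
        blocks.extend(_chains_for_cell(anchors, ca, cb, min_block, max_gaps))
    return _resolve_overlaps(blocks, overlap_window)


def self_synteny(
    table: HomologyTable,
    genome: Genome,
    min_block: int = 4,
    max_gaps: int = 50,
    overlap_window: int = 5,
    max_intervening: int = 5,
) -> list[CollinearBlock]:
    """Self-comparison synteny: each unordered pair once, tandem proximity excluded.

    Self-hits are dropped; each unordered gene pair is used once (upper
    triangle of the dotplot); same-chromosome pairs within tandem proximity
    (|xa - xb| <= max_intervening + 1) are excluded so tandem arrays do not
    masquerade as collinear blocks.
    """
    dedup = HomologyTable(search_space=table.search_space)
    for h in table.cross_gene():
        ga = genome.gene(h.query)
        gb = genome.gene(h.subject)
        key_a = (ga.chrom, ga.order_index)
        key_b = (gb.chrom, gb.order_index)
        if key_a >= key_b:
            continue  # keep one orientation of each unordered pair
        if ga.chrom == gb.chrom and abs(ga.order_index - gb.order_index) <= max_intervening + 1:
            continue
        dedup.add(h)
    return detect_blocks(dedup, genome, genome, min_block, max_gaps, overlap_window)


def block_summary(blocks: list[CollinearBlock]) -> dict:
    """Counts, pairs-per-block means and per-class pair percentages (1 decimal)."""
    n_blocks = len(blocks)
    n_pairs = sum(len(b) for b in blocks)
    out = {
        "n_blocks": n_blocks,
        "n_pairs": n_pairs,
        "pairs_per_block": round(n_pairs / n_blocks, 1) if n_blocks else 0.0,
        "by_class": {},
    }
    for cls in sorted({b.event_class for b in blocks}):
        sub = [b for b in blocks if b.event_class == cls]
        pairs = sum(len(b) for b in sub)
        out["by_class"][cls] = {
            "n_blocks": len(sub),
            "n_pairs": pairs,
            "pairs_per_block": round(pairs / len(sub), 1) if sub else 0.0,
            "pct_pairs": round(100.0 * pairs / n_pairs, 1) if n_pairs else 0.0,
        }
    return out


def write_blocks_tsv(blocks: list[CollinearBlock], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tchromA\tchromB\torientation\tgeneA\tgeneB\tpair_score\n")
        for b in blocks:
            for a in b.anchors:
                fh.write(
                    f"{b.block_id}\t{b.chrom_a}\t{b.chrom_b}\t{b.orientation}\t"
                    f"{a.gene_a}\t{a.gene_b}\t{a.pair_score:.1f}\n"
                )


def write_collinearity(blocks: list[CollinearBlock], path: str) -> None:
    """MCScanX '.collinearity'-style text output."""
    with open(path, "w") as fh:
        n_pairs = sum(len(b) for b in blocks)
        fh.write(f"# Collinear blocks: {len(blocks)}, gene pairs: {n_pairs}\n")
        for b in blocks:
            sign = "plus" if b.orientation == "plus" else "minus"
            fh.write(
                f"## Alignment {b.block_id}: score={b.score:.1f} "
                f"{b.chrom_a}&{b.chrom_b} {sign}\n"
            )
            for i, a in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i}:\t{a.gene_a}\t{a.gene_b}\n")
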