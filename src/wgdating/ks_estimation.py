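"""NG86 synonymous/nonsynonymous distances on protein-guided codon alignments.

Synonymous (Ks) and nonsynonymous (Ka) substitutions per site are estimated
with the Nei-Gojobori (1986) counting method: per-codon synonymous site
fractions are computed over the standard genetic code with mutations to stop
codons excluded from the site denominator; differences between codons that
differ at more than one position are averaged over all minimal mutational
pathways, excluding pathways that pass through a stop codon; and the
Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p) converts proportions to
distances.  Proportions at or beyond the 3/4 correction boundary yield a
``saturated`` status rather than infinities; alignments shorter than the
codon floor yield ``too_short``.

Codon alignments are built by global protein alignment (Needleman-Wunsch,
BLOSUM62, gap open 10 / extend 0.5) back-translated to codons; columns with
a gap, a stop codon or an ambiguous base are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log
from statistics import median

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from wgdating.genome_io import Genome, translate
from wgdating.synteny import CollinearBlock

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "align_codons",
    "ng86",
    "ks_for_pairs",
    "annotate_blocks_with_ks",
    "write_ks_tsv",
]

MIN_CODONS = 30  # floor for an ok estimate; guards against fragment alignments

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_CODE = dict(standard_dna_table.forward_table)  # sense codons -> aa
SENSE_CODONS = tuple(sorted(_CODE))  # the 61 sense codons


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free aligned codon columns for one gene pair."""

    gene_a: str
    gene_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KsEstimate:
    """NG86 site counts, differences and JC-corrected distances for one pair."""

    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float | None
    ka: float | None
    n_codons: int
    status: str  # {ok, saturated, too_short}


@lru_cache(maxsize=None)
def syn_fraction(codon: str, pos: int) -> float:
    """Fraction of non-stop single-base changes at ``pos`` that are synonymous."""
    aa = _CODE[codon]
    syn = 0
    valid = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt in _STOPS:
            continue
        valid += 1
        if _CODE[alt] == aa:
            syn += 1
    return syn / valid if valid else 0.0


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3); nonsynonymous = 3 - this."""
    return sum(syn_fraction(codon, pos) for pos in range(3))


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Multi-position differences are averaged over all orderings of the single
    changes; orderings passing through a stop codon are excluded (if every
    ordering does, all are used, stop steps counted as nonsynonymous).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
                nd += 1.0
            elif cur in _STOPS:
                nd += 1.0
            elif _CODE[cur] == _CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, through_stop

    paths = [walk(order) for order in permutations(diff)]
    clean = [(sd, nd) for sd, nd, bad in paths if not bad]
    if not clean:
        clean = [(sd, nd) for sd, nd, _ in paths]
    sd = sum(p[0] for p in clean) / len(clean)
    nd = sum(p[1] for p in clean) / len(clean)
    return sd, nd


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - (4.0 / 3.0) * p)


def align_codons(
    cds_a: str,
    cds_b: str,
    prot_a: str | None = None,
    prot_b: str | None = None,
    gene_a: str = "A",
    gene_b: str = "B",
) -> CodonAlignment:
    """Protein-guided codon alignment of two CDS.

    Proteins, when given, must match the CDS translations.  Columns with a
    gap, a stop codon, or any non-ACGT base are dropped.
    """
    ta = translate(cds_a, internal_stop="mask")
    tb = translate(cds_b, internal_stop="mask")
    for name, given, trans in (("A", prot_a, ta), ("B", prot_b, tb)):
        if given is not None and given.rstrip("*") != trans:
            raise ValueError(f"protein {name} inconsistent with CDS translation")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(ta.replace("*", "X") or "X", tb.replace("*", "X") or "X")[0]
    cols_a: list[str] = []
    cols_b: list[str] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            ca = cds_a[3 * i : 3 * i + 3]
            cb = cds_b[3 * j : 3 * j + 3]
            if len(ca) < 3 or len(cb) < 3:
                continue
            if ca in _STOPS or cb in _STOPS:
                continue
            if any(ch not in _BASES for ch in ca + cb):
                continue
            cols_a.append(ca)
            cols_b.append(cb)
    return CodonAlignment(gene_a, gene_b, tuple(cols_a), tuple(cols_b))


def ng86(alignment: CodonAlignment, min_codons: int = MIN_CODONS) -> KsEstimate:
    """NG86 Ks/Ka estimate for one codon alignment."""
    n = alignment.n_codons
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        S += 0.5 * (syn_sites(ca) + syn_sites(cb))
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * n - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jc(pS)
    ka = _jc(pN)
    if n < min_codons:
        status = "too_short"
        ks = ka = None
    elif ks is None or ka is None:
        status = "saturated"
        ks = ka = None
    else:
        status = "ok"
    return KsEstimate(alignment.gene_a, alignment.gene_b, S, N, Sd, Nd, pS, pN, ks, ka, n, status)


def ks_for_pairs(
    genome: Genome,
    pairs: list[tuple[str, str]],
    genome_b: Genome | None = None,
    min_codons: int = MIN_CODONS,
) -> dict[tuple[str, str], KsEstimate]:
    """NG86 estimates for a list of gene-id pairs (A-genome id, B-genome id)."""
    gb = genome_b if genome_b is not None else genome
    out: dict[tuple[str, str], KsEstimate] = {}
    for ga_id, gb_id in pairs:
        aln = align_codons(
            genome.cds[ga_id], gb.cds[gb_id],
            genome.proteins.get(ga_id), gb.proteins.get(gb_id),
            ga_id, gb_id,
        )
        out[(ga_id, gb_id)] = ng86(aln, min_codons=min_codons)
    return out


def annotate_blocks_with_ks(
    blocks: list[CollinearBlock],
    estimates: dict[tuple[str, str], KsEstimate],
) -> list[CollinearBlock]:
    """Attach the median anchor Ks to each block.

    Only ok-status anchors enter the median (an even count averages the two
    central values); blocks where fewer than half the anchors have an ok
    estimate are flagged ``low_ks_support``.
    """
    for blk in blocks:
        values: list[float] = []
        n_total = 0
        for a in blk.anchors:
            est = estimates.get((a.gene_a, a.gene_b)) or estimates.get((a.gene_b, a.gene_a))
            if est is None:
                raise ValueError(f"no Ks estimate for anchor {a.gene_a}/{a.gene_b}")
            n_total += 1
            if est.status == "ok":
                values.append(est.ks)
        blk.median_ks = median(values) if values else None
        blk.low_ks_support = len(values) < 0.5 * n_total if n_total else True
    return blocks


def write_ks_tsv(
    estimates: dict[tuple[str, str], KsEstimate],
    path: str,
    block_of: dict[tuple[str, str], int] | None = None,
) -> None:
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tblock_id\tS\tN\tSd\tNd\tka\tks\tstatus\n")
        for (ga, gb), e in estimates.items():
            bid = block_of.get((ga, gb), -1) if block_of else -1
            fh.write(
                f"{ga}\t{gb}\t{bid}\t{e.S:.2f}\t{e.N:.2f}\t{e.Sd:.2f}\t{e.Nd:.2f}\t"
                f"{fmt(e.ka)}\t{fmt(e.ks)}\t{e.status}\n"
            )
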