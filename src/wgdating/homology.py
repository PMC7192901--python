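"""Scored protein-pair homology: built-in local alignment or BLAST tabular input.

For desk-scale genomes an all-vs-all Smith-Waterman search (BLOSUM62,
affine gaps) stands in for BLASTP.  Raw scores are converted to bit scores
with fixed Karlin-Altschul constants and to e-values via E = m*n*2^(-S');
the constants are nominal gapped-BLOSUM62 values, adequate because every
downstream use (1e-5 / 1e-20 thresholds, family-size filter, best hits) is
a rank or threshold filter, not an absolute statistic.

The family-size filter removes every hit of any gene with more than
``max_matches`` distinct partners, applied symmetrically: a pair survives
only if both of its genes survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from wgdating.genome_io import Genome

__all__ = [
    "HomologyHit",
    "HomologyTable",
    "align_pair",
    "all_vs_all",
    "read_blast_tab",
    "write_blast_tab",
    "filter_families",
    "best_hits",
]

# Karlin-Altschul constants for gapped BLOSUM62 (open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class HomologyHit:
    """One scored pairwise protein match (direction: query -> subject)."""

    query: str
    subject: str
    bitscore: float
    evalue: float
    identity_pct: float
    aln_len: int

    @property
    def is_self(self) -> bool:
        return self.query == self.subject


@dataclass
class HomologyTable:
    """Best hit per ordered (query, subject) pair plus the search space."""

    hits: dict[tuple[str, str], HomologyHit] = field(default_factory=dict)
    search_space: tuple[int, int] = (0, 0)

    def add(self, hit: HomologyHit) -> None:
        key = (hit.query, hit.subject)
        old = self.hits.get(key)
        if old is None or hit.bitscore > old.bitscore:
            self.hits[key] = hit

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits.values())

    def cross_gene(self) -> list[HomologyHit]:
        return [h for h in self.hits.values() if not h.is_self]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (h.query, h.subject, h.identity_pct, h.aln_len, h.evalue, h.bitscore)
            for h in self.hits.values()
        ]
        return pd.DataFrame(
            rows, columns=["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]
        )


def _make_aligner(mode: str, open_gap: float, extend_gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def align_pair(
    prot_a: str,
    prot_b: str,
    query_id: str = "A",
    subject_id: str = "B",
    evalue_max: float = 1e-5,
    search_space: tuple[int, int] | None = None,
    _aligner: PairwiseAligner | None = None,
) -> HomologyHit | None:
    """Smith-Waterman local alignment of two proteins; None if above ``evalue_max``.

    The e-value uses the pairwise search space m*n unless ``search_space``
    supplies the database sizes of a larger all-vs-all search.
    """
    for name, seq in (("A", prot_a), ("B", prot_b)):
        if not seq:
            raise ValueError(f"empty protein sequence {name}")
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"non-amino-acid characters in sequence {name}: {sorted(bad)}")
    aligner = _aligner if _aligner is not None else _make_aligner("local", 11.0, 1.0)
    score = aligner.score(prot_a, prot_b)
    bitscore = (KA_LAMBDA * score - log(KA_K)) / log(2.0)
    m, n = search_space if search_space is not None else (len(prot_a), len(prot_b))
    evalue = m * n * 2.0 ** (-bitscore)
    if evalue > evalue_max:
        return None
    aln = aligner.align(prot_a, prot_b)[0]
    ident = 0
    length = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        length += a1 - a0
        ident += sum(1 for x, y in zip(prot_a[a0:a1], prot_b[b0:b1]) if x == y)
    # count gap columns inside the aligned region
    span_a = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    span_b = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    aln_len = max(span_a, span_b, 1)
    identity_pct = 100.0 * ident / aln_len
    return HomologyHit(query_id, subject_id, float(bitscore), float(evalue),
                       float(identity_pct), int(aln_len))


def _kmer_candidates(
    prots_a: dict[str, str], prots_b: dict[str, str], k: int, min_shared: int
) -> list[tuple[str, str]]:
    """Pairs sharing >= min_shared distinct k-mers (seed prefilter for all-vs-all)."""
    index: dict[str, list[str]] = {}
    for gid, seq in prots_b.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(gid)
    counts: dict[tuple[str, str], int] = {}
    for gid, seq in prots_a.items():
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for kmer in kmers:
            for sid in index.get(kmer, ()):
                key = (gid, sid)
                counts[key] = counts.get(key, 0) + 1
    return sorted(key for key, c in counts.items() if c >= min_shared)


def all_vs_all(
    genome_a: Genome,
    genome_b: Genome | None = None,
    evalue_max: float = 1e-5,
    seed_k: int = 5,
    min_shared_kmers: int = 2,
) -> HomologyTable:
    """All-vs-all protein search with a k-mer seed prefilter.

    Only pairs sharing ``min_shared_kmers`` distinct ``seed_k``-mers are
    aligned; unrelated random proteins essentially never pass the seed
    filter, so the cost scales with the number of true homolog pairs.
    Self comparisons (genome_b None) retain self-hits, as BLAST does.
    """
    genome_a.ensure_proteins()
    prots_a = genome_a.proteins
    if genome_b is None:
        prots_b = prots_a
    else:
        genome_b.ensure_proteins()
        prots_b = genome_b.proteins
    m = sum(len(s) for s in prots_a.values())
    n = sum(len(s) for s in prots_b.values())
    table = HomologyTable(search_space=(m, n))
    aligner = _make_aligner("local", 11.0, 1.0)
    for q, s in _kmer_candidates(prots_a, prots_b, seed_k, min_shared_kmers):
        hit = align_pair(
            prots_a[q], prots_b[s], q, s, evalue_max, search_space=(m, n), _aligner=aligner
        )
        if hit is not None:
            table.add(hit)
    return table


BLAST_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: str) -> HomologyTable:
    """Read 12-column BLAST tabular output (``-outfmt 6``).

    Duplicate (query, subject) rows collapse to the best bitscore.
    """
    table = HomologyTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            table.add(
                HomologyHit(
                    query=parts[0],
                    subject=parts[1],
                    bitscore=float(parts[11]),
                    evalue=float(parts[10]),
                    identity_pct=float(parts[2]),
                    aln_len=int(parts[3]),
                )
            )
    return table


def write_blast_tab(table: HomologyTable, path: str) -> None:
    with open(path, "w") as fh:
        for (q, s), h in sorted(table.hits.items()):
            fh.write(
                f"{q}\t{s}\t{h.identity_pct:.2f}\t{h.aln_len}\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def filter_families(table: HomologyTable, max_matches: int = 30) -> HomologyTable:
    """Drop every hit of genes with more than ``max_matches`` partners.

    Partner counts are per gene over distinct cross-gene partners (self-hits
    ignored); removal is symmetric, so a pair survives only if both genes
    are below the threshold.  Idempotent.
    """
    partners: dict[str, set[str]] = {}
    for h in table.cross_gene():
        partners.setdefault(h.query, set()).add(h.subject)
    big = {g for g, ps in partners.items() if len(ps) > max_matches}
    out = HomologyTable(search_space=table.search_space)
    for (q, s), h in table.hits.items():
        if q in big or s in big:
            continue
        out.hits[(q, s)] = h
    return out


def best_hits(table: HomologyTable) -> dict[str, str]:
    """Best-matched subject per query: max bitscore, ties by lower evalue then id."""
    best: dict[str, HomologyHit] = {}
    for h in table.cross_gene():
        cur = best.get(h.query)
        if cur is None or (-h.bitscore, h.evalue, h.subject) < (-cur.bitscore, cur.evalue, cur.subject):
            best[h.query] = h
    return {q: h.subject for q, h in best.items()}
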