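"""Genome annotation and sequence I/O, and the gene-order coordinate system.

Every downstream stage (synteny chaining, tandem detection) works in
gene-order space: each gene carries an ``order_index``, its rank along its
chromosome by ascending start coordinate.  Coordinates are 1-based inclusive
throughout, following the GFF3 convention.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "Genome",
    "read_gff",
    "read_fasta",
    "translate",
    "write_gff",
    "write_fasta",
]


@dataclass(frozen=True)
class Gene:
    """One gene model anchored to a chromosome.

    ``order_index`` is the 0-based rank of the gene along its chromosome,
    ordered by ascending start (ties: ascending end, then id).  It is the
    unit of distance for synteny gaps and tandem-intervening counts.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")


class Genome:
    """Gene models plus optional CDS and protein sequences.

    Genes are grouped by chromosome and indexed by id; ``order_index`` is
    always a bijection onto ``0..n-1`` within each chromosome.
    """

    def __init__(
        self,
        genes: Iterable[Gene],
        cds: Mapping[str, str] | None = None,
        proteins: Mapping[str, str] | None = None,
    ) -> None:
        self.by_chrom: dict[str, list[Gene]] = {}
        staged: dict[str, list[Gene]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            staged.setdefault(g.chrom, []).append(g)
        for chrom in sorted(staged):
            ranked = sorted(staged[chrom], key=lambda g: (g.start, g.end, g.id))
            self.by_chrom[chrom] = [
                Gene(g.id, g.chrom, g.start, g.end, g.strand, i) for i, g in enumerate(ranked)
            ]
        self.by_id: dict[str, Gene] = {g.id: g for gl in self.by_chrom.values() for g in gl}
        self.cds: dict[str, str] = dict(cds or {})
        self.proteins: dict[str, str] = dict(proteins or {})
        for name, seqs in (("cds", self.cds), ("protein", self.proteins)):
            missing = [gid for gid in seqs if gid not in self.by_id]
            if missing:
                raise ValueError(f"{name} sequences for unknown genes: {missing[:5]}")

    # -- views ------------------------------------------------------------
    @property
    def genes(self) -> list[Gene]:
        return [g for chrom in self.by_chrom.values() for g in chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.by_chrom)

    def __len__(self) -> int:
        return len(self.by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def gene(self, gene_id: str) -> Gene:
        return self.by_id[gene_id]

    def ensure_proteins(self) -> None:
        """Translate any CDS lacking a stored protein (longest-ORF free; the
        CDS is taken at face value)."""
        for gid, seq in self.cds.items():
            if gid not in self.proteins:
                self.proteins[gid] = translate(seq)

    def subset_chromosomes(self, chroms: Iterable[str]) -> "Genome":
        keep = set(chroms)
        genes = [g for g in self.genes if g.chrom in keep]
        ids = {g.id for g in genes}
        return Genome(
            genes,
            {k: v for k, v in self.cds.items() if k in ids},
            {k: v for k, v in self.proteins.items() if k in ids},
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_gff(
    path: str,
    feature_type: str = "gene",
    id_attribute: str = "ID",
    include_chroms: Iterable[str] | None = None,
) -> Genome:
    """Read gene models from GFF3 and assign per-chromosome order indices.

    Falls back to ``mRNA`` features when no ``feature_type`` features exist.
    ``include_chroms`` keeps only the listed chromosomes (order indices are
    re-ranked over the retained genes).
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        sort_attribute_values=True,
    )
    feats = list(db.features_of_type(feature_type))
    if not feats and feature_type == "gene":
        feats = list(db.features_of_type("mRNA"))
    keep = set(include_chroms) if include_chroms is not None else None
    genes: list[Gene] = []
    seen: set[str] = set()
    for f in feats:
        if id_attribute == "ID":
            gid = f.id
        else:
            vals = f.attributes.get(id_attribute)
            if not vals:
                raise ValueError(
                    f"{path}: feature at {f.seqid}:{f.start}-{f.end} lacks "
                    f"attribute {id_attribute!r}"
                )
            gid = vals[0]
        if gid is None or gid == "":
            raise ValueError(f"{path}: feature at {f.seqid}:{f.start}-{f.end} has no id")
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene id {gid!r}")
        seen.add(gid)
        if keep is not None and f.seqid not in keep:
            continue
        strand = f.strand if f.strand in ("+", "-") else "+"
        genes.append(Gene(gid, f.seqid, f.start, f.end, strand))
    return Genome(genes)


def write_gff(genome: Genome, path: str, feature_type: str = "gene", source: str = "wgdating") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genome.chromosomes:
            for g in genome.by_chrom[chrom]:
                fh.write(
                    f"{chrom}\t{source}\t{feature_type}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
                )


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    The id is the first whitespace token of the header.  Duplicate ids and
    empty records are hard errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def translate(cds: str, internal_stop: str = "error") -> str:
    """Translate a CDS with the standard code; the trailing stop is removed.

    ``internal_stop`` is ``"error"`` (default) or ``"mask"`` (internal stops
    become ``X``).
    """
    if cds == "":
        return ""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        if internal_stop == "mask":
            prot = prot.replace("*", "X")
        else:
            raise ValueError(f"internal stop codon at aa position {prot.index('*') + 1}")
    return prot
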