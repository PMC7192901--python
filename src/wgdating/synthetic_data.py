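"""Genome-evolution simulator with truth tables for parameter-recovery tests.

A diploid ancestor of random sense-codon genes evolves under a clock-like
nucleotide substitution process through a configurable history: one or two
whole-genome duplications at given ages, instant fractionation of the new
duplicates, tandem duplication bursts, and inversions/translocations of the
gene order.  The simulator's contract is the synonymous clock: proposed
mutations arrive as a Poisson process at ``neutral_rate`` expected
substitutions per site per year, mutations creating stop codons are
rejected, nonsynonymous proposals are accepted with probability ``omega``
and synonymous proposals always — so divergence at synonymous sites (as
NG86 counts them) matches 2 r t.  Amino-acid realism is secondary: codon
usage is uniform and there is a single substitution class.

Outputs are FASTA (CDS and protein), GFF3 and truth TSVs (WGD pair ages,
tandem arrays, the rearrangement log); re-reading them through
``genome_io`` reproduces the in-memory genome, and a fixed seed reproduces
the files byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wgdating.genome_io import Gene, Genome, write_fasta, write_gff, translate
from wgdating.ks_estimation import _CODE, _STOPS

__all__ = ["SimulationConfig", "TruthTables", "simulate", "evolve_sequence", "emit"]

_BASES = "ACGT"
_SENSE = sorted(_CODE)

# for each codon and position: the non-stop alternative bases, and which are synonymous
_ALT: dict[tuple[str, int], tuple[str, str]] = {}
for _c in _SENSE:
    for _p in range(3):
        alts = []
        syn = []
        for _b in _BASES:
            if _b == _c[_p]:
                continue
            _alt = _c[:_p] + _b + _c[_p + 1 :]
            if _alt in _STOPS:
                continue
            alts.append(_b)
            if _CODE[_alt] == _CODE[_c]:
                syn.append(_b)
        _ALT[(_c, _p)] = ("".join(alts), "".join(syn))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated genome history.

    Ages are in million years; ``neutral_rate`` is per site per year.
    ``wgd_times_mya`` must be sorted oldest first.  ``retention_prob`` is
    the probability that the new copy of a duplicated gene survives
    fractionation; ``omega`` scales acceptance of nonsynonymous changes.
    """

    n_ancestral_genes: int = 1500
    n_chromosomes: int = 5
    mean_cds_codons: int = 300
    wgd_times_mya: list[float] = field(default_factory=lambda: [60.0])
    neutral_rate: float = 3.39e-9
    omega: float = 0.15
    retention_prob: float = 0.35
    tandem_events: int = 40
    tandem_max_copies: int = 3
    n_inversions: int = 5
    n_translocations: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_ancestral_genes < 1:
            raise ValueError("n_ancestral_genes must be positive (empty genome)")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be positive")
        if sorted(self.wgd_times_mya, reverse=True) != list(self.wgd_times_mya):
            raise ValueError("wgd_times_mya must be sorted oldest first")
        if any(t <= 0 for t in self.wgd_times_mya):
            raise ValueError("WGD ages must be positive")
        for name in ("omega", "retention_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.retention_prob == 0.0 and self.wgd_times_mya:
            raise ValueError("retention_prob must be > 0 when WGDs are simulated")
        if self.neutral_rate <= 0:
            raise ValueError("neutral_rate must be positive")


@dataclass
class TruthTables:
    """Ground truth emitted next to the simulated genome."""

    wgd_pairs: pd.DataFrame  # gene_a, gene_b, event_index, time_mya, two_rt
    tandem_arrays: pd.DataFrame  # array_id, gene_id, source, time_mya
    rearrangements: pd.DataFrame  # op, chrom_from, seg_start, seg_end, chrom_to, insert_at


class _GeneRec:
    __slots__ = ("gid", "anc", "path", "seq", "strand")

    def __init__(self, gid: str, anc: str, path: tuple[int, ...], seq: list[str], strand: str):
        self.gid = gid
        self.anc = anc
        self.path = path
        self.seq = seq
        self.strand = strand


def _evolve_inplace(
    seq: list[str], years: float, neutral_rate: float, omega: float, rng: np.random.Generator
) -> None:
    length = len(seq)
    n_events = rng.poisson(neutral_rate * years * length)
    if n_events == 0:
        return
    positions = rng.integers(0, length, size=n_events)
    u_alt = rng.random(n_events)
    u_acc = rng.random(n_events)
    for k in range(n_events):
        pos = int(positions[k])
        c0 = 3 * (pos // 3)
        codon = "".join(seq[c0 : c0 + 3])
        key = (codon, pos - c0)
        if key not in _ALT:  # stop codon context (terminal stop): leave untouched
            continue
        alts, syn = _ALT[key]
        if not alts:
            continue
        base = alts[int(u_alt[k] * len(alts)) % len(alts)]
        if base not in syn and u_acc[k] >= omega:
            continue
        seq[pos] = base


def evolve_sequence(
    cds: str, years: float, neutral_rate: float = 3.39e-9, omega: float = 0.15,
    rng: np.random.Generator | None = None,
) -> str:
    """Evolve one CDS for ``years`` under the clock-calibrated codon process."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if rng is None:
        rng = np.random.default_rng(0)
    seq = list(cds)
    _evolve_inplace(seq, years, neutral_rate, omega, rng)
    return "".join(seq)


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    codons = ["ATG"] + [_SENSE[int(i)] for i in rng.integers(0, len(_SENSE), size=n_codons - 1)]
    codons.append("TAA")
    return list("".join(codons))


def simulate(config: SimulationConfig) -> tuple[Genome, TruthTables]:
    """Run the configured history and return the genome plus truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- ancestor ---------------------------------------------------------
    lengths = np.clip(rng.poisson(config.mean_cds_codons, size=config.n_ancestral_genes), 50, None)
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:06d}"

    chroms: list[list[_GeneRec]] = [[] for _ in range(config.n_chromosomes)]
    for i in range(config.n_ancestral_genes):
        gid = new_id()
        rec = _GeneRec(gid, gid, (), _random_cds(int(lengths[i]), rng), "+")
        chroms[i % config.n_chromosomes].append(rec)

    # --- event timeline (oldest first) ------------------------------------
    youngest = min(config.wgd_times_mya) if config.wgd_times_mya else 50.0
    tandem_times = sorted(rng.uniform(0.0, youngest, size=config.tandem_events), reverse=True)
    events: list[tuple[float, str, int]] = [
        (t, "wgd", i) for i, t in enumerate(config.wgd_times_mya)
    ] + [(t, "tandem", i) for i, t in enumerate(tandem_times)]
    events.sort(key=lambda e: (-e[0], e[1]))

    tandem_rows: list[tuple[int, str, str, float]] = []
    array_counter = 0
    current_time = events[0][0] if events else 0.0

    def evolve_all(dt_mya: float) -> None:
        if dt_mya <= 0:
            return
        years = dt_mya * 1e6
        for chrom in chroms:
            for rec in chrom:
                _evolve_inplace(rec.seq, years, config.neutral_rate, config.omega, rng)

    for t, kind, idx in events:
        evolve_all(current_time - t)
        current_time = t
        if kind == "wgd":
            new_chroms: list[list[_GeneRec]] = []
            for chrom in chroms:
                copy: list[_GeneRec] = []
                for rec in chrom:
                    rec.path = rec.path + (0,)
                    if rng.random() < config.retention_prob:
                        copy.append(
                            _GeneRec(new_id(), rec.anc, rec.path[:-1] + (1,), list(rec.seq), rec.strand)
                        )
                if copy:
                    new_chroms.append(copy)
            chroms.extend(new_chroms)
        else:  # tandem burst
            sizes = [len(c) for c in chroms]
            gene_pick = int(rng.integers(0, sum(sizes)))
            ci = 0
            while gene_pick >= sizes[ci]:
                gene_pick -= sizes[ci]
                ci += 1
            src = chroms[ci][gene_pick]
            n_copies = int(rng.integers(1, config.tandem_max_copies + 1))
            copies = [
                _GeneRec(new_id(), src.anc, src.path, list(src.seq), src.strand)
                for _ in range(n_copies)
            ]
            chroms[ci][gene_pick + 1 : gene_pick + 1] = copies
            tandem_rows.append((array_counter, src.gid, src.gid, t))
            for c in copies:
                tandem_rows.append((array_counter, c.gid, src.gid, t))
            array_counter += 1

    evolve_all(current_time)  # final leg to the present

    # --- rearrangements (gene order only) ---------------------------------
    rearr_rows: list[tuple[str, int, int, int, int, int]] = []
    for _ in range(config.n_inversions):
        eligible = [i for i, c in enumerate(chroms) if len(c) >= 4]
        if not eligible:
            break
        ci = eligible[int(rng.integers(0, len(eligible)))]
        n = len(chroms[ci])
        i = int(rng.integers(0, n - 1))
        j = min(n, i + 2 + int(rng.integers(0, 19)))
        seg = chroms[ci][i:j][::-1]
        for rec in seg:
            rec.strand = "-" if rec.strand == "+" else "+"
        chroms[ci][i:j] = seg
        rearr_rows.append(("inversion", ci, i, j, ci, i))
    for _ in range(config.n_translocations):
        eligible = [i for i, c in enumerate(chroms) if len(c) >= 6]
        if len(eligible) < 2 or len(chroms) < 2:
            break
        ci = eligible[int(rng.integers(0, len(eligible)))]
        n = len(chroms[ci])
        i = int(rng.integers(0, n - 2))
        j = min(n, i + 2 + int(rng.integers(0, 13)))
        seg = chroms[ci][i:j]
        del chroms[ci][i:j]
        others = [k for k in range(len(chroms)) if k != ci]
        cj = others[int(rng.integers(0, len(others)))]
        k = int(rng.integers(0, len(chroms[cj]) + 1))
        chroms[cj][k:k] = seg
        rearr_rows.append(("translocation", ci, i, j, cj, k))

    # --- materialize ------------------------------------------------------
    genes: list[Gene] = []
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    intergenic = 500
    for ci, chrom in enumerate(chroms):
        name = f"chr{ci + 1}"
        pos = 1
        for rec in chrom:
            seq = "".join(rec.seq)
            genes.append(Gene(rec.gid, name, pos, pos + len(seq) - 1, rec.strand))
            cds[rec.gid] = seq
            proteins[rec.gid] = translate(seq)
            pos += len(seq) + intergenic
    genome = Genome(genes, cds, proteins)

    # --- truth tables -----------------------------------------------------
    by_anc: dict[str, list[_GeneRec]] = {}
    for chrom in chroms:
        for rec in chrom:
            by_anc.setdefault(rec.anc, []).append(rec)
    wgd_rows: list[tuple[str, str, int, float, float]] = []
    for anc in sorted(by_anc):
        fam = sorted(by_anc[anc], key=lambda r: r.gid)
        for a in range(len(fam)):
            for b in range(a + 1, len(fam)):
                pa, pb = fam[a].path, fam[b].path
                if pa == pb:
                    continue  # tandem relatives, recorded separately
                event = next(i for i in range(len(pa)) if pa[i] != pb[i])
                t = config.wgd_times_mya[event]
                wgd_rows.append(
                    (fam[a].gid, fam[b].gid, event, t, 2.0 * config.neutral_rate * t * 1e6)
                )
    truth = TruthTables(
        wgd_pairs=pd.DataFrame(
            wgd_rows, columns=["gene_a", "gene_b", "event_index", "time_mya", "two_rt"]
        ),
        tandem_arrays=pd.DataFrame(
            tandem_rows, columns=["array_id", "gene_id", "source", "time_mya"]
        ),
        rearrangements=pd.DataFrame(
            rearr_rows,
            columns=["op", "chrom_from", "seg_start", "seg_end", "chrom_to", "insert_at"],
        ),
    )
    return genome, truth


def emit(genome: Genome, truth: TruthTables, outdir: str) -> dict[str, str]:
    """Write FASTA + GFF3 + truth TSVs; returns the path of each artifact."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "cds": os.path.join(outdir, "cds.fa"),
        "proteins": os.path.join(outdir, "prot.fa"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "wgd_pairs": os.path.join(outdir, "truth_wgd_pairs.tsv"),
        "tandem": os.path.join(outdir, "truth_tandem.tsv"),
        "rearrangements": os.path.join(outdir, "truth_rearrangements.tsv"),
    }
    order = [g.id for g in genome.genes]
    write_fasta({gid: genome.cds[gid] for gid in order}, paths["cds"])
    write_fasta({gid: genome.proteins[gid] for gid in order}, paths["proteins"])
    write_gff(genome, paths["gff"])
    truth.wgd_pairs.to_csv(paths["wgd_pairs"], sep="\t", index=False)
    truth.tandem_arrays.to_csv(paths["tandem"], sep="\t", index=False)
    truth.rearrangements.to_csv(paths["rearrangements"], sep="\t", index=False)
    return paths
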