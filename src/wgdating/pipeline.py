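"""End-to-end orchestration: ingest -> homology -> synteny -> Ks -> events -> duplications.

``run`` executes every stage from one ``RunConfig``, writes each stage's
table under a single run directory, and returns a report dictionary whose
every number is recomputable from those files.  A manifest records the
verbatim configuration, input checksums and package versions so a seed plus
manifest fully determine all outputs.

``map_concordance`` and ``hic_qc`` are small assembly-QC helpers: genetic-
map marker concordance given precomputed placements, and read-retention /
throughput arithmetic for chromosome-conformation-capture sequencing runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import re
import time
from dataclasses import asdict, dataclass, field

import pandas as pd

from wgdating import homology as _homology
from wgdating import ks_estimation as _ks
from wgdating import synteny as _synteny
from wgdating import wgd_events as _events
from wgdating import duplications as _dup
from wgdating.genome_io import Genome, read_fasta, read_gff
from wgdating.synthetic_data import SimulationConfig, emit, simulate

__all__ = ["RunConfig", "run", "map_concordance", "hic_qc"]

log = logging.getLogger("wgdating")


@dataclass
class RunConfig:
    """All inputs and stage parameters for one pipeline run."""

    outdir: str
    # inputs: either file paths ...
    gff: str | None = None
    cds: str | None = None
    proteins: str | None = None
    blast_tab: str | None = None
    domains: str | None = None
    markers: str | None = None
    # ... or a bundled simulation
    simulation: SimulationConfig | None = None
    # stage parameters (defaults follow the published analysis)
    evalue_homology: float = 1e-5
    evalue_tandem: float = 1e-20
    max_family: int = 30
    min_block: int = 4
    max_gaps: int = 50
    overlap_window: int = 5
    ks_threshold: float = 0.7
    rate: float = 3.39e-9
    max_intervening: int = 5
    min_codons: int = 30
    plot: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.min_block < 2:
            raise ValueError(f"min_block must be >= 2, got {self.min_block}")
        if self.max_gaps < 0 or self.overlap_window < 0 or self.max_intervening < 0:
            raise ValueError("gap/overlap/intervening parameters must be non-negative")
        if not (0 < self.evalue_homology and 0 < self.evalue_tandem):
            raise ValueError("e-value thresholds must be positive")
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")
        if self.simulation is None and (self.gff is None or self.cds is None):
            raise ValueError("either a simulation or gff+cds inputs are required")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage=%s wall=%.2fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def run(config: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written as report.md)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"parameters": {k: v for k, v in asdict(config).items() if k != "simulation"}}
    manifest: dict = {"config": report["parameters"], "inputs": {}}
    if config.simulation is not None:
        manifest["simulation"] = asdict(config.simulation)

    # -- ingest -----------------------------------------------------------
    if config.simulation is not None:
        genome, truth = simulate(config.simulation)
        emit(genome, truth, os.path.join(config.outdir, "simulated"))
    else:
        genome = read_gff(config.gff)
        genome.cds.update(read_fasta(config.cds))
        if config.proteins:
            genome.proteins.update(read_fasta(config.proteins))
        for p in (config.gff, config.cds, config.proteins):
            if p:
                manifest["inputs"][p] = _sha256(p)
    genome.ensure_proteins()
    report["n_genes"] = len(genome)
    report["n_chromosomes"] = len(genome.chromosomes)

    # -- homology ---------------------------------------------------------
    if config.blast_tab:
        table = _stage("homology")(_homology.read_blast_tab)(config.blast_tab)
        manifest["inputs"][config.blast_tab] = _sha256(config.blast_tab)
    else:
        table = _stage("homology")(_homology.all_vs_all)(genome, evalue_max=config.evalue_homology)
    report["n_hits"] = len(table)
    filtered = _homology.filter_families(table, config.max_family)
    report["n_hits_after_family_filter"] = len(filtered)
    _homology.write_blast_tab(filtered, os.path.join(config.outdir, "homology.tsv"))

    # -- synteny ----------------------------------------------------------
    blocks = _stage("synteny")(_synteny.self_synteny)(
        filtered, genome,
        min_block=config.min_block, max_gaps=config.max_gaps,
        overlap_window=config.overlap_window, max_intervening=config.max_intervening,
    )
    _synteny.write_blocks_tsv(blocks, os.path.join(config.outdir, "blocks.tsv"))
    _synteny.write_collinearity(blocks, os.path.join(config.outdir, "blocks.collinearity"))

    # -- Ks ---------------------------------------------------------------
    anchor_pairs = [(a.gene_a, a.gene_b) for b in blocks for a in b.anchors]
    estimates = _stage("ks")(_ks.ks_for_pairs)(genome, anchor_pairs, min_codons=config.min_codons)
    block_of = {(a.gene_a, a.gene_b): b.block_id for b in blocks for a in b.anchors}
    _ks.write_ks_tsv(estimates, os.path.join(config.outdir, "ks.tsv"), block_of)
    _ks.annotate_blocks_with_ks(blocks, estimates)
    report["n_saturated_pairs"] = sum(1 for e in estimates.values() if e.status == "saturated")

    # -- events -----------------------------------------------------------
    classes, n_undefined = _events.classify_blocks(blocks, config.ks_threshold)
    report["n_blocks_without_ks"] = n_undefined
    report["block_summary"] = _synteny.block_summary(blocks)
    dates = {}
    peak_rows = []
    for event in ("CRT", "ECH"):
        ks_vals = [
            estimates[(a.gene_a, a.gene_b)].ks
            for b in blocks if b.event_class == event
            for a in b.anchors
            if estimates[(a.gene_a, a.gene_b)].status == "ok"
        ]
        if len(ks_vals) < _events.MIN_KDE_VALUES:
            continue
        fit = _events.fit_ks_peaks(ks_vals)
        if not fit.peaks:
            continue
        peak = fit.peaks[0][0]
        date = _events.date_event(peak, config.rate, event)
        dates[event] = {"ks_peak": round(peak, 3), "time_mya": round(date.time_mya, 1),
                        "n_pairs": len(ks_vals)}
        peak_rows.append((event, round(peak, 4), round(date.time_mya, 2), len(ks_vals)))
        if config.plot:
            _plot_density(fit, event, os.path.join(config.outdir, f"ks_density_{event}.png"))
    report["dates"] = dates
    pd.DataFrame(peak_rows, columns=["event", "ks_peak", "time_mya", "n_pairs"]).to_csv(
        os.path.join(config.outdir, "dates.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [(c.block_id, c.event, round(c.median_ks, 4)) for c in classes],
        columns=["block_id", "event", "median_ks"],
    ).to_csv(os.path.join(config.outdir, "block_classes.tsv"), sep="\t", index=False)

    # -- duplications -----------------------------------------------------
    arrays = _stage("tandem")(_dup.detect_tandem)(
        table, genome, evalue_max=config.evalue_tandem, max_intervening=config.max_intervening
    )
    n_tandem, pct = _dup.tandem_fraction(arrays, genome)
    report["tandem"] = {"n_arrays": len(arrays), "n_genes": n_tandem, "pct_of_anchored": pct}
    pd.DataFrame(
        [(i, a.chrom, ",".join(a.members), a.span[0], a.span[1]) for i, a in enumerate(arrays)],
        columns=["array_id", "chrom", "members", "start", "end"],
    ).to_csv(os.path.join(config.outdir, "tandem.tsv"), sep="\t", index=False)

    if config.domains:
        dom = pd.read_csv(config.domains, sep="\t")
        nbs = _dup.classify_nbs(dom)
        counts: dict[str, int] = {}
        for g in nbs:
            counts[g.nbs_class] = counts.get(g.nbs_class, 0) + 1
        report["nbs"] = {"n_genes": len(nbs), "by_class": counts}
        pd.DataFrame(
            [(g.gene_id, g.nbs_class, ";".join(sorted(g.domains)), g.ambiguous) for g in nbs],
            columns=["gene_id", "nbs_class", "domains", "ambiguous"],
        ).to_csv(os.path.join(config.outdir, "nbs.tsv"), sep="\t", index=False)
        manifest["inputs"][config.domains] = _sha256(config.domains)

    if config.markers:
        placements = pd.read_csv(config.markers, sep="\t")
        n_unamb, pct_conc = map_concordance(placements)
        report["map_concordance"] = {"n_unambiguous": n_unamb, "pct_concordant": pct_conc}
        manifest["inputs"][config.markers] = _sha256(config.markers)

    # -- report + manifest ------------------------------------------------
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _write_report_md(report, os.path.join(config.outdir, "report.md"))
    return report


def _plot_density(fit, event: str, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(fit.grid, fit.density, lw=1.5)
    for ks, dens in fit.peaks:
        ax.axvline(ks, color="crimson", ls="--", lw=0.8)
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    ax.set_title(f"{event} Ks distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_report_md(report: dict, path: str) -> None:
    lines = ["# wgdating run report", ""]
    lines.append(f"- genes: {report['n_genes']} on {report['n_chromosomes']} chromosomes")
    lines.append(f"- homology hits: {report['n_hits']} "
                 f"({report['n_hits_after_family_filter']} after family filter)")
    bs = report["block_summary"]
    lines.append(f"- collinear blocks: {bs['n_blocks']} with {bs['n_pairs']} gene pairs "
                 f"({bs['pairs_per_block']} pairs/block)")
    for cls, sub in bs["by_class"].items():
        lines.append(f"  - {cls}: {sub['n_blocks']} blocks, {sub['n_pairs']} pairs "
                     f"({sub['pct_pairs']}% of pairs, {sub['pairs_per_block']}/block)")
    for event, d in report.get("dates", {}).items():
        lines.append(f"- {event}: Ks peak {d['ks_peak']} -> {d['time_mya']} Mya "
                     f"({d['n_pairs']} pairs)")
    t = report["tandem"]
    lines.append(f"- tandem: {t['n_arrays']} arrays, {t['n_genes']} genes "
                 f"({t['pct_of_anchored']}% of anchored genes)")
    if "nbs" in report:
        lines.append(f"- NBS genes: {report['nbs']['n_genes']} ({report['nbs']['by_class']})")
    if "map_concordance" in report:
        m = report["map_concordance"]
        lines.append(f"- map concordance: {m['pct_concordant']}% of {m['n_unambiguous']} "
                     f"unambiguous markers")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# QC helpers


_LG_RE = re.compile(r"(\d+)$")


def _lg_chrom(lg: str, mapping: dict[str, str] | None) -> str:
    if mapping is not None:
        if lg not in mapping:
            raise ValueError(f"unknown linkage group label {lg!r}")
        return mapping[lg]
    m = _LG_RE.search(str(lg))
    if not m:
        raise ValueError(f"unknown linkage group label {lg!r}")
    return f"chr{int(m.group(1))}"


def map_concordance(
    placements: pd.DataFrame,
    max_placements: int = 1,
    lg_to_chrom: dict[str, str] | None = None,
) -> tuple[int, float]:
    """Marker concordance between a genetic map and the assembly.

    ``placements`` has one row per genome placement with columns
    ``marker_id``, ``linkage_group``, ``chrom`` (and optionally positions).
    Markers with more than ``max_placements`` placements are removed as
    ambiguous; a retained marker is concordant when all its placements lie
    on the chromosome assigned to its linkage group (identity mapping
    LGxx -> chrxx unless ``lg_to_chrom`` overrides it).  Returns the number
    of unambiguous markers and the concordant percentage to 1 decimal.
    """
    required = {"marker_id", "linkage_group", "chrom"}
    missing = required - set(placements.columns)
    if missing:
        raise ValueError(f"placement table lacks columns: {sorted(missing)}")
    n_unambiguous = 0
    n_concordant = 0
    for marker, grp in placements.groupby("marker_id", sort=True):
        if len(grp) > max_placements:
            continue
        n_unambiguous += 1
        lgs = set(grp["linkage_group"])
        if len(lgs) != 1:
            raise ValueError(f"marker {marker!r} maps to multiple linkage groups")
        expected = _lg_chrom(lgs.pop(), lg_to_chrom)
        if all(c == expected for c in grp["chrom"]):
            n_concordant += 1
    pct = round(100.0 * n_concordant / n_unambiguous, 1) if n_unambiguous else 0.0
    return n_unambiguous, pct


def hic_qc(
    n_read_pairs_total: int,
    n_read_pairs_retained: int,
    read_length: int = 150,
    paired: bool = True,
) -> dict:
    """Retention and throughput arithmetic for a proximity-ligation sequencing run."""
    if n_read_pairs_retained > n_read_pairs_total:
        raise ValueError("retained read pairs exceed total")
    reads_per_pair = 2 if paired else 1
    return {
        "retained_pct": round(100.0 * n_read_pairs_retained / n_read_pairs_total, 1),
        "total_gigabases": round(n_read_pairs_total * reads_per_pair * read_length / 1e9, 1),
    }
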