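import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from wgdating.genome_io import Gene, Genome
from wgdating.homology import HomologyHit, HomologyTable
from wgdating.pipeline import RunConfig, run
from wgdating.synthetic_data import SimulationConfig, simulate


def make_genome(layout: dict[str, list[str]], cds=None, proteins=None) -> Genome:
    """Genome from {chrom: [gene ids in order]}; coordinates spaced by 1000."""
    genes = []
    for chrom, ids in layout.items():
        for i, gid in enumerate(ids):
            start = 1000 * i + 1
            genes.append(Gene(gid, chrom, start, start + 500, "+"))
    return Genome(genes, cds, proteins)


def make_table(pairs, bitscore=100.0, evalue=1e-50) -> HomologyTable:
    """HomologyTable from (query, subject[, bitscore[, evalue]]) tuples."""
    t = HomologyTable(search_space=(10_000, 10_000))
    for p in pairs:
        q, s = p[0], p[1]
        b = p[2] if len(p) > 2 else bitscore
        e = p[3] if len(p) > 3 else evalue
        t.add(HomologyHit(q, s, b, e, 90.0, 100))
    return t


@pytest.fixture(scope="session")
def wgd60_sim():
    """One WGD at 60 Mya, 30% fractionation, no tandem bursts: the synteny test bed."""
    config = SimulationConfig(
        n_ancestral_genes=300, n_chromosomes=4, wgd_times_mya=[60.0],
        retention_prob=0.7, tandem_events=0, n_inversions=3, n_translocations=1, seed=11,
    )
    return config, *simulate(config)


@pytest.fixture(scope="session")
def default_pipeline_report(tmp_path_factory):
    """Full pipeline run on the default simulated genome (~2000 genes, WGD at 60 Mya)."""
    outdir = tmp_path_factory.mktemp("run_default")
    config = RunConfig(outdir=str(outdir), simulation=SimulationConfig(seed=5), seed=5)
    return config, run(config)
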