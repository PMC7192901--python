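"""Tandem duplicate arrays, NBS resistance-gene classes and enrichment tests.

Tandem duplicates are homologous genes on the same chromosome separated by
at most five intervening genes (order-index distance <= 6); arrays are the
connected components of that proximity graph, merged transitively, so a
chain g1-g2-g3 forms one three-member array even when g1 and g3 were not
hit directly.

NBS genes carry an NB-ARC domain and are subclassified by their N-terminal
and C-terminal companion domains into N, NL, CN, CNL, TN and RN.  Domain
calls (Pfam, coiled-coil predictions) are inputs, not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from wgdating.genome_io import Genome
from wgdating.homology import HomologyTable

__all__ = [
    "TandemArray",
    "NbsGene",
    "detect_tandem",
    "tandem_fraction",
    "classify_nbs",
    "enrichment_test",
]

DEFAULT_TANDEM_EVALUE = 1e-20
DEFAULT_MAX_INTERVENING = 5

# canonical domain labels accepted from the input table, keyed by accession
DOMAIN_ACCESSIONS = {
    "PF00931": "NB-ARC",
    "PF13676": "TIR",
    "PF01582": "TIR",
    "PF00560": "LRR",
    "PF07723": "LRR",
    "PF07725": "LRR",
    "PF12799": "LRR",
    "PF13306": "LRR",
    "PF13516": "LRR",
    "PF13504": "LRR",
    "PF13855": "LRR",
    "cl34836": "LRR",
    "PF05659": "RPW8",
}


@dataclass
class TandemArray:
    chrom: str
    members: list[str]  # ordered by order_index
    span: tuple[int, int]  # (min start, max end)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class NbsGene:
    gene_id: str
    domains: frozenset[str]
    nbs_class: str  # {N, NL, CNL, CN, TN, RN}
    ambiguous: bool = False


def detect_tandem(
    table: HomologyTable,
    genome: Genome,
    evalue_max: float = DEFAULT_TANDEM_EVALUE,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[TandemArray]:
    """Tandem arrays as connected components of the same-chromosome proximity graph.

    An edge joins two homologous genes on one chromosome whose order-index
    distance is at most ``max_intervening + 1``; components of size >= 2 are
    arrays.  Symmetric in hit orientation and independent of hit order.
    """
    graph: nx.Graph = nx.Graph()
    for h in table.cross_gene():
        if h.evalue > evalue_max:
            continue
        if h.query not in genome.by_id or h.subject not in genome.by_id:
            continue
        ga, gb = genome.gene(h.query), genome.gene(h.subject)
        if ga.chrom != gb.chrom:
            continue
        if abs(ga.order_index - gb.order_index) <= max_intervening + 1:
            graph.add_edge(h.query, h.subject)
    arrays: list[TandemArray] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = sorted(comp, key=lambda gid: genome.gene(gid).order_index)
        chrom = genome.gene(members[0]).chrom
        starts = [genome.gene(g).start for g in members]
        ends = [genome.gene(g).end for g in members]
        arrays.append(TandemArray(chrom, members, (min(starts), max(ends))))
    arrays.sort(key=lambda a: (a.chrom, a.span))
    return arrays


def tandem_fraction(arrays: list[TandemArray], genome: Genome) -> tuple[int, float]:
    """Number of tandem genes and their percentage of anchored genes (1 decimal)."""
    n_tandem = sum(len(a) for a in arrays)
    n_genes = len(genome)
    pct = round(100.0 * n_tandem / n_genes, 1) if n_genes else 0.0
    return n_tandem, pct


def _class_from_domains(domains: frozenset[str]) -> tuple[str, bool]:
    has = domains.__contains__
    n_terminal = [d for d in ("TIR", "CC", "RPW8") if has(d)]
    ambiguous = len(n_terminal) > 1
    head = n_terminal[0] if n_terminal else None  # precedence TIR > CC > RPW8
    lrr = has("LRR")
    if head == "TIR":
        return "TN", ambiguous
    if head == "CC":
        return ("CNL" if lrr else "CN"), ambiguous
    if head == "RPW8":
        return "RN", ambiguous
    return ("NL" if lrr else "N"), False


def classify_nbs(domain_table: pd.DataFrame) -> list[NbsGene]:
    """Classify NBS genes from a per-gene domain hit table.

    Expects columns ``gene_id`` and either ``domain_label`` (one of NB-ARC,
    TIR, LRR, CC, RPW8) or ``accession`` (Pfam/CDD ids, mapped internally).
    Genes without an NB-ARC domain are not NBS genes and are omitted.  When
    several N-terminal domains co-occur the precedence TIR > CC > RPW8
    applies and the gene is flagged ambiguous.
    """
    labels: dict[str, set[str]] = {}
    for _, row in domain_table.iterrows():
        gid = str(row["gene_id"])
        label = None
        if "domain_label" in domain_table.columns and pd.notna(row.get("domain_label")):
            label = str(row["domain_label"])
        elif "accession" in domain_table.columns and pd.notna(row.get("accession")):
            label = DOMAIN_ACCESSIONS.get(str(row["accession"]))
        if label in ("NB-ARC", "TIR", "LRR", "CC", "RPW8"):
            labels.setdefault(gid, set()).add(label)
    out: list[NbsGene] = []
    for gid in sorted(labels):
        doms = frozenset(labels[gid])
        if "NB-ARC" not in doms:
            continue
        cls, ambiguous = _class_from_domains(doms)
        out.append(NbsGene(gid, doms, cls, ambiguous))
    return out


def enrichment_test(
    gene_set: set[str],
    annotation_map: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term, BH-adjusted.

    ``annotation_map`` maps term -> annotated gene ids.  Genes outside the
    universe are ignored on both sides.  Returns a frame sorted by adjusted
    p with a ``significant`` flag at ``alpha``.
    """
    gene_set = set(gene_set) & set(universe)
    M = len(universe)
    rows = []
    if not gene_set:
        return pd.DataFrame(
            columns=["term", "k", "term_size", "set_size", "universe", "p", "p_adj", "significant"]
        )
    for term in sorted(annotation_map):
        term_genes = set(annotation_map[term]) & set(universe)
        k = len(gene_set & term_genes)
        n = len(term_genes)
        N = len(gene_set)
        if n == 0:
            continue
        p = float(hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append((term, k, n, N, M, p))
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "term_size", "set_size", "universe", "p", "p_adj", "significant"]
        )
    df = pd.DataFrame(rows, columns=["term", "k", "term_size", "set_size", "universe", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < alpha
    return df.sort_values(["p_adj", "p", "term"]).reset_index(drop=True)
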