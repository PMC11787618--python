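"""Reciprocal-best-hit homology network and family census.

Candidate genes are searched against the full proteome of every other genome;
a homology edge joins two genes from different genomes exactly when each is
the other's best accepted hit (reciprocal best hit). The homolog family is
the connected component containing the seed gene — connectivity, not cliques,
so remote homologs can join through intermediates — and the census records
per-genome presence/absence of anchors and the family member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import batch_local_scores, local_align
from .anchors import ABSENT, CandidateInterval
from .genome_io import GeneFeature, GenomeRecord

logger = logging.getLogger(__name__)

GeneKey = tuple[str, str]  # (genome_id, gene_id)

DEFAULT_MIN_HIT_SCORE = 50.0
DEFAULT_MIN_HIT_COVERAGE = 0.25


@dataclass(frozen=True)
class Hit:
    """An accepted best hit of a query gene in a target genome."""

    gene: GeneKey
    score: float
    identity: float
    coverage: float  # aligned fraction of the shorter sequence


@dataclass(frozen=True)
class HomologyEdge:
    """Unordered reciprocal-best-hit edge between genes of two genomes."""

    gene_a: GeneKey
    gene_b: GeneKey
    score_ab: float
    score_ba: float
    identity_ab: float


@dataclass
class HomologyGraph:
    nodes: set[GeneKey] = field(default_factory=set)
    edges: list[HomologyEdge] = field(default_factory=list)

    def as_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b, score_ab=e.score_ab, score_ba=e.score_ba)
        return g


@dataclass
class HomologFamily:
    """Seed-connected component with at most one member per genome."""

    seed: GeneKey
    members: dict[str, str]  # genome_id -> gene_id
    orphans: list[GeneKey] = field(default_factory=list)


@dataclass
class CensusRow:
    genome_id: str
    taxon_group: str
    egt: str
    family_member: str
    bm9: str
    member_between_anchors: bool


class _Scorer:
    """Caches best-hit computations keyed by (query gene, target genome)."""

    def __init__(
        self,
        genomes: dict[str, GenomeRecord],
        min_hit_score: float = DEFAULT_MIN_HIT_SCORE,
        min_coverage: float = DEFAULT_MIN_HIT_COVERAGE,
    ) -> None:
        self.genomes = genomes
        self.min_hit_score = min_hit_score
        self.min_coverage = min_coverage
        self._cache: dict[tuple[GeneKey, str], Hit | None] = {}

    def best_hit(self, query: GeneKey, target_genome_id: str) -> Hit | None:
        key = (query, target_genome_id)
        if key not in self._cache:
            self._cache[key] = best_hit(
                self.genomes[query[0]].gene(query[1]),
                query[0],
                self.genomes[target_genome_id],
                self.min_hit_score,
                self.min_coverage,
            )
        return self._cache[key]


def best_hit(
    query: GeneFeature,
    query_genome_id: str,
    target: GenomeRecord,
    min_hit_score: float = DEFAULT_MIN_HIT_SCORE,
    min_coverage: float = DEFAULT_MIN_HIT_COVERAGE,
) -> Hit | None:
    """Highest-scoring accepted local alignment of a gene against a proteome.

    Acceptance requires score >= min_hit_score and alignment coverage of at
    least ``min_coverage`` of the shorter sequence. Ties break by higher
    score, then longer alignment, then lexicographic gene_id. Returns ``None``
    when no target protein passes.
    """
    if target.genome_id == query_genome_id:
        raise ValueError("best_hit target must be a different genome")
    ids = [g.gene_id for g in target.genes]
    seqs = [g.protein for g in target.genes]
    scores = batch_local_scores(query.protein, seqs)
    best: tuple[float, int, str] | None = None
    best_hit_: Hit | None = None
    for idx in np.argsort(-scores, kind="stable"):
        score = float(scores[idx])
        if score < min_hit_score:
            break
        if best is not None and -best[0] > score:
            break  # no later candidate can beat the accepted best
        aln = local_align(query.protein, seqs[idx], query_id=query.gene_id, subject_id=ids[idx])
        if aln.query_span is None:
            continue
        aligned_q = aln.query_span[1] - aln.query_span[0] + 1
        aligned_s = aln.subject_span[1] - aln.subject_span[0] + 1
        if len(query.protein) <= len(seqs[idx]):
            coverage = aligned_q / len(query.protein)
        else:
            coverage = aligned_s / len(seqs[idx])
        if coverage < min_coverage:
            continue
        key = (-aln.score, -aln.alignment_length, ids[idx])
        if best is None or key < best:
            best = key
            best_hit_ = Hit(
                gene=(target.genome_id, ids[idx]),
                score=aln.score,
                identity=aln.percent_identity,
                coverage=coverage,
            )
    return best_hit_


def build_graph(
    candidate_intervals: list[CandidateInterval],
    genomes: list[GenomeRecord],
    min_hit_score: float = DEFAULT_MIN_HIT_SCORE,
    min_coverage: float = DEFAULT_MIN_HIT_COVERAGE,
    scorer: _Scorer | None = None,
) -> HomologyGraph:
    """Reciprocal-best-hit graph over candidate genes and full proteomes.

    For every candidate gene g and every other genome G, the best hit h of g
    in G is computed; the unordered edge (g, h) is added iff h's best hit back
    in g's genome is g itself. Candidates are searched against full proteomes,
    and reciprocity is likewise checked against the full query proteome.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    by_id = {g.genome_id: g for g in genomes}
    scorer = scorer or _Scorer(by_id, min_hit_score, min_coverage)
    graph = HomologyGraph()
    seen_edges: set[frozenset[GeneKey]] = set()
    for interval in sorted(candidate_intervals, key=lambda iv: iv.genome_id):
        for gene_id in interval.candidates:
            g_key: GeneKey = (interval.genome_id, gene_id)
            graph.nodes.add(g_key)
            for other_id in sorted(by_id):
                if other_id == interval.genome_id:
                    continue
                fwd = scorer.best_hit(g_key, other_id)
                if fwd is None:
                    continue
                back = scorer.best_hit(fwd.gene, interval.genome_id)
                if back is None or back.gene != g_key:
                    continue
                pair = frozenset((g_key, fwd.gene))
                if pair in seen_edges:
                    continue
                seen_edges.add(pair)
                a, b = sorted((g_key, fwd.gene))
                if a == g_key:
                    edge = HomologyEdge(a, b, fwd.score, back.score, fwd.identity)
                else:
                    edge = HomologyEdge(a, b, back.score, fwd.score, back.identity)
                graph.edges.append(edge)
                graph.nodes.add(fwd.gene)
    return graph


def seed_component(
    graph: HomologyGraph,
    seed: GeneKey,
    genomes: dict[str, GenomeRecord] | None = None,
) -> HomologFamily:
    """Connected component of the seed; one member per genome.

    When a genome contributes several genes to the component, the gene with
    the highest local-alignment score to the seed protein becomes the member
    and the rest are reported as orphans (paralogy guard).
    """
    if seed not in graph.nodes:
        raise ValueError(f"seed {seed} not in homology graph")
    g = graph.as_networkx()
    component = nx.node_connected_component(g, seed)
    per_genome: dict[str, list[GeneKey]] = {}
    for node in component:
        per_genome.setdefault(node[0], []).append(node)
    members: dict[str, str] = {}
    orphans: list[GeneKey] = []
    for genome_id, nodes in sorted(per_genome.items()):
        if len(nodes) == 1:
            members[genome_id] = nodes[0][1]
            continue
        if genomes is None:
            raise ValueError(
                f"genome {genome_id} contributes {len(nodes)} genes; "
                "genomes required to rank them against the seed"
            )
        seed_protein = genomes[seed[0]].gene(seed[1]).protein
        ranked = sorted(
            nodes,
            key=lambda n: (
                -local_align(seed_protein, genomes[n[0]].gene(n[1]).protein).score,
                n[1],
            ),
        )
        members[genome_id] = ranked[0][1]
        orphans.extend(ranked[1:])
    return HomologFamily(seed=seed, members=members, orphans=sorted(orphans))


def census(
    family: HomologFamily,
    genomes: list[GenomeRecord],
    intervals: list[CandidateInterval],
) -> list[CensusRow]:
    """Per-genome presence/absence of anchors and the family member."""
    by_genome = {iv.genome_id: iv for iv in intervals}
    rows: list[CensusRow] = []
    for genome in genomes:
        iv = by_genome.get(genome.genome_id)
        egt = iv.egt_hit.gene_id if iv else ABSENT
        bm9 = iv.bm9_hit.gene_id if iv else ABSENT
        member = family.members.get(genome.genome_id, ABSENT)
        between = bool(iv and member != ABSENT and member in iv.candidates)
        rows.append(
            CensusRow(
                genome_id=genome.genome_id,
                taxon_group=genome.taxon_group,
                egt=egt,
                family_member=member,
                bm9=bm9,
                member_between_anchors=between,
            )
        )
    return rows
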