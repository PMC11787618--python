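"""Anchor-gene location and candidate-interval extraction.

The family search is synteny-anchored: in each genome, homologs of the two
anchor genes (egt and Bm9) are located by local alignment against reference
anchor proteins, and the genes lying strictly between the two anchors (the
shorter arc on circular genomes) become the candidate set. When Bm9 is absent
from a genome, a symmetric window of genes around egt is used instead —
"downstream of egt" is not directionally defined, and a symmetric window
cannot miss the true neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignmentResult, local_align
from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)

ABSENT = "ABSENT"

DEFAULT_MIN_ANCHOR_SCORE = 80.0
DEFAULT_MIN_ANCHOR_COVERAGE = 0.5
DEFAULT_FALLBACK_WINDOW = 10


@dataclass
class AnchorHit:
    """Best hit of a reference anchor protein in one genome (or ABSENT)."""

    genome_id: str
    anchor_name: str  # "egt" | "Bm9"
    gene_id: str  # gene_id or ABSENT
    score: float = 0.0
    identity: float = 0.0
    coverage: float = 0.0  # fraction of the reference anchor length aligned

    @property
    def absent(self) -> bool:
        return self.gene_id == ABSENT


@dataclass
class CandidateInterval:
    """Ordered candidate gene ids between the anchors of one genome."""

    genome_id: str
    egt_hit: AnchorHit
    bm9_hit: AnchorHit
    candidates: list[str] = field(default_factory=list)
    bm9_absent_fallback: bool = False


def find_anchor(
    genome: GenomeRecord,
    anchor_ref: str,
    anchor_name: str,
    min_score: float = DEFAULT_MIN_ANCHOR_SCORE,
    min_coverage: float = DEFAULT_MIN_ANCHOR_COVERAGE,
) -> AnchorHit:
    """Locate the best anchor homolog in a genome by local alignment.

    The reference anchor protein is aligned against every genome protein; the
    highest-scoring alignment is accepted iff its score and reference coverage
    meet the thresholds, otherwise the hit is ABSENT. Ties break by higher
    score, then longer alignment, then lexicographic gene_id.
    """
    if not genome.genes:
        raise ValueError(f"{genome.genome_id}: genome has no genes")
    best: tuple[float, int, str] | None = None
    best_aln: AlignmentResult | None = None
    for gene in genome.genes:
        aln = local_align(anchor_ref, gene.protein, query_id=anchor_name, subject_id=gene.gene_id)
        key = (-aln.score, -aln.alignment_length, gene.gene_id)
        if best is None or key < best:
            best = key
            best_aln = aln
    assert best_aln is not None
    coverage = 0.0
    if best_aln.query_span is not None:
        coverage = (best_aln.query_span[1] - best_aln.query_span[0] + 1) / len(anchor_ref)
    if best_aln.score >= min_score and coverage >= min_coverage:
        return AnchorHit(
            genome_id=genome.genome_id,
            anchor_name=anchor_name,
            gene_id=best_aln.subject_id,
            score=best_aln.score,
            identity=best_aln.percent_identity,
            coverage=coverage,
        )
    return AnchorHit(genome_id=genome.genome_id, anchor_name=anchor_name, gene_id=ABSENT)


def _shorter_arc(rank_a: int, rank_b: int, n: int, circular: bool) -> list[int]:
    """Ranks strictly between two anchor ranks, along the shorter arc.

    On circular genomes both arcs are enumerated and the shorter one chosen
    (ties go to the forward arc from rank_a to rank_b). Linear genomes have a
    single between-interval.
    """
    lo, hi = min(rank_a, rank_b), max(rank_a, rank_b)
    inner = list(range(lo + 1, hi))
    if not circular:
        return inner
    outer = list(range(hi + 1, n)) + list(range(0, lo))
    if len(outer) < len(inner):
        # wrap-around arc; order it walking forward from hi
        return outer
    return inner


def extract_candidates(
    genome: GenomeRecord,
    egt_hit: AnchorHit,
    bm9_hit: AnchorHit,
    fallback_window: int = DEFAULT_FALLBACK_WINDOW,
) -> CandidateInterval | None:
    """Genes strictly between the anchors, or a window around egt.

    Returns ``None`` (with a logged warning) when egt is absent: such genomes
    are excluded from candidate generation. When Bm9 is absent, up to
    ``fallback_window`` genes on each side of egt are taken and the interval
    is flagged ``bm9_absent_fallback``.
    """
    if egt_hit.absent:
        logger.warning("%s: egt anchor absent; genome skipped", genome.genome_id)
        return None
    n = genome.n_genes
    egt_rank = genome.gene(egt_hit.gene_id).rank
    circular = genome.topology == "circular"
    if not bm9_hit.absent:
        bm9_rank = genome.gene(bm9_hit.gene_id).rank
        ranks = _shorter_arc(egt_rank, bm9_rank, n, circular)
        fallback = False
    else:
        ranks = []
        for off in range(1, fallback_window + 1):
            for r in (egt_rank - off, egt_rank + off):
                if circular:
                    ranks.append(r % n)
                elif 0 <= r < n:
                    ranks.append(r)
        # unique, genome order, anchors excluded
        ranks = sorted({r for r in ranks if r != egt_rank})
        fallback = True
    anchor_ranks = {egt_rank}
    if not bm9_hit.absent:
        anchor_ranks.add(genome.gene(bm9_hit.gene_id).rank)
    candidates = [genome.genes[r].gene_id for r in ranks if r not in anchor_ranks]
    return CandidateInterval(
        genome_id=genome.genome_id,
        egt_hit=egt_hit,
        bm9_hit=bm9_hit,
        candidates=candidates,
        bm9_absent_fallback=fallback,
    )
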