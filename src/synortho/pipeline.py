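"""End-to-end census pipeline: anchors -> candidates -> RBH family -> reports.

Runs the whole workflow on a set of annotated genomes: locate the egt/Bm9
anchors, extract candidate genes between them, build the reciprocal-best-hit
graph, take the seed gene's connected component as the family, emit the
presence/absence census, scan family members for coiled coils, align the
coil fragments, classify column conservation, and build a neighbor-joining
family tree (optionally compared against a reference topology).

All thresholds live in :class:`PipelineConfig`; a plain ``key = value``
config file can override any of them, and unknown keys are rejected. Every
output table is reproducible by calling the underlying module function with
the same inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import anchors as anchors_mod
from . import coiledcoil, msa as msa_mod, network, phylo
from .genome_io import GenomeRecord, write_protein_fasta, write_tsv

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Bad or unknown pipeline configuration key/value."""


@dataclass
class PipelineConfig:
    """All tunable thresholds of the census pipeline, with defaults."""

    min_anchor_score: float = anchors_mod.DEFAULT_MIN_ANCHOR_SCORE
    min_anchor_coverage: float = anchors_mod.DEFAULT_MIN_ANCHOR_COVERAGE
    fallback_window: int = anchors_mod.DEFAULT_FALLBACK_WINDOW
    min_hit_score: float = network.DEFAULT_MIN_HIT_SCORE
    min_hit_coverage: float = network.DEFAULT_MIN_HIT_COVERAGE
    coil_window: int = coiledcoil.DEFAULT_WINDOW
    coil_threshold: float = coiledcoil.DEFAULT_THRESHOLD
    hydrophobic: str = "".join(sorted(coiledcoil.DEFAULT_HYDROPHOBIC))
    equivalence: str = "".join(sorted(msa_mod.DEFAULT_EQUIVALENCE))
    gap_open: float = 10.0
    gap_extend: float = 0.5
    poisson: bool = False
    align_full_length: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a ``key = value`` config file; unknown keys are rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (t.strip() for t in line.partition("="))
            if key not in fields:
                raise PipelineConfigError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(cls(), key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory artifacts of one census run."""

    genomes: list[GenomeRecord]
    intervals: list
    graph: network.HomologyGraph
    family: network.HomologFamily
    census: list[network.CensusRow]
    coils: dict[str, list[coiledcoil.CoiledCoilAnnotation]]
    msa: msa_mod.MSA | None
    conservation: msa_mod.ConservationReport | None
    tree: object | None
    rf: int | None
    skipped: list[str] = field(default_factory=list)


def run_census_pipeline(
    genomes: list[GenomeRecord],
    anchor_refs: dict[str, str],
    seed: tuple[str, str],
    config: PipelineConfig | None = None,
    reference_tree: str | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full anchored-homolog census on in-memory genomes.

    ``anchor_refs`` maps the anchor names ``egt`` and ``Bm9`` to reference
    proteins; ``seed`` is the (genome_id, gene_id) of the known family gene.
    When ``outdir`` is given, TSV/FASTA/Newick artifacts and a run log are
    written there.
    """
    config = config or PipelineConfig()
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    for name in ("egt", "Bm9"):
        if name not in anchor_refs:
            raise ValueError(f"anchor reference {name!r} missing")

    intervals = []
    skipped: list[str] = []
    for genome in genomes:
        egt_hit = anchors_mod.find_anchor(
            genome, anchor_refs["egt"], "egt", config.min_anchor_score, config.min_anchor_coverage
        )
        bm9_hit = anchors_mod.find_anchor(
            genome, anchor_refs["Bm9"], "Bm9", config.min_anchor_score, config.min_anchor_coverage
        )
        interval = anchors_mod.extract_candidates(genome, egt_hit, bm9_hit, config.fallback_window)
        if interval is None:
            skipped.append(genome.genome_id)
        else:
            intervals.append(interval)

    graph = network.build_graph(
        intervals, genomes, config.min_hit_score, config.min_hit_coverage
    )
    if seed not in graph.nodes:
        raise ValueError(f"seed gene {seed} not found among candidate-network nodes")
    by_id = {g.genome_id: g for g in genomes}
    family = network.seed_component(graph, seed, by_id)
    census_rows = network.census(family, genomes, intervals)

    # coiled-coil scan over family members; genome id keys
    hydrophobic = frozenset(config.hydrophobic)
    coils: dict[str, list[coiledcoil.CoiledCoilAnnotation]] = {}
    fragments: list[tuple[str, str]] = []
    for genome_id in sorted(family.members):
        gene_id = family.members[genome_id]
        protein = by_id[genome_id].gene(gene_id).protein
        anns = coiledcoil.scan_coiled_coil(
            protein, gene_id, config.coil_window, config.coil_threshold, hydrophobic
        )
        coils[genome_id] = anns
        if config.align_full_length or not anns:
            fragments.append((genome_id, protein))
        else:
            best = max(anns, key=lambda a: (a.score, a.end - a.start))
            fragments.append((genome_id, protein[best.start - 1 : best.end]))

    alignment = conservation = tree = rf = None
    if len(fragments) >= 2:
        alignment = msa_mod.align_family(fragments, gap_open=config.gap_open, gap_extend=config.gap_extend)
        groups = {gid: by_id[gid].taxon_group for gid, _ in fragments}
        conservation = msa_mod.conserved_columns(
            alignment, groups, frozenset(config.equivalence), reference=seed[0]
        )
    if len(fragments) >= 3:
        dm = phylo.distances_from_msa(alignment, poisson=config.poisson)
        tree = phylo.nj_tree(dm)
        if reference_tree is not None:
            rf = phylo.rf_distance(tree, phylo.read_newick(reference_tree))

    result = PipelineResult(
        genomes=genomes,
        intervals=intervals,
        graph=graph,
        family=family,
        census=census_rows,
        coils=coils,
        msa=alignment,
        conservation=conservation,
        tree=tree,
        rf=rf,
        skipped=skipped,
    )
    if outdir is not None:
        _write_outputs(result, config, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(
        ["genome_a", "gene_a", "genome_b", "gene_b", "score_ab", "score_ba", "identity_ab"],
        [
            [e.gene_a[0], e.gene_a[1], e.gene_b[0], e.gene_b[1], e.score_ab, e.score_ba, round(e.identity_ab, 1)]
            for e in sorted(result.graph.edges, key=lambda e: (e.gene_a, e.gene_b))
        ],
        outdir / "edges.tsv",
    )
    write_tsv(
        ["genome_id", "taxon_group", "egt", "family_member", "Bm9", "member_between_anchors"],
        [
            [r.genome_id, r.taxon_group, r.egt, r.family_member, r.bm9, str(r.member_between_anchors).lower()]
            for r in result.census
        ],
        outdir / "census.tsv",
    )
    by_id = {g.genome_id: g for g in result.genomes}
    write_protein_fasta(
        [
            (f"{gid} {result.family.members[gid]}", by_id[gid].gene(result.family.members[gid]).protein)
            for gid in sorted(result.family.members)
        ],
        outdir / "family.fasta",
    )
    coil_rows = []
    for gid in sorted(result.coils):
        for ann in result.coils[gid]:
            core = [
                r for r in range(ann.start, ann.end + 1) if ann.heptad_letter(r) in ("a", "d")
            ]
            coil_rows.append(
                [gid, ann.gene_id, ann.start, ann.end, ann.register_offset,
                 round(ann.score, 3), ",".join(map(str, core))]
            )
    write_tsv(
        ["genome_id", "gene_id", "start", "end", "phase", "score", "core_positions"],
        coil_rows,
        outdir / "coils.tsv",
    )
    if result.msa is not None:
        write_protein_fasta(result.msa.rows, outdir / "family_aln.fasta")
    if result.conservation is not None:
        write_tsv(
            ["column", "gap_free", "reference_residue", "class", "in_ILV_set"],
            [
                [c.column, str(c.gap_free).lower(), c.reference_residue if c.reference_residue is not None else "-",
                 c.conservation_class, str(c.in_equivalence_set).lower()]
                for c in result.conservation.columns
            ],
            outdir / "conservation.tsv",
        )
    if result.tree is not None:
        (outdir / "family_tree.nwk").write_text(phylo.write_newick(result.tree) + "\n")
    if result.rf is not None:
        (outdir / "rf.txt").write_text(f"{result.rf}\n")
    log_lines = [f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(config)]
    log_lines += [f"skipped_genome = {gid}" for gid in result.skipped]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
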