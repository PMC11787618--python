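"""Synthetic annotated viral genomes with a planted ortholog family.

The generator emulates the study system: small circular genomes of
single-exon CDS carrying two anchor genes (an egt-like ~500-aa and a
Bm9-like ~100-aa protein), one divergent family gene (~230 aa) located
between the anchors whose coiled-coil core (heptad a/d) positions are
constrained to {I, L, V}, and unrelated-looking decoy genes. Controlled
deletions reproduce the study's edge cases: genomes missing the Bm9 anchor
and a genome missing the family member entirely.

All proteins descend from a single ancestor proteome and evolve by i.i.d.
per-site substitution (probability = branch divergence, substitutions uniform
over the allowed non-identical residues). Evolution is indel-free by default
so ancestral residue numbering remains valid ground truth for conservation
and residue-mapping tests; a small per-site deletion rate is available for
stress tests. Site classes in the family protein:

* coil a/d positions: alphabet {I, L, V} (when ``core_constraint`` is on);
* other coil positions: the 17 residues outside {I, L, V}, so the a/d
  columns are exactly the all-{I,L,V} columns of any family alignment;
* everything else: all 20 residues.

Output is deterministic byte-for-byte for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genome_io import GeneFeature, GenomeRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ILV = "ILV"
NON_ILV = "".join(c for c in AA20 if c not in ILV)

# one fixed codon per residue for back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


class ConfigError(ValueError):
    """Contradictory or invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-condition parameters for the fixture generator.

    Defaults mirror the study design the fixtures emulate: a handful of
    genomes at moderate divergence, a Bm8-scale family protein with a 35-aa
    coiled coil, and at least five decoys per genome.
    """

    n_genomes: int = 6
    seed: int = 0
    tree: str = "star"  # "star" or a Newick string over genome ids
    divergence: float = 0.3  # substitutions/site per unit branch
    coil_length: int = 35  # residues, multiple of 7
    coil_start: int = 85  # 1-based residue in the family protein
    core_constraint: bool = True
    family_length: int = 230
    egt_length: int = 500
    bm9_length: int = 100
    decoy_count: int = 8  # per genome
    decoys_between: int = 2  # decoys placed inside the anchor interval
    delete_member_in: tuple[str, ...] = ()
    delete_bm9_in: tuple[str, ...] = ()
    delete_egt_in: tuple[str, ...] = ()
    indel_rate: float = 0.0  # per-site deletion probability (stress tests)
    group_split: bool = True  # first half group-I, second half group-II

    def genome_ids(self) -> list[str]:
        return [f"NPV{i:02d}" for i in range(self.n_genomes)]

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise ConfigError("need at least two genomes")
        if self.divergence < 0:
            raise ConfigError("divergence must be nonnegative")
        if self.coil_length < 14 or self.coil_length % 7:
            raise ConfigError("coil_length must be a multiple of 7, >= 14")
        if self.coil_start + self.coil_length - 1 > self.family_length:
            raise ConfigError("coil does not fit in the family protein")
        if self.decoy_count < self.decoys_between:
            raise ConfigError("decoys_between exceeds decoy_count")
        ids = set(self.genome_ids())
        for name, dels in (
            ("delete_member_in", self.delete_member_in),
            ("delete_bm9_in", self.delete_bm9_in),
            ("delete_egt_in", self.delete_egt_in),
        ):
            unknown = set(dels) - ids
            if unknown:
                raise ConfigError(f"{name} references unknown genomes: {sorted(unknown)}")
        if set(self.delete_member_in) >= ids:
            raise ConfigError("cannot delete the family member from every genome")


@dataclass
class GenomeTruth:
    """Per-genome ground truth of the planted genes."""

    genome_id: str
    egt_gene: str | None
    bm9_gene: str | None
    member_gene: str | None
    member_rank: int | None


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth accompanying a simulated fixture."""

    config: SimulationConfig
    genomes: dict[str, GenomeTruth]
    coil_interval: tuple[int, int]  # 1-based, family-protein coordinates
    coil_phase: int  # register offset: residue r has letter (r-1+phase) % 7
    constrained_columns: list[int]  # ancestral a/d residue numbers
    ancestor_egt: str
    ancestor_bm9: str
    ancestor_family: str
    tree: str

    @property
    def seed_gene(self) -> tuple[str, str]:
        """(genome_id, gene_id) of the seed member (first carrier genome)."""
        for gid in sorted(self.genomes):
            gt = self.genomes[gid]
            if gt.member_gene is not None:
                return (gid, gt.member_gene)
        raise ValueError("no genome carries the family member")


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _core_offsets(cfg: SimulationConfig) -> list[int]:
    """0-based offsets of a/d positions within the coil."""
    return [k for k in range(cfg.coil_length) if k % 7 in (0, 3)]


def _site_alphabets(cfg: SimulationConfig) -> list[str]:
    """Allowed alphabet per site of the family protein."""
    alphabets = [AA20] * cfg.family_length
    core = set(_core_offsets(cfg))
    for k in range(cfg.coil_length):
        pos = cfg.coil_start - 1 + k
        alphabets[pos] = ILV if (k in core and cfg.core_constraint) else NON_ILV
    return alphabets


def _evolve(
    protein: str,
    branch: float,
    rng: np.random.Generator,
    alphabets: list[str] | None = None,
) -> str:
    """Substitute each site with probability ``branch``.

    A substitution replaces the residue with a uniform draw from the site's
    allowed alphabet excluding the current residue.
    """
    p = min(branch, 0.95)
    out = list(protein)
    hits = rng.random(len(out)) < p
    for i in np.nonzero(hits)[0]:
        allowed = (alphabets[i] if alphabets else AA20).replace(out[i], "")
        out[i] = allowed[rng.integers(len(allowed))]
    return "".join(out)


def _apply_deletions(protein: str, rate: float, rng: np.random.Generator, protect: set[int]) -> str:
    """Delete unprotected sites with probability ``rate`` (stress mode)."""
    if rate <= 0:
        return protein
    keep = [
        c
        for i, c in enumerate(protein)
        if i in protect or rng.random() >= rate
    ]
    return "".join(keep)


def _evolve_along_tree(
    config: SimulationConfig,
    ancestor: list[str],
    site_alphabets: list[list[str] | None],
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Evolve the ancestor proteome to every genome.

    With ``tree="star"`` each genome sits at the end of its own unit branch;
    otherwise ``config.tree`` is a Newick string whose leaves are the genome
    ids and whose branch lengths multiply ``config.divergence``. Proteins are
    evolved in a fixed order along a deterministic preorder traversal.
    """
    ids = config.genome_ids()
    if config.tree == "star":
        out: dict[str, list[str]] = {}
        for gid in ids:
            out[gid] = [
                _evolve(p, config.divergence, rng, site_alphabets[k])
                for k, p in enumerate(ancestor)
            ]
        return out
    import dendropy

    try:
        tree = dendropy.Tree.get(data=config.tree, schema="newick")
    except Exception as exc:
        raise ConfigError(f"cannot parse generating tree: {exc}") from exc
    leaf_labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if leaf_labels != sorted(ids):
        raise ConfigError(
            f"generating tree leaves {leaf_labels} do not match genome ids {sorted(ids)}"
        )
    out = {}
    state: dict[int, list[str]] = {id(tree.seed_node): ancestor}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = state[id(node.parent_node)]
        branch = (node.edge.length or 0.0) * config.divergence
        evolved = [
            _evolve(p, branch, rng, site_alphabets[k]) for k, p in enumerate(parent)
        ]
        state[id(node)] = evolved
        if node.is_leaf():
            out[node.taxon.label] = evolved
    return out


def simulate(config: SimulationConfig) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate fixture genomes and their ground truth.

    Each genome's proteome is evolved from a shared ancestor (star tree by
    default), the family member is placed between the two anchors with
    ``decoys_between`` decoys interleaved, remaining decoys are shuffled
    around the rest of the circle, and the configured gene deletions are
    applied. Genomes are circular; gene ids are rank-ordered ORF numbers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    egt_anc = _random_protein(rng, config.egt_length)
    bm9_anc = _random_protein(rng, config.bm9_length)
    fam_alphabets = _site_alphabets(config)
    fam_anc = "".join(
        alph[rng.integers(len(alph))] for alph in fam_alphabets
    )
    decoy_lengths = rng.integers(80, 250, size=config.decoy_count)
    decoy_ancs = [_random_protein(rng, int(L)) for L in decoy_lengths]

    core = _core_offsets(config)
    constrained = [config.coil_start + k for k in core]
    coil_protect = {config.coil_start - 1 + k for k in range(config.coil_length)}

    ancestor_proteome = [egt_anc, bm9_anc, fam_anc, *decoy_ancs]
    site_alphabets = [None, None, fam_alphabets] + [None] * config.decoy_count
    leaf_proteomes = _evolve_along_tree(config, ancestor_proteome, site_alphabets, rng)

    genomes: list[GenomeRecord] = []
    truths: dict[str, GenomeTruth] = {}
    half = (config.n_genomes + 1) // 2
    for g_idx, gid in enumerate(config.genome_ids()):
        egt_p, bm9_p, fam_p, *decoys = leaf_proteomes[gid]
        fam_p = _apply_deletions(fam_p, config.indel_rate, rng, coil_protect)
        order = rng.permutation(config.decoy_count)

        # layout: outside decoys .. egt .. [interval decoys + member] .. Bm9 .. rest
        inside = [("decoy", int(k)) for k in order[: config.decoys_between]]
        member_slot = int(rng.integers(len(inside) + 1))
        interval = inside[:member_slot] + [("member", -1)] + inside[member_slot:]
        outside = [("decoy", int(k)) for k in order[config.decoys_between :]]
        cut = int(rng.integers(len(outside) + 1)) if outside else 0
        layout: list[tuple[str, int]] = (
            outside[:cut] + [("egt", -1)] + interval + [("bm9", -1)] + outside[cut:]
        )
        # deletions
        drop = set()
        if gid in config.delete_member_in:
            drop.add("member")
        if gid in config.delete_bm9_in:
            drop.add("bm9")
        if gid in config.delete_egt_in:
            drop.add("egt")
        layout = [item for item in layout if item[0] not in drop]
        rotation = int(rng.integers(len(layout)))
        layout = layout[rotation:] + layout[:rotation]

        genes: list[GeneFeature] = []
        pos = 1
        roles: dict[str, str] = {}
        member_rank: int | None = None
        for rank, (role, k) in enumerate(layout):
            protein = {
                "egt": egt_p,
                "bm9": bm9_p,
                "member": fam_p,
            }.get(role) or decoys[k]
            gene_id = f"{gid}_orf{rank + 1:03d}"
            if role != "decoy":
                roles[role] = gene_id
            if role == "member":
                member_rank = rank
            start = pos + 50  # intergenic spacer
            end = start + 3 * (len(protein) + 1) - 1
            strand = "+" if rng.random() < 0.7 else "-"
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    locus_tag=gene_id,
                    product_name=f"{role} protein" if role != "decoy" else "hypothetical protein",
                    start=start,
                    end=end,
                    strand=strand,
                    protein=protein,
                )
            )
            pos = end
        group = "group-I" if (config.group_split and g_idx < half) else (
            "group-II" if config.group_split else "unassigned"
        )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                accession=f"SYN_{gid}",
                taxon_group=group,
                topology="circular",
                length=pos + 100,
                genes=genes,
            )
        )
        truths[gid] = GenomeTruth(
            genome_id=gid,
            egt_gene=roles.get("egt"),
            bm9_gene=roles.get("bm9"),
            member_gene=roles.get("member"),
            member_rank=member_rank,
        )

    coil_phase = (-(config.coil_start - 1)) % 7
    truth = SyntheticTruth(
        config=config,
        genomes=truths,
        coil_interval=(config.coil_start, config.coil_start + config.coil_length - 1),
        coil_phase=coil_phase,
        constrained_columns=constrained,
        ancestor_egt=egt_anc,
        ancestor_bm9=bm9_anc,
        ancestor_family=fam_anc,
        tree=config.tree,
    )
    return genomes, truth


def truth_check(genomes: list[GenomeRecord], truth: SyntheticTruth) -> list[str]:
    """Verify every ground-truth assertion against emitted genomes.

    Returns a list of failure messages; an empty list means the fixture is
    internally consistent.
    """
    failures: list[str] = []
    by_id = {g.genome_id: g for g in genomes}
    cfg = truth.config
    for gid, gt in truth.genomes.items():
        genome = by_id.get(gid)
        if genome is None:
            failures.append(f"{gid}: genome record missing")
            continue
        missing = False
        for label, gene_id in (("egt", gt.egt_gene), ("bm9", gt.bm9_gene), ("member", gt.member_gene)):
            if gene_id is None:
                continue
            try:
                genome.gene(gene_id)
            except KeyError:
                failures.append(f"{gid}: {label} gene {gene_id} not in genome")
                missing = True
        if missing:
            continue
        if gt.member_gene is not None:
            member = genome.gene(gt.member_gene)
            if cfg.core_constraint and cfg.indel_rate == 0:
                lo, hi = truth.coil_interval
                for r in truth.constrained_columns:
                    if not lo <= r <= hi:
                        failures.append(f"constrained column {r} outside coil interval")
                    elif member.protein[r - 1] not in ILV:
                        failures.append(
                            f"{gid}: member residue {r} = {member.protein[r - 1]} not in ILV"
                        )
            if gt.egt_gene is not None and gt.bm9_gene is not None:
                n = genome.n_genes
                e = genome.gene(gt.egt_gene).rank
                b = genome.gene(gt.bm9_gene).rank
                m = genome.gene(gt.member_gene).rank
                lo_r, hi_r = min(e, b), max(e, b)
                inner = lo_r < m < hi_r
                outer = m < lo_r or m > hi_r
                between = inner if (hi_r - lo_r - 1) <= (n - (hi_r - lo_r + 1)) else outer
                if not between:
                    failures.append(f"{gid}: member rank {m} not between anchors ({e}, {b})")
    return failures


# ---------------------------------------------------------------------------
# serialization


def to_seqrecord(genome: GenomeRecord, rng_seed: int = 0) -> SeqRecord:
    """Render a GenomeRecord as an annotated nucleotide SeqRecord.

    CDS nucleotide sequence is a fixed-codon back-translation plus a TAA
    stop; intergenic spacers are deterministic from ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    seq = list("".join(rng.choice(list("ACGT"), size=genome.length)))
    features = []
    for gene in genome.genes:
        dna = "".join(_CODON[c] if c in _CODON else _CODON["A"] for c in gene.protein) + "TAA"
        if gene.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        seq[gene.start - 1 : gene.end] = list(dna)
        features.append(
            SeqFeature(
                FeatureLocation(gene.start - 1, gene.end, strand=1 if gene.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [gene.locus_tag],
                    "product": [gene.product_name],
                    "translation": [gene.protein],
                },
            )
        )
    record = SeqRecord(
        Seq("".join(seq)),
        id=genome.accession or genome.genome_id,
        name=genome.genome_id,
        description=f"synthetic genome {genome.genome_id}",
        features=features,
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    return record


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    SeqIO.write([to_seqrecord(genome)], str(path), "genbank")


def write_fixture(genomes: list[GenomeRecord], truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write GenBank files, anchor/seed FASTA and a truth TSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .genome_io import write_protein_fasta, write_tsv

    for genome in genomes:
        write_genbank(genome, outdir / f"{genome.genome_id}.gb")
    write_protein_fasta(
        [("egt", truth.ancestor_egt), ("Bm9", truth.ancestor_bm9)],
        outdir / "anchors.fasta",
    )
    rows = []
    for gid in sorted(truth.genomes):
        gt = truth.genomes[gid]
        rows.append(
            [gid, gt.egt_gene or "DELETED", gt.bm9_gene or "DELETED", gt.member_gene or "DELETED"]
        )
    write_tsv(["genome_id", "egt", "bm9", "member"], rows, outdir / "truth.tsv")
    seed_gid, seed_gene = truth.seed_gene
    (outdir / "seed.txt").write_text(f"{seed_gid}:{seed_gene}\n")
    lo, hi = truth.coil_interval
    (outdir / "coil.txt").write_text(
        f"interval\t{lo}\t{hi}\nphase\t{truth.coil_phase}\n"
        "constrained\t" + ",".join(map(str, truth.constrained_columns)) + "\n"
    )
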