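"""Annotated-genome and protein-set I/O.

Reads GenBank flat files into :class:`GenomeRecord` objects (one
:class:`GeneFeature` per single-interval CDS), and reads/writes protein FASTA
and TSV tables. Coordinates are 1-based inclusive throughout, matching the
GenBank convention; gene ranks are 0-based positions in start order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

from .align import ALPHABET

logger = logging.getLogger(__name__)

_VALID_RESIDUES = set(ALPHABET)  # 20 amino acids + X


class GenomeIOError(ValueError):
    """Raised for unreadable or empty genome inputs."""


@dataclass
class GeneFeature:
    """A single-exon protein-coding gene.

    ``start``/``end`` are 1-based inclusive base-pair coordinates; ``rank`` is
    the 0-based position of the gene in genome order (by start coordinate).
    The protein is stop-trimmed and uses the 20-letter alphabet plus X.
    """

    gene_id: str
    locus_tag: str
    product_name: str
    start: int
    end: int
    strand: str  # "+" or "-"
    protein: str
    rank: int = -1

    def __post_init__(self) -> None:
        if not self.protein:
            raise GenomeIOError(f"gene {self.gene_id}: empty protein")
        if "*" in self.protein:
            raise GenomeIOError(f"gene {self.gene_id}: internal stop in protein")
        if self.start > self.end:
            raise GenomeIOError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise GenomeIOError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """An annotated genome: ordered CDS features with protein translations."""

    genome_id: str
    accession: str = ""
    taxon_group: str = "unassigned"  # group-I | group-II | unassigned
    topology: str = "circular"
    length: int = 0
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._finalize()

    def _finalize(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        ids = set()
        for rank, gene in enumerate(self.genes):
            gene.rank = rank
            if gene.gene_id in ids:
                raise GenomeIOError(
                    f"{self.genome_id}: duplicate gene_id {gene.gene_id!r}"
                )
            ids.add(gene.gene_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"{self.genome_id}: no gene {gene_id!r}")

    def proteins(self) -> list[tuple[str, str]]:
        return [(g.gene_id, g.protein) for g in self.genes]


def normalize_protein(seq: str) -> str:
    """Upper-case, trim trailing stops, map non-standard residues to X."""
    seq = seq.upper().rstrip("*")
    return "".join(c if c in _VALID_RESIDUES else "X" for c in seq)


def read_genbank(
    path: str | Path,
    genome_id: str | None = None,
    taxon_group: str = "unassigned",
) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    One GeneFeature is produced per CDS carrying a translation qualifier (or
    translatable with the standard code when the qualifier is absent).
    Multi-interval ``join(..)`` CDS are skipped with a logged warning, since
    silently mistranslating a spliced CDS is worse than excluding it.
    Topology comes from the LOCUS line, defaulting to circular.
    """
    path = Path(path)
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError, FileNotFoundError) as exc:
        raise GenomeIOError(f"cannot read GenBank file {path}: {exc}") from exc
    genes: list[GeneFeature] = []
    n_cds = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        n_cds += 1
        if isinstance(feat.location, CompoundLocation):
            logger.warning(
                "%s: skipping multi-interval CDS at %s", path.name, feat.location
            )
            continue
        quals = feat.qualifiers
        gid = (
            quals.get("locus_tag", [None])[0]
            or quals.get("gene", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"cds_{n_cds}"
        )
        translation = quals.get("translation", [None])[0]
        if translation is None:
            dna = feat.extract(record.seq)
            translation = str(Seq(dna).translate(table=1, to_stop=True))
        protein = normalize_protein(translation)
        if not protein:
            logger.warning("%s: skipping CDS %s with empty translation", path.name, gid)
            continue
        genes.append(
            GeneFeature(
                gene_id=gid,
                locus_tag=quals.get("locus_tag", [gid])[0],
                product_name=quals.get("product", [""])[0],
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="+" if feat.location.strand != -1 else "-",
                protein=protein,
            )
        )
    if not genes:
        raise GenomeIOError(f"{path}: no usable CDS features")
    accession = record.id if record.id and record.id != "<unknown id>" else ""
    topology = record.annotations.get("topology", "circular") or "circular"
    return GenomeRecord(
        genome_id=genome_id or record.name or path.stem,
        accession=accession,
        taxon_group=taxon_group,
        topology=topology,
        length=len(record.seq),
        genes=genes,
    )


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA; ids are the first whitespace token of headers."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise GenomeIOError(f"{path}: duplicate FASTA id {rid!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeIOError(f"{path}: empty sequence for {rid!r}")
        seen.add(rid)
        records.append((rid, seq))
    return records


def write_protein_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, protein) pairs as FASTA wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_tsv(header: list[str], rows: list[list], path: str | Path) -> None:
    """Write a TSV table with a header row; values are str()-converted."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
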