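"""Readers and writers for the standard formats the pipeline touches.

Everything downstream consumes only the domain types defined here:
:class:`ProteinRecord`, :class:`DomainHit`, :class:`GeneModel`,
:class:`TaxonomyTable` and :class:`Tree`.

Coordinate conventions
----------------------
Internal sequence coordinates are 0-based half-open everywhere.  GFF3 keeps
its native 1-based inclusive convention only at the parse/write boundary, and
HMMER per-domain tables (1-based inclusive envelope coordinates) are converted
on input.  A single convention prevents off-by-one drift between modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "FormatError",
    "ProteinRecord",
    "DomainHit",
    "GeneModel",
    "TaxonomyTable",
    "TreeNode",
    "Tree",
    "parse_sequences",
    "write_sequences",
    "parse_domain_hits",
    "write_domain_hits",
    "parse_gene_models",
    "parse_taxonomy",
    "write_taxonomy",
    "parse_tree",
    "tree_from_newick",
    "serialize_tree",
    "strip_accession_version",
]

#: the 20 standard residues plus the ambiguity letter X
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DOMAIN_HIT_COLUMNS = ("protein_id", "accession", "start", "end", "score", "evalue")


class FormatError(ValueError):
    """Raised for malformed input files (with location information)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species and (possibly partial) lineage."""

    protein_id: str
    species_id: str
    sequence: str
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.protein_id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence):
            if ch not in AMINO_ACIDS:
                raise FormatError(
                    f"protein {self.protein_id!r}: non-amino-acid character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """A domain-model match on a protein, 0-based half-open coordinates."""

    protein_id: str
    accession: str
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"domain hit {self.accession} on {self.protein_id}: invalid "
                f"interval [{self.start}, {self.end})"
            )
        if self.evalue < 0:
            raise FormatError(
                f"domain hit {self.accession} on {self.protein_id}: negative E-value"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus (1-based inclusive genomic coordinates, as in GFF3)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    exon_count: int | None = None  # None = unknown

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end


class TaxonomyTable:
    """Mapping species_id -> lineage (ordered taxon names, may be partial).

    Besides ranked taxon names (phylum, subphylum, class) a species entry may
    carry free-form tags (e.g. ``early_diverging``); :meth:`members` treats
    both identically, so grouping labels need not be hard-coded phyla.
    """

    def __init__(
        self,
        lineages: Mapping[str, Sequence[str]],
        tags: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self._lineages = {sp: tuple(lin) for sp, lin in lineages.items()}
        self._tags = {sp: tuple(tg) for sp, tg in (tags or {}).items()}

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._lineages))

    def lineage(self, species_id: str) -> tuple[str, ...]:
        try:
            return self._lineages[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} absent from taxonomy") from None

    def tags(self, species_id: str) -> tuple[str, ...]:
        return self._tags.get(species_id, ())

    def members(self, taxon: str) -> tuple[str, ...]:
        """Species whose lineage or tags contain *taxon* (sorted)."""
        return tuple(
            sp
            for sp in self.species_ids
            if taxon in self._lineages[sp] or taxon in self.tags(sp)
        )


# ---------------------------------------------------------------------------
# FASTA


def _split_header(header: str, delimiter: str) -> tuple[str, str]:
    token = header.split()[0]
    if delimiter in token:
        species_id, _, protein_id = token.partition(delimiter)
        return species_id, protein_id or token
    return "", token


def parse_sequences(
    path: str | Path,
    *,
    taxonomy: TaxonomyTable | None = None,
    header_delimiter: str = "|",
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The default header convention is ``speciesID|proteinID``; when a sidecar
    *taxonomy* is given, lineages are attached from it.  Duplicate protein ids
    and non-amino-acid characters are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        species_id, protein_id = _split_header(entry.description, header_delimiter)
        if protein_id in seen:
            raise FormatError(f"duplicate protein id {protein_id!r} in {path}")
        seen.add(protein_id)
        lineage: tuple[str, ...] = ()
        if taxonomy is not None and species_id in taxonomy:
            lineage = taxonomy.lineage(species_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                species_id=species_id,
                sequence=str(entry.seq).upper(),
                lineage=lineage,
            )
        )
    return records


def write_sequences(
    records: Iterable[ProteinRecord], path: str | Path, *, header_delimiter: str = "|"
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = (
                f"{rec.species_id}{header_delimiter}{rec.protein_id}"
                if rec.species_id
                else rec.protein_id
            )
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Domain hits

_VERSION_RE = re.compile(r"\.\d+$")


def strip_accession_version(accession: str) -> str:
    """``PF03142.18`` -> ``PF03142``."""
    return _VERSION_RE.sub("", accession)


def _check_hit_bounds(
    hit: DomainHit, lengths: Mapping[str, int] | None, lineno: int, path: str | Path
) -> None:
    if lengths is not None and hit.protein_id in lengths:
        if hit.end > lengths[hit.protein_id]:
            raise FormatError(
                f"{path}:{lineno}: hit {hit.accession} ends at {hit.end}, beyond "
                f"protein {hit.protein_id} length {lengths[hit.protein_id]}"
            )


def parse_domain_hits(
    path: str | Path,
    dialect: str = "tsv",
    *,
    sequences: Iterable[ProteinRecord] | None = None,
) -> list[DomainHit]:
    """Read per-domain hits from a TSV table or a HMMER ``--domtblout`` file.

    ``tsv`` uses columns ``protein_id accession start end score evalue`` with
    0-based half-open coordinates (a header row naming those columns is
    allowed and skipped).  ``hmmer_domtbl`` is the standard whitespace-
    delimited per-domain table written by ``hmmsearch --domtblout`` (protein as
    target, profile as query): the domain accession is taken from the query
    accession column, coordinates from the 1-based inclusive envelope columns,
    the score/E-value from the per-domain columns.  Accession version
    suffixes are stripped; coordinates are normalised to 0-based half-open.
    """
    if dialect not in {"tsv", "hmmer_domtbl"}:
        raise ValueError(f"unknown domain-hit dialect {dialect!r}")
    lengths = (
        {rec.protein_id: len(rec) for rec in sequences}
        if sequences is not None
        else None
    )
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "tsv":
                    if tuple(fields[:6]) == DOMAIN_HIT_COLUMNS:
                        continue  # header row
                    if len(fields) < 6:
                        raise ValueError("expected 6 columns")
                    pid, acc = fields[0], fields[1]
                    start, end = int(fields[2]), int(fields[3])
                    score, evalue = float(fields[4]), float(fields[5])
                else:
                    if len(fields) < 22:
                        raise ValueError("expected >= 22 columns")
                    pid = fields[0]
                    acc = fields[4] if fields[4] != "-" else fields[3]
                    start = int(fields[19]) - 1  # envelope from, 1-based
                    end = int(fields[20])  # envelope to, inclusive
                    score, evalue = float(fields[13]), float(fields[12])
                hit = DomainHit(
                    protein_id=pid,
                    accession=strip_accession_version(acc),
                    start=start,
                    end=end,
                    score=score,
                    evalue=evalue,
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            _check_hit_bounds(hit, lengths, lineno, path)
            hits.append(hit)
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the documented TSV dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("\t".join(DOMAIN_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.accession}\t{h.start}\t{h.end}\t"
                f"{h.score:g}\t{h.evalue:g}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GFF3)


def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon features from a GFF3 file.

    ``exon_count`` is the number of exon features of the gene's primary
    transcript (the lexicographically first mRNA); genes without any exon
    features get ``exon_count=None`` (unknown).  A missing strand is an error.
    Orphan or unsorted features are tolerated by gffutils.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in {"+", "-"}:
            raise FormatError(
                f"{path}: gene {gene.id}: missing or invalid strand {gene.strand!r}"
            )
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        exon_count: int | None = None
        protein_id = gene.attributes.get("protein_id", [None])[0]
        if mrnas:
            primary = mrnas[0]
            if protein_id is None:
                protein_id = primary.attributes.get("protein_id", [None])[0]
            n = sum(1 for _ in db.children(primary, featuretype="exon"))
            exon_count = n if n > 0 else None
        else:
            n = sum(1 for _ in db.children(gene, featuretype="exon"))
            exon_count = n if n > 0 else None
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                protein_id=protein_id,
                exon_count=exon_count,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Taxonomy TSV

_TAXONOMY_RANKS = ("phylum", "subphylum", "class")


def parse_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV: ``species_id  phylum  subphylum  class  [tags]``.

    Empty rank cells are allowed (partial lineages); the optional ``tags``
    column is comma-separated.
    """
    lineages: dict[str, tuple[str, ...]] = {}
    tags: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "species_id":
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            sp = fields[0]
            ranks = tuple(f for f in fields[1:4] if f)
            lineages[sp] = ranks
            if len(fields) > 4 and fields[4]:
                tags[sp] = tuple(t for t in fields[4].split(",") if t)
    return TaxonomyTable(lineages, tags)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\t" + "\t".join(_TAXONOMY_RANKS) + "\ttags\n")
        for sp in taxonomy.species_ids:
            lin = list(taxonomy.lineage(sp))[:3]
            lin += [""] * (3 - len(lin))
            fh.write(f"{sp}\t" + "\t".join(lin) + "\t" + ",".join(taxonomy.tags(sp)) + "\n")


# ---------------------------------------------------------------------------
# Trees (Newick)


@dataclass
class TreeNode:
    """A rooted tree node; leaf labels are taxon names, internal labels carry
    bootstrap support values (as strings, [0, 100])."""

    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        names = [n.label or "" for n in self.root.leaves()]
        if len(set(names)) != len(names):
            raise FormatError("duplicate leaf names in tree")
        return names

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out


def _check_parentheses(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise FormatError(f"unbalanced '(' (depth {depth} at end of input)")


def tree_from_newick(text: str) -> Tree:
    """Parse a Newick string (optional branch lengths and internal support
    labels) into a :class:`Tree`."""
    _check_parentheses(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"Newick parse error: {exc}") from exc

    def convert(node: dendropy.Node) -> TreeNode:
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
        else:
            label = node.label
        return TreeNode(
            label=label,
            length=node.edge.length,
            children=[convert(c) for c in node.child_nodes()],
        )

    return Tree(root=convert(dtree.seed_node))


def parse_tree(path: str | Path) -> Tree:
    return tree_from_newick(Path(path).read_text())


def _format_length(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _node_newick(node: TreeNode) -> str:
    if node.is_leaf:
        body = node.label or ""
    else:
        body = "(" + ",".join(_node_newick(c) for c in node.children) + ")"
        body += node.label or ""
    if node.length is not None:
        body += ":" + _format_length(node.length)
    return body


def serialize_tree(tree: Tree) -> str:
    """Write Newick preserving topology, branch lengths (6 decimals) and
    internal support labels; parse -> serialize is the identity."""
    return _node_newick(tree.root) + ";"
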