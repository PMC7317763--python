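"""Readers, writers and the in-memory data model shared by all pipeline stages.

A phylome is a collection of per-gene trees (newick, branch lengths in
substitutions/site, internal-node supports) plus the in-frame nucleotide
alignments they were inferred from, a taxonomy table mapping every gene id to
a species and every species to a taxonomic section, gene coordinates (GFF3)
and scaffold lengths.  Everything downstream (QC, closest-sister-leaf
extraction, 4D-site dating, subgenome assignment) operates on the types
defined here.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class PhylomeError(Exception):
    """Base class for all data-model errors."""


class NewickParseError(PhylomeError):
    """Malformed newick input."""


class UnresolvedTaxonError(PhylomeError):
    """A leaf gene id is absent from the taxonomy table."""


class SeedAmbiguityError(PhylomeError):
    """Zero or multiple candidate seed leaves and no explicit seed gene."""


class AlignmentShapeError(PhylomeError):
    """Rows of a multiple alignment differ in width."""


class FrameError(PhylomeError):
    """Alignment width is not a multiple of three."""


class CoordinateError(PhylomeError):
    """A gene locus has start > end."""


class DuplicateIdError(PhylomeError):
    """The same gene id occurs twice where ids must be unique."""


class ConsistencyError(PhylomeError):
    """Tree and alignment disagree about which sequences exist."""


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyMap:
    """Total mapping gene_id -> species -> section.

    ``sections`` is the declared finite set of valid sections; species whose
    section is not in it are rejected at load time.
    """

    gene_to_species: dict[str, str]
    species_to_section: dict[str, str]

    def species_of(self, gene_id: str) -> str:
        try:
            return self.gene_to_species[gene_id]
        except KeyError:
            raise UnresolvedTaxonError(f"gene id {gene_id!r} not in taxonomy") from None

    def section_of_species(self, species: str) -> str:
        try:
            return self.species_to_section[species]
        except KeyError:
            raise UnresolvedTaxonError(f"species {species!r} has no section") from None

    def section_of(self, gene_id: str) -> str:
        return self.section_of_species(self.species_of(gene_id))

    @property
    def sections(self) -> set[str]:
        return set(self.species_to_section.values())


def read_taxonomy(source: str | Path) -> TaxonomyMap:
    """Read a taxonomy TSV with columns gene_id, species, section."""
    df = pd.read_csv(_as_buffer(source), sep="\t", dtype=str)
    required = {"gene_id", "species", "section"}
    if not required.issubset(df.columns):
        raise PhylomeError(f"taxonomy table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DuplicateIdError(f"duplicate gene id in taxonomy: {dup!r}")
    sp2sec: dict[str, str] = {}
    for sp, sec in zip(df["species"], df["section"]):
        if sp in sp2sec and sp2sec[sp] != sec:
            raise PhylomeError(f"species {sp!r} mapped to two sections")
        sp2sec[sp] = sec
    return TaxonomyMap(dict(zip(df["gene_id"], df["species"])), sp2sec)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """A rooted per-gene tree with branch lengths, supports and taxon labels.

    Wraps a :class:`dendropy.Tree`.  Leaf taxon labels are gene ids; supports
    live on ``node.support`` (float in [0, 1] or None for missing).  Exactly
    one leaf is the seed gene the tree was built for.
    """

    tree_id: str
    tree: dendropy.Tree
    seed_leaf: str
    taxonomy: TaxonomyMap
    unusable: bool = False  # set when QC removes the seed row

    # -- leaf access --------------------------------------------------------

    def leaf_nodes(self) -> list[dendropy.Node]:
        return [lf for lf in self.tree.leaf_nodes() if lf.taxon is not None]

    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.leaf_nodes()]

    def node_of(self, gene_id: str) -> dendropy.Node:
        for lf in self.leaf_nodes():
            if lf.taxon.label == gene_id:
                return lf
        raise PhylomeError(f"leaf {gene_id!r} not in tree {self.tree_id}")

    def species_of(self, gene_id: str) -> str:
        return self.taxonomy.species_of(gene_id)

    def section_of(self, gene_id: str) -> str:
        return self.taxonomy.section_of(gene_id)

    @property
    def seed_species(self) -> str:
        return self.taxonomy.species_of(self.seed_leaf)

    def n_species(self) -> int:
        return len({self.taxonomy.species_of(g) for g in self.leaf_ids()})

    # -- tree metrics --------------------------------------------------------

    def _ancestor_path(self, node: dendropy.Node) -> list[dendropy.Node]:
        path = [node]
        while path[-1].parent_node is not None:
            path.append(path[-1].parent_node)
        return path

    def mrca(self, a: str, b: str) -> dendropy.Node:
        pa = self._ancestor_path(self.node_of(a))
        pb = set(id(n) for n in self._ancestor_path(self.node_of(b)))
        for n in pa:
            if id(n) in pb:
                return n
        raise PhylomeError("disconnected tree")  # pragma: no cover

    def patristic(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path connecting leaves a and b."""
        if a == b:
            return 0.0
        pa = self._ancestor_path(self.node_of(a))
        depth_a = {}
        d = 0.0
        for n in pa:
            depth_a[id(n)] = d
            d += n.edge.length or 0.0
        node = self.node_of(b)
        d = 0.0
        while node is not None:
            if id(node) in depth_a:
                return d + depth_a[id(node)]
            d += node.edge.length or 0.0
            node = node.parent_node
        raise PhylomeError("disconnected tree")  # pragma: no cover

    def support_of(self, node: dendropy.Node) -> float | None:
        return getattr(node, "support", None)

    # -- surgery -------------------------------------------------------------

    def prune_to(self, keep_ids: Iterable[str]) -> None:
        """Prune to the given leaves, preserving patristic distances.

        Branch lengths of suppressed unifurcations are summed so distances
        among the surviving leaves are unchanged.  Removing the seed leaf
        marks the tree unusable instead of raising.
        """
        keep = set(keep_ids)
        present = {lf.taxon.label for lf in self.tree.leaf_nodes()
                   if lf.taxon is not None}
        if self.seed_leaf not in keep or self.seed_leaf not in present:
            self.unusable = True
        if not keep & present:
            self.tree = dendropy.Tree()  # nothing survives
            return
        drop = [t for t in self.tree.taxon_namespace if t.label not in keep]
        if drop:
            self.tree.prune_taxa(drop, suppress_unifurcations=True)

    def as_newick(self) -> str:
        """Serialize with supports as internal-node labels (fractions)."""
        clone = self.tree.clone(depth=1)
        for node in clone.preorder_node_iter():
            if not node.is_leaf():
                sup = getattr(node, "support", None)
                node.label = None if sup is None else format(sup, "g")
        s = clone.as_string(schema="newick", suppress_rooting=True,
                            unquoted_underscores=True)
        return s.strip()


def _parse_support(label: str | None, context: str) -> float | None:
    if label is None or label == "":
        return None
    try:
        v = float(label)
    except ValueError:
        return None
    if 0.0 <= v <= 1.0:
        return v
    if 1.0 < v <= 100.0:
        log.info("%s: support %s read as percent, divided by 100", context, label)
        return v / 100.0
    log.warning("%s: support label %s outside [0, 100]; treated as missing",
                context, label)
    return None


def read_gene_tree(
    newick_text: str,
    taxonomy: TaxonomyMap,
    *,
    seed_gene: str | None = None,
    seed_species: str | None = None,
    tree_id: str = "tree",
) -> GeneTree:
    """Parse one newick gene tree and resolve its taxonomy and seed leaf.

    Internal node labels are read as supports: numeric values in [0, 1] are
    taken as fractions, values in (1, 100] as percentages (divided by 100 and
    logged).  Unlabeled internal nodes get a missing support, never a silent
    1.0.  ``seed_gene`` pins the seed leaf explicitly (the phylome manifest
    entry); otherwise ``seed_species`` must match exactly one leaf — zero or
    several matches raise :class:`SeedAmbiguityError`.  ``seed_species`` may
    also name a section.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"{tree_id}: malformed newick: {exc}") from exc

    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None:
                raise NewickParseError(f"{tree_id}: unlabeled leaf")
        else:
            node.support = _parse_support(node.label, tree_id)

    leaf_ids = [lf.taxon.label for lf in tree.leaf_nodes()]
    if len(set(leaf_ids)) != len(leaf_ids):
        raise DuplicateIdError(f"{tree_id}: duplicate leaf ids")
    for gid in leaf_ids:
        taxonomy.species_of(gid)  # raises UnresolvedTaxonError

    if seed_gene is not None:
        if seed_gene not in leaf_ids:
            raise SeedAmbiguityError(
                f"{tree_id}: manifest seed {seed_gene!r} is not a leaf")
        seed = seed_gene
    else:
        if seed_species is None:
            raise SeedAmbiguityError(f"{tree_id}: no seed gene or species given")
        cands = [
            g for g in leaf_ids
            if taxonomy.species_of(g) == seed_species
            or taxonomy.section_of(g) == seed_species
        ]
        if len(cands) != 1:
            raise SeedAmbiguityError(
                f"{tree_id}: {len(cands)} candidate seed leaves for "
                f"{seed_species!r} and no manifest entry")
        seed = cands[0]

    for node in tree.preorder_node_iter():
        if node.edge.length is not None and not node.edge.length >= 0:
            raise PhylomeError(f"{tree_id}: negative or non-finite branch length")

    return GeneTree(tree_id=tree_id, tree=tree, seed_leaf=seed, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """An in-frame nucleotide MSA: ordered rows of equal width, frame at col 0.

    Characters outside {A, C, G, T, N, -} are mapped to N at load time.
    """

    rows: dict[str, str]  # insertion-ordered
    width: int

    def __post_init__(self) -> None:
        for gid, seq in self.rows.items():
            if len(seq) != self.width:
                raise AlignmentShapeError(
                    f"row {gid!r} has width {len(seq)} != {self.width}")
        if self.width % 3 != 0:
            raise FrameError(f"width {self.width} is not a multiple of 3")

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @property
    def n_codons(self) -> int:
        return self.width // 3

    def __getitem__(self, gene_id: str) -> str:
        try:
            return self.rows[gene_id]
        except KeyError:
            raise PhylomeError(f"sequence {gene_id!r} not in alignment") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.rows

    def n_fraction(self, gene_id: str) -> float:
        """Fraction of N among ungapped characters of one row."""
        seq = self[gene_id]
        ungapped = len(seq) - seq.count("-")
        if ungapped == 0:
            return 0.0
        return seq.count("N") / ungapped

    def subset(self, keep_ids: Iterable[str]) -> "CodonAlignment":
        keep = set(keep_ids)
        return CodonAlignment(
            {g: s for g, s in self.rows.items() if g in keep}, self.width)

    def to_fasta(self) -> str:
        return "".join(f">{g}\n{s}\n" for g, s in self.rows.items())


def read_codon_alignment(fasta_text: str) -> CodonAlignment:
    """Read an aligned in-frame FASTA; non-IUPAC characters become N (logged)."""
    rows: dict[str, str] = {}
    mapped = 0
    for rec in SeqIO.parse(_stdio.StringIO(fasta_text), "fasta"):
        if rec.id in rows:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        clean = "".join(c if c in VALID_CHARS else "N" for c in seq)
        mapped += sum(1 for a, b in zip(seq, clean) if a != b)
        rows[rec.id] = clean
    if not rows:
        raise AlignmentShapeError("empty FASTA")
    if mapped:
        log.info("mapped %d non-{A,C,G,T,N,-} characters to N", mapped)
    widths = {len(s) for s in rows.values()}
    if len(widths) > 1:
        raise AlignmentShapeError(f"ragged alignment: widths {sorted(widths)}")
    return CodonAlignment(rows, widths.pop())


# ---------------------------------------------------------------------------
# gene loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocus:
    """One gene's location: 1-based inclusive coordinates, per-scaffold rank."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    rank: int


def read_gene_loci(gff_text: str, feature_type: str = "gene") -> list[GeneLocus]:
    """Read gene loci from GFF3, sorted by (scaffold, start), ranks per scaffold.

    Strand is stored but never used by neighbor inference (gene order is
    positional only).
    """
    import gffutils

    db = gffutils.create_db(
        gff_text, dbfn=":memory:", from_string=True,
        merge_strategy="error", keep_order=True,
    )
    raw = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise DuplicateIdError(f"duplicate gene id {gid!r} in GFF")
        seen.add(gid)
        if feat.start > feat.end:
            raise CoordinateError(
                f"{gid}: start {feat.start} > end {feat.end}")
        raw.append((feat.seqid, feat.start, feat.end, feat.strand or ".", gid))
    raw.sort(key=lambda r: (r[0], r[1], r[4]))
    loci = []
    rank = 0
    prev_scaf = None
    for scaf, start, end, strand, gid in raw:
        rank = rank + 1 if scaf == prev_scaf else 1
        prev_scaf = scaf
        loci.append(GeneLocus(gid, scaf, start, end, strand, rank))
    return loci


def read_scaffold_lengths(source: str | Path) -> dict[str, int]:
    """Read a two-column (scaffold_id, length_bp) table; header optional."""
    df = pd.read_csv(_as_buffer(source), sep="\t", dtype=str, header=None)
    if str(df.iloc[0, 1]).lower() in {"length_bp", "length"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(records: Sequence, path: str | Path, columns: Sequence[str],
                sort_by: str | None = None) -> None:
    """Write stage records (dataclasses or dicts) as a deterministic TSV.

    Column order is fixed by ``columns``; rows are sorted by ``sort_by``.
    Empty input yields a header-only file.  The output round-trips through
    :func:`read_table`.
    """
    rows = []
    for rec in records:
        d = rec if isinstance(rec, dict) else rec.__dict__
        rows.append({c: d.get(c) for c in columns})
    df = pd.DataFrame(rows, columns=list(columns))
    if sort_by and len(df):
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# phylome dataset
# ---------------------------------------------------------------------------

@dataclass
class PhylomeDataset:
    """Everything one pipeline run consumes, with lazily parsed alignments."""

    trees: list[GeneTree]
    alignments: Mapping[str, CodonAlignment]
    taxonomy: TaxonomyMap
    loci: list[GeneLocus] | None = None
    scaffold_lengths: dict[str, int] | None = None

    def __iter__(self) -> Iterator[GeneTree]:
        return iter(self.trees)


class _LazyAlignments(Mapping):
    """Parse per-tree FASTA files on first access."""

    def __init__(self, directory: Path):
        self._dir = Path(directory)
        self._cache: dict[str, CodonAlignment] = {}
        self._ids = sorted(p.stem for p in self._dir.glob("*.fasta"))

    def __getitem__(self, tree_id: str) -> CodonAlignment:
        if tree_id not in self._cache:
            path = self._dir / f"{tree_id}.fasta"
            if not path.exists():
                raise KeyError(tree_id)
            self._cache[tree_id] = read_codon_alignment(path.read_text())
        return self._cache[tree_id]

    def __iter__(self):
        return iter(self._ids)

    def __len__(self):
        return len(self._ids)


def load_phylome(directory: str | Path) -> PhylomeDataset:
    """Load a phylome dump directory.

    Expected layout: ``trees.tsv`` (tree_id, seed_gene, newick),
    ``taxonomy.tsv``, ``alignments/<tree_id>.fasta``, and optionally
    ``genes.gff3`` and ``scaffolds.tsv``.
    """
    directory = Path(directory)
    taxonomy = read_taxonomy(directory / "taxonomy.tsv")
    trees_df = pd.read_csv(directory / "trees.tsv", sep="\t", dtype=str)
    trees = [
        read_gene_tree(row.newick, taxonomy, seed_gene=row.seed_gene,
                       tree_id=row.tree_id)
        for row in trees_df.itertuples()
    ]
    loci = None
    gff = directory / "genes.gff3"
    if gff.exists():
        loci = read_gene_loci(gff.read_text())
    lengths = None
    scaf = directory / "scaffolds.tsv"
    if scaf.exists():
        lengths = read_scaffold_lengths(scaf)
    return PhylomeDataset(
        trees=trees,
        alignments=_LazyAlignments(directory / "alignments"),
        taxonomy=taxonomy,
        loci=loci,
        scaffold_lengths=lengths,
    )


def _as_buffer(source: str | Path):
    if isinstance(source, Path) or "\t" not in str(source):
        return str(source)
    return _stdio.StringIO(str(source))
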