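"""Gene- and scaffold-level subgenome assignment for an allopolyploid.

Each seed gene is assigned to one of the two nominated parental sections via
the closest sufficiently supported parental leaf in its gene tree.  Genes
whose trees contain no parental leaf ("orphans") can inherit an assignment
from their genomic neighbors, and scaffolds are assigned by a 75% majority
among their parentally assigned genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GeneLocus, GeneTree, PhylomeError

log = logging.getLogger(__name__)

ORPHAN = "orphan"


class DuplicateSeedError(PhylomeError):
    """Two trees claim the same seed gene."""


@dataclass
class ParentalLeafRecord:
    """Closest qualifying parental-section leaf for one seed gene.

    ``support`` is the support of the node the leaf attaches to (its parent
    node) — the node that certifies the leaf's placement.  It is recorded in
    the output for auditability.
    """

    tree_id: str
    seed_gene: str
    section: str
    leaf: str
    distance: float
    support: float


@dataclass
class GeneAssignment:
    """Parental-origin call for one seed gene.

    provenance is "tree" when the gene's own tree yielded a parental leaf,
    "neighbor" when rescued from genomic neighbors, and None for orphans.
    """

    gene_id: str
    origin: str  # parental section name, or "orphan"
    provenance: str | None = None
    distance: float | None = None
    support: float | None = None


@dataclass
class ScaffoldAssignment:
    scaffold_id: str
    origin: str
    n_genes_total: int
    n_maternal: int
    n_paternal: int
    n_orphan: int
    length_bp: int | None


def closest_parental_leaf(
    tree: GeneTree,
    parental_sections: tuple[str, str],
    min_support: float = 0.9,
) -> ParentalLeafRecord | None:
    """Pick the nearest reliable parental-section leaf of the seed gene.

    Leaves of either parental section are ranked by patristic distance from
    the seed; a leaf qualifies when the support of the node it attaches to
    is at least ``min_support`` (missing support disqualifies).  If the
    nearest leaf fails support the next-nearest qualifying leaf is used.  An
    exact distance tie between qualifying leaves of the two different
    sections is refused (gene left orphan, tie logged).  Returns None when
    no parental leaf qualifies.
    """
    if tree.unusable:
        return None
    seed_sp = tree.seed_species
    pair = set(parental_sections)
    qualifying: list[tuple[float, str, str, float]] = []
    for gid in tree.leaf_ids():
        if gid == tree.seed_leaf or tree.species_of(gid) == seed_sp:
            continue
        sec = tree.section_of(gid)
        if sec not in pair:
            continue
        parent = tree.node_of(gid).parent_node
        sup = tree.support_of(parent) if parent is not None else None
        if sup is None or sup < min_support:
            continue
        qualifying.append((tree.patristic(tree.seed_leaf, gid), gid, sec, sup))
    if not qualifying:
        return None
    qualifying.sort(key=lambda t: (t[0], t[1]))
    dmin = qualifying[0][0]
    tied_sections = {sec for d, _, sec, _ in qualifying if d == dmin}
    if len(tied_sections) > 1:
        log.info("%s: parental leaves of both sections tie at distance %.6g; "
                 "gene left orphan", tree.tree_id, dmin)
        return None
    d, gid, sec, sup = qualifying[0]
    return ParentalLeafRecord(tree_id=tree.tree_id, seed_gene=tree.seed_leaf,
                              section=sec, leaf=gid, distance=d, support=sup)


def assign_genes(
    phylome: Iterable[GeneTree],
    parental_sections: tuple[str, str],
    min_support: float = 0.9,
) -> list[GeneAssignment]:
    """One assignment per seed gene: a parental section or orphan."""
    out: list[GeneAssignment] = []
    seen: set[str] = set()
    for tree in phylome:
        if tree.seed_leaf in seen:
            raise DuplicateSeedError(
                f"seed gene {tree.seed_leaf!r} appears in more than one tree")
        seen.add(tree.seed_leaf)
        rec = closest_parental_leaf(tree, parental_sections, min_support)
        if rec is None:
            out.append(GeneAssignment(gene_id=tree.seed_leaf, origin=ORPHAN))
        else:
            out.append(GeneAssignment(
                gene_id=tree.seed_leaf, origin=rec.section, provenance="tree",
                distance=rec.distance, support=rec.support))
    return out


def infer_orphans(
    assignments: Sequence[GeneAssignment],
    loci: Sequence[GeneLocus],
) -> list[GeneAssignment]:
    """Rescue orphans from the tree-based assignments of genomic neighbors.

    A single pass over orphans in coordinate order: both neighbors
    tree-assigned and concordant -> transfer; exactly one neighbor
    tree-assigned -> transfer; discordant -> left orphan.  Terminal genes use
    their single neighbor.  Only tree-provenance assignments count as
    evidence, so the pass never chains (a rescued gene is never evidence) and
    is idempotent.
    """
    by_gene = {a.gene_id: a for a in assignments}
    by_scaffold: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold_id, []).append(locus)
    updated = {a.gene_id: a for a in assignments}

    def tree_origin(locus: GeneLocus | None) -> str | None:
        if locus is None:
            return None
        a = by_gene.get(locus.gene_id)
        if a is not None and a.provenance == "tree":
            return a.origin
        return None

    for scaffold, genes in by_scaffold.items():
        genes = sorted(genes, key=lambda l: l.rank)
        for i, locus in enumerate(genes):
            a = by_gene.get(locus.gene_id)
            if a is None:
                continue
            if a.origin != ORPHAN:
                continue
            up = genes[i - 1] if i > 0 else None
            down = genes[i + 1] if i + 1 < len(genes) else None
            evidence = {o for o in (tree_origin(up), tree_origin(down))
                        if o is not None}
            if len(evidence) == 1:
                origin = evidence.pop()
                updated[locus.gene_id] = GeneAssignment(
                    gene_id=locus.gene_id, origin=origin, provenance="neighbor")
    for a in assignments:
        if a.gene_id not in {l.gene_id for l in loci} and a.origin == ORPHAN:
            log.debug("gene %s has no locus; left untouched", a.gene_id)
    return [updated[a.gene_id] for a in assignments]


def assign_scaffolds(
    assignments: Sequence[GeneAssignment],
    loci: Sequence[GeneLocus],
    scaffold_lengths: Mapping[str, int],
    parental_sections: tuple[str, str],
    majority: float = 0.75,
) -> list[ScaffoldAssignment]:
    """Majority-rule parental assignment of scaffolds.

    Among a scaffold's genes with a parental origin (tree or neighbor
    provenance, orphans ignored), the scaffold takes an origin when its
    most frequent origin reaches the majority fraction (default 75%),
    otherwise it stays orphan.  Scaffolds with no parentally assigned gene
    are orphan; gene-less scaffolds are excluded from the table.
    """
    maternal, paternal = parental_sections
    by_gene = {a.gene_id: a for a in assignments}
    by_scaffold: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold_id, []).append(locus)

    out = []
    for scaffold in sorted(by_scaffold):
        counts = {maternal: 0, paternal: 0, ORPHAN: 0}
        for locus in by_scaffold[scaffold]:
            a = by_gene.get(locus.gene_id)
            origin = a.origin if a is not None else ORPHAN
            counts[origin] = counts.get(origin, 0) + 1
        assigned = counts[maternal] + counts[paternal]
        if assigned == 0:
            origin = ORPHAN
        else:
            top = max((maternal, paternal), key=lambda s: counts[s])
            origin = top if counts[top] / assigned >= majority else ORPHAN
        length = scaffold_lengths.get(scaffold)
        if length is None:
            log.warning("scaffold %s has no length; reported as NA", scaffold)
        out.append(ScaffoldAssignment(
            scaffold_id=scaffold, origin=origin,
            n_genes_total=len(by_scaffold[scaffold]),
            n_maternal=counts[maternal], n_paternal=counts[paternal],
            n_orphan=counts[ORPHAN], length_bp=length))
    return out


def length_fraction(lengths: Mapping[str, float]) -> dict[str, float]:
    """Per-key percentage of the summed lengths, as printed (1 decimal scale)."""
    total = sum(lengths.values())
    if total == 0:
        return {k: 0.0 for k in lengths}
    return {k: 100.0 * v / total for k, v in lengths.items()}


def summarize_assignments(
    scaffold_assignments: Sequence[ScaffoldAssignment],
) -> pd.DataFrame:
    """Per-origin summary: scaffold count, total length, length fraction (%),
    mean scaffold length and mean genes per scaffold, plus a Total row.

    Scaffolds without a length are counted but excluded from length sums
    (with a warning upstream).
    """
    origins = sorted({s.origin for s in scaffold_assignments})
    rows = []
    groups = {o: [s for s in scaffold_assignments if s.origin == o]
              for o in origins}
    groups["Total"] = list(scaffold_assignments)
    total_len = sum(s.length_bp for s in scaffold_assignments
                    if s.length_bp is not None)
    for origin in origins + ["Total"]:
        grp = groups[origin]
        n = len(grp)
        lengths = [s.length_bp for s in grp if s.length_bp is not None]
        tot = sum(lengths)
        rows.append({
            "origin": origin,
            "n_scaffolds": n,
            "total_length": tot,
            "fraction_pct": round(100.0 * tot / total_len, 1) if total_len else 0.0,
            "avg_scaffold_length": round(tot / len(lengths), 1) if lengths else float("nan"),
            "avg_n_genes": round(sum(s.n_genes_total for s in grp) / n, 1) if n else float("nan"),
        })
    return pd.DataFrame(rows)
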