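"""Closest-sister-leaf (CSL) extraction, filtering and the parental census.

For each gene tree the CSL is the leaf (or subtree) occupying the tree
partition nearest the seed gene that belongs to a species other than the
seed species.  Counting which taxonomic section supplies the CSL across the
whole phylome nominates the two parental lineages of the hybrid: the two
most recurrent sections.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import dendropy

from .io import GeneTree, PhylomeError

log = logging.getLogger(__name__)


class NoCSLError(PhylomeError):
    """The tree contains no leaf from a non-seed species."""


@dataclass
class CSLRecord:
    """The seed gene's closest sister group and its summary measurements.

    ``csl_distance`` is the patristic distance from the seed to the nearest
    non-seed-species leaf inside the sister group; ``mrca_support`` is the
    support of the first ancestor of the seed whose other subtree contains a
    non-seed-species leaf.  ``leaf_distances`` keeps the per-leaf patristic
    distances for section resolution and auditing.
    """

    tree_id: str
    seed_gene: str
    sister_leaf_ids: frozenset[str]
    sister_species: frozenset[str]
    csl_leaf: str
    csl_distance: float
    mrca_support: float | None
    n_species: int
    resolved_section: str = "unresolved"
    leaf_distances: dict[str, float] = field(default_factory=dict)


@dataclass
class CSLFilterConfig:
    """Validity thresholds for a CSL record (all bounds inclusive)."""

    max_sister_species: int = 3
    max_csl_distance: float = 0.1
    min_mrca_support: float = 0.9
    min_species: int = 5

    def __post_init__(self) -> None:
        if min(self.max_sister_species, self.max_csl_distance,
               self.min_mrca_support, self.min_species) <= 0:
            raise ValueError("all CSL filter thresholds must be positive")


@dataclass
class FilterResult:
    """Per-criterion outcome of the four CSL validity filters."""

    min_species: bool
    max_sister_species: bool
    max_csl_distance: bool
    min_mrca_support: bool

    @property
    def passed(self) -> bool:
        return (self.min_species and self.max_sister_species
                and self.max_csl_distance and self.min_mrca_support)


def root_tree(tree: GeneTree, outgroup_section: str | None = None) -> str:
    """Root a tree in place for CSL extraction; returns the policy applied.

    If an outgroup section is configured and present (and does not contain
    the seed), the tree is rooted on the edge above the outgroup leaf nearest
    the seed (MRCA edge when the outgroup has several leaves); otherwise the
    tree is midpoint-rooted.  The choice is logged per tree.
    """
    og_leaves = []
    if outgroup_section is not None:
        og_leaves = [
            lf for lf in tree.leaf_nodes()
            if tree.section_of(lf.taxon.label) == outgroup_section
            and lf.taxon.label != tree.seed_leaf
        ]
    if og_leaves:
        if len(og_leaves) == 1:
            node = og_leaves[0]
        else:
            node = tree.tree.mrca(taxa=[lf.taxon for lf in og_leaves])
            if node is tree.tree.seed_node:  # outgroup not monophyletic here
                node = og_leaves[0]
        length = node.edge.length or 0.0
        tree.tree.reroot_at_edge(node.edge, length1=length / 2.0,
                                 length2=length / 2.0,
                                 suppress_unifurcations=True)
        policy = f"outgroup:{outgroup_section}"
    else:
        tree.tree.reroot_at_midpoint(suppress_unifurcations=True)
        policy = "midpoint"
    log.debug("%s: rooted by %s", tree.tree_id, policy)
    return policy


def find_csl(tree: GeneTree) -> CSLRecord:
    """Extract the closest sister leaf of the seed gene.

    Ascends from the seed leaf to the first ancestor whose other child
    subtree contains at least one leaf of a non-seed species; that subtree is
    the sister group.  Seed-species paralogs sitting in the immediate sister
    position are skipped by continuing the ascent, because the CSL must
    belong to a species different from the seed.
    """
    seed_sp = tree.seed_species
    node = tree.node_of(tree.seed_leaf)
    while node.parent_node is not None:
        parent = node.parent_node
        sister_leaves = [
            lf
            for child in parent.child_nodes()
            if child is not node
            for lf in child.leaf_iter()
        ]
        foreign = [lf for lf in sister_leaves
                   if tree.species_of(lf.taxon.label) != seed_sp]
        if foreign:
            dists = {lf.taxon.label: tree.patristic(tree.seed_leaf, lf.taxon.label)
                     for lf in foreign}
            csl_leaf = min(dists, key=lambda g: (dists[g], g))
            return CSLRecord(
                tree_id=tree.tree_id,
                seed_gene=tree.seed_leaf,
                sister_leaf_ids=frozenset(dists),
                sister_species=frozenset(
                    tree.species_of(g) for g in dists),
                csl_leaf=csl_leaf,
                csl_distance=dists[csl_leaf],
                mrca_support=tree.support_of(parent),
                n_species=tree.n_species(),
                leaf_distances=dict(dists),
            )
        node = parent
    raise NoCSLError(f"{tree.tree_id}: no non-seed-species leaf in tree")


def resolve_csl_section(rec: CSLRecord, tree: GeneTree) -> str:
    """Resolve the sister group to a single section.

    If every sister leaf belongs to one section, that section is returned;
    otherwise the section of the minimum-patristic-distance leaf wins, with
    exact distance ties broken lexicographically by gene id (logged).
    """
    sections = {tree.section_of(g) for g in rec.sister_leaf_ids}
    if len(sections) == 1:
        rec.resolved_section = sections.pop()
        return rec.resolved_section
    dmin = min(rec.leaf_distances.values())
    nearest = sorted(g for g, d in rec.leaf_distances.items() if d == dmin)
    if len(nearest) > 1 and len({tree.section_of(g) for g in nearest}) > 1:
        log.info("%s: CSL distance tie among %s; lexicographic tie-break",
                 rec.tree_id, nearest)
    rec.resolved_section = tree.section_of(nearest[0])
    return rec.resolved_section


def csl_filters(rec: CSLRecord, cfg: CSLFilterConfig) -> FilterResult:
    """Apply the four validity filters; missing support fails the support bound."""
    return FilterResult(
        min_species=rec.n_species >= cfg.min_species,
        max_sister_species=len(rec.sister_species) <= cfg.max_sister_species,
        max_csl_distance=rec.csl_distance <= cfg.max_csl_distance,
        min_mrca_support=(rec.mrca_support is not None
                          and rec.mrca_support >= cfg.min_mrca_support),
    )


@dataclass
class CensusResult:
    """Per-section CSL occurrence counts and the nominated parental pair."""

    counts: dict[str, int]
    parental_pair: tuple[str, str] | None
    warning: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def csl_census(records: list[CSLRecord]) -> CensusResult:
    """Count resolved sections over passing records; top-2 are the parents.

    Ranking ties are broken lexicographically for determinism.  With fewer
    than two distinct sections the census is still returned, with a warning
    and no nominated pair.
    """
    counts = Counter(r.resolved_section for r in records)
    counts.pop("unresolved", None)
    ranked = sorted(counts, key=lambda s: (-counts[s], s))
    if len(ranked) < 2:
        msg = "fewer than two distinct CSL sections; cannot nominate parents"
        log.warning(msg)
        return CensusResult(dict(counts), None, warning=msg)
    return CensusResult(dict(counts), (ranked[0], ranked[1]))


def closest_leaf_per_taxon(tree: GeneTree) -> dict[str, float]:
    """Minimum seed-to-leaf patristic distance for every non-seed section.

    Leaves of the seed species are excluded; sections without any leaf are
    simply absent from the map.
    """
    seed_sp = tree.seed_species
    out: dict[str, float] = {}
    for gid in tree.leaf_ids():
        if tree.species_of(gid) == seed_sp:
            continue
        sec = tree.section_of(gid)
        d = tree.patristic(tree.seed_leaf, gid)
        if sec not in out or d < out[sec]:
            out[sec] = d
    return out
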