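"""Alignment cleaning and tree-level species-count filtering.

Sequences whose fraction of undetermined bases (N) exceeds a threshold are
dropped from the alignment and their leaves pruned from the tree; trees left
with fewer than a minimum number of distinct species are discarded.  Two
presets mirror the two analysis arms: a strict 1% N cap for closest-sister
-leaf extraction and dating, a permissive 10% cap for subgenome assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import CodonAlignment, ConsistencyError, GeneTree

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds for alignment cleaning and tree retention.

    max_undetermined_frac: rows with an N fraction strictly greater than this
        are removed.  The N fraction is counted over ungapped characters only
        (gap columns are alignment artifacts, not sequence content).
    min_species: minimum number of distinct species a tree must retain.
    """

    max_undetermined_frac: float = 0.01
    min_species: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_undetermined_frac <= 1.0:
            raise ValueError("max_undetermined_frac must be in [0, 1]")
        if self.min_species < 2:
            raise ValueError("min_species must be >= 2")


#: preset for CSL extraction and dating (strict N cap)
CSL_PRESET = QCConfig(max_undetermined_frac=0.01, min_species=5)
#: preset for subgenome assignment (permissive N cap)
SUBGENOME_PRESET = QCConfig(max_undetermined_frac=0.10, min_species=5)


@dataclass
class QCReport:
    tree_id: str
    rows_removed: list[str] = field(default_factory=list)
    species_before: int = 0
    species_after: int = 0
    seed_removed: bool = False

    @property
    def n_removed(self) -> int:
        return len(self.rows_removed)


def clean_alignment(
    aln: CodonAlignment, tree: GeneTree, cfg: QCConfig
) -> tuple[CodonAlignment, GeneTree, QCReport]:
    """Drop over-undetermined rows and prune the tree to the survivors.

    A row is removed when its N count divided by its ungapped length is
    strictly greater than ``cfg.max_undetermined_frac`` (a row at exactly the
    threshold is kept).  Pruning sums the branch lengths of suppressed
    unifurcations, so patristic distances among surviving leaves are
    unchanged.  If the seed row is removed the tree is flagged unusable
    rather than raising.  The inputs are not modified.
    """
    leaf_ids = tree.leaf_ids()
    for gid in leaf_ids:
        if gid not in aln:
            raise ConsistencyError(
                f"{tree.tree_id}: leaf {gid!r} has no alignment row")
    report = QCReport(tree_id=tree.tree_id, species_before=tree.n_species())
    removed = []
    for gid in leaf_ids:
        frac = aln.n_fraction(gid)
        if frac > cfg.max_undetermined_frac:
            removed.append(gid)
            log.debug("%s: removing %s (N fraction %.4f > %.4f)",
                      tree.tree_id, gid, frac, cfg.max_undetermined_frac)
    keep = [g for g in leaf_ids if g not in set(removed)]
    report.rows_removed = removed
    report.seed_removed = tree.seed_leaf in set(removed)

    pruned = GeneTree(
        tree_id=tree.tree_id,
        tree=tree.tree.clone(depth=1),
        seed_leaf=tree.seed_leaf,
        taxonomy=tree.taxonomy,
        unusable=tree.unusable,
    )
    pruned.prune_to(keep)
    report.species_after = pruned.n_species() if keep else 0
    return aln.subset(keep), pruned, report


def species_count_filter(tree: GeneTree, cfg: QCConfig) -> bool:
    """True iff the tree covers at least ``cfg.min_species`` distinct species."""
    if not tree.leaf_ids():
        return False
    return tree.n_species() >= cfg.min_species
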