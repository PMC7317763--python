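"""Synthetic phylomes with known ground truth.

Emulates the data situation of an allotetraploid "seed" species whose genes
descend from two of several diploid sections: a fixed species history (an
ultrametric ladder of diploid sections), a hybrid whose gene copies attach to
the maternal or the paternal lineage at the hybridization time (one retained
copy per gene, drawn with a fractionation bias), site-wise sequence evolution
under a two-parameter (Ti/Tv) substitution process in which third positions
of four-fold degenerate codons evolve at the neutral rate and all other
positions at a constrained fraction of it, and a genome layout that packs
genes onto scaffolds with configurable subgenome intermixing.

Gene trees are emitted with lognormally perturbed branch lengths (modelling
tree-estimation error); the alignments themselves evolve along the true
expected branch lengths, so per-site divergence at 4D sites remains an
unbiased 2rT clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import (
    CodonAlignment,
    GeneLocus,
    GeneTree,
    PhylomeDataset,
    TaxonomyMap,
)

SENSE_CODONS: list[str] = sorted(
    b1 + b2 + b3
    for b1 in "ACGT" for b2 in "ACGT" for b3 in "ACGT"
    if b1 + b2 + b3 not in {"TAA", "TAG", "TGA"}
)

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_BASES = np.array(list("ACGT"))

from .dating import FOURFOLD_PREFIXES  # standard-code 4D families


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic phylome.

    Defaults emulate an old allotetraploid: hybridization 4.9 MyA, neutral
    rate 5e-9 substitutions/site/year, Ti/Tv rate ratio kappa = 2, a maternal
    retention bias of 0.54 and roughly a quarter of gene trees lacking both
    parental leaves.  Split times (MyA) place the two parental sections
    closest to the hybrid and four other diploid sections progressively
    further out.
    """

    maternal_section: str = "Noctiflorae"
    paternal_section: str = "Sylvestres"
    hybrid_section: str = "Suaveolentes"
    species_by_section: dict[str, str] = field(default_factory=lambda: {
        "Noctiflorae": "noctiflora",
        "Sylvestres": "sylvestris",
        "Petunioides": "attenuata",
        "Paniculatae": "cordifolia",
        "Trigonophyllae": "obtusifolia",
        "Tomentosae": "tomentosiformis",
        "Suaveolentes": "benthamiana",
    })
    hybridization_time: float = 4.9       # MyA
    parental_split_mya: float = 6.5
    outgroup_joins_mya: dict[str, float] = field(default_factory=lambda: {
        "Petunioides": 7.5,
        "Paniculatae": 9.0,
        "Trigonophyllae": 10.5,
        "Tomentosae": 15.0,
    })
    rate: float = 5e-9                    # neutral subs/site/year
    generations_per_year: float = 1.0
    constrained_rate_factor: float = 0.2  # non-4D positions
    kappa: float = 2.0                    # Ti/Tv rate ratio
    n_genes: int = 2000
    n_codons: int = 450
    genes_per_scaffold: float = 10.0
    switch_prob: float = 0.05
    fractionation_bias: float = 0.54      # P(retain maternal copy)
    orphan_prob: float = 0.23             # P(tree lacks both parental leaves)
    branch_noise_sd: float = 0.05         # lognormal sigma on tree lengths
    support_range: tuple[float, float] = (0.95, 1.0)
    low_support_prob: float = 0.0
    low_support_range: tuple[float, float] = (0.3, 0.8)
    intergenic_bp: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.switch_prob, self.fractionation_bias, self.orphan_prob,
                  self.low_support_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rate <= 0 or self.constrained_rate_factor < 0:
            raise ValueError("rates must be positive")
        if not self.hybridization_time < self.parental_split_mya:
            raise ValueError(
                "hybridization_time must predate the parental split")
        if any(t <= self.parental_split_mya
               for t in self.outgroup_joins_mya.values()):
            raise ValueError("outgroup join times must exceed the parental split")

    @property
    def subs_per_mya(self) -> float:
        return self.rate * 1e6 * self.generations_per_year

    def species_of(self, section: str) -> str:
        return self.species_by_section[section]


@dataclass
class TruthTable:
    """Ground truth emitted alongside a synthetic phylome."""

    genes: pd.DataFrame       # gene_id, tree_id, true_origin, orphan_tree, scaffold_id, rank
    scaffolds: pd.DataFrame   # scaffold_id, true_origin, n_genes, length_bp
    params: dict


@dataclass
class SyntheticPhylome:
    dataset: PhylomeDataset
    truth: TruthTable
    loci: list[GeneLocus]
    scaffold_lengths: dict[str, int]


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

def _leaf(tns: dendropy.TaxonNamespace, label: str,
          edge_len: float) -> dendropy.Node:
    node = dendropy.Node(edge_length=edge_len)
    node.taxon = tns.require_taxon(label=label)
    return node


def _build_true_tree(
    cfg: SimulationConfig, origin: str, gene_suffix: str,
    tns: dendropy.TaxonNamespace,
) -> tuple[dendropy.Tree, str]:
    """Species-history tree for one gene, seed grafted onto its true lineage.

    Edge lengths are expected substitutions/site at the neutral rate
    (rate x years), so the seed-to-parental-leaf patristic distance is
    2 x rate x hybridization_time.
    """
    s = cfg.subs_per_mya
    t_hyb, t_mp = cfg.hybridization_time, cfg.parental_split_mya
    seed_id = f"seed_{gene_suffix}"

    def section_leaf(section: str, height: float) -> dendropy.Node:
        return _leaf(tns, f"{cfg.species_of(section)}_{gene_suffix}",
                     height * s)

    children = {}
    for sec in (cfg.maternal_section, cfg.paternal_section):
        if sec == origin:
            graft = dendropy.Node(edge_length=(t_mp - t_hyb) * s)
            graft.add_child(section_leaf(sec, t_hyb))
            graft.add_child(_leaf(tns, seed_id, t_hyb * s))
            children[sec] = graft
        else:
            children[sec] = section_leaf(sec, t_mp)
    clade = dendropy.Node()
    clade.add_child(children[cfg.maternal_section])
    clade.add_child(children[cfg.paternal_section])

    prev_h = t_mp
    for sec, h in sorted(cfg.outgroup_joins_mya.items(), key=lambda kv: kv[1]):
        clade.edge.length = (h - prev_h) * s
        parent = dendropy.Node()
        parent.add_child(clade)
        parent.add_child(section_leaf(sec, h))
        clade = parent
        prev_h = h
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = clade
    return tree, seed_id


def simulate_gene_trees(
    cfg: SimulationConfig, rng: np.random.Generator | None = None,
) -> tuple[list[GeneTree], TruthTable]:
    """Draw per-gene origins and build the corresponding gene trees.

    Each tree is the species history restricted to its sampled leaves, with
    the single retained seed copy attached to its true parental lineage at
    the hybridization time.  With probability ``orphan_prob`` both
    parental-section leaves are dropped (branch lengths summed through the
    suppressed nodes).  True expected lengths are kept on each node as
    ``true_length``; the emitted ``edge.length`` carries lognormal noise.
    Internal supports are drawn from ``support_range`` (or, with probability
    ``low_support_prob``, from ``low_support_range``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    gene_to_species: dict[str, str] = {}
    taxonomy = TaxonomyMap(
        gene_to_species,
        {sp: sec for sec, sp in cfg.species_by_section.items()})

    trees: list[GeneTree] = []
    truth_rows = []
    parental_species = {cfg.species_of(cfg.maternal_section),
                        cfg.species_of(cfg.paternal_section)}
    for i in range(cfg.n_genes):
        suffix = f"g{i:05d}"
        tree_id = f"tree_{i:05d}"
        origin = (cfg.maternal_section
                  if rng.random() < cfg.fractionation_bias
                  else cfg.paternal_section)
        orphan = bool(rng.random() < cfg.orphan_prob)
        tns = dendropy.TaxonNamespace()
        dtree, seed_id = _build_true_tree(cfg, origin, suffix, tns)
        if orphan:
            drop = [t for t in tns
                    if t.label.rsplit("_", 1)[0] in parental_species]
            dtree.prune_taxa(drop, suppress_unifurcations=True)
        for node in dtree.preorder_node_iter():
            node.true_length = node.edge.length
            if node.edge.length is not None and cfg.branch_noise_sd > 0:
                sd = cfg.branch_noise_sd
                node.edge.length *= float(
                    rng.lognormal(mean=-0.5 * sd * sd, sigma=sd))
            if not node.is_leaf():
                if node.parent_node is None:
                    node.support = None
                elif rng.random() < cfg.low_support_prob:
                    node.support = float(rng.uniform(*cfg.low_support_range))
                else:
                    node.support = float(rng.uniform(*cfg.support_range))
        for lf in dtree.leaf_node_iter():
            label = lf.taxon.label
            gene_to_species[label] = (
                cfg.species_of(cfg.hybrid_section)
                if label == seed_id else label.rsplit("_", 1)[0])
        trees.append(GeneTree(tree_id=tree_id, tree=dtree, seed_leaf=seed_id,
                              taxonomy=taxonomy))
        truth_rows.append({"gene_id": seed_id, "tree_id": tree_id,
                           "true_origin": origin, "orphan_tree": orphan,
                           "scaffold_id": None, "rank": None})
    truth = TruthTable(
        genes=pd.DataFrame(truth_rows),
        scaffolds=pd.DataFrame(),
        params={"hybridization_time": cfg.hybridization_time,
                "rate": cfg.rate, "kappa": cfg.kappa},
    )
    return trees, truth


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _k80_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """Two-parameter (Kimura) substitution probabilities for branch length d
    (expected substitutions/site) and Ti/Tv rate ratio kappa."""
    if d <= 0:
        return np.eye(4)
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv
    P = np.full((4, 4), p_tv)
    for b in range(4):
        P[b, b] = p_same
        P[b, b ^ 2] = p_ts  # A<->G, C<->T partners under the ACGT encoding
    return P


def _evolve_branch(parent: np.ndarray, d: float, neutral_mask: np.ndarray,
                   cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if d is None or d <= 0:
        return parent.copy()
    P_neutral = _k80_transition_matrix(d, cfg.kappa)
    P_constr = _k80_transition_matrix(d * cfg.constrained_rate_factor, cfg.kappa)
    rows = np.where(neutral_mask[:, None], P_neutral[parent], P_constr[parent])
    cum = rows.cumsum(axis=1)
    u = rng.random(parent.size)
    return (u[:, None] < cum).argmax(axis=1)


def evolve_alignments(tree: GeneTree, cfg: SimulationConfig,
                      rng: np.random.Generator | None = None) -> CodonAlignment:
    """Evolve a gap-free in-frame alignment along one gene tree.

    The root codon sequence is drawn uniformly over the 61 sense codons (all
    eight 4D families represented in expectation).  Third positions of root
    codons in a 4D family evolve at the neutral rate, every other position at
    ``constrained_rate_factor`` times it; the site's rate class is fixed along
    the tree.  Branches use the true expected lengths when present (i.e. the
    emitted branch noise does not touch the sequences).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    L = 3 * cfg.n_codons
    codon_idx = rng.integers(0, len(SENSE_CODONS), size=cfg.n_codons)
    root_codons = [SENSE_CODONS[k] for k in codon_idx]
    root = np.array([_BASE_INDEX[b] for c in root_codons for b in c])
    neutral_mask = np.zeros(L, dtype=bool)
    for j, codon in enumerate(root_codons):
        if codon[:2] in FOURFOLD_PREFIXES:
            neutral_mask[3 * j + 2] = True

    seqs: dict[int, np.ndarray] = {}
    rows: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root
        else:
            d = getattr(node, "true_length", None)
            if d is None:
                d = node.edge.length
            seq = _evolve_branch(seqs[id(node.parent_node)], d, neutral_mask,
                                 cfg, rng)
        seqs[id(node)] = seq
        if node.is_leaf():
            rows[node.taxon.label] = "".join(_BASES[seq])
    ordered = {gid: rows[gid] for gid in sorted(rows)}
    return CodonAlignment(ordered, L)


def corrupt(aln: CodonAlignment, gene_id: str, frac: float,
            rng: np.random.Generator) -> CodonAlignment:
    """Overwrite a random run of one row with N to reach the given ungapped
    N fraction (tests the undetermined-character cleaning paths)."""
    seq = list(aln[gene_id])
    positions = [i for i, c in enumerate(seq) if c != "-"]
    n_target = int(round(frac * len(positions)))
    if n_target > 0:
        start = int(rng.integers(0, len(positions) - n_target + 1))
        for i in positions[start:start + n_target]:
            seq[i] = "N"
    rows = dict(aln.rows)
    rows[gene_id] = "".join(seq)
    return CodonAlignment(rows, aln.width)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def layout_genome(
    truth: TruthTable, cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneLocus], dict[str, int]]:
    """Pack seed genes onto scaffolds with configurable subgenome intermixing.

    Scaffold sizes are Poisson around ``genes_per_scaffold`` (minimum 1).
    Within a scaffold, consecutive genes switch subgenome with probability
    ``switch_prob`` (0 gives monomorphic scaffolds, 0.5 full intermixing);
    genes of the current subgenome are drawn from the per-origin pools, so
    the per-gene origins set at tree simulation are preserved.  Coordinates
    are 1-based, non-overlapping; scaffold true origin is the majority of its
    genes' true origins (ties broken toward the lexicographically smaller
    section).  Updates ``truth`` in place with scaffold ids and ranks.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    genes = truth.genes
    pools = {
        sec: list(genes.loc[genes.true_origin == sec, "gene_id"])
        for sec in (cfg.maternal_section, cfg.paternal_section)
    }
    other = {cfg.maternal_section: cfg.paternal_section,
             cfg.paternal_section: cfg.maternal_section}
    gene_len = 3 * cfg.n_codons
    loci: list[GeneLocus] = []
    scaffold_lengths: dict[str, int] = {}
    scaffold_rows = []
    placement: dict[str, tuple[str, int]] = {}
    scaffold_no = 0
    while pools[cfg.maternal_section] or pools[cfg.paternal_section]:
        scaffold_no += 1
        scaffold_id = f"scaffold_{scaffold_no:04d}"
        n_target = max(1, int(rng.poisson(cfg.genes_per_scaffold)))
        remaining = (len(pools[cfg.maternal_section]),
                     len(pools[cfg.paternal_section]))
        p_mat = remaining[0] / max(1, sum(remaining))
        current = (cfg.maternal_section if rng.random() < p_mat
                   else cfg.paternal_section)
        if not pools[current]:
            current = other[current]
        placed: list[tuple[str, str]] = []
        for j in range(n_target):
            if j > 0 and rng.random() < cfg.switch_prob and pools[other[current]]:
                current = other[current]
            if not pools[current]:
                if cfg.switch_prob == 0:
                    break  # keep the scaffold monomorphic
                current = other[current]
                if not pools[current]:
                    break
            placed.append((pools[current].pop(0), current))
        start = 1
        for rank, (gid, origin) in enumerate(placed, start=1):
            end = start + gene_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(GeneLocus(gid, scaffold_id, start, end, strand, rank))
            placement[gid] = (scaffold_id, rank)
            start = end + 1 + cfg.intergenic_bp
        scaffold_lengths[scaffold_id] = start - 1
        counts = pd.Series([o for _, o in placed]).value_counts()
        top = sorted(counts[counts == counts.max()].index)[0]
        scaffold_rows.append({"scaffold_id": scaffold_id, "true_origin": top,
                              "n_genes": len(placed),
                              "length_bp": scaffold_lengths[scaffold_id]})
    genes["scaffold_id"] = genes["gene_id"].map(
        lambda g: placement[g][0] if g in placement else None)
    genes["rank"] = genes["gene_id"].map(
        lambda g: placement[g][1] if g in placement else None)
    truth.scaffolds = pd.DataFrame(scaffold_rows)
    return loci, scaffold_lengths


# ---------------------------------------------------------------------------
# end-to-end convenience and serialization
# ---------------------------------------------------------------------------

def simulate_phylome(cfg: SimulationConfig) -> SyntheticPhylome:
    """Simulate trees, alignments and genome layout with one seeded stream."""
    rng = np.random.default_rng(cfg.rng_seed)
    trees, truth = simulate_gene_trees(cfg, rng)
    alignments = {t.tree_id: evolve_alignments(t, cfg, rng) for t in trees}
    loci, scaffold_lengths = layout_genome(truth, cfg, rng)
    taxonomy = trees[0].taxonomy if trees else TaxonomyMap({}, {})
    dataset = PhylomeDataset(trees=trees, alignments=alignments,
                             taxonomy=taxonomy, loci=loci,
                             scaffold_lengths=scaffold_lengths)
    return SyntheticPhylome(dataset=dataset, truth=truth, loci=loci,
                            scaffold_lengths=scaffold_lengths)


def write_dataset(synth: SyntheticPhylome, outdir: str | Path) -> None:
    """Emit the exact formats the loaders read: newick trees TSV, per-tree
    FASTA alignments, taxonomy TSV, GFF3 gene models, scaffold lengths and
    the truth tables."""
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    ds = synth.dataset
    with open(outdir / "trees.tsv", "w") as fh:
        fh.write("tree_id\tseed_gene\tnewick\n")
        for t in ds.trees:
            fh.write(f"{t.tree_id}\t{t.seed_leaf}\t{t.as_newick()}\n")
    for t in ds.trees:
        (outdir / "alignments" / f"{t.tree_id}.fasta").write_text(
            ds.alignments[t.tree_id].to_fasta())
    with open(outdir / "taxonomy.tsv", "w") as fh:
        fh.write("gene_id\tspecies\tsection\n")
        for gid in sorted(ds.taxonomy.gene_to_species):
            sp = ds.taxonomy.gene_to_species[gid]
            fh.write(f"{gid}\t{sp}\t{ds.taxonomy.species_to_section[sp]}\n")
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in sorted(synth.loci, key=lambda l: (l.scaffold_id, l.start)):
            fh.write(f"{locus.scaffold_id}\tphylophase\tgene\t{locus.start}\t"
                     f"{locus.end}\t.\t{locus.strand}\t.\tID={locus.gene_id}\n")
    with open(outdir / "scaffolds.tsv", "w") as fh:
        fh.write("scaffold_id\tlength_bp\n")
        for sid in sorted(synth.scaffold_lengths):
            fh.write(f"{sid}\t{synth.scaffold_lengths[sid]}\n")
    synth.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    synth.truth.scaffolds.to_csv(outdir / "truth_scaffolds.tsv", sep="\t",
                                 index=False)
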