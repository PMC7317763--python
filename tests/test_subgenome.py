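"""Gene assignment, orphan rescue and the scaffold majority rule."""

import pytest

from phylophase.io import GeneLocus, read_gene_tree
from phylophase.subgenome import (
    ORPHAN,
    DuplicateSeedError,
    GeneAssignment,
    assign_genes,
    assign_scaffolds,
    closest_parental_leaf,
    infer_orphans,
    length_fraction,
    summarize_assignments,
)
from conftest import make_taxonomy

PAIR = ("Noctiflorae", "Sylvestres")


class TestClosestParentalLeaf:
    def test_nearest_supported_leaf_wins(self, four_leaf_tree):
        rec = closest_parental_leaf(four_leaf_tree, PAIR)
        assert (rec.leaf, rec.section) == ("noc1", "Noctiflorae")
        assert rec.distance == pytest.approx(0.03)
        assert rec.support == pytest.approx(0.95)

    def test_next_nearest_used_when_support_fails(self, toy_taxonomy):
        gt = read_gene_tree(
            "((seed:0.01,noc1:0.02)0.5:0.005,(syl1:0.03,pet1:0.04)0.90:0.01);",
            toy_taxonomy, seed_gene="seed")
        rec = closest_parental_leaf(gt, PAIR)
        assert (rec.leaf, rec.section) == ("syl1", "Sylvestres")
        assert rec.distance == pytest.approx(0.055)

    def test_no_parental_leaf_gives_none(self, toy_taxonomy):
        gt = read_gene_tree("((seed:0.01,pet1:0.02)0.95:0.005,tom1:0.05);",
                            toy_taxonomy, seed_gene="seed")
        assert closest_parental_leaf(gt, PAIR) is None

    def test_cross_section_distance_tie_refused(self, toy_taxonomy):
        gt = read_gene_tree(
            "((seed:0.01,noc1:0.02)0.95:0.005,syl1:0.015)0.95;",
            toy_taxonomy, seed_gene="seed")
        d_noc = gt.patristic("seed", "noc1")
        d_syl = gt.patristic("seed", "syl1")
        assert d_noc == pytest.approx(d_syl)
        assert closest_parental_leaf(gt, PAIR) is None

    def test_unusable_tree_gives_none(self, four_leaf_tree):
        four_leaf_tree.unusable = True
        assert closest_parental_leaf(four_leaf_tree, PAIR) is None


class TestAssignGenes:
    def test_aggregation(self, toy_taxonomy, four_leaf_tree):
        t_pat = read_gene_tree(
            "((seedParalog:0.01,syl1:0.02)0.95:0.005,pet1:0.05);",
            toy_taxonomy, seed_gene="seedParalog", tree_id="t2")
        t_orp = read_gene_tree("(noc2:0.01,(pet1:0.02,tom1:0.03)0.2:0.01);",
                               toy_taxonomy, seed_gene="noc2", tree_id="t3")
        out = assign_genes([four_leaf_tree, t_pat, t_orp], PAIR)
        origins = {a.gene_id: a.origin for a in out}
        assert origins == {"seed": "Noctiflorae", "seedParalog": "Sylvestres",
                          "noc2": ORPHAN}

    def test_empty_phylome(self):
        assert assign_genes([], PAIR) == []

    def test_duplicate_seed_raises(self, four_leaf_tree):
        with pytest.raises(DuplicateSeedError):
            assign_genes([four_leaf_tree, four_leaf_tree], PAIR)

    def test_synthetic_truth_recovered(self, small_synth):
        """Non-orphan assignments match simulation truth almost everywhere."""
        from phylophase.pipeline import run_subgenome
        res = run_subgenome(small_synth.dataset, PAIR)
        truth = dict(zip(small_synth.truth.genes.gene_id,
                         small_synth.truth.genes.true_origin))
        scored = [(a.origin == truth[a.gene_id])
                  for a in res.gene_assignments if a.origin != ORPHAN]
        assert len(scored) > 200
        assert sum(scored) / len(scored) >= 0.95


def _locus(gid, scaf, rank):
    start = rank * 100
    return GeneLocus(gid, scaf, start, start + 50, "+", rank)


def _ga(gid, origin, prov="tree"):
    return GeneAssignment(gene_id=gid, origin=origin,
                          provenance=None if origin == ORPHAN else prov)


class TestInferOrphans:
    def test_concordant_neighbors_transfer(self):
        assigns = [_ga("a", "Noctiflorae"), _ga("b", ORPHAN),
                   _ga("c", "Noctiflorae")]
        loci = [_locus("a", "s", 1), _locus("b", "s", 2), _locus("c", "s", 3)]
        out = infer_orphans(assigns, loci)
        b = next(a for a in out if a.gene_id == "b")
        assert (b.origin, b.provenance) == ("Noctiflorae", "neighbor")

    def test_discordant_neighbors_stay_orphan(self):
        assigns = [_ga("a", "Noctiflorae"), _ga("b", ORPHAN),
                   _ga("c", "Sylvestres")]
        loci = [_locus(g, "s", i + 1) for i, g in enumerate("abc")]
        out = infer_orphans(assigns, loci)
        assert next(a for a in out if a.gene_id == "b").origin == ORPHAN

    def test_terminal_gene_uses_single_neighbor(self):
        assigns = [_ga("a", ORPHAN), _ga("b", "Sylvestres")]
        loci = [_locus("a", "s", 1), _locus("b", "s", 2)]
        out = infer_orphans(assigns, loci)
        assert next(a for a in out if a.gene_id == "a").origin == "Sylvestres"

    def test_neighbor_inferred_genes_are_not_evidence(self):
        # a(tree M) b(orphan) c(orphan): b is rescued from a, but c's only
        # tree-provenance neighbor evidence is nothing -> c stays orphan
        assigns = [_ga("a", "Noctiflorae"), _ga("b", ORPHAN), _ga("c", ORPHAN)]
        loci = [_locus(g, "s", i + 1) for i, g in enumerate("abc")]
        out = infer_orphans(assigns, loci)
        origins = {a.gene_id: a.origin for a in out}
        assert origins["b"] == "Noctiflorae" and origins["c"] == ORPHAN

    def test_idempotent(self):
        assigns = [_ga("a", "Noctiflorae"), _ga("b", ORPHAN), _ga("c", ORPHAN),
                   _ga("d", "Sylvestres")]
        loci = [_locus(g, "s", i + 1) for i, g in enumerate("abcd")]
        once = infer_orphans(assigns, loci)
        twice = infer_orphans(once, loci)
        assert [(a.gene_id, a.origin, a.provenance) for a in once] == \
               [(a.gene_id, a.origin, a.provenance) for a in twice]

    def test_gene_counts_conserved(self):
        assigns = [_ga("a", "Noctiflorae"), _ga("b", ORPHAN), _ga("c", ORPHAN),
                   _ga("d", "Sylvestres"), _ga("e", ORPHAN)]
        loci = [_locus(g, "s", i + 1) for i, g in enumerate("abcde")]
        out = infer_orphans(assigns, loci)
        assert len(out) == len(assigns)
        # origins only move orphan -> parental
        before = {a.gene_id: a.origin for a in assigns}
        for a in out:
            if before[a.gene_id] != ORPHAN:
                assert a.origin == before[a.gene_id]


LENGTHS = {"s": 1000}


class TestAssignScaffolds:
    def _run(self, origins, majority=0.75):
        assigns = [_ga(f"g{i}", o) for i, o in enumerate(origins)]
        loci = [_locus(f"g{i}", "s", i + 1) for i in range(len(origins))]
        return assign_scaffolds(assigns, loci, LENGTHS, PAIR, majority)[0]

    def test_three_quarters_is_enough(self):
        sc = self._run(["Noctiflorae"] * 3 + ["Sylvestres"])
        assert sc.origin == "Noctiflorae"  # 0.75 >= 0.75

    def test_even_split_is_orphan(self):
        assert self._run(["Noctiflorae", "Sylvestres"]).origin == ORPHAN

    def test_orphan_genes_ignored(self):
        sc = self._run([ORPHAN, ORPHAN, "Noctiflorae"])
        assert sc.origin == "Noctiflorae"  # 1/1 assigned genes

    def test_all_orphan_scaffold_is_orphan(self):
        assert self._run([ORPHAN, ORPHAN]).origin == ORPHAN

    def test_unanimity_boundary(self):
        """majority=1.0 assigns only monomorphic scaffolds."""
        assert self._run(["Noctiflorae"] * 9 + ["Sylvestres"],
                         majority=1.0).origin == ORPHAN
        assert self._run(["Noctiflorae"] * 9, majority=1.0).origin == \
            "Noctiflorae"

    def test_gene_tallies_conserved(self):
        sc = self._run(["Noctiflorae", ORPHAN, "Sylvestres", "Noctiflorae"])
        assert sc.n_maternal + sc.n_paternal + sc.n_orphan == sc.n_genes_total


class TestSummarize:
    def test_worked_arithmetic(self):
        scs = assign_scaffolds(
            [_ga("a", "Noctiflorae"), _ga("b", "Noctiflorae"), _ga("c", ORPHAN)],
            [_locus("a", "s1", 1), _locus("b", "s2", 1), _locus("c", "s3", 1)],
            {"s1": 100, "s2": 300, "s3": 100}, PAIR)
        df = summarize_assignments(scs).set_index("origin")
        assert df.loc["Noctiflorae", "fraction_pct"] == pytest.approx(80.0)
        assert df.loc["Noctiflorae", "avg_scaffold_length"] == pytest.approx(200)
        assert df.loc["Total", "n_scaffolds"] == 3

    def test_fractions_sum_to_hundred(self, small_synth):
        from phylophase.pipeline import run_subgenome
        res = run_subgenome(small_synth.dataset, PAIR)
        parts = res.summary[res.summary.origin != "Total"]
        assert abs(round(float(parts.fraction_pct.sum()), 1) - 100.0) <= 0.1

    def test_empty_input(self):
        df = summarize_assignments([])
        assert df.loc[df.origin == "Total", "n_scaffolds"].iloc[0] == 0

    def test_length_fraction_helper(self):
        fr = length_fraction({"m": 400, "p": 400, "o": 200})
        assert fr == pytest.approx({"m": 40.0, "p": 40.0, "o": 20.0})
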