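"""Ground-truth properties of the synthetic phylome generator."""

import numpy as np
import pytest

from phylophase.dating import count_4d_substitutions
from phylophase.io import read_gene_loci
from phylophase.simulate import (
    SimulationConfig,
    corrupt,
    evolve_alignments,
    layout_genome,
    simulate_gene_trees,
    simulate_phylome,
    write_dataset,
)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_output(self, tmp_path):
        cfg = SimulationConfig(n_genes=25, rng_seed=42)
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_phylome(cfg), a)
        write_dataset(simulate_phylome(cfg), b)
        for name in ("trees.tsv", "taxonomy.tsv", "genes.gff3",
                     "scaffolds.tsv", "truth_genes.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()
        for fa in sorted((a / "alignments").glob("*.fasta")):
            assert fa.read_bytes() == (b / "alignments" / fa.name).read_bytes()


class TestGeneTrees:
    def test_noiseless_topology_is_species_history(self):
        cfg = SimulationConfig(n_genes=5, branch_noise_sd=0.0, orphan_prob=0.0,
                               rng_seed=1)
        trees, truth = simulate_gene_trees(cfg)
        for tree, origin in zip(trees, truth.genes.true_origin):
            # seed's closest leaf is its true parental species, and the
            # ladder order of increasing distances matches the split times
            dists = {g: tree.patristic(tree.seed_leaf, g)
                     for g in tree.leaf_ids() if g != tree.seed_leaf}
            nearest = min(dists, key=dists.get)
            assert nearest.startswith(cfg.species_of(origin))
            ladder = sorted(dists.values())
            assert dists[nearest] == ladder[0]
            # deepest split: the outermost section joining at 15 MyA
            assert max(dists.values()) == pytest.approx(
                2 * 15.0 * cfg.subs_per_mya)

    def test_seed_parental_distance_is_two_r_t(self):
        cfg = SimulationConfig(n_genes=20, branch_noise_sd=0.0,
                               orphan_prob=0.0, rng_seed=2)
        trees, truth = simulate_gene_trees(cfg)
        expected = 2 * cfg.rate * cfg.hybridization_time * 1e6
        for tree, origin in zip(trees, truth.genes.true_origin):
            parent_leaf = [g for g in tree.leaf_ids()
                           if g.startswith(cfg.species_of(origin))][0]
            assert tree.patristic(tree.seed_leaf, parent_leaf) == \
                pytest.approx(expected, rel=1e-9)

    def test_fractionation_bias_is_binomial(self):
        cfg = SimulationConfig(n_genes=10000, fractionation_bias=0.5,
                               rng_seed=3)
        _, truth = simulate_gene_trees(cfg)
        n_mat = (truth.genes.true_origin == cfg.maternal_section).sum()
        sd = np.sqrt(10000 * 0.5 * 0.5)
        assert abs(n_mat - 5000) <= 3 * sd

    def test_orphan_trees_lack_parental_leaves(self):
        cfg = SimulationConfig(n_genes=40, orphan_prob=1.0, rng_seed=4)
        trees, truth = simulate_gene_trees(cfg)
        parental = {cfg.species_of(cfg.maternal_section),
                    cfg.species_of(cfg.paternal_section)}
        for tree in trees:
            species = {tree.species_of(g) for g in tree.leaf_ids()}
            assert not species & parental
            assert tree.seed_leaf in tree.leaf_ids()


class TestSequenceEvolution:
    def _pair_stats(self, kappa, rng_seed=5, n_codons=4000,
                    hybridization_time=4.9):
        cfg = SimulationConfig(n_genes=1, n_codons=n_codons, kappa=kappa,
                               branch_noise_sd=0.0, orphan_prob=0.0,
                               rng_seed=rng_seed,
                               hybridization_time=hybridization_time)
        trees, truth = simulate_gene_trees(cfg)
        aln = evolve_alignments(trees[0], cfg)
        origin = truth.genes.true_origin.iloc[0]
        parent_leaf = [g for g in aln.ids
                       if g.startswith(cfg.species_of(origin))][0]
        return count_4d_substitutions(aln, trees[0].seed_leaf, parent_leaf)

    def test_equal_rates_give_two_thirds_transversions(self):
        """kappa=1: two of the three possible changes are transversions."""
        stats = self._pair_stats(kappa=1.0)
        subs = stats.ti + stats.tv
        se = np.sqrt((2 / 3) * (1 / 3) / subs)
        assert stats.fourdtv == pytest.approx(2 / 3, abs=3 * se)

    def test_extreme_kappa_suppresses_transversions(self):
        stats = self._pair_stats(kappa=1e6)
        assert stats.tv == 0 and stats.ti > 0

    def test_default_kappa_matches_closed_form(self):
        """Observed 4DTv tends to 2/(kappa+2) at small divergence."""
        stats = self._pair_stats(kappa=2.0)
        subs = stats.ti + stats.tv
        se = np.sqrt(0.5 * 0.5 / subs)
        assert stats.fourdtv == pytest.approx(2 / (2 + 2), abs=3 * se)

    def test_zero_length_branches_give_identical_sequences(self):
        cfg = SimulationConfig(n_genes=1, n_codons=200, rate=1e-30,
                               branch_noise_sd=0.0, rng_seed=6)
        trees, _ = simulate_gene_trees(cfg)
        aln = evolve_alignments(trees[0], cfg)
        seqs = {aln[g] for g in aln.ids}
        assert len(seqs) == 1

    def test_d4_clock_is_unbiased(self):
        """Pairwise d4 at 4D sites approximates 2 r T."""
        stats = self._pair_stats(kappa=2.0, n_codons=20000)
        expected = 2 * 5e-9 * 4.9e6
        se = np.sqrt(expected / stats.n_4d_sites)
        assert stats.d4 == pytest.approx(expected, abs=4 * se)


class TestGenomeLayout:
    def test_zero_switch_prob_gives_monomorphic_scaffolds(self):
        cfg = SimulationConfig(n_genes=300, switch_prob=0.0, rng_seed=7)
        _, truth = simulate_gene_trees(cfg)
        loci, _lengths = layout_genome(truth, cfg)
        origin = dict(zip(truth.genes.gene_id, truth.genes.true_origin))
        by_scaf = {}
        for l in loci:
            by_scaf.setdefault(l.scaffold_id, set()).add(origin[l.gene_id])
        assert all(len(s) == 1 for s in by_scaf.values())

    def test_every_gene_placed_exactly_once(self):
        cfg = SimulationConfig(n_genes=120, rng_seed=8)
        _, truth = simulate_gene_trees(cfg)
        loci, lengths = layout_genome(truth, cfg)
        assert sorted(l.gene_id for l in loci) == \
            sorted(truth.genes.gene_id)
        for l in loci:
            assert 1 <= l.start <= l.end <= lengths[l.scaffold_id]

    def test_emitted_gff_reproduces_ranks(self, tmp_path):
        synth = simulate_phylome(SimulationConfig(n_genes=60, rng_seed=9))
        write_dataset(synth, tmp_path)
        loci = read_gene_loci((tmp_path / "genes.gff3").read_text())
        emitted = {(l.gene_id, l.scaffold_id, l.rank) for l in synth.loci}
        reread = {(l.gene_id, l.scaffold_id, l.rank) for l in loci}
        assert emitted == reread


class TestCorrupt:
    def test_reaches_target_n_fraction(self):
        synth = simulate_phylome(SimulationConfig(n_genes=2, rng_seed=10))
        tree = synth.dataset.trees[0]
        aln = synth.dataset.alignments[tree.tree_id]
        rng = np.random.default_rng(0)
        out = corrupt(aln, tree.seed_leaf, 0.05, rng)
        assert out.n_fraction(tree.seed_leaf) == pytest.approx(0.05, abs=0.01)
        assert aln.n_fraction(tree.seed_leaf) == 0.0  # input untouched
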