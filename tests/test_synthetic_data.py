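"""The ground-truthed alignment generator."""
import filecmp
import json

import numpy as np
import pytest

from phylocons.alignment_io import GenomeAlignment
from phylocons.neutral_model import NeutralModel, compress_patterns, \
    fit_class_scale
from phylocons.phylo_core import (MISSING, SubstitutionModel,
                                  site_log_likelihoods, total_branch_length)
from phylocons.synthetic_data import (ChromosomeSpec, SimulationConfig,
                                      emit_fixture_bundle, simulate_alignment,
                                      simulate_columns, simulate_tree)

SMALL = dict(
    n_taxa=10, total_branch_length=4.0,
    chromosomes=[ChromosomeSpec("macro1", 12000, "macro"),
                 ChromosomeSpec("micro1", 8000, "micro"),
                 ChromosomeSpec("sexZ", 6000, "sex")],
    missing_row_prob=0.1)


class TestSimulateTree:
    def test_total_branch_length_matches_target(self):
        for target in (4.3, 9.9, 16.5):
            t = simulate_tree(20, target, seed=3)
            assert total_branch_length(t) == pytest.approx(target, abs=1e-9)

    def test_deterministic_under_seed(self):
        a = simulate_tree(15, 5.0, seed=11)
        b = simulate_tree(15, 5.0, seed=11)
        assert a.to_newick() == b.to_newick()
        assert a.to_newick() != simulate_tree(15, 5.0, seed=12).to_newick()

    def test_leaf_and_ancestor_labels(self):
        t = simulate_tree(8, 2.0, seed=0)
        assert "ref" in t.leaf_labels and len(t.leaf_labels) == 8
        internals = [t.labels[i] for i in range(t.n_nodes) if not t.is_leaf(i)]
        assert all(lbl and lbl.startswith("anc") for lbl in internals)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 1.0, seed=0)


class TestSimulateColumns:
    def test_two_leaf_jc_difference_fraction(self, jc, rng):
        """Empirical substitution fraction on a two-leaf JC tree matches the
        closed form 3/4 (1 - exp(-4t/3))."""
        from phylocons.phylo_core import PhyloTree
        t = 0.2
        tree = PhyloTree.from_newick(f"(A:{t / 2},B:{t / 2});")
        X = simulate_columns(tree, jc, 40_000, rng=rng)
        p_hat = (X[:, 0] != X[:, 1]).mean()
        expected = 0.75 * (1 - np.exp(-4 * t / 3))
        assert p_hat == pytest.approx(expected, abs=0.006)

    def test_rate_zero_columns_identical(self, jc, rng):
        tree = simulate_tree(12, 8.0, rng)
        X = simulate_columns(tree, jc, 500, scale=0.0, rng=rng)
        assert np.all(X == X[:, :1])

    def test_stationary_base_composition(self, gtr, rng):
        tree = simulate_tree(6, 3.0, rng)
        X = simulate_columns(tree, gtr, 30_000, rng=rng)
        freq = np.bincount(X.ravel(), minlength=4) / X.size
        np.testing.assert_allclose(freq, gtr.frequencies, atol=0.01)


@pytest.fixture(scope="module")
def bundle():
    cfg = SimulationConfig(**SMALL)
    rng = np.random.default_rng(23)
    tree = simulate_tree(cfg.n_taxa, cfg.total_branch_length, rng)
    blocks, truth = simulate_alignment(tree, cfg, rng)
    return cfg, tree, blocks, truth


class TestSimulateAlignment:
    def test_truth_intervals_inside_chromosomes(self, bundle):
        cfg, _, _, truth = bundle
        sizes = {c.name: c.length for c in cfg.chromosomes}
        sizes[cfg.lineage_chrom] = cfg.lineage_chrom_length
        for e in truth.elements:
            assert 0 <= e["start"] < e["end"] <= sizes[e["chrom"]]
        for chrom, s, e in truth.repeats:
            assert 0 <= s < e <= sizes[chrom]

    def test_planted_elements_do_not_overlap(self, bundle):
        _, _, _, truth = bundle
        by_chrom = {}
        for e in truth.elements:
            by_chrom.setdefault(e["chrom"], []).append((e["start"], e["end"]))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_reference_never_dropped(self, bundle):
        cfg, _, blocks, _ = bundle
        for b in blocks:
            chrom = b.rows[0].chrom
            if chrom == cfg.lineage_chrom:
                continue  # clade-private regions legitimately lack ref
            assert "ref" in b.genomes()

    def test_ancestor_rows_present(self, bundle):
        _, tree, blocks, _ = bundle
        genomes = set()
        for b in blocks:
            genomes.update(b.genomes())
        internal = {tree.labels[i] for i in range(tree.n_nodes)
                    if not tree.is_leaf(i)}
        assert internal <= genomes

    def test_scenarios_disabled_leave_no_gene_events(self, rng):
        cfg = SimulationConfig(**SMALL, duplication=False, retrocopy=False,
                               insertion=False, genes=False)
        tree = simulate_tree(cfg.n_taxa, cfg.total_branch_length, rng)
        _, truth = simulate_alignment(tree, cfg, rng)
        assert truth.duplications == [] and truth.retrocopies == []
        assert truth.insertions == [] and truth.genes == []

    def test_rate_zero_elements_are_invariant_columns(self, rng):
        cfg = SimulationConfig(
            n_taxa=8, total_branch_length=6.0,
            chromosomes=[ChromosomeSpec("macro1", 4000, "macro")],
            conserved_rate=0.0, conserved_fraction=0.2, genes=False,
            lncrna_fraction=0, motif_fraction=0, accelerated_fraction=0,
            missing_row_prob=0.0, include_ancestors=False,
            duplication=False, retrocopy=False, insertion=False,
            class_scales={"macro": 1.0, "micro": 1.0, "sex": 1.0})
        tree = simulate_tree(cfg.n_taxa, cfg.total_branch_length, rng)
        blocks, truth = simulate_alignment(tree, cfg, rng)
        aln = GenomeAlignment.from_blocks(blocks, reference="ref")
        pos, X = aln.chroms["macro1"]
        planted = truth.element_positions("conserved", "macro1")
        inside = np.isin(pos, planted)
        assert inside.any()
        assert np.all(X[inside] == X[inside][:, :1])

    def test_class_scales_recovered_from_neutral_background(self):
        """Round trip: per-class neutral columns refit the configured class
        scale factors."""
        cfg = SimulationConfig(**{**SMALL, "genes": False,
                                  "duplication": False, "retrocopy": False,
                                  "insertion": False,
                                  "missing_row_prob": 0.0})
        rng = np.random.default_rng(31)
        tree = simulate_tree(cfg.n_taxa, cfg.total_branch_length, rng)
        blocks, truth = simulate_alignment(tree, cfg, rng)
        aln = GenomeAlignment.from_blocks(blocks, reference="ref")
        base = NeutralModel(tree, cfg.substitution_model())
        for spec in cfg.chromosomes:
            pos, X = aln.chroms[spec.name]
            # ancestral repeats label the guaranteed-neutral background
            ar = np.concatenate([np.arange(s, e) for c, s, e in truth.repeats
                                 if c == spec.name])
            neutral = np.isin(pos, ar)
            assert neutral.sum() > 500
            Xt = np.full((int(neutral.sum()), len(tree.leaf_labels)),
                         MISSING, dtype=np.int8)
            for k, leaf in enumerate(tree.leaf_labels):
                Xt[:, k] = X[neutral][:, aln.genomes.index(leaf)]
            scale = fit_class_scale(Xt, base)
            assert scale == pytest.approx(cfg.class_scales[spec.klass],
                                          abs=0.08)

    def test_likelihood_prefers_true_model(self, bundle):
        """Average column log-likelihood under the generating model exceeds
        that under rate-perturbed models."""
        cfg, tree, blocks, truth = bundle
        model = cfg.substitution_model()
        aln = GenomeAlignment.from_blocks(blocks, reference="ref")
        pos, X = aln.chroms["macro1"]
        ar = np.concatenate([np.arange(s, e) for c, s, e in truth.repeats
                             if c == "macro1"])
        keep = np.isin(pos, ar)  # neutral background only
        Xt = np.full((int(keep.sum()), len(tree.leaf_labels)), MISSING,
                     dtype=np.int8)
        for k, leaf in enumerate(tree.leaf_labels):
            Xt[:, k] = X[keep][:, aln.genomes.index(leaf)]
        ll_true = site_log_likelihoods(tree, model, Xt).mean()
        for s in (0.6, 1.7):
            assert ll_true > site_log_likelihoods(tree, model, Xt,
                                                  scale=s).mean()


class TestFixtureBundle:
    CFG = dict(n_taxa=8, total_branch_length=3.0,
               chromosomes=[ChromosomeSpec("macro1", 6000, "macro"),
                            ChromosomeSpec("micro1", 4000, "micro")],
               missing_row_prob=0.05)

    def test_bundle_regeneration_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(**self.CFG)
        emit_fixture_bundle(cfg, tmp_path / "a", seed=5)
        emit_fixture_bundle(cfg, tmp_path / "b", seed=5)
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert "alignment.maf" in names and "truth.json" in names
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert mismatch == [] and errors == []

    def test_bundle_files_are_consistent(self, tmp_path):
        from phylocons.alignment_io import read_maf
        from phylocons.phylo_core import PhyloTree
        cfg = SimulationConfig(**self.CFG)
        out = emit_fixture_bundle(cfg, tmp_path / "fix", seed=9)
        tree = PhyloTree.from_newick((tmp_path / "fix/tree.nwk").read_text())
        assert sorted(tree.leaf_labels) == sorted(out["tree"].leaf_labels)
        with open(tmp_path / "fix/alignment.maf") as fh:
            blocks = list(read_maf(fh))
        assert len(blocks) == len(out["blocks"])
        truth = json.loads((tmp_path / "fix/truth.json").read_text())
        assert truth["seed"] == 9
        classes = dict(
            line.split("\t") for line in
            (tmp_path / "fix/classes.tsv").read_text().splitlines())
        assert classes["macro1"] == "macro"

    def test_config_round_trip(self):
        cfg = SimulationConfig(**self.CFG)
        again = SimulationConfig.from_dict(
            json.loads(json.dumps(cfg.to_dict())))
        assert again.to_dict() == cfg.to_dict()
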