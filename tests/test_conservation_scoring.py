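"""CONACC scoring: rate fits, LRT p-values, track construction."""
import numpy as np
import pytest

from phylocons.alignment_io import GenomeAlignment
from phylocons.conservation_scoring import (column_rate_distribution,
                                            conacc_score, fit_column_scale,
                                            score_genome, write_wiggle,
                                            _score_matrix)
from phylocons.neutral_model import NeutralModel, ThreeRateModel
from phylocons.phylo_core import (PhyloTree, SubstitutionModel,
                                  encode_columns, fit_column_scales,
                                  site_log_likelihoods)
from phylocons.synthetic_data import (ChromosomeSpec, SimulationConfig,
                                      simulate_alignment, simulate_columns,
                                      simulate_tree)


def star_tree(n, bl):
    inner = ",".join(f"L{i}:{bl}" for i in range(n))
    return PhyloTree.from_newick(f"({inner});")


class TestConaccScore:
    def test_uninformative_column_unscored(self, four_leaf_tree, jc):
        assert conacc_score(four_leaf_tree, jc, {"A": "A", "B": "N"}) is None
        assert fit_column_scale(four_leaf_tree, jc, {"A": "A"}) is None

    def test_identical_column_is_conserved(self, four_leaf_tree, jc):
        s = conacc_score(four_leaf_tree, jc, {g: "A" for g in "ABCD"})
        assert s.rhat == 0.0
        assert s.lrt > 0 and s.score > 0 and 0 < s.pvalue < 1

    def test_star_tree_closed_form_lrt(self, jc):
        """Fully conserved column on a 4-leaf JC star: the LRT equals
        2*(log P(no change | r=0) - log P(no change | r=1)), both sides
        computable from the JC closed form."""
        tree = star_tree(4, 0.5)
        s = conacc_score(tree, jc, {f"L{i}": "A" for i in range(4)})
        # r=0: the column is certain given the root base -> loglik log(1/4)
        ll0 = np.log(0.25)
        # r=1: sum over root states of prod of JC transitions to 'A'
        p_same = 0.25 + 0.75 * np.exp(-4 * 0.5 / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * 0.5 / 3)
        lik1 = 0.25 * p_same ** 4 + 3 * 0.25 * p_diff ** 4
        expected = 2 * (ll0 - np.log(lik1))
        assert s.rhat == 0.0
        assert s.lrt == pytest.approx(expected, abs=1e-6)

    def test_score_sign_tracks_direction(self, jc):
        tree = star_tree(6, 0.1)
        conserved = conacc_score(tree, jc, {f"L{i}": "A" for i in range(6)})
        scrambled = conacc_score(
            tree, jc, dict(zip((f"L{i}" for i in range(6)), "ACGTAC")))
        assert conserved.score > 0 and conserved.rhat < 1
        assert scrambled.score < 0 and scrambled.rhat > 1

    def test_sign_invariants_on_random_columns(self, four_leaf_tree, gtr, rng):
        for _ in range(50):
            col = {g: rng.choice(list("ACGTN")) for g in "ABCD"}
            s = conacc_score(four_leaf_tree, gtr, col)
            if s is None:
                continue
            assert s.lrt >= 0
            if s.score > 0:
                assert s.rhat < 1
            elif s.score < 0:
                assert s.rhat > 1
            if s.pvalue == 1.0:
                assert s.score == 0.0


class TestFitAgainstGrid:
    def test_optimizer_matches_dense_grid(self, rng):
        """The vectorized fit agrees with a dense grid over [0, 10]."""
        tree = simulate_tree(8, 3.0, rng)
        model = SubstitutionModel((0.3, 0.2, 0.2, 0.3), (1, 4, 1, 1, 4, 1))
        X = simulate_columns(tree, model, 100, rng=rng)
        rhat, _ = fit_column_scales(tree, model, X)
        grid = np.linspace(0, 10, 5001)
        lls = np.stack([site_log_likelihoods(tree, model, X, scale=float(g))
                        for g in grid])
        g_best = grid[np.argmax(lls, axis=0)]
        assert np.max(np.abs(rhat - g_best)) <= 2e-3 + 1e-9

    def test_neutral_columns_fit_near_one(self, rng):
        tree = simulate_tree(60, 16.5, rng)
        model = SubstitutionModel((0.3, 0.2, 0.2, 0.3), (1, 4, 1, 1, 4, 1))
        X = simulate_columns(tree, model, 10_000, rng=rng)
        rhat, _ = fit_column_scales(tree, model, X)
        assert np.mean(rhat) == pytest.approx(1.0, abs=0.1)

    def test_null_pvalues_not_badly_anticonservative(self, rng):
        """Fraction of null columns with p < 0.05 stays below 0.06."""
        tree = simulate_tree(40, 16.5, rng)
        model = SubstitutionModel((0.3, 0.2, 0.2, 0.3), (1, 4, 1, 1, 4, 1))
        X = simulate_columns(tree, model, 10_000, rng=rng)
        res = _score_matrix(tree, model, X)
        assert (res["pvalue"] < 0.05).mean() <= 0.06

    def test_reparameterization_identity(self, rng):
        """Scoring under a class model with scale s fits multipliers that
        equal the base-model multipliers divided by s."""
        tree = simulate_tree(10, 5.0, rng)
        model = SubstitutionModel((0.3, 0.2, 0.2, 0.3), (1, 4, 1, 1, 4, 1))
        X = simulate_columns(tree, model, 300, rng=rng)
        s = 1.6
        scaled = tree.rescaled(s)
        r_base, _ = fit_column_scales(tree, model, X)
        r_class, ll_class = fit_column_scales(scaled, model, X)
        # where the multiplier is identified the identity holds pointwise
        keep = (r_base > 0.05) & (r_base < 2.5)
        assert keep.sum() > 50
        np.testing.assert_allclose(r_class[keep], r_base[keep] / s, atol=2e-3)
        # saturated columns sit on a likelihood plateau: the fits are only
        # equivalent in likelihood, not in the multiplier itself
        ll_at_mapped = site_log_likelihoods(scaled, model, X, scale=r_base / s)
        assert np.all(ll_class >= ll_at_mapped - 1e-6)


@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(99)
    cfg = SimulationConfig(
        n_taxa=20, total_branch_length=16.5,
        chromosomes=[ChromosomeSpec("chr1", 6000, "macro"),
                     ChromosomeSpec("chr20", 4000, "micro")],
        genes=False, lncrna_fraction=0, motif_fraction=0,
        conserved_fraction=0.15, conserved_rate=0.2,
        accelerated_fraction=0.0, missing_row_prob=0.02,
        include_ancestors=False, duplication=False, retrocopy=False,
        insertion=False)
    tree = simulate_tree(cfg.n_taxa, cfg.total_branch_length, rng)
    blocks, truth = simulate_alignment(tree, cfg, rng)
    aln = GenomeAlignment.from_blocks(blocks, reference="ref")
    base = NeutralModel(tree, cfg.substitution_model())
    return aln, base, truth, cfg


class TestScoreGenome:
    def test_deterministic(self, small_genome):
        aln, base, truth, _ = small_genome
        t1 = score_genome(aln, base)
        t2 = score_genome(aln, base)
        for chrom in t1.frames:
            np.testing.assert_array_equal(t1.frames[chrom]["score"],
                                          t2.frames[chrom]["score"])

    def test_covers_every_scorable_base(self, small_genome):
        aln, base, _, _ = small_genome
        track = score_genome(aln, base)
        assert track.n_scored() == aln.n_positions()  # all informative here

    def test_planted_elements_score_higher(self, small_genome):
        aln, base, truth, _ = small_genome
        track = score_genome(aln, base)
        df = track.frames["chr1"]
        planted = truth.element_positions("conserved", "chr1")
        in_el = df["pos"].isin(planted).to_numpy()
        assert df["score"][in_el].mean() > df["score"][~in_el].mean() + 1.0

    def test_three_rate_requires_class_map(self, small_genome):
        aln, base, _, _ = small_genome
        trm = ThreeRateModel(base, {"macro": 1.0, "micro": 0.9, "sex": 1.16})
        with pytest.raises(ValueError, match="unclassified"):
            score_genome(aln, trm, class_map={"chr1": "macro"})
        track = score_genome(aln, trm,
                             class_map={"chr1": "macro", "chr20": "micro"})
        assert set(track.frames) == {"chr1", "chr20"}

    def test_wiggle_output_format(self, small_genome, tmp_path):
        aln, base, _, _ = small_genome
        track = score_genome(aln, base)
        path = tmp_path / "scores.wig"
        write_wiggle(track, path)
        lines = path.read_text().splitlines()
        headers = [l for l in lines if l.startswith("fixedStep")]
        assert headers and "start=1" in headers[0]  # wiggle is 1-based
        values = [l for l in lines if not l.startswith("fixedStep")]
        assert len(values) == track.n_scored()
        assert all("." in v for v in values[:10])  # 4-decimal fixed point


class TestColumnRateDistribution:
    def test_deterministic_and_mode_near_one(self, small_genome):
        aln, base, _, _ = small_genome
        table, counts, edges = column_rate_distribution(aln, base, 800, seed=3)
        table2, counts2, _ = column_rate_distribution(aln, base, 800, seed=3)
        np.testing.assert_array_equal(counts, counts2)
        assert len(table) == 800

    def test_bimodal_when_half_conserved(self, rng):
        """A genome that is half planted at r=0.3 gives a rate histogram
        with local modes near 0.3 and 1.0."""
        cfg = SimulationConfig(
            n_taxa=30, total_branch_length=16.5,
            chromosomes=[ChromosomeSpec("chr1", 4000, "macro")],
            genes=False, lncrna_fraction=0, motif_fraction=0,
            conserved_fraction=0.5, conserved_rate=0.3,
            accelerated_fraction=0.0, missing_row_prob=0.0,
            include_ancestors=False, duplication=False, retrocopy=False,
            insertion=False)
        tree = simulate_tree(cfg.n_taxa, cfg.total_branch_length, rng)
        blocks, _ = simulate_alignment(tree, cfg, rng)
        aln = GenomeAlignment.from_blocks(blocks, reference="ref")
        base = NeutralModel(tree, cfg.substitution_model())
        bins = np.linspace(0, 2, 21)  # 0.1-wide bins
        _, counts, edges = column_rate_distribution(aln, base, 2000, seed=1,
                                                    bins=bins)
        lo = counts[(edges[:-1] >= 0.2) & (edges[:-1] < 0.4)].sum()
        hi = counts[(edges[:-1] >= 0.9) & (edges[:-1] < 1.1)].sum()
        mid = counts[(edges[:-1] >= 0.6) & (edges[:-1] < 0.7)].sum()
        assert lo > mid and hi > mid
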