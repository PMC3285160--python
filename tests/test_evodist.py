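"""Distances, neighbor joining and mirror-tree correlation."""

import numpy as np
import pytest

from coatmap.conservation import Msa
from coatmap.evodist import (
    DistanceMatrix,
    correlation_significance,
    distance_matrix,
    matrix_correlation,
    nj_tree,
    pairwise_distance,
)
from coatmap.synthetic import EvolutionScenario, generate_mirror_pair, simulate_family


class TestPairwiseDistance:
    def test_identical_sequences_distance_zero(self):
        assert pairwise_distance("ACDEF", "ACDEF") == (0.0, False)

    def test_poisson_closed_form_at_p01(self):
        # 1 difference in 10 comparable columns
        d, sat = pairwise_distance("AAAAAAAAAA", "AAAAAAAAAC")
        assert not sat
        assert d == pytest.approx(0.10536, abs=5e-6)

    def test_gamma_limits_to_poisson_for_large_alpha(self):
        seq_a, seq_b = "AAAAAAAAAA", "AAAAAAAAAC"
        d_poisson, _ = pairwise_distance(seq_a, seq_b, model="poisson")
        d_gamma, _ = pairwise_distance(seq_a, seq_b, model="gamma", alpha=1e6)
        assert abs(d_gamma - d_poisson) < 1e-3

    def test_gamma_closed_form(self):
        d, _ = pairwise_distance("AAAAAAAAAA", "AAAAAAAAAC", model="gamma", alpha=2.0)
        assert d == pytest.approx(2.0 * ((0.9) ** (-0.5) - 1.0), rel=1e-9)

    def test_saturation_caps_distance_with_flag(self):
        d, sat = pairwise_distance("AAAA", "CCCC")
        assert sat and d == 10.0

    def test_gaps_excluded_from_comparable_columns(self):
        d, _ = pairwise_distance("AA--AAAAAAAA", "AC--AAAAAAAA")
        assert d == pytest.approx(-np.log(1 - 0.1))

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("AA--", "--AA")


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        msa = Msa(species=["a", "b", "c"], sequences=["ACDE"] * 3)
        m = distance_matrix(msa)
        np.testing.assert_array_equal(m.values, 0.0)

    def test_error_names_the_offending_pair(self):
        msa = Msa(species=["a", "b", "c"],
                  sequences=["AC--", "ACAA", "--AA"])
        with pytest.raises(ValueError, match=r"\(a, c\)"):
            distance_matrix(msa)

    def test_estimates_track_true_path_lengths(self):
        fam = simulate_family(EvolutionScenario(n_taxa=12, n_sites=1000, seed=4))
        est = distance_matrix(fam.msa)
        from coatmap.evodist import PhyloTree

        true = PhyloTree(newick=fam.tree_newick).path_distance_matrix()
        est = est.restrict(true.species)
        r = np.corrcoef(est.upper_triangle(), true.upper_triangle())[0, 1]
        assert r > 0.9

    def test_phylip_roundtrip(self, tmp_path):
        m = DistanceMatrix(species=["a", "b", "c"],
                           values=np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        path = tmp_path / "m.phy"
        m.write_phylip(path)
        back = DistanceMatrix.read_phylip(path)
        assert back.species == m.species
        np.testing.assert_allclose(back.values, m.values)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        m = DistanceMatrix(species=["a", "b", "c"],
                           values=np.array([[0, d_ab, d_ac],
                                            [d_ab, 0, d_bc],
                                            [d_ac, 0.8, 0.0]]))
        tree = nj_tree(m)
        pdm = tree.path_distance_matrix()
        expect = {("a", "b"): d_ab, ("a", "c"): d_ac, ("b", "c"): d_bc}
        for (x, y), d in expect.items():
            i, j = pdm.species.index(x), pdm.species.index(y)
            assert pdm.values[i, j] == pytest.approx(d, abs=1e-5)

    def test_additive_matrix_recovered_exactly(self):
        # known 5-taxon additive tree -> NJ must reproduce all path lengths
        newick = "((a:0.10,b:0.20):0.05,(c:0.30,d:0.15):0.07,e:0.25);"
        from coatmap.evodist import PhyloTree

        true = PhyloTree(newick=newick).path_distance_matrix()
        tree = nj_tree(true)
        recovered = tree.path_distance_matrix()
        assert recovered.species == true.species
        np.testing.assert_allclose(recovered.values, true.values, atol=1e-5)
        assert tree.clamped_negative == 0

    def test_agrees_with_dendropy_nj_topology(self):
        import dendropy

        newick = "((a:0.11,b:0.23):0.04,((c:0.31,d:0.14):0.09,e:0.27):0.06,f:0.19);"
        from coatmap.evodist import PhyloTree

        true = PhyloTree(newick=newick).path_distance_matrix()
        mine = nj_tree(true).to_dendropy()

        pdm_src = "\n".join(
            [str(len(true.species))]
            + [
                "  ".join([sp] + [f"{v:.6f}" for v in row])
                for sp, row in zip(true.species, true.values)
            ]
        )
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(
                ","
                + ",".join(true.species)
                + "\n"
                + "\n".join(
                    sp + "," + ",".join(f"{v:.6f}" for v in row)
                    for sp, row in zip(true.species, true.values)
                )
            ),
            delimiter=",",
        )
        ref = pdm.nj_tree()
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=ref.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_equidistant_matrix_uses_tie_break_and_flags(self):
        m = DistanceMatrix(species=list("abcd"),
                           values=np.ones((4, 4)) - np.eye(4))
        tree = nj_tree(m)
        assert tree.tied_joins >= 1
        assert "a" in tree.newick  # deterministic output exists

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(species=["a", "b"], values=bad)


class TestMirrorCorrelation:
    def random_matrix(self, n, seed, labels=None):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 1.0, size=(n, n))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0.0)
        return DistanceMatrix(species=labels or [f"t{i}" for i in range(n)], values=m)

    def test_self_correlation_is_one(self):
        m = self.random_matrix(8, 0)
        assert matrix_correlation(m, m).r == pytest.approx(1.0)

    def test_affine_invariance(self):
        m = self.random_matrix(8, 1)
        scaled = DistanceMatrix(species=m.species, values=2.0 * m.values + 0.3
                                * (1 - np.eye(8)))
        assert matrix_correlation(m, scaled).r == pytest.approx(1.0)

    def test_three_species_anticorrelated_hand_value(self):
        a = DistanceMatrix(species=list("xyz"),
                           values=np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        b = DistanceMatrix(species=list("xyz"),
                           values=np.array([[0, 3, 2], [3, 0, 1], [2, 1, 0.0]]))
        res = matrix_correlation(a, b, min_species=3)
        assert res.r == pytest.approx(-1.0)

    def test_too_few_common_species_is_an_error(self):
        a = self.random_matrix(4, 2, labels=["a", "b", "c", "d"])
        b = self.random_matrix(4, 3, labels=["c", "d", "e", "f"])
        with pytest.raises(ValueError, match="common species"):
            matrix_correlation(a, b)

    def test_self_permutation_p_is_minimal(self):
        m = self.random_matrix(10, 4)
        res = correlation_significance(m, m, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_n_perm_floor(self):
        m = self.random_matrix(6, 5)
        with pytest.raises(ValueError, match="99"):
            correlation_significance(m, m, n_perm=10)

    def test_shared_tree_pairs_beat_independent_pairs(self):
        shared, independent = [], []
        for seed in range(8):
            fa, fb = generate_mirror_pair(
                EvolutionScenario(n_taxa=16, n_sites=500, shared_tree=True, seed=seed))
            shared.append(matrix_correlation(distance_matrix(fa.msa),
                                             distance_matrix(fb.msa)).r)
            fa, fb = generate_mirror_pair(
                EvolutionScenario(n_taxa=16, n_sites=500, shared_tree=False, seed=seed))
            independent.append(matrix_correlation(distance_matrix(fa.msa),
                                                  distance_matrix(fb.msa)).r)
        assert np.median(shared) - np.median(independent) >= 0.3
        assert min(shared) > max(independent)
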