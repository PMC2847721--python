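"""GeNorm stability: pairwise variation, M, stepwise exclusion, NF."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from earnorm import (GeneSpec, InsufficientDataError, SimulationConfig,
                     ValidationError, normalization_factor, pairwise_variation,
                     quantities_wide, quantity_table, simulate_experiment,
                     stability_m, stepwise_ranking)


def brute_force_m(quantities: pd.DataFrame) -> pd.Series:
    """Independent oracle: M_j as an explicit loop over all gene pairs."""
    genes = list(quantities.columns)
    out = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = np.log2(quantities[j].to_numpy() / quantities[k].to_numpy())
            vs.append(np.std(ratios, ddof=1))
        out[j] = float(np.mean(vs))
    return pd.Series(out)


class TestPairwiseVariation:
    def test_identical_genes_have_zero_variation(self):
        q = pd.Series([0.3, 0.7, 1.0, 0.5, 0.9], index=list("abcde"))
        assert pairwise_variation(q, q) == 0.0

    def test_proportional_genes_have_zero_variation(self):
        q = pd.Series([0.3, 0.7, 1.0], index=list("abc"))
        assert pairwise_variation(q, 0.37 * q) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_sample_case(self):
        # log2 ratios {0, 1}; sd with n-1 denominator = 1/sqrt(2)
        v = pairwise_variation(pd.Series({"a": 1.0, "b": 2.0}),
                               pd.Series({"a": 1.0, "b": 1.0}))
        assert v == pytest.approx(0.70710678, abs=1e-8)

    def test_single_sample_insufficient(self):
        with pytest.raises(InsufficientDataError):
            pairwise_variation(pd.Series({"a": 1.0}), pd.Series({"a": 1.0}))

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_variation(pd.Series({"a": 1.0, "b": 1.0}),
                               pd.Series({"a": 1.0, "c": 1.0}))


class TestStabilityM:
    def test_proportional_genes_all_zero(self):
        base = pd.Series([0.2, 0.5, 1.0, 0.8])
        q = pd.DataFrame({"g1": base, "g2": 2 * base, "g3": 0.5 * base})
        assert np.allclose(stability_m(q), 0.0)

    def test_matches_brute_force_on_hand_sized_matrix(self, rng):
        q = pd.DataFrame(np.exp(rng.normal(0, 1, size=(3, 3))),
                         index=list("abc"), columns=["g1", "g2", "g3"])
        pd.testing.assert_series_equal(stability_m(q), brute_force_m(q),
                                       check_names=False, atol=1e-12, rtol=0)

    def test_matches_brute_force_on_200_random_matrices(self, rng):
        """Oracle equivalence on matrices up to 6 genes x 8 samples."""
        for _ in range(200):
            n_genes = rng.integers(3, 7)
            n_samples = rng.integers(2, 9)
            q = pd.DataFrame(
                np.exp(rng.normal(0, 1, size=(n_samples, n_genes))),
                columns=[f"g{i}" for i in range(n_genes)])
            m = stability_m(q)
            oracle = brute_force_m(q)
            assert np.max(np.abs(m.to_numpy() - oracle.to_numpy())) < 1e-12

    def test_noisiest_gene_has_largest_m(self, rng):
        n = 12
        q = pd.DataFrame({
            "quiet1": np.exp(rng.normal(0, 0.05, n)),
            "quiet2": np.exp(rng.normal(0, 0.05, n)),
            "noisy": np.exp(rng.normal(0, 0.8, n)),
        })
        m = stability_m(q)
        assert m["noisy"] > m["quiet1"] and m["noisy"] > m["quiet2"]

    def test_two_genes_unresolvable(self):
        q = pd.DataFrame({"g1": [1.0, 2.0], "g2": [1.0, 1.0]})
        with pytest.raises(InsufficientDataError, match="unresolvable"):
            stability_m(q)

    def test_scale_invariance_of_m(self, rng):
        """Multiplying one gene's Q by a constant changes no M value."""
        q = pd.DataFrame(np.exp(rng.normal(0, 0.5, size=(6, 4))),
                         columns=list("wxyz"))
        m0 = stability_m(q)
        q2 = q.copy()
        q2["x"] = q2["x"] * 17.3
        assert np.allclose(stability_m(q2).to_numpy(), m0.to_numpy())

    def test_sample_permutation_invariance(self, rng):
        q = pd.DataFrame(np.exp(rng.normal(0, 0.5, size=(7, 4))),
                         columns=list("wxyz"))
        m0 = stability_m(q)
        perm = q.sample(frac=1.0, random_state=3)
        assert np.allclose(stability_m(perm).to_numpy(), m0.to_numpy())


class TestStepwiseRanking:
    def test_blood_panel_ordering_recovered_from_noise_classes(self):
        """Unstable genes exit in noise order; the low-noise trio survives.

        The simulated panel gives ACTB the most biological noise, then
        GAPDH, then B2M, with GNB2L1/HPRT1/YWHAZ quiet — so stepwise
        exclusion should remove ACTB, GAPDH, B2M first and select the
        quiet trio as references.
        """
        table, _ = simulate_experiment(SimulationConfig(seed=1))
        wide = quantities_wide(quantity_table(table))
        panel = [g for g in wide.columns if g not in ("BDNF", "EAR")]
        report = stepwise_ranking(wide, panel)
        assert report.exclusion_order[:3] == ["ACTB", "GAPDH", "B2M"]
        assert set(report.selected_references) == {"GNB2L1", "HPRT1", "YWHAZ"}
        assert all(report.last_evaluated_m[g] < 0.5
                   for g in report.selected_references)

    def test_proportional_genes_tie_broken_lexicographically(self):
        base = pd.Series([0.2, 0.5, 1.0, 0.8])
        q = pd.DataFrame({"b": base, "c": 2 * base, "a": 0.5 * base})
        report = stepwise_ranking(q)
        assert report.exclusion_order == ["a"]       # all M = 0, lexicographic
        assert report.final_pair == ("b", "c")
        assert set(report.selected_references) == {"a", "b", "c"}
        assert report.tie_notes                       # tie recorded

    def test_final_pair_is_rank_tied_and_sorted(self, rng):
        q = pd.DataFrame(np.exp(rng.normal(0, 0.3, size=(8, 4))),
                         columns=["d", "b", "c", "a"])
        report = stepwise_ranking(q)
        assert report.final_pair == tuple(sorted(report.final_pair))
        assert set(report.ranking) == {"a", "b", "c", "d"}

    def test_each_round_removes_exactly_one_gene(self, rng):
        q = pd.DataFrame(np.exp(rng.normal(0, 0.3, size=(10, 6))),
                         columns=list("abcdef"))
        report = stepwise_ranking(q)
        sizes = [len(r.remaining_genes) for r in report.rounds]
        assert sizes == [6, 5, 4, 3]
        assert len(report.exclusion_order) == 4

    def test_random_walk_gene_excluded_first(self):
        """A gene independent of the shared signal exits round one (>=95/100)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 10
            loading = np.exp(rng.normal(0, 0.5, n))
            q = pd.DataFrame({
                "g1": loading * np.exp(rng.normal(0, 0.05, n)),
                "g2": loading * np.exp(rng.normal(0, 0.05, n)),
                "g3": loading * np.exp(rng.normal(0, 0.05, n)),
                "wanderer": np.exp(np.cumsum(rng.normal(0, 0.5, n))),
            })
            q = q / q.max(axis=0)
            if stepwise_ranking(q).exclusion_order[0] == "wanderer":
                hits += 1
        assert hits >= 95

    def test_fewer_than_three_genes_rejected(self):
        q = pd.DataFrame({"g1": [1.0, 2.0], "g2": [1.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            stepwise_ranking(q)


class TestNormalizationFactor:
    def test_unit_quantities_give_unit_nf(self):
        q = pd.DataFrame({"g1": [1.0], "g2": [1.0], "g3": [1.0]})
        assert normalization_factor(q, ["g1", "g2", "g3"]).iloc[0] == 1.0

    def test_geometric_mean_of_2_4_8_is_4(self):
        q = pd.DataFrame({"g1": [2.0], "g2": [4.0], "g3": [8.0]})
        assert normalization_factor(q, ["g1", "g2", "g3"]).iloc[0] == pytest.approx(4.0)

    def test_direct_evaluation_case(self):
        q = pd.DataFrame({"g1": [0.5], "g2": [0.8], "g3": [0.9]})
        nf = normalization_factor(q, ["g1", "g2", "g3"]).iloc[0]
        assert nf == pytest.approx(0.36 ** (1 / 3), abs=1e-12)
        assert nf == pytest.approx(0.7114, abs=1e-4)

    def test_empty_reference_set_rejected(self):
        q = pd.DataFrame({"g1": [1.0]})
        with pytest.raises(ValidationError, match="empty"):
            normalization_factor(q, [])

    @settings(deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100))
    def test_scaling_one_gene_scales_nf_by_cube_root(self, c):
        q = pd.DataFrame({"g1": [0.5, 1.0], "g2": [0.8, 0.4], "g3": [0.9, 0.7]})
        nf0 = normalization_factor(q, list(q.columns))
        q2 = q.assign(g1=q["g1"] * c)
        nf1 = normalization_factor(q2, list(q.columns))
        assert np.allclose(nf1, nf0 * c ** (1 / 3))
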