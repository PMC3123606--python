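"""Model registry constraints, rate-matrix algebra, gamma discretization."""

from itertools import combinations

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.linalg import expm

from stemloop.models import (CANONICAL_PAIRS, MIXED_MODELS, PAIR6, REGISTRY,
                             SETUP_NAMES, STATES16, ModelError,
                             build_rate_matrix, count_free_parameters,
                             discretize_gamma, get_model)

ONE_STEP_MODELS = {"RNA6A", "RNA6B", "RNA6C", "RNA6D",
                   "RNA7A", "RNA7B", "RNA7D", "RNA16A"}
TWO_STEP_MODELS = {"RNA7C", "RNA7F", "RNA16", "RNA16B"}


class TestRegistry:
    def test_fourteen_setups(self):
        assert len(SETUP_NAMES) == 14
        assert SETUP_NAMES[0] == "GTR"
        assert len(MIXED_MODELS) == 13

    def test_step_classes(self):
        for name in ONE_STEP_MODELS:
            assert get_model(name).step_class == "one_step", name
        for name in TWO_STEP_MODELS:
            assert get_model(name).step_class == "two_step", name

    def test_mismatch_policies(self):
        for name, spec in REGISTRY.items():
            if name == "GTR":
                assert spec.mismatch_policy == "n/a"
            elif spec.n_states == 6:
                assert spec.mismatch_policy == "ignore"
            elif spec.n_states == 7:
                assert spec.mismatch_policy == "lump"
            else:
                assert spec.mismatch_policy == "distinct"

    def test_rna7e_flagged_as_default_classification(self):
        spec = get_model("RNA7E")
        assert spec.step_class == "two_step"
        assert spec.class_source == "implementation_default"
        others = {n for n in REGISTRY if n != "RNA7E"}
        assert all(REGISTRY[n].class_source == "literature" for n in others)

    def test_two_step_forbids_every_double_change(self):
        for name in TWO_STEP_MODELS:
            spec = get_model(name)
            m = spec.class_matrix()
            for i, j in combinations(range(spec.n_states), 2):
                si, sj = spec.states[i], spec.states[j]
                if "MM" in (si, sj):
                    continue
                double = (si[0] != sj[0]) and (si[1] != sj[1])
                if double:
                    assert m[i, j] < 0, (name, si, sj)

    def test_one_step_allows_some_double_change(self):
        for name in ONE_STEP_MODELS:
            spec = get_model(name)
            m = spec.class_matrix()
            doubles = [(i, j) for i, j in combinations(range(spec.n_states), 2)
                       if "MM" not in (spec.states[i], spec.states[j])
                       and spec.states[i][0] != spec.states[j][0]
                       and spec.states[i][1] != spec.states[j][1]]
            assert any(m[i, j] >= 0 for i, j in doubles), name

    def test_rna16_transition_counts_by_enumeration(self):
        # independent enumeration of Hamming classes on ordered pairs
        singles = sum(1 for a, b in combinations(STATES16, 2)
                      if (a[0] != b[0]) + (a[1] != b[1]) == 1)
        doubles = sum(1 for a, b in combinations(STATES16, 2)
                      if (a[0] != b[0]) + (a[1] != b[1]) == 2)
        assert singles == 48 and doubles == 72
        assert get_model("RNA16").n_exch_classes == 48
        assert len(get_model("RNA16").forbidden_pairs()) == 72
        # RNA16A additionally frees the canonical<->canonical doubles
        wc_doubles = sum(1 for a, b in combinations(sorted(CANONICAL_PAIRS), 2)
                         if a[0] != b[0] and a[1] != b[1])
        assert get_model("RNA16A").n_exch_classes == 48 + wc_doubles
        assert len(get_model("RNA16A").forbidden_pairs()) == 72 - wc_doubles


class TestRateMatrix:
    @pytest.mark.parametrize("name", SETUP_NAMES)
    def test_reversible_calibrated_generator(self, name):
        rm = build_rate_matrix(get_model(name))
        Q, pi = rm.Q, rm.pi
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-10)
        off = Q[~np.eye(len(pi), dtype=bool)]
        assert (off >= 0).all()
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-10)          # detailed balance
        assert abs(-(pi * np.diag(Q)).sum() - 1) < 1e-10      # mean rate 1

    @pytest.mark.parametrize("name", ["GTR", "RNA6A", "RNA7C", "RNA16"])
    def test_spectrum_and_transition_rows(self, name):
        rm = build_rate_matrix(get_model(name))
        eig = np.linalg.eigvals(rm.Q)
        assert np.sum(np.abs(eig) < 1e-9) == 1
        assert (np.real(eig) < 1e-9).all()
        for t in (0.01, 0.5, 3.0):
            P = rm.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-9)
            assert np.allclose(P, expm(rm.Q * t), atol=1e-8)

    def test_two_step_double_substitution_is_exactly_zero(self):
        rm16 = build_rate_matrix(get_model("RNA16"))
        au, gc = STATES16.index("AU"), STATES16.index("GC")
        assert rm16.Q[au, gc] == 0.0
        rm6 = build_rate_matrix(get_model("RNA6A"))
        assert rm6.Q[PAIR6.index("AU"), PAIR6.index("GC")] > 0.0

    def test_c_variant_ties_reverse_complement_frequencies(self):
        rm = build_rate_matrix(get_model("RNA6C"))
        for a, b in (("AU", "UA"), ("GC", "CG"), ("GU", "UG")):
            assert rm.pi[PAIR6.index(a)] == pytest.approx(rm.pi[PAIR6.index(b)])

    def test_parameter_errors(self):
        spec = get_model("RNA6A")
        with pytest.raises(ModelError, match="exchangeability"):
            build_rate_matrix(spec, exch=np.ones(3))
        with pytest.raises(ModelError, match="frequencies|frequency"):
            build_rate_matrix(spec, freqs=np.array([1, 0, 0, 0, 0, 0.0]))


class TestGamma:
    def test_point_mass_limit(self):
        # spread of the quartile means shrinks as 1/sqrt(alpha)
        dev6 = np.abs(np.array(discretize_gamma(1e6).rates) - 1).max()
        dev7 = np.abs(np.array(discretize_gamma(1e7).rates) - 1).max()
        assert dev7 < 1e-3 < 3 * dev6
        assert dev7 < dev6

    @pytest.mark.parametrize("alpha", [0.05, 0.3, 1.0, 7.5])
    def test_mean_one(self, alpha):
        g = discretize_gamma(alpha)
        assert abs(np.mean(g.rates) - 1.0) < 1e-10
        assert np.all(np.diff(g.rates) > 0)

    def test_quartile_means_match_numerical_integration(self):
        alpha = 0.5
        g = discretize_gamma(alpha)
        dist = stats.gamma(a=alpha, scale=1 / alpha)
        edges = dist.ppf([0, 0.25, 0.5, 0.75, 1.0])
        edges[-1] = np.inf
        for k in range(4):
            num, _ = integrate.quad(lambda x: x * dist.pdf(x),
                                    edges[k], edges[k + 1])
            assert g.rates[k] == pytest.approx(4 * num, rel=1e-6)

    def test_invalid_shape(self):
        with pytest.raises(ModelError):
            discretize_gamma(0.0)


class TestParameterCounts:
    def test_gtr_four_taxon_setup(self):
        # 5 exchangeabilities + 3 frequencies + 1 alpha + 5 branches
        assert count_free_parameters([get_model("GTR")], n_branches=5) == 14

    def test_rna6a_stem_model_counts(self):
        spec = get_model("RNA6A")
        assert spec.free_exchangeabilities == 14     # 15 state pairs, 1 tied
        assert spec.free_frequencies == 5

    def test_multi_partition_adds_rate_multipliers(self):
        gtr, rna = get_model("GTR"), get_model("RNA6A")
        single = count_free_parameters([gtr], 9)
        mixed = count_free_parameters([gtr, rna], 9)
        assert mixed == single + (rna.free_exchangeabilities
                                  + rna.free_frequencies + 1) + 1
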