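"""Map functions, gamete tables and configuration priors."""

import numpy as np
import pytest

from iqtlmap.linkage import (MISSING, MarkerMap, configuration_prior_table,
                             configuration_priors, gamete_distribution,
                             haldane_d, haldane_r, kosambi_d, kosambi_r)


class TestMapFunctions:
    def test_haldane_values(self):
        assert haldane_r(0.0) == pytest.approx(0.0)
        assert haldane_r(1e4) == pytest.approx(0.5)
        assert haldane_r(10.0) == pytest.approx((1 - np.exp(-0.2)) / 2)
        assert haldane_r(10.0) == pytest.approx(0.090635, abs=1e-6)

    @pytest.mark.parametrize("fwd,inv", [(haldane_r, haldane_d),
                                         (kosambi_r, kosambi_d)])
    def test_map_round_trip(self, fwd, inv):
        for d in (0.0, 1.0, 10.0, 50.0, 120.0):
            assert inv(fwd(d)) == pytest.approx(d, abs=1e-9)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-1.0)
        with pytest.raises(ValueError):
            kosambi_r(-0.1)


class TestGameteDistribution:
    def test_no_recombination(self):
        P = gamete_distribution(0.0, 0.0)
        assert P[0, 0, 0] == pytest.approx(0.5)
        assert P[1, 1, 1] == pytest.approx(0.5)
        assert P.sum() == pytest.approx(1.0)
        assert np.count_nonzero(P) == 2

    @pytest.mark.parametrize("r1,r2", [(0.0, 0.3), (0.1, 0.1), (0.5, 0.5),
                                       (0.05, 0.12)])
    def test_normalisation_and_swap_symmetry(self, r1, r2):
        P = gamete_distribution(r1, r2)
        assert P.sum() == pytest.approx(1.0)
        assert np.all(P >= 0)
        # simultaneous 1<->2, A<->a swap leaves the table invariant
        assert np.allclose(P, P[::-1, ::-1, ::-1])

    def test_derived_product_values(self):
        P = gamete_distribution(0.1, 0.1)
        assert P[0, 0, 0] == pytest.approx(0.405)
        assert P[0, 1, 0] == pytest.approx(0.005)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            gamete_distribution(0.6, 0.1)


class TestConfigurationPriors:
    def test_qtl_at_left_marker_homozygote(self):
        pr = configuration_priors("11", "12", 0.0, 0.2)
        assert pr[0] == pytest.approx(1.0)

    def test_double_heterozygote_origin_symmetry(self):
        pr = configuration_priors("12", "12", 0.1, 0.1)
        assert pr[1] == pytest.approx(pr[2])

    def test_missing_both_flanks_uninformative(self):
        pr = configuration_priors(MISSING, MISSING, 0.1, 0.2)
        assert np.allclose(pr, 0.25)

    @pytest.mark.parametrize("r1,r2", [(0.02, 0.3), (0.1, 0.1), (0.25, 0.4)])
    def test_all_classes_are_distributions(self, r1, r2):
        for pr in configuration_prior_table(r1, r2).values():
            assert np.all(pr >= 0)
            assert pr.sum() == pytest.approx(1.0)

    def test_marginalisation_consistency(self):
        # with the right flank missing the prior must equal the single-marker
        # conditional; P(maternal A) then depends only on the left marker
        r1, r2 = 0.08, 0.2
        for g in ("11", "12", "22"):
            pr = configuration_priors(g, MISSING, r1, r2)
            # single-marker closed form: maternal gamete carries left allele
            # 1 w.p. 1 for '11', 1/2 for '12', 0 for '22'
            p1 = {"11": 1.0, "12": 0.5, "22": 0.0}[g]
            p_matA = p1 * (1 - r1) + (1 - p1) * r1
            assert pr[0] + pr[1] == pytest.approx(p_matA)

    def test_matches_meiosis_simulation_oracle(self):
        # empirical configuration frequencies within each observed marker
        # class from simulated meioses, against the enumerated priors
        rng = np.random.default_rng(7)
        r1, r2 = 0.05, 0.12
        n = 200_000

        def gametes():
            left = rng.integers(0, 2, n)
            qtl = left ^ (rng.random(n) < r1)
            right = qtl ^ (rng.random(n) < r2)
            return left, qtl, right

        lm, qm, rm = gametes()
        lp, qp, rp = gametes()
        lg = np.char.add(*(np.sort(np.stack([lm, lp], 1), 1) + 1).astype(str).T)
        rg = np.char.add(*(np.sort(np.stack([rm, rp], 1), 1) + 1).astype(str).T)
        cfg = 2 * qm + qp
        for gl in ("11", "12", "22"):
            for gr in ("11", "12", "22"):
                mask = (lg == gl) & (rg == gr)
                emp = np.bincount(cfg[mask], minlength=4) / mask.sum()
                theo = configuration_priors(gl, gr, r1, r2)
                se = np.sqrt(theo * (1 - theo) / mask.sum())
                assert np.all(np.abs(emp - theo) <= 3 * np.maximum(se, 1e-9)), \
                    (gl, gr, emp, theo)


class TestMarkerMap:
    def test_interval_lookup(self):
        m = MarkerMap.from_table(["a", "b", "c"], ["1", "1", "1"], [0, 10, 30])
        iv = m.interval_at("1", 15.0)
        assert (iv.left_marker, iv.right_marker) == ("b", "c")
        assert iv.r == pytest.approx(iv.r1 + iv.r2 - 2 * iv.r1 * iv.r2)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            MarkerMap.from_table(["a", "b"], ["1", "1"], [5, 5])

    def test_position_outside_map_rejected(self):
        m = MarkerMap.from_table(["a", "b"], ["1", "1"], [0, 10])
        with pytest.raises(ValueError):
            m.interval_at("1", 11.0)
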