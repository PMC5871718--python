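import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpdp import quant


class TestIonAreas:
    @pytest.mark.parametrize(
        "intensities, acc, expected",
        [
            ([2.0e5], 50.0, [1.0e7]),
            ([0.0, 0.0], 30.0, [0.0, 0.0]),
            ([1e4, 2e4], 100.0, [1e6, 2e6]),
        ],
    )
    def test_area_is_intensity_times_accumulation(self, intensities, acc, expected):
        np.testing.assert_allclose(
            quant.compute_ion_areas(intensities, acc), expected
        )

    def test_nonpositive_accumulation_rejected(self):
        with pytest.raises(ValueError, match="accumulation"):
            quant.compute_ion_areas([1.0], 0.0)

    @given(scale=st.floats(0.1, 100.0))
    def test_linearity_preserves_channel_ratios(self, scale):
        base = np.array([1e4, 2e4, 5e3])
        a1 = quant.compute_ion_areas(base, 50.0)
        a2 = quant.compute_ion_areas(base * scale, 50.0)
        np.testing.assert_allclose(a2, a1 * scale, rtol=1e-12)
        np.testing.assert_allclose(a2 / a2[0], a1 / a1[0], rtol=1e-12)

    def test_table_drops_bad_accumulation_rows(self, psm_frame_factory):
        df = psm_frame_factory(
            3,
            intensities={"a": [1.0, 2.0, 3.0]},
            accumulation_time=[50.0, -1.0, 10.0],
        )
        out = quant.ion_area_table(df)
        assert len(out) == 2
        np.testing.assert_allclose(out["intensity_a"], [50.0, 30.0])


class TestFilterPsms:
    def test_passing_record_kept(self, psm_frame_factory):
        df = psm_frame_factory(
            1, identification_score=[16.0], precursor_s2b=[5.0], s2i=[0.6]
        )
        assert len(quant.filter_psms(df)) == 1

    @pytest.mark.parametrize(
        "column, boundary",
        [
            ("identification_score", 15.0),
            ("precursor_s2b", 4.0),
            ("s2i", 0.5),
        ],
    )
    def test_boundary_values_rejected(self, psm_frame_factory, column, boundary):
        df = psm_frame_factory(1, **{column: [boundary]})
        assert len(quant.filter_psms(df)) == 0

    def test_each_criterion_filters_independently(self, psm_frame_factory):
        # 10 records, 4 failing exactly one criterion each -> 6 retained
        df = psm_frame_factory(10)
        df.loc[0, "identification_score"] = 10.0
        df.loc[1, "identification_score"] = 15.0
        df.loc[2, "precursor_s2b"] = 3.0
        df.loc[3, "s2i"] = 0.4
        assert len(quant.filter_psms(df)) == 6


class TestIsotopePurity:
    def test_identity_matrix_is_noop(self):
        areas = np.array([3.0, 5.0, 7.0])
        np.testing.assert_allclose(
            quant.correct_isotope_purity(areas, np.eye(3)), areas
        )

    def test_two_channel_spillover_recovered(self):
        # 10% of channel 1 spills into channel 2; true signal (1, 1)
        purity = np.array([[0.9, 0.0], [0.1, 1.0]])
        observed = purity @ np.array([1.0, 1.0])
        np.testing.assert_allclose(
            quant.correct_isotope_purity(observed, purity), [1.0, 1.0]
        )

    def test_negative_solution_clipped_with_warning(self):
        purity = np.array([[0.9, 0.0], [0.1, 1.0]])
        observed = purity @ np.array([1.0, -0.1])
        with pytest.warns(UserWarning, match="negative"):
            corrected = quant.correct_isotope_purity(observed, purity)
        np.testing.assert_allclose(corrected, [1.0, 0.0], atol=1e-12)

    def test_singular_matrix_error_names_matrix(self):
        with pytest.raises(ValueError, match="singular"):
            quant.correct_isotope_purity([1.0, 1.0], np.ones((2, 2)))

    def test_roundtrip_matches_brute_force_solve(self, rng):
        # forward-mix then correct == identity, against an lstsq oracle
        for _ in range(20):
            m = np.eye(4) * rng.uniform(0.7, 1.0) + rng.uniform(0, 0.08, (4, 4))
            true = rng.uniform(0.5, 10.0, 4)
            observed = m @ true
            corrected = quant.correct_isotope_purity(observed, m)
            oracle, *_ = np.linalg.lstsq(m, observed, rcond=None)
            np.testing.assert_allclose(corrected, true, rtol=1e-8)
            np.testing.assert_allclose(corrected, oracle, rtol=1e-8)


class TestInterferenceAdjustment:
    def test_no_interference_returns_input(self):
        assert quant.adjust_interference(2.0, 1.0) == pytest.approx(2.0)

    def test_forward_mixing_inverted(self):
        s2i, true, bg = 0.8, 2.0, 1.0
        observed = s2i * true + (1 - s2i) * bg
        assert quant.adjust_interference(observed, s2i, bg) == pytest.approx(true)

    @pytest.mark.parametrize("s2i", [0.3, 0.6, 1.0])
    def test_unregulated_ratio_is_fixed_point(self, s2i):
        assert quant.adjust_interference(1.0, s2i, 1.0) == pytest.approx(1.0)

    def test_zero_s2i_excluded(self):
        with pytest.raises(ValueError, match="s2i"):
            quant.adjust_interference(2.0, 0.0)


class TestBootstrapQuant:
    def test_identical_spectra_give_zero_width_ci(self, psm_frame_factory):
        df = psm_frame_factory(
            5, intensities={"ref": [100.0] * 5, "t": [200.0] * 5}
        )
        q = quant.bootstrap_protein_quant(df, "ref", n_boot=100, seed=1)
        assert q.fold_changes["t"] == pytest.approx(2.0)
        assert q.ci_low["t"] == pytest.approx(q.ci_high["t"])

    def test_three_spectra_no_ci(self, psm_frame_factory):
        df = psm_frame_factory(
            3, intensities={"ref": [1.0, 2.0, 3.0], "t": [2.0, 4.0, 9.0]}
        )
        q = quant.bootstrap_protein_quant(df, "ref")
        assert q.ci_low is None and q.ci_high is None
        assert q.fold_changes["t"] == pytest.approx(15.0 / 6.0)

    def test_point_estimate_invariant_to_order_and_seed(self, psm_frame_factory, rng):
        df = psm_frame_factory(
            8,
            intensities={
                "ref": rng.uniform(10, 100, 8),
                "t": rng.uniform(10, 100, 8),
            },
        )
        q1 = quant.bootstrap_protein_quant(df, "ref", seed=1)
        q2 = quant.bootstrap_protein_quant(
            df.sample(frac=1, random_state=3), "ref", seed=99
        )
        assert q1.fold_changes["t"] == pytest.approx(q2.fold_changes["t"])
        # CI endpoints reproducible given the seed
        q3 = quant.bootstrap_protein_quant(df, "ref", seed=1)
        assert q1.ci_low["t"] == pytest.approx(q3.ci_low["t"])

    def test_insufficient_unique_peptides_returns_none(self, psm_frame_factory):
        df = psm_frame_factory(
            4,
            peptide_sequence=["SAME"] * 4,
            intensities={"ref": [1.0] * 4, "t": [2.0] * 4},
        )
        assert quant.bootstrap_protein_quant(df, "ref") is None

    def test_ci_covers_true_ratio_at_nominal_rate(self, psm_frame_factory):
        # Monte-Carlo coverage of the 95% percentile interval
        true_ratio = 2.0
        master = np.random.default_rng(42)
        hits = 0
        n_rep = 150
        for _ in range(n_rep):
            ref = master.lognormal(mean=np.log(100), sigma=0.4, size=50)
            # mean-one multiplicative noise so the sum-ratio targets true_ratio
            noise = master.lognormal(-0.3**2 / 2, 0.3, 50)
            t = true_ratio * ref * noise
            df = psm_frame_factory(50, intensities={"ref": ref, "t": t})
            q = quant.bootstrap_protein_quant(
                df, "ref", n_boot=300, seed=int(master.integers(2**31))
            )
            assert q.ci_low["t"] <= q.fold_changes["t"] <= q.ci_high["t"]
            if q.ci_low["t"] <= true_ratio <= q.ci_high["t"]:
                hits += 1
        assert 0.85 <= hits / n_rep <= 1.0


class TestSilacRatios:
    @pytest.mark.parametrize(
        "ratios, expected",
        [
            ([2.0, 2.0, 2.0], 2.0),
            ([1.0, 2.0, np.nan], 1.5),
            ([0.5, 1.0, 4.0], 1.0),
        ],
    )
    def test_median_of_valid_ratios(self, ratios, expected):
        df = pd.DataFrame(
            {
                "ratio": ratios,
                "identification_score": 40.0,
                "peptide_length": 10,
                "lsq_fit_quality": 0.05,
                "prior_ion_ratio": 0.1,
            }
        )
        assert quant.silac_protein_ratio(df) == pytest.approx(expected)

    def test_all_undetermined_is_unquantified(self):
        df = pd.DataFrame(
            {
                "ratio": [np.nan, np.nan],
                "identification_score": 40.0,
                "peptide_length": 10,
                "lsq_fit_quality": 0.05,
                "prior_ion_ratio": 0.1,
            }
        )
        assert np.isnan(quant.silac_protein_ratio(df))

    @given(
        bad_score=st.floats(0, 15),
        bad_len=st.integers(1, 5),
        bad_lsq=st.floats(0.11, 5.0),
    )
    @settings(max_examples=25)
    def test_invariant_to_peptides_failing_filters(self, bad_score, bad_len, bad_lsq):
        good = pd.DataFrame(
            {
                "ratio": [0.5, 1.0, 4.0],
                "identification_score": 40.0,
                "peptide_length": 10,
                "lsq_fit_quality": 0.05,
                "prior_ion_ratio": 0.1,
            }
        )
        bad = pd.DataFrame(
            {
                "ratio": [100.0, 100.0, 100.0],
                "identification_score": [bad_score, 40.0, 40.0],
                "peptide_length": [10, bad_len, 10],
                "lsq_fit_quality": [0.05, 0.05, bad_lsq],
                "prior_ion_ratio": 0.1,
            }
        )
        combined = pd.concat([good, bad], ignore_index=True)
        assert quant.silac_protein_ratio(combined) == quant.silac_protein_ratio(good)


class TestImputation:
    def test_missing_cell_gets_half_global_minimum(self):
        table = pd.DataFrame({"a": [0.08, 0.5], "b": [np.nan, 1.0]})
        imputed, mask = quant.impute_missing_abundance(table)
        assert imputed.loc[0, "b"] == pytest.approx(0.04)
        assert mask.loc[0, "b"] and mask.to_numpy().sum() == 1

    def test_no_missing_cells_unchanged(self):
        table = pd.DataFrame({"a": [0.1, 0.2]})
        imputed, mask = quant.impute_missing_abundance(table)
        pd.testing.assert_frame_equal(imputed, table)
        assert not mask.to_numpy().any()

    def test_rule_is_global(self):
        table = pd.DataFrame({"a": [0.2, np.nan], "b": [np.nan, 1.0]})
        imputed, _ = quant.impute_missing_abundance(table)
        assert imputed.loc[1, "a"] == imputed.loc[0, "b"] == pytest.approx(0.1)

    def test_fully_empty_table_errors(self):
        with pytest.raises(ValueError):
            quant.impute_missing_abundance(pd.DataFrame({"a": [np.nan]}))


class TestDonorConsistency:
    def _table(self, fcs, n_ssm=5):
        return pd.DataFrame(
            {
                "protein_group": ["P1"] * len(fcs),
                "condition": ["vehicle"] * len(fcs),
                "donor": list(range(len(fcs))),
                "fold_change": fcs,
                "n_ssm": n_ssm,
            }
        )

    def test_discordant_donors_removed(self):
        assert quant.donor_consistency_filter(self._table([0.1, 1.0])).empty

    def test_concordant_donors_kept(self):
        assert len(quant.donor_consistency_filter(self._table([0.5, 1.0]))) == 2

    def test_low_spectral_support_removed(self):
        assert quant.donor_consistency_filter(
            self._table([0.5, 1.0], n_ssm=2)
        ).empty
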