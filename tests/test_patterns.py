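"""Dietary-pattern PCA, scoring and the derived-score utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffqkit.adjust import aoac_from_nsp, energy_standardise, flag_misreporters
from ffqkit.derivation import frequency_matrix
from ffqkit.nutrients import BasisError, NutrientVector
from ffqkit.patterns import PatternModel, fit_patterns, score_patterns


@pytest.fixture(scope="module")
def freq_matrix(small_cohort):
    responses, _ = small_cohort
    return frequency_matrix(responses)


@pytest.fixture(scope="module")
def fitted(freq_matrix):
    return fit_patterns(freq_matrix, k=5)


class TestFitPatterns:
    def test_five_score_columns_per_participant(self, fitted, freq_matrix):
        _, scores = fitted
        assert scores.shape == (freq_matrix.shape[0], 5)

    def test_training_scores_have_mean_zero(self, fitted):
        _, scores = fitted
        assert np.all(np.abs(scores.mean(axis=0)) < 1e-8)

    def test_loading_columns_orthogonal(self, fitted):
        model, _ = fitted
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(model.k), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, fitted):
        model, _ = fitted
        for j in range(model.k):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_rotation_preserves_retained_variance(self, freq_matrix):
        m_rot, s_rot = fit_patterns(freq_matrix, k=5, rotation="varimax")
        m_raw, s_raw = fit_patterns(freq_matrix, k=5, rotation="none")
        assert s_rot.to_numpy().var(axis=0).sum() == pytest.approx(
            s_raw.to_numpy().var(axis=0).sum(), rel=1e-9)

    def test_k_exceeding_items_is_error(self, freq_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            fit_patterns(freq_matrix, k=freq_matrix.shape[1] + 1)

    def test_constant_column_is_error(self, freq_matrix):
        bad = freq_matrix.copy()
        bad["c200"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            fit_patterns(bad, k=3)

    def test_deterministic_given_input(self, freq_matrix):
        m1, s1 = fit_patterns(freq_matrix, k=5)
        m2, s2 = fit_patterns(freq_matrix, k=5)
        assert np.array_equal(m1.loadings, m2.loadings)
        assert s1.equals(s2)

    def test_recovers_planted_linear_structure(self):
        # independent check on a small factor model with known loadings
        rng = np.random.default_rng(99)
        p, k, n = 20, 3, 600
        L = np.zeros((p, k))
        for j in range(k):
            L[j * 6:(j + 1) * 6, j] = 1.0
        Z = rng.standard_normal((n, k))
        X = Z @ L.T + 0.3 * rng.standard_normal((n, p))
        model, _ = fit_patterns(
            pd.DataFrame(X, columns=[f"i{i}" for i in range(p)]), k=k)
        corr = np.abs(np.corrcoef(L.T, model.loadings.T)[:k, k:])
        best = corr.max(axis=1)
        assert np.all(best > 0.95)


class TestScorePatterns:
    def test_training_row_matches_fit_time_score(self, fitted, freq_matrix):
        model, scores = fitted
        again = score_patterns(model, freq_matrix.iloc[[7]])
        assert np.allclose(again.to_numpy(), scores.iloc[[7]].to_numpy())

    def test_mean_profile_scores_zero(self, fitted):
        model, _ = fitted
        row = pd.DataFrame([model.means], columns=model.items)
        assert np.allclose(score_patterns(model, row).to_numpy(), 0.0,
                           atol=1e-10)

    def test_one_sd_above_mean_scores_the_loading_row(self, fitted):
        model, _ = fitted
        item_ix = 3
        vals = model.means.copy()
        vals[item_ix] += model.scales[item_ix]
        row = pd.DataFrame([vals], columns=model.items)
        assert np.allclose(score_patterns(model, row).to_numpy()[0],
                           model.loadings[item_ix], atol=1e-10)

    def test_missing_item_is_error(self, fitted, freq_matrix):
        model, _ = fitted
        with pytest.raises(KeyError, match="c200"):
            score_patterns(model, freq_matrix.drop(columns=["c200"]))

    def test_json_round_trip(self, fitted, freq_matrix, tmp_path):
        model, scores = fitted
        p = tmp_path / "model.json"
        model.to_json(p)
        back = PatternModel.from_json(p)
        assert np.allclose(
            score_patterns(back, freq_matrix).to_numpy(), scores.to_numpy())


class TestAoac:
    def test_printed_factor(self):
        assert aoac_from_nsp(10.0) == pytest.approx(13.3)

    def test_zero(self):
        assert aoac_from_nsp(0.0) == 0.0

    def test_cohort_scale_value(self):
        assert aoac_from_nsp(14.9) == pytest.approx(19.817)

    def test_negative_is_error(self):
        with pytest.raises(ValueError):
            aoac_from_nsp(-1.0)

    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_additive(self, a, b):
        assert aoac_from_nsp(a + b) == pytest.approx(
            aoac_from_nsp(a) + aoac_from_nsp(b), abs=1e-9)


class TestEnergyStandardise:
    def _daily(self, energy_kj=7230.0, protein=69.3, fat=71.0, carb=213.0,
               iron=10.2):
        v = NutrientVector(basis="daily")
        v["energy_kj"] = energy_kj
        v["protein_g"] = protein
        v["fat_g"] = fat
        v["carbohydrate_g"] = carb
        v["iron_mg"] = iron
        return v

    def test_zero_fat_is_zero_percent(self):
        out = energy_standardise(self._daily(fat=0.0), "percent")
        assert out["fat_g"] == 0.0

    def test_protein_percent_energy(self):
        out = energy_standardise(self._daily(), "percent")
        assert out["protein_g"] == pytest.approx(69.3 * 17 / 7230 * 100)
        assert out["protein_g"] == pytest.approx(16.3, abs=0.05)

    def test_density_mode_iron_per_mj(self):
        out = energy_standardise(self._daily(), "density")
        assert out["iron_mg"] == pytest.approx(10.2 / 7.23)
        assert out["iron_mg"] == pytest.approx(1.41, abs=0.01)

    def test_zero_energy_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            energy_standardise(self._daily(energy_kj=0.0))

    def test_weekly_basis_rejected(self):
        with pytest.raises(BasisError):
            energy_standardise(NutrientVector(basis="weekly"))

    @given(scale=st.floats(0.1, 5))
    @settings(max_examples=30, deadline=None)
    def test_percent_invariant_under_proportional_scaling(self, scale):
        a = energy_standardise(self._daily(), "percent")
        b = energy_standardise(
            self._daily(7230 * scale, 69.3 * scale, 71 * scale, 213 * scale),
            "percent")
        for slot in a:
            assert b[slot] == pytest.approx(a[slot], rel=1e-9)


class TestMisreporterFlag:
    def test_ratio_below_lower_bound_is_under(self):
        # 60 kg: predicted = (0.062*60 + 2.036) * 1.4 = 8.06 MJ
        flag = flag_misreporters(3.0, 60.0)
        assert flag.category == "under"
        assert flag.ratio < 0.54

    def test_ratio_unity_is_plausible(self):
        predicted = (0.062 * 60 + 2.036) * 1.4
        flag = flag_misreporters(predicted, 60.0)
        assert flag.category == "plausible"
        assert flag.ratio == pytest.approx(1.0)

    def test_ratio_above_upper_bound_is_over(self):
        assert flag_misreporters(20.0, 60.0).category == "over"

    def test_missing_weight_is_plausible_with_caveat(self, caplog):
        with caplog.at_level("WARNING"):
            flag = flag_misreporters(7.0, None, participant_id="A1")
        assert flag.category == "plausible" and flag.ratio is None
        assert "A1" in caplog.text

    def test_nonpositive_weight_is_error(self):
        with pytest.raises(ValueError):
            flag_misreporters(7.0, 0.0)
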