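import numpy as np
import pandas as pd
import pytest

from polarhit import average_risk, counterfactual_delta, patient_curves, waterfall_data
from polarhit.explain import Attribution, exact_shapley, mc_shapley, shapley_attributions

from .oracles import brute_shapley


class TestAverageRisk:
    def test_zero_cif_gives_zero(self):
        assert average_risk(np.zeros((3, 10)), "death") == 0.0

    def test_constant_cif_gives_the_constant(self):
        pmf = np.zeros((3, 4))
        pmf[1, 0] = 0.3  # cif_death = 0.3 at every bin
        assert average_risk(pmf, "death") == pytest.approx(0.3)

    def test_hand_three_bin_mean(self):
        pmf = np.zeros((3, 3))
        pmf[0] = [0.1, 0.1, 0.1]  # cif = 0.1, 0.2, 0.3
        assert average_risk(pmf, "ACS") == pytest.approx(0.2)

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            average_risk(np.zeros((3, 3)), "stroke")


class TestShapleyEstimators:
    def test_linear_model_closed_form(self, rng):
        """For v(S) = sum_{i in S} beta_i x_i + const, phi_i = beta_i x_i."""
        beta = rng.standard_normal(6)
        x = rng.standard_normal(6)

        def v(mask):
            return float(beta[mask] @ x[mask])

        phi = exact_shapley(v, 6)
        np.testing.assert_allclose(phi, beta * x, atol=1e-10)

    def test_efficiency_symmetry_dummy(self):
        # v(S) = 3*[0 in S] + 3*[1 in S] + 5*[0 and 2 both in S]
        def v(mask):
            return 3.0 * mask[0] + 3.0 * mask[1] + 5.0 * (mask[0] and mask[2])

        phi = exact_shapley(v, 4)
        full = np.ones(4, dtype=bool)
        assert phi.sum() == pytest.approx(v(full) - v(~full), abs=1e-10)
        # players 0 and 2 split the interaction term equally (symmetry of
        # the interaction); player 3 is a dummy
        assert phi[3] == pytest.approx(0.0, abs=1e-10)
        assert phi[0] == pytest.approx(3.0 + 2.5, abs=1e-10)
        assert phi[2] == pytest.approx(2.5, abs=1e-10)

    def test_exact_matches_permutation_average_on_five_players(self, rng):
        table = rng.standard_normal(2**5)

        def v(mask):
            return float(table[int(np.dot(mask, 2 ** np.arange(5)))])

        np.testing.assert_allclose(
            exact_shapley(v, 5), brute_shapley(v, 5), atol=1e-10
        )

    def test_mc_estimate_within_three_se_of_enumeration(self, rng):
        table = rng.standard_normal(2**6)

        def v(mask):
            return float(table[int(np.dot(mask, 2 ** np.arange(6)))])

        exact = exact_shapley(v, 6)
        phi, se = mc_shapley(v, 6, n_permutations=400, rng=np.random.default_rng(0))
        assert (np.abs(phi - exact) <= 3 * np.maximum(se, 1e-12)).all()

    def test_mc_is_exactly_efficient(self, rng):
        table = rng.standard_normal(2**6)

        def v(mask):
            return float(table[int(np.dot(mask, 2 ** np.arange(6)))])

        phi, _ = mc_shapley(v, 6, n_permutations=16, rng=np.random.default_rng(1))
        full = np.ones(6, dtype=bool)
        assert phi.sum() == pytest.approx(v(full) - v(~full), abs=1e-10)


class _TruthModel:
    """Stand-in estimator computing pmf analytically from synthetic hazards.

    Exposes the same surface the explanation code needs (predict_pmf,
    feature_names_in_, use_images) but produces the generator's exact
    cause-specific distribution for the given clinical rows.
    """

    use_images = False

    def __init__(self, config, extent):
        from polarhit.cohort import CLINICAL_FEATURES

        self.config = config
        self.extent = extent
        self.feature_names_in_ = list(CLINICAL_FEATURES)

    def predict_pmf(self, clinical_df):
        from polarhit.simulate import compute_hazards

        n = len(clinical_df)
        h = compute_hazards(self.config, clinical_df, np.full(n, self.extent))
        total = h.sum(axis=1)
        surv_before = np.concatenate(
            [np.ones((n, 1)), np.cumprod(1 - total, axis=1)[:, :-1]], axis=1
        )
        return h * surv_before[:, None, :]


@pytest.fixture(scope="module")
def truth_model():
    from polarhit.simulate import default_config, generate_clinical

    cfg = default_config(n_patients=30, seed=8)
    rng = np.random.default_rng(8)
    clinical, _ = generate_clinical(cfg, rng)
    return _TruthModel(cfg, extent=0.1), clinical


class TestModelAttribution:
    def test_patient_identical_to_background_gets_zero_attributions(self, truth_model):
        model, clinical = truth_model
        patient = clinical.iloc[0].to_numpy(float)
        background = (None, clinical.iloc[[0]])
        # group the 15 features into 4 blocks so enumeration is exact
        groups = {n: f"g{i % 4}" for i, n in enumerate(model.feature_names_in_)}
        attr = shapley_attributions(
            model, None, patient, background, "death", groups=groups
        )
        np.testing.assert_allclose(attr.contributions, 0.0, atol=1e-12)
        assert attr.efficiency_gap() == pytest.approx(0.0, abs=1e-12)

    def test_exact_efficiency_for_grouped_players(self, truth_model):
        model, clinical = truth_model
        patient = clinical.iloc[3].to_numpy(float)
        background = (None, clinical.iloc[5:15])
        groups = {n: f"g{i % 5}" for i, n in enumerate(model.feature_names_in_)}
        attr = shapley_attributions(
            model, None, patient, background, "death", groups=groups
        )
        assert attr.efficiency_gap() == pytest.approx(0.0, abs=1e-10)

    def test_mc_efficiency_for_all_fifteen_players(self, truth_model):
        model, clinical = truth_model
        patient = clinical.iloc[2].to_numpy(float)
        background = (None, clinical.iloc[10:18])
        attr = shapley_attributions(
            model, None, patient, background, "death",
            n_permutations=8, seed=0,
        )
        assert attr.standard_errors is not None
        assert attr.efficiency_gap() == pytest.approx(0.0, abs=1e-10)

    def test_empty_background_rejected(self, truth_model):
        model, clinical = truth_model
        with pytest.raises(ValueError, match="background"):
            shapley_attributions(
                model, None, clinical.iloc[0].to_numpy(float),
                (None, clinical.iloc[:0]), "death",
            )


class TestWaterfall:
    def _attr(self, contributions, ev=0.10):
        contributions = np.asarray(contributions, dtype=float)
        return Attribution(
            features=[f"f{i}" for i in range(len(contributions))],
            contributions=contributions,
            expected_value=ev,
            final_value=ev + contributions.sum(),
            event="death",
        )

    def test_single_nonzero_contribution(self):
        wf = waterfall_data(self._attr([0.05, 0.0, 0.0]), top_n=3)
        assert wf["running_total"].iloc[0] == pytest.approx(0.15)
        assert wf["running_total"].iloc[-1] == pytest.approx(0.15)
        assert wf.attrs["expected_value"] == 0.10

    def test_truncation_residual_row_sums_remainder(self, rng):
        contribs = rng.standard_normal(20) * 0.01
        attr = self._attr(contribs)
        wf = waterfall_data(attr, top_n=3)
        assert len(wf) == 4
        ordered = np.sort(np.abs(contribs))[::-1]
        assert abs(wf["contribution"].iloc[:3]).to_numpy() == pytest.approx(ordered[:3])
        assert wf["running_total"].iloc[-1] == pytest.approx(attr.final_value)

    def test_all_zero_attributions(self):
        wf = waterfall_data(self._attr(np.zeros(5)), top_n=10)
        assert (wf["contribution"] == 0).all()
        assert wf["running_total"].iloc[-1] == pytest.approx(0.10)

    def test_invalid_top_n_rejected(self):
        with pytest.raises(ValueError):
            waterfall_data(self._attr([0.1]), top_n=0)

    def test_rows_ordered_by_absolute_contribution(self, rng):
        wf = waterfall_data(self._attr(rng.standard_normal(8)), top_n=8)
        mags = wf["contribution"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-15).all()


class TestCounterfactual:
    def test_empty_modification_is_identity(self, truth_model):
        model, clinical = truth_model
        out = counterfactual_delta(
            model, None, clinical.iloc[0].to_numpy(float), {}, "death"
        )
        assert out["percent_change"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_analytic_recomputation_on_truth(self, truth_model):
        """Lowering resting heart rate must reproduce the hazard-model
        recomputation exactly when the model IS the generator truth."""
        from polarhit.simulate import compute_hazards

        model, clinical = truth_model
        row = clinical.iloc[[4]].reset_index(drop=True)
        modified = row.copy()
        modified["resting_hr"] = 60.0

        def avg_death_risk(df):
            h = compute_hazards(model.config, df, np.array([model.extent]))
            total = h.sum(axis=1)
            sb = np.concatenate(
                [np.ones((1, 1)), np.cumprod(1 - total, axis=1)[:, :-1]], axis=1
            )
            cif = np.cumsum(h * sb[:, None, :], axis=2)
            return float(cif[0, 1, :].mean())

        expected = 100.0 * (
            avg_death_risk(row) - avg_death_risk(modified)
        ) / avg_death_risk(row)
        out = counterfactual_delta(
            model, None, row.iloc[0].to_numpy(float), {"resting_hr": 60.0}, "death"
        )
        assert out["percent_change"] == pytest.approx(expected, abs=1e-8)

    def test_disjoint_modifications_commute(self, truth_model):
        model, clinical = truth_model
        x = clinical.iloc[1].to_numpy(float)
        joint = counterfactual_delta(
            model, None, x, {"resting_hr": 65.0, "bmi": 24.0}, "death"
        )
        other_order = counterfactual_delta(
            model, None, x, {"bmi": 24.0, "resting_hr": 65.0}, "death"
        )
        assert joint["risk_after"] == pytest.approx(other_order["risk_after"], abs=1e-15)

    def test_lowering_every_hazard_lowers_every_event_risk(self, truth_model):
        """A modification that reduces all cause-specific hazards yields a
        positive percent reduction for each event."""
        model, clinical = truth_model
        x = clinical.iloc[6].to_numpy(float).copy()
        names = model.feature_names_in_
        x[names.index("resting_hr")] = 95.0
        x[names.index("stress_pharmacologic")] = 1.0
        mods = {"resting_hr": 60.0, "stress_pharmacologic": 0.0}
        for event in ("ACS", "death"):
            out = counterfactual_delta(model, None, x, mods, event)
            assert out["percent_change"] > 0

    def test_unknown_feature_rejected(self, truth_model):
        model, clinical = truth_model
        with pytest.raises(ValueError, match="unknown"):
            counterfactual_delta(
                model, None, clinical.iloc[0].to_numpy(float), {"nope": 1.0}, "death"
            )


class TestPatientCurves:
    def test_single_model_mean_is_that_model(self, rng):
        pmf = rng.random((4, 3, 6))
        pmf /= pmf.sum(axis=(1, 2), keepdims=True)
        out = patient_curves([pmf], patient=2)
        np.testing.assert_allclose(
            out["death"]["mean"], np.cumsum(pmf[2, 1, :]), atol=1e-15
        )

    def test_curves_non_decreasing(self, rng):
        sets = []
        for _ in range(3):
            pmf = rng.random((2, 3, 8))
            pmf /= pmf.sum(axis=(1, 2), keepdims=True)
            sets.append(pmf)
        out = patient_curves(sets, patient=0)
        for cause in out:
            assert (np.diff(out[cause]["mean"]) >= -1e-12).all()
            assert (np.diff(out[cause]["models"], axis=1) >= -1e-12).all()

    def test_mean_is_bin_wise_average(self, rng):
        sets = []
        for _ in range(10):
            pmf = rng.random((1, 3, 5))
            pmf /= pmf.sum(axis=(1, 2), keepdims=True)
            sets.append(pmf)
        out = patient_curves(sets, patient=0)
        hand = np.mean([np.cumsum(s[0, 0, :]) for s in sets], axis=0)
        np.testing.assert_allclose(out["ACS"]["mean"], hand, atol=1e-15)

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            patient_curves([], patient=0)
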