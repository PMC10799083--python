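"""Composition-based linear correction: shipped models, OLS refits, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpas.correction import (
    ELEMENTS,
    CorrectionModel,
    apply_correction,
    apply_correction_frame,
    default_models,
    fit_correction,
    regression_metrics,
)
from hpas.errors import ContractError
from hpas.synthetic import SyntheticSpec, synth_paired_table

BENZENE_COUNTS = {"h": 6, "c": 6, "b": 0, "s": 0, "o": 0, "n": 0}


class TestDefaultModels:
    def test_schema(self):
        models = default_models()
        assert set(models) == {"homo", "lumo", "gap", "aip", "aea", "energy"}
        for model in models.values():
            assert model.n_parameters == 8

    def test_shipped_coefficients(self):
        models = default_models()
        assert models["homo"].baseline_coef == pytest.approx(1.2397)
        assert models["homo"].intercept == pytest.approx(6.2841)
        assert models["energy"].element_coefs["s"] == pytest.approx(-395.1947)
        assert models["energy"].units == "Eh"
        assert models["aea"].units == "eV"

    def test_json_round_trip(self, tmp_path):
        model = default_models()["gap"]
        path = tmp_path / "gap.json"
        model.save(path)
        assert CorrectionModel.load(path) == model


class TestApply:
    def test_identity_model_returns_baseline(self):
        model = CorrectionModel(
            property_key="homo",
            element_coefs={e: 0.0 for e in ELEMENTS},
            baseline_coef=1.0,
            intercept=0.0,
        )
        assert apply_correction(model, BENZENE_COUNTS, -7.25) == pytest.approx(-7.25)

    def test_benzene_homo_hand_value(self):
        # 6*0.0124 + 6*0.0065 + 1.2397*(-13.0) + 6.2841
        corrected = apply_correction(default_models()["homo"], BENZENE_COUNTS, -13.0)
        assert corrected == pytest.approx(-9.7186, abs=1e-4)

    def test_linearity_without_intercept(self):
        model = CorrectionModel(
            property_key="homo",
            element_coefs={e: 0.1 * i for i, e in enumerate(ELEMENTS)},
            baseline_coef=0.7,
            intercept=0.0,
        )
        counts = {"h": 4, "c": 9, "b": 1, "s": 0, "o": 2, "n": 1}
        doubled = {k: 2 * v for k, v in counts.items()}
        assert apply_correction(model, doubled, -8.0) == pytest.approx(
            2 * apply_correction(model, counts, -4.0)
        )

    def test_missing_count_rejected(self):
        with pytest.raises(ContractError):
            apply_correction(default_models()["homo"], {"h": 6, "c": 6}, -13.0)

    def test_batch_equals_matrix_form(self):
        model = default_models()["homo"]
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                **{e: rng.integers(0, 12, size=64) for e in ELEMENTS},
                "baseline": rng.normal(-13, 1, size=64),
            }
        )
        batch = apply_correction_frame(model, frame)
        beta = model.parameter_vector()
        oracle = frame[[*ELEMENTS, "baseline"]].to_numpy() @ beta[:-1] + beta[-1]
        assert np.allclose(batch, oracle)
        loop = [
            apply_correction(model, {e: row[e] for e in ELEMENTS}, row["baseline"])
            for _, row in frame.iterrows()
        ]
        assert np.allclose(batch, loop)


class TestFit:
    def test_noiseless_fit_recovers_generator(self):
        spec = SyntheticSpec(
            n_molecules=200, generator_model=default_models()["gap"], noise_sd=0.0, seed=3
        )
        model, metrics = fit_correction(synth_paired_table(spec), seed=1)
        truth = default_models()["gap"].parameter_vector()
        assert np.allclose(model.parameter_vector(), truth, atol=1e-8)
        assert metrics.rmse < 1e-8

    @pytest.mark.parametrize("noise_sd", [1e-1, 1e-3, 1e-6])
    def test_parameter_error_shrinks_with_noise(self, noise_sd):
        spec = SyntheticSpec(
            n_molecules=4000,
            generator_model=default_models()["homo"],
            noise_sd=noise_sd,
            seed=10,
        )
        model, _ = fit_correction(synth_paired_table(spec), seed=2)
        error = np.abs(
            model.parameter_vector() - default_models()["homo"].parameter_vector()
        ).max()
        assert error < 20 * noise_sd

    def test_test_rmse_tracks_noise_level(self):
        spec = SyntheticSpec(n_molecules=5000, noise_sd=0.16, seed=8)
        _, metrics = fit_correction(synth_paired_table(spec), seed=5)
        assert abs(metrics.rmse - 0.16) / 0.16 < 0.2
        assert metrics.n_train == 4000 and metrics.n_test == 1000

    def test_fit_is_deterministic(self):
        table = synth_paired_table(SyntheticSpec(n_molecules=500, seed=1))
        first = fit_correction(table, seed=11)
        second = fit_correction(table, seed=11)
        assert first == second

    def test_absent_element_pinned_to_zero(self, caplog):
        spec = SyntheticSpec(n_molecules=300, noise_sd=0.01, seed=4)
        spec.composition_ranges["b"] = (0, 0)
        with caplog.at_level("WARNING"):
            model, _ = fit_correction(synth_paired_table(spec), seed=0)
        assert model.element_coefs["b"] == 0.0
        assert any("pinned" in message for message in caplog.messages)

    def test_too_few_rows_rejected(self):
        table = synth_paired_table(SyntheticSpec(n_molecules=8, seed=0))
        with pytest.raises(ContractError):
            fit_correction(table)


class TestMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.mae) == (1.0, 0.0, 0.0)

    def test_constant_offset(self):
        reference = np.array([0.0, 1.0, 5.0])
        m = regression_metrics(reference + 0.7, reference)
        assert m.mae == pytest.approx(0.7)
        assert m.rmse == pytest.approx(0.7)

    def test_mean_predictor_has_zero_r2(self):
        reference = np.array([1.0, 2.0, 3.0, 6.0])
        m = regression_metrics(np.full(4, reference.mean()), reference)
        assert m.r2 == pytest.approx(0.0)

    def test_zero_variance_reference(self):
        m = regression_metrics([1.0, 1.1], [2.0, 2.0])
        assert m.r2 is None

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=2,
            max_size=40,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_invariance_under_simultaneous_reordering(self, data, seed):
        predicted, reference = map(np.array, zip(*data))
        order = np.random.default_rng(seed).permutation(len(data))
        a = regression_metrics(predicted, reference)
        b = regression_metrics(predicted[order], reference[order])
        assert a.rmse == pytest.approx(b.rmse)
        assert a.mae == pytest.approx(b.mae)
        assert (a.r2 is None) == (b.r2 is None)
        if a.r2 is not None:
            assert a.r2 == pytest.approx(b.r2)


def test_histogram_overlap_grows_as_noise_shrinks():
    """Refit-and-correct on synthetic tables: the corrected-vs-reference
    distribution overlap on the test split increases as noise decreases."""
    overlaps = []
    for noise in (2.0, 0.5, 0.05):
        table = synth_paired_table(
            SyntheticSpec(n_molecules=2000, noise_sd=noise, seed=6)
        )
        model, _ = fit_correction(table, seed=6)
        corrected = apply_correction_frame(model, table.data)
        reference = table.data["reference"]
        bins = np.histogram_bin_edges(
            np.concatenate([corrected, reference]), bins=40
        )
        h1, _ = np.histogram(corrected, bins=bins, density=False)
        h2, _ = np.histogram(reference, bins=bins, density=False)
        overlaps.append(np.minimum(h1, h2).sum() / h1.sum())
    assert overlaps[0] < overlaps[1] < overlaps[2]
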