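import numpy as np
import pandas as pd
import pytest

from hetarray.errors import ModelError, ValidationError
from hetarray.normalization import (
    FactorRatioSet,
    adjust_residuals_positive,
    background_correct,
    channel_factor_levels,
    compute_factor_log_ratios,
    expression_matrix,
    fit_array_dye_model,
    loess_correct_ratios,
    loess_flatness,
)
from hetarray.synthetic_data import SimulationParams, simulate_signal_matrix

from conftest import make_spots


class TestBackgroundCorrect:
    def test_simple_subtraction(self):
        spots = make_spots([("A", "P1", 500, 100, 480, 95, False)])
        mat = background_correct(spots)
        assert mat.loc["P1", ("A", "ch1")] == 400
        assert mat.loc["P1", ("A", "ch2")] == 385

    def test_negative_after_subtraction_missing(self):
        spots = make_spots([("A", "P1", 90, 100, 480, 95, False)])
        mat = background_correct(spots)
        assert np.isnan(mat.loc["P1", ("A", "ch1")])

    def test_zero_after_subtraction_missing(self):
        spots = make_spots([("A", "P1", 200, 200, 480, 95, False)])
        assert np.isnan(background_correct(spots).loc["P1", ("A", "ch1")])


def _matrix(values, arrays=("A", "B"), genes=("g1", "g2")):
    cols = pd.MultiIndex.from_product(
        [arrays, ["ch1", "ch2"]], names=["array_id", "channel"]
    )
    return pd.DataFrame(values, index=list(genes), columns=cols)


class TestArrayDyeModel:
    def test_additive_zero_noise_residuals_zero(self):
        # value = gene + array + dye, identical per gene within a cell
        vals = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        fit = fit_array_dye_model(_matrix(2.0 ** vals), scale="log2")
        assert np.allclose(fit.residuals.to_numpy(), 0.0, atol=1e-12)

    def test_cell_values_10_20_centered(self):
        vals = np.array([[10.0, 1.0, 1.0, 1.0], [20.0, 1.0, 1.0, 1.0]])
        fit = fit_array_dye_model(_matrix(vals), scale="raw")
        assert fit.residuals.iloc[0, 0] == -5.0
        assert fit.residuals.iloc[1, 0] == 5.0

    def test_cell_mean_equivalence(self, small_experiment):
        mat, design, _ = small_experiment
        signals = np.power(2.0, mat)
        fit = fit_array_dye_model(signals)
        y = np.log2(signals)
        centered = y - y.mean(axis=0)
        np.testing.assert_allclose(
            fit.residuals.to_numpy(), centered.to_numpy(), rtol=1e-9, atol=1e-12
        )

    def test_ols_oracle_cell_means(self, rng):
        """Estimated cell means within 3 SE of the generating values."""
        n_genes, sd = 2000, 0.3
        params = SimulationParams(
            n_genes=n_genes, seed=11, noise_sd=sd, baseline_sd=0.0, baseline_mean=8.0
        )
        mat, design, _ = simulate_signal_matrix(params)
        fit = fit_array_dye_model(np.power(2.0, mat))
        # closed-form OLS of the saturated model == per-cell sample means;
        # truth: baseline + array + dye + interaction, noise SE = sd/sqrt(n)
        se = sd / np.sqrt(n_genes)
        y = np.log2(np.power(2.0, mat))
        truth_cell = mat.mean(axis=0)  # includes the realized noise means
        est = fit.grand_mean + fit.array_effects.reindex(
            [c[0] for c in mat.columns]
        ).to_numpy() + fit.dye_effects.reindex([c[1] for c in mat.columns]).to_numpy()
        inter = np.array(
            [fit.interaction_effects.loc[c[0], c[1]] for c in mat.columns]
        )
        np.testing.assert_allclose(est + inter, truth_cell.to_numpy(), atol=3 * se + 1e-9)

    def test_single_array_rejected(self):
        vals = np.ones((3, 2))
        cols = pd.MultiIndex.from_product(
            [["A"], ["ch1", "ch2"]], names=["array_id", "channel"]
        )
        df = pd.DataFrame(vals, index=["g1", "g2", "g3"], columns=cols)
        with pytest.raises(ModelError):
            fit_array_dye_model(df)

    def test_thin_cell_rejected(self):
        m = _matrix(np.ones((2, 4)))
        m.iloc[1, 0] = np.nan  # cell (A, ch1) has a single gene
        with pytest.raises(ModelError):
            fit_array_dye_model(m, scale="raw")

    def test_dye_swap_symmetry_zero_noise(self):
        """A sample's residual profile is identical on both halves of its
        dye-swap array pair once the dye effect is removed (noise -> 0)."""
        params = SimulationParams(
            n_genes=100, seed=5, noise_sd=0.0, effects={"temperature": (0.2, 1.5)}
        )
        mat, design, _ = simulate_signal_matrix(params)
        fit = fit_array_dye_model(np.power(2.0, mat))
        from hetarray.io_formats import dye_swap_pairs

        pairs = dye_swap_pairs(design)
        assert pairs  # the simulated design is fully dye-swapped
        lookup = design.set_index(["array_id", "dye"])["sample_id"]
        for a, b in pairs[:4]:
            for dye in ("ch1", "ch2"):
                sample = lookup[(a, dye)]
                other = "ch2" if dye == "ch1" else "ch1"
                assert lookup[(b, other)] == sample
                np.testing.assert_allclose(
                    fit.residuals[(a, dye)].to_numpy(),
                    fit.residuals[(b, other)].to_numpy(),
                    atol=1e-9,
                )


class TestAdjustResiduals:
    def _fit(self, residuals):
        from hetarray.normalization import ArrayDyeModelFit

        return ArrayDyeModelFit(
            array_effects=pd.Series(dtype=float),
            dye_effects=pd.Series(dtype=float),
            interaction_effects=pd.DataFrame(),
            residuals=residuals,
            grand_mean=0.0,
        )

    def test_example_shift(self):
        r = pd.DataFrame({"a": [-2.0, 0.0, 3.0]})
        adj = adjust_residuals_positive(self._fit(r), delta=1.0)
        assert list(adj["a"]) == [1.0, 3.0, 6.0]

    def test_all_equal_gives_delta(self):
        r = pd.DataFrame({"a": [5.0, 5.0]})
        adj = adjust_residuals_positive(self._fit(r), delta=2.0)
        assert set(adj["a"]) == {2.0}

    def test_min_is_delta(self, rng):
        r = pd.DataFrame(rng.normal(size=(10, 4)))
        adj = adjust_residuals_positive(self._fit(r), delta=1.0)
        assert np.nanmin(adj.to_numpy()) == pytest.approx(1.0)

    def test_rank_preserving_and_shift_equivariant(self, rng):
        r = pd.DataFrame(rng.normal(size=(20, 3)))
        a1 = adjust_residuals_positive(self._fit(r))
        a2 = adjust_residuals_positive(self._fit(r + 7.5))
        flat1, flat2 = a1.to_numpy().ravel(), a2.to_numpy().ravel()
        assert (np.argsort(flat1) == np.argsort(flat2)).all()
        np.testing.assert_allclose(flat1, flat2, rtol=1e-12)  # shift cancels


class TestFactorRatios:
    def _values(self, design, factor, level_values, genes=("g1",)):
        lv = channel_factor_levels(design, factor)
        cols = pd.MultiIndex.from_tuples(lv.index, names=["array_id", "channel"])
        data = np.array([[level_values[lv[c]] for c in lv.index] for _ in genes])
        return pd.DataFrame(data, index=list(genes), columns=cols)

    def test_level_means_8_2_gives_2(self, tiny_design):
        vals = self._values(tiny_design, "water", {"watered": 8.0, "drought": 2.0})
        rs = compute_factor_log_ratios(vals, tiny_design, "water")
        assert rs.data.loc["g1", "log2_ratio"] == pytest.approx(2.0)

    def test_equal_levels_zero(self, tiny_design):
        vals = self._values(tiny_design, "species", {"Ag": 4.0, "Sn": 4.0})
        rs = compute_factor_log_ratios(vals, tiny_design, "species")
        assert rs.data.loc["g1", "log2_ratio"] == pytest.approx(0.0)

    def test_orientation_swap_negates(self, tiny_design):
        a = self._values(tiny_design, "temperature", {"ambient": 6.0, "heated": 3.0})
        b = self._values(tiny_design, "temperature", {"ambient": 3.0, "heated": 6.0})
        ra = compute_factor_log_ratios(a, tiny_design, "temperature")
        rb = compute_factor_log_ratios(b, tiny_design, "temperature")
        assert ra.data.loc["g1", "log2_ratio"] == pytest.approx(
            -rb.data.loc["g1", "log2_ratio"]
        )

    def test_species_positive_means_higher_in_ag(self, tiny_design):
        vals = self._values(tiny_design, "species", {"Ag": 8.0, "Sn": 2.0})
        rs = compute_factor_log_ratios(vals, tiny_design, "species")
        assert rs.data.loc["g1", "log2_ratio"] > 0
        assert rs.levels == ("Ag", "Sn")

    def test_single_level_rejected(self, tiny_design):
        sub = tiny_design[tiny_design["species"] == "Ag"]
        vals = self._values(sub, "water", {"watered": 8.0, "drought": 2.0})
        with pytest.raises(ValidationError):
            compute_factor_log_ratios(vals, sub, "species")

    def test_incomplete_genes_dropped(self, tiny_design):
        vals = self._values(
            tiny_design, "water", {"watered": 8.0, "drought": 2.0}, genes=("g1", "g2")
        )
        vals.iloc[1, 0] = np.nan
        rs = compute_factor_log_ratios(vals, tiny_design, "water")
        assert list(rs.data.index) == ["g1"]

    def test_positivity_shift_cancels_in_expression_ratio(self, small_experiment):
        mat, design, _ = small_experiment
        fit = fit_array_dye_model(np.power(2.0, mat))
        a1 = adjust_residuals_positive(fit, delta=1.0)
        a2 = adjust_residuals_positive(fit, delta=5.0)
        r1 = compute_factor_log_ratios(expression_matrix(a1), design, "species")
        r2 = compute_factor_log_ratios(expression_matrix(a2), design, "species")
        np.testing.assert_allclose(
            r1.data["log2_ratio"], r2.data["log2_ratio"], rtol=1e-9
        )


def _ratio_set(x, r):
    return FactorRatioSet(
        "water",
        pd.DataFrame(
            {"log2_ratio": r, "log10_intensity": x}, index=[f"g{i}" for i in range(len(x))]
        ),
    )


class TestLoess:
    def test_planted_sinusoid_flattened(self):
        # bias 0.5*sin(x) over a realistic ~3-decade intensity range
        rng = np.random.default_rng(42)
        x = rng.uniform(1, 4, 2000)
        noise = rng.normal(0, 0.1, 2000)
        corrected = loess_correct_ratios(_ratio_set(x, noise + 0.5 * np.sin(x)))
        rmse = np.sqrt(np.mean((corrected.data["log2_ratio"].to_numpy() - noise) ** 2))
        assert rmse < 0.05

    def test_flat_input_nearly_unchanged(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 4, 10000)
        r = rng.normal(0, 0.2, 10000)
        corrected = loess_correct_ratios(_ratio_set(x, r))
        assert np.max(np.abs(corrected.data["log2_ratio"].to_numpy() - r)) < 0.05 * r.std()

    def test_constant_offset_absorbed(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 4, 500)
        r = rng.normal(0, 0.1, 500) + 3.0
        corrected = loess_correct_ratios(_ratio_set(x, r))
        assert abs(corrected.data["log2_ratio"].mean()) < 0.05

    def test_refit_flatness_on_gentle_trend(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 4, 1500)
        r = rng.normal(0, 0.1, 1500) + 0.3 * x
        corrected = loess_correct_ratios(_ratio_set(x, r))
        assert loess_flatness(corrected) < 0.05 * r.std()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            loess_correct_ratios(_ratio_set(np.arange(10.0), np.zeros(10)))
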