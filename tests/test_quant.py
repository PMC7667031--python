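"""Absolute quantification: iBAQ, standards filtering, calibration, TMT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import omniflux as om
from omniflux.errors import CalibrationError, DataError, UnitsError

from conftest import abundance


def spike(conc, signal, n_pep=None):
    frame = pd.DataFrame({
        "standard_id": [f"s{i}" for i in range(len(conc))],
        "known_concentration": conc,
        "measured_signal": signal,
    })
    if n_pep is not None:
        frame["n_unique_peptides"] = n_pep
    return frame


class TestIbaq:
    def test_sum_over_theoretical_peptides(self):
        ann = [om.GeneRecord("p1", 50.0, 3)]
        pep = pd.DataFrame({"protein_id": ["p1"] * 3,
                            "peptide_id": ["a", "b", "c"],
                            "intensity": [10.0, 20.0, 30.0]})
        out = om.compute_ibaq(pep, ann)
        assert out.data.loc["p1"].iloc[0] == pytest.approx(20.0)

    def test_single_peptide_single_theoretical(self):
        ann = [om.GeneRecord("p1", 50.0, 1)]
        pep = pd.DataFrame({"protein_id": ["p1"], "peptide_id": ["a"], "intensity": [5.0]})
        assert om.compute_ibaq(pep, ann).data.loc["p1"].iloc[0] == pytest.approx(5.0)

    def test_matches_group_sum_divide_oracle(self, rng):
        ann = [om.GeneRecord(f"p{i}", 50.0, int(rng.integers(1, 20))) for i in range(50)]
        rows = []
        for rec in ann:
            for k in range(rng.integers(1, 6)):
                rows.append((rec.gene_id, f"{rec.gene_id}_{k}", float(rng.uniform(1, 100))))
        pep = pd.DataFrame(rows, columns=["protein_id", "peptide_id", "intensity"])
        out = om.compute_ibaq(pep, ann)
        for rec in ann:
            expected = sum(r[2] for r in rows if r[0] == rec.gene_id) / rec.n_theoretical_peptides
            assert out.data.loc[rec.gene_id].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_technical_replicates_averaged(self):
        ann = [om.GeneRecord("p1", 50.0, 2)]
        pep = pd.DataFrame({"protein_id": ["p1"] * 2, "peptide_id": ["a", "a"],
                            "intensity": [10.0, 30.0], "replicate": [1, 2]})
        assert om.compute_ibaq(pep, ann).data.loc["p1"].iloc[0] == pytest.approx(10.0)

    def test_unknown_protein_named_in_error(self):
        pep = pd.DataFrame({"protein_id": ["ghost"], "peptide_id": ["a"], "intensity": [1.0]})
        with pytest.raises(DataError, match="ghost"):
            om.compute_ibaq(pep, [om.GeneRecord("p1", 50.0, 1)])


class TestFilterStandards:
    def test_five_of_fortyeight_below_threshold(self, rng):
        n_pep = [5] * 43 + [1, 1, 0, 1, 0]
        table = spike(rng.uniform(1, 100, 48), rng.uniform(1, 100, 48), n_pep)
        assert len(om.filter_standards(table, 2)) == 43

    def test_zero_threshold_keeps_positive_signals(self, rng):
        table = spike([1, 2, 3], [0.0, 5.0, 6.0], [0, 0, 0])
        out = om.filter_standards(table, 0)
        assert list(out["standard_id"]) == ["s1", "s2"]

    def test_matches_row_scan_oracle(self, rng):
        n = 40
        table = spike(rng.uniform(1, 10, n), rng.choice([0.0, 2.0, 9.0], n),
                      rng.integers(0, 6, n))
        out = om.filter_standards(table, 2)
        oracle = [i for i in range(n)
                  if table["n_unique_peptides"][i] >= 2 and table["measured_signal"][i] > 0]
        assert list(out.index) == oracle

    def test_everything_filtered_is_an_error(self):
        with pytest.raises(CalibrationError):
            om.filter_standards(spike([1.0], [1.0], [1]), 2)


class TestFitCalibration:
    def test_identity_line(self):
        vals = np.array([1.0, 10.0, 100.0, 1000.0])
        curve = om.fit_calibration(spike(vals, vals))
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        curve = om.fit_calibration(spike([10.0, 1000.0], [1.0, 100.0]))
        assert curve.n_points == 2 and curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(1.0) and curve.intercept == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, truth):
        cfg = om.CalibConfig(slope=0.9, intercept=2.0, noise_sd=0.1)
        _, spike_tab = om.simulate_mrna_assay(truth, cfg, seed=21)
        curve = om.fit_calibration(spike_tab)
        x = np.log10(spike_tab["measured_signal"].to_numpy())
        y = np.log10(spike_tab["known_concentration"].to_numpy())
        xm = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        assert curve.intercept == pytest.approx(beta[0], abs=1e-10)
        assert curve.slope == pytest.approx(beta[1], abs=1e-10)
        # configured truth within 3 SE of the OLS fit
        resid = y - xm @ beta
        s2 = resid @ resid / (len(x) - 2)
        se_slope = np.sqrt(s2 / ((x - x.mean()) ** 2).sum())
        assert abs(curve.slope - 0.9) < 3 * se_slope

    def test_degenerate_and_underdetermined_fits_rejected(self):
        with pytest.raises(CalibrationError):
            om.fit_calibration(spike([1.0, 2.0], [5.0, 5.0]))
        with pytest.raises(CalibrationError):
            om.fit_calibration(spike([1.0, 2.0], [0.0, 5.0]))


class TestApplyCalibration:
    def test_identity_curve_returns_input(self):
        sig = abundance(pd.DataFrame({"s1": [1.0, 5.0, 20.0]}, index=list("abc")),
                        units="signal")
        curve = om.CalibrationCurve(1.0, 0.0, 1.0, 2)
        out = om.apply_calibration(curve, sig)
        assert np.allclose(out.values, sig.values)
        assert out.units == "arbitrary_absolute"

    def test_power_law_arithmetic(self):
        sig = abundance(pd.DataFrame({"s1": [5.0]}, index=["a"]), units="signal")
        out = om.apply_calibration(om.CalibrationCurve(1.0, 1.0, 1.0, 2), sig)
        assert out.data.loc["a", "s1"] == pytest.approx(50.0)

    def test_zero_signal_becomes_missing(self):
        sig = abundance(pd.DataFrame({"s1": [0.0, 2.0]}, index=["a", "b"]), units="signal")
        out = om.apply_calibration(om.CalibrationCurve(1.0, 0.0, 1.0, 2), sig)
        assert np.isnan(out.data.loc["a", "s1"]) and out.data.loc["b", "s1"] == 2.0

    def test_units_mismatch_rejected(self):
        mat = abundance(pd.DataFrame({"s1": [1.0]}, index=["a"]))
        with pytest.raises(UnitsError):
            om.apply_calibration(om.CalibrationCurve(1.0, 0.0, 1.0, 2), mat)

    def test_noiseless_generator_round_trip(self, truth):
        cfg = om.CalibConfig(slope=0.9, intercept=2.0, noise_sd=0.0)
        signal, spike_tab = om.simulate_mrna_assay(truth, cfg, seed=5)
        curve = om.fit_calibration(spike_tab)
        recovered = om.apply_calibration(curve, signal)
        rel = np.abs(recovered.values / truth.true_mrna.values - 1.0)
        assert np.nanmax(rel) < 1e-9

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_equivariance(self, c):
        """Rescaling all signals by c shifts the intercept by -slope*log10(c)
        and leaves calibrated outputs unchanged."""
        conc = np.array([1.0, 30.0, 400.0, 9000.0])
        sig = np.array([2.0, 50.0, 700.0, 15000.0])
        base = om.fit_calibration(spike(conc, sig))
        scaled = om.fit_calibration(spike(conc, sig * c))
        assert scaled.slope == pytest.approx(base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(
            base.intercept - base.slope * np.log10(c), rel=1e-9, abs=1e-9)
        mat = abundance(pd.DataFrame({"s": sig}, index=list("abcd")), units="signal")
        mat_c = abundance(pd.DataFrame({"s": sig * c}, index=list("abcd")), units="signal")
        out = om.apply_calibration(base, mat)
        out_c = om.apply_calibration(scaled, mat_c)
        assert np.allclose(out.values, out_c.values, rtol=1e-9)


class TestPropagateTmt:
    def test_unit_ratio_reproduces_reference(self):
        ref = abundance(pd.DataFrame({"pooled": [100.0, 7.0]}, index=["a", "b"]),
                        units="arbitrary_absolute")
        ratios = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 1.0]}, index=["a", "b"])
        out = om.propagate_tmt(ref, ratios)
        assert np.allclose(out.values, [[100.0, 100.0], [7.0, 7.0]])

    def test_ratio_two_doubles(self):
        ref = abundance(pd.DataFrame({"pooled": [100.0]}, index=["a"]),
                        units="arbitrary_absolute")
        out = om.propagate_tmt(ref, pd.DataFrame({"s1": [2.0]}, index=["a"]))
        assert out.data.loc["a", "s1"] == pytest.approx(200.0)

    def test_missing_reference_proteins_are_dropped_not_invented(self):
        ref_frame = pd.DataFrame({"pooled": [100.0, np.nan]}, index=["a", "b"])
        ref = abundance(ref_frame, units="arbitrary_absolute")
        ratios = pd.DataFrame({"s1": [2.0, 3.0]}, index=["a", "b"])
        out = om.propagate_tmt(ref, ratios)
        assert list(out.data.index) == ["a"]

    def test_unaligned_sets_rejected(self):
        ref = abundance(pd.DataFrame({"pooled": [1.0]}, index=["a"]),
                        units="arbitrary_absolute")
        with pytest.raises(DataError, match="a"):
            om.propagate_tmt(ref, pd.DataFrame({"s1": [1.0]}, index=["zz"]))


def test_slope_recovery_under_default_noise(truth):
    """Median |slope error| over seeds stays well under 0.05."""
    errs = []
    for seed in range(20):
        _, spike_tab = om.simulate_mrna_assay(
            truth, om.CalibConfig(slope=0.9, intercept=2.0, noise_sd=0.1), seed=seed)
        errs.append(abs(om.fit_calibration(spike_tab).slope - 0.9))
    assert np.median(errs) < 0.05
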