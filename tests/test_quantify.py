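"""Composition, correction factors, absolute yield, LC-MS estimators."""

import numpy as np
import pytest

from nanocoa import quantify as qt


def cfs(values, sds=None):
    return qt.CorrectionFactors(values=dict(values), uncertainties=dict(sds or {}))


class TestEstimateCorrectionFactors:
    def test_simple_arithmetic(self):
        records = [dict(label="x", n_events=100, duration_s=100.0, concentration_uM=1.0)]
        result = qt.estimate_correction_factors(records)
        assert result.values["x"] == pytest.approx(1.0)
        assert result.uncertainties["x"] == pytest.approx(0.1)  # sqrt(100)/100

    def test_pooling_over_traces(self):
        records = [
            dict(label="x", n_events=60, duration_s=50.0, concentration_uM=2.0),
            dict(label="x", n_events=40, duration_s=100.0, concentration_uM=1.0),
        ]
        result = qt.estimate_correction_factors(records)
        assert result.values["x"] == pytest.approx(100 / 200.0)

    def test_identical_rates_give_zero_between_trace_sd(self):
        records = [
            dict(label="x", n_events=50, duration_s=100.0, concentration_uM=1.0),
            dict(label="x", n_events=50, duration_s=100.0, concentration_uM=1.0),
        ]
        assert qt.estimate_correction_factors(records).uncertainties["x"] == 0.0

    @pytest.mark.parametrize("bad", [dict(concentration_uM=0.0), dict(duration_s=0.0)])
    def test_zero_exposure_rejected(self, bad):
        record = dict(label="x", n_events=1, duration_s=10.0, concentration_uM=1.0)
        record.update(bad)
        with pytest.raises(ValueError):
            qt.estimate_correction_factors([record])


class TestEstimateComposition:
    def test_counts_proportional_to_cfs_give_equal_fractions(self):
        counts = {"cA3/4": 17, "cA5": 62, "cA6": 12}
        result = qt.estimate_composition(
            counts, 100.0, cfs({"cA3/4": 0.17, "cA5": 0.62, "cA6": 0.12})
        )
        for f in result.fractions.values():
            assert f == pytest.approx(1 / 3)
        assert result.event_rate == pytest.approx(0.91)

    def test_single_nonzero_class_gets_fraction_one(self):
        result = qt.estimate_composition(
            {"a": 40, "b": 0}, 10.0, cfs({"a": 0.2, "b": 0.5})
        )
        assert result.fractions["a"] == pytest.approx(1.0)
        assert result.fractions["b"] == 0.0

    def test_invariant_under_uniform_rescaling(self):
        table = cfs({"a": 0.3, "b": 0.7})
        f1 = qt.estimate_composition({"a": 30, "b": 50}, 100.0, table).fractions
        f2 = qt.estimate_composition({"a": 60, "b": 100}, 200.0, table).fractions
        assert f1 == pytest.approx(f2)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no classified events"):
            qt.estimate_composition({"a": 0}, 10.0, cfs({"a": 0.2}))


class TestPredictionInterval:
    def test_identical_fold_estimates_give_zero_width(self):
        folds = [{"a": 0.6, "b": 0.4}] * 5
        intervals = qt.prediction_interval(folds)
        assert intervals["a"] == (pytest.approx(0.6), pytest.approx(0.6))

    def test_interval_contains_the_mean(self, rng):
        folds = [{"a": float(v)} for v in rng.uniform(0.2, 0.8, 10)]
        lo, hi = qt.prediction_interval(folds)["a"]
        mean = np.mean([f["a"] for f in folds])
        assert lo <= mean <= hi

    def test_wider_fold_spread_widens_interval(self):
        base = np.array([0.4, 0.45, 0.5, 0.55, 0.6])
        widths = []
        for scale in [1.0, 2.0, 4.0]:
            folds = [{"a": 0.5 + scale * (v - 0.5)} for v in base]
            lo, hi = qt.prediction_interval(folds)["a"]
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_fewer_than_three_folds_rejected(self):
        with pytest.raises(ValueError):
            qt.prediction_interval([{"a": 0.5}, {"a": 0.6}])


PRINTED_CFS = {"cA3/4": 0.17, "cA5": 0.62, "cA6": 0.12}


def yield_from_rounded(re_, fracs, cf, d, cc):
    conc = sum(re_ * f / c for f, c in zip(fracs, cf))
    return conc * d / cc


class TestAbsoluteYield:
    def test_unit_construction_gives_one_molecule_per_complex(self):
        result = qt.absolute_yield(0.2, {"x": 1.0}, cfs({"x": 0.2}), 1.0, 1.0)
        assert result.total == pytest.approx(1.0)

    def test_enzymatic_worked_examples(self):
        # within the interval spanned by half-ulp rounding of every input
        cases = [
            (0.47, {"cA3/4": 0.89, "cA5": 0.08, "cA6": 0.03}, 21.0, 870.0, 5.0),
            (1.17, {"cA3/4": 0.81, "cA5": 0.12, "cA6": 0.07}, 27.6, 2800.0, 50.0),
        ]
        for r_e, fracs, d, printed, half_ulp in cases:
            result = qt.absolute_yield(r_e, fracs, cfs(PRINTED_CFS), d, 0.0625)
            lo = yield_from_rounded(
                r_e - 0.005, [f - 0.005 for f in fracs.values()],
                [c + 0.005 for c in PRINTED_CFS.values()], d - 0.05, 0.0625,
            )
            hi = yield_from_rounded(
                r_e + 0.005, [f + 0.005 for f in fracs.values()],
                [c - 0.005 for c in PRINTED_CFS.values()], d + 0.05, 0.0625,
            )
            assert lo - half_ulp <= printed <= hi + half_ulp
            assert result.total == pytest.approx(printed, rel=0.035)

    def test_homogeneous_in_event_rate_and_cfs(self):
        fracs = {"a": 0.7, "b": 0.3}
        base = qt.absolute_yield(0.5, fracs, cfs({"a": 0.2, "b": 0.4}), 10.0, 0.1)
        doubled_rate = qt.absolute_yield(1.0, fracs, cfs({"a": 0.2, "b": 0.4}), 10.0, 0.1)
        doubled_cfs = qt.absolute_yield(0.5, fracs, cfs({"a": 0.4, "b": 0.8}), 10.0, 0.1)
        for c in fracs:
            assert doubled_rate.per_class[c] == pytest.approx(2 * base.per_class[c])
            assert doubled_cfs.per_class[c] == pytest.approx(base.per_class[c] / 2)

    def test_zero_input_uncertainty_gives_zero_output_uncertainty(self):
        result = qt.absolute_yield(0.5, {"a": 1.0}, cfs({"a": 0.2}), 2.0, 0.1)
        assert result.total_sd == 0.0
        assert result.per_class_sd["a"] == 0.0

    def test_propagated_uncertainty_grows_with_input_uncertainty(self):
        small = qt.absolute_yield(
            0.47, {"a": 1.0}, cfs({"a": 0.17}, {"a": 0.01}), 21.0, 0.0625,
            event_rate_sd=0.05,
        )
        large = qt.absolute_yield(
            0.47, {"a": 1.0}, cfs({"a": 0.17}, {"a": 0.05}), 21.0, 0.0625,
            event_rate_sd=0.19,
        )
        assert 0 < small.total_sd < large.total_sd

    def test_missing_correction_factor_named(self):
        with pytest.raises(ValueError, match="cA5"):
            qt.absolute_yield(0.5, {"cA5": 1.0}, cfs({"cA6": 0.12}), 1.0, 1.0)


class TestLcms:
    def test_equal_volume_pooling_recovers_equimolar_mix(self):
        species = ["cA3", "cA4", "cA5", "cA6"]
        mono = {s: 40000.0 + 1000 * i for i, s in enumerate(species)}
        mix = {s: a / 4 for s, a in mono.items()}
        conc, _ = qt.lcms_concentrations(mono, mix)
        ratios, _ = qt.lcms_ratios(conc)
        for s in species:
            assert conc[s] == pytest.approx(12.5)
            assert ratios[s] == pytest.approx(25.0)

    def test_absent_species_gets_zero(self):
        conc, sd = qt.lcms_concentrations({"a": 100.0, "b": 100.0}, {"a": 0.0, "b": 50.0})
        ratios, _ = qt.lcms_ratios(conc)
        assert conc["a"] == 0.0 and ratios["a"] == 0.0

    def test_ratios_sum_to_100(self, rng):
        conc = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(1, 50, 4))}
        ratios, _ = qt.lcms_ratios(conc)
        assert sum(ratios.values()) == pytest.approx(100.0)

    def test_zero_monodisperse_area_rejected(self):
        with pytest.raises(ValueError, match="cA3"):
            qt.lcms_concentrations({"cA3": 0.0}, {"cA3": 10.0})
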