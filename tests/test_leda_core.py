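"""Ratio tables, system assembly, NNLS deconvolution and reconstruction."""

import numpy as np
import pytest

import leda
from leda import RatioTable, PairedDataPoint
from leda.leda_core import UnderdeterminedSystemError
from leda.synthetic_data import GaussianPeak, RunScenario, pure_isomer_scenario, simulate_run
from conftest import SimplexSearchOracle


def _table(ratios, mzs=None, isomers=("A", "B", "C"), sds=None):
    ratios = np.asarray(ratios, float)
    mzs = tuple(mzs or (100.0 + 10 * i for i in range(ratios.shape[0])))
    sds = np.full_like(ratios, 0.01) if sds is None else np.asarray(sds, float)
    return RatioTable("test", 353.0, tuple(isomers), tuple(mzs), ratios, sds)


def _exact_points(matrix, fractions, ri_profile):
    """Paired points whose spectra are exact mixtures of the matrix columns."""
    mix = matrix.design @ np.asarray(fractions, float)
    points = []
    for k, ri in enumerate(ri_profile):
        spectrum = tuple((mz, ri * r) for mz, r in zip(matrix.row_mzs, mix))
        points.append(PairedDataPoint(0.01 * k, ri, spectrum, 1))
    return points


class TestMatrixAssembly:
    def test_cqa_system_retains_all_four_ions(self, cqa_table):
        matrix = leda.assemble_leda_matrix(cqa_table, 0.02)
        assert matrix.design.shape == (4, 3)
        assert matrix.row_mzs == (191.0, 179.0, 173.0, 135.0)

    def test_dicqa_system_retains_all_five_ions(self, dicqa_table):
        matrix = leda.assemble_leda_matrix(dicqa_table, 0.02)
        assert matrix.design.shape == (5, 3)
        assert matrix.row_mzs == (353.0, 335.0, 317.0, 299.0, 203.0)

    def test_uninformative_ion_dropped(self):
        table = _table(
            [[0.30, 0.20, 0.25], [0.01, 0.01, 0.01], [0.05, 0.10, 0.02], [0.04, 0.02, 0.08]]
        )
        matrix = leda.assemble_leda_matrix(table, 0.02)
        assert matrix.design.shape == (3, 3)
        assert 110.0 not in matrix.row_mzs

    def test_underdetermined_after_filter_raises(self):
        table = _table(
            [[0.30, 0.20, 0.25], [0.01, 0.01, 0.01], [0.01, 0.005, 0.01], [0.05, 0.04, 0.03]]
        )
        with pytest.raises(UnderdeterminedSystemError):
            leda.assemble_leda_matrix(table, 0.02)


class TestSolve:
    @pytest.mark.parametrize("group", ["CQAs", "diCQAs"])
    @pytest.mark.parametrize("which", [0, 1, 2])
    def test_pure_column_identity(self, group, which):
        """Each pure-isomer fingerprint deconvolves to itself exactly."""
        table = leda.load_bundled_ratio_table(group)
        matrix = leda.assemble_leda_matrix(table)
        isomer = table.isomer_ids[which]
        result = leda.solve_leda(matrix, table.column(isomer))
        expected = np.eye(3)[which]
        assert result.fractions == pytest.approx(expected, abs=1e-9)

    def test_known_binary_mixture(self, cqa_table, cqa_matrix):
        measured = 0.5 * cqa_table.column("3-CQA") + 0.5 * cqa_table.column("5-CQA")
        assert measured == pytest.approx([0.265, 0.110, 0.010, 0.015])
        result = leda.solve_leda(cqa_matrix, measured)
        assert result.fractions == pytest.approx([0.5, 0.5, 0.0], abs=1e-6)

    def test_all_zero_vector_flagged(self, cqa_matrix):
        result = leda.solve_leda(cqa_matrix, np.zeros(4))
        assert result.fractions == pytest.approx(np.zeros(3))
        assert "no product signal" in result.flags
        assert result.unassigned == 1.0

    def test_dimension_mismatch(self, cqa_matrix):
        with pytest.raises(ValueError):
            leda.solve_leda(cqa_matrix, [0.1, 0.2])

    def test_collinear_columns_flagged(self):
        table = _table(
            [[0.30, 0.30, 0.10], [0.20, 0.20, 0.05], [0.10, 0.10, 0.30], [0.05, 0.05, 0.02]]
        )
        matrix = leda.assemble_leda_matrix(table)
        result = leda.solve_leda(matrix, table.ratios @ [0.5, 0.3, 0.2])
        assert "collinear design" in result.flags

    def test_matches_grid_search_oracle(self, cqa_matrix):
        """NNLS agrees with exhaustive simplex search on noiseless mixtures."""
        oracle = SimplexSearchOracle(cqa_matrix.design, resolution=0.001)
        rng = np.random.default_rng(42)
        for _ in range(100):
            f_true = rng.dirichlet(np.ones(3))
            b = cqa_matrix.design @ f_true
            got = leda.solve_leda(cqa_matrix, b).fractions
            best = oracle.best_fractions(b)
            assert np.max(np.abs(got - best)) < 0.002

    def test_monotone_in_true_share(self, cqa_matrix):
        """Raising one isomer's true share never lowers its recovered fraction."""
        previous = -1.0
        for share in np.linspace(0.0, 1.0, 21):
            f_true = np.array([share, (1 - share) * 0.6, (1 - share) * 0.4])
            got = leda.solve_leda(cqa_matrix, cqa_matrix.design @ f_true).fractions[0]
            assert got >= previous - 1e-12
            previous = got

    @pytest.mark.parametrize("group", ["CQAs", "diCQAs"])
    def test_median_error_under_ratio_noise(self, group):
        """5% multiplicative ratio noise, 30 scans: median |error| < 0.05."""
        table = leda.load_bundled_ratio_table(group)
        matrix = leda.assemble_leda_matrix(table)
        rng = np.random.default_rng(2024)
        sigma = np.sqrt(np.log1p(0.05**2))
        errors = []
        for _ in range(200):
            f_true = rng.dirichlet(np.ones(3))
            clean = matrix.design @ f_true
            scans = clean[None, :] * np.exp(
                rng.normal(-sigma**2 / 2, sigma, (30, clean.size))
            )
            result = leda.solve_leda(matrix, scans.mean(axis=0))
            errors.append(np.abs(result.fractions - f_true).max())
        assert np.median(errors) < 0.05


class TestCharacteristicRatios:
    def test_noiseless_roundtrip_recovers_generator_column(self, segments, cqa_table):
        scenario, window = pure_isomer_scenario("5-CQA")
        scans = simulate_run(scenario)
        points = [
            p
            for p in leda.pair_events(scans, segments[0])
            if window[0] <= p.retention_time <= window[1]
        ]
        means, sds = leda.compute_characteristic_ratios(
            points, cqa_table.product_mzs, cqa_table.reference_mz
        )
        assert means == pytest.approx(cqa_table.column("5-CQA"), abs=1e-4)
        assert sds == pytest.approx(np.zeros(4), abs=1e-4)

    def test_absent_product_ion_gives_zero_ratio(self, cqa_matrix):
        points = _exact_points(cqa_matrix, [1.0, 0.0, 0.0], [100.0, 200.0, 100.0])
        means, sds = leda.compute_characteristic_ratios(points, [999.0], 353.0)
        assert means[0] == 0.0 and sds[0] == 0.0

    def test_all_zero_reference_raises(self):
        points = [PairedDataPoint(1.0, 0.0, ((191.0, 5.0),), 1)]
        with pytest.raises(ValueError):
            leda.compute_characteristic_ratios(points, [191.0], 353.0)

    def test_noisy_means_concentrate_on_truth(self, segments, cqa_table):
        """At 5% noise the peak-averaged ratio lands within its standard error."""
        inside = 0
        n_seeds = 40
        for seed in range(n_seeds):
            scenario, window = pure_isomer_scenario("5-CQA", noise_cv=0.05, seed=seed)
            points = [
                p
                for p in leda.pair_events(simulate_run(scenario), segments[0])
                if window[0] <= p.retention_time <= window[1]
            ]
            means, sds = leda.compute_characteristic_ratios(
                points, (191.0,), cqa_table.reference_mz
            )
            se = sds[0] / np.sqrt(len(points))
            if abs(means[0] - 0.30) <= 3 * se:
                inside += 1
        assert inside >= 0.9 * n_seeds


class TestReconstruction:
    def test_pure_run_assigns_everything_to_that_isomer(self, segments, cqa_table, cqa_matrix):
        scenario = RunScenario(
            segments=(segments[0],),
            ratio_tables={1: cqa_table},
            isomer_peaks={"3-CQA": GaussianPeak(1.5, 0.3, 1e6)},
            seed=0,
        )
        points = leda.pair_events(simulate_run(scenario), segments[0])
        rec = leda.deconvolve_scanwise(points, cqa_matrix)
        gate = rec.ri_trace.max() * leda.leda_core.MIN_RI_GATE_FRACTION
        solved = rec.ri_trace >= gate
        # the interpolated reference ion differs from the true profile by
        # O((scan gap / peak width)^2), up to ~0.5% at the gated peak tails
        assert np.allclose(
            rec.per_isomer_traces["3-CQA"][solved], rec.ri_trace[solved], rtol=1e-2
        )
        assert rec.per_isomer_traces["5-CQA"][solved] == pytest.approx(0.0, abs=1e-9)

    def test_pointwise_conservation_with_noise(self, segments, cqa_table, cqa_matrix):
        scenario = RunScenario(
            segments=(segments[0],),
            ratio_tables={1: cqa_table},
            isomer_peaks={
                "5-CQA": GaussianPeak(1.5, 0.05, 1e6),
                "4-CQA": GaussianPeak(1.58, 0.05, 1e5),
            },
            noise_cv=0.05,
            baseline=300.0,
            seed=8,
        )
        points = leda.pair_events(simulate_run(scenario), segments[0])
        rec = leda.deconvolve_scanwise(points, cqa_matrix)
        total = sum(rec.per_isomer_traces.values()) + rec.residual_trace
        assert np.allclose(total, rec.ri_trace, rtol=1e-9, atol=1e-9)
        for trace in rec.per_isomer_traces.values():
            assert np.all(trace >= 0.0)

    def test_empty_points_rejected(self, cqa_matrix):
        with pytest.raises(ValueError):
            leda.deconvolve_scanwise([], cqa_matrix)


class TestPeakMode:
    def test_single_isomer_peak_purity(self, cqa_matrix):
        points = _exact_points(cqa_matrix, [0.0, 1.0, 0.0], [50.0, 400.0, 50.0])
        result = leda.deconvolve_peak(points, cqa_matrix)
        assert result.fractions == pytest.approx([0.0, 1.0, 0.0], abs=1e-9)

    def test_exact_binary_70_30(self, cqa_matrix):
        points = _exact_points(cqa_matrix, [0.7, 0.3, 0.0], [50.0, 400.0, 300.0, 50.0])
        result = leda.deconvolve_peak(points, cqa_matrix)
        assert result.fractions == pytest.approx([0.7, 0.3, 0.0], abs=1e-6)

    def test_simulated_coeluting_70_30(self, segments, cqa_table, cqa_matrix):
        scenario = RunScenario(
            segments=(segments[0],),
            ratio_tables={1: cqa_table},
            isomer_peaks={
                "3-CQA": GaussianPeak(1.5, 0.3, 7e5),
                "5-CQA": GaussianPeak(1.5, 0.3, 3e5),
            },
            seed=0,
        )
        points = leda.pair_events(simulate_run(scenario), segments[0])
        result = leda.deconvolve_peak(points, cqa_matrix, window=(1.0, 2.0))
        assert result.fractions == pytest.approx([0.7, 0.3, 0.0], abs=1e-3)

    def test_peak_mode_equals_weighted_scanwise_mean(self, cqa_matrix):
        """On exact data, peak fractions are the Ri-weighted mean of scanwise ones."""
        fractions = [0.5, 0.3, 0.2]
        ri_profile = [100.0, 400.0, 900.0, 400.0, 100.0]
        points = _exact_points(cqa_matrix, fractions, ri_profile)
        rec = leda.deconvolve_scanwise(points, cqa_matrix, min_ri_fraction=0.0)
        peak = leda.deconvolve_peak(points, cqa_matrix)
        times = rec.times
        ri_area = np.trapezoid(rec.ri_trace, times)
        weighted = [
            np.trapezoid(rec.per_isomer_traces[iso], times) / ri_area
            for iso in cqa_matrix.isomer_ids
        ]
        assert peak.fractions == pytest.approx(weighted, abs=1e-9)

    def test_zero_reference_area_raises(self, cqa_matrix):
        points = [
            PairedDataPoint(0.0, 0.0, ((191.0, 0.0),), 1),
            PairedDataPoint(0.1, 0.0, ((191.0, 0.0),), 1),
        ]
        with pytest.raises(ValueError):
            leda.deconvolve_peak(points, cqa_matrix)


class TestRatioTableIO:
    def test_csv_roundtrip(self, tmp_path, dicqa_table):
        path = tmp_path / "ratios.csv"
        dicqa_table.to_csv(path)
        back = RatioTable.from_csv(path)
        assert back.isomer_ids == dicqa_table.isomer_ids
        assert back.product_mzs == dicqa_table.product_mzs
        assert np.array_equal(back.ratios, dicqa_table.ratios)

    def test_needs_at_least_two_isomers(self):
        with pytest.raises(ValueError):
            RatioTable("x", 353.0, ("A",), (191.0,), np.array([[0.3]]), np.array([[0.01]]))
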