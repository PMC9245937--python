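"""Coverage statistic, neuron size, membrane counting, QC bookkeeping."""

import numpy as np
import pytest

from synapcover.config import PipelineConfig
from synapcover.coverage import (
    aggregate_case,
    compute_coverage,
    compute_neuron_size,
    count_membrane_synapses,
    qc_evaluate,
    quantify_image,
    summarize_qc,
)
from synapcover.errors import (
    CaseExcludedError,
    EmptyInputError,
    InvalidPairingError,
)
from synapcover.imgproc import detect_puncta, normalize_intensity, segment_neuron
from synapcover.simulate import render_degenerate_image, render_neuron_image
from synapcover.types import CoverageResult, NeuronMask, PunctaSet, Punctum, QCReport


def _square_mask(side=10, canvas=32, px=1.0):
    """Solid square region: interior (side−2)², boundary ring 4(side−1)."""
    region = np.zeros((canvas, canvas), bool)
    region[5:5 + side, 5:5 + side] = True
    inner = np.zeros_like(region)
    inner[6:4 + side, 6:4 + side] = True
    return NeuronMask(interior=inner, boundary=region & ~inner,
                      pixel_size=px, component_count=1, solidity=1.0)


def _punctum_at(x, y):
    return Punctum(centroid=(x, y), area_px=4,
                   mask=np.array([[y, x], [y, x + 1], [y + 1, x], [y + 1, x + 1]]),
                   peak_intensity=1.0)


class TestNeuronSize:
    def test_ten_by_ten_square_at_one_micron(self):
        mask = _square_mask(side=10, px=1.0)
        assert mask.interior.sum() == 64
        assert mask.boundary.sum() == 36
        assert compute_neuron_size(mask) == pytest.approx(100.0)

    def test_single_interior_pixel_with_ring(self):
        mask = _square_mask(side=3, canvas=16, px=0.2)
        assert mask.interior.sum() == 1
        assert mask.boundary.sum() == 8
        assert compute_neuron_size(mask) == pytest.approx(9 * 0.04)

    def test_planted_soma_size_recovered_within_3_percent(self):
        sizes = []
        for seed in range(6):
            stack, _ = render_neuron_image(531, 0.3, 0.2, seed=seed)
            norm = normalize_intensity(stack)
            neuron = segment_neuron(norm.channels["neurofilament"], 0.2)
            sizes.append(compute_neuron_size(neuron))
        assert np.mean(sizes) == pytest.approx(531, rel=0.03)


class TestMembraneCounting:
    def test_empty_puncta_set_counts_zero(self):
        mask = _square_mask()
        empty = PunctaSet(puncta=[], shape=mask.interior.shape)
        assert count_membrane_synapses(mask, empty, 0.5) == 0

    def test_far_away_puncta_do_not_count(self):
        mask = _square_mask(side=10, canvas=48, px=1.0)
        far = PunctaSet(puncta=[_punctum_at(40, 40)], shape=(48, 48))
        assert count_membrane_synapses(mask, far, 3.0) == 0

    def test_boundary_punctum_counts_once(self):
        mask = _square_mask(side=10, canvas=32, px=1.0)
        on_edge = PunctaSet(puncta=[_punctum_at(5, 5)], shape=(32, 32))
        assert count_membrane_synapses(mask, on_edge, 0.5) == 1

    def test_all_planted_membrane_puncta_counted_noise_free(self):
        from synapcover.config import SimulationParams

        sim = SimulationParams(punctum_min_separation_um=0.7)
        stack, truth = render_neuron_image(600, 0.2, 0.2, noise_sd=0.0,
                                           seed=1, params=sim)
        norm = normalize_intensity(stack)
        neuron = segment_neuron(norm.channels["neurofilament"], 0.2)
        puncta = detect_puncta(norm.channels["gad"], 0.2)
        assert count_membrane_synapses(neuron, puncta, 0.5) == truth.n_membrane_puncta

    def test_shape_mismatch_raises(self):
        mask = _square_mask(canvas=32)
        wrong = PunctaSet(puncta=[], shape=(64, 64))
        with pytest.raises(InvalidPairingError):
            count_membrane_synapses(mask, wrong, 0.5)


class TestComputeCoverage:
    def test_direct_division(self):
        # 12×12 square at 1 µm/px → A(d) = 144 µm²; plant 36 boundary puncta
        mask = _square_mask(side=12, canvas=40, px=1.0)
        ys, xs = np.nonzero(mask.boundary)
        chosen = list(zip(xs, ys))[:36]
        puncta = PunctaSet(puncta=[_punctum_at(int(x), int(y)) for x, y in chosen],
                           shape=mask.interior.shape)
        result = compute_coverage(mask, puncta, 0.5)
        assert result.n_synapses == 36
        assert result.area_ad_um2 == pytest.approx(144.0)
        assert result.coverage == pytest.approx(0.25)

    def test_zero_synapses_gives_zero_coverage(self):
        mask = _square_mask()
        empty = PunctaSet(puncta=[], shape=mask.interior.shape)
        assert compute_coverage(mask, empty, 0.5).coverage == 0.0

    def test_group_mean_coverage_recovered_within_5_percent(self, cfg):
        covs, planted = [], []
        for seed in range(15):
            stack, truth = render_neuron_image(450, 0.348, 0.2, seed=seed)
            covs.append(quantify_image(stack, cfg).coverage)
            planted.append(truth.planted_coverage)
        assert np.mean(covs) == pytest.approx(np.mean(planted), rel=0.05)

    def test_doubling_punctum_count_doubles_coverage(self, cfg):
        ratios = []
        for seed in range(4):
            lo = quantify_image(render_neuron_image(450, 0.16, 0.2, seed=seed)[0], cfg)
            hi = quantify_image(render_neuron_image(450, 0.32, 0.2, seed=seed)[0], cfg)
            ratios.append(hi.coverage / lo.coverage)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_coverage_stable_under_pixel_refinement(self):
        changes = []
        for seed in range(4):
            c = {}
            for px in (0.2, 0.1):
                stack, _ = render_neuron_image(450, 0.32, px, seed=seed)
                c[px] = quantify_image(stack, PipelineConfig(pixel_size_um=px)).coverage
            changes.append(abs(c[0.1] / c[0.2] - 1))
        assert np.mean(changes) < 0.03

    def test_synaptophysin_channel_uses_same_workflow(self, cfg):
        # total-synapse labelling goes through the identical pipeline
        stack, _ = render_neuron_image(450, 0.32, 0.2, seed=2)
        gad_result = quantify_image(stack, cfg)
        stack.channels["synaptophysin"] = stack.channels.pop("gad")
        syn_result = quantify_image(stack, cfg)
        assert syn_result.n_synapses == gad_result.n_synapses
        assert syn_result.coverage == pytest.approx(gad_result.coverage)

    def test_intensity_scale_invariance_after_normalization(self, cfg):
        drifts = []
        for seed in range(5):
            dim, t = render_neuron_image(450, 0.32, 0.2, seed=seed,
                                         intensity_scale=0.7)
            bright, _ = render_neuron_image(450, 0.32, 0.2, seed=seed,
                                            intensity_scale=1.3)
            c_dim = quantify_image(dim, cfg).coverage
            c_bright = quantify_image(bright, cfg).coverage
            drifts.append(abs(c_bright / c_dim - 1))
        assert np.mean(drifts) < 0.05


class TestQC:
    @pytest.mark.parametrize("kind", ["poor_contrast", "multi_process",
                                      "two_neurons", "incorrect_neuron"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_degenerate_fixture_gets_its_status(self, cfg, kind, seed):
        stack, _ = render_degenerate_image(kind, seed=seed)
        assert quantify_image(stack, cfg).qc_status == kind

    def test_clean_fixture_passes(self, cfg):
        stack, _ = render_neuron_image(450, 0.32, 0.2, seed=3)
        assert quantify_image(stack, cfg).qc_status == "pass"

    def test_statuses_are_exclusive_and_exhaustive(self, cfg):
        from synapcover.types import QC_STATUSES

        for kind_seed in [("poor_contrast", 0), ("two_neurons", 1)]:
            stack, _ = render_degenerate_image(kind_seed[0], seed=kind_seed[1])
            norm_fail = None
            status = quantify_image(stack, cfg).qc_status
            assert status in QC_STATUSES


class TestSummarizeQC:
    def test_printed_totals_bookkeeping(self):
        report = QCReport.from_counts(883, {"poor_contrast": 123,
                                            "multi_process": 14,
                                            "incorrect_neuron": 4,
                                            "two_neurons": 1,
                                            "unspecified": 97})
        assert report.n_deleted == 239
        assert report.n_retained == 644
        assert round(report.percent_deleted) == 27

    def test_no_deletions(self):
        results = [CoverageResult(1, 10.0, 0.1, 10.0, "pass", "c", f"i{k}")
                   for k in range(10)]
        report = summarize_qc(results)
        assert report.n_retained == 10
        assert report.percent_deleted == 0.0

    def test_reason_counts_sum_to_deletions(self):
        rng = np.random.default_rng(0)
        statuses = rng.choice(["pass", "poor_contrast", "multi_process",
                               "incorrect_neuron", "two_neurons"], size=200)
        results = [CoverageResult(0, 1.0, 0.0, 1.0, s, "c", str(i))
                   for i, s in enumerate(statuses)]
        report = summarize_qc(results)
        assert sum(report.deleted_by_reason.values()) == report.n_deleted
        assert report.n_retained + report.n_deleted == report.n_photographed
        assert report.n_deleted == (statuses != "pass").sum()

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            summarize_qc([])


class TestAggregateCase:
    def _result(self, cov, status="pass", case="c1"):
        return CoverageResult(10, 100.0, cov, 400.0, status, case, "img")

    def test_mean_of_passing_neurons(self):
        results = [self._result(0.2), self._result(0.4)]
        mean_cov, _, n = aggregate_case(results, "c1")
        assert mean_cov == pytest.approx(0.3)
        assert n == 2

    def test_failed_neurons_are_excluded_from_mean(self):
        results = [self._result(0.2), self._result(0.9, status="poor_contrast")]
        mean_cov, _, n = aggregate_case(results, "c1")
        assert mean_cov == pytest.approx(0.2)
        assert n == 1

    def test_all_failed_raises_case_excluded(self):
        results = [self._result(0.2, status="poor_contrast")]
        with pytest.raises(CaseExcludedError):
            aggregate_case(results, "c1")
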