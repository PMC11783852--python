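import json

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mvquant import (
    QuantResult,
    ScreenConfig,
    agreement,
    decide,
    generate,
    run_protocol,
    save_gray_png,
    spec_for_density,
)
from mvquant.errors import DegenerateRegressionError


def quant_result(percent, image_id="img"):
    """A QuantResult with the requested percent area on a 10x10 grid."""
    n = round(percent)  # percent of 100 pixels
    mask = np.zeros(100, dtype=bool)
    mask[:n] = True
    return QuantResult(image_id=image_id, class_label=2, mask=mask.reshape(10, 10),
                       gray_low=45, gray_high=255)


class TestDecide:
    @pytest.mark.parametrize("percent, flagged", [(5.0, True), (4.0, False), (3.9, False)])
    def test_strictly_greater_than_threshold(self, percent, flagged):
        d = decide(quant_result(percent), alert_threshold=4.0)
        assert d.flagged is flagged
        assert "4" in d.rationale

    def test_raising_threshold_shrinks_flagged_set(self):
        rng = np.random.default_rng(7)
        qrs = [quant_result(p, f"i{k}") for k, p in enumerate(rng.integers(0, 20, 30))]
        previous = None
        for threshold in (0.0, 2.0, 4.0, 8.0, 16.0):
            flagged = {d.image_id for d in (decide(q, threshold) for q in qrs) if d.flagged}
            if previous is not None:
                assert flagged <= previous
            previous = flagged


class TestAgreement:
    def test_exact_linearity(self):
        rep = agreement([1, 2, 3], [2, 4, 6])
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(0.0)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.p_value == 0.0

    def test_constant_manual_measurements(self):
        rep = agreement([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert rep.slope == pytest.approx(0.0)
        assert rep.r_squared == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "auto, manual",
        [([1, 2], [1, 2]), ([2, 2, 2], [1, 2, 3]), ([1, np.nan, 3], [1, 2, 3])],
    )
    def test_degenerate_inputs_rejected(self, auto, manual):
        with pytest.raises(DegenerateRegressionError):
            agreement(auto, manual)

    def test_recovers_known_slope_within_confidence_interval(self):
        rng = np.random.default_rng(7)
        auto = rng.uniform(0, 10, 50)
        manual = 1.2 * auto + rng.normal(0, 0.5, 50)
        rep = agreement(auto, manual)
        stderr = stats.linregress(auto, manual).stderr
        assert abs(rep.slope - 1.2) <= stats.t.ppf(0.975, 48) * stderr

    def test_r_squared_equals_squared_correlation(self):
        rng = np.random.default_rng(13)
        auto = rng.normal(size=40)
        manual = 0.7 * auto + rng.normal(size=40)
        rep = agreement(auto, manual)
        assert rep.r_squared == pytest.approx(np.corrcoef(auto, manual)[0, 1] ** 2, abs=1e-12)

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(17)
        auto = rng.uniform(0, 5, 30)
        manual = 0.9 * auto + rng.normal(0, 1, 30)
        rep = agreement(auto, manual)
        fit = sm.OLS(manual, sm.add_constant(auto)).fit()
        assert rep.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert rep.r_squared == pytest.approx(fit.rsquared, abs=1e-10)
        assert rep.f_statistic == pytest.approx(fit.fvalue, rel=1e-8)
        assert rep.p_value == pytest.approx(fit.f_pvalue, rel=1e-8)


@pytest.fixture(scope="module")
def density_batch(tmp_path_factory):
    """PNG files at true class-2 densities near 2%, 5% and 9%."""
    out = tmp_path_factory.mktemp("batch")
    truths = {}
    for target in (2.0, 5.0, 9.0):
        spec = spec_for_density(target, seed=7000 + int(target), width=256, height=256,
                                image_id=f"density-{int(target)}")
        img, _, true_pct = generate(spec)
        save_gray_png(img.pixels, out / f"{img.source_id}.png")
        truths[img.source_id] = true_pct
    return out, truths


class TestRunProtocol:
    def test_decisions_follow_fixture_ground_truth(self, fixture_model_256, density_batch):
        out, truths = density_batch
        paths = sorted(out.glob("*.png"))
        report = run_protocol(paths, fixture_model_256)
        by_image = {r["image"]: r for r in report.records}
        assert by_image["density-2"]["status"] == "clear"
        assert by_image["density-5"]["status"] == "flagged"
        assert by_image["density-9"]["status"] == "flagged"
        assert report.n_flagged == 2 and report.n_clear == 1
        assert report.exit_code == 0
        for image_id, rec in by_image.items():
            assert rec["percent_area"] == pytest.approx(truths[image_id], abs=1.0)

    def test_unreadable_file_isolated(self, fixture_model_256, density_batch, tmp_path):
        out, _ = density_batch
        bad = tmp_path / "broken.png"
        bad.write_text("not a png")
        paths = sorted(out.glob("*.png")) + [bad]
        report = run_protocol(paths, fixture_model_256)
        assert report.n_errors == 1
        assert report.n_flagged + report.n_clear == 3
        assert report.exit_code == 1

    def test_empty_batch_succeeds_with_zero_counts(self, fixture_model_256):
        report = run_protocol([], fixture_model_256)
        assert (report.n_flagged, report.n_clear, report.n_skipped, report.n_errors) == (0, 0, 0, 0)
        assert report.exit_code == 0

    def test_records_invariant_to_batch_order(self, fixture_model_256, density_batch):
        out, _ = density_batch
        paths = sorted(out.glob("*.png"))
        fwd = {r["image"]: r for r in run_protocol(paths, fixture_model_256).records}
        rev = {r["image"]: r for r in run_protocol(paths[::-1], fixture_model_256).records}
        assert fwd == rev

    def test_dark_image_skipped_never_flagged(self, fixture_model_256, tmp_path):
        dark = tmp_path / "dark.png"
        save_gray_png(np.zeros((64, 64), np.uint8), dark)
        report = run_protocol([dark], fixture_model_256)
        rec = report.records[0]
        assert rec["status"] == "skipped"
        assert rec["reason"] == "too dark"
        assert rec["flagged"] is False

    def test_jsonl_records_are_parseable(self, fixture_model_256, density_batch, tmp_path):
        out, _ = density_batch
        report = run_protocol(sorted(out.glob("*.png")), fixture_model_256, ScreenConfig())
        path = tmp_path / "decisions.jsonl"
        report.write_jsonl(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        assert all("percent_area" in json.loads(line) for line in lines)
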