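"""Feature extraction: autocorrelation, burst segmentation, response
times, output integration, responder calls, and noise decomposition."""

import numpy as np
import pytest

from burstabc.promoter_sim import (
    DEFAULT_PROFILE,
    KineticParams,
    PromoterModelSpec,
    Protocol,
    TraceDataset,
    build_topology,
    simulate_induction,
    simulate_population,
)
from burstabc.synthetic_data import add_measurement_noise
from burstabc.trace_features import (
    AcfSummary,
    allele_output_correlation,
    autocorrelation,
    classify_responder,
    extract_bursts,
    noise_decomposition,
    response_time,
    total_rna_output,
)


class TestAutocorrelation:
    def test_lag0_is_one_and_white_noise_decays(self, rng):
        noise = rng.normal(0, 1.5, 250)
        acf = autocorrelation(noise, max_lag=50, frame_interval=3.0)
        assert acf.acf[0] == 1.0
        assert abs(acf.lag1) < 3 / np.sqrt(250)

    def test_matches_statsmodels_estimator(self, small_dataset):
        # independent oracle: statsmodels' biased sample ACF
        from statsmodels.tsa.stattools import acf as sm_acf

        x = small_dataset.intensity[0]
        ours = autocorrelation(x, max_lag=40, frame_interval=3.0).acf
        theirs = sm_acf(x, nlags=40, adjusted=False, fft=False)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_half_life_of_known_signal(self, rng):
        # AR-free oracle: a pure cosine has ACF cos(2 pi lag / period),
        # which crosses 0.5 at period/6
        dt, period = 1.0, 60.0
        t = np.arange(2000) * dt
        x = np.cos(2 * np.pi * t / period) + 0.5 * np.cos(4 * np.pi * t / period)
        # closed-form ACF of the two-component signal:
        # (cos(w L) + 0.25 cos(2 w L)) / 1.25; solve crossing numerically
        lags = np.linspace(0, 30, 30001)
        theo = (np.cos(2 * np.pi * lags / period) + 0.25 * np.cos(4 * np.pi * lags / period)) / 1.25
        expected = lags[np.argmax(theo < 0.5)]
        acf = autocorrelation(x, max_lag=50, frame_interval=dt)
        assert acf.half_life == pytest.approx(expected, abs=dt)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            autocorrelation(np.ones(250), max_lag=50, frame_interval=3.0)


class TestBurstExtraction:
    def test_flat_trace_is_one_long_off(self):
        ann = extract_bursts(np.zeros(250), frame_interval=3.0)
        assert ann.on_intervals == []
        assert len(ann.off_intervals) == 1
        assert ann.off_intervals[0] == (0.0, 747.0)

    def test_two_known_ramps(self):
        # two steep rises of 12 RNA over 15 min, separated by decays
        dt = 3.0
        t = np.arange(120) * dt
        x = np.zeros(120)
        for start in (60.0, 240.0):
            rise = (t >= start) & (t < start + 15)
            x[rise] = (t[rise] - start) * 0.8
            fall = (t >= start + 15) & (t < start + 45)
            x[fall] = 12 * (1 - (t[fall] - start - 15) / 30)
        ann = extract_bursts(x, frame_interval=dt)
        assert len(ann.on_intervals) == 2
        assert ann.burst_sizes == pytest.approx([12.0, 12.0], rel=0.25)
        for (s, e), start in zip(ann.on_intervals, (60.0, 240.0)):
            assert s == pytest.approx(start, abs=2 * dt)

    def test_intervals_alternate_and_cover_span(self, small_dataset):
        tr = next(small_dataset.traces())
        ann = extract_bursts(tr)
        ivs = sorted(ann.on_intervals + ann.off_intervals)
        assert ivs[0][0] == tr.times[0]
        assert ivs[-1][1] == tr.times[-1]
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == pytest.approx(s2)
        assert len(ann.burst_sizes) == len(ann.on_intervals)
        assert np.all(ann.burst_sizes >= 0)

    def test_recovers_generating_off_time(self):
        # ground-truth closure: noise-free two-state population.  The
        # observable OFF gap joins consecutive OFF periods across ON
        # passages that initiate zero transcripts (geometric burst sizes:
        # P(0) = 1/(1+b)), so its mean is t_off * (1 + 1/b).
        t_off, b = 60.0, 10.0
        params = KineticParams(0.6, t_off, b)
        model = PromoterModelSpec(build_topology("1-1-0"), params)
        ds = simulate_population(model, 60, rng=np.random.default_rng(21))
        offs = []
        for tr in ds.traces():
            ann = extract_bursts(tr)
            offs.extend(ann.off_durations)
        assert np.mean(offs) == pytest.approx(t_off * (1 + 1 / b), rel=0.2)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            extract_bursts(np.zeros(3), frame_interval=3.0)


class TestResponseTime:
    def test_never_above_threshold_is_absent(self):
        assert response_time(np.zeros(100), frame_interval=1.5) is None

    def test_sustained_step_detected_at_step(self):
        x = np.zeros(200)
        x[80:] = 6.0
        rt = response_time(x, stimulus_min=51.0, frame_interval=1.5)
        # median filter half-window tolerance around the true step frame
        assert rt == pytest.approx(80 * 1.5 - 51.0, abs=3 * 1.5)

    def test_translation_equivariance(self, rng):
        base = np.zeros(200)
        base[100:140] = rng.uniform(3, 8, 40)
        r0 = response_time(base, frame_interval=1.5)
        shifted = np.roll(base, 20)
        r1 = response_time(shifted, frame_interval=1.5)
        assert r1 == pytest.approx(r0 + 20 * 1.5)

    def test_two_state_induction_cv_near_unity(self, reference_params):
        model = PromoterModelSpec(build_topology("1-1-5"), reference_params)
        rng = np.random.default_rng(6)
        ds = add_measurement_noise(simulate_induction(model, 120, rng=rng), rng=rng)
        rts = np.array(
            [r for tr in ds.traces() if (r := response_time(tr, stimulus_min=51.0)) is not None]
        )
        assert len(rts) > 100
        assert rts.std() / rts.mean() == pytest.approx(1.0, abs=0.2)


class TestTotalOutput:
    def test_zero_and_self_normalization(self):
        assert total_rna_output(np.zeros(100), frame_interval=3.0) == 0.0
        t = np.arange(0, 45, 0.05)
        one = DEFAULT_PROFILE(t)
        assert total_rna_output(one, frame_interval=0.05) == pytest.approx(1.0, rel=0.005)

    def test_output_arithmetic(self):
        # flat trace of 40 RNA for 800 min: AUC 32,000 RNA*min over a
        # 30 RNA*min unit profile area -> ~1,067 transcripts
        from burstabc.promoter_sim import SignalProfile

        prof = SignalProfile(delay=0.0, ramp=0.0, residence=30.0)
        x = np.full(801, 40.0)
        assert total_rna_output(x, prof, frame_interval=1.0) == pytest.approx(32000 / 30, rel=1e-6)

    def test_background_floor(self):
        x = np.full(100, 0.5)
        assert total_rna_output(x, background=1.0, frame_interval=3.0) == 0.0


class TestResponderClassification:
    def test_background_is_nonresponder_bursting_is_responder(self, rng, small_dataset):
        noise = rng.normal(0, 1.5, 250)
        assert not classify_responder(autocorrelation(noise, frame_interval=3.0))
        tr = next(small_dataset.traces())
        assert classify_responder(autocorrelation(tr))

    def test_responder_fraction_matches_no_event_probability(self):
        # responders are cells with at least one productive activation in
        # the window: activations arrive at rate 1/t_off but a geometric
        # burst initiates zero transcripts with probability 1/(1+b), so
        # P(responder) = 1 - exp(-T * (b/(1+b)) / t_off) ~ 0.47 at
        # t_off = 1082 min, T = 747 min (noise-free classification;
        # all-zero traces have an undefined ACF and count as
        # non-responders)
        t_off, b = 1082.0, 10.0
        params = KineticParams(0.6, t_off, b)
        model = PromoterModelSpec(build_topology("1-1-0"), params)
        ds = simulate_population(model, 300, rng=np.random.default_rng(13))
        calls = []
        for tr in ds.traces():
            try:
                calls.append(classify_responder(autocorrelation(tr)))
            except ValueError:
                calls.append(False)
        expected = 1 - np.exp(-747.0 * (b / (1 + b)) / t_off)
        assert np.mean(calls) == pytest.approx(expected, abs=0.1)


class TestNoiseDecomposition:
    def test_identical_cells_have_no_extrinsic_noise(self, rng):
        row = np.abs(rng.normal(5, 2, 200))
        X = np.tile(row, (12, 1))
        dec = noise_decomposition(X)
        assert dec.cv2_ext == pytest.approx(0.0, abs=1e-12)

    def test_constant_cells_have_no_intrinsic_noise(self):
        X = np.outer(np.arange(1, 13, dtype=float), np.ones(100))
        dec = noise_decomposition(X)
        assert dec.cv2_int == 0.0
        assert dec.cv2_ext > 0

    def test_total_is_exact_sum(self, small_dataset):
        dec = noise_decomposition(small_dataset)
        assert dec.cv2_total == pytest.approx(dec.cv2_int + dec.cv2_ext, rel=1e-12)
        # and, uncorrected, the split reproduces the pooled variance
        X = small_dataset.intensity
        assert dec.cv2_total == pytest.approx(X.var() / X.mean() ** 2, rel=1e-9)

    def test_frequency_modulated_scaling(self):
        # two-state, no extrinsic noise: total (= intrinsic) CV^2 follows
        # the inverse noise-mean law with a constant effective burst size
        # b_eff = (2b + 1) * int f^2 / int f  (geometric burst sizes,
        # near-instantaneous bursts)
        b = 8.0
        prof = DEFAULT_PROFILE
        s = np.linspace(0, 31, 31001)
        f = prof(s)
        b_eff = (2 * b + 1) * np.trapezoid(f**2, s) / np.trapezoid(f, s)
        products = []
        for i, t_off in enumerate((200.0, 100.0, 50.0)):
            params = KineticParams(0.56, t_off, b)
            model = PromoterModelSpec(build_topology("1-1-0"), params)
            ds = simulate_population(
                model, 200, Protocol(n_frames=400), rng=np.random.default_rng(30 + i)
            )
            dec = noise_decomposition(ds)
            products.append(dec.cv2_total * dec.mean_rna)
        products = np.array(products)
        np.testing.assert_allclose(products, b_eff, rtol=0.15)


class TestAlleleCorrelation:
    def _dual(self, intensity, n_cells):
        n_frames = intensity.shape[1]
        return TraceDataset(
            intensity=intensity,
            times=np.arange(n_frames) * 3.0,
            cell_ids=np.repeat(np.arange(n_cells), 2),
            allele_ids=np.tile([0, 1], n_cells),
        )

    def test_duplicated_alleles_give_unit_correlation(self, rng):
        traces = np.abs(rng.normal(5, 2, (15, 100)))
        ds = self._dual(np.repeat(traces, 2, axis=0), 15)
        corr = allele_output_correlation(ds, n_bootstrap=50, rng=rng)
        assert corr.pcc == pytest.approx(1.0)
        np.testing.assert_allclose(corr.per_cell_trace_pcc, 1.0)

    def test_independent_alleles_uncorrelated(self, reference_params):
        params = KineticParams(0.6, 50.0, 10.0)
        model = PromoterModelSpec(build_topology("1-1-0"), params)
        rng = np.random.default_rng(17)
        ds = simulate_population(model, 60, alleles_per_cell=2, rng=rng)
        corr = allele_output_correlation(ds, n_bootstrap=100, rng=rng)
        assert abs(corr.pcc) < 3 / np.sqrt(60)

    def test_unpaired_cells_rejected(self, rng):
        ds = TraceDataset(
            intensity=rng.normal(0, 1, (3, 50)),
            times=np.arange(50) * 3.0,
            cell_ids=np.array([0, 0, 1]),
            allele_ids=np.array([0, 1, 0]),
        )
        with pytest.raises(ValueError, match="exactly 2"):
            allele_output_correlation(ds, n_bootstrap=10, rng=rng)
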