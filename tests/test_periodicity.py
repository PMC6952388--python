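"""Autocorrelation amplitude, puncta detection, and group summaries."""

import numpy as np
import pytest

import axonquant as aq
from axonquant.errors import DegenerateProfileError, InvalidInputError
from conftest import normalize_self


def brute_force_peaks(y, min_prominence, distance):
    """Exhaustive scan for local maxima satisfying the same definition the
    detector uses: a sample strictly greater than both neighbours; peaks
    closer than ``distance`` samples to a taller peak are dropped (taller
    peaks claim ground first); survivors must rise at least
    ``min_prominence`` above the higher of the two minima separating them
    from the nearest taller ground on each side (or the signal edge)."""
    n = len(y)
    cands = [i for i in range(1, n - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]

    # distance pruning, taller peaks first
    alive = set(cands)
    for p in sorted(cands, key=lambda i: -y[i]):
        if p not in alive:
            continue
        for q in cands:
            if q != p and q in alive and abs(q - p) < distance:
                alive.discard(q)

    kept = []
    for p in sorted(alive):
        lmin = y[p]
        i = p - 1
        while i >= 0 and y[i] <= y[p]:
            lmin = min(lmin, y[i])
            i -= 1
        rmin = y[p]
        i = p + 1
        while i < n and y[i] <= y[p]:
            rmin = min(rmin, y[i])
            i += 1
        if y[p] - max(lmin, rmin) >= min_prominence:
            kept.append(p)
    return kept


class TestAutocorrelate:
    def test_pure_sinusoid_limit(self, cosine_profile):
        """cos(2πx/1µm) over 50 µm: first peak at 1.0 µm, amplitude ~2."""
        ac = aq.autocorrelate(cosine_profile, max_lag=5.0)
        assert ac.periodic
        assert abs(ac.first_peak_lag - 1.0) <= 2 * 0.063
        assert ac.amplitude == pytest.approx(2.0, abs=0.1)
        assert ac.valley_lags[0] < ac.first_peak_lag < ac.valley_lags[1]

    def test_lag_zero_is_one(self, cosine_profile):
        ac = aq.autocorrelate(cosine_profile)
        assert ac.r[0] == pytest.approx(1.0)
        assert ac.lags[0] == 0.0

    def test_amplitude_definition(self, cosine_profile):
        ac = aq.autocorrelate(cosine_profile)
        assert ac.amplitude == pytest.approx(
            ac.first_peak_r - 0.5 * (ac.valley_rs[0] + ac.valley_rs[1]))

    def test_constant_profile_is_degenerate(self):
        x = np.arange(100) * 0.063
        prof = aq.normalize_profile(aq.LineProfile(0.063, x, np.full(100, 2.0)), 2.0)
        with pytest.raises(DegenerateProfileError):
            aq.autocorrelate(prof)

    def test_unnormalized_profile_rejected(self):
        x = np.arange(100) * 0.063
        with pytest.raises(InvalidInputError):
            aq.autocorrelate(aq.LineProfile(0.063, x, np.random.default_rng(0).random(100)))

    def test_white_noise_null_amplitude(self):
        """Aperiodic profiles rarely show amplitude > 0.5 (200 seeds)."""
        small = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.arange(794) * 0.063
            prof = normalize_self(aq.LineProfile(0.063, x, np.abs(rng.normal(1, 0.2, 794))))
            ac = aq.autocorrelate(prof)
            amp = ac.amplitude if ac.periodic else 0.0
            if amp <= 0.5:
                small += 1
        assert small >= 0.95 * 200

    def test_affine_intensity_invariance(self):
        """autocorrelate(a·x + b) == autocorrelate(x) for a > 0."""
        prof, _ = aq.generate_profile(aq.PunctaModel(jitter_sd=0.05), seed=3)
        p1 = normalize_self(prof)
        scaled = aq.LineProfile(p1.sampling_interval, p1.arc_positions,
                                p1.raw * 3.7 + 11.0)
        p2 = aq.normalize_profile(scaled, 1.0)
        a1, a2 = aq.autocorrelate(p1), aq.autocorrelate(p2)
        np.testing.assert_allclose(a1.r, a2.r, atol=1e-9)
        assert a1.amplitude == pytest.approx(a2.amplitude, abs=1e-9)

    def test_gap_insertion_never_raises_amplitude(self):
        """Deleting signal in gaps degrades periodicity (seeded)."""
        for seed in range(20):
            noise = aq.NoiseModel("gaussian", gaussian_sd=0.05)
            p0, _ = aq.generate_profile(aq.PunctaModel(), noise=noise, seed=seed)
            pg, _ = aq.generate_profile(aq.PunctaModel(),
                                        aq.GapSpec(((15.0, 27.0),), 0.0), noise, seed=seed)
            ref = p0.raw.mean()
            a0 = aq.autocorrelate(aq.normalize_profile(p0, ref)).amplitude
            ag = aq.autocorrelate(aq.normalize_profile(pg, ref)).amplitude
            assert ag <= a0 + 0.05  # estimator-noise allowance

    def test_spacing_recovery_across_periods(self):
        """First-peak lag recovers spacing {0.8, 1.0, 1.5} µm at SNR 5
        in >= 95% of seeds."""
        for d in (0.8, 1.0, 1.5):
            hits = 0
            for seed in range(40):
                prof, _ = aq.generate_profile(
                    aq.PunctaModel(spacing_d=d),
                    noise=aq.NoiseModel("gaussian", gaussian_sd=0.2), seed=seed)
                ac = aq.autocorrelate(normalize_self(prof))
                if ac.periodic and abs(ac.first_peak_lag - d) <= 2 * 0.063:
                    hits += 1
            assert hits >= 0.95 * 40


class TestDetectPuncta:
    def test_noiseless_grid_detection(self):
        prof, truth = aq.generate_profile(aq.PunctaModel(), seed=0)
        pts = aq.detect_puncta(normalize_self(prof))
        # 51 puncta on the grid; endpoint samples cannot host a peak
        assert 49 <= pts.n <= 51
        assert pts.mean_spacing == pytest.approx(1.0, abs=0.063)

    def test_jittered_spacing_estimate_unbiased(self):
        """Mean of mean_spacing over 100 jittered profiles within 1.0±0.02 µm."""
        spacings = []
        for seed in range(100):
            prof, _ = aq.generate_profile(aq.PunctaModel(jitter_sd=0.05), seed=seed)
            spacings.append(aq.detect_puncta(normalize_self(prof)).mean_spacing)
        assert np.mean(spacings) == pytest.approx(1.0, abs=0.02)

    def test_single_peak_has_undefined_spacing(self):
        x = np.arange(200) * 0.063
        y = np.exp(-((x - 6.0) ** 2) / (2 * 0.15**2)) + 0.01
        pts = aq.detect_puncta(aq.normalize_profile(aq.LineProfile(0.063, x, y), 1.0))
        assert pts.n == 1
        assert np.isnan(pts.mean_spacing)

    @pytest.mark.parametrize("seed", range(8))
    def test_equivalence_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.arange(600) * 0.063
        y = np.abs(rng.normal(0.5, 0.3, 600))
        prof = aq.normalize_profile(aq.LineProfile(0.063, x, y), 1.0)
        pts = aq.detect_puncta(prof, min_prominence=0.3, min_separation=0.3)
        distance = max(1, round(0.3 / 0.063))
        oracle = brute_force_peaks(prof.normalized, 0.3, distance)
        got = np.round(pts.positions / 0.063).astype(int)
        assert sorted(got.tolist()) == sorted(oracle)


class TestPeriodicityReport:
    def _profiles(self, f, n, base_seed):
        out = []
        for s in range(n):
            p, _ = aq.generate_profile(
                aq.PunctaModel(jitter_sd=0.03, amplitude_cv=0.1, continuous_fraction=f),
                noise=aq.NoiseModel("gaussian", gaussian_sd=0.05),
                seed=base_seed + s)
            out.append(normalize_self(p))
        return out

    def test_identical_parameter_groups_agree(self):
        groups = {"a": self._profiles(0.0, 25, 0), "b": self._profiles(0.0, 25, 1000)}
        rep = aq.periodicity_report(groups).set_index("group")
        se = np.sqrt(rep.amplitude_sd["a"] ** 2 / 25 + rep.amplitude_sd["b"] ** 2 / 25)
        assert abs(rep.amplitude_mean["a"] - rep.amplitude_mean["b"]) <= 2 * se + 1e-9

    def test_continuous_group_has_lower_amplitude(self):
        groups = {"periodic": self._profiles(0.0, 10, 0),
                  "continuous": self._profiles(1.0, 10, 500)}
        rep = aq.periodicity_report(groups).set_index("group")
        assert (rep.amplitude_mean["continuous"] < rep.amplitude_mean["periodic"]
                or np.isnan(rep.amplitude_mean["continuous"]))

    def test_single_profile_group_reports_nan_sd(self):
        rep = aq.periodicity_report({"solo": self._profiles(0.0, 1, 7)})
        assert np.isnan(rep.amplitude_sd.iloc[0])

    def test_empty_group_skipped(self):
        rep = aq.periodicity_report({"empty": [], "ok": self._profiles(0.0, 2, 3)})
        assert rep.group.tolist() == ["ok"]
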