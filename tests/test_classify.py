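"""Attachment-gap classification rules and breakage linkage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import axonquant as aq
from axonquant.errors import InvalidInputError, ReconciliationError
from conftest import normalize_self


def profile_with_deleted_puncta(n_deleted, seed=0):
    """Noiseless periodic profile with ``n_deleted`` consecutive puncta
    fully removed (one 1 µm gap cell per punctum)."""
    if n_deleted:
        gaps = aq.GapSpec(((10.0 - 0.5, 10.0 + n_deleted - 0.5),), 0.0)
    else:
        gaps = aq.GapSpec()
    prof, _ = aq.generate_profile(aq.PunctaModel(), gaps, seed=seed)
    ref, _ = aq.generate_profile(aq.PunctaModel(), seed=seed)
    return aq.normalize_profile(prof, ref.raw.mean())


class TestL4Rule:
    def test_intact_profile_is_continuous(self):
        call = aq.classify_l4(profile_with_deleted_puncta(0), expected_spacing=1.0)
        assert call.n_subthreshold_puncta == 0
        assert call.label == "continuous"

    @pytest.mark.parametrize("n_deleted,label", [
        (4, "continuous"),
        (5, "continuous"),  # boundary: literal "> 5" rule
        (6, "gaps"),
        (8, "gaps"),
    ])
    def test_rule_flips_exactly_above_five(self, n_deleted, label):
        call = aq.classify_l4(profile_with_deleted_puncta(n_deleted), expected_spacing=1.0)
        assert call.n_subthreshold_puncta == n_deleted
        assert call.label == label

    def test_boundary_case_logged(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="axonquant.classify"):
            aq.classify_l4(profile_with_deleted_puncta(5), expected_spacing=1.0)
        assert any("boundary" in r.message for r in caplog.records)

    def test_short_profile_rejected(self):
        x = np.arange(5) * 0.063
        p = aq.normalize_profile(aq.LineProfile(0.063, x, np.ones(5)), 1.0)
        with pytest.raises(InvalidInputError):
            aq.classify_l4(p, expected_spacing=1.0)

    def test_spacing_from_puncta_set(self):
        prof = profile_with_deleted_puncta(0)
        pts = aq.detect_puncta(prof)
        call = aq.classify_l4(prof, puncta=pts)
        assert call.label == "continuous"

    @settings(max_examples=20, deadline=None)
    @given(t1=st.floats(0.05, 0.5), t2=st.floats(0.05, 0.5), seed=st.integers(0, 50))
    def test_threshold_monotonicity(self, t1, t2, seed):
        """A higher threshold never counts fewer missing puncta."""
        lo, hi = sorted((t1, t2))
        prof = profile_with_deleted_puncta(seed % 10, seed=seed)
        n_lo = aq.classify_l4(prof, expected_spacing=1.0, threshold=lo).n_subthreshold_puncta
        n_hi = aq.classify_l4(prof, expected_spacing=1.0, threshold=hi).n_subthreshold_puncta
        assert n_hi >= n_lo


class TestAdultRule:
    def make_profile(self, gap_um=None):
        gaps = aq.GapSpec(((20.0, 20.0 + gap_um),), 0.0) if gap_um else aq.GapSpec()
        prof, _ = aq.generate_profile(
            aq.PunctaModel(continuous_fraction=1.0), gaps, seed=0)
        ref, _ = aq.generate_profile(aq.PunctaModel(continuous_fraction=1.0), seed=0)
        return aq.normalize_profile(prof, ref.raw.mean())

    def test_plateau_profile_has_no_gap(self):
        call = aq.classify_adult(self.make_profile())
        assert call.longest_gap == 0.0
        assert call.label == "continuous"

    def test_twelve_um_gap_labels_gaps(self):
        call = aq.classify_adult(self.make_profile(12.0))
        assert call.longest_gap == pytest.approx(12.0, abs=0.2)
        assert call.label == "gaps"

    def test_nine_um_gap_stays_continuous(self):
        call = aq.classify_adult(self.make_profile(9.0))
        assert call.longest_gap == pytest.approx(9.0, abs=0.2)
        assert call.label == "continuous"

    def test_run_length_threshold_monotonicity(self):
        prof = self.make_profile(8.0)
        g_lo = aq.classify_adult(prof, threshold=0.1).longest_gap
        g_hi = aq.classify_adult(prof, threshold=0.4).longest_gap
        assert g_hi >= g_lo

    def test_fully_excluded_profile_rejected(self):
        prof = self.make_profile().with_exclusion([(0.0, 51.0)])
        with pytest.raises(InvalidInputError):
            aq.classify_adult(prof)

    def test_rule_fidelity_brute_force(self):
        """Label equals a direct re-evaluation of the printed rule."""
        for gap in (0, 5.0, 9.9, 10.1, 15.0):
            prof = self.make_profile(gap or None)
            call = aq.classify_adult(prof)
            below = prof.normalized < 0.2
            runs, cur = [], 0
            for b in below:
                cur = cur + 1 if b else 0
                runs.append(cur)
            longest = max(runs) * prof.sampling_interval
            assert call.label == ("gaps" if longest > 10.0 else "continuous")


class TestGeneratorAgreement:
    def test_noiseless_agreement_100_seeds(self):
        """Classifier labels equal generator ground truth, 100/100 seeds."""
        agree = 0
        for seed in range(100):
            gap_len = 6.0 + (seed % 10)  # 6..15 µm, straddles the 10 µm rule
            gaps = aq.GapSpec(((18.0, 18.0 + gap_len),), 0.0)
            prof, truth = aq.generate_profile(
                aq.PunctaModel(jitter_sd=0.02, amplitude_cv=0.05), gaps, seed=seed)
            ref, _ = aq.generate_profile(
                aq.PunctaModel(jitter_sd=0.02, amplitude_cv=0.05), seed=seed)
            norm = aq.normalize_profile(prof, ref.raw.mean())
            ok_l4 = aq.classify_l4(norm, expected_spacing=1.0).label == truth.true_label_l4
            ok_ad = aq.classify_adult(norm).label == truth.true_label_adult
            agree += ok_l4 and ok_ad
        assert agree == 100

    def test_noisy_agreement_at_snr5(self):
        """At peak SNR 5 (shot noise; peak σ = amplitude/5), the
        noise-robust classification settings agree with ground truth
        >= 95% over 100 seeds."""
        agree = 0
        for seed in range(100):
            gap_len = 5.5 + (seed % 10)
            gaps = aq.GapSpec(((18.0, 18.0 + gap_len),), 0.0)
            # photon_scale 26 counts/a.u.: sd at the punctum peak
            # sqrt(1.05/26) ~ 0.20 a.u. = amplitude/5
            noise = aq.NoiseModel("poisson", photon_scale=26.0)
            prof, truth = aq.generate_profile(aq.PunctaModel(), gaps, noise, seed=seed)
            ref, _ = aq.generate_profile(aq.PunctaModel(), seed=seed)
            norm = aq.normalize_profile(prof, ref.raw.mean())
            ok_l4 = aq.classify_l4(norm, expected_spacing=1.0, smooth_um=0.15,
                                   peak_prominence=0.4).label == truth.true_label_l4
            ok_ad = aq.classify_adult(norm, median_um=0.3,
                                      close_um=0.3).label == truth.true_label_adult
            agree += ok_l4 and ok_ad
        assert agree >= 95


class TestCrosstab:
    def test_degenerate_single_cell(self):
        calls = [aq.AdultGapCall(12.0, 10.0, "gaps", "broken")] * 7
        tab = aq.crosstab_attachment_breakage(calls)
        assert len(tab) == 1
        assert tab["count"].iloc[0] == 7

    def test_breaks_only_in_gap_animals(self):
        calls = ([aq.AdultGapCall(12.0, 10.0, "gaps", "broken")] * 5
                 + [aq.AdultGapCall(12.0, 10.0, "gaps", "intact")] * 3
                 + [aq.AdultGapCall(0.0, 10.0, "continuous", "intact")] * 8)
        tab = aq.crosstab_attachment_breakage(calls)
        broken_cont = tab[(tab.label == "continuous") & (tab.break_status == "broken")]
        assert broken_cont.empty

    def test_empty_input_gives_empty_table(self):
        assert aq.crosstab_attachment_breakage([]).empty

    def test_unknown_status_excluded(self):
        calls = [aq.AdultGapCall(12.0, 10.0, "gaps", "unknown"),
                 aq.AdultGapCall(12.0, 10.0, "gaps", "broken")]
        tab = aq.crosstab_attachment_breakage(calls)
        assert tab["count"].sum() == 1


class TestPredictiveLinkage:
    def _cohort(self, p_gap, p_cont, n_per_arm, seed):
        rng = np.random.default_rng(seed)
        l4, breaks = {}, {}
        for i in range(n_per_arm):
            l4[f"g{i}"] = "gaps"
            breaks[f"g{i}"] = bool(rng.random() < p_gap)
            l4[f"c{i}"] = "continuous"
            breaks[f"c{i}"] = bool(rng.random() < p_cont)
        return l4, breaks

    def test_proportions_recovered(self):
        l4, breaks = self._cohort(0.8, 0.05, 200, seed=0)
        tab = aq.predictive_linkage(l4, breaks).set_index("label")
        assert tab.p_broken["gaps"] == pytest.approx(0.8, abs=0.1)
        assert tab.p_broken["continuous"] == pytest.approx(0.05, abs=0.1)

    def test_null_cohort_intervals_overlap(self):
        l4, breaks = self._cohort(0.3, 0.3, 300, seed=1)
        tab = aq.predictive_linkage(l4, breaks).set_index("label")
        assert tab.ac_lower["gaps"] <= tab.ac_upper["continuous"]
        assert tab.ac_lower["continuous"] <= tab.ac_upper["gaps"]

    def test_empty_arm_not_estimable(self):
        tab = aq.predictive_linkage({"a": "gaps"}, {"a": True}).set_index("label")
        assert np.isnan(tab.p_broken["continuous"])

    def test_unmatched_ids_raise_with_offenders(self):
        with pytest.raises(ReconciliationError) as exc:
            aq.predictive_linkage({"a": "gaps"}, {"b": True})
        assert set(exc.value.offenders) == {"a", "b"}
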