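"""Synthetic cohort generator: fidelity, determinism, morphology, response."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from fetopulm.doppler import DopplerIndices, WaveformError, compute_indices, delta_change
from fetopulm.synthetic import (
    CohortConfig,
    apply_hyperoxygenation,
    config_from_yaml,
    generate_cohort,
    generate_waveform,
    read_cohort_csv,
    write_cohort_csv,
)

NAN = math.nan


def mpa_targets(pi=2.24, vti=10.7, psv=78.5, at=41.5, et=191.7):
    return DopplerIndices(PI=pi, VTI=vti, PSV=psv, AT=at, ET=et, AT_ET=at / et)


class TestGenerateWaveform:
    @pytest.mark.parametrize("pi,vti,psv,at,et", [
        (2.24, 10.7, 78.5, 41.5, 191.7),   # control baseline means
        (2.16, 9.15, 68.6, 44.8, 188.7),   # FGR baseline means
    ])
    def test_mpa_indices_reproduced_within_one_percent(self, pi, vti, psv, at, et):
        tg = mpa_targets(pi, vti, psv, at, et)
        w = generate_waveform("MPA", tg, cycle_s=pi * vti / psv)
        ix = compute_indices(w)
        for k in ("PI", "VTI", "PSV", "AT", "ET"):
            assert getattr(ix, k) == pytest.approx(getattr(tg, k), rel=0.01), k

    def test_mpa_vti_equals_closed_form_beat_integral(self):
        """The shoulder level is solved analytically, so the quadrature of
        the realized trace must return the requested integral to 0.1%."""
        tg = mpa_targets()
        w = generate_waveform("MPA", tg, cycle_s=2.24 * 10.7 / 78.5)
        vti = float(np.clip(w.cycle_velocity(), 0, None).sum() * w.dt_s)
        assert vti == pytest.approx(10.7, rel=1e-3)

    def test_mpa_zero_diastolic_velocity(self):
        w = generate_waveform("MPA", mpa_targets(), cycle_s=2.24 * 10.7 / 78.5)
        t = w.cycle_times()
        assert np.all(w.cycle_velocity()[t > 0.1925] == 0.0)

    def test_ipa_indices_and_reverse_lobe(self):
        tg = DopplerIndices(PI=3.69, VTI=7.03, PSV=NAN, AT=NAN, ET=NAN,
                            AT_ET=NAN, PEDRF=-13.9)
        w = generate_waveform("IPA", tg, cycle_s=60 / 140)
        ix = compute_indices(w)
        assert ix.PI == pytest.approx(3.69, rel=0.01)
        assert ix.VTI == pytest.approx(7.03, rel=0.01)
        assert ix.PEDRF == pytest.approx(-13.9, rel=0.01)
        assert w.cycle_velocity().min() < -10  # genuine reversal present

    def test_da_positive_throughout(self):
        tg = DopplerIndices(PI=NAN, VTI=NAN, PSV=70.0, AT=NAN, ET=NAN, AT_ET=NAN)
        w = generate_waveform("DA", tg, cycle_s=60 / 140)
        assert w.cycle_velocity().min() > 0

    def test_same_seed_bit_identical(self):
        tg = mpa_targets()
        a = generate_waveform("MPA", tg, 2.24 * 10.7 / 78.5, noise_sd=0.5,
                              rng=np.random.default_rng(7))
        b = generate_waveform("MPA", tg, 2.24 * 10.7 / 78.5, noise_sd=0.5,
                              rng=np.random.default_rng(7))
        assert np.array_equal(a.v_cm_s, b.v_cm_s)

    def test_inconsistent_targets_rejected(self):
        with pytest.raises(WaveformError, match="AT"):
            generate_waveform("MPA", mpa_targets(at=200.0, et=190.0), 0.4)
        with pytest.raises(WaveformError, match="positive"):
            generate_waveform("MPA", mpa_targets(psv=-5.0), 0.4)
        with pytest.raises(WaveformError):
            generate_waveform("MPA", mpa_targets(), cycle_s=-0.3)
        # the (PI, VTI, PSV) triple pins the cycle; a contradictory one fails
        with pytest.raises(WaveformError, match="implies a cycle"):
            generate_waveform("MPA", mpa_targets(), cycle_s=60 / 140)


class TestCohort:
    def test_empty_cohort(self):
        assert generate_cohort(CohortConfig(n_control=0, n_fgr=0)) == []

    def test_counts_and_completeness(self, small_cohort):
        assert len(small_cohort) == 16
        assert sum(s.group == "control" for s in small_cohort) == 8
        assert all(s.has_complete_waveforms() for s in small_cohort)
        assert all(s.efw_g > 0 and s.valve_diameter_mm > 0 for s in small_cohort)
        assert all(24 <= s.ga_weeks <= 37 for s in small_cohort)

    def test_fixed_seed_reproducible(self):
        cfg = CohortConfig(n_control=3, n_fgr=3, rng_seed=11)
        a = generate_cohort(cfg)
        b = generate_cohort(CohortConfig(n_control=3, n_fgr=3, rng_seed=11))
        for sa, sb in zip(a, b):
            assert sa.efw_g == sb.efw_g
            for key in sa.waveforms:
                assert np.array_equal(sa.waveforms[key].v_cm_s,
                                      sb.waveforms[key].v_cm_s)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_control=-1)
        with pytest.raises(ValueError):
            CohortConfig(reactive_fraction_fgr=1.3)
        with pytest.raises(ValueError):
            CohortConfig(ga_weeks_range=(20.0, 36.0))
        with pytest.raises(ValueError):
            CohortConfig(noise_sd_cm_s=-0.1)

    def test_group_means_track_published_targets(self, study_cohort):
        """At the study arm sizes every recomputed index group mean lies
        within 3 standard errors of its configured target."""
        cfg = CohortConfig()
        for group in ("control", "FGR"):
            subs = [s for s in study_cohort if s.group == group]
            for cond in ("baseline", "mhox"):
                for site, keys in (("MPA", ("PI", "VTI", "PSV", "AT", "ET")),
                                   ("IPA", ("PI", "VTI", "PEDRF"))):
                    vals = {k: [] for k in keys}
                    for s in subs:
                        ix = compute_indices(s.waveform(site, cond))
                        for k in keys:
                            vals[k].append(getattr(ix, k))
                    for k in keys:
                        target = cfg.index_targets[group][cond][site][k][0]
                        se = np.std(vals[k], ddof=1) / math.sqrt(len(subs))
                        assert abs(np.mean(vals[k]) - target) < 3 * se, (
                            f"{group}/{cond}/{site}/{k}")

    def test_morphology_constraints_hold_for_every_subject(self, small_cohort):
        noise = CohortConfig().noise_sd_cm_s
        for s in small_cohort:
            for cond in ("baseline", "mhox"):
                mpa = s.waveform("MPA", cond)
                t = mpa.cycle_times()
                et_s = s.index_draws[("MPA", cond)]["ET"] / 1e3
                diast = mpa.cycle_velocity()[t > et_s + 2e-3]
                assert np.abs(diast).max() <= 6 * noise + 1e-9
                assert s.waveform("DA", cond).cycle_velocity().min() > 0
                assert s.waveform("IPA", cond).cycle_velocity().min() < 0


class TestHyperoxygenation:
    def test_missing_baseline_rejected(self, small_cohort, rng):
        s = small_cohort[0]
        broken = replace(s, waveforms={k: v for k, v in s.waveforms.items()
                                       if k != ("DA", "baseline")})
        with pytest.raises(WaveformError, match="lacks baseline"):
            apply_hyperoxygenation(broken, rng)

    def test_non_reactive_null_change(self, study_cohort):
        """Non-reactive subjects change every MPA/IPA index only within the
        configured null-change tolerance (plus extraction error)."""
        tol = 3.5 * CohortConfig().null_change_tol
        for s in study_cohort[:60]:
            if s.reactivity != "non-reactive":
                continue
            for site in ("MPA", "IPA"):
                base = s.index_draws[(site, "baseline")]
                mhox = s.index_draws[(site, "mhox")]
                for k, v in base.items():
                    if k in ("cycle_s", "AT", "ET"):
                        continue
                    assert abs(mhox[k] - v) <= tol * abs(v) + 1e-9, (s.subject_id, site, k)

    def test_reactive_fgr_direction(self, study_cohort):
        """Reactive FGR: MPA peak velocity rises, acceleration time
        lengthens and IPA pulsatility falls toward the control
        post-oxygen level (cohort means)."""
        dpsv, dat, dpi = [], [], []
        ipa_pi_mhox = []
        for s in study_cohort:
            if not (s.group == "FGR" and s.reactivity == "reactive"):
                continue
            d = delta_change(compute_indices(s.waveform("MPA", "baseline")),
                             compute_indices(s.waveform("MPA", "mhox")))
            dpsv.append(d["PSV"])
            dat.append(d["AT"])
            b = compute_indices(s.waveform("IPA", "baseline"))
            m = compute_indices(s.waveform("IPA", "mhox"))
            dpi.append(m.PI - b.PI)
            ipa_pi_mhox.append(m.PI)
        assert np.mean(dpsv) > 0
        assert np.mean(dat) > 0
        assert np.mean(dpi) < 0
        # converged toward the control MHOx target rather than the FGR baseline
        assert abs(np.mean(ipa_pi_mhox) - 3.47) < abs(np.mean(ipa_pi_mhox) - 4.22)

    def test_reactive_arm_moves_more_than_non_reactive(self):
        """One-sided rank test on |delta VTI(MPA)|, 30 subjects per arm."""
        cohort = generate_cohort(CohortConfig(n_control=0, n_fgr=90, rng_seed=5))
        deltas = {"reactive": [], "non-reactive": []}
        for s in cohort:
            d = delta_change(compute_indices(s.waveform("MPA", "baseline")),
                             compute_indices(s.waveform("MPA", "mhox")))
            deltas[s.reactivity].append(abs(d["VTI"]))
        res = mannwhitneyu(deltas["reactive"][:30], deltas["non-reactive"][:30],
                           alternative="greater")
        assert res.pvalue < 0.01


class TestIO:
    def test_csv_round_trip(self, small_cohort, tmp_path):
        write_cohort_csv(small_cohort, tmp_path)
        back = read_cohort_csv(tmp_path)
        assert len(back) == len(small_cohort)
        orig = {s.subject_id: s for s in small_cohort}
        for s in back:
            o = orig[s.subject_id]
            assert s.group == o.group
            w, wo = s.waveform("IPA", "mhox"), o.waveform("IPA", "mhox")
            assert w.cycle_s == pytest.approx(wo.cycle_s)
            assert np.allclose(w.v_cm_s, wo.v_cm_s, atol=1e-3)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_file = tmp_path / "cohort.yaml"
        cfg_file.write_text(
            "n_control: 5\nn_fgr: 4\nrng_seed: 9\nnoise_sd_cm_s: 0.1\n"
            "heart_rate_bpm: [150, 5]\n")
        cfg = config_from_yaml(cfg_file)
        assert (cfg.n_control, cfg.n_fgr, cfg.rng_seed) == (5, 4, 9)
        assert cfg.heart_rate_bpm == (150, 5)
        assert cfg.reactive_fraction_fgr == 0.67  # untouched default
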