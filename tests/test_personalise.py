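"""NRMSE objective identities and circuit parameter recovery."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fetopulm import circuit
from fetopulm.doppler import Waveform
from fetopulm.personalise import (
    FACTOR_NAMES,
    FitOptions,
    fit_subject,
    nrmse,
    objective,
    reactivity_ratio,
)


class TestNRMSE:
    def test_identical_traces_zero(self, rng):
        v = rng.normal(size=100)
        assert nrmse(v, v) == 0.0

    def test_constant_offset_is_offset_over_range(self, rng):
        v = np.sin(np.linspace(0, 2 * math.pi, 100))
        c = 0.37
        assert nrmse(v, v + c) == pytest.approx(c / (v.max() - v.min()), rel=1e-12)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            nrmse(np.full(50, 3.0), np.zeros(50))

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_joint_rescaling_invariance(self, a):
        v = np.sin(np.linspace(0, 2 * math.pi, 64))
        m = v + 0.2 * np.cos(np.linspace(0, 4 * math.pi, 64))
        assert nrmse(a * v, a * m) == pytest.approx(nrmse(v, m), rel=1e-9)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            nrmse(np.ones(10), np.ones(11))


class TestObjective:
    def _traces(self):
        t = np.linspace(0, 1, 100)
        return {"DA": 20 + 30 * np.sin(math.pi * t), "IPA": 5 + 10 * np.sin(math.pi * t)}

    def test_identical_sites_give_zero(self):
        m = self._traces()
        assert objective(m, {k: v.copy() for k, v in m.items()}) == 0.0

    def test_single_site_offset_additivity(self):
        m = self._traces()
        mod = {"DA": m["DA"] + 3.0, "IPA": m["IPA"].copy()}
        rng_da = m["DA"].max() - m["DA"].min()
        assert objective(m, mod) == pytest.approx(3.0 / rng_da, rel=1e-12)

    def test_symmetric_under_site_relabelling(self):
        m = self._traces()
        mod = {"DA": m["DA"] * 1.1, "IPA": m["IPA"] * 0.9}
        swapped_m = {"DA": m["IPA"], "IPA": m["DA"]}
        swapped_mod = {"DA": mod["IPA"], "IPA": mod["DA"]}
        assert objective(m, mod) == pytest.approx(objective(swapped_m, swapped_mod))

    def test_missing_site_rejected(self):
        m = self._traces()
        with pytest.raises(ValueError, match="missing"):
            objective({"DA": m["DA"]}, m)


def _self_consistent_subject(small_cohort, factors, noise=0.0, seed=0):
    """Replace a subject's DA/IPA traces by circuit output at known factors."""
    from fetopulm.personalise import _input_flow

    rec = dataclasses.replace(small_cohort[0])
    rec.waveforms = dict(small_cohort[0].waveforms)
    p0 = circuit.nominal_parameters(rec.ga_weeks, rec.efw_g)
    q, cycle = _input_flow(rec, "baseline")
    res = circuit.harmonic_steady_state(p0.with_factors(*factors), q, cycle)
    rng = np.random.default_rng(seed)
    for site, v in (("DA", res.v_da_cm_s), ("IPA", res.v_ipa_cm_s)):
        noisy = v + rng.normal(0.0, noise * np.abs(v).max(), v.size)
        rec.waveforms[(site, "baseline")] = Waveform(
            site=site, condition="baseline", dt_s=cycle / v.size,
            v_cm_s=noisy, cycle_s=cycle)
    return rec, p0


class TestParameterRecovery:
    TRUE = (1.5, 0.8, 1.0, 1.0)

    def test_noiseless_recovery_within_5pct(self, small_cohort):
        rec, _ = _self_consistent_subject(small_cohort, self.TRUE)
        fit = fit_subject(rec, "baseline", FitOptions(rng_seed=1))
        assert fit.j < 0.02
        for name, true in zip(FACTOR_NAMES, self.TRUE):
            assert fit.factors[name] == pytest.approx(true, rel=0.05), name

    def test_start_at_truth_is_a_fixed_point(self, small_cohort):
        rec, _ = _self_consistent_subject(small_cohort, self.TRUE)
        opts = FitOptions(start=self.TRUE, multistart=1, rng_seed=1)
        fit = fit_subject(rec, "baseline", opts)
        # initial J is already ~0, so the optimiser must not leave the optimum
        assert fit.j < 0.02
        for name, true in zip(FACTOR_NAMES, self.TRUE):
            assert fit.factors[name] == pytest.approx(true, rel=0.05), name

    def test_noisy_recovery_median_within_15pct(self, small_cohort):
        """5% additive velocity noise: resistance factors recovered within
        15% in the median over 20 seeded replicates."""
        errs = []
        for rep in range(20):
            rec, _ = _self_consistent_subject(small_cohort, self.TRUE,
                                              noise=0.05, seed=100 + rep)
            fit = fit_subject(rec, "baseline",
                              FitOptions(multistart=3, rng_seed=rep))
            errs.append(max(abs(fit.factors["r_pulm"] / self.TRUE[0] - 1),
                            abs(fit.factors["r_sys"] / self.TRUE[1] - 1)))
        assert float(np.median(errs)) < 0.15

    def test_objective_never_worse_than_start(self, small_cohort):
        rec, _ = _self_consistent_subject(small_cohort, (2.0, 0.5, 1.3, 0.7))
        from fetopulm.personalise import _input_flow, measured_beats, modelled_beats

        opts = FitOptions(multistart=1, rng_seed=0)
        p0 = circuit.nominal_parameters(rec.ga_weeks, rec.efw_g)
        q, cycle = _input_flow(rec, "baseline")
        j_start = objective(measured_beats(rec, "baseline", opts.n_grid),
                            modelled_beats(p0, q, cycle, opts.n_grid))
        fit = fit_subject(rec, "baseline", opts)
        assert fit.j <= j_start + 1e-12

    def test_missing_waveform_rejected(self, small_cohort):
        rec = dataclasses.replace(small_cohort[1])
        rec.waveforms = {k: v for k, v in small_cohort[1].waveforms.items()
                         if k != ("IPA", "baseline")}
        from fetopulm.doppler import WaveformError

        with pytest.raises(WaveformError, match="lacks"):
            fit_subject(rec, "baseline")


class TestReactivityRatio:
    def _fit(self, sid="S1", r_pulm=17.0, converged=True):
        from fetopulm.personalise import FitResult

        return FitResult(subject_id=sid, condition="baseline",
                         factors=dict(zip(FACTOR_NAMES, (1, 1, 1, 1))),
                         r_pulm=r_pulm, r_sys=4.0, c_pulm=0.016, c_sys=0.1,
                         nrmse_da=0.1, nrmse_ipa=0.1, j=0.2, n_points=100,
                         n_evals=10, converged=converged)

    def test_identical_fits_give_unit_ratios(self):
        r = reactivity_ratio(self._fit(), self._fit())
        for k in ("r_pulm_ratio", "r_sys_ratio", "c_pulm_ratio", "c_sys_ratio"):
            assert r[k] == 1.0
        assert r["reliable"]

    def test_halved_resistance_gives_half_ratio(self):
        r = reactivity_ratio(self._fit(r_pulm=8.5), self._fit(r_pulm=17.0))
        assert r["r_pulm_ratio"] == 0.5

    def test_non_converged_marked_unreliable(self):
        r = reactivity_ratio(self._fit(converged=False), self._fit())
        assert not r["reliable"]

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same subject"):
            reactivity_ratio(self._fit(sid="A"), self._fit(sid="B"))
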