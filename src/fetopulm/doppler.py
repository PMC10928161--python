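"""Doppler waveform containers and index extraction.

This module holds the beat-level velocity envelope representation used across
the package and computes the standard obstetric Doppler indices from it:

* **PI** (pulsatility index): ``(Vmax - Vmin) / Vmean`` over one cardiac
  cycle, with ``Vmean`` the time-averaged envelope velocity (TAmean).  On an
  envelope trace TAmean and TAmax coincide, so a single path is implemented.
* **VTI** (velocity time integral, cm): per-cycle integral of the *forward*
  (positive) velocity; retrograde lobes are excluded, as in clinical
  envelope tracing.
* **PSV** (peak systolic velocity, cm/s): cycle maximum.
* **AT / ET** (acceleration / ejection time, ms): systolic-onset-to-peak and
  onset-to-end-of-forward-flow intervals.
* **PEDRF** (peak early-diastolic reverse flow, cm/s, <= 0): most negative
  velocity in the early-diastolic window, reported for the intrapulmonary
  artery only; 0 when no reversal is present.

Sites are the three insonation targets of the fetal pulmonary circulation:
``MPA`` (main pulmonary artery), ``IPA`` (intrapulmonary artery) and ``DA``
(ductus arteriosus); conditions are ``baseline`` and ``mhox`` (maternal
hyperoxygenation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SITES = ("MPA", "IPA", "DA")
CONDITIONS = ("baseline", "mhox")

#: Indices compared between conditions by :func:`delta_change`.
INDEX_NAMES = ("PI", "VTI", "PSV", "AT", "ET", "AT_ET", "PEDRF")


class WaveformError(ValueError):
    """Invalid waveform data or an index that cannot be computed from it."""


@dataclass(frozen=True)
class Waveform:
    """One site/condition velocity envelope spanning at least one cycle.

    Parameters
    ----------
    site:
        One of ``MPA``, ``IPA``, ``DA``.
    condition:
        ``baseline`` or ``mhox``.
    dt_s:
        Sampling interval in seconds.
    v_cm_s:
        Velocity samples in cm/s; the first sample is taken as t = 0.
    cycle_s:
        Cardiac cycle duration in seconds.  The series must span at least
        one full cycle.
    """

    site: str
    condition: str
    dt_s: float
    v_cm_s: np.ndarray
    cycle_s: float

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise WaveformError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.condition not in CONDITIONS:
            raise WaveformError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not (self.dt_s > 0):
            raise WaveformError(f"dt_s must be positive, got {self.dt_s}")
        if not (self.cycle_s > 0):
            raise WaveformError(f"cycle_s must be positive, got {self.cycle_s}")
        v = np.asarray(self.v_cm_s, dtype=float)
        object.__setattr__(self, "v_cm_s", v)
        if v.ndim != 1 or v.size < 2:
            raise WaveformError("v_cm_s must be a 1-D series with >= 2 samples")
        if not np.all(np.isfinite(v)):
            raise WaveformError("v_cm_s contains non-finite values")
        # Allow half a sample of slack so cycle_s = n*dt round-trips through IO.
        if v.size * self.dt_s < self.cycle_s - 0.5 * self.dt_s:
            raise WaveformError(
                f"series spans {v.size * self.dt_s:.4f} s, shorter than one "
                f"cycle of {self.cycle_s:.4f} s"
            )

    @property
    def n_cycle(self) -> int:
        """Number of samples in one cycle."""
        return min(int(round(self.cycle_s / self.dt_s)), self.v_cm_s.size)

    def cycle_velocity(self) -> np.ndarray:
        """Velocity samples of the first complete cycle."""
        return self.v_cm_s[: self.n_cycle]

    def cycle_times(self) -> np.ndarray:
        return np.arange(self.n_cycle) * self.dt_s


@dataclass(frozen=True)
class DopplerIndices:
    """Per-beat Doppler indices in the units of the clinical tables.

    ``AT``/``ET`` are milliseconds; ``PEDRF`` is cm/s (<= 0) and ``None`` for
    sites where early-diastolic reversal is not reported (MPA, DA).  ``AT``,
    ``ET`` and ``AT_ET`` are NaN when no systolic onset is detectable (e.g. a
    constant trace).
    """

    PI: float
    VTI: float
    PSV: float
    AT: float
    ET: float
    AT_ET: float
    PEDRF: Optional[float] = None
    site: Optional[str] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def _circular_moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with periodic wrap; identity for window <= 1."""
    if window <= 1:
        return v.astype(float)
    if window % 2 == 0:
        window += 1
    kernel = np.full(window, 1.0 / window)
    pad = window // 2
    ext = np.concatenate([v[-pad:], v, v[:pad]])
    return np.convolve(ext, kernel, mode="valid")


def _refine_peak(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Sub-sample peak time by parabolic interpolation around sample ``i``."""
    if i <= 0 or i >= v.size - 1:
        return t[i]
    denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
    if denom >= -1e-300:  # flat or non-concave: keep grid time
        return t[i]
    delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
    return t[i] + np.clip(delta, -1.0, 1.0) * (t[1] - t[0])


def compute_indices(
    w: Waveform,
    *,
    onset_threshold: float = 0.05,
    smooth_window: int = 5,
    pedrf_window_frac: float = 0.25,
) -> DopplerIndices:
    """Compute the Doppler indices of one beat.

    Systolic onset is located where the upstroke crosses
    ``onset_threshold`` (default 5%) of the peak above baseline, refined by
    linear back-projection to the baseline; the end of ejection is the
    mirrored crossing after the peak.  The baseline is the cycle minimum for
    all-positive traces (DA) and zero when retrograde flow is present (IPA) or
    the trace touches zero (MPA).  Extremes and crossings are read from a
    lightly smoothed copy of the envelope (``smooth_window`` samples,
    circular); integrals use the raw samples.

    Raises
    ------
    WaveformError
        If the cycle-mean velocity is ~0 (PI undefined).
    """
    n = w.n_cycle
    if n < 8:
        raise WaveformError("cycle too short to analyse")
    v = w.cycle_velocity().astype(float)
    dt = w.dt_s
    vs = _circular_moving_average(v, smooth_window)

    vmax = float(vs.max())
    vmin = float(vs.min())
    vmean = float(v.mean())
    vscale = max(abs(vmax), abs(vmin), 1e-12)
    if abs(vmean) < 1e-9 * vscale:
        raise WaveformError("cycle-mean velocity is zero; PI undefined")
    pi = (vmax - vmin) / vmean

    # Forward-flow integral; rectangle rule == trapezoid on a periodic signal.
    vti = float(np.clip(v, 0.0, None).sum() * dt)
    psv = vmax

    # Roll the beat so the (diastolic) minimum sits at index 0: the
    # below-threshold arc then brackets the systolic peak inside the window
    # regardless of how the cycle was phased.
    shift = -int(np.argmin(vs))
    vr = np.roll(vs, shift)
    vraw = np.roll(v, shift)
    centre = int(np.argmax(vr))
    t = np.arange(n) * dt

    def _crossing(i_guess: int, thr: float, baseline: float, rising: bool):
        """Sub-sample threshold crossing refined on the raw trace, then
        back-projected to the baseline along the local raw slope."""
        lo = max(i_guess - 2, 0)
        hi = min(i_guess + 3, n - 1)
        for j in range(lo, hi):
            a, b = vraw[j], vraw[j + 1]
            if (a < thr <= b) if rising else (a >= thr > b):
                s = (b - a) / dt
                t_thr = t[j] + (thr - a) / s
                return t_thr - (thr - baseline) / s
        # fall back to the smoothed trace (heavy noise)
        a, b = vr[i_guess], vr[i_guess + 1] if i_guess + 1 < n else vr[i_guess]
        s = (b - a) / dt if b != a else math.copysign(1e-9, 1 if rising else -1)
        t_thr = t[i_guess] + (thr - a) / s
        return t_thr - (thr - baseline) / s

    baseline = vmin if vmin > 1e-9 * vscale else 0.0
    height = vmax - baseline
    at = et = at_et = math.nan
    pedrf: Optional[float] = None
    t_end_r = None
    if height > 1e-9 * vscale:
        thr = baseline + onset_threshold * height

        below_left = np.nonzero(vr[:centre] < thr)[0]
        below_right = np.nonzero(vr[centre + 1:] < thr)[0]
        if below_left.size and below_right.size:
            i1 = int(below_left[-1])
            i2 = int(below_right[0]) + centre + 1
            t0 = _crossing(i1, thr, baseline, rising=True)
            t_end_r = _crossing(i2 - 1, thr, baseline, rising=False)
            t_peak = _refine_peak(t, vr, centre)
            at = (t_peak - t0) * 1e3
            et = (t_end_r - t0) * 1e3
            if et > 0 and at > 0:
                at_et = at / et
            else:
                at = et = at_et = math.nan
                t_end_r = None

    if w.site == "IPA":
        # Early-diastolic window (ET, ET + frac*cycle] after the ejection end.
        if t_end_r is None:
            pedrf = min(vmin, 0.0)
        else:
            j0 = int(math.ceil(t_end_r / dt))
            j1 = int(math.floor((t_end_r + pedrf_window_frac * w.cycle_s) / dt))
            j1 = min(j1, j0 + n - 1)
            window = vr[np.arange(j0 + 1, j1 + 1) % n]
            pedrf = min(float(window.min()), 0.0) if window.size else 0.0

    return DopplerIndices(
        PI=pi, VTI=vti, PSV=psv, AT=at, ET=et, AT_ET=at_et, PEDRF=pedrf, site=w.site
    )


def delta_change(base: DopplerIndices, mhox: DopplerIndices) -> dict:
    """Per-index signed change ``mhox - base`` for one site.

    Antisymmetric under argument swap.  ``PEDRF`` is differenced only when
    present on both sides (``None`` otherwise).

    Raises
    ------
    WaveformError
        If both operands carry a site tag and the sites differ.
    """
    if base.site is not None and mhox.site is not None and base.site != mhox.site:
        raise WaveformError(
            f"cannot difference indices from different sites: {base.site} vs {mhox.site}"
        )
    out = {}
    for name in INDEX_NAMES:
        a = getattr(base, name)
        b = getattr(mhox, name)
        if a is None or b is None:
            out[name] = None
        else:
            out[name] = b - a
    return out


def resample_beat(w: Waveform, m: int) -> np.ndarray:
    """Resample one cycle to a fixed-length vector of ``m`` samples.

    Samples are taken at ``t_j = j * cycle / m`` (periodic convention, so the
    beat vector tiles seamlessly), with linear interpolation between native
    samples.  When ``m`` equals the native samples per cycle the native values
    are returned unchanged.
    """
    if m < 2:
        raise WaveformError(f"need at least 2 samples, got m={m}")
    n = w.n_cycle
    v = w.cycle_velocity()
    t_native = np.arange(n) * w.dt_s
    t_new = np.arange(m) * (w.cycle_s / m)
    return np.interp(t_new, t_native, v, period=w.cycle_s)


def site_delta_table(base: "dict[str, DopplerIndices]", mhox: "dict[str, DopplerIndices]") -> dict:
    """Deltas for every site present in both condition maps."""
    return {s: delta_change(base[s], mhox[s]) for s in base if s in mhox}
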