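"""Linear–nonlinear (STA / NLD) spike prediction from base strain.

Campaniform sensilla at the haltere base are modelled as a two-step cascade:
the strain history is projected onto a unit-norm spike-triggered average
(STA), the projection is mapped through a sigmoidal nonlinear decision
function (NLD) to a firing probability, and a spike is placed at every local
maximum of the probability that exceeds a threshold (default 0.9).

The projection is referenced to a fixed strain scale σ₀ rather than being
re-normalised per recording:

    ξ(t) = tanh( STA · w(t) / (√n σ₀) ),

where w(t) is the strain window ending at t with the steady-state mean
removed and n is the number of STA taps.  The tanh keeps ξ in (−1, 1) and
reproduces the matched-filter limits (window ∝ STA → ξ → 1, orthogonal → 0,
sign-flipped → −1) while making the *existence* of spikes depend on signal
amplitude relative to σ₀ — which is what silences the lateral positions
when no body rotation is present — and leaving spike *times* invariant
under rescaling of the strain (tanh is monotone, so probability peaks do
not move).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuralFilter",
    "SpikeTrain",
    "TimingShift",
    "project_stimulus",
    "firing_probability",
    "extract_spikes",
    "predict_spikes",
    "timing_shift",
    "spikes_per_cycle",
]


@dataclass(frozen=True)
class NeuralFilter:
    """STA taps plus NLD parameters.

    ``taps[0]`` is the most recent lag (τ = 0); ``taps[k]`` multiplies the
    stimulus k·dt seconds in the past.  Taps are stored unit-norm.
    ``strain_scale`` is the reference strain σ₀ that maps physical strain
    onto the normalised projection axis ξ of the decision function.
    """

    taps: np.ndarray
    dt: float                   # tap sample interval, s
    xi0: float = 0.5            # sigmoid midpoint
    k: float = 0.08             # sigmoid slope parameter
    p_max: float = 1.0          # probability ceiling
    threshold: float = 0.9      # spike threshold on probability
    strain_scale: float = 5e-6  # σ₀, reference strain (dimensionless strain)

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        nrm = np.linalg.norm(taps)
        if nrm == 0 or not np.isfinite(nrm):
            raise ValueError("STA taps must have finite nonzero norm")
        object.__setattr__(self, "taps", taps / nrm)
        if self.dt <= 0:
            raise ValueError("tap interval must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def window_s(self) -> float:
        return self.taps.shape[0] * self.dt

    def with_params(self, **kw) -> "NeuralFilter":
        return replace(self, **kw)


@dataclass
class SpikeTrain:
    """Predicted spike times for one circumferential location/condition."""

    times: np.ndarray
    label: float | str = ""
    condition: str = ""
    window: tuple[float, float] | None = None
    frequency_hz: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        self.times = t

    def __len__(self) -> int:
        return self.times.shape[0]

    def phases(self) -> np.ndarray:
        """Phase (rad) of each spike within its flapping cycle."""
        if self.frequency_hz is None:
            raise ValueError("frequency_hz not set")
        t0 = self.window[0] if self.window else 0.0
        frac = (self.times - t0) * self.frequency_hz
        return 2.0 * np.pi * (frac - np.floor(frac))


def project_stimulus(
    strain: np.ndarray,
    times: np.ndarray,
    filt: NeuralFilter,
    analysis_start: float | None = None,
    return_raw: bool = False,
) -> tuple[np.ndarray, ...]:
    """Normalised STA projection ξ(t).

    The strain series is resampled to the filter's tap interval if needed,
    the mean over the analysis region (t ≥ ``analysis_start``) is removed,
    and ξ is returned on the resampled grid for every t with a complete
    window.  Returns ``(t_valid, xi)``, or ``(t_valid, xi, raw)`` with the
    pre-saturation projection if ``return_raw`` — the raw trace stays
    strictly varying where tanh rounds to ±1 and is used to localise
    probability peaks inside saturated plateaus.
    """
    strain = np.asarray(strain, dtype=float)
    times = np.asarray(times, dtype=float)
    if strain.shape != times.shape:
        raise ValueError("strain and times must have matching shape")
    dt_in = times[1] - times[0]
    if abs(dt_in - filt.dt) > 1e-12:
        grid = np.arange(times[0], times[-1] + 0.5 * filt.dt, filt.dt)
        s = np.interp(grid, times, strain)
    else:
        grid, s = times, strain
    n = filt.taps.shape[0]
    if s.shape[0] < n:
        raise ValueError("strain series shorter than the STA window")
    if analysis_start is None:
        analysis_start = grid[0]
    mask = grid >= analysis_start
    s = s - s[mask].mean()
    proj = np.convolve(s, filt.taps, mode="full")[n - 1 : s.shape[0]]
    raw = proj / (np.sqrt(n) * filt.strain_scale)
    xi = np.tanh(raw)
    if return_raw:
        return grid[n - 1 :], xi, raw
    return grid[n - 1 :], xi


def firing_probability(xi: np.ndarray, filt: NeuralFilter) -> np.ndarray:
    """Sigmoidal NLD: P = P_max / (1 + exp(−(ξ − ξ₀)/k))."""
    xi = np.asarray(xi, dtype=float)
    z = np.clip(-(xi - filt.xi0) / filt.k, -700.0, 700.0)  # avoid exp overflow
    return filt.p_max / (1.0 + np.exp(z))


def _quadratic_peak(y: np.ndarray, times: np.ndarray, i: int) -> float:
    """Sub-sample apex via a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= y.shape[0] - 1:
        return float(times[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    dt = times[i] - times[i - 1]
    offs = 0.0 if denom == 0 else 0.5 * dt * (y[i - 1] - y[i + 1]) / denom
    return float(times[i] + np.clip(offs, -dt, dt))


def _peak_runs(P: np.ndarray):
    """Indices (i1, i2) of local maxima, where a maximum may be a plateau
    run of exactly equal values strictly above both neighbours."""
    change = np.flatnonzero(np.diff(P) != 0.0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [P.shape[0] - 1]))
    vals = P[starts]
    out = []
    for j in range(1, starts.shape[0] - 1):
        if vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            out.append((starts[j], ends[j]))
    return out


def extract_spikes(
    P: np.ndarray,
    times: np.ndarray,
    filt: NeuralFilter | None = None,
    threshold: float | None = None,
    window: tuple[float, float] | None = None,
    label: float | str = "",
    condition: str = "",
    frequency_hz: float | None = None,
    refine: np.ndarray | None = None,
) -> SpikeTrain:
    """Spikes at local maxima of the firing probability above threshold.

    Isolated maxima are refined to sub-sample precision with a quadratic
    through the three surrounding samples; plateaus of equal probability
    produce a single spike at the plateau midpoint.  If ``refine`` is given
    (the raw, unsaturated projection underlying P), plateaus created by
    floating-point saturation are resolved at the exact-arithmetic peak —
    the maximum of ``refine`` within the run — which keeps spike times
    invariant under strain rescaling.
    """
    P = np.asarray(P, dtype=float)
    times = np.asarray(times, dtype=float)
    if threshold is None:
        threshold = filt.threshold if filt is not None else 0.9
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    spikes = []
    for i1, i2 in _peak_runs(P):
        if P[i1] <= threshold:
            continue
        if refine is not None:
            i = i1 + int(np.argmax(refine[i1 : i2 + 1]))
            t_spk = _quadratic_peak(refine, times, i)
        elif i1 == i2:
            t_spk = _quadratic_peak(P, times, i1)
        else:
            t_spk = 0.5 * (times[i1] + times[i2])
        spikes.append(t_spk)
    spikes = np.asarray(sorted(spikes))
    if window is not None:
        # half-open window: a periodic train contributes exactly one spike
        # per period regardless of edge alignment
        spikes = spikes[(spikes >= window[0]) & (spikes < window[1])]
    return SpikeTrain(
        times=spikes,
        label=label,
        condition=condition,
        window=window,
        frequency_hz=frequency_hz,
    )


def predict_spikes(
    strain: np.ndarray,
    times: np.ndarray,
    filt: NeuralFilter,
    window: tuple[float, float],
    label: float | str = "",
    condition: str = "",
    frequency_hz: float | None = None,
) -> SpikeTrain:
    """Full strain → spike-train cascade for one recording site.

    Runs projection, decision function and peak extraction, using the raw
    projection to localise peaks inside saturated probability plateaus.
    """
    tv, xi, raw = project_stimulus(strain, times, filt, window[0],
                                   return_raw=True)
    P = firing_probability(xi, filt)
    return extract_spikes(
        P, tv, filt, window=window, label=label, condition=condition,
        frequency_hz=frequency_hz, refine=raw,
    )


@dataclass(frozen=True)
class TimingShift:
    """Per-location spike-timing comparison between two conditions."""

    label: float | str
    mean_shift_ms: float | None
    shifts_ms: np.ndarray
    n_pairs: int
    rotation_only: bool = False


def timing_shift(
    train_flap: SpikeTrain,
    train_rot: SpikeTrain,
    f_phi: float,
) -> TimingShift:
    """Mean signed spike-time difference (rotation − flapping, ms).

    Each rotation-condition spike is paired with the nearest
    flapping-condition spike within half a flapping period; positive means
    the rotation spike lags.  A location silent without rotation is flagged
    ``rotation_only``.
    """
    if len(train_rot) == 0:
        return TimingShift(train_rot.label, None, np.array([]), 0, False)
    if len(train_flap) == 0:
        return TimingShift(train_rot.label, None, np.array([]), 0, True)
    period = 1.0 / f_phi
    tf = train_flap.times
    shifts = []
    for t in train_rot.times:
        j = np.argmin(np.abs(tf - t))
        d = t - tf[j]
        if abs(d) <= period / 2.0:
            shifts.append(d)
    n_cyc_f = _cycle_count(train_flap, f_phi)
    n_cyc_r = _cycle_count(train_rot, f_phi)
    if n_cyc_f != n_cyc_r:
        warnings.warn(
            "spike trains cover different cycle counts; using paired spikes only",
            stacklevel=2,
        )
    shifts_ms = 1e3 * np.asarray(shifts)
    mean = float(shifts_ms.mean()) if shifts_ms.size else None
    return TimingShift(train_rot.label, mean, shifts_ms, shifts_ms.size, False)


def _cycle_count(train: SpikeTrain, f_phi: float) -> int:
    if train.window is not None:
        return int(round((train.window[1] - train.window[0]) * f_phi))
    if len(train) < 2:
        return len(train)
    return int(round((train.times[-1] - train.times[0]) * f_phi)) + 1


def spikes_per_cycle(train: SpikeTrain, f_phi: float,
                     window: tuple[float, float] | None = None) -> float:
    """Spike count per flapping period over the analysis window."""
    window = window or train.window
    if window is None:
        raise ValueError("need an analysis window")
    n_periods = (window[1] - window[0]) * f_phi
    t = train.times
    count = int(np.sum((t >= window[0]) & (t < window[1])))
    return count / n_periods
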