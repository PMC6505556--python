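"""Synthetic neural filters and strain signals.

The encoding properties of cranefly haltere campaniform neurons are known
only as normalised curve shapes (an oscillatory, decaying spike-triggered
average and a sigmoidal decision function); their tap values are not
tabulated anywhere.  This module generates a Gabor-like stand-in STA —
a Gaussian-windowed sinusoid band-matched to the flapping frequency — and
synthetic strain signals with the structure the analysis assumes: a
dominant component at the flapping frequency f, a small quadrature
component at 2f (the Coriolis analogue, default 1/25 of the base
amplitude), a constant tensile offset (the centrifugal-tension analogue)
and optional seeded Gaussian noise.  Because the filter is a stand-in,
downstream timing predictions are validated as ranges, not point values.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .encoding import (
    NeuralFilter,
    extract_spikes,
    firing_probability,
    project_stimulus,
)

__all__ = [
    "STAParams",
    "SyntheticStrainParams",
    "make_sta",
    "make_strain",
    "reference_pipeline_fixture",
]


@dataclass(frozen=True)
class STAParams:
    """Stand-in STA shape parameters (times in ms).

    ``center_ms`` is the lag of the envelope peak before the spike;
    ``sigma_ms`` the Gaussian envelope width.  The default 4 ms width keeps
    the filter broadband enough to pass both the flapping frequency and its
    first harmonic, which carries the rotation signature.  ``phase_rad`` is
    the carrier phase at the envelope peak; the default π/2 (a cosine
    carrier) gives the filter pure linear phase — a constant group delay of
    ``center_ms`` — so the relative timing of stimulus harmonics, and hence
    any rotation-induced spike-timing shift, passes through undistorted.
    """

    window_ms: float = 50.0
    freq_hz: float = 40.0
    center_ms: float = 10.0
    sigma_ms: float = 4.0
    phase_rad: float = np.pi / 2.0
    dt_ms: float = 0.01


@dataclass(frozen=True)
class SyntheticStrainParams:
    """Two-tone synthetic strain: offset + A sin(2πft) + r·A_ref sin(4πft+ψ) + noise.

    ``amp_f`` is the base amplitude at the flapping frequency; ``rel_2f``
    the relative amplitude of the 2f quadrature component (default 1/25,
    mirroring the in-plane / out-of-plane ratio); ``ref_amp`` lets the 2f
    component be referenced to another location's base amplitude (used for
    the lateral-site analogue whose own f component vanishes).

    The default base amplitude matches the dorsal-fibre strain amplitude
    near the base of the simulated haltere (≈4.5×10⁻⁴ at the 300 μm site).
    """

    amp_f: float = 4.5e-4
    rel_2f: float = 1.0 / 25.0
    phase_2f: float = 0.0
    offset: float = 5e-6
    noise_sd: float = 0.0
    freq_hz: float = 40.0
    duration: float = 0.25
    dt: float = 1e-5
    seed: int = 0
    ref_amp: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def make_sta(params: STAParams = STAParams()) -> NeuralFilter:
    """Unit-norm Gabor stand-in STA.

    g(τ) = exp(−(τ−τ₀)²/2σ²) · sin(2π f (τ−τ₀) + φ_c) on lags
    τ ∈ [0, window], most recent tap first.
    """
    if params.window_ms < 2.0 * 1e3 / params.freq_hz:
        warnings.warn("STA window shorter than two oscillation periods",
                      stacklevel=2)
    lags = np.arange(0.0, params.window_ms, params.dt_ms)  # ms before spike
    tau = lags - params.center_ms
    sigma = params.sigma_ms if np.isfinite(params.sigma_ms) else None
    env = np.ones_like(tau) if sigma is None else np.exp(-(tau**2) / (2.0 * sigma**2))
    g = env * np.sin(2.0 * np.pi * params.freq_hz * tau * 1e-3 + params.phase_rad)
    return NeuralFilter(taps=g, dt=params.dt_ms * 1e-3)


def make_strain(params: SyntheticStrainParams) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (seeded) synthetic strain series ``(times, strain)``."""
    n = int(round(params.duration / params.dt))
    t = np.arange(n + 1) * params.dt
    w = 2.0 * np.pi * params.freq_hz
    ref = params.ref_amp if params.ref_amp is not None else params.amp_f
    s = (
        params.offset
        + params.amp_f * np.sin(w * t)
        + params.rel_2f * ref * np.sin(2.0 * w * t + params.phase_2f)
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        s = s + rng.normal(0.0, params.noise_sd, size=t.shape)
    return t, s


def _naive_spike_pipeline(strain, times, filt: NeuralFilter,
                          analysis_start: float):
    """Plain-loop reference path (independent of the vectorised one):
    direct dot products per window, explicit peak scan on the raw
    projection with the probability threshold applied at the peak."""
    n = filt.taps.shape[0]
    s = np.asarray(strain, float)
    s = s - s[times >= analysis_start].mean()
    scale = np.sqrt(n) * filt.strain_scale
    raw = np.empty(s.shape[0] - n + 1)
    for i in range(raw.shape[0]):
        w = s[i : i + n][::-1]  # most recent sample aligns with tap 0
        raw[i] = float(np.dot(filt.taps, w)) / scale
    P = filt.p_max / (1.0 + np.exp(-(np.tanh(raw) - filt.xi0) / filt.k))
    tv = times[n - 1 :]
    dt = tv[1] - tv[0]
    spikes = []
    for i in range(1, raw.shape[0] - 1):
        if raw[i] > raw[i - 1] and raw[i] >= raw[i + 1] and P[i] > filt.threshold:
            den = raw[i - 1] - 2 * raw[i] + raw[i + 1]
            off = 0.0 if den == 0 else 0.5 * dt * (raw[i - 1] - raw[i + 1]) / den
            spikes.append(tv[i] + off)
    return np.array([t for t in spikes if t >= analysis_start])


def reference_pipeline_fixture(out_dir=None, seed: int = 12345) -> dict:
    """Frozen end-to-end fixture for regression tests.

    Generates the stand-in filter, five synthetic strain series emulating
    circumferential positions between dorsal (pure f) and lateral (pure
    2f), and the expected spike tables computed by the plain-loop reference
    path.  If ``out_dir`` is given the bundle is written as small CSV/JSON
    files.  Returns the bundle plus a stable content hash so regeneration
    drift is detectable.
    """
    filt = make_sta()
    alphas = [0.0, np.pi / 8, np.pi / 4, 3 * np.pi / 8, np.pi / 2]
    analysis_start = 0.125
    bundle = {"seed": seed, "alphas": alphas, "strains": {}, "spikes": {}}
    for a in alphas:
        p = SyntheticStrainParams(
            amp_f=4.5e-4 * np.cos(a),
            rel_2f=(1.0 / 25.0) * np.sin(a),
            ref_amp=4.5e-4,
            phase_2f=0.0,
            noise_sd=0.0,
            seed=seed,
        )
        t, s = make_strain(p)
        spikes = _naive_spike_pipeline(s, t, filt, analysis_start)
        bundle["strains"][a] = (t, s)
        bundle["spikes"][a] = spikes
    h = hashlib.sha256()
    for a in alphas:
        h.update(np.round(bundle["spikes"][a], 9).tobytes())
    bundle["hash"] = h.hexdigest()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "sta.csv",
                   np.column_stack([np.arange(filt.taps.size) * filt.dt * 1e3,
                                    filt.taps]),
                   delimiter=",", header="lag_ms,tap", comments="")
        for a in alphas:
            np.savetxt(out / f"spikes_alpha_{a:.4f}.csv",
                       bundle["spikes"][a], delimiter=",",
                       header="time_s", comments="")
        (out / "meta.json").write_text(
            json.dumps({"seed": seed, "hash": bundle["hash"],
                        "alphas": alphas}, indent=2)
        )
    return bundle
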