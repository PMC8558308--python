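"""Kaiser-windowed FIR filtering with zero-phase application.

Filter length is derived from the Kaiser window design relations: the window
beta determines the achievable stopband attenuation A (beta = 0.1102(A - 8.7)
for A > 50 dB, with the standard intermediate/low-attenuation branches), and
the tap count follows from A and the normalized transition bandwidth as
N ≈ (A - 7.95) / (2.285 Δω). Taps are forced odd so the linear-phase filter
can be applied with exact group-delay compensation (a single symmetric pass,
matching a non-causal FIR; forward-backward filtering is available as an
option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal


@dataclass(frozen=True)
class FilterSpec:
    kind: str                      # "lowpass" | "highpass"
    cutoff: float                  # Hz
    kaiser_beta: float
    transition_bandwidth: float    # Hz
    causal: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError("kind must be 'lowpass' or 'highpass'")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.transition_bandwidth <= 0:
            raise ValueError("transition bandwidth must be positive")


#: 30 Hz low-pass used on the continuous recording before epoching.
LOWPASS_30HZ = FilterSpec("lowpass", cutoff=30.0, kaiser_beta=12.2653,
                          transition_bandwidth=10.0)
#: 0.1 Hz high-pass companion (long filter; mainly relevant for real data).
HIGHPASS_0p1HZ = FilterSpec("highpass", cutoff=0.1, kaiser_beta=5.6533,
                            transition_bandwidth=0.2)


def kaiser_attenuation_db(beta: float) -> float:
    """Stopband attenuation (dB) implied by a Kaiser window beta.

    Inverts the standard design relation; for beta <= 0 the window is
    rectangular (21 dB).
    """
    if beta <= 0:
        return 21.0
    hi = 0.1102 * (50.0 - 8.7)
    if beta >= hi:
        return beta / 0.1102 + 8.7
    f = lambda a: 0.5842 * (a - 21.0) ** 0.4 + 0.07886 * (a - 21.0) - beta
    return float(optimize.brentq(f, 21.0 + 1e-9, 50.0))


def kaiser_numtaps(beta: float, transition_bandwidth: float, sfreq: float) -> int:
    """Odd tap count for the requested transition width."""
    atten = kaiser_attenuation_db(beta)
    delta_omega = 2.0 * np.pi * transition_bandwidth / sfreq
    n = int(np.ceil((atten - 7.95) / (2.285 * delta_omega))) + 1
    return n if n % 2 else n + 1


def design_kaiser_fir(spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Tap weights for ``spec``; DC gain is 1 (lowpass) or 0 (highpass)."""
    if spec.cutoff >= sfreq / 2.0:
        raise ValueError(f"cutoff {spec.cutoff} Hz is at or above Nyquist ({sfreq / 2} Hz)")
    numtaps = kaiser_numtaps(spec.kaiser_beta, spec.transition_bandwidth, sfreq)
    return signal.firwin(
        numtaps,
        spec.cutoff,
        window=("kaiser", spec.kaiser_beta),
        pass_zero=spec.kind,
        fs=sfreq,
    )


def apply_zero_phase(x: np.ndarray, taps: np.ndarray, axis: int = -1,
                     forward_backward: bool = False) -> np.ndarray:
    """Filter without group delay.

    Default is a single pass with the (odd, symmetric) taps centred on each
    output sample, so a symmetric test pulse keeps its peak latency. With
    ``forward_backward`` the filter is applied twice (squared magnitude
    response). The first and last ``len(taps) // 2`` samples are influenced by
    the zero-padded edges and should be treated as unreliable.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] <= len(taps) // 2:
        raise ValueError("signal too short for the filter order")
    if len(taps) % 2 == 0:
        raise ValueError("zero-phase application requires an odd tap count")
    if forward_backward:
        return signal.filtfilt(taps, [1.0], x, axis=axis, padtype=None)
    x_moved = np.moveaxis(x, axis, -1)
    shape = [1] * x_moved.ndim
    shape[-1] = len(taps)
    out = signal.fftconvolve(x_moved, taps.reshape(shape), mode="same", axes=-1)
    return np.moveaxis(out, -1, axis)


def frequency_response(taps: np.ndarray, freqs, sfreq: float) -> np.ndarray:
    """Magnitude response at ``freqs`` (Hz); independent FFT-free evaluation."""
    _, h = signal.freqz(taps, worN=2.0 * np.pi * np.atleast_1d(freqs) / sfreq)
    return np.abs(h)


def bandpass(x: np.ndarray, sfreq: float,
             lowpass: FilterSpec = LOWPASS_30HZ,
             highpass: FilterSpec | None = None,
             axis: int = -1) -> np.ndarray:
    """Apply the high-pass (if any) followed by the low-pass, zero-phase."""
    if highpass is not None:
        x = apply_zero_phase(x, design_kaiser_fir(highpass, sfreq), axis=axis)
    return apply_zero_phase(x, design_kaiser_fir(lowpass, sfreq), axis=axis)
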