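"""Zero-phase FIR filtering shared by preprocessing and band-power estimation.

Filters are windowed-sinc (Hamming) designs applied by centred convolution,
so a linear-phase kernel yields zero net group delay ("non-causal" filtering
in the EEG sense).
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def _transition_bandwidth(edge_hz: float) -> float:
    """Transition bandwidth for one band edge: min(max(0.25*edge, 2 Hz), edge)."""
    return min(max(0.25 * edge_hz, 2.0), edge_hz)


def design_fir(
    fs: float,
    l_freq: float | None,
    h_freq: float | None,
) -> np.ndarray:
    """Design a linear-phase FIR kernel (odd length, Hamming window).

    ``l_freq=None`` gives a low-pass, ``h_freq=None`` a high-pass, both set a
    band-pass. The filter order follows the Hamming-window rule
    ``n_taps ~= 3.3 * fs / transition_bw`` using the narrower transition band.
    """
    if l_freq is None and h_freq is None:
        raise ValueError("at least one of l_freq, h_freq must be given")
    for f in (l_freq, h_freq):
        if f is not None and not 0.0 < f < fs / 2.0:
            raise ValueError(f"band edge {f} Hz outside (0, fs/2)")
    if l_freq is not None and h_freq is not None and l_freq >= h_freq:
        raise ValueError(f"invalid band: l_freq={l_freq} >= h_freq={h_freq}")

    edges = [f for f in (l_freq, h_freq) if f is not None]
    trans = min(_transition_bandwidth(f) for f in edges)
    n_taps = int(np.ceil(3.3 * fs / trans))
    n_taps += 1 - n_taps % 2  # odd length -> symmetric, integer delay

    if l_freq is None:
        taps = signal.firwin(n_taps, h_freq, window="hamming", fs=fs)
    elif h_freq is None:
        taps = signal.firwin(n_taps, l_freq, window="hamming", pass_zero=False, fs=fs)
    else:
        taps = signal.firwin(
            n_taps, [l_freq, h_freq], window="hamming", pass_zero=False, fs=fs
        )
    return taps


def filter_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with zero net delay.

    The kernel centre is aligned with each output sample (``mode='same'``),
    which for an odd, symmetric kernel cancels the group delay exactly.
    Edges are handled by reflecting the signal over one kernel half-length.
    """
    data = np.asarray(data, dtype=float)
    half = len(taps) // 2
    pad = min(half, data.shape[-1] - 1)
    padded = np.concatenate(
        [data[..., 1 : pad + 1][..., ::-1], data, data[..., -pad - 1 : -1][..., ::-1]],
        axis=-1,
    )
    out = signal.fftconvolve(padded, taps[(None,) * (data.ndim - 1)], mode="same", axes=-1)
    return out[..., pad : pad + data.shape[-1]]


def bandpass(data: np.ndarray, fs: float, l_freq: float, h_freq: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis."""
    return filter_zero_phase(data, design_fir(fs, l_freq, h_freq))
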