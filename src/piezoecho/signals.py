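"""Excitation waveforms, echo synthesis and echo metrics.

Waveforms live on a uniform time grid (default 20 MS/s over 100 us, the
acquisition settings of the detection electronics).  The impulsive
excitation is a Gaussian-windowed tone burst

    v(t) = 10 sin(ω t) exp{-[0.2 ω (t - 8π²/ω)]² / 20},

whose envelope peaks at t = 8π²/ω; the harmonic regime is a plain sine.
Echo waveforms are synthesised by superposing the excitation template at
each recorded arrival time, scaled by the arrival amplitude (transducers
are treated as perfectly coupled, so the pressure-to-voltage factor is 1).
Echo metrics are the window energy E = Σ|x(t)|², the peak amplitude, the
number of meaningful interactions and the one-sided magnitude spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .raytrace import AMPLITUDE_THRESHOLD, RECORD_CAP, EchoRecord

__all__ = [
    "Waveform",
    "gaussian_pulse",
    "harmonic_excitation",
    "synthesize_echo",
    "echo_metrics",
    "spectrum",
    "spectral_energy",
]

DEFAULT_RATE = 2e7        # samples per second
DEFAULT_DURATION = 1e-4   # s


@dataclass
class Waveform:
    """Uniformly sampled amplitude series (V-equivalent)."""

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    duration: float = DEFAULT_DURATION

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n = int(self.rate * self.duration)
        if self.samples.shape != (n,):
            raise ValueError(f"expected {n} samples for rate*duration, got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


def _time_axis(rate: float, duration: float) -> np.ndarray:
    return np.arange(int(rate * duration)) / rate


def gaussian_pulse(frequency: float, rate: float = DEFAULT_RATE,
                   duration: float = DEFAULT_DURATION) -> Waveform:
    """Impulsive excitation: 10 V Gaussian-windowed tone burst at ``frequency``."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    t = _time_axis(rate, duration)
    omega = 2.0 * np.pi * frequency
    arg = 0.2 * omega * (t - 8.0 * np.pi ** 2 / omega)
    samples = 10.0 * np.sin(omega * t) * np.exp(-arg ** 2 / 20.0)
    return Waveform(samples=samples, rate=rate, duration=duration)


def harmonic_excitation(frequency: float, amplitude: float = 10.0,
                        rate: float = DEFAULT_RATE,
                        duration: float = DEFAULT_DURATION) -> Waveform:
    """Harmonic excitation: pure sine at ``frequency`` (|amplitude| <= 10 V nominal)."""
    t = _time_axis(rate, duration)
    return Waveform(samples=amplitude * np.sin(2.0 * np.pi * frequency * t),
                    rate=rate, duration=duration)


def synthesize_echo(records: Sequence[EchoRecord], template: Waveform,
                    rate: float = DEFAULT_RATE,
                    duration: float = DEFAULT_DURATION) -> Waveform:
    """Superpose the template at each arrival time, scaled by its amplitude.

    Arrival times are quantised to the nearest sample; records beyond the
    time window are dropped with a warning.
    """
    n = int(rate * duration)
    out = np.zeros(n)
    tpl = template.samples
    for rec in records:
        shift = int(round(rec.time * rate))
        if shift >= n:
            warnings.warn(f"echo record at {rec.time * 1e6:.1f} us falls outside "
                          f"the {duration * 1e6:.0f} us window; dropped")
            continue
        m = min(tpl.size, n - shift)
        out[shift:shift + m] += rec.amplitude * tpl[:m]
    return Waveform(samples=out, rate=rate, duration=duration)


def spectrum(w: Waveform) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum (frequencies, |X_k|), unnormalised DFT."""
    mags = np.abs(np.fft.rfft(w.samples))
    freqs = np.fft.rfftfreq(w.samples.size, d=1.0 / w.rate)
    return freqs, mags


def spectral_energy(w: Waveform) -> float:
    """Signal energy computed from the one-sided spectrum.

    With the unnormalised DFT, Parseval gives Σ|x|² = (1/N) Σ_k |X_k|² over
    the full spectrum; interior one-sided bins count twice.
    """
    n = w.samples.size
    mags = np.abs(np.fft.rfft(w.samples))
    weights = np.full(mags.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    return float(np.sum(weights * mags ** 2) / n)


def echo_metrics(w: Waveform, threshold: float = AMPLITUDE_THRESHOLD,
                 records: Optional[Sequence[EchoRecord]] = None,
                 ) -> Tuple[float, float, int, np.ndarray]:
    """(energy, peak, n_interactions, spectrum magnitudes) of an echo waveform.

    Energy is Σ|x(t)|² over the window; n_interactions counts the records
    above ``threshold`` (capped at 1200) when a record list is supplied.
    """
    energy = float(np.sum(np.abs(w.samples) ** 2))
    peak = float(np.max(np.abs(w.samples))) if w.samples.size else 0.0
    if records is not None:
        n_inter = min(sum(1 for r in records if abs(r.amplitude) > threshold),
                      RECORD_CAP)
    else:
        n_inter = 0
    _, mags = spectrum(w)
    return energy, peak, n_inter, mags
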