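"""Frequency-domain characterization of AM envelopes.

Each band envelope is summarized by its modulation power spectrum: the
one-sided periodogram of the mean-removed envelope, zero-padded to at least
0.1 Hz resolution, normalized so that total power equals the envelope's
variance (Parseval).  "Frequency power" of a rhythm is the summed power
inside that rhythm's band — prosody (1, 4], syllable (4, 12], phoneme
(12, 40] Hz; content below 1 Hz is excluded from all band summaries, since
sub-1-Hz modulation reflects sentence-level rhythm rather than phonology.

Spectra are averaged pointwise within each direction group, and envelopes
can also be rendered as continuous-wavelet scalograms (0.1-40 Hz, dB,
maximum normalized to 0 dB) over a seeded random 4-s excerpt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .bands import RHYTHM_TO_BAND, band_of_rhythm
from .pad import AmHierarchy

#: (lo, hi] band-power windows, keyed by rhythm name.
POWER_BANDS = {r: (band_of_rhythm(r).lo_hz, band_of_rhythm(r).hi_hz)
               for r in ("prosody", "syllable", "phoneme")}


class FeatureValidationError(ValueError):
    pass


@dataclass
class ModulationSpectrum:
    """One-sided modulation power spectrum of one envelope."""

    freqs_hz: np.ndarray
    power: np.ndarray
    band_power: dict
    sample_id: str = ""
    band_name_of_source: str = ""
    n_averaged: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "band_name_of_source": self.band_name_of_source,
                "freq_hz": self.freqs_hz,
                "power": self.power,
            }
        )


@dataclass
class Scalogram:
    """CWT magnitude map of an envelope excerpt, max-normalized to 0 dB."""

    times_s: np.ndarray
    scales_hz: np.ndarray
    magnitude_db: np.ndarray  # (scales, times)
    sample_id: str = ""


def _band_powers(freqs, power):
    out = {}
    for rhythm, (lo, hi) in POWER_BANDS.items():
        sel = (freqs > lo) & (freqs <= hi)
        out[rhythm] = float(power[sel].sum())
    return out


def modulation_spectrum(
    envelope: np.ndarray,
    grid_hz: float,
    sample_id: str = "",
    band_name_of_source: str = "",
    min_duration_s: float = 10.0,
    resolution_hz: float = 0.1,
) -> ModulationSpectrum:
    """Periodogram of the mean-removed envelope with Parseval normalization.

    Zero-pads to reach at least ``resolution_hz`` frequency resolution; the
    total one-sided power equals the envelope variance exactly.
    """
    e = np.asarray(envelope, dtype=np.float64)
    if e.size < min_duration_s * grid_hz:
        raise FeatureValidationError(
            f"envelope shorter than {min_duration_s} s at {grid_hz} Hz"
        )
    n = e.size
    e = e - e.mean()
    m = max(n, int(np.ceil(grid_hz / resolution_hz)))
    spec = np.fft.rfft(e, n=m)
    power = np.abs(spec) ** 2 / (n * m)
    # one-sided doubling; DC (and Nyquist for even m) appear once in the FFT
    power[1:] *= 2.0
    if m % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(m, d=1.0 / grid_hz)
    return ModulationSpectrum(
        freqs_hz=freqs,
        power=power,
        band_power=_band_powers(freqs, power),
        sample_id=sample_id,
        band_name_of_source=band_name_of_source,
    )


def hierarchy_spectra(
    hierarchy: AmHierarchy, min_duration_s: float = 10.0
) -> dict:
    """Modulation spectrum of each rhythm band's own envelope.

    Also computes, as a cross-check, the spectrum of the broadband envelope
    (the product of the three rhythm-band envelopes), whose in-band powers
    offer an alternative reading of per-rhythm "frequency power"; it is
    returned under the key ``"broadband"``.
    """
    out = {}
    broadband = np.ones_like(hierarchy.bands[0][3])
    for name, _lo, _hi, env in hierarchy.bands:
        if name == "low_delta":
            continue
        broadband = broadband * env
        out[name] = modulation_spectrum(
            env,
            hierarchy.env_grid_hz,
            sample_id=hierarchy.source_sample_id,
            band_name_of_source=name,
            min_duration_s=min_duration_s,
        )
    out["broadband"] = modulation_spectrum(
        broadband,
        hierarchy.env_grid_hz,
        sample_id=hierarchy.source_sample_id,
        band_name_of_source="broadband",
        min_duration_s=min_duration_s,
    )
    return out


def rhythm_powers(spectra: dict) -> dict:
    """Per-rhythm frequency power: each band's power from its own envelope."""
    out = {}
    for rhythm, band in RHYTHM_TO_BAND.items():
        out[f"{rhythm}_power"] = spectra[band].band_power[rhythm]
        out[f"{rhythm}_power_broadband"] = spectra["broadband"].band_power[rhythm]
    return out


def group_average_spectra(spectra: list, grouping: dict) -> dict:
    """Pointwise mean spectrum per direction label.

    ``grouping`` maps sample_id -> direction_label.  Spectra on differing
    grids are linearly re-gridded onto the first spectrum's grid.  Empty
    groups are dropped with a warning.
    """
    by_label: dict[str, list[ModulationSpectrum]] = {}
    for s in spectra:
        label = grouping.get(s.sample_id)
        if label is None:
            warnings.warn(f"sample {s.sample_id!r} missing from grouping; skipped",
                          stacklevel=2)
            continue
        by_label.setdefault(label, []).append(s)

    out = {}
    for label in sorted(by_label):
        members = by_label[label]
        if not members:
            warnings.warn(f"group {label!r} is empty; excluded", stacklevel=2)
            continue
        grid = members[0].freqs_hz
        stack = []
        for s in members:
            if s.freqs_hz.size == grid.size and np.allclose(s.freqs_hz, grid):
                stack.append(s.power)
            else:
                stack.append(np.interp(grid, s.freqs_hz, s.power))
        mean_power = np.mean(stack, axis=0)
        band_power = {
            k: float(np.mean([s.band_power[k] for s in members]))
            for k in members[0].band_power
        }
        out[label] = ModulationSpectrum(
            freqs_hz=grid,
            power=mean_power,
            band_power=band_power,
            sample_id=label,
            band_name_of_source=members[0].band_name_of_source,
            n_averaged=len(members),
        )
    return out


def scalogram(
    envelope: np.ndarray,
    grid_hz: float,
    window_s: float = 4.0,
    freq_lo_hz: float = 0.1,
    freq_hi_hz: float = 40.0,
    n_scales: int = 64,
    seed: int = 0,
    sample_id: str = "",
) -> Scalogram:
    """Continuous-wavelet scalogram of a (random, seeded) 4-s excerpt.

    Uses an analytic complex-Morlet wavelet on log-spaced frequencies from
    0.1 to 40 Hz; magnitudes are in dB with the maximum normalized to 0 dB.
    """
    e = np.asarray(envelope, dtype=np.float64)
    n_win = int(round(window_s * grid_hz))
    if e.size < n_win:
        raise FeatureValidationError(
            f"envelope shorter than the {window_s}-s scalogram window"
        )
    if e.size > n_win:
        start = np.random.default_rng(seed).integers(0, e.size - n_win + 1)
    else:
        start = 0
    seg = e[start : start + n_win]
    seg = seg - seg.mean()

    freq_hi_hz = min(freq_hi_hz, grid_hz / 2.0)
    freqs = np.geomspace(freq_lo_hz, freq_hi_hz, n_scales)
    wavelet = "cmor1.5-1.0"
    scales = pywt.frequency2scale(wavelet, freqs / grid_hz)
    coeffs, _ = pywt.cwt(seg, scales, wavelet, sampling_period=1.0 / grid_hz)
    mag = np.abs(coeffs)
    peak = mag.max()
    if peak <= 0:
        mag_db = np.zeros_like(mag)
    else:
        mag_db = 20.0 * np.log10(np.maximum(mag, peak * 1e-8) / peak)
    times = start / grid_hz + np.arange(n_win) / grid_hz
    return Scalogram(times_s=times, scales_hz=freqs, magnitude_db=mag_db,
                     sample_id=sample_id)


def spectra_to_tidy(spectra: list) -> pd.DataFrame:
    """Long-format CSV table: sample_id, band_name_of_source, freq_hz, power."""
    return pd.concat([s.to_frame() for s in spectra], ignore_index=True)


def powers_to_tidy(rows: list) -> pd.DataFrame:
    """Wide per-sample power table with direction labels."""
    return pd.DataFrame(rows)
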