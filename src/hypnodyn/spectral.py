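"""Multitaper spectral power and frontal-occipital coherence.

Per-epoch 5-s windows are tapered with K = 3 discrete prolate spheroidal
sequences (time-bandwidth product NW = 2; half-bandwidth 2/5 s = 0.4 Hz)
and the eigenspectra averaged — the classical low-variance estimator for
short electrophysiology windows. Band powers are integrals of the PSD over
each scheme band (45-75 Hz gap excluded), normalised by the summed power
over all bands so shares sum to 1 and are invariant to channel gain.

Coherence between the two cortical channels is the magnitude-squared-root
coherency from taper- and window-averaged auto/cross spectra, variance-
stabilised by Fisher's z (atanh, with C clipped at 1 - 1e-6 so identical
channels stay finite).

Only artifact-free, non-transition epochs (label equal to both neighbours')
enter state averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import windows as spw

from .io import epoch_windows
from .types import BandScheme, EEGSession, Hypnogram, State, VIGILANCE_STATES, \
    default_band_scheme

__all__ = [
    "select_epochs",
    "multitaper_psd",
    "band_powers",
    "coherence_spectrum",
    "state_spectral_summary",
    "SpectralResult",
    "CoherenceResult",
]

_Z_CLIP = 1.0 - 1e-6


def select_epochs(h: Hypnogram) -> np.ndarray:
    """Boolean mask of retained epochs: artifact-free and non-transition.

    An epoch is retained iff it is not an artifact and its label equals the
    labels of both neighbours (edge epochs are compared to their single
    neighbour). This is the strictest reading of "non-transition epoch".
    """
    n = len(h)
    labels = h.labels
    mask = np.zeros(n, dtype=bool)
    for k in range(n):
        if labels[k] == State.ARTIFACT:
            continue
        left_ok = k == 0 or labels[k - 1] == labels[k]
        right_ok = k == n - 1 or labels[k + 1] == labels[k]
        mask[k] = left_ok and right_ok
    return mask


def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    tapers = spw.dpss(n, nw, Kmax=k)
    # unit-energy tapers -> PSD scaling reduces to 1/fs per eigenspectrum
    return tapers / np.sqrt((tapers ** 2).sum(axis=1, keepdims=True))


def _taper_ffts(window: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """Eigencoefficients: rFFT of each tapered copy, shape (K, n_freq)."""
    return np.fft.rfft(tapers * window[None, :], axis=1)


def multitaper_psd(window: np.ndarray, fs: float, nw: float = 2.0,
                   k: int = 3):
    """One-sided multitaper PSD of a single window.

    Returns ``(freqs, psd)``; a 5-s window gives a 0.2 Hz frequency grid.
    ``psd`` integrates (sum * df) to the window variance (Parseval).
    """
    window = np.asarray(window, dtype=float)
    n = window.size
    if n < 2:
        raise ValueError("window too short for spectral estimation")
    tapers = _dpss_tapers(n, nw, k)
    eig = _taper_ffts(window, tapers)
    psd = (np.abs(eig) ** 2).mean(axis=0) / fs
    # one-sided: double everything except DC (and Nyquist for even n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def band_powers(freqs: np.ndarray, psd: np.ndarray,
                scheme: Optional[BandScheme] = None) -> Dict[str, float]:
    """Normalised band powers: integrated PSD per band / sum over all bands.

    Excluded scheme gaps are removed from every band. Raises if a band lies
    outside the spectrum's support.
    """
    if scheme is None:
        scheme = default_band_scheme()
    df = float(freqs[1] - freqs[0])
    raw = {}
    for band in scheme:
        if band.f_hi > freqs[-1] + df / 2:
            raise ValueError(
                f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) outside "
                f"spectrum support (max {freqs[-1]:.1f} Hz)")
        m = scheme.keep_mask(freqs, band)
        raw[band.name] = float(psd[m].sum() * df)
    total = sum(raw.values())
    if total <= 0:
        return {name: np.nan for name in raw}
    return {name: v / total for name, v in raw.items()}


@dataclass
class SpectralResult:
    """Per (channel, state) mean PSD and normalised band powers."""

    freqs: np.ndarray
    psd: Dict[tuple, np.ndarray]            # (channel, state) -> mean PSD
    band_power: Dict[tuple, Dict[str, float]]
    n_windows: Dict[State, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chan, state), bp in self.band_power.items():
            for band, share in bp.items():
                rows.append({"channel": chan, "state": state.value,
                             "band": band, "norm_power": share})
        return pd.DataFrame(rows)


@dataclass
class CoherenceResult:
    """Per-state frontal-occipital coherence, Fisher-z, and band means."""

    freqs: np.ndarray
    coherence: Dict[State, np.ndarray]
    z: Dict[State, np.ndarray]
    band_z: Dict[State, Dict[str, float]]
    n_windows: Dict[State, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state, bz in self.band_z.items():
            for band, z in bz.items():
                rows.append({"state": state.value, "band": band, "z_coherence": z})
        return pd.DataFrame(rows)


def fisher_z(c: np.ndarray) -> np.ndarray:
    """Variance-stabilising transform of coherence, clipped to stay finite."""
    return np.arctanh(np.clip(c, 0.0, _Z_CLIP))


def coherence_spectrum(frontal_windows: Sequence[np.ndarray],
                       occipital_windows: Sequence[np.ndarray],
                       fs: float, nw: float = 2.0, k: int = 3,
                       scheme: Optional[BandScheme] = None):
    """Magnitude coherence from taper- and window-averaged cross-spectra.

    Needs >= 2 paired windows (a single estimate has coherence identically
    1). Returns ``(freqs, coherence, z, band_z)`` with the Fisher-z spectrum
    and per-band mean z (excluded gaps removed).
    """
    if len(frontal_windows) != len(occipital_windows):
        raise ValueError("paired channels need equal window counts")
    if len(frontal_windows) < 2:
        raise ValueError("coherence needs >= 2 windows")
    if scheme is None:
        scheme = default_band_scheme()
    n = len(frontal_windows[0])
    tapers = _dpss_tapers(n, nw, k)
    sxx = syy = sxy = None
    for wx, wy in zip(frontal_windows, occipital_windows):
        ex = _taper_ffts(np.asarray(wx, float), tapers)
        ey = _taper_ffts(np.asarray(wy, float), tapers)
        pxx = (np.abs(ex) ** 2).sum(axis=0)
        pyy = (np.abs(ey) ** 2).sum(axis=0)
        pxy = (ex * np.conj(ey)).sum(axis=0)
        sxx = pxx if sxx is None else sxx + pxx
        syy = pyy if syy is None else syy + pyy
        sxy = pxy if sxy is None else sxy + pxy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) / np.sqrt(sxx * syy)
    coh = np.nan_to_num(coh, nan=0.0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    z = fisher_z(coh)
    band_z = {}
    for band in scheme:
        m = scheme.keep_mask(freqs, band)
        band_z[band.name] = float(z[m].mean()) if m.any() else np.nan
    return freqs, coh, z, band_z


def state_spectral_summary(session: EEGSession, h: Hypnogram,
                           scheme: Optional[BandScheme] = None,
                           nw: float = 2.0, k: int = 3):
    """Mean PSD, band powers and coherence per vigilance state.

    Averages run over retained (artifact-free, non-transition) epochs only.
    States with no retained epochs — or too few for coherence — are simply
    absent from the results (mirroring REM exclusion under strong REM
    suppression); ``n_windows`` reports the count per state.
    """
    if scheme is None:
        scheme = default_band_scheme()
    mask = select_epochs(h)
    wins = epoch_windows(session, h, mask)
    by_state: Dict[State, list] = {}
    for _, state, chans in wins:
        by_state.setdefault(state, []).append(chans)

    freqs = None
    psd_out, bp_out = {}, {}
    coh_out, z_out, bz_out = {}, {}, {}
    n_windows = {s: len(v) for s, v in by_state.items()}
    for state, items in by_state.items():
        for chan in ("frontal", "occipital"):
            acc = None
            for chans in items:
                f, p = multitaper_psd(chans[chan], session.fs, nw, k)
                freqs = f
                acc = p if acc is None else acc + p
            mean_psd = acc / len(items)
            psd_out[(chan, state)] = mean_psd
            bp_out[(chan, state)] = band_powers(freqs, mean_psd, scheme)
        if len(items) >= 2:
            fw = [c["frontal"] for c in items]
            ow = [c["occipital"] for c in items]
            _, coh, z, bz = coherence_spectrum(fw, ow, session.fs, nw, k, scheme)
            coh_out[state], z_out[state], bz_out[state] = coh, z, bz
    spec = SpectralResult(freqs=freqs, psd=psd_out, band_power=bp_out,
                          n_windows=n_windows)
    coh = CoherenceResult(freqs=freqs, coherence=coh_out, z=z_out,
                          band_z=bz_out, n_windows=n_windows)
    return spec, coh
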