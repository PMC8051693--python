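"""Core domain types for sleep-EEG dynamics analysis.

The analysis operates on two aligned objects: a :class:`Hypnogram` (one
vigilance-state label per fixed-length scoring epoch) and an
:class:`EEGSession` (frontal + occipital cortical channels, optional EMG).
Frequency-band schemes for spectral/coherence analysis and for symbolic
transfer entropy are value objects carrying the band edges (and, for the
symbolic analysis, the per-band embedding delay in samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "State",
    "Hypnogram",
    "EEGSession",
    "Band",
    "BandScheme",
    "NSTEBand",
    "NSTEBandScheme",
    "PairedRecording",
    "PairedCohort",
    "DEFAULT_EPOCH_S",
    "default_band_scheme",
    "default_nste_scheme",
]

DEFAULT_EPOCH_S = 5.0


class State(str, Enum):
    """Vigilance-state alphabet: wake, NREM sleep, REM sleep, artifact."""

    WAKE = "W"
    NREM = "NREM"
    REM = "REM"
    ARTIFACT = "ARTIFACT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three behavioural states (artifact excluded), in canonical order.
VIGILANCE_STATES = (State.WAKE, State.NREM, State.REM)

_ALIASES = {
    "w": State.WAKE,
    "wake": State.WAKE,
    "n": State.NREM,
    "nrem": State.NREM,
    "r": State.REM,
    "rem": State.REM,
    "a": State.ARTIFACT,
    "artifact": State.ARTIFACT,
}


def parse_state(token: str) -> State:
    """Parse a state token, accepting case-insensitive aliases.

    Recognised: W/Wake, N/NREM, R/REM, A/Artifact.

    Raises
    ------
    ValueError
        If the token is not a recognised state label.
    """
    try:
        return _ALIASES[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognized state token: {token!r}") from None


@dataclass(frozen=True)
class Hypnogram:
    """A scored hypnogram: one state label per fixed-duration epoch.

    Parameters
    ----------
    labels : tuple of State
        One label per epoch, in temporal order.
    epoch_s : float
        Epoch duration in seconds (default 5 s).
    t0 : float
        Session start offset in seconds (default 0).
    """

    labels: tuple
    epoch_s: float = DEFAULT_EPOCH_S
    t0: float = 0.0

    def __post_init__(self):
        if len(self.labels) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        labels = tuple(
            lab if isinstance(lab, State) else parse_state(str(lab))
            for lab in self.labels
        )
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds."""
        return len(self.labels) * self.epoch_s

    def codes(self) -> np.ndarray:
        """Labels as integer codes: W=0, NREM=1, REM=2, ARTIFACT=-1."""
        lut = {State.WAKE: 0, State.NREM: 1, State.REM: 2, State.ARTIFACT: -1}
        return np.array([lut[s] for s in self.labels], dtype=np.int64)


@dataclass
class EEGSession:
    """Two-channel cortical EEG (frontal, occipital) with optional EMG.

    All channels must have equal length; ``fs`` is the sampling rate in Hz.
    """

    frontal: np.ndarray
    occipital: np.ndarray
    fs: float
    emg: Optional[np.ndarray] = None
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.frontal = np.asarray(self.frontal, dtype=float)
        self.occipital = np.asarray(self.occipital, dtype=float)
        if self.emg is not None:
            self.emg = np.asarray(self.emg, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.frontal)
        if len(self.occipital) != n or (self.emg is not None and len(self.emg) != n):
            raise ValueError("all channels must have the same length")

    @property
    def n_samples(self) -> int:
        return len(self.frontal)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channels(self) -> dict:
        out = {"frontal": self.frontal, "occipital": self.occipital}
        if self.emg is not None:
            out["emg"] = self.emg
        return out

    def check_alignment(self, h: Hypnogram) -> None:
        """Raise if session and hypnogram durations differ by >= one epoch."""
        if abs(self.duration_s - h.duration_s) >= h.epoch_s:
            raise ValueError(
                f"session duration {self.duration_s:.1f} s and hypnogram "
                f"duration {h.duration_s:.1f} s differ by one epoch or more"
            )


@dataclass(frozen=True)
class Band:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: need f_lo < f_hi")


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands for power/coherence, plus excluded gaps.

    Frequencies inside an excluded gap are removed from every analysis
    (band powers, coherence band means); the default scheme excludes
    45-75 Hz, where notch filtering in the source recordings makes the
    spectrum untrustworthy.
    """

    bands: tuple
    excluded: tuple = ()

    def __post_init__(self):
        ordered = sorted(self.bands, key=lambda b: b.f_lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.f_lo < a.f_hi:
                raise ValueError(f"bands {a.name} and {b.name} overlap")

    def names(self) -> list:
        return [b.name for b in self.bands]

    def __iter__(self):
        return iter(self.bands)

    def keep_mask(self, freqs: np.ndarray, band: Band) -> np.ndarray:
        """Boolean mask of frequencies in [f_lo, f_hi) minus excluded gaps."""
        m = (freqs >= band.f_lo) & (freqs < band.f_hi)
        for lo, hi in self.excluded:
            m &= ~((freqs >= lo) & (freqs < hi))
        return m


def default_band_scheme() -> BandScheme:
    """The 7-band spectral scheme: SO, delta, theta, sigma, beta, low/high gamma.

    45-75 Hz is excluded throughout.
    """
    return BandScheme(
        bands=(
            Band("so", 0.5, 1.0),
            Band("delta", 1.0, 4.0),
            Band("theta", 4.0, 9.0),
            Band("sigma", 9.0, 15.0),
            Band("beta", 15.0, 30.0),
            Band("low_gamma", 30.0, 45.0),
            Band("high_gamma", 75.0, 115.0),
        ),
        excluded=((45.0, 75.0),),
    )


@dataclass(frozen=True)
class NSTEBand:
    """A band for symbolic transfer entropy: edges plus embedding delay tau.

    ``tau_samples`` is the ordinal-pattern embedding delay in samples at the
    analysis rate (512 Hz); larger tau tunes the symbolisation to slower
    rhythms.
    """

    name: str
    f_lo: float
    f_hi: float
    tau_samples: int

    def __post_init__(self):
        if self.tau_samples < 1:
            raise ValueError("tau must be >= 1 sample")
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: need f_lo < f_hi")


@dataclass(frozen=True)
class NSTEBandScheme:
    """Band set for NSTE with embedding dimension and transfer-time search range."""

    entries: tuple
    embedding_dimension: int = 3
    delta_search: tuple = (1, 50)

    def __post_init__(self):
        if self.embedding_dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        lo, hi = self.delta_search
        if lo < 1 or hi < lo:
            raise ValueError("delta_search must be a nonempty range of lags >= 1")

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list:
        return [e.name for e in self.entries]


def default_nste_scheme() -> NSTEBandScheme:
    """Six NSTE bands with per-band tau (samples at 512 Hz): 64/28/17/9/6/2."""
    return NSTEBandScheme(
        entries=(
            NSTEBand("delta", 0.5, 4.0, 64),
            NSTEBand("theta", 4.0, 9.0, 28),
            NSTEBand("sigma", 9.0, 15.0, 17),
            NSTEBand("beta", 15.0, 30.0, 9),
            NSTEBand("low_gamma", 30.0, 45.0, 6),
            NSTEBand("high_gamma", 75.0, 115.0, 2),
        ),
        embedding_dimension=3,
        delta_search=(1, 50),
    )


@dataclass
class PairedRecording:
    """One subject's pair of (session, hypnogram) under the two conditions."""

    subject_id: str
    control_session: EEGSession
    control_hypnogram: Hypnogram
    treatment_session: EEGSession
    treatment_hypnogram: Hypnogram


@dataclass
class PairedCohort:
    """Within-subject paired cohort: each subject recorded under both arms."""

    subjects: list = field(default_factory=list)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject IDs must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)
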