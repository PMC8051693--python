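"""Synthetic hypnograms and state-conditioned EEG with known ground truth.

The hypnogram generator is a three-state (W, NREM, REM) first-order Markov
chain sampled at the 5-s epoch grid. Default transition matrices for the
two arms are built from the printed group-mean probabilities of the study
this package models (vehicle vs. chemogenetic-stimulation arms), each row
renormalised to sum exactly to 1.

The EEG synthesiser draws, per epoch, state-conditioned content: a set of
band-limited oscillators (slow oscillations and delta in NREM, theta in
REM, low-amplitude fast activity in wake) on top of 1/f background noise,
with a known directed frontal->occipital (or reverse) coupling implemented
as delayed linear mixing — so spectral, coherence, directed-connectivity
and complexity estimators can all be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .types import (
    DEFAULT_EPOCH_S,
    EEGSession,
    Hypnogram,
    PairedCohort,
    PairedRecording,
    State,
    VIGILANCE_STATES,
)

__all__ = [
    "ChainParams",
    "Oscillator",
    "StateEEGParams",
    "control_chain_params",
    "treatment_chain_params",
    "default_eeg_params",
    "simulate_hypnogram",
    "simulate_state_batch",
    "synthesize_eeg",
    "make_cohort",
]

_STATE_INDEX = {State.WAKE: 0, State.NREM: 1, State.REM: 2}


@dataclass(frozen=True)
class ChainParams:
    """Markov-chain parameters for hypnogram simulation.

    ``P[i, j]`` is the probability of moving from state i to state j in the
    next 5-s epoch, states ordered (W, NREM, REM). Rows must sum to 1.
    """

    P: np.ndarray
    initial_state: State = State.WAKE
    epoch_s: float = DEFAULT_EPOCH_S
    n_epochs: int = 4320  # 6 h of 5-s epochs

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.shape != (3, 3):
            raise ValueError("P must be 3x3 over (W, NREM, REM)")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each row of P must sum to 1 (within 1e-12)")
        object.__setattr__(self, "P", P)
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    def stationary(self) -> np.ndarray:
        """Stationary distribution of P (left eigenvector for eigenvalue 1)."""
        w, v = np.linalg.eig(self.P.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        return pi / pi.sum()


def _renorm(rows) -> np.ndarray:
    P = np.asarray(rows, dtype=float)
    return P / P.sum(axis=1, keepdims=True)


def control_chain_params(**kw) -> ChainParams:
    """Vehicle-arm transition matrix from the study's printed group means.

    Rows (W, NREM, REM); printed means do not sum exactly to 1, so each row
    is renormalised. Note the printed remain-in-REM probability equals the
    printed remain-in-NREM one (0.9621) — kept verbatim.
    """
    P = _renorm([
        [0.9205, 0.0790, 0.0],      # W -> (W, N, R); W->REM never observed
        [0.0310, 0.9621, 0.0072],   # N -> (W, N, R)
        [0.0625, 0.0030, 0.9621],   # R -> (W, N, R)
    ])
    return ChainParams(P=P, **kw)


def treatment_chain_params(**kw) -> ChainParams:
    """Stimulation-arm transition matrix (fragmented NREM, suppressed REM)."""
    P = _renorm([
        [0.8983, 0.1017, 0.0],
        [0.0600, 0.9384, 0.0017],
        [0.0833, 0.0110, 0.9052],
    ])
    return ChainParams(P=P, **kw)


def simulate_state_batch(params: ChainParams, n_chains: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n_chains`` independent chains at once.

    Returns an (n_chains, n_epochs) int array of state indices (W=0, NREM=1,
    REM=2). Vectorised over chains so large calibration runs stay fast.
    """
    cum = np.cumsum(params.P, axis=1)
    cum[:, -1] = 1.0  # guard against float round-off
    out = np.empty((n_chains, params.n_epochs), dtype=np.int8)
    out[:, 0] = _STATE_INDEX[params.initial_state]
    if params.n_epochs > 1:
        u = rng.random((n_chains, params.n_epochs - 1))
        for t in range(1, params.n_epochs):
            rows = cum[out[:, t - 1]]
            out[:, t] = (u[:, t - 1, None] >= rows).sum(axis=1)
    return out


def simulate_hypnogram(params: ChainParams, seed) -> Hypnogram:
    """Sample one hypnogram from the Markov chain; deterministic given seed."""
    rng = np.random.default_rng(seed)
    codes = simulate_state_batch(params, 1, rng)[0]
    labels = tuple(VIGILANCE_STATES[c] for c in codes)
    return Hypnogram(labels=labels, epoch_s=params.epoch_s)


@dataclass(frozen=True)
class Oscillator:
    """A band-limited rhythm: centre frequency, amplitude, per-channel weights.

    ``mod_freq_hz``/``mod_depth`` impose a slow amplitude modulation
    (envelope 1 + depth*sin(2*pi*f_mod*t + phase)), emulating the waxing and
    waning of slow-oscillation and spindle trains; depth 0 disables it.
    """

    freq_hz: float
    amplitude: float
    weights: Tuple[float, float] = (1.0, 1.0)  # (frontal, occipital)
    mod_freq_hz: float = 0.0
    mod_depth: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("oscillator amplitude must be >= 0")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("modulation depth must lie in [0, 1]")


@dataclass(frozen=True)
class StateEEGParams:
    """State-conditioned EEG generator parameters.

    ``oscillators`` maps each vigilance state to its rhythms; ``noise_amp``
    scales 1/f^exponent background noise (independent per channel);
    ``coupling`` = (direction, lag_ms, gain) adds a delayed copy of the
    source channel into the target, giving a known directed interaction.
    ``emg_tone`` sets per-state EMG RMS (wake high, REM atonia).
    """

    oscillators: dict = field(default_factory=dict)
    noise_amp: float = 1.0
    noise_exponent: float = 1.0
    coupling: Tuple[str, float, float] = ("frontal->occipital", 20.0, 0.5)
    emg_tone: dict = field(default_factory=dict)
    fs: float = 512.0

    def __post_init__(self):
        direction, lag_ms, gain = self.coupling
        if direction not in ("frontal->occipital", "occipital->frontal"):
            raise ValueError("coupling direction must be 'frontal->occipital' "
                             "or 'occipital->frontal'")
        if lag_ms < 0:
            raise ValueError("coupling lag must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def default_eeg_params(fs: float = 512.0) -> StateEEGParams:
    """Default state-conditioned EEG: SO/delta-dominated NREM, theta REM,
    low-amplitude fast wake, 1/f background, frontal->occipital coupling
    (20 ms lag, gain 0.5)."""
    return StateEEGParams(
        oscillators={
            State.WAKE: (Oscillator(7.0, 0.3), Oscillator(35.0, 0.2)),
            State.NREM: (
                Oscillator(0.75, 3.5, mod_freq_hz=0.3, mod_depth=0.8),
                Oscillator(2.5, 2.0, mod_freq_hz=0.5, mod_depth=0.8),
                Oscillator(12.0, 0.5, mod_freq_hz=0.4, mod_depth=1.0),
            ),
            State.REM: (Oscillator(7.0, 1.5, weights=(0.8, 1.2),
                                   mod_freq_hz=0.3, mod_depth=0.3),),
        },
        noise_amp=1.0,
        noise_exponent=1.0,
        coupling=("frontal->occipital", 20.0, 0.5),
        emg_tone={State.WAKE: 1.0, State.NREM: 0.2, State.REM: 0.05},
        fs=fs,
    )


def _one_over_f(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit std."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_eeg(h: Hypnogram, params: StateEEGParams, seed) -> EEGSession:
    """Generate a two-channel EEG session (plus EMG) conditioned on a hypnogram.

    Oscillator phases are randomised per bout (not per epoch) to avoid an
    artificial 5-s periodicity; background 1/f noise is continuous across the
    whole session. Directed coupling adds ``gain`` x source channel delayed
    by ``lag_ms`` into the target channel. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    fs = params.fs
    spe = int(round(h.epoch_s * fs))
    n = spe * len(h)
    direction, lag_ms, gain = params.coupling
    lag = int(round(lag_ms * fs / 1000.0))
    if lag >= spe:
        raise ValueError(
            f"coupling lag {lag} samples must be shorter than one {spe}-sample "
            "window")

    base = {
        "frontal": params.noise_amp * _one_over_f(n, params.noise_exponent, rng),
        "occipital": params.noise_amp * _one_over_f(n, params.noise_exponent, rng),
    }
    t = np.arange(n) / fs
    # bout boundaries: phases drawn once per maximal same-state run
    codes = h.codes()
    starts = [0] + [k for k in range(1, len(h)) if codes[k] != codes[k - 1]]
    starts.append(len(h))
    for b0, b1 in zip(starts, starts[1:]):
        state = h.labels[b0]
        lo, hi = b0 * spe, b1 * spe
        for osc in params.oscillators.get(state, ()):
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * osc.freq_hz * t[lo:hi] + phase)
            if osc.mod_depth > 0:
                mphase = rng.uniform(0, 2 * np.pi)
                wave = wave * (1.0 + osc.mod_depth * np.sin(
                    2 * np.pi * osc.mod_freq_hz * t[lo:hi] + mphase))
            base["frontal"][lo:hi] += osc.weights[0] * osc.amplitude * wave
            base["occipital"][lo:hi] += osc.weights[1] * osc.amplitude * wave

    src, dst = (("frontal", "occipital")
                if direction == "frontal->occipital" else ("occipital", "frontal"))
    delayed = np.zeros(n)
    if lag < n:
        delayed[lag:] = base[src][:n - lag] if lag else base[src]
    out = dict(base)
    out[dst] = base[dst] + gain * delayed

    emg = None
    if params.emg_tone:
        emg = np.zeros(n)
        for k, lab in enumerate(h.labels):
            tone = params.emg_tone.get(lab, 0.0)
            emg[k * spe:(k + 1) * spe] = tone * rng.standard_normal(spe)

    return EEGSession(frontal=out["frontal"], occipital=out["occipital"],
                      emg=emg, fs=fs)


def _jitter_chain(params: ChainParams, sd: float,
                  rng: np.random.Generator) -> ChainParams:
    """Per-subject between-animal variability: Gaussian jitter on the diagonal
    (self-transition) probabilities, off-diagonal mass rescaled per row."""
    if sd <= 0:
        return params
    P = params.P.copy()
    for i in range(3):
        d = float(np.clip(P[i, i] + rng.normal(0.0, sd), 0.0, 1.0))
        off = P[i].copy()
        off[i] = 0.0
        s = off.sum()
        if s > 0:
            P[i] = off * (1.0 - d) / s
        else:
            P[i] = 0.0
        P[i, i] = d
        P[i] /= P[i].sum()
    return replace(params, P=P)


def make_cohort(n_subjects: int,
                control: Tuple[ChainParams, StateEEGParams],
                treatment: Tuple[ChainParams, StateEEGParams],
                seed,
                jitter_sd: float = 0.01,
                with_eeg: bool = True) -> PairedCohort:
    """Simulate a within-subject paired cohort (default study size n = 11).

    Each subject gets independent seeds per arm (spawned from ``seed``) and,
    if ``jitter_sd`` > 0, its own diagonal-jittered transition matrices.
    ``with_eeg=False`` generates hypnograms only (zero-length signals),
    for fast state-dynamics studies.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    subjects = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        recs = {}
        for arm, (cp, ep) in (("control", control), ("treatment", treatment)):
            cp_i = _jitter_chain(cp, jitter_sd, rng)
            h = simulate_hypnogram(cp_i, rng.integers(2 ** 31))
            if with_eeg:
                sess = synthesize_eeg(h, ep, rng.integers(2 ** 31))
            else:
                spe = int(round(h.epoch_s * ep.fs))
                z = np.zeros(spe)  # placeholder channel, one epoch long
                sess = EEGSession(frontal=z, occipital=z.copy(), fs=ep.fs)
            sess.subject_id = f"s{i:02d}"
            sess.condition = arm
            recs[arm] = (sess, h)
        subjects.append(PairedRecording(
            subject_id=f"s{i:02d}",
            control_session=recs["control"][0],
            control_hypnogram=recs["control"][1],
            treatment_session=recs["treatment"][0],
            treatment_hypnogram=recs["treatment"][1],
        ))
    return PairedCohort(subjects=subjects)
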