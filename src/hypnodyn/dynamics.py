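"""Hypnogram state dynamics: bouts, state times, latencies, the Markov
transition model, fragmentation index and bout-duration histograms.

The transition model treats the scored hypnogram as a first-order Markov
chain on (W, NREM, REM): `P(X/Y)` is the number of Y->X epoch successions
divided by the number of Y epochs that have a successor. The fragmentation
index of a state is `FI = 1 - p(X/X)` — 0 when the state always persists,
1 when every occurrence is immediately left (complete fragmentation).

Artifact epochs are spliced out before transition counting: the epoch pair
spanning a removed artifact is not counted as a succession.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import Hypnogram, State, VIGILANCE_STATES

__all__ = [
    "BoutTable",
    "TransitionMatrix",
    "FragmentationIndex",
    "Latency",
    "segment_bouts",
    "state_times",
    "latency",
    "count_transitions",
    "transition_matrix",
    "pooled_transition_matrix",
    "fragmentation_index",
    "hourly_fi",
    "bout_histogram",
]

_IDX = {s: i for i, s in enumerate(VIGILANCE_STATES)}

#: Default bout-histogram bin widths (seconds) per state.
DEFAULT_HIST_BIN_S = {State.WAKE: 10.0, State.NREM: 50.0}


@dataclass(frozen=True)
class Bout:
    state: State
    start_s: float
    duration_s: float


class BoutTable:
    """Maximal same-state runs tiling the hypnogram without gaps or overlap."""

    def __init__(self, bouts: Sequence[Bout], epoch_s: float):
        self.bouts = list(bouts)
        self.epoch_s = epoch_s

    def __len__(self):
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def for_state(self, state: State) -> list:
        return [b for b in self.bouts if b.state == state]

    def durations(self, state: State) -> np.ndarray:
        return np.array([b.duration_s for b in self.for_state(state)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.state.value, b.start_s, b.duration_s) for b in self.bouts],
            columns=["state", "start_s", "duration_s"],
        )


def segment_bouts(h: Hypnogram) -> BoutTable:
    """Run-length encode the hypnogram into maximal same-state bouts.

    Artifact epochs form bouts of their own (and are excluded from
    per-state statistics downstream).
    """
    bouts = []
    start = 0
    for k in range(1, len(h) + 1):
        if k == len(h) or h.labels[k] != h.labels[start]:
            bouts.append(Bout(
                state=h.labels[start],
                start_s=h.t0 + start * h.epoch_s,
                duration_s=(k - start) * h.epoch_s,
            ))
            start = k
    return BoutTable(bouts, epoch_s=h.epoch_s)


def state_times(h: Hypnogram, bin_s: Optional[float] = None) -> pd.DataFrame:
    """Seconds (and percent of bin) spent in each state, total or per bin.

    With ``bin_s`` (e.g. 3600 for 1-h bins) the hypnogram is split into
    consecutive bins; a final partial bin is flagged in the ``partial``
    column. Percentages are of the bin duration, so they sum to 100 per bin
    (artifact time included as its own row).
    """
    if bin_s is not None and bin_s <= 0:
        raise ValueError("bin_s must be positive")
    codes = [h.labels[k] for k in range(len(h))]
    if bin_s is None:
        edges = [(0, len(h))]
    else:
        per = int(round(bin_s / h.epoch_s))
        if per < 1:
            raise ValueError("bin_s must cover at least one epoch")
        edges = [(i, min(i + per, len(h))) for i in range(0, len(h), per)]
    rows = []
    states = list(VIGILANCE_STATES) + [State.ARTIFACT]
    for b, (lo, hi) in enumerate(edges):
        span = (hi - lo) * h.epoch_s
        full = bin_s is None or hi - lo == int(round(bin_s / h.epoch_s))
        for s in states:
            sec = sum(h.epoch_s for k in range(lo, hi) if codes[k] == s)
            rows.append({
                "bin": b, "bin_start_s": h.t0 + lo * h.epoch_s,
                "state": s.value, "seconds": sec,
                "percent": 100.0 * sec / span, "partial": not full,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Latency:
    """Time to first occurrence of a state; censored if it never occurs."""

    seconds: float
    censored: bool


def latency(h: Hypnogram, state: State) -> Latency:
    """Latency from session start to the first epoch of ``state``.

    If the state never occurs the full recording duration is returned with
    ``censored=True`` (6 h of 5-s epochs -> 21,600 s), ready for survival
    analysis.
    """
    for k, lab in enumerate(h.labels):
        if lab == state:
            return Latency(seconds=k * h.epoch_s, censored=False)
    return Latency(seconds=h.duration_s, censored=True)


def _spliced_pairs(h: Hypnogram):
    """Adjacent (src, dst) epoch pairs after removing artifact epochs.

    Splicing: the pair that would span a removed artifact run is dropped,
    not bridged."""
    labels = h.labels
    for k in range(len(labels) - 1):
        if labels[k] != State.ARTIFACT and labels[k + 1] != State.ARTIFACT:
            yield labels[k], labels[k + 1]


def count_transitions(h: Hypnogram, src: State, dst: State,
                      bin_s: Optional[float] = None):
    """Count adjacent-epoch (src, dst) successions, total or per bin.

    Per-bin counting assigns each transition to the bin containing its
    destination epoch. ``src`` and ``dst`` must differ.
    """
    if src == dst:
        raise ValueError("src and dst must differ (use the transition matrix "
                         "for self-transitions)")
    labels = h.labels
    hits = [k + 1 for k in range(len(labels) - 1)
            if labels[k] == src and labels[k + 1] == dst]
    if bin_s is None:
        return len(hits)
    per = int(round(bin_s / h.epoch_s))
    n_bins = int(np.ceil(len(h) / per))
    counts = np.zeros(n_bins, dtype=int)
    for k in hits:
        counts[k // per] += 1
    return counts


class TransitionMatrix:
    """Empirical first-order Markov model of a hypnogram.

    Attributes
    ----------
    counts : (3, 3) int array
        Observed successions, rows = source state (W, NREM, REM).
    probs : (3, 3) float array
        Row-normalised conditional probabilities P(next | current); rows for
        states never observed with a successor are NaN.
    state_probs : (3,) float array
        Marginal frequency of each state over all (non-artifact) epochs.
    """

    states = VIGILANCE_STATES

    def __init__(self, counts: np.ndarray, state_probs: np.ndarray):
        self.counts = np.asarray(counts, dtype=np.int64)
        self.state_probs = np.asarray(state_probs, dtype=float)
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.probs = np.where(row > 0, self.counts / row, np.nan)

    @classmethod
    def from_hypnogram(cls, h: Hypnogram) -> "TransitionMatrix":
        return transition_matrix(h)

    def prob(self, src: State, dst: State) -> float:
        return float(self.probs[_IDX[src], _IDX[dst]])

    def to_frame(self) -> pd.DataFrame:
        names = [s.value for s in self.states]
        return pd.DataFrame(self.probs, index=names, columns=names)


def transition_matrix(h: Hypnogram) -> TransitionMatrix:
    """Estimate the transition matrix by conditional-probability counting.

    P(X/Y) = number of Y->X successions / number of Y epochs with a
    successor; marginal state probabilities are label frequencies over all
    non-artifact epochs. Needs >= 2 epochs and at least one non-artifact one.
    """
    if len(h) < 2:
        raise ValueError("need >= 2 epochs to count transitions")
    counts = np.zeros((3, 3), dtype=np.int64)
    for src, dst in _spliced_pairs(h):
        counts[_IDX[src], _IDX[dst]] += 1
    n_valid = sum(1 for lab in h.labels if lab != State.ARTIFACT)
    if n_valid == 0:
        raise ValueError("hypnogram contains only artifact epochs")
    freq = np.array([
        sum(1 for lab in h.labels if lab == s) / n_valid
        for s in VIGILANCE_STATES
    ])
    return TransitionMatrix(counts=counts, state_probs=freq)


def pooled_transition_matrix(hypnograms: Sequence[Hypnogram]) -> TransitionMatrix:
    """Transition matrix from succession counts pooled across hypnograms.

    Pooling the raw counts before row-normalising avoids the small-sample
    bias that averaging per-recording probabilities incurs for rarely
    visited states (REM rows in short sessions); use this for parameter
    recovery, and per-recording matrices for paired statistics.
    """
    if not hypnograms:
        raise ValueError("need at least one hypnogram")
    counts = np.zeros((3, 3), dtype=np.int64)
    n_states = np.zeros(3)
    n_valid = 0
    for h in hypnograms:
        tm = transition_matrix(h)
        counts += tm.counts
        k = sum(1 for lab in h.labels if lab != State.ARTIFACT)
        n_states += tm.state_probs * k
        n_valid += k
    return TransitionMatrix(counts=counts, state_probs=n_states / n_valid)


@dataclass(frozen=True)
class FragmentationIndex:
    """FI = 1 - p(X/X) for one state over one time window.

    ``value`` is NaN when the state was never observed with a successor
    (e.g. REM after strong REM suppression) — missing, not 0.
    """

    state: State
    value: float
    window: tuple = (None, None)

    @property
    def missing(self) -> bool:
        return bool(np.isnan(self.value))


def fragmentation_index(tm: TransitionMatrix, state: State,
                        window: tuple = (None, None)) -> FragmentationIndex:
    """Fragmentation index of ``state`` from an estimated transition matrix."""
    p_stay = tm.probs[_IDX[state], _IDX[state]]
    value = np.nan if np.isnan(p_stay) else 1.0 - float(p_stay)
    return FragmentationIndex(state=state, value=value, window=window)


def hourly_fi(h: Hypnogram, state: State, block_s: float = 3600.0) -> list:
    """FI per consecutive 1-h block, each from that block's own matrix.

    Requires at least one full block; a trailing partial block is ignored.
    Blocks where the state is absent yield a missing (NaN) FI.
    """
    per = int(round(block_s / h.epoch_s))
    if len(h) < per:
        raise ValueError("hypnogram shorter than one block")
    out = []
    for b in range(len(h) // per):
        lo, hi = b * per, (b + 1) * per
        sub = Hypnogram(labels=h.labels[lo:hi], epoch_s=h.epoch_s,
                        t0=h.t0 + lo * h.epoch_s)
        try:
            tm = transition_matrix(sub)
            fi = fragmentation_index(tm, state,
                                     window=(sub.t0, sub.t0 + block_s))
        except ValueError:  # all-artifact block
            fi = FragmentationIndex(state=state, value=np.nan,
                                    window=(sub.t0, sub.t0 + block_s))
        out.append(fi)
    return out


def bout_histogram(bt: BoutTable, state: State,
                   bin_width_s: Optional[float] = None) -> pd.DataFrame:
    """Probability histogram of bout durations for one state.

    Bins are [k*w, (k+1)*w); default widths follow the field convention of
    10 s for wakefulness and 50 s for NREM sleep. Counts are normalised to
    probabilities summing to 1. A state with no bouts yields an empty,
    flagged frame (``.attrs['empty'] = True``).
    """
    if bin_width_s is None:
        bin_width_s = DEFAULT_HIST_BIN_S.get(state)
        if bin_width_s is None:
            raise ValueError(f"no default bin width for state {state}; pass one")
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    durs = bt.durations(state)
    if durs.size == 0:
        df = pd.DataFrame(columns=["bin_lo_s", "bin_hi_s", "count", "probability"])
        df.attrs["empty"] = True
        return df
    n_bins = int(np.floor(durs.max() / bin_width_s)) + 1
    edges = np.arange(n_bins + 1) * bin_width_s
    counts, _ = np.histogram(durs, bins=edges)
    df = pd.DataFrame({
        "bin_lo_s": edges[:-1], "bin_hi_s": edges[1:],
        "count": counts, "probability": counts / counts.sum(),
    })
    df.attrs["empty"] = False
    return df
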