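"""Frozen Poisson patterns, jittered presentations, and full input streams.

A "frozen-noise" pattern is a single realization of the homogeneous Poisson
process over all N afferents, stored once and replayed at every
presentation.  At each replay every spike is independently shifted by a
uniform jitter in [-T, T].  Between presentations all afferents fire fresh
Poisson spikes at the same rate f, so the stream has identical first-order
statistics inside and outside the patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeData",
    "PatternSet",
    "StreamAnnotation",
    "generate_pattern_set",
    "jitter_presentation",
    "build_stream",
    "poisson_block",
]


@dataclass
class SpikeData:
    """A set of (afferent, time) spike events over ``n_afferents`` channels.

    ``afferents`` and ``times`` are parallel arrays sorted by time
    (ascending); times are in ms within [0, duration) for freshly generated
    data (jittered presentations may exceed the nominal block).
    """

    afferents: np.ndarray
    times: np.ndarray
    n_afferents: int
    duration: float

    def __post_init__(self) -> None:
        self.afferents = np.asarray(self.afferents, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.afferents.shape != self.times.shape:
            raise ValueError("afferents and times must have equal length")
        if self.afferents.size and (
            self.afferents.min() < 0 or self.afferents.max() >= self.n_afferents
        ):
            raise ValueError("afferent index out of range")
        if not np.all(np.diff(self.times) >= 0):
            order = np.argsort(self.times, kind="stable")
            self.afferents = self.afferents[order]
            self.times = self.times[order]

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeData):
            return NotImplemented
        return (
            self.n_afferents == other.n_afferents
            and self.duration == other.duration
            and np.array_equal(self.afferents, other.afferents)
            and np.array_equal(self.times, other.times)
        )


@dataclass
class PatternSet:
    """P frozen Poisson patterns sharing N afferents and duration L."""

    patterns: list[SpikeData]
    seed: object = None

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("PatternSet needs at least one pattern")
        n = {p.n_afferents for p in self.patterns}
        d = {p.duration for p in self.patterns}
        if len(n) != 1 or len(d) != 1:
            raise ValueError("all patterns must share n_afferents and duration")

    @property
    def P(self) -> int:
        return len(self.patterns)

    @property
    def n_afferents(self) -> int:
        return self.patterns[0].n_afferents

    @property
    def duration(self) -> float:
        return self.patterns[0].duration


@dataclass
class StreamAnnotation:
    """Pattern-presentation onsets within a stream.

    ``onsets`` is a list of (onset time ms, pattern id); pattern ids cycle
    0..P-1 because patterns are presented alternately at a fixed period.
    """

    onsets: list[tuple[float, int]] = field(default_factory=list)
    period: float = 400.0

    def __post_init__(self) -> None:
        t = [o[0] for o in self.onsets]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("onsets must be strictly increasing")


def poisson_block(n_afferents: int, rate_hz: float, duration: float, rng) -> SpikeData:
    """One realization of homogeneous Poisson firing over all afferents.

    The total spike count is Poisson(N * f * duration) and spikes are
    scattered uniformly over afferents and time, which is equivalent to N
    independent Poisson processes at rate f.
    """
    lam = n_afferents * rate_hz / 1000.0 * duration
    k = rng.poisson(lam)
    afferents = rng.integers(0, n_afferents, size=k)
    times = rng.uniform(0.0, duration, size=k)
    order = np.argsort(times, kind="stable")
    return SpikeData(afferents[order], times[order], n_afferents, duration)


def generate_pattern_set(params, seed) -> PatternSet:
    """Generate P independent frozen Poisson patterns of duration L.

    Patterns are drawn from the same process as the background noise, so a
    pattern is statistically indistinguishable from any other stretch of
    input; only its repetition makes it detectable.  Fully reproducible
    under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    patterns = [poisson_block(params.N, params.f, params.L, rng) for _ in range(params.P)]
    return PatternSet(patterns=patterns, seed=seed)


def jitter_presentation(pattern: SpikeData, T: float, rng) -> SpikeData:
    """Replay a frozen pattern with per-spike uniform jitter in [-T, T].

    Afferent identities and the spike count are preserved; times may leave
    the nominal [0, L) block and may reorder (no clipping, which would
    distort edge statistics).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if T == 0:
        return SpikeData(
            pattern.afferents.copy(), pattern.times.copy(), pattern.n_afferents, pattern.duration
        )
    shifts = rng.uniform(-T, T, size=pattern.n_events)
    return SpikeData(
        pattern.afferents.copy(), pattern.times + shifts, pattern.n_afferents, pattern.duration
    )


def build_stream(
    pattern_set: PatternSet,
    total_duration: float,
    T: float,
    f: float,
    rng,
    period: float = 400.0,
) -> tuple[SpikeData, StreamAnnotation]:
    """Alternate jittered pattern presentations with fresh Poisson noise.

    One presentation starts every ``period`` ms, cycling through the
    patterns 0..P-1.  During the L-long presentation window the (jittered)
    frozen pattern replaces background activity for all afferents; the
    remaining ``period - L`` ms of each cycle are fresh Poisson spikes at
    rate f.  The overall mean rate is f everywhere.

    Returns the merged stream plus the presentation annotation.
    """
    L = pattern_set.duration
    if period < L:
        raise ValueError(f"period ({period} ms) must be >= pattern duration ({L} ms)")
    n = pattern_set.n_afferents

    aff_chunks: list[np.ndarray] = []
    time_chunks: list[np.ndarray] = []
    onsets: list[tuple[float, int]] = []

    t = 0.0
    pid = 0
    while t < total_duration:
        onset = t
        if onset + L <= total_duration:
            pat = pattern_set.patterns[pid % pattern_set.P]
            jit = jitter_presentation(pat, T, rng)
            aff_chunks.append(jit.afferents)
            time_chunks.append(jit.times + onset)
            onsets.append((onset, pid % pattern_set.P))
            gap = min(period, total_duration - onset) - L
            if gap > 0:
                noise = poisson_block(n, f, gap, rng)
                aff_chunks.append(noise.afferents)
                time_chunks.append(noise.times + onset + L)
            pid += 1
        else:
            gap = total_duration - onset
            noise = poisson_block(n, f, gap, rng)
            aff_chunks.append(noise.afferents)
            time_chunks.append(noise.times + onset)
        t = onset + period

    afferents = np.concatenate(aff_chunks) if aff_chunks else np.empty(0, dtype=np.int64)
    times = np.concatenate(time_chunks) if time_chunks else np.empty(0)
    keep = (times >= 0.0) & (times < total_duration)  # jitter can spill over the ends
    order = np.argsort(times[keep], kind="stable")
    stream = SpikeData(afferents[keep][order], times[keep][order], n, total_duration)
    return stream, StreamAnnotation(onsets=onsets, period=period)
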