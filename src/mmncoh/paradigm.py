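"""Auditory oddball paradigms: stimulus sequences and stereo tone synthesis.

Two passive mismatch-negativity paradigms are generated:

* **Optimum-1** — a fast multi-feature design: 1,845 stimuli in three blocks,
  constant 0.5 s SOA, every second non-formation tone a standard (50%), the
  other half split evenly over five deviant families (duration, gap,
  frequency, intensity, location; 10% each).
* **Memory-Trace** — a slow design probing the auditory memory trace: 462
  stimuli in three 6-min blocks, 1-3 standards between successive deviants,
  inter-standard ISI drawn from {0.5, 1.5, 3} s and the ISI preceding every
  deviant fixed at 3 s.  Only duration and frequency deviants occur
  (66.2% standards, 16.9% per deviant type).

Each block opens with 15 formation standards that establish the standard's
memory trace.  The standard tone is a harmonic complex of 500/1000/1500 Hz
partials (second partial -3 dB, third -6 dB), 75 ms long with 5 ms linear
rise/fall ramps; each deviant alters exactly one stimulus dimension.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

TONE_DURATION_MS = 75.0
RISE_FALL_MS = 5.0
DURATION_DELTA_MS = 50.0
GAP_MS = 7.0
GAP_EDGE_MS = 1.0
FREQ_FACTOR = 0.10
INTENSITY_DELTA_DB = 10.0
ITD_US = 800.0

N_FORMATION = 15
OPTIMUM1_SOA_S = 0.5
MEMORYTRACE_ISI_CHOICES_S = (0.5, 1.5, 3.0)
MEMORYTRACE_DEVIANT_ISI_S = 3.0

#: Peak amplitude of the rendered standard tone.  Leaves 10 dB of headroom so
#: the +10 dB intensity deviant still peaks below full scale.
STANDARD_PEAK = 0.25


class DeviantKind(str, enum.Enum):
    """Stimulus kinds; each deviant alters one dimension of the standard."""

    STANDARD = "standard"
    DURATION = "duration"
    GAP = "gap"
    FREQUENCY_UP = "frequency_up"
    FREQUENCY_DOWN = "frequency_down"
    INTENSITY_UP = "intensity_up"
    INTENSITY_DOWN = "intensity_down"
    LOCATION_LEFT = "location_left"
    LOCATION_RIGHT = "location_right"

    @property
    def family(self) -> str:
        """Deviant family ('frequency_up' -> 'frequency')."""
        return self.value.split("_")[0]


#: The five deviant families of the Optimum-1 paradigm.
OPTIMUM1_FAMILIES = ("duration", "gap", "frequency", "intensity", "location")
#: Families with left/right or up/down variants, split 50/50 within family.
_FAMILY_VARIANTS = {
    "duration": (DeviantKind.DURATION,),
    "gap": (DeviantKind.GAP,),
    "frequency": (DeviantKind.FREQUENCY_UP, DeviantKind.FREQUENCY_DOWN),
    "intensity": (DeviantKind.INTENSITY_UP, DeviantKind.INTENSITY_DOWN),
    "location": (DeviantKind.LOCATION_LEFT, DeviantKind.LOCATION_RIGHT),
}


@dataclass(frozen=True)
class StimulusSpec:
    """Physical parameters of the standard tone and its synthesis."""

    partial_freqs_hz: tuple[float, float, float] = (500.0, 1000.0, 1500.0)
    partial_levels_db: tuple[float, float] = (-3.0, -6.0)
    duration_ms: float = TONE_DURATION_MS
    rise_ms: float = RISE_FALL_MS
    fall_ms: float = RISE_FALL_MS
    sample_rate_hz: float = 50_000.0

    def __post_init__(self) -> None:
        f = self.partial_freqs_hz
        if not (f[0] < f[1] < f[2]):
            raise ValueError("partial frequencies must be strictly increasing")
        if self.duration_ms <= self.rise_ms + self.fall_ms:
            raise ValueError("duration must exceed rise + fall time")
        if self.sample_rate_hz < 2 * max(f):
            raise ValueError("sample rate below Nyquist for the highest partial")


@dataclass(frozen=True)
class StimulusEvent:
    block: int
    onset_s: float
    kind: DeviantKind
    is_formation: bool


@dataclass
class StimulusSequence:
    """Ordered stimulus events of one paradigm run."""

    paradigm_id: str  # 'optimum1' | 'memory_trace'
    events: list[StimulusEvent]
    soa_or_isi: str
    seed: int
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def counts(self, include_formation: bool = False) -> dict[str, int]:
        """Event counts per kind value (formation tones excluded by default)."""
        out: dict[str, int] = {}
        for ev in self.events:
            if ev.is_formation and not include_formation:
                continue
            out[ev.kind.value] = out.get(ev.kind.value, 0) + 1
        return out

    def family_counts(self, include_formation: bool = False) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            if ev.is_formation and not include_formation:
                continue
            key = "standard" if ev.kind is DeviantKind.STANDARD else ev.kind.family
            out[key] = out.get(key, 0) + 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "block": [ev.block for ev in self.events],
                "onset_s": [ev.onset_s for ev in self.events],
                "kind": [ev.kind.value for ev in self.events],
                "is_formation": [ev.is_formation for ev in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _balanced_no_repeat_order(families: dict[str, int], rng: np.random.Generator) -> list[str]:
    """Random order of the family multiset with no two equal neighbours.

    Greedy draw with a feasibility guard: whenever one family holds more than
    half of the remaining slots it must be placed now, otherwise a uniform
    draw over the allowed families is taken.  For balanced counts this always
    terminates.
    """
    remaining = dict(families)
    order: list[str] = []
    prev: str | None = None
    slots = sum(remaining.values())
    while slots:
        allowed = [f for f, c in remaining.items() if c > 0 and f != prev]
        if not allowed:
            raise RuntimeError("no feasible arrangement")  # pragma: no cover
        forced = [f for f in allowed if remaining[f] > (slots - 1 + 1) // 2]
        if forced:
            pick = forced[0]
        else:
            weights = np.array([remaining[f] for f in allowed], dtype=float)
            pick = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
        order.append(pick)
        remaining[pick] -= 1
        prev = pick
        slots -= 1
    return order


def _assign_variants(family_order: list[str], rng: np.random.Generator) -> list[DeviantKind]:
    """Map family slots to concrete kinds, splitting two-variant families 50/50."""
    kinds: list[DeviantKind] = [DeviantKind.STANDARD] * len(family_order)
    for family, variants in _FAMILY_VARIANTS.items():
        idx = [i for i, f in enumerate(family_order) if f == family]
        if len(variants) == 1:
            for i in idx:
                kinds[i] = variants[0]
        else:
            half = len(idx) // 2
            order = rng.permutation(len(idx))
            for rank, j in enumerate(order):
                kinds[idx[j]] = variants[0] if rank < half else variants[1]
    return kinds


def generate_optimum1_sequence(seed: int) -> StimulusSequence:
    """Generate one Optimum-1 run: 3 blocks x (15 formation + 600 stimuli).

    Within each block the 600 non-formation stimuli alternate deviant/standard
    on a constant 0.5 s SOA grid, so 300 are standards and 300 deviants, 60
    per family.  Consecutive deviants always differ in family.
    """
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    for block in range(3):
        t = 0.0
        for _ in range(N_FORMATION):
            events.append(StimulusEvent(block, t, DeviantKind.STANDARD, True))
            t += OPTIMUM1_SOA_S
        family_order = _balanced_no_repeat_order({f: 60 for f in OPTIMUM1_FAMILIES}, rng)
        kinds = _assign_variants(family_order, rng)
        for kind in kinds:  # deviant, then the next standard
            events.append(StimulusEvent(block, t, kind, False))
            t += OPTIMUM1_SOA_S
            events.append(StimulusEvent(block, t, DeviantKind.STANDARD, False))
            t += OPTIMUM1_SOA_S
    return StimulusSequence(
        paradigm_id="optimum1",
        events=events,
        soa_or_isi=f"constant SOA {OPTIMUM1_SOA_S} s",
        seed=seed,
        metadata={
            "n_events": len(events),
            "note": "probabilities reported excluding the 15 formation tones "
                    "per block: 900/1800 standards (50%), 180 per deviant family (10%)",
        },
    )


#: Per-block inter-standard ISI multiset for the Memory-Trace paradigm.  The
#: fixed composition realises the pseudo-random {0.5, 1.5, 3} s assignment
#: while guaranteeing every block fits its 6-min slot for every seed.
_MT_STANDARD_ISI_POOL = (0.5,) * 34 + (1.5,) * 34 + (3.0,) * 33
_MT_N_STANDARD = 87      # non-formation standards per block
_MT_N_DEVIANT = 26       # per deviant type (duration, frequency) per block


def _mt_run_lengths(rng: np.random.Generator) -> list[int]:
    """52 standard-run lengths in [1, 3] summing to 87, uniformly perturbed."""
    n_runs = 2 * _MT_N_DEVIANT
    runs = [1] * n_runs
    extra = _MT_N_STANDARD - n_runs
    capacity = {i: 2 for i in range(n_runs)}
    for _ in range(extra):
        open_runs = [i for i, c in capacity.items() if c > 0]
        i = open_runs[rng.integers(len(open_runs))]
        runs[i] += 1
        capacity[i] -= 1
    return runs


def generate_memorytrace_sequence(seed: int) -> StimulusSequence:
    """Generate one Memory-Trace run: 3 blocks of 154 events (462 total).

    Each block: 15 formation standards, then 52 cycles of a 1-3 standard run
    followed by one deviant (26 duration + 26 frequency deviants in random
    order).  The ISI preceding every deviant is exactly 3 s; all other ISIs
    are drawn from the shuffled {0.5, 1.5, 3} s pool.  Onsets are
    offset-to-onset: next onset = onset + tone duration + ISI.
    """
    rng = np.random.default_rng(seed)
    tone_s = TONE_DURATION_MS / 1000.0
    events: list[StimulusEvent] = []
    for block in range(3):
        runs = _mt_run_lengths(rng)
        deviants = _assign_variants(
            list(rng.permutation(["duration"] * _MT_N_DEVIANT + ["frequency"] * _MT_N_DEVIANT)),
            rng,
        )
        kinds: list[tuple[DeviantKind, bool]] = [(DeviantKind.STANDARD, True)] * N_FORMATION
        for run_len, dev in zip(runs, deviants):
            kinds.extend([(DeviantKind.STANDARD, False)] * run_len)
            kinds.append((dev, False))
        isi_pool = list(_MT_STANDARD_ISI_POOL)
        rng.shuffle(isi_pool)
        t = 0.0
        for i, (kind, formation) in enumerate(kinds):
            events.append(StimulusEvent(block, t, kind, formation))
            if i + 1 < len(kinds):
                next_kind = kinds[i + 1][0]
                if next_kind is DeviantKind.STANDARD:
                    isi = isi_pool.pop()
                else:
                    isi = MEMORYTRACE_DEVIANT_ISI_S
                t += tone_s + isi
    return StimulusSequence(
        paradigm_id="memory_trace",
        events=events,
        soa_or_isi="inter-standard ISI in {0.5, 1.5, 3} s; 3 s before deviants",
        seed=seed,
        metadata={
            "n_events": len(events),
            "note": "306/462 standards (66.2%), 78 per deviant type (16.9%), "
                    "formation tones included in the totals",
        },
    )


@dataclass(frozen=True)
class StereoWaveform:
    """Two-channel audio snippet (amplitude in arbitrary units <= 1)."""

    left: np.ndarray
    right: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("channels must have equal length")

    @property
    def n_samples(self) -> int:
        return self.left.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def to_wav(self, path, dtype: str = "float32") -> None:
        from scipy.io import wavfile

        data = np.stack([self.left, self.right], axis=1)
        if dtype == "int16":
            data = np.round(data * 32767).astype(np.int16)
        else:
            data = data.astype(np.float32)
        wavfile.write(path, int(self.sample_rate_hz), data)


def _mono_tone(spec: StimulusSpec, duration_ms: float, freq_scale: float) -> np.ndarray:
    fs = spec.sample_rate_hz
    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) / fs
    amps = (1.0, 10 ** (spec.partial_levels_db[0] / 20.0), 10 ** (spec.partial_levels_db[1] / 20.0))
    x = np.zeros(n)
    for f, a in zip(spec.partial_freqs_hz, amps):
        x += a * np.sin(2 * np.pi * f * freq_scale * t)
    n_rise = int(round(spec.rise_ms * fs / 1000.0))
    n_fall = int(round(spec.fall_ms * fs / 1000.0))
    env = np.ones(n)
    if n_rise:
        env[:n_rise] = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    if n_fall:
        env[-n_fall:] = np.linspace(1.0, 0.0, n_fall)
    return x * env


def _apply_gap(x: np.ndarray, fs: float) -> np.ndarray:
    """Centered 7 ms silent gap whose 1 ms fall/rise edges are part of the gap."""
    n_gap = int(round(GAP_MS * fs / 1000.0))
    n_edge = int(round(GAP_EDGE_MS * fs / 1000.0))
    start = (x.size - n_gap) // 2
    env = np.ones(x.size)
    env[start:start + n_edge] = np.linspace(1.0, 0.0, n_edge)
    env[start + n_edge:start + n_gap - n_edge] = 0.0
    env[start + n_gap - n_edge:start + n_gap] = np.linspace(0.0, 1.0, n_edge)
    return x * env


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Windowed-sinc fractional delay (kernel half-width 32 samples)."""
    half = 32
    k = np.arange(-half, half + 1)
    kernel = np.sinc(k - (delay_samples - round(delay_samples)))
    kernel *= np.hamming(kernel.size)
    kernel /= kernel.sum()
    shifted = np.convolve(x, kernel, mode="same")
    return _integer_delay(shifted, int(round(delay_samples)))


def _integer_delay(x: np.ndarray, d: int) -> np.ndarray:
    return np.concatenate([np.zeros(d), x])


def synthesize_stimulus(
    spec: StimulusSpec = StimulusSpec(),
    kind: DeviantKind = DeviantKind.STANDARD,
    fractional_delay: bool = False,
) -> StereoWaveform:
    """Render one stimulus as a stereo waveform.

    The standard is the three-partial harmonic tone; deviants alter exactly
    one dimension: duration (-50 ms), gap (centered 7 ms silence), frequency
    (all partials +/-10%), intensity (+/-10 dB), location (800 us interaural
    time difference; the channel on the far side is delayed).

    Raises
    ------
    ValueError
        For location deviants when 800 us is not an integer number of samples
        at ``spec.sample_rate_hz`` (within 1%% of a sample), unless
        ``fractional_delay`` is enabled.
    """
    kind = DeviantKind(kind)
    duration_ms = spec.duration_ms
    freq_scale = 1.0
    gain = 1.0
    if kind is DeviantKind.DURATION:
        duration_ms = spec.duration_ms - DURATION_DELTA_MS
    elif kind is DeviantKind.FREQUENCY_UP:
        freq_scale = 1.0 + FREQ_FACTOR
    elif kind is DeviantKind.FREQUENCY_DOWN:
        freq_scale = 1.0 - FREQ_FACTOR
    elif kind is DeviantKind.INTENSITY_UP:
        gain = 10 ** (INTENSITY_DELTA_DB / 20.0)
    elif kind is DeviantKind.INTENSITY_DOWN:
        gain = 10 ** (-INTENSITY_DELTA_DB / 20.0)

    x = _mono_tone(spec, duration_ms, freq_scale)
    if kind is DeviantKind.GAP:
        x = _apply_gap(x, spec.sample_rate_hz)

    # Normalise so the standard peaks at STANDARD_PEAK; deviants reuse the
    # same master gain so relative levels are preserved.
    ref = _mono_tone(spec, spec.duration_ms, 1.0)
    x = x * (STANDARD_PEAK / np.max(np.abs(ref))) * gain

    left = right = x
    if kind in (DeviantKind.LOCATION_LEFT, DeviantKind.LOCATION_RIGHT):
        delay = ITD_US * 1e-6 * spec.sample_rate_hz
        if abs(delay - round(delay)) > 0.01 and not fractional_delay:
            raise ValueError(
                f"800 us is {delay:.3f} samples at {spec.sample_rate_hz} Hz; "
                "not an integer delay - enable fractional_delay or resample"
            )
        shift = _fractional_delay(x, delay) if fractional_delay else _integer_delay(x, int(round(delay)))
        lead = np.concatenate([x, np.zeros(shift.size - x.size)])
        if kind is DeviantKind.LOCATION_LEFT:  # sound from the left: right ear lags
            left, right = lead, shift
        else:
            left, right = shift, lead
    return StereoWaveform(left=np.asarray(left, float), right=np.asarray(right, float),
                          sample_rate_hz=spec.sample_rate_hz)


# ---------------------------------------------------------------------------
# Signal measurements (used by tests and the acceptance script)

def measured_duration_ms(wave: StereoWaveform, rel_threshold: float = 1e-4) -> float:
    """Envelope extent: time between first and last sample above threshold."""
    x = np.maximum(np.abs(wave.left), np.abs(wave.right))
    above = np.flatnonzero(x > rel_threshold * x.max())
    return (above[-1] - above[0] + 1) / wave.sample_rate_hz * 1000.0


def spectral_peaks_hz(wave: StereoWaveform, n_peaks: int = 3) -> np.ndarray:
    """Frequencies of the strongest spectral lines, ascending (zero-padded FFT)."""
    x = wave.left
    n = int(2 ** math.ceil(math.log2(x.size * 16)))
    spec = np.abs(np.fft.rfft(x, n))
    freqs = np.fft.rfftfreq(n, 1.0 / wave.sample_rate_hz)
    from scipy.signal import find_peaks

    idx, props = find_peaks(spec, height=spec.max() * 0.05)
    top = idx[np.argsort(props["peak_heights"])[-n_peaks:]]
    return np.sort(freqs[top])


def partial_level_db(wave: StereoWaveform, freq_hz: float, ref_hz: float) -> float:
    """Level of the spectral line at freq_hz relative to the line at ref_hz."""
    x = wave.left
    n = int(2 ** math.ceil(math.log2(x.size * 16)))
    spec = np.abs(np.fft.rfft(x, n))
    freqs = np.fft.rfftfreq(n, 1.0 / wave.sample_rate_hz)

    def line(f):
        band = (freqs > f - 50) & (freqs < f + 50)
        return spec[band].max()

    return 20 * np.log10(line(freq_hz) / line(ref_hz))


def rms_db_difference(a: StereoWaveform, b: StereoWaveform) -> float:
    """RMS level of `a` relative to `b` in dB (computed over the shorter extent)."""
    n = min(a.n_samples, b.n_samples)
    rms = lambda x: np.sqrt(np.mean(x[:n] ** 2))
    return 20 * np.log10(rms(a.left) / rms(b.left))


def interaural_lag_us(wave: StereoWaveform) -> float:
    """Cross-channel lag |left - right| via full cross-correlation, in us."""
    corr = np.correlate(wave.left, wave.right, mode="full")
    lag = np.argmax(corr) - (wave.n_samples - 1)
    return abs(lag) / wave.sample_rate_hz * 1e6
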