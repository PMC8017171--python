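"""Preprocessing chains for the coherence and MMN branches.

The coherence branch band-passes 1-30 Hz, drops noisy channels, re-references
to the average of the good channels, cuts a grid of 2-s resting epochs, and
randomly subsamples 20 clean epochs per subject and assessment.  The MMN
branch band-passes 1-35 Hz, interpolates noisy channels (average method),
re-references to the linked mastoids, cuts stimulus-locked epochs with
pre-stimulus baseline correction, and subsamples 50 clean trials.  Manual
artifact screening is replaced by deterministic amplitude thresholds
(|amplitude| > 100 uV or peak-to-peak > 150 uV on any good channel).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import signal

from .containers import EEGRecording, Epochs
from .montage import Montage

FLATLINE_VAR_UV2 = 0.01
ROBUST_Z_THRESHOLD = 5.0
DEFAULT_ABS_THRESHOLD_UV = 100.0
DEFAULT_PP_THRESHOLD_UV = 150.0
RESTING_EPOCH_S = 2.0
MMN_WINDOW_MS = (-100.0, 500.0)
MMN_BASELINE_MS = (-100.0, 0.0)


def bandpass(rec: EEGRecording, lo_hz: float, hi_hz: float) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass (24 dB/octave), length preserved."""
    nyq = rec.fs_hz / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(f"band ({lo_hz}, {hi_hz}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(4, [lo_hz, hi_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    info = dict(rec.info)
    info["bandpass_hz"] = (lo_hz, hi_hz)
    return rec.copy_with(data=filtered, info=info)


def detect_bad_channels(rec: EEGRecording) -> set[str]:
    """Flag flatline channels and robust variance outliers.

    A channel is bad when its variance is below ``FLATLINE_VAR_UV2`` or its
    variance has a robust z-score (median/MAD) above ``ROBUST_Z_THRESHOLD``.
    Deterministic, no randomness involved.
    """
    if rec.montage.n_channels < 2:
        raise ValueError("need at least 2 channels")
    variances = rec.data.var(axis=1)
    flat = variances < FLATLINE_VAR_UV2
    med = np.median(variances)
    mad = np.median(np.abs(variances - med))
    if mad == 0:
        z = np.zeros_like(variances)
    else:
        z = (variances - med) / (1.4826 * mad)
    noisy = z > ROBUST_Z_THRESHOLD
    return {lab for lab, bad in zip(rec.montage.labels, flat | noisy) if bad}


def match_channels(bad_a: set[str], bad_b: set[str], montage: Montage) -> tuple[str, ...]:
    """Good channels common to two assessments: montage minus (bad_a | bad_b).

    Mirrors the matched-channel convention for longitudinal coherence
    comparisons: both recordings of a pre/post (or pre/follow-up) pair are
    analysed on the identical channel set.
    """
    bad = set(bad_a) | set(bad_b)
    unknown = bad - set(montage.labels)
    if unknown:
        raise ValueError(f"bad labels not in montage: {sorted(unknown)}")
    good = tuple(lab for lab in montage.labels if lab not in bad)
    if len(good) < 2:
        raise ValueError("fewer than 2 good channels remain")
    return good


def rereference(obj, scheme: str = "average_of_good"):
    """Re-reference a recording or epochs.

    ``average_of_good`` subtracts the instantaneous mean over good channels;
    ``linked_mastoids`` subtracts (M1 + M2) / 2 from every channel.
    """
    if scheme not in ("average_of_good", "linked_mastoids"):
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = obj.montage.labels
    if scheme == "linked_mastoids":
        for m in ("M1", "M2"):
            if m not in labels:
                raise ValueError(f"linked-mastoid reference requires channel {m}")
        i1, i2 = labels.index("M1"), labels.index("M2")
        ref = (obj.data[..., i1, :] + obj.data[..., i2, :]) / 2.0
    else:
        good_idx = [i for i, lab in enumerate(labels) if lab not in obj.bads]
        ref = obj.data[..., good_idx, :].mean(axis=-2)
    data = obj.data - ref[..., None, :]
    info = dict(obj.info)
    info["reference"] = scheme
    return replace(obj, data=data, info=info)


def interpolate_bad(rec: EEGRecording, bad: set[str] | None = None) -> EEGRecording:
    """Replace bad channels by the mean of their good spatial neighbours.

    Channels without good neighbours (or without a neighbour map) fall back
    to the global mean over good channels.  The average method, i.e. no
    spline weighting.
    """
    bad = set(rec.bads if bad is None else bad)
    if not bad:
        return rec
    labels = rec.montage.labels
    good = [lab for lab in labels if lab not in bad]
    if not good:
        raise ValueError("all channels bad; nothing to interpolate from")
    data = rec.data.copy()
    global_mean = data[[labels.index(g) for g in good]].mean(axis=0)
    for lab in bad:
        neighbors = [n for n in rec.montage.neighbors.get(lab, ()) if n in good]
        if neighbors:
            data[labels.index(lab)] = data[[labels.index(n) for n in neighbors]].mean(axis=0)
        else:
            data[labels.index(lab)] = global_mean
    info = dict(rec.info)
    info["interpolated"] = sorted(bad)
    return rec.copy_with(data=data, bads=set(), info=info)


def _reject_mask(data: np.ndarray, good_idx, pp_threshold_uv, abs_threshold_uv) -> np.ndarray:
    sub = data[:, good_idx, :]
    peak = np.abs(sub).max(axis=(1, 2))
    pp = sub.max(axis=2) - sub.min(axis=2)
    return (peak <= abs_threshold_uv) & (pp.max(axis=1) <= pp_threshold_uv)


def epoch_resting(
    rec: EEGRecording,
    epoch_s: float = RESTING_EPOCH_S,
    pp_threshold_uv: float = DEFAULT_PP_THRESHOLD_UV,
    abs_threshold_uv: float = DEFAULT_ABS_THRESHOLD_UV,
) -> Epochs:
    """Cut a contiguous grid of fixed-length resting epochs and reject artifacts."""
    if pp_threshold_uv <= 0 or abs_threshold_uv <= 0:
        raise ValueError("thresholds must be positive")
    n_per = int(round(epoch_s * rec.fs_hz))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    data = rec.data[:, : n_epochs * n_per].reshape(rec.montage.n_channels, n_epochs, n_per)
    data = np.transpose(data, (1, 0, 2))
    good_idx = [i for i, lab in enumerate(rec.montage.labels) if lab not in rec.bads]
    keep = _reject_mask(data, good_idx, pp_threshold_uv, abs_threshold_uv)
    if not keep.any():
        raise ValueError("zero epochs survive artifact rejection")
    log = {"n_total": int(n_epochs), "n_rejected": int((~keep).sum()),
           "dropped": np.flatnonzero(~keep).tolist(),
           "pp_threshold_uv": pp_threshold_uv, "abs_threshold_uv": abs_threshold_uv}
    return Epochs(
        data=data[keep],
        montage=rec.montage,
        fs_hz=rec.fs_hz,
        tmin_s=0.0,
        labels=np.array(["resting"] * int(keep.sum()), dtype=object),
        paradigm_id="resting",
        bads=set(rec.bads),
        rejection_log=log,
        info=dict(rec.info),
    )


def epoch_stimulus_locked(
    rec: EEGRecording,
    events,
    window_ms: tuple[float, float] = MMN_WINDOW_MS,
    baseline_ms: tuple[float, float] | None = MMN_BASELINE_MS,
    pp_threshold_uv: float = DEFAULT_PP_THRESHOLD_UV,
    abs_threshold_uv: float = DEFAULT_ABS_THRESHOLD_UV,
    paradigm_id: str = "optimum1",
) -> Epochs:
    """Cut stimulus-locked epochs with baseline correction and artifact rejection.

    ``events`` is an iterable of (onset_sample, label); epochs reaching past
    either end of the recording are skipped and logged.
    """
    if pp_threshold_uv <= 0 or abs_threshold_uv <= 0:
        raise ValueError("thresholds must be positive")
    lo, hi = window_ms
    i_lo = int(round(lo * rec.fs_hz / 1000.0))
    i_hi = int(round(hi * rec.fs_hz / 1000.0))
    n_times = i_hi - i_lo + 1
    trials, labels, skipped = [], [], []
    for onset, label in events:
        start, stop = onset + i_lo, onset + i_lo + n_times
        if start < 0 or stop > rec.n_samples:
            skipped.append(int(onset))
            continue
        trials.append(rec.data[:, start:stop])
        labels.append(label)
    if not trials:
        raise ValueError("no events fall inside the recording")
    data = np.stack(trials)
    if baseline_ms is not None:
        b_lo = int(round(baseline_ms[0] * rec.fs_hz / 1000.0)) - i_lo
        b_hi = int(round(baseline_ms[1] * rec.fs_hz / 1000.0)) - i_lo
        data = data - data[:, :, b_lo : b_hi + 1].mean(axis=2, keepdims=True)
    good_idx = [i for i, lab in enumerate(rec.montage.labels) if lab not in rec.bads]
    keep = _reject_mask(data, good_idx, pp_threshold_uv, abs_threshold_uv)
    if not keep.any():
        raise ValueError("zero epochs survive artifact rejection")
    log = {"n_total": int(data.shape[0]), "n_rejected": int((~keep).sum()),
           "dropped": np.flatnonzero(~keep).tolist(), "skipped_onsets": skipped,
           "pp_threshold_uv": pp_threshold_uv, "abs_threshold_uv": abs_threshold_uv,
           "baseline_ms": baseline_ms}
    return Epochs(
        data=data[keep],
        montage=rec.montage,
        fs_hz=rec.fs_hz,
        tmin_s=lo / 1000.0,
        labels=np.array(labels, dtype=object)[keep],
        paradigm_id=paradigm_id,
        bads=set(rec.bads),
        rejection_log=log,
        info=dict(rec.info),
    )


def reject_epochs(
    ep: Epochs,
    pp_threshold_uv: float = DEFAULT_PP_THRESHOLD_UV,
    abs_threshold_uv: float = DEFAULT_ABS_THRESHOLD_UV,
) -> Epochs:
    """Apply the amplitude-threshold artifact proxy to already-epoched data."""
    if pp_threshold_uv <= 0 or abs_threshold_uv <= 0:
        raise ValueError("thresholds must be positive")
    good_idx = [i for i, lab in enumerate(ep.montage.labels) if lab not in ep.bads]
    keep = _reject_mask(ep.data, good_idx, pp_threshold_uv, abs_threshold_uv)
    if not keep.any():
        raise ValueError("zero epochs survive artifact rejection")
    log = dict(ep.rejection_log)
    log.update({"n_total": int(ep.n_trials), "n_rejected": int((~keep).sum()),
                "dropped": np.flatnonzero(~keep).tolist(),
                "pp_threshold_uv": pp_threshold_uv, "abs_threshold_uv": abs_threshold_uv})
    out = ep.take(np.flatnonzero(keep))
    out.rejection_log = log
    return out


class InsufficientTrialsError(ValueError):
    """Raised when fewer clean trials are available than requested.

    Mirrors the drop-out path of the study flow chart: a subject/assessment
    without enough artifact-free trials leaves the analysis.
    """

    def __init__(self, requested: int, available: int):
        self.requested = requested
        self.available = available
        super().__init__(f"requested {requested} trials but only {available} available")


def subsample_trials(ep: Epochs, n: int, seed: int = 0, condition: str | None = None) -> Epochs:
    """Uniformly sample ``n`` trials without replacement, preserving trial order."""
    pool = ep if condition is None else ep.select(condition)
    if n > pool.n_trials:
        raise InsufficientTrialsError(n, pool.n_trials)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pool.n_trials, size=n, replace=False))
    out = pool.take(idx)
    out.info = dict(out.info)
    out.info["subsample"] = {"n": n, "seed": seed, "condition": condition}
    return out


def derive_seed(global_seed: int, subject: str, session: str, stage: str) -> int:
    """Deterministic per-subject/session/stage seed below 2**31."""
    import hashlib

    key = f"{global_seed}:{subject}:{session}:{stage}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)
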