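"""ERP averaging, MMN amplitude at the fronto-central cluster, and the
auditory-memory-decay difference score.

The mismatch negativity (MMN) is measured as the mean of the
deviant-minus-standard difference wave, averaged over the Fz/FCz/Cz cluster,
in a 100-250 ms post-onset window (mean amplitude, not peak).  The decay
score subtracts the MMN obtained after long ISIs (Memory-Trace paradigm)
from the MMN after short ISIs (Optimum-1):

    delta_mmn = mmn_short - mmn_long

Higher (less negative) values indicate less automatic auditory memory decay.
Both inputs must come from the duration deviant of their paradigms; if either
is missing the subject is excluded rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Epochs

MMN_CLUSTER = ("Fz", "FCz", "Cz")
MMN_WINDOW_MS = (100.0, 250.0)


@dataclass
class ERP:
    """Trial-averaged evoked response (channels x time, uV)."""

    data: np.ndarray
    channels: tuple[str, ...]
    fs_hz: float
    tmin_s: float
    condition: str
    paradigm_id: str
    n_trials: int

    @property
    def times_ms(self) -> np.ndarray:
        return (self.tmin_s + np.arange(self.data.shape[1]) / self.fs_hz) * 1000.0

    def cluster_mean(self, cluster=MMN_CLUSTER) -> np.ndarray:
        missing = [c for c in cluster if c not in self.channels]
        if missing:
            raise ValueError(f"cluster channels missing: {missing}")
        idx = [self.channels.index(c) for c in cluster]
        return self.data[idx].mean(axis=0)


@dataclass
class MMNResult:
    """Per-subject/session MMN amplitudes and the decay difference score."""

    mmn_short_uv: float | None
    mmn_long_uv: float | None
    delta_mmn_uv: float | None
    window_ms: tuple[float, float] = MMN_WINDOW_MS
    cluster: tuple[str, ...] = MMN_CLUSTER

    def to_dict(self) -> dict:
        return {
            "mmn_short_uv": self.mmn_short_uv,
            "mmn_long_uv": self.mmn_long_uv,
            "delta_mmn_uv": self.delta_mmn_uv,
            "window_ms": list(self.window_ms),
            "cluster": list(self.cluster),
        }


def average_erp(ep: Epochs, condition: str) -> ERP:
    """Pointwise mean across all trials of one condition.

    Formation tones carry their own label upstream and are therefore never
    part of the 'standard' average.
    """
    sel = ep.select(condition)
    if sel.n_trials < 1:
        raise ValueError(f"no trials with condition {condition!r}")
    return ERP(
        data=sel.data.mean(axis=0),
        channels=tuple(ep.montage.labels),
        fs_hz=ep.fs_hz,
        tmin_s=ep.tmin_s,
        condition=condition,
        paradigm_id=ep.paradigm_id,
        n_trials=sel.n_trials,
    )


def mmn_amplitude(
    dev: ERP,
    std: ERP,
    window_ms: tuple[float, float] = MMN_WINDOW_MS,
    cluster: tuple[str, ...] = MMN_CLUSTER,
) -> float:
    """Mean deviant-minus-standard amplitude over the cluster and window (uV).

    Negative values indicate a present MMN.  Both ERPs must share paradigm,
    sampling and epoch window.
    """
    if dev.paradigm_id != std.paradigm_id:
        raise ValueError("ERPs come from different paradigms")
    if dev.data.shape != std.data.shape or dev.fs_hz != std.fs_hz or dev.tmin_s != std.tmin_s:
        raise ValueError("ERPs have mismatched epochs")
    diff = dev.cluster_mean(cluster) - std.cluster_mean(cluster)
    times = dev.times_ms
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} ms outside the epoch")
    return float(diff[mask].mean())


def delta_mmn(mmn_short_uv: float | None, mmn_long_uv: float | None) -> float:
    """Difference score: MMN after short ISI minus MMN after long ISI (uV)."""
    if mmn_short_uv is None or mmn_long_uv is None:
        raise ValueError(
            "delta_mmn requires the duration-deviant MMN from both paradigms; "
            "subjects missing either are excluded, never imputed"
        )
    return float(mmn_short_uv) - float(mmn_long_uv)


def mmn_result(
    epochs_short: Epochs,
    epochs_long: Epochs,
    deviant: str = "duration",
    window_ms: tuple[float, float] = MMN_WINDOW_MS,
    cluster: tuple[str, ...] = MMN_CLUSTER,
) -> MMNResult:
    """Full per-subject MMN measurement from both paradigms' epochs."""
    amps = []
    for ep in (epochs_short, epochs_long):
        dev = average_erp(ep, deviant)
        std = average_erp(ep, "standard")
        amps.append(mmn_amplitude(dev, std, window_ms=window_ms, cluster=cluster))
    return MMNResult(
        mmn_short_uv=amps[0],
        mmn_long_uv=amps[1],
        delta_mmn_uv=delta_mmn(amps[0], amps[1]),
        window_ms=window_ms,
        cluster=cluster,
    )
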