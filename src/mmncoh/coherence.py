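"""Pairwise spectral coherence and the global / region-pair coherence indices.

The magnitude-squared coherence between channels x and y is

    C_xy(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f))

with auto-/cross-spectra averaged across trial epochs (one Hann taper per
epoch, no sub-windowing).  The global index is the unweighted mean of C over
all unordered channel pairs and all frequency bins in the 1-30 Hz band;
region-pair indices average over frontal-temporal or frontal-parietal pairs
only.  Note the estimator is biased upward for finite trial counts
(E[C] ~ true + (1 - true)^2 / n_trials), which matters when comparing
conditions with different trial numbers — hence the fixed 20-trial protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Epochs
from .montage import Montage

DEFAULT_BAND_HZ = (1.0, 30.0)


@dataclass
class CoherenceResult:
    """Coherence per channel pair and frequency bin.

    ``values`` has shape (n_channels, n_channels, n_bins), is symmetric in
    the channel axes, with the diagonal identically 1.
    """

    channels: tuple[str, ...]
    freqs_hz: np.ndarray
    values: np.ndarray
    band_hz: tuple[float, float]
    n_trials: int
    squared: bool = True

    def pair(self, a: str, b: str) -> np.ndarray:
        return self.values[self.channels.index(a), self.channels.index(b)]

    def pair_frame(self) -> pd.DataFrame:
        """Long-format (channel_a, channel_b, freq_hz, coherence) over unordered pairs."""
        i, j = np.triu_indices(len(self.channels), k=1)
        rows = []
        for a, b in zip(i, j):
            for k, f in enumerate(self.freqs_hz):
                rows.append((self.channels[a], self.channels[b], f, self.values[a, b, k]))
        return pd.DataFrame(rows, columns=["channel_a", "channel_b", "freq_hz", "coherence"])


def coherence_matrix(
    ep: Epochs,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    channels: tuple[str, ...] | None = None,
    squared: bool = True,
) -> CoherenceResult:
    """Estimate pairwise coherence from trial epochs.

    One Hann taper per trial epoch; spectra averaged across trials.  With 2-s
    epochs the bin spacing is 0.5 Hz; band endpoints are inclusive.
    ``squared=False`` returns magnitude (unsquared) coherence.
    """
    if ep.n_trials < 2:
        raise ValueError("coherence needs >= 2 trials (degenerate at 1)")
    if channels is None:
        channels = ep.good_labels
    if len(channels) < 2:
        raise ValueError("need >= 2 channels")
    idx = [ep.montage.index(c) for c in channels]
    data = ep.data[:, idx, :]
    n_times = data.shape[-1]
    taper = np.hanning(n_times)
    spec = np.fft.rfft(data * taper, axis=-1)
    freqs = np.fft.rfftfreq(n_times, 1.0 / ep.fs_hz)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError(f"no frequency bins inside {band_hz} Hz")
    spec = spec[:, :, in_band]
    # Cross-spectral cube averaged over trials: S[c, d, f]
    s = np.einsum("tcf,tdf->cdf", spec, spec.conj()) / ep.n_trials
    auto = np.real(np.einsum("ccf->cf", s))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(s) ** 2 / denom
    c = np.clip(np.nan_to_num(c, nan=0.0), 0.0, 1.0)
    n = len(channels)
    c[np.arange(n), np.arange(n), :] = 1.0
    if not squared:
        c = np.sqrt(c)
    return CoherenceResult(
        channels=tuple(channels),
        freqs_hz=freqs[in_band],
        values=c,
        band_hz=band_hz,
        n_trials=ep.n_trials,
        squared=squared,
    )


def global_coherence(res: CoherenceResult, band_hz: tuple[float, float] | None = None) -> float:
    """Mean coherence over all unordered pairs (no self-pairs) and band bins."""
    mask = _band_mask(res, band_hz)
    i, j = np.triu_indices(len(res.channels), k=1)
    if i.size == 0:
        raise ValueError("need at least one channel pair")
    return float(res.values[i, j][:, mask].mean())


def region_coherence(
    res: CoherenceResult,
    montage: Montage,
    pair_class: str,
    band_hz: tuple[float, float] | None = None,
) -> float:
    """Mean coherence over fronto-temporal or fronto-parietal channel pairs."""
    targets = {"fronto_temporal": "temporal", "fronto_parietal": "parietal"}
    if pair_class not in targets:
        raise ValueError(f"pair_class must be one of {sorted(targets)}")
    mask = _band_mask(res, band_hz)
    frontal = {c for c in res.channels if montage.regions.get(c) == "frontal"}
    other = {c for c in res.channels if montage.regions.get(c) == targets[pair_class]}
    pairs = [
        (res.channels.index(a), res.channels.index(b)) for a in frontal for b in other
    ]
    if not pairs:
        raise ValueError(f"no {pair_class} pairs among the good channels")
    vals = np.array([res.values[a, b][mask] for a, b in pairs])
    return float(vals.mean())


def _band_mask(res: CoherenceResult, band_hz) -> np.ndarray:
    if band_hz is None:
        return np.ones(res.freqs_hz.size, dtype=bool)
    mask = (res.freqs_hz >= band_hz[0]) & (res.freqs_hz <= band_hz[1])
    if not mask.any():
        raise ValueError(f"no bins inside {band_hz} Hz")
    return mask


def summary(res: CoherenceResult, montage: Montage) -> dict:
    """JSON-ready summary: global and region-pair indices plus metadata."""
    out = {
        "global_coherence": global_coherence(res),
        "band_hz": list(res.band_hz),
        "n_trials": res.n_trials,
        "n_channels": len(res.channels),
        "squared": res.squared,
    }
    for pair_class in ("fronto_temporal", "fronto_parietal"):
        try:
            out[pair_class] = region_coherence(res, montage, pair_class)
        except ValueError:
            out[pair_class] = None
    return out
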