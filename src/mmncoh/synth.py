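"""Ground-truthed synthetic EEG and cohort data.

Three generators feed the downstream analyses with inputs whose correct
answer is known in closed form:

* :func:`simulate_resting` — resting EEG built from a shared band-limited
  Gaussian source: channel ``c = a_c * s(t) + sqrt(1 - a_c^2) * n_c(t)``.
  With unit-variance processes the magnitude-squared coherence between
  channels i and j is exactly ``a_i^2 * a_j^2`` across the band, so the
  global coherence index has the analytic value :func:`expected_global_msc`.
* :func:`simulate_mmn_epochs` — oddball epochs where deviant trials carry an
  added Gaussian-shaped negativity of known amplitude/latency/width on the
  fronto-central target channels (never on the mastoids).
* :func:`simulate_cohort` — a three-group intervention cohort (cognitive
  training / physical training / wait-list control) with a continuous
  lifestyle score in [0, 1] and pre/post(/follow-up) outcomes whose change
  contains known Group x Time and Lifestyle x Time effects.

Default cohort sizes (16/18/20) and the lifestyle/outcome scales mirror a
typical small at-risk-for-dementia training trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EEGRecording, Epochs
from .montage import Montage, default_montage

GROUPS = ("CT", "PT", "WLC")
SESSIONS = ("pre", "post", "followup")

#: Default MMN target channels (fronto-central cluster plus near neighbours).
MMN_TARGETS = ("Fz", "FCz", "Cz", "F3", "F4", "FC1", "FC2")


@dataclass(frozen=True)
class CoherenceGroundTruth:
    """Shared-source mixing weights; expected pair MSC is a_i^2 * a_j^2."""

    a: tuple[float, ...] | float = 0.8
    band_hz: tuple[float, float] = (1.0, 30.0)
    noise: str = "gaussian"  # 'gaussian' (flat in band, closed form) | 'pink'

    def weights(self, n_channels: int) -> np.ndarray:
        a = np.broadcast_to(np.asarray(self.a, dtype=float), (n_channels,)).copy()
        if np.any((a < 0) | (a > 1)):
            raise ValueError("mixing weights must lie in [0, 1]")
        return a


def expected_global_msc(truth: CoherenceGroundTruth, n_channels: int) -> float:
    """Analytic global magnitude-squared coherence: mean of a_i^2 a_j^2 over pairs."""
    a = truth.weights(n_channels)
    i, j = np.triu_indices(n_channels, k=1)
    return float(np.mean(a[i] ** 2 * a[j] ** 2))


def _bandlimited_noise(shape, lo_hz, hi_hz, fs_hz, rng, pink=False) -> np.ndarray:
    """Unit-variance Gaussian noise with support restricted to [lo, hi] Hz.

    Built in the frequency domain (hard band edges) so the per-frequency
    mixing model holds exactly and the coherence closed form is unbiased.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
    mask = (freqs >= lo_hz) & (freqs <= hi_hz)
    spec = rng.standard_normal(shape[:-1] + (freqs.size,)) + 1j * rng.standard_normal(
        shape[:-1] + (freqs.size,)
    )
    spec[..., ~mask] = 0.0
    if pink:
        with np.errstate(divide="ignore"):
            spec[..., mask] *= 1.0 / np.sqrt(freqs[mask])
    x = np.fft.irfft(spec, n=n)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_resting(
    montage: Montage | None = None,
    truth: CoherenceGroundTruth = CoherenceGroundTruth(),
    duration_s: float = 120.0,
    fs_hz: float = 200.0,
    amplitude_uv: float = 10.0,
    seed: int = 0,
) -> EEGRecording:
    """Simulate resting EEG with analytically known inter-channel coherence.

    Each channel mixes one shared source with an independent noise process,
    both unit-variance Gaussian and band-limited to ``truth.band_hz``.
    """
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60")
    if fs_hz < 100:
        raise ValueError("fs_hz must be >= 100")
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    a = truth.weights(montage.n_channels)
    n = int(round(duration_s * fs_hz))
    pink = truth.noise == "pink"
    s = _bandlimited_noise((n,), *truth.band_hz, fs_hz, rng, pink)
    noise = _bandlimited_noise((montage.n_channels, n), *truth.band_hz, fs_hz, rng, pink)
    data = amplitude_uv * (a[:, None] * s[None, :] + np.sqrt(1 - a**2)[:, None] * noise)
    return EEGRecording(
        data=data,
        montage=montage,
        fs_hz=fs_hz,
        info={
            "ground_truth": {"a": a.tolist(), "band_hz": list(truth.band_hz),
                             "noise": truth.noise,
                             "expected_global_msc": expected_global_msc(truth, montage.n_channels)},
            "seed": seed,
        },
    )


@dataclass(frozen=True)
class MMNGroundTruth:
    """Injected deviant-minus-standard component: A * exp(-(t-mu)^2 / 2 sigma^2)."""

    amplitude_uv: float = -2.0          # negative = mismatch negativity
    latency_ms: float = 150.0
    width_ms: float = 30.0
    target_channels: tuple[str, ...] = MMN_TARGETS
    noise_sd_uv: float = 10.0

    def window_mean(self, window_ms: tuple[float, float]) -> float:
        """Analytic mean of the injected component over a measurement window.

        Closed form via the Gaussian integral:
        A * sqrt(pi/2) * sigma * (erf(z_b) - erf(z_a)) / (b - a).
        """
        from scipy.special import erf

        a, b = window_ms
        z = lambda t: (t - self.latency_ms) / (np.sqrt(2) * self.width_ms)
        integral = np.sqrt(np.pi / 2) * self.width_ms * (erf(z(b)) - erf(z(a)))
        return float(self.amplitude_uv * integral / (b - a))


def simulate_mmn_epochs(
    montage: Montage | None = None,
    truth: MMNGroundTruth = MMNGroundTruth(),
    n_standard: int = 150,
    n_deviant: int = 75,
    epoch_window_ms: tuple[float, float] = (-100.0, 500.0),
    fs_hz: float = 1000.0,
    deviant_label: str = "duration",
    paradigm_id: str = "optimum1",
    seed: int = 0,
) -> Epochs:
    """Simulate stimulus-locked epochs with an injected MMN in deviant trials.

    Standard epochs are pure noise; deviant epochs add the Gaussian component
    on the target channels.  Mastoid channels never receive the component, so
    a linked-mastoid reference leaves the injected amplitude intact.
    """
    if n_standard < 1 or n_deviant < 1:
        raise ValueError("need at least one trial per condition")
    lo, hi = epoch_window_ms
    if not (lo <= truth.latency_ms - 2 * truth.width_ms
            and truth.latency_ms + 2 * truth.width_ms <= hi):
        raise ValueError("epoch window must contain latency +/- 2 widths")
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    n_times = int(round((hi - lo) * fs_hz / 1000.0)) + 1
    times_ms = lo + np.arange(n_times) / fs_hz * 1000.0
    n_trials = n_standard + n_deviant
    data = truth.noise_sd_uv * rng.standard_normal((n_trials, montage.n_channels, n_times))
    bump = truth.amplitude_uv * np.exp(
        -((times_ms - truth.latency_ms) ** 2) / (2 * truth.width_ms**2)
    )
    targets = [montage.index(c) for c in truth.target_channels if c in montage.labels]
    data[n_standard:, targets, :] += bump[None, None, :]
    labels = np.array(["standard"] * n_standard + [deviant_label] * n_deviant, dtype=object)
    order = rng.permutation(n_trials)
    return Epochs(
        data=data[order],
        montage=montage,
        fs_hz=fs_hz,
        tmin_s=lo / 1000.0,
        labels=labels[order],
        paradigm_id=paradigm_id,
        info={
            "ground_truth": {
                "amplitude_uv": truth.amplitude_uv,
                "latency_ms": truth.latency_ms,
                "width_ms": truth.width_ms,
                "noise_sd_uv": truth.noise_sd_uv,
                "target_channels": list(truth.target_channels),
            },
            "seed": seed,
        },
    )


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of the synthetic intervention cohort.

    The outcome model for subject i in group g at session t is::

        y_it = mu + b_i + delta_t + beta_group[g] * 1[t] + beta_lifestyle * L_i * 1[t] + eps_it

    where ``1[t]`` indicates post (and follow-up, with its own coefficients),
    ``b_i ~ N(0, subject_sd^2)`` and ``eps_it ~ N(0, residual_sd^2)``.
    Lifestyle ``L_i ~ Beta(5.7, 13.9)`` (mean 0.29, SD 0.10 — the scale of a
    CHAMPS variety-of-activities index in senior cohorts).
    """

    n_ct: int = 16
    n_pt: int = 18
    n_wlc: int = 20
    baseline_mean: float = 0.30
    subject_sd: float = 0.10
    residual_sd: float = 0.09
    retest: float = 0.0
    beta_group: dict = field(default_factory=lambda: {"CT": 0.0, "PT": 0.0, "WLC": 0.0})
    beta_lifestyle: float = 0.0
    retest_followup: float = 0.0
    beta_group_followup: dict | None = None
    beta_lifestyle_followup: float | None = None
    lifestyle_beta_params: tuple[float, float] = (5.7, 13.9)
    sessions: tuple[str, ...] = ("pre", "post")
    outcome: str = "global_coherence"

    def __post_init__(self) -> None:
        if min(self.n_ct, self.n_pt, self.n_wlc) < 2:
            raise ValueError("group sizes must be >= 2")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not set(self.sessions) <= set(SESSIONS):
            raise ValueError(f"sessions must be among {SESSIONS}")


def simulate_cohort(params: CohortParams = CohortParams(), seed: int = 0) -> pd.DataFrame:
    """Simulate a long-format cohort table (subject, group, lifestyle, session, outcome)."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(GROUPS, [params.n_ct, params.n_pt, params.n_wlc])
    n = groups.size
    subjects = np.array([f"S{i:03d}" for i in range(n)])
    lifestyle = rng.beta(*params.lifestyle_beta_params, size=n)
    b = params.subject_sd * rng.standard_normal(n)
    bg_fu = params.beta_group_followup if params.beta_group_followup is not None else params.beta_group
    bl_fu = (params.beta_lifestyle_followup
             if params.beta_lifestyle_followup is not None else params.beta_lifestyle)
    rows = []
    for i in range(n):
        for sess in params.sessions:
            if sess == "pre":
                delta = 0.0
            elif sess == "post":
                delta = (params.retest + params.beta_group[groups[i]]
                         + params.beta_lifestyle * lifestyle[i])
            else:
                delta = params.retest_followup + bg_fu[groups[i]] + bl_fu * lifestyle[i]
            eps = params.residual_sd * rng.standard_normal()
            rows.append(
                (subjects[i], groups[i], lifestyle[i], sess, params.outcome,
                 params.baseline_mean + b[i] + delta + eps)
            )
    return pd.DataFrame(rows, columns=["subject", "group", "lifestyle", "session",
                                       "outcome_name", "outcome"])
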