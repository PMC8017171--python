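"""End-to-end orchestration: simulate -> preprocess -> coherence/MMN -> stats.

``run_pipeline`` executes the eight stages below from one :class:`RunConfig`
and writes a manifest with per-file SHA-256 hashes; re-running the same
config reproduces every numeric output bit-identically.

1. paradigm_optimum1     - Optimum-1 event list (TSV, optional WAV rendering)
2. paradigm_memorytrace  - Memory-Trace event list
3. resting_sim           - synthetic resting EEG (native npz+JSON format)
4. coherence             - 20-trial global / region coherence summary
5. mmn_epochs_short      - synthetic Optimum-1 oddball epochs
6. mmn_result            - 50-trial MMN amplitudes and the decay score
7. cohort                - synthetic trial cohort table (CSV)
8. stats                 - mixed-model F-tests, Hedges' g, paired t-tests
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .config import RunConfig
from .montage import default_montage
from . import coherence as coh
from . import io as mio
from . import mmn as mmn_mod
from . import paradigm as par
from . import preprocess as pre
from . import stats as st
from .synth import (
    CohortParams,
    CoherenceGroundTruth,
    MMNGroundTruth,
    simulate_cohort,
    simulate_mmn_epochs,
    simulate_resting,
)

logger = logging.getLogger("mmncoh.pipeline")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = default_montage()
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    outputs: dict[str, list[Path]] = {}

    def stage(name):
        def wrap(fn):
            try:
                logger.info("stage %s", name)
                outputs[name] = [Path(p) for p in fn()]
            except Exception as exc:  # noqa: BLE001 - aborts with stage name
                raise StageError(name, exc) from exc
        return wrap

    @stage("paradigm_optimum1")
    def _():
        seq = par.generate_optimum1_sequence(config.paradigm.optimum1_seed)
        path = out / "optimum1_events.tsv"
        seq.to_tsv(path)
        files = [path]
        if config.paradigm.render_audio:
            spec = par.StimulusSpec(sample_rate_hz=config.paradigm.sample_rate_hz)
            for kind in par.DeviantKind:
                wav = out / f"stimulus_{kind.value}.wav"
                par.synthesize_stimulus(spec, kind).to_wav(wav)
                files.append(wav)
        return files

    @stage("paradigm_memorytrace")
    def _():
        seq = par.generate_memorytrace_sequence(config.paradigm.memorytrace_seed)
        path = out / "memorytrace_events.tsv"
        seq.to_tsv(path)
        return [path]

    @stage("resting_sim")
    def _():
        truth = CoherenceGroundTruth(a=config.simulation.coherence_mixing_a)
        rec = simulate_resting(
            montage, truth,
            duration_s=config.simulation.resting_duration_s,
            fs_hz=config.simulation.resting_fs_hz,
            seed=pre.derive_seed(config.seed, "demo", "pre", "resting"),
        )
        d = mio.save_recording(rec, out / "resting")
        return [d / "recording.npz", d / "recording.json"]

    @stage("coherence")
    def _():
        raw = mio.load_recording(out / "resting")
        raw = pre.bandpass(raw, *config.coherence.band_hz)
        raw.bads = pre.detect_bad_channels(raw)
        referenced = pre.rereference(raw, "average_of_good")
        sub_seed = pre.derive_seed(config.seed, "demo", "pre", "cohsub")

        def chain(rec):
            ep = pre.epoch_resting(rec, config.preprocess.resting_epoch_s,
                                   config.preprocess.pp_threshold_uv,
                                   config.preprocess.abs_threshold_uv)
            ep = pre.subsample_trials(ep, config.coherence.n_trials, seed=sub_seed)
            return coh.coherence_matrix(ep, band_hz=config.coherence.band_hz,
                                        squared=config.coherence.squared)

        res = chain(referenced)
        report = coh.summary(res, montage)
        # The average reference removes a spatially uniform shared source, so
        # the ground-truth closed form applies to the unreferenced data only.
        report["global_coherence_unreferenced"] = coh.global_coherence(chain(raw))
        report["expected_global_msc_unreferenced"] = (
            raw.info.get("ground_truth", {}).get("expected_global_msc"))
        path = out / "coherence_summary.json"
        _write_json(path, report)
        pairs = out / "coherence_pairs.csv"
        res.pair_frame().to_csv(pairs, index=False)
        return [path, pairs]

    @stage("mmn_epochs_short")
    def _():
        truths = {
            "short": MMNGroundTruth(amplitude_uv=config.simulation.mmn_amplitude_short_uv,
                                    noise_sd_uv=config.simulation.mmn_noise_sd_uv),
            "long": MMNGroundTruth(amplitude_uv=config.simulation.mmn_amplitude_long_uv,
                                   noise_sd_uv=config.simulation.mmn_noise_sd_uv),
        }
        files = []
        for tag, truth in truths.items():
            ep = simulate_mmn_epochs(
                montage, truth,
                n_standard=config.simulation.n_standard,
                n_deviant=config.simulation.n_deviant,
                fs_hz=config.simulation.mmn_fs_hz,
                paradigm_id="optimum1" if tag == "short" else "memory_trace",
                seed=pre.derive_seed(config.seed, "demo", "pre", f"mmn_{tag}"),
            )
            d = mio.save_epochs(ep, out / f"mmn_epochs_{tag}")
            files += [d / "epochs.npz", d / "epochs.json"]
        return files

    @stage("mmn_result")
    def _():
        measured = {}
        for tag in ("short", "long"):
            ep = mio.load_epochs(out / f"mmn_epochs_{tag}")
            ep = pre.rereference(ep, "linked_mastoids")
            ep = pre.reject_epochs(ep, config.preprocess.pp_threshold_uv,
                                   config.preprocess.abs_threshold_uv)
            dev = pre.subsample_trials(
                ep, config.mmn.n_trials, condition="duration",
                seed=pre.derive_seed(config.seed, "demo", "pre", f"mmnsub_{tag}_dev"))
            stdn = pre.subsample_trials(
                ep, config.mmn.n_trials, condition="standard",
                seed=pre.derive_seed(config.seed, "demo", "pre", f"mmnsub_{tag}_std"))
            measured[tag] = mmn_mod.mmn_amplitude(
                mmn_mod.average_erp(dev, "duration"),
                mmn_mod.average_erp(stdn, "standard"),
                window_ms=config.mmn.window_ms, cluster=config.mmn.cluster)
        result = mmn_mod.MMNResult(
            mmn_short_uv=measured["short"], mmn_long_uv=measured["long"],
            delta_mmn_uv=mmn_mod.delta_mmn(measured["short"], measured["long"]),
            window_ms=config.mmn.window_ms, cluster=config.mmn.cluster)
        path = out / "mmn_result.json"
        _write_json(path, result.to_dict())
        return [path]

    @stage("cohort")
    def _():
        params = CohortParams(
            n_ct=config.cohort.n_ct, n_pt=config.cohort.n_pt, n_wlc=config.cohort.n_wlc,
            beta_lifestyle=config.cohort.beta_lifestyle,
            beta_group={"CT": config.cohort.beta_group_ct,
                        "PT": config.cohort.beta_group_pt, "WLC": 0.0},
            residual_sd=config.cohort.residual_sd,
            subject_sd=config.cohort.subject_sd,
            sessions=config.cohort.sessions,
        )
        table = simulate_cohort(params, seed=pre.derive_seed(config.seed, "cohort", "all", "sim"))
        path = out / "cohort.csv"
        table.to_csv(path, index=False)
        return [path]

    @stage("stats")
    def _():
        import pandas as pd

        table = pd.read_csv(out / "cohort.csv")
        res = st.fit_interaction_model(table, sessions=config.cohort.sessions)
        wide = table.pivot_table(index=["subject", "group"], columns="session",
                                 values="outcome").reset_index()
        diffs = {g: (wide.loc[wide["group"] == g, "post"]
                     - wide.loc[wide["group"] == g, "pre"]).to_numpy()
                 for g in ("CT", "PT", "WLC")}
        report = {
            "group_time": vars(res.group_time),
            "lifestyle_time": vars(res.lifestyle_time) if res.lifestyle_time else None,
            "hedges_g_ct_vs_wlc": vars(st.hedges_g(diffs["CT"], diffs["WLC"])),
            "hedges_g_pt_vs_wlc": vars(st.hedges_g(diffs["PT"], diffs["WLC"])),
            "paired_t": {g: dict(zip(("t", "df", "p"),
                                     st.paired_t(wide.loc[wide["group"] == g, "pre"],
                                                 wide.loc[wide["group"] == g, "post"])))
                         for g in ("CT", "PT", "WLC")},
            "method": res.method,
        }
        path = out / "stats_report.json"
        _write_json(path, report)
        return [path]

    for name, files in outputs.items():
        manifest["stages"][name] = {str(p.relative_to(out)): _sha256(p) for p in files}
    manifest_path = out / "manifest.json"
    _write_json(manifest_path, manifest)
    logger.info("wrote %s", manifest_path)
    return manifest
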