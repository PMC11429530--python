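"""End-to-end per-group orchestration.

One config + one seed produce, under ``out_dir``: behaviour.csv,
spectra.csv, fpca/, tpca-Go/, tpca-NoGo/, measures.csv, links.csv and a
manifest.json with per-stage trial counts, the seed fan-out and a config
hash.  Identical config + seed give byte-identical CSVs.

Seed fan-out: the run seed feeds one ``numpy.random.SeedSequence``; child 0
drives the simulation, children 1..n_subjects the per-subject trial-count
matching, in subject order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, linkage, pca, preprocess, spectra, synth
from .errors import InvalidInputError
from .io_core.containers import EpochSet, MeasureTable, Recording
from .io_core.edf import read_edf
from .io_core.tables import write_tables

logger = logging.getLogger(__name__)

#: the printed method constants the default config must reproduce
DEFAULTS = {
    "band_hz": (0.1, 30.0),
    "epoch_window_ms": (-500.0, 600.0),
    "baseline_ms": (-100.0, 0.0),
    "extreme_abs_uv": 150.0,
    "jump_uv": 50.0,
    "flat_delta_uv": 0.05,
    "flat_window_ms": 100.0,
    "dft_points": 512,
    "window_correction": 1.05,
    "padding_correction": 2.0,
    "variance_threshold_pct": 1.5,
    "fpca_rotation": "promax",
    "tpca_rotation": "varimax",
    "soa_ms": 1100.0,
}


@dataclass
class RunConfig:
    group: str = "sim"
    seed: int = 0
    out_dir: str = "out"
    edf_paths: list = field(default_factory=list)      # ingest route
    sim: synth.SimConfig | None = None                 # simulate route
    thresholds: preprocess.RejectionThresholds = field(
        default_factory=preprocess.RejectionThresholds)
    promax_kappa: float = 3.0
    variance_threshold_pct: float = pca.VARIANCE_THRESHOLD_PCT
    soa_ms: float = 1100.0

    def to_jsonable(self) -> dict:
        doc = {
            "group": self.group, "seed": self.seed, "out_dir": str(self.out_dir),
            "edf_paths": [str(p) for p in self.edf_paths],
            "thresholds": self.thresholds.__dict__,
            "promax_kappa": self.promax_kappa,
            "variance_threshold_pct": self.variance_threshold_pct,
            "soa_ms": self.soa_ms,
            "defaults": {k: list(v) if isinstance(v, tuple) else v
                         for k, v in DEFAULTS.items()},
        }
        return doc


def average_erps(epochs: EpochSet, condition: str) -> np.ndarray:
    """Condition-mean ERP per channel on the 256 Hz -100..600 ms grid.

    Averages the accepted, matched trials, then half-samples (every 2nd
    sample of the 512 Hz grid), yielding 179 points.
    """
    mask = epochs.accepted_mask(condition)
    if not mask.any():
        raise InvalidInputError(f"no accepted {condition} trials")
    mean = epochs.data[mask][:, epochs.eeg_index].mean(axis=0)
    if epochs.fs != 512.0:
        raise InvalidInputError("ERP averaging expects the 512 Hz grid")
    ks = np.arange(-25, 154)  # 256 Hz grid indices
    idx = epochs.t0_index + 2 * ks
    if idx.min() < 0 or idx.max() >= epochs.n_samples:
        raise InvalidInputError("epoch window too short for the ERP grid")
    return mean[:, idx]


def _process_subject(recording: Recording, seed: int,
                     cfg: RunConfig) -> tuple[EpochSet, dict, behaviour.BehaviourSummary]:
    epochs, _, manifest = preprocess.run_preprocess(
        recording, seed=seed, thresholds=cfg.thresholds, soa_ms=cfg.soa_ms)
    classes = behaviour.classify_trials(recording.events, recording.responses,
                                        cfg.soa_ms, recording.fs)
    rts = epochs.rt_ms[epochs.accepted_mask("Go")]
    summary = behaviour.summarise(classes, rts)
    return epochs, manifest, summary


def _component_tables(components: pca.ComponentSet) -> dict[str, pd.DataFrame]:
    axis = components.variable_axis
    loadings = pd.DataFrame(components.loadings,
                            columns=[f"c{k+1}" for k in range(components.n_components)])
    loadings.insert(0, components.axis_unit, axis)
    scaled = pd.DataFrame(components.scaled_loadings, columns=loadings.columns[1:])
    scaled.insert(0, components.axis_unit, axis)
    return {"loadings": loadings, "scaled_loadings": scaled,
            "summary": components.summary()}


def run_group(cfg: RunConfig) -> dict:
    """Run the full analysis for one group; returns the manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)

    if cfg.sim is not None:
        sim_seed = int(ss.spawn(1)[0].generate_state(1)[0])
        recordings, truth = synth.simulate_group(cfg.sim, sim_seed)
        truth.to_json(out_dir / "truth.json")
    elif cfg.edf_paths:
        recordings = {Path(p).stem: read_edf(p) for p in cfg.edf_paths}
    else:
        raise InvalidInputError("config needs either a simulation or EDF paths")

    subjects = list(recordings)
    match_seeds = ss.spawn(1 + len(subjects))[1:]
    per_subject_epochs: dict[str, EpochSet] = {}
    manifest = {"group": cfg.group, "seed": cfg.seed, "subjects": {}}
    beh_rows = {}
    for subject, child in zip(subjects, match_seeds):
        epochs, sub_manifest, summary = _process_subject(
            recordings[subject], int(child.generate_state(1)[0]), cfg)
        per_subject_epochs[subject] = epochs
        manifest["subjects"][subject] = sub_manifest
        beh_rows[subject] = summary.to_dict()
        logger.info("subject %s: %d matched epochs per condition", subject,
                    int(epochs.accepted_mask("Go").sum()))

    beh_frame = pd.DataFrame.from_dict(beh_rows, orient="index")
    beh_frame.index.name = "subject"
    write_tables({"behaviour": beh_frame.reset_index()}, out_dir)

    # ---- spectra + frequency-domain PCA --------------------------------
    spectrum_set = spectra.mean_spectra(per_subject_epochs)
    spectrum_set.to_frame().to_csv(out_dir / "spectra.csv", index=False,
                                   float_format="%.12g")
    f_input = pca.assemble_fpca_input(spectrum_set)
    f_components = pca.select_and_scale(
        pca.promax(pca.covariance_pca(f_input), kappa=cfg.promax_kappa),
        cfg.variance_threshold_pct)
    eeg_amps = pca.peak_amplitudes(f_components, f_input, mode="pooled")
    eeg_amps.columns = [f"EEG_{c}" for c in eeg_amps.columns]
    write_tables(_component_tables(f_components), out_dir / "fpca")

    # ---- ERPs + temporal PCA per condition -----------------------------
    erp_frames = {}
    for condition in ("Go", "NoGo"):
        erp_data = np.stack([average_erps(per_subject_epochs[s], condition)
                             for s in subjects])
        first = per_subject_epochs[subjects[0]]
        ch_names = [first.channel_names[i] for i in first.eeg_index]
        t_input = pca.assemble_tpca_input(erp_data, subjects, ch_names,
                                          pca.tpca_times_ms(), condition)
        t_components = pca.select_and_scale(
            pca.varimax(pca.covariance_pca(t_input)),
            cfg.variance_threshold_pct)
        amps = pca.peak_amplitudes(t_components, t_input, mode="pooled")
        amps.columns = [f"ERP{condition}_{c}" for c in amps.columns]
        erp_frames[condition] = amps
        write_tables(_component_tables(t_components), out_dir / f"tpca-{condition}")

    # ---- measures + linkage --------------------------------------------
    domain = {c: "EEG" for c in eeg_amps.columns}
    domain |= {c: "ERP-Go" for c in erp_frames["Go"].columns}
    domain |= {c: "ERP-NoGo" for c in erp_frames["NoGo"].columns}
    domain |= {c: "behaviour" for c in beh_frame.columns}
    measures_frame = (eeg_amps.join(erp_frames["Go"]).join(erp_frames["NoGo"])
                      .join(beh_frame))
    measures = MeasureTable(measures_frame, domain)
    write_tables({"measures": measures_frame.rename_axis("subject").reset_index()},
                 out_dir)
    links = linkage.build_link_table(measures)
    write_tables({"links": links}, out_dir)

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg.to_jsonable(), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest["artefacts"] = sorted(str(p.relative_to(out_dir))
                                   for p in out_dir.rglob("*.csv"))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
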