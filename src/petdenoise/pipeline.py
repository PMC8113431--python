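"""End-to-end pipeline: simulate -> prepare -> train -> denoise -> evaluate -> compare.

Per synthetic test subject the pipeline produces the five evaluated image
sets (4 min; 1.5 min with and without CNN; 1 min with and without CNN),
computes per-lesion SUVmax/SUVpeak and per-subject liver COV for each,
and runs the omnibus + pairwise statistical battery. Everything is a pure
function of the configuration and its master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import metrics as met
from . import phantom as ph
from . import stats as st
from .io import write_volume
from .model import DenoisingCNN
from .traindata import AugmentParams, TrainSource, build_pairs, crop_central

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config", "save_config"]


def derive_seed(master: int, *tags) -> int:
    """Stable 31-bit child seed from a master seed and a tag path."""
    h = hashlib.sha256(repr((master,) + tags).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one full synthetic study.

    Defaults are desk-scale: a 71 x 64 x 64 voxel grid, three training
    subjects (10 subsets x 4 short reconstructions x 2 samples = 240 pairs
    per network) and small-capacity networks that train on one CPU in
    minutes. Betas follow the standard clinical pairing: 200 for the 6-min
    training target, 300 for the 4-min reference, 500 for 1.5 and 1 min.
    """

    grid: Tuple[int, int, int] = (71, 64, 64)
    voxel_size: Tuple[float, float, float] = ph.DEFAULT_VOXEL_SIZE
    n_train_subjects: int = 3
    n_test_subjects: int = 10
    n_lesions: int = 3
    betas: Dict[float, float] = field(
        default_factory=lambda: {6.0: 200.0, 4.0: 300.0, 1.5: 500.0, 1.0: 500.0}
    )
    train_durations: Tuple[float, ...] = (1.0, 1.5)
    crop_slices: int = 50
    subset_depth: int = 5
    n_aug: int = 1
    sensitivity: float = 1.0
    psf_fwhm_mm: float = 4.0
    weight_kg: float = 70.0
    injected_mbq: float = 280.0
    model: Dict = field(
        default_factory=lambda: {
            "n_layers": 5,
            "n_filters": 8,
            "epochs": 20,
            "batch_size": 8,
            "learning_rate": 0.3,
            "momentum": 0.9,
        }
    )
    seed: int = 0
    write_volumes: bool = False

    def calib(self) -> ph.ScannerCalib:
        return ph.ScannerCalib(
            sensitivity=self.sensitivity, psf_fwhm_mm=self.psf_fwhm_mm
        )

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["betas"] = {str(k): v for k, v in d["betas"].items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    if "betas" in d:
        d["betas"] = {float(k): float(v) for k, v in d["betas"].items()}
    for key in ("grid", "voxel_size", "train_durations"):
        if key in d:
            d[key] = tuple(d[key])
    return RunConfig(**d)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)


# --------------------------------------------------------------------- stages


def _recon(cfg: RunConfig, frame: ph.CountVolume, beta: float, label: str):
    return ph.emulate_reconstruction(
        frame,
        beta=beta,
        calib=cfg.calib(),
        voxel_size=cfg.voxel_size,
        weight_kg=cfg.weight_kg,
        injected_mbq=cfg.injected_mbq,
        label=label,
    )


def simulate_training_sources(
    cfg: RunConfig,
) -> Dict[float, List[TrainSource]]:
    """Emulate the training acquisition design.

    Each training subject contributes one 6-min frame; the frame is split
    into four 1.5-min intervals and (separately) six 1-min intervals of
    which the first four are used, mirroring interval extraction from one
    list-mode acquisition. The 6-min reconstruction (low beta) is the
    clean target; the short intervals (high beta) are the noisy inputs.
    """
    calib = cfg.calib()
    sources: Dict[float, List[TrainSource]] = {d: [] for d in cfg.train_durations}
    for i in range(cfg.n_train_subjects):
        spec = ph.random_phantom_spec(
            derive_seed(cfg.seed, "train-phantom", i),
            shape=cfg.grid,
            voxel_size=cfg.voxel_size,
            n_lesions=cfg.n_lesions,
        )
        act = ph.build_phantom(spec)
        frame6 = ph.simulate_frame(
            act, 6.0, calib, derive_seed(cfg.seed, "train-frame", i)
        )
        clean = crop_central(
            _recon(cfg, frame6, cfg.betas[6.0], "6 min").values, cfg.crop_slices
        )
        for dur, n_int in ((1.5, 4), (1.0, 6)):
            if dur not in sources:
                continue
            subs = ph.split_frame(
                frame6, n_int, derive_seed(cfg.seed, "train-split", i, dur)
            )[:4]
            noisy = [
                crop_central(
                    _recon(cfg, sf, cfg.betas[dur], f"{dur} min #{j}").values,
                    cfg.crop_slices,
                )
                for j, sf in enumerate(subs)
            ]
            sources[dur].append(
                TrainSource(
                    source_id=f"train_{i}",
                    clean=clean,
                    noisy=noisy,
                    clean_id="6 min",
                    noisy_ids=[f"{dur} min #{j}" for j in range(len(noisy))],
                )
            )
    return sources


def train_networks(cfg: RunConfig) -> Dict[float, DenoisingCNN]:
    """Train one independent network per short acquisition time."""
    if not cfg.train_durations or cfg.n_train_subjects == 0:
        warnings.warn("no short-duration training data; training stage skipped")
        return {}
    sources = simulate_training_sources(cfg)
    models: Dict[float, DenoisingCNN] = {}
    for dur, srcs in sources.items():
        pairs = build_pairs(
            srcs,
            n_aug=cfg.n_aug,
            depth=cfg.subset_depth,
            params=AugmentParams(),
            seed=derive_seed(cfg.seed, "pairs", dur),
        )
        if not pairs:
            warnings.warn(f"no pairs for {dur} min; training stage skipped")
            continue
        model = DenoisingCNN(
            **cfg.model, random_state=derive_seed(cfg.seed, "model", dur)
        )
        model.fit_pairs(pairs)
        models[dur] = model
    return models


def simulate_test_subject(
    cfg: RunConfig, index: int
) -> Tuple[ph.ActivityVolume, Dict[str, ph.SUVVolume]]:
    """The three acquired image sets of one test subject.

    The subject is scanned for 4 min; 1.5-min and 1-min frames are
    extracted from the same acquisition by exact count splitting into
    0.5-min chunks (3 chunks -> 1.5 min, 2 chunks -> 1 min).
    """
    calib = cfg.calib()
    spec = ph.random_phantom_spec(
        derive_seed(cfg.seed, "test-phantom", index),
        shape=cfg.grid,
        voxel_size=cfg.voxel_size,
        n_lesions=cfg.n_lesions,
    )
    act = ph.build_phantom(spec)
    frame4 = ph.simulate_frame(
        act, 4.0, calib, derive_seed(cfg.seed, "test-frame", index)
    )
    chunks = ph.split_frame(frame4, 8, derive_seed(cfg.seed, "test-split", index))
    frames = {
        "4 min": frame4,
        "1.5 min": ph.sum_frames(chunks[:3]),
        "1 min": ph.sum_frames(chunks[:2]),
    }
    volumes = {
        label: _recon(cfg, fr, cfg.betas[fr.duration_min], label)
        for label, fr in frames.items()
    }
    return act, volumes


def _subject_rois(
    act: ph.ActivityVolume,
) -> Tuple[met.LiverROISet, Dict[str, met.VOI]]:
    """Liver circles and lesion VOIs from the ground-truth masks.

    ROIs/VOIs are defined once per subject (on the reference anatomy) and
    applied unchanged to all image sets.
    """
    liver = act.masks["liver"]
    zc, rc, cc = (float(v) for v in ndimage.center_of_mass(liver))
    rois = met.LiverROISet.centered_on(
        int(round(zc)), (rc, cc), image_set="4 min"
    )
    vois = {}
    for name, mask in act.masks.items():
        if name.startswith("lesion"):
            vois[name] = met.VOI(
                label=name,
                mask=ndimage.binary_dilation(mask),
                image_set="4 min",
            )
    return rois, vois


def evaluate_subject(
    cfg: RunConfig,
    subject_id: str,
    act: ph.ActivityVolume,
    volumes: Dict[str, ph.SUVVolume],
) -> List[met.MetricsRecord]:
    rois, vois = _subject_rois(act)
    records: List[met.MetricsRecord] = []
    for label, vol in volumes.items():
        records.append(
            met.MetricsRecord(
                subject=subject_id,
                image_set=label,
                cov=met.cov_liver(vol.values, rois, cfg.voxel_size),
            )
        )
        for name, voi in vois.items():
            records.append(
                met.MetricsRecord(
                    subject=subject_id,
                    image_set=label,
                    lesion=name,
                    suv_max=met.suv_max(vol.values, voi),
                    suv_peak=met.suv_peak(vol.values, voi, cfg.voxel_size),
                )
            )
    return records


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    report: Optional[st.ComparisonReport]
    models: Dict[float, DenoisingCNN]
    manifest: Dict
    outdir: Optional[Path]


def run_pipeline(cfg: RunConfig, outdir=None) -> PipelineResult:
    """Run the full study; re-running with the same config is bitwise stable."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest: Dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": [],
    }

    def _stage(name):
        manifest["stages"].append(name)
        if outdir is not None:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        _stage("train")
        models = train_networks(cfg)
        manifest["trained_networks"] = {
            f"{d} min": len(m.loss_history_) for d, m in models.items()
        }

        _stage("simulate+denoise+evaluate")
        all_records: List[met.MetricsRecord] = []
        n_sets = None
        for i in range(cfg.n_test_subjects):
            sid = f"subject_{i:03d}"
            act, volumes = simulate_test_subject(cfg, i)
            for dur, model in models.items():
                src = volumes[f"{dur:g} min"]
                volumes[f"{dur:g} min CNN"] = ph.SUVVolume(
                    values=model.denoise_volume(src.values),
                    voxel_size=src.voxel_size,
                    label=f"{dur:g} min CNN",
                )
            n_sets = len(volumes)
            if cfg.write_volumes and outdir is not None:
                vdir = outdir / "volumes" / sid
                vdir.mkdir(parents=True, exist_ok=True)
                for label, vol in volumes.items():
                    write_volume(vol, vdir / f"{label.replace(' ', '_')}.nii.gz")
            all_records.extend(evaluate_subject(cfg, sid, act, volumes))

        metrics_df = met.records_to_frame(all_records)
        manifest["examinations"] = int(cfg.n_test_subjects * (n_sets or 0))
        manifest["n_image_sets"] = n_sets

        _stage("compare")
        report = None
        if n_sets == len(st.IMAGE_SETS):
            report = st.run_comparison_suite(metrics_df)
        else:
            warnings.warn(
                "not all five image sets were produced; comparison stage skipped"
            )

        if outdir is not None:
            metrics_df.to_csv(outdir / "metrics.csv", index=False)
            if report is not None:
                report.omnibus.to_csv(outdir / "report_omnibus.csv", index=False)
                report.pairwise.to_csv(outdir / "report_pairwise.csv", index=False)
                (outdir / "report_summary.txt").write_text(report.summary())
            for dur, model in models.items():
                model.save(outdir / f"model_{dur:g}min.zip")
        _stage("done")
    except Exception as exc:  # persist partial provenance before propagating
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "?"
        manifest["error"] = str(exc)
        if outdir is not None:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        metrics=metrics_df, report=report, models=models, manifest=manifest,
        outdir=outdir,
    )
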