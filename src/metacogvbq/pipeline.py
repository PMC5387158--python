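"""End-to-end reproducible pipeline: behaviour -> summaries -> maps -> VBQ.

Every stage receives a deterministic child seed derived from the master seed
and the stage name (stable SHA-256 hash), so each stage is reproducible on
its own and the full run is checksum-identical under a fixed master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour, behaviour_stats, maps, glm


def child_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Stable child seed from (master seed, stage name[, index]); < 2**31."""
    h = hashlib.sha256(f"{master_seed}|{stage}|{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything one run needs; serializes losslessly to YAML/JSON."""

    seed: int = 0
    n_subjects: int = 48
    n_main_trials: int = 320
    n_blocks: int = 8
    voxel_size_mm: float = 2.0
    noise_fwhm_mm: float = 4.0
    n_permutations: int = 500
    cluster_forming_p: float = 0.001
    voi_radius_mm: float = 5.0
    map_types: tuple = ("MT", "R1", "R2star")
    contrasts: tuple = ("pos", "neg")
    modes: tuple = ("peak", "cluster")
    write_maps: bool = True
    output_dir: str = "metacogvbq_output"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("map_types", "contrasts", "modes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate-behaviour -> analyse-behaviour -> simulate-maps -> VBQ.

    Returns a manifest dict (also written as ``manifest.json``) listing every
    output file with its SHA-256 checksum.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _stage(name):
        return np.random.default_rng(child_seed(config.seed, name))

    # --- simulate behaviour -------------------------------------------------
    stage = "simulate-behaviour"
    try:
        session_config = behaviour.SessionConfig(
            n_main_trials=config.n_main_trials, n_blocks=config.n_blocks)
        sessions, truth = behaviour.simulate_cohort(
            config.n_subjects, session_config, _stage(stage))
        beh_dir = out / "behaviour"
        beh_dir.mkdir(exist_ok=True)
        for i, s in enumerate(sessions):
            behaviour.write_trials(s.trials, beh_dir / f"sub-{i:03d}_trials.csv")
            written.append(beh_dir / f"sub-{i:03d}_trials.csv")
        truth.to_csv(beh_dir / "true_params.csv", index=False)
        written.append(beh_dir / "true_params.csv")
    except Exception as e:                                  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- analyse behaviour --------------------------------------------------
    stage = "analyse-behaviour"
    try:
        summaries, tables, reports = behaviour_stats.summarise_cohort(
            sessions, truth)
        summaries.to_csv(out / "subject_summaries.csv")
        written.append(out / "subject_summaries.csv")
        (out / "filter_reports.json").write_text(json.dumps(
            [r.to_dict() for r in reports], indent=1))
        written.append(out / "filter_reports.json")
        anova = behaviour_stats.staircase_stability_anova(tables)
        anova.to_csv(out / "staircase_stability_anova.csv", index=False)
        written.append(out / "staircase_stability_anova.csv")
    except Exception as e:                                  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- simulate maps ------------------------------------------------------
    stage = "simulate-maps"
    try:
        grid = maps.GridSpec.default(config.voxel_size_mm)
        cohort = maps.generate_cohort_maps(
            summaries, grid=grid, noise_fwhm_mm=config.noise_fwhm_mm,
            rng=_stage(stage))
        if config.write_maps:
            manifest_maps = maps.write_cohort(cohort, out / "maps")
            written.extend((out / "maps" / n)
                           for names in manifest_maps["files"].values()
                           for n in names)
            written.append(out / "maps" / "gm_mask.nii")
            written.append(out / "maps" / "cohort.json")
    except Exception as e:                                  # noqa: BLE001
        raise StageError(stage, e) from e

    # --- voxelwise GLM ------------------------------------------------------
    stage = "run-vbq"
    try:
        design = glm.build_design(summaries)
        voi_mask, _ = glm.make_voi_mask(grid, radius_mm=config.voi_radius_mm)
        results = []
        stat_dir = out / "stats"
        stat_dir.mkdir(exist_ok=True)
        for k, map_type in enumerate(config.map_types):
            res = glm.VoxelwiseRegression.from_cohort(
                cohort, design, map_type).fit()
            import nibabel as nib
            timg = nib.Nifti1Image(
                np.nan_to_num(res.t_volume("pos")).astype(np.float32),
                grid.affine)
            nib.save(timg, stat_dir / f"tmap_{map_type}.nii")
            written.append(stat_dir / f"tmap_{map_type}.nii")
            for contrast in config.contrasts:
                for mode in config.modes:
                    rng = np.random.default_rng(child_seed(
                        config.seed, f"{stage}|{map_type}|{contrast}|{mode}"))
                    results.append(res.permutation_fwe(
                        mode=mode, contrast=contrast,
                        voi_mask=voi_mask if mode == "peak" else None,
                        cluster_forming_p=config.cluster_forming_p,
                        n_perm=config.n_permutations, rng=rng))
        report = glm.report_tables(results, stat_dir / "report.csv")
        written.append(stat_dir / "report.csv")
    except StageError:
        raise
    except Exception as e:                                  # noqa: BLE001
        raise StageError(stage, e) from e

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "n_report_rows": int(len(report)),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
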