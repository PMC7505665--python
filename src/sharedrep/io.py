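"""Shared I/O, configuration and pipeline orchestration.

Volumes are NIfTI (.nii/.nii.gz) with an affine built from the grid's
voxel size; masked vectors are linearized x-fastest (see
:mod:`sharedrep.grid`).  The pipeline runs the full synthetic analysis in
the order of the scientific workflow: within-modality decoding,
between-modality cross-prediction, weight-map similarity (octants,
spatial correlation, permutation test), bootstrap reliability maps with
conjunction, specificity against the arousal contrast, the pooled
modality-general decoder, and thermal transfer.  All randomness flows
from the seeds recorded in the configuration, so a config fully
determines the results directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import decode, patstats, transfer
from .grid import VolumeGrid, make_grid
from .simulate import plant_patterns, simulate_subjects, simulate_thermal

__all__ = ["read_volume", "write_volume", "AnalysisConfig", "run_pipeline"]

log = logging.getLogger("sharedrep")


def write_volume(
    data: np.ndarray, grid: VolumeGrid, path: str | Path
) -> None:
    """Write a 3-D lattice (or masked vector) as float32 NIfTI."""
    data = np.asarray(data)
    if data.ndim == 1:
        data = grid.to_volume(data)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def grid_from_mask(path: str | Path) -> VolumeGrid:
    """Build a VolumeGrid from a mask volume on disk."""
    data, affine = read_volume(path)
    voxel_size = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
    return VolumeGrid(data.shape, voxel_size, data > 0)


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs, with explicit seeds throughout."""

    # synthetic-data geometry and generative settings
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mask_fill: float = 1.0
    n_subjects: int = 30
    n_shared: int = 60
    n_unique: int = 40
    n_arousal: int = 40
    noise_sd: float = 1.0
    subject_sd: float = 0.5
    thermal_subjects: int = 33
    thermal_levels: int = 6
    thermal_slope: float = 0.75
    rating_noise: float = 1.0
    # decoder settings
    C: float = 1.0
    n_folds: int = 10
    n_repeats: int = 10
    # resampling settings
    n_perm: int = 1000
    n_boot: int = 1000
    q: float = 0.05
    min_mm3: float = 100.0
    # seeds (all explicit)
    seed_mask: int = 0
    seed_truth: int = 1
    seed_subjects: int = 2
    seed_thermal: int = 3
    seed_cv: int = 4
    seed_perm: int = 5
    seed_boot: int = 6

    def __post_init__(self):
        if not (0 < self.q < 1):
            raise ValueError("q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("grid_shape", "voxel_size_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _seeded(base: int, offset: int) -> int:
    return (base * 1000003 + offset) % (2**31)


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic analysis and write a results bundle.

    Stage failures are logged with the stage name and downstream stages
    that depend on the failed output are skipped; independent stages
    still run.  Returns the results dictionary that is also written to
    ``results.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config.to_dict(), "config_hash": config.digest()}
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config hash %s", config.digest())

    grid = make_grid(
        config.grid_shape, config.voxel_size_mm, config.mask_fill, config.seed_mask
    )
    truth = plant_patterns(
        grid,
        config.n_shared,
        config.n_unique,
        config.n_unique,
        config.n_arousal,
        seed=config.seed_truth,
        noise_sd=config.noise_sd,
        subject_sd=config.subject_sd,
    )
    dataset = simulate_subjects(truth, config.n_subjects, seed=config.seed_subjects)
    scheme = decode.CVScheme(config.n_folds, config.n_repeats, config.seed_cv)

    def stage(name, fn):
        try:
            log.info("stage %s: start", name)
            out = fn()
            log.info("stage %s: done", name)
            return out
        except Exception as exc:  # log and continue with independent stages
            log.error("stage %s failed: %s", name, exc)
            results.setdefault("failed_stages", []).append(name)
            return None

    # univariate group t-maps + overlap
    def univariate():
        out = {}
        thr = {}
        for m in ("NS", "FE"):
            _, pain, ctrl = dataset.paired(m, "pain", "control")
            tmap = patstats.group_ttest(pain - ctrl)
            rej = patstats.fdr_threshold(tmap.p, config.q)
            rej = patstats.extent_filter(rej, grid, config.min_mm3)
            thr[m] = (rej, tmap.stat)
            write_volume(tmap.stat, grid, out_dir / f"tmap_{m}.nii.gz")
            out[m] = {"n_sig_voxels": int(rej.sum())}
        overlap = patstats.conjunction(
            thr["NS"][0], thr["FE"][0], thr["NS"][1], thr["FE"][1],
            require_same_sign=True,
        )
        out["overlap_voxels"] = int(overlap.sum())
        return out

    results["univariate"] = stage("univariate", univariate)

    # whole-brain decoding, within and between modality
    def whole_brain():
        out = {}
        for m in ("NS", "FE"):
            out[f"within_{m}"] = decode.repeated_cv(dataset, m, scheme, config.C).as_dict()
        out["between_NStoFE"] = decode.cross_modality_eval(
            dataset, "NS", "FE", scheme, config.C
        ).as_dict()
        out["between_FEtoNS"] = decode.cross_modality_eval(
            dataset, "FE", "NS", scheme, config.C
        ).as_dict()
        return out

    results["decoding"] = stage("decoding", whole_brain)

    # modality-specific final patterns: similarity, octants, permutation test
    def similarity():
        models = {
            m: decode.train_final(dataset, modalities=(m,), C=config.C)
            for m in ("NS", "FE")
        }
        for m, model in models.items():
            write_volume(model.weights, grid, out_dir / f"weights_{m}.nii.gz")
        oct_sum = patstats.octant_analysis(
            models["FE"].weights, models["NS"].weights
        )
        octants = {
            "counts": oct_sum.counts.tolist(),
            "ssd": oct_sum.ssd.tolist(),
            "excluded_zero": oct_sum.excluded_zero,
        }
        pairs = {
            m: dataset.paired(m, "pain", "control")[1:] for m in ("NS", "FE")
        }
        perm = patstats.permutation_similarity(
            pairs["NS"], pairs["FE"], patstats.svm_weight_builder(config.C),
            n_perm=config.n_perm, seed=config.seed_perm,
        )
        return {
            "octants": octants,
            "weight_correlation": {
                "r": perm.r_obs, "p": perm.p, "n_perm": perm.n_perm,
                "seed": config.seed_perm,
            },
        }, models, pairs

    sim_out = stage("similarity", similarity)
    models = pairs = None
    if sim_out is not None:
        results["similarity"], models, pairs = sim_out

    # bootstrap reliability maps + conjunction
    def bootstrap():
        masks = {}
        out = {}
        for m in ("NS", "FE"):
            pain, ctrl = pairs[m]
            rmap = patstats.bootstrap_weights(
                pain, ctrl,
                n_boot=config.n_boot,
                seed=_seeded(config.seed_boot, 0 if m == "NS" else 1),
                grid=grid, q=config.q, min_mm3=config.min_mm3,
            )
            write_volume(rmap.stat, grid, out_dir / f"bootstrap_z_{m}.nii.gz")
            masks[m] = rmap
            out[m] = {"n_reliable_voxels": int(rmap.thresholded_mask.sum())}
        conj = patstats.conjunction(
            masks["NS"].thresholded_mask, masks["FE"].thresholded_mask,
            masks["NS"].stat, masks["FE"].stat, require_same_sign=True,
        )
        write_volume(conj.astype(float), grid, out_dir / "bootstrap_conjunction.nii.gz")
        out["conjunction_voxels"] = int(conj.sum())
        return out

    if pairs is not None:
        results["bootstrap"] = stage("bootstrap", bootstrap)

    # specificity: pain decoders on the negative-vs-neutral contrast
    def specificity():
        return {
            m: transfer.specificity_eval(dataset, m, scheme, config.C).as_dict()
            for m in ("NS", "FE")
        }

    results["specificity"] = stage("specificity", specificity)

    # modality-general pattern + thermal transfer
    def general():
        model = decode.train_final(dataset, modalities=("NS", "FE"), C=config.C)
        write_volume(model.weights, grid, out_dir / "weights_general.nii.gz")
        thermal = simulate_thermal(
            truth,
            n_subjects=config.thermal_subjects,
            n_levels=config.thermal_levels,
            slope=config.thermal_slope,
            rating_noise=config.rating_noise,
            seed=config.seed_thermal,
        )
        series = transfer.expression_series(model, thermal)
        series.to_csv(out_dir / "thermal_expression.tsv", sep="\t", index=False)
        r_t, df_t, p_t = transfer.expression_correlation(series, "level")
        r_r, df_r, p_r = transfer.expression_correlation(series, "rating")
        lv = config.thermal_levels
        high_low = transfer.level_contrast_2afc(series, {1, 2}, {lv - 1, lv})
        out = {
            "corr_temperature": {"r": r_t, "df": df_t, "p": p_t},
            "corr_rating": {"r": r_r, "df": df_r, "p": p_r},
            "high_vs_low": high_low.as_dict(),
        }
        if models is not None:
            out["similarity_to_modality_patterns"] = {
                m: patstats.spatial_correlation(model.weights, models[m].weights)
                for m in ("NS", "FE")
            }
        return out

    results["general_pattern"] = stage("general_pattern", general)

    (out_dir / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float)
    )
    log.removeHandler(handler)
    handler.close()
    return results
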