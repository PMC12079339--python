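"""NIfTI/TSV/JSON readers-writers, voxel-space alignment, run
configuration, and the umbrella pipeline.

All volumes are NIfTI-1; stacks are 4-D images with a 3-D uint8 mask
and a TSV metadata table (one row per volume); weight maps are 3-D
images with a JSON sidecar carrying the intercept, label map and
training provenance. Tables are TSV with BIDS-flavoured column names.
Every stochastic stage draws its seed from the run configuration, so
two runs with equal configs produce byte-identical reports.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .decoder import LinearPatternModel
from .stack import MaskedImageStack, Parcellation

__all__ = [
    "save_stack",
    "load_stack",
    "save_weights",
    "load_weights",
    "save_parcellation",
    "resample_weights",
    "RunConfig",
    "run_pipeline",
]

AFFINE_ATOL = 1e-4


# ---------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------
def save_stack(stack: MaskedImageStack, prefix: str | Path) -> dict[str, Path]:
    """Write a stack as <prefix>.nii.gz + <prefix>_mask.nii.gz +
    <prefix>_meta.tsv; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vols = np.zeros(stack.grid_shape + (stack.n_obs,), dtype=np.float64)
    vols[stack.mask] = stack.data.T
    paths = {
        "data": prefix.with_name(prefix.name + ".nii.gz"),
        "mask": prefix.with_name(prefix.name + "_mask.nii.gz"),
        "meta": prefix.with_name(prefix.name + "_meta.tsv"),
    }
    nib.save(nib.Nifti1Image(vols, stack.affine), paths["data"])
    nib.save(
        nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine), paths["mask"]
    )
    stack.obs_meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


def load_stack(
    nifti_4d: str | Path, mask_nifti: str | Path, meta_tsv: str | Path
) -> MaskedImageStack:
    """Load a 4-D stack, mask and metadata table into a MaskedImageStack.

    Refuses silent problems: affine mismatch beyond 1e-4, volume/
    metadata count mismatch, NaNs in the data (listing voxels), or an
    empty mask.
    """
    img = nib.load(str(nifti_4d))
    mask_img = nib.load(str(mask_nifti))
    if not np.allclose(img.affine, mask_img.affine, atol=AFFINE_ATOL):
        raise ValueError("data and mask affines differ beyond 1e-4")
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError("mask has 0 voxels")
    data4d = np.asarray(img.dataobj, dtype=np.float64)
    if data4d.ndim == 3:
        data4d = data4d[..., None]
    meta = pd.read_csv(meta_tsv, sep="\t")
    if len(meta) != data4d.shape[3]:
        raise ValueError(
            f"metadata has {len(meta)} rows but the image has "
            f"{data4d.shape[3]} volumes"
        )
    data = data4d[mask].T
    if np.isnan(data).any():
        bad = np.argwhere(np.isnan(data))
        raise ValueError(
            f"NaNs in loaded data at (volume, voxel) {bad[:5].tolist()}"
            + ("..." if len(bad) > 5 else "")
        )
    return MaskedImageStack(data=data, mask=mask, affine=img.affine, obs_meta=meta)


# ---------------------------------------------------------------------
# weight maps
# ---------------------------------------------------------------------
def save_weights(
    model: LinearPatternModel,
    mask: np.ndarray,
    affine: np.ndarray,
    prefix: str | Path,
) -> dict[str, Path]:
    """Write a signature as a 3-D NIfTI weight map + JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vol = np.zeros(mask.shape, dtype=np.float64)
    vol[mask] = model.weights
    paths = {
        "weights": prefix.with_name(prefix.name + ".nii.gz"),
        "sidecar": prefix.with_name(prefix.name + ".json"),
    }
    nib.save(nib.Nifti1Image(vol, affine), paths["weights"])
    sidecar = {
        "intercept": model.intercept,
        "label_map": model.label_map,
        "C": model.C,
        "training_subjects": list(model.training_subjects),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths


def load_weights(
    weights_nifti: str | Path, mask: np.ndarray, sidecar: str | Path | None = None
) -> LinearPatternModel:
    """Load a weight map, restricted to ``mask``, plus optional sidecar."""
    img = nib.load(str(weights_nifti))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.shape != mask.shape:
        raise ValueError("weight map grid does not match the mask grid")
    meta = {"intercept": 0.0, "label_map": {"positive": 1, "negative": -1}, "C": 1.0,
            "training_subjects": []}
    if sidecar is not None:
        meta.update(json.loads(Path(sidecar).read_text()))
    return LinearPatternModel(
        weights=vol[np.asarray(mask, dtype=bool)],
        intercept=float(meta["intercept"]),
        label_map={k: int(v) for k, v in meta["label_map"].items()},
        C=float(meta["C"]),
        training_subjects=list(meta["training_subjects"]),
    )


def save_parcellation(
    parc: Parcellation, mask: np.ndarray, affine: np.ndarray, prefix: str | Path
) -> dict[str, Path]:
    """Write a parcellation as an integer NIfTI + TSV label table."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vol = np.zeros(mask.shape, dtype=np.int16)
    vol[np.asarray(mask, dtype=bool)] = parc.roi_labels
    paths = {
        "labels": prefix.with_name(prefix.name + ".nii.gz"),
        "table": prefix.with_name(prefix.name + "_labels.tsv"),
    }
    nib.save(nib.Nifti1Image(vol, affine), paths["labels"])
    parc.to_table().to_csv(paths["table"], sep="\t", index=False)
    return paths


def resample_weights(
    weight_img: nib.Nifti1Image | str | Path,
    target_mask_img: nib.Nifti1Image | str | Path,
    min_overlap: float = 0.10,
) -> tuple[np.ndarray, float]:
    """Nearest-neighbour resampling of a weight map onto a target grid.

    Each in-mask target voxel is mapped through the affines into the
    source grid and takes the nearest source voxel's value;
    out-of-support voxels get 0. Returns ``(vector, overlap_fraction)``
    where the overlap is the fraction of in-mask target voxels with
    in-bounds source support; below ``min_overlap`` is an error.
    """
    if not isinstance(weight_img, nib.spatialimages.SpatialImage):
        weight_img = nib.load(str(weight_img))
    if not isinstance(target_mask_img, nib.spatialimages.SpatialImage):
        target_mask_img = nib.load(str(target_mask_img))
    src = np.asarray(weight_img.dataobj, dtype=np.float64)
    mask = np.asarray(target_mask_img.dataobj) > 0
    ijk = np.argwhere(mask)  # n x 3 target voxel indices
    hom = np.c_[ijk, np.ones(len(ijk))]
    world = hom @ target_mask_img.affine.T
    src_ijk = world @ np.linalg.inv(weight_img.affine).T
    src_ijk = np.round(src_ijk[:, :3]).astype(int)
    in_bounds = np.all((src_ijk >= 0) & (src_ijk < np.array(src.shape)), axis=1)
    values = np.zeros(len(ijk))
    values[in_bounds] = src[tuple(src_ijk[in_bounds].T)]
    overlap = float(in_bounds.mean())
    if overlap < min_overlap:
        raise ValueError(
            f"only {overlap:.1%} of target voxels overlap the weight map "
            f"(minimum {min_overlap:.0%})"
        )
    return values, overlap


# ---------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------
@dataclass
class RunConfig:
    """Reference-pipeline configuration; round-trips losslessly to YAML."""

    out_dir: str = "sps_run"
    seed: int = 0
    # synthetic cohort
    grid: tuple[int, int, int] = (16, 16, 16)
    subject_count: int = 20
    noise_sd: float = 0.2
    rho_shared: float = 0.5
    trials_per_task: int = 60
    # decoding
    C: float = 1.0
    k: int = 10
    n_repeats: int = 20
    use_intercept: bool = False
    # core systems
    n_boot: int = 200
    q: float = 0.05
    haufe_per_subject: bool = True
    # observation set for the Haufe covariance: "trials" (120 per subject)
    # or "conditions" (4 per subject; too few for a stable covariance at
    # desk-scale noise, kept for parity with the condition-image protocol)
    haufe_obs: str = "trials"
    # similarity
    n_rois: int = 24
    n_networks: int = 7
    contribution_mode: str = "argmax"
    # mediation
    n_boot_mediation: int = 2000
    standardize_mediation: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid"] = list(d["grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid"] = tuple(d["grid"])
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["grid"] = list(d["grid"])
        d.pop("out_dir")  # where outputs land is not part of what was computed
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_report(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=True, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute simulate -> train -> evaluate -> core -> similarity ->
    stratify -> mediate on a synthetic cohort, writing TSV/JSON reports
    plus a provenance sidecar into ``config.out_dir``.

    Deterministic: rerunning with an equal config reproduces every
    output byte-for-byte.
    """
    from . import core as core_mod
    from . import mediation as med_mod
    from . import ratings as rat_mod
    from . import similarity as sim_mod
    from .decoder import repeated_cv_evaluate, train_signature
    from .synth import (
        SyntheticTruth,
        generate_contrast_stack,
        generate_parcellation,
        generate_trial_stack,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    truth = SyntheticTruth(
        grid_shape=config.grid,
        subject_count=config.subject_count,
        noise_sd=config.noise_sd,
        rho_shared=config.rho_shared,
        trial_counts={"exclusion": config.trials_per_task,
                      "separation": config.trials_per_task},
        seed=int(seeds[0]),
    )
    contrasts = generate_contrast_stack(truth)
    trials = generate_trial_stack(truth)
    parc = generate_parcellation(truth, config.n_rois, config.n_networks)
    save_stack(contrasts, out / "contrasts")
    save_stack(trials, out / "trials")
    save_parcellation(parc, truth.mask, truth.affine, out / "parcellation")

    specs = {
        "exclusion_vs_rest": (["exclusion"], ["inclusion", "separation", "company"]),
        "separation_vs_rest": (["separation"], ["exclusion", "inclusion", "company"]),
        "exclusion_vs_separation": (["exclusion"], ["separation"]),
        "pain_vs_nopain": (["exclusion", "separation"], ["inclusion", "company"]),
    }
    models = {}
    for name, (pos, neg) in specs.items():
        models[name] = train_signature(contrasts, pos, neg, C=config.C)
        save_weights(models[name], truth.mask, truth.affine, out / f"weights_{name}")

    cv_rows = []
    for name, (pos, neg) in specs.items():
        reports = repeated_cv_evaluate(
            contrasts, pos, neg, C=config.C, k=config.k,
            n_repeats=config.n_repeats, seed=int(seeds[1]),
            use_intercept=config.use_intercept,
        )
        for (a, b), rep in reports.items():
            cv_rows.append(
                {
                    "signature": name, "cond_a": a, "cond_b": b,
                    "accuracy_pct": rep.accuracy_mean,
                    "accuracy_sd_pct": rep.accuracy_sd,
                    "p_value": rep.p_value, "auc": rep.auc,
                    "cohens_d": rep.cohens_d, "n_subjects": rep.n_subjects,
                }
            )
    cv_table = pd.DataFrame(cv_rows).set_index("signature")
    _write_report(cv_table, out / "cv_evaluation.tsv")

    core_maps = {}
    for name in ("exclusion_vs_rest", "separation_vs_rest"):
        pos, neg = specs[name]
        bmap = core_mod.bootstrap_weights(
            contrasts, pos, neg, C=config.C, n_boot=config.n_boot,
            q=config.q, seed=int(seeds[2]),
        )
        emap = core_mod.haufe_encode(
            trials if config.haufe_obs == "trials" else contrasts,
            models[name], q=config.q,
            per_subject=config.haufe_per_subject,
        )
        cmap = core_mod.conjunction_core(bmap, emap, models[name])
        core_maps[name] = cmap
        vol = np.zeros(truth.grid_shape)
        vol[truth.mask] = cmap.core_weights
        nib.save(nib.Nifti1Image(vol, truth.affine), out / f"core_{name}.nii.gz")
        voxel_report = pd.DataFrame(
            {
                "z": bmap.z, "p_boot": bmap.p, "t_encoding": emap.t,
                "p_encoding": emap.p, "core": cmap.mask.astype(int),
            }
        )
        voxel_report.index.name = "voxel"
        _write_report(voxel_report, out / f"core_{name}_voxels.tsv")

    maps = {name: np.abs(cm.core_weights) for name, cm in core_maps.items()}
    for level in ("network", "roi"):
        dec = sim_mod.regional_cosine(maps, parc, level=level)
        _write_report(dec.cosines, out / f"similarity_cosine_{level}.tsv")
        shares = sim_mod.contribution_shares(maps, parc, level=level)
        _write_report(shares.shares, out / f"similarity_shares_{level}.tsv")

    strat = rat_mod.stratified_forced_choice(
        models["exclusion_vs_separation"], trials, "exclusion", "separation"
    )
    _write_report(
        rat_mod.accuracy_profile(strat).set_index("rating"),
        out / "rating_stratified.tsv",
    )

    med_model = LinearPatternModel(
        weights=truth.mediator_pattern, intercept=0.0,
        label_map={"exclusion": 1, "separation": -1},
    )
    med = med_mod.signature_mediation(
        trials, models["pain_vs_nopain"], med_model,
        n_boot=config.n_boot_mediation, seed=int(seeds[3]),
        standardize=config.standardize_mediation,
    )
    med_out = {
        direction: {
            "means": res.means, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p": res.p, "mediation": res.mediation_type,
            "n_subjects": res.n_subjects,
        }
        for direction, res in med.items()
    }
    (out / "mediation.json").write_text(
        json.dumps(med_out, indent=2, sort_keys=True)
    )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ["simulate", "train", "evaluate", "core", "similarity",
                   "stratify", "mediate"],
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    return {
        "truth": truth, "contrasts": contrasts, "trials": trials,
        "models": models, "cv": cv_table, "core": core_maps,
        "stratified": strat, "mediation": med, "out_dir": out,
    }
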