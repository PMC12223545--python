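"""Readers, writers, run configuration and provenance sidecars.

Conventions: tables are TSV with headers; matrices live in a single ``.npz``
container per artifact; voxel maps are NIfTI written on the input grid and
affine, with the masked-vector ↔ volume mapping (voxel linear indices, C
order) recorded once in the JSON sidecar. Every run writes a sidecar with
the config, seed, package versions and convergence info so any numeric
artifact is regenerable from its sidecar alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .connectivity import DeltaMatrix, TimecourseSet, devectorize_fnc
from .decomposition import FusionResult
from .simulate import CohortConfig, GroundTruth, SyntheticCohort

__all__ = [
    "RunConfig",
    "read_timecourses",
    "write_timecourses",
    "vector_to_nifti",
    "write_nifti_map",
    "save_cohort",
    "load_cohort",
    "save_fusion_result",
    "load_fusion_result",
    "write_sidecar",
    "save_delta_matrix",
    "load_delta_matrix",
]


@dataclass
class RunConfig:
    """Pipeline driver configuration with validated thresholds."""

    output_dir: str = "results"
    n_networks: int = 53
    domain_sizes: tuple[int, ...] = (5, 2, 9, 9, 17, 7, 4)
    k: int | str = 5  # component count or "elbow"
    seed: int = 0
    qc_thresholds: tuple[float, float, float] = (0.75, 0.55, 0.8)
    fdr_q_loadings: float = 0.05
    fdr_q_maps: float = 0.05
    fdr_q_gender: float = 0.001
    fisher_z_fnc: bool = False
    residualize_site: bool = False
    age_regression: bool = False

    def __post_init__(self) -> None:
        for name in ("fdr_q_loadings", "fdr_q_maps", "fdr_q_gender"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for v in self.qc_thresholds:
            if not 0 < v < 1:
                raise ValueError("QC thresholds must lie in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonable))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "domain_sizes" in data:
            data["domain_sizes"] = tuple(data["domain_sizes"])
        if "qc_thresholds" in data:
            data["qc_thresholds"] = tuple(data["qc_thresholds"])
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_sidecar(path: str | Path, **entries) -> None:
    """JSON provenance sidecar: config, seed, versions, convergence, ..."""
    payload = {
        "deltafuse_version": __version__,
        "numpy_version": np.__version__,
        **entries,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable, sort_keys=True))


# ---------------------------------------------------------------- timecourses

def read_timecourses(
    tc_path: str | Path,
    motion_path: str | Path | None,
    subject_id: str,
    timepoint: str,
    tr_seconds: float,
) -> TimecourseSet:
    """Load one scan's TC table (T × networks TSV) and motion TSV."""
    tc = pd.read_csv(tc_path, sep="\t").to_numpy(float)
    motion = None
    if motion_path is not None:
        motion = pd.read_csv(motion_path, sep="\t").to_numpy(float)
    return TimecourseSet(subject_id, timepoint, tc, tr_seconds, motion)


def write_timecourses(tcs: TimecourseSet, tc_path: str | Path, motion_path: str | Path | None = None) -> None:
    n = tcs.tc.shape[1]
    pd.DataFrame(tcs.tc, columns=[f"icn{i + 1:02d}" for i in range(n)]).to_csv(
        tc_path, sep="\t", index=False
    )
    if motion_path is not None and tcs.motion is not None:
        cols = ["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]
        pd.DataFrame(tcs.motion, columns=cols).to_csv(motion_path, sep="\t", index=False)


# --------------------------------------------------------------------- NIfTI

def vector_to_nifti(
    vec: np.ndarray, mask: np.ndarray, affine: np.ndarray | None = None
) -> nib.Nifti1Image:
    """Unpack a masked voxel vector into a NIfTI volume (C-order indices)."""
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) != np.asarray(vec).shape[-1]:
        raise ValueError("vector length does not match mask voxel count")
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask] = np.asarray(vec, float)
    if affine is None:
        affine = np.eye(4)
    return nib.Nifti1Image(vol, affine)


def write_nifti_map(path: str | Path, vec: np.ndarray, mask: np.ndarray, affine=None) -> None:
    nib.save(vector_to_nifti(vec, mask, affine), str(path))


# -------------------------------------------------------------------- cohort

def save_cohort(cohort: SyntheticCohort, out_dir: str | Path, config: CohortConfig | None = None) -> None:
    """Serialize a synthetic cohort: npz matrices + demographics/scores TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = cohort.truth
    np.savez_compressed(
        out / "cohort.npz",
        delta_fnc=cohort.delta_fnc,
        delta_gmv=cohort.delta_gmv,
        mask=cohort.mask,
        S_F_true=t.S_F_true,
        S_G_true=t.S_G_true,
        A_F_true=t.A_F_true,
        A_G_true=t.A_G_true,
        rho=t.rho,
        rho_sex=t.rho_sex,
        beta_score=t.beta_score,
        noise_sd=np.array(t.noise_sd),
        seed=np.array(t.seed),
        sex=t.sex.astype("U1"),
        delta_psych=cohort.delta_psych,
        delta_cog=cohort.delta_cog,
    )
    demo = cohort.demographics.copy()
    demo["delta_psych"] = cohort.delta_psych
    demo["delta_cog"] = cohort.delta_cog
    demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
    sidecar = {"seed": t.seed, "n_subjects": cohort.n_subjects}
    if config is not None:
        sidecar["config"] = asdict(config)
    write_sidecar(out / "cohort.json", **sidecar)


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    src = Path(in_dir)
    with np.load(src / "cohort.npz") as z:
        truth = GroundTruth(
            S_F_true=z["S_F_true"],
            S_G_true=z["S_G_true"],
            A_F_true=z["A_F_true"],
            A_G_true=z["A_G_true"],
            rho=z["rho"],
            rho_sex=z["rho_sex"],
            beta_score=z["beta_score"],
            noise_sd=float(z["noise_sd"]),
            seed=int(z["seed"]),
            sex=z["sex"],
        )
        delta_fnc = z["delta_fnc"]
        delta_gmv = z["delta_gmv"]
        mask = z["mask"]
        delta_psych = z["delta_psych"]
        delta_cog = z["delta_cog"]
    demo = pd.read_csv(src / "demographics.tsv", sep="\t")
    return SyntheticCohort(
        delta_fnc=delta_fnc,
        delta_gmv=delta_gmv,
        mask=mask,
        demographics=demo.drop(columns=["delta_psych", "delta_cog"]),
        delta_psych=delta_psych,
        delta_cog=delta_cog,
        truth=truth,
    )


def export_gmv_niftis(cohort: SyntheticCohort, out_dir: str | Path, affine=None) -> list[Path]:
    """Optional per-subject ΔGMV NIfTI export."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sid in enumerate(cohort.demographics["subject_id"]):
        p = out / f"{sid}_delta-gmv.nii.gz"
        write_nifti_map(p, cohort.delta_gmv[i], cohort.mask, affine)
        paths.append(p)
    return paths


# ------------------------------------------------------------- delta matrices

def save_delta_matrix(dm: DeltaMatrix, path: str | Path) -> None:
    np.savez_compressed(
        Path(path),
        data=dm.data,
        feature_space=np.array(dm.feature_space),
        subject_ids=np.array(dm.subject_ids),
        excluded=np.array(dm.excluded_subjects),
    )


def load_delta_matrix(path: str | Path) -> DeltaMatrix:
    with np.load(Path(path), allow_pickle=False) as z:
        return DeltaMatrix(
            data=z["data"],
            feature_space=str(z["feature_space"]),
            subject_ids=[str(s) for s in z["subject_ids"]],
            excluded_subjects=[str(s) for s in z["excluded"]],
        )


# ------------------------------------------------------------- fusion results

def save_fusion_result(
    result: FusionResult,
    out_dir: str | Path,
    subject_ids: list[str] | None = None,
    mask: np.ndarray | None = None,
    n_networks: int | None = None,
    affine=None,
    prefix: str = "fusion",
) -> None:
    """Write loadings TSV, sources (npz + optional TSV/NIfTI) and sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = result.k
    if subject_ids is None:
        subject_ids = [f"sub-{i:05d}" for i in range(result.A_F.shape[0])]
    cols = [f"comp{j + 1}" for j in range(k)]
    pd.DataFrame(result.A_F, index=subject_ids, columns=cols).rename_axis(
        "subject_id"
    ).to_csv(out / f"{prefix}_loadings_fnc.tsv", sep="\t", float_format="%.10g")
    arrays = {"S_F": result.S_F, "A_F": result.A_F}
    if result.A_G is not None:
        pd.DataFrame(result.A_G, index=subject_ids, columns=cols).rename_axis(
            "subject_id"
        ).to_csv(out / f"{prefix}_loadings_gmv.tsv", sep="\t", float_format="%.10g")
        arrays.update(S_G=result.S_G, A_G=result.A_G)
    if result.canonical_correlations is not None:
        arrays["canonical_correlations"] = result.canonical_correlations
    np.savez_compressed(out / f"{prefix}_sources.npz", **arrays)

    if n_networks is not None:
        for j in range(k):
            m = devectorize_fnc(result.S_F[j], n_networks)
            pd.DataFrame(m.values).to_csv(
                out / f"{prefix}_source-fnc_comp{j + 1}.tsv",
                sep="\t", index=False, header=False, float_format="%.6g",
            )
    if mask is not None and result.S_G is not None:
        for j in range(k):
            write_nifti_map(
                out / f"{prefix}_source-gmv_comp{j + 1}.nii.gz",
                result.S_G[j], mask, affine,
            )
    write_sidecar(
        out / f"{prefix}.json",
        seed=result.seed,
        k=k,
        iterations=result.iterations,
        converged=result.converged,
        canonical_correlations=result.canonical_correlations,
        meta={k_: v for k_, v in result.meta.items() if not isinstance(v, np.ndarray)},
        mask_linear_indices=(
            np.flatnonzero(np.asarray(mask, bool).ravel(order="C")) if mask is not None else None
        ),
    )


def load_fusion_result(out_dir: str | Path, prefix: str = "fusion") -> FusionResult:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{prefix}.json").read_text())
    with np.load(out / f"{prefix}_sources.npz") as z:
        return FusionResult(
            A_F=z["A_F"],
            S_F=z["S_F"],
            A_G=z["A_G"] if "A_G" in z else None,
            S_G=z["S_G"] if "S_G" in z else None,
            canonical_correlations=(
                z["canonical_correlations"] if "canonical_correlations" in z else None
            ),
            iterations=sidecar["iterations"],
            converged=sidecar["converged"],
            seed=sidecar["seed"],
        )
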