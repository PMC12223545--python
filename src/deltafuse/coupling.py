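"""Structure–function coupling maps and group / quartile contrasts.

The asymmetric arm correlates one ICA loading column against the raw ΔGMV
matrix voxel by voxel, producing a correlation map with BH-FDR-adjusted
significance. Contrasts compare such maps (or loading–loading correlation
grids in the symmetric arm) between groups — female vs male, or upper vs
lower quartile of a Δ-composite score — using the Fisher-z two-independent-
sample test per element, again FDR-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import DeltaMatrix
from .decomposition import FusionResult
from .inference import bh_fdr, fisher_z_two_sample

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingMap",
    "GroupCouplingContrast",
    "QuartileContrast",
    "voxelwise_coupling",
    "gender_contrast_asym",
    "gender_contrast_sym",
    "quartile_contrast",
]


@dataclass
class CouplingMap:
    """Per-voxel correlation between one loading column and ΔGMV."""

    component_index: int
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_mask: np.ndarray
    n_subjects_used: int
    q_threshold: float

    @property
    def n_sig(self) -> int:
        return int(self.sig_mask.sum())


@dataclass
class GroupCouplingContrast:
    """Difference of coupling between two groups (a − b, e.g. female − male)."""

    map_a: CouplingMap | np.ndarray
    map_b: CouplingMap | np.ndarray
    difference: np.ndarray
    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_mask: np.ndarray
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    q_threshold: float


@dataclass
class QuartileContrast:
    """Upper-minus-lower score-quartile coupling contrast."""

    score_name: str
    upper_map: CouplingMap
    lower_map: CouplingMap
    difference: np.ndarray
    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_mask: np.ndarray


def _column_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of vector x against every column of Y; NaN for constants."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    xn = np.linalg.norm(xc)
    yn = np.linalg.norm(yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (xn * yn)
    r[yn == 0] = np.nan
    if xn == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))


def _correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of a Pearson r under the t_{n−2} null."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def voxelwise_coupling(
    loadings_col: np.ndarray,
    delta_gmv: DeltaMatrix | np.ndarray,
    q_threshold: float = 0.05,
    component_index: int = 0,
) -> CouplingMap:
    """Voxel-wise Pearson correlation map with BH-FDR significance.

    Correlates one subject-loading column against the raw ΔGMV matrix per
    voxel; BH-FDR runs across all in-mask voxels with defined correlations,
    and the significance mask marks q < ``q_threshold``. Constant voxels are
    excluded from the family and logged.
    """
    y = delta_gmv.data if isinstance(delta_gmv, DeltaMatrix) else np.asarray(delta_gmv, float)
    x = np.asarray(loadings_col, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("loading column and ΔGMV matrix disagree on subjects")
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 subjects")
    r = _column_correlations(x, y)
    defined = np.isfinite(r)
    if not defined.all():
        logger.warning(
            "%d constant voxel(s) excluded from the FDR family", int((~defined).sum())
        )
    p = np.full(r.shape, np.nan)
    q = np.full(r.shape, np.nan)
    sig = np.zeros(r.shape, dtype=bool)
    p[defined] = _correlation_p(r[defined], n)
    if defined.any():
        q[defined], sig[defined] = bh_fdr(p[defined], q_threshold)
    return CouplingMap(
        component_index=component_index,
        r=r,
        p=p,
        q=q,
        sig_mask=sig,
        n_subjects_used=n,
        q_threshold=q_threshold,
    )


def _contrast_from_maps(
    r_a: np.ndarray,
    n_a: int,
    r_b: np.ndarray,
    n_b: int,
    q_threshold: float,
    use_raw_p: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    diff = r_a - r_b
    defined = np.isfinite(r_a) & np.isfinite(r_b)
    z = np.full(diff.shape, np.nan)
    p = np.full(diff.shape, np.nan)
    q = np.full(diff.shape, np.nan)
    sig = np.zeros(diff.shape, dtype=bool)
    z[defined], p[defined] = fisher_z_two_sample(r_a[defined], n_a, r_b[defined], n_b)
    if defined.any():
        q[defined], sig[defined] = bh_fdr(p[defined], q_threshold)
        if use_raw_p:
            sig = np.zeros(diff.shape, dtype=bool)
            sig[defined] = p[defined] < q_threshold
    return diff, z, p, q, sig


def gender_contrast_asym(
    loadings_col: np.ndarray,
    delta_gmv: DeltaMatrix | np.ndarray,
    sex: np.ndarray,
    q_threshold: float = 0.001,
    on: str = "q",
    component_index: int = 0,
) -> GroupCouplingContrast:
    """Female-minus-male voxel-wise coupling contrast (asymmetric arm).

    Computes per-sex coupling maps, their difference r_F − r_M, and a
    per-voxel Fisher-z two-sample test FDR-corrected at ``q_threshold``
    (default 0.001). ``on="p"`` thresholds the raw p instead of q.
    """
    y = delta_gmv.data if isinstance(delta_gmv, DeltaMatrix) else np.asarray(delta_gmv, float)
    sex = np.asarray(sex)
    x = np.asarray(loadings_col, float)
    f_idx = sex == "F"
    m_idx = sex == "M"
    if f_idx.sum() < 10 or m_idx.sum() < 10:
        raise ValueError("each sex group needs at least 10 subjects")
    map_f = voxelwise_coupling(x[f_idx], y[f_idx], q_threshold, component_index)
    map_m = voxelwise_coupling(x[m_idx], y[m_idx], q_threshold, component_index)
    diff, z, p, q, sig = _contrast_from_maps(
        map_f.r, map_f.n_subjects_used, map_m.r, map_m.n_subjects_used,
        q_threshold, use_raw_p=(on == "p"),
    )
    return GroupCouplingContrast(
        map_a=map_f,
        map_b=map_m,
        difference=diff,
        statistic=z,
        p=p,
        q=q,
        sig_mask=sig,
        group_labels=("F", "M"),
        group_sizes=(int(f_idx.sum()), int(m_idx.sum())),
        q_threshold=q_threshold,
    )


def _loading_pair_grid(a_g: np.ndarray, a_f: np.ndarray) -> np.ndarray:
    """k × k grid of Pearson r between GMV loading i and FNC loading j."""
    k_g, k_f = a_g.shape[1], a_f.shape[1]
    grid = np.empty((k_g, k_f))
    for i in range(k_g):
        grid[i] = _column_correlations(a_g[:, i], a_f)
    return grid


def gender_contrast_sym(
    result: FusionResult,
    sex: np.ndarray,
    q_threshold: float = 0.001,
    on: str = "q",
) -> GroupCouplingContrast:
    """Female-minus-male loading–loading coupling contrast (symmetric arm).

    For every pair (i, j) of GMV component i and FNC component j the
    within-sex Pearson correlations of the loading columns are compared via
    Fisher z, BH-FDR across the k² pairs.
    """
    if result.A_G is None:
        raise ValueError("fusion result lacks the GMV modality")
    sex = np.asarray(sex)
    f_idx = sex == "F"
    m_idx = sex == "M"
    if f_idx.sum() < 10 or m_idx.sum() < 10:
        raise ValueError("each sex group needs at least 10 subjects")
    r_f = _loading_pair_grid(result.A_G[f_idx], result.A_F[f_idx])
    r_m = _loading_pair_grid(result.A_G[m_idx], result.A_F[m_idx])
    diff, z, p, q, sig = _contrast_from_maps(
        r_f, int(f_idx.sum()), r_m, int(m_idx.sum()),
        q_threshold, use_raw_p=(on == "p"),
    )
    return GroupCouplingContrast(
        map_a=r_f,
        map_b=r_m,
        difference=diff,
        statistic=z,
        p=p,
        q=q,
        sig_mask=sig,
        group_labels=("F", "M"),
        group_sizes=(int(f_idx.sum()), int(m_idx.sum())),
        q_threshold=q_threshold,
    )


def quartile_contrast(
    loadings_col: np.ndarray,
    delta_gmv: DeltaMatrix | np.ndarray,
    scores: np.ndarray,
    q_threshold: float = 0.05,
    score_name: str = "score",
    component_index: int = 0,
) -> QuartileContrast:
    """Upper-vs-lower score-quartile coupling contrast.

    Subjects whose Δ-score falls within or below the first quartile form the
    lower group, within or above the third quartile the upper group
    (empirical quantiles, linear interpolation; ties keep all tied
    subjects). Each group gets its own FDR-corrected coupling map; the
    difference map is upper − lower with a Fisher-z test per voxel.
    """
    y = delta_gmv.data if isinstance(delta_gmv, DeltaMatrix) else np.asarray(delta_gmv, float)
    x = np.asarray(loadings_col, float)
    scores = np.asarray(scores, float)
    if scores.shape[0] != x.shape[0] or scores.shape[0] != y.shape[0]:
        raise ValueError("scores, loadings and ΔGMV disagree on subjects")
    if scores.shape[0] < 40:
        raise ValueError("need scores for at least 40 subjects")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    if q1 == q3:
        raise ValueError("degenerate score distribution: quartiles coincide")
    lower = scores <= q1
    upper = scores >= q3
    lower_map = voxelwise_coupling(x[lower], y[lower], q_threshold, component_index)
    upper_map = voxelwise_coupling(x[upper], y[upper], q_threshold, component_index)
    diff, z, p, q, sig = _contrast_from_maps(
        upper_map.r, upper_map.n_subjects_used,
        lower_map.r, lower_map.n_subjects_used,
        q_threshold, use_raw_p=False,
    )
    return QuartileContrast(
        score_name=score_name,
        upper_map=upper_map,
        lower_map=lower_map,
        difference=diff,
        statistic=z,
        p=p,
        q=q,
        sig_mask=sig,
    )
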