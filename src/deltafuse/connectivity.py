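"""Per-scan FNC estimation, QC and longitudinal Δ-matrix construction.

The functional input is one set of network time courses per scan (T × 53
after the spatially constrained ICA stage upstream). Before correlation the
time courses are cleaned in four steps: polynomial detrending (up to cubic),
despiking, regression of the six motion parameters and their first
differences, and a zero-phase 0.01–0.15 Hz bandpass. Static functional
network connectivity (FNC) is then the Pearson correlation matrix of the
cleaned columns.

Longitudinal change matrices are formed as baseline minus 2-year follow-up
(F0 − F2 and G0 − G2). Under this convention a *negative* one-sample T on a
component's loadings means the change pattern's expression increases with
age; the constant :data:`DELTA_CONVENTION` records this in one place.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DELTA_CONVENTION",
    "QC_THRESHOLDS",
    "BANDPASS_HZ",
    "TimecourseSet",
    "FNCMatrix",
    "DeltaMatrix",
    "QCReport",
    "postprocess_timecourses",
    "compute_fnc",
    "individual_mask",
    "qc_filter",
    "vectorize_fnc",
    "devectorize_fnc",
    "build_delta",
]

#: Δ = baseline − follow-up. Negative loading T ⇒ expression increases with age.
DELTA_CONVENTION = "baseline_minus_followup"

#: (top-10-slices, bottom-10-slices, whole-mask) correlation pass thresholds.
QC_THRESHOLDS = (0.75, 0.55, 0.8)

#: Zero-phase Butterworth band for time-course filtering, in Hz.
BANDPASS_HZ = (0.01, 0.15)


@dataclass
class TimecourseSet:
    """One scan's network time courses plus motion regressors."""

    subject_id: str
    timepoint: str  # "baseline" | "year2"
    tc: np.ndarray  # T × n_networks
    tr_seconds: float
    motion: np.ndarray | None = None  # T × 6 (3 rotations, 3 translations)

    def __post_init__(self) -> None:
        self.tc = np.asarray(self.tc, dtype=float)
        if self.tc.ndim != 2:
            raise ValueError("tc must be a T × n_networks matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape[0] != self.tc.shape[0]:
                raise ValueError("motion and tc row counts differ")


@dataclass
class FNCMatrix:
    """Static FNC: symmetric unit-diagonal Pearson correlation matrix."""

    values: np.ndarray  # n × n
    network_order: list[str] | None = None
    undefined: np.ndarray | None = None  # boolean per network (zero-variance)

    @property
    def n_networks(self) -> int:
        return self.values.shape[0]


@dataclass
class DeltaMatrix:
    """Subjects × features longitudinal change matrix."""

    data: np.ndarray
    feature_space: str  # "fnc_cells" | "gmv_voxels"
    subject_ids: list[str]
    feature_index: np.ndarray | None = None  # cell (i,j) pairs or voxel coords
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass
class QCReport:
    """Mask-agreement QC for one scan."""

    scan_id: str
    r_top10: float
    r_bottom10: float
    r_whole: float

    @property
    def passed(self) -> bool:
        t, b, w = QC_THRESHOLDS
        return self.r_top10 > t and self.r_bottom10 > b and self.r_whole > w


def _detrend_poly(x: np.ndarray, degree: int = 3) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, x.shape[0])
    basis = np.vander(t, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ beta


def _despike(x: np.ndarray, z_thresh: float = 3.0) -> np.ndarray:
    """Replace |robust z| > 3 samples by cubic-spline interpolation."""
    out = x.copy()
    t = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        col = out[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        scale = 1.4826 * mad if mad > 0 else np.std(col)
        if scale == 0:
            continue
        bad = np.abs(col - med) / scale > z_thresh
        if not bad.any() or bad.all():
            continue
        good = ~bad
        if good.sum() >= 4:
            spl = interpolate.CubicSpline(t[good], col[good])
            col[bad] = spl(t[bad])
        else:
            col[bad] = np.interp(t[bad], t[good], col[good])
    return out


def _regress_out(x: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(x.shape[0]), regressors])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def bandpass_sos(tr_seconds: float, order: int = 5, band: tuple[float, float] = BANDPASS_HZ):
    """Second-order sections for the zero-phase Butterworth bandpass."""
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    lo, hi = band
    if hi >= nyq:
        raise ValueError(
            f"bandpass upper edge {hi} Hz is not below Nyquist {nyq:.3f} Hz at TR {tr_seconds}s"
        )
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def postprocess_timecourses(
    tcs: TimecourseSet,
    detrend_degree: int = 3,
    z_thresh: float = 3.0,
    filter_order: int = 5,
    band: tuple[float, float] = BANDPASS_HZ,
) -> TimecourseSet:
    """Clean network time courses in four ordered steps.

    1. remove polynomial trends up to ``detrend_degree`` (cubic),
    2. replace outlier samples (robust z > ``z_thresh``) by spline
       interpolation of their neighbours,
    3. regress out the motion parameters and their first differences,
    4. zero-phase Butterworth bandpass over ``band`` (0.01–0.15 Hz).
    """
    x = np.asarray(tcs.tc, dtype=float)
    sos = bandpass_sos(tcs.tr_seconds, order=filter_order, band=band)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= padlen:
        raise ValueError(
            f"time series too short for stable zero-phase filtering: need "
            f"T > {padlen} samples at filter order {filter_order}, got {x.shape[0]}"
        )

    x = _detrend_poly(x, degree=detrend_degree)
    x = _despike(x, z_thresh=z_thresh)
    if tcs.motion is not None:
        dmotion = np.diff(tcs.motion, axis=0, prepend=tcs.motion[:1])
        # polynomial basis kept in the design so motion removal is an exact
        # projection even after the earlier detrending pass
        t = np.linspace(-1.0, 1.0, x.shape[0])
        trends = np.vander(t, detrend_degree + 1, increasing=True)[:, 1:]
        x = _regress_out(x, np.column_stack([tcs.motion, dmotion, trends]))
    x = signal.sosfiltfilt(sos, x, axis=0)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values after postprocessing")
    return TimecourseSet(tcs.subject_id, tcs.timepoint, x, tcs.tr_seconds, tcs.motion)


def compute_fnc(tcs: TimecourseSet, network_order: list[str] | None = None) -> FNCMatrix:
    """Pearson-correlation FNC of (postprocessed) time courses.

    Zero-variance columns yield undefined correlations: the affected rows /
    columns are set to NaN (diagonal kept at 1) and flagged in
    ``FNCMatrix.undefined``.
    """
    x = np.asarray(tcs.tc, dtype=float)
    sd = x.std(axis=0)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.asarray(c, dtype=float)
    if zero_var.any():
        logger.warning(
            "%d zero-variance network time course(s); correlations set undefined",
            int(zero_var.sum()),
        )
        c[zero_var, :] = np.nan
        c[:, zero_var] = np.nan
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    finite = np.isfinite(c)
    c[finite] = np.clip(c[finite], -1.0, 1.0)
    return FNCMatrix(values=c, network_order=network_order, undefined=zero_var)


def individual_mask(first_volume: np.ndarray) -> np.ndarray:
    """Voxels exceeding 90% of the whole-brain mean of the first volume."""
    vol = np.asarray(first_volume, dtype=float)
    return vol > 0.9 * vol.mean()


def _slab_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two binary slabs with a defined degenerate limit."""
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(stats.pearsonr(a, b).statistic)


def qc_filter(
    individual_masks: dict[str, np.ndarray],
    group_mask: np.ndarray | None = None,
    agreement: float = 0.9,
    n_slices: int = 10,
) -> list[QCReport]:
    """Mask-agreement QC of normalized scans.

    The group mask marks voxels present in more than ``agreement`` (90%) of
    the individual masks. Each scan's mask is correlated with the group mask
    over the top ``n_slices`` axial slices, the bottom ``n_slices`` slices,
    and the whole volume; a scan passes at (0.75, 0.55, 0.8).
    """
    ids = list(individual_masks)
    if not ids:
        raise ValueError("no masks supplied")
    shapes = {np.asarray(m).shape for m in individual_masks.values()}
    if len(shapes) != 1:
        raise ValueError("all masks must share one grid")
    shape = shapes.pop()
    if len(shape) != 3 or shape[2] < 2 * n_slices:
        raise ValueError(
            f"need a 3D grid with at least {2 * n_slices} axial slices, got {shape}"
        )
    stack = np.stack([np.asarray(individual_masks[i], dtype=bool) for i in ids])
    if group_mask is None:
        group_mask = stack.mean(axis=0) > agreement
    reports = []
    top = slice(shape[2] - n_slices, shape[2])
    bottom = slice(0, n_slices)
    for i, scan_id in enumerate(ids):
        m = stack[i]
        reports.append(
            QCReport(
                scan_id=scan_id,
                r_top10=_slab_corr(m[:, :, top], group_mask[:, :, top]),
                r_bottom10=_slab_corr(m[:, :, bottom], group_mask[:, :, bottom]),
                r_whole=_slab_corr(m, group_mask),
            )
        )
    return reports


def vectorize_fnc(m: FNCMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (excl. diagonal) of a symmetric matrix."""
    values = m.values if isinstance(m, FNCMatrix) else np.asarray(m, dtype=float)
    finite = np.isfinite(values)
    if not np.allclose(
        np.where(finite, values, 0.0), np.where(finite.T, values.T, 0.0), atol=1e-10
    ):
        raise ValueError("matrix must be symmetric")
    iu = np.triu_indices(values.shape[0], 1)
    return values[iu]


def devectorize_fnc(v: np.ndarray, n: int) -> FNCMatrix:
    """Inverse of :func:`vectorize_fnc`; unit diagonal restored."""
    v = np.asarray(v, dtype=float)
    expected = n * (n - 1) // 2
    if v.shape[0] != expected:
        raise ValueError(f"vector length {v.shape[0]} != n(n-1)/2 = {expected}")
    out = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    out[iu] = v
    out = out + out.T
    np.fill_diagonal(out, 1.0)
    return FNCMatrix(values=out)


def build_delta(
    first: pd.DataFrame | dict[str, np.ndarray],
    second: pd.DataFrame | dict[str, np.ndarray],
    space: str,
    feature_index: np.ndarray | None = None,
) -> DeltaMatrix:
    """Baseline-minus-follow-up change matrix over overlapping subjects.

    ``first`` holds baseline feature vectors per subject, ``second`` the
    2-year follow-up; rows are F0 − F2 (or G0 − G2). Subjects missing either
    timepoint are excluded and logged.
    """
    if isinstance(first, dict):
        first = pd.DataFrame({k: np.asarray(v) for k, v in first.items()}).T
    if isinstance(second, dict):
        second = pd.DataFrame({k: np.asarray(v) for k, v in second.items()}).T
    common = [s for s in first.index if s in set(second.index)]
    excluded = sorted(
        (set(first.index) | set(second.index)) - set(common), key=str
    )
    if not common:
        raise ValueError("no subjects present at both timepoints")
    if first.shape[1] != second.shape[1]:
        raise ValueError("feature spaces of the two timepoints differ")
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} subject(s) missing a timepoint: "
            f"{excluded[:5]}{'...' if len(excluded) > 5 else ''}",
            stacklevel=2,
        )
    delta = first.loc[common].to_numpy(float) - second.loc[common].to_numpy(float)
    return DeltaMatrix(
        data=delta,
        feature_space=space,
        subject_ids=[str(s) for s in common],
        feature_index=feature_index,
        excluded_subjects=[str(s) for s in excluded],
    )
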