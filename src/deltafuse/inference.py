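"""Loading-level statistics: t-tests, BH-FDR, Fisher-z, site residuals.

Direction semantics follow the Δ = baseline − follow-up convention: a
significantly *negative* one-sample T on a loading column means the change
pattern's expression increases with age, a positive T a decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import DELTA_CONVENTION
from .decomposition import FusionResult

__all__ = [
    "TestResult",
    "one_sample_t",
    "two_sample_t_by_group",
    "bh_fdr",
    "fisher_z_two_sample",
    "residualize_site",
    "summarize_loading_tests",
    "label_direction",
]

INCREASE = "increase-with-age"
DECREASE = "decrease-with-age"
NS = "n.s."


@dataclass
class TestResult:
    statistic: float
    dof: float
    p: float
    q: float
    direction: str

    def as_dict(self) -> dict:
        return {
            "T": self.statistic,
            "dof": self.dof,
            "p": self.p,
            "q": self.q,
            "direction": self.direction,
        }


def label_direction(statistic: float, q: float, threshold: float = 0.05) -> str:
    """Age-direction label under the Δ = F0 − F2 sign convention."""
    assert DELTA_CONVENTION == "baseline_minus_followup"
    if q >= threshold:
        return NS
    return INCREASE if statistic < 0 else DECREASE


def one_sample_t(loadings_col: np.ndarray, q_threshold: float = 0.05) -> TestResult:
    """One-sample t-test of a loading column against zero.

    Returned ``q`` equals the raw two-sided p (a single test is its own
    family); :func:`summarize_loading_tests` re-adjusts across the full
    modality × component family.
    """
    x = np.asarray(loadings_col, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero-variance loading column")
    res = stats.ttest_1samp(x, 0.0)
    t, p = float(res.statistic), float(res.pvalue)
    return TestResult(t, float(x.size - 1), p, p, label_direction(t, p, q_threshold))


def two_sample_t_by_group(
    loadings_col: np.ndarray, labels: np.ndarray, q_threshold: float = 0.05
) -> TestResult:
    """Welch two-sample t-test between the two label groups (e.g. sex)."""
    x = np.asarray(loadings_col, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)  # sorted: ("F", "M") tests female − male
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {len(levels)}")
    a, b = x[labels == levels[0]], x[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    dof = float(res.df)
    direction = NS if p >= q_threshold else (INCREASE if t < 0 else DECREASE)
    return TestResult(t, dof, p, p, direction)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted q-values and rejections at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return q_adj.reshape(p.shape), reject.reshape(p.shape)


def fisher_z_two_sample(
    r1: np.ndarray, n1: int, r2: np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z test for the difference of two independent correlations.

    Returns (z statistic, two-sided p), vectorized over correlation arrays.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need at least 4 observations per group")
    eps = 1e-12
    r1 = np.clip(np.asarray(r1, float), -1 + eps, 1 - eps)
    r2 = np.clip(np.asarray(r2, float), -1 + eps, 1 - eps)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def residualize_site(loadings: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Remove additive site effects from each loading column.

    Deviation-coded least-squares projection: per-site mean differences are
    removed while the grand mean is preserved, so loading-level tests against
    zero keep their target effect (the with/without-site robustness check
    stays meaningful). Sites with fewer than two subjects are excluded from
    the site design with a warning. Requires at least two modeled sites.
    """
    x = np.atleast_2d(np.asarray(loadings, dtype=float))
    if x.shape[0] == 1 and np.asarray(site).shape[0] != 1:
        x = x.T
    site = np.asarray(site)
    levels, counts = np.unique(site, return_counts=True)
    valid = levels[counts >= 2]
    if len(valid) < len(levels):
        warnings.warn(
            f"dropping {len(levels) - len(valid)} singleton site(s) from the site design"
        )
    if len(valid) < 2:
        raise ValueError("need at least 2 sites with >= 2 subjects each")
    dummies = np.column_stack([(site == lv).astype(float) for lv in valid])
    design = dummies - dummies.mean(axis=0)  # deviation coding
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def summarize_loading_tests(
    result: FusionResult,
    sex: np.ndarray | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Loading-level test table across modalities and components.

    One-sample t-tests per modality × component, BH-FDR-corrected jointly
    across that family, with age-direction labels; optionally a Welch
    two-sample sex contrast per column (its own FDR family).
    """
    rows = []
    modalities = [("FNC", result.A_F)]
    if result.A_G is not None:
        modalities.append(("GMV", result.A_G))
    for name, a in modalities:
        for j in range(a.shape[1]):
            tr = one_sample_t(a[:, j], q_threshold)
            rows.append(
                {
                    "modality": name,
                    "component": j + 1,
                    "test": "one_sample_t",
                    "T": tr.statistic,
                    "dof": tr.dof,
                    "p": tr.p,
                }
            )
    table = pd.DataFrame(rows)
    table["q"], _ = bh_fdr(table["p"].to_numpy(), q_threshold)
    table["direction"] = [
        label_direction(t, qv, q_threshold) for t, qv in zip(table["T"], table["q"])
    ]

    if sex is not None:
        sex_rows = []
        for name, a in modalities:
            for j in range(a.shape[1]):
                tr = two_sample_t_by_group(a[:, j], sex, q_threshold)
                sex_rows.append(
                    {
                        "modality": name,
                        "component": j + 1,
                        "test": "two_sample_t_sex",
                        "T": tr.statistic,
                        "dof": tr.dof,
                        "p": tr.p,
                    }
                )
        sex_table = pd.DataFrame(sex_rows)
        sex_table["q"], _ = bh_fdr(sex_table["p"].to_numpy(), q_threshold)
        sex_table["direction"] = NS
        table = pd.concat([table, sex_table], ignore_index=True)
    return table
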