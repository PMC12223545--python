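"""Synthetic linked multimodal cohorts with known ground truth.

Generates subject × cell ΔFNC and subject × voxel ΔGMV change matrices as
low-rank mixtures ``A @ S`` plus Gaussian noise, with

* block-modular connectivity sources (functional change patterns) laid out
  over a partition of networks into functional domains,
* compact Gaussian-blob sources (structural change patterns) on a 3D grid,
* per-component cross-modal correlation ``rho`` between the loading columns
  of the two modalities, optionally offset by ``rho_sex`` for females,
* linear links from selected loading columns to Δ-composite
  psychopathology / cognition scores.

Everything is a deterministic function of an integer seed, so recovery tests
can compare estimates against the stored truth bit-for-bit across reruns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NEUROMARK_DOMAINS",
    "DEFAULT_DOMAIN_SIZES",
    "GroundTruth",
    "SyntheticCohort",
    "CohortConfig",
    "make_fcp_sources",
    "make_scp_sources",
    "sample_linked_loadings",
    "make_ground_truth",
    "assemble_cohort",
    "simulate_cohort",
]

# 53 intrinsic connectivity networks grouped into 7 functional domains
# (subcortical, auditory, sensorimotor, visual, cognitive control, default
# mode, cerebellar). The sizes are a configurable default, not a fixed fact.
NEUROMARK_DOMAINS: dict[str, int] = {
    "subcortical": 5,
    "auditory": 2,
    "sensorimotor": 9,
    "visual": 9,
    "cognitive_control": 17,
    "default_mode": 7,
    "cerebellar": 4,
}
DEFAULT_DOMAIN_SIZES: tuple[int, ...] = tuple(NEUROMARK_DOMAINS.values())


class InvalidConfiguration(ValueError):
    """Raised when generator parameters are internally inconsistent."""


@dataclass
class GroundTruth:
    """Planted sources, loadings and effect sizes of one synthetic cohort."""

    S_F_true: np.ndarray  # k × n_cells
    S_G_true: np.ndarray  # k × n_voxels
    A_F_true: np.ndarray  # n_subjects × k
    A_G_true: np.ndarray  # n_subjects × k
    rho: np.ndarray  # length k, cross-modal loading correlation (males / base)
    rho_sex: np.ndarray  # length k, female-minus-male coupling offset
    beta_score: np.ndarray  # k × 2, linear effect on (delta_psych, delta_cog)
    noise_sd: float
    seed: int
    sex: np.ndarray = field(default=None)  # per-subject {"F","M"}

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.rho_sex = np.asarray(self.rho_sex, dtype=float)
        if np.any(np.abs(self.rho) > 1) or np.any(np.abs(self.rho + self.rho_sex) > 1):
            raise InvalidConfiguration(
                "rho and rho + rho_sex must both lie in [-1, 1] per component"
            )
        for name in ("S_F_true", "S_G_true"):
            S = getattr(self, name)
            if np.any(np.all(S == 0, axis=1)):
                raise InvalidConfiguration(f"{name} contains an all-zero source row")

    @property
    def k(self) -> int:
        return self.S_F_true.shape[0]


@dataclass
class SyntheticCohort:
    """Generated ΔFNC + ΔGMV matrices with demographics, scores and truth."""

    delta_fnc: np.ndarray  # n_subjects × n_cells
    delta_gmv: np.ndarray  # n_subjects × n_voxels
    mask: np.ndarray  # 3D boolean grid; mask.sum() == n_voxels
    demographics: pd.DataFrame  # subject_id, sex, age_months_t0/_t2, site
    delta_psych: np.ndarray
    delta_cog: np.ndarray
    truth: GroundTruth

    @property
    def n_subjects(self) -> int:
        return self.delta_fnc.shape[0]

    @property
    def sex(self) -> np.ndarray:
        return self.demographics["sex"].to_numpy()


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the connectivity layout analysed in practice: 53 networks
    in 7 domains (1378 FNC cells), a 12×14×12 grid (2016 voxels, full mask),
    k = 5 linked components with cross-modal loading correlation 0.5 and
    residual noise at SD 0.2 relative to unit-variance loadings.
    """

    n_subjects: int = 500
    n_networks: int = 53
    domain_sizes: tuple[int, ...] = DEFAULT_DOMAIN_SIZES
    grid_shape: tuple[int, int, int] = (12, 14, 12)
    k: int = 5
    rho: float | np.ndarray = 0.5
    rho_sex: float | np.ndarray = 0.0
    beta_score: np.ndarray | None = None  # default ties psych→comp 3, cog→comp 1
    noise_sd: float = 0.2
    score_noise_sd: float = 1.0
    n_sites: int = 4
    seed: int = 0

    def rho_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.rho, float), (self.k,)).copy()

    def rho_sex_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.rho_sex, float), (self.k,)).copy()

    def beta_matrix(self) -> np.ndarray:
        if self.beta_score is not None:
            beta = np.asarray(self.beta_score, dtype=float)
            if beta.shape != (self.k, 2):
                raise InvalidConfiguration(
                    f"beta_score must be k × 2 = {self.k} × 2, got {beta.shape}"
                )
            return beta
        beta = np.zeros((self.k, 2))
        beta[min(3, self.k - 1), 0] = 0.5  # psychopathology link
        beta[min(1, self.k - 1), 1] = 0.5  # cognition link
        return beta


def _domain_blocks(n_domains: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_domains) for j in range(i, n_domains)]


def make_fcp_sources(
    n_networks: int,
    domain_sizes: tuple[int, ...] | list[int],
    k: int,
    seed: int,
    blocks_per_source: tuple[int, int] = (2, 3),
) -> np.ndarray:
    """Block-modular functional-change sources in FNC cell space.

    Each source is the row-major upper-triangle vectorization of a symmetric
    zero-diagonal n×n matrix whose nonzero entries fill a handful of
    domain-by-domain blocks; block amplitude is constant × Uniform(0.5, 1)
    with a random sign per block. Components draw disjoint block supports,
    so distinct sources are exactly orthogonal.

    Returns a k × n_cells array, n_cells = n_networks(n_networks−1)/2.
    """
    domain_sizes = tuple(int(s) for s in domain_sizes)
    if sum(domain_sizes) != n_networks:
        raise InvalidConfiguration(
            f"domain_sizes sum {sum(domain_sizes)} != n_networks {n_networks}"
        )
    if k < 1:
        raise InvalidConfiguration("k must be >= 1")
    rng = np.random.default_rng(seed)
    n_domains = len(domain_sizes)
    blocks = _domain_blocks(n_domains)
    lo, hi = blocks_per_source
    hi = min(hi, len(blocks) // k)  # keep supports disjoint
    lo = min(lo, hi)
    if hi < 1:
        raise InvalidConfiguration(
            f"{k} sources exceed the {len(blocks)} available domain-pair "
            "blocks; reduce k or use a finer domain partition"
        )
    starts = np.concatenate([[0], np.cumsum(domain_sizes)])
    order = rng.permutation(len(blocks))
    iu = np.triu_indices(n_networks, 1)

    sources = np.zeros((k, len(iu[0])))
    pos = 0
    for comp in range(k):
        n_blocks = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        mat = np.zeros((n_networks, n_networks))
        for b in range(n_blocks):
            di, dj = blocks[order[pos]]
            pos += 1
            amp = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            sl_i = slice(starts[di], starts[di + 1])
            sl_j = slice(starts[dj], starts[dj + 1])
            mat[sl_i, sl_j] = amp
            mat[sl_j, sl_i] = amp
        np.fill_diagonal(mat, 0.0)
        sources[comp] = mat[iu]
    return sources


def make_scp_sources(
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    k: int,
    seed: int,
    n_blobs: tuple[int, int] = (1, 3),
    sigma_range: tuple[float, float] = (1.5, 2.5),
) -> np.ndarray:
    """Structural-change sources: sums of Gaussian blobs inside a brain mask.

    Each source is 1–3 isotropic Gaussian blobs centred on in-mask voxels,
    peak-normalized to 1, returned as the masked voxel vector (k × n_voxels).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(grid_shape):
        raise InvalidConfiguration(f"mask shape {mask.shape} != grid {grid_shape}")
    if not mask.any():
        raise InvalidConfiguration("mask is empty")
    if k < 1:
        raise InvalidConfiguration("k must be >= 1")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)  # n_voxels × 3
    grid = np.indices(grid_shape).reshape(3, -1).T[mask.ravel()]  # == coords

    lo, hi = n_blobs
    sources = np.zeros((k, coords.shape[0]))
    for comp in range(k):
        nb = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        vol = np.zeros(coords.shape[0])
        for _ in range(nb):
            center = coords[rng.integers(coords.shape[0])]
            sigma = rng.uniform(*sigma_range)
            d2 = np.sum((grid - center) ** 2, axis=1)
            vol += np.exp(-d2 / (2.0 * sigma**2))
        sources[comp] = vol / vol.max()
    return sources


def sample_linked_loadings(
    n_subjects: int,
    k: int,
    rho: np.ndarray,
    rho_sex: np.ndarray,
    sex: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw cross-modally correlated loading matrices (A_F, A_G).

    Per component j the pair of loading columns is bivariate normal with unit
    variances and correlation ``rho[j] + rho_sex[j]`` for females and
    ``rho[j]`` for males; distinct components are independent.
    """
    rho = np.broadcast_to(np.asarray(rho, float), (k,))
    rho_sex = np.broadcast_to(np.asarray(rho_sex, float), (k,))
    sex = np.asarray(sex)
    if sex.shape[0] != n_subjects:
        raise InvalidConfiguration("sex labels must have n_subjects entries")
    r_f = rho + rho_sex
    if np.any(np.abs(rho) > 1) or np.any(np.abs(r_f) > 1):
        raise InvalidConfiguration("implied correlations must lie in [-1, 1]")

    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal((n_subjects, k))
    z2 = rng.standard_normal((n_subjects, k))
    is_f = (sex == "F")[:, None]
    r = np.where(is_f, r_f[None, :], rho[None, :])
    a_f = z1
    a_g = r * z1 + np.sqrt(1.0 - r**2) * z2
    return a_f, a_g


def make_ground_truth(config: CohortConfig) -> GroundTruth:
    """Generate sources, sex labels and linked loadings for a config."""
    rng = np.random.default_rng(config.seed)
    # Independent child streams so each piece is reproducible in isolation.
    seed_fcp, seed_scp, seed_load, seed_sex = rng.integers(0, 2**31 - 1, size=4)

    sex_rng = np.random.default_rng(seed_sex)
    n_f = config.n_subjects // 2
    sex = np.array(["F"] * n_f + ["M"] * (config.n_subjects - n_f))
    sex_rng.shuffle(sex)

    S_F = make_fcp_sources(
        config.n_networks, config.domain_sizes, config.k, int(seed_fcp)
    )
    mask = np.ones(config.grid_shape, dtype=bool)
    S_G = make_scp_sources(config.grid_shape, mask, config.k, int(seed_scp))
    A_F, A_G = sample_linked_loadings(
        config.n_subjects,
        config.k,
        config.rho_vector(),
        config.rho_sex_vector(),
        sex,
        int(seed_load),
    )
    return GroundTruth(
        S_F_true=S_F,
        S_G_true=S_G,
        A_F_true=A_F,
        A_G_true=A_G,
        rho=config.rho_vector(),
        rho_sex=config.rho_sex_vector(),
        beta_score=config.beta_matrix(),
        noise_sd=config.noise_sd,
        seed=config.seed,
        sex=sex,
    )


def assemble_cohort(truth: GroundTruth, config: CohortConfig) -> SyntheticCohort:
    """Mix planted truth into data matrices, demographics and Δ-scores."""
    n, k = truth.A_F_true.shape
    if truth.S_F_true.shape[0] != k or truth.S_G_true.shape[0] != k:
        raise InvalidConfiguration("loading / source component counts disagree")
    if truth.sex is None or len(truth.sex) != n:
        raise InvalidConfiguration("truth.sex must hold one label per subject")

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5EED]))
    delta_fnc = truth.A_F_true @ truth.S_F_true
    delta_gmv = truth.A_G_true @ truth.S_G_true
    if truth.noise_sd > 0:
        delta_fnc = delta_fnc + truth.noise_sd * rng.standard_normal(delta_fnc.shape)
        delta_gmv = delta_gmv + truth.noise_sd * rng.standard_normal(delta_gmv.shape)

    scores = truth.A_F_true @ truth.beta_score  # n × 2
    scores = scores + config.score_noise_sd * rng.standard_normal(scores.shape)

    age_t0 = rng.normal(119.0, 8.0, size=n).round()  # months, baseline ~9.9 y
    age_t2 = age_t0 + rng.normal(24.0, 1.5, size=n).round()
    site = rng.integers(0, config.n_sites, size=n)
    demographics = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:05d}" for i in range(n)],
            "sex": truth.sex,
            "age_months_t0": age_t0.astype(int),
            "age_months_t2": age_t2.astype(int),
            "site": [f"site{s:02d}" for s in site],
        }
    )
    mask = np.ones(config.grid_shape, dtype=bool)
    return SyntheticCohort(
        delta_fnc=delta_fnc,
        delta_gmv=delta_gmv,
        mask=mask,
        demographics=demographics,
        delta_psych=scores[:, 0],
        delta_cog=scores[:, 1],
        truth=truth,
    )


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Convenience wrapper: config → ground truth → assembled cohort."""
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    return assemble_cohort(make_ground_truth(config), config)
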