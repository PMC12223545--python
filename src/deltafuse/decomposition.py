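"""Matrix-factorization core for change-matrix fusion.

Two arms share this module:

* **asymmetric** — infomax ICA on a single change matrix ``X ≈ A·S``
  (subjects × features), with A recovered through the de-whitening
  transform; downstream the loadings A are correlated voxel-wise against the
  other modality's raw data.
* **symmetric** — mCCA + joint ICA on two change matrices sharing the
  subject dimension: per-modality feature PCA to k, multiset CCA aligning
  the score matrices into maximally correlated canonical variates, then one
  ICA on the horizontally concatenated associated maps so both modalities
  share a mixing structure: ``X_k ≈ A_k·S_k`` with ``A_k = D_k·W⁻¹``.

mCCA maximizes the SSQCOR objective (sum of squared pairwise correlations
between same-index variates) by stage-wise deflation; with exactly two sets
this reduces to classical CCA, which serves as the closed-form oracle in
the tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import DeltaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "FusionResult",
    "MCCAResult",
    "select_components_elbow",
    "infomax_ica",
    "mcca",
    "mcca_jica",
    "fix_signs_and_order",
]


@dataclass
class PCAModel:
    """Channel-space PCA with explicit whitening / de-whitening transforms.

    Fit on an (n_channels × n_samples) matrix; ``project`` maps centred data
    to k whitened rows (identity covariance), ``back_project`` inverts on
    the retained subspace.
    """

    mean: np.ndarray  # per-channel mean (n_channels,)
    eigenvalues: np.ndarray  # descending, length k
    whitening: np.ndarray  # k × n_channels
    dewhitening: np.ndarray  # n_channels × k

    @classmethod
    def fit(cls, x: np.ndarray, k: int) -> "PCAModel":
        x = np.asarray(x, dtype=float)
        n_ch, n_s = x.shape
        mean = x.mean(axis=1)
        xc = x - mean[:, None]
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        ev = s**2 / n_s
        if k > np.sum(s > s[0] * 1e-12):
            raise ValueError(f"requested k={k} exceeds numerical rank {int(np.sum(s > s[0] * 1e-12))}")
        d = np.sqrt(ev[:k])
        whitening = (u[:, :k] / d).T  # k × n_ch
        dewhitening = u[:, :k] * d  # n_ch × k
        return cls(mean=mean, eigenvalues=ev[:k], whitening=whitening, dewhitening=dewhitening)

    def project(self, x: np.ndarray) -> np.ndarray:
        return self.whitening @ (np.asarray(x, float) - self.mean[:, None])

    def back_project(self, z: np.ndarray) -> np.ndarray:
        return self.dewhitening @ z + self.mean[:, None]


@dataclass
class FusionResult:
    """Loadings and sources of one fusion run (one or two modalities)."""

    A_F: np.ndarray  # n_subjects × k
    S_F: np.ndarray  # k × n_cells
    A_G: np.ndarray | None = None  # n_subjects × k
    S_G: np.ndarray | None = None  # k × n_voxels
    canonical_correlations: np.ndarray | None = None  # symmetric arm only
    iterations: int = 0
    converged: bool = True
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.S_F.shape[0]

    @property
    def is_multimodal(self) -> bool:
        return self.S_G is not None


@dataclass
class MCCAResult:
    """Canonical variates and transforms from multiset CCA."""

    variates: list[np.ndarray]  # per set: n × k canonical variates D
    weights: list[np.ndarray]  # per set: p_i × k (original feature space)
    canonical_correlations: np.ndarray  # length k (mean pairwise r per index)


def select_components_elbow(eigenvalues: np.ndarray, override: int | None = None) -> int:
    """Model order at the elbow of the sorted eigenvalue curve.

    The elbow is the point of maximum perpendicular distance from the
    normalized (x, λ) curve to the chord joining its endpoints. ``override``
    short-circuits the heuristic (the reference analysis fixed k = 5 for
    both modalities).
    """
    if override is not None:
        if override < 1:
            raise ValueError("override must be >= 1")
        return int(override)
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 3:
        raise ValueError("need at least 3 eigenvalues")
    if np.any(ev <= 0):
        raise ValueError("eigenvalues must be positive")
    if np.any(np.diff(ev) > 1e-12 * ev[0]):
        raise ValueError("eigenvalues must be in descending order")
    n = ev.size
    x = np.linspace(0.0, 1.0, n)
    span = ev[0] - ev[-1]
    if span <= 1e-12 * ev[0]:
        warnings.warn("flat eigenvalue spectrum; elbow undefined, returning 1")
        return 1
    y = (ev - ev[-1]) / span
    # distance from each point to the chord (0,1)-(1,0): |x + y - 1| / sqrt(2)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    if dist.max() < 1e-9:
        warnings.warn("linear eigenvalue spectrum; elbow undefined, returning 1")
        return 1
    return int(np.argmax(dist)) + 1  # 1-based component count


def _random_orthogonal(k: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((k, k)))
    return q * np.sign(np.diag(r))


def _infomax_core(
    z: np.ndarray,
    seed: int | None,
    lr: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 2048,
    anneal: float = 0.9,
) -> tuple[np.ndarray, int, bool]:
    """Natural-gradient infomax with logistic nonlinearity on whitened data.

    ``z`` is k × N with identity covariance. Returns the square unmixing
    matrix W (sources = W @ z), the iteration count and a convergence flag.
    The learning rate anneals by ``anneal`` whenever successive weight
    updates turn by more than 60°, the usual heuristic against oscillation.
    """
    k, n = z.shape
    rng = np.random.default_rng(seed)
    w = _random_orthogonal(k, rng)
    eye = np.eye(k)
    prev_delta = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = w @ z
        y = 1.0 / (1.0 + np.exp(-u))
        grad = (eye + (1.0 - 2.0 * y) @ u.T / n) @ w
        delta = lr * grad
        if not np.all(np.isfinite(delta)):
            lr *= 0.5
            w = _random_orthogonal(k, rng)
            prev_delta = None
            continue
        if prev_delta is not None:
            num = float(np.sum(delta * prev_delta))
            den = float(np.linalg.norm(delta) * np.linalg.norm(prev_delta))
            if den > 0 and num / den < 0.5:  # turn > 60°
                lr *= anneal
        w = w + delta
        change = float(np.max(np.abs(delta)))
        prev_delta = delta
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"infomax did not converge within {max_iter} iterations")
    return w, it, converged


def infomax_ica(
    x: np.ndarray | DeltaMatrix,
    k: int,
    seed: int | None = None,
    lr: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 2048,
) -> FusionResult:
    """Single-modality ICA decomposition ``X ≈ A·S`` of a change matrix.

    Subjects are the mixture channels: the matrix is reduced to k whitened
    rows by PCA over subjects, infomax estimates the square unmixing W, the
    sources are ``S = W·Z`` and the subject loadings come back through the
    de-whitening transform ``A = K⁺·W⁻¹``.
    """
    if isinstance(x, DeltaMatrix):
        x = x.data
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than components ({k})")
    if p < k:
        raise ValueError("need at least k features")
    pca = PCAModel.fit(x, k)
    z = pca.project(x)  # k × p, identity covariance
    w, iters, converged = _infomax_core(z, seed, lr=lr, tol=tol, max_iter=max_iter)
    s = w @ z
    a = pca.dewhitening @ np.linalg.inv(w)  # n × k
    result = FusionResult(
        A_F=a, S_F=s, iterations=iters, converged=converged, seed=seed,
        meta={"algorithm": "infomax", "row_mean": pca.mean},
    )
    return fix_signs_and_order(result)


def _whiten_columns(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Column-centred orthonormal basis Z (n × r) with Y_c = Z·T."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    return u[:, :rank], (s[:rank, None] * vt[:rank]), rank


def mcca(
    y_list: list[np.ndarray],
    k: int,
    tol: float = 1e-13,
    max_iter: int = 5000,
) -> MCCAResult:
    """Multiset CCA by stage-wise SSQCOR maximization.

    Finds, per index s = 1..k, one unit-variance variate per data set such
    that the sum over set pairs of squared correlations between same-index
    variates is maximal, with successive variates orthogonal within each
    set. For two sets the fixed-point iteration is the power method on the
    cross-correlation operator and converges to classical CCA.
    """
    if len(y_list) < 2:
        raise ValueError("mcca needs at least two data sets")
    n = y_list[0].shape[0]
    if any(y.shape[0] != n for y in y_list):
        raise ValueError("all sets must share the subject dimension")
    zs, ranks = [], []
    for y in y_list:
        z, _, r = _whiten_columns(np.asarray(y, float))
        if r < k:
            raise ValueError(
                f"data set rank {r} < k={k}; reduce the requested component count"
            )
        zs.append(z)
        ranks.append(r)
    m = len(zs)
    # cross-correlation matrices in the whitened bases
    r_cross = {(i, j): zs[i].T @ zs[j] for i in range(m) for j in range(m) if i != j}

    w_found = [np.zeros((ranks[i], 0)) for i in range(m)]
    variate_w = [np.zeros((ranks[i], k)) for i in range(m)]
    ccorr = np.zeros(k)
    for stage in range(k):
        # projectors onto the orthogonal complement of previous directions
        projs = [
            np.eye(ranks[i]) - w_found[i] @ w_found[i].T for i in range(m)
        ]
        # initialize from the leading pair of the (projected) first two sets
        r12 = projs[0] @ r_cross[(0, 1)] @ projs[1]
        u, s, vt = np.linalg.svd(r12)
        ws = [projs[0] @ u[:, 0], projs[1] @ vt[0]]
        for i in range(2, m):
            v = projs[i] @ r_cross[(i, 0)] @ ws[0]
            nv = np.linalg.norm(v)
            ws.insert(i, v / nv if nv > 0 else projs[i][:, stage])
        ws = [w / np.linalg.norm(w) for w in ws]

        for _ in range(max_iter):
            max_change = 0.0
            for i in range(m):
                acc = np.zeros(ranks[i])
                for j in range(m):
                    if j == i:
                        continue
                    rv = r_cross[(i, j)] @ ws[j]
                    acc += rv * float(rv @ ws[i])
                v = projs[i] @ acc
                nv = np.linalg.norm(v)
                if nv == 0:
                    continue
                v /= nv
                if float(v @ ws[i]) < 0:
                    v = -v
                max_change = max(max_change, float(np.max(np.abs(v - ws[i]))))
                ws[i] = v
            if max_change < tol:
                break
        # fix signs so pairwise correlations with set 0 are positive
        for i in range(1, m):
            if float(ws[i] @ r_cross[(i, 0)] @ ws[0]) < 0:
                ws[i] = -ws[i]
        pair_r = [
            float(ws[i] @ r_cross[(i, j)] @ ws[j])
            for i in range(m)
            for j in range(i + 1, m)
        ]
        ccorr[stage] = float(np.mean(pair_r))
        for i in range(m):
            variate_w[i][:, stage] = ws[i]
            w_found[i] = np.column_stack([w_found[i], ws[i]])

    variates = [np.sqrt(n) * zs[i] @ variate_w[i] for i in range(m)]
    # weights in original feature space: w_orig solves Y_c w_orig = Z w
    weights = []
    for i, y in enumerate(y_list):
        yc = np.asarray(y, float) - np.asarray(y, float).mean(axis=0)
        w_orig, *_ = np.linalg.lstsq(yc, zs[i] @ variate_w[i], rcond=None)
        weights.append(w_orig)
    return MCCAResult(variates=variates, weights=weights, canonical_correlations=ccorr)


def _normalize_modality(x: np.ndarray) -> tuple[np.ndarray, dict]:
    """z-score features, then scale the modality to unit mean sum-of-squares."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    xz = (x - mu) / sd_safe
    scale = float(np.sqrt(np.mean(xz**2)))
    if scale == 0:
        raise ValueError("modality is identically zero after z-scoring")
    return xz / scale, {"mean": mu, "sd": sd_safe, "modality_scale": scale}


def mcca_jica(
    x_fnc: np.ndarray | DeltaMatrix,
    x_gmv: np.ndarray | DeltaMatrix,
    k: int,
    seed: int | None = None,
    **ica_kwargs,
) -> FusionResult:
    """Symmetric two-modality fusion: mCCA to align, joint ICA to separate.

    Pipeline: per-modality feature normalization → feature-space PCA to k
    scores → mCCA on the two score matrices (canonical variates D_k and
    least-squares associated maps C_k with X_k ≈ D_k·C_k) → infomax ICA on
    the concatenation [C_F | C_G] giving unmixing W → sources are the split
    of W applied to the maps and per-modality loadings A_k = D_k·W⁻¹, so
    X_k ≈ A_k·S_k in each modality.
    """
    ids_f = x_fnc.subject_ids if isinstance(x_fnc, DeltaMatrix) else None
    ids_g = x_gmv.subject_ids if isinstance(x_gmv, DeltaMatrix) else None
    if ids_f is not None and ids_g is not None and ids_f != ids_g:
        raise ValueError("subject tables of the two modalities do not match")
    xf = x_fnc.data if isinstance(x_fnc, DeltaMatrix) else np.asarray(x_fnc, float)
    xg = x_gmv.data if isinstance(x_gmv, DeltaMatrix) else np.asarray(x_gmv, float)
    if xf.shape[0] != xg.shape[0]:
        raise ValueError(
            f"modalities disagree on subject count: {xf.shape[0]} vs {xg.shape[0]}"
        )

    norms = []
    scores = []
    mats = []
    for x in (xf, xg):
        xn, info = _normalize_modality(x)
        u, s, _ = np.linalg.svd(xn, full_matrices=False)
        if k > np.sum(s > s[0] * 1e-10):
            raise ValueError("requested k exceeds the rank of a modality")
        scores.append(u[:, :k] * s[:k])  # n × k PCA scores
        mats.append(xn)
        norms.append(info)

    cca = mcca(scores, k)
    d_f, d_g = cca.variates  # n × k

    maps = []
    for d, xn in zip((d_f, d_g), mats):
        c, *_ = np.linalg.lstsq(d, xn, rcond=None)  # k × p
        maps.append(c)
    joint = np.concatenate(maps, axis=1)  # k × (pF + pG)

    # whiten the joint map rows (no centring: keeps X = D·C reconstruction exact)
    cov = joint @ joint.T / joint.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= evals[0] * 1e-12:
        raise ValueError("joint map matrix is rank deficient; reduce k")
    wh = (evecs / np.sqrt(evals)).T  # k × k
    z = wh @ joint
    w, iters, converged = _infomax_core(z, seed, **ica_kwargs)

    s_joint = w @ z
    mixing = np.linalg.inv(w @ wh)  # k × k, joint ≈ mixing @ s_joint
    p_f = maps[0].shape[1]
    s_f, s_g = s_joint[:, :p_f], s_joint[:, p_f:]
    # sources back on the raw feature scale (loadings are shared across
    # modalities up to these per-feature scales; X_k ≈ A_k·S_k + column means)
    s_f = s_f * norms[0]["sd"] * norms[0]["modality_scale"]
    s_g = s_g * norms[1]["sd"] * norms[1]["modality_scale"]
    a_f = d_f @ mixing
    a_g = d_g @ mixing
    result = FusionResult(
        A_F=a_f,
        S_F=s_f,
        A_G=a_g,
        S_G=s_g,
        canonical_correlations=cca.canonical_correlations,
        iterations=iters,
        converged=converged,
        seed=seed,
        meta={
            "algorithm": "mcca_jica",
            "normalization": [
                {"modality_scale": n["modality_scale"]} for n in norms
            ],
            "mean_fnc": norms[0]["mean"],
            "mean_gmv": norms[1]["mean"],
        },
    )
    return fix_signs_and_order(result)


def reconstruct(result: FusionResult, modality: str = "fnc") -> np.ndarray:
    """Model reconstruction ``A_k·S_k`` (+ stored column means, if any)."""
    if modality == "fnc":
        x = result.A_F @ result.S_F
        mean = result.meta.get("mean_fnc")
    elif modality == "gmv":
        if result.A_G is None:
            raise ValueError("result has no GMV modality")
        x = result.A_G @ result.S_G
        mean = result.meta.get("mean_gmv")
    else:
        raise ValueError("modality must be 'fnc' or 'gmv'")
    return x if mean is None else x + np.asarray(mean)[None, :]


def fix_signs_and_order(result: FusionResult) -> FusionResult:
    """Canonicalize the sign / scale / permutation ambiguity of a fusion.

    Source rows are scaled to unit norm (loadings absorb the scale), flipped
    so the largest-magnitude element of each (joint) source row is positive,
    and components are ordered by explained variance in the FNC modality.
    ``A·S`` is unchanged; applying twice equals applying once.
    """
    a_f = result.A_F.copy()
    s_f = result.S_F.copy()
    a_g = result.A_G.copy() if result.A_G is not None else None
    s_g = result.S_G.copy() if result.S_G is not None else None
    k = s_f.shape[0]

    for j in range(k):
        norm_f = np.linalg.norm(s_f[j])
        if norm_f > 0:
            s_f[j] /= norm_f
            a_f[:, j] *= norm_f
        if s_g is not None:
            norm_g = np.linalg.norm(s_g[j])
            if norm_g > 0:
                s_g[j] /= norm_g
                a_g[:, j] *= norm_g
    joint = s_f if s_g is None else np.concatenate([s_f, s_g], axis=1)
    for j in range(k):
        sign = np.sign(joint[j][np.argmax(np.abs(joint[j]))])
        if sign < 0:
            s_f[j] *= -1
            a_f[:, j] *= -1
            if s_g is not None:
                s_g[j] *= -1
                a_g[:, j] *= -1

    ev = np.sum(a_f**2, axis=0) * np.sum(s_f**2, axis=1)
    order = np.argsort(-ev, kind="stable")
    s_f = s_f[order]
    a_f = a_f[:, order]
    ccorr = result.canonical_correlations
    if s_g is not None:
        s_g = s_g[order]
        a_g = a_g[:, order]
    return FusionResult(
        A_F=a_f,
        S_F=s_f,
        A_G=a_g,
        S_G=s_g,
        canonical_correlations=ccorr,
        iterations=result.iterations,
        converged=result.converged,
        seed=result.seed,
        meta=result.meta,
    )
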