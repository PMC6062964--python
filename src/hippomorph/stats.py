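"""Vertex-wise and volumetric group statistics.

The statistical core of the pipeline:

* head-size correction of volumes by the covariance method — the slope
  ``alpha`` of volume on total intracranial volume (TIV) is estimated in
  controls only, and every subject's volume is shifted to the control mean
  TIV:  ``HV_adj = HV - alpha * (TIV - mean TIV of controls)``;
* fixed-effects group comparison of adjusted volumes with age as covariate;
* Spearman rank correlations of volumes with clinical scores;
* a mass-univariate general linear model at every vertex of the radial
  distance grid, with group as the effect of interest and age and TIV as
  nuisance covariates (negative t = surface inward in patients);
* family-wise error control by permutation of the maximum supra-threshold
  cluster size, with clusters found by flood fill on the cylindrical grid
  (4-neighbor connectivity with circumferential wrap);
* threshold-free cluster enhancement (TFCE) as an alternative to a fixed
  cluster-forming threshold;
* head/body/tail region-of-interest analyses as band-restricted re-runs of
  the permutation test.

Permutations respect the nuisance covariates via the Freedman-Lane scheme:
residuals of the reduced (covariates-only) model are permuted, the reduced
fit is added back, and the full model is refit.  Plain group-label
permutation is available for transparency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .contours import CohortTable
from .errors import ValidationError
from .surface import RadialMap

__all__ = [
    "TIVAdjustmentModel",
    "DesignMatrix",
    "VertexStatsMap",
    "ClusterResult",
    "RoiPartition",
    "fit_tiv_adjustment",
    "apply_tiv_adjustment",
    "group_volume_test",
    "clinical_correlation",
    "build_design",
    "vertex_glm",
    "flood_fill_clusters",
    "permutation_cluster_test",
    "tfce_enhance",
    "roi_partition",
    "roi_cluster_test",
]

#: Bonferroni-adjusted significance level for the two (left/right) volume tests.
VOLUME_ALPHA = 0.025

_T_CAP = 1e6  # numerical cap for zero-residual fits
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# TIV adjustment (covariance method)
# ---------------------------------------------------------------------------

@dataclass
class TIVAdjustmentModel:
    """Slope of volume on TIV in controls, and the control TIV mean."""

    alpha: float
    control_mean_tiv: float


def fit_tiv_adjustment(volumes: np.ndarray, tivs: np.ndarray) -> TIVAdjustmentModel:
    """OLS slope of hippocampal volume on TIV, fitted on controls only.

    Parameters are per-control arrays in mm^3; at least 3 controls and
    non-zero TIV variance are required.
    """
    volumes = np.asarray(volumes, float)
    tivs = np.asarray(tivs, float)
    if len(volumes) < 3 or len(volumes) != len(tivs):
        raise ValidationError("need >= 3 paired control volumes and TIVs")
    if np.var(tivs) == 0:
        raise ValidationError("TIV variance is zero; slope undefined")
    slope, _ = np.polyfit(tivs, volumes, 1)
    return TIVAdjustmentModel(alpha=float(slope), control_mean_tiv=float(tivs.mean()))


def apply_tiv_adjustment(
    model: TIVAdjustmentModel, volume: np.ndarray | float, tiv: np.ndarray | float
):
    """Shift volumes to the control mean TIV: ``HV - alpha * (TIV - mean_c)``."""
    return volume - model.alpha * (np.asarray(tiv, float) - model.control_mean_tiv)


# ---------------------------------------------------------------------------
# volume and clinical tests
# ---------------------------------------------------------------------------

def group_volume_test(
    adjusted_volumes: np.ndarray,
    group: np.ndarray,
    age: np.ndarray,
    alpha: float = VOLUME_ALPHA,
) -> dict:
    """Fixed-effects comparison of adjusted volumes: ``HV_adj ~ group + age``.

    Returns the partial F statistic and p-value for the group term and a
    significance flag at the Bonferroni level (default 0.025, two
    hemispheres).  ``group`` is any two-level vector; patients are whichever
    level is coded 1 by the caller's convention.
    """
    import statsmodels.api as sm

    y = np.asarray(adjusted_volumes, float)
    g = np.asarray(group, float)
    a = np.asarray(age, float)
    if len(np.unique(g)) != 2:
        raise ValidationError("group must have exactly two levels")
    for lvl in np.unique(g):
        if (g == lvl).sum() < 3:
            raise ValidationError("need >= 3 subjects per group")
    X = sm.add_constant(np.column_stack([g, a]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design (group confounded with age?)")
    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, sm.add_constant(a)).fit()
    f_res = full.compare_f_test(reduced)
    F, p = float(f_res[0]), float(f_res[1])
    return {
        "F": F,
        "p": p,
        "df": (1, int(full.df_resid)),
        "significant": p < alpha,
        "alpha_level": alpha,
        "group_coef": float(full.params[1]),
    }


def clinical_correlation(volumes: np.ndarray, scores: np.ndarray) -> dict:
    """Spearman rank correlation of volumes with a clinical score.

    Pairs with missing scores are dropped; at least 5 complete pairs are
    required and an all-tied score vector is rejected.
    """
    v = np.asarray(volumes, float)
    s = np.asarray(scores, float)
    keep = np.isfinite(v) & np.isfinite(s)
    v, s = v[keep], s[keep]
    if len(v) < 5:
        raise ValidationError(f"need >= 5 complete pairs, got {len(v)}")
    if np.all(s == s[0]):
        raise ValidationError("score vector is constant; rank correlation undefined")
    rho, p = sps.spearmanr(v, s)
    return {"rho": float(rho), "p": float(p), "n": int(len(v))}


# ---------------------------------------------------------------------------
# vertex-wise GLM
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Design for the per-vertex GLM: intercept, group, nuisance covariates.

    ``contrast`` selects the group column; the group indicator codes
    patients 1 and controls 0 so that a negative contrast estimate means the
    patient surface lies inward of the control surface.
    """

    X: np.ndarray
    contrast: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.contrast = np.asarray(self.contrast, float)
        n, k = self.X.shape
        if np.linalg.matrix_rank(self.X) < k:
            raise ValidationError("design matrix is rank deficient")
        if n < k + 2:
            raise ValidationError(f"need >= {k + 2} subjects for a {k}-column design")
        if len(self.contrast) != k:
            raise ValidationError("contrast length does not match design columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def group_col(self) -> int:
        return int(np.flatnonzero(self.contrast)[0])


def build_design(
    table: CohortTable, covariates: Sequence[str] = ("age", "tiv")
) -> DesignMatrix:
    """Assemble intercept + group + covariates from a cohort table."""
    cols = [np.ones(len(table.data)), table.group_indicator.astype(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        cols.append(table.data[cov].to_numpy(float))
        names.append(cov)
    contrast = np.zeros(len(cols))
    contrast[1] = 1.0
    return DesignMatrix(np.column_stack(cols), contrast, tuple(names))


@dataclass
class VertexStatsMap:
    """Per-vertex t and two-sided p maps from the group contrast."""

    t_values: np.ndarray
    p_values: np.ndarray
    dof: int


def _stack_maps(maps: Sequence[RadialMap] | np.ndarray) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        arr = maps
    else:
        arr = np.stack([m.distances if isinstance(m, RadialMap) else m for m in maps])
    if arr.ndim != 3:
        raise ValidationError("expected n_subjects x L x C radial data")
    return np.asarray(arr, float)


def _contrast_t(Y: np.ndarray, X: np.ndarray, pinv: np.ndarray, c: np.ndarray,
                var_c: float, dof: int) -> np.ndarray:
    """t statistic of contrast c at every column of Y (flattened vertices).

    Vertices whose residual variance is indistinguishable from rounding
    noise (perfect fits) get t = +/-cap when the effect is real and t = 0
    when the effect is itself at rounding level.
    """
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * var_c)
    eff = c @ beta
    scale2 = (Y**2).mean(axis=0)  # squared data magnitude per vertex
    eps = float(np.finfo(Y.dtype).eps)
    degenerate = sigma2 <= (32.0 * eps) ** 2 * scale2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / se
    eff_real = np.abs(eff) > 32.0 * eps * np.sqrt(scale2)
    t[degenerate] = np.where(
        eff_real[degenerate], np.sign(eff[degenerate]) * _T_CAP, 0.0
    )
    return np.clip(np.nan_to_num(t, nan=0.0), -_T_CAP, _T_CAP)


def vertex_glm(
    maps: Sequence[RadialMap] | np.ndarray, design: DesignMatrix
) -> VertexStatsMap:
    """Independent OLS fit of radial distance on the design at every vertex.

    Returns the t map for the group contrast and two-sided p values from the
    t distribution with ``n - rank`` degrees of freedom.
    """
    Y = _stack_maps(maps)
    n, L, C = Y.shape
    if n != design.n:
        raise ValidationError(f"{n} maps but design has {design.n} rows")
    X = design.X
    rank = X.shape[1]
    dof = n - rank
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    var_c = float(design.contrast @ xtx_inv @ design.contrast)
    t = _contrast_t(Y.reshape(n, -1), X, pinv, design.contrast, var_c, dof)
    p = np.maximum(2.0 * sps.t.sf(np.abs(t), dof), _P_FLOOR)
    return VertexStatsMap(t.reshape(L, C), p.reshape(L, C), dof)


# ---------------------------------------------------------------------------
# flood-fill clustering on the cylindrical grid
# ---------------------------------------------------------------------------

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_STRUCT8 = np.ones((3, 3), bool)


def _label_wrap(mask: np.ndarray, structure: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components with circumferential wrap (col 0 ~ col C-1)."""
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0 or mask.shape[1] < 2:
        return labels, n
    # union labels joined across the seam
    left, right = labels[:, 0], labels[:, -1]
    if structure[1, 0]:  # same-row adjacency across the seam
        pairs = np.column_stack([left, right])
    else:
        pairs = np.empty((0, 2), int)
    if structure[0, 0]:  # diagonal adjacency across the seam (8-connectivity)
        pairs = np.vstack(
            [pairs, np.column_stack([left[1:], right[:-1]]),
             np.column_stack([left[:-1], right[1:]])]
        )
    pairs = pairs[(pairs[:, 0] > 0) & (pairs[:, 1] > 0)]
    if len(pairs):
        parent = np.arange(n + 1)

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        roots = np.array([find(i) for i in range(n + 1)])
        # compress to contiguous labels 1..K
        uniq = np.unique(roots[1:])
        remap = np.zeros(n + 1, int)
        remap[uniq] = np.arange(1, len(uniq) + 1)
        labels = remap[roots][labels]
        n = len(uniq)
    return labels, n


def flood_fill_clusters(
    mask: np.ndarray, connectivity: Literal[4, 8] = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Label connected components of a supra-threshold mask.

    The grid is a tube: column 0 and column C-1 are adjacent (circumferential
    wrap); there is no wrap across levels.  Returns ``(label_map, sizes)``
    with labels contiguous 1..K ordered by decreasing size (0 = background).
    """
    mask = np.asarray(mask, bool)
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    labels, n = _label_wrap(mask, structure)
    if n == 0:
        return labels, np.empty(0, int)
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(-sizes, kind="stable")
    remap = np.zeros(n + 1, int)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[labels], sizes[order]


def _max_cluster_size(
    t_flat: np.ndarray, shape: tuple[int, int], t_thresh: float,
    structure: np.ndarray, mask: np.ndarray | None
) -> int:
    """Largest supra-threshold cluster over both signs (permutation statistic)."""
    tmap = t_flat.reshape(shape)
    best = 0
    for signed in (tmap >= t_thresh, tmap <= -t_thresh):
        if mask is not None:
            signed = signed & mask
        if not signed.any():
            continue
        labels, n = _label_wrap(signed, structure)
        if n:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


# ---------------------------------------------------------------------------
# permutation cluster test
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Observed clusters with permutation-corrected family-wise p-values."""

    label_map: np.ndarray
    cluster_sizes: np.ndarray
    cluster_signs: np.ndarray
    corrected_p: np.ndarray
    n_permutations: int
    seed: int
    t_threshold: float
    null_max_sizes: np.ndarray = field(repr=False, default=None)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": np.arange(1, len(self.cluster_sizes) + 1),
                "size": self.cluster_sizes,
                "sign": np.where(self.cluster_signs < 0, "inward", "outward"),
                "corrected_p": self.corrected_p,
            }
        )


def _observed_clusters(
    tmap: np.ndarray, t_thresh: float, connectivity: Literal[4, 8],
    mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sign-segregated supra-threshold clusters of the observed t map."""
    L, C = tmap.shape
    label_map = np.zeros((L, C), int)
    sizes, signs = [], []
    offset = 0
    for sign, m in ((1, tmap >= t_thresh), (-1, tmap <= -t_thresh)):
        if mask is not None:
            m = m & mask
        labels, s = (
            flood_fill_clusters(m, connectivity)
            if m.any()
            else (np.zeros((L, C), int), np.empty(0, int))
        )
        label_map[labels > 0] = labels[labels > 0] + offset
        sizes.extend(s.tolist())
        signs.extend([sign] * len(s))
        offset += len(s)
    sizes = np.array(sizes, int)
    signs = np.array(signs, int)
    # renumber by decreasing size across both signs
    order = np.argsort(-sizes, kind="stable")
    remap = np.zeros(len(sizes) + 1, int)
    remap[order + 1] = np.arange(1, len(sizes) + 1)
    return remap[label_map], sizes[order], signs[order]


def permutation_cluster_test(
    maps: Sequence[RadialMap] | np.ndarray,
    design: DesignMatrix,
    cluster_forming_p: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    scheme: Literal["freedman-lane", "label"] = "freedman-lane",
    connectivity: Literal[4, 8] = 4,
    mask: np.ndarray | None = None,
) -> ClusterResult:
    """Max-cluster-size permutation test of the group effect on radial maps.

    The observed t map is thresholded two-sided at the vertex-level
    ``cluster_forming_p``; inward (t < 0) and outward (t > 0) deformation
    clusters are kept separate.  The null distribution of the maximum
    cluster size (over both signs) is built from ``n_perm`` permutations —
    Freedman-Lane residual permutation by default, plain group-label
    permutation via ``scheme="label"``.  Corrected p-values use the add-one
    rule ``(1 + #{null >= size}) / (n_perm + 1)``, so p = 0 is impossible.

    A mandatory ``seed`` makes the result bit-reproducible.  When plain
    label permutation admits fewer distinct relabelings than ``n_perm``,
    the test enumerates them exhaustively with a warning.
    """
    if seed is None:
        raise ValueError("seed is mandatory for permutation tests")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y3 = _stack_maps(maps)
    n, L, C = Y3.shape
    if n != design.n:
        raise ValidationError(f"{n} maps but design has {design.n} rows")
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != (L, C):
            raise ValidationError("ROI mask shape does not match the maps")

    X = design.X
    c = design.contrast
    rank = X.shape[1]
    dof = n - rank
    pinv = np.linalg.pinv(X)
    var_c = float(c @ np.linalg.inv(X.T @ X) @ c)
    t_thresh = float(sps.t.isf(cluster_forming_p / 2.0, dof))
    Y = Y3.reshape(n, -1)

    t_obs = _contrast_t(Y, X, pinv, c, var_c, dof)
    label_map, sizes, signs = _observed_clusters(
        t_obs.reshape(L, C), t_thresh, connectivity, mask
    )

    rng = np.random.default_rng(seed)
    perms = _permutation_rows(n, n_perm, design, scheme, rng)

    if scheme == "freedman-lane":
        keep = [j for j in range(rank) if c[j] == 0.0]
        Z = X[:, keep]
        pinv_z = np.linalg.pinv(Z)
        fitted_r = Z @ (pinv_z @ Y)
        resid_r = Y - fitted_r
        # single precision inside the null loop: the statistic only enters
        # a threshold comparison, and the loop is memory-bandwidth bound
        f32 = np.float32
        fitted32, resid32 = fitted_r.astype(f32), resid_r.astype(f32)
        X32, pinv32, c32 = X.astype(f32), pinv.astype(f32), c.astype(f32)
        null_max = np.empty(len(perms), int)
        for i, pr in enumerate(perms):
            t_p = _contrast_t(fitted32 + resid32[pr], X32, pinv32, c32, var_c, dof)
            null_max[i] = _max_cluster_size(t_p, (L, C), t_thresh, structure, mask)
    else:  # permute the group column of the design
        null_max = np.empty(len(perms), int)
        gcol = design.group_col
        for i, pr in enumerate(perms):
            Xp = X.copy()
            Xp[:, gcol] = X[pr, gcol]
            pinv_p = np.linalg.pinv(Xp)
            var_cp = float(c @ np.linalg.inv(Xp.T @ Xp) @ c)
            t_p = _contrast_t(Y, Xp, pinv_p, c, var_cp, dof)
            null_max[i] = _max_cluster_size(t_p, (L, C), t_thresh, structure, mask)

    m = len(null_max)
    corrected = np.array(
        [(1 + int((null_max >= s).sum())) / (m + 1) for s in sizes], float
    )
    return ClusterResult(
        label_map=label_map,
        cluster_sizes=sizes,
        cluster_signs=signs,
        corrected_p=corrected,
        n_permutations=m,
        seed=seed,
        t_threshold=t_thresh,
        null_max_sizes=null_max,
    )


def _permutation_rows(
    n: int, n_perm: int, design: DesignMatrix, scheme: str, rng: np.random.Generator
) -> list[np.ndarray]:
    """Row permutations for the null; exhaustive when the label space is tiny."""
    if scheme == "label":
        g = design.X[:, design.group_col]
        n1 = int((g == g.max()).sum())
        n_distinct = math.comb(n, n1)
        if n_distinct <= n_perm:
            warnings.warn(
                f"only {n_distinct} distinct group relabelings; enumerating exhaustively",
                stacklevel=3,
            )
            base = np.flatnonzero(g == g.max())
            rest = np.flatnonzero(g != g.max())
            perms = []
            for combo in combinations(range(n), n1):
                pr = np.empty(n, int)
                pr[np.array(combo)] = base
                pr[np.setdiff1d(np.arange(n), combo)] = rest
                perms.append(pr)
            return perms
    return [rng.permutation(n) for _ in range(n_perm)]


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def tfce_enhance(
    t_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: Literal[4, 8] = 4,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    For every vertex the enhanced value is the discrete sum over thresholds
    ``h = dh, 2dh, ... <= t`` of ``extent(h)**E * h**H * dh``, where
    ``extent(h)`` is the size of the connected component containing the
    vertex at threshold ``h`` (cylindrical-grid connectivity).  Negative
    values are enhanced on the negated map and returned with their sign.

    ``dh`` defaults to ``max|t| / 100``.
    """
    t_map = np.asarray(t_map, float)
    if not np.all(np.isfinite(t_map)):
        raise ValidationError("t map must be finite")
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    peak = float(np.abs(t_map).max())
    if peak == 0.0:
        return np.zeros_like(t_map)
    if dh is None:
        dh = peak / 100.0
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    out = np.zeros_like(t_map)
    for sign in (1.0, -1.0):
        vals = sign * t_map
        vmax = vals.max()
        if vmax < dh:
            continue
        n_steps = int(np.floor(vmax / dh + 1e-12))
        for k in range(1, n_steps + 1):
            h = k * dh
            m = vals >= h
            if not m.any():
                break
            labels, n = _label_wrap(m, structure)
            sizes = np.bincount(labels.ravel())
            contrib = (sizes[labels] ** E) * (h**H) * dh
            out[m] += sign * contrib[m]
    return out


# ---------------------------------------------------------------------------
# head / body / tail regions of interest
# ---------------------------------------------------------------------------

@dataclass
class RoiPartition:
    """Head/body/tail masks: contiguous longitudinal bands partitioning the grid."""

    masks: dict[str, np.ndarray]
    boundaries: tuple[int, ...]


def roi_partition(
    L: int, C: int, fractions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)
) -> RoiPartition:
    """Split the grid into head (anterior), body and tail bands of whole levels.

    ``fractions`` must be positive and sum to 1; every band gets at least
    one level.
    """
    fractions = np.asarray(fractions, float)
    if np.any(fractions <= 0):
        raise ValueError("fractions must be positive")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions.sum():.6g}")
    edges = np.round(np.cumsum(fractions) * L).astype(int)
    edges[-1] = L
    bounds = np.concatenate([[0], edges])
    if np.any(np.diff(bounds) < 1):
        raise ValueError("a band would contain zero levels")
    names = ("head", "body", "tail")
    masks = {}
    for name, lo, hi in zip(names, bounds[:-1], bounds[1:]):
        m = np.zeros((L, C), bool)
        m[lo:hi] = True
        masks[name] = m
    return RoiPartition(masks=masks, boundaries=tuple(int(b) for b in bounds))


def roi_cluster_test(
    maps: Sequence[RadialMap] | np.ndarray,
    design: DesignMatrix,
    partition: RoiPartition,
    **kwargs,
) -> dict[str, ClusterResult]:
    """Re-run the permutation cluster test restricted to each ROI band.

    The max-cluster null is computed within each mask, so the correction is
    per-ROI, mirroring a targeted regional hypothesis.
    """
    return {
        name: permutation_cluster_test(maps, design, mask=mask, **kwargs)
        for name, mask in partition.masks.items()
    }
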