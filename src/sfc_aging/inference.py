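"""Voxel-wise group contrasts with permutation-based family-wise error control.

Group contrasts of SFC maps are ordinary-least-squares GLMs fit independently
per node (two-sample group contrast with sex and education as centred
covariates), with FWE control via the permutation distribution of the maximum
statistic: either max |t| (maxT) or threshold-free cluster enhancement (TFCE)
of |t| over the voxel 6-connectivity graph.  Covariate designs are permuted
with the Freedman-Lane scheme (permute residuals of the reduced model), the de
facto standard for nonparametric GLM inference in neuroimaging; a simple
label-permutation fallback is available.  The medial-vs-lateral comparison is
a paired (one-sample-on-differences) t-test whose permutation null is random
sign flips of the per-subject difference maps.

Corrected p-values use the add-one convention p = (1 + b) / (1 + n_perm),
which guarantees p >= 1/(n_perm + 1) and a valid level-alpha test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy import stats

from .io import NodeTable, SubjectRecord
from .sfc import NEIGHBOR_OFFSETS

__all__ = [
    "DesignMatrix",
    "StatMap",
    "FWEResult",
    "RegionSets",
    "two_sample_design",
    "glm_tmap",
    "tfce_enhance",
    "permutation_fwe",
    "paired_tmap",
    "paired_permutation_fwe",
    "grid_adjacency",
    "derive_region_sets",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignMatrix:
    """Subjects x predictors design: intercept, group coding, centred covariates."""

    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("design must be 2D (subjects x columns)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.X = X

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def two_sample_design(
    records: list[SubjectRecord],
    group_a: str,
    group_b: str,
    covariates: tuple[str, ...] = ("sex", "education"),
) -> tuple[DesignMatrix, np.ndarray]:
    """Design and contrast for a two-sample comparison (A minus B) with covariates.

    Group coding is +1/2 for A and -1/2 for B so the contrast [0, 1, 0, ...]
    estimates the adjusted A-B mean difference.  Covariates are centred.
    """
    groups = [r.group for r in records]
    if not set(groups) <= {group_a, group_b}:
        raise ValueError("records contain subjects outside the two compared groups")
    cols = [np.ones(len(records))]
    names = ["intercept"]
    coding = np.array([0.5 if g == group_a else -0.5 for g in groups])
    cols.append(coding)
    names.append(f"{group_a}_vs_{group_b}")
    for cov in covariates:
        if cov == "sex":
            v = np.array([1.0 if r.sex == "F" else 0.0 for r in records])
        elif cov == "education":
            v = np.array([r.education_years for r in records])
        elif cov == "age":
            v = np.array([r.age_years for r in records])
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        v = v - v.mean()
        if np.allclose(v, 0):
            continue  # constant covariate carries no information
        cols.append(v)
        names.append(cov)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X, names), contrast


@dataclass
class StatMap:
    """Per-node t-statistic with its degrees of freedom; NaN where variance is zero."""

    t: np.ndarray
    df: int


@dataclass
class FWEResult:
    """FWE-corrected permutation p-values and the significance mask at alpha."""

    p_corrected: np.ndarray
    mask: np.ndarray
    tmap: StatMap
    method: str
    n_permutations: int
    alpha: float


def _fit_t(X: np.ndarray, pinv: np.ndarray, cvc: float, contrast: np.ndarray, Y: np.ndarray, df: int) -> np.ndarray:
    """Vectorised per-node OLS t for a contrast; NaN at zero-residual-variance nodes."""
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    effect = contrast @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(cvc * sigma2)
    t[sigma2 <= 0] = np.nan
    return t


def glm_tmap(maps: np.ndarray, design: DesignMatrix, contrast: np.ndarray) -> StatMap:
    """Per-node OLS fit; t = c'beta / sqrt(c'(X'X)^-1 c * sigma^2), df = n - rank(X)."""
    Y = np.asarray(maps, dtype=float)
    X = design.X
    contrast = np.asarray(contrast, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("maps must be subjects x nodes matching the design rows")
    if contrast.shape != (X.shape[1],):
        raise ValueError("contrast length must equal the number of design columns")
    if np.allclose(contrast, 0):
        raise ValueError("contrast must be a nonzero vector")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than design columns")
    df = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    cvc = float(contrast @ xtx_inv @ contrast)
    t = _fit_t(X, pinv, cvc, contrast, Y, df)
    return StatMap(t, df)


def grid_adjacency(node_table: NodeTable, connectivity: int = 6) -> sparse.csr_matrix:
    """Sparse node-node adjacency from voxel neighbourhood in the atlas grid."""
    offsets = NEIGHBOR_OFFSETS[connectivity]
    index = node_table.index_of_voxel()
    rows, cols = [], []
    for i, c in enumerate(node_table.coords):
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = node_table.n_nodes
    return sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def tfce_enhance(
    stat: np.ndarray,
    adjacency: sparse.spmatrix,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative statistic map.

    TFCE(p) = sum over thresholds h = dh, 2dh, ..., h_p of
    extent(p, h)^E * h^H * dh, where extent is the size of the connected
    component containing p in the supra-threshold graph.  Defaults E = 0.5,
    H = 2 and dh = max/100 are the standard published values.
    """
    s = np.asarray(stat, dtype=float)
    s = np.where(np.isfinite(s), s, 0.0)
    if np.any(s < 0):
        raise ValueError("TFCE input must be non-negative (apply to |t|)")
    smax = s.max()
    if smax == 0:
        return np.zeros_like(s)
    if dh is None:
        dh = smax / 100.0
    if dh <= 0:
        raise ValueError(f"dh must be positive, got {dh}")
    adjacency = sparse.csr_matrix(adjacency)
    out = np.zeros_like(s)
    h = dh
    while h <= smax + 1e-12:
        active = s >= h
        if not active.any():
            break
        sub = adjacency[active][:, active]
        _, labels = connected_components(sub, directed=False)
        sizes = np.bincount(labels)
        out[active] += sizes[labels] ** E * h**H * dh
        h += dh
    return out


def _fwe_from_max(observed: np.ndarray, max_null: np.ndarray, valid: np.ndarray) -> np.ndarray:
    n_perm = len(max_null)
    p = np.full(observed.shape, np.nan)
    exceed = (max_null[:, None] >= observed[None, valid]).sum(axis=0)
    p[valid] = (1.0 + exceed) / (1.0 + n_perm)
    return p


def permutation_fwe(
    maps: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray,
    n_perm: int = 5000,
    enhancer: str = "none",
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    adjacency: sparse.spmatrix | None = None,
    scheme: str = "freedman_lane",
    tfce_params: dict | None = None,
) -> FWEResult:
    """Max-statistic permutation FWE for a GLM contrast on subject x node maps.

    ``enhancer`` is "none" (maxT on |t|) or "tfce" (TFCE of |t| over
    ``adjacency``).  Exchangeability with covariates is obtained with the
    Freedman-Lane scheme: nuisance-model residuals are permuted and the
    nuisance fit added back before refitting the full model
    (``scheme="labels"`` permutes design rows directly).
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value granularity (min p = {1 / (n_perm + 1):.3g})",
            stacklevel=2,
        )
    if enhancer not in ("none", "tfce"):
        raise ValueError(f"unknown enhancer {enhancer!r}")
    if enhancer == "tfce" and adjacency is None:
        raise ValueError("TFCE requires a node adjacency")
    Y = np.asarray(maps, dtype=float)
    observed_t = glm_tmap(Y, design, contrast)
    valid = np.isfinite(observed_t.t)
    X = design.X
    contrast = np.asarray(contrast, dtype=float)
    df = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    cvc = float(contrast @ xtx_inv @ contrast)
    tfce_params = tfce_params or {}

    def enhance(t: np.ndarray) -> np.ndarray:
        a = np.abs(np.where(np.isfinite(t), t, 0.0))
        if enhancer == "tfce":
            return tfce_enhance(a, adjacency, **tfce_params)
        return a

    observed = enhance(observed_t.t)

    n = X.shape[0]
    if scheme == "freedman_lane":
        nuisance = np.abs(contrast) < 1e-12
        Z = X[:, nuisance]
        hz = Z @ np.linalg.pinv(Z) if Z.size else np.zeros((n, n))
        fitted = hz @ Y
        resid = Y - fitted
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            Yb = fitted + resid[perm]
            tb = _fit_t(X, pinv, cvc, contrast, Yb, df)
            eb = enhance(tb)
            max_null[b] = np.nanmax(eb[valid]) if valid.any() else 0.0
    elif scheme == "labels":
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            tb = _fit_t(X[perm], np.linalg.pinv(X[perm]), cvc, contrast, Y, df)
            eb = enhance(tb)
            max_null[b] = np.nanmax(eb[valid]) if valid.any() else 0.0
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    p = _fwe_from_max(observed, max_null, valid)
    mask = np.where(np.isfinite(p), p <= alpha, False)
    method = "maxT" if enhancer == "none" else "tfce"
    return FWEResult(p, mask, observed_t, method, n_perm, alpha)


def paired_tmap(maps_a: np.ndarray, maps_b: np.ndarray) -> StatMap:
    """One-sample t on per-subject difference maps (A minus B, same subjects/order)."""
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("paired map sets must share shape (same subjects, same order)")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"paired t-test needs at least 3 subjects, got {n}")
    D = A - B
    return _one_sample_t(D)


def _one_sample_t(D: np.ndarray) -> StatMap:
    n = D.shape[0]
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return StatMap(t, n - 1)


def paired_permutation_fwe(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 5000,
    enhancer: str = "none",
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    adjacency: sparse.spmatrix | None = None,
    tfce_params: dict | None = None,
) -> FWEResult:
    """Sign-flip max-statistic FWE for the paired (e.g. medial-vs-lateral) contrast.

    The permutation null randomly negates each subject's difference map, which
    is exact when the difference distribution is symmetric about zero.
    """
    rng = np.random.default_rng() if rng is None else rng
    if enhancer == "tfce" and adjacency is None:
        raise ValueError("TFCE requires a node adjacency")
    D = np.asarray(maps_a, dtype=float) - np.asarray(maps_b, dtype=float)
    observed_t = paired_tmap(maps_a, maps_b)
    valid = np.isfinite(observed_t.t)
    tfce_params = tfce_params or {}

    def enhance(t: np.ndarray) -> np.ndarray:
        a = np.abs(np.where(np.isfinite(t), t, 0.0))
        if enhancer == "tfce":
            return tfce_enhance(a, adjacency, **tfce_params)
        return a

    observed = enhance(observed_t.t)
    n = D.shape[0]
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        tb = _one_sample_t(D * signs[:, None])
        eb = enhance(tb.t)
        max_null[b] = np.nanmax(eb[valid]) if valid.any() else 0.0
    p = _fwe_from_max(observed, max_null, valid)
    mask = np.where(np.isfinite(p), p <= alpha, False)
    method = "maxT" if enhancer == "none" else "tfce"
    return FWEResult(p, mask, observed_t, method, n_perm, alpha)


@dataclass
class RegionSets:
    """Partition of named regions into MCR, LCR and the remainder of the brain.

    MCR (medial caudate connected regions): stronger step-1 connectivity with
    the medial than the lateral caudate seed; LCR the converse; ``rest`` is
    everything else.  Pairwise disjoint, union = all regions.
    """

    mcr: list[str]
    lcr: list[str]
    rest: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.mcr), set(self.lcr), set(self.rest)]
        total = sum(len(s) for s in sets)
        if len(set.union(*sets)) != total:
            raise ValueError("MCR / LCR / rest must be pairwise disjoint")

    @property
    def all_regions(self) -> list[str]:
        return self.mcr + self.lcr + self.rest

    def set_of(self, region: str) -> str:
        if region in self.mcr:
            return "MCR"
        if region in self.lcr:
            return "LCR"
        return "rest"

    def to_json(self) -> dict:
        return {"MCR": self.mcr, "LCR": self.lcr, "rest": self.rest}

    @classmethod
    def from_json(cls, obj: dict) -> "RegionSets":
        return cls(list(obj["MCR"]), list(obj["LCR"]), list(obj["rest"]))


def derive_region_sets(
    paired_result: FWEResult,
    node_table: NodeTable,
    region_labels: list[int] | None = None,
    min_frac: float = 0.1,
) -> RegionSets:
    """Name regions MCR / LCR from the step-1 medial-vs-lateral paired contrast.

    A region joins MCR when at least ``min_frac`` of its voxels are significant
    with t > 0 (medial > lateral); LCR analogously for t < 0.  A region
    qualifying for both is resolved by the majority of its significant voxels;
    an exact tie goes to rest (logged).  Remaining regions form ``rest``.
    """
    atlas = node_table.atlas
    if region_labels is None:
        region_labels = atlas.labels_of_class("cortical_parcel", "subcortical_parcel")
    t = paired_result.tmap.t
    sig = paired_result.mask
    mcr, lcr, rest = [], [], []
    for label in region_labels:
        name = atlas.dictionary[label].name
        nodes = node_table.nodes_with_label(label)
        if nodes.size == 0:
            raise ValueError(f"region {name!r} has no voxels in the atlas")
        s = sig[nodes]
        pos = int(np.sum(s & (t[nodes] > 0)))
        neg = int(np.sum(s & (t[nodes] < 0)))
        frac_pos = pos / nodes.size
        frac_neg = neg / nodes.size
        if frac_pos >= min_frac and frac_neg >= min_frac:
            if pos > neg:
                mcr.append(name)
            elif neg > pos:
                lcr.append(name)
            else:
                logger.info("region %s ties between MCR and LCR; assigned to rest", name)
                rest.append(name)
        elif frac_pos >= min_frac:
            mcr.append(name)
        elif frac_neg >= min_frac:
            lcr.append(name)
        else:
            rest.append(name)
    if not mcr and not lcr:
        warnings.warn("no significant voxels anywhere: MCR and LCR are empty", stacklevel=2)
    return RegionSets(mcr, lcr, rest)
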