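"""Texture matrices (GLCM, GLRLM, GLSZM, NGTDM, GLDM) and their features.

All five families operate on a :class:`~radrobust.preprocess.DiscretizedROI`:
an integer grid with levels 1..Ng inside the ROI and 0 outside.

Conventions (documented because the literature varies):

* neighborhoods are 3D at Chebyshev distance 1 (26 neighbors, 13 unique
  direction pairs);
* GLCM is symmetrized per direction; GLCM and GLRLM features are computed
  per direction and then averaged over the 13 directions;
* GLSZM zones are 26-connected;
* NGTDM is stored as an (Ng, 2) matrix of per-level counts ``n_i`` and
  absolute-difference sums ``s_i``;
* GLDM uses dependence tolerance alpha = 0 (exact level match); the
  dependence index ``j`` of the matrix column is the number of dependent
  neighbors plus one, so j ranges over 1..27.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedROI

TEXTURE_KINDS = ("GLCM", "GLRLM", "GLSZM", "NGTDM", "GLDM")

def _unique_directions():
    """The 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair)."""
    dirs = []
    for dx in (0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d[0] == 0 and (d[1], d[2]) < (0, 0):
                    continue
                if d[0] == 0 and d[1] == 0 and d[2] < 0:
                    continue
                dirs.append(d)
    return tuple(dirs)


DIRECTIONS_13 = _unique_directions()
assert len(DIRECTIONS_13) == 13

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TextureMatrix:
    """Counts for one texture family.

    ``matrices`` holds one 2D count array per direction for GLCM
    (Ng x Ng) and GLRLM (Ng x max-run); a single array for GLSZM
    (Ng x max-zone), GLDM (Ng x 27) and NGTDM (Ng x 2 of n_i, s_i).
    """

    kind: str
    matrices: list[np.ndarray]
    n_levels: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TEXTURE_KINDS:
            raise ValueError(f"unknown texture matrix kind {self.kind!r}")
        for m in self.matrices:
            if (np.asarray(m) < 0).any():
                raise ValueError("texture matrix entries must be non-negative")


def _shift_slices(shape, d):
    """Slice pairs (src, dst) such that arr[src] aligns with arr[dst] offset by d."""
    src, dst = [], []
    for n, o in zip(shape, d):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# matrix construction


def _glcm(disc: DiscretizedROI) -> list[np.ndarray]:
    L = disc.levels
    ng = disc.n_levels
    mats = []
    for d in DIRECTIONS_13:
        src, dst = _shift_slices(L.shape, d)
        a, b = L[src].ravel(), L[dst].ravel()
        ok = (a > 0) & (b > 0)
        idx = (a[ok] - 1) * ng + (b[ok] - 1)
        P = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
        mats.append(P + P.T)  # symmetric co-occurrences
    return mats


def _glrlm_direction(L: np.ndarray, d) -> np.ndarray:
    """Run-length counts along one direction via slab-wise dynamic programming."""
    ng = int(L.max())
    valid = L > 0
    # same[x] is True when x and x+d are both in the ROI with equal level
    src, dst = _shift_slices(L.shape, d)
    same = np.zeros(L.shape, dtype=bool)
    same[src] = valid[src] & valid[dst] & (L[src] == L[dst])

    pivot = next(ax for ax in range(3) if d[ax] != 0)
    rest = tuple(o for ax, o in enumerate(d) if ax != pivot)

    def shift2d(arr2d):
        out = np.zeros_like(arr2d)
        (s0, s1), (t0, t1) = _shift_slices(arr2d.shape, rest)
        out[s0, s1] = arr2d[t0, t1]
        return out

    # length of the maximal run continuing from each voxel in direction d
    run_from = np.ones(L.shape, dtype=np.int64)
    n_piv = L.shape[pivot]
    sl = [slice(None)] * 3
    for i in range(n_piv - 2, -1, -1):
        sl[pivot] = i
        cur = tuple(sl)
        sl[pivot] = i + 1
        nxt = tuple(sl)
        cont = shift2d(run_from[nxt])
        run_from[cur] = np.where(same[cur], cont + 1, 1)

    # run starts: in-ROI voxels whose predecessor x-d does not continue them
    prev_same = np.zeros(L.shape, dtype=bool)
    prev_same[dst] = same[src]
    starts = valid & ~prev_same
    levels = L[starts] - 1
    lengths = run_from[starts]
    max_len = int(lengths.max()) if lengths.size else 1
    M = np.zeros((ng, max_len), dtype=np.float64)
    np.add.at(M, (levels, lengths - 1), 1.0)
    return M


def _glrlm(disc: DiscretizedROI) -> list[np.ndarray]:
    return [_glrlm_direction(disc.levels, d) for d in DIRECTIONS_13]


def _glszm(disc: DiscretizedROI) -> list[np.ndarray]:
    L = disc.levels
    ng = disc.n_levels
    zones = []  # (level, size)
    for g in range(1, ng + 1):
        labels, n = ndimage.label(L == g, structure=_CONN26)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    M = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        M[g - 1, s - 1] += 1.0
    return [M]


def _ngtdm(disc: DiscretizedROI) -> list[np.ndarray]:
    L = disc.levels.astype(np.float64)
    valid = disc.levels > 0
    ng = disc.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(L * valid, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(valid.astype(np.float64), kernel, mode="constant", cval=0.0)
    has_nb = valid & (nb_cnt > 0)
    avg = np.zeros(L.shape)
    avg[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    diff = np.abs(L - avg)
    M = np.zeros((ng, 2), dtype=np.float64)
    lv = disc.levels[has_nb] - 1
    np.add.at(M[:, 0], lv, 1.0)
    np.add.at(M[:, 1], lv, diff[has_nb])
    return [M]


def _gldm(disc: DiscretizedROI, alpha: int = 0) -> list[np.ndarray]:
    L = disc.levels
    valid = L > 0
    ng = disc.n_levels
    dep = np.zeros(L.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        src, dst = _shift_slices(L.shape, d)
        hit = valid[src] & valid[dst] & (np.abs(L[src] - L[dst]) <= alpha)
        dep[src] += hit
        dep[dst] += hit
    M = np.zeros((ng, 27), dtype=np.float64)
    np.add.at(M, (L[valid] - 1, dep[valid]), 1.0)
    # trim trailing all-zero dependence columns (j = dep + 1 >= 1)
    last = int(np.max(np.nonzero(M.sum(axis=0))[0])) if M.any() else 0
    return [M[:, : last + 1]]


def compute_texture(disc: DiscretizedROI, kind: str, **params) -> TextureMatrix:
    """Build the texture matrix of the requested family from a discretized ROI."""
    if disc.n_levels < 1:
        raise ValueError("discretized ROI must have at least one level")
    n_voxels = int((disc.levels > 0).sum())
    params = {"n_voxels": n_voxels, **params}
    kind = kind.upper()
    if kind == "GLCM":
        mats = _glcm(disc)
        params = {"distance": 1, "n_directions": 13, "symmetric": True, **params}
    elif kind == "GLRLM":
        mats = _glrlm(disc)
        params = {"n_directions": 13, **params}
    elif kind == "GLSZM":
        mats = _glszm(disc)
        params = {"connectivity": 26, **params}
    elif kind == "NGTDM":
        mats = _ngtdm(disc)
        params = {"distance": 1, "neighborhood": 26, **params}
    elif kind == "GLDM":
        alpha = int(params.pop("alpha", 0))
        mats = _gldm(disc, alpha=alpha)
        params = {"distance": 1, "alpha": alpha, **params}
    else:
        raise ValueError(f"unknown texture matrix kind {kind!r}")
    return TextureMatrix(kind=kind, matrices=mats, n_levels=disc.n_levels, params=params)


# ---------------------------------------------------------------------------
# features

_EPS = np.finfo(np.float64).eps

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

TEXTURE_FEATURE_NAMES = {
    "GLCM": GLCM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
    "GLDM": GLDM_FEATURES,
}


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    total = P.sum()
    if total == 0:
        return dict.fromkeys(GLCM_FEATURES, float("nan"))
    p = P / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = (i * px).sum()
    uy = (i * py).sum()
    sx = np.sqrt(((i - ux) ** 2 * px).sum())
    sy = np.sqrt(((i - uy) ** 2 * py).sum())

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    pxy_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    pxy_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kd = np.arange(0, ng, dtype=np.float64)

    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    with np.errstate(divide="ignore"):
        lpxpy = np.where(px[:, None] * py[None, :] > 0,
                         np.log2(np.maximum(px[:, None] * py[None, :], _EPS)), 0.0)
    hxy1 = float(-(p * lpxpy).sum())
    hxy2 = float(-((px[:, None] * py[None, :]) * lpxpy).sum())

    da = (kd * pxy_diff).sum()
    contrast = ((ii - jj) ** 2 * p).sum()

    out = {
        "Autocorrelation": (ii * jj * p).sum(),
        "ClusterProminence": (((ii + jj - ux - uy) ** 4) * p).sum(),
        "ClusterShade": (((ii + jj - ux - uy) ** 3) * p).sum(),
        "ClusterTendency": (((ii + jj - ux - uy) ** 2) * p).sum(),
        "Contrast": contrast,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(pxy_diff),
        "DifferenceVariance": ((kd - da) ** 2 * pxy_diff).sum(),
        "Id": (p / (1.0 + kdiff)).sum(),
        "Idm": (p / (1.0 + kdiff**2)).sum(),
        "Idmn": (p / (1.0 + (kdiff / ng) ** 2)).sum(),
        "Idn": (p / (1.0 + kdiff / ng)).sum(),
        "JointAverage": (ii * p).sum(),
        "JointEnergy": (p**2).sum(),
        "JointEntropy": hxy,
        "MaximumProbability": p.max(),
        "SumAverage": (ks * pxy_sum).sum(),
        "SumEntropy": _entropy(pxy_sum),
        "SumSquares": (((ii - ux) ** 2) * p).sum(),
    }

    out["Correlation"] = (
        ((ii * jj * p).sum() - ux * uy) / (sx * sy) if sx * sy > 0 else 1.0
    )
    mask_off = kdiff > 0
    out["InverseVariance"] = (
        (p[mask_off] / kdiff[mask_off] ** 2).sum() if mask_off.any() else 0.0
    )
    div = max(hx, hy)
    out["Imc1"] = (hxy - hxy1) / div if div > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["Imc2"] = float(np.sqrt(max(arg, 0.0)))

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px_i py_k)
    if ng > 1 and (px > 0).sum() > 1:
        nz = px > 0
        pp = p[np.ix_(nz, nz)]
        pxn, pyn = px[nz], py[nz]
        Q = (pp / pxn[:, None]) @ (pp / np.maximum(pyn, _EPS)[:, None]).T
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        out["MCC"] = float(np.sqrt(max(eig[-2], 0.0))) if eig.size > 1 else 1.0
    else:
        out["MCC"] = 1.0
    return {k: float(v) for k, v in out.items()}


def _rlm_like_features(M: np.ndarray, names, n_voxels: int | None):
    """Shared feature algebra for run-length / size-zone / dependence matrices.

    ``M[i-1, j-1]`` counts entities of gray level i and size/length/dependence
    j; the three families differ only in naming and in the normalizing voxel
    count used by the percentage features.
    """
    ng, nj = M.shape
    nz = M.sum()
    if nz == 0:
        return dict.fromkeys(names, float("nan"))
    p = M / nz
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nj + 1, dtype=np.float64)
    pg = p.sum(axis=1)  # per gray level
    pj = p.sum(axis=0)  # per size
    mu_i = (i * pg).sum()
    mu_j = (j * pj).sum()
    out = {
        "GLN": ((M.sum(axis=1) ** 2).sum()) / nz,
        "GLNN": (pg**2).sum(),
        "GLV": (((i - mu_i) ** 2) * pg).sum(),
        "HGL": ((i**2) * pg).sum(),
        "LGL": ((pg / i**2)).sum(),
        "LJ": ((j**2) * pj).sum(),
        "SJ": ((pj / j**2)).sum(),
        "JN": ((M.sum(axis=0) ** 2).sum()) / nz,
        "JNN": (pj**2).sum(),
        "JV": (((j - mu_j) ** 2) * pj).sum(),
        "ENT": _entropy(p.ravel()),
        "LJHGL": (((j**2)[None, :] * (i**2)[:, None] * p).sum()),
        "LJLGL": (((j**2)[None, :] / (i**2)[:, None] * p).sum()),
        "SJHGL": (((i**2)[:, None] / (j**2)[None, :] * p).sum()),
        "SJLGL": ((p / ((i**2)[:, None] * (j**2)[None, :])).sum()),
        "PCT": nz / n_voxels if n_voxels else float("nan"),
    }
    return out


def _glrlm_features_single(M: np.ndarray, n_voxels: int) -> dict[str, float]:
    f = _rlm_like_features(M, GLRLM_FEATURES, n_voxels)
    return {
        "GrayLevelNonUniformity": f["GLN"],
        "GrayLevelNonUniformityNormalized": f["GLNN"],
        "GrayLevelVariance": f["GLV"],
        "HighGrayLevelRunEmphasis": f["HGL"],
        "LongRunEmphasis": f["LJ"],
        "LongRunHighGrayLevelEmphasis": f["LJHGL"],
        "LongRunLowGrayLevelEmphasis": f["LJLGL"],
        "LowGrayLevelRunEmphasis": f["LGL"],
        "RunEntropy": f["ENT"],
        "RunLengthNonUniformity": f["JN"],
        "RunLengthNonUniformityNormalized": f["JNN"],
        "RunPercentage": f["PCT"],
        "RunVariance": f["JV"],
        "ShortRunEmphasis": f["SJ"],
        "ShortRunHighGrayLevelEmphasis": f["SJHGL"],
        "ShortRunLowGrayLevelEmphasis": f["SJLGL"],
    }


def _glszm_features(M: np.ndarray, n_voxels: int) -> dict[str, float]:
    f = _rlm_like_features(M, GLSZM_FEATURES, n_voxels)
    return {
        "GrayLevelNonUniformity": f["GLN"],
        "GrayLevelNonUniformityNormalized": f["GLNN"],
        "GrayLevelVariance": f["GLV"],
        "HighGrayLevelZoneEmphasis": f["HGL"],
        "LargeAreaEmphasis": f["LJ"],
        "LargeAreaHighGrayLevelEmphasis": f["LJHGL"],
        "LargeAreaLowGrayLevelEmphasis": f["LJLGL"],
        "LowGrayLevelZoneEmphasis": f["LGL"],
        "SizeZoneNonUniformity": f["JN"],
        "SizeZoneNonUniformityNormalized": f["JNN"],
        "SmallAreaEmphasis": f["SJ"],
        "SmallAreaHighGrayLevelEmphasis": f["SJHGL"],
        "SmallAreaLowGrayLevelEmphasis": f["SJLGL"],
        "ZoneEntropy": f["ENT"],
        "ZonePercentage": f["PCT"],
        "ZoneVariance": f["JV"],
    }


def _gldm_features(M: np.ndarray) -> dict[str, float]:
    f = _rlm_like_features(M, GLDM_FEATURES, None)
    return {
        "DependenceEntropy": f["ENT"],
        "DependenceNonUniformity": f["JN"],
        "DependenceNonUniformityNormalized": f["JNN"],
        "DependenceVariance": f["JV"],
        "GrayLevelNonUniformity": f["GLN"],
        "GrayLevelVariance": f["GLV"],
        "HighGrayLevelEmphasis": f["HGL"],
        "LargeDependenceEmphasis": f["LJ"],
        "LargeDependenceHighGrayLevelEmphasis": f["LJHGL"],
        "LargeDependenceLowGrayLevelEmphasis": f["LJLGL"],
        "LowGrayLevelEmphasis": f["LGL"],
        "SmallDependenceEmphasis": f["SJ"],
        "SmallDependenceHighGrayLevelEmphasis": f["SJHGL"],
        "SmallDependenceLowGrayLevelEmphasis": f["SJLGL"],
    }


def _ngtdm_features(M: np.ndarray) -> dict[str, float]:
    n_i, s_i = M[:, 0], M[:, 1]
    nvp = n_i.sum()
    if nvp == 0:
        return dict.fromkeys(NGTDM_FEATURES, float("nan"))
    p_i = n_i / nvp
    ng = M.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p_i[present], s_i[present]

    coarse_den = (pp * sp).sum()
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6  # capped, flat ROI

    if ngp > 1:
        diff_ij = np.abs(ip[:, None] - ip[None, :])
        pij = pp[:, None] * pp[None, :]
        contrast = (pij * diff_ij**2).sum() / (ngp * (ngp - 1)) * (sp.sum() / nvp)
        busy_den = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
        busyness = (pp * sp).sum() / busy_den if busy_den > 0 else 0.0
        complexity = (
            np.abs(ip[:, None] - ip[None, :])
            * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :])
        ).sum() / nvp
        s_sum = sp.sum()
        strength = (
            ((pp[:, None] + pp[None, :]) * diff_ij**2).sum() / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }


def texture_features(tm: TextureMatrix) -> dict[str, float]:
    """Feature values for one texture matrix; directional families (GLCM,
    GLRLM) are averaged over their 13 per-direction matrices."""
    kind = tm.kind
    if kind == "GLCM":
        # directions with no valid voxel pair (e.g. out-of-plane on a
        # single-slice ROI) contribute nothing to the average
        per_dir = [_glcm_features_single(P) for P in tm.matrices if P.sum() > 0]
        if not per_dir:
            return dict.fromkeys(GLCM_FEATURES, float("nan"))
        return {
            name: float(np.mean([f[name] for f in per_dir]))
            for name in GLCM_FEATURES
        }
    if kind == "GLRLM":
        n_vox = tm.params.get("n_voxels")
        per_dir = [
            _glrlm_features_single(M, n_vox) for M in tm.matrices if M.sum() > 0
        ]
        if not per_dir:
            return dict.fromkeys(GLRLM_FEATURES, float("nan"))
        return {
            name: float(np.mean([f[name] for f in per_dir]))
            for name in GLRLM_FEATURES
        }
    if kind == "GLSZM":
        return {
            k: float(v)
            for k, v in _glszm_features(
                tm.matrices[0], tm.params.get("n_voxels")
            ).items()
        }
    if kind == "NGTDM":
        return _ngtdm_features(tm.matrices[0])
    if kind == "GLDM":
        return {k: float(v) for k, v in _gldm_features(tm.matrices[0]).items()}
    raise ValueError(f"unknown texture matrix kind {kind!r}")
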