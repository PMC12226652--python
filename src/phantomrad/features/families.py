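"""The five texture-feature families computed from their matrices.

GLCM and GLRLM features are computed per direction and averaged over the
13 unique 3D directions; GLSZM, GLDM and NGTDM are direction-free.
Feature definitions follow the reference radiomics feature set: 24 GLCM,
16 run-length, 16 size-zone, 14 dependence and 5 gray-tone-difference
features.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRoi
from .matrices import (glcm_matrix, gldm_matrix, glrlm_matrix, glszm_matrix,
                       ngtdm_table, unique_directions)

__all__ = [
    "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "GLDM_NAMES", "NGTDM_NAMES",
    "glcm_features", "glrlm_features", "glszm_features", "gldm_features",
    "ngtdm_features",
]

COARSENESS_MAX = 1e6  # cap when the NGTDM coarseness denominator vanishes

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)

GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _plogp(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)) + 0.0)  # +0.0 avoids IEEE -0.0


# ------------------------------------------------------------------ GLCM

def _glcm_features_single(P: np.ndarray, ng: int, degenerate: set):
    """24 co-occurrence features from one symmetric count matrix."""
    total = P.sum()
    if total == 0:
        # no voxel pairs along this direction: treat as single-cell
        p = np.zeros((ng, ng))
        p[0, 0] = 1.0
    else:
        p = P / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))

    # difference and sum distributions
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, p.ravel())

    da = float(np.sum(k_diff * p_diff))
    feats = {
        "Autocorrelation": float(np.sum(I * J * p)),
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((I + J - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((I + J - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((I + J - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((I - J) ** 2 * p)),
        "DifferenceAverage": da,
        "DifferenceEntropy": _plogp(p_diff),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(p * p)),
        "JointEntropy": _plogp(p.ravel()),
        "Id": float(np.sum(p / (1.0 + np.abs(I - J)))),
        "Idm": float(np.sum(p / (1.0 + (I - J) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + (I - J) ** 2 / ng ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(I - J) / ng))),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": _plogp(p_sum),
        "SumSquares": sigma2,
    }

    off = I != J
    iv = np.zeros_like(p)
    iv[off] = p[off] / (I[off] - J[off]) ** 2
    feats["InverseVariance"] = float(iv.sum())

    if sigma2 > 0:
        feats["Correlation"] = float(
            (np.sum(I * J * p) - mu * mu) / sigma2)
    else:
        feats["Correlation"] = 1.0
        degenerate.add("Correlation")

    # information measures of correlation
    hxy = feats["JointEntropy"]
    pxy = np.outer(px, px)
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-np.sum(p[mask] * np.log2(pxy[mask])))
    mask2 = pxy > 0
    hxy2 = float(-np.sum(pxy[mask2] * np.log2(pxy[mask2])))
    hx = _plogp(px)
    feats["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    feats["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if ng == 1:
        feats["MCC"] = 1.0
        degenerate.add("MCC")
    else:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
        pk = np.where(px > 0, px, 1.0)
        Q = (p / pk[:, None]) @ (p / pk[None, :]).T
        ev = np.linalg.eigvals(Q)
        ev = np.sort(np.real(ev))
        second = ev[-2] if ev.size >= 2 else 0.0
        feats["MCC"] = float(np.sqrt(max(0.0, second)))
    return feats


def glcm_features(droi: DiscretizedRoi, distance: int = 1,
                  three_d: bool = True):
    """24 GLCM features averaged over directions."""
    degenerate: set[str] = set()
    dirs = unique_directions(three_d)
    acc = {name: 0.0 for name in GLCM_NAMES}
    for d in dirs:
        off = tuple(c * distance for c in d)
        P = glcm_matrix(droi.levels, droi.ng, off)
        f = _glcm_features_single(P, droi.ng, degenerate)
        for name in GLCM_NAMES:
            acc[name] += f[name]
    n = len(dirs)
    return {name: v / n for name, v in acc.items()}, degenerate


# ------------------------------------------------- run-length / size-zone

def _rl_sz_features(P: np.ndarray, np_voxels: int, names, kind: str):
    """Shared weighted-sum machinery for run-length and size-zone matrices.

    ``kind`` selects the name prefix mapping ('run' or 'zone').
    """
    nz = P.sum()
    if nz == 0:
        P = np.zeros((1, 1))
        P[0, 0] = 1.0
        nz = 1.0
    ng, nr = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nr + 1, dtype=np.float64)
    pg = P.sum(axis=1)  # per gray level
    pr = P.sum(axis=0)  # per run length / zone size
    p = P / nz
    mu_i = float(np.sum(i * pg / nz))
    mu_j = float(np.sum(j * pr / nz))

    vals = {
        "sre": float(np.sum(pr / j ** 2) / nz),
        "lre": float(np.sum(pr * j ** 2) / nz),
        "gln": float(np.sum(pg ** 2) / nz),
        "glnn": float(np.sum(pg ** 2) / nz ** 2),
        "rln": float(np.sum(pr ** 2) / nz),
        "rlnn": float(np.sum(pr ** 2) / nz ** 2),
        "rp": float(nz / np_voxels),
        "glv": float(np.sum((i - mu_i) ** 2 * pg / nz)),
        "rv": float(np.sum((j - mu_j) ** 2 * pr / nz)),
        "re": _plogp(p.ravel()),
        "lgle": float(np.sum(pg / i ** 2) / nz),
        "hgle": float(np.sum(pg * i ** 2) / nz),
        "srlgle": float(np.sum(P / np.outer(i ** 2, j ** 2)) / nz),
        "srhgle": float(np.sum(P * np.outer(i ** 2, 1.0 / j ** 2)) / nz),
        "lrlgle": float(np.sum(P * np.outer(1.0 / i ** 2, j ** 2)) / nz),
        "lrhgle": float(np.sum(P * np.outer(i ** 2, j ** 2)) / nz),
    }
    if kind == "run":
        mapping = {
            "GrayLevelNonUniformity": "gln",
            "GrayLevelNonUniformityNormalized": "glnn",
            "GrayLevelVariance": "glv",
            "HighGrayLevelRunEmphasis": "hgle",
            "LongRunEmphasis": "lre",
            "LongRunHighGrayLevelEmphasis": "lrhgle",
            "LongRunLowGrayLevelEmphasis": "lrlgle",
            "LowGrayLevelRunEmphasis": "lgle",
            "RunEntropy": "re",
            "RunLengthNonUniformity": "rln",
            "RunLengthNonUniformityNormalized": "rlnn",
            "RunPercentage": "rp",
            "RunVariance": "rv",
            "ShortRunEmphasis": "sre",
            "ShortRunHighGrayLevelEmphasis": "srhgle",
            "ShortRunLowGrayLevelEmphasis": "srlgle",
        }
    else:
        mapping = {
            "GrayLevelNonUniformity": "gln",
            "GrayLevelNonUniformityNormalized": "glnn",
            "GrayLevelVariance": "glv",
            "HighGrayLevelZoneEmphasis": "hgle",
            "LargeAreaEmphasis": "lre",
            "LargeAreaHighGrayLevelEmphasis": "lrhgle",
            "LargeAreaLowGrayLevelEmphasis": "lrlgle",
            "LowGrayLevelZoneEmphasis": "lgle",
            "SizeZoneNonUniformity": "rln",
            "SizeZoneNonUniformityNormalized": "rlnn",
            "SmallAreaEmphasis": "sre",
            "SmallAreaHighGrayLevelEmphasis": "srhgle",
            "SmallAreaLowGrayLevelEmphasis": "srlgle",
            "ZoneEntropy": "re",
            "ZonePercentage": "rp",
            "ZoneVariance": "rv",
        }
    return {name: vals[key] for name, key in mapping.items()}


def glrlm_features(droi: DiscretizedRoi, three_d: bool = True):
    """16 run-length features averaged over directions."""
    dirs = unique_directions(three_d)
    acc = {name: 0.0 for name in GLRLM_NAMES}
    for d in dirs:
        P = glrlm_matrix(droi.levels, droi.ng, d)
        f = _rl_sz_features(P, droi.n_voxels, GLRLM_NAMES, "run")
        for name in GLRLM_NAMES:
            acc[name] += f[name]
    n = len(dirs)
    return {name: v / n for name, v in acc.items()}, set()


def glszm_features(droi: DiscretizedRoi, three_d: bool = True):
    """16 size-zone features (no direction averaging)."""
    P = glszm_matrix(droi.levels, droi.ng, three_d=three_d)
    return _rl_sz_features(P, droi.n_voxels, GLSZM_NAMES, "zone"), set()


# ------------------------------------------------------------------ GLDM

def gldm_features(droi: DiscretizedRoi, alpha: int = 0, distance: int = 1,
                  three_d: bool = True):
    """14 dependence-matrix features."""
    P = gldm_matrix(droi.levels, droi.ng, alpha=alpha, distance=distance,
                    three_d=three_d)
    nz = P.sum()
    ng, nd = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nd + 1, dtype=np.float64)  # dependence + 1
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    p = P / nz
    mu_i = float(np.sum(i * pg / nz))
    mu_j = float(np.sum(j * pd / nz))
    feats = {
        "SmallDependenceEmphasis": float(np.sum(pd / j ** 2) / nz),
        "LargeDependenceEmphasis": float(np.sum(pd * j ** 2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg ** 2) / nz),
        "DependenceNonUniformity": float(np.sum(pd ** 2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd ** 2) / nz ** 2),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * pg / nz)),
        "DependenceVariance": float(np.sum((j - mu_j) ** 2 * pd / nz)),
        "DependenceEntropy": _plogp(p.ravel()),
        "LowGrayLevelEmphasis": float(np.sum(pg / i ** 2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(pg * i ** 2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            np.sum(P / np.outer(i ** 2, j ** 2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(
            np.sum(P * np.outer(i ** 2, 1.0 / j ** 2)) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(
            np.sum(P * np.outer(1.0 / i ** 2, j ** 2)) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(
            np.sum(P * np.outer(i ** 2, j ** 2)) / nz),
    }
    return feats, set()


# ----------------------------------------------------------------- NGTDM

def ngtdm_features(droi: DiscretizedRoi, distance: int = 1,
                   three_d: bool = True):
    """5 neighbourhood gray-tone difference features."""
    degenerate: set[str] = set()
    n_i, s_i = ngtdm_table(droi.levels, droi.ng, distance=distance,
                           three_d=three_d)
    nvp = n_i.sum()
    p_i = n_i / nvp if nvp > 0 else n_i
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, droi.ng + 1, dtype=np.float64)

    coarse_den = float(np.sum(p_i * s_i))
    if coarse_den > 0:
        coarseness = min(1.0 / coarse_den, COARSENESS_MAX)
        if 1.0 / coarse_den > COARSENESS_MAX:
            degenerate.add("Coarseness")
    else:
        coarseness = COARSENESS_MAX
        degenerate.add("Coarseness")

    ii = i[present]
    pp = p_i[present]
    ss = s_i[present]

    if ngp > 1:
        diff2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = (float(np.sum(np.outer(pp, pp) * diff2))
                    / (ngp * (ngp - 1))) * (float(s_i.sum()) / nvp)
    else:
        contrast = 0.0

    ipi = ii * pp
    busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
    busyness = float(np.sum(pp * ss)) / busy_den if busy_den > 0 else 0.0

    if ngp > 0:
        num = np.abs(ii[:, None] - ii[None, :]) * (
            (pp * ss)[:, None] + (pp * ss)[None, :])
        den = pp[:, None] + pp[None, :]
        complexity = float(np.sum(num / den)) / nvp
    else:
        complexity = 0.0

    s_total = float(ss.sum())
    if s_total > 0 and ngp > 1:
        strength = float(np.sum(
            (pp[:, None] + pp[None, :]) * (ii[:, None] - ii[None, :]) ** 2
        )) / s_total
    else:
        strength = 0.0

    feats = {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
    return feats, degenerate
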