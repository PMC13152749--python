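"""Curvature features of the DEM's implicit isosurfaces.

Every voxel is treated as lying on the level surface of the DEM through it.
From gradient g and Hessian H of the map, the standard implicit-surface
formulas give Gaussian curvature

    K = (gᵀ adj(H) g) / |g|⁴        (adj = adjugate)

and mean curvature

    H_c = (gᵀ H g − |g|² trace H) / (2 |g|³),

with principal curvatures κ1 ≥ κ2 = H_c ± sqrt(max(H_c² − K, 0)).  The
orientation convention follows the gradient direction of the map: a
spherical distance field r has κ1 = κ2 = −1/r and K = 1/r² under these
formulas.

Derived descriptors: shape index S = (2/π)·atan((κ1+κ2)/(κ1−κ2)) ∈ [−1, 1]
(flat umbilics map to 0, curved umbilics to sign(H_c)), curvedness
sqrt((κ1²+κ2²)/2), sharpness κ1−κ2, and total curvature Σ|K| over the ROI.
Voxels whose gradient magnitude falls below a relative floor have no
well-defined isosurface normal and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dem import DerivativeField, derivative_fields
from .volume import ImageVolume

__all__ = ["CurvatureSet", "curvature_features"]

#: voxels with |g| below this fraction of the ROI maximum are excluded
GRADIENT_FLOOR = 1e-6


@dataclass
class CurvatureSet:
    """Per-voxel curvature maps over ROI voxels plus scalar summaries.

    The per-voxel arrays are 1D, aligned with ``np.argwhere(valid)``.
    ``defined`` is False when every ROI voxel fell below the gradient floor,
    in which case the summaries are NaN.
    """

    gaussian: np.ndarray
    mean: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray
    shape_index: np.ndarray
    curvedness: np.ndarray
    sharpness: np.ndarray
    total_curvature: float
    valid: np.ndarray
    defined: bool
    summaries: dict[str, float] = field(default_factory=dict)


def _summaries(cs: dict[str, np.ndarray], total: float, defined: bool) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, arr in cs.items():
        for stat, fn in (("mean", np.mean), ("median", np.median), ("max", np.max)):
            key = f"curv_{name}_{stat}"
            out[key] = float(fn(arr)) if defined and arr.size else float("nan")
    out["curv_total_curvature"] = total if defined else float("nan")
    return out


def curvature_features(
    dem_values: np.ndarray,
    mask: np.ndarray,
    sigma: float = 1.0,
    deriv: DerivativeField | None = None,
) -> CurvatureSet:
    """Curvature descriptors of the DEM isosurfaces inside the mask.

    ``deriv`` may supply precomputed derivative fields (e.g. analytic ones in
    tests); otherwise Gaussian derivatives at scale ``sigma`` are taken on
    the full ``dem_values`` array.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    if deriv is None:
        vol = ImageVolume(np.asarray(dem_values, dtype=float))
        deriv = derivative_fields(vol, sigma_deriv=sigma)
    g = deriv.gradient[mask]
    H = deriv.hessian[mask]
    gnorm = np.linalg.norm(g, axis=1)
    floor = GRADIENT_FLOOR * max(float(gnorm.max()), np.finfo(float).tiny)
    ok = gnorm >= max(floor, np.finfo(float).tiny)
    defined = bool(ok.any())
    g, H, gnorm = g[ok], H[ok], gnorm[ok]

    if defined:
        # adjugate of a symmetric 3x3: cofactor matrix (equals its transpose)
        adj = np.empty_like(H)
        a, b, c = H[:, 0, 0], H[:, 0, 1], H[:, 0, 2]
        d, e, f = H[:, 1, 1], H[:, 1, 2], H[:, 2, 2]
        adj[:, 0, 0] = d * f - e * e
        adj[:, 0, 1] = adj[:, 1, 0] = c * e - b * f
        adj[:, 0, 2] = adj[:, 2, 0] = b * e - c * d
        adj[:, 1, 1] = a * f - c * c
        adj[:, 1, 2] = adj[:, 2, 1] = b * c - a * e
        adj[:, 2, 2] = a * d - b * b
        K = np.einsum("ni,nij,nj->n", g, adj, g) / gnorm**4
        gHg = np.einsum("ni,nij,nj->n", g, H, g)
        trH = np.trace(H, axis1=1, axis2=2)
        Hc = (gHg - gnorm**2 * trH) / (2.0 * gnorm**3)
        disc = np.sqrt(np.maximum(Hc**2 - K, 0.0))
        k1 = Hc + disc
        k2 = Hc - disc
        denom = k1 - k2
        num = k1 + k2
        tiny = 1e-12 * max(float(np.abs(np.concatenate([k1, k2])).max()), 1.0)
        safe = np.where(denom > tiny, denom, 1.0)
        shape_index = np.where(
            denom > tiny,
            (2.0 / np.pi) * np.arctan(num / safe),
            np.where(np.abs(num) > tiny, np.sign(num), 0.0),
        )
        curvedness = np.sqrt((k1**2 + k2**2) / 2.0)
        sharpness = k1 - k2
        total = float(np.abs(K).sum())
    else:
        K = Hc = k1 = k2 = shape_index = curvedness = sharpness = np.empty(0)
        total = float("nan")

    maps = {
        "gaussian": K,
        "mean": Hc,
        "kappa1": k1,
        "kappa2": k2,
        "shape_index": shape_index,
        "curvedness": curvedness,
        "sharpness": sharpness,
    }
    return CurvatureSet(
        gaussian=K,
        mean=Hc,
        kappa1=k1,
        kappa2=k2,
        shape_index=shape_index,
        curvedness=curvedness,
        sharpness=sharpness,
        total_curvature=total,
        valid=ok,
        defined=defined,
        summaries=_summaries(maps, total, defined),
    )
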