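"""Differential Elasticity Map (DEM) generation.

The DEM is a per-voxel scalar response computed from Gaussian-derivative
fields of a CT ROI under the assumption that soft tissue deforms locally in
an approximately affine way.  With gradient g = ∇I and Hessian H, the
elasticity response is

    E = gᵀ (H + εI)⁻¹ g  =  trace((H + εI)⁻¹ (g gᵀ)),

which is invariant to invertible linear coordinate changes I'(x) = I(Ax)
(g' = Aᵀg, H' = AᵀHA cancel exactly) and to intensity offsets.  ε is a small
regulariser for poorly conditioned second-order structure.  Because H is in
general indefinite, E can be negative; the magnitude |E| is taken before the
monotone root compression and the final min–max rescale to [0, 255].

The whole module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume, extract_roi, resample_isotropic

__all__ = [
    "DemParams",
    "DerivativeField",
    "ElasticityMap",
    "gaussian_smooth",
    "derivative_fields",
    "elasticity_response",
    "compress_normalize",
    "generate_dem",
]

#: width of the Gaussian-derivative kernels in standard deviations; the
#: default scipy value (4) leaves ~0.5% truncation error in second
#: derivatives of smooth fields, 6 brings it below 1e-5.
_TRUNCATE = 6.0


@dataclass
class DemParams:
    """Parameters of the DEM computation.

    sigma_smooth / sigma_deriv are in voxels (== mm after 1 mm isotropic
    resampling).  ``epsilon=None`` selects a scale-aware default of
    1e-3 × max|eig(H)| over the ROI, floored at 1e-6.  ``compression_exponent``
    is the root exponent r ∈ (0, 1] applied before rescaling.
    """

    sigma_smooth: float = 1.0
    sigma_deriv: float = 1.0
    epsilon: float | None = None
    compression_exponent: float = 0.5
    output_range: tuple[float, float] = (0.0, 255.0)
    target_mm: float = 1.0
    roi_pad: int = 4

    def __post_init__(self) -> None:
        if self.sigma_smooth <= 0 or self.sigma_deriv <= 0:
            raise ValueError("smoothing and derivative sigmas must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive (or None for automatic)")
        if not 0 < self.compression_exponent <= 1:
            raise ValueError("compression exponent must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "sigma_smooth": self.sigma_smooth,
            "sigma_deriv": self.sigma_deriv,
            "epsilon": self.epsilon,
            "compression_exponent": self.compression_exponent,
            "output_range": list(self.output_range),
            "target_mm": self.target_mm,
            "roi_pad": self.roi_pad,
        }


@dataclass
class DerivativeField:
    """Per-voxel gradient (…, 3) and symmetric Hessian (…, 3, 3)."""

    gradient: np.ndarray
    hessian: np.ndarray


@dataclass
class ElasticityMap:
    """DEM aligned to its source grid.

    ``raw_values`` holds |E| before compression, ``normalized_values`` the
    [0, 255] map.  ``diagnostics`` records the ε actually used, the fraction
    of negative-response voxels and the count of numerically singular voxels.
    """

    raw_values: np.ndarray
    normalized_values: np.ndarray
    params: DemParams
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diagnostics: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.normalized_values.shape


def gaussian_smooth(volume: ImageVolume, sigma: float = 1.0) -> ImageVolume:
    """Linear shift-invariant Gaussian smoothing (reflect boundary)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = ndimage.gaussian_filter(volume.data, sigma=sigma, mode="reflect", truncate=_TRUNCATE)
    return ImageVolume(out, volume.spacing, volume.origin)


def _derivative_kernels(sigma: float, truncate: float = _TRUNCATE):
    """Sampled derivative-of-Gaussian kernels with exact discrete moments.

    The raw sampled kernels carry small truncation/discretisation residuals
    (the order-2 kernel does not sum exactly to zero), which would make the
    Hessian — and hence the elasticity response — sensitive to intensity
    offsets.  The kernels are corrected so that, discretely, order 0 sums to
    1, order 1 annihilates constants and reproduces the slope of a ramp, and
    order 2 annihilates constants and ramps and reproduces the second
    derivative of a parabola.
    """
    r = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    k0 = g / g.sum()
    k1 = x * g
    k1 = k1 / (x * k1).sum()  # correlate1d: out = sum k[j] f(x+j)
    k2 = (x**2 / sigma**2 - 1.0) * g
    k2 = k2 - (k2.sum() / g.sum()) * g  # zero total mass, keeps symmetry
    k2 = k2 * (2.0 / (x**2 * k2).sum())
    return k0, k1, k2


def derivative_fields(volume: ImageVolume, sigma_deriv: float = 1.0) -> DerivativeField:
    """Gaussian-derivative gradient and Hessian of a volume.

    Uses separable, moment-corrected derivative-of-Gaussian kernels at scale
    ``sigma_deriv`` with reflect boundaries.  Exact for affine and quadratic
    fields in the interior and exactly invariant to intensity offsets.
    """
    data = volume.data
    if any(n < 4 for n in data.shape):
        raise ValueError(f"volume too small for derivative filters: {data.shape}")
    k0, k1, k2 = _derivative_kernels(sigma_deriv)

    def separable(kernels):
        out = data
        for axis, k in enumerate(kernels):
            out = ndimage.correlate1d(out, k, axis=axis, mode="reflect")
        return out

    grad = np.empty(data.shape + (3,))
    hess = np.empty(data.shape + (3, 3))
    for i in range(3):
        grad[..., i] = separable([k1 if a == i else k0 for a in range(3)])
    for i in range(3):
        for j in range(i, 3):
            if i == j:
                kernels = [k2 if a == i else k0 for a in range(3)]
            else:
                kernels = [k1 if a in (i, j) else k0 for a in range(3)]
            d = separable(kernels)
            hess[..., i, j] = d
            hess[..., j, i] = d
    return DerivativeField(grad, hess)


def _auto_epsilon(eigvals: np.ndarray) -> float:
    lam_max = float(np.abs(eigvals).max()) if eigvals.size else 0.0
    return max(1e-3 * lam_max, 1e-6)


def elasticity_response(
    deriv: DerivativeField,
    epsilon: float | None = None,
    roi: np.ndarray | None = None,
):
    """Per-voxel elasticity response |gᵀ(H+εI)⁻¹g|.

    The inversion goes through the symmetric eigendecomposition of H with
    every eigenvalue shifted by ε (exactly the spectrum of H + εI).  Voxels
    where a shifted eigenvalue underflows are set to 0 and counted.  If
    ``roi`` (a boolean array) is given, the automatic ε is calibrated on ROI
    voxels only.

    Returns ``(E, diagnostics)`` with E ≥ 0 everywhere and diagnostics
    recording ε, the fraction of negative raw responses inside the ROI and
    the number of singular voxels.
    """
    g = deriv.gradient
    H = deriv.hessian
    shape = g.shape[:-1]
    lam, vec = np.linalg.eigh(H.reshape(-1, 3, 3))
    gf = g.reshape(-1, 3)
    scope = lam if roi is None else lam.reshape(shape + (3,))[roi].reshape(-1, 3)
    if epsilon is None:
        epsilon = _auto_epsilon(scope)
    # sign-preserving magnitude shift: lam -> sign(lam) (|lam| + eps).
    # The plain shift lam + eps is singular wherever lam = -eps, which sprays
    # unbounded response spikes across any ROI with indefinite second-order
    # structure; this variant has the same eps -> 0 limit, agrees exactly for
    # positive semi-definite Hessians, and bounds the response by |g|^2/eps.
    sign = np.where(lam < 0, -1.0, 1.0)
    shifted = sign * (np.abs(lam) + epsilon)
    proj = np.einsum("ni,nij->nj", gf, vec)
    terms = proj**2 / shifted
    e_signed = terms.sum(axis=1)
    bad = ~np.isfinite(e_signed)
    e_signed[bad] = 0.0
    e_signed = e_signed.reshape(shape)
    inside = np.ones(shape, bool) if roi is None else roi
    n_in = max(int(inside.sum()), 1)
    diagnostics = {
        "epsilon": float(epsilon),
        "negative_fraction": float((e_signed[inside] < 0).sum() / n_in),
        "singular_voxels": int(bad.sum()),
    }
    return np.abs(e_signed), diagnostics


def compress_normalize(
    raw: np.ndarray,
    r: float = 0.5,
    out_range: tuple[float, float] = (0.0, 255.0),
    stats_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Root compression v ↦ vʳ followed by linear min–max rescale.

    Min/max statistics are taken over ``stats_mask`` voxels when given (so
    background cannot dominate the rescale).  Rank order is preserved; a
    constant raw map yields an all-zero output by convention.  Output is
    clipped to the range, which only affects voxels outside the stats mask.
    """
    if not 0 < r <= 1:
        raise ValueError("compression exponent must lie in (0, 1]")
    raw = np.asarray(raw, dtype=float)
    if raw.min() < 0:
        raise ValueError("raw elasticity values must be non-negative")
    comp = np.power(raw, r)
    sel = comp if stats_mask is None else comp[stats_mask]
    if sel.size == 0:
        raise ValueError("empty statistics mask")
    lo, hi = float(sel.min()), float(sel.max())
    a, b = out_range
    if hi - lo <= 0:
        return np.zeros_like(comp)
    out = (comp - lo) / (hi - lo) * (b - a) + a
    return np.clip(out, a, b)


def generate_dem(
    volume: ImageVolume,
    mask: BinaryMask,
    params: DemParams | None = None,
):
    """Full DEM pipeline: resample → smooth → derivatives → E → normalize.

    Both volume and mask are resampled to ``params.target_mm`` isotropic
    voxels, the ROI is cropped with ``params.roi_pad`` margin, and the
    response is computed on the crop.  Normalisation statistics use only the
    padded mask (mask dilated by the pad) so background air does not set the
    rescale; voxels outside it are zeroed.  The map is re-embedded into the
    full resampled grid.

    Returns ``(ElasticityMap, BinaryMask)`` where the mask is the resampled
    lymph-node mask aligned with the map.
    """
    if params is None:
        params = DemParams()
    if mask.count() == 0:
        raise ValueError("empty mask")
    v_iso = resample_isotropic(volume, params.target_mm, mode="trilinear")
    m_iso = resample_isotropic(mask, params.target_mm, mode="nearest")
    if m_iso.count() == 0:
        raise ValueError("mask empty after resampling")
    v_roi, m_roi = extract_roi(v_iso, m_iso, pad=params.roi_pad)
    if params.roi_pad > 0:
        padded = ndimage.binary_dilation(m_roi.data, iterations=params.roi_pad)
    else:
        padded = m_roi.data
    smooth = gaussian_smooth(v_roi, params.sigma_smooth)
    deriv = derivative_fields(smooth, params.sigma_deriv)
    raw, diagnostics = elasticity_response(deriv, params.epsilon, roi=padded)
    norm = compress_normalize(
        raw, params.compression_exponent, params.output_range, stats_mask=padded
    )
    norm = np.where(padded, norm, 0.0)
    # re-embed the crop into the resampled grid
    lo = np.round(
        (np.asarray(v_roi.origin) - np.asarray(v_iso.origin)) / params.target_mm
    ).astype(int)
    full_raw = np.zeros(v_iso.shape)
    full_norm = np.zeros(v_iso.shape)
    sl = tuple(slice(a, a + n) for a, n in zip(lo, v_roi.shape))
    full_raw[sl] = raw
    full_norm[sl] = np.where(padded, norm, 0.0)
    dem = ElasticityMap(
        raw_values=full_raw,
        normalized_values=full_norm,
        params=params,
        spacing=v_iso.spacing,
        origin=v_iso.origin,
        diagnostics=diagnostics,
    )
    return dem, m_iso
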