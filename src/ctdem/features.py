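"""Combined per-lesion feature extraction from a DEM and its mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curvature import curvature_features
from .dem import ElasticityMap
from .firstorder import first_order_features
from .fractal import fd_feature_set

__all__ = ["FeatureParams", "extract_all", "TABLE2_FEATURES"]

#: the five feature names the study's selection retained
TABLE2_FEATURES = (
    "E_original_firstorder_Entropy",
    "max_FD_feature",
    "best_FD_feature",
    "average_FD_feature",
    "median_FD_feature",
)


@dataclass
class FeatureParams:
    """Knobs of the feature extractors.

    ``bin_width`` discretises the [0, 255] DEM histogram (None to use
    ``bin_count``); ``fd_thresholds`` (DEM levels) default to the deciles of
    masked values; ``fd_mode`` is '3d' or '2d' (per-slice).
    """

    bin_width: float | None = 25.0
    bin_count: int | None = None
    fd_thresholds: tuple[float, ...] | None = None
    fd_n_offsets: int = 8
    fd_mode: str = "3d"
    curvature_sigma: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "bin_count": self.bin_count,
            "fd_thresholds": None if self.fd_thresholds is None else list(self.fd_thresholds),
            "fd_n_offsets": self.fd_n_offsets,
            "fd_mode": self.fd_mode,
            "curvature_sigma": self.curvature_sigma,
            "seed": self.seed,
        }


def extract_all(
    dem: ElasticityMap | np.ndarray,
    mask: np.ndarray,
    params: FeatureParams | None = None,
) -> dict[str, float]:
    """Run every feature extractor on one lesion.

    Accepts an :class:`ElasticityMap` or a bare normalised-value array plus a
    boolean mask on the same grid.  Deterministic for a fixed
    ``params.seed``.  Returns a flat name → value mapping containing the
    first-order family, the five fractal-dimension aggregates and the
    curvature summaries (NaN when curvature is undefined, e.g. for a
    constant DEM).
    """
    if params is None:
        params = FeatureParams()
    values = dem.normalized_values if isinstance(dem, ElasticityMap) else np.asarray(dem, float)
    mask = np.asarray(mask).astype(bool)
    if values.shape != mask.shape:
        raise ValueError("DEM and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")

    out: dict[str, float] = {}
    out.update(
        first_order_features(values[mask], bin_width=params.bin_width, bin_count=params.bin_count)
    )
    thresholds = None if params.fd_thresholds is None else np.asarray(params.fd_thresholds)
    fd_feats, _ = fd_feature_set(
        values,
        mask,
        thresholds=thresholds,
        n_offsets=params.fd_n_offsets,
        seed=params.seed,
        mode=params.fd_mode,
    )
    out.update(fd_feats)
    curv = curvature_features(values, mask, sigma=params.curvature_sigma)
    out.update(curv.summaries)
    return out
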