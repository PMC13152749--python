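"""First-order (histogram) features of the DEM inside the lymph-node mask."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["first_order_entropy", "first_order_features"]


def _histogram(values: np.ndarray, bin_width: float | None, bin_count: int | None):
    """Discretise values with either a fixed bin width or a fixed bin count.

    Fixed-width edges start at ``floor(min / w) * w`` so bin boundaries are
    stable under masking; this is the usual convention of first-order
    radiomics extractors.
    """
    values = np.asarray(values, dtype=float)
    if bin_width is not None:
        lo = np.floor(values.min() / bin_width) * bin_width
        n = max(int(np.ceil((values.max() - lo) / bin_width)), 1)
        edges = lo + bin_width * np.arange(n + 1)
        # guard: make sure the max falls inside the last bin
        if edges[-1] <= values.max():
            edges = np.append(edges, edges[-1] + bin_width)
    else:
        edges = np.histogram_bin_edges(values, bins=bin_count)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def first_order_entropy(
    values: np.ndarray,
    bin_width: float | None = 25.0,
    bin_count: int | None = None,
) -> float:
    """Shannon entropy (bits) of the discretised intensity histogram.

    −Σ p_k log2 p_k over occupied bins.  The default bin width of 25 on the
    [0, 255] DEM scale gives ≈10 bins.  Pass ``bin_width=None`` together with
    ``bin_count`` for fixed-bin-count discretisation.  Constant input has
    zero entropy.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty mask: no values for entropy")
    if np.ptp(values) == 0:
        return 0.0
    counts, _ = _histogram(values, bin_width, bin_count)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def first_order_features(
    values: np.ndarray,
    bin_width: float | None = 25.0,
    bin_count: int | None = None,
    prefix: str = "E_original_firstorder_",
) -> dict[str, float]:
    """First-order statistics of masked DEM values, named pyradiomics-style."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty mask: no values for first-order features")
    constant = np.ptp(v) == 0
    feats = {
        "Entropy": first_order_entropy(v, bin_width, bin_count),
        "Mean": float(v.mean()),
        "Variance": float(v.var()),
        "Skewness": 0.0 if constant else float(sps.skew(v)),
        "Kurtosis": 0.0 if constant else float(sps.kurtosis(v)),
        "Energy": float((v**2).sum()),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(np.ptp(v)),
        "Median": float(np.median(v)),
        "Percentile10": float(np.percentile(v, 10)),
        "Percentile90": float(np.percentile(v, 90)),
        "InterquartileRange": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }
    return {prefix + k: val for k, val in feats.items()}
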