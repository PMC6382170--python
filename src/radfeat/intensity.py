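"""First-order statistics, intensity-histogram and intensity-volume-histogram features.

First-order statistics run on the raw (un-discretized) ROI intensities with
population moments.  The histogram family runs on integer grey levels; the IVH
family runs on its own, independently configured discretization.
Percentiles interpolate linearly between order statistics.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_core import EmptyVOIError
from .preprocess import ROI, DiscretizedROI

__all__ = ["first_order", "ih_features", "ivh_features", "LEGACY_LABELS"]

# The serialization labels historically used a few misspellings; this alias map
# lets byte-compatible output reproduce them while the canonical names stay fixed.
LEGACY_LABELS = {
    "Mean absolute deviation": "Mean absolut deviation",
    "Root mean square": "Root mean",
}


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/variance/skewness/excess-kurtosis (divide by N)."""
    mu = float(x.mean())
    d = x - mu
    m2 = float(np.mean(d**2))
    if m2 == 0:
        return mu, 0.0, 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mu, m2, m3 / m2**1.5, m4 / m2**2 - 3.0


def _percentile_stats(x: np.ndarray) -> dict[str, float]:
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    robust_mad = float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0
    denom = p75 + p25
    return {
        "median": float(med),
        "10th percentile": float(p10),
        "90th percentile": float(p90),
        "Interquartile range": float(p75 - p25),
        "Robust mean absolute deviation": robust_mad,
        "Median absolute deviation": float(np.abs(x - med).mean()),
        "Quartile coefficient": float((p75 - p25) / denom) if denom != 0 else float("nan"),
    }


def first_order(roi: ROI) -> dict[str, float]:
    """Statistical features on raw ROI intensities."""
    x = roi.intensities.astype(float)
    if x.size == 0:
        raise EmptyVOIError("empty ROI")
    mu, var, skew, kurt = _moments(x)
    pct = _percentile_stats(x)
    energy = float(np.sum(x**2))
    out = {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": pct["median"],
        "minimum": float(x.min()),
        "10th percentile": pct["10th percentile"],
        "90th percentile": pct["90th percentile"],
        "maximum": float(x.max()),
        "Interquartile range": pct["Interquartile range"],
        "range": float(x.max() - x.min()),
        "Mean absolute deviation": float(np.abs(x - mu).mean()),
        "Robust mean absolute deviation": pct["Robust mean absolute deviation"],
        "Median absolute deviation": pct["Median absolute deviation"],
        "Coefficient of variation": float(np.sqrt(var) / mu) if mu != 0 else float("nan"),
        "Quartile coefficient": pct["Quartile coefficient"],
        "Energy": energy,
        "Root mean square": float(np.sqrt(energy / x.size)),
    }
    return out


def ih_features(droi: DiscretizedROI) -> dict[str, float]:
    """Intensity-histogram features on integer grey levels 1..Ng.

    Histogram gradients use central differences H'(i) = (H(i+1) - H(i-1))/2
    with one-sided differences at both ends; the mode takes the lowest level
    on ties.
    """
    g = droi.roi_levels.astype(float)
    ng = droi.ng
    if g.size == 0 or ng < 1:
        raise EmptyVOIError("empty discretized ROI")
    hist = np.bincount(droi.roi_levels, minlength=ng + 1)[1:].astype(float)
    p = hist / hist.sum()
    nz = p > 0
    mu, var, skew, kurt = _moments(g)
    pct = _percentile_stats(g)
    energy = float(np.sum(g**2))
    out = {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": pct["median"],
        "minimum": float(g.min()),
        "10th percentile": pct["10th percentile"],
        "90th percentile": pct["90th percentile"],
        "maximum": float(g.max()),
        "mode": float(np.argmax(hist) + 1),
        "Interquartile range": pct["Interquartile range"],
        "range": float(g.max() - g.min()),
        "Mean absolute deviation": float(np.abs(g - mu).mean()),
        "Robust mean absolute deviation": pct["Robust mean absolute deviation"],
        "Median absolute deviation": pct["Median absolute deviation"],
        "Coefficient of variation": float(np.sqrt(var) / mu) if mu != 0 else float("nan"),
        "Quartile coefficient": pct["Quartile coefficient"],
        "Entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "Uniformity": float(np.sum(p**2)),
        "Energy": energy,
    }
    if ng == 1:
        grad = np.zeros(1)
    else:
        grad = np.empty(ng)
        grad[0] = hist[1] - hist[0]
        grad[-1] = hist[-1] - hist[-2]
        if ng > 2:
            grad[1:-1] = (hist[2:] - hist[:-2]) / 2.0
    out["Maximum histogram gradient"] = float(grad.max())
    out["Maximum histogram gradient grey level"] = float(np.argmax(grad) + 1)
    out["Minimum histogram gradient"] = float(grad.min())
    out["Minimum histogram gradient grey level"] = float(np.argmin(grad) + 1)
    return out


def _tail_fraction(levels: np.ndarray, threshold: float, strict: bool) -> float:
    if strict:
        return float(np.mean(levels > threshold))
    return float(np.mean(levels >= threshold))


def ivh_features(droi: DiscretizedROI, strict: bool = True) -> dict[str, float]:
    """Intensity-volume-histogram summaries.

    The intensity fraction of level i is gamma(i) = (i - imin)/(imax - imin);
    nu(gamma) is the fraction of ROI voxels with level strictly above the
    gamma-threshold level (``strict=False`` switches to >=).  V10/V90 read the
    curve at gamma = 0.10/0.90; I10/I90 are the smallest intensities whose
    tail fraction is <= 0.10/0.90, reported in original intensity units when
    the source intensities are available.
    """
    g = droi.roi_levels
    gmin, gmax = int(g.min()), int(g.max())
    if droi.source_image is not None:
        src = droi.source_image[droi.intensity_mask]
    else:
        src = g.astype(float)

    def intensity_of_level(level: int) -> float:
        sel = src[g == level]
        return float(sel.min()) if sel.size else float(level)

    if gmax == gmin:
        warnings.warn("constant ROI: IVH fraction curve is a single step", stacklevel=2)
        c = intensity_of_level(gmin)
        return {
            "volume at int fraction 10": 0.0,
            "volume at int fraction 90": 0.0,
            "int at vol fraction 10": c,
            "int at vol fraction 90": c,
            "difference vol at int fraction": 0.0,
            "difference int at volume fraction": 0.0,
        }

    def nu_at(gamma: float) -> float:
        return _tail_fraction(g, gmin + gamma * (gmax - gmin), strict)

    v10 = nu_at(0.10)
    v90 = nu_at(0.90)

    def intensity_at_volume(frac: float) -> float:
        for level in range(gmin, gmax + 1):
            if _tail_fraction(g, level, strict=True) <= frac:
                return intensity_of_level(level) if np.any(g == level) else float(level)
        return intensity_of_level(gmax)

    i10 = intensity_at_volume(0.10)
    i90 = intensity_at_volume(0.90)
    return {
        "volume at int fraction 10": v10,
        "volume at int fraction 90": v90,
        "int at vol fraction 10": i10,
        "int at vol fraction 90": i90,
        "difference vol at int fraction": v10 - v90,
        "difference int at volume fraction": i10 - i90,
    }
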