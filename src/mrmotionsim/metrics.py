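"""Image-quality metrics for paired and reference-free evaluation.

Paired metrics (reference f vs comparison g, N pixels, population SDs):

    RMSE = sqrt( sum_i (f_i - g_i)^2 / N )
    PSNR = 10 log10( S_peak^2 / RMSE^2 )            [dB]
    CC   = Pearson correlation of f and g over pixels
    UQI  = 4 mu_f mu_g sigma_fg / ((mu_f^2 + mu_g^2)(sigma_f^2 + sigma_g^2))

UQI is computed globally over the whole frame (no sliding window).
Reference-free metrics use k-means intensity clustering to delineate
background (air) and gray-matter regions:

    COV = sigma_b / mu_b          (background coefficient of variation)
    CNR = (mu_t - mu_b) / sqrt(sigma_t^2 + sigma_b^2)

All standard deviations are population SDs (divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "rmse", "psnr", "cc", "uqi",
    "kmeans_segment", "cov_background", "cnr",
    "paired_ttest", "evaluate_pairs", "MetricsReport",
]


def _check_pair(f: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape:
        raise ValueError(f"image shapes differ: {f.shape} vs {g.shape}")
    if f.size < 1:
        raise ValueError("empty images")
    return f, g


def rmse(f: np.ndarray, g: np.ndarray) -> float:
    """Root mean square error between reference ``f`` and comparison ``g``."""
    f, g = _check_pair(f, g)
    return float(np.sqrt(np.mean((f - g) ** 2)))


def psnr(f: np.ndarray, g: np.ndarray, s_peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB.

    ``s_peak`` defaults to the maximum of the reference image. Identical
    images give ``inf`` (a sentinel, so batch evaluation never aborts).
    """
    f, g = _check_pair(f, g)
    if s_peak is None:
        s_peak = float(np.max(f))
    if s_peak <= 0:
        raise ValueError("s_peak must be positive")
    err = rmse(f, g)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(s_peak**2 / err**2))


def cc(f: np.ndarray, g: np.ndarray) -> float:
    """Pearson correlation coefficient over pixels."""
    f, g = _check_pair(f, g)
    if np.ptp(f) == 0 or np.ptp(g) == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.corrcoef(f.ravel(), g.ravel())[0, 1])


def uqi(f: np.ndarray, g: np.ndarray) -> float:
    """Universal image quality index, computed globally over the frame."""
    f, g = _check_pair(f, g)
    mu_f, mu_g = f.mean(), g.mean()
    var_f, var_g = f.var(), g.var()  # population variance
    cov_fg = ((f - mu_f) * (g - mu_g)).mean()
    denom = (mu_f**2 + mu_g**2) * (var_f + var_g)
    if denom == 0:
        raise ValueError("UQI undefined: zero denominator (constant zero-mean images)")
    return float(4.0 * mu_f * mu_g * cov_fg / denom)


def kmeans_segment(image: np.ndarray, k: int = 4, seed: int = 0) -> np.ndarray:
    """Cluster voxel intensities into ``k`` classes (2D slice or 3D volume).

    Labels are re-indexed by ascending cluster mean, so label 0 is always
    the darkest cluster (background/air) and label ``k-1`` the brightest
    (CSF-like on T2 contrast).
    """
    image = np.asarray(image, dtype=np.float64)
    if k < 2:
        raise ValueError("k must be at least 2")
    values = image.reshape(-1, 1)
    if len(np.unique(values)) < k:
        raise ValueError(f"image has fewer than k={k} distinct intensities")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(values)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return remap[raw].reshape(image.shape)


def cov_background(image: np.ndarray, background_mask: np.ndarray) -> float:
    """Coefficient of variation sigma/mu of the masked background pixels."""
    image = np.asarray(image, dtype=np.float64)
    vals = image[np.asarray(background_mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty background mask")
    mu = vals.mean()
    if mu == 0:
        raise ValueError("COV undefined: zero-mean background")
    return float(vals.std() / mu)


def cnr(image: np.ndarray, tissue_mask: np.ndarray,
        background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio (mu_t - mu_b) / sqrt(sigma_t^2 + sigma_b^2)."""
    image = np.asarray(image, dtype=np.float64)
    t = image[np.asarray(tissue_mask, dtype=bool)]
    b = image[np.asarray(background_mask, dtype=bool)]
    if t.size == 0 or b.size == 0:
        raise ValueError("empty tissue or background mask")
    denom = np.sqrt(t.var() + b.var())
    if denom == 0:
        raise ValueError("CNR undefined: both regions are constant")
    return float((t.mean() - b.mean()) / denom)


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on per-pair metric values; returns (t, p)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length sequences with at least 2 entries")
    d = a - b
    if np.ptp(d) == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError("constant nonzero differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetricsReport:
    """Per-pair metric values with mean ± SD aggregates.

    ``per_pair`` has one row per image pair and one column per metric;
    ``aggregate`` maps metric name to (mean, SD). Infinite PSNR values
    (identical images) are excluded from the PSNR aggregate and counted in
    ``n_infinite_psnr``.
    """

    per_pair: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]
    n_infinite_psnr: int = 0
    ttests: dict[str, tuple[float, float]] | None = None

    def summary(self) -> str:
        lines = [f"{name}: {m:.4f} ± {s:.4f}"
                 for name, (m, s) in self.aggregate.items()]
        return "\n".join(lines)


def evaluate_pairs(
    references: Sequence[np.ndarray],
    comparisons: Sequence[np.ndarray],
    comparisons2: Sequence[np.ndarray] | None = None,
    s_peak: float | None = None,
) -> MetricsReport:
    """Compute RMSE/PSNR/UQI/CC for each pair and aggregate as mean ± SD.

    When a second comparison set is given (e.g. two correction methods),
    paired t-tests between the two sets' per-pair metric values are added.
    """
    if len(references) != len(comparisons):
        raise ValueError("references and comparisons must have equal length")
    if len(references) == 0:
        raise ValueError("no image pairs to evaluate")

    def metric_rows(comps):
        rows = []
        for ref, comp in zip(references, comps):
            rows.append({
                "rmse": rmse(ref, comp),
                "psnr": psnr(ref, comp, s_peak=s_peak),
                "uqi": uqi(ref, comp),
                "cc": cc(ref, comp),
            })
        return pd.DataFrame(rows)

    df = metric_rows(comparisons)
    finite_psnr = df["psnr"][np.isfinite(df["psnr"])]
    aggregate = {}
    for name in ("rmse", "psnr", "uqi", "cc"):
        vals = finite_psnr if name == "psnr" else df[name]
        aggregate[name] = (float(vals.mean()), float(vals.std(ddof=0)))

    ttests = None
    if comparisons2 is not None:
        if len(comparisons2) != len(references):
            raise ValueError("second comparison set must match references in length")
        df2 = metric_rows(comparisons2)
        ttests = {}
        for name in ("rmse", "psnr", "uqi", "cc"):
            x, y = df[name].to_numpy(), df2[name].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            ttests[name] = paired_ttest(x[ok], y[ok])

    return MetricsReport(
        per_pair=df, aggregate=aggregate,
        n_infinite_psnr=int(np.sum(~np.isfinite(df["psnr"]))),
        ttests=ttests,
    )
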