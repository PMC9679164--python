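"""Visual-field coverage maps and pRF size-by-eccentricity profiles.

Coverage renders every retained pRF as a *peak-normalized* Gaussian in
visual-field space and records the maximum density at each grid point across
all pRFs and both hemispheres.  Peak (rather than unit-volume) normalization
means a single large foveal pRF produces high coverage over a broad area —
the conservative reading for detecting residual foveal signal.

Size profiles bin pRF sizes by eccentricity (1-deg bins over 0.5-8.5 deg)
and take the per-bin median; sparsely populated bins (fewer than 10% of the
count in the equivalent bin of a reference, typically the non-selective
condition of the same subject) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoverageMap",
    "SizeEccProfile",
    "coverage_map",
    "size_ecc_profile",
    "group_envelope",
]


@dataclass(frozen=True)
class CoverageMap:
    coords: np.ndarray  # (H,) grid coordinates in deg, symmetric about 0
    values: np.ndarray  # (H, H) in [0, 1]

    def mean_within(self, radius: float) -> float:
        x, y = np.meshgrid(self.coords, self.coords)
        mask = np.hypot(x, y) <= radius
        return float(self.values[mask].mean())

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.values, header=" ".join(map(str, self.coords)))

    def plot(self, path: str | Path, max_ecc: float | None = None) -> None:
        """Heat-map export (PNG or any matplotlib-supported format)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        extent = [self.coords[0], self.coords[-1]] * 2
        im = ax.imshow(
            self.values, origin="lower", extent=extent, vmin=0, vmax=1, cmap="magma"
        )
        if max_ecc is not None:
            circ = plt.Circle((0, 0), max_ecc, fill=False, color="w", lw=1)
            ax.add_patch(circ)
        ax.set_xlabel("x (deg)")
        ax.set_ylabel("y (deg)")
        fig.colorbar(im, ax=ax, label="max pRF density")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def coverage_map(
    prf_table: pd.DataFrame,
    max_ecc: float = 8.6,
    spacing_deg: float = 0.1,
) -> CoverageMap:
    """Maximum peak-normalized pRF density over a square visual-field grid.

    ``prf_table`` needs columns x, y, sigma (already thresholded).  An empty
    table yields an all-zero map.
    """
    n = int(round(2 * max_ecc / spacing_deg)) + 1
    coords = np.linspace(-max_ecc, max_ecc, n)
    gx, gy = np.meshgrid(coords, coords)
    values = np.zeros_like(gx)
    for _, row in prf_table.iterrows():
        if not np.isfinite(row["sigma"]) or row["sigma"] <= 0:
            continue
        g = np.exp(
            -((gx - row["x"]) ** 2 + (gy - row["y"]) ** 2)
            / (2.0 * row["sigma"] ** 2)
        )
        np.maximum(values, g, out=values)
    return CoverageMap(coords, values)


DEFAULT_BIN_EDGES = np.arange(0.5, 8.6, 1.0)  # [0.5, 1.5), ..., [7.5, 8.5)


@dataclass(frozen=True)
class SizeEccProfile:
    bin_edges: np.ndarray
    median_sigma: np.ndarray  # NaN for excluded bins
    counts: np.ndarray
    excluded: np.ndarray

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_centre": self.bin_centres,
                "median_sigma": self.median_sigma,
                "n": self.counts,
                "excluded": self.excluded,
            }
        )


def size_ecc_profile(
    prf_table: pd.DataFrame,
    reference_counts: np.ndarray | None = None,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
    min_fraction: float = 0.10,
) -> SizeEccProfile:
    """Median pRF size per 1-deg eccentricity bin with sparse-bin exclusion.

    A bin is excluded when its count is *fewer than* ``min_fraction`` times
    the count of the equivalent bin in ``reference_counts`` (the
    non-selective condition); exactly 10% is retained.  Without a reference
    no bins are excluded (a warning is emitted).
    """
    edges = np.asarray(bin_edges, dtype=float)
    ecc = prf_table["ecc"].to_numpy()
    sigma = prf_table["sigma"].to_numpy()
    n_bins = edges.size - 1
    counts = np.zeros(n_bins, dtype=int)
    medians = np.full(n_bins, np.nan)
    for b in range(n_bins):
        in_bin = (ecc >= edges[b]) & (ecc < edges[b + 1])
        counts[b] = int(in_bin.sum())
        if counts[b]:
            medians[b] = float(np.median(sigma[in_bin]))
    if reference_counts is None:
        warnings.warn("no reference counts: sparse-bin exclusion skipped")
        excluded = counts == 0
    else:
        ref = np.asarray(reference_counts, dtype=float)
        if ref.size != n_bins:
            raise ValueError("reference_counts length does not match bins")
        excluded = counts < min_fraction * ref
        excluded |= counts == 0
    medians[excluded] = np.nan
    return SizeEccProfile(edges, medians, counts, excluded)


def group_envelope(profiles: list, level: float = 0.95) -> pd.DataFrame:
    """Per-bin group mean with t-based CI and empirical percentile range.

    Profiles contribute to a bin only where they are not excluded there.
    Returns a frame with bin_centre, mean, ci_lo, ci_hi, range_lo, range_hi, n.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three profiles")
    edges = profiles[0].bin_edges
    vals = np.stack([p.median_sigma for p in profiles])  # (S, B)
    centres = profiles[0].bin_centres
    rows = []
    for b in range(centres.size):
        v = vals[:, b]
        v = v[np.isfinite(v)]
        k = v.size
        if k == 0:
            rows.append(
                dict(bin_centre=centres[b], mean=np.nan, ci_lo=np.nan,
                     ci_hi=np.nan, range_lo=np.nan, range_hi=np.nan, n=0)
            )
            continue
        m = v.mean()
        if k > 1:
            half = stats.t.ppf((1 + level) / 2, k - 1) * v.std(ddof=1) / np.sqrt(k)
        else:
            half = 0.0
        lo, hi = np.percentile(v, [50 * (1 - level), 100 - 50 * (1 - level)])
        rows.append(
            dict(bin_centre=centres[b], mean=m, ci_lo=m - half, ci_hi=m + half,
                 range_lo=lo, range_hi=hi, n=k)
        )
    return pd.DataFrame(rows)
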