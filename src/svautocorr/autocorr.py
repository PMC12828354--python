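"""Per-voxel lagged autocorrelation with a 4-second lag cap.

The statistic for voxel series ``x`` of length N at lag k is the unbiased
lagged product sum normalized by the biased lag-0 variance::

    c(k) = (1 / (N - k)) * sum_{t=1..N-k} x~(t) x~(t+k)      x~ = x - mean(x)
    r(k) = c(k) / ((1 / N) * sum_t x~(t)^2)

This matches the "unbiased" cross-correlation convention: the lag-k product
sum is divided by the number of overlapping samples, compensating for the
shrinking overlap window, so |r(k)| can slightly exceed 1 at small N (bounded
by N / (N - k)); values are reported as computed, never clamped. The number
of lags is capped so the total temporal shift never exceeds 4 seconds, the
window over which gray-matter BOLD autocorrelation remains distinguishable
from noise: at TR = 2 s that is 2 lags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import RoiMask, VoxelTimecourses

__all__ = [
    "AutocorrMap",
    "max_lags",
    "single_voxel_autocorrelation",
    "autocorr_map",
    "DegenerateVoxelError",
]

logger = logging.getLogger(__name__)

LAG_CAP_SECONDS = 4.0

NORMALIZATIONS = ("lag0-normalized", "raw-covariance")


class DegenerateVoxelError(ValueError):
    """Raised for a zero-variance (constant) series."""


@dataclass
class AutocorrMap:
    """Voxels x lags matrix of lagged autocorrelation values for one ROI.

    ``values[v, k-1]`` is r_v(k); lag k is in units of TR. ``valid`` marks
    non-degenerate voxels (constant series are excluded, not imputed).
    """

    values: np.ndarray  # (voxels, n_lags)
    n_lags: int
    tr_seconds: float
    mask_ref: RoiMask | None = None
    normalization: str = "lag0-normalized"
    valid: np.ndarray | None = None  # bool per voxel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != self.n_lags:
            raise ValueError("values column count != n_lags")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.valid is None:
            self.valid = np.isfinite(self.values).all(axis=1)

    @property
    def lag1(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def max_lags(tr_seconds: float, cap_seconds: float = LAG_CAP_SECONDS) -> int:
    """Largest number of lags whose total shift does not exceed the cap.

    floor(cap / TR), at least 1: 2 lags at TR = 2 s, 4 at TR = 1 s.
    """
    if not tr_seconds > 0:
        raise ValueError("tr_seconds must be positive")
    return max(1, int(np.floor(cap_seconds / tr_seconds)))


def single_voxel_autocorrelation(
    x: np.ndarray,
    n_lags: int,
    normalization: str = "lag0-normalized",
    demean: bool = True,
) -> np.ndarray:
    """Lagged autocorrelation vector [r(1) ... r(n_lags)] of one series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1D")
    out = _lagged_products(x[None, :], n_lags, normalization, demean)[0]
    if not np.isfinite(out).all():
        raise DegenerateVoxelError("zero-variance series has no autocorrelation")
    return out


def autocorr_map(
    data: VoxelTimecourses,
    n_lags: int | None = None,
    normalization: str = "lag0-normalized",
    demean: bool = True,
) -> AutocorrMap:
    """Autocorrelation vectors for every mask voxel.

    Degenerate (constant) voxels get NaN rows and ``valid=False``; they are
    excluded from downstream clustering with a logged count. An all-degenerate
    ROI is an error.
    """
    if n_lags is None:
        n_lags = max_lags(data.tr_seconds)
    N = data.values.shape[1]
    if N < n_lags + 2:
        raise ValueError(f"need at least {n_lags + 2} timepoints for {n_lags} lags")
    values = _lagged_products(data.values, n_lags, normalization, demean)
    valid = np.isfinite(values).all(axis=1)
    n_bad = int((~valid).sum())
    if n_bad == data.values.shape[0]:
        raise DegenerateVoxelError("every voxel in the ROI is constant")
    if n_bad:
        logger.warning("%d degenerate voxel(s) excluded from autocorrelation map", n_bad)
    return AutocorrMap(
        values=values,
        n_lags=n_lags,
        tr_seconds=data.tr_seconds,
        mask_ref=data.mask_ref,
        normalization=normalization,
        valid=valid,
    )


def _lagged_products(
    x: np.ndarray, n_lags: int, normalization: str, demean: bool
) -> np.ndarray:
    """Vectorized unbiased lagged products for a (voxels, time) matrix."""
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}")
    N = x.shape[1]
    if N < n_lags + 2:
        raise ValueError("series too short for requested lags")
    xt = x - x.mean(axis=1, keepdims=True) if demean else x.astype(float)
    out = np.empty((x.shape[0], n_lags), dtype=float)
    for k in range(1, n_lags + 1):
        out[:, k - 1] = (xt[:, :-k] * xt[:, k:]).sum(axis=1) / (N - k)
    if normalization == "lag0-normalized":
        denom = (xt * xt).sum(axis=1) / N  # biased lag-0 variance
        with np.errstate(divide="ignore", invalid="ignore"):
            out = out / denom[:, None]
        out[denom <= 0] = np.nan
    return out
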