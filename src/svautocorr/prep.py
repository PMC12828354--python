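"""Signal conditioning applied before autocorrelation.

Order contract: component-based nuisance regression and spike (scrubbing)
regression first, then zero-phase low-pass filtering, then the lagged
autocorrelation. Flagged frames are removed by regression against one-hot
spike columns rather than deleted, which keeps the time axis contiguous —
deleting frames would corrupt lagged products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import BoldRun, VoxelTimecourses

__all__ = [
    "ConfoundSet",
    "compcor_components",
    "scrub_flags",
    "build_confounds",
    "regress_confounds",
    "lowpass_filter",
    "prep_timecourses",
]

# defaults (config-overridable)
N_COMPCOR = 5
Z_THRESH = 3.0
TRANS_THRESH_MM = 1.0
ROT_THRESH_RAD = 0.05
CUTOFF_HZ = 0.09


@dataclass
class ConfoundSet:
    """Nuisance design: component columns plus one-hot spike columns."""

    regressors: np.ndarray  # (timepoints, k)
    flags: np.ndarray  # bool per timepoint
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.regressors.shape[0] != self.flags.shape[0]:
            raise ValueError("regressor rows must equal run timepoints")
        if len(self.provenance) not in (0, self.regressors.shape[1]):
            raise ValueError("provenance labels must match column count")


def compcor_components(noise_timecourses: VoxelTimecourses | np.ndarray, k: int = N_COMPCOR) -> np.ndarray:
    """Top-k principal-component time series of a noise ROI (CompCor).

    Each noise voxel's series is demeaned, and the leading right singular
    vectors of the voxels x time matrix are returned as unit-norm columns
    ordered by explained variance. If the matrix has rank < k, the available
    components are returned with a warning.
    """
    X = noise_timecourses.values if isinstance(noise_timecourses, VoxelTimecourses) else np.asarray(noise_timecourses, dtype=float)
    if X.ndim != 2:
        raise ValueError("noise timecourses must be voxels x time")
    X = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < k:
        warnings.warn(
            f"noise ROI supports only {rank} components (requested {k})",
            stacklevel=2,
        )
        k = rank
    comps = vt[:k].T  # (timepoints, k), unit-norm columns
    return comps


def scrub_flags(
    run: BoldRun | None,
    motion: np.ndarray,
    global_signal: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    z_thresh: float = Z_THRESH,
    trans_thresh_mm: float = TRANS_THRESH_MM,
    rot_thresh_rad: float = ROT_THRESH_RAD,
) -> np.ndarray:
    """Artifact flags per frame (ART-style scrubbing).

    A frame is flagged when its global signal is ``z_thresh`` or more SDs from
    the mean, or when any frame-to-frame realignment difference exceeds
    ``trans_thresh_mm`` (translations) or ``rot_thresh_rad`` (rotations).
    The first frame's difference is zero by convention; a constant global
    signal (SD = 0) contributes no flags.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be timepoints x 6")
    if global_signal is None:
        if run is None:
            raise ValueError("need either a run or a precomputed global signal")
        if motion.shape[0] != run.n_timepoints:
            raise ValueError("motion trace length must equal run timepoints")
        mask = brain_mask if brain_mask is not None else np.ones(run.shape3d, dtype=bool)
        global_signal = run.data[mask].mean(axis=0)
    global_signal = np.asarray(global_signal, dtype=float)
    if global_signal.shape[0] != motion.shape[0]:
        raise ValueError("global signal length must equal motion trace length")

    sd = global_signal.std()
    if sd > 0:
        z = np.abs(global_signal - global_signal.mean()) / sd
        flag_global = z >= z_thresh
    else:
        flag_global = np.zeros_like(global_signal, dtype=bool)

    d = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    flag_trans = np.abs(d[:, :3]).max(axis=1) > trans_thresh_mm
    flag_rot = np.abs(d[:, 3:]).max(axis=1) > rot_thresh_rad
    return flag_global | flag_trans | flag_rot


def build_confounds(
    components: np.ndarray | None,
    flags: np.ndarray,
    motion: np.ndarray | None = None,
) -> ConfoundSet:
    """Assemble the nuisance design: components, spike one-hots, optional motion."""
    flags = np.asarray(flags, dtype=bool)
    t = flags.shape[0]
    cols, labels = [], []
    if components is not None:
        components = np.atleast_2d(np.asarray(components, dtype=float))
        if components.shape[0] != t:
            raise ValueError("component rows must equal timepoints")
        cols.append(components)
        labels += [f"compcor_{i + 1}" for i in range(components.shape[1])]
    for fi in np.flatnonzero(flags):
        spike = np.zeros((t, 1))
        spike[fi, 0] = 1.0
        cols.append(spike)
        labels.append(f"spike_{fi}")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != t:
            raise ValueError("motion rows must equal timepoints")
        cols.append(motion)
        labels += [f"motion_{i + 1}" for i in range(motion.shape[1])]
    regressors = np.hstack(cols) if cols else np.empty((t, 0))
    return ConfoundSet(regressors=regressors, flags=flags, provenance=labels)


def regress_confounds(data: VoxelTimecourses, confounds: ConfoundSet) -> VoxelTimecourses:
    """Per-voxel least-squares residual against [intercept | confounds].

    One-hot spike columns absorb flagged frames entirely, so the residual at
    a flagged frame is exactly zero. Regressing the same confounds twice is a
    no-op (projection idempotence).
    """
    t = data.values.shape[1]
    if confounds.regressors.shape[0] != t:
        raise ValueError("confound rows must equal data timepoints")
    design = np.hstack([np.ones((t, 1)), confounds.regressors])
    if np.linalg.matrix_rank(design) >= t:
        raise ValueError("confound design is over-parameterized (rank >= timepoints)")
    beta, *_ = np.linalg.lstsq(design, data.values.T, rcond=None)
    resid = data.values.T - design @ beta
    # spike columns zero the flagged frames up to round-off; make it exact
    resid[confounds.flags, :] = 0.0
    return VoxelTimecourses(values=resid.T, mask_ref=data.mask_ref, tr_seconds=data.tr_seconds)


def lowpass_filter(
    data: VoxelTimecourses,
    cutoff_hz: float = CUTOFF_HZ,
    order: int = 4,
    dialect: str = "butterworth",
) -> VoxelTimecourses:
    """Zero-phase low-pass filter per voxel, preserving the per-voxel mean.

    The default is a forward-backward (zero-phase) Butterworth of the given
    order, which does not distort the phase structure the lagged products
    depend on. A rectangular FFT dialect (hard cutoff) is selectable.
    """
    fs = 1.0 / data.tr_seconds
    nyq = fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq:.3f}) Hz")
    x = data.values
    mu = x.mean(axis=1, keepdims=True)
    xd = x - mu
    if dialect == "butterworth":
        sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
        y = sps.sosfiltfilt(sos, xd, axis=1)
    elif dialect == "fft":
        freqs = np.fft.rfftfreq(x.shape[1], d=data.tr_seconds)
        spec = np.fft.rfft(xd, axis=1)
        spec[:, freqs > cutoff_hz] = 0.0
        y = np.fft.irfft(spec, n=x.shape[1], axis=1)
    else:
        raise ValueError(f"unknown filter dialect {dialect!r}")
    y = y - y.mean(axis=1, keepdims=True) + mu
    return VoxelTimecourses(values=y, mask_ref=data.mask_ref, tr_seconds=data.tr_seconds)


def prep_timecourses(
    data: VoxelTimecourses,
    confounds: ConfoundSet,
    cutoff_hz: float = CUTOFF_HZ,
    dialect: str = "butterworth",
) -> VoxelTimecourses:
    """Conditioning pipeline in the contract order: regression, then filtering."""
    return lowpass_filter(regress_confounds(data, confounds), cutoff_hz=cutoff_hz, dialect=dialect)
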