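"""Synthetic cohorts with the statistical structure the analysis assumes.

Each participant's hippocampus-like ROI voxels follow AR(1) dynamics,
x_t = phi_v * x_{t-1} + eps_t, the minimal process with a controllable
lag-1/lag-2 autocorrelation signature (r(k) -> phi^k as T grows). The AR
coefficient follows a high -> low anterior-medial -> posterior-lateral
gradient discretized into three latent bands, which gives the clustering
stage an unambiguous ground truth; a smooth-gradient mode exists for
robustness checks but carries no truth labels. The left-TLE-like group gets
an additive phi boost in the anterior-medial band of both hemispheres,
matching the bilateral character of the group effect the pipeline is built
to detect. Memory scores are noisy linear functions of realized anterior-
medial cluster preservation, so the preservation-memory correlation layer
has a known generating slope to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .io import BoldRun, ParticipantRecord, RoiMask, write_participants

__all__ = [
    "SimSpec",
    "SimOutput",
    "make_roi_masks",
    "simulate_participant",
    "simulate_cohort",
    "simulate_memory_scores",
    "memory_noise_for_target_r",
    "write_bids_dir",
]

BURN_IN = 50  # AR(1) warm-up frames discarded


@dataclass
class SimSpec:
    """Generator settings; the defaults are the study conditions.

    ``band_phis`` orders the three latent bands anterior-medial,
    intermediate, posterior-lateral; ``ltle_anterior_boost`` is added to the
    anterior-medial phi of the ltle group (bilaterally by default).
    """

    n_per_group: int = 20
    t: int = 180
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] = (32, 32, 20)
    voxel_mm: float = 2.0
    band_phis: tuple[float, float, float] = (0.8, 0.5, 0.0)
    ltle_anterior_boost: float = 0.15
    boost_bilateral: bool = True
    noise_sd: float = 1.0
    motion_spike_rate: float = 0.01
    memory_slope: float = 1.0
    memory_noise_sd: float = 0.15
    gradient_mode: str = "bands"  # "bands" | "smooth"
    seed: int = 0

    def __post_init__(self) -> None:
        phis = list(self.band_phis) + [self.band_phis[0] + self.ltle_anterior_boost]
        if any(abs(p) >= 1 for p in phis):
            raise ValueError("all AR coefficients (including boosted) must lie in (-1, 1)")
        from .autocorr import max_lags

        if self.t < 3 * max_lags(self.tr_seconds):
            raise ValueError("t must be at least 3x the maximum lag")
        if self.gradient_mode not in ("bands", "smooth"):
            raise ValueError(f"unknown gradient_mode {self.gradient_mode!r}")


@dataclass
class SimOutput:
    runs: list[BoldRun]
    masks: tuple[RoiMask, RoiMask]  # (left, right)
    truth_labels: dict[str, np.ndarray] | None  # hemisphere -> band per voxel
    motion: dict[str, np.ndarray]  # pid -> (t, 6)
    participants: list[ParticipantRecord]
    truth: SimSpec
    child_seeds: dict[str, int] = field(default_factory=dict)


def _affine(spec: SimSpec) -> np.ndarray:
    """RAS+ affine with world origin at the grid center (left = negative x)."""
    aff = np.diag([spec.voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.array(spec.grid_shape) - 1) / 2.0 * spec.voxel_mm
    return aff


def make_roi_masks(spec: SimSpec) -> tuple[RoiMask, RoiMask, dict[str, np.ndarray] | None]:
    """Two mirrored ellipsoidal masks with three latent bands each.

    The band of a voxel is set by a composite coordinate mixing its position
    along the mask's long (anterior-posterior) axis with its medial-lateral
    offset (anterior and medial score high); rank-based tercile cuts make the
    three bands equal-sized to within one voxel. The right mask is the exact
    x-mirror of the left, so voxel counts match.
    """
    nx, ny, nz = spec.grid_shape
    # long axis along y (anterior-posterior); semi-axes scale with the grid
    rx, ry, rz = 0.14 * nx, 0.34 * ny, 0.26 * nz
    cx, cy, cz = (nx - 1) / 2.0 - nx / 4.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    left_grid = (
        ((i - cx) / rx) ** 2 + ((j - cy) / ry) ** 2 + ((k - cz) / rz) ** 2
    ) <= 1.0
    right_grid = left_grid[::-1, :, :].copy()
    if left_grid.sum() < 300:
        raise ValueError(
            f"grid {spec.grid_shape} too small: ellipsoid has {int(left_grid.sum())} voxels (< 300)"
        )
    aff = _affine(spec)
    left = RoiMask(grid=left_grid, hemisphere="left", affine=aff)
    right = RoiMask(grid=right_grid, hemisphere="right", affine=aff)
    if spec.gradient_mode == "smooth":
        return left, right, None
    truth = {
        "left": _band_labels(left),
        "right": _band_labels(right),
    }
    return left, right, truth


def _composite_axis(mask: RoiMask) -> np.ndarray:
    """Anterior-medial score in [0, 1]: 0.7 x anterior + 0.3 x medial."""
    w = mask.world_mm
    ap = _unit(w[:, 1])  # +y is anterior in RAS+
    med = _unit(-np.abs(w[:, 0]))  # closer to the midline scores higher
    return 0.7 * ap + 0.3 * med


def _band_labels(mask: RoiMask) -> np.ndarray:
    """Tercile cut of the composite coordinate: 0 = anterior-medial band."""
    u = _composite_axis(mask)
    order = np.argsort(-u, kind="stable")
    bands = np.empty(mask.n_voxels, dtype=int)
    for b, chunk in enumerate(np.array_split(order, 3)):
        bands[chunk] = b
    return bands


def _unit(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    return np.zeros_like(x, dtype=float) if hi == lo else (x - lo) / (hi - lo)


def voxel_phis(
    spec: SimSpec,
    group: str,
    masks: tuple[RoiMask, RoiMask],
    truth_labels: dict[str, np.ndarray] | None,
) -> dict[str, np.ndarray]:
    """Per-voxel AR coefficient for each hemisphere, with the group boost."""
    out = {}
    for mask in masks:
        hemi = mask.hemisphere
        if spec.gradient_mode == "smooth":
            u = _composite_axis(mask)
            phi = spec.band_phis[2] + u * (spec.band_phis[0] - spec.band_phis[2])
            if group == "ltle":
                boosted = hemi == "left" or spec.boost_bilateral
                if boosted:
                    phi = phi + spec.ltle_anterior_boost * u  # strongest anteriorly
        else:
            bands = truth_labels[hemi]
            phi = np.asarray(spec.band_phis, dtype=float)[bands].copy()
            if group == "ltle" and (spec.boost_bilateral or hemi == "left"):
                phi[bands == 0] += spec.ltle_anterior_boost
        if np.any(np.abs(phi) >= 1):
            raise ValueError("unstable AR coefficient (|phi| >= 1)")
        out[hemi] = phi
    return out


def _ar1_matrix(phi: np.ndarray, t: int, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate (n_voxels, t) AR(1) rows; burn-in discarded."""
    n = phi.shape[0]
    total = t + BURN_IN
    eps = rng.standard_normal((n, total)) * noise_sd
    x = np.empty((n, total))
    x[:, 0] = eps[:, 0]
    for s in range(1, total):
        x[:, s] = phi * x[:, s - 1] + eps[:, s]
    return x[:, BURN_IN:]


def _motion_trace(t: int, spike_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Realignment trace: slow drift plus injected > 1 mm displacement spikes."""
    drift = np.cumsum(
        rng.standard_normal((t, 6)) * np.array([0.01] * 3 + [0.002] * 3), axis=0
    )
    spikes = rng.random(t) < spike_rate
    spikes[0] = False  # first frame's difference is zero by convention
    for fi in np.flatnonzero(spikes):
        drift[fi:, rng.integers(0, 3)] += rng.uniform(1.2, 2.0) * rng.choice([-1, 1])
    return drift


def simulate_participant(
    spec: SimSpec,
    record: ParticipantRecord,
    masks: tuple[RoiMask, RoiMask],
    truth_labels: dict[str, np.ndarray] | None,
    rng: np.random.Generator,
) -> tuple[BoldRun, np.ndarray]:
    """One participant's 4D run plus its realignment trace.

    Mask voxels are AR(1) with band phis (plus the group boost); voxels
    outside the masks are white noise.
    """
    phis = voxel_phis(spec, record.group, masks, truth_labels)
    data = rng.standard_normal(spec.grid_shape + (spec.t,)) * spec.noise_sd
    for mask in masks:
        x = _ar1_matrix(phis[mask.hemisphere], spec.t, spec.noise_sd, rng)
        i, j, k = mask.voxel_index.T
        data[i, j, k, :] = x
    run = BoldRun(
        data=data, tr_seconds=spec.tr_seconds, affine=_affine(spec), run_id=record.pid
    )
    motion = _motion_trace(spec.t, spec.motion_spike_rate, rng)
    return run, motion


def _make_records(spec: SimSpec) -> list[ParticipantRecord]:
    records = []
    counter = 1
    for group in ("control", "ltle", "rtle"):
        for i in range(spec.n_per_group):
            records.append(
                ParticipantRecord(
                    pid=f"sub-{counter:03d}",
                    group=group,
                    # alternate MTS status within patient groups
                    mts="n/a" if group == "control" else ("mts" if i % 2 == 0 else "no_mts"),
                )
            )
            counter += 1
    return records


def simulate_cohort(spec: SimSpec) -> SimOutput:
    """A full cohort: n_per_group participants in each of the three groups.

    Each participant draws from an independent child stream of the root seed,
    so the cohort is bit-reproducible and any participant can be replayed.
    """
    if spec.n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    left, right, truth = make_roi_masks(spec)
    records = _make_records(spec)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(records))
    runs, motion, child_seeds = [], {}, {}
    for record, child in zip(records, children):
        rng = np.random.default_rng(child)
        run, mtrace = simulate_participant(spec, record, (left, right), truth, rng)
        runs.append(run)
        motion[record.pid] = mtrace
        child_seeds[record.pid] = int(child.generate_state(1)[0] % (2**31))
    return SimOutput(
        runs=runs,
        masks=(left, right),
        truth_labels=truth,
        motion=motion,
        participants=records,
        truth=spec,
        child_seeds=child_seeds,
    )


def simulate_memory_scores(
    preservation: np.ndarray,
    spec: SimSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Scores as a noisy linear function of anterior-medial preservation.

    score_i = memory_slope * J_i + Normal(0, memory_noise_sd^2). Returns the
    scores together with the generating slope for recovery tests.
    """
    j = np.asarray(preservation, dtype=float)
    if np.any((j < 0) | (j > 1)):
        raise ValueError("preservation values must lie in [0, 1]")
    scores = spec.memory_slope * j + rng.standard_normal(j.shape) * spec.memory_noise_sd
    return scores, spec.memory_slope


def memory_noise_for_target_r(slope: float, sd_j: float, target_r: float) -> float:
    """Noise SD giving population Pearson r = target for score = slope*J + noise."""
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must lie in (0, 1)")
    return abs(slope) * sd_j * np.sqrt(1.0 / target_r**2 - 1.0)


def write_bids_dir(out_dir, sim: SimOutput) -> None:
    """Write the cohort as a BIDS-flavored directory of plain NIfTI/TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = sim.masks[0].affine
    for mask in sim.masks:
        nib.save(
            nib.Nifti1Image(mask.grid.astype(np.int16), aff),
            out / f"mask-{mask.hemisphere}.nii.gz",
        )
    for run, rec in zip(sim.runs, sim.participants):
        img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
        img.header.set_zooms((sim.truth.voxel_mm,) * 3 + (run.tr_seconds,))
        nib.save(img, out / f"{rec.pid}_bold.nii.gz")
        np.savetxt(out / f"{rec.pid}_motion.txt", sim.motion[rec.pid], fmt="%.6f")
    write_participants(sim.participants, out / "participants.tsv")
    truth = asdict(sim.truth)
    truth["grid_shape"] = list(truth["grid_shape"])
    truth["band_phis"] = list(truth["band_phis"])
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    if sim.truth_labels is not None:
        np.savetxt(out / "truth-labels-left.txt", sim.truth_labels["left"], fmt="%d")
        np.savetxt(out / "truth-labels-right.txt", sim.truth_labels["right"], fmt="%d")
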