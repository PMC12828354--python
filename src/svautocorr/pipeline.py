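"""End-to-end orchestration: cohort -> autocorrelation -> clusters -> statistics.

Stage order follows the analysis contract: (optional) nuisance regression and
scrubbing, then low-pass filtering, then per-voxel lagged autocorrelation,
then similarity/modularity clustering per participant and hemisphere, group
maps by averaging similarity matrices, preservation against the control
group reference, and the statistics layer on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import prep as prep_mod
from .autocorr import AutocorrMap, autocorr_map, max_lags
from .cluster import (
    ClusterMap,
    group_similarity,
    label_clusters_by_autocorr,
    modularity_clusters,
    similarity_matrix,
)
from .io import extract_roi_timecourses
from .preservation import cluster_preservation
from .stats import build_cell_means
from .synth import SimOutput, simulate_memory_scores

__all__ = ["CohortResult", "analyze_cohort", "attach_memory_scores"]

HEMISPHERES = ("left", "right")


@dataclass
class CohortResult:
    acmaps: dict[tuple[str, str], AutocorrMap]  # (pid, hemisphere)
    cluster_maps: dict[tuple[str, str], ClusterMap]
    group_maps: dict[tuple[str, str], ClusterMap]  # (group, hemisphere)
    group_acmaps: dict[tuple[str, str], AutocorrMap]
    preservation: pd.DataFrame  # pid, group, hemisphere, role, jaccard
    cells: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def preservation_values(self, group: str, hemisphere: str, role: str) -> pd.DataFrame:
        p = self.preservation
        sel = (p["group"] == group) & (p["hemisphere"] == hemisphere) & (p["role"] == role)
        return p.loc[sel, ["pid", "jaccard"]]


def analyze_cohort(
    sim: SimOutput,
    seed: int = 0,
    n_restarts: int = 10,
    do_prep: bool = False,
    lag_mode: str = "lag1",
    expected_clusters: int | None = 3,
    reference_group: str = "control",
    with_preservation: bool = True,
) -> CohortResult:
    """Run the full analysis on a simulated cohort.

    Per participant and hemisphere: ROI extraction, optional conditioning,
    the lagged autocorrelation map, similarity and modularity clustering,
    and autocorrelation-rank role labels. Group maps come from clustering the
    mean similarity matrix of each group's members (individuals whose map
    does not have ``expected_clusters`` clusters are excluded from group
    averaging and the cell-means table, and flagged). Preservation is each
    individual's per-role Jaccard against the reference group's map.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 912021)))
    n_lags = max_lags(sim.truth.tr_seconds)
    acmaps: dict[tuple[str, str], AutocorrMap] = {}
    cmaps: dict[tuple[str, str], ClusterMap] = {}
    sims: dict[tuple[str, str], object] = {}
    excluded: list[tuple[str, str]] = []

    noise_idx = None
    if do_prep:
        in_mask = sim.masks[0].grid | sim.masks[1].grid
        candidates = np.argwhere(~in_mask)
        take = min(200, candidates.shape[0])
        noise_idx = candidates[
            rng.choice(candidates.shape[0], size=take, replace=False)
        ]

    for record, run in zip(sim.participants, sim.runs):
        for mask in sim.masks:
            tc = extract_roi_timecourses(run, mask)
            if do_prep:
                i, j, k = noise_idx.T
                noise_tc = run.data[i, j, k, :]
                comps = prep_mod.compcor_components(noise_tc)
                flags = prep_mod.scrub_flags(run, sim.motion[record.pid])
                confounds = prep_mod.build_confounds(comps, flags)
                tc = prep_mod.prep_timecourses(tc, confounds)
            acmap = autocorr_map(tc, n_lags=n_lags)
            S = similarity_matrix(acmap)
            cm = modularity_clusters(
                S, seed=int(rng.integers(2**31)), n_restarts=n_restarts
            )
            cm = label_clusters_by_autocorr(cm, acmap)
            key = (record.pid, mask.hemisphere)
            acmaps[key], cmaps[key], sims[key] = acmap, cm, S
            if expected_clusters is not None and cm.n_clusters != expected_clusters:
                excluded.append(key)

    groups = sorted({r.group for r in sim.participants}) if with_preservation else []
    group_maps: dict[tuple[str, str], ClusterMap] = {}
    group_acmaps: dict[tuple[str, str], AutocorrMap] = {}
    for group in groups:
        members = [r.pid for r in sim.participants if r.group == group]
        for hemi in HEMISPHERES:
            keys = [
                (pid, hemi)
                for pid in members
                if (pid, hemi) not in excluded
            ]
            if not keys:
                continue
            gS = group_similarity([sims[k] for k in keys], source=f"{group}/{hemi}")
            g_ac = AutocorrMap(
                values=np.mean([acmaps[k].values for k in keys], axis=0),
                n_lags=n_lags,
                tr_seconds=sim.truth.tr_seconds,
                mask_ref=acmaps[keys[0]].mask_ref,
            )
            gcm = modularity_clusters(
                gS, seed=int(rng.integers(2**31)), n_restarts=n_restarts
            )
            gcm = label_clusters_by_autocorr(gcm, g_ac)
            group_maps[(group, hemi)] = gcm
            group_acmaps[(group, hemi)] = g_ac

    pres_rows = []
    by_pid = {r.pid: r for r in sim.participants}
    for (pid, hemi), cm in cmaps.items():
        ref = group_maps.get((reference_group, hemi))
        if ref is None or (pid, hemi) in excluded:
            continue
        score = cluster_preservation(cm, ref, pid=pid, reference_id=f"{reference_group}/{hemi}")
        for role, j in score.jaccard.items():
            pres_rows.append(
                {
                    "pid": pid,
                    "group": by_pid[pid].group,
                    "hemisphere": hemi,
                    "role": role,
                    "jaccard": j,
                }
            )
    preservation = pd.DataFrame(pres_rows)

    entries = [
        (by_pid[pid], hemi, acmaps[(pid, hemi)], cmaps[(pid, hemi)])
        for (pid, hemi) in cmaps
    ]
    cells = build_cell_means(entries, lag_mode=lag_mode, expected_clusters=expected_clusters)
    return CohortResult(
        acmaps=acmaps,
        cluster_maps=cmaps,
        group_maps=group_maps,
        group_acmaps=group_acmaps,
        preservation=preservation,
        cells=cells,
        excluded=excluded,
    )


def attach_memory_scores(result: CohortResult, sim: SimOutput, rng: np.random.Generator) -> None:
    """Generate memory scores from realized anterior-medial preservation.

    Verbal scores of the ltle group are built on left-hemisphere
    anterior-medial preservation; visuospatial scores of the rtle group on
    the right — the material-specific, lateralized design the correlation
    layer is meant to detect. All other scores are pure noise of the same
    scale.
    """
    spec = sim.truth
    pres = result.preservation.set_index(["pid", "hemisphere", "role"])["jaccard"]
    for record in sim.participants:
        for attr, hemi, generating_group in (
            ("verbal_memory", "left", "ltle"),
            ("visuospatial_memory", "right", "rtle"),
        ):
            key = (record.pid, hemi, "anterior-medial")
            if record.group == generating_group and key in pres.index and np.isfinite(pres[key]):
                score, _ = simulate_memory_scores(np.array([pres[key]]), spec, rng)
                setattr(record, attr, float(score[0]))
            else:
                setattr(
                    record,
                    attr,
                    float(rng.standard_normal() * spec.memory_noise_sd),
                )
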