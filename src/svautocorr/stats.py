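"""Group statistics: cell means, the mixed model, and FDR-corrected correlations.

The headline inference is a linear mixed-effects model on per-participant
cluster-mean autocorrelation with cluster role, group, and hemisphere as
crossed fixed effects and participant as a random intercept (REML). Term
F statistics are Wald tests on sum-coded factors (so each term's test is a
Type-III ANOVA test), with containment denominator degrees of freedom:
between-subject terms use n_subjects - g and within-subject terms use
N - n_subjects - (p - g), where g counts the between-subject cells and p the
fixed-effect columns. For balanced designs these equal the classical
split-plot df. Post-hoc pairwise contrasts of estimated marginal means use
the Tukey (studentized-range) correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .autocorr import AutocorrMap
from .cluster import ClusterMap
from .io import ParticipantRecord

__all__ = [
    "LmeResult",
    "cluster_mean_autocorr",
    "build_cell_means",
    "fit_lme",
    "pairwise_contrasts",
    "pearson_with_fdr",
    "mts_cells",
    "flipped_hemisphere_recode",
]

LAG_MODES = ("lag1", "mean-of-lags")


@dataclass
class LmeResult:
    """Fixed-effect F tests, post-hoc contrasts and fit diagnostics."""

    anova: pd.DataFrame  # term, F, df_num, df_den, p
    contrasts: pd.DataFrame  # factor, level_a, level_b, estimate, se, t, df, p_tukey
    df_method: str
    converged: bool
    n_obs: int
    n_subjects: int
    fit: object = field(repr=False, default=None)
    _ctx: dict = field(repr=False, default_factory=dict)

    def term_p(self, term: str) -> float:
        row = self.anova.loc[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r}; have {list(self.anova['term'])}")
        return float(row["p"].iloc[0])


def cluster_mean_autocorr(
    acmap: AutocorrMap, cm: ClusterMap, lag_mode: str = "lag1"
) -> dict[str, float]:
    """Mean autocorrelation per cluster role (lag 1 or mean over lags)."""
    if lag_mode not in LAG_MODES:
        raise ValueError(f"lag_mode must be one of {LAG_MODES}")
    stat = acmap.lag1 if lag_mode == "lag1" else acmap.values.mean(axis=1)
    out = {}
    for role in cm.roles:
        vox = cm.role_voxels(role)
        out[role] = float(np.nanmean(stat[vox])) if vox.size else np.nan
    return out


def build_cell_means(
    entries: list[tuple[ParticipantRecord, str, AutocorrMap, ClusterMap]],
    lag_mode: str = "lag1",
    expected_clusters: int | None = 3,
) -> pd.DataFrame:
    """Cell-means table: one row per (pid, hemisphere, role).

    Maps whose cluster count differs from ``expected_clusters`` are excluded
    (flagged upstream), mirroring the exclusion of non-three-cluster
    solutions from the group analysis.
    """
    rows = []
    for record, hemisphere, acmap, cm in entries:
        if expected_clusters is not None and cm.n_clusters != expected_clusters:
            continue
        means = cluster_mean_autocorr(acmap, cm, lag_mode=lag_mode)
        for role, mean in means.items():
            rows.append(
                {
                    "pid": record.pid,
                    "group": record.group,
                    "hemisphere": hemisphere,
                    "role": role,
                    "mean_autocorr": mean,
                    "cluster_size": int(cm.role_voxels(role).size),
                }
            )
    return pd.DataFrame(rows)


def fit_lme(
    cells: pd.DataFrame,
    formula_terms: tuple[str, ...] = ("role", "group", "hemisphere"),
    random_intercept: str = "pid",
    dependent: str = "mean_autocorr",
    posthoc_factors: tuple[str, ...] | None = None,
) -> LmeResult:
    """REML mixed model with full-factorial fixed effects and a random intercept.

    Factors with a single level in the data are dropped from the fixed
    effects (with a warning). Post-hoc Tukey contrasts are computed for each
    requested factor's estimated marginal means.
    """
    cells = cells.dropna(subset=[dependent]).copy()
    factors = []
    for f in formula_terms:
        if cells[f].nunique() >= 2:
            factors.append(f)
        else:
            warnings.warn(f"factor {f!r} has < 2 levels; dropped", stacklevel=2)
    if not factors:
        raise ValueError("no factor has 2 or more levels")
    rhs = " * ".join(f"C({f}, Sum)" for f in factors)
    formula = f"{dependent} ~ {rhs}"
    model = smf.mixedlm(formula, data=cells, groups=cells[random_intercept])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    converged = bool(getattr(res, "converged", True))

    design_info = model.data.design_info
    k_fe = len(res.fe_params)
    beta = np.asarray(res.fe_params)
    V = np.asarray(res.cov_params())[:k_fe, :k_fe]

    n_subjects = cells[random_intercept].nunique()
    n_obs = len(cells)
    between = {
        f for f in factors if cells.groupby(random_intercept)[f].nunique().max() == 1
    }
    g_between = (
        cells.drop_duplicates(random_intercept)[sorted(between)]
        .drop_duplicates()
        .shape[0]
        if between
        else 1
    )
    df_between = n_subjects - g_between
    df_within = n_obs - n_subjects - (k_fe - g_between)

    def term_df(term_factors: list[str]) -> int:
        return df_between if set(term_factors) <= between else df_within

    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k_fe)[sl]
        raw = [f for f in factors if f"C({f}, Sum)" in term]
        b = beta[idx]
        Vt = V[np.ix_(idx, idx)]
        q = len(idx)
        F = float(b @ np.linalg.solve(Vt, b)) / q
        dden = term_df(raw)
        rows.append(
            {
                "term": ":".join(raw),
                "F": F,
                "df_num": q,
                "df_den": dden,
                "p": float(sps.f.sf(F, q, dden)),
            }
        )
    anova = pd.DataFrame(rows)

    ctx = {
        "design_info": design_info,
        "factors": factors,
        "levels": {f: sorted(cells[f].unique()) for f in factors},
        "beta": beta,
        "V": V,
        "between": between,
        "df_between": df_between,
        "df_within": df_within,
    }
    contrast_frames = []
    for f in posthoc_factors if posthoc_factors is not None else factors:
        if f in factors:
            contrast_frames.append(_pairwise(ctx, f))
    contrasts = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame()
    )
    return LmeResult(
        anova=anova,
        contrasts=contrasts,
        df_method="containment",
        converged=converged,
        n_obs=n_obs,
        n_subjects=n_subjects,
        fit=res,
        _ctx=ctx,
    )


def pairwise_contrasts(result: LmeResult, factor: str, by: str | None = None) -> pd.DataFrame:
    """Tukey-corrected pairwise contrasts of a factor's marginal means.

    With ``by``, contrasts are computed within each level of the other
    factor (simple effects), each level forming its own Tukey family.
    """
    ctx = result._ctx
    if factor not in ctx["factors"]:
        raise KeyError(f"unknown factor {factor!r}")
    if by is None:
        return _pairwise(ctx, factor)
    frames = [
        _pairwise(ctx, factor, fix={by: lev}) for lev in ctx["levels"][by]
    ]
    return pd.concat(frames, ignore_index=True)


def _pairwise(ctx: dict, factor: str, fix: dict | None = None) -> pd.DataFrame:
    from patsy import dmatrix

    levels = ctx["levels"]
    grid_factors = ctx["factors"]
    combos = [
        dict(zip(grid_factors, vals))
        for vals in product(*(levels[f] for f in grid_factors))
    ]
    if fix:
        combos = [c for c in combos if all(c[k] == v for k, v in fix.items())]
    grid = pd.DataFrame(combos)
    X = np.asarray(dmatrix(ctx["design_info"], grid))
    rows_for = {
        lev: X[(grid[factor] == lev).to_numpy()].mean(axis=0) for lev in levels[factor]
    }
    k = len(levels[factor])
    df = (
        ctx["df_between"] if {factor} <= ctx["between"] else ctx["df_within"]
    )
    out = []
    for la, lb in combinations(levels[factor], 2):
        L = rows_for[la] - rows_for[lb]
        est = float(L @ ctx["beta"])
        se = float(np.sqrt(L @ ctx["V"] @ L))
        t = est / se if se > 0 else np.nan
        p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df)) if np.isfinite(t) else np.nan
        out.append(
            {
                "factor": factor,
                "within": ", ".join(f"{k_}={v}" for k_, v in (fix or {}).items()),
                "level_a": la,
                "level_b": lb,
                "estimate": est,
                "se": se,
                "t": t,
                "df": df,
                "p_tukey": min(1.0, p) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(out)


def pearson_with_fdr(pairs: list[tuple[np.ndarray, np.ndarray, str]]) -> pd.DataFrame:
    """Pearson r per labeled pair with Benjamini-Hochberg adjustment.

    The declared family is exactly the supplied list (no silent inflation);
    pairs with missing values are reduced to their complete observations.
    """
    rows = []
    for x, y, label in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError(f"pair {label!r} has fewer than 3 complete observations")
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"pair {label!r} has a zero-variance variable")
        r, p = sps.pearsonr(x, y)
        rows.append({"label": label, "r": float(r), "n": int(x.size), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    return df


def mts_cells(
    cells: pd.DataFrame,
    participants: list[ParticipantRecord],
    exclude_possible: bool = True,
) -> pd.DataFrame:
    """Patient cell means annotated with MTS status, for MTS-factor models.

    Controls are dropped (MTS is undefined for them); patients with only a
    possible hippocampal abnormality are excluded by default since their MTS
    status is unconfirmed. The result feeds ``fit_lme`` with
    ``formula_terms=("mts", "group", "hemisphere")`` on, e.g., the
    anterior-medial rows.
    """
    status = {r.pid: r.mts for r in participants}
    out = cells.copy()
    out["mts"] = out["pid"].map(status)
    out = out[out["mts"].isin(("mts", "no_mts", "possible"))]
    if exclude_possible:
        out = out[out["mts"] != "possible"]
    return out.reset_index(drop=True)


def flipped_hemisphere_recode(
    cells: pd.DataFrame,
    participants: list[ParticipantRecord],
    controls: str = "exclude",
) -> pd.DataFrame:
    """Recode the hemisphere factor to epileptogenic vs healthy per patient.

    Controls have no epileptogenic hemisphere and are excluded by default
    (``controls="keep"`` retains their rows unrecoded). Recoding is an
    involution on patient rows: applying the inverse map restores them.
    """
    epi = {r.pid: r.epi_hemisphere for r in participants}
    group = {r.pid: r.group for r in participants}
    out = cells.copy()
    is_control = out["pid"].map(group) == "control"
    patient_rows = out.loc[~is_control]
    missing = [p for p in patient_rows["pid"].unique() if epi.get(p, "n/a") == "n/a"]
    if missing:
        raise ValueError(f"patients without an epileptogenic hemisphere: {missing}")
    recoded = np.where(
        patient_rows["hemisphere"] == patient_rows["pid"].map(epi),
        "epileptogenic",
        "healthy",
    )
    out.loc[~is_control, "hemisphere"] = recoded
    if controls == "exclude":
        out = out.loc[~is_control].reset_index(drop=True)
    return out
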