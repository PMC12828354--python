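import numpy as np
import pandas as pd
import pytest

import svautocorr as sv
from svautocorr.autocorr import AutocorrMap
from svautocorr.cluster import (
    ROLE_ANTERIOR_MEDIAL,
    ROLE_INTERMEDIATE,
    ROLE_POSTERIOR_LATERAL,
    ClusterMap,
)
from svautocorr.stats import cluster_mean_autocorr, pairwise_contrasts


def brute_bh(p):
    """Step-up Benjamini-Hochberg oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def _labeled_map(labels, means=(0.6, 0.4, 0.2)):
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    roles = [ROLE_ANTERIOR_MEDIAL, ROLE_INTERMEDIATE, ROLE_POSTERIOR_LATERAL][:k]
    if k == 2:
        roles = [ROLE_ANTERIOR_MEDIAL, ROLE_POSTERIOR_LATERAL]
    return ClusterMap(
        labels=labels,
        n_clusters=k,
        modularity_q=0.1,
        seed=0,
        role_order=dict(enumerate(roles)),
        role_means=dict(zip(roles, means)),
    )


class TestClusterMeans:
    def test_uniform_map_gives_equal_role_means(self):
        ac = AutocorrMap(values=np.full((9, 2), 0.3), n_lags=2, tr_seconds=2.0)
        cm = _labeled_map([0, 0, 0, 1, 1, 1, 2, 2, 2])
        means = cluster_mean_autocorr(ac, cm)
        assert all(v == pytest.approx(0.3) for v in means.values())

    def test_mean_of_lags_between_lag_values(self):
        rng = np.random.default_rng(0)
        vals = np.column_stack([rng.uniform(0.4, 0.6, 30), rng.uniform(0.2, 0.3, 30)])
        ac = AutocorrMap(values=vals, n_lags=2, tr_seconds=2.0)
        cm = _labeled_map(np.zeros(30, dtype=int), means=(0.5,))
        lag1 = cluster_mean_autocorr(ac, cm, lag_mode="lag1")[ROLE_ANTERIOR_MEDIAL]
        mol = cluster_mean_autocorr(ac, cm, lag_mode="mean-of-lags")[ROLE_ANTERIOR_MEDIAL]
        assert vals[:, 1].mean() < mol < lag1

    def test_bad_lag_mode_rejected(self):
        ac = AutocorrMap(values=np.zeros((2, 2)), n_lags=2, tr_seconds=2.0)
        with pytest.raises(ValueError, match="lag_mode"):
            cluster_mean_autocorr(ac, _labeled_map([0, 1]), lag_mode="banana")


def _cells(rng, n_per_group=8, effects=None, tau=0.05, sigma=0.03):
    effects = effects or {}
    rows = []
    pid = 0
    for g in ("control", "ltle", "rtle"):
        for _ in range(n_per_group):
            pid += 1
            u = rng.normal(0, tau)
            for r in ("anterior-medial", "intermediate", "posterior-lateral"):
                for h in ("left", "right"):
                    mu = effects.get((g, r), 0.0)
                    rows.append(
                        {
                            "pid": f"s{pid:03d}",
                            "group": g,
                            "hemisphere": h,
                            "role": r,
                            "mean_autocorr": mu + u + rng.normal(0, sigma),
                            "cluster_size": 100,
                        }
                    )
    return pd.DataFrame(rows)


class TestFitLme:
    def test_recovers_injected_interaction(self):
        rng = np.random.default_rng(0)
        cells = _cells(rng, effects={("ltle", "anterior-medial"): 0.15})
        res = sv.fit_lme(cells)
        assert res.converged
        assert res.term_p("role:group") < 0.01
        assert res.df_method == "containment"

    def test_containment_df_match_balanced_design(self):
        rng = np.random.default_rng(1)
        cells = _cells(rng, n_per_group=10)
        res = sv.fit_lme(cells)
        n_subj, n_obs, k_fe, g = 30, 180, 18, 3
        between = res.anova.set_index("term").loc["group"]
        within = res.anova.set_index("term").loc["role"]
        assert between["df_den"] == n_subj - g
        assert within["df_den"] == n_obs - n_subj - (k_fe - g)

    def test_group_posthoc_detects_elevated_group(self):
        rng = np.random.default_rng(2)
        cells = _cells(
            rng,
            effects={
                ("ltle", "anterior-medial"): 0.2,
                ("ltle", "intermediate"): 0.2,
                ("ltle", "posterior-lateral"): 0.2,
            },
        )
        res = sv.fit_lme(cells)
        grp = res.contrasts.query("factor == 'group'")
        lc = grp.query("level_a == 'control' and level_b == 'ltle'").iloc[0]
        cr = grp.query("level_a == 'control' and level_b == 'rtle'").iloc[0]
        assert lc["p_tukey"] < 0.001
        assert cr["p_tukey"] > 0.05

    def test_simple_effects_within_level(self):
        rng = np.random.default_rng(3)
        cells = _cells(rng, effects={("ltle", "anterior-medial"): 0.2})
        res = sv.fit_lme(cells)
        by_role = pairwise_contrasts(res, "group", by="role")
        am = by_role.query("within == 'role=anterior-medial' and level_a == 'control' and level_b == 'ltle'")
        pl = by_role.query("within == 'role=posterior-lateral' and level_a == 'control' and level_b == 'ltle'")
        assert am["p_tukey"].iloc[0] < 0.001
        assert pl["p_tukey"].iloc[0] > 0.05

    def test_single_level_factor_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        cells = _cells(rng)
        cells = cells[cells["hemisphere"] == "left"]
        with pytest.warns(UserWarning, match="dropped"):
            res = sv.fit_lme(cells)
        assert not any("hemisphere" in t for t in res.anova["term"])


class TestPearsonFdr:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        out = sv.pearson_with_fdr([(x, 2 * x, "lin")])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_worked_bh_case(self):
        # raw p = [.01, .02, .03, .04] with m = 4 -> all adjusted to .04
        rng = np.random.default_rng(0)
        adj = brute_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, 0.04)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1], adj
        )

    def test_bh_matches_brute_force_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], brute_bh(p), atol=1e-12
            )

    def test_adjusted_at_least_raw_and_family_is_explicit(self):
        rng = np.random.default_rng(2)
        pairs = [
            (rng.standard_normal(20), rng.standard_normal(20), f"pair{i}") for i in range(4)
        ]
        out = sv.pearson_with_fdr(pairs)
        assert len(out) == 4
        assert (out["p_fdr"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_fdr"] <= 1.0).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sv.pearson_with_fdr([(np.ones(5), np.arange(5.0), "flat")])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            sv.pearson_with_fdr([(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "tiny")])


class TestFlippedRecode:
    def _participants(self):
        return [
            sv.ParticipantRecord(pid="c1", group="control"),
            sv.ParticipantRecord(pid="l1", group="ltle", epi_hemisphere="left"),
            sv.ParticipantRecord(pid="r1", group="rtle", epi_hemisphere="right"),
        ]

    def _cells(self):
        rows = []
        for pid in ("c1", "l1", "r1"):
            for h in ("left", "right"):
                rows.append(
                    {"pid": pid, "group": {"c": "control", "l": "ltle", "r": "rtle"}[pid[0]],
                     "hemisphere": h, "role": "anterior-medial", "mean_autocorr": 0.5}
                )
        return pd.DataFrame(rows)

    def test_ltle_and_rtle_mirror(self):
        out = sv.flipped_hemisphere_recode(self._cells(), self._participants())
        l1 = out[out.pid == "l1"].set_index("hemisphere")
        assert set(l1.index) == {"epileptogenic", "healthy"}
        r1 = out[out.pid == "r1"]
        assert (
            r1.loc[r1.hemisphere == "epileptogenic"].index.size == 1
        )
        # controls excluded by default
        assert "c1" not in set(out.pid)

    def test_recode_is_involution_on_patients(self):
        cells = self._cells()
        out = sv.flipped_hemisphere_recode(cells, self._participants())
        epi = {"l1": "left", "r1": "right"}
        back = out.copy()
        back["hemisphere"] = [
            epi[p] if h == "epileptogenic" else ({"left": "right", "right": "left"}[epi[p]])
            for p, h in zip(out.pid, out.hemisphere)
        ]
        orig = cells[cells.pid != "c1"].sort_values(["pid", "hemisphere"]).reset_index(drop=True)
        back = back.sort_values(["pid", "hemisphere"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(orig, back)

    def test_missing_epi_hemisphere_rejected(self):
        parts = self._participants()
        parts[1] = sv.ParticipantRecord(pid="l1", group="ltle")
        parts[1].epi_hemisphere = "n/a"
        with pytest.raises(ValueError, match="epileptogenic"):
            sv.flipped_hemisphere_recode(self._cells(), parts)


class TestMtsCells:
    def test_controls_and_possible_excluded(self):
        parts = [
            sv.ParticipantRecord(pid="c1", group="control"),
            sv.ParticipantRecord(pid="l1", group="ltle", mts="mts"),
            sv.ParticipantRecord(pid="l2", group="ltle", mts="possible"),
            sv.ParticipantRecord(pid="r1", group="rtle", mts="no_mts"),
        ]
        rows = []
        for p in parts:
            for h in ("left", "right"):
                rows.append({"pid": p.pid, "group": p.group, "hemisphere": h,
                             "role": "anterior-medial", "mean_autocorr": 0.5})
        cells = pd.DataFrame(rows)
        out = sv.mts_cells(cells, parts)
        assert set(out["pid"]) == {"l1", "r1"}
        assert set(out["mts"]) == {"mts", "no_mts"}
        kept = sv.mts_cells(cells, parts, exclude_possible=False)
        assert "l2" in set(kept["pid"])

    def test_feeds_mts_factor_model(self):
        rng = np.random.default_rng(9)
        rows = []
        pid = 0
        for g in ("ltle", "rtle"):
            for i in range(10):
                pid += 1
                u = rng.normal(0, 0.05)
                for h in ("left", "right"):
                    rows.append({"pid": f"s{pid}", "group": g, "hemisphere": h,
                                 "role": "anterior-medial",
                                 "mts": "mts" if i % 2 == 0 else "no_mts",
                                 "mean_autocorr": u + rng.normal(0, 0.03)})
        cells = pd.DataFrame(rows)
        res = sv.fit_lme(cells, formula_terms=("mts", "group", "hemisphere"))
        assert res.converged
        assert res.term_p("mts") > 0.0  # well-defined test for the MTS factor
        assert "mts:group" in set(res.anova["term"])
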