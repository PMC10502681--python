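"""Statistics-stage tests: every test statistic is checked against either a
hand-computed fixture, an independent brute-force implementation, or a
Monte-Carlo property."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qsmpipe.masking import BinaryMask, ROILabelMap
from qsmpipe.phantom import CohortSpec, SubjectRecord, records_to_frame, simulate_cohort
from qsmpipe.roistats import (AgeModel, _oneway_anova, age_correct,
                              ancova_slopes, cognition_regress,
                              demographics_compare, fbtcs_analyses,
                              fit_age_model, group_anova, lilliefors_statistic,
                              normality_check, onset_corr, paired_lr_test,
                              quality_compare, roi_summary, tukey_kramer,
                              volume_corr)


def _table(rows):
    return pd.DataFrame(rows)


def _roi_rows(values_by_subject, roi="hippocampus", hemi="left",
              measure="chi_ppm"):
    rows = []
    for sid, v in values_by_subject.items():
        rows.append({"subject_id": sid, "roi": roi, "hemisphere": hemi,
                     "measure": measure, "mean": v, "std": 0.0,
                     "voxel_count": 100, "method": "t"})
    return rows


class TestRoiSummary:
    def _fixture(self, rng):
        vals = rng.standard_normal((8, 8, 8))
        lab = np.zeros((8, 8, 8), int)
        lab[1:4, 1:4, 1:4] = 1
        lab[5:7, 5:7, 5:7] = 2
        labels = ROILabelMap(lab, {1: ("caudate", "left"), 2: ("caudate", "right")})
        mask = BinaryMask(np.ones((8, 8, 8), bool))
        return vals, labels, mask

    def test_constant_roi(self, rng):
        vals, labels, mask = self._fixture(rng)
        vals[labels.values == 1] = 0.05
        t = roi_summary(vals, labels, mask)
        row = t[t.hemisphere == "left"].iloc[0]
        assert row["mean"] == pytest.approx(0.05)
        assert row["std"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        vals, labels, mask = self._fixture(rng)
        t = roi_summary(vals, labels, mask)
        for lid, (name, hemi) in labels.table.items():
            sel = vals[(labels.values == lid) & mask.values]
            row = t[(t.roi == name) & (t.hemisphere == hemi)].iloc[0]
            assert row["mean"] == pytest.approx(sel.mean(), abs=1e-12)
            assert row["std"] == pytest.approx(sel.std(), abs=1e-12)
            assert row["voxel_count"] == sel.size

    def test_label_outside_mask_dropped(self, rng):
        vals, labels, mask = self._fixture(rng)
        m = mask.values.copy()
        m[labels.values == 2] = False
        t = roi_summary(vals, labels, BinaryMask(m))
        assert set(t.hemisphere) == {"left"}

    def test_all_empty_raises(self, rng):
        vals, labels, _ = self._fixture(rng)
        with pytest.raises(ValueError, match="every ROI"):
            roi_summary(vals, labels, BinaryMask(np.zeros((8, 8, 8), bool)))


class TestOneWayAnovaOracle:
    def test_hand_computed_fixture(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]),
                  np.array([3.0, 4, 5])]
        f, p, eta2, dfb, dfw, msw = _oneway_anova(groups)
        # brute force from sums of squares
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_ref = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(f_ref, abs=1e-12)
        assert eta2 == pytest.approx(ssb / (ssb + ssw), abs=1e-12)
        f_sp, p_sp = stats.f_oneway(*groups)
        assert f == pytest.approx(f_sp, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-10)

    def test_identical_groups(self):
        g = [np.array([1.0, 2, 3])] * 3
        f, p, eta2, *_ = _oneway_anova(g)
        assert f == 0.0 and eta2 == 0.0

    def test_eta2_bounded(self, rng):
        for _ in range(200):
            groups = [rng.standard_normal(rng.integers(3, 8))
                      for _ in range(3)]
            _, _, eta2, *_ = _oneway_anova(groups)
            assert 0.0 <= eta2 <= 1.0


class TestGroupAnova:
    def test_fixture_and_errors(self):
        rows = (_roi_rows({f"h{i}": v for i, v in enumerate([1, 2, 3])})
                + _roi_rows({f"l{i}": v for i, v in enumerate([2, 3, 4])})
                + _roi_rows({f"r{i}": v for i, v in enumerate([3, 4, 5])}))
        groups = {f"h{i}": "HC" for i in range(3)}
        groups |= {f"l{i}": "LTLE" for i in range(3)}
        groups |= {f"r{i}": "RTLE" for i in range(3)}
        rep = group_anova(_table(rows), groups)
        f_ref, p_ref = stats.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert rep.iloc[0]["statistic"] == pytest.approx(f_ref, abs=1e-10)
        assert rep.iloc[0]["p"] == pytest.approx(p_ref, abs=1e-10)
        groups["r2"] = None  # drops a subject: RTLE has 2 left, still ok
        small = {k: v for k, v in groups.items() if v}
        small = {k: v for k, v in small.items() if not (v == "RTLE" and k != "r0")}
        with pytest.raises(ValueError, match="need >= 2"):
            group_anova(_table(rows)[_table(rows).subject_id.isin(small)], small)


class TestTukeyKramer:
    def test_identical_groups_null(self):
        rows = []
        groups = {}
        for gi, gname in enumerate(("HC", "LTLE", "RTLE")):
            for i, v in enumerate([1.0, 2.0, 3.0]):
                sid = f"{gname}{i}"
                rows += _roi_rows({sid: v})
                groups[sid] = gname
        rep = tukey_kramer(_table(rows), groups)
        assert (rep["p"] > 0.95).all()
        assert np.allclose(rep["effect"].astype(float), 0.0)

    def test_cohens_d_hand_computed(self):
        rows = []
        groups = {}
        for gname, vals in (("HC", [1.0, 2, 3]), ("LTLE", [2.0, 3, 4]),
                            ("RTLE", [2.0, 3, 4])):
            for i, v in enumerate(vals):
                sid = f"{gname}{i}"
                rows += _roi_rows({sid: v})
                groups[sid] = gname
        rep = tukey_kramer(_table(rows), groups)
        row = rep[rep.contrast == "HC vs LTLE"].iloc[0]
        # pooled SD 1, difference 1 -> |d| = 1
        assert abs(row["effect"]) == pytest.approx(1.0, abs=1e-12)

    def test_equal_n_reduces_to_scipy_tukey_hsd(self, rng):
        arrs = [rng.standard_normal(8) for _ in range(3)]
        rows, groups = [], {}
        for gname, a in zip(("HC", "LTLE", "RTLE"), arrs):
            for i, v in enumerate(a):
                sid = f"{gname}{i}"
                rows += _roi_rows({sid: v})
                groups[sid] = gname
        rep = tukey_kramer(_table(rows), groups)
        ref = stats.tukey_hsd(*arrs)
        pairs = {("HC vs LTLE"): (0, 1), ("HC vs RTLE"): (0, 2),
                 ("LTLE vs RTLE"): (1, 2)}
        for contrast, (i, j) in pairs.items():
            p_mine = rep[rep.contrast == contrast].iloc[0]["p"]
            assert p_mine == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_familywise_error_under_null(self, rng):
        """Tukey-Kramer FWE stays at/below ~5% with unequal n (null)."""
        reps, fw = 400, 0
        for _ in range(reps):
            arrs = [rng.standard_normal(n) for n in (10, 8, 12)]
            _, _, _, _, dfw, msw = _oneway_anova(arrs)
            sig = False
            for (i, gi), (j, gj) in itertools.combinations(enumerate(arrs), 2):
                se = np.sqrt(msw / 2 * (1 / gi.size + 1 / gj.size))
                q = abs(gi.mean() - gj.mean()) / se
                if stats.studentized_range.sf(q, 3, dfw) < 0.05:
                    sig = True
                    break
            fw += sig
        assert fw / reps <= 0.075  # 5.5% guarantee + Monte-Carlo slack


class TestPairedLR:
    def _rows(self, left, right, group="HC"):
        rows, groups = [], {}
        for i, (l, r) in enumerate(zip(left, right)):
            sid = f"s{i}"
            rows += _roi_rows({sid: l}, hemi="left")
            rows += _roi_rows({sid: r}, hemi="right")
            groups[sid] = group
        return _table(rows), groups

    def test_equal_sides_null(self):
        t, g = self._rows([1, 2, 3, 4], [1, 2, 3, 4])
        rep = paired_lr_test(t, g)
        assert rep.iloc[0]["statistic"] == 0.0
        assert rep.iloc[0]["p"] == 1.0

    def test_fixed_offset_degenerate(self):
        t, g = self._rows([1, 2, 3], [0, 1, 2])
        rep = paired_lr_test(t, g)
        assert "degenerate" in rep.iloc[0]["note"]
        assert np.isnan(rep.iloc[0]["statistic"])

    def test_six_pairs_match_hand_formula(self, rng):
        left = rng.standard_normal(6)
        right = rng.standard_normal(6)
        t, g = self._rows(left, right)
        rep = paired_lr_test(t, g)
        d = left - right
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert rep.iloc[0]["statistic"] == pytest.approx(t_ref, abs=1e-10)
        assert rep.iloc[0]["effect"] == pytest.approx(d.mean() / d.std(ddof=1),
                                                      abs=1e-10)

    def test_missing_hemisphere_dropped(self):
        t, g = self._rows([1, 2, 3, 4], [0, 1, 2, 5])
        t = t[~((t.subject_id == "s3") & (t.hemisphere == "right"))]
        rep = paired_lr_test(t, g)
        assert rep.iloc[0]["n"] == 3


class TestAgeModel:
    def _hc_table(self, ages, lam=0.04, theta=0.001):
        rows = []
        for sid, a in ages.items():
            for hemi in ("left", "right"):
                rows += _roi_rows({sid: lam + theta * a}, hemi=hemi)
        return _table(rows)

    def test_exact_linear_fit(self):
        ages = {f"s{i}": 20.0 + 5 * i for i in range(6)}
        model = fit_age_model(self._hc_table(ages), ages)
        lam, theta = model.params[("hippocampus", "chi_ppm")]
        assert lam == pytest.approx(0.04, abs=1e-12)
        assert theta == pytest.approx(0.001, abs=1e-12)
        assert model.mu == pytest.approx(np.mean(list(ages.values())))

    def test_zero_slope_recovered(self, rng):
        cover = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            ages = {f"s{i}": r.uniform(20, 60) for i in range(27)}
            rows = []
            for sid, a in ages.items():
                rows += _roi_rows({sid: 0.04 + r.normal(0, 0.02)})
            model = fit_age_model(_table(rows), ages)
            _, theta = model.params[("hippocampus", "chi_ppm")]
            av = np.array(list(ages.values()))
            y_sd = 0.02
            se = y_sd / np.sqrt(((av - av.mean()) ** 2).sum())
            cover += abs(theta) < 2 * se
        assert cover >= 90

    def test_correction_identities(self):
        model = AgeModel({("hippocampus", "chi_ppm"): (0.0, 0.001)}, mu=30.0)
        t = _table(_roi_rows({"s1": 0.1}))
        # A = mu leaves the value unchanged
        assert age_correct(t, model, {"s1": 30.0}).iloc[0]["mean"] == 0.1
        # theta = 0 leaves the value unchanged
        m0 = AgeModel({("hippocampus", "chi_ppm"): (0.0, 0.0)}, mu=30.0)
        assert age_correct(t, m0, {"s1": 50.0}).iloc[0]["mean"] == 0.1
        # direct substitution: 0.1 + 0.001 * (30 - 40) = 0.09
        out = age_correct(t, model, {"s1": 40.0})
        assert out.iloc[0]["mean"] == pytest.approx(0.09, abs=1e-12)

    def test_missing_entry_names_roi(self):
        model = AgeModel({}, mu=30.0)
        t = _table(_roi_rows({"s1": 0.1}))
        with pytest.raises(KeyError, match="hippocampus"):
            age_correct(t, model, {"s1": 30.0})

    def test_too_few_controls(self):
        ages = {"s0": 30.0, "s1": 40.0}
        with pytest.raises(ValueError, match=">= 3"):
            fit_age_model(self._hc_table(ages), ages)

    def test_corrected_hc_slope_near_zero(self):
        """Refitting the age model on corrected control values gives a slope
        indistinguishable from zero in most simulated cohorts."""
        ok = 0
        reps = 60
        for rep in range(reps):
            recs, tab = simulate_cohort(CohortSpec(seed=3000 + rep))
            cov = records_to_frame(recs)
            ages = dict(zip(cov.subject_id, cov.age))
            hc = [r.subject_id for r in recs if r.group == "HC"]
            hc_tab = tab[tab.subject_id.isin(hc)]
            model = fit_age_model(hc_tab, ages)
            corr = age_correct(hc_tab, model, ages)
            sel = corr[(corr.roi == "putamen") & (corr.measure == "chi_ppm")]
            a = sel.subject_id.map(ages).to_numpy(float)
            y = sel["mean"].to_numpy(float)
            theta, lam = np.polyfit(a, y, 1)
            resid = y - (lam + theta * a)
            se = (np.sqrt((resid**2).sum() / (len(y) - 2))
                  / np.sqrt(((a - a.mean()) ** 2).sum()))
            ok += abs(theta) < 2 * se
        assert ok / reps >= 0.90


class TestNormality:
    def test_statistic_matches_brute_force(self, rng):
        x = rng.standard_normal(10)
        d = lilliefors_statistic(x)
        xs = np.sort(x)
        z = (xs - xs.mean()) / xs.std(ddof=1)
        cdf = stats.norm.cdf(z)
        n = len(xs)
        d_ref = max(max((i + 1) / n - cdf[i] for i in range(n)),
                    max(cdf[i] - i / n for i in range(n)))
        assert d == pytest.approx(d_ref, abs=1e-12)

    def test_matches_statsmodels_statistic(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf

        x = rng.standard_normal(40)
        d_sm, _ = sm_lf(x, dist="norm")
        assert lilliefors_statistic(x) == pytest.approx(d_sm, abs=1e-10)

    def test_normal_samples_rarely_rejected(self, rng):
        rej = sum(normality_check(rng.standard_normal(200)).iloc[0]["p"] < 0.01
                  for _ in range(300))
        assert rej / 300 <= 0.02

    def test_exponential_samples_rejected(self, rng):
        rej = sum(normality_check(rng.exponential(size=100)).iloc[0]["p"] < 0.01
                  for _ in range(100))
        assert rej / 100 >= 0.90

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check(np.ones(10))


class TestAncova:
    def test_matches_brute_force_rss(self, rng):
        rows, ages, groups = [], {}, {}
        for gi, gname in enumerate(("HC", "LTLE")):
            for i in range(10):
                sid = f"{gname}{i}"
                a = 20 + 4 * i
                y = 0.1 + (0.001 + 0.002 * gi) * a + rng.normal(0, 0.01)
                rows += _roi_rows({sid: y})
                ages[sid], groups[sid] = a, gname
        rep = ancova_slopes(_table(rows), ages, groups)
        # brute force: RSS of separate-slopes fit vs common-slope fit
        df = pd.DataFrame({"sid": list(ages)})
        df["a"] = df.sid.map(ages)
        df["g"] = (df.sid.map(groups) == "LTLE").astype(float)
        tab = _table(rows)
        df["y"] = df.sid.map(dict(zip(tab.subject_id, tab["mean"])))
        X_full = np.column_stack([np.ones(len(df)), df.a, df.g, df.a * df.g])
        X_red = X_full[:, :3]
        rss = []
        for X in (X_red, X_full):
            beta, *_ = np.linalg.lstsq(X, df.y, rcond=None)
            rss.append(((df.y - X @ beta) ** 2).sum())
        f_ref = (rss[0] - rss[1]) / 1 / (rss[1] / (len(df) - 4))
        assert rep.iloc[0]["statistic"] == pytest.approx(f_ref, rel=1e-8)

    def test_type_one_error_near_alpha(self):
        rej, reps = 0, 150
        for rep in range(reps):
            r = np.random.default_rng(rep)
            rows, ages, groups = [], {}, {}
            for gname in ("HC", "LTLE", "RTLE"):
                for i in range(12):
                    sid = f"{gname}{i}"
                    a = r.uniform(20, 60)
                    rows += _roi_rows({sid: 0.1 + 0.001 * a + r.normal(0, 0.02)})
                    ages[sid], groups[sid] = a, gname
            rep_df = ancova_slopes(_table(rows), ages, groups)
            rej += rep_df.iloc[0]["p"] < 0.05
        assert 0.01 <= rej / reps <= 0.12

    def test_different_slope_detected(self):
        rej, reps = 0, 30
        for rep in range(reps):
            r = np.random.default_rng(10_000 + rep)
            rows, ages, groups = [], {}, {}
            for gname, slope in (("HC", 0.001), ("LTLE", 0.002), ("RTLE", 0.001)):
                for i in range(30):
                    sid = f"{gname}{i}"
                    a = r.uniform(20, 60)
                    rows += _roi_rows({sid: 0.1 + slope * a + r.normal(0, 0.005)})
                    ages[sid], groups[sid] = a, gname
            rep_df = ancova_slopes(_table(rows), ages, groups)
            rej += rep_df.iloc[0]["p"] < 0.05
        assert rej / reps >= 0.90


def _patients(n=12, seed=0, group="LTLE", onset=None, fbtcs=None, scores=None,
              volumes=None):
    r = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        sid = f"{group}{i}"
        freq = None
        status = "none"
        if fbtcs is not None:
            status, freq = fbtcs[i]
        recs.append(SubjectRecord(
            sid, group, age=40.0 + i, sex="F",
            age_of_onset=(onset[i] if onset is not None else 20.0 + i),
            fbtcs_status=status, fbtcs_frequency=freq,
            cognitive_scores=(scores[i] if scores else {}),
            hippocampal_volume=(volumes[i] if volumes is not None else 3000.0)))
    del r
    return recs


class TestOnsetCorr:
    def test_monotone_and_reverse(self):
        onset = list(np.linspace(10, 40, 8))
        recs = _patients(8, onset=onset)
        rows = _roi_rows({f"LTLE{i}": onset[i] * 0.001 for i in range(8)})
        rep = onset_corr(_table(rows), recs)
        assert rep.iloc[0]["statistic"] == pytest.approx(1.0)
        rows_r = _roi_rows({f"LTLE{i}": -onset[i] * 0.001 for i in range(8)})
        rep_r = onset_corr(_table(rows_r), recs)
        assert rep_r.iloc[0]["statistic"] == pytest.approx(-1.0)

    def test_ties_match_midrank_formula(self):
        onset = [10.0, 10.0, 20.0, 30.0, 30.0, 40.0]
        vals = [1.0, 2.0, 2.0, 3.0, 5.0, 4.0]
        recs = _patients(6, onset=onset)
        rows = _roi_rows({f"LTLE{i}": vals[i] for i in range(6)})
        rep = onset_corr(_table(rows), recs)
        # brute-force midranks + Pearson on ranks
        def midrank(x):
            x = np.asarray(x)
            out = np.empty(len(x))
            for i, v in enumerate(x):
                out[i] = np.mean(np.nonzero(np.sort(x) == v)[0] + 1)
            return out
        rx, ry = midrank(onset), midrank(vals)
        rho_ref = np.corrcoef(rx, ry)[0, 1]
        assert rep.iloc[0]["statistic"] == pytest.approx(rho_ref, abs=1e-12)

    def test_all_tied_raises(self):
        recs = _patients(6, onset=[20.0] * 6)
        rows = _roi_rows({f"LTLE{i}": float(i) for i in range(6)})
        with pytest.raises(ValueError, match="tied"):
            onset_corr(_table(rows), recs)


class TestFBTCS:
    def test_log_frequency_perfect_correlation(self):
        vals = np.linspace(0.01, 0.06, 6)
        fbtcs = [("recent", float(np.exp(v * 100))) for v in vals]
        recs = _patients(6, fbtcs=fbtcs)
        rows = _roi_rows({f"LTLE{i}": vals[i] for i in range(6)})
        rep = fbtcs_analyses(_table(rows), recs)
        corr_rows = rep[rep.analysis == "fbtcs_logfreq_corr"]
        assert corr_rows.iloc[0]["statistic"] == pytest.approx(1.0)

    def test_ipsi_contra_relabelling(self):
        recs = (_patients(6, group="LTLE",
                          fbtcs=[("recent", 2.0)] * 6)
                + _patients(6, seed=1, group="RTLE",
                            fbtcs=[("recent", 3.0)] * 6))
        rows = []
        for r in recs:
            rows += _roi_rows({r.subject_id: 0.1}, hemi="left")
            rows += _roi_rows({r.subject_id: 0.2}, hemi="right")
        rep = fbtcs_analyses(_table(rows), recs)
        corr_rows = rep[rep.analysis == "fbtcs_logfreq_corr"]
        assert set(corr_rows.hemisphere) == {"ipsilateral", "contralateral"}
        # LTLE left and RTLE right both pooled as ipsilateral: n = 12
        ipsi = corr_rows[corr_rows.hemisphere == "ipsilateral"].iloc[0]
        assert ipsi["n"] == 12

    def test_stratum_anova_null_calibrated(self):
        rej, reps = 0, 120
        for rep in range(reps):
            r = np.random.default_rng(rep)
            fbtcs = [(s, 2.0 if s == "recent" else None)
                     for s in r.choice(["none", "historic", "recent"], 18)]
            recs = _patients(18, seed=rep, fbtcs=fbtcs)
            rows = _roi_rows({f"LTLE{i}": r.normal() for i in range(18)})
            rep_df = fbtcs_analyses(_table(rows), recs)
            an = rep_df[rep_df.analysis == "fbtcs_anova"]
            if len(an):
                rej += an.iloc[0]["p"] < 0.05
        assert 0.005 <= rej / reps <= 0.12


class TestCognition:
    def test_bh_hand_applied(self):
        from statsmodels.stats.multitest import multipletests

        rej, _, _, _ = multipletests([0.01, 0.02, 0.04], alpha=0.05,
                                     method="fdr_bh")
        assert rej.all()  # 0.01<=0.0167, 0.02<=0.0333, 0.04<=0.05

    def test_bh_order_invariance_and_monotone_in_q(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        r1 = multipletests(p, 0.05, "fdr_bh")[0]
        r2 = multipletests(p[perm], 0.05, "fdr_bh")[0]
        assert np.array_equal(r1[perm], r2)
        # brute-force BH step-up oracle
        def bh(pv, q):
            m = len(pv)
            order = np.argsort(pv)
            passed = np.zeros(m, bool)
            kmax = 0
            for k, idx in enumerate(order, 1):
                if pv[idx] <= q * k / m:
                    kmax = k
            passed[order[:kmax]] = True
            return passed
        assert np.array_equal(r1, bh(p, 0.05))
        assert bh(p, 0.01).sum() <= bh(p, 0.10).sum()

    def test_slope_recovery(self):
        r = np.random.default_rng(5)
        scores, rows = [], []
        recs = []
        for g, gname in ((0.0, "LTLE"), (1.0, "RTLE")):
            for i in range(15):
                sid = f"{gname}{i}"
                val = r.uniform(0, 1)
                score = 2.0 * val + r.normal(0, 0.1)
                rows += _roi_rows({sid: val})
                recs.append(SubjectRecord(sid, gname, 40.0, "F",
                                          age_of_onset=20.0,
                                          cognitive_scores={"test": score},
                                          hippocampal_volume=3000.0))
        rep = cognition_regress(_table(rows), recs)
        beta = rep[rep.contrast == "test:score"].iloc[0]["effect"]
        # value ~ score: true coefficient is 1/2 (score = 2 * value)
        assert beta == pytest.approx(0.5, abs=0.05)

    def test_null_coefficients_covered(self):
        cover, reps = 0, 60
        for rep in range(reps):
            r = np.random.default_rng(rep)
            rows, recs = [], []
            for g, gname in ((0.0, "LTLE"), (1.0, "RTLE")):
                for i in range(15):
                    sid = f"{gname}{i}"
                    val = r.normal(0.1, 0.02)
                    rows += _roi_rows({sid: val})
                    recs.append(SubjectRecord(
                        sid, gname, 40.0, "F", age_of_onset=20.0,
                        cognitive_scores={"t": r.normal()},
                        hippocampal_volume=3000.0))
            rep_df = cognition_regress(_table(rows), recs)
            row = rep_df[rep_df.contrast == "t:group01"].iloc[0]
            cover += row["p"] >= 0.05
        assert cover / reps >= 0.85

    def test_small_n_skipped(self):
        recs = _patients(4)
        for r in recs:
            r.cognitive_scores["t"] = 1.0
        rows = _roi_rows({r.subject_id: 0.1 for r in recs})
        rep = cognition_regress(_table(rows), recs)
        assert len(rep) == 0


class TestVolumeCorr:
    def test_proportional_gives_unit_correlation(self):
        vols = np.linspace(2500, 3500, 6)
        recs = _patients(6, volumes=vols)
        rows = _roi_rows({f"LTLE{i}": vols[i] * 1e-5 for i in range(6)},
                         measure="r2star_per_s")
        rep = volume_corr(_table(rows), recs)
        assert rep.iloc[0]["statistic"] == pytest.approx(1.0)

    def test_six_point_fixture_matches_covariance_formula(self, rng):
        vols = rng.uniform(2500, 3500, 6)
        vals = rng.standard_normal(6)
        recs = _patients(6, volumes=vols)
        rows = _roi_rows({f"LTLE{i}": vals[i] for i in range(6)})
        rep = volume_corr(_table(rows), recs)
        r_ref = (np.mean(vols * vals) - vols.mean() * vals.mean()) / (
            vols.std() * vals.std())
        assert rep.iloc[0]["statistic"] == pytest.approx(r_ref, abs=1e-12)

    def test_independent_p_roughly_uniform(self):
        ps = []
        for rep in range(100):
            r = np.random.default_rng(rep)
            vols = r.uniform(2500, 3500, 10)
            recs = _patients(10, seed=rep, volumes=vols)
            rows = _roi_rows({f"LTLE{i}": r.normal() for i in range(10)})
            rep_df = volume_corr(_table(rows), recs)
            ps.append(rep_df.iloc[0]["p"])
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.13


class TestDemographics:
    def test_identical_groups_h_near_zero(self):
        recs = []
        for gname in ("HC", "LTLE", "RTLE"):
            for i in range(5):
                recs.append(SubjectRecord(f"{gname}{i}", gname, 30.0 + i, "F",
                                          age_of_onset=None if gname == "HC" else 20.0,
                                          hippocampal_volume=3000.0))
        rep = demographics_compare(recs)
        age_row = rep[(rep.contrast == "age")].iloc[0]
        assert age_row["statistic"] == pytest.approx(0.0, abs=1e-10)

    def test_chi_square_hand_computed(self):
        recs = []
        for i in range(10):
            recs.append(SubjectRecord(f"a{i}", "HC", 30.0, "F",
                                      hippocampal_volume=3000.0))
        for i in range(10):
            recs.append(SubjectRecord(f"b{i}", "LTLE", 30.0, "M",
                                      age_of_onset=20.0,
                                      hippocampal_volume=3000.0))
        rep = demographics_compare(recs)
        sex = rep[rep.contrast == "sex"].iloc[0]
        assert sex["statistic"] == pytest.approx(20.0, abs=1e-10)

    def test_h_matches_brute_force_with_ties(self):
        g1, g2, g3 = [1.0, 2, 2, 3], [2.0, 3, 4, 4], [1.0, 4, 5, 6]
        recs = []
        for gname, vals in (("HC", g1), ("LTLE", g2), ("RTLE", g3)):
            for i, v in enumerate(vals):
                recs.append(SubjectRecord(
                    f"{gname}{i}", gname, age=v, sex="F",
                    age_of_onset=None if gname == "HC" else 1.0,
                    hippocampal_volume=3000.0))
        rep = demographics_compare(recs)
        h = rep[rep.contrast == "age"].iloc[0]["statistic"]
        h_ref, _ = stats.kruskal(g1, g2, g3)
        # brute-force tie-corrected H
        allv = np.concatenate([g1, g2, g3])
        ranks = stats.rankdata(allv)
        n = len(allv)
        groups = [ranks[:4], ranks[4:8], ranks[8:]]
        h_raw = 12 / (n * (n + 1)) * sum(
            len(g) * (g.mean() - (n + 1) / 2) ** 2 for g in groups)
        _, counts = np.unique(allv, return_counts=True)
        tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
        assert h == pytest.approx(h_raw / tie, abs=1e-10)
        assert h == pytest.approx(h_ref, abs=1e-10)


class TestQualityCompare:
    def _tables(self, shift=0.0, n_subj=20, seed=0):
        r = np.random.default_rng(seed)
        base = {}
        tables = {}
        for m_i, meth in enumerate(("itertik", "nltv", "whqsm")):
            rows = []
            for s in range(n_subj):
                for roi in ("hippocampus", "putamen"):
                    key = (s, roi)
                    if key not in base:
                        base[key] = r.uniform(0.005, 0.01)
                    std = base[key] * (1 + (shift if meth == "nltv" else 0.0))
                    std *= 1 + 0.05 * r.standard_normal()
                    rows.append({"subject_id": f"s{s}", "roi": roi,
                                 "hemisphere": "left", "measure": "chi_ppm",
                                 "mean": 0.0, "std": std, "voxel_count": 100,
                                 "method": meth})
            tables[meth] = pd.DataFrame(rows)
        return tables

    def test_identical_tables_null(self):
        t = self._tables()
        same = {m: t["itertik"].assign(method=m) for m in t}
        rep = quality_compare(same)
        an = rep[rep.test == "anova"]
        assert np.allclose(an["statistic"].astype(float), 0.0)
        assert (rep[rep.test == "tukey_kramer"]["p"] > 0.95).all()

    def test_inflated_method_flagged(self):
        rep = quality_compare(self._tables(shift=0.5))
        tk = rep[rep.test == "tukey_kramer"]
        flagged = tk[(tk.contrast.str.contains("nltv")) & (tk.p < 0.05)]
        assert len(flagged) >= 2  # nltv vs both others, per ROI

    def test_mismatched_subjects_rejected(self):
        t = self._tables()
        t["nltv"] = t["nltv"][t["nltv"].subject_id != "s0"]
        with pytest.raises(ValueError, match="differ"):
            quality_compare(t)
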