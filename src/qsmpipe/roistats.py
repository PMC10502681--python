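"""ROI summarisation, age correction, and group / clinical statistics.

Everything downstream of map reconstruction lives here: per-ROI means and
standard deviations, the method-quality comparison (per-subject ROI standard
deviations compared across reconstruction methods by one-way ANOVA with
Tukey-Kramer post hocs), the linear age correction fitted on healthy
controls, and the full group/clinical battery: Lilliefors normality checks,
Kruskal-Wallis / chi-square demographics, one-way ANOVA with eta-squared,
Tukey-Kramer contrasts with Cohen's d, paired left-right t tests, ANCOVA of
value-vs-age slopes, Spearman correlations with age of epilepsy onset,
FBTCS stratification and log-frequency Pearson correlations, cognitive-score
multiple regressions with group interaction and Benjamini-Hochberg FDR, and
hippocampal volume correlations.

All results come back as tidy DataFrames ("StatReport" rows) with columns
``analysis, roi, hemisphere, measure, contrast, test, statistic, p, effect,
effect_name, n, multiplicity, note`` (unused columns NaN/empty), ready to
write as CSV.

Age correction: with a least-squares linear fit ``Y_i = lambda_i + theta_i A``
across controls in ROI i (hemispheres pooled), the corrected value for
subject j is ``Y_ij + theta_i (mu - A_j)`` where mu is the control mean age.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AgeModel",
    "report_row",
    "roi_summary",
    "quality_compare",
    "fit_age_model",
    "age_correct",
    "lilliefors_statistic",
    "normality_check",
    "group_anova",
    "tukey_kramer",
    "paired_lr_test",
    "ancova_slopes",
    "onset_corr",
    "fbtcs_analyses",
    "cognition_regress",
    "volume_corr",
    "demographics_compare",
]

REPORT_COLUMNS = ["analysis", "roi", "hemisphere", "measure", "contrast",
                  "test", "statistic", "p", "effect", "effect_name", "n",
                  "multiplicity", "note"]


def report_row(**kw):
    row = {c: kw.get(c, np.nan) for c in REPORT_COLUMNS}
    for c in ("analysis", "roi", "hemisphere", "measure", "contrast", "test",
              "effect_name", "multiplicity", "note"):
        if not isinstance(row[c], str) and not (isinstance(row[c], float) and np.isnan(row[c])):
            row[c] = str(row[c])
    return row


def _report(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# ROI summaries


def roi_summary(map_values, labels, mask, *, subject_id="subject", measure="chi_ppm",
                method="") -> pd.DataFrame:
    """Per-ROI mean/std/voxel-count of a map within ``mask``.

    ``labels`` is an ROILabelMap, ``mask`` a BinaryMask (or plain arrays).
    Labels whose intersection with the mask is empty are dropped with a
    warning; if every label is empty an error is raised.
    """
    vals = getattr(map_values, "values", map_values)
    lab = getattr(labels, "values", labels)
    table = getattr(labels, "table", None)
    m = getattr(mask, "values", mask).astype(bool)
    if vals.shape != lab.shape or vals.shape != m.shape:
        raise ValueError("map, labels and mask grids are not aligned")
    rows = []
    for label_id in sorted(set(np.unique(lab)) - {0}):
        sel = (lab == label_id) & m
        n = int(sel.sum())
        name, hemi = (table[label_id] if table else (str(label_id), ""))
        if n == 0:
            logger.warning("ROI %s (%s): no voxels inside mask; row dropped",
                           name, hemi)
            continue
        v = vals[sel]
        rows.append({"subject_id": subject_id, "roi": name, "hemisphere": hemi,
                     "measure": measure, "mean": float(v.mean()),
                     "std": float(v.std(ddof=0)), "voxel_count": n,
                     "method": method})
    if not rows:
        raise ValueError("every ROI label is empty inside the mask")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shared test helpers


def _oneway_anova(groups):
    """One-way ANOVA from raw group arrays: (F, p, eta2, df_b, df_w, msw)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_t = ss_b + ss_w
    df_b, df_w = k - 1, n - k
    msw = ss_w / df_w if df_w > 0 else np.nan
    if ss_w == 0:
        f = 0.0 if ss_b == 0 else np.inf
    else:
        f = (ss_b / df_b) / msw
    p = 1.0 if ss_t == 0 else float(stats.f.sf(f, df_b, df_w))
    eta2 = 0.0 if ss_t == 0 else float(ss_b / ss_t)
    return float(f), p, eta2, df_b, df_w, msw


def _tukey_pairs(groups, names, msw, df_w):
    """Tukey-Kramer pairwise contrasts given the ANOVA mean square within."""
    k = len(groups)
    out = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
        ni, nj = gi.size, gj.size
        diff = gi.mean() - gj.mean()
        se = np.sqrt(msw / 2.0 * (1.0 / ni + 1.0 / nj))
        q = np.abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(stats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        if se == 0 and diff == 0:
            p = 1.0
        pooled = np.sqrt(((ni - 1) * gi.var(ddof=1) + (nj - 1) * gj.var(ddof=1))
                         / (ni + nj - 2))
        d = diff / pooled if pooled > 0 else np.nan
        note = "" if pooled > 0 else "zero pooled SD: d undefined"
        out.append((f"{names[i]} vs {names[j]}", q, p, d, ni + nj, note))
    return out


def _bh(pvals, q=0.05):
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Method-quality comparison


def quality_compare(tables: dict, measure="chi_ppm") -> pd.DataFrame:
    """Compare per-subject ROI standard deviations across methods.

    ``tables`` maps method name -> ROI table (from :func:`roi_summary` over
    subjects).  Per (roi, hemisphere): one-way ANOVA of the per-subject ROI
    std across methods, then Tukey-Kramer pairwise contrasts.  All tables
    must cover the same subjects.
    """
    methods = list(tables)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    subj_sets = {m: set(t["subject_id"]) for m, t in tables.items()}
    ref = subj_sets[methods[0]]
    for m, s in subj_sets.items():
        if s != ref:
            raise ValueError(
                f"subject sets differ between methods: {m} vs {methods[0]}: "
                f"{sorted(s ^ ref)}")
    rows = []
    t0 = tables[methods[0]]
    keys = t0[t0["measure"] == measure][["roi", "hemisphere"]].drop_duplicates()
    for _, (roi, hemi) in keys.iterrows():
        groups = []
        for m in methods:
            t = tables[m]
            sel = t[(t["roi"] == roi) & (t["hemisphere"] == hemi)
                    & (t["measure"] == measure)].sort_values("subject_id")
            groups.append(sel["std"].to_numpy(dtype=float))
        f, p, eta2, df_b, df_w, msw = _oneway_anova(groups)
        n = sum(g.size for g in groups)
        rows.append(report_row(analysis="quality_compare", roi=roi,
                               hemisphere=hemi, measure=measure,
                               contrast=" vs ".join(methods), test="anova",
                               statistic=f, p=p, effect=eta2,
                               effect_name="eta2", n=n))
        for contrast, q_stat, p_tk, d, n_pair, note in _tukey_pairs(
                groups, methods, msw, df_w):
            rows.append(report_row(analysis="quality_compare", roi=roi,
                                   hemisphere=hemi, measure=measure,
                                   contrast=contrast, test="tukey_kramer",
                                   statistic=q_stat, p=p_tk, effect=d,
                                   effect_name="cohens_d", n=n_pair,
                                   multiplicity="tukey_kramer", note=note))
    return _report(rows)


# ---------------------------------------------------------------------------
# Age correction


@dataclass
class AgeModel:
    """Linear age model fitted on healthy controls, hemispheres pooled.

    ``params`` maps (roi, measure) -> (lambda, theta); ``mu`` is the control
    group's mean age in years.
    """

    params: dict = field(default_factory=dict)
    mu: float = 0.0


def _age_of(ages, sid):
    if isinstance(ages, pd.DataFrame):
        return float(ages.set_index("subject_id").loc[sid, "age"])
    return float(ages[sid])


def fit_age_model(hc_table: pd.DataFrame, ages) -> AgeModel:
    """Least-squares linear fit of ROI mean vs age across controls.

    ``hc_table`` holds the HC rows of an ROI table; ``ages`` maps subject_id
    to age (dict, Series, or DataFrame with those columns).  Hemispheres are
    pooled into a single fit per (roi, measure).
    """
    if isinstance(ages, pd.DataFrame):
        ages = ages.set_index("subject_id")["age"]
    ages = dict(ages)
    n_subj = hc_table["subject_id"].nunique()
    if n_subj < 3:
        raise ValueError(f"need >= 3 control subjects, got {n_subj}")
    params = {}
    for (roi, meas), grp in hc_table.groupby(["roi", "measure"]):
        a = grp["subject_id"].map(ages).to_numpy(dtype=float)
        y = grp["mean"].to_numpy(dtype=float)
        if np.unique(a).size < 2:
            raise ValueError(f"degenerate ages for ROI {roi}")
        theta, lam = np.polyfit(a, y, 1)
        params[(roi, meas)] = (float(lam), float(theta))
    mu = float(np.mean([ages[s] for s in hc_table["subject_id"].unique()]))
    return AgeModel(params=params, mu=mu)


def age_correct(table: pd.DataFrame, model: AgeModel, ages) -> pd.DataFrame:
    """Apply the linear age correction: Y + theta * (mu - A)."""
    if isinstance(ages, pd.DataFrame):
        ages = ages.set_index("subject_id")["age"]
    ages = dict(ages)
    out = table.copy()
    corrected = np.empty(len(out))
    for idx, (_, row) in enumerate(out.iterrows()):
        key = (row["roi"], row["measure"])
        if key not in model.params:
            raise KeyError(f"age model has no entry for ROI {key[0]!r} / {key[1]!r}")
        _, theta = model.params[key]
        corrected[idx] = row["mean"] + theta * (model.mu - ages[row["subject_id"]])
    out["mean"] = corrected
    return out


# ---------------------------------------------------------------------------
# Normality (Lilliefors with Monte-Carlo null tables)

_LILLIEFORS_CACHE: dict[int, np.ndarray] = {}
_LILLIEFORS_DRAWS = 10_000
_LILLIEFORS_SEED = 745_211


def lilliefors_statistic(values) -> float:
    """KS sup-distance between the sample ECDF and the fitted normal."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    cdf = stats.norm.cdf((x - mu) / sd)
    up = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(max((up - cdf).max(), (cdf - lo).max()))


def _lilliefors_table(n: int) -> np.ndarray:
    if n not in _LILLIEFORS_CACHE:
        rng = np.random.default_rng(_LILLIEFORS_SEED + n)
        draws = rng.standard_normal((_LILLIEFORS_DRAWS, n))
        stats_null = np.empty(_LILLIEFORS_DRAWS)
        for i, row in enumerate(draws):
            stats_null[i] = lilliefors_statistic(row)
        _LILLIEFORS_CACHE[n] = np.sort(stats_null)
    return _LILLIEFORS_CACHE[n]


def normality_check(values, label="") -> pd.DataFrame:
    """Lilliefors composite-normality test, Monte-Carlo p-value.

    The null distribution of the statistic is simulated (10^4 standard-normal
    samples of the same size, cached per n); p is the upper-tail proportion.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4 for the normality test")
    d = lilliefors_statistic(x)
    table = _lilliefors_table(x.size)
    p = float((table >= d - 1e-15).mean())
    return _report([report_row(analysis="normality", contrast=label,
                               test="lilliefors", statistic=d, p=p, n=x.size)])


# ---------------------------------------------------------------------------
# Group comparisons


def _group_arrays(table, groups, roi, hemi, meas, order=None):
    sel = table[(table["roi"] == roi) & (table["measure"] == meas)]
    if hemi is not None:
        sel = sel[sel["hemisphere"] == hemi]
    g = sel["subject_id"].map(dict(groups) if not isinstance(groups, dict) else groups)
    names = order or sorted(g.dropna().unique())
    return [sel.loc[g == name, "mean"].to_numpy(dtype=float) for name in names], names


def group_anova(table: pd.DataFrame, groups, order=("HC", "LTLE", "RTLE")) -> pd.DataFrame:
    """One-way ANOVA per (roi, hemisphere, measure) with eta-squared."""
    groups = dict(groups)
    rows = []
    keys = table[["roi", "hemisphere", "measure"]].drop_duplicates()
    for _, (roi, hemi, meas) in keys.iterrows():
        arrs, names = _group_arrays(table, groups, roi, hemi, meas, list(order))
        for name, a in zip(names, arrs):
            if a.size < 2:
                raise ValueError(f"group {name} has {a.size} subjects for "
                                 f"{roi}/{hemi}/{meas}; need >= 2")
        f, p, eta2, df_b, df_w, _ = _oneway_anova(arrs)
        rows.append(report_row(analysis="group_anova", roi=roi, hemisphere=hemi,
                               measure=meas, contrast=" vs ".join(names),
                               test="anova", statistic=f, p=p, effect=eta2,
                               effect_name="eta2", n=sum(a.size for a in arrs)))
    return _report(rows)


def tukey_kramer(table: pd.DataFrame, groups, order=("HC", "LTLE", "RTLE")) -> pd.DataFrame:
    """Tukey-Kramer pairwise contrasts with Cohen's d per pair."""
    groups = dict(groups)
    rows = []
    keys = table[["roi", "hemisphere", "measure"]].drop_duplicates()
    for _, (roi, hemi, meas) in keys.iterrows():
        arrs, names = _group_arrays(table, groups, roi, hemi, meas, list(order))
        _, _, _, _, df_w, msw = _oneway_anova(arrs)
        for contrast, q, p, d, n, note in _tukey_pairs(arrs, names, msw, df_w):
            rows.append(report_row(analysis="tukey_kramer", roi=roi,
                                   hemisphere=hemi, measure=meas,
                                   contrast=contrast, test="tukey_kramer",
                                   statistic=q, p=p, effect=d,
                                   effect_name="cohens_d", n=n,
                                   multiplicity="tukey_kramer", note=note))
    return _report(rows)


def paired_lr_test(table: pd.DataFrame, groups) -> pd.DataFrame:
    """Paired t test of intra-subject left minus right per (roi, measure, group)."""
    groups = dict(groups)
    rows = []
    wide = table.pivot_table(index=["subject_id", "roi", "measure"],
                             columns="hemisphere", values="mean")
    wide = wide.reset_index()
    dropped = wide[wide[["left", "right"]].isna().any(axis=1)]
    for _, r in dropped.iterrows():
        logger.info("paired_lr_test: subject %s missing a hemisphere for %s; dropped",
                    r["subject_id"], r["roi"])
    wide = wide.dropna(subset=["left", "right"])
    wide["group"] = wide["subject_id"].map(groups)
    for (roi, meas, grp), sub in wide.groupby(["roi", "measure", "group"]):
        diff = (sub["left"] - sub["right"]).to_numpy(dtype=float)
        n = diff.size
        if n < 2:
            continue
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                t, p, d, note = 0.0, 1.0, 0.0, ""
            else:
                t, p, d = np.nan, np.nan, np.nan
                note = "zero-variance nonzero differences: degenerate"
        else:
            t, p = stats.ttest_rel(sub["left"], sub["right"])
            d = diff.mean() / sd
            note = ""
        rows.append(report_row(analysis="paired_lr", roi=roi, hemisphere="left-right",
                               measure=meas, contrast=grp, test="paired_t",
                               statistic=float(t), p=float(p), effect=float(d),
                               effect_name="cohens_d", n=n, note=note))
    return _report(rows)


def ancova_slopes(table: pd.DataFrame, ages, groups) -> pd.DataFrame:
    """Equality of value-vs-age slopes across groups (hemispheres pooled).

    Tests the group x age interaction by an extra-sum-of-squares F test
    between ``value ~ age + group`` and ``value ~ age * group``.
    """
    if isinstance(ages, pd.DataFrame):
        ages = ages.set_index("subject_id")["age"]
    ages, groups = dict(ages), dict(groups)
    rows = []
    for (roi, meas), sub in table.groupby(["roi", "measure"]):
        df = pd.DataFrame({
            "value": sub["mean"].to_numpy(dtype=float),
            "age": sub["subject_id"].map(ages).to_numpy(dtype=float),
            "group": sub["subject_id"].map(groups),
        })
        counts = df.groupby("group")["value"].count()
        if (counts < 3).any():
            raise ValueError(f"need >= 3 subjects per group for ANCOVA in {roi}")
        full = ols("value ~ age * C(group)", data=df).fit()
        if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
            raise ValueError(f"rank-deficient ANCOVA design for {roi}/{meas}")
        reduced = ols("value ~ age + C(group)", data=df).fit()
        f, p, df_diff = full.compare_f_test(reduced)
        rows.append(report_row(analysis="ancova_slopes", roi=roi, hemisphere="pooled",
                               measure=meas, contrast="group x age", test="ancova_f",
                               statistic=float(f), p=float(p), n=len(df),
                               note=f"df_num={int(df_diff)}"))
    return _report(rows)


# ---------------------------------------------------------------------------
# Clinical correlations


def onset_corr(table: pd.DataFrame, records) -> pd.DataFrame:
    """Spearman correlation of ROI values with age of epilepsy onset.

    Run per (roi, hemisphere, measure, patient group); rows with fewer than
    5 complete cases are skipped and logged.  Midranks handle ties.
    """
    onset = {r.subject_id: r.age_of_onset for r in records
             if r.age_of_onset is not None}
    grp = {r.subject_id: r.group for r in records}
    rows = []
    sub = table[table["subject_id"].isin(onset)]
    for (roi, hemi, meas, g), s in sub.groupby(
            ["roi", "hemisphere", "measure", sub["subject_id"].map(grp)]):
        x = s["subject_id"].map(onset).to_numpy(dtype=float)
        y = s["mean"].to_numpy(dtype=float)
        if x.size < 5:
            logger.info("onset_corr: only %d cases for %s/%s/%s/%s; skipped",
                        x.size, roi, hemi, meas, g)
            continue
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            raise ValueError(f"all-tied input for onset correlation in {roi}")
        rho, p = stats.spearmanr(x, y)
        rows.append(report_row(analysis="onset_corr", roi=roi, hemisphere=hemi,
                               measure=meas, contrast=g, test="spearman",
                               statistic=float(rho), p=float(p),
                               effect=float(rho), effect_name="rho", n=x.size))
    return _report(rows)


def _ipsi_contra(roi_hemi, group):
    side = {"LTLE": "left", "RTLE": "right"}[group]
    return "ipsilateral" if roi_hemi == side else "contralateral"


def fbtcs_analyses(table: pd.DataFrame, records) -> pd.DataFrame:
    """FBTCS stratification ANOVA and log-frequency Pearson correlations.

    (a) Per (roi, hemisphere, measure): one-way ANOVA of patient ROI values
    across FBTCS strata (none / historic / recent); strata with no members
    are skipped and logged.  (b) In patients with recent FBTCS, Pearson
    correlation of ROI value vs log(monthly frequency), with hemispheres
    relabelled ipsilateral/contralateral to each patient's seizure side and
    the two patient groups pooled.
    """
    status = {r.subject_id: r.fbtcs_status for r in records if r.group != "HC"}
    freq = {r.subject_id: r.fbtcs_frequency for r in records
            if r.fbtcs_frequency is not None}
    grp = {r.subject_id: r.group for r in records}
    rows = []
    pat = table[table["subject_id"].isin(status)]
    for (roi, hemi, meas), s in pat.groupby(["roi", "hemisphere", "measure"]):
        st = s["subject_id"].map(status)
        arrs, names = [], []
        for stratum in ("none", "historic", "recent"):
            a = s.loc[st == stratum, "mean"].to_numpy(dtype=float)
            if a.size == 0:
                logger.info("fbtcs ANOVA: empty stratum %s for %s/%s; skipped",
                            stratum, roi, hemi)
                continue
            arrs.append(a)
            names.append(stratum)
        if len(arrs) < 2:
            continue
        f, p, eta2, *_ = _oneway_anova(arrs)
        rows.append(report_row(analysis="fbtcs_anova", roi=roi, hemisphere=hemi,
                               measure=meas, contrast=" vs ".join(names),
                               test="anova", statistic=f, p=p, effect=eta2,
                               effect_name="eta2", n=sum(a.size for a in arrs)))
    # (b) log-frequency correlations, ipsi/contra pooled across patient groups
    rec = table[table["subject_id"].isin(freq)].copy()
    if len(rec):
        rec["laterality"] = [
            _ipsi_contra(h, grp[s]) for s, h in zip(rec["subject_id"],
                                                    rec["hemisphere"])]
        for (roi, lat, meas), s in rec.groupby(["roi", "laterality", "measure"]):
            x = np.log(s["subject_id"].map(freq).to_numpy(dtype=float))
            y = s["mean"].to_numpy(dtype=float)
            if x.size < 3:
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(report_row(analysis="fbtcs_logfreq_corr", roi=roi,
                                   hemisphere=lat, measure=meas,
                                   contrast="LTLE+RTLE pooled", test="pearson",
                                   statistic=float(r), p=float(p),
                                   effect=float(r), effect_name="r", n=x.size))
    return _report(rows)


def cognition_regress(table: pd.DataFrame, records, q: float = 0.05,
                      min_cases: int = 8) -> pd.DataFrame:
    """Cognitive-score multiple regressions with group interaction and FDR.

    Per (roi, side, measure, test): ``value ~ score + group01 + score:group01``
    over patients (group01: LTLE = 0, RTLE = 1).  Left- and right-sided ROIs
    form separate regressions.  Complete-case deletion per regression, with n
    reported; regressions with fewer than ``min_cases`` cases are skipped.
    Benjamini-Hochberg FDR is applied across the whole family of reported
    coefficient p-values, per side and measure.
    """
    scores = {}
    for r in records:
        for name, val in r.cognitive_scores.items():
            scores.setdefault(name, {})[r.subject_id] = val
    grp01 = {r.subject_id: {"LTLE": 0.0, "RTLE": 1.0}[r.group]
             for r in records if r.group != "HC"}
    rows = []
    pat = table[table["subject_id"].isin(grp01)]
    for test_name, smap in scores.items():
        for (roi, hemi, meas), s in pat.groupby(["roi", "hemisphere", "measure"]):
            df = pd.DataFrame({
                "value": s["mean"].to_numpy(dtype=float),
                "score": s["subject_id"].map(smap),
                "group01": s["subject_id"].map(grp01),
            }).dropna()
            n = len(df)
            if n < min_cases:
                logger.info("cognition_regress: %d complete cases for "
                            "%s/%s/%s/%s; skipped", n, roi, hemi, meas, test_name)
                continue
            model = ols("value ~ score + group01 + score:group01", data=df)
            exog = model.exog
            if np.linalg.matrix_rank(exog) < exog.shape[1]:
                raise ValueError(
                    f"collinear design for {roi}/{hemi}/{meas}/{test_name}: "
                    f"regressors {model.exog_names}")
            fit = model.fit()
            for coef in ("score", "group01", "score:group01"):
                rows.append(report_row(
                    analysis="cognition_regress", roi=roi, hemisphere=hemi,
                    measure=meas, contrast=f"{test_name}:{coef}",
                    test="ols_t", statistic=float(fit.tvalues[coef]),
                    p=float(fit.pvalues[coef]), effect=float(fit.params[coef]),
                    effect_name="beta", n=n))
    report = _report(rows)
    if len(report):
        report["multiplicity"] = f"fdr_bh(q={q})"
        report["p_fdr"] = np.nan
        report["significant"] = False
        for (hemi, meas), idx in report.groupby(["hemisphere", "measure"]).groups.items():
            rej, p_adj = _bh(report.loc[idx, "p"].to_numpy(), q)
            report.loc[idx, "p_fdr"] = p_adj
            report.loc[idx, "significant"] = rej
    return report


def volume_corr(table: pd.DataFrame, records) -> pd.DataFrame:
    """Pearson correlation of hippocampal volume with hippocampal chi and R2*.

    Run per group and hemisphere; groups with fewer than 5 cases are skipped
    and logged.
    """
    vol = {r.subject_id: r.hippocampal_volume for r in records
           if r.hippocampal_volume}
    grp = {r.subject_id: r.group for r in records}
    rows = []
    hip = table[(table["roi"] == "hippocampus") & table["subject_id"].isin(vol)]
    for (hemi, meas, g), s in hip.groupby(
            ["hemisphere", "measure", hip["subject_id"].map(grp)]):
        x = s["subject_id"].map(vol).to_numpy(dtype=float)
        if np.any(x <= 0):
            raise ValueError("hippocampal volumes must be positive")
        y = s["mean"].to_numpy(dtype=float)
        if x.size < 5:
            logger.info("volume_corr: %d cases for %s/%s/%s; skipped",
                        x.size, hemi, meas, g)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(report_row(analysis="volume_corr", roi="hippocampus",
                               hemisphere=hemi, measure=meas, contrast=g,
                               test="pearson", statistic=float(r), p=float(p),
                               effect=float(r), effect_name="r", n=x.size))
    return _report(rows)


def demographics_compare(records) -> pd.DataFrame:
    """Kruskal-Wallis (continuous) and chi-square (categorical) demographics.

    Continuous: age across all groups; age of onset and FBTCS frequency
    across patient groups.  Categorical: sex across all groups, FBTCS status
    across patient groups (chi-square without continuity correction;
    zero-count categories dropped and logged).  The Kruskal-Wallis effect
    size is eta2 = (H - k + 1) / (n - k).
    """
    df = pd.DataFrame([{ "subject_id": r.subject_id, "group": r.group,
                         "age": r.age, "age_of_onset": r.age_of_onset,
                         "fbtcs_frequency": r.fbtcs_frequency,
                         "sex": r.sex, "fbtcs_status": r.fbtcs_status}
                       for r in records])
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    continuous = [("age", df), ("age_of_onset", df[df["group"] != "HC"]),
                  ("fbtcs_frequency", df[df["group"] != "HC"])]
    for var, d in continuous:
        arrs = [g.dropna().to_numpy(dtype=float)
                for _, g in d.groupby("group")[var] if g.notna().sum() > 0]
        arrs = [a for a in arrs if a.size > 0]
        if len(arrs) < 2:
            continue
        h, p = stats.kruskal(*arrs)
        n, k = sum(a.size for a in arrs), len(arrs)
        eta2 = (h - k + 1) / (n - k) if n > k else np.nan
        rows.append(report_row(analysis="demographics", contrast=var,
                               test="kruskal_wallis", statistic=float(h),
                               p=float(p), effect=float(eta2),
                               effect_name="eta2", n=n))
    categorical = [("sex", df), ("fbtcs_status", df[df["group"] != "HC"])]
    for var, d in categorical:
        ct = pd.crosstab(d["group"], d[var])
        empty = ct.columns[(ct.sum(axis=0) == 0)]
        if len(empty):
            logger.info("demographics: dropping empty categories %s for %s",
                        list(empty), var)
            ct = ct.drop(columns=empty)
        if ct.shape[1] < 2 or ct.shape[0] < 2:
            continue
        chi2, p, dof, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
        rows.append(report_row(analysis="demographics", contrast=var,
                               test="chi_square", statistic=float(chi2),
                               p=float(p), n=int(ct.to_numpy().sum()),
                               note=f"dof={dof}"))
    return _report(rows)
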