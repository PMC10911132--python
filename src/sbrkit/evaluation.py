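"""Diagnostic and distributional statistics for comparing correction methods.

PD is the positive class throughout, with the clinical decision rule
"SBR <= threshold => PD" (striatal binding falls with dopaminergic loss).
AUC is computed through the Mann-Whitney rank identity (ties get half
credit), ROC thresholds are midpoints between adjacent distinct scores
plus the two infinite endpoints, and Youden-threshold ties break toward
higher sensitivity — the clinically conservative direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import Cohort
from .errors import DegenerateDataError, ValidationError


# ---------------------------------------------------------------------------
# ROC / Youden

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    low_is_positive: bool = True
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": float(self.auc),
            "youden_threshold": float(self.youden_threshold),
            "youden_j": float(self.youden_j),
            "sensitivity_at_youden": float(
                self.sensitivity[int(np.argmax(self.thresholds == self.youden_threshold))]
            ),
            "specificity_at_youden": float(
                self.specificity[int(np.argmax(self.thresholds == self.youden_threshold))]
            ),
            "low_is_positive": self.low_is_positive,
            "degenerate": self.degenerate,
        }


def roc_analysis(scores, labels, low_is_positive: bool = True) -> RocResult:
    """ROC curve, AUC and Youden-optimal threshold for HC/PD labels.

    With ``low_is_positive`` (the default), a record is called PD when its
    score is <= the threshold.  AUC is P(score_PD < score_HC) + 0.5
    P(tie) under that orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == "PD"
    neg = labels == "HC"
    if not pos.any() or not neg.any():
        raise DegenerateDataError("ROC needs both HC and PD records")
    n1, n0 = int(pos.sum()), int(neg.sum())

    oriented = -scores if low_is_positive else scores
    ranks = stats.rankdata(oriented)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    distinct = np.unique(scores)
    if distinct.size == 1:
        thr = np.array([-np.inf, np.inf])
        if low_is_positive:
            sens = np.array([0.0, 1.0])
            spec = np.array([1.0, 0.0])
        else:
            sens = np.array([1.0, 0.0])
            spec = np.array([0.0, 1.0])
        return RocResult(thr, sens, spec, 0.5, float(distinct[0]), 0.0,
                         low_is_positive, degenerate=True)

    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    if low_is_positive:
        called_pd = scores[None, :] <= thresholds[:, None]
    else:
        called_pd = scores[None, :] >= thresholds[:, None]
    sens = called_pd[:, pos].mean(axis=1)
    spec = (~called_pd)[:, neg].mean(axis=1)

    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(np.isclose(j, best_j))
    # tie-break toward higher sensitivity
    best = candidates[np.argmax(sens[candidates])]
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), youden_threshold=float(thresholds[best]),
        youden_j=float(j[best]), low_is_positive=low_is_positive,
    )


# ---------------------------------------------------------------------------
# Effect size

@dataclass
class EffectSize:
    g: float
    pooled_sd: float
    correction_j: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def to_dict(self) -> dict:
        return {
            "hedges_g": float(self.g),
            "pooled_sd": float(self.pooled_sd),
            "small_sample_correction": float(self.correction_j),
            "group1": {"mean": self.mean1, "sd": self.sd1, "n": self.n1},
            "group2": {"mean": self.mean2, "sd": self.sd2, "n": self.n2},
        }


def hedges_g_from_summary(m1: float, s1: float, n1: int,
                          m2: float, s2: float, n2: int) -> EffectSize:
    """Hedges's g from group summaries.

    g = J * (m1 - m2) / s_pooled with the small-sample correction
    J = 1 - 3 / (4(n1 + n2) - 9).
    """
    if s1 <= 0 or s2 <= 0:
        raise DegenerateDataError(f"group SDs must be positive, got {s1}, {s2}")
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("both groups need n >= 2")
    sp_sq = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    if sp_sq == 0:
        if m1 != m2:
            raise DegenerateDataError("zero pooled variance with unequal means")
        return EffectSize(0.0, 0.0, 1.0, m1, s1, n1, m2, s2, n2)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = J * (m1 - m2) / np.sqrt(sp_sq)
    return EffectSize(float(g), float(np.sqrt(sp_sq)), float(J),
                      float(m1), float(s1), n1, float(m2), float(s2), n2)


def hedges_g(x, y) -> EffectSize:
    """Hedges's g between two samples (group 1 minus group 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("both groups need n >= 2")
    s1, s2 = x.std(ddof=1), y.std(ddof=1)
    m1, m2 = x.mean(), y.mean()
    if s1 == 0 and s2 == 0:
        if m1 != m2:
            raise DegenerateDataError("zero pooled variance with unequal means")
        return EffectSize(0.0, 0.0, 1.0, m1, 0.0, len(x), m2, 0.0, len(y))
    return hedges_g_from_summary(m1, max(s1, np.finfo(float).tiny), len(x),
                                 m2, max(s2, np.finfo(float).tiny), len(y))


# ---------------------------------------------------------------------------
# Heteroscedastic one-way ANOVA (Brown-Forsythe adjusted F for means)

@dataclass
class AnovaResult:
    f: float
    df1: float
    df2: float
    p: float
    variant: str
    groups: list[dict]

    def to_dict(self) -> dict:
        return {"F": float(self.f), "df1": float(self.df1), "df2": float(self.df2),
                "p": float(self.p), "variant": self.variant, "groups": self.groups}


def brown_forsythe_anova(groups: list, labels: list[str] | None = None) -> AnovaResult:
    """Brown-Forsythe adjusted one-way ANOVA for equal means.

    F* = sum n_i (xbar_i - xbar)^2 / sum (1 - n_i/N) s_i^2 with a
    Satterthwaite-type denominator df from the (1 - n_i/N) s_i^2 weights.
    Robust to unequal group variances, unlike the classic F.
    """
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA needs >= 2 groups")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    arrs = [np.asarray(g, dtype=float) for g in groups]
    ns = np.array([len(a) for a in arrs], dtype=float)
    if (ns < 2).any():
        bad = [labels[i] for i in np.flatnonzero(ns < 2)]
        raise DegenerateDataError(f"group(s) {bad} have fewer than 2 observations")
    variances = np.array([a.var(ddof=1) for a in arrs])
    if (variances == 0).any():
        bad = [labels[i] for i in np.flatnonzero(variances == 0)]
        raise DegenerateDataError(f"group(s) {bad} have zero variance")
    means = np.array([a.mean() for a in arrs])
    N = ns.sum()
    grand = (ns * means).sum() / N

    numerator = (ns * (means - grand) ** 2).sum()
    weights = (1.0 - ns / N) * variances
    denominator = weights.sum()
    f = numerator / denominator

    c = weights / denominator
    df2 = 1.0 / (c ** 2 / (ns - 1)).sum()
    df1 = len(arrs) - 1.0
    p = float(stats.f.sf(f, df1, df2))
    summaries = [
        {"label": labels[i], "n": int(ns[i]), "mean": float(means[i]),
         "sd": float(np.sqrt(variances[i]))}
        for i in range(len(arrs))
    ]
    return AnovaResult(float(f), df1, float(df2), p, "brown_forsythe", summaries)


def classic_anova(groups: list, labels: list[str] | None = None) -> AnovaResult:
    """Classic one-way F (equal-variance assumption), for cross-checks."""
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    ns = [len(g) for g in groups]
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    summaries = [
        {"label": labels[i], "n": ns[i],
         "mean": float(np.mean(groups[i])), "sd": float(np.std(groups[i], ddof=1))}
        for i in range(len(groups))
    ]
    return AnovaResult(float(f), len(groups) - 1.0, float(sum(ns) - len(groups)),
                       float(p), "classic", summaries)


# ---------------------------------------------------------------------------
# Post-hoc pairwise t-tests with Benjamini-Hochberg FDR

@dataclass
class PairwiseResult:
    label_a: str
    label_b: str
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def to_dict(self) -> dict:
        return {"pair": [self.label_a, self.label_b], "t": self.t, "df": self.df,
                "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
                "significant": self.significant}


def posthoc_ttests_fdr(groups: dict[str, np.ndarray], alpha: float = 0.05,
                       equal_var: bool = False) -> list[PairwiseResult]:
    """All pairwise two-sample t-tests (Welch by default) with BH adjustment."""
    names = list(groups)
    if len(names) < 2:
        raise DegenerateDataError("post-hoc tests need >= 2 groups")
    pairs, stats_out = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            pairs.append((names[i], names[j]))
            stats_out.append((float(res.statistic), float(res.df), float(res.pvalue)))
    reject, p_adj, _, _ = multipletests([s[2] for s in stats_out],
                                        alpha=alpha, method="fdr_bh")
    return [
        PairwiseResult(a, b, t, df, p, float(q), bool(r))
        for (a, b), (t, df, p), q, r in zip(pairs, stats_out, p_adj, reject)
    ]


def benjamini_hochberg(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up rejections and adjusted p-values for a p-value family."""
    reject, p_adj, _, _ = multipletests(np.asarray(pvalues, dtype=float),
                                        alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Normality, agreement, misclassification

def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; valid for 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise DegenerateDataError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(values)}"
        )
    w, p = stats.shapiro(values)
    return float(w), float(p)


@dataclass
class AgreementResult:
    pearson_r: float
    slope: float
    intercept: float
    residual_sd: float
    residuals: np.ndarray
    fitted: np.ndarray

    def to_dict(self) -> dict:
        return {"pearson_r": float(self.pearson_r), "slope": float(self.slope),
                "intercept": float(self.intercept),
                "residual_sd": float(self.residual_sd)}


def method_agreement(x, y) -> AgreementResult:
    """Pearson correlation and OLS of y on x, with residuals for plotting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("agreement needs aligned samples with n >= 3")
    if x.std() == 0:
        raise DegenerateDataError("zero variance in x; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic) if y.std() > 0 else float("nan")
    lin = stats.linregress(x, y)
    fitted = lin.slope * x + lin.intercept
    resid = y - fitted
    return AgreementResult(
        pearson_r=r,
        slope=float(lin.slope), intercept=float(lin.intercept),
        residual_sd=float(resid.std(ddof=1)) if len(resid) > 1 else 0.0,
        residuals=resid, fitted=fitted,
    )


@dataclass
class MisclassificationAudit:
    threshold: float
    false_positives: list[dict]  # HCs called PD (score <= threshold)
    false_negatives: list[dict]  # PDs called HC (score > threshold)

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "n_false_positive": len(self.false_positives),
            "n_false_negative": len(self.false_negatives),
        }


def misclassification_audit(scores, labels, threshold: float,
                            ids=None) -> MisclassificationAudit:
    """Partition records at a fixed threshold (SBR <= threshold => PD).

    Reports each misclassified record with its margin (score - threshold);
    PDs with scores above the threshold are the scan-negative patients
    ("SWEDD"-like false negatives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(threshold):
        raise ValidationError(f"threshold must be finite, got {threshold}")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(scores))]
    called_pd = scores <= threshold
    fp = [
        {"id": ids[i], "score": float(scores[i]), "margin": float(scores[i] - threshold)}
        for i in np.flatnonzero(called_pd & (labels == "HC"))
    ]
    fn = [
        {"id": ids[i], "score": float(scores[i]), "margin": float(scores[i] - threshold)}
        for i in np.flatnonzero(~called_pd & (labels == "PD"))
    ]
    return MisclassificationAudit(float(threshold), fp, fn)


# ---------------------------------------------------------------------------
# Cross-method report

@dataclass
class StageMetrics:
    roc: RocResult
    effect: EffectSize
    site_anova: dict[str, AnovaResult | None]   # per diagnosis stratum
    shapiro: dict[str, tuple[float, float]]     # per diagnosis group
    audit: MisclassificationAudit

    def to_dict(self) -> dict:
        return {
            "roc": self.roc.to_dict(),
            "effect_size": self.effect.to_dict(),
            "site_anova": {k: (v.to_dict() if v is not None else None)
                           for k, v in self.site_anova.items()},
            "shapiro_wilk": {k: {"W": w, "p": p} for k, (w, p) in self.shapiro.items()},
            "misclassification": self.audit.to_dict(),
        }


@dataclass
class EvaluationReport:
    stages: dict[str, StageMetrics]
    method_mean_anova: dict[str, dict]   # per diagnosis: ANOVA + FDR post-hoc
    agreement: dict | None               # combat vs prospective
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stages": {k: v.to_dict() for k, v in self.stages.items()},
            "method_mean_anova": self.method_mean_anova,
            "agreement": self.agreement,
            "notes": self.notes,
        }


def _site_anova_by_stratum(cohort: Cohort) -> dict[str, AnovaResult | None]:
    """Brown-Forsythe site test within each diagnosis stratum.

    Sites contributing fewer than 2 records to a stratum are dropped (a site
    with no controls simply does not enter the HC test); if fewer than two
    sites remain the test is undefined and reported as None.
    """
    out: dict[str, AnovaResult | None] = {}
    for dx in ("HC", "PD"):
        sub = cohort.data[cohort.data["diagnosis"] == dx]
        scores = cohort.scores()[(cohort.data["diagnosis"] == dx).to_numpy()]
        groups, labels = [], []
        for site in sorted(sub["site"].unique()):
            mask = (sub["site"] == site).to_numpy()
            if mask.sum() >= 2:
                groups.append(scores[mask])
                labels.append(site)
        out[dx] = brown_forsythe_anova(groups, labels) if len(groups) >= 2 else None
    return out


def evaluate_stage(cohort: Cohort, low_is_positive: bool = True) -> StageMetrics:
    """All single-stage diagnostics on the per-record mean SBR."""
    scores = cohort.scores()
    labels = cohort.labels()
    roc = roc_analysis(scores, labels, low_is_positive)
    effect = hedges_g(scores[labels == "HC"], scores[labels == "PD"])
    shapiro = {
        dx: normality_test(scores[labels == dx]) for dx in ("HC", "PD")
        if (labels == dx).sum() >= 3
    }
    audit = misclassification_audit(scores, labels, roc.youden_threshold,
                                    ids=cohort.ids.tolist())
    return StageMetrics(roc=roc, effect=effect,
                        site_anova=_site_anova_by_stratum(cohort),
                        shapiro=shapiro, audit=audit)


def compare_methods(cohorts: dict[str, Cohort],
                    low_is_positive: bool = True,
                    comparison_stages: tuple[str, ...] = ("original", "prospective", "combat"),
                    alpha: float = 0.05) -> EvaluationReport:
    """Evaluate every stage and compare methods head to head.

    All stages must contain exactly the same participants.  The cross-stage
    method-mean comparison (Brown-Forsythe ANOVA over the stage means, with
    BH-adjusted pairwise post-hoc t-tests) runs separately within HCs and
    PDs over ``comparison_stages``; agreement (Pearson r, regression
    residuals) compares the combat stage against the prospective stage.
    """
    if not cohorts:
        raise ValidationError("no cohorts to compare")
    ref_ids = None
    for stage, cohort in cohorts.items():
        ids = set(cohort.ids)
        if ref_ids is None:
            ref_ids, ref_stage = ids, stage
        elif ids != ref_ids:
            diff = sorted(ids.symmetric_difference(ref_ids))
            raise ValidationError(
                f"stages '{ref_stage}' and '{stage}' differ in ids: {diff[:10]}"
            )

    stage_metrics = {s: evaluate_stage(c, low_is_positive) for s, c in cohorts.items()}

    notes: list[str] = []
    present = [s for s in comparison_stages if s in cohorts]
    method_anova: dict[str, dict] = {}
    if len(present) >= 2:
        base = cohorts[present[0]]
        dx_all = base.labels()
        for dx in ("HC", "PD"):
            groups = {s: cohorts[s].scores()[cohorts[s].labels() == dx] for s in present}
            if any(len(v) < 2 for v in groups.values()):
                method_anova[dx] = {}
                continue
            anova = brown_forsythe_anova(list(groups.values()), list(groups.keys()))
            posthoc = posthoc_ttests_fdr(groups, alpha=alpha)
            method_anova[dx] = {
                "anova": anova.to_dict(),
                "posthoc": [p.to_dict() for p in posthoc],
            }
        notes.append(
            "method-mean comparison runs all stage pairs within each diagnosis "
            "stratum; the adjustment family is the set of pairwise tests per stratum"
        )
        del dx_all

    agreement = None
    if "combat" in cohorts and "prospective" in cohorts:
        agr = method_agreement(cohorts["prospective"].scores(),
                               cohorts["combat"].scores())
        agreement = agr.to_dict()

    return EvaluationReport(stages=stage_metrics, method_mean_anova=method_anova,
                            agreement=agreement, notes=notes)
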