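"""Survival machinery and prognosis-aware drug-target nomination.

Kaplan-Meier curves (via lifelines), a k-group log-rank test with an
optional ordinal-trend variant, and a Cox proportional-hazards fitter
(Newton-Raphson maximization of the Efron partial likelihood, written
in-package so that cohort-wide per-protein screens stay fast).  On top
sit the cohort analyses: the Table-1-style univariate/multivariate
overall-survival model, the per-protein median-split survival screen,
and the two target-nomination rules — the "genomic" screen over a fixed
druggable driver list (no survival gate; the survival statistics are
annotated) and the "proteomic" screen requiring overexpression in more
than half the tumors, a druggable category, and poor-prognosis
association (log-rank P < 0.05 with HR > 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from .io import AnnotationTable, ClinicalTable
from .quantify import RatioMatrix
from .stats import TestResult

logger = logging.getLogger(__name__)

COEF_CAP = 15.0  # |ln HR| cap applied on complete separation


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def kaplan_meier(times, events, label: str | None = None) -> KaplanMeierFitter:
    """Product-limit survival estimate (fitted lifelines object)."""
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=int), label=label)
    return kmf


def logrank_test(times, events, groups, trend_weights=None) -> TestResult:
    """k-group log-rank test; with *trend_weights*, the ordinal score variant.

    The unweighted statistic is (O-E)' V^- (O-E) on df = k-1.  With
    weights w per group the statistic is (sum w_g (O_g - E_g))^2 /
    (w' V w) on df = 1, sensitive to hazards ordered along w.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels, gidx = np.unique(groups, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    counts = np.bincount(gidx, minlength=k)
    if np.any(counts == 0):
        raise ValueError("every group must contain at least one subject")

    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        n_gt = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dead = (times == t) & (events == 1)
        d_t = dead.sum()
        d_gt = np.bincount(gidx[dead], minlength=k).astype(float)
        O += d_gt
        E += n_gt * d_t / n_t
        if n_t > 1:
            frac = n_gt / n_t
            V += (
                d_t
                * (n_t - d_t)
                / (n_t - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
    diff = O - E
    if trend_weights is not None:
        w = np.asarray(trend_weights, dtype=float)
        if w.size != k:
            raise ValueError("one trend weight per group required")
        num = float(w @ diff)
        var = float(w @ V @ w)
        if var <= 0:
            return TestResult(0.0, 1.0, "logrank-trend", 0.0, degenerate=True)
        stat = num**2 / var
        p = float(sps.chi2.sf(stat, df=1))
        return TestResult(stat, min(p, 1.0), "logrank-trend", num, extra={"df": 1})
    Vsub = V[: k - 1, : k - 1]
    dsub = diff[: k - 1]
    try:
        stat = float(dsub @ np.linalg.solve(Vsub, dsub))
    except np.linalg.LinAlgError:
        stat = float(dsub @ np.linalg.pinv(Vsub) @ dsub)
    if stat <= 0:
        return TestResult(0.0, 1.0, "logrank", 0.0, degenerate=True, extra={"df": k - 1})
    p = float(sps.chi2.sf(stat, df=k - 1))
    return TestResult(stat, min(p, 1.0), "logrank", float(diff[0]), extra={"df": k - 1})


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    """Fitted Cox model: ln(HR) per covariate with Wald inference.

    ``coefficients`` has one row per covariate: coef (= ln HR), hr, se,
    z, p, ci_lower, ci_upper (95% on the HR scale).
    """

    coefficients: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    separation: bool = False

    def summary(self) -> pd.DataFrame:
        return self.coefficients.copy()

    @property
    def coef(self) -> pd.Series:
        return self.coefficients["coef"]

    @property
    def hr(self) -> pd.Series:
        return self.coefficients["hr"]


def _efron_loglik_grad_hess(beta, X, times, events):
    """Efron partial log-likelihood with gradient and information matrix."""
    eta = X @ beta
    # protect exp from overflow during capped-separation iterations
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    loglik = 0.0
    p = X.shape[1]
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        wr = w[risk]
        Xr = X[risk]
        S0 = wr.sum()
        S1 = Xr.T @ wr
        S2 = (Xr * wr[:, None]).T @ Xr
        wd = w[dead]
        Xd = X[dead]
        S0d = wd.sum()
        S1d = Xd.T @ wd
        S2d = (Xd * wd[:, None]).T @ Xd
        loglik += float(eta[dead].sum())
        for ell in range(d):
            f = ell / d
            s0 = S0 - f * S0d
            s1 = S1 - f * S1d
            s2 = S2 - f * S2d
            loglik -= np.log(s0)
            mean = s1 / s0
            grad -= mean
            info += s2 / s0 - np.outer(mean, mean)
        grad += Xd.sum(axis=0)
    return loglik, grad, info


def cox_fit(
    design,
    times,
    events,
    *,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> SurvivalFit:
    """Cox proportional-hazards regression with Efron tie handling.

    *design* is a DataFrame (or array) of covariates per subject; no
    covariate may be constant.  Newton-Raphson maximizes the partial
    likelihood; on complete separation the diverging coefficient is
    capped at +/-15 with a warning, and failure to converge within
    *max_iter* iterations raises with the gradient norm.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    X = pd.DataFrame(design)
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if Xv.ndim != 2 or Xv.shape[0] != times.size:
        raise ValueError("design and times must align")
    const = np.all(Xv == Xv[0], axis=0)
    if const.any():
        raise ValueError(f"constant covariate: {names[int(np.argmax(const))]!r}")
    n, p = Xv.shape
    beta = np.zeros(p)
    loglik, grad, info = _efron_loglik_grad_hess(beta, Xv, times, events)
    separation = False
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_info = _efron_loglik_grad_hess(new_beta, Xv, times, events)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_loglik_grad_hess(
                new_beta, Xv, times, events
            )
            halvings += 1
        improved = new_ll - loglik
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if np.any(np.abs(beta) > COEF_CAP):
            logger.warning("complete separation suspected; capping |coef| at %g", COEF_CAP)
            separation = True
            beta = np.clip(beta, -COEF_CAP, COEF_CAP)
            loglik, grad, info = _efron_loglik_grad_hess(beta, Xv, times, events)
            converged = True
            break
        if np.max(np.abs(grad)) < tol or abs(improved) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * sps.norm.sf(np.abs(z))
    zcrit = sps.norm.ppf(0.975)
    coef_table = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "z": z,
            "p": pvals,
            "ci_lower": np.exp(np.clip(beta - zcrit * se, -700, 700)),
            "ci_upper": np.exp(np.clip(beta + zcrit * se, -700, 700)),
        },
        index=pd.Index(names, name="covariate"),
    )
    return SurvivalFit(
        coefficients=coef_table,
        log_likelihood=float(loglik),
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# Table-1-style cohort analysis
# ---------------------------------------------------------------------------


def _covariate_blocks(clinical: ClinicalTable) -> dict[str, pd.DataFrame]:
    """Expand clinical covariates into design blocks (dummies for categoricals)."""
    df = clinical.data
    blocks: dict[str, pd.DataFrame] = {}
    blocks["age"] = df[["age"]].astype(float)
    gender = pd.get_dummies(df["gender"], drop_first=True, dtype=float)
    gender.columns = [f"gender_{c}" for c in gender.columns]
    blocks["gender"] = gender
    blocks["chemo"] = df[["chemo"]].astype(float)
    site = pd.get_dummies(df["site"], drop_first=True, dtype=float)
    site.columns = [f"site_{c}" for c in site.columns]
    blocks["site"] = site
    blocks["stage"] = clinical.stage_ordinal().to_frame("stage")
    if "tp53_mutant" in df.columns:
        blocks["tp53_mutant"] = df[["tp53_mutant"]].astype(float)
    return blocks


def _subtype_designs(subtype: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    levels = sorted(subtype.unique())
    cat = pd.get_dummies(subtype.astype("category"), dtype=float)
    cat = cat[[c for c in cat.columns]]
    cat = cat.drop(columns=cat.columns[0])  # first level is the reference
    cat.columns = [f"subtype_{c}" for c in cat.columns]
    trend = subtype.map({lev: i + 1 for i, lev in enumerate(levels)}).astype(float)
    return cat, trend.to_frame("subtype_trend")


def table1_analysis(
    clinical: ClinicalTable,
    univariate_p: float = 0.05,
) -> dict:
    """Univariate and multivariate overall-survival Cox analysis.

    Each covariate block (age, gender, adjuvant chemotherapy, tumor site,
    ordinal stage, optional TP53 status, proteomic subtype as categorical
    with the first level as reference and as ordinal trend) is fitted
    univariately; clinical blocks reaching P < *univariate_p* enter the
    multivariate model alongside subtype.  Subjects with missing values
    are dropped with the count logged.
    """
    df = clinical.data
    if "subtype" not in df.columns:
        raise ValueError("clinical table must carry subtype labels")
    blocks = _covariate_blocks(clinical)
    cat, trend = _subtype_designs(df["subtype"])
    blocks["subtype"] = cat
    blocks["subtype_trend"] = trend

    times = df["os_months"].astype(float)
    events = df["event"].astype(int)

    univariate: dict[str, SurvivalFit] = {}
    for name, X in blocks.items():
        keep = X.notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("univariate %s: dropped %d subjects with missing values", name, dropped)
        univariate[name] = cox_fit(X[keep], times[keep], events[keep])

    include = [
        name
        for name, fit in univariate.items()
        if name not in ("subtype", "subtype_trend")
        and (fit.coefficients["p"] < univariate_p).any()
    ]
    out: dict = {"univariate": univariate, "included_covariates": include}
    for label, subtype_block in (("multivariate", cat), ("multivariate_trend", trend)):
        X = pd.concat([blocks[name] for name in include] + [subtype_block], axis=1)
        keep = X.notna().all(axis=1)
        out[label] = cox_fit(X[keep], times[keep], events[keep])
    return out


# ---------------------------------------------------------------------------
# per-protein screen and target nomination
# ---------------------------------------------------------------------------


def protein_survival_screen(
    ratios: RatioMatrix,
    clinical: ClinicalTable,
    mode: str = "median-split",
    min_patients: int = 5,
) -> pd.DataFrame:
    """Per-protein association between T/N ratio and overall survival.

    Restricted to patients in which the protein was detected (either
    tissue) and to proteins detected in strictly more than *min_patients*
    of them.  ``median-split`` dichotomizes at the median detected ratio
    (ties go to "low") and reports the binary Cox ln(HR) plus the
    two-group log-rank p; ``continuous`` uses the log10 ratio directly
    (the log-rank column then repeats the Cox Wald p).
    """
    if mode not in ("median-split", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    common = ratios.patients.intersection(clinical.patients)
    times_all = clinical.data.loc[common, "os_months"].astype(float)
    events_all = clinical.data.loc[common, "event"].astype(int)
    detected = ratios.detected_either()[common]
    lr = ratios.log_ratios[common]
    rows = []
    for protein in ratios.proteins:
        det = detected.loc[protein]
        patients = det.index[det]
        if len(patients) <= min_patients:
            continue
        values = lr.loc[protein, patients]
        times = times_all.loc[patients]
        events = events_all.loc[patients]
        if mode == "median-split":
            median = values.median()
            high = (values > median).astype(float)
            if high.nunique() < 2:
                rows.append(
                    {"protein": protein, "n": len(patients), "skipped": True}
                )
                continue
            fit = cox_fit(high.to_frame("high"), times, events)
            lr_test = logrank_test(times, events, high)
            cox_p = float(fit.coefficients["p"].iloc[0])
            logrank_p = lr_test.p_value
        else:
            if values.nunique() < 2:
                rows.append(
                    {"protein": protein, "n": len(patients), "skipped": True}
                )
                continue
            fit = cox_fit(values.to_frame("ratio"), times, events)
            cox_p = logrank_p = float(fit.coefficients["p"].iloc[0])
        rows.append(
            {
                "protein": protein,
                "n": len(patients),
                "ln_hr": float(fit.coefficients["coef"].iloc[0]),
                "hr": float(fit.coefficients["hr"].iloc[0]),
                "cox_p": cox_p,
                "logrank_p": logrank_p,
                "skipped": False,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("protein")
    return out


def nominate_genomic_targets(
    screen: pd.DataFrame,
    annotation: AnnotationTable,
    overexpression: pd.DataFrame,
    *,
    frac_min: float = 0.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Evaluate the fixed druggable driver ("genomic-159") list.

    Members of the list that were screened (detected in enough patients)
    and overexpressed in strictly more than *frac_min* of tumors are
    returned with their survival statistics; there is no survival gate,
    but ``survival_unfavorable`` marks log-rank P < *p_max* with HR > 1
    and ``better_os`` marks the protective significant association.
    """
    flagged = annotation.data.index[annotation.data["genomic_target"]]
    rows = screen.index.intersection(flagged)
    out = screen.loc[rows].copy()
    out = out[~out.get("skipped", pd.Series(False, index=out.index)).astype(bool)]
    out["overexpressed_fraction"] = overexpression["fraction_all"].reindex(out.index)
    out = out[out["overexpressed_fraction"] > frac_min]
    out["survival_unfavorable"] = (out["logrank_p"] < p_max) & (out["hr"] > 1)
    out["better_os"] = (out["logrank_p"] < p_max) & (out["hr"] < 1)
    out["screen"] = "genomic"
    return out


def nominate_proteomic_targets(
    overexpression: pd.DataFrame,
    annotation: AnnotationTable,
    screen: pd.DataFrame,
    *,
    frac_min: float = 0.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Proteome-driven nomination: all three criteria must hold.

    (1) overexpressed (>3-fold) in strictly more than *frac_min* of
    tumors; (2) annotated in a conventionally druggable category; (3)
    overexpression associated with poor survival (log-rank P < *p_max*
    and HR > 1).
    """
    druggable = annotation.data.index[annotation.data["druggable"]]
    candidates = screen.index.intersection(druggable)
    out = screen.loc[candidates].copy()
    out = out[~out.get("skipped", pd.Series(False, index=out.index)).astype(bool)]
    out["overexpressed_fraction"] = overexpression["fraction_all"].reindex(out.index)
    if "category" in annotation.data.columns:
        out["category"] = annotation.data["category"].reindex(out.index)
    mask = (
        (out["overexpressed_fraction"] > frac_min)
        & (out["logrank_p"] < p_max)
        & (out["hr"] > 1)
    )
    out = out[mask]
    out["screen"] = "proteomic"
    return out


def upper_quartile_flag(values: pd.Series, min_detected: int = 4) -> pd.Series:
    """High/low marker status at the upper quartile of detected values.

    A patient is "high" when the detected value is at or above the 75th
    percentile (linear-interpolation convention) of all detected values;
    undetected patients are low and excluded from the percentile.  With
    fewer than *min_detected* detected values everyone is low.
    """
    values = pd.Series(values, dtype=float)
    detected = values.dropna()
    if len(detected) < min_detected:
        logger.warning(
            "only %d detected values (< %d); flagging all patients low",
            len(detected),
            min_detected,
        )
        return pd.Series(False, index=values.index, name="high")
    q3 = float(np.percentile(detected.to_numpy(), 75))
    return (values >= q3).fillna(False).rename("high")
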