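"""Diagnostic test-accuracy meta-analysis: per-study ROC dichotomization and
summary ROC pooling.

Continuous expression is dichotomized per study at the Youden-optimal
threshold (orientation: expression above the threshold calls a case), giving
per-study 2x2 tables.  Tables are pooled on the (logit sensitivity, logit
specificity) scale: each margin gets DerSimonian-Laird random-effects
pooling, the between-study covariance is estimated by method of moments, and
the summary curve is traced from the implied between-study regression of
logit sensitivity on logit false-positive rate.  Positive/negative likelihood
ratios and the diagnostic odds ratio are evaluated at the summary operating
point with delta-method confidence intervals.  A Moses-Littenberg linear
model is available as the classical fallback when too few studies support
the bivariate fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from metaexpr.meta_pool import Z95, _dl_arrays

#: number of (FPR, sens) points sampled along the summary curve
CURVE_POINTS = 200


@dataclass(frozen=True)
class DiagStudy:
    """One study's diagnostic 2x2 table at a chosen expression cut-off."""

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float = float("nan")
    auc_single: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n_case(self) -> int:
        return self.tp + self.fn

    @property
    def n_ctrl(self) -> int:
        return self.fp + self.tn

    def corrected(self) -> tuple[float, float, float, float]:
        """Cell counts with a 0.5 continuity correction if any cell is zero."""
        cells = (self.tp, self.fp, self.fn, self.tn)
        if min(cells) == 0:
            return tuple(c + 0.5 for c in cells)
        return tuple(float(c) for c in cells)

    @property
    def sens(self) -> float:
        tp, _, fn, _ = self.corrected()
        return tp / (tp + fn)

    @property
    def spec(self) -> float:
        _, fp, _, tn = self.corrected()
        return tn / (fp + tn)

    @property
    def dor(self) -> float:
        tp, fp, fn, tn = self.corrected()
        return (tp * tn) / (fp * fn)


@dataclass(frozen=True)
class SrocResult:
    pooled_sens: float
    sens_ci: tuple[float, float]
    pooled_spec: float
    spec_ci: tuple[float, float]
    plr: float
    plr_ci: tuple[float, float]
    nlr: float
    nlr_ci: tuple[float, float]
    dor: float
    dor_ci: tuple[float, float]
    auc: float
    auc_restricted: float
    fpr_range: tuple[float, float]
    curve: np.ndarray  # (CURVE_POINTS, 2) of (1 - spec, sens)
    model: str  # bivariate | moses
    k: int
    flags: tuple[str, ...] = ()


def roc_auc(case_values, ctrl_values) -> float:
    """Mann-Whitney AUC: P(case > control) + 0.5 P(tie), via midranks."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(ctrl_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float((r1 - len(x) * (len(x) + 1) / 2.0) / (len(x) * len(y)))


def youden_cutoff(
    case_values, ctrl_values, study_id: str = ""
) -> tuple[float, DiagStudy]:
    """Youden-optimal dichotomization of continuous expression.

    Scans all midpoints between adjacent sorted unique values and picks the
    threshold maximizing sensitivity + specificity - 1, orienting "above
    threshold calls a case"; ties break toward the smallest threshold.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(ctrl_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    uniq = np.unique(np.concatenate([x, y]))
    if len(uniq) == 1:
        cuts = np.array([uniq[0] - 0.5])
    else:
        cuts = (uniq[:-1] + uniq[1:]) / 2.0
        # also allow calling everything positive
        cuts = np.concatenate([[uniq[0] - 0.5], cuts])
    sens = (x[:, None] > cuts[None, :]).mean(axis=0)
    spec = (y[:, None] <= cuts[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (= smallest) maximizer
    cut = float(cuts[best])
    tp = int((x > cut).sum())
    fn = len(x) - tp
    tn = int((y <= cut).sum())
    fp = len(y) - tn
    study = DiagStudy(
        study_id=study_id, tp=tp, fp=fp, fn=fn, tn=tn, cutoff=cut,
        auc_single=roc_auc(x, y),
    )
    return cut, study


def _logit_arrays(studies: list[DiagStudy]):
    """Per-study (logit sens, logit spec) with binomial within-study variances."""
    tp, fp, fn, tn = np.array([s.corrected() for s in studies], dtype=float).T
    eta = np.log(tp / fn)  # logit sensitivity
    xi = np.log(tn / fp)  # logit specificity
    v_eta = 1.0 / tp + 1.0 / fn
    v_xi = 1.0 / fp + 1.0 / tn
    return eta, xi, v_eta, v_xi


def _summary_measures(mu_eta, se_eta, mu_xi, se_xi):
    """Summary-point sens/spec, LRs and DOR with delta-method CIs."""
    p = float(expit(mu_eta))
    q = float(expit(mu_xi))
    sens_ci = (float(expit(mu_eta - Z95 * se_eta)), float(expit(mu_eta + Z95 * se_eta)))
    spec_ci = (float(expit(mu_xi - Z95 * se_xi)), float(expit(mu_xi + Z95 * se_xi)))
    # log-scale gradients of the ratios w.r.t. (mu_eta, mu_xi)
    ln_plr = np.log(p) - np.log(1 - q)
    ln_nlr = np.log(1 - p) - np.log(q)
    se_ln_plr = float(np.sqrt(((1 - p) * se_eta) ** 2 + (q * se_xi) ** 2))
    se_ln_nlr = float(np.sqrt((p * se_eta) ** 2 + ((1 - q) * se_xi) ** 2))
    se_ln_dor = float(np.sqrt(se_eta**2 + se_xi**2))
    ln_dor = mu_eta + mu_xi
    ci = lambda m, s: (float(np.exp(m - Z95 * s)), float(np.exp(m + Z95 * s)))
    return {
        "sens": p, "sens_ci": sens_ci, "spec": q, "spec_ci": spec_ci,
        "plr": float(np.exp(ln_plr)), "plr_ci": ci(ln_plr, se_ln_plr),
        "nlr": float(np.exp(ln_nlr)), "nlr_ci": ci(ln_nlr, se_ln_nlr),
        "dor": float(np.exp(ln_dor)), "dor_ci": ci(ln_dor, se_ln_dor),
    }


def _curve_auc(curve: np.ndarray, fpr_lo: float, fpr_hi: float):
    """Trapezoidal AUC over (0,1) and restricted to the observed FPR range."""
    fpr, sens = curve[:, 0], curve[:, 1]
    auc = float(np.trapezoid(sens, fpr))
    sel = (fpr >= fpr_lo) & (fpr <= fpr_hi)
    if sel.sum() >= 2 and fpr_hi > fpr_lo:
        auc_restricted = float(
            np.trapezoid(sens[sel], fpr[sel]) / (fpr[sel][-1] - fpr[sel][0])
        )
    else:
        auc_restricted = auc
    return auc, auc_restricted


def pool_bivariate(studies: list[DiagStudy]) -> SrocResult:
    """Bivariate-normal pooling of per-study (logit sens, logit spec).

    Each margin is pooled by DerSimonian-Laird random effects; the
    between-study covariance comes from the method of moments (sample
    covariance of the observed logits, within-study covariance being zero
    for independent binomial margins).  The summary curve is the implied
    regression of logit sensitivity on logit FPR across studies.  Fewer than
    3 studies falls back to the Moses-Littenberg model with a warning flag.
    """
    if len(studies) < 3:
        res = pool_moses(studies)
        return SrocResult(**{**res.__dict__, "flags": res.flags + ("bivariate_fallback_moses",)})
    eta, xi, v_eta, v_xi = _logit_arrays(studies)
    dl_eta = _dl_arrays(eta, v_eta)
    dl_xi = _dl_arrays(xi, v_xi)
    mu_eta, se_eta = float(dl_eta["mu"]), float(dl_eta["se"])
    mu_xi, se_xi = float(dl_xi["mu"]), float(dl_xi["se"])
    tau2_eta = float(dl_eta["tau2"])
    tau2_xi = float(dl_xi["tau2"])

    # method-of-moments between-study covariance; the within-study
    # covariance of the two margins is zero (independent binomials)
    cov_b = float(np.cov(eta, xi, ddof=1)[0, 1])
    if tau2_eta > 0 and tau2_xi > 0:
        # bound the implied correlation away from +/-1
        rho = float(np.clip(cov_b / np.sqrt(tau2_eta * tau2_xi), -0.999, 0.999))
        cov_b = rho * np.sqrt(tau2_eta * tau2_xi)
    else:
        cov_b = 0.0

    # summary curve: regression of logit sens (eta) on logit FPR (= -xi),
    # slope = cov(eta, -xi) / var(-xi) = -cov_b / tau2_xi
    flags: tuple[str, ...] = ()
    if tau2_xi > 0:
        slope = -cov_b / tau2_xi
    else:
        slope = 0.0
        flags += ("no_threshold_spread",)
    fpr0 = float(expit(-mu_xi))
    fpr = np.linspace(1e-4, 1 - 1e-4, CURVE_POINTS)
    sens_curve = expit(mu_eta + slope * (logit(fpr) - logit(fpr0)))
    curve = np.column_stack([fpr, sens_curve])

    obs_fpr = 1.0 - np.array([s.spec for s in studies])
    auc, auc_restricted = _curve_auc(curve, float(obs_fpr.min()), float(obs_fpr.max()))
    m = _summary_measures(mu_eta, se_eta, mu_xi, se_xi)
    return SrocResult(
        pooled_sens=m["sens"], sens_ci=m["sens_ci"],
        pooled_spec=m["spec"], spec_ci=m["spec_ci"],
        plr=m["plr"], plr_ci=m["plr_ci"], nlr=m["nlr"], nlr_ci=m["nlr_ci"],
        dor=m["dor"], dor_ci=m["dor_ci"],
        auc=auc, auc_restricted=auc_restricted,
        fpr_range=(float(obs_fpr.min()), float(obs_fpr.max())),
        curve=curve, model="bivariate", k=len(studies), flags=flags,
    )


def pool_moses(studies: list[DiagStudy]) -> SrocResult:
    """Moses-Littenberg linear summary ROC.

    Regresses D = ln DOR = logit(TPR) - logit(FPR) on the threshold proxy
    S = logit(TPR) + logit(FPR) by ordinary least squares; the fitted line
    defines the summary curve logit(TPR) = (a + (1+b) logit FPR)/(1 - b).
    With no spread in S (identical operating points) the symmetric
    constant-DOR curve through the common point is returned.
    """
    if len(studies) < 2:
        raise ValueError("Moses model needs k >= 2")
    eta, xi, v_eta, v_xi = _logit_arrays(studies)
    D = eta + xi  # logit TPR - logit FPR  (logit FPR = -xi)
    S = eta - xi  # logit TPR + logit FPR
    flags: tuple[str, ...] = ()
    if np.ptp(S) < 1e-9:
        a, b = float(np.mean(D)), 0.0
        flags += ("degenerate_s_spread",)
    else:
        fit = stats.linregress(S, D)
        a, b = float(fit.intercept), float(fit.slope)
    if abs(1.0 - b) < 1e-9:
        raise ValueError("moses slope ~ 1: summary curve undefined")
    fpr = np.linspace(1e-4, 1 - 1e-4, CURVE_POINTS)
    sens_curve = expit((a + (1.0 + b) * logit(fpr)) / (1.0 - b))
    curve = np.column_stack([fpr, sens_curve])

    # summary operating point: simple inverse-variance pooling of the margins
    dl_eta = _dl_arrays(eta, v_eta)
    dl_xi = _dl_arrays(xi, v_xi)
    m = _summary_measures(
        float(dl_eta["mu"]), float(dl_eta["se"]), float(dl_xi["mu"]), float(dl_xi["se"])
    )
    obs_fpr = 1.0 - np.array([s.spec for s in studies])
    auc, auc_restricted = _curve_auc(curve, float(obs_fpr.min()), float(obs_fpr.max()))
    return SrocResult(
        pooled_sens=m["sens"], sens_ci=m["sens_ci"],
        pooled_spec=m["spec"], spec_ci=m["spec_ci"],
        plr=m["plr"], plr_ci=m["plr_ci"], nlr=m["nlr"], nlr_ci=m["nlr_ci"],
        dor=m["dor"], dor_ci=m["dor_ci"],
        auc=auc, auc_restricted=auc_restricted,
        fpr_range=(float(obs_fpr.min()), float(obs_fpr.max())),
        curve=curve, model="moses", k=len(studies), flags=flags,
    )
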