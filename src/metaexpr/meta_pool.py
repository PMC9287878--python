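"""Pooling of per-study effects and meta-analytic diagnostics.

Fixed-effect pooling uses inverse-variance weights; the random-effects model
estimates the between-study variance tau^2 by the DerSimonian-Laird method
of moments, tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w)
computed from the fixed-effect weights.  Heterogeneity is summarized by
Cochran's Q and I^2 = max(0, (Q - df)/Q) * 100.  Confidence intervals are
normal-theory (pooled +/- 1.96 se), matching the conventions of the classic
STATA metan toolchain.

Diagnostics: subgroup pooling, leave-one-out sensitivity analysis, Egger's
regression test and Begg's rank-correlation test for funnel asymmetry.

The private array helpers (`_fixed_arrays`, `_dl_arrays`) pool many effect
series at once along the last axis; the genome-wide screen and the
simulation studies reuse them so that every pooled number in the package
comes from a single implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats

from metaexpr.effect_size import StudyEffect

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    ci_low: float
    ci_high: float
    se: float
    Q: float
    df: int
    tau2: float
    I2: float
    model: str  # fixed | random
    weights: tuple[float, ...]
    k: int
    q_p: float = float("nan")  # p-value of the Q heterogeneity test
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BiasTestResult:
    method: str  # begg | egger
    statistic: float
    p: float
    intercept: float = float("nan")
    intercept_se: float = float("nan")


@dataclass(frozen=True)
class LeaveOneOutResult:
    results: tuple[tuple[str, MetaResult], ...]
    min_i2_study: str


# ---------------------------------------------------------------------------
# vectorized cores: y, v are (..., k) arrays, mask selects valid studies
# ---------------------------------------------------------------------------

def _fixed_arrays(y, v, mask=None):
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if mask is None:
        mask = np.isfinite(y) & np.isfinite(v) & (v > 0)
    w = np.where(mask, 1.0 / np.where(mask, v, 1.0), 0.0)
    sw = w.sum(axis=-1)
    sw2 = (w**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = (w * np.where(mask, y, 0.0)).sum(axis=-1) / sw
        Q = (w * (np.where(mask, y, 0.0) - mu[..., None]) ** 2).sum(axis=-1)
        se = 1.0 / np.sqrt(sw)
    k = mask.sum(axis=-1)
    return {"mu": mu, "se": se, "Q": Q, "k": k, "w": w, "sw": sw, "sw2": sw2,
            "mask": mask}


def _dl_arrays(y, v, mask=None):
    """DerSimonian-Laird random-effects pooling along the last axis."""
    fx = _fixed_arrays(y, v, mask)
    mask = fx["mask"]
    k = fx["k"]
    df = np.maximum(k - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = fx["sw"] - fx["sw2"] / fx["sw"]
        tau2 = np.where(
            (df > 0) & (C > 0), np.maximum(0.0, (fx["Q"] - df) / np.where(C > 0, C, 1.0)), 0.0
        )
        wr = np.where(mask, 1.0 / (np.asarray(v, dtype=float) + tau2[..., None]), 0.0)
        swr = wr.sum(axis=-1)
        mu = (wr * np.where(mask, np.asarray(y, dtype=float), 0.0)).sum(axis=-1) / swr
        se = 1.0 / np.sqrt(swr)
        I2 = np.where(
            (fx["Q"] > 0) & (df > 0),
            np.maximum(0.0, (fx["Q"] - df) / np.where(fx["Q"] > 0, fx["Q"], 1.0)) * 100.0,
            0.0,
        )
    return {"mu": mu, "se": se, "tau2": tau2, "Q": fx["Q"], "I2": I2, "k": k,
            "w": wr, "mask": mask, "Q_fixed_se": fx["se"]}


# ---------------------------------------------------------------------------
# public API on StudyEffect lists
# ---------------------------------------------------------------------------

def _unpack(effects: list[StudyEffect]):
    y = np.array([e.y for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return y, v


def _i2_from_q(Q: float, df: int) -> float:
    if df < 1 or Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def _q_p(Q: float, df: int) -> float:
    return float(stats.chi2.sf(Q, df)) if df >= 1 else float("nan")


def pool_fixed(effects: list[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with heterogeneity statistics."""
    if len(effects) == 0:
        raise ValueError("cannot pool an empty study list")
    y, v = _unpack(effects)
    fx = _fixed_arrays(y, v)
    mu, se, Q = float(fx["mu"]), float(fx["se"]), float(fx["Q"])
    k = len(effects)
    df = k - 1
    w = fx["w"] / fx["sw"]
    return MetaResult(
        pooled=mu, ci_low=mu - Z95 * se, ci_high=mu + Z95 * se, se=se,
        Q=Q, df=df, tau2=0.0, I2=_i2_from_q(Q, df), model="fixed",
        weights=tuple(w.tolist()), k=k, q_p=_q_p(Q, df),
    )


def pool_random_dl(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling."""
    if len(effects) < 2:
        raise ValueError("need_two_studies: random-effects pooling needs k >= 2")
    y, v = _unpack(effects)
    dl = _dl_arrays(y, v)
    mu, se = float(dl["mu"]), float(dl["se"])
    k = len(effects)
    df = k - 1
    w = dl["w"] / dl["w"].sum()
    return MetaResult(
        pooled=mu, ci_low=mu - Z95 * se, ci_high=mu + Z95 * se, se=se,
        Q=float(dl["Q"]), df=df, tau2=float(dl["tau2"]), I2=float(dl["I2"]),
        model="random", weights=tuple(w.tolist()), k=k,
        q_p=_q_p(float(dl["Q"]), df),
    )


def subgroup_pool(
    effects: list[StudyEffect], group_of
) -> tuple[dict[str, MetaResult], MetaResult]:
    """Random-effects pooling within each subgroup plus the overall pool.

    ``group_of`` maps study_id -> label (a dict or a callable).  A subgroup
    with a single study is reported as a degenerate fixed result flagged
    ``singleton_subgroup``.
    """
    get = group_of.get if hasattr(group_of, "get") else group_of
    labels: dict[str, list[StudyEffect]] = {}
    for e in effects:
        lab = get(e.study_id)
        if lab is None:
            raise ValueError(f"study {e.study_id} has no subgroup label")
        labels.setdefault(str(lab), []).append(e)
    out: dict[str, MetaResult] = {}
    for lab, es in sorted(labels.items()):
        if len(es) == 1:
            r = pool_fixed(es)
            out[lab] = MetaResult(
                **{**r.__dict__, "flags": ("singleton_subgroup",)}
            )
        else:
            out[lab] = pool_random_dl(es)
    return out, pool_random_dl(effects)


def leave_one_out(effects: list[StudyEffect]) -> LeaveOneOutResult:
    """Re-pool with each study omitted in turn (random effects).

    Also identifies the omission minimizing residual I^2 — the study whose
    removal most reduces heterogeneity, hence the likeliest heterogeneity
    source.  Ties go to the first study in input order.
    """
    if len(effects) < 3:
        raise ValueError("leave-one-out needs k >= 3")
    results = []
    for i, e in enumerate(effects):
        rest = effects[:i] + effects[i + 1:]
        results.append((e.study_id, pool_random_dl(rest)))
    best = min(results, key=lambda t: t[1].I2)[0]
    return LeaveOneOutResult(results=tuple(results), min_i2_study=best)


def egger_test(effects: list[StudyEffect]) -> BiasTestResult:
    """Egger's regression test for funnel-plot asymmetry.

    OLS of the standardized effect z_i = y_i / se_i on the precision
    1/se_i; the intercept measures small-study asymmetry and is tested with
    t = intercept / SE(intercept) on k - 2 df.
    """
    if len(effects) < 3:
        raise ValueError("Egger's test needs k >= 3")
    y, v = _unpack(effects)
    prec = 1.0 / np.sqrt(v)
    if np.ptp(prec) < 1e-12:
        raise ValueError("no_precision_spread: all study variances identical")
    z = y * prec
    fit = stats.linregress(prec, z)
    t = fit.intercept / fit.intercept_stderr
    p = float(2 * stats.t.sf(abs(t), len(effects) - 2))
    return BiasTestResult(
        method="egger", statistic=float(t), p=p,
        intercept=float(fit.intercept), intercept_se=float(fit.intercept_stderr),
    )


def _kendall_s(u: np.ndarray, v: np.ndarray) -> int:
    """Kendall score S = (# concordant) - (# discordant) pairs."""
    du = np.sign(u[:, None] - u[None, :])
    dv = np.sign(v[:, None] - v[None, :])
    iu = np.triu_indices(len(u), k=1)
    return int(np.sum(du[iu] * dv[iu]))


def _exact_kendall_p(s_obs: int, k: int) -> float:
    """Two-sided P(|S| >= |s_obs|) under the uniform-permutation null."""
    total = 0
    hits = 0
    base = np.arange(k, dtype=float)
    for perm in permutations(range(k)):
        s = _kendall_s(base, np.array(perm, dtype=float))
        total += 1
        if abs(s) >= abs(s_obs):
            hits += 1
    return hits / total


#: study counts at or below which Begg's test enumerates the exact
#: permutation null instead of using the normal approximation
BEGG_EXACT_MAX_K = 8


def begg_test(effects: list[StudyEffect], warn=None) -> BiasTestResult:
    """Begg's rank-correlation (adjusted Kendall) test for funnel asymmetry.

    Effects are standardized as u_i = (y_i - mu_fixed) / sqrt(v_i - se_fixed^2)
    and Kendall's S between u and v is referenced to the no-tie null
    variance k(k-1)(2k+5)/18; for k <= 8 the exact permutation null is
    enumerated instead.
    """
    if len(effects) < 3:
        raise ValueError("Begg's test needs k >= 3")
    y, v = _unpack(effects)
    fx = _fixed_arrays(y, v)
    mu, se = float(fx["mu"]), float(fx["se"])
    denom2 = v - se**2
    if (denom2 <= 0).any():
        if warn is not None:
            warn("begg_variance_floored")
        denom2 = np.maximum(denom2, 1e-12)
    u = (y - mu) / np.sqrt(denom2)
    k = len(effects)
    s = _kendall_s(u, v)
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs
    if k <= BEGG_EXACT_MAX_K:
        p = _exact_kendall_p(s, k)
    else:
        z = s / np.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
        p = float(2 * stats.norm.sf(abs(z)))
    return BiasTestResult(method="begg", statistic=float(tau), p=p)


def forest_table(effects: list[StudyEffect]) -> "pd.DataFrame":
    """Per-study forest-plot data: effect, CI and both model weights."""
    import pandas as pd

    fixed = pool_fixed(effects)
    random = pool_random_dl(effects) if len(effects) >= 2 else fixed
    rows = []
    for e, wf, wr in zip(effects, fixed.weights, random.weights):
        rows.append(
            {
                "study_id": e.study_id,
                "y": e.y,
                "v": e.v,
                "ci_low": e.y - Z95 * e.se,
                "ci_high": e.y + Z95 * e.se,
                "weight_fixed": wf,
                "weight_random": wr,
            }
        )
    return pd.DataFrame(rows)
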