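"""Genome-wide screening around an index gene.

Two pooled quantities are computed for every gene across cohorts: a
random-effects pooled standardized mean difference (case vs control) for
differential-expression calling, and a Fisher-z pooled Pearson correlation
with the index gene for co-expression calling.  Screening thresholds follow
the effect-size convention for multi-cohort expression studies: genes with
pooled SMD > 1 are "up", < -1 "down"; genes with pooled |r| > 0.5 and
pooled-z p < 0.05 are positively / negatively co-expressed; the two screens
are intersected (up & positive, down & negative).  All inequalities are
strict and no multiple-testing correction is applied.

Correlations are computed across all samples of a cohort (cases and
controls mixed), then pooled; a per-group mode is available via
``within_group``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from metaexpr.effect_size import hedges_j
from metaexpr.expression_io import ExpressionCohort
from metaexpr.meta_pool import Z95, _dl_arrays

#: default minimum number of contributing cohorts for any pooled quantity
DEFAULT_MIN_K = 3
#: |r| = 1 is clamped here before the atanh transform
R_CLAMP = 0.9999

SMD_UP = 1.0
R_MIN = 0.5
P_MAX = 0.05

FLAG_COLUMNS = ("up", "down", "pos_corr", "neg_corr", "up_and_pos", "down_and_neg")


def _cohort_gene_effects(
    cohort: ExpressionCohort, genes: pd.Index, estimator: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (y, v) for one cohort aligned to ``genes``; NaN where absent
    or degenerate (zero pooled SD)."""
    vals = cohort.values.reindex(genes)
    case = vals.loc[:, (cohort.groups == "case").to_numpy()].to_numpy(dtype=float)
    ctrl = vals.loc[:, (cohort.groups == "control").to_numpy()].to_numpy(dtype=float)
    n1, n0 = case.shape[1], ctrl.shape[1]
    m1, m0 = case.mean(axis=1), ctrl.mean(axis=1)
    s1 = case.std(axis=1, ddof=1)
    s0 = ctrl.std(axis=1, ddof=1)
    sp2 = ((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / (n1 + n0 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (m1 - m0) / np.sqrt(sp2)
    d = np.where(sp2 > 0, d, np.nan)
    n = n1 + n0
    y = d * hedges_j(n) if estimator == "hedges_g" else d
    v = n / (n1 * n0) + y**2 / (2.0 * n)
    return y, v


def genomewide_smd(
    cohorts: list[ExpressionCohort],
    min_k: int = DEFAULT_MIN_K,
    estimator: str = "hedges_g",
) -> pd.DataFrame:
    """Random-effects pooled SMD per gene across cohorts.

    Genes contribute per cohort only where present with a positive pooled
    SD; genes below ``min_k`` contributing cohorts are omitted (the count of
    omissions is stored in ``DataFrame.attrs["n_omitted"]``).
    """
    if min_k < 2:
        raise ValueError("min_k must be >= 2")
    genes = pd.Index(sorted(set().union(*(c.values.index for c in cohorts))))
    Y = np.full((len(genes), len(cohorts)), np.nan)
    V = np.full_like(Y, np.nan)
    for j, c in enumerate(cohorts):
        Y[:, j], V[:, j] = _cohort_gene_effects(c, genes, estimator)
    dl = _dl_arrays(Y, V)
    keep = dl["k"] >= min_k
    if not keep.any():
        raise ValueError(f"no gene is measurable in at least {min_k} cohorts")
    out = pd.DataFrame(
        {
            "smd": dl["mu"][keep],
            "ci_low": dl["mu"][keep] - Z95 * dl["se"][keep],
            "ci_high": dl["mu"][keep] + Z95 * dl["se"][keep],
            "tau2": dl["tau2"][keep],
            "k": dl["k"][keep].astype(int),
        },
        index=genes[keep],
    )
    out.index.name = "gene"
    out.attrs["n_omitted"] = int((~keep).sum())
    out.attrs["estimator"] = estimator
    return out


def _cohort_correlations(
    cohort: ExpressionCohort, genes: pd.Index, index_gene: str, within_group: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Fisher z vs the index gene and its variance 1/(n-3)."""

    def corr_block(mat: np.ndarray, idx: np.ndarray) -> np.ndarray:
        mat = mat - mat.mean(axis=1, keepdims=True)
        idx = idx - idx.mean()
        denom = np.sqrt((mat**2).sum(axis=1) * (idx**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (mat @ idx) / denom
        return np.where(denom > 0, r, np.nan)

    vals = cohort.values.reindex(genes)
    idx_row = cohort.values.loc[index_gene].to_numpy(dtype=float)
    if within_group:
        zs, ws = [], []
        for g in ("case", "control"):
            sel = (cohort.groups == g).to_numpy()
            if sel.sum() < 4:
                continue
            r = np.clip(corr_block(vals.to_numpy(dtype=float)[:, sel], idx_row[sel]),
                        -R_CLAMP, R_CLAMP)
            zs.append(np.arctanh(r))
            ws.append(np.full(len(genes), sel.sum() - 3.0))
        if not zs:
            return np.full(len(genes), np.nan), np.full(len(genes), np.nan)
        z = np.nansum([zi * wi for zi, wi in zip(zs, ws)], axis=0) / np.sum(ws, axis=0)
        var = 1.0 / np.sum(ws, axis=0)
        return z, var
    n = len(cohort.samples)
    if n < 4:
        return np.full(len(genes), np.nan), np.full(len(genes), np.nan)
    r = np.clip(corr_block(vals.to_numpy(dtype=float), idx_row), -R_CLAMP, R_CLAMP)
    return np.arctanh(r), np.full(len(genes), 1.0 / (n - 3.0))


def correlation_to_index(
    cohorts: list[ExpressionCohort],
    index_gene: str,
    min_k: int = DEFAULT_MIN_K,
    within_group: bool = False,
) -> pd.DataFrame:
    """Fisher-z pooled Pearson correlation of every gene with the index gene.

    Per cohort, r is computed across all samples (or within each group when
    ``within_group``), transformed to z = atanh(r) with variance 1/(n-3),
    pooled across cohorts by DerSimonian-Laird random effects, then
    back-transformed; p tests pooled z != 0.  Cohorts where a gene has zero
    variance are skipped for that gene; |r| = 1 is clamped to 0.9999 and the
    gene flagged degenerate.
    """
    usable = [c for c in cohorts if index_gene in c.values.index]
    if not usable:
        raise ValueError(f"index gene {index_gene!r} absent from all cohorts")
    genes = pd.Index(sorted(set().union(*(c.values.index for c in usable))))
    Zm = np.full((len(genes), len(usable)), np.nan)
    Vm = np.full_like(Zm, np.nan)
    for j, c in enumerate(usable):
        Zm[:, j], Vm[:, j] = _cohort_correlations(c, genes, index_gene, within_group)
    degenerate = np.nanmax(np.abs(Zm), axis=1) >= np.arctanh(R_CLAMP) - 1e-12
    dl = _dl_arrays(Zm, Vm)
    keep = dl["k"] >= min_k
    z_stat = np.where(dl["se"] > 0, dl["mu"] / dl["se"], np.inf)
    p = 2 * stats.norm.sf(np.abs(z_stat))
    out = pd.DataFrame(
        {
            "r_pooled": np.tanh(dl["mu"][keep]),
            "r_ci_low": np.tanh(dl["mu"][keep] - Z95 * dl["se"][keep]),
            "r_ci_high": np.tanh(dl["mu"][keep] + Z95 * dl["se"][keep]),
            "p_r": p[keep],
            "k": dl["k"][keep].astype(int),
            "degenerate_corr": degenerate[keep],
        },
        index=genes[keep],
    )
    out.index.name = "gene"
    out.attrs["index_gene"] = index_gene
    return out


def screen_and_intersect(
    smd_table: pd.DataFrame,
    corr_table: pd.DataFrame,
    smd_up: float = SMD_UP,
    r_min: float = R_MIN,
    p_max: float = P_MAX,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the DEG / co-expression thresholds and intersect the calls.

    Outer-joins the two tables; a flag whose inputs are missing on one side
    is False.  Returns the per-gene record table plus the six set sizes.
    """
    rec = smd_table.rename(columns={"k": "k_smd"}).join(
        corr_table.rename(columns={"k": "k_r"}), how="outer"
    )
    smd = rec["smd"] if "smd" in rec else pd.Series(np.nan, index=rec.index)
    r = rec["r_pooled"] if "r_pooled" in rec else pd.Series(np.nan, index=rec.index)
    p = rec["p_r"] if "p_r" in rec else pd.Series(np.nan, index=rec.index)
    rec["up"] = (smd > smd_up).fillna(False)
    rec["down"] = (smd < -smd_up).fillna(False)
    rec["pos_corr"] = ((r > r_min) & (p < p_max)).fillna(False)
    rec["neg_corr"] = ((r < -r_min) & (p < p_max)).fillna(False)
    rec["up_and_pos"] = rec["up"] & rec["pos_corr"]
    rec["down_and_neg"] = rec["down"] & rec["neg_corr"]
    counts = {f: int(rec[f].sum()) for f in FLAG_COLUMNS}
    return rec, counts


def top_correlate(records: pd.DataFrame, index_gene: str) -> str:
    """The positively co-expressed gene with the highest pooled correlation.

    The index gene itself is excluded; ties break lexicographically.
    """
    if records.empty:
        raise ValueError("empty screen table")
    cand = records[(records["pos_corr"]) & (records.index != index_gene)]
    if cand.empty:
        raise ValueError("no positively co-expressed genes")
    best_r = cand["r_pooled"].max()
    return str(sorted(cand.index[cand["r_pooled"] == best_r])[0])
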