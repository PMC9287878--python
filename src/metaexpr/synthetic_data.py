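"""Synthetic multi-cohort case-control expression data with known truth.

The generator emulates the structure of a multi-platform expression
meta-analysis: K independent case-control cohorts measured on a shared gene
universe, plus literature-style studies known only through per-arm
summaries, plus diagnostic 2x2 tables.  Everything is Gaussian on the log2
scale.

Index gene: its true per-cohort standardized effect delta_k is drawn from
Normal(theta, tau^2) — theta is the grand-mean SMD and tau the
between-cohort SD, the quantities the random-effects pooling estimates.

Partner genes: each partner j mixes the standardized within-cohort index
signal with independent noise, value ~ lambda_j * z_index +
sqrt(1 - lambda_j^2) * eps, so its within-cohort Pearson correlation with
the index gene has expectation lambda_j (the loading is the target
correlation directly).  Because the index signal carries the group shift,
partners inherit an attenuated differential-expression effect as real
co-expressed genes would.

Background genes: a configurable fraction carries a fixed nonzero SMD
(drawn once per gene); the rest are pure noise.

Seeding: one master seed; per-cohort child streams are spawned
deterministically so cohort sets are reproducible regardless of generation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metaexpr.diagnostic_meta import DiagStudy
from metaexpr.expression_io import ArmSummary, ExpressionCohort, LiteratureStudy


def _default_partners() -> dict[str, float]:
    return {f"PARTNER{j:03d}": 0.8 for j in range(1, 21)}


@dataclass
class SimConfig:
    """Ground-truth configuration of the synthetic multi-cohort study.

    Defaults mirror the shape of a typical nine-microarray meta-analysis of
    a strongly upregulated gene: grand-mean SMD ``theta`` = 2.5 with
    between-cohort SD ``tau`` = 1.0 (substantial heterogeneity), 20 partner
    genes at loading 0.8, 10% of background genes differentially expressed,
    and 20 samples per arm per cohort.
    """

    n_cohorts: int = 9
    n_case: int = 20
    n_ctrl: int = 20
    n_genes: int = 500
    index_gene: str = "IDX"
    theta: float = 2.5
    tau: float = 1.0
    partner_loadings: dict[str, float] = field(default_factory=_default_partners)
    background_de: float = 0.10
    background_effect_sd: float = 1.5
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    heavy_tails: bool = False  # t(3 df) residuals for robustness checks
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_cohorts < 1:
            problems.append("n_cohorts must be >= 1")
        if self.n_case < 3 or self.n_ctrl < 3:
            problems.append("per-arm sample sizes must be >= 3")
        if self.n_genes < 1 + len(self.partner_loadings):
            problems.append("n_genes must cover index + partners")
        if self.tau < 0:
            problems.append("tau must be >= 0")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be > 0")
        if not 0 <= self.background_de <= 1:
            problems.append("background_de must be in [0, 1]")
        for g, lam in self.partner_loadings.items():
            if not -1 < lam < 1:
                problems.append(f"loading for {g} must be in (-1, 1)")
        if self.index_gene in self.partner_loadings:
            problems.append("index gene cannot also be a partner")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    @property
    def gene_names(self) -> list[str]:
        n_bg = self.n_genes - 1 - len(self.partner_loadings)
        return (
            [self.index_gene]
            + sorted(self.partner_loadings)
            + [f"G{j:05d}" for j in range(1, n_bg + 1)]
        )


def _residuals(rng: np.random.Generator, size, heavy: bool) -> np.ndarray:
    if heavy:
        # unit-variance t with 3 df
        return rng.standard_t(3, size=size) / np.sqrt(3.0)
    return rng.standard_normal(size)


def simulate_cohorts(config: SimConfig) -> tuple[list[ExpressionCohort], pd.DataFrame]:
    """Generate the cohorts plus the ground-truth table.

    Returns ``(cohorts, truth)`` where ``truth`` has one row per gene with
    columns ``true_smd_mean`` (direct group effect in residual-SD units),
    ``tau`` (between-cohort SD of that effect) and ``lambda`` (target
    correlation with the index gene; 0 for non-partners).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    genes = config.gene_names

    # gene-level truth, shared across cohorts
    baselines = config.baseline_mean + config.baseline_sd * master.standard_normal(
        len(genes)
    )
    lam = np.array([config.partner_loadings.get(g, 0.0) for g in genes])
    beta = np.zeros(len(genes))
    bg = [i for i, g in enumerate(genes)
          if g != config.index_gene and g not in config.partner_loadings]
    n_de = int(round(config.background_de * len(bg)))
    de_idx = master.choice(bg, size=n_de, replace=False) if n_de else np.array([], int)
    beta[de_idx] = config.background_effect_sd * master.standard_normal(n_de)
    tau_col = np.zeros(len(genes))
    tau_col[0] = config.tau
    truth = pd.DataFrame(
        {"true_smd_mean": beta, "tau": tau_col, "lambda": lam}, index=pd.Index(genes, name="gene")
    )
    truth.loc[config.index_gene, "true_smd_mean"] = config.theta

    cohorts = []
    for k, child in enumerate(ss.spawn(config.n_cohorts), start=1):
        rng = np.random.default_rng(child)
        delta_k = config.theta + config.tau * rng.standard_normal()
        n1, n0 = config.n_case, config.n_ctrl
        n = n1 + n0
        is_case = np.concatenate([np.ones(n1), np.zeros(n0)])
        sigma = config.noise_sd

        mat = np.empty((len(genes), n))
        # index gene
        x = baselines[0] + delta_k * sigma * is_case + sigma * _residuals(
            rng, n, config.heavy_tails
        )
        mat[0] = x
        z = (x - x.mean()) / x.std()
        # partners: loading on the standardized index signal
        for i, g in enumerate(genes):
            if i == 0:
                continue
            l = lam[i]
            if l != 0.0:
                eps = _residuals(rng, n, config.heavy_tails)
                mat[i] = baselines[i] + sigma * (l * z + np.sqrt(1 - l**2) * eps)
            else:
                mat[i] = (
                    baselines[i]
                    + beta[i] * sigma * is_case
                    + sigma * _residuals(rng, n, config.heavy_tails)
                )

        cid = f"SYN{k:03d}"
        samples = [f"{cid}_S{j:03d}" for j in range(1, n + 1)]
        values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
        groups = pd.Series(
            np.where(is_case == 1, "case", "control"), index=samples
        )
        cohorts.append(
            ExpressionCohort(cohort_id=cid, values=values, groups=groups,
                             meta={"true_delta": float(delta_k), "seed": config.seed})
        )
    return cohorts, truth


def simulate_literature(
    n_studies: int,
    assay_smd: float,
    n_range: tuple[int, int] = (10, 60),
    assay: str = "PCR",
    seed: int | np.random.Generator = 0,
    study_prefix: str = "LIT",
) -> list[LiteratureStudy]:
    """Literature-style summary studies with study-level SMD expectation
    ``assay_smd``.

    Raw arms are drawn as Normal(assay_smd, 1) vs Normal(0, 1) and
    summarized, so observed SMDs scatter around ``assay_smd`` with the
    proper sampling noise.  ``n_range`` bounds the per-arm sample sizes.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = n_range
    studies = []
    for j in range(1, n_studies + 1):
        n1 = int(rng.integers(lo, hi + 1))
        n0 = int(rng.integers(lo, hi + 1))
        case = assay_smd + rng.standard_normal(n1)
        ctrl = rng.standard_normal(n0)
        studies.append(
            LiteratureStudy(
                study_id=f"{study_prefix}{j:03d}",
                case=ArmSummary(n1, float(case.mean()), float(case.std(ddof=1))),
                control=ArmSummary(n0, float(ctrl.mean()), float(ctrl.std(ddof=1))),
                assay=assay,
            )
        )
    return studies


def simulate_diagnostic(
    sens: float,
    spec: float,
    k: int,
    n_per_arm: int = 50,
    seed: int | np.random.Generator = 0,
) -> list[DiagStudy]:
    """Binomial 2x2 tables at a common true operating point.

    tp ~ Binomial(n_case, sens) and tn ~ Binomial(n_ctrl, spec) per study.
    """
    if not (0 < sens < 1 and 0 < spec < 1):
        raise ValueError("sens and spec must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    studies = []
    for j in range(1, k + 1):
        tp = int(rng.binomial(n_per_arm, sens))
        tn = int(rng.binomial(n_per_arm, spec))
        studies.append(
            DiagStudy(
                study_id=f"DIAG{j:03d}",
                tp=tp, fn=n_per_arm - tp, tn=tn, fp=n_per_arm - tn,
                auc_single=(tp / n_per_arm + tn / n_per_arm) / 2.0,
            )
        )
    return studies
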