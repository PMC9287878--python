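"""Orchestration of the three sub-analyses from a single run configuration.

``run_index_gene_meta`` pools the index gene's SMD across cohorts and
literature studies and attaches the heterogeneity / sensitivity /
publication-bias diagnostics; ``run_diagnostic_meta`` builds per-cohort
Youden 2x2 tables and pools them into a summary ROC; ``run_screen`` runs the
genome-wide DEG + co-expression screen.  Each writes plain-text artifacts
(CSV/TSV/JSON) plus a manifest recording the configuration, seed, package
version and SHA256 of every input file, so that identical configurations
reproduce byte-identical reports (wall-clock timestamps go to a separate
``run_info.json``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metaexpr import __version__
from metaexpr.coexpression_screen import (
    DEFAULT_MIN_K,
    correlation_to_index,
    genomewide_smd,
    screen_and_intersect,
    top_correlate,
)
from metaexpr.diagnostic_meta import SrocResult, pool_bivariate, youden_cutoff
from metaexpr.effect_size import effects_from_literature, smd_from_cohort
from metaexpr.expression_io import (
    CohortValidationError,
    normalize_log2,
    read_cohort,
    read_literature,
)
from metaexpr.meta_pool import (
    MetaResult,
    begg_test,
    egger_test,
    forest_table,
    leave_one_out,
    pool_fixed,
    pool_random_dl,
    subgroup_pool,
)
from metaexpr.synthetic_data import SimConfig, simulate_cohorts, simulate_literature

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML or JSON."""

    cohorts: list[dict] = field(default_factory=list)  # {matrix, metadata, id?}
    literature: str | None = None
    index_gene: str = "IDX"
    estimator: str = "hedges_g"
    model: str = "random"
    smd_up: float = 1.0
    r_min: float = 0.5
    p_max: float = 0.05
    min_k: int = DEFAULT_MIN_K
    subgroups: dict[str, str] = field(default_factory=dict)  # study_id -> label
    omit: list[str] = field(default_factory=list)
    seed: int = 0
    simulate: dict | None = None  # SimConfig overrides; replaces file cohorts

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.smd_up <= 0 or self.r_min <= 0 or self.p_max <= 0:
            raise ValueError("thresholds must be positive")
        if not self.index_gene:
            raise ValueError("index_gene must be named")
        if self.estimator not in ("hedges_g", "cohen_d"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.model not in ("random", "fixed"):
            raise ValueError(f"unknown model {self.model!r}")


def _load_cohorts(config: RunConfig):
    """Cohorts from disk, or freshly simulated when ``simulate`` is set."""
    if config.simulate is not None:
        sim = SimConfig(**{"seed": config.seed, **config.simulate})
        cohorts, truth = simulate_cohorts(sim)
        return [normalize_log2(c, already_log=True) for c in cohorts], truth, sim
    cohorts = []
    for entry in config.cohorts:
        try:
            c = read_cohort(entry["matrix"], entry["metadata"], entry.get("id"))
        except CohortValidationError as exc:
            logger.warning(json.dumps({"event": "cohort_rejected",
                                       "cohort": str(entry), "reason": exc.reason}))
            continue
        cohorts.append(normalize_log2(c))
    return cohorts, None, None


def _meta_to_dict(r: MetaResult) -> dict:
    d = dataclasses.asdict(r)
    d["weights"] = list(d["weights"])
    d["flags"] = list(d["flags"])
    return d


def _sroc_to_dict(r: SrocResult) -> dict:
    d = dataclasses.asdict(r)
    d.pop("curve")
    d["flags"] = list(d["flags"])
    for key in ("sens_ci", "spec_ci", "plr_ci", "nlr_ci", "dor_ci", "fpr_range"):
        d[key] = list(d[key])
    return d


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")


def _manifest(config: RunConfig, outdir: Path, extra: dict) -> None:
    inputs = {}
    for entry in config.cohorts:
        for key in ("matrix", "metadata"):
            p = Path(entry[key])
            if p.exists():
                inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    if config.literature and Path(config.literature).exists():
        p = Path(config.literature)
        inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    _write_json(
        {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "version": __version__,
            "input_sha256": inputs,
            **extra,
        },
        outdir / "manifest.json",
    )
    (outdir / "run_info.json").write_text(
        json.dumps({"finished_unix": time.time()}) + "\n"
    )


def run_index_gene_meta(config: RunConfig, outdir: str | Path) -> dict:
    """Index-gene SMD meta-analysis with the full diagnostic battery."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts, _, _ = _load_cohorts(config)

    effects = []
    subgroup_labels = dict(config.subgroups)
    for c in cohorts:
        if config.index_gene not in c.values.index:
            logger.warning(json.dumps({"event": "index_gene_missing", "cohort": c.cohort_id}))
            continue
        effects.append(smd_from_cohort(c, config.index_gene, config.estimator))
        subgroup_labels.setdefault(c.cohort_id, "expression_matrix")
    if config.literature:
        lit = read_literature(config.literature)
        effects.extend(effects_from_literature(lit, config.estimator))
        for s in lit:
            subgroup_labels.setdefault(s.study_id, s.assay)
    if len(effects) < 2:
        raise ValueError("need at least 2 usable studies")

    pooled = pool_random_dl(effects) if config.model == "random" else pool_fixed(effects)
    report = {
        "k": len(effects),
        "pooled": _meta_to_dict(pooled),
        "fixed": _meta_to_dict(pool_fixed(effects)),
    }
    forest_table(effects).to_csv(outdir / "forest.csv", index=False)

    if len(effects) >= 3:
        loo = leave_one_out(effects)
        pd.DataFrame(
            [
                {"omitted": sid, "pooled": r.pooled, "ci_low": r.ci_low,
                 "ci_high": r.ci_high, "I2": r.I2, "tau2": r.tau2}
                for sid, r in loo.results
            ]
        ).to_csv(outdir / "loo.csv", index=False)
        report["sensitivity_min_i2_omits"] = loo.min_i2_study
        bias = {
            "egger": dataclasses.asdict(egger_test(effects)),
            "begg": dataclasses.asdict(begg_test(effects)),
        }
        _write_json(bias, outdir / "bias.json")
        report["bias"] = bias

    groups, overall = subgroup_pool(effects, subgroup_labels)
    report["subgroups"] = {lab: _meta_to_dict(r) for lab, r in groups.items()}

    if config.omit:
        kept = [e for e in effects if e.study_id not in set(config.omit)]
        if len(kept) >= 2:
            report["after_omission"] = {
                "omitted": sorted(set(config.omit)),
                "pooled": _meta_to_dict(pool_random_dl(kept)),
                "subgroups": {
                    lab: _meta_to_dict(r)
                    for lab, r in subgroup_pool(kept, subgroup_labels)[0].items()
                },
            }
    _write_json(report, outdir / "meta.json")
    _manifest(config, outdir, {"analysis": "index_gene_meta"})
    return report


def run_diagnostic_meta(config: RunConfig, outdir: str | Path) -> dict:
    """Per-cohort Youden dichotomization and summary-ROC pooling."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts, _, _ = _load_cohorts(config)
    studies = []
    for c in cohorts:
        if config.index_gene not in c.values.index:
            continue
        case = c.arm_values(config.index_gene, "case")
        ctrl = c.arm_values(config.index_gene, "control")
        _, study = youden_cutoff(case, ctrl, study_id=c.cohort_id)
        studies.append(study)
    if not studies:
        raise ValueError("no cohort provides the index gene")
    sroc = pool_bivariate(studies)
    pd.DataFrame(
        [
            {"study_id": s.study_id, "tp": s.tp, "fp": s.fp, "fn": s.fn,
             "tn": s.tn, "cutoff": s.cutoff, "auc_single": s.auc_single,
             "sens": s.sens, "spec": s.spec}
            for s in studies
        ]
    ).to_csv(outdir / "tables.csv", index=False)
    _write_json(_sroc_to_dict(sroc), outdir / "sroc.json")
    pd.DataFrame(sroc.curve, columns=["fpr", "sens"]).to_csv(
        outdir / "curve.csv", index=False
    )
    _manifest(config, outdir, {"analysis": "diagnostic_meta"})
    return _sroc_to_dict(sroc)


def run_screen(config: RunConfig, outdir: str | Path) -> dict:
    """Genome-wide DEG + co-expression screen around the index gene."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts, truth, _ = _load_cohorts(config)
    if not cohorts:
        raise ValueError("no usable cohorts")
    smd_table = genomewide_smd(cohorts, min_k=config.min_k, estimator=config.estimator)
    corr_table = correlation_to_index(cohorts, config.index_gene, min_k=config.min_k)
    records, counts = screen_and_intersect(
        smd_table, corr_table, smd_up=config.smd_up,
        r_min=config.r_min, p_max=config.p_max,
    )
    records.to_csv(outdir / "screen.tsv", sep="\t", float_format="%.10g")
    sets = {
        "counts": counts,
        "n_genes": int(len(records)),
        "n_omitted_smd": smd_table.attrs["n_omitted"],
        "thresholds": {"smd_up": config.smd_up, "r_min": config.r_min,
                       "p_max": config.p_max},
        "multiple_testing_correction": "none",
    }
    try:
        sets["top_correlate"] = top_correlate(records, config.index_gene)
    except ValueError:
        sets["top_correlate"] = None
    _write_json(sets, outdir / "sets.json")
    for flag in ("up_and_pos", "down_and_neg"):
        (outdir / f"genes_{flag}.txt").write_text(
            "\n".join(sorted(records.index[records[flag]])) + "\n"
        )
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t")
    _manifest(config, outdir, {"analysis": "screen"})
    return sets


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    return {
        "meta": run_index_gene_meta(config, outdir / "meta"),
        "sroc": run_diagnostic_meta(config, outdir / "sroc"),
        "screen": run_screen(config, outdir / "screen"),
    }
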