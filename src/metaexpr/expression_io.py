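"""Reading, validation and normalization of per-cohort expression matrices.

A cohort is a genes x samples matrix of log2 expression together with a
case/control label per sample.  Cohorts enter the meta-analysis only if both
groups are present with at least three samples each, mirroring the usual
inclusion rule for case-control expression series.  Literature-only studies
(no raw matrix, only per-arm n/mean/SD) are read from a summary CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 3
#: matrices whose maximum exceeds this are assumed to be on the raw
#: (un-logged) intensity scale during auto-detection
LOG_DETECT_MAX = 50.0

GROUPS = ("case", "control")


class CohortValidationError(ValueError):
    """A cohort violates an inclusion rule.

    ``reason`` is a stable machine-readable code such as
    ``"group_too_small"`` or ``"missing_group"``.
    """

    def __init__(self, reason: str, message: str) -> None:
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm summary statistics of one study: n, mean, sample SD (ddof=1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < MIN_GROUP_SIZE:
            raise CohortValidationError(
                "group_too_small", f"arm has n={self.n} < {MIN_GROUP_SIZE}"
            )
        if not np.isfinite(self.mean):
            raise ValueError("arm mean must be finite")
        if not (self.sd >= 0):
            raise ValueError(f"arm SD must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class LiteratureStudy:
    """A study known only through published per-arm summaries."""

    study_id: str
    case: ArmSummary
    control: ArmSummary
    assay: str = "PCR"  # PCR, ELISA or microarray


@dataclass
class ExpressionCohort:
    """One cohort's gene x sample log2 expression matrix with group labels.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns;
    ``groups`` maps each sample id to ``"case"`` or ``"control"``.
    """

    cohort_id: str
    values: pd.DataFrame
    groups: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_case(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_ctrl(self) -> int:
        return int((self.groups == "control").sum())

    def arm_values(self, gene: str, group: str) -> np.ndarray:
        """Expression values of ``gene`` in one arm, as a float vector."""
        if gene not in self.values.index:
            raise KeyError(f"gene_not_found: {gene!r} not in cohort {self.cohort_id}")
        mask = (self.groups == group).to_numpy()
        return self.values.loc[gene].to_numpy(dtype=float)[mask]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise CohortValidationError(
                "duplicate_genes",
                f"cohort {self.cohort_id}: duplicated gene symbols {list(dupes)[:5]}",
            )
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise CohortValidationError(
                "unlabelled_samples",
                f"cohort {self.cohort_id}: samples without group label {missing[:5]}",
            )
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise CohortValidationError(
                "unknown_group", f"cohort {self.cohort_id}: unknown group labels {bad}"
            )
        for g in GROUPS:
            n = int((self.groups == g).sum())
            if n == 0:
                raise CohortValidationError(
                    "missing_group", f"cohort {self.cohort_id}: no {g} samples"
                )
            if n < MIN_GROUP_SIZE:
                raise CohortValidationError(
                    "group_too_small",
                    f"cohort {self.cohort_id}: {g} group has {n} < "
                    f"{MIN_GROUP_SIZE} samples",
                )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise CohortValidationError(
                "nonfinite_values",
                f"cohort {self.cohort_id}: matrix contains non-finite values",
            )


def read_cohort(
    matrix_path: str | Path,
    metadata_path: str | Path,
    cohort_id: str | None = None,
) -> ExpressionCohort:
    """Read a tab-delimited expression matrix plus its sample metadata.

    The matrix has a header row of sample ids and a first column of feature
    ids.  The metadata TSV must contain columns ``sample_id``, ``cohort_id``
    and ``group``; matrix samples absent from the metadata are dropped with a
    logged warning.  Cohorts failing an inclusion rule (a missing group, or a
    group with fewer than three samples) raise :class:`CohortValidationError`
    with the corresponding reason code.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "cohort_id", "group"}
    if not required.issubset(meta.columns):
        raise CohortValidationError(
            "bad_metadata",
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}",
        )
    if cohort_id is None:
        ids = meta["cohort_id"].unique()
        if len(ids) != 1:
            raise CohortValidationError(
                "ambiguous_cohort",
                f"metadata contains {len(ids)} cohorts; pass cohort_id explicitly",
            )
        cohort_id = str(ids[0])
    meta = meta[meta["cohort_id"] == cohort_id]
    group_of = meta.set_index("sample_id")["group"]

    known = [s for s in matrix.columns if s in group_of.index]
    dropped = [s for s in matrix.columns if s not in group_of.index]
    if dropped:
        logger.warning(
            "cohort %s: dropping %d samples absent from metadata: %s",
            cohort_id,
            len(dropped),
            dropped[:5],
        )
    matrix = matrix[known]
    return ExpressionCohort(
        cohort_id=cohort_id,
        values=matrix.astype(float),
        groups=group_of.loc[known],
        meta={"dropped_samples": dropped},
    )


def write_cohort(cohort: ExpressionCohort, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write a cohort back to the TSV pair that :func:`read_cohort` accepts."""
    cohort.values.to_csv(matrix_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {
            "sample_id": cohort.samples,
            "cohort_id": cohort.cohort_id,
            "group": cohort.groups.to_numpy(),
        }
    ).to_csv(metadata_path, sep="\t", index=False)


def normalize_log2(
    cohort: ExpressionCohort, already_log: bool | None = None
) -> ExpressionCohort:
    """Put a cohort on the log2 scale.

    When ``already_log`` is False the matrix is transformed as log2(x + 1)
    (the +1 offset admits zero intensities); when True it passes through
    unchanged.  ``already_log=None`` auto-detects: a matrix whose maximum
    exceeds ``LOG_DETECT_MAX`` is treated as raw intensities.
    """
    vals = cohort.values
    if already_log is None:
        already_log = float(vals.to_numpy().max()) <= LOG_DETECT_MAX
        logger.info(
            "cohort %s: auto-detected already_log=%s", cohort.cohort_id, already_log
        )
    if already_log:
        return cohort
    if (vals.to_numpy() < 0).any():
        raise ValueError(
            f"cohort {cohort.cohort_id}: negative raw values cannot be log-transformed"
        )
    return ExpressionCohort(
        cohort_id=cohort.cohort_id,
        values=np.log2(vals + 1.0),
        groups=cohort.groups,
        meta={**cohort.meta, "log2_applied": True},
    )


def collapse_probes(
    features: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a feature (probe) x sample matrix to one row per gene.

    Among the probes mapping to a gene, the probe with the largest mean
    across samples is kept; unmapped probes are dropped.
    """
    if len(mapping) == 0:
        raise ValueError("empty probe-to-gene mapping")
    mapped = features.loc[[f for f in features.index if f in mapping]].copy()
    if mapped.empty:
        raise ValueError("no matrix feature is covered by the mapping")
    gene = pd.Series({f: mapping[f] for f in mapped.index}, name="gene")
    order = mapped.mean(axis=1)
    # highest-mean probe last within each gene, then keep the last
    keep = (
        pd.DataFrame({"gene": gene, "mean": order})
        .sort_values(["gene", "mean"], kind="stable")
        .groupby("gene", sort=True)
        .tail(1)
    )
    out = mapped.loc[keep.index]
    out.index = pd.Index(keep["gene"], name="gene")
    return out.sort_index()


def read_literature(path: str | Path) -> list[LiteratureStudy]:
    """Read the literature summary CSV.

    Expected columns: study_id, n_case, mean_case, sd_case, n_ctrl,
    mean_ctrl, sd_ctrl, assay.
    """
    tab = pd.read_csv(path)
    required = {
        "study_id",
        "n_case",
        "mean_case",
        "sd_case",
        "n_ctrl",
        "mean_ctrl",
        "sd_ctrl",
        "assay",
    }
    if not required.issubset(tab.columns):
        raise ValueError(
            f"literature table must have columns {sorted(required)}, "
            f"got {list(tab.columns)}"
        )
    studies = []
    for row in tab.itertuples(index=False):
        studies.append(
            LiteratureStudy(
                study_id=str(row.study_id),
                case=ArmSummary(int(row.n_case), float(row.mean_case), float(row.sd_case)),
                control=ArmSummary(int(row.n_ctrl), float(row.mean_ctrl), float(row.sd_ctrl)),
                assay=str(row.assay),
            )
        )
    return studies
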