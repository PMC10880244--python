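"""Domain types and IO for two-arm immunotherapy trial data.

A :class:`TrialDataset` bundles the clinical table of a randomized trial with
an ICI (immune checkpoint inhibitor) arm and a chemotherapy control arm,
together with a genes x patients expression matrix.  Readers/writers use a
single TSV dialect with the literal string ``NA`` as the missing-value
sentinel.  Prediction files are validated with the same three check families
a challenge submission system would apply: type, completeness and sample
matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("ICI", "CHEMO")
SUBCHALLENGES = ("PFS", "OS", "BOR")
DIRECTIONS = ("benefit_high", "benefit_low")

#: exact clinical TSV column order
CLINICAL_COLUMNS = [
    "patient_id", "arm", "sex", "histology", "smoking", "ecog",
    "tmb", "pdl1", "pfs_time", "pfs_event", "os_time", "os_event", "bor_pd",
]

_CATEGORICAL_LEVELS = {
    "arm": {"ICI", "CHEMO"},
    "sex": {"male", "female"},
    "histology": {"squamous", "nonsquamous"},
    "smoking": {"ever", "never"},
}


class TrialDataError(ValueError):
    """Base class for trial-data validation failures."""


class DuplicatePatientIdError(TrialDataError):
    """Clinical table contains a repeated patient identifier."""


class SampleMismatchError(TrialDataError):
    """Expression columns and clinical patient ids do not match exactly."""


class NonNumericOutcomeError(TrialDataError):
    """An outcome/measurement field holds a value that cannot be parsed."""


class EmptyDatasetError(TrialDataError):
    """Dataset has no patients."""


@dataclass
class GeneSet:
    """Named, duplicate-free list of gene identifiers."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise TrialDataError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        dropped = 0
        for g in self.genes:
            if g in seen:
                dropped += 1
            else:
                seen[g] = None
        if dropped:
            warnings.warn(
                f"gene set {self.name!r}: dropped {dropped} duplicate identifier(s)",
                stacklevel=2,
            )
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModelScore:
    """Per-patient real-valued prediction from one model for one sub-challenge.

    ``direction`` declares whether larger values mean better predicted
    outcome on the ICI arm (``benefit_high``) or worse (``benefit_low``).
    """

    model_name: str
    subchallenge: str
    scores: dict[str, float]
    direction: str = "benefit_high"

    def __post_init__(self) -> None:
        if self.subchallenge not in SUBCHALLENGES:
            raise ValueError(f"unknown subchallenge {self.subchallenge!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    def aligned_to(self, patient_ids: Iterable[str]) -> np.ndarray:
        """Score vector in the order of ``patient_ids`` (KeyError if absent)."""
        return np.asarray([self.scores[p] for p in patient_ids], dtype=float)


@dataclass
class TrialDataset:
    """Patients of a two-arm trial: covariates, TMB, PD-L1, expression, outcomes.

    ``clinical`` holds one row per patient with the columns of
    :data:`CLINICAL_COLUMNS`; ``expression`` is a genes x patients DataFrame
    (log-scale, library-normalized abundance) whose columns match
    ``clinical.patient_id`` exactly.
    """

    clinical: pd.DataFrame
    expression: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.clinical = self.clinical.reset_index(drop=True)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def patient_ids(self) -> list[str]:
        return self.clinical["patient_id"].tolist()

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def arm_mask(self, arm: str) -> np.ndarray:
        return (self.clinical["arm"] == arm).to_numpy()

    def subset(self, mask: np.ndarray) -> "TrialDataset":
        clin = self.clinical.loc[np.asarray(mask)].reset_index(drop=True)
        expr = self.expression
        if not expr.empty:
            expr = expr.loc[:, clin["patient_id"].tolist()]
        return TrialDataset(clin, expr)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        clin = self.clinical
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
        if missing_cols:
            raise TrialDataError(f"clinical table lacks columns: {missing_cols}")
        if len(clin) == 0:
            raise EmptyDatasetError("dataset has no patients")
        ids = clin["patient_id"].astype(str)
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise DuplicatePatientIdError(f"duplicate patient ids: {dups}")
        for col, levels in _CATEGORICAL_LEVELS.items():
            bad = set(clin[col].dropna().unique()) - levels
            if bad:
                raise TrialDataError(f"column {col!r} has invalid levels {sorted(bad)}")
        for col in ("tmb", "pdl1", "pfs_time", "pfs_event", "os_time", "os_event", "bor_pd", "ecog"):
            try:
                pd.to_numeric(clin[col])
            except (ValueError, TypeError) as exc:
                raise NonNumericOutcomeError(f"column {col!r} is not numeric: {exc}") from None
        for col in ("pfs_time", "os_time"):
            if not (pd.to_numeric(clin[col]) > 0).all():
                raise TrialDataError(f"column {col!r} must be strictly positive")
        for col in ("pfs_event", "os_event"):
            if not clin[col].isin([0, 1]).all():
                raise TrialDataError(f"column {col!r} must be 0/1")
        bor = clin["bor_pd"].dropna()
        if not bor.isin([0, 1]).all():
            raise TrialDataError("bor_pd must be 0/1 or missing")
        pdl1 = pd.to_numeric(clin["pdl1"]).dropna()
        if len(pdl1) and not ((pdl1 >= 0) & (pdl1 <= 100)).all():
            raise TrialDataError("pdl1 must lie in [0, 100]")
        tmb = pd.to_numeric(clin["tmb"]).dropna()
        if len(tmb) and not (tmb >= 0).all():
            raise TrialDataError("tmb must be nonnegative")
        if not self.expression.empty:
            expr_cols = list(map(str, self.expression.columns))
            if sorted(expr_cols) != sorted(ids):
                only_clin = sorted(set(ids) - set(expr_cols))
                only_expr = sorted(set(expr_cols) - set(ids))
                raise SampleMismatchError(
                    f"expression/clinical sample mismatch: clinical-only={only_clin}, "
                    f"expression-only={only_expr}"
                )

    def require_both_arms(self) -> None:
        present = set(self.clinical["arm"].unique())
        if present != set(ARMS):
            raise TrialDataError(f"both arms required for evaluation, found {sorted(present)}")


# -- IO ---------------------------------------------------------------------

def read_trial(clinical_path, expression_path=None) -> TrialDataset:
    """Read a trial from a clinical TSV and an optional expression TSV."""
    clin = pd.read_csv(
        clinical_path, sep="\t", dtype={"patient_id": str},
        na_values=["NA"], keep_default_na=False,
    )
    clin["patient_id"] = clin["patient_id"].astype(str)
    for col in ("tmb", "pdl1", "pfs_time", "pfs_event", "os_time", "os_event", "bor_pd", "ecog"):
        if col in clin.columns:
            try:
                clin[col] = pd.to_numeric(clin[col])
            except (ValueError, TypeError) as exc:
                raise NonNumericOutcomeError(f"column {col!r} is not numeric: {exc}") from None
    expr = pd.DataFrame()
    if expression_path is not None:
        expr = pd.read_csv(expression_path, sep="\t", index_col=0,
                           na_values=["NA"], keep_default_na=False)
        expr.columns = expr.columns.astype(str)
        expr.index.name = None  # header label "gene_id" is an IO detail
    return TrialDataset(clin, expr)


def write_trial(dataset: TrialDataset, clinical_path, expression_path=None) -> None:
    """Write the trial to TSV; ``NA`` encodes missing values.

    The text encoding round-trips exactly: ``read_trial(write_trial(d)) == d``.
    """
    dataset.validate()
    dataset.clinical.to_csv(clinical_path, sep="\t", index=False, na_rep="NA")
    if expression_path is not None and not dataset.expression.empty:
        out = dataset.expression.copy()
        out.index.name = "gene_id"
        out.to_csv(expression_path, sep="\t", na_rep="NA")


def read_gene_sets(path) -> list[GeneSet]:
    """Parse a GMT file (name, description, genes; tab-separated)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TrialDataError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, _desc, *genes = fields
            sets.append(GeneSet(name, [g for g in genes if g]))
    return sets


def write_gene_sets(gene_sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# -- prediction validation --------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of the submission-style format checks; empty iff all pass."""

    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok


def validate_predictions(dataset: TrialDataset, score: ModelScore) -> ValidationReport:
    """Check a score map for valid type, completeness and sample matching.

    Total function: failures become report entries, never exceptions.
    """
    failures: list[str] = []
    patients = set(dataset.patient_ids)
    scored = set(score.scores)
    for pid in sorted(patients - scored):
        failures.append(f"completeness: patient {pid!r} has no score")
    for pid in sorted(scored - patients):
        failures.append(f"sample matching: scored id {pid!r} not in dataset")
    for pid in sorted(scored & patients):
        val = score.scores[pid]
        if isinstance(val, bool) or not isinstance(val, (int, float, np.integer, np.floating)):
            failures.append(f"type: score for {pid!r} is not numeric ({val!r})")
        elif not np.isfinite(val):
            failures.append(f"type: score for {pid!r} is not finite ({val!r})")
    return ValidationReport(failures)


def read_predictions(path, model_name: str, subchallenge: str,
                     direction: str = "benefit_high") -> ModelScore:
    """Read a two-column predictions TSV (patient_id, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return ModelScore(model_name, subchallenge,
                      dict(zip(df["patient_id"], df["score"].astype(float))),
                      direction)


def write_predictions(score: ModelScore, path) -> None:
    pd.DataFrame({"patient_id": list(score.scores), "score": list(score.scores.values())}
                 ).to_csv(path, sep="\t", index=False)
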