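"""In-memory cohort containers and their on-disk text formats.

A subject is a pair of files:

* ``<id>_matrix.tsv`` — square labeled tab-separated count matrix (header
  row and first column carry node labels);
* ``<id>_waytotals.tsv`` — two columns, node label and waytotal.

The clinical table is one CSV with a documented column set; missing values
are empty cells. All readers validate aggressively (square shape, zero
diagonal, nonnegative counts, positive waytotals, label consistency,
referential integrity of subject ids) because silent coercion of a
malformed connectivity matrix is a classic source of downstream artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("male", "female")
LATERALITIES = ("left", "right", "bilateral", "unclear")

CLINICAL_COLUMNS = (
    "subject_id",
    "drug_resistant",
    "duration_years",
    "age_at_mri",
    "sex",
    "laterality",
    "lesion_dummy",
    "onset_age",
    "operated",
    "ilae_class",
    "followup_years",
)


@dataclass(frozen=True)
class RawConnectome:
    """Asymmetric streamline-count matrix with per-region waytotals."""

    subject_id: str
    labels: tuple[str, ...]
    counts: np.ndarray  # (n, n) nonnegative integers, zero diagonal
    waytotals: np.ndarray  # (n,) positive

    def __post_init__(self):
        counts = np.asarray(self.counts)
        way = np.asarray(self.waytotals, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError(f"{self.subject_id}: duplicate node labels")
        if counts.ndim != 2 or counts.shape != (n, n):
            raise ValueError(f"{self.subject_id}: matrix must be {n}x{n}")
        if np.any(counts < 0):
            i, j = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise ValueError(
                f"{self.subject_id}: negative count at "
                f"({self.labels[i]}, {self.labels[j]})"
            )
        if np.any(np.diag(counts) != 0):
            i = int(np.argmax(np.diag(counts) != 0))
            raise ValueError(
                f"{self.subject_id}: nonzero diagonal at {self.labels[i]}"
            )
        if way.shape != (n,) or np.any(way <= 0):
            raise ValueError(f"{self.subject_id}: waytotals must be positive, length {n}")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "waytotals", way)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's covariates and outcome labels.

    ``None`` encodes missingness throughout: a subject meeting neither
    drug-resistance criterion carries ``drug_resistant=None`` and is
    excluded from group comparisons; ``ilae_class`` is meaningful only for
    operated subjects with at least one year of postoperative follow-up.
    """

    subject_id: str
    drug_resistant: bool | None
    duration_years: float | None
    age_at_mri: float
    sex: str
    laterality: str
    lesion_dummy: int
    onset_age: float
    operated: bool = False
    ilae_class: int | None = None
    followup_years: float | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"{self.subject_id}: sex must be one of {SEXES}")
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"{self.subject_id}: laterality must be one of {LATERALITIES}"
            )
        if self.lesion_dummy not in (0, 1):
            raise ValueError(f"{self.subject_id}: lesion_dummy must be 0 or 1")
        if self.duration_years is not None and self.duration_years < 0:
            raise ValueError(f"{self.subject_id}: negative duration")
        if self.ilae_class is not None and not 1 <= self.ilae_class <= 6:
            raise ValueError(f"{self.subject_id}: ilae_class must be 1..6")

    @property
    def outcome_evaluable(self) -> bool:
        """ILAE outcome usable: operated, class known, follow-up >= 1 year."""
        return (
            self.operated
            and self.ilae_class is not None
            and self.followup_years is not None
            and self.followup_years >= 1.0
        )


# ---------------------------------------------------------------------------
# serialization


def write_connectome(connectome: RawConnectome, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = pd.DataFrame(
        connectome.counts, index=connectome.labels, columns=connectome.labels
    )
    mat.to_csv(directory / f"{connectome.subject_id}_matrix.tsv", sep="\t")
    way = pd.DataFrame(
        {"label": connectome.labels, "waytotal": connectome.waytotals}
    )
    way.to_csv(
        directory / f"{connectome.subject_id}_waytotals.tsv",
        sep="\t",
        index=False,
        float_format="%.17g",
    )


def read_connectome(
    matrix_path: str | Path, waytotal_path: str | Path, subject_id: str | None = None
) -> RawConnectome:
    matrix_path = Path(matrix_path)
    if subject_id is None:
        subject_id = matrix_path.name.removesuffix("_matrix.tsv")
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels = tuple(str(c) for c in mat.columns)
    if tuple(str(i) for i in mat.index) != labels:
        raise ValueError(f"{subject_id}: row labels do not match column labels")
    way = pd.read_csv(waytotal_path, sep="\t", float_precision="round_trip")
    if tuple(str(v) for v in way["label"]) != labels:
        raise ValueError(f"{subject_id}: waytotal labels do not match matrix labels")
    return RawConnectome(
        subject_id=subject_id,
        labels=labels,
        counts=mat.to_numpy(),
        waytotals=way["waytotal"].to_numpy(dtype=float),
    )


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "drug_resistant": None if r.drug_resistant is None else int(r.drug_resistant),
                "duration_years": r.duration_years,
                "age_at_mri": r.age_at_mri,
                "sex": r.sex,
                "laterality": r.laterality,
                "lesion_dummy": r.lesion_dummy,
                "onset_age": r.onset_age,
                "operated": int(r.operated),
                "ilae_class": r.ilae_class,
                "followup_years": r.followup_years,
            }
        )
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    clinical_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(CLINICAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    records = []
    for row in frame.to_dict("records"):
        dr = _opt(row["drug_resistant"])
        ilae = _opt(row["ilae_class"])
        records.append(
            ClinicalRecord(
                subject_id=str(row["subject_id"]),
                drug_resistant=None if dr is None else bool(int(dr)),
                duration_years=_opt(row["duration_years"]),
                age_at_mri=float(row["age_at_mri"]),
                sex=str(row["sex"]),
                laterality=str(row["laterality"]),
                lesion_dummy=int(row["lesion_dummy"]),
                onset_age=float(row["onset_age"]),
                operated=bool(int(row["operated"])),
                ilae_class=None if ilae is None else int(ilae),
                followup_years=_opt(row["followup_years"]),
            )
        )
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in clinical table")
    return records


def read_cohort(
    matrix_dir: str | Path, clinical_path: str | Path
) -> tuple[list[RawConnectome], list[ClinicalRecord]]:
    """Load and cross-validate a cohort directory + clinical table.

    Errors on duplicate subject ids, on matrices whose label sets disagree
    across subjects, and on clinical rows referencing unknown subjects.
    """
    matrix_dir = Path(matrix_dir)
    matrix_files = sorted(matrix_dir.glob("*_matrix.tsv"))
    if not matrix_files:
        raise FileNotFoundError(f"no *_matrix.tsv files in {matrix_dir}")
    connectomes = []
    for mpath in matrix_files:
        sid = mpath.name.removesuffix("_matrix.tsv")
        wpath = matrix_dir / f"{sid}_waytotals.tsv"
        if not wpath.exists():
            raise FileNotFoundError(f"{sid}: missing waytotal file {wpath}")
        connectomes.append(read_connectome(mpath, wpath, subject_id=sid))
    ids = [c.subject_id for c in connectomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids among matrix files")
    ref = connectomes[0].labels
    for c in connectomes[1:]:
        if c.labels != ref:
            raise ValueError(
                f"label mismatch: subject {c.subject_id} differs from {ids[0]}"
            )
    clinical = read_clinical(clinical_path)
    known = set(ids)
    for r in clinical:
        if r.subject_id not in known:
            raise ValueError(
                f"clinical row references unknown subject {r.subject_id!r}"
            )
    return connectomes, clinical
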