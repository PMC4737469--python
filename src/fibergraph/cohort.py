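"""Subjects and cohort metadata: group labels, nuisance covariates, matrices.

A cohort is a list of subjects, each carrying a diagnostic group label
("AD" or "NC" by default), the four nuisance covariates regressed out before
inference (age, gender, education, intracranial volume), and one
connectivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .atlas import RoiAtlas, load_atlas
from .matrices import ConnectivityMatrix, read_matrix, write_matrix

__all__ = ["Subject", "read_cohort", "write_cohort", "covariate_frame"]

#: Covariate columns used in the nuisance regression, in design order.
COVARIATE_COLUMNS = ("age", "gender", "education", "icv")


@dataclass(frozen=True)
class Subject:
    """One participant: identity, group, covariates, connectivity matrix.

    ``gender`` is coded as a 0/1 indicator with female = 1; ``icv`` is the
    intracranial volume in mm^3.
    """

    id: str
    group: str
    age: float
    gender: int
    education: float
    icv: float
    matrix: ConnectivityMatrix

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"subject {self.id}: age must be positive")
        if self.education <= 0:
            raise ValueError(f"subject {self.id}: education must be positive")
        if self.icv <= 0:
            raise ValueError(f"subject {self.id}: icv must be positive")
        if self.gender not in (0, 1):
            raise ValueError(
                f"subject {self.id}: gender must be 0/1 (female = 1)"
            )


def covariate_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    """Covariate table in design order, indexed by subject id."""
    return pd.DataFrame(
        {
            "age": [s.age for s in cohort],
            "gender": [s.gender for s in cohort],
            "education": [s.education for s in cohort],
            "icv": [s.icv for s in cohort],
        },
        index=[s.id for s in cohort],
    )


def read_cohort(
    metadata_path: str | Path, atlas: RoiAtlas | None = None
) -> list[Subject]:
    """Read a cohort from a metadata table plus per-subject matrix files.

    The tab-separated metadata table has columns ``id, group, age, gender,
    education, icv, matrix_path``; matrix paths are resolved relative to the
    metadata file's directory.
    """
    atlas = atlas or load_atlas()
    metadata_path = Path(metadata_path)
    table = pd.read_csv(metadata_path, sep="\t")
    required = {"id", "group", "age", "gender", "education", "icv", "matrix_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing columns {sorted(missing)}")
    base = metadata_path.parent
    subjects = []
    for row in table.itertuples(index=False):
        mpath = Path(row.matrix_path)
        if not mpath.is_absolute():
            mpath = base / mpath
        subjects.append(
            Subject(
                id=str(row.id),
                group=str(row.group),
                age=float(row.age),
                gender=int(row.gender),
                education=float(row.education),
                icv=float(row.icv),
                matrix=read_matrix(mpath, atlas),
            )
        )
    return subjects


def write_cohort(
    cohort: Sequence[Subject],
    out_dir: str | Path,
    dialect: str = "full",
    atlas: RoiAtlas | None = None,
) -> Path:
    """Write metadata.tsv plus one matrix file per subject; returns the
    metadata path."""
    atlas = atlas or load_atlas()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.id}.tsv"
        write_matrix(s.matrix, out_dir / fname, dialect=dialect, atlas=atlas)
        rows.append(
            dict(
                id=s.id,
                group=s.group,
                age=s.age,
                gender=s.gender,
                education=s.education,
                icv=s.icv,
                matrix_path=fname,
            )
        )
    meta = out_dir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
    return meta
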