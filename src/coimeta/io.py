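"""Plain-text (TSV) readers and writers for cohorts and expression studies.

Every artifact the pipeline exchanges between stages is a header-bearing TSV
so any stage can be re-run standalone or inspected by hand.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError
from .synthetic import ExpressionStudy

COHORT_COLUMNS = ["patient_id", "age", "uf", "ec", "other_gyn"]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort file {path} missing columns: {missing}")
    return df


def write_study(study: ExpressionStudy, matrix_path: str | Path, groups_path: str | Path) -> None:
    """Write one study as a genes x samples matrix TSV plus a sample->group sidecar."""
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.6g")
    study.groups.rename_axis("sample").to_frame("group").to_csv(groups_path, sep="\t")


def read_study(
    study_id: str,
    matrix_path: str | Path,
    groups_path: str | Path,
    region: str = "unknown",
    study_date: int = 0,
) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    groups_df = pd.read_csv(groups_path, sep="\t", index_col="sample")
    if "group" not in groups_df.columns:
        raise DataError(f"groups sidecar {groups_path} lacks a 'group' column")
    groups = groups_df["group"]

    extra = set(matrix.columns) - set(groups.index)
    if extra:
        raise DataError(
            f"study {study_id}: matrix columns absent from groups sidecar: {sorted(extra)}"
        )
    orphan = set(groups.index) - set(matrix.columns)
    if orphan:
        raise DataError(
            f"study {study_id}: sidecar samples absent from matrix: {sorted(orphan)}"
        )
    return ExpressionStudy(
        study_id=study_id, matrix=matrix, groups=groups, region=region, study_date=study_date
    )


def write_study_collection(
    studies: list[ExpressionStudy], out_dir: str | Path, truth: dict[str, float] | None = None
) -> Path:
    """Write each study plus a manifest TSV; returns the manifest path.

    Manifest columns: study_id, matrix_path, groups_path, region, date
    (paths relative to the manifest's directory). A ground-truth TSV
    (gene, planted_lfc) is written alongside when ``truth`` is given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in studies:
        mpath = f"{s.study_id}_matrix.tsv"
        gpath = f"{s.study_id}_groups.tsv"
        write_study(s, out_dir / mpath, out_dir / gpath)
        rows.append(
            {
                "study_id": s.study_id,
                "matrix_path": mpath,
                "groups_path": gpath,
                "region": s.region,
                "date": s.study_date,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if truth is not None:
        pd.DataFrame(
            {"gene": list(truth), "planted_lfc": list(truth.values())}
        ).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest


def read_study_manifest(path: str | Path) -> list[ExpressionStudy]:
    """Load a study collection from a manifest TSV.

    Validates each study: every matrix column must be annotated in the groups
    sidecar and labels restricted to {case, control}.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"study manifest not found: {path}")
    base = path.parent
    df = pd.read_csv(path, sep="\t")
    required = ["study_id", "matrix_path", "groups_path", "region", "date"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"manifest {path} missing columns: {missing}")
    studies = []
    for row in df.itertuples(index=False):
        mpath = base / row.matrix_path
        gpath = base / row.groups_path
        if not mpath.exists():
            raise DataError(f"study {row.study_id}: matrix file not found: {mpath}")
        if not gpath.exists():
            raise DataError(f"study {row.study_id}: groups file not found: {gpath}")
        studies.append(
            read_study(row.study_id, mpath, gpath, region=row.region, study_date=int(row.date))
        )
    return studies
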