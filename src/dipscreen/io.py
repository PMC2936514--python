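"""TSV readers/writers and schema validation for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import INSTANCE_COLUMNS

__all__ = [
    "read_expression",
    "read_instances",
    "read_calls",
    "read_relations",
    "read_tanimoto",
    "read_atc",
    "write_matrix",
    "validate_dataset",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Probe x instance log2 matrix: first column probe id, header = instance ids."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique()[:5]
        raise ValueError(f"{path}: duplicate probe ids {list(dupes)}")
    if matrix.isna().to_numpy().any():
        bad = matrix.index[matrix.isna().any(axis=1)][:5]
        raise ValueError(f"{path}: NaN values (e.g. probes {list(bad)})")
    return matrix


def read_instances(path: str | Path) -> pd.DataFrame:
    instances = pd.read_csv(path, sep="\t")
    missing = [c for c in INSTANCE_COLUMNS if c not in instances.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if instances.instance_id.duplicated().any():
        dupes = instances.instance_id[instances.instance_id.duplicated()][:5]
        raise ValueError(f"{path}: duplicate instance ids {list(dupes)}")
    bad_batches = [
        str(b) for b, g in instances.groupby("batch_id")
        if g.cell_line.nunique() > 1 or g.platform.nunique() > 1
    ]
    if bad_batches:
        raise ValueError(
            f"{path}: batches spanning several cell lines/platforms: {bad_batches[:5]}"
        )
    instances["is_control"] = instances.is_control.astype(bool)
    return instances


def read_calls(path: str | Path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = set(pd.unique(calls.to_numpy().ravel()))
    bad = values - {"P", "A", "M"}
    if bad:
        raise ValueError(f"{path}: detection calls outside P/A/M: {sorted(bad)[:5]}")
    return calls


def read_relations(path: str | Path) -> pd.DataFrame:
    relations = pd.read_csv(path, sep="\t")
    required = {"drug_id", "gene_id", "action", "confidence", "channel"}
    missing = required - set(relations.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out_of_range = ~relations.confidence.between(0.0, 1.0)
    if out_of_range.any():
        raise ValueError(f"{path}: confidences outside [0, 1] in rows "
                         f"{list(relations.index[out_of_range][:5])}")
    return relations


def read_tanimoto(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"drug_a", "drug_b", "tanimoto"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def read_atc(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"drug_id", "atc_code"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t")


def validate_dataset(
    expression: pd.DataFrame,
    instances: pd.DataFrame,
    calls: pd.DataFrame | None = None,
) -> None:
    """Cross-check tables before any computation; abort naming the offender."""
    missing = [i for i in instances.instance_id if i not in expression.columns]
    if missing:
        raise ValueError(
            f"instances missing from the expression matrix: {missing[:5]}"
        )
    if calls is not None:
        if not calls.index.equals(expression.index):
            raise ValueError("detection-call matrix probe ids differ from expression")
        missing = [i for i in instances.instance_id if i not in calls.columns]
        if missing:
            raise ValueError(
                f"instances missing from the detection-call matrix: {missing[:5]}"
            )
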