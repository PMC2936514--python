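"""Instance filtering, per-batch centering, replicate merging, presence flags.

The normalization at the heart of the pipeline is *population mean-centering*:
for every probe and every production batch, subtract the mean over all drug
treatments in that batch (not the vehicle controls).  With batches of 26+
heterogeneous treatments this estimates the batch background far more stably
than the handful of controls and simultaneously down-weights shared stress
responses.  The classical treatment-vs-control baseline is provided as
:func:`control_center_batch` for comparison.

Conventions fixed here (all exposed as parameters):

* batch-size filter keeps batches with **strictly more than** ``min_batch_size``
  treatments (default 25);
* vehicle controls are dropped from the analysis set;
* per (drug, cell line), only instances at the **highest** tested concentration
  are kept; ties at the maximum are replicates and all remain;
* presence thresholds ("at least half" for ranking, "one tenth" for the target
  screen) are inclusive (>=);
* 'marginal' detection calls do not count as present;
* centering happens before replicate merging; profiles from different array
  platforms are never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_instances",
    "select_highest_concentration",
    "mean_center_batch",
    "control_center_batch",
    "merge_replicates",
    "assign_presence",
    "PresenceSet",
]

INSTANCE_COLUMNS = [
    "instance_id", "drug_id", "cell_line", "batch_id", "platform",
    "concentration_value", "concentration_unit", "is_control",
]


@dataclass(frozen=True)
class PresenceSet:
    """Probes called 'Present in a cell line' at a given threshold fraction."""

    cell_line: str
    threshold_fraction: float
    probes: frozenset[str]

    def __contains__(self, probe: str) -> bool:
        return probe in self.probes

    def __len__(self) -> int:
        return len(self.probes)


def _require_columns(instances: pd.DataFrame) -> None:
    missing = [c for c in INSTANCE_COLUMNS if c not in instances.columns]
    if missing:
        raise ValueError(f"instance table is missing columns: {missing}")


def filter_instances(
    instances: pd.DataFrame,
    min_batch_size: int = 25,
    allowed_platforms: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Keep treatments from large-enough batches on allowed platforms.

    A batch survives iff it contains strictly more than *min_batch_size*
    treatment (non-control) instances.  Vehicle controls are dropped.
    *allowed_platforms* maps cell line -> allowed platform identifiers; cell
    lines not listed (or ``None``) accept any platform.
    """
    _require_columns(instances)
    treatments = instances[~instances.is_control.astype(bool)]
    if allowed_platforms is not None:
        keep = treatments.apply(
            lambda r: r.platform in allowed_platforms.get(r.cell_line, {r.platform}),
            axis=1,
        )
        treatments = treatments[keep]
    batch_sizes = treatments.groupby("batch_id").size()
    big = set(batch_sizes.index[batch_sizes > min_batch_size])
    out = treatments[treatments.batch_id.isin(big)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no treatment instances survive the batch-size/platform filter")
    return out


def select_highest_concentration(instances: pd.DataFrame) -> pd.DataFrame:
    """Per (drug, cell line), keep only instances at the maximum concentration.

    Equal-maximum instances are replicates and all remain.  Mixed concentration
    units within one (drug, cell line) are not comparable and raise.
    """
    _require_columns(instances)
    kept = []
    for (drug, cell), group in instances.groupby(["drug_id", "cell_line"], sort=False):
        units = group.concentration_unit.unique()
        if len(units) > 1:
            raise ValueError(
                f"mixed concentration units {sorted(units)} for drug {drug!r} "
                f"in cell line {cell!r}"
            )
        top = group.concentration_value.max()
        kept.append(group[group.concentration_value == top])
    if not kept:
        return instances.iloc[0:0].copy()
    return pd.concat(kept).sort_index().reset_index(drop=True)


def _columns_by_batch(
    matrix: pd.DataFrame, instances: pd.DataFrame, include_controls: bool
) -> dict[str, list[str]]:
    sub = instances if include_controls else instances[~instances.is_control.astype(bool)]
    missing = [i for i in sub.instance_id if i not in matrix.columns]
    if missing:
        raise ValueError(f"instances absent from expression matrix: {missing[:5]}")
    return {
        str(batch): list(group.instance_id)
        for batch, group in sub.groupby("batch_id", sort=False)
    }


def mean_center_batch(matrix: pd.DataFrame, instances: pd.DataFrame) -> pd.DataFrame:
    """Subtract, per probe, the mean over all drug treatments in each batch.

    Returns the centered treatment columns (controls, if present in
    *instances*, are excluded from both the mean and the output).  Batches with
    a single treatment column are rejected: their centered values would be
    identically zero.
    """
    _require_columns(instances)
    if matrix.isna().to_numpy().any():
        raise ValueError("expression matrix contains NaN values")
    by_batch = _columns_by_batch(matrix, instances, include_controls=False)
    pieces = []
    for batch, cols in by_batch.items():
        if len(cols) < 2:
            raise ValueError(f"batch {batch!r} has a single treatment: cannot mean-center")
        block = matrix[cols]
        pieces.append(block.sub(block.mean(axis=1), axis=0))
    centered = pd.concat(pieces, axis=1)
    order = [i for i in matrix.columns if i in centered.columns]
    return centered[order]


def control_center_batch(matrix: pd.DataFrame, instances: pd.DataFrame) -> pd.DataFrame:
    """Subtract, per probe, the mean of the vehicle-control columns per batch.

    The treatment-vs-control baseline the population mean-centering replaces.
    Every batch must carry at least one control instance.
    """
    _require_columns(instances)
    if matrix.isna().to_numpy().any():
        raise ValueError("expression matrix contains NaN values")
    is_ctrl = instances.is_control.astype(bool)
    pieces = []
    for batch, group in instances.groupby("batch_id", sort=False):
        ctrl_cols = list(group.instance_id[is_ctrl.loc[group.index]])
        treat_cols = list(group.instance_id[~is_ctrl.loc[group.index]])
        if not ctrl_cols:
            raise ValueError(f"batch {batch!r} has no control instances")
        if not treat_cols:
            continue
        background = matrix[ctrl_cols].mean(axis=1)
        pieces.append(matrix[treat_cols].sub(background, axis=0))
    if not pieces:
        raise ValueError("no treatment columns to center")
    centered = pd.concat(pieces, axis=1)
    order = [i for i in matrix.columns if i in centered.columns]
    return centered[order]


def merge_replicates(
    matrix: pd.DataFrame, instances: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Average replicate treatment columns into one profile per (drug, cell line).

    *matrix* must already be centered.  Profiles measured on different array
    platforms within one cell line are kept apart: if a cell line spans several
    platforms, its profile groups are keyed ``"<cell_line>|<platform>"``,
    otherwise plainly ``"<cell_line>"``.  Returns a mapping from that group key
    to a probe x drug DataFrame of amplitude profiles ("average difference").
    """
    _require_columns(instances)
    treatments = instances[~instances.is_control.astype(bool)]
    treatments = treatments[treatments.instance_id.isin(matrix.columns)]
    result: dict[str, pd.DataFrame] = {}
    for cell, cgroup in treatments.groupby("cell_line", sort=False):
        platforms = list(dict.fromkeys(cgroup.platform))
        for platform in platforms:
            pgroup = cgroup[cgroup.platform == platform]
            key = cell if len(platforms) == 1 else f"{cell}|{platform}"
            profiles = {}
            for drug, dgroup in pgroup.groupby("drug_id", sort=True):
                profiles[drug] = matrix[list(dgroup.instance_id)].mean(axis=1)
            result[key] = pd.DataFrame(profiles)
    return result


def assign_presence(
    calls: pd.DataFrame,
    instances: pd.DataFrame,
    threshold_fraction: float,
    cell_line: str | None = None,
) -> PresenceSet | dict[str, PresenceSet]:
    """Flag probes called 'P' in >= *threshold_fraction* of a cell line's treatments.

    With *cell_line* given, returns that single :class:`PresenceSet`;
    otherwise a dict keyed by cell line.  Marginal ('M') calls never count.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    _require_columns(instances)
    treatments = instances[~instances.is_control.astype(bool)]
    cells = [cell_line] if cell_line is not None else sorted(treatments.cell_line.unique())
    out: dict[str, PresenceSet] = {}
    for cell in cells:
        cols = list(treatments.instance_id[treatments.cell_line == cell])
        cols = [c for c in cols if c in calls.columns]
        if not cols:
            raise ValueError(f"no treatment instances for cell line {cell!r}")
        frac = (calls[cols] == "P").sum(axis=1) / len(cols)
        probes = frozenset(calls.index[frac >= threshold_fraction])
        out[cell] = PresenceSet(cell, threshold_fraction, probes)
    return out[cell_line] if cell_line is not None else out
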