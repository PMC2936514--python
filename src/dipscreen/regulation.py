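"""Screen for drug-induced differential regulation of drug-target mRNAs.

For every (target gene, action) hypothesis the mean-centered expression change
of the target's probes under drugs annotated to act on it is compared against
the change under every other drug treatment in the compendium — the feedback-
loop question: does inhibiting (or activating) a protein shift the mRNA of
that same protein?

Statistics, per hypothesis:

* per cell line, a Welch two-sample t-test of per-drug target amplitude,
  targeting drugs vs all other drugs;
* across cell lines, a two-way fixed-effects ANOVA (no interaction) on the
  pooled per-drug amplitudes with factors targeting-group and cell line,
  reporting the targeting-group p-value; with a single cell line this reduces
  to a one-way ANOVA, whose F equals the pooled-variance t squared.  A
  ``pooled`` one-way alternative ignoring the cell-line factor is selectable.
* Benjamini-Hochberg q-values over the whole hypothesis family; the default
  significance call is q < 0.05.

Relation filters mirror the interaction-database conventions: confidence
strictly above 0.7, experimental/curated-database evidence channels only, and
'binding' actions folded into 'inhibition' (with a manual-override hook for
the relations where binding is known to mean something else).  Targets with
no probe called present in at least one tenth of a cell line's treatments are
excluded in that cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_relations",
    "filter_expressed_targets",
    "target_amplitudes",
    "target_change_test",
    "RegulationResult",
    "screen",
    "multiple_testing",
    "multi_target_report",
]

ALLOWED_CHANNELS = ("experimental", "database")


def filter_relations(
    relations: pd.DataFrame,
    min_confidence: float = 0.7,
    channels: tuple[str, ...] = ALLOWED_CHANNELS,
    action_overrides: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """High-confidence relations from trusted channels, with binding folded in.

    Keeps rows with confidence strictly greater than *min_confidence* and an
    evidence channel in *channels*.  'binding' actions become 'inhibition'
    unless *action_overrides* maps the (drug_id, gene_id) pair to something
    else.
    """
    out = relations[
        (relations.confidence > min_confidence)
        & relations.channel.isin(set(channels))
    ].copy()
    overrides = action_overrides or {}

    def _action(row):
        override = overrides.get((row.drug_id, row.gene_id))
        if override is not None:
            return override
        return "inhibition" if row.action == "binding" else row.action

    out["action"] = [_action(r) for r in out.itertuples()]
    return out.reset_index(drop=True)


def filter_expressed_targets(
    relations: pd.DataFrame,
    presence: dict[str, object],
    probe_map: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Restrict each target to the cell lines where it is expressed.

    *presence* maps cell line -> PresenceSet computed at threshold 1/10.
    *probe_map* maps gene -> probe ids (defaults to the relation table's own
    ``probe_id`` column).  Returns the relations whose target is expressed in
    at least one cell line, plus a gene -> expressed-cell-lines map (a gene
    absent in some cell line is simply not tested there).
    """
    if probe_map is None:
        probe_map = {
            gene: set(group.probe_id)
            for gene, group in relations.groupby("gene_id")
        }
    expressed_in: dict[str, set[str]] = {}
    for gene, probes in probe_map.items():
        cells = set()
        for cell, pres in presence.items():
            pres_probes = pres.probes if hasattr(pres, "probes") else pres
            if probes & set(pres_probes):
                cells.add(cell)
        expressed_in[gene] = cells
    keep = relations.gene_id.map(lambda g: bool(expressed_in.get(g)))
    return relations[keep].reset_index(drop=True), expressed_in


def target_amplitudes(
    profiles: pd.DataFrame,
    target_probes: set[str],
    presence_probes: set[str] | None = None,
) -> pd.Series:
    """Per-drug target amplitude: mean over the target's (present) probes.

    Multi-probe targets are reduced by an unweighted mean over the probes that
    are both mapped to the gene and present in the cell line.
    """
    probes = set(target_probes)
    if presence_probes is not None:
        probes &= set(presence_probes)
    probes &= set(profiles.index)
    if not probes:
        raise ValueError("no present probe maps to the target in this cell line")
    return profiles.loc[sorted(probes)].mean(axis=0)


@dataclass
class RegulationResult:
    """One (target gene, action) hypothesis of the feedback screen."""

    gene_id: str
    action: str
    targeting_drugs: tuple[str, ...]
    per_cell_line: pd.DataFrame      # cell_line, n_targeting, mean_targeting,
                                     # mean_background, t, p
    anova_p: float
    direction: str                   # 'up' | 'down'
    mean_difference: float
    q_value: float = np.nan
    significant: bool = False


def _anova_group_p(long: pd.DataFrame, design: str) -> float:
    """Targeting-group p-value from the fixed-effects ANOVA on pooled amplitudes."""
    n_cells = long.cell_line.nunique()
    if design == "two_way" and n_cells > 1:
        model = ols("value ~ C(group) + C(cell_line)", data=long).fit()
    else:
        model = ols("value ~ C(group)", data=long).fit()
    table = anova_lm(model, typ=2)
    return float(table.loc["C(group)", "PR(>F)"])


def target_change_test(
    profiles: dict[str, pd.DataFrame],
    gene_id: str,
    action: str,
    target_probes: set[str],
    targeting_drugs: set[str],
    presence: dict[str, object] | None = None,
    expressed_cells: set[str] | None = None,
    anova_design: str = "two_way",
) -> RegulationResult | None:
    """Test one (target, action) hypothesis against the treatment background.

    *profiles* maps cell line -> probe x drug amplitude-profile matrix.  Cell
    lines where the target is not expressed (per *expressed_cells*) are
    skipped, mirroring the blank columns of a per-cell-line report.  Returns
    ``None`` when no cell line yields >= 2 observations per group.
    """
    if anova_design not in ("two_way", "pooled"):
        raise ValueError("anova_design must be 'two_way' or 'pooled'")
    rows = []
    long_parts = []
    for cell, prof in profiles.items():
        if expressed_cells is not None and cell not in expressed_cells:
            continue
        pres = None
        if presence is not None and cell in presence:
            p = presence[cell]
            pres = set(p.probes if hasattr(p, "probes") else p)
        try:
            amplitude = target_amplitudes(prof, target_probes, pres)
        except ValueError:
            continue
        targeting = sorted(set(targeting_drugs) & set(amplitude.index))
        background = sorted(set(amplitude.index) - set(targeting_drugs))
        if len(targeting) < 1 or len(background) < 2:
            continue
        t_vals = amplitude[targeting].to_numpy()
        b_vals = amplitude[background].to_numpy()
        if len(t_vals) >= 2:
            t, p = stats.ttest_ind(t_vals, b_vals, equal_var=False)
        else:
            t, p = np.nan, np.nan  # Welch test needs >= 2 targeting observations
        rows.append((cell, len(t_vals), float(t_vals.mean()), float(b_vals.mean()),
                     float(t), float(p)))
        long_parts.append(pd.DataFrame({
            "value": np.concatenate([t_vals, b_vals]),
            "group": ["target"] * len(t_vals) + ["background"] * len(b_vals),
            "cell_line": cell,
        }))
    if not long_parts:
        return None
    long = pd.concat(long_parts, ignore_index=True)
    if (long.group == "target").sum() < 2 or (long.group == "background").sum() < 2:
        return None
    anova_p = _anova_group_p(long, anova_design)
    pooled_diff = (
        long.value[long.group == "target"].mean()
        - long.value[long.group == "background"].mean()
    )
    per_cell = pd.DataFrame(
        rows,
        columns=["cell_line", "n_targeting", "mean_targeting", "mean_background",
                 "t", "p"],
    )
    return RegulationResult(
        gene_id=gene_id,
        action=action,
        targeting_drugs=tuple(sorted(targeting_drugs)),
        per_cell_line=per_cell,
        anova_p=anova_p,
        direction="up" if pooled_diff > 0 else "down",
        mean_difference=float(pooled_diff),
    )


def multiple_testing(
    results: list[RegulationResult], alpha: float = 0.05
) -> list[RegulationResult]:
    """Attach Benjamini-Hochberg q-values across the whole hypothesis family."""
    if not results:
        return results
    p = np.array([r.anova_p for r in results])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv < alpha)
    return results


def screen(
    profiles: dict[str, pd.DataFrame],
    relations: pd.DataFrame,
    presence: dict[str, object],
    probe_map: dict[str, set[str]] | None = None,
    min_confidence: float = 0.7,
    alpha: float = 0.05,
    anova_design: str = "two_way",
    pre_filtered: bool = False,
) -> list[RegulationResult]:
    """Full feedback screen: filter relations, test every (gene, action), BH-correct."""
    rel = relations if pre_filtered else filter_relations(rel_confidence(relations),
                                                          min_confidence)
    rel, expressed_in = filter_expressed_targets(rel, presence, probe_map)
    if probe_map is None:
        probe_map = {
            gene: set(group.probe_id) for gene, group in rel.groupby("gene_id")
        }
    results = []
    for (gene, action), group in rel.groupby(["gene_id", "action"], sort=True):
        res = target_change_test(
            profiles,
            gene_id=gene,
            action=action,
            target_probes=probe_map[gene],
            targeting_drugs=set(group.drug_id),
            presence=presence,
            expressed_cells=expressed_in.get(gene),
            anova_design=anova_design,
        )
        if res is not None:
            results.append(res)
    return multiple_testing(results, alpha=alpha)


def rel_confidence(relations: pd.DataFrame) -> pd.DataFrame:
    """Hook for schema normalization before filtering (identity for conforming tables)."""
    required = {"drug_id", "gene_id", "action", "confidence", "channel"}
    missing = required - set(relations.columns)
    if missing:
        raise ValueError(f"relation table missing columns: {sorted(missing)}")
    return relations


def results_table(results: list[RegulationResult]) -> pd.DataFrame:
    """Flatten screen results into a per-hypothesis report table."""
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "action": r.action,
            "n_targeting_drugs": len(r.targeting_drugs),
            "anova_p": r.anova_p,
            "q_value": r.q_value,
            "significant": r.significant,
            "direction": r.direction,
            "mean_difference": r.mean_difference,
        }
        for cell_row in r.per_cell_line.itertuples():
            row[f"t_{cell_row.cell_line}"] = cell_row.t
            row[f"p_{cell_row.cell_line}"] = cell_row.p
            row[f"mean_targeting_{cell_row.cell_line}"] = cell_row.mean_targeting
        rows.append(row)
    return pd.DataFrame(rows)


def multi_target_report(
    relations: pd.DataFrame, results: list[RegulationResult]
) -> pd.DataFrame:
    """Drugs acting on >= 2 targets, with their significantly regulated targets.

    Lists, per multi-target drug: total target count, count of its targets
    called significant, and the (gene, direction) pairs of those calls.
    """
    significant = {
        (r.gene_id, r.action): r.direction for r in results if r.significant
    }
    rows = []
    for drug, group in relations.groupby("drug_id", sort=True):
        targets = sorted(set(group.gene_id))
        if len(targets) < 2:
            continue
        hits = []
        for rel in group.itertuples():
            direction = significant.get((rel.gene_id, rel.action))
            if direction is not None:
                hits.append((rel.gene_id, direction))
        hits = sorted(set(hits))
        rows.append({
            "drug_id": drug,
            "n_targets": len(targets),
            "n_regulated_targets": len({g for g, _ in hits}),
            "regulated_targets": ";".join(f"{g}:{d}" for g, d in hits),
        })
    report = pd.DataFrame(rows, columns=["drug_id", "n_targets",
                                         "n_regulated_targets", "regulated_targets"])
    return report
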