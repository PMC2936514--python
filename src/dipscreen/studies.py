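"""Canonical in-silico study designs exercising the whole pipeline.

Three synthetic-compendium studies, with one source of truth for their
conditions so that tests, scripts and documentation all run the same designs:

* **category study** — one cell line, three 26-treatment batches with two
  vehicle controls each and a strong batch term; replicated drugs populate the
  same-drug categories.  Instance-level DIPS scores are stratified into the
  four drug/batch categories under both centering modes to show that the
  control-based background carries a batch effect which population
  mean-centering removes.
* **similarity study** — three cell lines, 48 drugs of which 12 triplets share
  their expression signature ("structurally similar" groups); the combined
  DIPS score is benchmarked by ROC against the known similar pairs.
* **regulation study** — two single-batch cell lines, 30 drugs, six targets
  with five annotated drugs each; run with no injected feedback for
  calibration and with a 3-sigma injected effect for power/recovery.

Problem sizes are chosen so each study finishes in minutes on one core while
keeping enough pairs/hypotheses for stable statistics.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .benchmark import labels_from_ground_truth, pair_key, roc
from .dips import CategoryAnalysis, categorize_pairs, combine_cell_lines, dips_matrix
from .preprocess import (
    assign_presence,
    control_center_batch,
    filter_instances,
    mean_center_batch,
    merge_replicates,
    select_highest_concentration,
)
from .ranking import extract_signature, rank_profile
from .regulation import filter_relations, screen
from .synthetic import SimulationConfig, SyntheticDataset, generate_dataset

__all__ = [
    "CATEGORY_STUDY",
    "SIMILARITY_STUDY",
    "REGULATION_NULL_STUDY",
    "REGULATION_POWER_STUDY",
    "preprocess_dataset",
    "run_category_study",
    "run_similarity_study",
    "permuted_auc_mean",
    "run_regulation_study",
]

CATEGORY_STUDY = SimulationConfig(
    n_probes=1500, n_drugs=60, n_cell_lines=1, batches_per_cell_line=3,
    treatments_per_batch=26, replicate_rate=0.3, signature_size=100,
    signature_amplitude=0.6, batch_sd=0.5, noise_sd=0.3,
    n_similar_groups=0, n_relations=0, controls_per_batch=2,
    low_concentration_rate=0.0, seed=0,
)

SIMILARITY_STUDY = SimulationConfig(
    n_probes=1500, n_drugs=48, n_cell_lines=3, batches_per_cell_line=2,
    treatments_per_batch=26, replicate_rate=0.1, signature_size=100,
    signature_amplitude=0.6, batch_sd=0.5, noise_sd=0.3,
    n_similar_groups=12, similar_group_size=3, n_relations=0,
    controls_per_batch=2, low_concentration_rate=0.2, seed=0,
)

REGULATION_NULL_STUDY = SimulationConfig(
    n_probes=300, n_drugs=30, n_cell_lines=2, batches_per_cell_line=1,
    treatments_per_batch=30, replicate_rate=0.0, signature_size=30,
    signature_amplitude=0.6, batch_sd=0.4, noise_sd=0.3,
    n_similar_groups=0, n_relations=30, drugs_per_target=5,
    regulation_effect=0.9, fraction_regulated=0.0,
    controls_per_batch=0, low_concentration_rate=0.0, seed=0,
)

#: identical conditions with every target truly regulated at |delta| = 3 sigma_e
REGULATION_POWER_STUDY = replace(REGULATION_NULL_STUDY, fraction_regulated=1.0)

SIGNATURE_N = 100


def preprocess_dataset(
    ds: SyntheticDataset, center: str = "population", min_batch_size: int = 25
):
    """Filter + center + presence; returns (centered matrix, filtered instances,
    presence sets at the ranking threshold)."""
    filtered = select_highest_concentration(
        filter_instances(ds.instances, min_batch_size))
    if center == "population":
        centered = mean_center_batch(ds.expression, filtered)
    elif center == "control":
        ctrl = ds.instances[
            ds.instances.is_control.astype(bool)
            & ds.instances.batch_id.isin(set(filtered.batch_id))
        ]
        centered = control_center_batch(
            ds.expression, pd.concat([filtered, ctrl], ignore_index=True))
    else:
        raise ValueError("center must be 'population' or 'control'")
    presence = assign_presence(ds.calls, filtered, 0.5)
    return centered, filtered, presence


def run_category_study(seed: int) -> dict[str, CategoryAnalysis]:
    """Instance-level DIPS category analysis under both centering modes."""
    ds = generate_dataset(replace(CATEGORY_STUDY, seed=seed))
    out = {}
    for center in ("control", "population"):
        centered, filtered, presence = preprocess_dataset(ds, center)
        out[center] = categorize_pairs(
            centered, filtered, presence, signature_n=SIGNATURE_N)
    return out


def _profile_matrices(ds: SyntheticDataset, center: str):
    centered, filtered, presence = preprocess_dataset(ds, center)
    profiles = merge_replicates(centered, filtered)
    matrices = {}
    for key, frame in profiles.items():
        cell = key.split("|")[0]
        present = presence[cell].probes
        rankings = {d: rank_profile(frame[d], present, d, cell)
                    for d in frame.columns}
        sigs = {d: extract_signature(rankings[d], SIGNATURE_N) for d in rankings}
        matrices[key] = dips_matrix(rankings, sigs)
    return matrices


def run_similarity_study(seed: int) -> dict:
    """Combined-DIPS ROC against ground-truth similar pairs, both centerings."""
    ds = generate_dataset(replace(SIMILARITY_STUDY, seed=seed))
    labels = labels_from_ground_truth(
        ds.truth.similar_pairs, [f"D{i:03d}" for i in range(ds.config.n_drugs)])
    out = {"labels": labels}
    for center in ("population", "control"):
        combined = combine_cell_lines(_profile_matrices(ds, center))
        out[f"combined_{center}"] = combined
        out[f"roc_{center}"] = roc(combined, labels)
    return out


def permuted_auc_mean(
    combined: pd.DataFrame, labels, n_permutations: int = 20, seed: int = 0
) -> float:
    """Mean AUC after shuffling the pair labels (the benchmark's null)."""
    from .benchmark import PairLabelSet

    rng = np.random.default_rng(seed)
    keys = list(labels.labels)
    values = np.array([labels.labels[k] for k in keys])
    aucs = []
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        shuffled = PairLabelSet(dict(zip(keys, perm.tolist())), "permuted")
        aucs.append(roc(combined, shuffled).auc)
    return float(np.mean(aucs))


def run_regulation_study(config: SimulationConfig, seeds) -> pd.DataFrame:
    """Feedback screen over several seeded compendia; one row per hypothesis.

    Columns: seed, gene_id, action, q_value, significant, direction,
    truly_regulated, true_direction.
    """
    rows = []
    for seed in seeds:
        ds = generate_dataset(replace(config, seed=seed))
        filtered = select_highest_concentration(
            filter_instances(ds.instances, 25))
        centered = mean_center_batch(ds.expression, filtered)
        profiles = merge_replicates(centered, filtered)
        presence = assign_presence(ds.calls, filtered, 0.1)
        relations = filter_relations(ds.relations)
        results = screen(profiles, relations, presence, pre_filtered=True)
        truth = ds.truth.relations[ds.truth.relations.channel == "experimental"]
        truth_by_gene = truth.groupby("gene_id").agg(
            regulated=("regulated", "any"), effect=("effect", "sum"))
        for r in results:
            t = truth_by_gene.loc[r.gene_id]
            rows.append({
                "seed": seed,
                "gene_id": r.gene_id,
                "action": r.action,
                "q_value": r.q_value,
                "significant": r.significant,
                "direction": r.direction,
                "truly_regulated": bool(t.regulated),
                "true_direction": "up" if t.effect > 0 else
                                  ("down" if t.effect < 0 else "none"),
            })
    return pd.DataFrame(rows)
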