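"""Synthetic drug-perturbation compendia with known ground truth.

Emulates a CMap-like experiment: several cultured cell lines, each profiled in
production batches of ~26+ treatment arrays, where every array measures one
drug treatment (optionally replicated, optionally at two concentrations) on a
shared probe panel.  The generative model is additive on the log2 scale:

    x[p, t] = mu_p + b[batch(t), p] + c_t * s[drug(t), p]
              + delta_effect * 1{p targets a regulated relation of drug(t)}
              + eps[p, t]

with a per-probe baseline ``mu_p ~ Normal(7, 1)``, a batch effect
``b ~ Normal(0, batch_sd^2)`` drawn independently per batch x probe, a sparse
drug signature ``s`` (nonzero on exactly ``signature_size`` probes, shared
verbatim between drugs of the same "structurally similar" group), a
concentration factor ``c_t`` (1 at the drug's highest concentration, 1/1.5 at
a lower one) and iid noise ``eps ~ Normal(0, noise_sd^2)``.

Drug-target feedback regulation is injected by adding ``delta_effect`` to the
target probe in every instance of a targeting drug: for relations flagged
regulated, ``delta_effect = regulation_effect`` for inhibitors (compensatory
up-regulation when the config value is positive) and ``-regulation_effect``
for activators (agonist-induced down-regulation).  The concentration factor is
deliberately not applied to the feedback term, so the injected effect is an
exact, known constant for every instance of a targeting drug.

Everything the downstream pipeline consumes is produced here: expression
matrix, instance sheet, detection-call matrix, drug-target relation table,
pairwise chemical-similarity (Tanimoto-like) table and ATC-like codes — plus a
:class:`GroundTruth` record that stores the latent truth losslessly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = ["SimulationConfig", "GroundTruth", "SyntheticDataset", "generate_dataset"]

CELL_LINE_POOL = ("MCF7", "PC3", "HL60")
DEFAULT_PLATFORM = "HT_HG-U133A"

#: log2-scale action sign of an injected feedback effect.  A positive
#: ``regulation_effect`` means compensatory up-regulation under inhibitors and
#: agonist-induced down-regulation under activators.
ACTION_SIGN = {"inhibition": +1.0, "activation": -1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic compendium (defaults are the study conditions)."""

    n_probes: int = 1500
    n_drugs: int = 48
    n_cell_lines: int = 3
    batches_per_cell_line: int = 2
    treatments_per_batch: int = 26
    replicate_rate: float = 0.15
    signature_size: int = 100
    signature_amplitude: float = 1.0
    batch_sd: float = 0.5
    noise_sd: float = 0.3
    n_similar_groups: int = 8
    similar_group_size: int = 2
    n_relations: int = 40
    drugs_per_target: int = 5
    regulation_effect: float = 1.0
    fraction_regulated: float = 0.25
    present_rate: float = 0.6
    controls_per_batch: int = 0
    low_concentration_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_probes": self.n_probes,
            "n_drugs": self.n_drugs,
            "n_cell_lines": self.n_cell_lines,
            "batches_per_cell_line": self.batches_per_cell_line,
            "treatments_per_batch": self.treatments_per_batch,
            "signature_size": self.signature_size,
            "drugs_per_target": self.drugs_per_target,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.treatments_per_batch < 2:
            raise ValueError(
                "treatments_per_batch < 2: per-batch mean-centering is undefined"
            )
        if self.signature_size >= self.n_probes:
            raise ValueError("signature_size must be < n_probes")
        if not 1 <= self.n_cell_lines <= len(CELL_LINE_POOL):
            raise ValueError(f"n_cell_lines must be in 1..{len(CELL_LINE_POOL)}")
        for name in ("replicate_rate", "fraction_regulated", "present_rate",
                     "low_concentration_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        slots = self.batches_per_cell_line * self.treatments_per_batch
        if slots < self.n_drugs:
            raise ValueError(
                f"batch grid has {slots} slots per cell line but n_drugs={self.n_drugs}"
            )
        if self.n_similar_groups * self.similar_group_size > self.n_drugs:
            raise ValueError("similar groups require more drugs than available")
        if self.n_relations < 0:
            raise ValueError("n_relations must be >= 0")


@dataclass
class GroundTruth:
    """Latent truth of one simulated compendium."""

    signatures: dict[str, frozenset[str]]          # drug -> signal probe ids
    signature_values: pd.DataFrame                  # probe x drug sparse-as-dense effects
    similar_pairs: set[tuple[str, str]]             # sorted drug-id pairs sharing a group
    group_of: dict[str, int]                        # drug -> similar-group index (groups only)
    relations: pd.DataFrame                         # relation table + regulated/direction
    atc: pd.DataFrame                               # drug_id, atc_code
    tanimoto: pd.DataFrame                          # drug_a, drug_b, tanimoto
    instances: pd.DataFrame                         # full instance sheet
    batch_effects: dict[str, np.ndarray] = field(default_factory=dict)

    def is_similar(self, drug_a: str, drug_b: str) -> bool:
        return tuple(sorted((drug_a, drug_b))) in self.similar_pairs


@dataclass
class SyntheticDataset:
    """Bundle of every table the pipeline consumes, plus the ground truth."""

    expression: pd.DataFrame        # probe x instance log2 values
    instances: pd.DataFrame         # instance sheet (one row per array)
    calls: pd.DataFrame             # probe x instance detection calls P/A/M
    relations: pd.DataFrame         # drug_id, gene_id, probe_id, action, confidence, channel
    tanimoto: pd.DataFrame          # drug_a, drug_b, tanimoto
    atc: pd.DataFrame               # drug_id, atc_code
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        """Write all tables as TSV (plus ground truth as TSV/JSON) into *outdir*."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        self.instances.to_csv(outdir / "instances.tsv", sep="\t", index=False)
        self.calls.to_csv(outdir / "calls.tsv", sep="\t")
        self.relations.to_csv(outdir / "relations.tsv", sep="\t", index=False)
        self.tanimoto.to_csv(outdir / "tanimoto.tsv", sep="\t", index=False)
        self.atc.to_csv(outdir / "atc.tsv", sep="\t", index=False)
        self.truth.relations.to_csv(outdir / "truth_relations.tsv", sep="\t", index=False)
        pairs = pd.DataFrame(sorted(self.truth.similar_pairs), columns=["drug_a", "drug_b"])
        pairs.to_csv(outdir / "truth_similar_pairs.tsv", sep="\t", index=False)
        sigs = {drug: sorted(probes) for drug, probes in self.truth.signatures.items()}
        (outdir / "truth_signatures.json").write_text(json.dumps(sigs, indent=1))
        (outdir / "sim_config.json").write_text(json.dumps(asdict(self.config), indent=1))


def _atc_code(group: int | None, member: int, drug_index: int) -> str:
    """WHO-format ATC-like code (L DD L L DD).

    Drugs in the same similar group share the 5-character level-4 prefix
    (fourth/fifth characters 'GA'); ungrouped drugs get unique prefixes marked
    'XB', so no spurious level-4 sharing can occur.
    """
    if group is not None:
        prefix = f"{chr(65 + group % 26)}{group % 100:02d}GA"
        return f"{prefix}{member % 100:02d}"
    prefix = f"{chr(65 + drug_index % 26)}{drug_index % 100:02d}XB"
    return f"{prefix}01"


def _design_cell_line(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    cell_line: str,
    drugs: list[str],
    replicate_pool: list[str],
) -> pd.DataFrame:
    """Lay out one cell line's instances across its batch grid."""
    n_slots = cfg.batches_per_cell_line * cfg.treatments_per_batch
    assigned = list(drugs)
    extra = n_slots - len(drugs)
    if extra > 0:
        pool = replicate_pool if replicate_pool else list(drugs)
        assigned.extend(pool[i % len(pool)] for i in range(extra))
    order = rng.permutation(len(assigned))
    assigned = [assigned[i] for i in order]

    rows = []
    platform = DEFAULT_PLATFORM
    for b in range(cfg.batches_per_cell_line):
        batch_id = f"{cell_line}.b{b:02d}"
        batch_drugs = assigned[b * cfg.treatments_per_batch:(b + 1) * cfg.treatments_per_batch]
        for drug in batch_drugs:
            rows.append((drug, cell_line, batch_id, platform, False))
        for c in range(cfg.controls_per_batch):
            rows.append(("CTRL", cell_line, batch_id, platform, True))
    frame = pd.DataFrame(rows, columns=["drug_id", "cell_line", "batch_id", "platform",
                                        "is_control"])

    # concentrations: highest concentration carries the full signature amplitude;
    # for a fraction of multiply-profiled drugs one instance is a lower dose.
    frame["concentration_value"] = 10.0
    frame["concentration_unit"] = "uM"
    for drug, idx in frame[~frame.is_control].groupby("drug_id").groups.items():
        if len(idx) >= 2 and rng.random() < cfg.low_concentration_rate:
            frame.loc[idx[-1], "concentration_value"] = 1.0
    return frame


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full compendium under *config*; same seed => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    probes = np.array([f"P{i:05d}" for i in range(config.n_probes)])
    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    cells = list(CELL_LINE_POOL[: config.n_cell_lines])

    mu = rng.normal(7.0, 1.0, size=config.n_probes)

    # --- drug-target relations (targets drawn from abundant, signature-free probes)
    n_targets = (
        int(np.ceil(config.n_relations / config.drugs_per_target))
        if config.n_relations else 0
    )
    abundant = np.flatnonzero(mu >= 7.0)
    if n_targets > len(abundant):
        raise ValueError("not enough abundant probes to host the requested targets")
    target_probe_idx = rng.choice(abundant, size=n_targets, replace=False)
    target_genes = [f"GENE{i:03d}" for i in range(n_targets)]

    # --- drug signatures (shared verbatim within similar groups)
    free = np.setdiff1d(np.arange(config.n_probes), target_probe_idx)
    group_of: dict[str, int] = {}
    for g in range(config.n_similar_groups):
        for m in range(config.similar_group_size):
            group_of[drugs[g * config.similar_group_size + m]] = g

    sig_values = pd.DataFrame(0.0, index=probes, columns=drugs)
    signatures: dict[str, frozenset[str]] = {}
    group_sig_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for d_i, drug in enumerate(drugs):
        g = group_of.get(drug)
        if g is not None and g in group_sig_cache:
            idx, signs = group_sig_cache[g]
        else:
            idx = rng.choice(free, size=config.signature_size, replace=False)
            signs = rng.choice([-1.0, 1.0], size=config.signature_size)
            if g is not None:
                group_sig_cache[g] = (idx, signs)
        sig_values.iloc[idx, d_i] = config.signature_amplitude * signs
        signatures[drug] = frozenset(probes[idx])

    similar_pairs: set[tuple[str, str]] = set()
    for g in range(config.n_similar_groups):
        members = [d for d, gg in group_of.items() if gg == g]
        for a, b in itertools.combinations(sorted(members), 2):
            similar_pairs.add((a, b))

    # --- relation table with injected regulation flags
    rel_rows = []
    drug_cycle = list(rng.permutation(drugs))
    regulated_targets = set(
        rng.choice(n_targets, size=round(config.fraction_regulated * n_targets),
                   replace=False)
    ) if n_targets else set()
    rel_count = 0
    for t_i in range(n_targets):
        action = "inhibition" if t_i % 2 == 0 else "activation"
        for _ in range(config.drugs_per_target):
            if rel_count >= config.n_relations:
                break
            drug = drug_cycle[rel_count % len(drug_cycle)]
            regulated = t_i in regulated_targets
            effect = config.regulation_effect * ACTION_SIGN[action] if regulated else 0.0
            rel_rows.append(
                (drug, target_genes[t_i], probes[target_probe_idx[t_i]], action,
                 float(rng.uniform(0.75, 0.95)), "experimental", regulated, effect)
            )
            rel_count += 1
    # distractor relations that must fall to the confidence/channel filter
    for j in range(config.n_relations // 4):
        t_i = int(rng.integers(0, n_targets)) if n_targets else 0
        if not n_targets:
            break
        rel_rows.append(
            (drug_cycle[(rel_count + j) % len(drug_cycle)], target_genes[t_i],
             probes[target_probe_idx[t_i]], "inhibition",
             float(rng.uniform(0.2, 0.69)), "text_mining", False, 0.0)
        )
    truth_relations = pd.DataFrame(
        rel_rows,
        columns=["drug_id", "gene_id", "probe_id", "action", "confidence", "channel",
                 "regulated", "effect"],
    )
    relations = truth_relations.drop(columns=["regulated", "effect"]).copy()

    # per-drug injected effect vector (sum over its regulated relations)
    injected = pd.DataFrame(0.0, index=probes, columns=drugs)
    for row in truth_relations.itertuples():
        if row.regulated and row.drug_id in injected.columns:
            injected.loc[row.probe_id, row.drug_id] += row.effect

    # --- instance design
    n_rep_pool = round(config.replicate_rate * config.n_drugs)
    replicate_pool = list(rng.permutation(drugs)[:n_rep_pool])
    frames = []
    for cell in cells:
        frames.append(_design_cell_line(rng, config, cell, drugs, replicate_pool))
    instances = pd.concat(frames, ignore_index=True)
    instances.insert(0, "instance_id",
                     [f"I{i:05d}" for i in range(len(instances))])

    # --- expression matrix
    n_inst = len(instances)
    values = np.tile(mu[:, None], (1, n_inst))
    batch_effects: dict[str, np.ndarray] = {}
    for batch_id, idx in instances.groupby("batch_id").groups.items():
        b = rng.normal(0.0, config.batch_sd, size=config.n_probes)
        batch_effects[str(batch_id)] = b
        values[:, np.asarray(idx)] += b[:, None]
    sig_arr = sig_values.to_numpy()
    inj_arr = injected.to_numpy()
    drug_pos = {d: i for i, d in enumerate(drugs)}
    max_conc = instances[~instances.is_control].groupby(
        ["cell_line", "drug_id"])["concentration_value"].max()
    for col, row in enumerate(instances.itertuples()):
        if row.is_control:
            continue
        d_i = drug_pos[row.drug_id]
        top = max_conc.loc[(row.cell_line, row.drug_id)]
        factor = 1.0 if row.concentration_value == top else 1.0 / 1.5
        values[:, col] += factor * sig_arr[:, d_i] + inj_arr[:, d_i]
    values += rng.normal(0.0, config.noise_sd, size=values.shape)

    expression = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                              columns=instances.instance_id.to_numpy())

    # --- detection calls: presence probability logistic in the baseline abundance,
    # with the midpoint placed so the average presence rate ~ present_rate.
    midpoint = 7.0 + norm.ppf(1.0 - config.present_rate)
    p_present = expit((mu - midpoint) / 0.4)
    draws = rng.random((config.n_probes, n_inst))
    marginal = rng.random((config.n_probes, n_inst)) < 0.2
    calls_arr = np.where(draws[:, :] < p_present[:, None], "P",
                         np.where(marginal, "M", "A"))
    calls = pd.DataFrame(calls_arr, index=expression.index, columns=expression.columns)

    # --- chemical-similarity and ATC-like labels
    tan_rows = []
    for a, b in itertools.combinations(drugs, 2):
        if (a, b) in similar_pairs:
            tan = 0.9
        else:
            tan = float(rng.uniform(0.0, 0.6))
        tan_rows.append((a, b, tan))
    tanimoto = pd.DataFrame(tan_rows, columns=["drug_a", "drug_b", "tanimoto"])

    member_counter: dict[int, int] = {}
    atc_rows = []
    for d_i, drug in enumerate(drugs):
        g = group_of.get(drug)
        m = member_counter.get(g, 0) if g is not None else 0
        if g is not None:
            member_counter[g] = m + 1
        atc_rows.append((drug, _atc_code(g, m, d_i)))
    atc = pd.DataFrame(atc_rows, columns=["drug_id", "atc_code"])

    truth = GroundTruth(
        signatures=signatures,
        signature_values=sig_values,
        similar_pairs=similar_pairs,
        group_of=group_of,
        relations=truth_relations,
        atc=atc,
        tanimoto=tanimoto,
        instances=instances,
        batch_effects=batch_effects,
    )
    return SyntheticDataset(
        expression=expression,
        instances=instances,
        calls=calls,
        relations=relations,
        tanimoto=tanimoto,
        atc=atc,
        truth=truth,
        config=config,
    )
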