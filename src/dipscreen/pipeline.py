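"""End-to-end pipeline driver: filter -> center -> merge -> rank -> score -> screen.

Stage order mirrors the workflow the package implements: instance filtering
(batch size, platforms, vehicle controls, highest concentration), per-batch
centering (population mean or biological controls), replicate merging into
per-(drug, cell line) amplitude profiles, two-step ranking and signature
extraction, pairwise DIPS per cell line and combined, ROC benchmarking
against chemical-similarity and ATC labels, and the drug-target regulation
screen.  Every stage writes its artifact to the run directory; a JSON
manifest records the configuration, seed and per-stage row counts.  Runs are
deterministic: identical config + inputs => byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .benchmark import labels_from_atc, labels_from_tanimoto, roc
from .dips import combine_cell_lines, dips_matrix
from .preprocess import (
    assign_presence,
    control_center_batch,
    filter_instances,
    mean_center_batch,
    merge_replicates,
    select_highest_concentration,
)
from .ranking import extract_signature, rank_profile
from .regulation import filter_relations, results_table, screen

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the standard thresholds."""

    expression: str = ""
    instances: str = ""
    calls: str = ""
    relations: str = ""
    tanimoto: str = ""
    atc: str = ""
    out_dir: str = "run"
    min_batch_size: int = 25
    center_mode: str = "population"           # 'population' | 'control'
    presence_threshold_ranking: float = 0.5
    presence_threshold_regulation: float = 0.1
    signature_n: int = 250
    ks_weighting: str = "classic"
    confidence_threshold: float = 0.7
    fpr_cutoff: float = 0.1
    fdr_alpha: float = 0.05
    anova_design: str = "two_way"
    allowed_platforms: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.center_mode not in ("population", "control"):
            raise ValueError("center_mode must be 'population' or 'control'")
        for name in ("presence_threshold_ranking", "presence_threshold_regulation"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0.0 < self.fpr_cutoff <= 1.0:
            raise ValueError("fpr_cutoff must be in (0, 1]")
        if self.signature_n < 1:
            raise ValueError("signature_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: PipelineConfig, log=print) -> dict:
    """Execute all stages and write artifacts + manifest into ``config.out_dir``.

    Returns the manifest dict.  No stage mutates its inputs; intermediates are
    saved so each stage can be re-run independently.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    expression = dio.read_expression(config.expression)
    instances = dio.read_instances(config.instances)
    calls = dio.read_calls(config.calls) if config.calls else None
    dio.validate_dataset(expression, instances, calls)
    manifest["stages"]["input"] = {
        "instances": len(instances), "probes": len(expression)}
    log(f"[input] {len(instances)} instances x {len(expression)} probes")

    filtered = filter_instances(
        instances, config.min_batch_size,
        config.allowed_platforms or None)
    filtered = select_highest_concentration(filtered)
    manifest["stages"]["filter"] = {"instances": len(filtered)}
    log(f"[filter] {len(filtered)} treatment instances retained")
    filtered.to_csv(out / "instances_filtered.tsv", sep="\t", index=False)

    if config.center_mode == "population":
        centered = mean_center_batch(expression, filtered)
    else:
        ctrl = instances[
            instances.is_control.astype(bool)
            & instances.batch_id.isin(set(filtered.batch_id))
        ]
        centered = control_center_batch(
            expression, pd.concat([filtered, ctrl], ignore_index=True))
    dio.write_matrix(centered, out / "centered.tsv")
    manifest["stages"]["center"] = {
        "mode": config.center_mode, "columns": centered.shape[1]}

    profiles = merge_replicates(centered, filtered)
    manifest["stages"]["merge"] = {
        key: frame.shape[1] for key, frame in profiles.items()}
    log(f"[merge] profiles per cell line: "
        f"{ {k: v.shape[1] for k, v in profiles.items()} }")
    for key, frame in profiles.items():
        dio.write_matrix(frame, out / f"profiles_{key.replace('|', '_')}.tsv")

    rankings: dict[str, dict] = {}
    signatures: dict[str, dict] = {}
    presence_rank = presence_reg = None
    if calls is not None:
        presence_rank = assign_presence(
            calls, filtered, config.presence_threshold_ranking)
        presence_reg = assign_presence(
            calls, filtered, config.presence_threshold_regulation)
    matrices = {}
    for key, frame in profiles.items():
        cell = key.split("|")[0]
        present = (
            presence_rank[cell].probes if presence_rank is not None
            else frozenset(frame.index)
        )
        rankings[key] = {}
        signatures[key] = {}
        for drug in frame.columns:
            ranked = rank_profile(frame[drug], present, drug_id=drug, cell_line=cell)
            rankings[key][drug] = ranked
            signatures[key][drug] = extract_signature(ranked, config.signature_n)
        matrices[key] = dips_matrix(
            rankings[key], signatures[key], weighting=config.ks_weighting)
        dio.write_matrix(matrices[key], out / f"dips_{key.replace('|', '_')}.tsv")
    combined = combine_cell_lines(matrices)
    dio.write_matrix(combined, out / "dips_combined.tsv")
    n_scores = sum(m.shape[0] * (m.shape[0] - 1) // 2 for m in matrices.values())
    manifest["stages"]["dips"] = {"pairwise_scores": n_scores}
    log(f"[dips] {n_scores} pairwise scores across {len(matrices)} profile groups")

    long_rows = []
    for key, m in matrices.items():
        for a in m.index:
            for b in m.columns:
                if a < b:
                    long_rows.append((a, b, key, m.loc[a, b]))
    pd.DataFrame(long_rows, columns=["drug_a", "drug_b", "cell_line", "score"]).to_csv(
        out / "dips_long.tsv", sep="\t", index=False)

    bench_rows = []
    if config.tanimoto:
        labels = labels_from_tanimoto(dio.read_tanimoto(config.tanimoto))
        r = roc(combined, labels, config.fpr_cutoff)
        bench_rows.append(("tanimoto", r.auc, r.partial_auc, r.n_positive, r.n_negative))
    if config.atc:
        labels = labels_from_atc(dio.read_atc(config.atc))
        r = roc(combined, labels, config.fpr_cutoff)
        bench_rows.append(("atc_level4", r.auc, r.partial_auc,
                           r.n_positive, r.n_negative))
    if bench_rows:
        bench = pd.DataFrame(
            bench_rows,
            columns=["label_source", "auc", "partial_auc", "n_positive", "n_negative"])
        bench.to_csv(out / "benchmark.tsv", sep="\t", index=False)
        manifest["stages"]["benchmark"] = bench.to_dict("records")
        log(f"[benchmark] {bench.to_dict('records')}")

    if config.relations and calls is not None:
        relations = filter_relations(
            dio.read_relations(config.relations), config.confidence_threshold)
        cell_profiles = {key.split("|")[0]: frame for key, frame in profiles.items()}
        results = screen(
            cell_profiles, relations, presence_reg,
            alpha=config.fdr_alpha, anova_design=config.anova_design,
            pre_filtered=True)
        table = results_table(results)
        table.to_csv(out / "regulation.tsv", sep="\t", index=False)
        manifest["stages"]["regulation"] = {
            "hypotheses": len(table),
            "significant": int(table.significant.sum()) if len(table) else 0,
        }
        log(f"[regulation] {manifest['stages']['regulation']}")

    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
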