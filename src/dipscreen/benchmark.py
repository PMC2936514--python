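"""ROC benchmarking of pairwise drug-similarity scores against external labels.

Two label sources mirror standard practice in drug-profile evaluation: a pair
is "positive" when the drugs are chemically near-identical (2D Tanimoto
coefficient strictly above 0.8) or when they share a level-4 ATC code (the
chemical/therapeutic subgroup, i.e. the first five characters of the WHO
code).  Scores are evaluated with a standard ROC over descending thresholds;
tied scores contribute diagonal segments, so the trapezoid AUC equals the
Mann-Whitney concordance probability with ties counted 1/2.  The partial AUC
below an FPR cutoff is reported unnormalized (a perfect classifier attains
the cutoff value itself).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "PairLabelSet",
    "ROCResult",
    "labels_from_tanimoto",
    "labels_from_atc",
    "labels_from_ground_truth",
    "roc",
]

ATC_PREFIX_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


def pair_key(drug_a: str, drug_b: str) -> tuple[str, str]:
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


@dataclass
class PairLabelSet:
    """Binary labels over unordered drug pairs."""

    labels: dict[tuple[str, str], int]
    label_source: str
    threshold: float | int | None = None

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return sum(self.labels.values())


def labels_from_tanimoto(
    similarity: pd.DataFrame, threshold: float = 0.8
) -> PairLabelSet:
    """Positive iff Tanimoto similarity is strictly greater than *threshold*.

    Expects long-form columns ``drug_a, drug_b, tanimoto``; rows with a
    similarity outside [0, 1] are rejected with a warning.  Pairs missing from
    the table are simply unlabeled.
    """
    labels: dict[tuple[str, str], int] = {}
    bad = 0
    for row in similarity.itertuples():
        sim = float(row.tanimoto)
        if not 0.0 <= sim <= 1.0:
            bad += 1
            continue
        labels[pair_key(row.drug_a, row.drug_b)] = int(sim > threshold)
    if bad:
        warnings.warn(f"rejected {bad} similarity rows outside [0, 1]")
    return PairLabelSet(labels, "tanimoto", threshold)


def _valid_atc(code: str) -> bool:
    return (
        len(code) == 7
        and code[0].isalpha()
        and code[1:3].isdigit()
        and code[3].isalpha()
        and code[4].isalpha()
        and code[5:7].isdigit()
    )


def labels_from_atc(atc: pd.DataFrame, level: int = 4) -> PairLabelSet:
    """Positive iff any ATC code of one drug shares the level-*level* prefix
    with any code of the other.

    Expects columns ``drug_id, atc_code`` (several rows per drug allowed).
    Drugs without any valid code are excluded from the labeled set; malformed
    codes are rejected with a warning.
    """
    if level not in ATC_PREFIX_LENGTH:
        raise ValueError(f"ATC level must be in {sorted(ATC_PREFIX_LENGTH)}")
    k = ATC_PREFIX_LENGTH[level]
    codes: dict[str, set[str]] = {}
    bad = 0
    for row in atc.itertuples():
        code = str(row.atc_code).strip()
        if not _valid_atc(code):
            bad += 1
            continue
        codes.setdefault(row.drug_id, set()).add(code[:k])
    if bad:
        warnings.warn(f"rejected {bad} malformed ATC codes")
    labels: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(sorted(codes), 2):
        labels[pair_key(a, b)] = int(bool(codes[a] & codes[b]))
    return PairLabelSet(labels, f"atc_level{level}", level)


def labels_from_ground_truth(similar_pairs, drugs) -> PairLabelSet:
    """Labels straight from a synthetic compendium's shared-signature groups."""
    similar = {pair_key(a, b) for a, b in similar_pairs}
    labels = {
        pair_key(a, b): int(pair_key(a, b) in similar)
        for a, b in itertools.combinations(sorted(drugs), 2)
    }
    return PairLabelSet(labels, "ground_truth")


@dataclass
class ROCResult:
    """ROC curve with trapezoid AUC and unnormalized partial AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    partial_auc: float
    fpr_cutoff: float
    n_positive: int
    n_negative: int


def _scores_and_labels(
    scores: dict[tuple[str, str], float] | pd.DataFrame,
    labels: PairLabelSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Listwise-complete intersection of scored and labeled pairs."""
    if isinstance(scores, pd.DataFrame):
        score_map: dict[tuple[str, str], float] = {}
        for a, b in itertools.combinations(sorted(scores.index), 2):
            v = scores.loc[a, b]
            if np.isfinite(v):
                score_map[pair_key(a, b)] = float(v)
    else:
        score_map = {pair_key(*k): float(v) for k, v in scores.items()
                     if np.isfinite(v)}
    y, s = [], []
    for key, label in labels.labels.items():
        if key in score_map:
            y.append(label)
            s.append(score_map[key])
    return np.asarray(y, dtype=int), np.asarray(s, dtype=float)


def roc(
    scores: dict[tuple[str, str], float] | pd.DataFrame,
    labels: PairLabelSet,
    fpr_cutoff: float = 0.1,
) -> ROCResult:
    """ROC / AUC / partial AUC of *scores* against *labels*.

    *scores* is either a symmetric drug x drug DataFrame (NaN = unscored) or a
    mapping from unordered pair to score.  Pairs lacking either a score or a
    label are excluded listwise.
    """
    if not 0.0 < fpr_cutoff <= 1.0:
        raise ValueError("fpr_cutoff must be in (0, 1]")
    y, s = _scores_and_labels(scores, labels)
    if len(y) == 0:
        raise ValueError("no pair has both a score and a label")
    if y.min() == y.max():
        raise ValueError("labels are all one class; ROC undefined")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    # unnormalized area below the cutoff, interpolating the curve at the cutoff
    grid = np.unique(np.concatenate([fpr[fpr < fpr_cutoff], [fpr_cutoff]]))
    tpr_grid = np.interp(grid, fpr, tpr)
    partial = float(np.trapezoid(tpr_grid, grid))
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        partial_auc=partial,
        fpr_cutoff=fpr_cutoff,
        n_positive=int(y.sum()),
        n_negative=int((1 - y).sum()),
    )
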