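"""Drug-induced profile similarity (DIPS): bidirectional KS enrichment scoring.

The similarity of two drugs' expression responses is quantified by running the
up- and down-sets of each drug's optimal signature through the other drug's
full ranked profile with a Kolmogorov–Smirnov running-sum enrichment statistic
(the GSEA ES): walking the ranked list, the sum rises by ``w_i / sum(w)`` at
each query-set member ("hit") and falls by ``1 / (N - |S|)`` at each non-member
("miss"); the ES is the signed extreme deviation from zero and lies in
[-1, 1].  Two weighting modes are available:

* ``classic`` (default) — unit hit increments, the original KS statistic;
* ``weighted`` — hit increments proportional to the probe's |effective value|
  (weight exponent 1).

For a drug pair (X, Y) the four scores ES(up_X in Y), ES(down_X in Y),
ES(up_Y in X), ES(down_Y in X) are combined as the mean of the two directional
scores (ES_up - ES_down)/2.  The sign correction matters: for a concordant
pair ES_down is negative, so a plain four-way mean would cancel the signal;
the combination used here yields exactly +1 for a self-comparison and -1 for a
rank-reversed profile, and is symmetric in (X, Y) by construction.  The
combination lives in :func:`combine_directional` alone so alternative
averaging rules can be swapped in.

Per-cell-line scores for a pair are merged across cell lines by an unweighted
arithmetic mean over the cell lines where both drugs were profiled.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ranking import RankedProfile, Signature

__all__ = [
    "EnrichmentScore",
    "ks_enrichment",
    "dips_pair",
    "dips_matrix",
    "combine_cell_lines",
    "pairwise_pearson",
    "categorize_pairs",
    "CategoryAnalysis",
    "cross_cellline_merge",
    "CATEGORIES",
]

WEIGHTINGS = ("classic", "weighted")

CATEGORIES = (
    "same_drug_same_batch",
    "same_drug_different_batch",
    "different_drug_same_batch",
    "different_drug_different_batch",
)


@dataclass(frozen=True)
class EnrichmentScore:
    """Signed KS running-sum enrichment of a probe set in a ranked list."""

    value: float
    query_set_size: int
    list_length: int
    weighting: str


def _es_walk(positions: np.ndarray, n_total: int, weights: np.ndarray | None) -> float:
    """ES from sorted 0-based hit positions; closed form over hit-adjacent extremes.

    Between hits the running sum decreases linearly, so its extremes occur
    immediately after a hit (maximum candidates) or immediately before one
    (minimum candidates); scanning those 2m points reproduces the full O(N)
    walk exactly.
    """
    m = positions.size
    if m == 0 or m >= n_total:
        raise ValueError("query set must be non-empty and smaller than the list")
    miss_penalty = (positions - np.arange(m)) / (n_total - m)
    if weights is None:
        cum_hit = np.arange(1, m + 1) / m
    else:
        total = weights.sum()
        if total == 0.0:
            # degenerate all-zero weights (query inside the zero block):
            # fall back to uniform increments
            cum_hit = np.arange(1, m + 1) / m
        else:
            cum_hit = np.cumsum(weights) / total
    after = cum_hit - miss_penalty
    before = np.concatenate(([0.0], cum_hit[:-1])) - miss_penalty
    best_up = after.max()
    best_down = before.min()
    return float(best_up if best_up >= -best_down else best_down)


def ks_enrichment(
    query_set: set[str] | list[str] | tuple[str, ...],
    ranked: RankedProfile,
    weighting: str = "classic",
) -> EnrichmentScore:
    """KS/GSEA enrichment score of *query_set* within a ranked profile."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    query = list(dict.fromkeys(query_set))
    n_total = len(ranked)
    if not 0 < len(query) < n_total:
        raise ValueError("query set must be non-empty and smaller than the profile")
    positions = ranked.positions(query)
    if (positions < 0).any():
        missing = [q for q, p in zip(query, positions) if p < 0]
        raise ValueError(f"query probes absent from the ranked profile: {missing[:5]}")
    positions = np.sort(positions)
    weights = np.abs(ranked.effective[positions]) if weighting == "weighted" else None
    value = _es_walk(positions, n_total, weights)
    return EnrichmentScore(value, len(query), n_total, weighting)


def _query_positions(
    probes: tuple[str, ...], partner: RankedProfile, min_overlap: float = 0.9
) -> np.ndarray:
    positions = partner.positions(probes)
    found = positions[positions >= 0]
    if found.size < min_overlap * len(probes):
        raise ValueError(
            f"only {found.size}/{len(probes)} signature probes found in the "
            "partner profile (need >= 90%)"
        )
    return np.sort(found)


def _directional(
    sig: Signature, partner: RankedProfile, weighting: str
) -> float:
    """(ES_up - ES_down)/2 of one drug's signature in the partner's profile."""
    n_total = len(partner)
    up_pos = _query_positions(sig.up, partner)
    down_pos = _query_positions(sig.down, partner)
    if weighting == "weighted":
        es_up = _es_walk(up_pos, n_total, np.abs(partner.effective[up_pos]))
        es_down = _es_walk(down_pos, n_total, np.abs(partner.effective[down_pos]))
    else:
        es_up = _es_walk(up_pos, n_total, None)
        es_down = _es_walk(down_pos, n_total, None)
    return (es_up - es_down) / 2.0


def combine_directional(score_xy: float, score_yx: float) -> float:
    """Final pair score from the two directional scores (plain mean)."""
    return (score_xy + score_yx) / 2.0


def dips_pair(
    sig_x: Signature,
    ranked_x: RankedProfile,
    sig_y: Signature,
    ranked_y: RankedProfile,
    weighting: str = "classic",
) -> float:
    """DIPS score of a drug pair within one cell line; symmetric in (X, Y)."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    return combine_directional(
        _directional(sig_x, ranked_y, weighting),
        _directional(sig_y, ranked_x, weighting),
    )


def dips_matrix(
    rankings: dict[str, RankedProfile],
    signatures: dict[str, Signature],
    weighting: str = "classic",
    subset: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric drug x drug DIPS matrix over one cell line's profiles.

    *subset* restricts the computation to the listed drugs (the full pairwise
    problem is O(D^2) score evaluations).
    """
    drugs = sorted(subset) if subset is not None else sorted(rankings)
    out = pd.DataFrame(np.nan, index=drugs, columns=drugs, dtype=float)
    directional = {}
    for x, y in itertools.permutations(drugs, 2):
        directional[(x, y)] = _directional(signatures[x], rankings[y], weighting)
    for x, y in itertools.combinations(drugs, 2):
        score = combine_directional(directional[(x, y)], directional[(y, x)])
        out.loc[x, y] = score
        out.loc[y, x] = score
    for x in drugs:
        out.loc[x, x] = combine_directional(
            _directional(signatures[x], rankings[x], weighting),
            _directional(signatures[x], rankings[x], weighting),
        )
    return out


def combine_cell_lines(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Average per-cell-line DIPS matrices over the cell lines scoring each pair."""
    if not matrices:
        raise ValueError("no per-cell-line matrices given")
    drugs = sorted(set().union(*(m.index for m in matrices.values())))
    stack = np.full((len(matrices), len(drugs), len(drugs)), np.nan)
    for k, m in enumerate(matrices.values()):
        aligned = m.reindex(index=drugs, columns=drugs)
        stack[k] = aligned.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs stay NaN
        combined = np.nanmean(stack, axis=0)
    return pd.DataFrame(combined, index=drugs, columns=drugs)


def pairwise_pearson(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between amplitude profiles (columns of *profiles*).

    Zero-variance profiles have no defined correlation; their rows/columns are
    NaN and a warning names them rather than silently reporting 0.
    """
    degenerate = profiles.columns[profiles.std(axis=0, ddof=0) == 0.0]
    if len(degenerate):
        warnings.warn(
            f"zero-variance profiles have undefined correlations: {list(degenerate)}"
        )
    return profiles.corr(method="pearson")


@dataclass
class CategoryAnalysis:
    """Instance-pair DIPS scores stratified by drug/batch category."""

    scores: pd.DataFrame      # instance_a, instance_b, cell_line, category, score
    means: pd.Series          # category -> mean score
    tests: pd.DataFrame       # category_a, category_b, t, p, n_a, n_b

    def scores_in(self, category: str) -> np.ndarray:
        return self.scores.score[self.scores.category == category].to_numpy()

    def test(self, category_a: str, category_b: str) -> tuple[float, float]:
        row = self.tests[
            (self.tests.category_a == category_a) & (self.tests.category_b == category_b)
        ]
        if row.empty:
            row = self.tests[
                (self.tests.category_a == category_b)
                & (self.tests.category_b == category_a)
            ]
        if row.empty:
            raise KeyError((category_a, category_b))
        return float(row.t.iloc[0]), float(row.p.iloc[0])


def categorize_pairs(
    matrix: pd.DataFrame,
    instances: pd.DataFrame,
    presence,
    signature_n: int,
    weighting: str = "classic",
    max_pairs_per_category: int | None = None,
    seed: int = 0,
) -> CategoryAnalysis:
    """Score all within-cell-line instance pairs and label the four categories.

    Works on instance-level (pre-merge) centered profiles so that the
    same-drug/same-batch category exists.  Categories follow the drug/batch
    cross: (same drug?, same batch?).  Welch two-sample t-tests are run
    between every category pair with >= 2 scores each.
    """
    from .ranking import extract_signature, rank_profile  # local to avoid cycle noise

    treatments = instances[~instances.is_control.astype(bool)]
    treatments = treatments[treatments.instance_id.isin(matrix.columns)]
    rows = []
    for cell, group in treatments.groupby("cell_line", sort=False):
        pres = presence[cell] if isinstance(presence, dict) else presence
        pres_probes = pres.probes if hasattr(pres, "probes") else pres
        ranked = {}
        sigs = {}
        for inst in group.itertuples():
            r = rank_profile(matrix[inst.instance_id], pres_probes,
                             drug_id=inst.drug_id, cell_line=cell)
            ranked[inst.instance_id] = r
            sigs[inst.instance_id] = extract_signature(r, signature_n)
        meta = group.set_index("instance_id")
        for a, b in itertools.combinations(list(group.instance_id), 2):
            same_drug = meta.drug_id[a] == meta.drug_id[b]
            same_batch = meta.batch_id[a] == meta.batch_id[b]
            category = CATEGORIES[(0 if same_drug else 2) + (0 if same_batch else 1)]
            score = dips_pair(sigs[a], ranked[a], sigs[b], ranked[b], weighting)
            rows.append((a, b, cell, category, score))
    scores = pd.DataFrame(
        rows, columns=["instance_a", "instance_b", "cell_line", "category", "score"]
    )
    if max_pairs_per_category is not None:
        rng = np.random.default_rng(seed)
        kept = []
        for cat, g in scores.groupby("category", sort=False):
            if len(g) > max_pairs_per_category:
                g = g.iloc[rng.choice(len(g), max_pairs_per_category, replace=False)]
            kept.append(g)
        scores = pd.concat(kept).reset_index(drop=True)
    means = scores.groupby("category").score.mean()

    test_rows = []
    for cat_a, cat_b in itertools.combinations(CATEGORIES, 2):
        a = scores.score[scores.category == cat_a]
        b = scores.score[scores.category == cat_b]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"category pair ({cat_a}, {cat_b}) has <2 scores; test skipped")
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        test_rows.append((cat_a, cat_b, float(t), float(p), len(a), len(b)))
    tests = pd.DataFrame(
        test_rows, columns=["category_a", "category_b", "t", "p", "n_a", "n_b"]
    )
    return CategoryAnalysis(scores=scores, means=means, tests=tests)


def cross_cellline_merge(
    matrices: dict[str, pd.DataFrame],
    presence: dict[str, object],
) -> pd.DataFrame:
    """Concatenate per-cell-line profile matrices on probes present in all lines.

    Columns are suffixed ``@<cell_line>``; the probe space is the intersection
    of the cell lines' presence sets (error if empty).
    """
    if len(matrices) < 2:
        raise ValueError("cross-cell-line merge needs >= 2 cell lines")
    probe_sets = []
    for cell in matrices:
        pres = presence[cell]
        probe_sets.append(set(pres.probes if hasattr(pres, "probes") else pres))
    shared = sorted(set.intersection(*probe_sets))
    if not shared:
        raise ValueError("no probe is 'Present' in every cell line")
    pieces = []
    for cell, m in matrices.items():
        sub = m.loc[shared].copy()
        sub.columns = [f"{c}@{cell}" for c in sub.columns]
        pieces.append(sub)
    return pd.concat(pieces, axis=1)
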