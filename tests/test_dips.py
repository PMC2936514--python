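"""Enrichment-score walk, DIPS combination, Pearson variant, categories, merge."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dipscreen.dips import (
    CATEGORIES,
    categorize_pairs,
    combine_cell_lines,
    cross_cellline_merge,
    dips_matrix,
    dips_pair,
    ks_enrichment,
    pairwise_pearson,
)
from dipscreen.ranking import extract_signature, rank_profile
from conftest import make_instances


def brute_force_es(n_total, hit_positions, weights=None):
    """Literal O(N) running-sum walk, written independently of the package.

    Returns (max over the walk, min over the walk); the signed ES follows the
    same prefer-positive rule the package documents.
    """
    hits = dict.fromkeys(hit_positions)
    m = len(hits)
    if weights is not None:
        w = dict(zip(hit_positions, weights))
        total = sum(w.values())
        if total == 0:
            w = {h: 1.0 for h in hit_positions}
            total = float(m)
    else:
        w = {h: 1.0 for h in hit_positions}
        total = float(m)
    run, hi, lo = 0.0, 0.0, 0.0
    for i in range(n_total):
        if i in hits:
            run += w[i] / total
        else:
            run -= 1.0 / (n_total - m)
        hi = max(hi, run)
        lo = min(lo, run)
    return hi, lo


def signed(hi, lo):
    return hi if hi >= -lo else lo


def _ranked(values: pd.Series, present=None):
    return rank_profile(values, present if present is not None else set(values.index))


class TestKsEnrichment:
    def test_matches_brute_force_walk(self, rng):
        probes = None
        for _ in range(300):
            n = int(rng.integers(10, 200))
            probes = [f"p{i:04d}" for i in range(n)]
            values = pd.Series(rng.normal(size=n), index=probes)
            present = set(rng.choice(probes, size=max(1, n // 2), replace=False))
            ranked = rank_profile(values, present)
            m = int(rng.integers(1, n))
            query = list(rng.choice(probes, size=m, replace=False))
            positions = np.sort(ranked.positions(query))
            for weighting in ("classic", "weighted"):
                wts = (np.abs(ranked.effective[positions])
                       if weighting == "weighted" else None)
                hi, lo = brute_force_es(n, list(positions),
                                        None if wts is None else list(wts))
                got = ks_enrichment(query, ranked, weighting).value
                want = signed(hi, lo)
                if abs(abs(hi) - abs(lo)) < 1e-9:
                    assert abs(abs(got) - abs(want)) < 1e-12
                else:
                    assert abs(got - want) < 1e-12

    def test_top_set_scores_plus_one(self, rng):
        values = pd.Series(rng.normal(size=100), index=[f"p{i}" for i in range(100)])
        ranked = _ranked(values)
        es = ks_enrichment(list(ranked.probes[:10]), ranked, "classic")
        assert es.value == 1.0

    def test_bottom_set_scores_minus_one(self, rng):
        values = pd.Series(rng.normal(size=100), index=[f"p{i}" for i in range(100)])
        ranked = _ranked(values)
        assert ks_enrichment(list(ranked.probes[-10:]), ranked, "classic").value == -1.0

    def test_bounds_on_random_draws(self, rng):
        values = pd.Series(rng.normal(size=60), index=[f"p{i}" for i in range(60)])
        ranked = _ranked(values)
        for _ in range(500):
            m = int(rng.integers(1, 60))
            query = list(rng.choice(ranked.probes, size=m, replace=False))
            for weighting in ("classic", "weighted"):
                assert -1.0 <= ks_enrichment(query, ranked, weighting).value <= 1.0

    def test_empty_and_full_sets_rejected(self, rng):
        values = pd.Series(rng.normal(size=10), index=[f"p{i}" for i in range(10)])
        ranked = _ranked(values)
        with pytest.raises(ValueError):
            ks_enrichment([], ranked)
        with pytest.raises(ValueError):
            ks_enrichment(list(ranked.probes), ranked)


class TestDipsPair:
    def _profile_pair(self, rng, n=300, sig_n=25):
        values = pd.Series(rng.normal(size=n), index=[f"p{i:04d}" for i in range(n)])
        ranked = _ranked(values)
        return values, ranked, extract_signature(ranked, sig_n)

    def test_self_comparison_is_one(self, rng):
        _, ranked, sig = self._profile_pair(rng)
        assert dips_pair(sig, ranked, sig, ranked) == 1.0

    def test_reversed_profile_is_minus_one(self, rng):
        values, ranked, sig = self._profile_pair(rng)
        rev = _ranked(-values)
        rev_sig = extract_signature(rev, 25)
        assert dips_pair(sig, ranked, rev_sig, rev) == -1.0

    def test_symmetry_is_bit_exact(self, rng):
        for _ in range(200):
            _, rx, sx = self._profile_pair(rng, n=120, sig_n=10)
            _, ry, sy = self._profile_pair(rng, n=120, sig_n=10)
            assert dips_pair(sx, rx, sy, ry) == dips_pair(sy, ry, sx, rx)

    def test_null_distribution_centered_at_zero(self, rng):
        scores = []
        for _ in range(500):
            _, rx, sx = self._profile_pair(rng, n=1000, sig_n=50)
            _, ry, sy = self._profile_pair(rng, n=1000, sig_n=50)
            scores.append(dips_pair(sx, rx, sy, ry))
        assert abs(np.mean(scores)) < 0.05

    def test_insufficient_signature_overlap_rejected(self, rng):
        values, ranked, sig = self._profile_pair(rng, n=100, sig_n=20)
        other = pd.Series(rng.normal(size=100),
                          index=[f"q{i:04d}" for i in range(100)])
        other_ranked = _ranked(other)
        other_sig = extract_signature(other_ranked, 20)
        with pytest.raises(ValueError, match="90%"):
            dips_pair(sig, ranked, other_sig, other_ranked)


def test_combine_cell_lines_is_mean_over_available():
    def single(value, drugs=("a", "b")):
        m = pd.DataFrame(np.nan, index=drugs, columns=drugs)
        m.loc[drugs[0], drugs[1]] = m.loc[drugs[1], drugs[0]] = value
        return m

    combined = combine_cell_lines(
        {"c1": single(0.4), "c2": single(0.6), "c3": single(0.8)})
    assert combined.loc["a", "b"] == pytest.approx(0.6)
    assert combine_cell_lines({"c1": single(0.3)}).loc["a", "b"] == pytest.approx(0.3)
    assert combine_cell_lines(
        {"c1": single(0.5), "c2": single(-0.5)}).loc["a", "b"] == pytest.approx(0.0)
    # pair scored in one cell line only contributes just that cell line
    partial = combine_cell_lines(
        {"c1": single(0.2), "c2": single(0.9, drugs=("a", "c"))})
    assert partial.loc["a", "b"] == pytest.approx(0.2)
    assert partial.loc["a", "c"] == pytest.approx(0.9)
    assert np.isnan(partial.loc["b", "c"])


class TestPairwisePearson:
    def test_self_and_negation(self):
        prof = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
        prof["neg"] = -prof.x
        corr = pairwise_pearson(prof)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        prof = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 4.0]})
        # closed form: cov=3/2, var_x=1, var_y=7/3 => r = 3/sqrt(2*42/9)
        assert pairwise_pearson(prof).loc["x", "y"] == pytest.approx(
            3 / np.sqrt(84 / 9), abs=1e-10)

    def test_zero_variance_flagged_not_zeroed(self):
        prof = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="flat"):
            corr = pairwise_pearson(prof)
        assert np.isnan(corr.loc["x", "flat"])


class TestCategorizePairs:
    def test_category_assignment(self, rng):
        inst = make_instances([
            ("i1", "d1", "MCF7", "b1", 10.0, False),
            ("i2", "d1", "MCF7", "b1", 10.0, False),
            ("i3", "d1", "MCF7", "b2", 10.0, False),
            ("i4", "d2", "MCF7", "b1", 10.0, False),
            ("i5", "d2", "MCF7", "b2", 10.0, False),
        ])
        probes = [f"p{i:03d}" for i in range(60)]
        mat = pd.DataFrame(rng.normal(size=(60, 5)), index=probes,
                           columns=list(inst.instance_id))
        analysis = categorize_pairs(mat, inst, {"MCF7": set(probes)}, signature_n=5)
        cats = analysis.scores.set_index(["instance_a", "instance_b"]).category
        assert cats.loc[("i1", "i2")] == "same_drug_same_batch"
        assert cats.loc[("i1", "i3")] == "same_drug_different_batch"
        assert cats.loc[("i1", "i4")] == "different_drug_same_batch"
        assert cats.loc[("i1", "i5")] == "different_drug_different_batch"
        assert set(analysis.scores.category) == set(CATEGORIES)


class TestCrossCellLineMerge:
    def _mat(self, probes, cols):
        return pd.DataFrame(0.0, index=list(probes), columns=cols)

    def test_intersection_of_presence_sets(self):
        out = cross_cellline_merge(
            {"c1": self._mat("ABC", ["x"]), "c2": self._mat("ABC", ["y"]),
             "c3": self._mat("ABC", ["z"])},
            {"c1": {"A", "B", "C"}, "c2": {"B", "C"}, "c3": {"B", "C", "D"}},
        )
        assert sorted(out.index) == ["B", "C"]
        assert list(out.columns) == ["x@c1", "y@c2", "z@c3"]

    def test_identical_sets_keep_all_probes(self):
        out = cross_cellline_merge(
            {"c1": self._mat("AB", ["x"]), "c2": self._mat("AB", ["y"])},
            {"c1": {"A", "B"}, "c2": {"A", "B"}},
        )
        assert sorted(out.index) == ["A", "B"]

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError, match="Present"):
            cross_cellline_merge(
                {"c1": self._mat("A", ["x"]), "c2": self._mat("B", ["y"])},
                {"c1": {"A"}, "c2": {"B"}},
            )
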