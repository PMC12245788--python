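"""Retrospective enrichment metrics against independent oracles."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from dockfp.enrich import (EnrichError, RankedScreen, auc, bedroc,
                           enrichment_factor, evaluate_ligand, rank_targets,
                           read_actives, rie, roc_points, total_gain)
from dockfp.ingest import ScoreMatrix


def make_screen(ranks, n, alpha=20.0):
    """Screen with actives at the given 1-based ranks, distinct scores."""
    labels = np.zeros(n, dtype=bool)
    labels[np.asarray(ranks) - 1] = True
    scores = np.linspace(-60.0, -20.0, n)
    targets = [f"T{i:04d}" for i in range(n)]
    return RankedScreen(ligand_id="L", targets=targets, scores=scores,
                        labels=labels, alpha=alpha)


def random_screen(rng, n=200, n_a=20, alpha=20.0):
    ranks = rng.choice(n, size=n_a, replace=False) + 1
    return make_screen(sorted(ranks), n, alpha=alpha)


def rie_direct_sum(ranks, n, n_a, alpha):
    """Independent direct-sum RIE (explicit Python loop, no numpy)."""
    num = sum(math.exp(-alpha * r / n) for r in ranks) / n_a
    denom = (1.0 / n) * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1)
    return num / denom


def bedroc_direct(ranks, n, n_a, alpha):
    """Independent BEDROC from the discrete definition."""
    ra = n_a / n
    r = rie_direct_sum(ranks, n, n_a, alpha)
    scale = ra * math.sinh(alpha / 2) / (
        math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
    return r * scale + 1 / (1 - math.exp(alpha * (1 - ra)))


class TestReadActives:
    def _read(self, body, **kw):
        return read_actives(
            io.StringIO("ligand_id,uniprot_id,pchembl\n" + body), **kw)

    def test_max_pchembl_kept_for_duplicates(self):
        got = self._read("THC,P01116,3.9\nTHC,P01116,4.1\n")
        assert got == {("THC", "P01116")}

    def test_boundary_is_strict(self):
        assert self._read("THC,P01116,4.0\nCBD,P01116,4.0\n") == set()

    def test_non_numeric_rows_rejected(self):
        got = self._read("THC,P01116,high\nCBD,P01116,5.0\n")
        assert got == {("CBD", "P01116")}

    def test_matches_brute_force_filter(self, rng):
        rows = []
        for i in range(100):
            rows.append((f"L{int(rng.integers(4))}",
                         f"P{int(rng.integers(20)):05d}",
                         float(np.round(rng.uniform(2, 8), 3))))
        body = "".join(f"{l},{t},{p}\n" for l, t, p in rows)
        got = self._read(body)
        best = {}
        for l, t, p in rows:
            best[(l, t)] = max(best.get((l, t), -1), p)
        assert got == {k for k, p in best.items() if p > 4}


class TestRankTargets:
    def _matrix(self, scores, targets):
        return ScoreMatrix(scores=pd.DataFrame([scores], index=["THC"],
                                               columns=targets))

    def test_ranks_and_relative_ranks(self):
        m = self._matrix([-60.0, -50.0, -40.0], ["T1", "T2", "T3"])
        rs = rank_targets(m, "THC", {("THC", "T2")})
        assert list(rs.ranks) == [2]
        assert rs.ranks[0] / rs.n == pytest.approx(2 / 3)

    def test_tied_scores_broken_by_accession(self):
        m = self._matrix([-50.0, -50.0, -40.0], ["B0TEST", "A0TEST", "C0TEST"])
        rs1 = rank_targets(m, "THC", {("THC", "C0TEST")})
        rs2 = rank_targets(m, "THC", {("THC", "C0TEST")})
        assert rs1.targets == ["A0TEST", "B0TEST", "C0TEST"] == rs2.targets

    def test_unscored_actives_dropped_with_count(self):
        m = self._matrix([-60.0, -50.0], ["T1", "T2"])
        rs = rank_targets(m, "THC", {("THC", "T1"), ("THC", "ZZ9999")})
        assert rs.n_actives == 1 and rs.n_actives_dropped == 1

    def test_zero_usable_actives_fatal(self):
        m = self._matrix([-60.0, -50.0], ["T1", "T2"])
        with pytest.raises(EnrichError):
            rank_targets(m, "THC", {("CBD", "T1")})

    def test_matches_independent_sort_oracle(self, rng):
        targets = [f"Q{j:05d}" for j in range(500)]
        scores = rng.normal(-50, 5, 500)
        m = self._matrix(list(scores), targets)
        active_targets = set(rng.choice(targets, 25, replace=False))
        rs = rank_targets(m, "THC", {("THC", t) for t in active_targets})
        expected_order = [t for _, t in sorted(zip(scores, targets))]
        assert rs.targets == expected_order
        expected_ranks = sorted(expected_order.index(t) + 1
                                for t in active_targets)
        assert list(rs.ranks) == expected_ranks


class TestRocAndAuc:
    def test_active_first(self):
        rs = make_screen([1], 2)
        assert roc_points(rs) == [(0, 0), (0, 1), (1, 1)]
        assert auc(rs) == 1.0

    def test_active_last(self):
        rs = make_screen([2], 2)
        assert roc_points(rs) == [(0, 0), (1, 0), (1, 1)]
        assert auc(rs) == 0.0

    def test_alternating_labels_pair_counting(self):
        # ascending scores labelled A,I,A,I: 3 of 4 (active, inactive)
        # pairs have the active scoring better
        assert auc(make_screen([1, 3], 4)) == 0.75

    def test_pure_ties_give_half(self):
        rs = make_screen([1, 3], 4)
        rs.scores = np.zeros(4)
        assert auc(rs) == 0.5

    def test_trapezoid_area_equals_auc(self, rng):
        for _ in range(20):
            rs = random_screen(rng)
            pts = np.array(roc_points(rs))
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert area == pytest.approx(auc(rs), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        rs = random_screen(rng)
        base = auc(rs)
        rs.scores = np.exp(rs.scores / 10) * 3 - 7
        assert auc(rs) == pytest.approx(base, abs=1e-12)

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(5):
            rs = random_screen(rng, n=60, n_a=7)
            a = rs.scores[rs.labels]
            i = rs.scores[~rs.labels]
            wins = sum((x < y) + 0.5 * (x == y) for x in a for y in i)
            assert auc(rs) == pytest.approx(wins / (len(a) * len(i)),
                                            abs=1e-12)


class TestEnrichmentFactor:
    def test_analytic_maximum(self):
        rs = make_screen(range(1, 11), 100)
        assert enrichment_factor(rs, 0.10) == 10.0

    def test_uniform_spread_gives_one(self):
        rs = make_screen(range(10, 101, 10), 100)
        assert enrichment_factor(rs, 0.10) == 1.0

    def test_matches_prefix_count_oracle(self, rng):
        for f in (0.05, 0.10, 0.25, 1.0):
            rs = random_screen(rng)
            n_top = math.ceil(f * rs.n)
            hits = sum(r <= n_top for r in rs.ranks)
            expected = (hits / n_top) / (rs.n_actives / rs.n)
            assert enrichment_factor(rs, f) == pytest.approx(expected)

    def test_bounds(self, rng):
        for _ in range(50):
            rs = random_screen(rng, n=80, n_a=8)
            ef = enrichment_factor(rs, 0.1)
            assert 0 <= ef <= min(1 / 0.1, rs.n / rs.n_actives)


class TestRieBedroc:
    def test_rie_vanishing_alpha_limit(self, rng):
        rs = random_screen(rng, alpha=1e-6)
        assert rie(rs) == pytest.approx(1.0, abs=1e-3)

    def test_rie_matches_direct_sum(self, rng):
        for _ in range(100):
            rs = random_screen(rng)
            expected = rie_direct_sum(list(rs.ranks), rs.n, rs.n_actives, 20.0)
            assert rie(rs) == pytest.approx(expected, abs=1e-9)

    def test_rie_mean_over_random_permutations_is_one(self):
        rng = np.random.default_rng(777)
        vals = [rie(random_screen(rng)) for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_bedroc_perfect_and_worst(self):
        perfect = bedroc(make_screen(range(1, 11), 100))
        worst = bedroc(make_screen(range(91, 101), 100))
        assert perfect == pytest.approx(1.0, abs=0.01)
        assert worst == pytest.approx(0.0, abs=0.01)

    def test_bedroc_matches_direct_definition(self, rng):
        for _ in range(100):
            rs = random_screen(rng)
            expected = bedroc_direct(list(rs.ranks), rs.n, rs.n_actives, 20.0)
            assert bedroc(rs) == pytest.approx(expected, abs=1e-6)

    def test_bedroc_matches_rdkit_reference(self, rng):
        from rdkit.ML.Scoring.Scoring import CalcBEDROC, CalcRIE

        for _ in range(100):
            rs = random_screen(rng)
            ordered = [[0.0, int(lab)] for lab in rs.labels]
            assert bedroc(rs) == pytest.approx(CalcBEDROC(ordered, 1, 20.0),
                                               abs=1e-6)
            assert rie(rs) == pytest.approx(CalcRIE(ordered, 1, 20.0),
                                            abs=1e-6)

    def test_bedroc_in_unit_interval(self, rng):
        for _ in range(200):
            rs = random_screen(rng, n=int(rng.integers(30, 300)),
                               n_a=int(rng.integers(1, 15)))
            assert 0.0 <= bedroc(rs) <= 1.0


class TestTotalGain:
    def test_flat_predictiveness_is_zero(self):
        scores = np.arange(20.0)
        labels = np.tile([True, False], 10)
        assert total_gain(scores, labels, bins=1) == 0.0

    def test_perfect_separation_two_bins(self):
        scores = np.arange(20.0)
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        assert total_gain(scores, labels, bins=2) == 1.0

    def test_hand_computed_bin_sum(self):
        # 20 targets, 4 bins of 5; actives at sorted positions 1-3, 6, 11
        # so the bins hold 3, 1, 1, 0 actives
        scores = np.arange(20.0)
        labels = np.zeros(20, bool)
        labels[[0, 1, 2, 5, 10]] = True
        pi = 5 / 20
        rates = [3 / 5, 1 / 5, 1 / 5, 0 / 5]
        expected = sum(0.25 * abs(r - pi) for r in rates) / (2 * pi * (1 - pi))
        assert total_gain(scores, labels, bins=4) == pytest.approx(
            expected, abs=1e-12)

    def test_single_class_fatal(self):
        with pytest.raises(EnrichError):
            total_gain(np.arange(20.0), np.ones(20, bool))

    def test_clipped_to_unit_interval(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 200))
            labels = rng.random(n) < 0.1
            if labels.all() or not labels.any():
                continue
            tg = total_gain(rng.normal(size=n), labels)
            assert 0.0 <= tg <= 1.0


class TestEvaluateLigand:
    def _planted(self, rng, delta, n=500, n_a=50):
        targets = [f"Q{j:05d}" for j in range(n)]
        active_targets = rng.choice(targets, n_a, replace=False)
        scores = rng.normal(-50, 5, n)
        idx = {t: i for i, t in enumerate(targets)}
        for t in active_targets:
            scores[idx[t]] -= delta * 5
        m = ScoreMatrix(scores=pd.DataFrame([scores], index=["L"],
                                            columns=targets))
        return m, {("L", t) for t in active_targets}

    def test_null_shift_gives_chance_auc(self):
        rng = np.random.default_rng(4242)
        m, actives = self._planted(rng, delta=0.0)
        rep = evaluate_ligand(m, "L", actives)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_large_shift_gives_perfect_separation(self):
        rng = np.random.default_rng(4242)
        m, actives = self._planted(rng, delta=50.0)
        rep = evaluate_ligand(m, "L", actives)
        assert rep.auc == 1.0
        assert rep.ef["0.1"] == pytest.approx(min(1 / 0.1, 500 / 50))

    def test_report_internally_consistent(self):
        rng = np.random.default_rng(11)
        m, actives = self._planted(rng, delta=1.0)
        rep = evaluate_ligand(m, "L", actives)
        pts = np.array(rep.roc)
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(
            rep.auc, abs=1e-12)
        assert rep.n_actives == 50 and rep.n == 500
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
        assert rep.roc[0] == (0.0, 0.0) and rep.roc[-1] == (1.0, 1.0)

    def test_monotone_response_to_planted_shift(self):
        means = []
        for delta in (0.0, 1.0, 3.0):
            aucs, beds = [], []
            for seed in range(10):
                rng = np.random.default_rng(1000 + seed)
                m, actives = self._planted(rng, delta, n=200, n_a=20)
                rep = evaluate_ligand(m, "L", actives)
                aucs.append(rep.auc)
                beds.append(rep.bedroc)
            means.append((np.mean(aucs), np.mean(beds)))
        assert means[0][0] <= means[1][0] <= means[2][0]
        assert means[0][1] <= means[1][1] <= means[2][1]
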