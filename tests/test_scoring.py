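"""Gap-null model, region scoring, calibration, timepoint selection."""

import numpy as np
import pandas as pd
import pytest

from minitn import (
    EssentialityClassifier,
    GenomeScorer,
    ScoringModel,
    assign_feature_essentiality,
    calibrate_read_threshold,
    classify_call,
    essential_landscape,
    gap_null_probability,
    score_region,
    select_timepoint,
)
from minitn.annotation import GenomeAnnotation
from minitn.scoring import TimepointError, round2

from conftest import brute_force_call, make_table


class TestRounding:
    def test_half_up_boundary(self):
        # exactly 0.005 rounds up; anything below rounds to zero
        assert round2(5, 1000) == 0.01
        assert round2(4999, 1_000_000) == 0.00
        assert round2(4999999, 1_000_000_000) == 0.00
        assert round2(123, 200) == 0.62  # 0.615 half-up, exact in integers

    def test_extremes(self):
        assert round2(0, 7) == 0.0
        assert round2(7, 7) == 1.0


class TestGapNull:
    def test_degenerate_spans(self):
        assert gap_null_probability(0, 1000, 1000) == 1.0
        assert gap_null_probability(1000, 5, 1000) == 0.0
        assert gap_null_probability(100, 0, 1000) == 1.0

    def test_closed_form(self):
        assert gap_null_probability(100, 10, 1000) == pytest.approx(0.9**10, abs=1e-12)
        assert gap_null_probability(100, 10, 1000) == pytest.approx(0.34868, abs=2e-3)

    @pytest.mark.parametrize("bad", [(-1, 5, 100), (101, 5, 100), (5, -1, 100), (5, 5, 0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            gap_null_probability(*bad)

    def test_monotone_in_L_and_N(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            G = int(rng.integers(100, 10_000))
            L = int(rng.integers(1, G))
            N = int(rng.integers(1, 200))
            p = gap_null_probability(L, N, G)
            assert gap_null_probability(min(L + 1, G), N, G) <= p
            assert gap_null_probability(L, N + 1, G) <= p

    def test_matches_monte_carlo(self):
        # uniform placement frequency within 3 standard errors
        rng = np.random.default_rng(1)
        trials = 1_000_000
        batch = 100_000
        for _ in range(8):
            G = int(rng.integers(200, 5_000))
            N = int(rng.integers(1, 40))
            L = int(rng.integers(1, G // 2))
            empty = 0
            for _b in range(trials // batch):
                pos = rng.integers(0, G, size=(batch, N))
                empty += int((pos >= L).all(axis=1).sum())
            freq = empty / trials
            p = gap_null_probability(L, N, G)
            se = max(np.sqrt(p * (1 - p) / trials), 1e-9)
            assert abs(freq - p) <= 3 * se + 1e-12


class TestClassifyRule:
    @pytest.mark.parametrize(
        "pe,pne,expected",
        [
            (0.37, 0.00, "E"),
            (0.00, 0.90, "NE"),
            (0.00, 0.00, "F"),
            (0.50, 0.20, "F"),
            (1.00, 1.00, "F"),
        ],
    )
    def test_rule(self, pe, pne, expected):
        assert classify_call(pe, pne) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            classify_call(1.2, 0.0)


def _toy_positions():
    """500 sites on G=10,000 engineered for the three textbook regions.

    Region A [5000,5499] sits in a 600-bp insertion-free interval with
    no site within w=10 of it; region B [3000,3199] has sites every
    20 bp; region C [7000,7059] is insertion-free inside a 90-bp gap
    (below the 92-bp significance length).
    """
    G = 10_000
    forbidden = [(4950, 5549), (7000 - 15, 7059 + 16), (3000, 3199)]
    special = [4949, 5550] + list(range(3010, 3191, 20)) + [6985, 7076]
    taken = set(special)
    fill = []
    step = 19
    p = 1
    while p <= G:
        if not any(a <= p <= b for a, b in forbidden) and p not in taken:
            fill.append(p)
        p += step
    positions = set(special + fill)
    # adjust to exactly 500 sites far from the test regions, keeping
    # every gap below the 92-bp significance length
    i = 0
    while len(positions) > 500:
        cand = [q for q in sorted(positions) if 500 <= q <= 2500 and q not in special]
        positions.remove(cand[i % len(cand)])
        i += 3
    extra = 507
    while len(positions) < 500:
        if extra not in positions:
            positions.add(extra)
        extra += 9
    positions = sorted(positions)
    assert len(positions) == 500
    return G, positions


class TestScoreRegion:
    def setup_method(self):
        self.G, self.positions = _toy_positions()
        self.model = ScoringModel(G=self.G, N=500, alpha=0.01, read_threshold=1, w=10)
        self.scorer = GenomeScorer(np.array(self.positions), self.model)
        assert self.model.w == 10

    def test_essential_region(self):
        call = self.scorer.score(5000, 5499, "A")
        assert (call.P_E, call.P_NE, call.category) == (1.00, 0.00, "E")

    def test_nonessential_region(self):
        call = self.scorer.score(3000, 3199, "B")
        assert (call.P_E, call.P_NE, call.category) == (0.00, 1.00, "NE")
        assert call.n_insertions == 10

    def test_fitness_region_short_gap(self):
        call = self.scorer.score(7000, 7059, "C")
        assert (call.P_E, call.P_NE, call.category) == (0.00, 0.00, "F")

    def test_matches_brute_force_oracle(self):
        for pe_impl, pne_impl, region in self._sweep():
            pe, pne, cat = brute_force_call(
                self.positions, self.G, 0.01, 10, 500, *region
            )
            assert (pe_impl.P_E, pe_impl.P_NE) == (pe, pne), region
            assert pe_impl.category == cat

    def _sweep(self):
        rng = np.random.default_rng(5)
        out = []
        for _ in range(20):
            start = int(rng.integers(1, self.G - 400))
            end = start + int(rng.integers(30, 400))
            out.append((self.scorer.score(start, end), None, (start, end)))
        return [(c, None, r) for c, _n, r in out]

    def test_score_region_wrapper(self):
        table = make_table(self.positions, self.G)
        call = score_region(("A", 5000, 5499), table, self.model)
        assert call.category == "E"

    def test_zero_sites_error(self):
        with pytest.raises(ValueError, match="N=0|no threshold-passing"):
            GenomeScorer(np.array([], dtype=int), self.model)


class TestOracleEquivalenceRandom:
    def test_random_toy_genomes(self):
        """Implementation == independent per-base labeling oracle,
        exact rounded equality, on random toy genomes."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            G = 10_000
            N = 500
            positions = np.sort(rng.choice(np.arange(1, G + 1), size=N, replace=False))
            model = ScoringModel(G=G, N=N, alpha=0.01, read_threshold=1)
            scorer = GenomeScorer(positions, model)
            for _ in range(4):
                start = int(rng.integers(1, G - 500))
                end = start + int(rng.integers(50, 500))
                call = scorer.score(start, end)
                pe, pne, cat = brute_force_call(
                    list(positions), G, 0.01, model.w, N, start, end
                )
                assert (call.P_E, call.P_NE, call.category) == (pe, pne, cat)


class TestInvariances:
    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        G, N = 10_000, 300
        positions = np.sort(rng.choice(np.arange(1, G + 1), size=N, replace=False))
        model = ScoringModel(G=G, N=N, alpha=0.01, read_threshold=1)
        scorer = GenomeScorer(positions, model)
        start, end = 4000, 4800
        base = scorer.score(start, end)
        for shift in (137, 5000, 9000):
            rot = (positions - 1 + shift) % G + 1
            s2 = GenomeScorer(rot, model)
            r_start = (start - 1 + shift) % G + 1
            r_end = (end - 1 + shift) % G + 1
            call = s2.score(r_start, r_end)  # may wrap the origin
            assert (call.P_E, call.P_NE, call.category) == (
                base.P_E, base.P_NE, base.category
            ), shift

    def test_strand_reflection_invariance(self):
        rng = np.random.default_rng(8)
        G, N = 10_000, 300
        positions = np.sort(rng.choice(np.arange(1, G + 1), size=N, replace=False))
        model = ScoringModel(G=G, N=N, alpha=0.01, read_threshold=1)
        base = GenomeScorer(positions, model).score(2000, 2900)
        mirrored = GenomeScorer(G + 1 - positions, model).score(G + 1 - 2900, G + 1 - 2000)
        assert (base.P_E, base.P_NE) == (mirrored.P_E, mirrored.P_NE)


def _calibration_setup(e_reads, ne_reads):
    """One gold-E and one gold-NE gene with the given insertion reads."""
    G = 10_000
    ann = GenomeAnnotation(
        features=pd.DataFrame(
            [
                ("geneE", "ORF", 1000, 1999, "+"),
                ("geneNE", "ORF", 5000, 5999, "+"),
            ],
            columns=["id", "type", "start", "end", "strand"],
        ),
        G=G,
    )
    positions = list(range(1000, 1000 + len(e_reads))) + list(
        range(5000, 5000 + len(ne_reads))
    )
    table = make_table(positions, G, reads=list(e_reads) + list(ne_reads))
    from minitn import GoldSet

    return table, GoldSet(["geneE"], ["geneNE"]), ann


class TestCalibration:
    def test_well_separated_example(self):
        table, gold, ann = _calibration_setup([1, 2, 3], [100, 150])
        cal = calibrate_read_threshold(table, gold, ann)
        assert (cal.relaxed, cal.stringent) == (4, 100)

    def test_overlapping_example(self):
        table, gold, ann = _calibration_setup([1, 2, 10], [5, 20, 30])
        cal = calibrate_read_threshold(table, gold, ann)
        assert (cal.relaxed, cal.stringent) == (3, 20)
        assert cal.curve["error"].min() == 1

    def test_exhaustive_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            e = rng.integers(1, 40, size=rng.integers(2, 20))
            ne = rng.integers(1, 200, size=rng.integers(2, 20))
            table, gold, ann = _calibration_setup(e, ne)
            cal = calibrate_read_threshold(table, gold, ann)
            # independent exhaustive search
            ts = range(1, int(max(e.max(), ne.max())) + 2)
            errs = {t: int((e >= t).sum() + (ne < t).sum()) for t in ts}
            best = min(errs.values())
            mins = [t for t, v in errs.items() if v == best]
            assert cal.relaxed == min(mins) and cal.stringent == max(mins)

    def test_identical_distributions_warn(self):
        table, gold, ann = _calibration_setup([5, 7, 9], [5, 7, 9])
        with pytest.warns(UserWarning, match="degenerate"):
            cal = calibrate_read_threshold(table, gold, ann)
        assert cal.relaxed == cal.stringent
        assert cal.degenerate

    def test_empty_gold_class_error(self):
        table, gold, ann = _calibration_setup([1, 2], [10])
        table.df = table.df[table.df["position"] < 3000]  # drop NE insertions
        with pytest.raises(ValueError, match="calibration undefined"):
            calibrate_read_threshold(table, gold, ann)


def _day_tables(e_counts, ne_counts, n_e=20, n_ne=20):
    """Tables whose per-gold-gene mean insertion counts follow the series."""
    G = 100_000
    rows = []
    for i in range(n_e):
        rows.append((f"E{i}", "ORF", 1 + 1000 * i, 900 + 1000 * i, "+"))
    for i in range(n_ne):
        rows.append((f"N{i}", "ORF", 50_001 + 1000 * i, 50_900 + 1000 * i, "+"))
    ann = GenomeAnnotation(
        features=pd.DataFrame(rows, columns=["id", "type", "start", "end", "strand"]), G=G
    )
    from minitn import GoldSet

    gold = GoldSet([f"E{i}" for i in range(n_e)], [f"N{i}" for i in range(n_ne)])
    tables = {}
    for day, (ec, nc) in enumerate(zip(e_counts, ne_counts)):
        positions = []
        ne_total = int(round(nc * n_ne))
        e_total = int(round(ec * n_e))
        for j in range(e_total):
            positions.append(1 + 1000 * (j % n_e) + 10 + 2 * (j // n_e))
        for j in range(ne_total):
            positions.append(50_001 + 1000 * (j % n_ne) + 10 + 2 * (j // n_ne))
        tables[4 * (day + 1)] = make_table(sorted(set(positions)), G, day=4 * (day + 1))
    return tables, gold, ann


class TestSelectTimepoint:
    def test_series_selects_decayed_day(self):
        tables, gold, ann = _day_tables([5.0, 1.0, 0.05], [20, 19, 19])
        day, diag = select_timepoint(tables, gold, ann)
        assert day == 12
        assert list(diag.index) == [4, 8, 12]

    def test_bottleneck_errors(self):
        tables, gold, ann = _day_tables([5.0, 1.0, 0.05], [20, 19, 2])
        with pytest.raises(TimepointError):
            select_timepoint(tables, gold, ann)

    def test_single_day_warns(self):
        tables, gold, ann = _day_tables([0.05], [20])
        with pytest.warns(UserWarning, match="single-day"):
            day, _ = select_timepoint(tables, gold, ann)
        assert day == 4


class TestLandscapeToy:
    def test_single_gap_segment(self):
        # one 1,000-bp insertion-free interval on an otherwise dense genome
        G = 10_000
        positions = [p for p in range(1, G + 1, 19) if not 2000 <= p <= 2999]
        positions += [1999, 3000]
        positions = sorted(set(positions))
        table = make_table(positions, G)
        model = ScoringModel.from_table(table)
        ann = GenomeAnnotation(
            features=pd.DataFrame(
                [("orf1", "ORF", 2100, 2700, "+")],
                columns=["id", "type", "start", "end", "strand"],
            ),
            G=G,
        )
        ls = essential_landscape(ann, table, model)
        assert ls.essential_bp == 1000
        assert ls.essential_fraction == pytest.approx(0.10)
        seg = ls.segments
        assert len(seg) == 1 and (seg.iloc[0]["start"], seg.iloc[0]["end"]) == (2000, 2999)
        assert ls.calls.loc["orf1", "category"] == "E"


class TestFeatureAssignment:
    def _ann_and_calls(self):
        feats = pd.DataFrame(
            [
                ("orfE", "ORF", 1000, 1999, "+", None),
                ("orfNE", "ORF", 3000, 3999, "+", None),
                ("nc_over_E", "ncRNA", 1200, 1400, "-", None),
                ("nc_free", "ncRNA", 5000, 5100, "+", None),
            ],
            columns=["id", "type", "start", "end", "strand", "truth"],
        ).drop(columns="truth")
        ann = GenomeAnnotation(features=feats, G=10_000)
        calls = pd.DataFrame(
            {
                "type": ["ORF", "ORF", "ncRNA", "ncRNA"],
                "category": ["E", "NE", "E", "NE"],
            },
            index=pd.Index(["orfE", "orfNE", "nc_over_E", "nc_free"], name="id"),
        )
        return ann, calls

    def test_ncrna_overlapping_essential_orf_unassignable(self):
        ann, calls = self._ann_and_calls()
        summ = assign_feature_essentiality(ann, calls, "ncRNA")
        assert summ.n_unassignable == 1
        assert summ.n == 1 and summ.counts["NE"] == 1

    def test_short_intergenic_excluded(self):
        ann, calls = self._ann_and_calls()
        # complement-derived intergenic regions: all > 100 bp here except none;
        # check the 80-bp case explicitly
        feats = ann.features.copy()
        feats.loc[len(feats)] = ("orfX", "ORF", 4000, 4919, "+")
        ann2 = GenomeAnnotation(features=feats, G=10_000)
        ig = ann2.intergenic_regions(min_length=101)
        assert not ((ig["end"] - ig["start"] + 1) <= 100).any()
        # the 80-bp gap between orfX (ends 4919) and nc_free (starts 5000) is gone
        assert not ((ig["start"] == 4920) & (ig["end"] == 4999)).any()

    def test_no_ncrnas_no_error(self):
        ann, calls = self._ann_and_calls()
        feats = ann.features[ann.features["type"] != "ncRNA"].reset_index(drop=True)
        ann3 = GenomeAnnotation(features=feats, G=10_000)
        summ = assign_feature_essentiality(ann3, calls, "ncRNA")
        assert summ.n == 0

    def test_unknown_class_error(self):
        ann, calls = self._ann_and_calls()
        with pytest.raises(ValueError):
            assign_feature_essentiality(ann, calls, "plasmid")


class TestEstimatorInterface:
    def test_get_set_params_clone(self, fitted_classifier):
        from sklearn.base import clone

        clf, table, gold = fitted_classifier
        params = clf.get_params()
        assert params["read_threshold"] == "stringent"
        fresh = clone(clf)
        assert fresh.get_params() == params
        with pytest.raises(RuntimeError):
            fresh.predict(pd.DataFrame({"start": [1], "end": [100]}))

    def test_predict_categories(self, fitted_classifier):
        clf, table, gold = fitted_classifier
        regions = pd.DataFrame({"start": [1], "end": [500]})
        cats = clf.predict(regions)
        assert cats[0] in ("E", "NE", "F")

    def test_integer_threshold_skips_gold(self, small_sim):
        cfg, genome, truth, tables = small_sim
        clf = EssentialityClassifier(read_threshold=5).fit(tables[4])
        assert clf.model_.read_threshold == 5
        assert clf.calibration_ is None
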