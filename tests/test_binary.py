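import numpy as np
import pytest
from scipy.special import comb

from markercut import candidate_cutoffs
from markercut.binary import (
    ConfusionTable,
    auto_orientation,
    binary_scan,
    confusion_at,
    constrained_cutoff,
    equivocal_zone,
    fisher_p,
    odds_ratio,
    optimize_binary_significance,
    optimize_roc,
    proportion_significant,
    roc_curve,
    wilson_ci,
)
from conftest import make_dataset
from oracles import fisher_two_sided, wilson_by_formula


def random_binary_instance(seed, n=40):
    rng = np.random.default_rng(seed)
    marker = rng.normal(size=n)
    outcome = rng.random(n) < 0.3 + 0.4 * (marker > 0)
    if outcome.all() or (~outcome).all():
        outcome[0] = not outcome[0]
    return make_dataset(marker, outcome=outcome)


class TestConfusion:
    ds = make_dataset([1, 2, 3, 4], outcome=[False, False, True, True])

    def test_perfect_separation(self):
        t = confusion_at(self.ds, 3, "high_positive")
        assert (t.tp, t.fn, t.tn, t.fp) == (2, 0, 2, 0)
        assert t.sensitivity == 1.0 and t.specificity == 1.0

    def test_everything_high(self):
        t = confusion_at(self.ds, 0, "high_positive")
        assert (t.tp, t.fp, t.tn, t.fn) == (2, 2, 0, 0)

    def test_orientation_flip(self):
        t = confusion_at(self.ds, 3, "low_positive")
        assert (t.tp, t.fn, t.tn, t.fp) == (0, 2, 0, 2)

    def test_outcome_required(self):
        with pytest.raises(ValueError, match="outcome"):
            confusion_at(make_dataset([1, 2]), 1.5)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_p(ConfusionTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # only the two perfectly separated tables are as extreme
        p = fisher_p(ConfusionTable(tp=10, fp=0, tn=10, fn=0))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, tn, fn = rng.integers(0, 9, size=4)
        p = fisher_p(ConfusionTable(int(tp), int(fp), int(tn), int(fn)))
        assert p == pytest.approx(fisher_two_sided(int(tp), int(fn), int(fp), int(tn)), rel=1e-9)


class TestOddsRatio:
    def test_cross_product_and_logistic_agree(self):
        or_, lo, hi, p, corrected = odds_ratio(ConfusionTable(tp=10, fp=2, fn=3, tn=15))
        assert or_ == pytest.approx(25.0, rel=1e-12)
        assert not corrected and lo < or_ < hi
        # independent logistic fit: coefficient of the binary predictor
        import statsmodels.api as sm

        y = np.array([1] * 10 + [0] * 2 + [1] * 3 + [0] * 15)
        x = np.array([1] * 12 + [0] * 18)
        res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.log(or_) == pytest.approx(res.params[1], abs=1e-6)
        assert lo == pytest.approx(np.exp(res.conf_int()[1][0]), rel=1e-4)

    def test_null_table(self):
        or_, lo, hi, _, _ = odds_ratio(ConfusionTable(5, 5, 5, 5))
        assert or_ == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_zero_cell_haldane(self):
        or_, lo, hi, _, corrected = odds_ratio(ConfusionTable(tp=10, fp=0, tn=8, fn=3))
        assert corrected and np.isfinite(or_) and np.isfinite(hi)


class TestWilson:
    def test_zero_successes(self):
        low, high = wilson_ci(0, 10)
        z = 1.959963984540054
        assert low == pytest.approx(0.0, abs=1e-12)
        assert high == pytest.approx(z**2 / (10 + z**2), rel=1e-9)

    def test_all_successes_mirror(self):
        low, high = wilson_ci(10, 10)
        assert high == pytest.approx(1.0, abs=1e-12)
        assert low == pytest.approx(1 - wilson_ci(0, 10)[1], rel=1e-9)

    @pytest.mark.parametrize("k,n", [(5, 10), (1, 7), (30, 40), (13, 200)])
    def test_matches_direct_formula(self, k, n):
        assert wilson_ci(k, n) == pytest.approx(wilson_by_formula(k, n), rel=1e-9)

    def test_coverage_in_simulation(self):
        # 95% Wilson interval covers p=0.3 between 93% and 97% of the time
        rng = np.random.default_rng(77)
        k = rng.binomial(40, 0.3, size=1000)
        covered = np.array([wilson_ci(int(ki), 40) for ki in k])
        frac = np.mean((covered[:, 0] <= 0.3) & (0.3 <= covered[:, 1]))
        assert 0.93 <= frac <= 0.97

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestMinimalP:
    def test_perfect_split_selected(self):
        ds = make_dataset(range(1, 11), outcome=[False] * 5 + [True] * 5)
        res, scan = optimize_binary_significance(ds, candidate_cutoffs(ds))
        assert res.cutoff == 6
        assert res.statistics["fisher_p"] == pytest.approx(2 / comb(10, 5), rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan(self, seed):
        ds = random_binary_instance(seed, n=20)
        grid = candidate_cutoffs(ds)
        res, scan = optimize_binary_significance(ds, grid)
        brute = []
        for v in grid.cutoffs:
            high = ds.marker >= v
            tp = int((high & ds.outcome).sum())
            fp = int((high & ~ds.outcome).sum())
            fn = int((~high & ds.outcome).sum())
            tn = int((~high & ~ds.outcome).sum())
            brute.append(fisher_two_sided(tp, fn, fp, tn))
        brute = np.asarray(brute)
        assert res.statistics["fisher_p"] == pytest.approx(brute.min(), rel=1e-9)
        assert res.cutoff == grid.cutoffs[np.argmin(brute)]

    def test_tie_breaks_to_lower_cutoff(self):
        # symmetric marker/outcome: p-values tie pairwise; lowest cutoff wins
        ds = make_dataset([1, 2, 3, 4], outcome=[True, False, False, True])
        res, scan = optimize_binary_significance(ds, candidate_cutoffs(ds))
        ties = scan.cutoffs[np.isclose(scan.p, scan.p.min())]
        assert res.cutoff == ties.min()

    def test_independent_outcome_warns(self):
        ds = make_dataset([1, 2, 3, 4], outcome=[True, False, True, False])
        res, _ = optimize_binary_significance(ds, candidate_cutoffs(ds))
        assert res.warnings


class TestROC:
    def test_perfect_marker_passes_corner(self):
        ds = make_dataset(range(1, 11), outcome=[False] * 5 + [True] * 5)
        roc = roc_curve(ds, candidate_cutoffs(ds))
        assert any(f == 0 and t == 1 for f, t in zip(*roc.interior))
        for metric in ("euclidean", "manhattan"):
            res = optimize_roc(roc, metric)
            assert res.cutoff == 6
            assert res.statistics["youden_j"] == pytest.approx(1.0)

    def test_reversed_orientation_reflects(self):
        ds = random_binary_instance(3)
        grid = candidate_cutoffs(ds)
        hi = roc_curve(ds, grid, "high_positive")
        lo = roc_curve(ds, grid, "low_positive")
        # sens_lo = 1 - sens_hi and spec_lo = 1 - spec_hi per cutoff:
        # the curve reflects through the diagonal
        order = np.argsort(hi.cutoffs)
        order_lo = np.argsort(lo.cutoffs)
        f_hi, t_hi = hi.interior
        f_lo, t_lo = lo.interior
        np.testing.assert_allclose(t_lo[order_lo], 1 - t_hi[order], atol=1e-12)
        np.testing.assert_allclose(f_lo[order_lo], 1 - f_hi[order], atol=1e-12)

    def test_null_marker_auc_near_half(self):
        rng = np.random.default_rng(12)
        ds = make_dataset(rng.normal(size=600), outcome=rng.random(600) < 0.5)
        roc = roc_curve(ds, candidate_cutoffs(ds))
        auc = np.trapezoid(roc.tpr, roc.fpr)
        se = np.sqrt(0.25 / 300)  # rough binomial-scale SE
        assert abs(auc - 0.5) < 3 * se

    def test_hand_computed_distances(self):
        # (sens, spec) = (0.9, 0.7) vs (0.8, 0.85): both metrics prefer the
        # second point (J = 0.65 > 0.6; dist 0.25 < 0.316)
        from markercut.binary import ROCCurve

        roc = ROCCurve(
            fpr=np.array([0.0, 0.3, 0.15, 1.0]),
            tpr=np.array([0.0, 0.9, 0.8, 1.0]),
            cutoffs=np.array([1.0, 2.0]),
            orientation="high_positive",
        )
        assert optimize_roc(roc, "euclidean").cutoff == 2.0
        assert optimize_roc(roc, "manhattan").cutoff == 2.0

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan"])
    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_matches_brute_force(self, metric, seed):
        ds = random_binary_instance(seed, n=60)
        grid = candidate_cutoffs(ds)
        roc = roc_curve(ds, grid)
        res = optimize_roc(roc, metric)
        best, best_cut = np.inf, None
        for v in grid.cutoffs:
            t = confusion_at(ds, v)
            d = (
                np.hypot(1 - t.sensitivity, 1 - t.specificity)
                if metric == "euclidean"
                else (1 - t.sensitivity) + (1 - t.specificity)
            )
            if d < best - 1e-15:
                best, best_cut = d, v
        assert res.cutoff == best_cut

    def test_manhattan_maximizes_youden(self):
        ds = random_binary_instance(9, n=100)
        grid = candidate_cutoffs(ds)
        res = optimize_roc(roc_curve(ds, grid), "manhattan")
        js = []
        for v in grid.cutoffs:
            t = confusion_at(ds, v)
            js.append(t.sensitivity + t.specificity - 1)
        assert res.statistics["youden_j"] == pytest.approx(max(js), abs=1e-12)


class TestConstrained:
    def test_perfect_marker(self):
        ds = make_dataset(range(1, 11), outcome=[False] * 5 + [True] * 5)
        scan = binary_scan(ds, candidate_cutoffs(ds))
        assert constrained_cutoff(scan, "sensitivity", 0.9).cutoff == 6
        assert constrained_cutoff(scan, "specificity", 0.9).cutoff == 6

    def test_unsatisfiable_threshold(self):
        ds = make_dataset([1, 2, 3, 4], outcome=[True, False, False, True])
        scan = binary_scan(ds, candidate_cutoffs(ds))
        with pytest.raises(ValueError, match="threshold must lie"):
            constrained_cutoff(scan, "sensitivity", 1.0)

    @pytest.mark.parametrize("constraint", ["sensitivity", "specificity"])
    @pytest.mark.parametrize("seed", [31, 32])
    def test_matches_brute_force(self, constraint, seed):
        ds = random_binary_instance(seed, n=80)
        grid = candidate_cutoffs(ds)
        scan = binary_scan(ds, grid)
        res = constrained_cutoff(scan, constraint, 0.7)
        best = (-np.inf, None)
        for v in grid.cutoffs:
            t = confusion_at(ds, v)
            meas = t.sensitivity if constraint == "sensitivity" else t.specificity
            comp = t.specificity if constraint == "sensitivity" else t.sensitivity
            if meas > 0.7 and comp > best[0] + 1e-15:
                best = (comp, v)
        comp_key = "specificity" if constraint == "sensitivity" else "sensitivity"
        assert res.statistics[comp_key] == pytest.approx(best[0], abs=1e-12)


class TestDiagnostics:
    def test_proportion_significant_counts(self):
        class Scan:
            p = np.array([0.01, 0.2, 0.03, 0.8])

        assert proportion_significant(Scan(), 0.05) == pytest.approx(0.5)
        Scan.p = np.ones(4)
        assert proportion_significant(Scan(), 0.05) == 0.0
        Scan.p = np.full(4, 0.001)
        assert proportion_significant(Scan(), 0.05) == 1.0

    def test_sensitivity_consistent_with_miss_rate(self):
        ds = random_binary_instance(41, n=50)
        grid = candidate_cutoffs(ds)
        scan = binary_scan(ds, grid)
        for i, v in enumerate(grid.cutoffs):
            miss = np.mean(ds.marker[ds.outcome] < v)  # positives called low
            assert scan.sensitivity[i] == pytest.approx(1 - miss, abs=1e-12)

    def test_auto_orientation(self):
        ds = make_dataset([1, 2, 3, 4], outcome=[False, False, True, True])
        assert auto_orientation(ds) == "high_positive"
        flipped = make_dataset([1, 2, 3, 4], outcome=[True, True, False, False])
        assert auto_orientation(flipped) == "low_positive"


class TestEquivocalZone:
    def test_perfect_marker_zone_collapses(self):
        ds = make_dataset(range(1, 11), outcome=[False] * 5 + [True] * 5)
        zone = equivocal_zone(ds, candidate_cutoffs(ds), 0.9, 0.9)
        assert zone.lower == zone.upper == 6
        assert zone.fraction_equivocal == 0.0

    def test_overlapping_classes_reliable_calls_meet_thresholds(self):
        rng = np.random.default_rng(56)
        marker = np.concatenate([rng.normal(0, 1, 250), rng.normal(2.5, 1, 250)])
        ds = make_dataset(marker, outcome=np.repeat([False, True], 250))
        zone = equivocal_zone(ds, candidate_cutoffs(ds), 0.9, 0.9)
        calls = zone.classify(ds.marker)
        reliable = calls != "equivocal"
        sens = np.mean(calls[ds.outcome & reliable] == "positive")
        spec = np.mean(calls[~ds.outcome & reliable] == "negative")
        assert sens > 0.9 and spec > 0.9
        assert zone.lower <= zone.upper
        assert 0 < zone.fraction_equivocal < 0.2

    def test_looser_thresholds_narrow_zone(self):
        rng = np.random.default_rng(56)
        marker = np.concatenate([rng.normal(0, 1, 200), rng.normal(1.5, 1, 200)])
        ds = make_dataset(marker, outcome=np.repeat([False, True], 200))
        grid = candidate_cutoffs(ds)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # loose thresholds may invert the zone
            tight = equivocal_zone(ds, grid, 0.95, 0.95)
            loose = equivocal_zone(ds, grid, 0.5, 0.5)
        width_tight = tight.upper - tight.lower
        width_loose = loose.upper - loose.lower
        assert width_loose <= width_tight
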