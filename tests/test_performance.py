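import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from nodemetric.data import TruthStatus
from nodemetric.performance import (
    ConfusionMatrix,
    Orientation,
    auc_ci,
    classify_at_cutoff,
    confusion_from_predictions,
    default_orientation,
    logistic_fit_single,
    performance_metrics,
    roc_curve,
    round_half_up,
    transfer_validation,
    youden_optimal_cutoff,
)
from nodemetric.simulate import default_config, generate_cohort
from nodemetric.ratios import annotate_ratios
from nodemetric.data import build_sln_set

LOWER = Orientation.LOWER_IS_POSITIVE
HIGHER = Orientation.HIGHER_IS_POSITIVE


def brute_force_auc(values, pos, orientation):
    """Pairwise concordance: P(positive scores more malignant) + half ties."""
    v = np.asarray(values, float)
    s = -v if orientation is LOWER else v
    x, y = s[pos], s[~pos]
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return (gt + 0.5 * eq) / (x.size * y.size)


def brute_force_youden(values, pos, orientation):
    """Exhaustive threshold scan over the observed unique values."""
    v = np.asarray(values, float)
    best = -np.inf
    for t in np.unique(v):
        pred = v <= t if orientation is LOWER else v >= t
        j = pred[pos].mean() - pred[~pos].mean()
        best = max(best, j)
    return best


def random_fixture(rng, n=40):
    pos = rng.random(n) < rng.uniform(0.2, 0.8)
    if pos.all() or not pos.any():
        pos[0] = True
        pos[1] = False
    values = np.where(
        pos,
        rng.normal(0.5, 0.15, n),
        rng.normal(0.65, 0.15, n),
    )
    if rng.random() < 0.5:  # inject ties
        values = np.round(values, 1)
    return values, pos


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], LOWER)
        assert roc.auc == 1.0

    def test_uninformative_constant_values(self):
        roc = roc_curve([5.0] * 8, [1, 0] * 4, LOWER)
        assert roc.auc == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_concordance(self, seed):
        rng = np.random.default_rng(seed)
        values, pos = random_fixture(rng)
        for orientation in (LOWER, HIGHER):
            roc = roc_curve(values, pos, orientation)
            assert roc.auc == pytest.approx(
                brute_force_auc(values, pos, orientation), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        values, pos = random_fixture(rng)
        roc = roc_curve(values, pos, LOWER)
        assert roc.auc == pytest.approx(roc_auc_score(pos, -values), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        values, pos = random_fixture(rng)
        values = np.abs(values) + 0.1
        a1 = roc_curve(values, pos, LOWER).auc
        a2 = roc_curve(np.log(values), pos, LOWER).auc
        a3 = roc_curve(values**3, pos, LOWER).auc
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert a1 == pytest.approx(a3, abs=1e-12)

    def test_orientation_duality(self, rng):
        values, pos = random_fixture(rng)
        a_low = roc_curve(values, pos, LOWER).auc
        a_high = roc_curve(-values, pos, HIGHER).auc
        assert a_low == pytest.approx(a_high, abs=1e-12)

    def test_points_monotone_after_orientation(self, rng):
        values, pos = random_fixture(rng)
        roc = roc_curve(values, pos, HIGHER)
        sens = [p[1] for p in roc.points]
        fpr = [p[2] for p in roc.points]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(fpr, fpr[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 2, 3], [1, 1, 1], LOWER)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            roc_curve([1, 2, 3], [1, 0], LOWER)


class TestAucCI:
    def test_upper_bound_truncated_at_one(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], LOWER)
        lo, hi = auc_ci(roc, method="delong")
        assert hi == 1.0
        assert lo <= roc.auc

    def test_bootstrap_deterministic_given_seed(self, rng):
        values, pos = random_fixture(rng)
        roc = roc_curve(values, pos, LOWER)
        ci1 = auc_ci(roc, method="bootstrap", n_boot=200, seed=42)
        ci2 = auc_ci(roc, method="bootstrap", n_boot=200, seed=42)
        assert ci1 == ci2

    def test_delong_matches_structural_component_oracle(self, rng):
        values, pos = random_fixture(rng, n=30)
        roc = roc_curve(values, pos, LOWER)
        lo, hi = auc_ci(roc, method="delong")
        # independent slow computation with explicit loops
        s = -values
        x, y = s[pos], s[~pos]
        m, n = len(x), len(y)
        psi = np.zeros((m, n))
        for i in range(m):
            for j in range(n):
                psi[i, j] = 1.0 if x[i] > y[j] else (0.5 if x[i] == y[j] else 0.0)
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        auc = psi.mean()
        z = 1.959963984540054
        assert lo == pytest.approx(max(auc - z * np.sqrt(var), 0.0), abs=1e-12)
        assert hi == pytest.approx(min(auc + z * np.sqrt(var), 1.0), abs=1e-12)

    def test_delong_needs_two_per_class(self):
        roc = roc_curve([1, 5, 6, 7], [1, 0, 0, 0], LOWER)
        with pytest.raises(ValueError, match="bootstrap"):
            auc_ci(roc, method="delong")


class TestYoudenCutoff:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], LOWER)
        cut = youden_optimal_cutoff(roc)
        assert cut.youden_j == 1.0
        assert 3 <= cut.cutoff < 10

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        values, pos = random_fixture(rng)
        for orientation in (LOWER, HIGHER):
            roc = roc_curve(values, pos, orientation)
            cut = youden_optimal_cutoff(roc)
            assert cut.youden_j == pytest.approx(
                brute_force_youden(values, pos, orientation), abs=1e-12
            )

    def test_j_identity_at_cutoff(self, rng):
        values, pos = random_fixture(rng)
        roc = roc_curve(values, pos, LOWER)
        cut = youden_optimal_cutoff(roc)
        assert cut.youden_j == pytest.approx(
            cut.sens_at_cutoff + cut.spec_at_cutoff - 1.0, abs=1e-15
        )

    def test_published_operating_point_shape(self):
        """71/4 positives below/above and 2/67 negatives below/above the
        optimum reproduce the published sens 0.95 / spec 0.97 / J 0.92."""
        values = np.r_[[0.40] * 71, [0.90] * 4, [0.38] * 2, [0.85] * 67]
        pos = np.r_[np.ones(75, bool), np.zeros(69, bool)]
        cut = youden_optimal_cutoff(roc_curve(values, pos, LOWER))
        assert cut.cutoff == pytest.approx(0.40)
        assert round_half_up(cut.sens_at_cutoff) == 0.95
        assert round_half_up(cut.spec_at_cutoff) == 0.97
        assert round_half_up(cut.youden_j) == 0.92

    def test_tie_broken_toward_higher_sensitivity(self):
        # thresholds 2 and 4 both give J = 0.5; 4 has sens 1.0
        values = [1, 2, 3, 4, 3, 4, 5, 6]
        pos = [1, 1, 1, 1, 0, 0, 0, 0]
        cut = youden_optimal_cutoff(roc_curve(values, pos, LOWER))
        assert cut.sens_at_cutoff == 1.0
        assert cut.cutoff == 4


class TestClassifyAtCutoff:
    def test_value_at_cutoff_is_positive_for_lower_oriented(self):
        assert classify_at_cutoff([0.49], 0.49, LOWER) == [True]

    def test_ratio_below_cutoff_is_metastatic(self):
        assert classify_at_cutoff([0.38], 0.49, LOWER) == [True]

    def test_ordinal_score_below_cutoff_is_benign(self):
        assert classify_at_cutoff([2], 3, HIGHER) == [False]

    def test_absent_values_stay_absent(self):
        preds = classify_at_cutoff([0.4, None, float("nan")], 0.49, LOWER)
        assert preds == [True, None, None]

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify_at_cutoff([1.0], float("nan"), LOWER)


class TestPerformanceMetrics:
    def test_published_pooled_set_row(self):
        perf = performance_metrics(ConfusionMatrix(tp=71, tn=67, fp=2, fn=4))
        got = [round_half_up(x) for x in
               (perf.sens, perf.spec, perf.ppv, perf.npv, perf.acc, perf.youden_j)]
        assert got == [0.95, 0.97, 0.97, 0.94, 0.96, 0.92]

    def test_published_second_reader_row(self):
        perf = performance_metrics(ConfusionMatrix(tp=81, tn=48, fp=21, fn=1))
        got = [round_half_up(x) for x in
               (perf.sens, perf.spec, perf.ppv, perf.npv, perf.acc, perf.youden_j)]
        assert got == [0.99, 0.70, 0.79, 0.98, 0.85, 0.68]

    def test_perfect_classifier(self):
        perf = performance_metrics(ConfusionMatrix(tp=5, tn=7, fp=0, fn=0))
        assert (perf.sens, perf.spec, perf.ppv, perf.npv, perf.acc) == (1,) * 5
        assert perf.youden_j == 1.0

    def test_identities_hold_exactly(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            if tp + fp + tn + fn == 0:
                continue
            cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
            perf = performance_metrics(cm)
            assert perf.acc * cm.total == pytest.approx(cm.tp + cm.tn, abs=1e-9)
            if perf.sens is not None and perf.spec is not None:
                assert perf.youden_j == pytest.approx(
                    perf.sens + perf.spec - 1.0, abs=1e-15
                )

    def test_undefined_denominator_flagged_not_zero(self):
        perf = performance_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=3))
        assert perf.ppv is None
        assert "ppv" in perf.undefined
        assert perf.youden_j is not None  # sens and spec still defined

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            performance_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_fnr_of_two_in_seven(self):
        perf = performance_metrics(ConfusionMatrix(tp=5, tn=62, fp=2, fn=2))
        assert round_half_up(perf.fnr) == 0.29


@pytest.fixture(scope="module")
def annotated_sln():
    records, panels, _ = generate_cohort(default_config(seed=3))
    annotate_ratios(records, panels)
    return build_sln_set(records)


class TestTransferValidation:
    def test_self_transfer_matches_derivation(self, annotated_sln):
        from nodemetric.data import Reader, metric_values

        aset = annotated_sln
        r1 = aset.reader_records(Reader.R1)
        vals = [metric_values(r, "adc_epi") for r in r1]
        labels = [r.truth_status for r in r1]
        roc = roc_curve(vals, labels, LOWER)
        cut = youden_optimal_cutoff(roc)
        cm, perf = transfer_validation(cut, aset, "adc_epi", reader=Reader.R1)
        assert perf.sens == pytest.approx(cut.sens_at_cutoff, abs=1e-12)
        assert perf.spec == pytest.approx(cut.spec_at_cutoff, abs=1e-12)

    def test_deterministic(self, annotated_sln):
        from nodemetric.data import Reader

        a = transfer_validation(0.8, annotated_sln, "cadc_epi", reader=Reader.R1)
        b = transfer_validation(0.8, annotated_sln, "cadc_epi", reader=Reader.R1)
        assert (a[0].tp, a[0].fp, a[0].tn, a[0].fn) == (b[0].tp, b[0].fp, b[0].tn, b[0].fn)

    def test_absent_metric_counted(self, annotated_sln):
        from nodemetric.data import Reader

        # volumetric ADC is not re-measured by reader 2
        with pytest.raises(ValueError, match="present"):
            transfer_validation(900.0, annotated_sln, "adc_vol", reader=Reader.R2)

    def test_engineered_quadruple(self):
        """A target classification of TP=70 TN=64 FP=5 FN=5 yields the
        published acc 0.93 and J 0.86."""
        values = np.r_[[0.4] * 70, [0.9] * 5, [0.4] * 5, [0.9] * 64]
        pos = np.r_[np.ones(75, bool), np.zeros(69, bool)]
        preds = classify_at_cutoff(values, 0.49, LOWER)
        perf = performance_metrics(confusion_from_predictions(pos, preds))
        assert round_half_up(perf.acc) == 0.93
        assert round_half_up(perf.youden_j) == 0.86

    def test_transfer_close_to_derivation_on_fresh_sample(self):
        """Monte-Carlo: a cut-off applied to a fresh cohort drawn from the
        same generating distribution performs close to its derivation."""
        from nodemetric.data import Reader, metric_values
        from nodemetric.simulate import recovery_config

        def arrays(seed):
            records, panels, _ = generate_cohort(recovery_config(seed=seed, n_per_group=200))
            annotate_ratios(records, panels)
            r1 = [r for r in records if r.reader is Reader.R1]
            vals = [metric_values(r, "madc_epi") for r in r1]
            labels = [r.truth_status for r in r1]
            return vals, labels, r1

        vals, labels, _ = arrays(11)
        cut = youden_optimal_cutoff(roc_curve(vals, labels, LOWER))
        _, _, target = arrays(12)
        _, perf = transfer_validation(cut, target, "madc_epi")
        assert perf.sens == pytest.approx(cut.sens_at_cutoff, abs=0.10)
        assert perf.spec == pytest.approx(cut.spec_at_cutoff, abs=0.10)


class TestLogisticFit:
    def test_uninformative_predictor(self, rng):
        values = rng.normal(0, 1, 400)
        labels = rng.random(400) < 0.5
        fit = logistic_fit_single(values, labels)
        assert abs(fit.slope) < 0.2
        assert fit.mcfadden_r2 < 0.02
        assert not fit.separation

    def test_loglik_matches_numeric_maximization(self, rng):
        values = np.r_[rng.normal(0.45, 0.1, 12), rng.normal(0.65, 0.1, 15)]
        labels = np.r_[np.ones(12), np.zeros(15)].astype(bool)
        fit = logistic_fit_single(values, labels)

        def negll(beta):
            eta = beta[0] + beta[1] * values
            return -np.sum(labels * eta - np.log1p(np.exp(eta)))

        res = minimize(negll, x0=[0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert fit.intercept == pytest.approx(res.x[0], rel=1e-3, abs=1e-3)
        assert fit.slope == pytest.approx(res.x[1], rel=1e-3, abs=1e-3)

    def test_mcfadden_definition(self, rng):
        values = np.r_[rng.normal(0.45, 0.1, 30), rng.normal(0.60, 0.1, 30)]
        labels = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        fit = logistic_fit_single(values, labels)
        assert fit.mcfadden_r2 == pytest.approx(
            1.0 - fit.loglik / fit.null_loglik, abs=1e-12
        )
        assert 0.0 <= fit.mcfadden_r2 < 1.0

    def test_complete_separation_flagged(self):
        values = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        labels = [1, 1, 1, 0, 0, 0]
        fit = logistic_fit_single(values, labels)
        assert fit.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_fit_single([1.0, 2.0], [1, 1])


def test_default_orientations():
    assert default_orientation("madc_epi") is LOWER
    assert default_orientation("adc_vol") is LOWER
    assert default_orientation("sad") is HIGHER
    assert default_orientation("node_rads") is HIGHER
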