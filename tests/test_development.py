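"""Development pipeline: diagnostics, binarization, fitting, selection,
score points, discrimination/calibration statistics and orchestration.

Each numerical operation is checked against an independent oracle
(exhaustive sweeps, pairwise counts, likelihood grid search) rather than
against the implementation's own machinery.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest

from easilung.development import (
    CohortDataset,
    auc,
    backward_eliminate,
    bootstrap_stability,
    build_design,
    decile_logit_table,
    derive_score_points,
    develop_score,
    fit_logistic,
    hosmer_lemeshow,
    overall_performance,
    two_by_two_odds_ratio,
    youden_binarization,
    youden_threshold,
)
from easilung.errors import ContractError, EstimationError
from easilung.scoring import published_model
from easilung.spectrum import CLASSES, SpectrumProfile
from easilung.synthetic_data import SimulationConfig, simulate_cohort

# ---------------------------------------------------------------------------
# oracles


def auc_pairwise_oracle(scores, labels):
    """O(n^2) comparison count: wins + half-ties over positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def youden_sweep_oracle(values, labels):
    """Best J over every observed cutoff and both directions, by direct loops."""
    best = (-np.inf, None, None)
    for c in [-np.inf, *sorted(set(values))]:
        for direction in ("greater", "less"):
            if direction == "greater":
                se = np.mean([v > c for v, y in zip(values, labels) if y == 1])
                sp = np.mean([v <= c for v, y in zip(values, labels) if y == 0])
            else:
                se = np.mean([v <= c for v, y in zip(values, labels) if y == 1])
                sp = np.mean([v > c for v, y in zip(values, labels) if y == 0])
            j = se + sp - 1
            if j > best[0] + 1e-12:
                best = (j, c, direction)
    return best


def logistic_grid_oracle(x, y):
    """Brute-force likelihood maximization over (intercept, slope) by
    iteratively refined grid search, independent of any fitting library."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def nll(b0, b1):
        eta = b0 + b1 * x
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    b0_lo, b0_hi, b1_lo, b1_hi = -10.0, 10.0, -10.0, 10.0
    for _ in range(8):
        b0s = np.linspace(b0_lo, b0_hi, 41)
        b1s = np.linspace(b1_lo, b1_hi, 41)
        grid = np.array([[nll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        db0 = (b0_hi - b0_lo) / 40
        db1 = (b1_hi - b1_lo) / 40
        b0_lo, b0_hi = b0s[i] - 2 * db0, b0s[i] + 2 * db0
        b1_lo, b1_hi = b1s[j] - 2 * db1, b1s[j] + 2 * db1
    return b0s[i], b1s[j]


# ---------------------------------------------------------------------------
# diagnostics


class TestDecileLogitTable:
    def test_recovers_slope_of_logit_linear_data(self, rng):
        x = rng.uniform(0, 10, 5000)
        y = (rng.random(5000) < expit(-2 + 0.5 * x)).astype(int)
        table = decile_logit_table(x, y)
        assert len(table) == 10
        slope = np.polyfit(table["mean_value"], table["logit"], 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)

    def test_single_class_labels_not_computable(self):
        with pytest.raises(ContractError):
            decile_logit_table([1, 2, 3], [1, 1, 1])

    def test_constant_values_collapse_to_one_group(self, caplog):
        with caplog.at_level("WARNING"):
            table = decile_logit_table([2.0] * 20, [0, 1] * 10)
        assert len(table) == 1

    def test_pure_groups_use_continuity_corrected_logit(self):
        table = decile_logit_table(list(range(20)), [0] * 10 + [1] * 10, groups=2)
        assert table["logit"].iloc[0] == pytest.approx(math.log(0.5 / 10.5))
        assert np.isfinite(table["logit"]).all()


class TestYoudenBinarization:
    def test_perfect_split(self):
        res = youden_binarization([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.cutoff == 2 and res.youden_j == pytest.approx(1.0)
        assert res.direction == "greater"

    def test_anticorrelated_values_flip_direction_same_j(self):
        fwd = youden_binarization([1, 2, 3, 4], [0, 0, 1, 1])
        rev = youden_binarization([1, 2, 3, 4], [1, 1, 0, 0])
        assert rev.direction == "less"
        assert rev.youden_j == pytest.approx(fwd.youden_j)

    def test_constant_values_degenerate(self):
        with pytest.raises(ContractError):
            youden_binarization([3.0] * 10, [0, 1] * 5)

    def test_matches_exhaustive_sweep_on_random_data(self, rng):
        values = rng.normal(size=50).round(1)  # rounding forces ties
        labels = (rng.random(50) < expit(values)).astype(int)
        res = youden_binarization(values, labels)
        j_star, c_star, dir_star = youden_sweep_oracle(values, labels)
        assert res.youden_j == pytest.approx(j_star)
        if dir_star == res.direction:
            assert res.cutoff == pytest.approx(c_star)


# ---------------------------------------------------------------------------
# logistic fitting and selection


class TestFitLogistic:
    def test_symmetric_balanced_data_zero_intercept(self):
        # mirror-symmetric design: p(-2) = 0.2, p(+2) = 0.8 empirically
        x = np.array([-2.0] * 10 + [2.0] * 10)
        y = np.array([1, 1] + [0] * 8 + [0, 0] + [1] * 8)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.terms[0].beta == pytest.approx(math.log(4) / 2, abs=1e-6)

    def test_matches_likelihood_grid_oracle(self, rng):
        x = rng.normal(size=20)
        y = (rng.random(20) < expit(0.3 + 0.8 * x)).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        b0, b1 = logistic_grid_oracle(x, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-3)
        assert fit.terms[0].beta == pytest.approx(b1, abs=1e-3)

    def test_odds_ratio_is_exp_beta(self, rng):
        x = rng.normal(size=(80, 3))
        y = (rng.random(80) < expit(x @ [0.5, -0.5, 0.2])).astype(int)
        fit = fit_logistic(pd.DataFrame(x, columns=list("abc")), y)
        for t in fit.terms:
            assert t.odds_ratio == pytest.approx(math.exp(t.beta))

    def test_perfect_separation_reported(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(EstimationError):
            fit_logistic(pd.DataFrame({"x": x}), y)

    def test_rank_deficiency_names_collinear_predictors(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.raises(EstimationError, match="collinear"):
            fit_logistic(df, y)


class TestBackwardElimination:
    def test_alpha_one_keeps_the_full_model(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = (rng.random(100) < 0.5).astype(int)
        selected, _ = backward_eliminate(df, y, alpha=1.0)
        assert selected == list("abcd")

    def test_strong_predictors_all_survive(self, rng):
        n = 400
        x = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(x @ [1.5, -1.5])).astype(int)
        selected, fit = backward_eliminate(pd.DataFrame(x, columns=["u", "v"]), y, alpha=0.2)
        assert selected == ["u", "v"]
        assert all(t.p_value <= 0.2 for t in fit.terms)

    def test_noise_predictor_usually_eliminated(self, rng):
        # a zero-effect covariate has p > 0.2 about 80% of the time
        removed = 0
        reps = 40
        for _ in range(reps):
            n = 500
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = (rng.random(n) < expit(1.2 * x)).astype(int)
            selected, _ = backward_eliminate(
                pd.DataFrame({"signal": x, "noise": noise}), y, alpha=0.2
            )
            removed += "noise" not in selected
        assert removed / reps > 0.6
        assert "signal" in selected


@pytest.fixture(scope="module")
def strong_plus_noise():
    rng = np.random.default_rng(11)
    n = 1000
    exposed = (rng.random(n) < 0.4).astype(float)  # OR ~ 14 predictor
    noise = rng.normal(size=n)
    y = (rng.random(n) < expit(-2.0 + math.log(14) * exposed)).astype(int)
    return pd.DataFrame({"exposed": exposed, "noise": noise}), y


class TestBootstrapStability:
    def test_strong_predictor_retained_noise_dropped(self, strong_plus_noise):
        design, y = strong_plus_noise
        stable, freqs = bootstrap_stability(design, y, B=200, retain_fraction=0.6, seed=3)
        assert freqs["exposed"] >= 0.95
        assert freqs["noise"] < 0.5
        assert stable == ["exposed"]

    def test_fixed_seed_reproducible(self, strong_plus_noise):
        design, y = strong_plus_noise
        out1 = bootstrap_stability(design, y, B=30, seed=42)
        out2 = bootstrap_stability(design, y, B=30, seed=42)
        assert out1 == out2


class TestScorePoints:
    @pytest.mark.parametrize(
        "beta,points",
        [(1.7547, 175), (-0.7317, -73), (0.6209, 62), (-0.0863, -9),
         (0.005, 1), (-0.005, -1), (0.0049, 0)],
    )
    def test_round_half_away_from_zero_of_100_beta(self, beta, points):
        from easilung.development import FittedModel, TermEstimate

        fit = FittedModel(
            terms=[TermEstimate("t", beta, 0.1, 0.01, math.exp(beta), (0, 1))],
            intercept=0.5,
            intercept_se=0.1,
            log_likelihood=-1.0,
        )
        assert derive_score_points(fit) == {"t": points}

    def test_points_reconstruct_linear_predictor_within_rounding(self, rng):
        from easilung.development import FittedModel, TermEstimate

        betas = rng.normal(scale=0.5, size=6)
        fit = FittedModel(
            terms=[TermEstimate(f"t{i}", b, 0.1, 0.01, math.exp(b), (0, 1)) for i, b in enumerate(betas)],
            intercept=0.0, intercept_se=0.1, log_likelihood=-1.0,
        )
        points = derive_score_points(fit)
        x = rng.uniform(0, 40, size=6)
        score = sum(points[f"t{i}"] * x[i] for i in range(6))
        exact = 100 * sum(b * xi for b, xi in zip(betas, x))
        assert abs(score - exact) <= 0.5 * 6 * x.max()


# ---------------------------------------------------------------------------
# discrimination / calibration statistics


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_with_ties(self, rng):
        scores = rng.integers(0, 10, size=30).astype(float)  # many ties
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(auc_pairwise_oracle(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            auc([1, 2, 3], [1, 1, 1])


class TestHosmerLemeshow:
    def test_exact_groupwise_agreement_gives_zero_statistic(self):
        # 10 risk levels, 10 samples each, observed rate == predicted rate
        probs, labels = [], []
        for k in range(1, 11):
            p = k / 11
            n_events = round(10 * p)
            probs += [p] * 10
            labels += [1] * n_events + [0] * (10 - n_events)
        stat, df, p_value = hosmer_lemeshow(probs, labels, groups=10)
        expected_stat = sum(
            (round(10 * k / 11) - 10 * k / 11) ** 2 / (10 * (k / 11) * (1 - k / 11))
            for k in range(1, 11)
        )
        assert stat == pytest.approx(expected_stat, abs=1e-9)
        assert df == 8

    def test_matches_hand_computation_on_20_samples(self):
        probs = np.linspace(0.05, 0.95, 20)
        labels = np.array([0, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1])
        stat, df, _ = hosmer_lemeshow(probs, labels, groups=10)
        manual = 0.0
        for g in range(10):  # pairs of consecutive samples form the deciles
            o = labels[2 * g] + labels[2 * g + 1]
            e = probs[2 * g] + probs[2 * g + 1]
            manual += (o - e) ** 2 / (e * (1 - e / 2))
        assert stat == pytest.approx(manual, abs=1e-9)
        assert df == 8

    def test_p_values_approximately_uniform_under_correct_model(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(150):
            n = 400
            x = rng.normal(size=n)
            y = (rng.random(n) < expit(-0.5 + x)).astype(int)
            fit = fit_logistic(pd.DataFrame({"x": x}), y)
            probs = expit(fit.intercept + fit.terms[0].beta * x)
            pvals.append(hosmer_lemeshow(probs, y)[2])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestYoudenThreshold:
    def test_perfect_split_degenerate_cis(self):
        res = youden_threshold([-10, -5, 5, 10], [0, 0, 1, 1])
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.sensitivity_ci == (1.0, 1.0)

    def test_matches_exhaustive_sweep(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < expit(2 * scores)).astype(int)
        res = youden_threshold(scores, labels)
        j_star, c_star, _ = youden_sweep_oracle(scores, labels)
        assert res.youden_j == pytest.approx(j_star)
        assert res.threshold == pytest.approx(c_star)

    def test_ci_half_width_shrinks_like_inverse_sqrt_n(self, rng):
        widths = []
        for n in (200, 800):
            scores = rng.normal(size=n)
            labels = (rng.random(n) < expit(scores)).astype(int)
            res = youden_threshold(scores, labels)
            widths.append(res.sensitivity_ci[1] - res.sensitivity_ci[0])
        assert widths[1] < widths[0]
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.6)  # ~1/sqrt(4)


# ---------------------------------------------------------------------------
# overall performance and 2x2 odds ratios


def _profile(sample_id, ca, ct, target_mb=50.0, total=100):
    counts = {c: 0 for c in CLASSES}
    counts["C>A"] = ca
    counts["C>T"] = total - ca if ct is None else ct
    counts["G>A"] = total - counts["C>A"] - counts["C>T"]
    return SpectrumProfile.from_counts(sample_id, counts, target_mb)


class TestOverallPerformance:
    def test_gate_dominance_for_specificity(self):
        # every non-lung sample below 1 sub/Mb: specificity 100% whatever its spectrum
        model = published_model()
        profiles, labels = [], {}
        for i in range(5):
            counts = {c: 0 for c in CLASSES}
            counts["C>A"] = 30  # lung-looking spectrum
            counts["C>T"] = 10
            profiles.append(SpectrumProfile.from_counts(f"N{i}", counts, 100.0))  # 0.4 sub/Mb
            labels[f"N{i}"] = "non-lung"
        profiles.append(_profile("L0", 30, 10))
        labels["L0"] = "lung"
        perf = overall_performance(CohortDataset(profiles, labels), model)
        assert perf.specificity == 1.0

    def test_matches_naive_per_sample_tally(self, default_cohort):
        from easilung.scoring import LABEL_LUNG, classify_sample

        cohort, _ = default_cohort
        model = published_model()
        perf = overall_performance(cohort, model)
        tp = fn = tn = fp = 0
        for p in cohort.profiles:
            is_lung = cohort.labels[p.sample_id] == "lung"
            called_lung = classify_sample(p, model).label == LABEL_LUNG
            tp += is_lung and called_lung
            fn += is_lung and not called_lung
            tn += (not is_lung) and (not called_lung)
            fp += (not is_lung) and called_lung
        assert perf.sensitivity == pytest.approx(tp / (tp + fn))
        assert perf.specificity == pytest.approx(tn / (tn + fp))

    def test_low_burden_lung_cases_count_as_misses(self):
        model = published_model()
        profiles, labels = [], {}
        profiles.append(_profile("L1", 30, 10))  # scored, lung-like, 2 sub/Mb
        counts = {c: 0 for c in CLASSES}
        counts["C>A"] = 10
        profiles.append(SpectrumProfile.from_counts("L2", counts, 50.0))  # 0.2 sub/Mb, gated
        profiles.append(_profile("N1", 0, 60))
        labels.update({"L1": "lung", "L2": "lung", "N1": "non-lung"})
        perf = overall_performance(CohortDataset(profiles, labels), model)
        assert perf.sensitivity == pytest.approx(0.5)  # the gated lung tumor is a miss


class TestTwoByTwoOddsRatio:
    def test_balanced_table_or_one(self):
        res = two_by_two_odds_ratio(10, 20, 5, 10)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci95[0] < 1 < res.ci95[1]

    def test_zero_cell_haldane_correction(self, caplog):
        with caplog.at_level("WARNING"):
            res = two_by_two_odds_ratio(5, 0, 3, 7)
        assert np.isfinite(res.odds_ratio)

    def test_negative_count_rejected(self):
        with pytest.raises(ContractError):
            two_by_two_odds_ratio(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# orchestration


class TestDevelopScore:
    def test_fixed_seed_identical_report(self, default_cohort):
        cohort, _ = default_cohort
        r1 = develop_score(cohort, bootstrap_B=20, seed=123)
        r2 = develop_score(cohort, bootstrap_B=20, seed=123)
        assert r1.to_dict() == r2.to_dict()

    def test_label_independent_spectra_yield_no_out_of_sample_discrimination(self):
        # Develop on a cohort whose labels are independent of the spectra.
        # In-sample statistics are inflated by the Youden cut-point and
        # backward-selection optimism, so the honest null check is out of
        # sample: the developed score must not discriminate a fresh cohort.
        from easilung.scoring import easilung_score
        from easilung.synthetic_data import preset_profiles

        lung, _ = preset_profiles()
        means = {"lung": lung, "non-lung": lung}  # labels carry no signal
        cohort, _ = simulate_cohort(
            SimulationConfig(n_samples=800, seed=19, lung_fraction=0.3, spectrum_means=means)
        )
        try:
            report = develop_score(cohort, bootstrap_B=40, seed=19)
        except EstimationError:
            return  # nothing survived selection at all: an acceptable null outcome
        fresh, _ = simulate_cohort(
            SimulationConfig(n_samples=800, seed=20, lung_fraction=0.3, spectrum_means=means)
        )
        scored = fresh.scored_subset()
        scores = [easilung_score(p.freqs, report.score_model) for p in scored]
        assert auc(scores, fresh.y(scored)) == pytest.approx(0.5, abs=0.1)

    def test_auto_binarization_runs_and_selects_something(self, default_cohort):
        cohort, _ = default_cohort
        scored = cohort.scored_subset()
        y = cohort.y(scored)
        design, cuts = build_design(cohort.freq_frame(scored), y, binarize="auto")
        assert design.shape[1] == 12
        assert set(cuts) <= set(CLASSES)
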