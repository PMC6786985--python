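"""Score-development pipeline.

Re-implements the full procedure that produced the published score from a
labelled cohort of spectrum profiles:

1. low-burden gate — samples with < 1 sub/Mb are set aside as non-lung;
2. log-linearity diagnostics per class (decile empirical-logit table) and
   Youden-index binarization of classes with threshold-like behavior;
3. full multivariable logistic regression on the 12 predictors;
4. backward elimination at p = 0.2;
5. bootstrap stability selection (predictors retained in a fraction of
   resamples at or above ``retain_fraction`` survive);
6. refit on the stable set; integer score points = round(100·β);
7. logit calibration of the outcome on the integer score, AUC,
   Hosmer–Lemeshow calibration test, Youden decision threshold with
   Wald confidence intervals, and overall sensitivity/specificity with
   the gate folded back in.

Logistic fits are maximum-likelihood via statsmodels; the ROC/Youden
machinery, Hosmer–Lemeshow statistic and Woolf odds-ratio intervals are
implemented here because their exact conventions (tie-breaks, continuity
corrections, grouping) are part of the procedure being reproduced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, rankdata, spearmanr

from .errors import ContractError, EstimationError
from .scoring import (
    LABEL_LUNG,
    BinaryTerm,
    ContinuousTerm,
    EasilungCall,
    ScoreModel,
    classify_sample,
)
from .spectrum import CLASSES, FROM_SHORT, SHORT_LABELS, SpectrumProfile

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile used throughout for 95% intervals

#: Classes binarized in the reference development analysis; the remaining
#: four (C>T, G>A, A>C, T>G) enter the model as continuous percents.
DEFAULT_BINARIZED = ("C>A", "G>T", "C>G", "G>C", "A>G", "T>C", "A>T", "T>A")


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class CohortDataset:
    """Labelled collection of spectrum profiles (lung vs non-lung)."""

    profiles: list[SpectrumProfile]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        valid = {LABEL_LUNG, "non-lung"}
        for p in self.profiles:
            lab = self.labels.get(p.sample_id)
            if lab is None:
                raise ContractError(f"sample {p.sample_id!r} has no label")
            if lab not in valid:
                raise ContractError(f"label {lab!r} for {p.sample_id!r} not in {valid}")

    def y(self, profiles: Sequence[SpectrumProfile] | None = None) -> np.ndarray:
        ps = self.profiles if profiles is None else profiles
        return np.array([1 if self.labels[p.sample_id] == LABEL_LUNG else 0 for p in ps])

    def scored_subset(self, low_burden_cutoff: float = 1.0) -> list[SpectrumProfile]:
        """Profiles that pass the burden gate (and have a defined spectrum)."""
        return [
            p
            for p in self.profiles
            if p.prevalence >= low_burden_cutoff and p.freqs is not None
        ]

    def freq_frame(self, profiles: Sequence[SpectrumProfile] | None = None) -> pd.DataFrame:
        """Percent frequencies as a DataFrame with compact class columns."""
        ps = self.profiles if profiles is None else profiles
        data = {
            SHORT_LABELS[c]: [p.freqs[c] if p.freqs else np.nan for p in ps]
            for c in CLASSES
        }
        return pd.DataFrame(data, index=[p.sample_id for p in ps])


# ---------------------------------------------------------------------------
# diagnostics & binarization


def decile_logit_table(
    values: Sequence[float], labels: Sequence[int], groups: int = 10
) -> pd.DataFrame:
    """Empirical-logit table over decile groups of a predictor.

    Groups samples into (up to) ``groups`` equal-count bins of the
    predictor (stable ranks break ties) and reports per group the mean
    predictor value, the observed lung fraction and its logit.  Pure
    groups use the +0.5 continuity-corrected empirical logit
    ln((y+0.5)/(n−y+0.5)).  Used to judge log-linearity of a class before
    deciding to binarize it.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ContractError("values and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ContractError("both label classes required for the logit diagnostic")
    if np.all(v == v[0]):
        logger.warning("constant predictor: single diagnostic group")
        bins = np.zeros(len(v), dtype=int)
    else:
        ranks = pd.Series(v).rank(method="first")
        bins = pd.qcut(ranks, q=min(groups, len(v)), labels=False, duplicates="drop")
        if bins.max() + 1 < groups:
            logger.warning(
                "only %d distinct decile groups formed (requested %d)", bins.max() + 1, groups
            )
        bins = np.asarray(bins, dtype=int)
    rows = []
    for g in sorted(set(bins)):
        mask = bins == g
        n_g = int(mask.sum())
        events = int(y[mask].sum())
        frac = events / n_g
        if events == 0 or events == n_g:
            logit = math.log((events + 0.5) / (n_g - events + 0.5))
        else:
            logit = math.log(frac / (1 - frac))
        rows.append(
            {
                "group": g,
                "n": n_g,
                "mean_value": float(v[mask].mean()),
                "lung_fraction": frac,
                "logit": logit,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BinarizationResult:
    """Optimal Youden cut-point for one predictor."""

    cutoff: float
    direction: str  # 'greater': positive when value > cutoff; 'less': value <= cutoff
    youden_j: float
    sensitivity: float
    specificity: float


def _roc_points(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(cutoffs, sensitivity, specificity) for the predicate value > cutoff."""
    pos = np.sort(values[labels == 1])
    neg = np.sort(values[labels == 0])
    cand = np.concatenate(([-np.inf], np.unique(values)))
    se = (len(pos) - np.searchsorted(pos, cand, side="right")) / len(pos)
    sp = np.searchsorted(neg, cand, side="right") / len(neg)
    return cand, se, sp


def youden_binarization(values: Sequence[float], labels: Sequence[int]) -> BinarizationResult:
    """Cut-point maximizing Youden's J = sensitivity + specificity − 1.

    The search runs over all observed values (plus a −inf sentinel) with
    the predicate ``value > cutoff``; the positive direction is chosen so
    the resulting 2×2 odds ratio is ≥ 1 (high values predictive in the
    'greater' direction, low values in the 'less' direction).  Ties break
    toward the smallest cutoff.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ContractError("both label classes required for Youden binarization")
    if np.all(v == v[0]):
        raise ContractError("constant predictor: ROC degenerate at AUC = 0.5")
    cand, se, sp = _roc_points(v, y)
    j = se + sp - 1.0
    i_g = int(np.argmax(j))          # argmax returns the first (smallest cutoff)
    i_l = int(np.argmax(-j))
    if j[i_g] >= -j[i_l]:
        return BinarizationResult(float(cand[i_g]), "greater", float(j[i_g]), float(se[i_g]), float(sp[i_g]))
    # flipped direction: positive when value <= cutoff
    return BinarizationResult(
        float(cand[i_l]), "less", float(-j[i_l]), float(1 - se[i_l]), float(1 - sp[i_l])
    )


# ---------------------------------------------------------------------------
# logistic fitting


@dataclass(frozen=True)
class TermEstimate:
    name: str
    beta: float
    se: float
    p_value: float
    odds_ratio: float
    ci95: tuple[float, float]


@dataclass
class FittedModel:
    """Maximum-likelihood logistic fit with Wald inference per term."""

    terms: list[TermEstimate]
    intercept: float
    intercept_se: float
    log_likelihood: float

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def coef(self, name: str) -> float:
        for t in self.terms:
            if t.name == name:
                return t.beta
        raise KeyError(name)


def _safe_exp(x: float) -> float:
    # Wald CI bounds can overflow exp() near-separation; cap at float max.
    return math.exp(x) if x < 700 else math.inf


def _check_design(design: pd.DataFrame) -> None:
    const = [c for c in design.columns if design[c].nunique() <= 1]
    if const:
        raise EstimationError(f"constant predictors cannot be fitted: {const}")
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        cols = list(design.columns)
        for c in cols:
            sub = design.drop(columns=[c]).to_numpy(dtype=float)
            Xs = np.column_stack([np.ones(len(design)), sub])
            if np.linalg.matrix_rank(Xs) == Xs.shape[1]:
                collinear.append(c)
        raise EstimationError(f"design is rank deficient; collinear predictors: {collinear}")


def fit_logistic(design: pd.DataFrame, labels: Sequence[int]) -> FittedModel:
    """Fit label ~ predictors by maximum likelihood (Wald inference).

    Raises :class:`EstimationError` on perfect separation, non-convergence
    or a rank-deficient design (naming the collinear predictors).
    """
    y = np.asarray(labels, dtype=float)
    if len(design) != len(y):
        raise ContractError("design and labels must have equal length")
    if len(design) <= design.shape[1]:
        raise EstimationError("more predictors than samples")
    if len(np.unique(y)) < 2:
        raise EstimationError("labels are single-class")
    _check_design(design)
    X = sm.add_constant(design.astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or np.max(np.abs(res.params)) > 1e3:
        raise EstimationError(
            "logistic fit did not converge (possible perfect separation)"
        )
    terms = []
    for name in design.columns:
        beta = float(res.params[name])
        se = float(res.bse[name])
        terms.append(
            TermEstimate(
                name=name,
                beta=beta,
                se=se,
                p_value=float(res.pvalues[name]),
                odds_ratio=math.exp(beta),
                ci95=(_safe_exp(beta - Z95 * se), _safe_exp(beta + Z95 * se)),
            )
        )
    return FittedModel(
        terms=terms,
        intercept=float(res.params["const"]),
        intercept_se=float(res.bse["const"]),
        log_likelihood=float(res.llf),
    )


def backward_eliminate(
    design: pd.DataFrame, labels: Sequence[int], alpha: float = 0.2
) -> tuple[list[str], FittedModel]:
    """Backward selection: drop the worst predictor while its p > alpha.

    Ties on the p-value break toward the earlier column.  Returns the
    selected predictor names (original order) and the final fit.
    """
    cols = list(design.columns)
    fit = fit_logistic(design[cols], labels)
    while cols:
        worst = max(fit.terms, key=lambda t: t.p_value)
        if worst.p_value <= alpha:
            break
        cols.remove(worst.name)
        if not cols:
            raise EstimationError("backward elimination removed every predictor")
        fit = fit_logistic(design[cols], labels)
    return cols, fit


def bootstrap_stability(
    design: pd.DataFrame,
    labels: Sequence[int],
    B: int = 1000,
    retain_fraction: float = 0.6,
    alpha: float = 0.2,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 100,
) -> tuple[list[str], dict[str, float]]:
    """Stability selection by bootstrap resampling.

    Runs backward elimination on ``B`` with-replacement resamples of the
    cohort and keeps predictors selected in at least ``retain_fraction``
    of them.  Resamples with a single label class (or a failed fit) are
    redrawn, up to ``max_retries`` per resample.  Returns the stable set
    (design column order) and per-predictor selection frequencies.
    """
    if B < 1:
        raise ContractError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    counts = dict.fromkeys(design.columns, 0)
    for b in range(B):
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if len(np.unique(yb)) < 2:
                logger.debug("resample %d: single-class, redrawn", b)
                continue
            try:
                selected, _ = backward_eliminate(design.iloc[idx].reset_index(drop=True), yb, alpha)
            except EstimationError as exc:
                logger.debug("resample %d: fit failed (%s), redrawn", b, exc)
                continue
            for name in selected:
                counts[name] += 1
            break
        else:
            raise EstimationError(f"resample {b}: no usable bootstrap draw in {max_retries} tries")
    freqs = {name: counts[name] / B for name in design.columns}
    stable = [name for name in design.columns if freqs[name] >= retain_fraction]
    return stable, freqs


def derive_score_points(model: FittedModel) -> dict[str, int]:
    """Integer score points per term: round-half-away-from-zero of 100·β.

    The intercept is excluded — it lives in the logit calibration, not in
    the score.
    """
    return {
        t.name: int(math.copysign(math.floor(abs(100.0 * t.beta) + 0.5), t.beta))
        for t in model.terms
    }


# ---------------------------------------------------------------------------
# discrimination, calibration, thresholds


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (midranks for ties); equals Mann–Whitney U/(n1·n0)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ContractError("both label classes required for the AUC")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def hosmer_lemeshow(
    probs: Sequence[float], labels: Sequence[int], groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit test on deciles of predicted risk.

    Returns (chi-square statistic, degrees of freedom = groups−2, upper
    tail p).  Groups are equal-count bins of the predicted probability;
    bins with zero expected events are merged with their neighbor.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) < groups:
        raise ContractError(f"need at least {groups} samples for {groups} groups")
    ranks = pd.Series(p).rank(method="first")
    bins = np.asarray(pd.qcut(ranks, q=groups, labels=False, duplicates="drop"), dtype=int)
    # collect per-group observed/expected, merging degenerate groups forward
    grp: list[tuple[float, float, int]] = []
    for g in sorted(set(bins)):
        mask = bins == g
        grp.append((float(y[mask].sum()), float(p[mask].sum()), int(mask.sum())))
    merged: list[tuple[float, float, int]] = []
    for o, e, n_g in grp:
        if merged and (e <= 0 or e >= n_g):
            logger.warning("Hosmer-Lemeshow: merging degenerate risk group")
            po, pe, pn = merged[-1]
            merged[-1] = (po + o, pe + e, pn + n_g)
        else:
            merged.append((o, e, n_g))
    stat = 0.0
    for o, e, n_g in merged:
        denom = e * (1.0 - e / n_g)
        if denom <= 0:
            continue  # a fully degenerate single group carries no information
        stat += (o - e) ** 2 / denom
    df = len(merged) - 2
    p_value = float(chi2.sf(stat, df)) if df >= 1 else float("nan")
    return float(stat), df, p_value


def wald_ci(p_hat: float, n: int) -> tuple[float, float]:
    """Wald 95% interval for a proportion: p ± 1.96·sqrt(p(1−p)/n)."""
    if n <= 0:
        raise ContractError("n must be positive")
    half = Z95 * math.sqrt(p_hat * (1 - p_hat) / n)
    return (p_hat - half, p_hat + half)


@dataclass(frozen=True)
class ThresholdResult:
    """Youden-optimal decision threshold with Wald-interval se/sp."""

    threshold: float
    youden_j: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> ThresholdResult:
    """Score threshold maximizing Youden's J, with Wald 95% CIs.

    The decision rule is "score > threshold ⇒ lung", matching the score's
    published usage; ties break toward the smallest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    res = youden_binarization(s, y)
    if res.direction != "greater":
        raise EstimationError(
            "score is anti-predictive (higher score favors non-lung); "
            "check the model orientation"
        )
    n1 = int(y.sum())
    n0 = len(y) - n1
    return ThresholdResult(
        threshold=res.cutoff,
        youden_j=res.youden_j,
        sensitivity=res.sensitivity,
        sensitivity_ci=wald_ci(res.sensitivity, n1),
        specificity=res.specificity,
        specificity_ci=wald_ci(res.specificity, n0),
    )


@dataclass(frozen=True)
class OverallPerformance:
    """Cohort-level se/sp with the low-burden gate folded in."""

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    sensitivity_counts: tuple[int, int]  # (true positives, lung total)
    specificity: float
    specificity_ci: tuple[float, float]
    specificity_counts: tuple[int, int]  # (true negatives incl. gated, non-lung total)


def overall_performance(cohort: CohortDataset, model: ScoreModel) -> OverallPerformance:
    """Sensitivity/specificity over the whole cohort, gate included.

    Sensitivity counts every lung case (a gated low-burden lung tumor is a
    miss); specificity credits non-lung cases labelled non-lung either by
    the gate or by the score threshold.
    """
    calls: list[EasilungCall] = [classify_sample(p, model) for p in cohort.profiles]
    y = cohort.y()
    pred_lung = np.array([c.label == LABEL_LUNG for c in calls])
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ContractError("both label classes required for overall performance")
    tp = int(np.sum(pred_lung & (y == 1)))
    tn = int(np.sum(~pred_lung & (y == 0)))
    sens = tp / n1
    spec = tn / n0
    return OverallPerformance(
        sensitivity=sens,
        sensitivity_ci=wald_ci(sens, n1),
        sensitivity_counts=(tp, n1),
        specificity=spec,
        specificity_ci=wald_ci(spec, n0),
        specificity_counts=(tn, n0),
    )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci95: tuple[float, float]


def two_by_two_odds_ratio(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Odds ratio (a·d)/(b·c) with the Woolf 95% interval.

    Cells: a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  Any zero cell triggers the Haldane +0.5
    correction (logged).
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ContractError(f"negative cell count in {cells}")
    if any(x == 0 for x in cells):
        logger.warning("zero cell in 2x2 table; applying Haldane +0.5 correction")
        a, b, c, d = (x + 0.5 for x in cells)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=or_,
        ci95=(math.exp(math.log(or_) - Z95 * se), math.exp(math.log(or_) + Z95 * se)),
    )


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class DevelopmentReport:
    """Everything the development pipeline produces, ready for audit."""

    binarized: dict[str, BinarizationResult]
    full_model: FittedModel
    backward_selected: list[str]
    bootstrap_frequencies: dict[str, float]
    stable_predictors: list[str]
    final_model: FittedModel
    score_points: dict[str, int]
    score_model: ScoreModel
    calibration: tuple[float, float]
    auc: float
    hosmer_lemeshow: tuple[float, int, float]
    threshold: ThresholdResult
    overall: OverallPerformance
    n_total: int
    n_scored: int
    n_gated: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_scored": self.n_scored,
            "n_gated": self.n_gated,
            "seed": self.seed,
            "binarized": {
                k: {"cutoff": v.cutoff, "direction": v.direction, "youden_j": v.youden_j}
                for k, v in self.binarized.items()
            },
            "full_model": _fit_dict(self.full_model),
            "backward_selected": self.backward_selected,
            "bootstrap_frequencies": self.bootstrap_frequencies,
            "stable_predictors": self.stable_predictors,
            "final_model": _fit_dict(self.final_model),
            "score_points": self.score_points,
            "score_model": self.score_model.to_dict(),
            "calibration": {"intercept": self.calibration[0], "slope": self.calibration[1]},
            "auc": self.auc,
            "hosmer_lemeshow": {
                "statistic": self.hosmer_lemeshow[0],
                "df": self.hosmer_lemeshow[1],
                "p_value": self.hosmer_lemeshow[2],
            },
            "threshold": {
                "value": self.threshold.threshold,
                "youden_j": self.threshold.youden_j,
                "sensitivity": self.threshold.sensitivity,
                "sensitivity_ci": list(self.threshold.sensitivity_ci),
                "specificity": self.threshold.specificity,
                "specificity_ci": list(self.threshold.specificity_ci),
            },
            "overall": {
                "sensitivity": self.overall.sensitivity,
                "sensitivity_ci": list(self.overall.sensitivity_ci),
                "sensitivity_counts": list(self.overall.sensitivity_counts),
                "specificity": self.overall.specificity,
                "specificity_ci": list(self.overall.specificity_ci),
                "specificity_counts": list(self.overall.specificity_counts),
            },
        }


def _fit_dict(fit: FittedModel) -> dict:
    return {
        "intercept": fit.intercept,
        "log_likelihood": fit.log_likelihood,
        "terms": [
            {
                "name": t.name,
                "beta": t.beta,
                "se": t.se,
                "p_value": t.p_value,
                "odds_ratio": t.odds_ratio,
                "ci95": list(t.ci95),
            }
            for t in fit.terms
        ],
    }


def _binary_name(short: str, cutoff: float) -> str:
    return f"{short}>{cutoff:g}"


def build_design(
    freqs: pd.DataFrame,
    labels: Sequence[int],
    binarize: Iterable[str] | str = "default",
    spearman_cutoff: float = 0.9,
) -> tuple[pd.DataFrame, dict[str, BinarizationResult]]:
    """Assemble the 12-predictor design matrix.

    ``binarize`` selects which classes enter as Youden-thresholded binary
    indicators rather than raw percents: ``"default"`` uses the fixed
    reference set, ``"auto"`` binarizes classes whose decile-logit trend
    is visibly non-monotone (|Spearman rho| of group logit vs group mean
    below ``spearman_cutoff``), and an explicit iterable of class labels
    is taken as-is.
    """
    y = np.asarray(labels, dtype=int)
    if binarize == "default":
        to_bin = list(DEFAULT_BINARIZED)
    elif binarize == "auto":
        to_bin = []
        for c in CLASSES:
            table = decile_logit_table(freqs[SHORT_LABELS[c]].to_numpy(), y)
            if len(table) < 3:
                to_bin.append(c)
                continue
            rho = spearmanr(table["mean_value"], table["logit"]).statistic
            if not np.isfinite(rho) or abs(rho) < spearman_cutoff:
                to_bin.append(c)
    else:
        to_bin = [c if ">" in c else FROM_SHORT.get(c, c) for c in binarize]
        unknown = set(to_bin) - set(CLASSES)
        if unknown:
            raise ContractError(f"unknown classes in binarize: {sorted(unknown)}")
    design = pd.DataFrame(index=freqs.index)
    cuts: dict[str, BinarizationResult] = {}
    for c in CLASSES:
        short = SHORT_LABELS[c]
        if c in to_bin:
            res = youden_binarization(freqs[short].to_numpy(), y)
            cuts[c] = res
            design[_binary_name(short, res.cutoff)] = (
                freqs[short].to_numpy() > res.cutoff
            ).astype(float)
        else:
            design[short] = freqs[short].to_numpy(dtype=float)
    return design, cuts


def develop_score(
    cohort: CohortDataset,
    *,
    binarize: Iterable[str] | str = "default",
    alpha: float = 0.2,
    bootstrap_B: int = 1000,
    retain_fraction: float = 0.6,
    hl_groups: int = 10,
    low_burden_cutoff: float = 1.0,
    seed: int | None = None,
) -> DevelopmentReport:
    """Run the whole development pipeline on a labelled cohort.

    Deterministic given ``seed`` (the bootstrap is the only stochastic
    stage).  Returns a :class:`DevelopmentReport` whose ``score_model``
    can be applied to new samples via :func:`easilung.scoring.classify_sample`.
    """
    scored = cohort.scored_subset(low_burden_cutoff)
    if not scored:
        raise ContractError("no samples pass the low-burden gate")
    y = cohort.y(scored)
    if y.sum() == 0 or y.sum() == len(y):
        raise ContractError("both label classes required after the low-burden gate")
    freqs = cohort.freq_frame(scored)

    design, cuts = build_design(freqs, y, binarize)
    full_fit = fit_logistic(design, y)
    selected, _ = backward_eliminate(design, y, alpha)
    rng = np.random.default_rng(seed)
    stable, boot_freqs = bootstrap_stability(
        design[selected], y, B=bootstrap_B, retain_fraction=retain_fraction, alpha=alpha, seed=rng
    )
    if not stable:
        raise EstimationError("no predictor survived bootstrap stability selection")
    final_fit = fit_logistic(design[stable], y)
    points = derive_score_points(final_fit)

    # assemble the ScoreModel from the retained terms
    binary_terms = []
    continuous_terms = []
    name_to_class = {}
    for c in CLASSES:
        short = SHORT_LABELS[c]
        if c in cuts:
            name_to_class[_binary_name(short, cuts[c].cutoff)] = c
        else:
            name_to_class[short] = c
    for name in stable:
        c = name_to_class[name]
        if c in cuts:
            binary_terms.append(BinaryTerm(c, cuts[c].cutoff, ">", points[name]))
        else:
            continuous_terms.append(ContinuousTerm(c, points[name]))

    scores = design[stable].to_numpy(dtype=float) @ np.array([points[n] for n in stable], dtype=float)

    cal_fit = fit_logistic(pd.DataFrame({"score": scores}), y)
    calibration = (cal_fit.intercept, cal_fit.coef("score"))
    probs = 1.0 / (1.0 + np.exp(-(calibration[0] + calibration[1] * scores)))
    auc_value = auc(scores, y)
    hl = hosmer_lemeshow(probs, y, hl_groups)
    thr = youden_threshold(scores, y)

    score_model = ScoreModel(
        binary_terms=tuple(binary_terms),
        continuous_terms=tuple(continuous_terms),
        calibration=calibration,
        decision_threshold=thr.threshold,
        low_burden_cutoff=low_burden_cutoff,
        name="developed",
    )
    overall = overall_performance(cohort, score_model)

    return DevelopmentReport(
        binarized=cuts,
        full_model=full_fit,
        backward_selected=selected,
        bootstrap_frequencies=boot_freqs,
        stable_predictors=stable,
        final_model=final_fit,
        score_points=points,
        score_model=score_model,
        calibration=calibration,
        auc=auc_value,
        hosmer_lemeshow=hl,
        threshold=thr,
        overall=overall,
        n_total=len(cohort.profiles),
        n_scored=len(scored),
        n_gated=len(cohort.profiles) - len(scored),
        seed=seed,
    )


__all__ = [
    "CohortDataset",
    "FittedModel",
    "TermEstimate",
    "BinarizationResult",
    "ThresholdResult",
    "OverallPerformance",
    "OddsRatioResult",
    "DevelopmentReport",
    "DEFAULT_BINARIZED",
    "decile_logit_table",
    "youden_binarization",
    "fit_logistic",
    "backward_eliminate",
    "bootstrap_stability",
    "derive_score_points",
    "auc",
    "hosmer_lemeshow",
    "wald_ci",
    "youden_threshold",
    "overall_performance",
    "two_by_two_odds_ratio",
    "build_design",
    "develop_score",
]
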