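"""Applying the EASILUNG score to a spectrum profile.

The score is an integer-weighted linear combination of 8 of the 12
substitution-class relative frequencies: four thresholded binary terms
(+175 if %CA > 12, +62 if %GT > 13, −74 if %AG > 5, −73 if %TC > 5) and
four continuous per-percent terms (−9·%CT, −6·%GA, −17·%AC, −17·%TG).
Point values are 100× the logistic regression coefficients of the final
development model, rounded to the nearest integer.

A logit calibration maps the score to a probability of lung origin
(probability = expit(intercept + slope·score)) and a decision threshold
turns the score into a label.  Samples with a mutational burden below
1 sub/Mb are labelled non-lung before any scoring (the low-burden gate):
lung tumors in smokers almost always exceed that burden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

from scipy.special import expit

from .errors import ConfigurationError, ContractError
from .spectrum import CLASSES, SpectrumProfile

LABEL_LUNG = "lung"
LABEL_NON_LUNG = "non-lung"
LABEL_LOW_BURDEN = "non-lung-low-burden"

PUBLISHED_VARIANTS = ("development", "validation")


@dataclass(frozen=True)
class BinaryTerm:
    """A thresholded score term: ``points`` awarded when freq comparator cutoff."""

    cls: str
    cutoff: float
    comparator: str  # only ">" is used by the published model
    points: float

    def fires(self, value: float) -> bool:
        if self.comparator == ">":
            return value > self.cutoff
        if self.comparator == ">=":
            return value >= self.cutoff
        raise ContractError(f"unsupported comparator {self.comparator!r}")


@dataclass(frozen=True)
class ContinuousTerm:
    """A per-percent score term: contributes ``points * freq``."""

    cls: str
    points: float


@dataclass(frozen=True)
class ScoreModel:
    """Score terms + logit calibration + decision rule."""

    binary_terms: tuple[BinaryTerm, ...]
    continuous_terms: tuple[ContinuousTerm, ...]
    calibration: tuple[float, float]  # (intercept, slope) on the logit scale
    decision_threshold: float
    low_burden_cutoff: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        for term in (*self.binary_terms, *self.continuous_terms):
            if term.cls not in CLASSES:
                raise ContractError(f"unknown substitution class {term.cls!r} in model")
        if self.calibration[1] <= 0:
            raise ContractError("calibration slope must be positive")

    def with_calibration(
        self, intercept: float, slope: float, decision_threshold: float, name: str | None = None
    ) -> "ScoreModel":
        """Same score terms under a new calibration/threshold (recalibration)."""
        return replace(
            self,
            calibration=(float(intercept), float(slope)),
            decision_threshold=float(decision_threshold),
            name=name or f"{self.name}-recalibrated",
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "binary_terms": [
                {"class": t.cls, "cutoff": t.cutoff, "comparator": t.comparator, "points": t.points}
                for t in self.binary_terms
            ],
            "continuous_terms": [{"class": t.cls, "points": t.points} for t in self.continuous_terms],
            "calibration": {"intercept": self.calibration[0], "slope": self.calibration[1]},
            "decision_threshold": self.decision_threshold,
            "low_burden_cutoff": self.low_burden_cutoff,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreModel":
        return cls(
            binary_terms=tuple(
                BinaryTerm(t["class"], float(t["cutoff"]), t.get("comparator", ">"), float(t["points"]))
                for t in d["binary_terms"]
            ),
            continuous_terms=tuple(
                ContinuousTerm(t["class"], float(t["points"])) for t in d["continuous_terms"]
            ),
            calibration=(float(d["calibration"]["intercept"]), float(d["calibration"]["slope"])),
            decision_threshold=float(d["decision_threshold"]),
            low_burden_cutoff=float(d.get("low_burden_cutoff", 1.0)),
            name=str(d.get("name", "custom")),
        )


def load_model(path: str | Path) -> ScoreModel:
    """Load a ScoreModel from a JSON config file."""
    with open(path) as fh:
        return ScoreModel.from_dict(json.load(fh))


def published_model(variant: str = "development") -> ScoreModel:
    """The published EASILUNG model.

    ``variant="development"`` carries the development-cohort calibration
    (logit = 1.216 + 0.010·score) and threshold −303; ``"validation"``
    carries the identical score terms with the external-validation
    recalibration (logit = 2.094 + 0.008·score) and threshold −467.
    """
    if variant not in PUBLISHED_VARIANTS:
        raise ConfigurationError(
            f"unknown model variant {variant!r}; expected one of {PUBLISHED_VARIANTS}"
        )
    name = {"development": "development-2019", "validation": "validation-2019"}[variant]
    data = resources.files("easilung").joinpath(f"models/{name}.json").read_text()
    return ScoreModel.from_dict(json.loads(data))


def easilung_score(freqs: Mapping[str, float], model: ScoreModel) -> float:
    """Evaluate the score on a percent-frequency map.

    With the published model:
    ``+175·[%CA>12] + 62·[%GT>13] − 9·%CT − 6·%GA − 17·%AC − 17·%TG
    − 74·[%AG>5] − 73·[%TC>5]``.
    """
    score = 0.0
    for bt in model.binary_terms:
        if bt.cls not in freqs:
            raise ContractError(f"frequency for class {bt.cls!r} missing")
        if bt.fires(freqs[bt.cls]):
            score += bt.points
    for ct in model.continuous_terms:
        if ct.cls not in freqs:
            raise ContractError(f"frequency for class {ct.cls!r} missing")
        score += ct.points * freqs[ct.cls]
    return score


def probability(score: float, calibration: tuple[float, float]) -> float:
    """Calibrated probability of lung origin: expit(intercept + slope·score)."""
    intercept, slope = calibration
    return float(expit(intercept + slope * score))


@dataclass(frozen=True)
class EasilungCall:
    """Final per-sample result: score, calibrated probability and label.

    ``score`` and ``probability`` are ``None`` for low-burden samples
    (< low_burden_cutoff sub/Mb), which are labelled non-lung without
    scoring.
    """

    sample_id: str
    prevalence: float
    score: float | None
    probability: float | None
    label: str
    model_name: str = ""
    threshold: float | None = None


def classify_sample(profile: SpectrumProfile, model: ScoreModel) -> EasilungCall:
    """Apply the gate, the score and the decision rule to one profile.

    The low-burden gate precedes scoring; a gated sample gets no score or
    probability.  At exactly the threshold the label is non-lung (the rule
    is strictly "greater than").
    """
    if profile.prevalence < model.low_burden_cutoff:
        return EasilungCall(
            sample_id=profile.sample_id,
            prevalence=profile.prevalence,
            score=None,
            probability=None,
            label=LABEL_LOW_BURDEN,
            model_name=model.name,
            threshold=model.decision_threshold,
        )
    if profile.freqs is None:
        raise ContractError(
            f"sample {profile.sample_id!r}: prevalence >= {model.low_burden_cutoff} "
            "but no substitutions recorded (target_mb misdeclared?)"
        )
    score = easilung_score(profile.freqs, model)
    return EasilungCall(
        sample_id=profile.sample_id,
        prevalence=profile.prevalence,
        score=score,
        probability=probability(score, model.calibration),
        label=LABEL_LUNG if score > model.decision_threshold else LABEL_NON_LUNG,
        model_name=model.name,
        threshold=model.decision_threshold,
    )


__all__ = [
    "BinaryTerm",
    "ContinuousTerm",
    "ScoreModel",
    "EasilungCall",
    "published_model",
    "load_model",
    "easilung_score",
    "probability",
    "classify_sample",
    "LABEL_LUNG",
    "LABEL_NON_LUNG",
    "LABEL_LOW_BURDEN",
]
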