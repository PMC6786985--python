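"""Synthetic labelled cohorts with the statistical structure the test assumes.

Each simulated tumor gets a label (lung with probability ``lung_fraction``),
an exome target size drawn uniformly from the platform range, a mutational
burden drawn log-normally per label (the lung distribution sits well above
1 sub/Mb, the non-lung distribution straddles the gate), a per-tumor
spectrum drawn from a Dirichlet around the label's mean 12-class profile
(Dirichlet-multinomial rather than plain multinomial, to give realistic
inter-tumor dispersion), and finally class counts from a multinomial with
total = round(burden × target Mb).

The label mean spectra are anchored on the published worked examples:
a C>A/G>T-rich lung-like profile with transcriptional strand bias and a
C>T/G>A-rich non-lung-like profile, each completed to 12 classes by
spreading the unassigned remainder equally over C>G, G>C, A>T and T>A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .development import CohortDataset
from .errors import ConfigurationError
from .scoring import LABEL_LUNG, LABEL_NON_LUNG
from .spectrum import CLASSES, SpectrumProfile
from .variant_io import SampleVariants, SubstitutionCall, write_pair_list

#: Dirichlet concentrations below this floor are clamped so classes with a
#: zero mean stay representable (a strictly-zero alpha is not a Dirichlet).
_ALPHA_FLOOR = 0.01


def preset_profiles() -> tuple[dict[str, float], dict[str, float]]:
    """(lung-like, non-lung-like) mean 12-class percent vectors.

    Lung-like: %CA=27, %GT=19, %CT=8, %GA=12, %AC=0, %TG=0, %AG=3, %TC=5,
    remainder split equally over C>G/G>C/A>T/T>A.  Non-lung-like: %CA=2,
    %GT=2, %CT=27, %GA=37, %AC=4, %TG=1, %AG=6, %TC=5, remainder likewise.
    Both sum to 100.
    """
    lung = {
        "C>A": 27.0, "G>T": 19.0, "C>T": 8.0, "G>A": 12.0,
        "A>C": 0.0, "T>G": 0.0, "A>G": 3.0, "T>C": 5.0,
        "C>G": 6.5, "G>C": 6.5, "A>T": 6.5, "T>A": 6.5,
    }
    non_lung = {
        "C>A": 2.0, "G>T": 2.0, "C>T": 27.0, "G>A": 37.0,
        "A>C": 4.0, "T>G": 1.0, "A>G": 6.0, "T>C": 5.0,
        "C>G": 4.0, "G>C": 4.0, "A>T": 4.0, "T>A": 4.0,
    }
    return (
        {c: lung[c] for c in CLASSES},
        {c: non_lung[c] for c in CLASSES},
    )


@dataclass
class SimulationConfig:
    """Cohort generator settings.

    Defaults emulate a development-style cohort: ~10% lung tumors, exome
    captures between 36 and 64 Mb, lung burdens log-normal with median
    ≈ 5 sub/Mb (few lung tumors below the 1 sub/Mb gate), non-lung burdens
    log-normal with median ≈ 1.4 sub/Mb (a sizable minority gated).  The
    spectrum concentration of 3 gives the heavy inter-tumor dispersion
    real cohorts show (roughly half of lung tumors exceed the %CA and %GT
    cut-offs, under a tenth of non-lung tumors do); much larger values
    make the classes nearly separable, which real spectra are not.
    """

    n_samples: int = 2000
    lung_fraction: float = 0.1
    spectrum_means: dict[str, dict[str, float]] | None = None  # per label; presets if None
    concentration: float = 3.0
    burden_log_mean: dict[str, float] = field(
        default_factory=lambda: {LABEL_LUNG: 1.6, LABEL_NON_LUNG: 0.35}
    )
    burden_log_sd: dict[str, float] = field(
        default_factory=lambda: {LABEL_LUNG: 1.0, LABEL_NON_LUNG: 1.5}
    )
    target_mb_range: tuple[float, float] = (36.0, 64.0)
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_samples < 1:
            bad.append(f"n_samples={self.n_samples}")
        if not 0 < self.lung_fraction < 1:
            bad.append(f"lung_fraction={self.lung_fraction}")
        if self.concentration <= 0:
            bad.append(f"concentration={self.concentration}")
        lo, hi = self.target_mb_range
        if lo <= 0 or hi < lo:
            bad.append(f"target_mb_range={self.target_mb_range}")
        for label in (LABEL_LUNG, LABEL_NON_LUNG):
            if label not in self.burden_log_mean:
                bad.append(f"burden_log_mean missing {label!r}")
            if self.burden_log_sd.get(label, -1) <= 0:
                bad.append(f"burden_log_sd[{label!r}]={self.burden_log_sd.get(label)}")
        if self.spectrum_means is not None:
            for label, means in self.spectrum_means.items():
                total = sum(means.get(c, 0.0) for c in CLASSES)
                if abs(total - 100.0) > 1e-6:
                    bad.append(f"spectrum_means[{label!r}] sums to {total}, not 100")
        if bad:
            raise ConfigurationError("invalid simulation config: " + "; ".join(bad))

    def means(self) -> dict[str, dict[str, float]]:
        if self.spectrum_means is not None:
            return self.spectrum_means
        lung, non_lung = preset_profiles()
        return {LABEL_LUNG: lung, LABEL_NON_LUNG: non_lung}


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[CohortDataset, pd.DataFrame]:
    """Draw a labelled cohort; optionally write pair-list files + truth table.

    Fully reproducible from ``config.seed``.  Returns the cohort and a
    truth DataFrame (sample_id, label, target_mb, burden, total).  When
    ``out_dir`` is given, one two-column pair-list file per sample plus
    ``truth.tsv`` and a ``config.json`` echo are written there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    means = config.means()
    alphas = {
        label: np.maximum(
            config.concentration * np.array([means[label][c] for c in CLASSES]) / 100.0,
            _ALPHA_FLOOR,
        )
        for label in (LABEL_LUNG, LABEL_NON_LUNG)
    }

    profiles: list[SpectrumProfile] = []
    labels: dict[str, str] = {}
    truth_rows = []
    lo, hi = config.target_mb_range
    for i in range(config.n_samples):
        sample_id = f"S{i:05d}"
        label = LABEL_LUNG if rng.random() < config.lung_fraction else LABEL_NON_LUNG
        target_mb = rng.uniform(lo, hi)
        burden = rng.lognormal(config.burden_log_mean[label], config.burden_log_sd[label])
        total = int(round(burden * target_mb))
        probs = rng.dirichlet(alphas[label])
        counts_vec = rng.multinomial(total, probs) if total > 0 else np.zeros(len(CLASSES), int)
        counts = {c: int(k) for c, k in zip(CLASSES, counts_vec)}
        profiles.append(SpectrumProfile.from_counts(sample_id, counts, target_mb))
        labels[sample_id] = label
        truth_rows.append(
            {
                "sample_id": sample_id,
                "label": label,
                "target_mb": target_mb,
                "burden": burden,
                "total": total,
            }
        )
    cohort = CohortDataset(profiles=profiles, labels=labels)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        write_cohort(cohort, truth, config, out_dir)
    return cohort, truth


def expand_calls(profile: SpectrumProfile) -> SampleVariants:
    """Materialize a profile's counts as explicit (ref, alt) calls."""
    calls = [
        SubstitutionCall(c[0], c[2], None, profile.sample_id)
        for c in CLASSES
        for _ in range(profile.counts[c])
    ]
    return SampleVariants(profile.sample_id, calls, profile.target_mb)


def write_cohort(
    cohort: CohortDataset, truth: pd.DataFrame, config: SimulationConfig, out_dir: str | Path
) -> None:
    """Emit per-sample pair-list files, truth.tsv and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for profile in cohort.profiles:
        write_pair_list(expand_calls(profile), out / f"{profile.sample_id}.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)


def simulate_labels_from_calibration(
    scores: np.ndarray, intercept: float, slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli labels from a logit calibration: P(lung) = expit(A + B·score)."""
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * np.asarray(scores, dtype=float))))
    return (rng.random(len(p)) < p).astype(int)


__all__ = [
    "SimulationConfig",
    "preset_profiles",
    "simulate_cohort",
    "write_cohort",
    "expand_calls",
    "simulate_labels_from_calibration",
]
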