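"""Twelve-class somatic substitution spectra.

A substitution read on the coding non-transcribed strand belongs to one of
the 12 ordered classes C>A, G>T, C>G, G>C, C>T, G>A, A>C, T>G, A>G, T>C,
A>T, T>A.  Keeping all 12 (instead of collapsing complementary pairs to 6)
preserves transcriptional strand bias — e.g. tobacco-exposed lung tumors
show more G>T than complementary C>A on the non-transcribed strand.

This module classifies calls, tallies per-sample counts, converts them to
relative frequencies (percent of total) and computes the mutational burden
(prevalence, substitutions per megabase of targeted exome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

from .errors import ContractError, UndefinedSpectrumError

if TYPE_CHECKING:  # pragma: no cover
    from .variant_io import SampleVariants

BASES = ("A", "C", "G", "T")

#: The 12 substitution classes in canonical reporting order.
CLASSES: tuple[str, ...] = (
    "C>A", "G>T", "C>G", "G>C", "C>T", "G>A",
    "A>C", "T>G", "A>G", "T>C", "A>T", "T>A",
)

#: Compact labels (no '>') used for table column names, e.g. "CA" for "C>A".
SHORT_LABELS: dict[str, str] = {c: c.replace(">", "") for c in CLASSES}
FROM_SHORT: dict[str, str] = {v: k for k, v in SHORT_LABELS.items()}

COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Watson–Crick complementary class pairs (C>A <-> G>T, ...).
COMPLEMENT_CLASS: dict[str, str] = {
    c: f"{COMPLEMENT[c[0]]}>{COMPLEMENT[c[2]]}" for c in CLASSES
}


def classify_substitution(ref: str, alt: str) -> str:
    """Return the substitution class label ``"ref>alt"``.

    Raises :class:`ContractError` if the bases are not distinct canonical
    DNA letters.
    """
    if ref not in BASES or alt not in BASES:
        raise ContractError(f"bases must be in {BASES}, got ({ref!r}, {alt!r})")
    if ref == alt:
        raise ContractError(f"ref and alt are identical ({ref!r}); not a substitution")
    return f"{ref}>{alt}"


def count_spectrum(sv: "SampleVariants") -> tuple[dict[str, int], int]:
    """Tally a sample's calls into the 12 classes.

    Returns ``(counts, total)`` where absent classes have count 0 and the
    total equals the number of calls.
    """
    counts = dict.fromkeys(CLASSES, 0)
    for call in sv.calls:
        counts[classify_substitution(call.ref_base, call.alt_base)] += 1
    return counts, len(sv.calls)


def relative_frequencies(
    counts: Mapping[str, int], total: int, *, round_to_int: bool = False
) -> dict[str, float]:
    """Per-class relative frequencies as percent of the total.

    ``round_to_int`` applies round-half-up to whole percent, reproducing
    integer worked-example arithmetic; by default frequencies are carried
    at full floating precision.
    """
    if total <= 0:
        raise UndefinedSpectrumError(
            "relative frequencies undefined for a zero-substitution sample; "
            "route it through the <1 sub/Mb low-burden gate instead"
        )
    freqs = {c: 100.0 * counts.get(c, 0) / total for c in CLASSES}
    if round_to_int:
        freqs = {c: float(math.floor(f + 0.5)) for c, f in freqs.items()}
    return freqs


def prevalence(total: int, target_mb: float) -> float:
    """Mutational burden in substitutions per megabase: ``total / target_mb``."""
    if target_mb <= 0:
        raise ContractError(f"target_mb must be positive, got {target_mb}")
    if total < 0:
        raise ContractError(f"total must be non-negative, got {total}")
    return total / target_mb


@dataclass
class SpectrumProfile:
    """The full 12-class spectrum summary for one tumor.

    ``freqs`` is ``None`` for a zero-substitution sample (the spectrum is
    undefined; the sample is handled by the low-burden gate downstream).
    """

    sample_id: str
    counts: dict[str, int]
    total: int
    freqs: dict[str, float] | None
    target_mb: float
    prevalence: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ContractError(
                f"total {self.total} != sum of counts {sum(self.counts.values())}"
            )
        if self.target_mb <= 0:
            raise ContractError(f"target_mb must be positive, got {self.target_mb}")

    @property
    def has_spectrum(self) -> bool:
        """True when the sample has at least one substitution."""
        return self.total > 0

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: Mapping[str, int],
        target_mb: float,
        *,
        round_freqs: bool = False,
    ) -> "SpectrumProfile":
        """Build a profile from class counts (e.g. simulated tallies)."""
        full = {c: int(counts.get(c, 0)) for c in CLASSES}
        unknown = set(counts) - set(CLASSES)
        if unknown:
            raise ContractError(f"unknown substitution classes: {sorted(unknown)}")
        total = sum(full.values())
        freqs = (
            relative_frequencies(full, total, round_to_int=round_freqs)
            if total > 0
            else None
        )
        return cls(
            sample_id=sample_id,
            counts=full,
            total=total,
            freqs=freqs,
            target_mb=float(target_mb),
            prevalence=prevalence(total, target_mb),
        )


def build_profile(sv: "SampleVariants", *, round_freqs: bool = False) -> SpectrumProfile:
    """Classify, count and summarize one sample's calls into a profile."""
    counts, total = count_spectrum(sv)
    return SpectrumProfile(
        sample_id=sv.sample_id,
        counts=counts,
        total=total,
        freqs=relative_frequencies(counts, total, round_to_int=round_freqs)
        if total > 0
        else None,
        target_mb=float(sv.target_region_mb),
        prevalence=prevalence(total, sv.target_region_mb),
    )
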