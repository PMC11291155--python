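"""Mendelian segregation statistics for genetic crosses.

Biallelic loci with genotypes written ``+/+``, ``+/-`` and ``-/-``.
Independent assortment is assumed throughout: expectations for multi-locus
crosses are products of per-locus transmission probabilities.  A Pearson
chi-square goodness-of-fit test detects departures such as sub-Mendelian
production of knockout offspring, and target-genotype frequencies can be
compared across genetic backgrounds with an exact (2x2) or chi-square
(2xk) contingency test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

Genotype = tuple[str, ...]

_ALLELE_ORDER = {"+": 0, "-": 1}


def normalize_genotype(genotype: str) -> str:
    """Canonicalise a single-locus genotype string (``-/+`` -> ``+/-``)."""
    parts = genotype.replace("−", "-").split("/")
    if len(parts) != 2 or any(a not in _ALLELE_ORDER for a in parts):
        raise ValueError(f"malformed genotype {genotype!r}; expected e.g. '+/-'")
    parts.sort(key=_ALLELE_ORDER.__getitem__)
    return "/".join(parts)


def normalize_genotype_tuple(genotype: Sequence[str] | str) -> Genotype:
    if isinstance(genotype, str):
        genotype = genotype.split(";")
    return tuple(normalize_genotype(g) for g in genotype)


@dataclass
class GenotypeCounts:
    """Offspring genotype counts over an ordered list of loci."""

    loci: list[str]
    counts: dict[Genotype, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def add(self, genotype: Sequence[str] | str, n: int = 1) -> None:
        key = normalize_genotype_tuple(genotype)
        if len(key) != len(self.loci):
            raise ValueError(
                f"genotype {key} has {len(key)} loci; expected {len(self.loci)}"
            )
        self.counts[key] = self.counts.get(key, 0) + n


@dataclass
class SegregationResult:
    expected: dict[Genotype, float]
    chi2: float
    df: int
    p_value: float


def _locus_offspring_probs(parent1: str, parent2: str) -> dict[str, float]:
    """Offspring genotype distribution at one locus from two parent genotypes."""
    g1 = normalize_genotype(parent1).split("/")
    g2 = normalize_genotype(parent2).split("/")
    probs: dict[str, float] = {}
    for a1 in g1:
        for a2 in g2:
            child = normalize_genotype(f"{a1}/{a2}")
            probs[child] = probs.get(child, 0.0) + 0.25
    return probs


def expected_mendelian(
    parent1: Sequence[str] | str, parent2: Sequence[str] | str
) -> dict[Genotype, float]:
    """Expected offspring genotype fractions under independent assortment.

    Each parent is a per-locus genotype tuple (or ``;``-joined string); a
    heterozygous parent transmits each allele with probability 1/2, a
    homozygote transmits its allele with probability 1.
    """
    p1 = normalize_genotype_tuple(parent1)
    p2 = normalize_genotype_tuple(parent2)
    if len(p1) != len(p2):
        raise ValueError("parents must have the same number of loci")
    per_locus = [_locus_offspring_probs(a, b) for a, b in zip(p1, p2)]
    expected: dict[Genotype, float] = {}
    for combo in itertools.product(*(p.items() for p in per_locus)):
        genotype = tuple(g for g, _ in combo)
        prob = float(np.prod([p for _, p in combo]))
        expected[genotype] = expected.get(genotype, 0.0) + prob
    return expected


def goodness_of_fit(
    observed: GenotypeCounts, expected: Mapping[Genotype, float]
) -> SegregationResult:
    """Pearson chi-square test of observed genotype counts against expectations.

    Categories with expected fraction 0 are excluded from the statistic; an
    observed count in such a category is an impossible outcome and raises.
    A warning recommends an exact test when any expected count falls below 1.
    """
    total = observed.total
    if total <= 0:
        raise ValueError("no observed offspring")
    expected = {normalize_genotype_tuple(g): f for g, f in expected.items()}
    for genotype, n in observed.counts.items():
        if n > 0 and expected.get(genotype, 0.0) == 0.0:
            raise ValueError(
                f"observed genotype {genotype} has expected fraction 0 "
                "(impossible outcome under the stated cross)"
            )
    cats = [g for g, f in expected.items() if f > 0]
    obs = np.array([observed.counts.get(g, 0) for g in cats], dtype=float)
    exp = np.array([expected[g] * total for g in cats], dtype=float)
    # chisquare requires sums to match; expected fractions sum to 1 by design
    if np.any(exp < 1):
        warnings.warn(
            "expected count below 1 in at least one category; "
            "consider an exact multinomial test",
            stacklevel=2,
        )
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(cats) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return SegregationResult(expected=dict(expected), chi2=chi2, df=df, p_value=p)


def compare_backgrounds(
    counts_by_background: Mapping[str, tuple[int, int]],
) -> dict[str, float | str]:
    """Compare a target genotype's frequency across genetic backgrounds.

    ``counts_by_background`` maps background name to
    ``(target_genotype_count, other_count)``.  Backgrounds with zero total
    are excluded with a warning.  With two backgrounds a two-sided Fisher
    exact test is used; with more, a chi-square test of the 2xk table.
    """
    table = []
    names = []
    for name, (target, other) in counts_by_background.items():
        if target + other == 0:
            warnings.warn(f"background {name!r} has zero total; excluded", stacklevel=2)
            continue
        names.append(name)
        table.append([target, other])
    if len(table) < 2:
        raise ValueError("need at least two backgrounds with nonzero totals")
    arr = np.array(table, dtype=int).T  # 2 x k
    if arr.shape[1] == 2:
        stat, p = stats.fisher_exact(arr, alternative="two-sided")
        test = "fisher"
    else:
        stat, p, _, _ = stats.chi2_contingency(arr)
        test = "chi2"
    return {"statistic": float(stat), "p_value": float(p), "test": test}
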