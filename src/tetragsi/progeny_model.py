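"""Expected progeny S-phenotype distributions and observable marginals.

A cross combines the seed parent's egg gametes (never S-filtered: GSI
acts on pollen only) with the pollen parent's gamete classes after
stylar filtering and optional per-class transmission weighting.  The
observable unit is the *phenotype class*: the set of distinct S-alleles
a presence/absence PCR assay detects in one individual — dosage-blind,
so an egg pair and a pollen pair sharing an allele collapse to a
three-allele class.

With unit weights, no filtering and alpha = 0, the self progeny of a
four-distinct-allele tetraploid falls into 6 two-allele, 4 three-allele
and 1 four-allele class in the exact ratio 1:1:1:1:1:1:6:6:6:6:6 over
the 36 gamete pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .compatibility import CompatibilityRuleSet, StyleContext, is_pollen_accepted
from .slocus_model import (
    DoubleReductionRate,
    GameteClass,
    ParentGenotype,
    SLocusError,
    allele_sort_key,
    enumerate_gametes,
)

__all__ = [
    "CrossSpec",
    "PhenotypeClass",
    "PhenotypeDistribution",
    "FullyIncompatibleCrossError",
    "expected_phenotype_distribution",
    "allele_marginals",
    "containing_marginals",
    "collapse_over_parent",
    "canonical_gamete_token",
]


def canonical_gamete_token(tokens: Iterable[str]) -> tuple[str, ...]:
    """Canonical (naturally sorted) form of a gamete's allele-label tuple,
    the key under which pollen transmission weights are looked up."""

    def parse(tok: str):
        species, _, label = tok.partition("-")
        return allele_sort_key((species, label))

    return tuple(sorted(tokens, key=parse))


class FullyIncompatibleCrossError(SLocusError):
    """Every pollen gamete class was rejected (or weighted to zero)."""


@dataclass(frozen=True)
class PhenotypeClass:
    """Set of distinct S-alleles detectable in one progeny individual."""

    alleles: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", frozenset(self.alleles))
        if not self.alleles:
            raise SLocusError("phenotype class must contain at least one allele")

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "PhenotypeClass":
        """Build from ``"Species-Label"`` strings, e.g. ``["Pps-S1", "Pa-S2"]``."""
        keys = []
        for token in labels:
            species, _, label = token.partition("-")
            if not species or not label:
                raise SLocusError(f"malformed allele token {token!r}")
            keys.append((species, label))
        return cls(frozenset(keys))

    @property
    def sort_key(self):
        labels = tuple(sorted(self.alleles, key=allele_sort_key))
        return (len(labels), tuple(allele_sort_key(k) for k in labels))

    def label(self) -> str:
        return "+".join(
            f"{sp}-{lb}" for sp, lb in sorted(self.alleles, key=allele_sort_key)
        )

    def __str__(self) -> str:
        return self.label()


@dataclass(frozen=True)
class CrossSpec:
    """A pollination: parents, SI rules, double reduction, pollen weights.

    ``pollen_weights`` maps a pollen gamete class — keyed by its sorted
    tuple of ``"Species-Label"`` strings, e.g. ``("Pps-S1", "Pps-S5")``
    — to a non-negative transmission weight (relative pollen-tube
    performance).  Unlisted classes get weight 1.
    """

    seed_parent: ParentGenotype
    pollen_parent: ParentGenotype
    rules: CompatibilityRuleSet = CompatibilityRuleSet()
    dr: DoubleReductionRate = DoubleReductionRate()
    pollen_weights: Mapping[tuple[str, ...], float | int | Fraction] | None = None
    name: str = ""

    def weight_of(self, gamete: GameteClass) -> Fraction:
        if self.pollen_weights is None:
            return Fraction(1)
        normalized = {
            canonical_gamete_token(k): v for k, v in self.pollen_weights.items()
        }
        w = normalized.get(canonical_gamete_token(gamete.display_key), 1)
        w = Fraction(w)
        if w < 0:
            raise SLocusError(f"negative pollen weight for {gamete}")
        return w

    def accepted_pollen(self) -> list[GameteClass]:
        """Pollen gamete classes after stylar filtering and re-weighting,
        renormalized to total probability 1."""
        style = StyleContext.from_parent(self.seed_parent)
        weighted = []
        for g in enumerate_gametes(self.pollen_parent, self.dr):
            if not is_pollen_accepted(g, style, self.rules):
                continue
            mass = g.probability * self.weight_of(g)
            if mass > 0:
                weighted.append((g, mass))
        total = sum(m for _, m in weighted)
        if total == 0:
            raise FullyIncompatibleCrossError(
                f"cross fully incompatible: no pollen gamete of "
                f"{self.pollen_parent.name} is accepted on "
                f"{self.seed_parent.name} styles with positive weight"
            )
        return [GameteClass(g.alleles, m / total) for g, m in weighted]


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Mapping of phenotype classes to exact probabilities, plus provenance."""

    classes: Mapping[PhenotypeClass, Fraction]
    provenance: CrossSpec | None = None

    def ordered(self) -> list[tuple[PhenotypeClass, Fraction]]:
        """Classes in report order: by size, then natural allele order."""
        return sorted(self.classes.items(), key=lambda kv: kv[0].sort_key)

    def ratio_terms(
        self, order: Sequence[PhenotypeClass] | None = None
    ) -> tuple[list[PhenotypeClass], list[int]]:
        """Integer ratio vector equivalent to the probabilities.

        Probabilities are scaled by the LCM of their denominators and
        reduced by their GCD, e.g. the unfiltered tetraploid self cross
        yields (1, 1, 1, 1, 1, 1, 6, 6, 6, 6, 6).  ``order`` may include
        classes with probability zero under this distribution.
        """
        from math import gcd, lcm

        if order is None:
            items = self.ordered()
        else:
            items = [(c, self.classes.get(c, Fraction(0))) for c in order]
        denoms = [p.denominator for _, p in items if p > 0]
        scale = lcm(*denoms) if denoms else 1
        terms = [int(p * scale) for _, p in items]
        g = gcd(*terms) if any(terms) else 1
        return [c for c, _ in items], [t // g for t in terms]

    def probabilities(self, order: Sequence[PhenotypeClass]) -> list[Fraction]:
        return [self.classes.get(c, Fraction(0)) for c in order]


def expected_phenotype_distribution(cross: CrossSpec) -> PhenotypeDistribution:
    """Expected progeny phenotype-class distribution of a cross.

    Eggs are taken unfiltered from the seed parent; pollen classes are
    filtered by the stylar rules and re-weighted; the zygote's phenotype
    class is the union of the distinct alleles of the two gametes.
    Output probabilities are exact when weights are rational.

    Raises
    ------
    FullyIncompatibleCrossError
        If no pollen class survives filtering with positive weight.
    """
    eggs = enumerate_gametes(cross.seed_parent, cross.dr)
    pollen = cross.accepted_pollen()
    out: dict[PhenotypeClass, Fraction] = {}
    for egg in eggs:
        for pol in pollen:
            cls = PhenotypeClass(
                frozenset(h.key for h in egg.alleles)
                | frozenset(h.key for h in pol.alleles)
            )
            out[cls] = out.get(cls, Fraction(0)) + egg.probability * pol.probability
    return PhenotypeDistribution(out, provenance=cross)


def allele_marginals(counts: Mapping[PhenotypeClass, int]) -> dict[str, int]:
    """Per-allele individual counts: each individual contributes to every
    allele it carries (so the marginals sum to sum(count × class size))."""
    out: dict[tuple[str, str], int] = {}
    for cls, n in counts.items():
        for key in cls.alleles:
            out[key] = out.get(key, 0) + n
    return {
        f"{sp}-{lb}": out[(sp, lb)]
        for sp, lb in sorted(out, key=allele_sort_key)
    }


def containing_marginals(
    counts: Mapping[PhenotypeClass, int],
    targets: Sequence[Iterable[str]],
) -> dict[str, int]:
    """Individuals containing *all* alleles of each target combination.

    ``targets`` is a sequence of allele-label collections such as
    ``[("Pps-S1", "Pps-S5"), ...]``; this generalizes
    :func:`allele_marginals` to the pairwise co-occurrence rows of a
    segregation report.
    """
    out: dict[str, int] = {}
    for target in targets:
        cls = PhenotypeClass.from_labels(list(target))
        total = sum(
            n for c, n in counts.items() if cls.alleles <= c.alleles
        )
        out[cls.label()] = total
    return out


def collapse_over_parent(
    counts: Mapping[PhenotypeClass, int], parent_species: str
) -> dict[PhenotypeClass, int]:
    """Sum counts over classes that agree once alleles of one species are
    removed (e.g. collapse a 2x × 4x progeny table over the diploid
    parent's alleles to recover the pollen-pair classes)."""
    out: dict[PhenotypeClass, int] = {}
    for cls, n in counts.items():
        remaining = frozenset(k for k in cls.alleles if k[0] != parent_species)
        if not remaining:
            raise SLocusError(
                f"collapsing {cls} over {parent_species!r} leaves no alleles"
            )
        collapsed = PhenotypeClass(remaining)
        out[collapsed] = out.get(collapsed, 0) + n
    return out
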