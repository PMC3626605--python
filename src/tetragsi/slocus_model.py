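"""Core S-locus data types and gamete formation.

Models the S-locus of gametophytically self-incompatible *Prunus*: each
haplotype couples a stylar S-RNase allele with a pollen-expressed SFB
allele, either of which may be non-functional (a "style-part" or
"pollen-part" mutant).  Tetraploid parents form diploid gametes; under
tetrasomic inheritance the four homologous chromosomes pair at random, so
a parent with four distinct haplotypes produces all C(4,2) = 6 unordered
hetero-diploid gamete classes at equal frequency.  Double reduction (a
gamete receiving two copies of the same parental chromosome) is exposed
as the standard tetrasomic nuisance rate ``alpha`` and defaults to 0.
An alternative fixed-pairing (disomic) mode models allopolyploids such as
sour cherry, where only the four inter-subgenome gamete combinations
occur.

Probabilities are exact :class:`fractions.Fraction` values so that
expected segregation ratios downstream are reproduced as exact integer
ratio vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
import re
from typing import Iterable, Sequence

__all__ = [
    "SHaplotype",
    "ParentGenotype",
    "GameteClass",
    "DoubleReductionRate",
    "SLocusError",
    "enumerate_gametes",
    "allele_sort_key",
]


class SLocusError(ValueError):
    """Invalid S-locus configuration (genotype, pairing mode, rates)."""


_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def allele_sort_key(key: tuple[str, str]) -> tuple[str, str, int, str]:
    """Natural sort key for a (species, label) allele key.

    Labels of the common form ``S<number>`` sort numerically (S2 < S13);
    anything else falls back to lexical order.
    """
    species, label = key
    m = _LABEL_RE.match(label)
    if m:
        return (species, m.group(1), int(m.group(2)), "")
    return (species, label, -1, label)


@dataclass(frozen=True)
class SHaplotype:
    """One S-haplotype: a labelled S-RNase/SFB pair with functionality flags.

    Parameters
    ----------
    label:
        Short allele identifier, e.g. ``"S1"``.
    species:
        Species tag scoping the label, e.g. ``"Pps"`` (*P. pseudocerasus*)
        or ``"Pa"`` (*P. avium*).  Specificities are only comparable
        within a species.
    style_active:
        Whether the stylar S-RNase is functional.
    pollen_active:
        Whether the pollen SFB is functional; a pollen-part mutant
        (``False``) is invisible to stylar rejection.
    """

    label: str
    species: str = "Pps"
    style_active: bool = True
    pollen_active: bool = True

    def __post_init__(self) -> None:
        if not self.label:
            raise SLocusError("S-haplotype label must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        """Species-scoped identity, ignoring functionality flags."""
        return (self.species, self.label)

    def __str__(self) -> str:
        return f"{self.species}-{self.label}"


@dataclass(frozen=True)
class DoubleReductionRate:
    """Probability ``alpha`` that a diploid gamete carries two copies of
    the same parental chromosome (a homozygous, double-reduction gamete)."""

    alpha: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        a = _as_fraction(self.alpha)
        object.__setattr__(self, "alpha", a)
        if not (0 <= a <= 1):
            raise SLocusError(f"double-reduction rate must be in [0, 1], got {a}")


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x)
    raise SLocusError(f"cannot interpret {x!r} as a probability")


@dataclass(frozen=True)
class ParentGenotype:
    """A cultivar's ploidy and its S-haplotype complement.

    ``pairing_mode`` selects how a tetraploid forms diploid gametes:
    ``"tetrasomic"`` (random pairing of all four homologues, the Chinese
    cherry case) or ``"disomic_fixed"`` (two fixed subgenome pairs, the
    sour cherry case; requires ``subgenome_pairs``).
    """

    name: str
    ploidy: int
    haplotypes: tuple[SHaplotype, ...]
    pairing_mode: str = "tetrasomic"
    subgenome_pairs: tuple[tuple[SHaplotype, SHaplotype], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotypes", tuple(self.haplotypes))
        if self.ploidy not in (2, 4):
            raise SLocusError(f"{self.name}: ploidy must be 2 or 4, got {self.ploidy}")
        if len(self.haplotypes) != self.ploidy:
            raise SLocusError(
                f"{self.name}: expected {self.ploidy} haplotypes, "
                f"got {len(self.haplotypes)}"
            )
        if self.pairing_mode not in ("tetrasomic", "disomic_fixed"):
            raise SLocusError(f"{self.name}: unknown pairing mode {self.pairing_mode!r}")
        if self.pairing_mode == "disomic_fixed":
            if self.ploidy != 4:
                raise SLocusError(f"{self.name}: disomic_fixed requires ploidy 4")
            if self.subgenome_pairs is None:
                raise SLocusError(
                    f"{self.name}: disomic_fixed requires subgenome_pairs"
                )
            pairs = tuple(tuple(p) for p in self.subgenome_pairs)
            object.__setattr__(self, "subgenome_pairs", pairs)
            flat = [h for pair in pairs for h in pair]
            if sorted(h.key for h in flat) != sorted(h.key for h in self.haplotypes):
                raise SLocusError(
                    f"{self.name}: subgenome_pairs must partition the haplotypes"
                )

    @property
    def keys(self) -> tuple[tuple[str, str], ...]:
        return tuple(h.key for h in self.haplotypes)

    def haplotype(self, label: str) -> SHaplotype:
        """Look up a haplotype of this parent by bare label."""
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise SLocusError(f"{self.name} carries no haplotype {label!r}")

    def __str__(self) -> str:
        alleles = "".join(h.label for h in self.haplotypes)
        return f"{self.name}({alleles})"


@dataclass(frozen=True)
class GameteClass:
    """An unordered gamete allele multiset with its formation probability."""

    alleles: tuple[SHaplotype, ...]
    probability: Fraction

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.alleles, key=lambda h: allele_sort_key(h.key)))
        object.__setattr__(self, "alleles", ordered)
        object.__setattr__(self, "probability", _as_fraction(self.probability))

    @property
    def key(self) -> tuple[tuple[str, str], ...]:
        """Canonical sorted multiset of (species, label) pairs."""
        return tuple(h.key for h in self.alleles)

    @property
    def display_key(self) -> tuple[str, ...]:
        """Sorted multiset of ``"Species-Label"`` strings (weight-map key)."""
        return tuple(str(h) for h in self.alleles)

    def __str__(self) -> str:
        return "+".join(self.display_key)


def enumerate_gametes(
    parent: ParentGenotype,
    dr: DoubleReductionRate | float | Fraction = DoubleReductionRate(),
) -> list[GameteClass]:
    """Enumerate the gamete classes of a parent with exact probabilities.

    Diploid parents give the two monoploid gametes at 1/2 each (``dr`` is
    ignored).  Tetrasomic tetraploids with four distinct haplotypes give
    the six unordered pairs at (1-alpha)/6 each plus, when alpha > 0, the
    four double-reduction homozygous doubletons at alpha/4 each.
    ``disomic_fixed`` parents give only the four inter-subgenome pairs at
    1/4 each; alpha does not apply.

    Raises
    ------
    SLocusError
        For duplicated haplotype labels in a tetrasomic parent (the model
        covers fully heterozygous genotypes only, as in the cultivars it
        was built for) or a disomic parent without subgenome pairs.
    """
    if not isinstance(dr, DoubleReductionRate):
        dr = DoubleReductionRate(_as_fraction(dr))
    alpha = dr.alpha

    if parent.ploidy == 2:
        a, b = parent.haplotypes
        if a.key == b.key:
            raise SLocusError(
                f"{parent.name}: duplicated haplotype {a} in a diploid parent "
                "is not modeled (gamete output would be degenerate)"
            )
        return [
            GameteClass((a,), Fraction(1, 2)),
            GameteClass((b,), Fraction(1, 2)),
        ]

    if len({h.key for h in parent.haplotypes}) != 4:
        raise SLocusError(
            f"{parent.name}: tetraploid parents must carry four distinct "
            "haplotypes; duplicated alleles are not modeled"
        )

    if parent.pairing_mode == "disomic_fixed":
        (a, b), (c, d) = parent.subgenome_pairs  # type: ignore[misc]
        return [
            GameteClass((x, y), Fraction(1, 4))
            for x in (a, b)
            for y in (c, d)
        ]

    gametes = [
        GameteClass(pair, (1 - alpha) / 6)
        for pair in combinations(parent.haplotypes, 2)
    ]
    if alpha > 0:
        gametes.extend(
            GameteClass((h, h), alpha / 4) for h in parent.haplotypes
        )
    return gametes
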