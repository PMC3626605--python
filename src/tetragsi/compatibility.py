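"""Gametophytic self-incompatibility rules for pollen acceptance.

In S-RNase based GSI the style rejects a pollen tube whose (single,
functional) S-specificity matches any stylar S-RNase.  Hetero-diploid
pollen from a tetraploid carries two S-haplotypes; when both are
functional and different, each SFB can detoxify the other's cognate
S-RNase — *competitive interaction* — and the grain is accepted even on
a self style.  A pollen-part-dead haplotype contributes no specificity,
so a hetero-diploid grain carrying one dead and one live haplotype acts
like a monoploid grain of the live specificity and is rejected by self
styles.

Specificity matching is species-scoped: a *P. avium* style has no
S-RNase cognate to a *P. pseudocerasus* specificity, so interspecific
pollen is never rejected on label coincidence alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .slocus_model import GameteClass, ParentGenotype

__all__ = [
    "StyleContext",
    "CompatibilityRuleSet",
    "effective_pollen_specificities",
    "is_pollen_accepted",
]


@dataclass(frozen=True)
class StyleContext:
    """The set of functional stylar S-specificities of a seed parent."""

    style_alleles: frozenset[tuple[str, str]]

    @classmethod
    def from_parent(cls, parent: ParentGenotype) -> "StyleContext":
        return cls(frozenset(h.key for h in parent.haplotypes if h.style_active))


@dataclass(frozen=True)
class CompatibilityRuleSet:
    """Switches selecting the pollen-rejection model.

    competitive_interaction:
        When two or more distinct functional specificities co-occur in
        one grain, the grain is accepted regardless of the style
        (default, the model supported by the progeny data).  With
        ``False`` every specificity is independently lethal: a grain is
        rejected if *any* functional specificity matches the style.
    si_enabled:
        ``False`` disables rejection entirely (fully compatible cross,
        used to derive null expected ratios).
    accept_pollenless:
        How to treat grains with *no* functional specificity: accepted
        (default; a fully pollen-part-dead grain escapes recognition) or
        rejected (modelling a lethal mutant that aborts the grain).
    """

    competitive_interaction: bool = True
    si_enabled: bool = True
    accept_pollenless: bool = True


def effective_pollen_specificities(gamete: GameteClass) -> frozenset[tuple[str, str]]:
    """Distinct functional (pollen-active) specificities carried by a grain.

    Pollen-part-dead haplotypes are invisible to the style and are
    dropped; a homozygous doubleton contributes one specificity.
    """
    return frozenset(h.key for h in gamete.alleles if h.pollen_active)


def is_pollen_accepted(
    gamete: GameteClass,
    style: StyleContext,
    rules: CompatibilityRuleSet = CompatibilityRuleSet(),
) -> bool:
    """Decide whether the style accepts this pollen gamete class."""
    if not rules.si_enabled:
        return True
    effective = effective_pollen_specificities(gamete)
    if not effective:
        return rules.accept_pollenless
    if len(effective) >= 2 and rules.competitive_interaction:
        return True
    return not (effective & style.style_alleles)
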