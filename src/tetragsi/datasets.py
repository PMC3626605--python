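"""Published study data: cultivars, progeny count tables, fitted ratios.

The packaged study comprises two self-compatible tetraploid Chinese
cherry (*Prunus pseudocerasus*, tag ``Pps``) cultivars — "Dabai"
(S1 S2 S5 S8) and "Taishanganying" (S1 S2 S4 S6) — and the diploid sweet
cherry (*P. avium*, tag ``Pa``) cultivar "Summit" (S1 S2), together with
the S-genotype class counts of their four genotyped progenies: the two
self-pollinations and the two interspecific crosses Summit × Dabai and
Summit × Taishanganying.

Pps-S2 is configured pollen-part dead (its SFB was never detected and
the self-progeny data behave exactly as if grains carrying only the S2
specificity were rejected); Pps-S8's SFB was likewise not amplified but
is left pollen-functional, the amplification failure being plausibly
technical.  Both flags are plain data and can be overridden by
rebuilding the parents.

All counts are desk-scale published observations, embedded here so every
analysis in the package can be re-run without any external file.
"""

from __future__ import annotations

from .compatibility import CompatibilityRuleSet
from .progeny_model import CrossSpec, PhenotypeClass
from .slocus_model import DoubleReductionRate, ParentGenotype, SHaplotype

__all__ = [
    "dabai",
    "taishanganying",
    "summit",
    "study_parents",
    "study_cross",
    "study_counts",
    "STUDY_CROSSES",
    "MARGINAL_TABLES",
]


def dabai(s2_pollen_dead: bool = True) -> ParentGenotype:
    """Tetraploid 'Dabai' (Pps S1 S2 S5 S8)."""
    return ParentGenotype(
        name="Dabai",
        ploidy=4,
        haplotypes=(
            SHaplotype("S1", "Pps"),
            SHaplotype("S2", "Pps", pollen_active=not s2_pollen_dead),
            SHaplotype("S5", "Pps"),
            SHaplotype("S8", "Pps"),
        ),
    )


def taishanganying(s2_pollen_dead: bool = True) -> ParentGenotype:
    """Tetraploid 'Taishanganying' (Pps S1 S2 S4 S6)."""
    return ParentGenotype(
        name="Taishanganying",
        ploidy=4,
        haplotypes=(
            SHaplotype("S1", "Pps"),
            SHaplotype("S2", "Pps", pollen_active=not s2_pollen_dead),
            SHaplotype("S4", "Pps"),
            SHaplotype("S6", "Pps"),
        ),
    )


def summit() -> ParentGenotype:
    """Diploid 'Summit' (Pa S1 S2)."""
    return ParentGenotype(
        name="Summit",
        ploidy=2,
        haplotypes=(SHaplotype("S1", "Pa"), SHaplotype("S2", "Pa")),
    )


def study_parents(s2_pollen_dead: bool = True) -> dict[str, ParentGenotype]:
    return {
        "Dabai": dabai(s2_pollen_dead),
        "Taishanganying": taishanganying(s2_pollen_dead),
        "Summit": summit(),
    }


STUDY_CROSSES = (
    "dabai_self",
    "taishanganying_self",
    "summit_x_dabai",
    "summit_x_taishanganying",
)


def study_cross(
    name: str,
    si_enabled: bool = False,
    s2_pollen_dead: bool = True,
    competitive_interaction: bool = True,
    alpha: float = 0.0,
    pollen_weights=None,
) -> CrossSpec:
    """One of the four study pollinations as a :class:`CrossSpec`.

    The default ``si_enabled=False`` is the null model used to derive
    the published expected segregation ratios (all gamete pairs
    transmitted); switch SI on to model the compatibility-filtered
    cross.
    """
    parents = study_parents(s2_pollen_dead)
    seed, pollen = {
        "dabai_self": ("Dabai", "Dabai"),
        "taishanganying_self": ("Taishanganying", "Taishanganying"),
        "summit_x_dabai": ("Summit", "Dabai"),
        "summit_x_taishanganying": ("Summit", "Taishanganying"),
    }[name]
    return CrossSpec(
        seed_parent=parents[seed],
        pollen_parent=parents[pollen],
        rules=CompatibilityRuleSet(
            competitive_interaction=competitive_interaction,
            si_enabled=si_enabled,
        ),
        dr=DoubleReductionRate(alpha),
        pollen_weights=pollen_weights,
        name=name,
    )


def _cls(*labels: str) -> PhenotypeClass:
    return PhenotypeClass.from_labels(labels)


def _pps(*nums: int) -> PhenotypeClass:
    return _cls(*[f"Pps-S{n}" for n in nums])


# Observed S-genotype class counts of the four progenies.  Self progenies
# have 11 reachable classes (6 pair + 4 triple + 1 quadruple); the
# interspecific progenies have 12 (6 Pps pairs x 2 Pa alleles).
_DABAI_SELF = {
    _pps(1, 2): 0, _pps(1, 5): 90, _pps(1, 8): 4,
    _pps(2, 5): 0, _pps(2, 8): 0, _pps(5, 8): 53,
    _pps(1, 2, 5): 14, _pps(1, 2, 8): 6, _pps(1, 5, 8): 211,
    _pps(2, 5, 8): 0, _pps(1, 2, 5, 8): 60,
}

_TAISHANGANYING_SELF = {
    _pps(1, 2): 0, _pps(1, 4): 41, _pps(1, 6): 9,
    _pps(2, 4): 0, _pps(2, 6): 0, _pps(4, 6): 0,
    _pps(1, 2, 4): 124, _pps(1, 2, 6): 13, _pps(1, 4, 6): 133,
    _pps(2, 4, 6): 3, _pps(1, 2, 4, 6): 127,
}

_SUMMIT_X_DABAI = {
    _cls("Pps-S1", "Pps-S2", "Pa-S1"): 2, _cls("Pps-S1", "Pps-S2", "Pa-S2"): 4,
    _cls("Pps-S1", "Pps-S5", "Pa-S1"): 8, _cls("Pps-S1", "Pps-S5", "Pa-S2"): 5,
    _cls("Pps-S1", "Pps-S8", "Pa-S1"): 10, _cls("Pps-S1", "Pps-S8", "Pa-S2"): 5,
    _cls("Pps-S2", "Pps-S5", "Pa-S1"): 0, _cls("Pps-S2", "Pps-S5", "Pa-S2"): 0,
    _cls("Pps-S2", "Pps-S8", "Pa-S1"): 0, _cls("Pps-S2", "Pps-S8", "Pa-S2"): 0,
    _cls("Pps-S5", "Pps-S8", "Pa-S1"): 5, _cls("Pps-S5", "Pps-S8", "Pa-S2"): 10,
}

_SUMMIT_X_TAISHANGANYING = {
    _cls("Pps-S1", "Pps-S2", "Pa-S1"): 2, _cls("Pps-S1", "Pps-S2", "Pa-S2"): 4,
    _cls("Pps-S1", "Pps-S4", "Pa-S1"): 5, _cls("Pps-S1", "Pps-S4", "Pa-S2"): 1,
    _cls("Pps-S1", "Pps-S6", "Pa-S1"): 5, _cls("Pps-S1", "Pps-S6", "Pa-S2"): 1,
    _cls("Pps-S2", "Pps-S4", "Pa-S1"): 0, _cls("Pps-S2", "Pps-S4", "Pa-S2"): 0,
    _cls("Pps-S2", "Pps-S6", "Pa-S1"): 0, _cls("Pps-S2", "Pps-S6", "Pa-S2"): 1,
    _cls("Pps-S4", "Pps-S6", "Pa-S1"): 2, _cls("Pps-S4", "Pps-S6", "Pa-S2"): 3,
}

_COUNTS = {
    "dabai_self": _DABAI_SELF,
    "taishanganying_self": _TAISHANGANYING_SELF,
    "summit_x_dabai": _SUMMIT_X_DABAI,
    "summit_x_taishanganying": _SUMMIT_X_TAISHANGANYING,
}


def study_counts(name: str) -> dict[PhenotypeClass, int]:
    """Observed progeny class counts for one of the four pollinations."""
    return dict(_COUNTS[name])


# Published marginal segregation rows: (progeny, marginal kind) ->
# (ordered labels, observed counts, fitted small-integer ratio).
# The single-allele and pair rows derive from the class tables above via
# allele_marginals / containing_marginals / collapse_over_parent.
MARGINAL_TABLES = {
    ("summit_x_dabai", "pa_alleles"): (
        ("Pa-S1", "Pa-S2"), (25, 24), (1, 1)),
    ("summit_x_dabai", "pps_alleles"): (
        ("Pps-S1", "Pps-S2", "Pps-S5", "Pps-S8"), (34, 6, 28, 30), (5, 1, 5, 5)),
    ("summit_x_dabai", "pps_pairs"): (
        ("Pps-S1+Pps-S2", "Pps-S1+Pps-S5", "Pps-S1+Pps-S8",
         "Pps-S5+Pps-S8", "Pps-S2+Pps-S5", "Pps-S2+Pps-S8"),
        (6, 13, 15, 15, 0, 0), (1, 2, 2, 2, 0, 0)),
    ("summit_x_taishanganying", "pa_alleles"): (
        ("Pa-S1", "Pa-S2"), (14, 10), (1, 1)),
    ("summit_x_taishanganying", "pps_alleles"): (
        ("Pps-S1", "Pps-S2", "Pps-S4", "Pps-S6"), (18, 7, 11, 12), (2, 1, 2, 2)),
    ("summit_x_taishanganying", "pps_pairs"): (
        ("Pps-S1+Pps-S2", "Pps-S1+Pps-S4", "Pps-S1+Pps-S6",
         "Pps-S2+Pps-S4", "Pps-S2+Pps-S6", "Pps-S4+Pps-S6"),
        (6, 6, 6, 0, 1, 5), (6, 6, 6, 0, 1, 6)),
    ("dabai_self", "pps_alleles"): (
        ("Pps-S1", "Pps-S2", "Pps-S5", "Pps-S8"), (385, 80, 428, 334), (5, 1, 5, 4)),
    ("dabai_self", "pps_pairs"): (
        ("Pps-S1+Pps-S2", "Pps-S1+Pps-S5", "Pps-S1+Pps-S8",
         "Pps-S2+Pps-S5", "Pps-S2+Pps-S8", "Pps-S5+Pps-S8"),
        (80, 375, 281, 74, 66, 324), (3, 16, 12, 3, 3, 16)),
    ("taishanganying_self", "pps_alleles"): (
        ("Pps-S1", "Pps-S2", "Pps-S4", "Pps-S6"), (447, 267, 428, 285), (3, 2, 3, 2)),
    ("taishanganying_self", "pps_pairs"): (
        ("Pps-S1+Pps-S2", "Pps-S1+Pps-S4", "Pps-S1+Pps-S6",
         "Pps-S2+Pps-S4", "Pps-S2+Pps-S6", "Pps-S4+Pps-S6"),
        (264, 425, 282, 254, 143, 263), (2, 3, 2, 2, 1, 2)),
}
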