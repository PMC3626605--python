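"""Expected progeny distributions, marginals and collapse operations."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from tetragsi import (
    CompatibilityRuleSet,
    CrossSpec,
    FullyIncompatibleCrossError,
    PhenotypeClass,
    allele_marginals,
    collapse_over_parent,
    containing_marginals,
    expected_phenotype_distribution,
    enumerate_gametes,
)
from tetragsi import datasets


def cls_of(*labels):
    return PhenotypeClass.from_labels(labels)


def pps(*nums):
    return cls_of(*[f"Pps-S{n}" for n in nums])


def brute_force_distribution(cross):
    """Independent oracle: double loop over all gamete pairs with an inline
    restatement of the acceptance rule, exact Fractions throughout."""
    eggs = enumerate_gametes(cross.seed_parent, cross.dr)
    pollen = enumerate_gametes(cross.pollen_parent, cross.dr)
    style = {h.key for h in cross.seed_parent.haplotypes if h.style_active}
    rules = cross.rules

    def accepted(g):
        if not rules.si_enabled:
            return True
        eff = {h.key for h in g.alleles if h.pollen_active}
        if not eff:
            return rules.accept_pollenless
        if len(eff) >= 2 and rules.competitive_interaction:
            return True
        return not (eff & style)

    weighted = [
        (g, g.probability * cross.weight_of(g)) for g in pollen if accepted(g)
    ]
    total = sum(w for _, w in weighted)
    out = {}
    for egg in eggs:
        for pol, w in weighted:
            key = frozenset(h.key for h in egg.alleles) | frozenset(
                h.key for h in pol.alleles
            )
            out[key] = out.get(key, Fraction(0)) + egg.probability * w / total
    return out


class TestExpectedDistribution:
    def test_tetraploid_self_without_filtering_is_1x6_6x6_over_36(self):
        cross = datasets.study_cross("dabai_self", si_enabled=False)
        dist = expected_phenotype_distribution(cross)
        classes, terms = dist.ratio_terms()
        assert [c.label() for c in classes] == [
            "Pps-S1+Pps-S2", "Pps-S1+Pps-S5", "Pps-S1+Pps-S8",
            "Pps-S2+Pps-S5", "Pps-S2+Pps-S8", "Pps-S5+Pps-S8",
            "Pps-S1+Pps-S2+Pps-S5", "Pps-S1+Pps-S2+Pps-S8",
            "Pps-S1+Pps-S5+Pps-S8", "Pps-S2+Pps-S5+Pps-S8",
            "Pps-S1+Pps-S2+Pps-S5+Pps-S8",
        ]
        assert terms == [1, 1, 1, 1, 1, 1, 6, 6, 6, 6, 6]
        assert all(
            p.denominator == 36 or p == Fraction(1, 6)
            for p in dist.classes.values()
        )

    def test_interspecific_cross_gives_12_equiprobable_classes(self):
        cross = datasets.study_cross("summit_x_dabai", si_enabled=False)
        dist = expected_phenotype_distribution(cross)
        assert len(dist.classes) == 12
        assert set(dist.classes.values()) == {Fraction(1, 12)}
        assert all(len(c.alleles) == 3 for c in dist.classes)

    def test_pollen_dead_s2_with_competition_filters_pollen(self):
        cross = datasets.study_cross("dabai_self", si_enabled=True)
        accepted = {
            tuple(g.display_key): g.probability for g in cross.accepted_pollen()
        }
        assert accepted == {
            ("Pps-S1", "Pps-S5"): Fraction(1, 3),
            ("Pps-S1", "Pps-S8"): Fraction(1, 3),
            ("Pps-S5", "Pps-S8"): Fraction(1, 3),
        }
        dist = expected_phenotype_distribution(cross)
        # S2 can only arrive via the egg side, never as a pollen pair member
        for zero_cls in (pps(1, 2), pps(2, 5), pps(2, 8)):
            assert dist.classes.get(zero_cls, Fraction(0)) == 0
        assert sum(dist.classes.values()) == 1

    def test_self_cross_with_competition_off_is_fully_incompatible(self):
        cross = datasets.study_cross(
            "dabai_self", si_enabled=True, competitive_interaction=False
        )
        with pytest.raises(FullyIncompatibleCrossError):
            expected_phenotype_distribution(cross)

    def test_no_singleton_classes_without_double_reduction(self):
        """At alpha=0 the 36 gamete pairs of a tetraploid self cross split
        6/24/6 over class sizes 2/3/4 and produce no single-allele class."""
        cross = datasets.study_cross("dabai_self", si_enabled=False)
        dist = expected_phenotype_distribution(cross)
        by_size = {}
        for c, p in dist.classes.items():
            by_size[len(c.alleles)] = by_size.get(len(c.alleles), Fraction(0)) + p
        assert by_size == {
            2: Fraction(6, 36), 3: Fraction(24, 36), 4: Fraction(6, 36)
        }

    @pytest.mark.parametrize("name", datasets.STUDY_CROSSES)
    @pytest.mark.parametrize("si_enabled", [False, True])
    def test_equals_brute_force_oracle_exactly(self, name, si_enabled):
        cross = datasets.study_cross(name, si_enabled=si_enabled)
        dist = expected_phenotype_distribution(cross)
        oracle = brute_force_distribution(cross)
        got = {c.alleles: p for c, p in dist.classes.items() if p > 0}
        assert got == {k: v for k, v in oracle.items() if v > 0}

    def test_oracle_equivalence_with_weights_and_double_reduction(self):
        weights = {
            ("Pps-S1", "Pps-S5"): 16, ("Pps-S1", "Pps-S8"): 12,
            ("Pps-S5", "Pps-S8"): 16, ("Pps-S1", "Pps-S2"): 3,
            ("Pps-S2", "Pps-S5"): 3, ("Pps-S2", "Pps-S8"): 3,
        }
        cross = datasets.study_cross(
            "dabai_self", si_enabled=False, alpha=0.1, pollen_weights=weights
        )
        dist = expected_phenotype_distribution(cross)
        oracle = brute_force_distribution(cross)
        assert {c.alleles: p for c, p in dist.classes.items()} == oracle
        assert sum(dist.classes.values()) == 1

    def test_uniform_weights_leave_distribution_invariant(self):
        base = expected_phenotype_distribution(
            datasets.study_cross("dabai_self", si_enabled=False)
        )
        scaled = expected_phenotype_distribution(
            datasets.study_cross(
                "dabai_self",
                si_enabled=False,
                pollen_weights={
                    tuple(g.display_key): 7
                    for g in enumerate_gametes(datasets.dabai())
                },
            )
        )
        assert base.classes == scaled.classes


class TestMarginals:
    def test_self_progeny_allele_marginals_match_published_row(self):
        counts = datasets.study_counts("dabai_self")
        assert allele_marginals(counts) == {
            "Pps-S1": 385, "Pps-S2": 80, "Pps-S5": 428, "Pps-S8": 334
        }

    def test_cross_progeny_allele_marginals(self):
        counts = datasets.study_counts("summit_x_dabai")
        marg = allele_marginals(counts)
        assert marg["Pps-S1"] == 34
        assert marg["Pps-S2"] == 6
        assert marg["Pps-S5"] == 28
        assert marg["Pps-S8"] == 30
        assert (marg["Pa-S1"], marg["Pa-S2"]) == (25, 24)

    def test_empty_counts_give_empty_marginals(self):
        assert allele_marginals({}) == {}
        assert allele_marginals({pps(1, 5): 0}) == {"Pps-S1": 0, "Pps-S5": 0}

    def test_marginal_total_is_count_weighted_class_size(self):
        counts = datasets.study_counts("taishanganying_self")
        marg = allele_marginals(counts)
        assert sum(marg.values()) == sum(
            n * len(c.alleles) for c, n in counts.items()
        )

    def test_pair_containment_marginals(self):
        counts = datasets.study_counts("dabai_self")
        pairs = containing_marginals(
            counts,
            [("Pps-S1", "Pps-S2"), ("Pps-S1", "Pps-S5"), ("Pps-S1", "Pps-S8"),
             ("Pps-S2", "Pps-S5"), ("Pps-S2", "Pps-S8"), ("Pps-S5", "Pps-S8")],
        )
        assert list(pairs.values()) == [80, 375, 281, 74, 66, 324]


class TestCollapse:
    def test_collapse_cross_progeny_over_diploid_parent(self):
        counts = datasets.study_counts("summit_x_dabai")
        collapsed = collapse_over_parent(counts, "Pa")
        assert {c.label(): n for c, n in collapsed.items()} == {
            "Pps-S1+Pps-S2": 6, "Pps-S1+Pps-S5": 13, "Pps-S1+Pps-S8": 15,
            "Pps-S2+Pps-S5": 0, "Pps-S2+Pps-S8": 0, "Pps-S5+Pps-S8": 15,
        }

    def test_collapse_taishanganying_cross(self):
        counts = datasets.study_counts("summit_x_taishanganying")
        collapsed = collapse_over_parent(counts, "Pa")
        assert {c.label(): n for c, n in collapsed.items()} == {
            "Pps-S1+Pps-S2": 6, "Pps-S1+Pps-S4": 6, "Pps-S1+Pps-S6": 6,
            "Pps-S2+Pps-S4": 0, "Pps-S2+Pps-S6": 1, "Pps-S4+Pps-S6": 5,
        }

    def test_collapse_preserves_total_count(self):
        counts = datasets.study_counts("summit_x_dabai")
        assert sum(collapse_over_parent(counts, "Pa").values()) == sum(
            counts.values()
        )

    def test_collapse_over_absent_species_is_identity(self):
        counts = datasets.study_counts("dabai_self")
        assert collapse_over_parent(counts, "Pa") == counts


@given(scale=st.integers(min_value=1, max_value=1000))
def test_weight_scale_invariance(scale):
    """Multiplying every pollen weight by a constant leaves the expected
    distribution unchanged (weights are relative)."""
    weights = {
        ("Pps-S1", "Pps-S5"): 5 * scale,
        ("Pps-S5", "Pps-S8"): 2 * scale,
        ("Pps-S1", "Pps-S8"): 1 * scale,
    }
    cross = datasets.study_cross(
        "dabai_self", si_enabled=True, pollen_weights=weights
    )
    base = datasets.study_cross(
        "dabai_self",
        si_enabled=True,
        pollen_weights={k: v // scale for k, v in weights.items()},
    )
    assert (
        expected_phenotype_distribution(cross).classes
        == expected_phenotype_distribution(base).classes
    )
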