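from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from tetragsi import datasets

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dabai():
    return datasets.dabai()


@pytest.fixture(scope="session")
def dabai_all_functional():
    return datasets.dabai(s2_pollen_dead=False)


@pytest.fixture(scope="session")
def taishanganying():
    return datasets.taishanganying()


@pytest.fixture(scope="session")
def summit():
    return datasets.summit()


def ordered_chromosome_gamete_oracle(parent, alpha=Fraction(0)):
    """Independent gamete-frequency oracle: enumerate ordered chromosome
    draws at the individual-chromosome level and collapse to multisets.

    Without double reduction a diploid gamete is an ordered draw of two
    distinct chromosomes (4 x 3 equally likely outcomes); with double
    reduction, probability ``alpha`` is spread uniformly over the four
    same-chromosome doubletons.  Returns {sorted label multiset: Fraction}.
    """
    alpha = Fraction(alpha)
    out = {}
    if parent.ploidy == 2:
        for h in parent.haplotypes:
            out[(h.key,)] = out.get((h.key,), Fraction(0)) + Fraction(1, 2)
        return out
    chroms = parent.haplotypes
    for i, a in enumerate(chroms):
        for j, b in enumerate(chroms):
            if i == j:
                continue
            key = tuple(sorted([a.key, b.key]))
            out[key] = out.get(key, Fraction(0)) + (1 - alpha) * Fraction(1, 12)
    if alpha > 0:
        for h in chroms:
            key = (h.key, h.key)
            out[key] = out.get(key, Fraction(0)) + alpha / 4
    return out
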