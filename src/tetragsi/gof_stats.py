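"""Pearson χ² goodness-of-fit against segregation ratio vectors.

Observed progeny class counts are tested against a theoretical ratio
vector (e.g. all-ones for undistorted segregation, or 1:1:1:1:1:1:6:6:6:6:6
for the unfiltered tetraploid self cross).  The statistic is the plain
Pearson sum Σ (obs − exp)² / exp with expected counts proportional to the
ratio; no continuity correction is applied.

Zero-ratio cells follow the convention required for fitted ratios that
predict structural zeros: expected 0 with observed 0 contributes nothing,
expected 0 with observed > 0 makes the model impossible (χ² = +inf,
flagged).  Degrees of freedom are k − 1 counting *all* cells of the
vector, including zero-ratio ones.  Critical values are always recomputed
from the χ² distribution at the stated df — published tables occasionally
mislabel them (see docs/methods.md).

Also provided: an exhaustive small-integer ratio search formalizing the
"approximate ratio" eyeballing used in segregation studies, an optional
exact multinomial p-value for small tables, and the ≥2% fruit-set
compatibility classifier used in field pollination tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd, inf, isfinite
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RatioVector",
    "GoFResult",
    "chi2_gof",
    "critical_value",
    "find_candidate_ratios",
    "classify_fruit_set",
    "exact_multinomial_pvalue",
]

_SEARCH_CAP = 2_000_000  # max ratio vectors scored by find_candidate_ratios


@dataclass(frozen=True)
class RatioVector:
    """A segregation ratio such as 1:2:2:2:0:0, aligned to a class order."""

    terms: tuple[float, ...]

    def __post_init__(self) -> None:
        terms = tuple(float(t) for t in self.terms)
        object.__setattr__(self, "terms", terms)
        if not terms or all(t == 0 for t in terms):
            raise ValueError("ratio vector needs at least one positive term")
        if any(t < 0 for t in terms):
            raise ValueError("ratio terms must be non-negative")

    def __str__(self) -> str:
        return ":".join(
            str(int(t)) if float(t).is_integer() else f"{t:g}" for t in self.terms
        )


@dataclass(frozen=True)
class GoFResult:
    """Outcome of one Pearson goodness-of-fit test."""

    chi2: float
    df: int
    alpha_level: float
    critical: float
    fits: bool
    contributions: tuple[float, ...]
    expected: tuple[float, ...]
    impossible: bool = False  # observed count in a zero-ratio cell

    @property
    def chi2_display(self) -> float:
        """Statistic rounded to 3 decimals, the conventional print format."""
        return round(self.chi2, 3)


def critical_value(df: int, alpha_level: float = 0.05) -> float:
    """Upper-tail χ² quantile, e.g. 3.84 (df=1), 11.07 (df=5), 18.31 (df=10)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must be in (0, 1)")
    return float(stats.chi2.ppf(1 - alpha_level, df))


def chi2_gof(
    observed: Sequence[int],
    ratio: RatioVector | Sequence[float],
    alpha_level: float = 0.05,
) -> GoFResult:
    """Pearson χ² goodness-of-fit of observed counts against a ratio vector."""
    if not isinstance(ratio, RatioVector):
        ratio = RatioVector(tuple(ratio))
    obs = [int(o) for o in observed]
    if len(obs) != len(ratio.terms):
        raise ValueError(
            f"observed has {len(obs)} cells but ratio has {len(ratio.terms)}"
        )
    if any(o < 0 for o in obs):
        raise ValueError("observed counts must be non-negative")
    total = sum(obs)
    if total == 0:
        raise ValueError("total observed count must be positive")

    ratio_sum = sum(ratio.terms)
    expected = tuple(total * t / ratio_sum for t in ratio.terms)
    impossible = False
    contributions = []
    for o, e in zip(obs, expected):
        if e == 0:
            if o > 0:
                impossible = True
                contributions.append(inf)
            else:
                contributions.append(0.0)
        else:
            contributions.append((o - e) ** 2 / e)
    chi2 = inf if impossible else float(sum(contributions))

    df = len(obs) - 1
    crit = critical_value(df, alpha_level)
    return GoFResult(
        chi2=chi2,
        df=df,
        alpha_level=alpha_level,
        critical=crit,
        fits=isfinite(chi2) and chi2 <= crit,
        contributions=tuple(contributions),
        expected=expected,
        impossible=impossible,
    )


def _canonical(terms: tuple[int, ...]) -> tuple[int, ...]:
    g = gcd(*terms)
    return tuple(t // g for t in terms) if g > 1 else terms


def find_candidate_ratios(
    observed: Sequence[int],
    max_term: int,
    top_k: int = 10,
) -> list[tuple[RatioVector, float]]:
    """Exhaustively score small-integer ratio vectors against the counts.

    All vectors with terms in 0..max_term (excluding the all-zero vector,
    deduplicated up to common scaling) are scored by Pearson χ² and
    returned ranked ascending, ties broken by lexical term order.
    Vectors predicting a structural zero where a count was observed score
    +inf and therefore rank last.
    """
    obs = np.asarray(observed, dtype=float)
    k = len(obs)
    if max_term < 1:
        raise ValueError("max_term must be >= 1")
    if k > 8:
        raise ValueError("ratio search supports at most 8 classes")
    n_vectors = (max_term + 1) ** k
    if n_vectors > _SEARCH_CAP:
        raise ValueError(
            f"search space of {n_vectors} ratio vectors exceeds the cap of "
            f"{_SEARCH_CAP}; reduce max_term or the number of classes"
        )

    grid = np.stack(
        np.unravel_index(np.arange(n_vectors), (max_term + 1,) * k), axis=1
    ).astype(float)
    grid = grid[grid.sum(axis=1) > 0]
    total = obs.sum()
    expected = total * grid / grid.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (obs - expected) ** 2 / expected
    # zero-ratio cells: 0 contribution when observed 0, inf otherwise
    zero_cells = expected == 0
    contrib[zero_cells & (obs == 0)] = 0.0
    contrib[zero_cells & (obs > 0)] = np.inf
    scores = contrib.sum(axis=1)

    order = np.lexsort((*[grid[:, i] for i in range(k - 1, -1, -1)], scores))
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[RatioVector, float]] = []
    for idx in order:
        terms = _canonical(tuple(int(t) for t in grid[idx]))
        if terms in seen:
            continue
        seen.add(terms)
        out.append((RatioVector(terms), float(scores[idx])))
        if len(out) >= top_k:
            break
    return out


def exact_multinomial_pvalue(
    observed: Sequence[int], ratio: RatioVector | Sequence[float]
) -> float:
    """Exact multinomial goodness-of-fit p-value for small tables.

    Enumerates all outcomes of the multinomial(n, p) null and sums the
    probability of outcomes no more probable than the observed one.
    Intended for small n and few classes; the enumeration is capped.
    """
    if not isinstance(ratio, RatioVector):
        ratio = RatioVector(tuple(ratio))
    obs = tuple(int(o) for o in observed)
    if len(obs) != len(ratio.terms):
        raise ValueError("length mismatch")
    if any(o > 0 and t == 0 for o, t in zip(obs, ratio.terms)):
        return 0.0
    live = [i for i, t in enumerate(ratio.terms) if t > 0]
    n = sum(obs)
    k = len(live)
    from math import comb
    if comb(n + k - 1, k - 1) > 500_000:
        raise ValueError("table too large for exact enumeration")
    p = np.array([ratio.terms[i] for i in live], dtype=float)
    p /= p.sum()
    dist = stats.multinomial(n, p)
    p_obs = dist.pmf([obs[i] for i in live])

    def compositions(total: int, cells: int):
        if cells == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, cells - 1):
                yield (first, *rest)

    pval = 0.0
    for comp in compositions(n, k):
        q = dist.pmf(comp)
        if q <= p_obs * (1 + 1e-10):
            pval += q
    return float(min(pval, 1.0))


def classify_fruit_set(
    set_fruits: int, pollinated_flowers: int, threshold_percent: float = 2.0
) -> str:
    """Field-test compatibility call: fruit set ≥ threshold (default 2%)
    classifies a pollination as ``"compatible"``."""
    if pollinated_flowers <= 0:
        raise ValueError("pollinated_flowers must be positive")
    if not 0 <= set_fruits <= pollinated_flowers:
        raise ValueError("set_fruits must be between 0 and pollinated_flowers")
    percent = 100.0 * set_fruits / pollinated_flowers
    return "compatible" if percent >= threshold_percent else "incompatible"
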