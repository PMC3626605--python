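"""Synthetic progeny count tables with the model's statistical structure.

Progeny genotyping yields one multinomial draw over the phenotype-class
distribution of the cross, so the generator samples class counts
directly from the closed-form expectation.  An event-level mode draws
individual pollination events (egg draw + pollen rejection sampling
against the style, with transmission-weight thinning) and exists to
cross-validate the closed form; both modes agree in distribution.

Reproducibility: one :class:`numpy.random.SeedSequence` is built from
the configured seed and spawned once per replicate, so replicate *r* is
independent of the others and individually reproducible from
``(seed, r)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .gof_stats import GoFResult, RatioVector, chi2_gof
from .progeny_model import (
    CrossSpec,
    FullyIncompatibleCrossError,
    PhenotypeClass,
    PhenotypeDistribution,
    expected_phenotype_distribution,
)
from .slocus_model import enumerate_gametes

__all__ = [
    "SimulationConfig",
    "simulate_progeny_counts",
    "simulate_progeny_counts_events",
    "recover_parameters",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation run: cross, progeny size, seed, replicate count."""

    cross: CrossSpec
    n_progeny: int
    seed: int
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _replicate_rngs(cfg: SimulationConfig) -> list[np.random.Generator]:
    root = np.random.SeedSequence(cfg.seed)
    return [np.random.default_rng(s) for s in root.spawn(cfg.n_replicates)]


def simulate_progeny_counts(
    cfg: SimulationConfig,
) -> list[dict[PhenotypeClass, int]]:
    """Multinomial progeny-class counts, one dict per replicate.

    Each replicate is a single multinomial draw of size ``n_progeny``
    from the expected phenotype distribution of the cross; counts sum to
    ``n_progeny`` and include zero-count classes so every reachable
    class has an entry.
    """
    dist = expected_phenotype_distribution(cfg.cross)
    ordered = dist.ordered()
    classes = [c for c, _ in ordered]
    probs = np.array([float(p) for _, p in ordered])
    probs /= probs.sum()
    out = []
    for rng in _replicate_rngs(cfg):
        draw = rng.multinomial(cfg.n_progeny, probs)
        out.append({c: int(n) for c, n in zip(classes, draw)})
    return out


def simulate_progeny_counts_events(
    cfg: SimulationConfig,
) -> list[dict[PhenotypeClass, int]]:
    """Event-level simulator: per-individual egg draw plus pollen
    rejection sampling (stylar acceptance, then weight thinning).

    Statistically equivalent to :func:`simulate_progeny_counts`; kept as
    an independent route for validating the closed-form distribution.
    """
    eggs = enumerate_gametes(cfg.cross.seed_parent, cfg.cross.dr)
    pollen_all = enumerate_gametes(cfg.cross.pollen_parent, cfg.cross.dr)
    # acceptance set and weights; raises if fully incompatible
    accepted_keys = {g.key for g in cfg.cross.accepted_pollen()}
    weights = {g.key: float(cfg.cross.weight_of(g)) for g in pollen_all}
    wmax = max(w for k, w in weights.items() if k in accepted_keys)

    egg_probs = np.array([float(g.probability) for g in eggs])
    pol_probs = np.array([float(g.probability) for g in pollen_all])
    out = []
    for rng in _replicate_rngs(cfg):
        counts: dict[PhenotypeClass, int] = {}
        for _ in range(cfg.n_progeny):
            egg = eggs[rng.choice(len(eggs), p=egg_probs)]
            while True:
                pol = pollen_all[rng.choice(len(pollen_all), p=pol_probs)]
                if pol.key not in accepted_keys:
                    continue  # rejected by the style
                if rng.random() < weights[pol.key] / wmax:
                    break  # transmitted
            cls = PhenotypeClass(
                frozenset(h.key for h in egg.alleles)
                | frozenset(h.key for h in pol.alleles)
            )
            counts[cls] = counts.get(cls, 0) + 1
        out.append(counts)
    return out


def recover_parameters(
    observed: dict[PhenotypeClass, int],
    candidate_models: list[CrossSpec],
    alpha_level: float = 0.05,
) -> list[tuple[CrossSpec, GoFResult]]:
    """Rank candidate cross models by goodness-of-fit to observed counts.

    All candidates are scored over the common class universe (union of
    the candidates' reachable classes and the observed classes); a class
    a candidate cannot reach counts as a zero-ratio cell, so observing
    it makes that candidate impossible (χ² = +inf).  A candidate whose
    cross is fully incompatible predicts no progeny at all and likewise
    scores +inf.  Returned ascending by χ²; ties keep input order.
    """
    dists: list[PhenotypeDistribution | None] = []
    universe: set[PhenotypeClass] = set(observed)
    for cand in candidate_models:
        try:
            d = expected_phenotype_distribution(cand)
        except FullyIncompatibleCrossError:
            d = None
        dists.append(d)
        if d is not None:
            universe.update(d.classes)
    order = sorted(universe, key=lambda c: c.sort_key)
    obs_vec = [observed.get(c, 0) for c in order]

    scored = []
    for cand, d in zip(candidate_models, dists):
        if d is None:
            ratio = RatioVector((1,) * len(order))  # placeholder geometry
            res = chi2_gof(obs_vec, ratio, alpha_level)
            res = GoFResult(
                chi2=float("inf"),
                df=res.df,
                alpha_level=alpha_level,
                critical=res.critical,
                fits=False,
                contributions=(float("inf"),) * len(order),
                expected=(0.0,) * len(order),
                impossible=True,
            )
        else:
            probs = d.probabilities(order)
            terms = tuple(float(p) for p in probs)
            res = chi2_gof(obs_vec, RatioVector(terms), alpha_level)
        scored.append((cand, res))
    return [
        pair
        for _, pair in sorted(enumerate(scored), key=lambda t: (t[1][1].chi2, t[0]))
    ]
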