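"""Operating-characteristic simulations: type-I error, power, rate recovery.

These helpers run the full pipeline path (simulate -> classify -> summarize
-> permutation test) over many replicate cohorts to measure rejection rates,
and pool per-hemisegment classifications to compare empirical defect
frequencies against their analytic expectations:

* earlier-division defects occur at exactly ``r_early``;
* symmetric defects at ``1 - (1 - r_sym)^2`` per A2-A7 hemisegment (to first
  order; opposite-signed failures of the two Tin progenitors can cancel);
* Svp-lineage defects at ``1 - (1-r)^2 - 2 r^2 w_cc w_pc``
  (see :func:`cardiodiv.simulate.svp_defect_probability`).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .classify import classify_embryo, summarize_embryo
from .permstats import permutation_test_interaction, permutation_test_two_group
from .simulate import (
    CohortDesign,
    DivisionErrorRates,
    asym_rate_for_defect_prob,
    simulate_cohort,
)

__all__ = [
    "simulate_summaries",
    "two_group_rejection_rate",
    "interaction_rejection_rate",
    "empirical_category_frequencies",
]


def simulate_summaries(
    genotypes: Mapping[str, tuple[int, DivisionErrorRates]],
    seed: int,
):
    """Simulate a cohort and return its per-embryo defect summaries."""
    design = CohortDesign(genotypes=dict(genotypes), seed=seed)
    out = []
    for emb in simulate_cohort(design):
        s = summarize_embryo(emb)
        if s is not None:
            out.append(s)
    return out


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def two_group_rejection_rate(
    rates_ref: DivisionErrorRates,
    rates_mut: DivisionErrorRates,
    n_ref: int = 14,
    n_mut: int = 14,
    category: str = "svp_lineage",
    n_reps: int = 500,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicate cohorts whose two-group permutation p is < alpha.

    With ``rates_ref == rates_mut`` this measures type-I error (should sit
    at alpha); with elevated mutant rates it measures power.
    """
    seeds = _child_seeds(seed, n_reps)
    rejections = 0
    for rep, s in enumerate(seeds):
        summaries = simulate_summaries(
            {"ref": (n_ref, rates_ref), "mut": (n_mut, rates_mut)}, seed=int(s)
        )
        y = np.array([x.proportions[category] for x in summaries])
        g = np.array([1 if x.genotype == "mut" else 0 for x in summaries])
        res = permutation_test_two_group(y, g, n_perm=n_perm, seed=int(s) + 1)
        rejections += res.p < alpha
    return rejections / n_reps


def interaction_rejection_rate(
    pi_p: float,
    pi_q: float,
    pi_double: float,
    n_per_group: int = 14,
    category: str = "svp_lineage",
    n_reps: int = 500,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the Smith interaction test over replicate cohorts.

    The three genotype groups (p-het, q-het, double-het) are simulated with
    asymmetric-division error rates chosen so each group's per-hemisegment
    Svp-defect probability equals the given ``pi``; with
    ``pi_double == pi_p + pi_q`` the effects are exactly additive (type-I
    calibration), larger values inject synergy (power).
    """
    def rates_for(pi: float) -> DivisionErrorRates:
        return DivisionErrorRates(r_asym=asym_rate_for_defect_prob(pi))

    genos = {
        "p_het": (n_per_group, rates_for(pi_p)),
        "q_het": (n_per_group, rates_for(pi_q)),
        "double": (n_per_group, rates_for(pi_double)),
    }
    seeds = _child_seeds(seed, n_reps)
    rejections = 0
    for s in seeds:
        summaries = simulate_summaries(genos, seed=int(s))
        y = np.array([x.proportions[category] for x in summaries])
        ip = np.array([1 if x.genotype in ("p_het", "double") else 0 for x in summaries])
        iq = np.array([1 if x.genotype in ("q_het", "double") else 0 for x in summaries])
        res = permutation_test_interaction(y, ip, iq, n_perm=n_perm, seed=int(s) + 1)
        rejections += res.p < alpha
    return rejections / n_reps


def empirical_category_frequencies(
    rates: DivisionErrorRates,
    n_embryos: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Pooled per-hemisegment defect frequencies over a simulated cohort.

    Returns the fraction of scoreable hemisegments flagged per category
    (UNKNOWN flags not counted), plus the number of hemisegments pooled
    under key ``n``.
    """
    design = CohortDesign(genotypes={"g": (n_embryos, rates)}, seed=seed)
    counts = {"svp_lineage": 0, "symmetric": 0, "asymmetric": 0, "earlier": 0}
    n = 0
    for emb in simulate_cohort(design):
        for _, call in classify_embryo(emb):
            n += 1
            for cat in counts:
                if call.flag(cat) is True:
                    counts[cat] += 1
    freqs = {cat: c / n for cat, c in counts.items()}
    freqs["n"] = n
    return freqs
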