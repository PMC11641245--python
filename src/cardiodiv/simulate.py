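"""Synthetic heart-lineage cohort generator.

The wild-type *Drosophila* embryonic heart is metameric: every abdominal
hemisegment from A2 to A7 carries two Seven-up cardial cells (Svp-CC), each
paired with a Seven-up pericardial cell (Svp-PC), followed by four Tinman
cardial cells (Tin-CC); A8 is truncated to two Tin-CCs.  These counts arise
from a stereotyped lineage: an early division produces two Svp progenitors,
each of which divides asymmetrically into one Svp-CC and one Svp-PC, while
two Tin progenitors (one in A8) each divide symmetrically into two Tin-CCs.

This module simulates that lineage per hemisegment, perturbed by three
independent error processes:

* **earlier-division errors** (rate ``r_early``): the early division yields
  one or three Svp progenitors instead of two;
* **asymmetric-division errors** (rate ``r_asym`` per Svp progenitor): a
  progenitor produces two CCs, two PCs, or — on karyokinesis failure — a
  single enlarged CC with no PC;
* **symmetric-division errors** (rate ``r_sym`` per Tin progenitor): a Tin
  progenitor yields one or three Tin-CCs instead of two.

Hemisegments may additionally be unscoreable (microscopy dropout) with rate
``r_dropout``; unscoreable hemisegments carry no counts.

All randomness flows from a single integer seed via per-hemisegment
substreams keyed by (genotype, embryo index, hemisegment index), so cohorts
are bit-reproducible and independent of generation order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SEGMENTS",
    "SIDES",
    "MISSING",
    "DivisionErrorRates",
    "HemisegmentCounts",
    "EmbryoRecord",
    "CohortDesign",
    "expected_tin",
    "n_tin_progenitors",
    "simulate_hemisegment",
    "simulate_embryo",
    "simulate_cohort",
    "mask_pericardial",
    "svp_defect_probability",
    "asym_rate_for_defect_prob",
]

SEGMENTS: tuple[str, ...] = ("A2", "A3", "A4", "A5", "A6", "A7", "A8")
SIDES: tuple[str, str] = ("L", "R")

#: Sentinel for pericardial counts that were not visualized.
MISSING = None


def n_tin_progenitors(segment: str) -> int:
    """Number of Tin progenitors in a hemisegment (two in A2-A7, one in A8)."""
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment label {segment!r}; expected one of {SEGMENTS}")
    return 1 if segment == "A8" else 2


def expected_tin(segment: str) -> int:
    """Expected wild-type Tin-CC count: four in A2-A7, two in the truncated A8."""
    return 2 * n_tin_progenitors(segment)


@dataclass(frozen=True)
class DivisionErrorRates:
    """Per-division error probabilities for one genotype.

    Parameters
    ----------
    r_early
        Probability the early division yields 1 or 3 Svp progenitors
        (split evenly) instead of 2.
    r_asym
        Per-progenitor probability that an asymmetric division fails.
    asym_mode_weights
        Probabilities over the three asymmetric failure modes
        (both-CC, both-PC, karyokinesis failure); must sum to 1.
    r_sym
        Per-progenitor probability that a Tin symmetric division fails.
    sym_mode_weights
        Probabilities over the two symmetric failure modes
        (no division -> 1 cell, extra division -> 3 cells); must sum to 1.
    r_dropout
        Probability a hemisegment is unscoreable.
    """

    r_early: float = 0.0
    r_asym: float = 0.0
    asym_mode_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    r_sym: float = 0.0
    sym_mode_weights: tuple[float, float] = (0.5, 0.5)
    r_dropout: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_early", "r_asym", "r_sym", "r_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, k in (("asym_mode_weights", 3), ("sym_mode_weights", 2)):
            w = tuple(float(x) for x in getattr(self, name))
            object.__setattr__(self, name, w)
            if len(w) != k or any(x < 0 for x in w):
                raise ValueError(f"{name} must be {k} non-negative probabilities")
            if not math.isclose(sum(w), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {sum(w)})")


#: Zero-error rates: every hemisegment reproduces the wild-type pattern.
WILDTYPE_RATES = DivisionErrorRates()


@dataclass(frozen=True)
class HemisegmentCounts:
    """Observed cell counts for one hemisegment."""

    segment: str
    side: str
    n_tin_cc: int = 0
    n_svp_cc: int = 0
    n_svp_pc: int | None = 0  # MISSING (None) when PCs were not visualized
    n_enlarged_svp_cc: int = 0
    scoreable: bool = True

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment label {self.segment!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be L or R, got {self.side!r}")
        if self.scoreable:
            if self.n_tin_cc < 0 or self.n_svp_cc < 0:
                raise ValueError("cell counts must be non-negative")
            if self.n_svp_pc is not MISSING and self.n_svp_pc < 0:
                raise ValueError("pericardial count must be non-negative")
            if not 0 <= self.n_enlarged_svp_cc <= self.n_svp_cc:
                raise ValueError("n_enlarged_svp_cc must lie in [0, n_svp_cc]")


@dataclass(frozen=True)
class EmbryoRecord:
    """One embryo: genotype label plus its 14 hemisegments (A2-A8 x L/R)."""

    embryo_id: str
    genotype: str
    hemisegments: tuple[HemisegmentCounts, ...]

    def __post_init__(self) -> None:
        keys = [(h.segment, h.side) for h in self.hemisegments]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (segment, side) in embryo")


@dataclass(frozen=True)
class CohortDesign:
    """Mapping genotype -> (number of embryos, division-error rates)."""

    genotypes: Mapping[str, tuple[int, DivisionErrorRates]]
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (n, rates) in self.genotypes.items():
            if n < 1:
                raise ValueError(f"genotype {g!r}: n_embryos must be >= 1")
            if not isinstance(rates, DivisionErrorRates):
                raise TypeError(f"genotype {g!r}: rates must be DivisionErrorRates")


def _genotype_key(genotype: str) -> int:
    # stable across sessions (hash() is salted; crc32 is not)
    return zlib.crc32(genotype.encode("utf-8"))


def _hemisegment_rng(seed: int, genotype: str, embryo_index: int, hemi_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), _genotype_key(genotype), int(embryo_index), int(hemi_index)])
    return np.random.default_rng(ss)


def simulate_hemisegment(
    segment: str,
    rates: DivisionErrorRates,
    rng: np.random.Generator,
    side: str = "L",
) -> HemisegmentCounts:
    """Draw one hemisegment's counts from the perturbed lineage model.

    The Svp lineage is drawn first (progenitor count, then one asymmetric
    division per progenitor), then the Tin lineage (one symmetric division
    per progenitor).  Dropout is handled by the caller.
    """
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment label {segment!r}")

    # earlier division: number of Svp progenitors
    if rng.random() < rates.r_early:
        k = 1 if rng.random() < 0.5 else 3
    else:
        k = 2

    n_cc = n_pc = n_enl = 0
    for _ in range(k):
        if rng.random() < rates.r_asym:
            mode = rng.choice(3, p=rates.asym_mode_weights)
            if mode == 0:  # both daughters become CCs
                n_cc += 2
            elif mode == 1:  # both daughters become PCs
                n_pc += 2
            else:  # karyokinesis failure: one undivided enlarged CC
                n_cc += 1
                n_enl += 1
        else:
            n_cc += 1
            n_pc += 1

    n_tin = 0
    for _ in range(n_tin_progenitors(segment)):
        if rng.random() < rates.r_sym:
            n_tin += 1 if rng.random() < rates.sym_mode_weights[0] else 3
        else:
            n_tin += 2

    return HemisegmentCounts(
        segment=segment,
        side=side,
        n_tin_cc=n_tin,
        n_svp_cc=n_cc,
        n_svp_pc=n_pc,
        n_enlarged_svp_cc=n_enl,
    )


def simulate_embryo(
    embryo_id: str,
    genotype: str,
    rates: DivisionErrorRates,
    seed: int,
    embryo_index: int = 0,
) -> EmbryoRecord:
    """Simulate one embryo: 14 hemisegments (A2-A8 on both sides).

    Each hemisegment uses its own RNG substream keyed by
    (seed, genotype, embryo_index, hemisegment index), so results do not
    depend on generation order.
    """
    hemis = []
    idx = 0
    for segment in SEGMENTS:
        for side in SIDES:
            rng = _hemisegment_rng(seed, genotype, embryo_index, idx)
            if rng.random() < rates.r_dropout:
                hemis.append(
                    HemisegmentCounts(segment=segment, side=side, n_tin_cc=0,
                                      n_svp_cc=0, n_svp_pc=0, n_enlarged_svp_cc=0,
                                      scoreable=False)
                )
            else:
                hemis.append(simulate_hemisegment(segment, rates, rng, side=side))
            idx += 1
    return EmbryoRecord(embryo_id=embryo_id, genotype=genotype, hemisegments=tuple(hemis))


def simulate_cohort(design: CohortDesign) -> list[EmbryoRecord]:
    """Simulate every embryo of a cohort design, reproducibly from its seed."""
    embryos: list[EmbryoRecord] = []
    for genotype, (n_embryos, rates) in design.genotypes.items():
        for i in range(n_embryos):
            embryos.append(
                simulate_embryo(
                    embryo_id=f"{genotype}_{i:03d}",
                    genotype=genotype,
                    rates=rates,
                    seed=design.seed,
                    embryo_index=i,
                )
            )
    return embryos


def mask_pericardial(embryo: EmbryoRecord) -> EmbryoRecord:
    """Hide pericardial information, emulating Mef2+Svp-only antibody staining.

    Sets every hemisegment's ``n_svp_pc`` to MISSING and clears the enlarged-
    nucleus marker (nuclear size was only scored when the svp-lacZ enhancer
    trap was present).  Idempotent.
    """
    hemis = tuple(
        replace(h, n_svp_pc=MISSING, n_enlarged_svp_cc=0) for h in embryo.hemisegments
    )
    return replace(embryo, hemisegments=hemis)


def svp_defect_probability(r_asym: float, asym_mode_weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)) -> float:
    """Probability a hemisegment (k=2, r_early=0) deviates from the (2,2,0) pattern.

    The wild-type triple also arises when one progenitor produces two CCs and
    the other two PCs, so the detectable rate is
    ``1 - (1-r)^2 - 2 r^2 w_cc w_pc``.
    """
    w_cc, w_pc = asym_mode_weights[0], asym_mode_weights[1]
    return 1.0 - (1.0 - r_asym) ** 2 - 2.0 * r_asym**2 * w_cc * w_pc


def asym_rate_for_defect_prob(pi: float, asym_mode_weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)) -> float:
    """Invert :func:`svp_defect_probability`: the r_asym giving defect probability ``pi``.

    The defect probability expands to ``pi = 2r - (1 + 2 w_cc w_pc) r^2``;
    this solves the quadratic for the root in [0, 1].  Used to build cohorts
    whose per-hemisegment defect probabilities are exactly additive (or
    exactly super-additive) across genotypes when calibrating the synergy
    test.
    """
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must lie in [0, 1)")
    w_cc, w_pc = asym_mode_weights[0], asym_mode_weights[1]
    a = 1.0 + 2.0 * w_cc * w_pc
    if pi == 0.0:
        return 0.0
    # smaller root of a r^2 - 2 r + pi = 0
    r = (2.0 - math.sqrt(4.0 - 4.0 * a * pi)) / (2.0 * a)
    return float(r)
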