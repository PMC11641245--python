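"""Per-hemisegment defect classification and per-embryo summaries.

Two scoring modes mirror the two staining strategies used to phenotype the
embryonic heart:

* **full information** (svp-lacZ enhancer trap present): Tin-CCs, Svp-CCs and
  Svp-PCs are all counted, so asymmetric-division errors can be separated
  from earlier-division errors by reasoning over which lineage histories
  could have produced the observed (Svp-CC, Svp-PC, enlarged-CC) triple;
* **cardial-cells only** (Mef2 + Svp antibodies): pericardial cells are
  invisible, so any deviation from two Svp-CCs is reported as a generic
  Svp-lineage defect without attributing it to the asymmetric or the earlier
  division.

Classification in the full-information mode works by exhaustive enumeration
of lineage explanations: for each possible Svp progenitor number k in
{1, 2, 3}, each progenitor is assigned an asymmetric-division outcome
(normal, both-CC, both-PC, or karyokinesis failure), and explanations whose
predicted counts match the observation are retained.  Among the matching
explanations the minimal-error ones (fewest deviations from the wild-type
lineage) decide the category flags; if the minimal explanations disagree on
a flag it is reported as UNKNOWN (``None``) rather than guessed.

Symmetric (Tin-lineage) defects are independent of the Svp reasoning: a
hemisegment is symmetric-defective iff its Tin-CC count deviates from the
segment's expectation (four in A2-A7, two in A8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

from .simulate import (
    MISSING,
    EmbryoRecord,
    HemisegmentCounts,
    expected_tin,
)

__all__ = [
    "CATEGORIES",
    "Outcome",
    "LineageExplanation",
    "DefectCall",
    "EmbryoSummary",
    "enumerate_consistent_explanations",
    "classify_hemisegment_full",
    "classify_hemisegment_cc_only",
    "classify_embryo",
    "summarize_embryo",
]

logger = logging.getLogger(__name__)

#: Defect categories summarized per embryo.
CATEGORIES = ("svp_lineage", "symmetric", "asymmetric", "earlier", "any")

# asymmetric-division outcomes: (svp_cc, svp_pc, enlarged) produced per progenitor
NORMAL = "NORMAL"
BOTH_CC = "BOTH_CC"
BOTH_PC = "BOTH_PC"
KARYOKINESIS_FAIL = "KARYOKINESIS_FAIL"

Outcome = str
_OUTCOME_YIELD: dict[Outcome, tuple[int, int, int]] = {
    NORMAL: (1, 1, 0),
    BOTH_CC: (2, 0, 0),
    BOTH_PC: (0, 2, 0),
    KARYOKINESIS_FAIL: (1, 0, 1),
}


@dataclass(frozen=True)
class LineageExplanation:
    """A lineage history consistent with an observed Svp-count triple.

    ``error_weight`` counts deviations from the wild-type lineage: |k - 2|
    for the earlier division plus one per failed asymmetric division.
    """

    k: int
    outcomes: tuple[Outcome, ...]

    @property
    def error_weight(self) -> int:
        return abs(self.k - 2) + sum(1 for o in self.outcomes if o != NORMAL)

    @property
    def has_asym_failure(self) -> bool:
        return any(o != NORMAL for o in self.outcomes)

    def predicted_counts(self) -> tuple[int, int, int]:
        cc = pc = enl = 0
        for o in self.outcomes:
            dc, dp, de = _OUTCOME_YIELD[o]
            cc += dc
            pc += dp
            enl += de
        return cc, pc, enl


@dataclass(frozen=True)
class DefectCall:
    """Category flags for one hemisegment.

    ``asymmetric`` and ``earlier`` are three-valued: ``True``, ``False`` or
    ``None`` (UNKNOWN — either pericardial cells were not visualized, or the
    minimal lineage explanations disagree).  ``svp_lineage`` is true for any
    Svp-lineage anomaly, attributed or not.  ``inconsistent`` marks
    observations no lineage (k <= 3) can produce.
    """

    symmetric: bool
    asymmetric: bool | None
    earlier: bool | None
    svp_lineage: bool
    inconsistent: bool = False

    def flag(self, category: str) -> bool | None:
        if category == "any":
            anomalous = self.symmetric or self.svp_lineage
            return bool(anomalous)
        return getattr(self, category)


@lru_cache(maxsize=None)
def enumerate_consistent_explanations(
    n_svp_cc: int,
    n_svp_pc: int,
    n_enlarged: int = 0,
    enlarged_marker_reliable: bool = True,
) -> frozenset[LineageExplanation]:
    """Exhaustively enumerate lineage explanations of an Svp-count triple.

    For each progenitor number k in {1, 2, 3} every assignment of
    asymmetric-division outcomes is tested against the observed counts.
    With ``enlarged_marker_reliable`` (default) the number of karyokinesis
    failures must equal the observed enlarged-CC count; otherwise enlarged
    nuclei may have been missed, so explanations with at least the observed
    number of failures are admitted.

    An empty set signals an observation inconsistent with the lineage model.
    This function is the brute-force oracle behind
    :func:`classify_hemisegment_full`.
    """
    if min(n_svp_cc, n_svp_pc, n_enlarged) < 0:
        raise ValueError("counts must be non-negative")
    if n_enlarged > n_svp_cc:
        raise ValueError("n_enlarged cannot exceed n_svp_cc")
    out: set[LineageExplanation] = set()
    for k in (1, 2, 3):
        for outcomes in combinations_with_replacement(_OUTCOME_YIELD, k):
            expl = LineageExplanation(k=k, outcomes=tuple(sorted(outcomes)))
            cc, pc, enl = expl.predicted_counts()
            if (cc, pc) != (n_svp_cc, n_svp_pc):
                continue
            if enlarged_marker_reliable:
                if enl != n_enlarged:
                    continue
            elif enl < n_enlarged:
                continue
            out.add(expl)
    return frozenset(out)


def minimal_explanations(
    n_svp_cc: int,
    n_svp_pc: int,
    n_enlarged: int = 0,
    enlarged_marker_reliable: bool = True,
) -> frozenset[LineageExplanation]:
    """The consistent explanations of minimal error weight (may be empty).

    These are the histories classification reasons over: the most
    parsimonious lineage accounts of the observed triple.
    """
    expls = enumerate_consistent_explanations(
        n_svp_cc, n_svp_pc, n_enlarged, enlarged_marker_reliable
    )
    if not expls:
        return expls
    min_w = min(e.error_weight for e in expls)
    return frozenset(e for e in expls if e.error_weight == min_w)


def _tri_all(values: Iterable[bool]) -> bool | None:
    """True if all, False if none, None (UNKNOWN) on disagreement."""
    vals = set(values)
    if vals == {True}:
        return True
    if vals == {False}:
        return False
    return None


@lru_cache(maxsize=None)
def _classify_svp_triple(
    n_svp_cc: int,
    n_svp_pc: int,
    n_enlarged: int,
    enlarged_marker_reliable: bool,
) -> tuple[bool | None, bool | None, bool, bool]:
    """(asymmetric, earlier, svp_lineage, inconsistent) from the Svp triple."""
    expls = enumerate_consistent_explanations(
        n_svp_cc, n_svp_pc, n_enlarged, enlarged_marker_reliable
    )
    if not expls:
        return None, None, True, True
    min_w = min(e.error_weight for e in expls)
    minimal = [e for e in expls if e.error_weight == min_w]
    earlier = _tri_all(e.k != 2 for e in minimal)
    asymmetric = _tri_all(e.has_asym_failure for e in minimal)
    svp_lineage = min_w > 0
    return asymmetric, earlier, svp_lineage, False


def classify_hemisegment_full(
    counts: HemisegmentCounts,
    enlarged_marker_reliable: bool = True,
) -> DefectCall:
    """Classify a hemisegment with pericardial cells visualized.

    Requires a scoreable hemisegment with a non-MISSING pericardial count;
    use :func:`classify_hemisegment_cc_only` otherwise.
    """
    if not counts.scoreable:
        raise ValueError("cannot classify an unscoreable hemisegment")
    if counts.n_svp_pc is MISSING:
        raise ValueError(
            "pericardial count is MISSING; use classify_hemisegment_cc_only"
        )
    symmetric = counts.n_tin_cc != expected_tin(counts.segment)
    asymmetric, earlier, svp_lineage, inconsistent = _classify_svp_triple(
        counts.n_svp_cc,
        counts.n_svp_pc,
        counts.n_enlarged_svp_cc,
        enlarged_marker_reliable,
    )
    return DefectCall(
        symmetric=symmetric,
        asymmetric=asymmetric,
        earlier=earlier,
        svp_lineage=svp_lineage,
        inconsistent=inconsistent,
    )


def classify_hemisegment_cc_only(counts: HemisegmentCounts) -> DefectCall:
    """Classify a hemisegment when pericardial cells were not visualized.

    Any deviation from two Svp-CCs marks a generic Svp-lineage defect
    (asymmetric or earlier division, unattributable); the Tin-CC rule is
    unchanged.
    """
    if not counts.scoreable:
        raise ValueError("cannot classify an unscoreable hemisegment")
    symmetric = counts.n_tin_cc != expected_tin(counts.segment)
    svp_lineage = counts.n_svp_cc != 2
    return DefectCall(
        symmetric=symmetric,
        asymmetric=None,
        earlier=None,
        svp_lineage=svp_lineage,
        inconsistent=False,
    )


def classify_embryo(
    embryo: EmbryoRecord,
    enlarged_marker_reliable: bool = True,
) -> list[tuple[HemisegmentCounts, DefectCall]]:
    """Classify every scoreable hemisegment of an embryo.

    The full-information classifier is used where pericardial counts are
    present; the CC-only classifier where they are MISSING.
    """
    calls = []
    for h in embryo.hemisegments:
        if not h.scoreable:
            continue
        if h.n_svp_pc is MISSING:
            calls.append((h, classify_hemisegment_cc_only(h)))
        else:
            calls.append((h, classify_hemisegment_full(h, enlarged_marker_reliable)))
    return calls


@dataclass(frozen=True)
class EmbryoSummary:
    """Per-embryo defect proportions: the response variable of the regressions."""

    embryo_id: str
    genotype: str
    n_scoreable: int
    proportions: dict[str, float]

    def __getitem__(self, category: str) -> float:
        return self.proportions[category]


def summarize_embryo(
    embryo: EmbryoRecord,
    calls: Sequence[tuple[HemisegmentCounts, DefectCall]] | None = None,
    enlarged_marker_reliable: bool = True,
) -> EmbryoSummary | None:
    """Per-embryo proportion of defective hemisegments for every category.

    UNKNOWN flags never count toward their specific category (asymmetric or
    earlier) but the underlying anomaly still counts toward ``svp_lineage``
    and ``any``.  Returns ``None`` (with a warning) for an embryo with no
    scoreable hemisegments, which cannot contribute a response value.
    """
    if calls is None:
        calls = classify_embryo(embryo, enlarged_marker_reliable)
    n = len(calls)
    if n == 0:
        logger.warning("embryo %s has no scoreable hemisegments; excluded", embryo.embryo_id)
        return None
    props = {
        cat: sum(1 for _, c in calls if c.flag(cat) is True) / n for cat in CATEGORIES
    }
    return EmbryoSummary(
        embryo_id=embryo.embryo_id,
        genotype=embryo.genotype,
        n_scoreable=n,
        proportions=props,
    )
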