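"""Defect classifier: enumeration oracle, category flags, embryo summaries."""

from itertools import combinations_with_replacement

import numpy as np
import pytest

from cardiodiv.classify import (
    classify_embryo,
    classify_hemisegment_cc_only,
    classify_hemisegment_full,
    enumerate_consistent_explanations,
    minimal_explanations,
    summarize_embryo,
)
from cardiodiv.simulate import (
    MISSING,
    DivisionErrorRates,
    HemisegmentCounts,
    mask_pericardial,
    simulate_cohort,
    CohortDesign,
    simulate_embryo,
)


def hemi(t, s, q, e=0, segment="A3"):
    return HemisegmentCounts(segment=segment, side="L", n_tin_cc=t, n_svp_cc=s,
                             n_svp_pc=q, n_enlarged_svp_cc=e)


# independent oracle: enumerate outcome multisets directly from their yields,
# without LineageExplanation machinery
_YIELDS = {"N": (1, 1, 0), "CC": (2, 0, 0), "PC": (0, 2, 0), "KF": (1, 0, 1)}


def oracle_explanations(s, q, e, strict=True):
    found = []
    for k in (1, 2, 3):
        for combo in combinations_with_replacement(_YIELDS, k):
            cc = sum(_YIELDS[o][0] for o in combo)
            pc = sum(_YIELDS[o][1] for o in combo)
            enl = sum(_YIELDS[o][2] for o in combo)
            if (cc, pc) != (s, q):
                continue
            if strict and enl != e:
                continue
            if not strict and enl < e:
                continue
            weight = abs(k - 2) + sum(1 for o in combo if o != "N")
            found.append((k, tuple(sorted(combo)), weight))
    return found


def oracle_flags(s, q, e):
    """(asymmetric, earlier, svp_lineage, inconsistent) recomputed directly."""
    expls = oracle_explanations(s, q, e)
    if not expls:
        return None, None, True, True
    w = min(x[2] for x in expls)
    minimal = [x for x in expls if x[2] == w]
    earliers = {k != 2 for k, _, _ in minimal}
    asyms = {any(o != "N" for o in combo) for _, combo, _ in minimal}
    tri = lambda vals: True if vals == {True} else (False if vals == {False} else None)
    return tri(asyms), tri(earliers), w > 0, False


class TestEnumeration:
    def test_wildtype_minimal_explanation_is_all_normal(self):
        minimal = minimal_explanations(2, 2, 0)
        assert len(minimal) == 1
        (expl,) = minimal
        assert expl.k == 2 and set(expl.outcomes) == {"NORMAL"}

    def test_one_extra_cc_explained_by_both_cc_mode(self):
        minimal = minimal_explanations(3, 1, 0)
        assert {(e.k, e.outcomes) for e in minimal} == {(2, ("BOTH_CC", "NORMAL"))}

    def test_strict_marker_makes_2_1_0_inconsistent(self):
        assert enumerate_consistent_explanations(2, 1, 0) == frozenset()

    def test_relaxed_marker_explains_2_1_0_as_missed_karyokinesis(self):
        expls = enumerate_consistent_explanations(2, 1, 0, enlarged_marker_reliable=False)
        assert {(e.k, e.outcomes) for e in expls} == {
            (2, ("KARYOKINESIS_FAIL", "NORMAL"))
        }

    def test_matches_independent_oracle_on_grid(self):
        for s in range(7):
            for q in range(7):
                for e in range(min(s, 3) + 1):
                    got = {
                        (x.k, x.outcomes)
                        for x in enumerate_consistent_explanations(s, q, e)
                    }
                    long = {"N": "NORMAL", "CC": "BOTH_CC", "PC": "BOTH_PC",
                            "KF": "KARYOKINESIS_FAIL"}
                    want = {
                        (k, tuple(sorted(long[o] for o in combo)))
                        for k, combo, _ in oracle_explanations(s, q, e)
                    }
                    assert got == want, (s, q, e)


class TestFullClassifier:
    @pytest.mark.parametrize(
        "counts,expect",
        [
            # (t, s, q, e) -> (symmetric, asymmetric, earlier)
            ((4, 2, 2, 0), (False, False, False)),   # wild-type
            ((4, 3, 1, 0), (False, True, False)),    # asymmetric: extra CC, one PC
            ((4, 1, 1, 0), (False, False, True)),    # earlier: single Svp pair
            ((3, 2, 2, 0), (True, False, False)),    # symmetric only
            ((4, 1, 0, 1), (False, True, True)),     # karyokinesis on a lone progenitor
        ],
    )
    def test_worked_examples(self, counts, expect):
        t, s, q, e = counts
        call = classify_hemisegment_full(hemi(t, s, q, e))
        assert (call.symmetric, call.asymmetric, call.earlier) == expect

    def test_oracle_equivalence_full_grid(self):
        """Classifier flags agree with labels recomputed from brute-force
        enumeration for every triple with counts up to 6."""
        for s in range(7):
            for q in range(7):
                for e in range(min(s, 3) + 1):
                    call = classify_hemisegment_full(hemi(4, s, q, e))
                    assert (call.asymmetric, call.earlier, call.svp_lineage,
                            call.inconsistent) == oracle_flags(s, q, e), (s, q, e)

    def test_a8_expected_tin_is_two(self):
        assert not classify_hemisegment_full(hemi(2, 2, 2, segment="A8")).symmetric
        assert classify_hemisegment_full(hemi(4, 2, 2, segment="A8")).symmetric

    def test_missing_pericardial_rejected(self):
        with pytest.raises(ValueError):
            classify_hemisegment_full(hemi(4, 2, MISSING))

    def test_inconsistent_observation_flagged(self):
        call = classify_hemisegment_full(hemi(4, 2, 1, 0))
        assert call.inconsistent and call.svp_lineage


class TestCCOnlyClassifier:
    @pytest.mark.parametrize(
        "t,s,svp,sym",
        [(4, 2, False, False), (4, 3, True, False), (5, 2, False, True), (4, 1, True, False)],
    )
    def test_deviation_from_two_svp_ccs(self, t, s, svp, sym):
        call = classify_hemisegment_cc_only(hemi(t, s, MISSING))
        assert (call.svp_lineage, call.symmetric) == (svp, sym)
        assert call.asymmetric is None and call.earlier is None

    def test_consistency_with_full_classifier(self):
        # whenever the full classifier attributes an Svp-lineage defect and the
        # CC count deviates, the CC-only classifier must also flag the lineage
        for s in range(7):
            for q in range(7):
                for e in range(min(s, 3) + 1):
                    full = classify_hemisegment_full(hemi(4, s, q, e))
                    cc = classify_hemisegment_cc_only(hemi(4, s, MISSING))
                    if (full.asymmetric is True or full.earlier is True) and s != 2:
                        assert cc.svp_lineage


class TestSummaries:
    def test_clean_embryo_all_zero(self, wildtype_embryo):
        s = summarize_embryo(wildtype_embryo)
        assert s.n_scoreable == 14
        assert all(v == 0.0 for v in s.proportions.values())

    def test_proportion_arithmetic(self):
        hemis = [hemi(4, 2, 2, segment=seg) for seg in ("A2", "A3", "A4", "A5", "A6", "A7")]
        hemis += [hemi(3, 2, 2, segment="A2"), hemi(5, 2, 2, segment="A3")]
        hemis = [
            HemisegmentCounts(h.segment, side, h.n_tin_cc, h.n_svp_cc, h.n_svp_pc,
                              h.n_enlarged_svp_cc)
            for h, side in zip(hemis, ["L", "L", "L", "L", "L", "L", "R", "R"])
        ]
        from cardiodiv.simulate import EmbryoRecord

        emb = EmbryoRecord("e", "g", tuple(hemis))
        s = summarize_embryo(emb)
        assert s.proportions["symmetric"] == pytest.approx(2 / 8)
        assert s.proportions["svp_lineage"] == 0.0

    def test_dropouts_excluded_from_denominator(self):
        rates = DivisionErrorRates(r_dropout=0.5, r_sym=1.0)
        emb = simulate_embryo("e", "g", rates, seed=4)
        s = summarize_embryo(emb)
        n_score = sum(1 for h in emb.hemisegments if h.scoreable)
        assert s.n_scoreable == n_score < 14

    def test_all_dropout_embryo_excluded_with_none(self):
        emb = simulate_embryo("e", "g", DivisionErrorRates(r_dropout=1.0), seed=4)
        assert summarize_embryo(emb) is None

    def test_order_invariance(self):
        rates = DivisionErrorRates(r_asym=0.4, r_sym=0.3)
        emb = simulate_embryo("e", "g", rates, seed=9)
        from cardiodiv.simulate import EmbryoRecord

        rev = EmbryoRecord("e", "g", tuple(reversed(emb.hemisegments)))
        assert summarize_embryo(emb).proportions == summarize_embryo(rev).proportions


class TestRoundTripWithSimulator:
    def test_single_error_type_frequencies_converge(self):
        # earlier defects occur at exactly r_early
        from cardiodiv.calibration import empirical_category_frequencies

        f = empirical_category_frequencies(DivisionErrorRates(r_early=0.12), n_embryos=250, seed=3)
        se = np.sqrt(0.12 * 0.88 / f["n"])
        assert abs(f["earlier"] - 0.12) < 4 * se
        assert f["symmetric"] == 0.0

        f = empirical_category_frequencies(DivisionErrorRates(r_sym=0.08), n_embryos=250, seed=3)
        # per A2-A7 hemisegment 1-(1-r)^2, per A8 r; pooled expectation
        p_a27 = 1 - (1 - 0.08) ** 2
        expected = (12 * p_a27 + 2 * 0.08) / 14
        se = np.sqrt(expected * (1 - expected) / f["n"])
        assert abs(f["symmetric"] - expected) < 4 * se

    def test_masked_cohort_matches_full_when_cc_count_deviates(self):
        design = CohortDesign(
            genotypes={"m": (40, DivisionErrorRates(r_asym=0.3, r_early=0.1))}, seed=6
        )
        for emb in simulate_cohort(design):
            masked = mask_pericardial(emb)
            for (h, full), (_, cc) in zip(classify_embryo(emb), classify_embryo(masked)):
                if h.n_svp_cc != 2:
                    assert cc.svp_lineage
                    assert full.svp_lineage
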