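"""Expression-side bookkeeping: DE gating, low-expression exclusion, RT-qPCR.

Differential expression here is a mutant-versus-wild-type contrast on the
log2 scale, so a *negative* log2 fold change means the gene's expression
drops when the regulator is removed, i.e. the gene is *activated* by the
regulator; a positive log2FC marks repression.  Gating applies a fold-change
threshold (stringent |log2FC| > 1 or relaxed |log2FC| > 0.5, both strict)
together with FDR < 0.1.  Before gating, the lowest-expressed 30% of genes
(by log2CPM) are excluded.

RT-qPCR validation uses the 2^-ddCT method — cycle thresholds of the gene of
interest are normalized to a reference gene within each condition and then
to the control condition — with one-tailed, two-sample, unequal-variance
(Welch) t-tests for significance.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_reference_de_table",
    "low_expression_filter",
    "gate_de",
    "ddct_relative_expression",
    "welch_one_tailed",
]

DE_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")
FDR_CUTOFF = 0.1
STRINGENCIES = {"stringent": 1.0, "relaxed": 0.5}


def load_reference_de_table() -> pd.DataFrame:
    """The 21 regulator-activated genes selected for phenotypic analysis.

    Log2 fold changes, p-values and FDRs of mutant-vs-wild-type mesodermal
    expression for the 21 genes whose loss-of-function phenotypes were
    scored (the published selection, transcribed from the printed table).
    """
    with resources.files("cardiodiv").joinpath("data/jumu_de_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def low_expression_filter(records: pd.DataFrame, fraction: float = 0.3) -> pd.DataFrame:
    """Drop the lowest-expressed ``floor(fraction * n)`` genes by log2CPM.

    Ties are broken by stable input order (earlier rows are dropped first).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if "log2cpm" not in records.columns or records["log2cpm"].isna().any():
        raise ValueError("every record must carry a log2cpm value")
    n_drop = math.floor(fraction * len(records))
    if n_drop == 0:
        return records.copy()
    order = np.argsort(records["log2cpm"].to_numpy(), kind="stable")
    keep = np.ones(len(records), dtype=bool)
    keep[order[:n_drop]] = False
    return records.iloc[keep].copy()


def gate_de(
    records: pd.DataFrame,
    stringency: Literal["stringent", "relaxed"] | float = "stringent",
    fdr_cutoff: float = FDR_CUTOFF,
    activated_sign: int = -1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into (activated, repressed) gene sets.

    With the default sign convention (mutant vs wild-type), activated genes
    satisfy ``log2fc < -threshold`` and repressed genes ``log2fc >
    threshold``, each with ``fdr < fdr_cutoff``; all inequalities strict.
    ``stringency`` may be "stringent" (1.0), "relaxed" (0.5) or a custom
    positive threshold.  ``activated_sign=+1`` flips the convention for
    contrasts coded the other way.
    """
    threshold = STRINGENCIES.get(stringency, stringency)
    if not isinstance(threshold, (int, float)) or threshold <= 0:
        raise ValueError(f"invalid stringency {stringency!r}")
    if activated_sign not in (-1, 1):
        raise ValueError("activated_sign must be -1 or +1")
    fc = records["log2fc"] * activated_sign
    sig = records["fdr"] < fdr_cutoff
    activated = records[(fc > threshold) & sig].copy()
    repressed = records[(fc < -threshold) & sig].copy()
    return activated, repressed


def _mean_ct(ct: float | Sequence[float]) -> float:
    # technical replicates are averaged on the CT scale before any delta
    arr = np.atleast_1d(np.asarray(ct, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("CT values must be finite")
    return float(arr.mean())


def ddct_relative_expression(
    test_ct_target: float | Sequence[float],
    test_ct_ref: float | Sequence[float],
    ctrl_ct_target: float | Sequence[float],
    ctrl_ct_ref: float | Sequence[float],
) -> float:
    """Relative expression of the test condition by the 2^-ddCT method.

    dCT = CT(target) - CT(reference) within each condition;
    ddCT = dCT(test) - dCT(control); returns ``2 ** -ddCT`` (1 = no change,
    0.5 = halved expression in the test condition).  Sequences are averaged
    on the CT scale first.
    """
    d_test = _mean_ct(test_ct_target) - _mean_ct(test_ct_ref)
    d_ctrl = _mean_ct(ctrl_ct_target) - _mean_ct(ctrl_ct_ref)
    return float(2.0 ** -(d_test - d_ctrl))


def welch_one_tailed(
    x: Sequence[float],
    y: Sequence[float],
    direction: Literal["greater", "less"] = "less",
) -> float:
    """One-tailed Welch (unequal-variance) two-sample t-test p-value.

    ``direction`` is the alternative for mean(x) relative to mean(y);
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both samples")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=direction)
    return float(res.pvalue)
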