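"""TSV schemas shared by the pipeline stages.

The counts table carries one scoreable-or-not hemisegment per row with an
empty ``n_svp_pc`` field standing for MISSING (pericardial cells not
visualized).  Calls and summary tables use 0/1 flags with ``NA`` for
UNKNOWN three-valued flags.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classify import CATEGORIES, DefectCall, EmbryoSummary
from .simulate import MISSING, EmbryoRecord, HemisegmentCounts

__all__ = [
    "COUNTS_COLUMNS",
    "write_counts_table",
    "read_counts_table",
    "write_calls_table",
    "write_summary_table",
    "read_summary_table",
]

COUNTS_COLUMNS = (
    "embryo_id",
    "genotype",
    "segment",
    "side",
    "n_tin_cc",
    "n_svp_cc",
    "n_svp_pc",
    "n_enlarged_svp_cc",
    "scoreable",
)


def write_counts_table(embryos: Iterable[EmbryoRecord], path: str | Path) -> None:
    rows = []
    for emb in embryos:
        for h in emb.hemisegments:
            rows.append(
                {
                    "embryo_id": emb.embryo_id,
                    "genotype": emb.genotype,
                    "segment": h.segment,
                    "side": h.side,
                    "n_tin_cc": h.n_tin_cc,
                    "n_svp_cc": h.n_svp_cc,
                    "n_svp_pc": "" if h.n_svp_pc is MISSING else h.n_svp_pc,
                    "n_enlarged_svp_cc": h.n_enlarged_svp_cc,
                    "scoreable": int(h.scoreable),
                }
            )
    pd.DataFrame(rows, columns=list(COUNTS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> list[EmbryoRecord]:
    """Read a counts TSV back into embryo records (lossless round-trip).

    Blank ``n_svp_pc`` fields are preserved as MISSING.  Unknown or missing
    columns and non-integer counts raise with the offending name.
    """
    df = pd.read_csv(path, sep="\t", dtype={"n_svp_pc": "Int64"})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    extra = set(df.columns) - set(COUNTS_COLUMNS)
    if extra:
        raise ValueError(f"counts table has unknown columns: {sorted(extra)}")
    for col in ("n_tin_cc", "n_svp_cc", "n_enlarged_svp_cc", "scoreable"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"column {col!r} must contain integers")
    embryos = []
    for (embryo_id, genotype), grp in df.groupby(["embryo_id", "genotype"], sort=False):
        hemis = []
        for row in grp.itertuples(index=False):
            scoreable = bool(row.scoreable)
            pc = MISSING if pd.isna(row.n_svp_pc) else int(row.n_svp_pc)
            hemis.append(
                HemisegmentCounts(
                    segment=row.segment,
                    side=row.side,
                    n_tin_cc=int(row.n_tin_cc),
                    n_svp_cc=int(row.n_svp_cc),
                    n_svp_pc=pc,
                    n_enlarged_svp_cc=int(row.n_enlarged_svp_cc),
                    scoreable=scoreable,
                )
            )
        embryos.append(EmbryoRecord(embryo_id=str(embryo_id), genotype=str(genotype), hemisegments=tuple(hemis)))
    return embryos


def _flag(v: bool | None) -> str:
    return "NA" if v is None else str(int(v))


def write_calls_table(
    calls_by_embryo: Iterable[tuple[EmbryoRecord, Sequence[tuple[HemisegmentCounts, DefectCall]]]],
    path: str | Path,
) -> None:
    rows = []
    for emb, calls in calls_by_embryo:
        for h, c in calls:
            rows.append(
                {
                    "embryo_id": emb.embryo_id,
                    "segment": h.segment,
                    "side": h.side,
                    "symmetric": _flag(c.symmetric),
                    "asymmetric": _flag(c.asymmetric),
                    "earlier": _flag(c.earlier),
                    "svp_lineage": _flag(c.svp_lineage),
                    "inconsistent": _flag(c.inconsistent),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_table(summaries: Iterable[EmbryoSummary], path: str | Path) -> None:
    rows = []
    for s in summaries:
        row = {"embryo_id": s.embryo_id, "genotype": s.genotype, "n_scoreable": s.n_scoreable}
        row.update({f"prop_{cat}": s.proportions[cat] for cat in CATEGORIES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_summary_table(path: str | Path) -> list[EmbryoSummary]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EmbryoSummary(
                embryo_id=str(row.embryo_id),
                genotype=str(row.genotype),
                n_scoreable=int(row.n_scoreable),
                proportions={cat: float(getattr(row, f"prop_{cat}")) for cat in CATEGORIES},
            )
        )
    return out
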