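"""Reading, validating and writing GWAS summary-statistic tables.

The canonical on-disk dialect is a tab-separated file with a header row

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

one row per SNP. ``beta`` is the per-effect-allele association (log-odds for
binary traits), ``se`` its standard error, ``pval`` the association p-value
and ``n`` the GWAS sample size (effective sample size for case-control
traits). ``eaf`` (effect-allele frequency) may be missing: palindromic SNPs
are excluded outright downstream, so EAF is never needed to resolve strand
ambiguity. Files written by other pipelines are mapped onto this layout via a
``dialect`` column-name map.

Validation is total: rows violating any per-SNP invariant are dropped with a
recorded reason and never reach the analysis modules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order of the on-disk dialect.
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Columns that must be present; ``eaf`` alone may be absent.
MANDATORY_COLUMNS = tuple(c for c in CANONICAL_COLUMNS if c != "eaf")

def format_float(x: float) -> str:
    """Format a float the way published MR tables print them.

    Six decimal places for ordinary magnitudes (0.032207 -> "0.032207",
    1.032731 -> "1.032731"); six significant digits in scientific notation
    for very small or very large values so p-values like 6.7e-34 survive a
    round trip.
    """
    if x != x:  # NaN
        return ""
    if x == 0:
        return "0"
    if 1e-4 <= abs(x) < 1e7:
        return f"{x:.6f}"
    return f"{x:.6g}"


@dataclass
class TraitTable:
    """Validated per-SNP association records for one trait.

    ``records`` is a DataFrame in canonical column order, one row per SNP,
    all invariants already enforced. ``rejected`` logs every dropped input
    row as ``(snp_id, reason)``.
    """

    trait_id: str
    trait_type: str  # "exposure" | "mediator" | "outcome"
    records: pd.DataFrame
    n_cases: int | None = None
    n_controls: int | None = None
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        if not self.trait_id:
            raise FormatError("trait_id must be non-empty")
        if self.trait_type not in ("exposure", "mediator", "outcome"):
            raise FormatError(f"unknown trait_type {self.trait_type!r}")

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.records)


def validate_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply every per-SNP invariant to ``raw``; return (valid, rejected).

    Alleles are upper-cased before checking; anything that is not a single
    A/C/G/T (indels, multi-allelic tokens) is rejected. Row order is
    preserved. The first failing check per row is the recorded reason.
    """
    df = raw.copy()
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan

    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        reason[(reason == "") & mask.fillna(False).astype(bool)] = why

    flag(~df["effect_allele"].isin(VALID_ALLELES), "invalid effect allele")
    flag(~df["other_allele"].isin(VALID_ALLELES), "invalid other allele")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(df["pos"].isna() | (df["pos"] <= 0), "nonpositive position")
    flag(df["beta"].isna(), "missing beta")
    flag(df["se"].isna() | (df["se"] <= 0), "nonpositive SE")
    flag(df["pval"].isna() | (df["pval"] <= 0) | (df["pval"] > 1), "p-value outside (0,1]")
    flag(df["n"].isna() | (df["n"] <= 0), "nonpositive sample size")
    flag(df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)), "EAF outside (0,1)")
    flag(df["snp_id"].duplicated(keep="first"), "duplicate snp_id")

    bad = reason != ""
    rejected = pd.DataFrame(
        {"snp_id": df.loc[bad, "snp_id"], "reason": reason[bad]}
    ).reset_index(drop=True)
    for _, row in rejected.iterrows():
        logger.warning("rejected SNP %s: %s", row.snp_id, row.reason)

    valid = df.loc[~bad].reset_index(drop=True)
    valid["pos"] = valid["pos"].astype(np.int64)
    valid["n"] = valid["n"].astype(float)
    return valid[list(CANONICAL_COLUMNS)], rejected


def read_summary_table(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "exposure",
    sep: str = "\t",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> TraitTable:
    """Read a delimited summary-statistic file into a validated TraitTable.

    Parameters
    ----------
    dialect
        Map from canonical field name to the column name used in the file,
        e.g. ``{"snp_id": "rsid", "pval": "p"}``. Unmapped fields must carry
        their canonical names.
    trait_id
        Defaults to the file stem.

    Raises
    ------
    FormatError
        If a mandatory column is missing (after dialect mapping).
    EmptyInputError
        If no row survives validation.
    """
    raw = pd.read_csv(path, sep=sep)
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in raw.columns}
        missing_src = [src for canon, src in dialect.items() if src not in raw.columns]
        if missing_src:
            raise FormatError(
                f"dialect column(s) not found in file: {', '.join(missing_src)}"
            )
        raw = raw.rename(columns=rename)
    valid, rejected = validate_records(raw)
    if len(valid) == 0:
        raise EmptyInputError(f"no valid summary rows in {path}")
    tid = trait_id if trait_id is not None else _stem(path)
    return TraitTable(
        trait_id=tid,
        trait_type=trait_type,
        records=valid,
        n_cases=n_cases,
        n_controls=n_controls,
        rejected=rejected,
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def _as_frame(records) -> pd.DataFrame:
    """Coerce a DataFrame / sequence of dataclasses / dicts to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    if isinstance(records, TraitTable):
        return records.records
    rows = []
    for r in records:
        if isinstance(r, Mapping):
            rows.append(dict(r))
        elif hasattr(r, "__dataclass_fields__"):
            from dataclasses import asdict

            rows.append(asdict(r))
        else:
            raise FormatError(f"cannot serialize record of type {type(r)!r}")
    return pd.DataFrame(rows)


def write_table(records, path, allow_empty: bool = False, sep: str = "\t") -> None:
    """Write any result table as delimited text.

    Column order follows the input frame; floats are formatted by
    :func:`format_float` so that re-reading reproduces values to the
    printed precision.
    """
    frame = _as_frame(records)
    if len(frame) == 0 and not allow_empty:
        raise EmptyInputError("refusing to write an empty table (pass allow_empty=True)")
    frame.to_csv(path, sep=sep, index=False, float_format=format_float)


def write_json(records, path, allow_empty: bool = False) -> None:
    """Write a result table (or one record) as JSON records."""
    if isinstance(records, Mapping):
        payload = dict(records)
    elif hasattr(records, "__dataclass_fields__"):
        from dataclasses import asdict

        payload = asdict(records)
    else:
        frame = _as_frame(records)
        if len(frame) == 0 and not allow_empty:
            raise EmptyInputError(
                "refusing to write an empty table (pass allow_empty=True)"
            )
        payload = frame.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"cannot serialize {type(obj)!r}")


def write_trait_table(table: TraitTable, path, sep: str = "\t") -> None:
    """Write a TraitTable's records in the canonical dialect."""
    write_table(table.records, path, allow_empty=False, sep=sep)
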