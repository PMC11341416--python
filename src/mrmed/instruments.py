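"""Instrument selection and exposure-outcome harmonization.

Selection follows the conventional two-sample MR recipe: keep SNPs
associated with the exposure at p < 1e-5, prune to approximately independent
variants by greedy LD clumping (r^2 < 0.001 within 10,000 kb), drop weak
instruments (F < 10, with F approximated by the squared z-score) and drop
palindromic (A/T, C/G) SNPs outright, since their strand cannot be resolved
without allele frequencies.

Harmonization aligns the outcome table to the exposure's effect allele:
swapped alleles flip the outcome beta's sign; strand-complement alleles are
complemented first and then aligned. Palindromes are removed before any
strand logic (for a palindromic pair, "complement" and "swap" are
indistinguishable). Every exclusion is recorded with its stage and reason.

The filter order is: validate -> intersect -> palindrome drop -> p-threshold
-> F filter -> clump. Clumping runs last, on the post-threshold set, so the
retained instruments are the clumped representatives of the significant
SNPs. Clumping needs pairwise LD, which summary files do not carry; the
operations take an explicit LD table (the synthetic module emits one; real
use would supply a reference-panel export). An absent pair means r^2 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientInstrumentsError
from .io import TraitTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SelectionParams:
    """Instrument-selection thresholds (defaults follow the standard recipe)."""

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    f_min: float = 10.0
    drop_palindromes: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigError("p_threshold must be in (0, 1)")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ConfigError("clump_r2 must be in [0, 1]")
        if self.clump_kb <= 0:
            raise ConfigError("clump_kb must be > 0")
        if self.f_min < 0:
            raise ConfigError("f_min must be >= 0")


@dataclass
class HarmonizedSet:
    """Exposure-outcome aligned instruments: the unit every estimator consumes.

    ``table`` columns: snp_id, chrom, pos, beta_exp, se_exp, pval_exp,
    beta_out, se_out, n_exp, n_out, flipped. ``exclusions`` records every
    dropped SNP as (snp_id, stage, reason).
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "stage", "reason"])
    )
    params: SelectionParams = field(default_factory=SelectionParams)

    @property
    def nsnp(self) -> int:
        return len(self.table)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.table)


def is_palindromic(effect_allele, other_allele):
    """True iff the unordered allele pair is {A,T} or {C,G}.

    Accepts scalars or array-likes (vectorized).
    """
    ea = np.char.upper(np.asarray(effect_allele, dtype=str))
    oa = np.char.upper(np.asarray(other_allele, dtype=str))
    out = ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | \
          ((ea == "C") & (oa == "G")) | ((ea == "G") & (oa == "C"))
    if out.ndim == 0:
        return bool(out)
    return out


def f_statistic(beta, se):
    """Single-SNP instrument-strength F statistic, (beta/se)^2.

    The squared z-score is the standard single-SNP approximation to the
    first-stage F; it is monotone in the R^2-based formula
    R^2 (n-2) / (1 - R^2) and agrees with it closely for GWAS-scale n.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    out = (beta / se) ** 2
    if out.ndim == 0:
        return float(out)
    return out


def _ld_lookup(ld: pd.DataFrame | None) -> dict[tuple[str, str], float]:
    if ld is None or len(ld) == 0:
        return {}
    table: dict[tuple[str, str], float] = {}
    for i, j, r2 in zip(ld["snp_i"], ld["snp_j"], ld["r2"]):
        table[(str(i), str(j))] = max(float(r2), table.get((str(i), str(j)), 0.0))
        table[(str(j), str(i))] = table[(str(i), str(j))]
    return table


def clump(
    records: pd.DataFrame,
    ld: pd.DataFrame | None,
    params: SelectionParams | None = None,
) -> list[str]:
    """Greedy LD clumping; returns the retained snp_ids.

    Repeatedly take the lowest-p unclaimed SNP as index and discard every
    unclaimed SNP on the same chromosome within ``clump_kb`` kilobases whose
    r^2 with the index is >= ``clump_r2``. Ties on p-value break
    lexicographically by snp_id, so the result is deterministic. A pair
    absent from the LD table has r^2 = 0.

    ``records`` needs columns snp_id, chrom, pos, pval.
    """
    params = params or SelectionParams()
    if len(records) == 0:
        return []
    lut = _ld_lookup(ld)
    df = records.sort_values(["pval", "snp_id"], kind="mergesort").reset_index(drop=True)
    snp = df["snp_id"].astype(str).to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    window = int(params.clump_kb) * 1_000
    claimed = np.zeros(len(df), dtype=bool)
    retained: list[str] = []
    for i in range(len(df)):
        if claimed[i]:
            continue
        retained.append(snp[i])
        claimed[i] = True
        near = (
            ~claimed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        for j in np.flatnonzero(near):
            if lut.get((snp[i], snp[j]), 0.0) >= params.clump_r2:
                claimed[j] = True
    return retained


def harmonize(
    exposure: TraitTable,
    outcome: TraitTable,
    params: SelectionParams | None = None,
    ld: pd.DataFrame | None = None,
) -> HarmonizedSet:
    """Select instruments and align the outcome to the exposure's alleles.

    Raises
    ------
    InsufficientInstrumentsError
        If no SNP survives selection (estimators needing more instruments
        raise their own errors downstream).
    """
    params = params or SelectionParams()
    excl: list[tuple[str, str, str]] = []

    exp = exposure.records.rename(
        columns={
            "beta": "beta_exp", "se": "se_exp", "pval": "pval_exp",
            "n": "n_exp", "eaf": "eaf_exp",
            "effect_allele": "ea_exp", "other_allele": "oa_exp",
        }
    )
    out = outcome.records.rename(
        columns={
            "beta": "beta_out", "se": "se_out", "pval": "pval_out",
            "n": "n_out", "eaf": "eaf_out",
            "effect_allele": "ea_out", "other_allele": "oa_out",
        }
    )[["snp_id", "ea_out", "oa_out", "beta_out", "se_out", "pval_out", "n_out"]]

    merged = exp.merge(out, on="snp_id", how="left", indicator=True)
    for s in merged.loc[merged["_merge"] == "left_only", "snp_id"]:
        excl.append((s, "intersect", "missing in outcome"))
    m = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()

    if params.drop_palindromes and len(m):
        pal = is_palindromic(m["ea_exp"], m["oa_exp"])
        for s in m.loc[pal, "snp_id"]:
            excl.append((s, "palindrome", "palindromic"))
        m = m[~pal]

    if len(m):
        direct = (m["ea_out"] == m["ea_exp"]) & (m["oa_out"] == m["oa_exp"])
        swapped = (m["ea_out"] == m["oa_exp"]) & (m["oa_out"] == m["ea_exp"])
        cea = m["ea_out"].map(_COMPLEMENT)
        coa = m["oa_out"].map(_COMPLEMENT)
        comp_direct = ~direct & ~swapped & (cea == m["ea_exp"]) & (coa == m["oa_exp"])
        comp_swapped = ~direct & ~swapped & (cea == m["oa_exp"]) & (coa == m["ea_exp"])
        ok = direct | swapped | comp_direct | comp_swapped
        for s in m.loc[~ok, "snp_id"]:
            excl.append((s, "align", "incompatible alleles"))
        m = m[ok].copy()
        flip = (swapped | comp_swapped)[m.index]
        m["beta_out"] = np.where(flip, -m["beta_out"], m["beta_out"])
        m["flipped"] = flip.to_numpy()

    if len(m):
        weak_p = m["pval_exp"] > params.p_threshold
        for s in m.loc[weak_p, "snp_id"]:
            excl.append((s, "p_threshold", f"exposure p > {params.p_threshold:g}"))
        m = m[~weak_p]

    if len(m):
        f = f_statistic(m["beta_exp"], m["se_exp"])
        weak_f = f < params.f_min
        for s in m.loc[weak_f, "snp_id"]:
            excl.append((s, "f_filter", f"F < {params.f_min:g}"))
        m = m[~weak_f]

    if len(m):
        kept = set(
            clump(
                m[["snp_id", "chrom", "pos"]].assign(pval=m["pval_exp"]),
                ld,
                params,
            )
        )
        pruned = ~m["snp_id"].isin(kept)
        for s in m.loc[pruned, "snp_id"]:
            excl.append((s, "clump", "in LD with a lower-p instrument"))
        m = m[~pruned]

    exclusions = pd.DataFrame(excl, columns=["snp_id", "stage", "reason"])
    if len(m) == 0:
        raise InsufficientInstrumentsError(
            0, 1, context=f"{exposure.trait_id} -> {outcome.trait_id}"
        )

    table = m[
        [
            "snp_id", "chrom", "pos",
            "beta_exp", "se_exp", "pval_exp",
            "beta_out", "se_out",
            "n_exp", "n_out", "flipped",
        ]
    ].reset_index(drop=True)
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        table=table,
        exclusions=exclusions,
        params=params,
    )
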