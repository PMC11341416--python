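"""Batch screening: many exposures against one outcome.

Runs the full selection + estimation pipeline per exposure-outcome pair,
records pairs that fail instrument requirements with their reason (never
silently skipped), flags significance at a raw alpha on the primary
method's p-value, and attaches Benjamini-Hochberg q-values across the
screen. The headline significance flag uses the raw alpha rule — the rule
the screening design actually applied — while the q-values expose what a
formal multiple-testing correction would have concluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientInstrumentsError
from .estimators import METHOD_LABELS, ivw, mr_all, sensitivity_report
from .instruments import SelectionParams, harmonize
from .io import TraitTable


@dataclass
class ScreenResult:
    """Per-pair estimates, diagnostics and screen-level summary counts."""

    table: pd.DataFrame
    failures: pd.DataFrame
    alpha: float
    primary_method: str = "ivw"

    @property
    def n_significant(self) -> int:
        return int(self._primary()["significant"].sum())

    @property
    def n_positive(self) -> int:
        p = self._primary()
        return int((p["significant"] & (p["beta"] > 0)).sum())

    @property
    def n_negative(self) -> int:
        p = self._primary()
        return int((p["significant"] & (p["beta"] < 0)).sum())

    def _primary(self) -> pd.DataFrame:
        # primary rows are exactly those that received a q-value
        if "q_value" not in self.table.columns:
            return self.table.iloc[0:0]
        return self.table[self.table["q_value"].notna()]


def screen_pairs(
    exposures: Sequence[TraitTable],
    outcome: TraitTable,
    params: SelectionParams | None = None,
    ld: pd.DataFrame | None = None,
    alpha: float = 0.05,
    all_methods: bool = False,
    n_boot: int = 0,
    seed: int = 0,
) -> ScreenResult:
    """Screen every exposure against the outcome.

    By default only IVW is fitted per pair (``all_methods=True`` adds the
    full panel; bootstrap SEs for median/mode need ``n_boot > 0``).
    Sensitivity diagnostics are computed per pair when >= 2 instruments
    remain. Significance and BH q-values are taken on the primary (IVW)
    p-values.
    """
    params = params or SelectionParams()
    rows: list[dict] = []
    failures: list[tuple[str, str]] = []
    seeds = np.random.SeedSequence(seed).spawn(len(exposures))
    for exp_t, ss in zip(exposures, seeds):
        try:
            h = harmonize(exp_t, outcome, params=params, ld=ld)
        except InsufficientInstrumentsError as err:
            failures.append((exp_t.trait_id, str(err)))
            continue
        pair_seed = int(ss.generate_state(1)[0] % 2**31)
        if all_methods:
            ests = mr_all(h, n_boot=n_boot, seed=pair_seed)
        elif h.nsnp >= 2:
            ests = [ivw(h)]
        else:
            ests = mr_all(h)  # single instrument: Wald ratio
        rep = sensitivity_report(h) if h.nsnp >= 2 else None
        for e in ests:
            row = {
                "exposure_id": exp_t.trait_id,
                "outcome_id": outcome.trait_id,
                "method": METHOD_LABELS.get(e.method, e.method),
                "nsnp": e.nsnp,
                "beta": e.beta,
                "se": e.se,
                "pval": e.pval,
                "or": e.or_,
                "or_lci95": e.or_lci95,
                "or_uci95": e.or_uci95,
            }
            if rep is not None:
                row.update(
                    q_stat=rep.cochran_q,
                    q_pval=rep.q_pval,
                    egger_intercept=rep.egger_intercept,
                    egger_intercept_pval=rep.egger_intercept_pval,
                    steiger_direction=rep.steiger_direction,
                    steiger_pval=rep.steiger_pval,
                    n_loo_outliers=int(rep.leave_one_out["outlier"].sum()),
                )
            rows.append(row)

    table = pd.DataFrame(rows)
    fail_frame = pd.DataFrame(failures, columns=["exposure_id", "reason"])
    primary_label = METHOD_LABELS["ivw"]
    if len(table):
        table["significant"] = False
        table["q_value"] = np.nan
        prim = table["method"] == primary_label
        # pairs whose single instrument forced a Wald ratio still count as primary
        orphan = ~table["exposure_id"].isin(table.loc[prim, "exposure_id"])
        prim = prim | (orphan & (table["method"] == METHOD_LABELS["wald_ratio"]))
        pvals = table.loc[prim, "pval"].to_numpy()
        if len(pvals):
            _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
            table.loc[prim, "q_value"] = qvals
            table.loc[prim, "significant"] = pvals < alpha
    return ScreenResult(table=table, failures=fail_frame, alpha=alpha)
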