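"""Model comparison by DIC and backward elimination of covariates.

The selection rule: the lowest-DIC model is preferred only when its DIC is
at least ``DIC_THRESHOLD`` (4) below the runner-up; otherwise the comparison
is reported as ambiguous and the tie-break note names the simpler candidate
(fewest estimated columns).  Temporal terms are never subject to
significance-based elimination — only DIC arbitrates between temporal forms;
backward elimination applies to covariates alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from . import pglmm
from .pglmm import ChainSettings, ModelSpec, ModelSpecError, PhyloCovariance, PosteriorFit

__all__ = [
    "DIC_THRESHOLD",
    "SIGNIFICANCE_LEVEL",
    "compare",
    "backward_eliminate",
    "comparison_report",
]

DIC_THRESHOLD = 4.0
SIGNIFICANCE_LEVEL = 0.05


def compare(fits: Mapping[str, PosteriorFit]) -> pd.DataFrame:
    """Compare >= 2 fits of the same response table by DIC.

    Returns a table with one row per candidate (label, dic, pd, n_params,
    delta_dic, selected, note), sorted by DIC with deterministic label
    tie-breaking.  Exactly the minimum-DIC row has ``delta_dic == 0``; it is
    flagged ``selected`` only when the runner-up is at least
    ``DIC_THRESHOLD`` DIC units worse.  The table's ``attrs["status"]`` is
    "selected" or "ambiguous".
    """
    if len(fits) < 2:
        raise ModelSpecError("need at least two fits to compare")
    hashes = {f.data_hash for f in fits.values()}
    if len(hashes) > 1:
        raise ModelSpecError("fits were made on different response tables")

    rows = [
        {
            "model": label,
            "dic": f.dic,
            "pd": f.pd_effective_params,
            "n_params": f.n_params,
        }
        for label, f in fits.items()
    ]
    df = pd.DataFrame(rows).sort_values(["dic", "model"]).reset_index(drop=True)
    df["delta_dic"] = df["dic"] - df["dic"].iloc[0]
    decisive = df["delta_dic"].iloc[1] >= DIC_THRESHOLD
    df["selected"] = False
    df["note"] = ""
    if decisive:
        df.loc[0, "selected"] = True
        df.attrs["status"] = "selected"
    else:
        close = df[df["delta_dic"] < DIC_THRESHOLD]
        simplest = close.sort_values(["n_params", "model"]).iloc[0]["model"]
        df.attrs["status"] = "ambiguous"
        df.loc[0, "note"] = (
            f"ambiguous (runner-up within {DIC_THRESHOLD} DIC); "
            f"simpler candidate: {simplest}"
        )
    return df


def comparison_report(table: pd.DataFrame) -> str:
    """Human-readable report of a comparison table."""
    lines = ["model comparison by DIC (threshold delta >= %.0f)" % DIC_THRESHOLD]
    for _, row in table.iterrows():
        mark = "*" if row["selected"] else " "
        lines.append(
            f" {mark} {row['model']}: DIC={row['dic']:.2f} pD={row['pd']:.2f} "
            f"deltaDIC={row['delta_dic']:.2f}{('  ' + row['note']) if row['note'] else ''}"
        )
    status = table.attrs.get("status", "unknown")
    if status == "selected":
        lines.append(f"selected: {table.loc[table['selected'], 'model'].iloc[0]}")
    else:
        lines.append("no model selected (ambiguous)")
    return "\n".join(lines)


def backward_eliminate(
    table: pd.DataFrame,
    spec: ModelSpec,
    cov: PhyloCovariance,
    settings: ChainSettings,
    seed: int = 0,
) -> tuple[PosteriorFit, list[dict]]:
    """Backward-eliminate non-significant covariates, one per refit.

    At each step the covariate with the largest pMCMC >= 0.05 is removed and
    the model refitted, until every remaining covariate is significant or
    none remain.  Temporal terms and intercepts are never candidates for
    removal.  Returns the final fit and a log of removals, each recording
    the covariate and its pMCMC at removal.
    """
    log: list[dict] = []
    current = spec
    step = 0
    while True:
        f = pglmm.fit(table, current, cov, settings=settings, seed=seed + step)
        if not current.covariates:
            return f, log
        summ_cov = summarize_covariates(f, current.covariates)
        worst = summ_cov["pmcmc"].idxmax()
        worst_p = float(summ_cov.loc[worst, "pmcmc"])
        if worst_p < SIGNIFICANCE_LEVEL:
            return f, log
        log.append({"removed": worst, "pmcmc": worst_p, "step": step})
        current = replace(
            current, covariates=tuple(c for c in current.covariates if c != worst)
        )
        step += 1


def summarize_covariates(f: PosteriorFit, covariates: Sequence[str]) -> pd.DataFrame:
    summ = pglmm.summarize(f)
    return summ.loc[[c for c in covariates if c in summ.index]]
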