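"""Genotype contrast summaries.

The headline outputs of a WT-vs-events trial: per-genotype means ± SEM,
percent change of each event against the wild type, the unweighted average
percent change across events, and many-to-one (Dunnett) comparison
decisions delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InvalidArgumentError

__all__ = ["ContrastResult", "genotype_contrast"]


@dataclass
class ContrastResult:
    table: pd.DataFrame  # one row per genotype
    average_pct_change: float  # unweighted mean over non-WT genotypes
    trait: str
    wt_label: str


def genotype_contrast(
    results: pd.DataFrame,
    trait: str,
    wt_label: str = "WT",
    alpha: float = 0.05,
    alpha_marginal: float = 0.10,
) -> ContrastResult:
    """Compare every transgenic genotype against the wild type for one trait.

    Percent change per event is 100·(mean_event − mean_WT)/mean_WT; the
    "average change" is the unweighted mean of the events' percent changes.
    Many-to-one familywise-controlled p-values come from Dunnett's test
    (decisions at ``alpha``, marginal at ``alpha_marginal``).
    """
    if trait not in results.columns:
        raise ConfigurationError(f"trait '{trait}' not in results table")
    if "genotype" not in results.columns:
        raise ConfigurationError("results table has no 'genotype' column")
    labels = list(dict.fromkeys(results["genotype"]))
    if wt_label not in labels:
        raise ConfigurationError(f"WT label '{wt_label}' absent from results")
    groups = {
        g: results.loc[results["genotype"] == g, trait].dropna().to_numpy()
        for g in labels
    }
    if any(len(v) < 2 for v in groups.values()):
        raise InvalidArgumentError("need >= 2 plants per genotype")
    wt = groups[wt_label]
    events = [g for g in labels if g != wt_label]
    identical = all(
        np.array_equal(groups[g], wt) and len(groups[g]) == len(wt) for g in events
    )
    if identical or all(np.ptp(np.concatenate([groups[g], wt])) == 0 for g in events):
        pvals = {g: 1.0 for g in events}
    else:
        res = sps.dunnett(*[groups[g] for g in events], control=wt)
        pvals = dict(zip(events, res.pvalue))

    rows = []
    wt_mean = float(np.mean(wt))
    for g in labels:
        v = groups[g]
        mean = float(np.mean(v))
        pct = 0.0 if g == wt_label else 100.0 * (mean - wt_mean) / wt_mean
        p = np.nan if g == wt_label else float(pvals[g])
        rows.append({
            "genotype": g, "n": len(v), "mean": mean,
            "sem": float(sps.sem(v)) if len(v) > 1 else np.nan,
            "pct_change_vs_wt": pct,
            "p_dunnett": p,
            "significant": bool(p < alpha) if g != wt_label else False,
            "marginal": bool(alpha <= p < alpha_marginal) if g != wt_label else False,
        })
    table = pd.DataFrame(rows)
    avg = float(table.loc[table["genotype"] != wt_label, "pct_change_vs_wt"].mean())
    return ContrastResult(table=table, average_pct_change=avg, trait=trait, wt_label=wt_label)
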