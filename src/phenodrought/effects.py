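"""Relative drought effects (RDE) and per-day significance counting.

The RDE of a genotype for a trait is the percent change of its mean
value under drought relative to its mean under control:

    RDE = 100 * (mean_drought - mean_control) / mean_control

For in-time traits the genotype means are taken over carriers of the
analysis-ready carrier-mean table; for post-harvest traits over plants.
RDE is undefined where the control mean is missing or smaller in
magnitude than a configurable floor (near-zero-background traits would
otherwise blow up).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CONTROL_FLOOR = 1e-8


def relative_effect(mean_drought: float, mean_control: float,
                    control_floor: float = DEFAULT_CONTROL_FLOOR) -> float:
    """Percent drought effect; NaN when the control mean is below the floor."""
    if not np.isfinite(mean_drought) or not np.isfinite(mean_control):
        return float("nan")
    if abs(mean_control) < control_floor:
        return float("nan")
    return 100.0 * (mean_drought - mean_control) / mean_control


def rde_table(
    cm: pd.DataFrame,
    control_floor: float = DEFAULT_CONTROL_FLOOR,
    by_day: bool = True,
) -> pd.DataFrame:
    """Long RDE table from a carrier-mean (or post-harvest) table.

    Genotype condition means are taken over the replicate column present
    (carriers for in-time data, plants for post-harvest data).  Returns
    columns ``[day,] genotype, trait, rde`` with undefined entries absent.
    """
    keys = (["day"] if by_day and "day" in cm.columns else []) + ["genotype", "trait"]
    means = (
        cm.groupby(keys + ["treatment"])["value"].mean().unstack("treatment")
    )
    for col in ("control", "drought"):
        if col not in means.columns:
            means[col] = np.nan
    denom_ok = means["control"].abs() >= control_floor
    rde = 100.0 * (means["drought"] - means["control"]) / means["control"]
    rde = rde.where(denom_ok)
    out = rde.rename("rde").reset_index().dropna(subset=["rde"])
    return out


def rde_matrix(rde: pd.DataFrame, day: int | None = None) -> pd.DataFrame:
    """Genotype x trait RDE matrix (one day of a stack, or a day-less table)."""
    sub = rde if day is None else rde[rde["day"] == day]
    return sub.pivot_table(index="genotype", columns="trait", values="rde",
                           aggfunc="first")


def mean_effect_profile(rde: pd.DataFrame, trait: str,
                        n_days: int | None = None) -> pd.Series:
    """Per-day mean over genotypes of the defined RDEs of one trait.

    Days with no defined RDE are NaN; ``n_days`` forces the full 1..n
    index so profiles align across traits.
    """
    sub = rde[rde["trait"] == trait]
    prof = sub.groupby("day")["rde"].mean()
    if n_days is not None:
        prof = prof.reindex(range(1, n_days + 1))
    prof.name = trait
    return prof


def mean_effect_profiles(rde: pd.DataFrame, n_days: int) -> pd.DataFrame:
    """Trait-by-day matrix of genotype-mean RDE profiles."""
    wide = rde.groupby(["trait", "day"])["rde"].mean().unstack("day")
    return wide.reindex(columns=range(1, n_days + 1))


def significant_trait_counts(pvalues: pd.DataFrame, alpha: float = 0.05,
                             m: int | None = None) -> pd.Series:
    """Per-day count of traits whose mean drought effect is significant
    after Bonferroni adjustment over ``m`` accepted traits.

    ``pvalues`` is a long frame with columns trait, day, pvalue (e.g.
    ``FitSurface.pvalue_table()``); non-converged fits should already be
    excluded by the caller.  ``m`` defaults to the number of distinct
    traits present.
    """
    if m is None:
        m = int(pvalues["trait"].nunique())
    thr = alpha / max(m, 1)
    hits = pvalues[pvalues["pvalue"] < thr]
    counts = hits.groupby("day")["trait"].nunique()
    return counts.reindex(sorted(pvalues["day"].unique()), fill_value=0)
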