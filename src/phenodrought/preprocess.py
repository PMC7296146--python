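"""Preprocessing of per-plant observations.

Three stages precede all modelling:

1. iterative two-sided Grubbs outlier removal within each homogeneous
   design cell (genotype x treatment x day x trait, pooling the plants of
   both carriers);
2. averaging of surviving plant observations within carriers, producing
   the analysis-ready carrier-mean table;
3. a replicate-repeatability filter: per trait and watering condition,
   the Pearson correlation between the two carriers' pooled
   (genotype, day) time courses must exceed a threshold (default 0.2,
   strict) in *both* conditions for the trait to be accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_GRUBBS_ALPHA = 0.05
DEFAULT_MAX_REMOVALS = 2
DEFAULT_REPLICATE_THRESHOLD = 0.2


@lru_cache(maxsize=None)
def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n``.

    ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with ``t`` the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier_removal(
    values: np.ndarray,
    alpha: float = DEFAULT_GRUBBS_ALPHA,
    max_removals: int = DEFAULT_MAX_REMOVALS,
) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided Grubbs test on one sample.

    Repeatedly removes the single most extreme value while its statistic
    G = max|x_i - mean| / sd exceeds the critical value, stopping after
    ``max_removals`` removals, or when fewer than 3 values remain, or when
    the sample variance is zero.  Degenerate inputs pass through
    unchanged.  Returns the kept values (original order) and the removed
    indices into the input.
    """
    if not (0.0 < alpha <= 0.5):
        raise ValueError("alpha must lie in (0, 0.5]")
    x = np.asarray(values, dtype=float)
    keep = np.arange(x.size)
    removed: list[int] = []
    while len(removed) < max_removals and keep.size >= 3:
        sub = x[keep]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - mean)
        i = int(np.argmax(dev))
        if dev[i] / sd > grubbs_critical_value(keep.size, alpha):
            removed.append(int(keep[i]))
            keep = np.delete(keep, i)
        else:
            break
    return x[keep], removed


def remove_outliers(
    obs: pd.DataFrame,
    alpha: float = DEFAULT_GRUBBS_ALPHA,
    max_removals: int = DEFAULT_MAX_REMOVALS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grubbs removal applied cell-wise to a plant-observation table.

    Cells are (genotype, treatment, day, trait), pooling the plants of
    both carriers (n <= 8 in the default design).  Returns the cleaned
    table and a log of removed rows.

    A vectorized screen computes every cell's first Grubbs statistic at
    once; only the few flagged cells enter the iterative per-cell loop.
    """
    # composite integer cell code (vectorized screen over ~1e5 tiny cells)
    g_codes, _ = pd.factorize(obs["genotype"].to_numpy())
    t_codes, _ = pd.factorize(obs["treatment"].to_numpy())
    tr_codes, _ = pd.factorize(obs["trait"].to_numpy())
    day = obs["day"].to_numpy(np.int64)
    cell = ((tr_codes * (day.max() + 1) + day) * (t_codes.max() + 1)
            + t_codes) * (g_codes.max() + 1) + g_codes
    cell = pd.factorize(cell)[0]
    n_cells = cell.max() + 1
    val = obs["value"].to_numpy(dtype=float)

    n = np.bincount(cell, minlength=n_cells)
    s = np.bincount(cell, weights=val, minlength=n_cells)
    s2 = np.bincount(cell, weights=val * val, minlength=n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        var = (s2 - n * mean * mean) / np.maximum(n - 1, 1)
    sd = np.sqrt(np.clip(var, 0.0, None))

    crit = np.full(n_cells, np.inf)
    for size in np.unique(n):
        if size >= 3:
            crit[n == size] = grubbs_critical_value(int(size), alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        gstat = np.abs(val - mean[cell]) / sd[cell]
    row_flag = (n[cell] >= 3) & (sd[cell] > 0) & (gstat > crit[cell])
    if not row_flag.any():
        return obs, obs.iloc[0:0]

    flagged_cells = np.unique(cell[row_flag])
    in_flagged = np.isin(cell, flagged_cells)
    drop_index: list = []
    sub = obs.loc[in_flagged]
    for _, cell_rows in sub.groupby(cell[in_flagged], sort=False):
        _, removed = grubbs_outlier_removal(
            cell_rows["value"].to_numpy(), alpha, max_removals)
        drop_index.extend(cell_rows.index[removed])
    removed_rows = obs.loc[drop_index]
    return obs.drop(index=drop_index), removed_rows


def average_within_carriers(obs: pd.DataFrame) -> pd.DataFrame:
    """Mean of surviving plant observations per (genotype, treatment,
    carrier, day, trait) cell; cells with no plants are simply absent."""
    return (
        obs.groupby(["genotype", "treatment", "carrier", "day", "trait"],
                    as_index=False, sort=True)["value"]
        .mean()
    )


def _carrier_pair_frame(cm: pd.DataFrame, trait: str, treatment: str) -> pd.DataFrame:
    sub = cm[(cm["trait"] == trait) & (cm["treatment"] == treatment)]
    carriers = sorted(sub["carrier"].unique())
    if len(carriers) != 2:
        return pd.DataFrame(columns=["a", "b"])
    wide = sub.pivot_table(index=["genotype", "day"], columns="carrier",
                           values="value", aggfunc="first")
    wide = wide.dropna()
    wide.columns = ["a", "b"][: len(wide.columns)]
    return wide


def replicate_correlation(cm: pd.DataFrame, trait: str, treatment: str,
                          per_genotype: bool = False) -> float:
    """Pearson correlation between the two carriers of one condition.

    Default pools all complete (genotype, day) pairs into one
    coefficient (acceptance is per trait, not per genotype); the
    ``per_genotype`` variant instead averages per-genotype correlations
    over genotypes with at least 3 complete days.  Returns NaN when
    undefined (fewer than 3 complete pairs, or zero variance).
    """
    wide = _carrier_pair_frame(cm, trait, treatment)
    if wide.empty:
        return float("nan")
    if per_genotype:
        rs = []
        for _, g in wide.groupby(level="genotype"):
            if len(g) >= 3 and g["a"].std() > 0 and g["b"].std() > 0:
                rs.append(float(np.corrcoef(g["a"], g["b"])[0, 1]))
        return float(np.mean(rs)) if rs else float("nan")
    if len(wide) < 3 or wide["a"].std() == 0 or wide["b"].std() == 0:
        return float("nan")
    return float(np.corrcoef(wide["a"], wide["b"])[0, 1])


@dataclass
class AcceptanceReport:
    """Outcome of the replicate-correlation filter over all traits."""

    table: pd.DataFrame  # trait, r_control, r_drought, empty, accepted, reason

    @property
    def accepted_traits(self) -> list[str]:
        return self.table.loc[self.table["accepted"], "trait"].tolist()

    @property
    def n_empty(self) -> int:
        return int(self.table["empty"].sum())

    @property
    def n_rejected(self) -> int:
        return int((~self.table["accepted"] & ~self.table["empty"]).sum())


def filter_traits(
    cm: pd.DataFrame,
    threshold: float = DEFAULT_REPLICATE_THRESHOLD,
    treatments: tuple[str, str] = ("control", "drought"),
    all_traits: list[str] | None = None,
    per_genotype: bool = False,
) -> AcceptanceReport:
    """Accept a trait iff both per-condition replicate correlations are
    computable and strictly exceed ``threshold``.

    ``all_traits`` may list the full trait catalogue so traits with no
    observations at all are reported as empty rather than omitted.
    """
    observed = sorted(cm["trait"].unique())
    traits = sorted(set(observed) | set(all_traits or []))
    rows = []
    for trait in traits:
        if trait not in observed:
            rows.append((trait, np.nan, np.nan, True, False, "no observations"))
            continue
        r_c = replicate_correlation(cm, trait, treatments[0], per_genotype)
        r_d = replicate_correlation(cm, trait, treatments[1], per_genotype)
        ok = bool(np.isfinite(r_c) and np.isfinite(r_d)
                  and r_c > threshold and r_d > threshold)
        reason = "" if ok else (
            "correlation undefined" if not (np.isfinite(r_c) and np.isfinite(r_d))
            else f"correlation <= {threshold}"
        )
        rows.append((trait, r_c, r_d, False, ok, reason))
    return AcceptanceReport(pd.DataFrame(
        rows, columns=["trait", "r_control", "r_drought", "empty",
                       "accepted", "reason"]))
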