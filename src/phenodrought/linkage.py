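"""Linking in-time traits to post-harvest traits through RDE correlations.

For every image trait, post-harvest target, and day, the Pearson
correlation across genotypes between the trait's RDE on that day and the
target's RDE is computed with a two-sided t test (p from
t = r sqrt(n-2)/sqrt(1-r^2), n-2 df).  Days with p below a threshold
(default 0.001) are counted, split by the sign of r — the "days with
correlation" statistic.  The selection rule then keeps, inside each
joint profile-shape category, the trait(s) with the maximal count,
provided that maximum strictly exceeds the upper quartile of the count
distribution over all traits.

Also here: PCA of a genotype-by-trait RDE matrix to identify the
genotypes most contrasting in drought response (extremes of the first
principal component of, e.g., the four main-spike trait RDEs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DAYCOUNT_ALPHA = 0.001


def correlation_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value on pairwise-complete data.

    Returns (nan, nan) with fewer than 3 complete pairs or a degenerate
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclass
class CorrelationProfile:
    """Per-day correlation of one trait's RDE with one target's RDE."""

    trait: str
    target: str
    table: pd.DataFrame  # index day; columns r, p, n


def rde_correlation_profiles(
    time_rde: pd.DataFrame,
    target_rde: pd.DataFrame,
    targets: list[str] | None = None,
    traits: list[str] | None = None,
) -> dict[tuple[str, str], CorrelationProfile]:
    """Correlation profiles for every (time trait, post-harvest target).

    ``time_rde``: long frame (day, genotype, trait, rde);
    ``target_rde``: long frame (genotype, trait, rde) for the
    post-harvest traits.  Days with fewer than 3 complete genotype pairs
    yield NaN entries.
    """
    traits = traits if traits is not None else sorted(time_rde["trait"].unique())
    targets = targets if targets is not None else sorted(target_rde["trait"].unique())
    tmat = target_rde.pivot_table(index="genotype", columns="trait",
                                  values="rde", aggfunc="first")
    days = sorted(time_rde["day"].unique())
    # genotype x (day, trait) matrix of time RDEs, built once
    wide = time_rde.pivot_table(index="genotype", columns=["trait", "day"],
                                values="rde", aggfunc="first")
    profiles: dict[tuple[str, str], CorrelationProfile] = {}
    for trait in traits:
        if trait not in wide.columns.get_level_values(0):
            continue
        tw = wide[trait]
        for target in targets:
            tg = tmat[target].reindex(tw.index) if target in tmat else None
            rows = []
            for day in days:
                if tg is None or day not in tw.columns:
                    rows.append((day, np.nan, np.nan, 0))
                    continue
                x = tw[day].to_numpy()
                y = tg.to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                r, p = correlation_test(x[ok], y[ok])
                rows.append((day, r, p, int(ok.sum())))
            tab = pd.DataFrame(rows, columns=["day", "r", "p", "n"]).set_index("day")
            profiles[(trait, target)] = CorrelationProfile(trait, target, tab)
    return profiles


def value_correlation_profiles(
    cm: pd.DataFrame, ph: pd.DataFrame, treatment: str,
    targets: list[str] | None = None,
) -> dict[tuple[str, str], CorrelationProfile]:
    """Absolute-value variant: correlate genotype-mean trait *values*
    (within one condition) instead of RDEs."""
    tv = (cm[cm["treatment"] == treatment]
          .groupby(["day", "genotype", "trait"], as_index=False)["value"].mean()
          .rename(columns={"value": "rde"}))
    pv = (ph[ph["treatment"] == treatment]
          .groupby(["genotype", "trait"], as_index=False)["value"].mean()
          .rename(columns={"value": "rde"}))
    return rde_correlation_profiles(tv, pv, targets=targets)


def average_profiles(
    profiles: dict[tuple[str, str], CorrelationProfile],
    subset: list[str],
    name: str = "average",
) -> dict[tuple[str, str], CorrelationProfile]:
    """Average r over a subset of post-harvest targets, per time trait.

    Used for correlated target complexes (e.g. the four main-spike
    traits); the averaged r is a clustering input only — no significance
    is attached to it.  Every member profile must be present.
    """
    traits = sorted({t for (t, _) in profiles})
    out: dict[tuple[str, str], CorrelationProfile] = {}
    for trait in traits:
        member_tabs = []
        for target in subset:
            if (trait, target) not in profiles:
                raise ValueError(f"missing profile for ({trait!r}, {target!r})")
            member_tabs.append(profiles[(trait, target)].table["r"])
        avg = pd.concat(member_tabs, axis=1).mean(axis=1)
        tab = pd.DataFrame({"r": avg, "p": np.nan,
                            "n": profiles[(trait, subset[0])].table["n"]})
        out[(trait, name)] = CorrelationProfile(trait, name, tab)
    return out


@dataclass
class CorrelationDays:
    trait: str
    target: str
    n_pos: int
    n_neg: int

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg


def days_with_correlation(profile: CorrelationProfile,
                          alpha: float = DEFAULT_DAYCOUNT_ALPHA) -> CorrelationDays:
    """Count days with p < alpha, split by the sign of r."""
    tab = profile.table
    sig = tab["p"] < alpha
    n_pos = int((sig & (tab["r"] > 0)).sum())
    n_neg = int((sig & (tab["r"] < 0)).sum())
    return CorrelationDays(profile.trait, profile.target, n_pos, n_neg)


def correlation_days_table(
    profiles: dict[tuple[str, str], CorrelationProfile],
    alpha: float = DEFAULT_DAYCOUNT_ALPHA,
) -> pd.DataFrame:
    rows = []
    for (trait, target), prof in profiles.items():
        d = days_with_correlation(prof, alpha)
        rows.append((trait, target, d.n_pos, d.n_neg, d.n_total))
    return pd.DataFrame(rows, columns=["trait", "target", "n_pos", "n_neg",
                                       "n_total"])


def upper_quartile(counts: np.ndarray) -> float:
    """75th percentile by linear interpolation at rank 1 + 0.75 (n-1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count vector")
    return float(np.quantile(counts, 0.75))  # linear interpolation default


@dataclass
class SelectionResult:
    """Outcome of the quartile selection rule for one target."""

    target: str
    q3: float
    selected: list
    per_category: pd.DataFrame  # category, max count, selected traits


def select_traits(joint_categories: pd.Series, day_counts: pd.Series,
                  q3: float | None = None, target: str = "") -> SelectionResult:
    """Within each joint category keep the trait(s) attaining the
    category-maximal days-with-correlation count iff that maximum
    strictly exceeds the upper quartile Q3 of counts over all traits.

    ``joint_categories``: trait -> hashable category; ``day_counts``:
    trait -> n_total.  Ties at the category maximum are all retained.
    """
    missing = set(joint_categories.index) - set(day_counts.index)
    if missing:
        raise ValueError(f"traits without day counts: {sorted(missing)[:10]}")
    counts = day_counts.reindex(joint_categories.index)
    if q3 is None:
        q3 = upper_quartile(counts.to_numpy())
    selected: list = []
    rows = []
    frame = pd.DataFrame({"category": joint_categories, "count": counts})
    for cat, grp in frame.groupby("category", sort=False):
        cmax = grp["count"].max()
        winners = sorted(grp.index[grp["count"] == cmax].tolist())
        take = cmax > q3
        if take:
            selected.extend(winners)
        rows.append((cat, cmax, winners if take else []))
    return SelectionResult(
        target=target, q3=float(q3), selected=sorted(selected),
        per_category=pd.DataFrame(rows, columns=["category", "max_count",
                                                 "selected"]),
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame     # genotype x PC
    loadings: pd.DataFrame   # trait x PC
    explained: np.ndarray
    extreme_low: str
    extreme_high: str


def pca_contrast_lines(rde_matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of a centered genotype-by-trait RDE matrix.

    Returns scores, loadings (sign fixed so each component's
    largest-magnitude loading is positive) and the genotypes with the
    minimal and maximal first-component score — the lines most
    contrasting in drought response.
    """
    mat = rde_matrix.dropna()
    if mat.shape[0] < 3 or mat.shape[1] < 2:
        raise ValueError("need >= 3 genotypes and >= 2 traits with complete RDE")
    X = mat.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    ncomp = min(n_components, rank)
    V = Vt[:ncomp].T
    for j in range(ncomp):  # sign convention
        i = int(np.abs(V[:, j]).argmax())
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = X @ V
    cols = [f"PC{i + 1}" for i in range(ncomp)]
    score_df = pd.DataFrame(scores, index=mat.index, columns=cols)
    loading_df = pd.DataFrame(V, index=mat.columns, columns=cols)
    explained = (s[:ncomp] ** 2) / (s ** 2).sum()
    pc1 = score_df["PC1"]
    return PCAResult(
        scores=score_df, loadings=loading_df, explained=explained,
        extreme_low=str(pc1.idxmin()), extreme_high=str(pc1.idxmax()),
    )
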