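"""PLS regression of post-harvest RDE on image-trait RDE, with
two-group cross-validated PRESS profiles over days.

The regression engine is NIPALS partial least squares; predictors and
targets are autoscaled (centered, unit column variance) with statistics
taken from the training fold only — trait units are heterogeneous, so
autoscaling is the conventional choice.  Model quality over the
experiment is summarized as a PRESS profile: for each imaging day, the
genotypes are split into two groups, each half is predicted by a model
fitted on the other, and the predictive residual error sum of squares is
accumulated on the standardized-target scale (making values comparable
across target sets).

Fold assignment is deterministic by default — alternation over
genotypes sorted by identifier — with a seeded random split available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

DEFAULT_NCOMP = 2


@dataclass
class PLSModel:
    """Fitted PLS model plus the training-fold scaling constants."""

    n_components: int
    x_weights: pd.DataFrame
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    x_scores: pd.DataFrame
    coef: pd.DataFrame          # predictor x target, original units
    x_mean: pd.Series
    x_std: pd.Series
    y_mean: pd.Series
    y_std: pd.Series
    dropped_predictors: list[str]

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predict targets (original units) for new genotype rows."""
        Xs = X[self.coef.index]
        pred = (Xs - self.x_mean).to_numpy() @ self.coef.to_numpy() \
            + self.y_mean.to_numpy()
        return pd.DataFrame(pred, index=X.index, columns=self.coef.columns)


def pls_fit(X: pd.DataFrame, Y: pd.DataFrame, ncomp: int = DEFAULT_NCOMP) -> PLSModel:
    """Fit NIPALS PLS on complete rows of X and Y.

    Zero-variance predictor columns are dropped with a warning; ``ncomp``
    beyond what the data supports raises.
    """
    if isinstance(Y, pd.Series):
        Y = Y.to_frame()
    rows = X.dropna().index.intersection(Y.dropna().index)
    X, Y = X.loc[rows], Y.loc[rows]
    sd = X.std(ddof=1)
    dropped = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {dropped[:5]}",
                      stacklevel=2)
        X = X.drop(columns=dropped)
    max_comp = min(len(rows) - 1, X.shape[1])
    if ncomp > max_comp:
        raise ValueError(f"ncomp={ncomp} exceeds the rank limit {max_comp}")
    eng = PLSRegression(n_components=ncomp, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eng.fit(X.to_numpy(), Y.to_numpy())
    comp = [f"C{i + 1}" for i in range(ncomp)]
    # sklearn's coef_ is (n_targets, n_features) on original units
    coef = pd.DataFrame(eng.coef_.T, index=X.columns, columns=Y.columns)
    return PLSModel(
        n_components=ncomp,
        x_weights=pd.DataFrame(eng.x_weights_, index=X.columns, columns=comp),
        x_loadings=pd.DataFrame(eng.x_loadings_, index=X.columns, columns=comp),
        y_loadings=pd.DataFrame(eng.y_loadings_, index=Y.columns, columns=comp),
        x_scores=pd.DataFrame(eng.x_scores_, index=rows, columns=comp),
        coef=coef,
        x_mean=pd.Series(eng._x_mean, index=X.columns),
        x_std=pd.Series(eng._x_std, index=X.columns),
        y_mean=pd.Series(eng._y_mean, index=Y.columns),
        y_std=pd.Series(eng._y_std, index=Y.columns),
        dropped_predictors=dropped,
    )


def alternating_folds(index: pd.Index) -> pd.Series:
    """Deterministic two-group assignment: alternation over sorted ids."""
    ordered = sorted(index)
    fold = {g: i % 2 for i, g in enumerate(ordered)}
    return pd.Series([fold[g] for g in index], index=index, name="fold")


def random_folds(index: pd.Index, seed: int) -> pd.Series:
    rng = np.random.default_rng(seed)
    ordered = sorted(index)
    labels = np.arange(len(ordered)) % 2
    rng.shuffle(labels)
    fold = dict(zip(ordered, labels))
    return pd.Series([fold[g] for g in index], index=index, name="fold")


def press_two_fold(X: pd.DataFrame, Y: pd.DataFrame, ncomp: int,
                   folds: pd.Series | None = None) -> float:
    """Two-group cross-validated PRESS on the standardized-target scale.

    Fit on fold 0 and predict fold 1, and vice versa; each held-out
    squared error is divided by the training-fold target variance.  If a
    training fold has fewer rows than ``ncomp`` allows, the component
    count is truncated for that fold (a warning flags it).
    """
    if isinstance(Y, pd.Series):
        Y = Y.to_frame()
    rows = X.dropna().index.intersection(Y.dropna().index)
    X, Y = X.loc[rows], Y.loc[rows]
    folds = alternating_folds(rows) if folds is None else folds.reindex(rows)
    press = 0.0
    for held in (0, 1):
        train = folds.index[folds != held]
        test = folds.index[folds == held]
        if len(train) == 0 or len(test) == 0:
            raise ValueError("both folds must be non-empty")
        max_comp = min(len(train) - 1, X.shape[1])
        use = min(ncomp, max_comp)
        if use < ncomp:
            warnings.warn(
                f"fold with {len(train)} rows truncates components to {use}",
                stacklevel=2)
        model = pls_fit(X.loc[train], Y.loc[train], use)
        pred = model.predict(X.loc[test])
        err = (Y.loc[test, model.coef.columns] - pred) / model.y_std
        press += float((err.to_numpy() ** 2).sum())
    return press


@dataclass
class PressProfile:
    """Per-day PRESS for one named predictor set."""

    predictor_set: str
    press: pd.Series  # day -> PRESS


def press_profile(
    time_rde: pd.DataFrame,
    target_rde: pd.DataFrame,
    targets: list[str],
    predictor_sets: dict[str, list[str]],
    ncomp: int = DEFAULT_NCOMP,
    folds: pd.Series | None = None,
    min_rows: int = 8,
) -> dict[str, PressProfile]:
    """PRESS per day per predictor set.

    ``time_rde`` long (day, genotype, trait, rde); ``target_rde`` long
    (genotype, trait, rde).  Days with fewer than ``min_rows`` complete
    genotype rows are skipped.
    """
    Ymat = target_rde.pivot_table(index="genotype", columns="trait",
                                  values="rde", aggfunc="first")[targets]
    out: dict[str, PressProfile] = {}
    for name, traits in predictor_sets.items():
        vals = {}
        for day, sub in time_rde.groupby("day"):
            Xmat = sub.pivot_table(index="genotype", columns="trait",
                                   values="rde", aggfunc="first")
            cols = [t for t in traits if t in Xmat.columns]
            if not cols:
                continue
            Xd = Xmat[cols].dropna()
            rows = Xd.index.intersection(Ymat.dropna().index)
            if len(rows) < min_rows:
                continue
            f = folds.reindex(rows) if folds is not None else None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals[int(day)] = press_two_fold(Xd.loc[rows], Ymat.loc[rows],
                                                ncomp, f)
        out[name] = PressProfile(name, pd.Series(vals, name=name).sort_index())
    return out


@dataclass
class BiplotCoordinates:
    scores: pd.DataFrame     # genotype x (C1, C2)
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame


def biplot_coordinates(model: PLSModel) -> BiplotCoordinates:
    """Genotype scores and predictor/target loadings on components 1-2."""
    if model.n_components < 2:
        raise ValueError("biplot requires at least 2 components")
    comp = ["C1", "C2"]
    return BiplotCoordinates(
        scores=model.x_scores[comp],
        x_loadings=model.x_loadings[comp],
        y_loadings=model.y_loadings[comp],
    )
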