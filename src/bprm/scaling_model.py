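"""Size-scale clustering of low attenuation densities and the airflow model.

The predictive model of airflow limitation regresses FEV1/FVC% on 40
predictors: the summed low attenuation density (LAD, in % of parenchyma) of
clusters falling into 10 size scales x 2 lobe groups (upper/lower) x 2 lesion
types (severe emphysema on inspiratory CT, fSAD on co-registered expiratory
CT).  Scales are fitted by optimal univariate k-means (dynamic programming,
globally minimal within-cluster sum of squares); the full 40-term ordinary
least squares fit is reduced by backward selection until every retained
predictor has p < alpha, and evaluated by repeated stratified five-fold
cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .core import (
    CatalogError,
    DegenerateScaleError,
    FitError,
    ParameterError,
    UndefinedCorrelationError,
)

N_SCALES = 10
GROUPS = ("upper", "lower")
LESION_TYPES = ("emph950", "fsad")


def predictor_name(scale: int, group: str, lesion_type: str) -> str:
    return f"{lesion_type}_{group}_s{scale:02d}"


#: Canonical order of the 40 predictors: type-major, then group, then scale.
PREDICTOR_NAMES: list[str] = [
    predictor_name(s, g, t)
    for t in LESION_TYPES
    for g in GROUPS
    for s in range(1, N_SCALES + 1)
]


def parse_predictor_name(name: str) -> tuple[int, str, str]:
    """Inverse of :func:`predictor_name` -> (scale, group, lesion_type)."""
    lesion_type, group, stag = name.rsplit("_", 2)
    return int(stag[1:]), group, lesion_type


# ---------------------------------------------------------------------------
# Optimal 1-D k-means
# ---------------------------------------------------------------------------


@dataclass
class CkmeansResult:
    labels: np.ndarray  # cluster index (0..k-1) per input value, input order
    boundaries: np.ndarray  # (k-1,) ascending cut points
    centers: np.ndarray  # (k,) cluster means, ascending
    wss: float  # total within-cluster sum of squares


def ckmeans_1d(values, k: int) -> CkmeansResult:
    """Globally optimal univariate k-means by dynamic programming.

    Clusters are contiguous in sorted order; the partition minimizes the total
    within-cluster sum of squares, exactly (O(k n^2) DP).  Deterministic: ties
    are broken toward the earliest split point.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if not (1 <= k <= n):
        raise ParameterError(f"need 1 <= k <= n, got k={k}, n={n}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_cost(j: np.ndarray, i: int) -> np.ndarray:
        # WSS of xs[j..i] inclusive (vectorized over start indices j)
        cnt = i - j + 1
        s = c1[i + 1] - c1[j]
        return (c2[i + 1] - c2[j]) - s * s / cnt

    D = np.full((k, n), np.inf)
    B = np.zeros((k, n), dtype=np.intp)
    # first row: a single cluster covering xs[0..i]
    idx = np.arange(1, n + 1)
    D[0] = (c2[1:] - c2[0]) - (c1[1:] - c1[0]) ** 2 / idx
    for m in range(1, k):
        for i in range(m, n):
            j = np.arange(m, i + 1)
            cost = D[m - 1, j - 1] + seg_cost(j, i)
            a = int(np.argmin(cost))
            D[m, i] = cost[a]
            B[m, i] = j[a]

    labels_sorted = np.empty(n, dtype=np.intp)
    i = n - 1
    for m in range(k - 1, -1, -1):
        j = int(B[m, i]) if m > 0 else 0
        labels_sorted[j : i + 1] = m
        i = j - 1
    labels = np.empty(n, dtype=np.intp)
    labels[order] = labels_sorted

    boundaries = np.empty(k - 1)
    centers = np.empty(k)
    for m in range(k):
        seg = xs[labels_sorted == m]
        centers[m] = seg.mean()
        if m < k - 1:
            nxt = xs[labels_sorted == m + 1]
            boundaries[m] = 0.5 * (seg.max() + nxt.min())
    wss = float(max(D[k - 1, n - 1], 0.0))
    return CkmeansResult(labels=labels, boundaries=boundaries, centers=centers, wss=wss)


# ---------------------------------------------------------------------------
# Scale model
# ---------------------------------------------------------------------------


@dataclass
class ScaleModel:
    """Boundary-lookup assignment of LAD values to 10 size scales.

    ``boundaries`` are midpoints between adjacent cluster extremes of the
    optimal DP partition of the pooled training LADs, so assigning the
    training pool by boundaries reproduces the optimal partition exactly.
    New values below/above all boundaries clamp to scale 1 / k.
    """

    k: int
    boundaries: np.ndarray  # (k-1,) ascending
    centers: np.ndarray  # (k,)
    provenance: str = "inspiratory"  # which LAD pool was fitted

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ParameterError("scale boundaries must be strictly ascending")

    def assign(self, lads) -> np.ndarray:
        """Scale index 1..k per LAD value (a value equal to a boundary goes low)."""
        lads = np.asarray(lads, dtype=float)
        return np.searchsorted(self.boundaries, lads, side="left") + 1

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "boundaries": self.boundaries.tolist(),
            "centers": self.centers.tolist(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleModel":
        return cls(
            k=int(d["k"]),
            boundaries=np.asarray(d["boundaries"], dtype=float),
            centers=np.asarray(d["centers"], dtype=float),
            provenance=d.get("provenance", "inspiratory"),
        )


def fit_scale_model(
    pooled_lads,
    k: int = N_SCALES,
    provenance: str = "inspiratory",
    max_fit_n: int = 3000,
) -> ScaleModel:
    """Fit scale boundaries by optimal 1-D k-means on a pooled LAD sample.

    Pools larger than ``max_fit_n`` are thinned to an even quantile subsample
    of the sorted values (deterministic) before the O(k n^2) DP.
    """
    lads = np.sort(np.asarray(pooled_lads, dtype=float).ravel())
    if np.unique(lads).size < k:
        raise DegenerateScaleError(
            f"need at least {k} distinct LAD values, got {np.unique(lads).size}"
        )
    if lads.size > max_fit_n:
        lads = lads[np.linspace(0, lads.size - 1, max_fit_n).round().astype(int)]
    res = ckmeans_1d(lads, k)
    return ScaleModel(k=k, boundaries=res.boundaries, centers=res.centers,
                      provenance=provenance)


# ---------------------------------------------------------------------------
# Predictor assembly
# ---------------------------------------------------------------------------


def assemble_predictors(lacs, scale_models: dict) -> pd.Series:
    """Sum per-cluster LAD% into the 40 (scale, group, type) predictors.

    ``lacs`` is an iterable of :class:`bprm.lac.LACRecord`.  Inspiratory
    clusters contribute as type ``emph950``; expiratory clusters classified
    ``fsad`` contribute their *fSAD-voxel* density (not the full cluster
    density); emphysema-predominant expiratory clusters are excluded.
    ``scale_models`` maps lesion type -> :class:`ScaleModel`.
    """
    x = pd.Series(0.0, index=PREDICTOR_NAMES)
    for rec in lacs:
        if rec.phase == "inspiratory":
            lesion_type = "emph950"
            lad = rec.lad
        else:
            if rec.lac_class == "emph_predominant":
                continue
            lesion_type = "fsad"
            if rec.voxel_count == 0:
                continue
            lad = rec.lad * rec.fsad_voxels / rec.voxel_count
        if lad <= 0:
            continue
        if rec.group not in GROUPS:
            raise CatalogError(f"LAC {rec.id} lacks a region/group assignment")
        scale = int(scale_models[lesion_type].assign([lad])[0])
        x[predictor_name(scale, rec.group, lesion_type)] += 100.0 * lad
    return x


# ---------------------------------------------------------------------------
# Linear model, backward selection, cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FullModel:
    """An OLS fit with per-coefficient two-sided t-test p-values."""

    X: pd.DataFrame  # the (possibly rank-reduced) design, no constant column
    y: np.ndarray
    params: pd.Series  # includes 'const'
    pvalues: pd.Series
    dropped: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [c for c in self.params.index if c != "const"]


def _ols(X: pd.DataFrame, y: np.ndarray):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit()


def fit_full_model(X, y) -> FullModel:
    """Ordinary least squares of the response on all predictors.

    Rank-deficient columns (zero variance or exact collinearity) are dropped
    with a warning before fitting; n must exceed the retained predictor count
    plus one.
    """
    X = pd.DataFrame(X)
    if not all(isinstance(c, str) for c in X.columns):
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise FitError("X and y disagree on the number of subjects")

    keep = [c for c in X.columns if np.ptp(X[c].to_numpy()) > 0]
    dropped = [c for c in X.columns if c not in keep]
    Xk = X[keep]
    if Xk.shape[1]:
        # rank check via pivoted QR on the centered design
        M = Xk.to_numpy() - Xk.to_numpy().mean(axis=0)
        import scipy.linalg

        r_diag = np.abs(np.diag(scipy.linalg.qr(M, mode="r", pivoting=True)[0]))
        rank = int(np.sum(r_diag > max(M.shape) * np.finfo(float).eps * r_diag.max()))
        if rank < Xk.shape[1]:
            piv = scipy.linalg.qr(M, mode="r", pivoting=True)[1]
            keep_idx = sorted(piv[:rank])
            dropped += [c for i, c in enumerate(Xk.columns) if i not in keep_idx]
            Xk = Xk.iloc[:, keep_idx]
    if dropped:
        warnings.warn(f"dropping rank-deficient predictors: {dropped}", stacklevel=2)
    if y.size <= Xk.shape[1] + 1:
        raise FitError(
            f"n={y.size} too small for {Xk.shape[1]} predictors; reduce first"
        )
    res = _ols(Xk, y)
    return FullModel(X=Xk, y=y, params=res.params, pvalues=res.pvalues,
                     dropped=dropped)


@dataclass
class ModelTerm:
    name: str
    scale: int | None
    group: str | None
    lesion_type: str | None
    coefficient: float
    p_value: float


@dataclass
class AirflowModel:
    """Backward-selected linear predictor of FEV1/FVC% from LAD% scales."""

    intercept: float
    terms: list[ModelTerm]
    alpha: float = 0.05

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def coefficients(self) -> pd.Series:
        return pd.Series({t.name: t.coefficient for t in self.terms})

    def predict(self, X) -> np.ndarray:
        """Predict FEV1/FVC% from a predictor table/Series (missing terms = 0)."""
        if isinstance(X, (pd.Series, dict)):
            X = pd.DataFrame([pd.Series(X)])
        X = pd.DataFrame(X)
        yhat = np.full(X.shape[0], self.intercept, dtype=float)
        for t in self.terms:
            if t.name in X.columns:
                yhat += t.coefficient * X[t.name].to_numpy(dtype=float)
        return yhat

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "alpha": self.alpha,
            "terms": [
                {
                    "name": t.name,
                    "scale": t.scale,
                    "group": t.group,
                    "lesion_type": t.lesion_type,
                    "coefficient": t.coefficient,
                    "p_value": t.p_value,
                }
                for t in self.terms
            ],
        }

    def to_json(self, path, extra: dict | None = None) -> None:
        d = self.to_dict()
        if extra:
            d.update(extra)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AirflowModel":
        terms = [
            ModelTerm(
                name=t["name"], scale=t.get("scale"), group=t.get("group"),
                lesion_type=t.get("lesion_type"),
                coefficient=float(t["coefficient"]), p_value=float(t["p_value"]),
            )
            for t in d["terms"]
        ]
        return cls(intercept=float(d["intercept"]), terms=terms,
                   alpha=float(d.get("alpha", 0.05)))

    @classmethod
    def from_json(cls, path) -> "AirflowModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _term_from(name: str, coef: float, p: float) -> ModelTerm:
    try:
        scale, group, lesion_type = parse_predictor_name(name)
    except (ValueError, IndexError):
        scale = group = lesion_type = None  # type: ignore[assignment]
    return ModelTerm(name=name, scale=scale, group=group, lesion_type=lesion_type,
                     coefficient=float(coef), p_value=float(p))


def backward_select(full: FullModel, alpha: float = 0.05) -> AirflowModel:
    """Iteratively drop the highest-p predictor until all remaining p < alpha.

    The intercept is always kept.  Ties on p are broken by removing the
    largest column index first, so the result is invariant to column order.
    If every predictor is removed an intercept-only model is returned with a
    warning.
    """
    cols = list(full.X.columns)
    params, pvalues = full.params, full.pvalues
    while cols:
        pv = pvalues.drop("const")
        worst = float(pv.max())
        if worst < alpha:
            break
        # tie-break: among predictors at the max p, drop the largest index
        at_max = [c for c in cols if pvalues[c] >= worst - 1e-15]
        drop = max(at_max, key=cols.index)
        cols.remove(drop)
        if not cols:
            break
        res = _ols(full.X[cols], full.y)
        params, pvalues = res.params, res.pvalues
    if not cols:
        warnings.warn("backward selection removed every predictor; "
                      "returning an intercept-only model", stacklevel=2)
        return AirflowModel(intercept=float(np.mean(full.y)), terms=[], alpha=alpha)
    terms = [_term_from(c, params[c], pvalues[c]) for c in cols]
    return AirflowModel(intercept=float(params["const"]), terms=terms, alpha=alpha)


def fit_airflow_model(X, y, alpha: float = 0.05) -> AirflowModel:
    """Convenience: full OLS fit followed by backward selection."""
    return backward_select(fit_full_model(X, y), alpha=alpha)


@dataclass
class CVResult:
    per_repeat_r: np.ndarray  # pooled out-of-fold Pearson r, one per repeat
    records: pd.DataFrame  # columns: repeat, fold, n_test, r

    @property
    def mean_r(self) -> float:
        return float(self.per_repeat_r.mean())

    @property
    def sd_r(self) -> float:
        return float(self.per_repeat_r.std(ddof=1)) if self.per_repeat_r.size > 1 else 0.0


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator,
                      stratify: bool) -> np.ndarray:
    """Fold index per subject; strata are response quintiles when stratifying."""
    n = y.size
    if stratify:
        ranks = scipy.stats.rankdata(y, method="ordinal") - 1
        strata = (ranks * 5 // n).astype(int)
    else:
        strata = np.zeros(n, dtype=int)
    fold_of = np.empty(n, dtype=int)
    offset = 0
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            fold_of[i] = (pos + offset) % folds
        offset += idx.size
    return fold_of


def cross_validate(
    X,
    y,
    folds: int = 5,
    repeats: int = 30,
    seed: int = 0,
    alpha: float = 0.05,
    stratify: bool = True,
    reselect: bool = True,
) -> CVResult:
    """Repeated stratified k-fold CV of the full-fit + backward-selection pipeline.

    Per repeat, subjects are shuffled by a seeded generator into folds
    stratified by response quintile; the model is refitted (and, by default,
    re-selected) on each training split and the Pearson r between pooled
    out-of-fold predictions and observations is recorded.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < folds:
        raise ParameterError(f"n={n} smaller than fold count {folds}")
    if n // folds < 2:
        raise ParameterError("each fold needs at least 2 subjects")
    children = np.random.SeedSequence(seed).spawn(repeats)
    rows = []
    per_repeat = np.empty(repeats)
    for rep in range(repeats):
        rng = np.random.default_rng(children[rep])
        fold_of = _stratified_folds(y, folds, rng, stratify)
        yhat = np.empty(n)
        fixed_model = None
        if not reselect:
            fixed_model = fit_airflow_model(X, y, alpha=alpha)
        for f in range(folds):
            test = fold_of == f
            if not reselect:
                # refit only the retained terms' coefficients on the training split
                names = [nm for nm in fixed_model.term_names if nm in X.columns]
                res = _ols(X.loc[~test, names], y[~test])
                pred = np.full(int(test.sum()), float(res.params["const"]))
                for nm in names:
                    pred += float(res.params[nm]) * X.loc[test, nm].to_numpy(float)
            else:
                model = fit_airflow_model(X.loc[~test], y[~test], alpha=alpha)
                pred = model.predict(X.loc[test])
            yhat[test] = pred
            r_fold = (
                pearson(pred, y[test])[0]
                if np.ptp(pred) > 0 and np.ptp(y[test]) > 0 and test.sum() >= 3
                else np.nan
            )
            rows.append({"repeat": rep, "fold": f, "n_test": int(test.sum()),
                         "r": r_fold})
        per_repeat[rep] = pearson(yhat, y)[0]
    return CVResult(per_repeat_r=per_repeat,
                    records=pd.DataFrame(rows))


def pearson(a, b) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-distribution p-value."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise UndefinedCorrelationError("need two equal-length vectors, n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r, p = scipy.stats.pearsonr(a, b)
    return float(r), float(p)
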