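"""Predictor selection: LASSO shortlist, exhaustive subset search, 10-fold CV.

The screened covariate survivors (plus a season indicator, season
interactions and — for pooled multi-city models — a city indicator and city
interactions) first pass through a LASSO path that shrinks the candidate set
to at most 15 terms.  All subsets of those candidates with at most 6
parameters are then enumerated and each is fit by ordinary least squares
under a shared 10-fold cross-validation split; the subset with the lowest
cross-validated RMSE wins.  When an interaction is selected without its main
effect, the main effect is forced into the model (which may push the final
model past the enumeration cap — parameter counting applies at enumeration
time).

Parameter counting: the intercept is free; each covariate main effect, the
season (or city) indicator, and each interaction term counts as one
parameter, even when a categorical indicator spans several design columns.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

MAX_LASSO_VARS = 15
MAX_PARAMS = 6
TIE_EPS = 1e-10


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------
@dataclass
class Standardizer:
    """Column-wise z-scoring with stored training constants."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def fit(self, df: pd.DataFrame) -> "Standardizer":
        for c in df.columns:
            col = df[c].to_numpy(float)
            sd = col.std(ddof=1)
            self.means[c] = float(col.mean())
            self.sds[c] = float(sd if sd > 0 else 1.0)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c in df.columns:
            if c not in self.means:
                raise KeyError(f"column {c!r} not seen at fit time")
            out[c] = (df[c].to_numpy(float) - self.means[c]) / self.sds[c]
        return pd.DataFrame(out, index=df.index)

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


# ---------------------------------------------------------------------------
# model specification and term-column bookkeeping
# ---------------------------------------------------------------------------
def is_interaction(term: str) -> bool:
    return ":" in term


def interaction_parts(term: str) -> tuple[str, str]:
    a, b = term.split(":", 1)
    return a, b


@dataclass(frozen=True)
class ModelSpec:
    """A candidate predictor subset.

    ``terms`` are canonical names: covariate names, ``"season"``, ``"city"``,
    or interactions ``"<covariate>:season"`` / ``"<covariate>:city"``.
    """

    outcome: str
    terms: tuple[str, ...]
    scope: str = "city"  # "city" (single-city model) or "pooled"
    coefficients: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(sorted(self.terms)))

    @property
    def main_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if not is_interaction(t))

    @property
    def interaction_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if is_interaction(t))

    @property
    def n_parameters(self) -> int:
        return len(self.terms)

    def repaired(self) -> "ModelSpec":
        """Force main effects for every interaction term."""
        need = set(self.terms)
        for t in self.interaction_terms:
            a, b = interaction_parts(t)
            need.add(a)
            need.add(b)
        return ModelSpec(self.outcome, tuple(sorted(need)), self.scope, self.coefficients)

    def to_dict(self) -> dict:
        return dict(
            outcome=self.outcome,
            terms=list(self.terms),
            scope=self.scope,
            coefficients=dict(self.coefficients) if self.coefficients else None,
        )


class TermSet:
    """Design columns for every available term, built once per dataset.

    A term maps to one or more design columns ("city" spans the non-baseline
    city dummies).  ``matrix_for(terms)`` assembles [1 | columns] for a spec.
    """

    def __init__(self, cov_z: pd.DataFrame, samples: pd.DataFrame, scope: str = "city"):
        if len(cov_z) != len(samples):
            raise ValueError("covariates and samples must align row-wise")
        self.scope = scope
        cols: dict[str, np.ndarray] = {}
        term_cols: dict[str, list[str]] = {}

        seasons = sorted(samples["season"].unique())
        summer = (samples["season"] == seasons[-1]).to_numpy(float) if len(seasons) > 1 else None

        for name in cov_z.columns:
            cols[name] = cov_z[name].to_numpy(float)
            term_cols[name] = [name]

        if summer is not None:
            cols["season"] = summer
            term_cols["season"] = ["season"]
            for name in cov_z.columns:
                t = f"{name}:season"
                cols[t] = cols[name] * summer
                term_cols[t] = [t]

        if scope == "pooled":
            cities = sorted(samples["city"].unique())
            dummies = []
            for c in cities[1:]:
                cn = f"city_{c}"
                cols[cn] = (samples["city"] == c).to_numpy(float)
                dummies.append(cn)
            if dummies:
                term_cols["city"] = dummies
                for name in cov_z.columns:
                    t = f"{name}:city"
                    sub = []
                    for cn in dummies:
                        icn = f"{name}:{cn}"
                        cols[icn] = cols[name] * cols[cn]
                        sub.append(icn)
                    term_cols[t] = sub

        self.frame = pd.DataFrame(cols, index=samples.index)
        self.term_cols = term_cols
        self._col_index = {c: i for i, c in enumerate(self.frame.columns)}
        self.matrix = self.frame.to_numpy(float)

    @property
    def terms(self) -> list[str]:
        return list(self.term_cols)

    def columns_for(self, terms: Iterable[str]) -> list[int]:
        idx: list[int] = []
        for t in terms:
            if t not in self.term_cols:
                raise KeyError(f"unknown term {t!r}")
            idx.extend(self._col_index[c] for c in self.term_cols[t])
        return idx

    def matrix_for(self, terms: Iterable[str]) -> tuple[np.ndarray, list[str]]:
        idx = self.columns_for(terms)
        names = ["intercept"] + [self.frame.columns[i] for i in idx]
        X = np.column_stack([np.ones(len(self.frame))] + [self.matrix[:, i] for i in idx])
        return X, names


# ---------------------------------------------------------------------------
# LASSO shortlist
# ---------------------------------------------------------------------------
def lasso_reduce(
    termset: TermSet, y, max_vars: int = MAX_LASSO_VARS, n_alphas: int = 100
) -> list[str]:
    """Shrink the term pool to <= ``max_vars`` candidates along a LASSO path.

    Columns are standardised internally; the path runs over ``n_alphas``
    log-spaced penalties from the smallest penalty that zeroes every
    coefficient down to 1e-4 of it.  Returns the terms of the largest support
    not exceeding ``max_vars`` (support counted in terms, not design columns).
    """
    y = np.asarray(y, float)
    M = termset.matrix
    if M.shape[1] == 0:
        raise ValueError("no candidate columns")
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (M - mu) / sd
    yc = y - y.mean()

    n = len(y)
    alpha_max = np.max(np.abs(Xs.T @ yc)) / n
    if alpha_max == 0:
        return []
    alphas = np.logspace(math.log10(alpha_max), math.log10(alpha_max * 1e-4), n_alphas)
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # only support sizes are read off the path; looser convergence at the
        # smallest penalties does not change which terms are active
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(Xs, yc, alphas=alphas, max_iter=10_000, tol=1e-4)

    col_names = list(termset.frame.columns)
    col_to_term: dict[str, str] = {}
    for term, cs in termset.term_cols.items():
        for c in cs:
            col_to_term[c] = term

    best_terms: list[str] = []
    for k in range(coefs.shape[1]):
        nz = np.flatnonzero(np.abs(coefs[:, k]) > 1e-12)
        terms = sorted({col_to_term[col_names[i]] for i in nz})
        if len(best_terms) < len(terms) <= max_vars:
            best_terms = terms
    return best_terms


# ---------------------------------------------------------------------------
# exhaustive enumeration
# ---------------------------------------------------------------------------
def enumerate_subsets(
    candidates: Sequence[str],
    max_params: int = MAX_PARAMS,
    outcome: str = "coarse",
    scope: str = "city",
) -> Iterator[ModelSpec]:
    """Yield every candidate subset with <= ``max_params`` parameters.

    Subsets containing an interaction without its main effect are repaired by
    forcing the main effect in; repair may exceed the cap.  Repaired
    duplicates are emitted once.
    """
    candidates = sorted(set(candidates))
    seen: set[tuple[str, ...]] = set()
    for k in range(0, max_params + 1):
        for combo in itertools.combinations(candidates, k):
            spec = ModelSpec(outcome, combo, scope).repaired()
            if spec.terms in seen:
                continue
            seen.add(spec.terms)
            yield spec


def count_subsets(n_candidates: int, max_params: int = MAX_PARAMS) -> int:
    """Closed-form count for main-effect-only candidate pools."""
    return sum(math.comb(n_candidates, k) for k in range(0, max_params + 1))


# ---------------------------------------------------------------------------
# cross-validated selection
# ---------------------------------------------------------------------------
def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random fold labels 0..k-1 with sizes differing by at most one."""
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k  # sizes n//k or n//k + 1
    return labels[rng.permutation(n)]


def _cv_predictions(
    X: np.ndarray, y: np.ndarray, folds: np.ndarray
) -> np.ndarray | None:
    """Held-out predictions under one fold assignment; None if any training
    design is rank deficient."""
    pred = np.empty_like(y)
    p = X.shape[1]
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        Xtr = X[train]
        beta, _, rank, _ = np.linalg.lstsq(Xtr, y[train], rcond=None)
        if rank < p:
            return None
        pred[test] = X[test] @ beta
    return pred


@dataclass
class SelectionResult:
    best: ModelSpec
    cv_rmse: float
    cv_r2: float
    ranked: list[dict]
    fold_seed: int
    n_evaluated: int
    n_discarded: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dict(
            best=self.best.to_dict(),
            cv_rmse=self.cv_rmse,
            cv_r2=self.cv_r2,
            ranked=self.ranked,
            fold_seed=self.fold_seed,
            n_evaluated=self.n_evaluated,
            n_discarded=self.n_discarded,
        )
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def select_best(
    specs: Iterable[ModelSpec],
    termset: TermSet,
    y,
    k: int = 10,
    seed: int = 0,
    n_ranked: int = 10,
) -> SelectionResult:
    """Evaluate every spec under one shared k-fold split; return the lowest
    cross-validated RMSE (ties: fewer parameters, then lexicographic terms).
    """
    y = np.asarray(y, float)
    folds = make_folds(len(y), k, seed)
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    results: list[tuple[float, int, tuple[str, ...], float, ModelSpec]] = []
    n_discarded = 0
    for spec in specs:
        X, _ = termset.matrix_for(spec.terms)
        pred = _cv_predictions(X, y, folds)
        if pred is None:
            n_discarded += 1
            continue
        sse = float(np.sum((y - pred) ** 2))
        rmse = math.sqrt(sse / len(y))
        r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
        results.append((rmse, spec.n_parameters, spec.terms, r2, spec))
    if not results:
        raise ValueError("no fittable candidate specification")

    results.sort(key=lambda t: (round(t[0] / TIE_EPS) * TIE_EPS, t[1], t[2]))
    best_rmse, _, _, best_r2, best_spec = results[0]

    fitted = fit_ols_spec(best_spec, termset, y)
    ranked = [
        dict(terms=list(t[2]), cv_rmse=t[0], cv_r2=t[3]) for t in results[:n_ranked]
    ]
    return SelectionResult(
        best=fitted,
        cv_rmse=best_rmse,
        cv_r2=best_r2,
        ranked=ranked,
        fold_seed=seed,
        n_evaluated=len(results),
        n_discarded=n_discarded,
    )


def fit_ols_spec(spec: ModelSpec, termset: TermSet, y) -> ModelSpec:
    """Fit a spec on the full data, returning it with coefficients attached."""
    y = np.asarray(y, float)
    X, names = termset.matrix_for(spec.terms)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient design for terms {spec.terms}")
    return ModelSpec(
        spec.outcome, spec.terms, spec.scope,
        coefficients=tuple(zip(names, (float(b) for b in beta))),
    )


# ---------------------------------------------------------------------------
# end-to-end selection for one outcome/scope
# ---------------------------------------------------------------------------
def select_model(
    cov_screened,
    samples: pd.DataFrame,
    y,
    outcome: str = "coarse",
    scope: str = "city",
    k: int = 10,
    seed: int = 0,
    max_vars: int = MAX_LASSO_VARS,
    max_params: int = MAX_PARAMS,
) -> tuple[SelectionResult, TermSet, Standardizer]:
    """Screened survivors -> LASSO shortlist -> exhaustive search -> CV pick."""
    std = Standardizer()
    cov_z = std.fit_transform(cov_screened.data.reset_index(drop=True))
    termset = TermSet(cov_z, samples.reset_index(drop=True), scope)
    candidates = lasso_reduce(termset, y, max_vars=max_vars)
    specs = enumerate_subsets(candidates, max_params, outcome=outcome, scope=scope)
    result = select_best(specs, termset, y, k=k, seed=seed)
    return result, termset, std
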