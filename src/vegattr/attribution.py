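"""Attribution engines: PLSR, permutation importance, geographical detector.

Per-pixel vegetation-change slopes are attributed to factor-change
covariates three independent ways, run separately on increasing-vegetation
and decreasing-vegetation pixels:

* **PLSR** (partial least squares regression, NIPALS): sequential latent
  directions maximizing covariance between the standardized covariates and
  the response; the per-covariate "weight of coefficients" is the absolute
  standardized regression coefficient scaled by 100.
* **Permutation importance** (%IncMSE): a bagged regression-tree ensemble;
  each covariate's importance is the mean over trees of the increase in
  out-of-bag MSE when that covariate is permuted, normalized by its
  standard error across trees (the convention of the classical
  random-forest implementation).
* **Geographical detector**: factors are discretized into strata and
  q = 1 - SSW/SST measures the share of response variance explained by the
  stratification (SSW = sum over strata of N_h * sigma_h^2 with population
  variances, SST = N * sigma^2). Pairs of factors are cross-stratified and
  the interaction q is classified into weaken/enhance/independent
  categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .preprocess import MaskLayer
from .trend import TrendResult

DEFAULT_N_TREES = 500
DEFAULT_M_TRY = 4
DEFAULT_TRAIN_FRAC = 0.7
DEFAULT_STRATA = 5
DEFAULT_N_COMPONENTS = 2

INTERACTION_CATEGORIES = ("nonlinear_weaken", "univariate_weaken",
                          "bivariate_enhance", "independent",
                          "nonlinear_enhance")


# ---------------------------------------------------------------------------
# Sample table

@dataclass
class SampleTable:
    """Pixel-level response (trend slope) plus factor-change covariates."""

    data: pd.DataFrame  # columns: response, <covariates...>, pattern
    covariate_names: list[str]
    index_kind: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.covariate_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=float)

    def subset(self, pattern: str) -> "SampleTable":
        """Restrict to one vegetation-change pattern; re-splits 70/30."""
        if pattern not in ("increase", "decrease"):
            raise ValueError("pattern must be 'increase' or 'decrease'")
        sub = self.data[self.data["pattern"] == pattern].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(
                f"no pixels in the {pattern!r} pattern; adjust the scenario "
                "so both increasing and decreasing slopes occur")
        train, test = _split_indices(len(sub), DEFAULT_TRAIN_FRAC, self.seed)
        return SampleTable(sub, list(self.covariate_names), self.index_kind,
                           train, test, self.seed)


def _split_indices(n: int, train_frac: float, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng([int(seed) % (2**31), 70])
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def build_sample_table(trend: TrendResult,
                       covariate_changes: dict[str, np.ndarray],
                       mask: MaskLayer | None = None, *,
                       index_kind: str = "NDVI", seed: int = 0,
                       train_frac: float = DEFAULT_TRAIN_FRAC) -> SampleTable:
    """Assemble the attribution sample from grid-aligned layers.

    Rows are kept pixels with a finite nonzero slope and complete
    covariates; the pattern label is the slope sign. A seeded 70/30
    train/test partition is recorded.
    """
    names = list(covariate_changes)
    shape = trend.beta.shape
    for name, layer in covariate_changes.items():
        if np.asarray(layer).shape != shape:
            raise ValueError(f"covariate {name!r} is not grid-aligned")
    keep = np.isfinite(trend.beta)
    if mask is not None:
        if mask.grid != trend.grid:
            raise ValueError("mask grid differs from trend grid")
        keep &= mask.keep
    cov_stack = np.stack([np.asarray(covariate_changes[n], dtype=float)
                          for n in names])
    keep &= np.isfinite(cov_stack).all(axis=0)
    keep &= trend.beta != 0.0  # sign-undefined pixels carry no pattern
    rows, cols = np.nonzero(keep)
    beta = trend.beta[rows, cols]
    data = pd.DataFrame({"response": beta})
    for k, name in enumerate(names):
        data[name] = cov_stack[k, rows, cols]
    data["pattern"] = np.where(beta > 0, "increase", "decrease")
    data["row"] = rows
    data["col"] = cols
    train, test = _split_indices(len(data), train_frac, seed)
    return SampleTable(data, names, index_kind, train, test, int(seed))


# ---------------------------------------------------------------------------
# PLSR (NIPALS)

@dataclass
class PLSRModel:
    """Single-response PLSR fit on standardized variables."""

    n_components: int
    covariate_names: list[str]
    x_weights: np.ndarray   # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray      # (n, A)
    coefficients: np.ndarray       # (p,), standardized scale
    coefficient_weight: np.ndarray  # |coefficient| * 100
    r2: float
    dropped: list[str] = field(default_factory=list)

    def ranking(self) -> list[str]:
        order = np.argsort(-self.coefficient_weight)
        return [self.covariate_names[i] for i in order]


def plsr_fit(X, y, n_components: int = DEFAULT_N_COMPONENTS,
             covariate_names: list[str] | None = None) -> PLSRModel:
    """NIPALS partial least squares with a single response.

    Covariates and the response are standardized internally; components are
    extracted sequentially with deflation of X and y, and the regression
    coefficients are assembled back on the standardized scale as
    B = W (P'W)^-1 q. Zero-variance covariates are dropped with a warning.
    With as many components as the rank of X the fit equals ordinary least
    squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n_samples, n_covariates) matching y")
    names = list(covariate_names) if covariate_names else [
        f"x{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    dropped = [names[j] for j in np.nonzero(degenerate)[0]]
    if dropped:
        warnings.warn(f"dropping zero-variance covariates: {dropped}")
        X, sd = X[:, ~degenerate], sd[~degenerate]
        names = [n for n, bad in zip(names, degenerate) if not bad]
    if X.shape[1] == 0:
        raise ValueError("no covariates with variance left")
    Xs = (X - X.mean(axis=0)) / sd
    y_sd = y.std()
    if y_sd == 0:
        raise ValueError("response has zero variance")
    ys = (y - y.mean()) / y_sd

    n, p = Xs.shape
    A = min(int(n_components), p, n - 1)
    Xd, yd = Xs.copy(), ys.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    a = 0
    for a in range(A):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:  # nothing left to extract
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pvec = Xd.T @ t / tt
        qa = yd @ t / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        Xd -= np.outer(t, pvec)
        yd -= qa * t
        a += 1
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    if a == 0:
        coef = np.zeros(p)
    else:
        coef = W @ np.linalg.solve(P.T @ W, q)
    pred = Xs @ coef
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum(ys ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PLSRModel(a, names, W, P, q, T, coef, np.abs(coef) * 100.0,
                     r2, dropped)


# ---------------------------------------------------------------------------
# Bagged-tree permutation importance (%IncMSE)

@dataclass
class ImportanceResult:
    covariate_names: list[str]
    inc_mse_pct: np.ndarray
    rmse: float
    r2: float
    n_trees: int
    m_try: int
    seed: int

    def ranking(self) -> list[str]:
        order = np.argsort(-self.inc_mse_pct)
        return [self.covariate_names[i] for i in order]


def _tree_predict(tree: DecisionTreeRegressor, X32: np.ndarray) -> np.ndarray:
    # low-level predict: skips per-call validation, which dominates runtime
    # when querying hundreds of trees
    return tree.tree_.predict(X32).ravel()


def rf_importance(table: SampleTable, *, n_trees: int = DEFAULT_N_TREES,
                  m_try: int = DEFAULT_M_TRY, seed: int = 0,
                  max_oob_eval: int | None = None) -> ImportanceResult:
    """Permutation importance from a bagged regression-tree ensemble.

    Trees are grown on bootstrap resamples of the training rows, considering
    ``m_try`` covariates per split. For each tree, the out-of-bag rows give
    a baseline MSE and a permuted MSE per covariate; the importance is
    mean(permuted - baseline) over trees, divided by its standard error
    across trees. Held-out RMSE and R^2 come from the recorded 30% test
    partition.
    """
    p = len(table.covariate_names)
    if m_try > p:
        warnings.warn(f"m_try={m_try} exceeds {p} covariates; clipping")
        m_try = p
    X = table.X
    y = table.y
    Xtr, ytr = X[table.train_idx], y[table.train_idx]
    Xte, yte = X[table.test_idx], y[table.test_idx]
    n = len(ytr)
    rng = np.random.default_rng([int(seed) % (2**31), 41])
    diffs = np.zeros((n_trees, p))
    test_pred = np.zeros(len(yte))
    Xte32 = np.ascontiguousarray(Xte, dtype=np.float32)
    for b in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=m_try,
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(Xtr[boot], ytr[boot])
        if len(yte):
            test_pred += _tree_predict(tree, Xte32)
        if len(oob) < 2:
            continue
        if max_oob_eval is not None and len(oob) > max_oob_eval:
            oob = rng.choice(oob, max_oob_eval, replace=False)
        Xo = np.ascontiguousarray(Xtr[oob], dtype=np.float32)
        yo = ytr[oob]
        base_mse = float(np.mean((_tree_predict(tree, Xo) - yo) ** 2))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            perm_mse = float(np.mean((_tree_predict(tree, Xp) - yo) ** 2))
            diffs[b, j] = perm_mse - base_mse
    mean_d = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(n_trees)
    inc = np.where(se > 0, mean_d / np.where(se > 0, se, 1.0), 0.0)
    if len(yte):
        test_pred /= n_trees
        resid = yte - test_pred
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        sst = float(np.sum((yte - yte.mean()) ** 2))
        r2 = float(1.0 - np.sum(resid ** 2) / sst) if sst > 0 else 0.0
    else:
        rmse, r2 = float("nan"), float("nan")
    return ImportanceResult(list(table.covariate_names), inc, rmse, r2,
                            n_trees, m_try, int(seed))


# ---------------------------------------------------------------------------
# Geographical detector

@dataclass
class StrataAssignment:
    """Discretization of one covariate into strata."""

    name: str
    L: int
    breaks: np.ndarray          # inner break edges (may be empty)
    labels: np.ndarray          # stratum index per sample, 0..L-1
    counts: np.ndarray          # N_h
    variances: np.ndarray       # sigma_h^2 (population)
    flagged_constant: bool = False

    @classmethod
    def from_labels(cls, labels, name: str = "custom") -> "StrataAssignment":
        labels = np.asarray(labels)
        uniq, lab = np.unique(labels, return_inverse=True)
        counts = np.bincount(lab)
        variances = np.zeros(len(uniq))
        return cls(name, len(uniq), np.array([]), lab, counts, variances)


def discretize(values, L: int = DEFAULT_STRATA, method: str = "quantile",
               name: str = "") -> StrataAssignment:
    """Bin a continuous covariate into at most ``L`` strata.

    Quantile binning keeps strata balanced for skewed covariates; duplicate
    break edges are collapsed, empty strata dropped and strata with fewer
    than two samples merged into the adjacent stratum, so every final
    stratum has a defined variance. A constant covariate yields a single
    flagged stratum (its q is 0 by construction).
    """
    values = np.asarray(values, dtype=float).ravel()
    if not np.isfinite(values).all():
        raise ValueError("covariate contains non-finite values")
    if L < 2:
        raise ValueError("need at least 2 strata")
    if method not in ("quantile", "equal_interval"):
        raise ValueError(f"unknown discretization method {method!r}")
    if np.ptp(values) == 0:
        n = len(values)
        return StrataAssignment(name, 1, np.array([]), np.zeros(n, dtype=int),
                                np.array([n]), np.array([0.0]),
                                flagged_constant=True)
    if method == "quantile":
        edges = np.quantile(values, np.linspace(0, 1, L + 1))
    else:
        edges = np.linspace(values.min(), values.max(), L + 1)
    inner = np.unique(edges[1:-1])
    labels = np.searchsorted(inner, values, side="right")
    labels = _compact_labels(labels)
    labels = _merge_small_strata(values, labels)
    uniq = np.unique(labels)
    counts = np.array([(labels == u).sum() for u in uniq])
    variances = np.array([values[labels == u].var() for u in uniq])
    return StrataAssignment(name, len(uniq), inner, labels, counts, variances)


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _merge_small_strata(values: np.ndarray, labels: np.ndarray,
                        min_size: int = 2) -> np.ndarray:
    labels = labels.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1:
            break
        small = uniq[counts < min_size]
        if len(small) == 0:
            break
        h = small[0]
        pos = int(np.nonzero(uniq == h)[0][0])
        target = uniq[pos - 1] if pos > 0 else uniq[pos + 1]
        labels[labels == h] = target
        labels = _compact_labels(labels)
    return labels


@dataclass
class QResult:
    q: float
    ssw: float
    sst: float
    L: int


def q_statistic(y, strata: StrataAssignment) -> QResult:
    """Variance-explained q of a stratification: q = 1 - SSW/SST.

    SSW sums N_h * sigma_h^2 over strata (population variances); SST is
    N * sigma^2 over all samples. q lies in [0, 1]; a degenerate SST of 0
    yields q = 0 by convention.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(strata.labels):
        raise ValueError("response and strata lengths differ")
    sst = len(y) * y.var()
    if sst == 0:
        return QResult(0.0, 0.0, 0.0, strata.L)
    ssw = 0.0
    for h in range(strata.labels.max() + 1):
        sel = strata.labels == h
        n_h = int(sel.sum())
        if n_h:
            ssw += n_h * y[sel].var()
    q = float(np.clip(1.0 - ssw / sst, 0.0, 1.0))
    return QResult(q, float(ssw), float(sst), int(strata.labels.max() + 1))


def interaction_q(y, strata_a: StrataAssignment, strata_b: StrataAssignment
                  ) -> QResult:
    """q of the cross-stratification: each nonempty (h_A, h_B) pair is one
    stratum."""
    if len(strata_a.labels) != len(strata_b.labels):
        raise ValueError("stratifications cover different samples")
    k = strata_b.labels.max() + 1
    combined = strata_a.labels * k + strata_b.labels
    return q_statistic(y, StrataAssignment.from_labels(combined, "interaction"))


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-9) -> str:
    """Five-way interaction taxonomy from q1, q2 and the pair q12.

    q12 < min -> nonlinear_weaken; min <= q12 < max -> univariate_weaken;
    max <= q12 < q1+q2 -> bivariate_enhance (the q12 = max boundary resolves
    here); q12 = q1+q2 (within tol) -> independent; q12 > q1+q2 ->
    nonlinear_enhance.
    """
    for v in (q1, q2, q12):
        if not (0.0 <= v <= 1.0 + tol):
            raise ValueError("q values must lie in [0, 1]")
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "nonlinear_enhance"
    if q12 < lo:
        return "nonlinear_weaken"
    if q12 < hi:
        return "univariate_weaken"
    return "bivariate_enhance"


def gd_analysis(table: SampleTable, *, L: int = DEFAULT_STRATA,
                method: str = "quantile") -> pd.DataFrame:
    """Factor q values and all pairwise interactions for one sample table.

    Returns a tidy frame: rows are single factors (factor_b empty) and
    factor pairs, with q / q12 and the interaction category.
    """
    y = table.y
    strata = {n: discretize(table.data[n].to_numpy(), L, method, name=n)
              for n in table.covariate_names}
    qs = {n: q_statistic(y, s).q for n, s in strata.items()}
    rows = [{"factor_a": n, "factor_b": "", "q": qs[n], "category": ""}
            for n in table.covariate_names]
    names = table.covariate_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            q12 = interaction_q(y, strata[a], strata[b]).q
            rows.append({"factor_a": a, "factor_b": b, "q": q12,
                         "category": classify_interaction(qs[a], qs[b], q12)})
    return pd.DataFrame(rows)
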