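"""Random-intercept mixed models, likelihood-ratio tests and BH-FDR.

Neurons reconstructed from the same brain are dependent, so every
morphometric response is modelled as

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, sigma_u^2),
                                      e_ij ~ N(0, sigma_e^2),

with the animal as the random intercept and fluid (EtOH vs H2O), treatment
(CNO vs VEH) and their interaction as fixed effects.  Estimation is maximum
likelihood (not REML) so that likelihood-ratio tests between nested
fixed-effect specifications are valid.  For a given variance ratio
``lambda = sigma_u^2 / sigma_e^2`` both beta and sigma_e^2 have closed-form
profiled solutions; the fit therefore reduces to a 1-D search over
``lambda`` in [0, inf), done on a log-spaced grid refined by golden-section
search, with the boundary ``lambda = 0`` (no animal variance) permitted.

p-values come from likelihood-ratio tests against the chi-square(df)
upper tail; main effects are tested by dropping each term from the additive
model and the interaction by comparing the full model with the additive one
(a type-II convention).  Families of p-values are adjusted with the
Benjamini-Hochberg step-up procedure and reported as q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .morphometry import MORPHOMETRY_PARAMETERS
from .sholl import SHOLL_MEASURES

EFFECTS = ("fluid", "treatment", "interaction")


class SingularDesignError(ValueError):
    """Raised when the fixed-effect design matrix is rank deficient."""


class RandomInterceptLMM(BaseEstimator):
    """Gaussian linear mixed model with one random intercept per group.

    scikit-learn style estimator: ``fit(X, y, groups)`` where X is the
    fixed-effect design (without intercept when ``fit_intercept``), y the
    response and ``groups`` the clustering labels (animals).

    Fitted attributes
    -----------------
    coef_ : fixed-effect estimates for the columns of X
    intercept_ : fitted intercept (0.0 when ``fit_intercept=False``)
    sigma_u2_, sigma_e2_ : between-group and residual variances (ML)
    lambda_ : fitted variance ratio sigma_u2 / sigma_e2
    loglik_ : maximized log-likelihood
    df_model_ : number of fixed-effect coefficients (incl. intercept)
    """

    def __init__(self, fit_intercept: bool = True, grid_size: int = 41,
                 lambda_max: float = 1e4):
        self.fit_intercept = fit_intercept
        self.grid_size = grid_size
        self.lambda_max = lambda_max

    # -- profiled likelihood --------------------------------------------

    def _profile(self, lam: float):
        """beta-hat, sigma_e^2-hat and log-likelihood at fixed lambda."""
        c = lam / (1.0 + lam * self._n_i)           # per-group shrinkage
        A = self._XtX - (self._Sx.T * c) @ self._Sx
        b = self._Xty - self._Sx.T @ (c * self._Sy)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise SingularDesignError(
                "singular fixed-effect design (confounded factors?)")
        yy_v = self._yty - float(c @ (self._Sy ** 2))
        q = yy_v - 2.0 * float(b @ beta) + float(beta @ A @ beta)
        n = self._n
        # relative floor keeps perfectly-fitting (zero-residual) models on a
        # common likelihood scale, so degenerate LRTs come out as exactly 0
        sigma2 = max(q / n, 1e-12 * max(1.0, self._yty / n))
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2)
                     + float(np.sum(np.log1p(lam * self._n_i))) + n)
        return beta, sigma2, ll

    def fit(self, X, y, groups):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) > 1:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if X.size == 0:
            X = np.empty((n, 0))
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
        if X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        codes, _ = pd.factorize(np.asarray(groups))
        if codes.max() + 1 < 2:
            raise ValueError("need >= 2 groups (animals) to fit the LMM")
        if n - X.shape[1] < 1:
            raise ValueError("no residual degrees of freedom")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError(
                "singular fixed-effect design (confounded factors?)")

        G = codes.max() + 1
        self._n = n
        self._n_i = np.bincount(codes, minlength=G).astype(float)
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)
        # per-group column sums of X and y
        Sx = np.zeros((G, X.shape[1]))
        for j in range(X.shape[1]):
            Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=G)
        self._Sx = Sx
        self._Sy = np.bincount(codes, weights=y, minlength=G)

        # 1-D search over lambda: 0 plus a log grid, then golden-section
        grid = np.concatenate([[0.0], np.logspace(
            -4, np.log10(self.lambda_max), self.grid_size)])
        lls = np.array([self._profile(l)[2] for l in grid])
        k = int(np.argmax(lls))
        lam = grid[k]
        if k > 0:
            lo = np.log10(grid[max(k - 1, 1)])
            hi = np.log10(grid[min(k + 1, len(grid) - 1)])
            if hi > lo:
                lam = 10.0 ** _golden_max(
                    lambda t: self._profile(10.0 ** t)[2], lo, hi)
            # the boundary can still win after refinement
            if self._profile(lam)[2] < lls[0]:
                lam = 0.0

        beta, sigma2, ll = self._profile(lam)
        self.lambda_ = float(lam)
        self.sigma_e2_ = float(sigma2)
        self.sigma_u2_ = float(lam * sigma2)
        self.loglik_ = float(ll)
        self.df_model_ = int(X.shape[1])
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.beta_ = beta.copy()
        self.n_groups_ = int(G)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_


def _golden_max(f, lo: float, hi: float, tol: float = 1e-9,
                max_iter: int = 120) -> float:
    """Golden-section maximization of a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# likelihood-ratio test and BH adjustment
# ---------------------------------------------------------------------------

def lrt_stat(loglik_full: float, loglik_reduced: float,
             df: int) -> tuple[float, int, float]:
    """(Lambda, df, p): Lambda = 2*(ll_full - ll_reduced) clipped at zero."""
    lam = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    return lam, df, float(stats.chi2.sf(lam, df))


def lrt(full: RandomInterceptLMM, reduced: RandomInterceptLMM
        ) -> tuple[float, int, float]:
    """Likelihood-ratio test between two fitted nested models."""
    df = full.df_model_ - reduced.df_model_
    if df < 0:
        raise ValueError("reduced model has more fixed effects than full")
    return lrt_stat(full.loglik_, reduced.loglik_, df)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of min(1, m * p_(j) / j) for sorted p-values,
    which enforces monotonicity; single p-values are returned unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[0]
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# design construction and per-response testing
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Treatment-coded design columns for subsets of the 2x2 factors."""
    cols = []
    xf = (df["fluid"].to_numpy() == "EtOH").astype(float)
    xt = (df["treatment"].to_numpy() == "CNO").astype(float)
    for term in terms:
        if term == "fluid":
            cols.append(xf)
        elif term == "treatment":
            cols.append(xt)
        elif term == "interaction":
            cols.append(xf * xt)
        else:
            raise ValueError(f"unknown fixed-effect term {term!r}")
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def fit_random_intercept_lmm(data: pd.DataFrame, response: str,
                             fixed_terms: tuple[str, ...] = (
                                 "fluid", "treatment", "interaction"),
                             group_col: str = "animal_id"
                             ) -> RandomInterceptLMM:
    """Fit the model for one response column of a tidy observation table."""
    model = RandomInterceptLMM()
    model.fit(_design(data, fixed_terms), data[response].to_numpy(),
              data[group_col].to_numpy())
    model.fixed_terms_ = tuple(fixed_terms)
    return model


@dataclass(frozen=True)
class LmmResult:
    """Per-effect inference for one response under the nested model."""
    response: str
    effect: str
    beta: float
    sigma_u2: float
    sigma_e2: float
    loglik: float
    lrt: float
    df: int
    p: float
    q: float = np.nan


def test_effects(data: pd.DataFrame, response: str,
                 group_col: str = "animal_id") -> list[LmmResult]:
    """Fluid, treatment and interaction LRTs for one response.

    The interaction is tested against the additive model; each main effect
    by dropping its term from the additive model.
    """
    full = fit_random_intercept_lmm(
        data, response, ("fluid", "treatment", "interaction"), group_col)
    additive = fit_random_intercept_lmm(
        data, response, ("fluid", "treatment"), group_col)
    out = []
    lam, df, p = lrt(full, additive)
    out.append(LmmResult(response, "interaction", full.coef_[2],
                         full.sigma_u2_, full.sigma_e2_, full.loglik_,
                         lam, df, p))
    for term, kept, idx in (("fluid", ("treatment",), 0),
                            ("treatment", ("fluid",), 1)):
        reduced = fit_random_intercept_lmm(data, response, kept, group_col)
        lam, df, p = lrt(additive, reduced)
        out.append(LmmResult(response, term, additive.coef_[idx],
                             additive.sigma_u2_, additive.sigma_e2_,
                             additive.loglik_, lam, df, p))
    return out


# ---------------------------------------------------------------------------
# full morphology analysis
# ---------------------------------------------------------------------------

@dataclass
class MorphologyResults:
    """Tidy inference tables plus a human-readable report.

    ``scalar``: the eight morphometric parameters (BH family = the
    parameters, within each effect).  ``sholl``: per-radius tests (BH family
    = radii within one measure and effect).  ``auc``: Sholl AUCs (BH family
    = the four measures within each effect).
    """
    scalar: pd.DataFrame
    sholl: pd.DataFrame = field(default_factory=pd.DataFrame)
    auc: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = 0.05

    def report(self) -> str:
        lines = [
            "Nested morphology analysis (random-intercept LMM, ML, LRT)",
            "FDR families: morphometric parameters within each effect; "
            "Sholl radii within each measure and effect; Sholl AUC "
            "measures within each effect.",
            f"Significance tiers at alpha = {self.alpha}: "
            "'q<a' (survives FDR), 'p<a' (nominal only), 'ns'.",
            "",
        ]
        for name, tab in (("Morphometric parameters", self.scalar),
                          ("Sholl AUC", self.auc)):
            if tab.empty:
                continue
            lines.append(f"== {name} ==")
            for _, r in tab.iterrows():
                lines.append(
                    f"  {r['response']:<22s} {r['effect']:<12s} "
                    f"beta={r['beta']:+.4g} LRT={r['lrt']:.3f} "
                    f"p={r['p']:.4g} q={r['q']:.4g} [{r['tier']}]")
            lines.append("")
        if not self.sholl.empty:
            sig = self.sholl[self.sholl["tier"] != "ns"]
            lines.append(f"== Sholl radii == ({len(self.sholl)} tests, "
                         f"{len(sig)} below alpha before/after FDR)")
        return "\n".join(lines)


def _tiers(p: np.ndarray, q: np.ndarray, alpha: float) -> list[str]:
    return ["q<a" if qq < alpha else ("p<a" if pp < alpha else "ns")
            for pp, qq in zip(p, q)]


def _check_cells(manifest: pd.DataFrame, table: pd.DataFrame,
                 what: str) -> None:
    missing = set(manifest["cell_id"]) - set(table["cell_id"])
    if missing:
        raise KeyError(
            f"cell id(s) missing from the {what} table: "
            f"{', '.join(sorted(missing))}")


def run_morphometry_analysis(manifest: pd.DataFrame,
                             morphometry: pd.DataFrame,
                             sholl_long: pd.DataFrame | None = None,
                             sholl_auc: pd.DataFrame | None = None,
                             alpha: float = 0.05) -> MorphologyResults:
    """Fluid/treatment/interaction inference across all morphology outputs.

    Parameters with zero variance are skipped with a warning.  Every
    manifest cell must appear in each supplied table (hard error naming the
    missing cells otherwise).
    """
    _check_cells(manifest, morphometry, "morphometry")
    meta_cols = ["cell_id", "animal_id", "fluid", "treatment"]
    merged = manifest[meta_cols].merge(morphometry, on="cell_id")

    rows = []
    params = [p for p in MORPHOMETRY_PARAMETERS if p in morphometry.columns]
    for param in params:
        if np.var(merged[param].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"parameter {param!r} has zero variance; skipped",
                          stacklevel=2)
            continue
        rows.extend(test_effects(merged, param))
    scalar = pd.DataFrame([r.__dict__ for r in rows])
    if not scalar.empty:
        scalar = scalar.rename(columns={"response": "response"})
        qs = np.empty(len(scalar))
        for eff in EFFECTS:
            mask = scalar["effect"] == eff
            qs[mask.to_numpy()] = bh_adjust(scalar.loc[mask, "p"].to_numpy())
        scalar["q"] = qs
        scalar["tier"] = _tiers(scalar["p"].to_numpy(), qs, alpha)

    sholl_res = pd.DataFrame()
    if sholl_long is not None and not sholl_long.empty:
        _check_cells(manifest, sholl_long, "Sholl")
        srows = []
        for measure in SHOLL_MEASURES:
            sub = sholl_long[sholl_long["measure"] == measure]
            for radius in sorted(sub["radius"].unique()):
                shell = sub[sub["radius"] == radius][["cell_id", "value"]]
                data = manifest[meta_cols].merge(shell, on="cell_id",
                                                 how="left")
                data["value"] = data["value"].fillna(0.0)
                if np.var(data["value"].to_numpy()) == 0.0:
                    continue
                for r in test_effects(data, "value"):
                    srows.append({"measure": measure, "radius": radius,
                                  **r.__dict__})
        sholl_res = pd.DataFrame(srows)
        if not sholl_res.empty:
            qs = np.empty(len(sholl_res))
            for measure in SHOLL_MEASURES:
                for eff in EFFECTS:
                    mask = ((sholl_res["measure"] == measure)
                            & (sholl_res["effect"] == eff)).to_numpy()
                    if mask.any():
                        qs[mask] = bh_adjust(
                            sholl_res.loc[mask, "p"].to_numpy())
            sholl_res["q"] = qs
            sholl_res["tier"] = _tiers(sholl_res["p"].to_numpy(), qs, alpha)

    auc_res = pd.DataFrame()
    if sholl_auc is not None and not sholl_auc.empty:
        _check_cells(manifest, sholl_auc, "Sholl AUC")
        merged_auc = manifest[meta_cols].merge(sholl_auc, on="cell_id")
        arows = []
        for m in SHOLL_MEASURES:
            col = f"auc_{m}"
            if col not in merged_auc.columns:
                continue
            if np.var(merged_auc[col].to_numpy(dtype=float)) == 0.0:
                warnings.warn(f"{col} has zero variance; skipped",
                              stacklevel=2)
                continue
            arows.extend(test_effects(merged_auc, col))
        auc_res = pd.DataFrame([r.__dict__ for r in arows])
        if not auc_res.empty:
            qs = np.empty(len(auc_res))
            for eff in EFFECTS:
                mask = (auc_res["effect"] == eff).to_numpy()
                qs[mask] = bh_adjust(auc_res.loc[mask, "p"].to_numpy())
            auc_res["q"] = qs
            auc_res["tier"] = _tiers(auc_res["p"].to_numpy(), qs, alpha)

    return MorphologyResults(scalar=scalar, sholl=sholl_res, auc=auc_res,
                             alpha=alpha)
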