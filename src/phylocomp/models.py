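"""Phylogenetic regression models.

Two estimators for the association between continuous traits measured on the
tips of a phylogeny:

``PGLS``
    Generalized least squares whose error covariance is proportional to the
    (lambda-transformed) phylogenetic VCV matrix.  Pagel's lambda may be held
    fixed or profiled out by maximum likelihood over [0, 1].

``ContrastRegression``
    Regression through the origin on Felsenstein's standardized independent
    contrasts; under Brownian motion its slope is identical to the PGLS
    (lambda = 1) slope.

Both follow the statsmodels convention: a model object is built from data
and ``fit()`` returns a results object carrying estimates, standard errors,
t statistics, p-values and a ``summary()`` table.

Degrees of freedom
------------------
The study this package reproduces fixed df = n_taxa - 3 for its n = 14
analyses (one df for computing contrasts, two for slope and intercept).
``df_convention="paper"`` applies that rule; ``"standard"`` uses the usual
n - (k + 1) for PGLS and n_contrasts - 1 for contrast regression.  The
chosen df is used both as the residual-variance denominator and as the
Student-t reference df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .contrasts import ContrastSet, felsenstein_contrasts
from .tree import PhyloCovariance, PhyloTree

__all__ = [
    "PGLS",
    "PGLSResults",
    "ContrastRegression",
    "ContrastRegressionResults",
    "CorrelationResult",
    "pearson_correlation",
    "student_t_two_tailed_p",
    "fic_regression",
    "pgls_fit",
    "estimate_lambda_ml",
    "pgls_residualize",
    "LambdaProfile",
]

_LAMBDA_GRID_POINTS = 41
_LAMBDA_TOL = 1e-6


def student_t_two_tailed_p(t: float, df: int) -> float:
    """Two-tailed Student-t p-value via the regularized incomplete beta.

    p = I_x(df/2, 1/2) with x = df / (df + t^2), which equals
    2 * (1 - CDF(|t|; df)).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = float(t)
    if not np.isfinite(t):
        return 0.0
    if t == 0.0:
        return 1.0
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


# ---------------------------------------------------------------------
# PGLS


def _whiten(V: np.ndarray):
    """Cholesky factor and log-determinant of a covariance matrix."""
    L = np.linalg.cholesky(V)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return L, logdet


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS normal equations solved through the Cholesky whitening route."""
    L, logdet = _whiten(V)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    q, r = np.linalg.qr(Xw)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(r))):
        raise np.linalg.LinAlgError("singular whitened design matrix")
    beta = linalg.solve_triangular(r, q.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    rinv = linalg.solve_triangular(r, np.eye(r.shape[0]))
    xtx_inv = rinv @ rinv.T
    return beta, rss, xtx_inv, logdet, yw, Xw, resid_w


def _profile_llf(y, X, V) -> float:
    """Gaussian log-likelihood with sigma^2 profiled out (ML)."""
    n = len(y)
    _, rss, _, logdet, _, _, _ = _gls_core(y, X, V)
    sigma2 = rss / n
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


@dataclass
class LambdaProfile:
    """Profile log-likelihood of Pagel's lambda over [0, 1]."""

    lambdas: np.ndarray
    log_likelihoods: np.ndarray
    lambda_hat: float
    flat: bool = False  # star tree: likelihood does not depend on lambda


@dataclass
class PGLSResults:
    """Fitted phylogenetic GLS regression.

    Attributes mirror statsmodels results: ``params``, ``bse``, ``tvalues``,
    ``pvalues`` are indexed by predictor name; ``lambda_`` is the Pagel's
    lambda in force (fixed or ML); ``llf`` is the ML log-likelihood with
    sigma^2 profiled out; ``resid`` are raw-scale residuals in taxon order.
    """

    params: pd.Series
    bse: pd.Series
    df_resid: int
    lambda_: float
    lambda_mode: str
    sigma2: float
    llf: float
    resid: pd.Series
    rsquared: float
    nobs: int
    df_convention: str
    lambda_profile: LambdaProfile | None = None

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues
        return pd.Series(
            [student_t_two_tailed_p(v, self.df_resid) for v in t], index=t.index
        )

    def summary(self) -> str:
        lines = [
            "Phylogenetic GLS regression",
            "=" * 62,
            f"n obs: {self.nobs:>5d}    df resid: {self.df_resid:>3d} "
            f"({self.df_convention})",
            f"lambda: {self.lambda_:.6f} ({self.lambda_mode})    "
            f"sigma2: {self.sigma2:.6g}    logLik: {self.llf:.4f}",
            f"R2 (squared corr): {self.rsquared:.4f}",
            "-" * 62,
            f"{'':>14s}{'coef':>12s}{'std err':>12s}{'t':>10s}{'P>|t|':>12s}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:>14s}{self.params[name]:>12.6f}{self.bse[name]:>12.6f}"
                f"{self.tvalues[name]:>10.4f}{self.pvalues[name]:>12.6g}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)


class PGLS:
    """Phylogenetic generalized least squares with Pagel's lambda.

    Parameters
    ----------
    endog
        Response values, one per taxon (pandas Series indexed by taxon, or
        array aligned with ``vcv.taxa``).
    exog
        Predictor columns (DataFrame indexed by taxon, or 2-D array aligned
        with ``vcv.taxa``).  An intercept column is added automatically.
    vcv
        Untransformed phylogenetic covariance (:class:`PhyloCovariance`) or a
        :class:`PhyloTree` from which it is built.

    Examples
    --------
    >>> model = PGLS.from_dataframe(df, "log_lifespan", ["gene_count"], tree)
    >>> res = model.fit(lam=1.0)
    >>> res.pvalues["gene_count"]
    """

    def __init__(self, endog, exog, vcv: PhyloCovariance | PhyloTree):
        if isinstance(vcv, PhyloTree):
            vcv = vcv.vcv()
        if vcv.lambda_applied is not None:
            raise ValueError("PGLS expects the untransformed covariance")
        self.vcv = vcv
        taxa = vcv.taxa
        if isinstance(endog, pd.Series):
            if sorted(endog.index) != sorted(taxa):
                raise ValueError("endog taxa do not match covariance taxa")
            endog = endog.loc[taxa]
            self.endog_name = endog.name or "y"
        else:
            self.endog_name = "y"
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.Series):
            exog = exog.to_frame(exog.name or "x1")
        if isinstance(exog, pd.DataFrame):
            if sorted(exog.index) != sorted(taxa):
                raise ValueError("exog taxa do not match covariance taxa")
            exog = exog.loc[taxa]
            self.exog_names = ["const"] + list(exog.columns)
        else:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != len(taxa):
                exog = exog.T
            self.exog_names = ["const"] + [f"x{i+1}" for i in range(exog.shape[1])]
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.exog = np.column_stack([np.ones(len(taxa)), X])
        if self.endog.shape[0] != len(taxa) or self.exog.shape[0] != len(taxa):
            raise ValueError("trait length does not match taxon count")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, predictors: list[str],
        tree: PhyloTree | PhyloCovariance,
    ) -> "PGLS":
        """Build a PGLS model from a taxon-indexed DataFrame."""
        return cls(data[response], data[list(predictors)], tree)

    # -- lambda machinery ---------------------------------------------

    def _v_at(self, lam: float) -> np.ndarray:
        return self.vcv.transform(lam).matrix

    def profile_lambda(self, n_grid: int = _LAMBDA_GRID_POINTS) -> LambdaProfile:
        """Profile the log-likelihood over lambda in [0, 1].

        Coarse grid followed by bounded refinement to 1e-6.  On a star tree
        (all off-diagonals zero) the likelihood is flat in lambda; the
        profile is flagged and ``lambda_hat`` reported as NaN.
        """
        V0 = self.vcv.matrix
        off = V0 - np.diag(np.diag(V0))
        if np.max(np.abs(off)) <= 1e-12 * max(np.max(np.diag(V0)), 1.0):
            grid = np.linspace(0, 1, n_grid)
            ll = np.full(n_grid, _profile_llf(self.endog, self.exog, V0))
            return LambdaProfile(grid, ll, float("nan"), flat=True)
        grid = np.linspace(0.0, 1.0, n_grid)
        ll = np.array(
            [_profile_llf(self.endog, self.exog, self._v_at(l)) for l in grid]
        )
        i = int(np.argmax(ll))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            lambda l: -_profile_llf(self.endog, self.exog, self._v_at(l)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _LAMBDA_TOL},
        )
        cand = {float(res.x): -float(res.fun)}
        # boundary maxima reported exactly as 0 or 1
        for b in (0.0, 1.0):
            cand[b] = float(ll[0] if b == 0.0 else ll[-1])
        lam_hat = max(cand, key=lambda k: cand[k])
        return LambdaProfile(grid, ll, float(lam_hat), flat=False)

    # -- fitting -------------------------------------------------------

    def _df_resid(self, df_convention: str) -> int:
        n, k = self.exog.shape
        if df_convention == "paper":
            return n - 3
        if df_convention == "standard":
            return n - k
        raise ValueError(f"unknown df convention {df_convention!r}")

    def fit(self, lam: float | str = 1.0, df_convention: str = "standard") -> PGLSResults:
        """Fit the GLS regression under lambda ``lam`` (or ``"ml"``)."""
        profile = None
        mode = "fixed"
        if isinstance(lam, str):
            if lam != "ml":
                raise ValueError(f"lam must be a float in [0,1] or 'ml', got {lam!r}")
            profile = self.profile_lambda()
            if profile.flat:
                raise ValueError(
                    "lambda is indeterminate on a star tree (flat likelihood)"
                )
            lam_val = profile.lambda_hat
            mode = "ml"
        else:
            lam_val = float(lam)
        V = self._v_at(lam_val)
        y, X = self.endog, self.exog
        try:
            beta, rss, xtx_inv, logdet, yw, Xw, resid_w = _gls_core(y, X, V)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular whitened design: {self.exog_names}") from exc
        n = len(y)
        df = self._df_resid(df_convention)
        if df < 1:
            raise ValueError("non-positive residual degrees of freedom")
        sigma2_hat = rss / df
        bse = np.sqrt(np.diag(xtx_inv) * sigma2_hat)
        sigma2_ml = rss / n
        llf = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
        fitted = X @ beta
        if np.std(fitted) > 0 and np.std(y) > 0:
            r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        else:
            r2 = 0.0
        taxa = self.vcv.taxa
        return PGLSResults(
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            df_resid=df,
            lambda_=lam_val,
            lambda_mode=mode,
            sigma2=sigma2_ml,
            llf=llf,
            resid=pd.Series(y - fitted, index=taxa),
            rsquared=r2,
            nobs=n,
            df_convention=df_convention,
            lambda_profile=profile,
        )


# ---------------------------------------------------------------------
# Contrast regression


@dataclass
class ContrastRegressionResults:
    """Regression through the origin on positivized contrast pairs."""

    slope: float
    bse: float
    df_resid: int
    nobs: int
    n_taxa: int
    rss: float
    df_convention: str

    @property
    def tvalue(self) -> float:
        return self.slope / self.bse if self.bse > 0 else np.inf

    @property
    def pvalue(self) -> float:
        return student_t_two_tailed_p(self.tvalue, self.df_resid)

    def summary(self) -> str:
        return (
            "Independent-contrasts regression (through origin)\n"
            f"contrast pairs: {self.nobs}   taxa: {self.n_taxa}   "
            f"df: {self.df_resid} ({self.df_convention})\n"
            f"slope {self.slope:.6f}  se {self.bse:.6f}  "
            f"t {self.tvalue:.4f}  p {self.pvalue:.6g}"
        )


class ContrastRegression:
    """Slope of y-contrasts on x-contrasts, forced through the origin.

    Contrast pairs are positivized on the x variable (both members of a pair
    flipped so the x-contrast is >= 0; exact-zero x-contrasts keep their
    original orientation), the standard convention that makes the regression
    invariant to the arbitrary sign of each contrast.
    """

    def __init__(self, x_contrasts: ContrastSet, y_contrasts: ContrastSet):
        if x_contrasts.node_ids != y_contrasts.node_ids:
            raise ValueError("contrast sets come from different trees/orders")
        sign = np.where(x_contrasts.contrasts < 0, -1.0, 1.0)
        self.x = x_contrasts.contrasts * sign
        self.y = y_contrasts.contrasts * sign
        self.n_taxa = x_contrasts.n_taxa

    @classmethod
    def from_traits(cls, tree: PhyloTree, x, y) -> "ContrastRegression":
        return cls(felsenstein_contrasts(tree, x), felsenstein_contrasts(tree, y))

    def fit(self, df_convention: str = "standard") -> ContrastRegressionResults:
        sxx = float(self.x @ self.x)
        if sxx == 0.0:
            raise ValueError("degenerate fit: all x-contrasts are zero")
        slope = float(self.x @ self.y) / sxx
        rss = float(np.sum((self.y - slope * self.x) ** 2))
        if df_convention == "paper":
            df = self.n_taxa - 3
        elif df_convention == "standard":
            df = len(self.x) - 1
        else:
            raise ValueError(f"unknown df convention {df_convention!r}")
        if df < 1:
            raise ValueError("non-positive residual degrees of freedom")
        bse = float(np.sqrt(rss / df / sxx))
        return ContrastRegressionResults(
            slope=slope,
            bse=bse,
            df_resid=df,
            nobs=len(self.x),
            n_taxa=self.n_taxa,
            rss=rss,
            df_convention=df_convention,
        )


# ---------------------------------------------------------------------
# Ordinary correlation


@dataclass
class CorrelationResult:
    r: float
    r2: float
    n: int
    t: float
    df: int
    p: float


def pearson_correlation(x, y, df_convention: str = "standard") -> CorrelationResult:
    """Pearson correlation with the study's t-test df convention.

    t = r * sqrt(df) / sqrt(1 - r^2); df is n - 2 ("standard") or n - 3
    ("paper").  A perfect correlation yields p = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if df_convention == "paper":
        df = n - 3
    elif df_convention == "standard":
        df = n - 2
    else:
        raise ValueError(f"unknown df convention {df_convention!r}")
    r2 = r * r
    if r2 >= 1.0:
        return CorrelationResult(r=r, r2=r2, n=n, t=np.inf, df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r2)
    return CorrelationResult(
        r=r, r2=r2, n=n, t=float(t), df=df, p=student_t_two_tailed_p(t, df)
    )


# ---------------------------------------------------------------------
# Functional wrappers


def fic_regression(
    x_contrasts: ContrastSet, y_contrasts: ContrastSet,
    df_convention: str = "standard",
) -> ContrastRegressionResults:
    return ContrastRegression(x_contrasts, y_contrasts).fit(df_convention)


def pgls_fit(
    endog, exog, V: PhyloCovariance | PhyloTree,
    lam: float | str = 1.0, df_convention: str = "standard",
) -> PGLSResults:
    return PGLS(endog, exog, V).fit(lam=lam, df_convention=df_convention)


def estimate_lambda_ml(endog, exog, V: PhyloCovariance | PhyloTree) -> LambdaProfile:
    return PGLS(endog, exog, V).profile_lambda()


def pgls_residualize(
    trait, covariate, V: PhyloCovariance | PhyloTree, lam: float = 1.0
) -> pd.Series:
    """Residuals of ``trait`` on ``covariate`` (with intercept) under PGLS.

    Used pairwise to draw residual--residual scatter plots: regress each of
    two traits on a nuisance covariate under the same phylogenetic
    covariance, then correlate the residuals.
    """
    res = PGLS(trait, covariate, V).fit(lam=lam)
    return res.resid
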