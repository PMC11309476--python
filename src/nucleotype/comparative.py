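"""Phylogenetic comparative statistics.

PGLS regression with Pagel's lambda (fixed or profiled by maximum
likelihood), the likelihood-ratio test of phylogenetic signal, and the two
rank statistics used alongside them (Spearman correlation, Wilcoxon rank-sum
with exact small-sample p-values).

The lambda profile is evaluated efficiently by a one-off eigendecomposition
of the phylogenetic correlation matrix R: with V(lambda) =
D^1/2 (lambda R + (1 - lambda) I) D^1/2 and R = Q Lam Q', every candidate
lambda costs O(n k^2) after whitening through Q' D^-1/2, instead of a fresh
O(n^3) factorisation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import Phylogeny, PhyloCovariance, phylo_covariance

__all__ = [
    "PGLSFit",
    "SignalResult",
    "pgls_fit",
    "pagel_lambda_signal",
    "spearman_rho",
    "wilcoxon_rank_sum",
    "LambdaGLS",
]

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-12


class LambdaGLS:
    """Reusable GLS engine for one covariance matrix.

    Holds the eigendecomposition of the phylogenetic correlation matrix so
    that likelihood evaluations across lambda are cheap. Construct once per
    tree/data alignment and reuse across regressions (the d-separation tests
    of the path-analysis module rely on this).
    """

    def __init__(self, cov: np.ndarray):
        cov = np.asarray(cov, dtype=float)
        d = np.diag(cov)
        if np.any(d <= 0):
            raise ValueError("covariance diagonal must be positive")
        self._sqrt_d = np.sqrt(d)
        corr = cov / np.outer(self._sqrt_d, self._sqrt_d)
        eigval, eigvec = np.linalg.eigh(corr)
        self._eigval = np.maximum(eigval, _EIG_FLOOR)
        self._eigvec = eigvec
        self._logdet_d = float(np.sum(np.log(d)))
        self.n = cov.shape[0]

    def whiten_basis(self, arr: np.ndarray) -> np.ndarray:
        """Rotate data into the eigenbasis (columns treated independently)."""
        if arr.ndim == 1:
            return self._eigvec.T @ (arr / self._sqrt_d)
        return self._eigvec.T @ (arr / self._sqrt_d[:, None])

    def _weights_logdet(self, lam: float) -> tuple[np.ndarray, float]:
        v = lam * self._eigval + (1.0 - lam)
        v = np.maximum(v, _EIG_FLOOR)
        return 1.0 / v, float(np.sum(np.log(v))) + self._logdet_d

    def gls(self, ytil: np.ndarray, xtil: np.ndarray, lam: float):
        """GLS fit in the whitened basis at a given lambda.

        Returns (beta, XtWX_inv, rss, logdetV, loglik_ML).
        """
        w, logdet = self._weights_logdet(lam)
        xw = xtil * w[:, None]
        xtwx = xtil.T @ xw
        xtwy = xw.T @ ytil
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix") from exc
        beta = xtwx_inv @ xtwy
        resid = ytil - xtil @ beta
        rss = float(resid @ (w * resid))
        n = self.n
        sigma2_ml = max(rss / n, 1e-300)
        loglik = -0.5 * (n * (math.log(2 * math.pi) + math.log(sigma2_ml) + 1.0) + logdet)
        return beta, xtwx_inv, rss, logdet, loglik

    def profile_lambda(self, ytil: np.ndarray, xtil: np.ndarray) -> float:
        """ML estimate of lambda on [0, 1] for a given response/design."""

        def neg_ll(lam: float) -> float:
            return -self.gls(ytil, xtil, lam)[4]

        res = optimize.minimize_scalar(
            neg_ll, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        best_lam, best_val = float(res.x), float(res.fun)
        # bounded Brent can miss boundary optima; check the endpoints
        for lam in (0.0, 1.0):
            v = neg_ll(lam)
            if v < best_val:
                best_lam, best_val = lam, v
        return best_lam


@dataclass
class PGLSFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    tvalues: pd.Series
    lambda_hat: float
    sigma2: float
    log_likelihood: float
    r2: float
    n: int
    df_resid: int
    response: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )


def _align(tree: Phylogeny, data: pd.DataFrame, columns: list[str]):
    """Prune tree/data to complete cases, warn about dropped species.

    Returns (cov_matrix, aligned_frame) with rows in sorted tip order.
    """
    if data.index.has_duplicates:
        raise ValueError("trait table has duplicated species")
    tips = set(tree.tip_labels)
    present = data.loc[data.index.isin(tips), columns].dropna()
    dropped = sorted(tips - set(present.index))
    if dropped:
        logger.warning(
            "dropping %d species without complete data: %s", len(dropped), dropped
        )
        if len(tips) - len(dropped) < 3:
            raise ValueError("fewer than 3 species with complete data")
        tree = tree.prune_to(list(present.index))
    cov = phylo_covariance(tree)
    return cov.matrix, present.loc[cov.labels]


def pgls_fit(
    tree: Phylogeny,
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    lam: "float | str" = "ML",
    engine: LambdaGLS | None = None,
) -> PGLSFit:
    """Phylogenetic generalized least squares.

    ``data`` is indexed by species. With ``lam='ML'`` Pagel's lambda is
    profiled on [0, 1]; a float fixes it. The error covariance is the
    lambda-scaled Brownian matrix of the (pruned) tree. r^2 is computed in
    the V-whitened space against the GLS intercept-only fit.
    """
    cols = [response] + list(predictors)
    if engine is None:
        covmat, frame = _align(tree, data, cols)
        engine = LambdaGLS(covmat)
    else:
        frame = data[cols]
        if len(frame) != engine.n or frame.isna().any().any():
            raise ValueError("pre-built engine requires complete, aligned data")
    n = len(frame)
    k = len(predictors) + 1
    if n <= k:
        raise ValueError(f"need more species ({n}) than parameters ({k})")
    y = frame[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] + [frame[p].to_numpy(dtype=float) for p in predictors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"singular design matrix: columns {['intercept'] + list(predictors)} "
            "are collinear"
        )
    ytil = engine.whiten_basis(y)
    xtil = engine.whiten_basis(X)

    if lam == "ML":
        lam_hat = engine.profile_lambda(ytil, xtil)
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
    beta, xtwx_inv, rss, _, loglik = engine.gls(ytil, xtil, lam_hat)

    df_resid = n - k
    s2 = rss / df_resid
    se = np.sqrt(s2 * np.diag(xtwx_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    # r^2 against the GLS intercept-only model in the same whitened space
    ones_til = engine.whiten_basis(np.ones(n))
    _, _, tss, _, _ = engine.gls(ytil, ones_til[:, None], lam_hat)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    names = ["intercept"] + list(predictors)
    return PGLSFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        tvalues=pd.Series(tvals, index=names),
        lambda_hat=lam_hat,
        sigma2=rss / n,
        log_likelihood=loglik,
        r2=float(min(max(r2, 0.0), 1.0)),
        n=n,
        df_resid=df_resid,
        response=response,
    )


@dataclass
class SignalResult:
    lambda_hat: float
    logL_at_hat: float
    logL_at_zero: float
    lr_statistic: float
    p_value: float
    n: int


def pagel_lambda_signal(tree: Phylogeny, trait: "pd.Series | dict") -> SignalResult:
    """Pagel's lambda phylogenetic signal of a single trait.

    lambda is profiled by ML in the intercept-only model; the p-value is the
    chi-square(1) likelihood-ratio test of lambda = 0 against lambda-hat.
    """
    trait = pd.Series(trait, dtype=float)
    frame = trait.to_frame("trait")
    covmat, frame = _align(tree, frame, ["trait"])
    y = frame["trait"].to_numpy()
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant: signal likelihood is degenerate")
    engine = LambdaGLS(covmat)
    n = len(y)
    ytil = engine.whiten_basis(y)
    xtil = engine.whiten_basis(np.ones(n))[:, None]
    lam_hat = engine.profile_lambda(ytil, xtil)
    ll_hat = engine.gls(ytil, xtil, lam_hat)[4]
    ll_zero = engine.gls(ytil, xtil, 0.0)[4]
    lr = max(2.0 * (ll_hat - ll_zero), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(lam_hat, ll_hat, ll_zero, lr, p, n)


def _rank_average(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p for n <= 10.

    Larger samples use the usual t approximation. Ties receive average
    ranks in both branches.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    if n > 10:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rx = _rank_average(x)
    ry = _rank_average(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    rho_obs = float(rx_c @ ry_c) / denom
    # exact permutation null: all orderings of y's ranks against x's ranks
    perms = np.array(list(itertools.permutations(ry_c)))
    rhos = perms @ rx_c / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of the first sample (average ranks for ties). The
    p-value is exact by enumeration when n_a + n_b <= 12 (twice the smaller
    tail, capped at 1), otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _rank_average(pooled)
    w = float(ranks[:na].sum())
    n = na + nb
    if n <= 12:
        sums = np.array([
            sum(c) for c in itertools.combinations(ranks, na)
        ])
        lo = np.mean(sums <= w + 1e-12)
        hi = np.mean(sums >= w - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        return w, float(p)
    mean_w = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return w, float(min(p, 1.0))
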