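"""Species abundance tables and phylogenetic gamma regression.

The observational layer turns long-format OTU counts into per-sample
proportions, aggregates OTUs to species, and applies a prevalence filter.
The model layer fits a Bayesian gamma regression with a log link,

    y_si ~ Gamma(shape alpha, mean mu_si),
    log mu_si = x_s' beta + u_i,      u ~ MVN(0, phylo_sd^2 R),

where R is the phylogenetic correlation matrix (Brownian covariance scaled
to unit diagonal) and the fixed effects encode one of three environment
interactions with genome size: temperature (linear, temp x gs), ocean
region (region main effects and region x gs), or latitude (cubic B-spline
varying-coefficient smooth). Continuous covariates are centered, except
latitude and the response.

Posterior sampling is by an adaptive random-walk Metropolis-within-Gibbs
sampler with a non-centered parameterization of the species effects
(u = phylo_sd * L z with L the Cholesky factor of R), blocked as: fixed
effects (multivariate adaptive proposal), species effects in sub-blocks,
and the two scalars (log phylo_sd, log shape). Priors are weakly
informative: Normal(0, 5) on regression coefficients (Normal(0, 1) ridge
on spline coefficients), half-Normal(0, 2) on phylo_sd, Exponential(1) on
the gamma shape.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, special

from .phylo import Phylogeny, lambda_transform, phylo_covariance

__all__ = [
    "counts_to_relative",
    "aggregate_species",
    "filter_prevalence",
    "AbundanceFit",
    "fit_gamma_abundance",
    "significance",
    "predict_interaction",
    "bayes_r2",
    "DEFAULT_TEMPERATURE_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE_GRID = (0.0, 10.0, 20.0, 30.0)
VARIANTS = ("latitude", "region", "temperature")


# ---------------------------------------------------------------------------
# observational layer


def counts_to_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each OTU count by its sample's total count.

    Expects columns ``otu_id, sample_id, count``; adds ``proportion``.
    """
    if (table["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = table.groupby("sample_id")["count"].transform("sum")
    zero = table.loc[totals == 0, "sample_id"].unique()
    if len(zero):
        raise ValueError(f"samples with zero total count: {sorted(zero)}")
    out = table.copy()
    out["proportion"] = out["count"] / totals
    return out


def aggregate_species(
    table: pd.DataFrame, assignments: "dict[str, str] | None" = None
) -> pd.DataFrame:
    """Sum OTU proportions per species per sample.

    OTU-to-species assignments come either from an explicit map or a
    ``species`` column; unassigned OTUs are dropped (with a logged count).
    Returns columns ``species, sample_id, rel_abundance``.
    """
    df = table.copy()
    if assignments is not None:
        df["species"] = df["otu_id"].map(assignments)
    if "species" not in df.columns:
        raise ValueError("need OTU->species assignments or a species column")
    df["species"] = df["species"].replace("", np.nan)
    if "proportion" not in df.columns:
        # proportions are relative to the whole sample, so normalize before
        # dropping unassigned OTUs
        df = counts_to_relative(df)
    n_drop = int(df["species"].isna().sum())
    if n_drop:
        logger.info("dropping %d OTU rows without species assignment", n_drop)
    df = df.dropna(subset=["species"])
    agg = (
        df.groupby(["species", "sample_id"], sort=True)["proportion"]
        .sum()
        .reset_index()
        .rename(columns={"proportion": "rel_abundance"})
    )
    return agg[agg["rel_abundance"] > 0].reset_index(drop=True)


def filter_prevalence(table: pd.DataFrame, min_samples: int = 10) -> pd.DataFrame:
    """Keep species detected (rel_abundance > 0) in >= min_samples samples."""
    pos = table[table["rel_abundance"] > 0]
    counts = pos.groupby("species")["sample_id"].nunique()
    keep = counts[counts >= min_samples].index
    return table[table["species"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# design matrices


def _spline_basis(lat: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k = 3
    x = np.clip(lat, knots[k], knots[-k - 1])
    return interpolate.BSpline.design_matrix(x, knots, k).toarray()


@dataclass
class _DesignContext:
    variant: str
    gs_mean: float
    temp_mean: float = 0.0
    regions: tuple[str, ...] = ()
    knots: np.ndarray | None = None
    lat_range: tuple[float, float] = (0.0, 0.0)
    gs_range: tuple[float, float] = (0.0, 0.0)


def _make_context(df: pd.DataFrame, variant: str, n_knots: int = 8) -> _DesignContext:
    gs = df["genome_size_log10"].to_numpy(dtype=float)
    ctx = _DesignContext(variant=variant, gs_mean=float(gs.mean()))
    ctx.gs_range = (float(gs.min()), float(gs.max()))
    if variant == "temperature":
        ctx.temp_mean = float(df["temperature_c"].mean())
    elif variant == "region":
        ctx.regions = tuple(sorted(df["ocean_region"].unique()))
        if len(ctx.regions) < 2:
            raise ValueError("region variant needs >= 2 ocean regions")
    elif variant == "latitude":
        lat = df["latitude_deg"].to_numpy(dtype=float)
        lo, hi = float(lat.min()), float(lat.max())
        interior = np.quantile(lat, np.linspace(0, 1, n_knots + 2)[1:-1])
        ctx.knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
        ctx.lat_range = (lo, hi)
    else:
        raise ValueError(f"unknown variant {variant!r}; use one of {VARIANTS}")
    return ctx


def _design(df: pd.DataFrame, ctx: _DesignContext):
    """Build (X, column names, prior sds) for the fixed effects."""
    n = len(df)
    g = df["genome_size_log10"].to_numpy(dtype=float) - ctx.gs_mean
    ones = np.ones(n)
    if ctx.variant == "temperature":
        t = df["temperature_c"].to_numpy(dtype=float) - ctx.temp_mean
        X = np.column_stack([ones, t, g, t * g])
        names = ["intercept", "temperature_c", "genome_size", "temperature_c:genome_size"]
        prior_sd = np.full(4, 5.0)
    elif ctx.variant == "region":
        reg = df["ocean_region"].astype(str)
        unknown = set(reg) - set(ctx.regions)
        if unknown:
            raise ValueError(f"regions not seen at fit time: {sorted(unknown)}")
        cols, names = [ones], ["intercept"]
        for r in ctx.regions[1:]:
            cols.append((reg == r).to_numpy(dtype=float))
            names.append(f"region[{r}]")
        cols.append(g)
        names.append("genome_size")
        for r in ctx.regions[1:]:
            cols.append((reg == r).to_numpy(dtype=float) * g)
            names.append(f"region[{r}]:genome_size")
        X = np.column_stack(cols)
        prior_sd = np.full(X.shape[1], 5.0)
    else:  # latitude
        lat = df["latitude_deg"].to_numpy(dtype=float)
        B = _spline_basis(lat, ctx.knots)[:, 1:]  # drop first col (absorbed by intercept)
        nb = B.shape[1]
        X = np.column_stack([ones, B, g, B * g[:, None]])
        names = (
            ["intercept"]
            + [f"s(lat)[{i}]" for i in range(nb)]
            + ["genome_size"]
            + [f"s(lat):genome_size[{i}]" for i in range(nb)]
        )
        prior_sd = np.concatenate([[5.0], np.ones(nb), [5.0], np.ones(nb)])
    return X, names, prior_sd


# ---------------------------------------------------------------------------
# the sampler


def _gamma_loglik(y: np.ndarray, log_y: np.ndarray, eta: np.ndarray, alpha: float) -> float:
    # y ~ Gamma(shape alpha, mean mu = exp(eta)); rate = alpha / mu
    if not np.isfinite(eta).all():
        return -np.inf
    val = (
        len(y) * (alpha * math.log(alpha) - special.gammaln(alpha))
        - alpha * float(eta.sum())
        + (alpha - 1.0) * float(log_y.sum())
        - alpha * float((y * np.exp(-eta)).sum())
    )
    return val if np.isfinite(val) else -np.inf


@dataclass
class AbundanceFit:
    """Posterior sample of the phylogenetic gamma abundance model."""

    variant: str
    coef_names: list[str]
    species: list[str]
    beta: np.ndarray        # (chains, draws, p)
    z: np.ndarray           # (chains, draws, m)
    phylo_sd: np.ndarray    # (chains, draws)
    gamma_shape: np.ndarray  # (chains, draws)
    rhat: pd.Series = field(default_factory=pd.Series)
    converged: bool = True
    ctx: _DesignContext | None = None
    chol_R: np.ndarray | None = None
    X: np.ndarray | None = None
    species_idx: np.ndarray | None = None
    seed: int = 0

    def draws(self, parameter: str) -> np.ndarray:
        """Flattened posterior draws of a named parameter."""
        if parameter in self.coef_names:
            j = self.coef_names.index(parameter)
            return self.beta[:, :, j].ravel()
        if parameter == "phylo_sd":
            return self.phylo_sd.ravel()
        if parameter == "gamma_shape":
            return self.gamma_shape.ravel()
        raise KeyError(f"unknown parameter {parameter!r}")

    def credible_interval(self, parameter: str, level: float = 0.95):
        d = self.draws(parameter)
        a = (1 - level) / 2
        return float(np.quantile(d, a)), float(np.quantile(d, 1 - a))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.coef_names + ["phylo_sd", "gamma_shape"]:
            d = self.draws(name)
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append(
                {"parameter": name, "mean": d.mean(), "sd": d.std(ddof=1),
                 "q2.5": lo, "q97.5": hi,
                 "rhat": self.rhat.get(name, np.nan)}
            )
        return pd.DataFrame(rows).set_index("parameter")


def _split_rhat(draws: np.ndarray) -> float:
    """Split potential-scale-reduction factor; draws shaped (chains, n)."""
    c, n = draws.shape
    half = n // 2
    segs = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n2 = segs.shape
    means = segs.mean(axis=1)
    b = n2 * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def fit_gamma_abundance(
    table: pd.DataFrame,
    tree: "Phylogeny | None",
    variant: str = "temperature",
    chains: int = 2,
    iterations: int = 10_000,
    warmup: int | None = None,
    seed: int = 0,
    lam: float = 1.0,
) -> AbundanceFit:
    """Fit the phylogenetic gamma abundance regression by MCMC.

    ``table`` needs columns ``species, rel_abundance, genome_size_log10``
    plus the variant's environment column(s). ``tree=None`` drops the
    phylogenetic random effect (useful for reductions and checks). Default
    chain settings: 2 chains of 10,000 iterations, first half discarded as
    warmup.
    """
    y = table["rel_abundance"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError(
            "rel_abundance must be strictly positive: drop zero rows "
            "(aggregate_species / filter_prevalence do this) before fitting"
        )
    ctx = _make_context(table, variant)
    X, names, prior_sd = _design(table, ctx)
    p = X.shape[1]

    if tree is not None:
        species = sorted(table["species"].unique())
        missing = set(species) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"species not on the tree: {sorted(missing)}")
        sub = tree.prune_to(species) if set(tree.tip_labels) != set(species) else tree
        cov = lambda_transform(phylo_covariance(sub), lam)
        R = cov.to_correlation()
        order = {s: i for i, s in enumerate(cov.labels)}
        species = cov.labels
        chol_R = linalg.cholesky(R + 1e-10 * np.eye(len(R)), lower=True)
        spec_idx = table["species"].map(order).to_numpy(dtype=np.int64)
        m = len(species)
    else:
        species = []
        chol_R = np.zeros((0, 0))
        spec_idx = np.zeros(len(table), dtype=np.int64)
        m = 0

    if warmup is None:
        warmup = iterations // 2
    n_keep = iterations - warmup
    log_y = np.log(y)

    # z updated in sub-blocks of <= 10 species for acceptable mixing
    z_blocks = [np.arange(s, min(s + 10, m)) for s in range(0, m, 10)]

    # Fixed-effect columns that are constant within species (intercept,
    # genome size) lie in the span of the species effects: the likelihood
    # only sees their sum, so plain blockwise updates crawl along the ridge.
    # For each such column f we add a translation move beta_j -> beta_j + d,
    # z -> z - d * L^-1 f_species / sd, which leaves eta exactly unchanged
    # and is accepted on the prior ratio alone.
    confounded: list[tuple[int, np.ndarray]] = []
    if m:
        first_row = np.full(m, -1, dtype=np.int64)
        for row, s_i in enumerate(spec_idx):
            if first_row[s_i] < 0:
                first_row[s_i] = row
        for j in range(p):
            f_sp = X[first_row, j]
            if np.allclose(X[:, j], f_sp[spec_idx]):
                linv_f = linalg.solve_triangular(chol_R, f_sp, lower=True)
                confounded.append((j, linv_f))

    beta_out = np.empty((chains, n_keep, p))
    z_out = np.empty((chains, n_keep, m))
    sd_out = np.empty((chains, n_keep))
    alpha_out = np.empty((chains, n_keep))

    for chain in range(chains):
        rng = np.random.default_rng((seed, chain))
        beta = np.zeros(p)
        beta[0] = float(np.log(y.mean()))
        z = np.zeros(m)
        log_sd = math.log(0.5)
        log_alpha = 0.0

        xb = X @ beta
        lz = chol_R @ z if m else np.zeros(0)
        sd = math.exp(log_sd)
        alpha = math.exp(log_alpha)

        def log_prior_beta(b):
            return -0.5 * float(np.sum((b / prior_sd) ** 2))

        def log_prior_z(zv):
            return -0.5 * float(zv @ zv)

        def log_prior_sd(lsd):
            s = math.exp(lsd)
            return -(s * s) / 8.0 + lsd  # half-Normal(0,2) + Jacobian

        def log_prior_alpha(la):
            a = math.exp(la)
            return -a + la  # Exponential(1) + Jacobian

        def loglik(xb_, lz_, sd_, alpha_):
            eta = xb_ + sd_ * lz_[spec_idx] if m else xb_
            return _gamma_loglik(y, log_y, eta, alpha_)

        ll = loglik(xb, lz, sd, alpha)

        # the adaptive MVN block updates only the non-ridge columns; the
        # species-level (confounded) columns move via translation moves,
        # whose marginal variance would otherwise swamp this block's
        # conditional proposal covariance
        conf_cols = {j for j, _ in confounded}
        bidx = np.array([j for j in range(p) if j not in conf_cols] or list(range(p)))
        pb = len(bidx)

        # adaptive proposal state
        s_beta = 0.1 / math.sqrt(pb)
        chol_prop = np.eye(pb)
        run_mean = np.zeros(pb)
        run_cov = np.eye(pb) * 1e-4
        s_z = [0.5] * len(z_blocks)
        s_tr = [0.5] * len(confounded)
        s_coord = [0.1] * p
        s_sd, s_alpha, s_cen = 0.5, 0.5, 0.5
        target_mv, target_sc = 0.234, 0.44

        kept = 0
        for it in range(iterations):
            adapting = it < warmup
            gam = min(0.1, 5.0 / math.sqrt(it + 10.0))

            # --- beta block (non-ridge columns)
            prop = beta.copy()
            prop[bidx] += s_beta * (chol_prop @ rng.standard_normal(pb))
            xb_prop = X @ prop
            ll_prop = loglik(xb_prop, lz, sd, alpha)
            logr = ll_prop - ll + log_prior_beta(prop) - log_prior_beta(beta)
            acc = math.log(rng.uniform()) < logr
            if acc:
                beta, xb, ll = prop, xb_prop, ll_prop
            if adapting:
                s_beta *= math.exp(gam * ((1.0 if acc else 0.0) - target_mv))
                bsub = beta[bidx]
                delta = bsub - run_mean
                run_mean += delta / (it + 2.0)
                run_cov += gam * (np.outer(delta, bsub - run_mean) - run_cov)
                if it >= 200 and it % 50 == 0:
                    try:
                        chol_prop = np.linalg.cholesky(run_cov + 1e-10 * np.eye(pb))
                    except np.linalg.LinAlgError:
                        pass

            # --- per-coordinate beta sweep (rank-1 update of X beta);
            # complements the joint block, which under-serves strongly
            # correlated designs (region dummies, spline bases)
            for j in range(p):
                d = s_coord[j] * rng.standard_normal()
                b_new = beta[j] + d
                xb_prop = xb + d * X[:, j]
                ll_prop = loglik(xb_prop, lz, sd, alpha)
                logr = ll_prop - ll - 0.5 * (
                    (b_new / prior_sd[j]) ** 2 - (beta[j] / prior_sd[j]) ** 2
                )
                acc = math.log(rng.uniform()) < logr
                if acc:
                    beta = beta.copy()
                    beta[j] = b_new
                    xb, ll = xb_prop, ll_prop
                if adapting:
                    s_coord[j] *= math.exp(gam * ((1.0 if acc else 0.0) - target_sc))

            # --- z sub-blocks
            for bi, idx_blk in enumerate(z_blocks):
                z_prop = z.copy()
                z_prop[idx_blk] += s_z[bi] * rng.standard_normal(len(idx_blk))
                lz_prop = chol_R @ z_prop
                ll_prop = loglik(xb, lz_prop, sd, alpha)
                logr = ll_prop - ll + log_prior_z(z_prop) - log_prior_z(z)
                acc = math.log(rng.uniform()) < logr
                if acc:
                    z, lz, ll = z_prop, lz_prop, ll_prop
                if adapting:
                    s_z[bi] *= math.exp(gam * ((1.0 if acc else 0.0) - target_mv))

            # --- translation moves along likelihood-invariant ridges
            for ti, (j, linv_f) in enumerate(confounded):
                d = s_tr[ti] * rng.standard_normal()
                b_new = beta[j] + d
                z_prop = z - (d / sd) * linv_f
                logr = (
                    -0.5 * ((b_new / prior_sd[j]) ** 2 - (beta[j] / prior_sd[j]) ** 2)
                    + log_prior_z(z_prop) - log_prior_z(z)
                )
                acc = math.log(rng.uniform()) < logr
                if acc:
                    beta = beta.copy()
                    beta[j] = b_new
                    z = z_prop
                    lz = chol_R @ z
                    xb = X @ beta
                if adapting:
                    s_tr[ti] *= math.exp(gam * ((1.0 if acc else 0.0) - target_sc))

            # --- log phylo_sd (non-centered RW)
            if m:
                lsd_prop = log_sd + s_sd * rng.standard_normal()
                sd_prop = math.exp(lsd_prop)
                ll_prop = loglik(xb, lz, sd_prop, alpha)
                logr = ll_prop - ll + log_prior_sd(lsd_prop) - log_prior_sd(log_sd)
                acc = math.log(rng.uniform()) < logr
                if acc:
                    log_sd, sd, ll = lsd_prop, sd_prop, ll_prop
                if adapting:
                    s_sd *= math.exp(gam * ((1.0 if acc else 0.0) - target_sc))

            # --- interweaved centered update of phylo_sd: hold u = sd*z
            # fixed (likelihood invariant), random-walk log_sd in the
            # centered parameterization where v = sd*z ~ N(0, sd^2 I)
            if m:
                v = sd * z
                vv = float(v @ v)

                def centered_logp(lsd: float) -> float:
                    s2 = math.exp(2.0 * lsd)
                    return -0.5 * vv / s2 - m * lsd + log_prior_sd(lsd)

                lsd_prop = log_sd + s_cen * rng.standard_normal()
                logr = centered_logp(lsd_prop) - centered_logp(log_sd)
                acc = math.log(rng.uniform()) < logr
                if acc:
                    log_sd = lsd_prop
                    sd = math.exp(log_sd)
                    z = v / sd
                    # lz scales the same way; ll unchanged (u fixed)
                    lz = chol_R @ z
                if adapting:
                    s_cen *= math.exp(gam * ((1.0 if acc else 0.0) - target_sc))

            # --- log gamma shape
            la_prop = log_alpha + s_alpha * rng.standard_normal()
            a_prop = math.exp(la_prop)
            ll_prop = loglik(xb, lz, sd, a_prop)
            logr = ll_prop - ll + log_prior_alpha(la_prop) - log_prior_alpha(log_alpha)
            acc = math.log(rng.uniform()) < logr
            if acc:
                log_alpha, alpha, ll = la_prop, a_prop, ll_prop
            if adapting:
                s_alpha *= math.exp(gam * ((1.0 if acc else 0.0) - target_sc))

            if it >= warmup:
                beta_out[chain, kept] = beta
                z_out[chain, kept] = z
                sd_out[chain, kept] = sd
                alpha_out[chain, kept] = alpha
                kept += 1

    # convergence: split-Rhat per parameter
    rhat = {}
    for j, name in enumerate(names):
        rhat[name] = _split_rhat(beta_out[:, :, j])
    if m:
        rhat["phylo_sd"] = _split_rhat(sd_out)
    rhat["gamma_shape"] = _split_rhat(alpha_out)
    rhat = pd.Series(rhat)
    converged = bool((rhat < 1.1).all())
    if not converged:
        bad = rhat[rhat >= 1.1]
        warnings.warn(
            f"MCMC did not converge (Rhat >= 1.1): {bad.to_dict()}",
            RuntimeWarning,
            stacklevel=2,
        )

    return AbundanceFit(
        variant=variant, coef_names=names, species=list(species),
        beta=beta_out, z=z_out, phylo_sd=sd_out, gamma_shape=alpha_out,
        rhat=rhat, converged=converged, ctx=ctx, chol_R=chol_R,
        X=X, species_idx=spec_idx, seed=seed,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def significance(fit: AbundanceFit, parameter: str) -> bool:
    """True iff the 95% credible interval excludes zero (both ends same sign)."""
    lo, hi = fit.credible_interval(parameter)
    return bool(lo > 0) or bool(hi < 0)


def predict_interaction(
    fit: AbundanceFit,
    grid: "pd.DataFrame | None" = None,
    temperatures=DEFAULT_TEMPERATURE_GRID,
    n_gs: int = 11,
) -> pd.DataFrame:
    """Population-level posterior predictions of mean abundance over a grid.

    Without an explicit grid, a default is built: for the temperature
    variant, the four temperatures {0, 10, 20, 30} C crossed with genome
    sizes spanning the fitted range; analogous grids for region and
    latitude. Returns posterior mean and 95% interval of mu per grid row.
    """
    ctx = fit.ctx
    if grid is None:
        gs_vals = np.linspace(*ctx.gs_range, n_gs)
        if fit.variant == "temperature":
            grid = pd.DataFrame(
                [(t, g) for t in temperatures for g in gs_vals],
                columns=["temperature_c", "genome_size_log10"],
            )
        elif fit.variant == "region":
            grid = pd.DataFrame(
                [(r, g) for r in ctx.regions for g in gs_vals],
                columns=["ocean_region", "genome_size_log10"],
            )
        else:
            lats = np.linspace(*ctx.lat_range, 25)
            grid = pd.DataFrame(
                [(la, g) for la in lats for g in gs_vals],
                columns=["latitude_deg", "genome_size_log10"],
            )
    gmin, gmax = ctx.gs_range
    if (grid["genome_size_log10"].min() < gmin - 1e-9
            or grid["genome_size_log10"].max() > gmax + 1e-9):
        warnings.warn("prediction grid extrapolates beyond fitted genome sizes",
                      UserWarning, stacklevel=2)
    if fit.variant == "temperature":
        tc = grid["temperature_c"]
        span = fit.X[:, 1]  # centered temperature at fit time
        if (tc - ctx.temp_mean).min() < span.min() - 1e-9 or \
           (tc - ctx.temp_mean).max() > span.max() + 1e-9:
            warnings.warn("prediction grid extrapolates beyond fitted temperatures",
                          UserWarning, stacklevel=2)
    Xg, _, _ = _design(grid, ctx)
    B = fit.beta.reshape(-1, fit.beta.shape[-1])
    eta = Xg @ B.T  # (grid, draws)
    mu = np.exp(eta)
    out = grid.copy()
    out["mean"] = mu.mean(axis=1)
    out["q2.5"] = np.quantile(mu, 0.025, axis=1)
    out["q97.5"] = np.quantile(mu, 0.975, axis=1)
    return out


def bayes_r2(fit: AbundanceFit, max_draws: int = 2000) -> float:
    """Posterior-mean Bayesian r^2 of the gamma model.

    Per draw: var(mu) / (var(mu) + mean(mu^2) / alpha), with mu the fitted
    means including the species effects; the residual term is the expected
    gamma variance mu^2 / alpha.
    """
    chains, draws, p = fit.beta.shape
    total = chains * draws
    step = max(1, total // max_draws)
    B = fit.beta.reshape(total, p)[::step]
    Z = fit.z.reshape(total, -1)[::step]
    S = fit.phylo_sd.reshape(total)[::step]
    A = fit.gamma_shape.reshape(total)[::step]
    r2s = np.empty(len(B))
    for i in range(len(B)):
        eta = fit.X @ B[i]
        if Z.shape[1]:
            eta = eta + S[i] * (fit.chol_R @ Z[i])[fit.species_idx]
        mu = np.exp(eta)
        v = mu.var()
        resid = float(np.mean(mu**2)) / A[i]
        r2s[i] = v / (v + resid)
    return float(r2s.mean())
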