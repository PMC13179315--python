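"""Ex-Gaussian likelihood and Bayesian multilevel models of turn-timing.

FTO distributions are leptokurtic with a peak near 0 ms and a long right
tail, which the exponentially modified Gaussian (ex-Gaussian) captures well:
``X = N(mu, sigma^2) + Exp(tau)``, with mean ``mu + tau`` and variance
``sigma^2 + tau^2``.

The group comparison is a Bayesian multilevel regression with an ex-Gaussian
likelihood: fixed effects Group × Task (treatment coding, reference levels
Group = ASD and Task = Introduction), and by-dyad random intercepts plus
random Task slopes on the Gaussian location ``mu``; ``sigma`` and ``tau``
are global per model.  Three model subsets mirror the analysis design: the
full signed FTO range, gaps only (FTO > 0) and overlaps only (FTO < 0; the
magnitudes are modelled and contrast signs flipped back on report).

Posterior sampling uses the latent-exponential data augmentation
``y_i = mu_i + sigma * z_i + e_i`` with ``e_i ~ Exp(tau)``:

* ``e_i | rest`` is truncated normal on ``[0, inf)`` (exact draw);
* the fixed and random effects jointly have a conjugate Gaussian
  conditional given ``y - e`` (one Cholesky solve per sweep);
* ``sigma``, ``tau`` and the random-effect SDs (half-Normal priors) are
  updated by univariate slice sampling on the log scale.

This Gibbs scheme mixes quickly for these models, so desk-scale settings
(2 chains x 1000 sweeps, 500 warm-up) already give stable summaries; the
default settings are 4 chains x 4000 iterations with 2000 warm-up.

Effects are reported as posterior contrasts delta with an equal-tailed 95%
credible interval and the posterior probability P(delta > 0).  An effect is
*robust* when the 95% CI excludes zero (or misses it only by a small
margin) and max(P, 1-P) >= 0.89.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr

from .annotation_io import CONTEXTS, GROUPS
from .turn_extraction import TransitionTable
from . import typology

__all__ = [
    "ExGaussParams",
    "ModelSpec",
    "PosteriorSummary",
    "HierarchicalPosterior",
    "FitError",
    "exgauss_logpdf",
    "exgauss_rvs",
    "fit_exgauss_mle",
    "fit_hierarchical",
    "summarise_contrast",
    "is_robust",
    "posterior_predictive_check",
]

logger = logging.getLogger(__name__)

# Weakly informative priors, all centred at zero, spanning the feasible FTO
# range (a few seconds): fixed effects Normal(0, 1000 ms); sigma, tau and
# random-effect SDs half-Normal(0, 500 ms).
PRIOR_SD_FIXED_MS = 1000.0
PRIOR_SCALE_HALFNORMAL_MS = 500.0


class FitError(RuntimeError):
    """Raised when an optimisation or sampler cannot produce a usable fit."""


# ---------------------------------------------------------------------------
# Ex-Gaussian distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian parameters in milliseconds."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.tau > 0):
            raise ValueError(f"sigma and tau must be positive, got {self}")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        return self.sigma**2 + self.tau**2

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def exgauss_logpdf(x, params: ExGaussParams) -> np.ndarray:
    """Log-density of the ex-Gaussian, stable in both tails.

    ``log f(x) = -log tau + sigma^2/(2 tau^2) - (x - mu)/tau
    + log Phi((x - mu)/sigma - sigma/tau)``, with the normal log-CDF term
    computed via ``log_ndtr`` so extreme arguments do not underflow.
    """
    x = np.asarray(x, dtype=float)
    mu, sigma, tau = params.mu, params.sigma, params.tau
    if not (sigma > 0 and tau > 0):
        raise ValueError("sigma and tau must be positive")
    z = (x - mu) / sigma
    return (
        -np.log(tau)
        + sigma**2 / (2.0 * tau**2)
        - (x - mu) / tau
        + log_ndtr(z - sigma / tau)
    )


def exgauss_rvs(
    params: ExGaussParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the ex-Gaussian as Normal(mu, sigma) + Exponential(tau)."""
    return rng.normal(params.mu, params.sigma, size) + rng.exponential(params.tau, size)


def _moment_start(x: np.ndarray) -> tuple[float, float, float]:
    """Skewness-based starting values for ex-Gaussian likelihood maximisation."""
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    g1 = float(stats.skew(x, bias=False))
    if g1 > 0:
        tau0 = s * min((g1 / 2.0) ** (1.0 / 3.0), 0.95)
    else:
        tau0 = 0.05 * s
    tau0 = max(tau0, 0.02 * s)
    sigma0 = float(np.sqrt(max(s**2 - tau0**2, (0.05 * s) ** 2)))
    return m - tau0, sigma0, tau0


def fit_exgauss_mle(values: Sequence[float]) -> ExGaussParams:
    """Maximum-likelihood ex-Gaussian fit with moment-based initialisation.

    Optimises over ``(mu, log sigma, log tau)`` with L-BFGS-B; near-Gaussian
    samples converge to a tau near its effective lower bound with mu close
    to the sample mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 values for an ex-Gaussian fit, got {x.size}")
    mu0, sigma0, tau0 = _moment_start(x)

    def nll(theta: np.ndarray) -> float:
        params = ExGaussParams(theta[0], float(np.exp(theta[1])), float(np.exp(theta[2])))
        return -float(np.sum(exgauss_logpdf(x, params)))

    res = optimize.minimize(
        nll,
        np.array([mu0, np.log(sigma0), np.log(tau0)]),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    if not res.success or not np.isfinite(res.fun):
        raise FitError(f"ex-Gaussian MLE did not converge: {res.message} (fun={res.fun})")
    return ExGaussParams(float(res.x[0]), float(np.exp(res.x[1])), float(np.exp(res.x[2])))


# ---------------------------------------------------------------------------
# Model specification and posterior containers
# ---------------------------------------------------------------------------

SUBSETS = ("full", "gaps_only", "overlaps_only")


@dataclass(frozen=True)
class ModelSpec:
    """Sampler and model settings for one multilevel fit."""

    subset: str = "full"
    chains: int = 4
    iterations: int = 4000  # total sweeps per chain, warm-up included
    warmup: int = 2000
    seed: int = 0
    likelihood: str = "exgauss"  # "exgauss" | "gaussian" (diagnostic baseline)

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")
        if self.likelihood not in ("exgauss", "gaussian"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if not (0 < self.warmup < self.iterations):
            raise ValueError("need 0 < warmup < iterations")

    @classmethod
    def desk_scale(cls, subset: str = "full", seed: int = 0, **kw) -> "ModelSpec":
        """Reduced settings (2 chains x 1000/500) for fast pipelines.

        Not the headline analysis configuration — use the defaults for that.
        """
        kw.setdefault("chains", 2)
        kw.setdefault("iterations", 1000)
        kw.setdefault("warmup", 500)
        return cls(subset=subset, seed=seed, **kw)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary of one contrast on the FTO scale (ms)."""

    contrast: str
    delta_mean: float
    ci95: tuple[float, float]
    p_delta_gt_zero: float
    rhat: float
    ess: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.delta_mean <= hi):
            raise ValueError("posterior mean must lie inside its 95% CI")
        if not (0.0 <= self.p_delta_gt_zero <= 1.0):
            raise ValueError("p_delta_gt_zero must be a probability")


@dataclass
class HierarchicalPosterior:
    """MCMC draws and design information from one multilevel fit.

    Arrays have shape (chains, draws, ...).  ``tau`` is None for the
    Gaussian-likelihood baseline.  ``sign_flip`` marks the overlaps-only
    model, whose contrasts are reported back on the signed FTO scale.
    """

    spec: ModelSpec
    coef_names: list[str]
    beta: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray | None
    sd_u: np.ndarray
    sd_u_names: list[str]
    u: np.ndarray
    dyad_ids: list[str]
    groups_present: list[str]
    contexts_present: list[str]
    sign_flip: bool
    y: np.ndarray
    W: np.ndarray
    n_fixed: int

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def to_dict(self) -> dict[str, np.ndarray]:
        out = {name: self.beta[:, :, i] for i, name in enumerate(self.coef_names)}
        out["sigma"] = self.sigma
        if self.tau is not None:
            out["tau"] = self.tau
        for i, name in enumerate(self.sd_u_names):
            out[f"sd_dyad_{name}"] = self.sd_u[:, :, i]
        return out

    def idata(self):
        import arviz as az

        return az.from_dict(posterior=self.to_dict())

    def diagnostics(self) -> dict[str, float]:
        import arviz as az

        idata = self.idata()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        max_rhat = float(max(rhat[v].values.max() for v in rhat.data_vars))
        min_ess = float(min(ess[v].values.min() for v in ess.data_vars))
        return {"max_rhat": max_rhat, "min_ess_bulk": min_ess}

    # -- contrast draws -----------------------------------------------------

    def _coef(self, name: str) -> np.ndarray:
        try:
            i = self.coef_names.index(name)
        except ValueError as exc:
            raise KeyError(
                f"coefficient {name!r} not in model ({self.coef_names})"
            ) from exc
        return self.beta[:, :, i]

    def group_contrast_draws(self, context: str | None = None) -> np.ndarray:
        """Draws of delta = non-ASD − ASD, at one context or marginally
        (equal weight over the contexts present in the data)."""
        if "group[non-ASD]" not in self.coef_names:
            raise KeyError("model was fitted on a single group; no group contrast")
        base = self._coef("group[non-ASD]")
        non_ref = [c for c in self.contexts_present if c != "Introduction"]
        if context is None:
            inter = sum(
                (self._coef(f"group[non-ASD]:context[{c}]") for c in non_ref),
                np.zeros_like(base),
            )
            delta = base + inter / max(len(self.contexts_present), 1)
        else:
            if context not in self.contexts_present:
                raise KeyError(f"context {context!r} not in model")
            delta = base.copy()
            if context != "Introduction":
                delta = delta + self._coef(f"group[non-ASD]:context[{context}]")
        return -delta if self.sign_flip else delta

    def context_contrast_draws(self, c1: str, c2: str, group: str) -> np.ndarray:
        """Draws of delta = context c1 − context c2 within one group."""
        if group not in self.groups_present:
            raise KeyError(f"group {group!r} not in model")

        def ctx_effect(c: str) -> np.ndarray:
            if c not in self.contexts_present:
                raise KeyError(f"context {c!r} not in model")
            eff = np.zeros_like(self.beta[:, :, 0])
            if c != "Introduction":
                eff = eff + self._coef(f"context[{c}]")
                if group == "non-ASD" and "group[non-ASD]" in self.coef_names:
                    eff = eff + self._coef(f"group[non-ASD]:context[{c}]")
            return eff

        delta = ctx_effect(c1) - ctx_effect(c2)
        return -delta if self.sign_flip else delta

    def contrast_draws(self, contrast: str) -> np.ndarray:
        """Resolve a contrast name to posterior draws.

        Grammar: ``"group"`` (marginal over contexts), ``"group@<Context>"``,
        or ``"<Context1>-<Context2>@<Group>"``.
        """
        if contrast == "group":
            return self.group_contrast_draws()
        if contrast.startswith("group@"):
            return self.group_contrast_draws(contrast.split("@", 1)[1])
        if "@" in contrast and "-" in contrast:
            pair, group = contrast.split("@", 1)
            c1, c2 = pair.split("-", 1)
            return self.context_contrast_draws(c1, c2, group)
        raise KeyError(f"cannot parse contrast {contrast!r}")


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _subset_frame(df: pd.DataFrame, subset: str) -> tuple[pd.DataFrame, bool]:
    df = df[df["type"].isin(["gap", "between_overlap"])].dropna(subset=["fto_ms"])
    if subset == "full":
        return df.copy(), False
    if subset == "gaps_only":
        return df[df["fto_ms"] > 0].copy(), False
    out = df[df["fto_ms"] < 0].copy()
    out["fto_ms"] = -out["fto_ms"]  # model overlap magnitudes
    return out, True


def _build_design(df: pd.DataFrame):
    groups_present = [g for g in GROUPS if g in set(df["group"])]
    contexts_present = [c for c in CONTEXTS if c in set(df["context"])]
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    g_ind = (df["group"] == "non-ASD").to_numpy(float)
    if len(groups_present) == 2:
        cols.append(g_ind)
        names.append("group[non-ASD]")
    ctx_dummies = {}
    for c in contexts_present:
        if c == "Introduction":
            continue
        d = (df["context"] == c).to_numpy(float)
        ctx_dummies[c] = d
        cols.append(d)
        names.append(f"context[{c}]")
    if len(groups_present) == 2:
        for c, d in ctx_dummies.items():
            cols.append(g_ind * d)
            names.append(f"group[non-ASD]:context[{c}]")
    X = np.column_stack(cols)

    dyad_ids = sorted(df["dyad_id"].unique())
    dyad_index = {d: i for i, d in enumerate(dyad_ids)}
    re_names = ["Intercept"] + [f"context[{c}]" for c in ctx_dummies]
    k_re = len(re_names)
    q = len(dyad_ids) * k_re
    Z = np.zeros((n, q))
    rows = np.arange(n)
    d_idx = df["dyad_id"].map(dyad_index).to_numpy()
    Z[rows, d_idx * k_re] = 1.0
    for j, (c, d) in enumerate(ctx_dummies.items(), start=1):
        Z[rows, d_idx * k_re + j] = d
    return X, names, Z, dyad_ids, re_names, groups_present, contexts_present


# ---------------------------------------------------------------------------
# Slice sampler (univariate, stepping out + shrinkage)
# ---------------------------------------------------------------------------


def _slice_sample(logf, x0: float, w: float, rng: np.random.Generator, max_out: int = 50) -> float:
    logy = logf(x0) - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    j = int(max_out * rng.random())
    k = max_out - 1 - j
    while j > 0 and logf(left) > logy:
        left -= w
        j -= 1
    while k > 0 and logf(right) > logy:
        right += w
        k -= 1
    while True:
        x1 = left + (right - left) * rng.random()
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


# ---------------------------------------------------------------------------
# Hierarchical fit
# ---------------------------------------------------------------------------


def _halfnormal_logscale_target(scale: float):
    """log prior kernel of a half-Normal evaluated at s = exp(ls), with the
    log-scale Jacobian included."""

    def term(ls: float, s: float) -> float:
        return -(s**2) / (2.0 * scale**2) + ls

    return term


def _run_chain(
    y: np.ndarray,
    W: np.ndarray,
    n_fixed: int,
    k_re: int,
    n_dyads: int,
    spec: ModelSpec,
    chain_seed: np.random.SeedSequence,
):
    rng = np.random.default_rng(chain_seed)
    n, p = W.shape
    q = p - n_fixed
    WtW = W.T @ W
    Wty = W.T @ y
    hn = PRIOR_SCALE_HALFNORMAL_MS

    # moment-based initialisation
    mu0, sigma0, tau0 = _moment_start(y)
    sigma = max(sigma0, 1.0)
    tau = max(tau0, 1.0)
    gaussian = spec.likelihood == "gaussian"
    if gaussian:
        sigma = float(np.std(y, ddof=1))
    theta = np.zeros(p)
    theta[0] = mu0 if not gaussian else float(np.mean(y))
    sd_u = np.full(k_re, 100.0)
    e = np.zeros(n) if gaussian else rng.exponential(tau, n)

    # indices of each random-effect coefficient kind within theta
    re_kind = np.tile(np.arange(k_re), n_dyads)

    n_keep = spec.iterations - spec.warmup
    out_beta = np.empty((n_keep, n_fixed))
    out_sigma = np.empty(n_keep)
    out_tau = np.empty(n_keep) if not gaussian else None
    out_sd = np.empty((n_keep, k_re))
    out_u = np.empty((n_keep, q))

    prior_var = np.empty(p)
    prior_var[:n_fixed] = PRIOR_SD_FIXED_MS**2

    for sweep in range(spec.iterations):
        mu_lin = W @ theta
        if not gaussian:
            m = (y - mu_lin) - sigma**2 / tau
            a = -m / sigma
            e = stats.truncnorm.rvs(a, np.inf, loc=m, scale=sigma, random_state=rng)
        r = y - e

        # joint conjugate update of fixed + random effects
        prior_var[n_fixed:] = sd_u[re_kind] ** 2
        A = WtW / sigma**2 + np.diag(1.0 / prior_var)
        b = (Wty - W.T @ e) / sigma**2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
        theta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        resid = r - W @ theta
        ss = float(resid @ resid)

        def logf_sigma(ls: float) -> float:
            s = np.exp(ls)
            return -n * ls - ss / (2.0 * s**2) - s**2 / (2.0 * hn**2) + ls

        sigma = float(np.exp(_slice_sample(logf_sigma, np.log(sigma), 0.5, rng)))

        if not gaussian:
            se = float(np.sum(e))

            def logf_tau(lt: float) -> float:
                t = np.exp(lt)
                return -n * lt - se / t - t**2 / (2.0 * hn**2) + lt

            tau = float(np.exp(_slice_sample(logf_tau, np.log(tau), 0.5, rng)))

        u = theta[n_fixed:]
        for k in range(k_re):
            uk = u[re_kind == k]
            ssu = float(uk @ uk)
            qk = uk.size

            def logf_sd(ls: float) -> float:
                s = np.exp(ls)
                return -qk * ls - ssu / (2.0 * s**2) - s**2 / (2.0 * hn**2) + ls

            sd_u[k] = float(np.exp(_slice_sample(logf_sd, np.log(sd_u[k]), 0.5, rng)))

        if sweep >= spec.warmup:
            j = sweep - spec.warmup
            out_beta[j] = theta[:n_fixed]
            out_sigma[j] = sigma
            if out_tau is not None:
                out_tau[j] = tau
            out_sd[j] = sd_u
            out_u[j] = theta[n_fixed:]

    return out_beta, out_sigma, out_tau, out_sd, out_u


def fit_hierarchical(
    table: TransitionTable | pd.DataFrame, spec: ModelSpec
) -> HierarchicalPosterior:
    """Fit the multilevel ex-Gaussian FTO model and return posterior draws.

    The table is subset per ``spec.subset`` (full: all signed FTOs;
    gaps_only: FTO > 0; overlaps_only: FTO < 0, modelled as magnitudes).
    Requires at least two dyads per group present in the subset.  Issues a
    warning when the split-chain R-hat exceeds 1.01.
    """
    df = table.df if isinstance(table, TransitionTable) else table
    sub, sign_flip = _subset_frame(df, spec.subset)
    if sub.empty:
        raise FitError(f"subset {spec.subset!r} selected no transitions")
    if sub["group"].isna().any() or sub["context"].isna().any():
        raise FitError("model input needs group and context on every row")
    dyads_per_group = sub.groupby("group", observed=True)["dyad_id"].nunique()
    if (dyads_per_group < 2).any():
        raise FitError(
            f"need at least 2 dyads per group, got {dyads_per_group.to_dict()}"
        )

    X, names, Z, dyad_ids, re_names, groups_present, contexts_present = _build_design(sub)
    y = sub["fto_ms"].to_numpy(float)
    W = np.hstack([X, Z])
    n_fixed = X.shape[1]
    k_re = len(re_names)

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    results = [
        _run_chain(y, W, n_fixed, k_re, len(dyad_ids), spec, s) for s in seeds
    ]
    beta = np.stack([r[0] for r in results])
    sigma = np.stack([r[1] for r in results])
    tau = None if results[0][2] is None else np.stack([r[2] for r in results])
    sd_u = np.stack([r[3] for r in results])
    u = np.stack([r[4] for r in results])

    post = HierarchicalPosterior(
        spec=spec,
        coef_names=names,
        beta=beta,
        sigma=sigma,
        tau=tau,
        sd_u=sd_u,
        sd_u_names=re_names,
        u=u,
        dyad_ids=list(dyad_ids),
        groups_present=groups_present,
        contexts_present=contexts_present,
        sign_flip=sign_flip,
        y=y,
        W=W,
        n_fixed=n_fixed,
    )
    if spec.chains >= 2:
        diag = post.diagnostics()
        if diag["max_rhat"] > 1.01:
            warnings.warn(
                f"sampler convergence suspect: max R-hat {diag['max_rhat']:.3f}, "
                f"min bulk ESS {diag['min_ess_bulk']:.0f}",
                RuntimeWarning,
                stacklevel=2,
            )
    return post


# ---------------------------------------------------------------------------
# Contrast summaries and the robustness criterion
# ---------------------------------------------------------------------------


def summarise_contrast(
    post: HierarchicalPosterior | np.ndarray,
    contrast: str,
) -> PosteriorSummary:
    """Posterior mean, equal-tailed 95% CI and P(delta > 0) for a contrast.

    ``post`` may be a fitted posterior (the contrast name is resolved via
    :meth:`HierarchicalPosterior.contrast_draws`) or a raw draws array of
    shape (chains, draws) / (draws,).
    """
    if isinstance(post, HierarchicalPosterior):
        draws = post.contrast_draws(contrast)
    else:
        draws = np.asarray(post, float)
        if draws.ndim == 1:
            draws = draws[None, :]
    flat = draws.reshape(-1)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    if draws.shape[0] >= 2:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(draws))
            ess = float(az.ess(draws))
    else:
        rhat, ess = float("nan"), float(flat.size)
    return PosteriorSummary(
        contrast=contrast,
        delta_mean=float(flat.mean()),
        ci95=(float(lo), float(hi)),
        p_delta_gt_zero=float(np.mean(flat > 0)),
        rhat=rhat,
        ess=ess,
    )


def is_robust(
    summary: PosteriorSummary,
    p_threshold: float = 0.89,
    margin_fraction: float = 0.02,
) -> bool:
    """Apply the robustness criterion to a posterior contrast.

    True iff the 95% CI excludes zero — or includes it only by a small
    margin, namely zero lies within ``margin_fraction`` of the CI width
    from an endpoint — and the directional posterior probability
    ``max(P(delta>0), 1-P(delta>0))`` is at least ``p_threshold``.
    """
    lo, hi = summary.ci95
    width = hi - lo
    excludes = lo > 0 or hi < 0
    narrowly = (lo <= 0 <= hi) and min(abs(lo), abs(hi)) <= margin_fraction * width
    p = summary.p_delta_gt_zero
    return (excludes or narrowly) and max(p, 1.0 - p) >= p_threshold


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

_PPC_WARN_BOUNDS = (0.01, 0.99)


def _ppc_stats(x: np.ndarray) -> dict[str, float]:
    cats = typology.categorise_array(x)
    n = x.size
    out = {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "median": float(np.median(x)),
    }
    for c in typology.CATEGORIES:
        out[f"prop_{c}"] = float(np.sum(cats == c) / n)
    return out


def posterior_predictive_check(
    post: HierarchicalPosterior,
    n_rep: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Compare replicated FTO datasets from the posterior with the observed data.

    For each of ``n_rep`` thinned posterior draws a full replicated dataset
    is simulated from the fitted model (same design), and the tail-area
    probability P(T_rep <= T_obs) is reported for the mean, SD, median and
    the five transition-category proportions.  Tail areas outside
    (0.01, 0.99) flag the statistic as extreme (likely misfit).
    """
    rng = rng if rng is not None else np.random.default_rng(post.spec.seed + 1)
    c, s, _ = post.beta.shape
    total = c * s
    idx = np.linspace(0, total - 1, min(n_rep, total)).astype(int)
    beta = post.beta.reshape(total, -1)[idx]
    u = post.u.reshape(total, -1)[idx]
    sigma = post.sigma.reshape(total)[idx]
    tau = None if post.tau is None else post.tau.reshape(total)[idx]

    sign = -1.0 if post.sign_flip else 1.0
    obs = _ppc_stats(sign * post.y)
    n = post.y.size
    rep_rows = []
    for j in range(len(idx)):
        theta = np.concatenate([beta[j], u[j]])
        mu_lin = post.W @ theta
        y_rep = mu_lin + rng.normal(0.0, sigma[j], n)
        if tau is not None:
            y_rep = y_rep + rng.exponential(tau[j], n)
        rep_rows.append(_ppc_stats(sign * y_rep))
    rep = pd.DataFrame(rep_rows)

    records = []
    for stat, value in obs.items():
        rep_vals = rep[stat].to_numpy()
        tail = float(np.mean(rep_vals <= value))
        records.append(
            {
                "statistic": stat,
                "observed": value,
                "rep_mean": float(rep_vals.mean()),
                "rep_sd": float(rep_vals.std(ddof=1)),
                "tail_prob": tail,
                "extreme": tail < _PPC_WARN_BOUNDS[0] or tail > _PPC_WARN_BOUNDS[1],
            }
        )
    report = pd.DataFrame(records)
    n_extreme = int(report["extreme"].sum())
    if n_extreme:
        logger.warning("posterior predictive check: %d extreme statistics", n_extreme)
    return report
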