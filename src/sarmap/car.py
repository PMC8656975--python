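"""Bayesian spatial Poisson smoothing of relative risks.

Admission counts O_i with expecteds E_i are modelled as
O_i ~ Poisson(E_i * theta_i) with log theta_i decomposed according to the
prior family:

- ``bym``     log theta_i = alpha + u_i + v_i, u ~ ICAR(tau_u), v iid N(0, 1/tau_v)
- ``icar``    log theta_i = alpha + u_i
- ``leroux``  log theta_i = alpha + b_i,  b ~ N(0, [tau((1-lam)I + lam Q)]^-1)
- ``iid``     log theta_i = alpha + v_i (no spatial term; comparison baseline)

Q = D - W is the graph Laplacian of the tract contiguity graph.  Posterior
sampling is Metropolis-within-Gibbs: conjugate gamma updates for the
precisions, colour-blocked random-walk updates for the fields (a colour
class is an independent set of the graph, so its single-site full
conditionals can be updated simultaneously), adaptive step sizes during
burn-in, and re-centering of the improper ICAR field after every sweep
with the intercept absorbing the level.

The results object reports the smoothed relative risk SRR_i (posterior
mean of 100 * theta_i, percent scale as in SAR maps), 95% credible
intervals, the posterior exceedance probability PP_i = P(theta_i > 1), and
DIC/WAIC for model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, gammaln, logit, logsumexp

from .graph import AdjacencyGraph, IsolatedTractError, greedy_coloring

MODELS = ("bym", "icar", "leroux", "iid")


def build_icar_precision(graph: AdjacencyGraph, allow_islands: bool = False) -> sp.csr_matrix:
    """Structure matrix Q = D - W of the intrinsic CAR prior.

    Symmetric, rows sum to zero, rank n minus the number of connected
    components.  Isolated tracts (zero rows) make the ICAR prior undefined
    and are refused unless ``allow_islands``.
    """
    islands = graph.isolated_tracts()
    if islands and not allow_islands:
        raise IsolatedTractError(
            f"{len(islands)} isolated tract(s), e.g. {islands[0]}: ICAR undefined"
        )
    W = graph.adjacency_matrix()
    D = sp.diags(np.asarray(W.sum(axis=1)).ravel())
    return (D - W).tocsr()


# --------------------------------------------------------------- functional
# posterior summaries

def posterior_probability(theta_draws: np.ndarray, threshold: float = 0.8):
    """Exceedance probability PP_i = P(theta_i > 1) from posterior draws.

    Returns ``(pp, exceeds)`` where ``exceeds`` flags PP >= ``threshold``
    (0.8 marks a statistically significant admission excess).
    """
    theta_draws = np.atleast_2d(np.asarray(theta_draws, dtype=float))
    if theta_draws.shape[0] < 1 or theta_draws.size == 0:
        raise ValueError("at least one retained draw is required")
    pp = np.mean(theta_draws > 1.0, axis=0)
    return pp, pp >= threshold


def _pointwise_loglik(theta_draws: np.ndarray, O: np.ndarray, E: np.ndarray) -> np.ndarray:
    mu = E[None, :] * theta_draws
    return O[None, :] * np.log(mu) - mu - gammaln(O + 1.0)[None, :]


def dic(theta_draws: np.ndarray, O: np.ndarray, E: np.ndarray) -> tuple[float, float]:
    """Deviance information criterion and effective parameters p_D.

    DIC = mean deviance + p_D, p_D = mean deviance - deviance at the
    posterior mean of theta; deviance is -2 x Poisson log likelihood with
    offsets E.
    """
    theta_draws = np.atleast_2d(np.asarray(theta_draws, dtype=float))
    if theta_draws.shape[0] < 2:
        raise ValueError("DIC needs at least 2 posterior draws")
    ll = _pointwise_loglik(theta_draws, np.asarray(O, float), np.asarray(E, float))
    dev = -2.0 * ll.sum(axis=1)
    dbar = dev.mean()
    theta_hat = theta_draws.mean(axis=0)
    dhat = -2.0 * _pointwise_loglik(theta_hat[None, :], np.asarray(O, float),
                                    np.asarray(E, float)).sum()
    p_d = dbar - dhat
    return dbar + p_d, p_d


def waic(theta_draws: np.ndarray, O: np.ndarray, E: np.ndarray) -> tuple[float, float]:
    """Watanabe-Akaike information criterion (variance form), deviance scale.

    WAIC = -2 (lppd - p_WAIC); lppd_i = log mean_s p(O_i | theta_i^(s));
    p_WAIC = sum_i Var_s log p(O_i | theta_i^(s)) (sample variance).
    """
    theta_draws = np.atleast_2d(np.asarray(theta_draws, dtype=float))
    S = theta_draws.shape[0]
    if S < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    ll = _pointwise_loglik(theta_draws, np.asarray(O, float), np.asarray(E, float))
    lppd = (logsumexp(ll, axis=0) - np.log(S)).sum()
    p_w = ll.var(axis=0, ddof=1).sum()
    return -2.0 * (lppd - p_w), p_w


def compare_models(fits: list["CARResults"]) -> pd.DataFrame:
    """Rank fitted models on the same data by DIC and WAIC."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if (not np.array_equal(f.observed, ref.observed)
                or not np.allclose(f.expected, ref.expected)):
            raise ValueError("model comparison requires fits on identical data")
    tab = pd.DataFrame({
        "model": [f.model for f in fits],
        "DIC": [f.dic for f in fits],
        "p_D": [f.p_d for f in fits],
        "WAIC": [f.waic for f in fits],
        "p_WAIC": [f.p_waic for f in fits],
    })
    tab["dDIC"] = tab["DIC"] - tab["DIC"].min()
    tab["dWAIC"] = tab["WAIC"] - tab["WAIC"].min()
    tab["rank_DIC"] = tab["DIC"].rank(method="min").astype(int)
    tab["rank_WAIC"] = tab["WAIC"].rank(method="min").astype(int)
    tab["best_DIC"] = tab["dDIC"] == 0
    tab["best_WAIC"] = tab["dWAIC"] == 0
    return tab.sort_values("DIC").reset_index(drop=True)


# ------------------------------------------------------------------ sampler

def _adapt(log_step, acc, t, target):
    gamma = min(0.25, 2.0 / np.sqrt(t + 1.0))
    return log_step + gamma * (acc - target)


def _run_chain(model, O, E, graph_arrays, hyper, n_iter, burnin, thin, lam_fixed, rng):
    """One MCMC chain.  Returns dict of retained draws."""
    W, deg, colors, color_rows, comp_labels, ncomp, ei, ej, evals = graph_arrays
    n = O.shape[0]
    a_tau, b_tau = hyper["tau_shape"], hyper["tau_rate"]
    alpha_var = hyper["alpha_var"]
    likelihood_on = hyper.get("likelihood_on", True)
    if not likelihood_on:
        O = np.zeros_like(O)
        E = np.zeros_like(E)

    has_u = model in ("bym", "icar")
    has_v = model in ("bym", "iid")
    is_ler = model == "leroux"

    # data-driven start: decompose the empirical log-rate into level,
    # neighbour-smoothed (spatial) and residual parts — a cold all-zero
    # start lets short runs stall in an over-smoothed state
    pos = E > 0
    eta0 = np.zeros(n)
    eta0[pos] = np.log((O[pos] + 0.5) / E[pos])
    alpha = float(eta0[pos].mean()) if pos.any() else 0.0
    resid = np.where(pos, eta0 - alpha, 0.0)
    deg_safe = np.maximum(deg, 1.0)
    smooth0 = 0.5 * (resid + (W @ resid) / deg_safe)

    def _prec(x):
        return float(np.clip(1.0 / max(np.var(x), 1e-3), 0.1, 100.0))

    u = np.zeros(n)
    v = np.zeros(n)
    b = np.zeros(n)
    tau_u = tau_v = tau_b = 1.0
    lam = 0.5 if lam_fixed is None else float(lam_fixed)
    if has_u:
        u = smooth0 - smooth0.mean()
        tau_u = _prec(u)
    if model == "bym":
        v = resid - smooth0
        tau_v = _prec(v)
    elif model == "iid":
        v = resid.copy()
        tau_v = _prec(v)
    elif model == "leroux":
        b = resid - resid.mean() if (lam_fixed is not None and lam >= 1.0) else resid.copy()
        tau_b = _prec(b)

    ls_u = np.full(n, np.log(0.3))
    ls_v = np.full(n, np.log(0.3))
    ls_b = np.full(n, np.log(0.3))
    ls_alpha = np.log(0.1)
    ls_lam = np.log(0.5)

    n_keep = (n_iter - burnin) // thin
    out = {
        "theta": np.empty((n_keep, n)),
        "alpha": np.empty(n_keep),
    }
    if has_u:
        out["tau_u"] = np.empty(n_keep)
    if has_v:
        out["tau_v"] = np.empty(n_keep)
    if is_ler:
        out["tau"] = np.empty(n_keep)
        out["lam"] = np.empty(n_keep)
    kept = 0

    sum_O = O.sum()

    def center_field(x, shift_alpha=True, scale=1.0):
        # project onto the per-component sum-to-zero subspace; the removed
        # level is absorbed by the intercept (exact for connected graphs)
        nonlocal alpha
        if ncomp == 1:
            m = x.mean()
            x -= m
            if shift_alpha:
                alpha += scale * m
        else:
            g = x.mean()
            means = np.bincount(comp_labels, weights=x) / np.bincount(comp_labels)
            x -= means[comp_labels]
            if shift_alpha:
                alpha += scale * g
        return x

    O_S = [O[S] for S in colors]
    E_S = [E[S] for S in colors]
    deg_S = [deg[S] for S in colors]

    for t in range(n_iter):
        adapting = t < burnin

        if has_u:
            base_all = E * np.exp(alpha + v) if has_v else E * np.exp(alpha)
            for ci, S in enumerate(colors):
                nbr = color_rows[ci] @ u
                uS = u[S]
                step = np.exp(ls_u[S])
                up = uS + step * rng.standard_normal(S.size)
                dpri = -0.5 * tau_u * (deg_S[ci] * (up**2 - uS**2) - 2.0 * (up - uS) * nbr)
                dlik = O_S[ci] * (up - uS) - base_all[S] * (np.exp(up) - np.exp(uS))
                acc = np.log(rng.random(S.size)) < dpri + dlik
                u[S] = np.where(acc, up, uS)
                if adapting:
                    ls_u[S] = _adapt(ls_u[S], acc.astype(float), t, 0.44)
            u = center_field(u)
            quad = np.sum((u[ei] - u[ej]) ** 2)
            tau_u = rng.gamma(a_tau + 0.5 * (n - ncomp), 1.0 / (b_tau + 0.5 * quad))

        if has_v:
            stepv = np.exp(ls_v)
            vp = v + stepv * rng.standard_normal(n)
            base = E * np.exp(alpha + (u if has_u else 0.0))
            dlik = O * (vp - v) - base * (np.exp(vp) - np.exp(v))
            dpri = -0.5 * tau_v * (vp**2 - v**2)
            acc = np.log(rng.random(n)) < dpri + dlik
            v = np.where(acc, vp, v)
            if adapting:
                ls_v = _adapt(ls_v, acc.astype(float), t, 0.44)
            tau_v = rng.gamma(a_tau + 0.5 * n, 1.0 / (b_tau + 0.5 * np.sum(v**2)))

        if is_ler:
            for ci, S in enumerate(colors):
                nbr = color_rows[ci] @ b
                bS = b[S]
                step = np.exp(ls_b[S])
                bp = bS + step * rng.standard_normal(S.size)
                pr_diag = (1.0 - lam) + lam * deg_S[ci]
                dpri = -0.5 * tau_b * (pr_diag * (bp**2 - bS**2)
                                       - 2.0 * lam * (bp - bS) * nbr)
                base = E_S[ci] * np.exp(alpha)
                dlik = O_S[ci] * (bp - bS) - base * (np.exp(bp) - np.exp(bS))
                acc = np.log(rng.random(S.size)) < dpri + dlik
                b[S] = np.where(acc, bp, bS)
                if adapting:
                    ls_b[S] = _adapt(ls_b[S], acc.astype(float), t, 0.44)
            if lam_fixed is not None and lam >= 1.0:
                b = center_field(b)
            quad_sp = np.sum((b[ei] - b[ej]) ** 2)
            quad = (1.0 - lam) * np.sum(b**2) + lam * quad_sp
            rank = n - ncomp if (lam_fixed is not None and lam >= 1.0) else n
            tau_b = rng.gamma(a_tau + 0.5 * rank, 1.0 / (b_tau + 0.5 * quad))
            if lam_fixed is None:
                lo = logit(lam)
                lp = lo + np.exp(ls_lam) * rng.standard_normal()
                lamp = float(expit(lp))
                sumsq = np.sum(b**2)

                def lam_logpost(x):
                    # 0.5 log det((1-x)I + xQ) - 0.5 tau b'R(x)b + logit Jacobian
                    return (0.5 * np.sum(np.log1p(x * (evals - 1.0)))
                            - 0.5 * tau_b * ((1.0 - x) * sumsq + x * quad_sp)
                            + np.log(x) + np.log1p(-x))

                acc_l = np.log(rng.random()) < lam_logpost(lamp) - lam_logpost(lam)
                if acc_l:
                    lam = lamp
                if adapting:
                    ls_lam = _adapt(ls_lam, float(acc_l), t, 0.44)

        # intercept random walk
        eta_rest = (u if has_u else 0.0) + (v if has_v else 0.0) + (b if is_ler else 0.0)
        s_e = np.sum(E * np.exp(eta_rest))
        ap = alpha + np.exp(ls_alpha) * rng.standard_normal()
        dlik = sum_O * (ap - alpha) - s_e * (np.exp(ap) - np.exp(alpha))
        dpri = -0.5 * (ap**2 - alpha**2) / alpha_var
        acc_a = np.log(rng.random()) < dlik + dpri
        if acc_a:
            alpha = ap
        if adapting:
            ls_alpha = _adapt(ls_alpha, float(acc_a), t, 0.44)

        if t >= burnin and (t - burnin) % thin == 0:
            out["theta"][kept] = np.exp(alpha + eta_rest)
            out["alpha"][kept] = alpha
            if has_u:
                out["tau_u"][kept] = tau_u
            if has_v:
                out["tau_v"][kept] = tau_v
            if is_ler:
                out["tau"][kept] = tau_b
                out["lam"][kept] = lam
            kept += 1
    return out


# -------------------------------------------------------------------- model

class CARModel:
    """Spatial Poisson model for per-tract counts with CAR random effects.

    Parameters
    ----------
    observed, expected : arrays in ``graph.tract_ids`` order
        Observed counts O_i and indirectly standardised expecteds E_i.
        Tracts with E_i = 0 are excluded from the likelihood (their SRR is
        undefined) but kept in the output.
    graph : AdjacencyGraph
        Tract contiguity; drives the CAR structure matrix Q = D - W.
    model : {"bym", "icar", "leroux", "iid"}
    lam : float, optional
        Fix the Leroux mixing parameter instead of sampling it (lam=0 is
        the independent-effects limit, lam=1 the intrinsic CAR limit).
    tau_prior : (shape, rate)
        Gamma hyperprior on all precisions; default gamma(1, 0.0005).
    alpha_prior_var : float
        Variance of the normal prior on the intercept.
    """

    def __init__(self, observed, expected, graph: AdjacencyGraph, model: str = "bym",
                 lam: float | None = None, tau_prior: tuple[float, float] = (1.0, 5e-4),
                 alpha_prior_var: float = 1e3, allow_islands: bool = False):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {model!r}")
        O = np.asarray(observed, dtype=float)
        E = np.asarray(expected, dtype=float)
        if O.shape != (graph.n,) or E.shape != (graph.n,):
            raise ValueError("observed/expected must be vectors in graph tract order")
        if (O < 0).any() or (E < 0).any():
            raise ValueError("observed and expected counts must be non-negative")
        if not (E > 0).any():
            raise ValueError("all tracts have zero expected count")
        if tau_prior[0] <= 0 or tau_prior[1] <= 0:
            raise ValueError("gamma hyperprior shape and rate must be positive")
        if lam is not None and not (0.0 <= lam <= 1.0):
            raise ValueError("lam must lie in [0, 1]")
        if model in ("bym", "icar") or (model == "leroux" and lam != 0.0):
            build_icar_precision(graph, allow_islands=allow_islands)  # raises on islands
        self.model = model
        self.lam = lam
        self.graph = graph
        self.observed = O
        self.expected = E
        self.likelihood_mask = E > 0
        if not self.likelihood_mask.all():
            warnings.warn(
                f"{(~self.likelihood_mask).sum()} tract(s) with E=0 excluded from the "
                "likelihood; their SRR is undefined", stacklevel=2)
        self.tau_prior = tau_prior
        self.alpha_prior_var = alpha_prior_var

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, graph: AdjacencyGraph, sex: str | None = None,
                       **kwargs) -> "CARModel":
        """Build from a ``tract_id, [sex,] O, E`` table (e.g. SAR output)."""
        if sex is not None:
            df = df[df["sex"] == sex]
        d = df.set_index("tract_id")
        missing = [t for t in graph.tract_ids if t not in d.index]
        if missing:
            raise ValueError(f"{len(missing)} tract(s) missing from table, e.g. {missing[0]}")
        d = d.loc[list(graph.tract_ids)]
        return cls(d["O"].to_numpy(), d["E"].to_numpy(), graph, **kwargs)

    def _graph_arrays(self):
        g = self.graph
        W = g.adjacency_matrix()
        deg = np.asarray(W.sum(axis=1)).ravel()
        colors = greedy_coloring(g)
        color_rows = [W[S] for S in colors]
        comp_labels = g.component_labels()
        ncomp = int(comp_labels.max()) + 1
        idx = g.index
        ei = np.array([idx[tuple(e)[0]] for e in g.edges], dtype=int)
        ej = np.array([idx[tuple(e)[1]] for e in g.edges], dtype=int)
        evals = None
        if self.model == "leroux" and self.lam is None:
            evals = np.linalg.eigvalsh((sp.diags(deg) - W).toarray())
            evals = np.clip(evals, 0.0, None)
        return W, deg, colors, color_rows, comp_labels, ncomp, ei, ej, evals

    def fit(self, n_iter: int = 5000, burnin: int | None = None, thin: int = 1,
            chains: int = 4, seed: int = 0, likelihood_on: bool = True) -> "CARResults":
        """Run the MCMC and summarise the posterior.

        ``likelihood_on=False`` runs the sampler against the prior only
        (prior-predictive validation of the MCMC machinery).
        """
        if burnin is None:
            burnin = n_iter // 2
        if not (n_iter > burnin >= 0):
            raise ValueError("need n_iter > burnin >= 0")
        O = np.where(self.likelihood_mask, self.observed, 0.0)
        E = np.where(self.likelihood_mask, self.expected, 0.0)
        graph_arrays = self._graph_arrays()
        hyper = {"tau_shape": self.tau_prior[0], "tau_rate": self.tau_prior[1],
                 "alpha_var": self.alpha_prior_var, "likelihood_on": likelihood_on}
        chains_out = []
        for cs in np.random.SeedSequence(seed).spawn(chains):
            rng = np.random.default_rng(cs)
            chains_out.append(_run_chain(self.model, O, E, graph_arrays, hyper,
                                         n_iter, burnin, thin, self.lam, rng))
        return CARResults._from_chains(self, chains_out, dict(
            n_iter=n_iter, burnin=burnin, thin=thin, chains=chains, seed=seed))


@dataclass
class CARResults:
    """Posterior summary of a fitted :class:`CARModel`."""

    model: str
    tract_ids: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    likelihood_mask: np.ndarray
    theta_chains: np.ndarray          # (chains, kept, n)
    hyper_chains: dict                # name -> (chains, kept)
    mcmc: dict = field(default_factory=dict)
    pp_threshold: float = 0.8

    @classmethod
    def _from_chains(cls, model: CARModel, chains_out: list[dict], mcmc: dict) -> "CARResults":
        theta = np.stack([c["theta"] for c in chains_out])
        hyper = {k: np.stack([c[k] for c in chains_out])
                 for k in chains_out[0] if k != "theta"}
        return cls(model.model, model.graph.tract_ids, model.observed, model.expected,
                   model.likelihood_mask, theta, hyper, mcmc)

    # ------------------------------------------------------------ summaries

    @property
    def theta_draws(self) -> np.ndarray:
        """Retained draws of theta, chains stacked: (draws, n_tracts)."""
        c, k, n = self.theta_chains.shape
        return self.theta_chains.reshape(c * k, n)

    @property
    def srr(self) -> np.ndarray:
        """Smoothed relative risk: posterior mean of 100*theta (NaN if E=0)."""
        s = 100.0 * self.theta_draws.mean(axis=0)
        return np.where(self.likelihood_mask, s, np.nan)

    @property
    def srr_median(self) -> np.ndarray:
        s = 100.0 * np.median(self.theta_draws, axis=0)
        return np.where(self.likelihood_mask, s, np.nan)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Equal-tail credible interval for 100*theta, shape (n, 2)."""
        a = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(100.0 * self.theta_draws, [a, 100.0 - a], axis=0)
        lo = np.where(self.likelihood_mask, lo, np.nan)
        hi = np.where(self.likelihood_mask, hi, np.nan)
        return np.column_stack([lo, hi])

    @property
    def pp(self) -> np.ndarray:
        """Posterior probability that the relative risk exceeds 100."""
        p, _ = posterior_probability(self.theta_draws)
        return np.where(self.likelihood_mask, p, np.nan)

    @property
    def exceeds(self) -> np.ndarray:
        return self.pp >= self.pp_threshold

    def _masked(self):
        m = self.likelihood_mask
        return self.theta_draws[:, m], self.observed[m], self.expected[m]

    @property
    def dic(self) -> float:
        return dic(*self._masked())[0]

    @property
    def p_d(self) -> float:
        return dic(*self._masked())[1]

    @property
    def waic(self) -> float:
        return waic(*self._masked())[0]

    @property
    def p_waic(self) -> float:
        return waic(*self._masked())[1]

    def hyper_summary(self) -> pd.DataFrame:
        rows = []
        names = ["alpha"] + [k for k in self.hyper_chains if k != "alpha"]
        for name in names:
            d = self.hyper_chains[name].ravel()
            rows.append({"param": name, "mean": d.mean(), "sd": d.std(ddof=1),
                         "q2.5": np.percentile(d, 2.5), "median": np.median(d),
                         "q97.5": np.percentile(d, 97.5)})
        return pd.DataFrame(rows)

    # ---------------------------------------------------------- diagnostics

    def rhat(self) -> dict[str, float]:
        """Max split-chain R-hat for theta, plus each hyperparameter."""
        import arviz as az
        post = {"theta": self.theta_chains}
        post.update(self.hyper_chains)
        idata = az.from_dict(posterior=post)
        r = az.rhat(idata)
        out = {"theta": float(np.nanmax(r["theta"].values))}
        for k in self.hyper_chains:
            out[k] = float(r[k].values)
        return out

    def ess(self) -> dict[str, float]:
        """Min bulk effective sample size for theta, plus hyperparameters."""
        import arviz as az
        post = {"theta": self.theta_chains}
        post.update(self.hyper_chains)
        e = az.ess(az.from_dict(posterior=post))
        out = {"theta": float(np.nanmin(e["theta"].values))}
        for k in self.hyper_chains:
            out[k] = float(e[k].values)
        return out

    @property
    def converged(self) -> bool:
        """True when every split-R-hat is at or below 1.1."""
        ok = max(self.rhat().values()) <= 1.1
        if not ok:
            warnings.warn("MCMC convergence warning: split R-hat above 1.1", stacklevel=2)
        return ok

    # -------------------------------------------------------------- exports

    def to_frame(self, level: float = 0.95) -> pd.DataFrame:
        ci = self.conf_int(level)
        return pd.DataFrame({
            "tract_id": list(self.tract_ids),
            "O": self.observed,
            "E": self.expected,
            "SRR": self.srr,
            "SRR_median": self.srr_median,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "PP": self.pp,
            "exceeds_0.8": self.exceeds,
        })

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        hs = self.hyper_summary()
        lines = [
            f"Spatial Poisson model ({self.model} prior), {len(self.tract_ids)} tracts",
            f"MCMC: {self.mcmc.get('chains')} chains x {self.mcmc.get('n_iter')} iterations "
            f"(burn-in {self.mcmc.get('burnin')}, thin {self.mcmc.get('thin')}, "
            f"seed {self.mcmc.get('seed')})",
            f"DIC = {self.dic:.2f} (p_D = {self.p_d:.2f}); "
            f"WAIC = {self.waic:.2f} (p_WAIC = {self.p_waic:.2f})",
            f"Tracts with PP >= {self.pp_threshold}: {int(np.nansum(self.exceeds))}",
            "",
            hs.to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    def plot_map(self, n_rows=None, n_cols=None, value="SRR", ax=None):
        """Heat-map of a per-tract posterior summary on a lattice geometry."""
        from .plotting import plot_lattice_values
        vals = {"SRR": self.srr, "PP": self.pp}[value]
        return plot_lattice_values(self.tract_ids, vals, n_rows, n_cols,
                                   title=f"{value} ({self.model})", ax=ax)
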