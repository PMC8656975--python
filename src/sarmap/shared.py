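"""Joint smoothing of male and female admission risks.

Shared-component model (Knorr-Held / Best family): one spatial field
delta_i is common to both sexes, entering the male log-risk scaled by
kappa and the female log-risk by 1/kappa, plus sex-specific unstructured
effects:

    log theta_i,m = alpha_m + kappa * delta_i + v_i,m
    log theta_i,f = alpha_f + delta_i / kappa + v_i,f

delta ~ ICAR(tau_delta), v_.,s iid N(0, 1/tau_v,s), log kappa ~ N(0,
sigma_kappa^2) (log-normal with median 1: a priori neither sex loads more
on the shared field).  Borrowing strength across sexes sharpens both risk
maps when the underlying geography of risk is common, which is the model's
purpose; the posterior of kappa and of the cross-sex correlation of
log-risks quantify how shared the geography actually is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .car import CARResults, _adapt, build_icar_precision, dic, waic
from .graph import AdjacencyGraph, greedy_coloring


def sar_cross_correlation(sar_male, sar_female) -> float:
    """Pearson correlation of male vs female per-tract SAR values.

    Undefined SARs (NaN) are dropped pairwise; needs >= 3 common tracts
    with variation in both sexes.
    """
    x = np.asarray(sar_male, dtype=float)
    y = np.asarray(sar_female, dtype=float)
    if x.shape != y.shape:
        raise ValueError("SAR vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 tracts with defined SAR in both sexes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in SAR values")
    return float(np.corrcoef(x, y)[0, 1])


def _run_joint_chain(Om, Em, Of, Ef, graph_arrays, hyper, n_iter, burnin, thin, rng):
    W, deg, colors, color_rows, comp_labels, ncomp, ei, ej = graph_arrays
    n = Om.shape[0]
    a_tau, b_tau = hyper["tau_shape"], hyper["tau_rate"]
    alpha_var = hyper["alpha_var"]
    sk = hyper["kappa_log_sd"]
    kappa_fixed = hyper.get("kappa_fixed")

    # data-driven start (see car._run_chain): shared field from the mean
    # of the two sexes' empirical log-rates, residuals to the iid terms
    O2 = np.stack([Om, Of])
    E2 = np.stack([Em, Ef])
    alpha = np.zeros(2)                      # male, female intercepts
    resid = np.zeros((2, n))
    for s in range(2):
        pos = E2[s] > 0
        eta0 = np.zeros(n)
        eta0[pos] = np.log((O2[s][pos] + 0.5) / E2[s][pos])
        alpha[s] = eta0[pos].mean() if pos.any() else 0.0
        resid[s] = np.where(pos, eta0 - alpha[s], 0.0)
    delta = 0.5 * (resid[0] + resid[1])
    delta -= delta.mean()
    v = resid - delta[None, :]
    clip_prec = lambda x: float(np.clip(1.0 / max(np.var(x), 1e-3), 0.1, 100.0))  # noqa: E731
    tau_d = clip_prec(delta)
    tau_v = np.array([clip_prec(v[0]), clip_prec(v[1])])
    kappa = 1.0 if kappa_fixed is None else float(kappa_fixed)

    ls_d = np.full(n, np.log(0.3))
    ls_v = np.full((2, n), np.log(0.3))
    ls_a = np.full(2, np.log(0.1))
    ls_k = np.log(0.1)

    O = np.stack([Om, Of])
    E = np.stack([Em, Ef])
    sum_O = O.sum(axis=1)

    n_keep = (n_iter - burnin) // thin
    out = {"theta": np.empty((n_keep, 2, n)), "delta": np.empty((n_keep, n)),
           "alpha_m": np.empty(n_keep), "alpha_f": np.empty(n_keep),
           "kappa": np.empty(n_keep), "tau_delta": np.empty(n_keep),
           "tau_v_m": np.empty(n_keep), "tau_v_f": np.empty(n_keep)}
    kept = 0
    load = lambda: np.array([kappa, 1.0 / kappa])  # noqa: E731

    # static per-colour gathers
    O_S = [[O[s][S] for S in colors] for s in range(2)]
    deg_S = [deg[S] for S in colors]

    for t in range(n_iter):
        adapting = t < burnin
        ld = load()

        # shared spatial field, colour-blocked random walk
        expav = [E[s] * np.exp(alpha[s] + v[s]) for s in range(2)]
        for ci, S in enumerate(colors):
            nbr = color_rows[ci] @ delta
            dS = delta[S]
            dp = dS + np.exp(ls_d[S]) * rng.standard_normal(S.size)
            dpri = -0.5 * tau_d * (deg_S[ci] * (dp**2 - dS**2) - 2.0 * (dp - dS) * nbr)
            dlik = np.zeros(S.size)
            for s in range(2):
                dlik += (O_S[s][ci] * ld[s] * (dp - dS)
                         - expav[s][S] * (np.exp(ld[s] * dp) - np.exp(ld[s] * dS)))
            acc = np.log(rng.random(S.size)) < dpri + dlik
            delta[S] = np.where(acc, dp, dS)
            if adapting:
                ls_d[S] = _adapt(ls_d[S], acc.astype(float), t, 0.44)
        # centre delta; the removed level enters each sex scaled by its loading
        if ncomp == 1:
            m = delta.mean()
            delta -= m
            alpha += ld * m
        else:
            g = delta.mean()
            means = np.bincount(comp_labels, weights=delta) / np.bincount(comp_labels)
            delta -= means[comp_labels]
            alpha += ld * g
        quad = np.sum((delta[ei] - delta[ej]) ** 2)
        tau_d = rng.gamma(a_tau + 0.5 * (n - ncomp), 1.0 / (b_tau + 0.5 * quad))

        # sex-specific unstructured effects
        for s in range(2):
            vp = v[s] + np.exp(ls_v[s]) * rng.standard_normal(n)
            base = E[s] * np.exp(alpha[s] + ld[s] * delta)
            dlik = O[s] * (vp - v[s]) - base * (np.exp(vp) - np.exp(v[s]))
            dpri = -0.5 * tau_v[s] * (vp**2 - v[s] ** 2)
            acc = np.log(rng.random(n)) < dpri + dlik
            v[s] = np.where(acc, vp, v[s])
            if adapting:
                ls_v[s] = _adapt(ls_v[s], acc.astype(float), t, 0.44)
            tau_v[s] = rng.gamma(a_tau + 0.5 * n, 1.0 / (b_tau + 0.5 * np.sum(v[s] ** 2)))

        # sharing parameter, random walk on the log scale
        if kappa_fixed is None:
            lk = np.log(kappa)
            lkp = lk + np.exp(ls_k) * rng.standard_normal()
            kp = np.exp(lkp)
            ldp = np.array([kp, 1.0 / kp])
            dlik = 0.0
            for s in range(2):
                base = E[s] * np.exp(alpha[s] + v[s])
                dlik += (np.sum(O[s] * (ldp[s] - ld[s]) * delta)
                         - np.sum(base * (np.exp(ldp[s] * delta) - np.exp(ld[s] * delta))))
            dpri = -0.5 * (lkp**2 - lk**2) / sk**2
            acc_k = np.log(rng.random()) < dlik + dpri
            if acc_k:
                kappa = kp
                ld = ldp
            if adapting:
                ls_k = _adapt(ls_k, float(acc_k), t, 0.44)

        # intercepts
        for s in range(2):
            rest = ld[s] * delta + v[s]
            s_e = np.sum(E[s] * np.exp(rest))
            ap = alpha[s] + np.exp(ls_a[s]) * rng.standard_normal()
            dlik = sum_O[s] * (ap - alpha[s]) - s_e * (np.exp(ap) - np.exp(alpha[s]))
            dpri = -0.5 * (ap**2 - alpha[s] ** 2) / alpha_var
            acc_a = np.log(rng.random()) < dlik + dpri
            if acc_a:
                alpha[s] = ap
            if adapting:
                ls_a[s] = _adapt(ls_a[s], float(acc_a), t, 0.44)

        if t >= burnin and (t - burnin) % thin == 0:
            for s in range(2):
                out["theta"][kept, s] = np.exp(alpha[s] + ld[s] * delta + v[s])
            out["delta"][kept] = delta
            out["alpha_m"][kept] = alpha[0]
            out["alpha_f"][kept] = alpha[1]
            out["kappa"][kept] = kappa
            out["tau_delta"][kept] = tau_d
            out["tau_v_m"][kept] = tau_v[0]
            out["tau_v_f"][kept] = tau_v[1]
            kept += 1
    return out


class SharedComponentModel:
    """Bivariate (male/female) spatial Poisson model with a shared CAR field."""

    def __init__(self, observed_male, expected_male, observed_female, expected_female,
                 graph: AdjacencyGraph, tau_prior=(1.0, 5e-4), alpha_prior_var=1e3,
                 kappa_log_sd: float = 0.5, kappa: float | None = None,
                 allow_islands: bool = False):
        arrays = [np.asarray(a, dtype=float) for a in
                  (observed_male, expected_male, observed_female, expected_female)]
        for a in arrays:
            if a.shape != (graph.n,):
                raise ValueError("all count vectors must match the graph tract set")
            if (a < 0).any():
                raise ValueError("counts must be non-negative")
        build_icar_precision(graph, allow_islands=allow_islands)
        self.graph = graph
        self.Om, self.Em, self.Of, self.Ef = arrays
        self.mask = (self.Em > 0) & (self.Ef > 0)
        if not self.mask.all():
            warnings.warn(f"{(~self.mask).sum()} tract(s) with E=0 in at least one sex "
                          "excluded from the likelihood", stacklevel=2)
        self.tau_prior = tau_prior
        self.alpha_prior_var = alpha_prior_var
        self.kappa_log_sd = kappa_log_sd
        self.kappa_fixed = kappa

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, graph: AdjacencyGraph, **kwargs):
        """Build from a long ``tract_id, sex, O, E`` table covering both sexes."""
        parts = {}
        for sex in ("male", "female"):
            d = df[df["sex"] == sex].set_index("tract_id")
            missing = [t for t in graph.tract_ids if t not in d.index]
            if missing:
                raise ValueError(f"sex {sex!r}: {len(missing)} tract(s) missing")
            d = d.loc[list(graph.tract_ids)]
            parts[sex] = (d["O"].to_numpy(), d["E"].to_numpy())
        return cls(*parts["male"], *parts["female"], graph, **kwargs)

    def fit(self, n_iter: int = 5000, burnin: int | None = None, thin: int = 1,
            chains: int = 4, seed: int = 0) -> "SharedComponentResults":
        if burnin is None:
            burnin = n_iter // 2
        if not (n_iter > burnin >= 0):
            raise ValueError("need n_iter > burnin >= 0")
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
        ga = (W, deg, colors, color_rows, comp_labels, ncomp, ei, ej)
        m = self.mask
        hyper = {"tau_shape": self.tau_prior[0], "tau_rate": self.tau_prior[1],
                 "alpha_var": self.alpha_prior_var, "kappa_log_sd": self.kappa_log_sd,
                 "kappa_fixed": self.kappa_fixed}
        Om = np.where(m, self.Om, 0.0)
        Em = np.where(m, self.Em, 0.0)
        Of = np.where(m, self.Of, 0.0)
        Ef = np.where(m, self.Ef, 0.0)
        chains_out = []
        for cs in np.random.SeedSequence(seed).spawn(chains):
            rng = np.random.default_rng(cs)
            chains_out.append(_run_joint_chain(Om, Em, Of, Ef, ga, hyper,
                                               n_iter, burnin, thin, rng))
        return SharedComponentResults._from_chains(self, chains_out, dict(
            n_iter=n_iter, burnin=burnin, thin=thin, chains=chains, seed=seed))


@dataclass
class SharedComponentResults:
    """Posterior summary of the joint male/female fit."""

    tract_ids: tuple[str, ...]
    observed: dict
    expected: dict
    likelihood_mask: np.ndarray
    theta_chains: np.ndarray          # (chains, kept, 2, n); axis 2 = male, female
    delta_chains: np.ndarray
    hyper_chains: dict
    mcmc: dict = field(default_factory=dict)

    @classmethod
    def _from_chains(cls, model, chains_out, mcmc):
        theta = np.stack([c["theta"] for c in chains_out])
        delta = np.stack([c["delta"] for c in chains_out])
        hyper = {k: np.stack([c[k] for c in chains_out])
                 for k in chains_out[0] if k not in ("theta", "delta")}
        return cls(model.graph.tract_ids,
                   {"male": model.Om, "female": model.Of},
                   {"male": model.Em, "female": model.Ef},
                   model.mask, theta, delta, hyper, mcmc)

    def _sex_axis(self, sex: str) -> int:
        return {"male": 0, "female": 1}[sex]

    def theta_draws(self, sex: str) -> np.ndarray:
        c, k, _, n = self.theta_chains.shape
        return self.theta_chains[:, :, self._sex_axis(sex), :].reshape(c * k, n)

    def per_sex(self, sex: str) -> CARResults:
        """View one sex of the joint fit as a standard results object."""
        s = self._sex_axis(sex)
        return CARResults(
            model=f"shared-component ({sex})",
            tract_ids=self.tract_ids,
            observed=self.observed[sex],
            expected=self.expected[sex],
            likelihood_mask=self.likelihood_mask,
            theta_chains=self.theta_chains[:, :, s, :],
            hyper_chains=self.hyper_chains,
            mcmc=self.mcmc,
        )

    def srr(self, sex: str) -> np.ndarray:
        return self.per_sex(sex).srr

    def pp(self, sex: str) -> np.ndarray:
        return self.per_sex(sex).pp

    @property
    def kappa_draws(self) -> np.ndarray:
        return self.hyper_chains["kappa"].ravel()

    def kappa_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(self.kappa_draws, [a, 100.0 - a])
        return float(lo), float(hi)

    @property
    def cross_correlation_draws(self) -> np.ndarray:
        """Per-draw Pearson correlation over tracts of male vs female log-risk."""
        m = self.likelihood_mask
        lm = np.log(self.theta_draws("male")[:, m])
        lf = np.log(self.theta_draws("female")[:, m])
        lm = lm - lm.mean(axis=1, keepdims=True)
        lf = lf - lf.mean(axis=1, keepdims=True)
        num = (lm * lf).sum(axis=1)
        den = np.sqrt((lm**2).sum(axis=1) * (lf**2).sum(axis=1))
        return num / den

    @property
    def cross_correlation(self) -> float:
        return float(self.cross_correlation_draws.mean())

    def fit_indices(self) -> dict:
        """DIC/WAIC over the joint (both-sex) Poisson likelihood."""
        m = self.likelihood_mask
        th = np.concatenate([self.theta_draws("male")[:, m],
                             self.theta_draws("female")[:, m]], axis=1)
        O = np.concatenate([self.observed["male"][m], self.observed["female"][m]])
        E = np.concatenate([self.expected["male"][m], self.expected["female"][m]])
        d, pd_ = dic(th, O, E)
        w, pw = waic(th, O, E)
        return {"DIC": d, "p_D": pd_, "WAIC": w, "p_WAIC": pw}

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for sex in ("male", "female"):
            f = self.per_sex(sex).to_frame()
            f.insert(1, "sex", sex)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        ki = self.kappa_interval()
        fi = self.fit_indices()
        lines = [
            f"Shared-component spatial model, {len(self.tract_ids)} tracts x 2 sexes",
            f"MCMC: {self.mcmc.get('chains')} chains x {self.mcmc.get('n_iter')} iterations "
            f"(burn-in {self.mcmc.get('burnin')}, seed {self.mcmc.get('seed')})",
            f"kappa: mean {self.kappa_draws.mean():.3f}, 95% CrI ({ki[0]:.3f}, {ki[1]:.3f})",
            f"cross-sex log-risk correlation: {self.cross_correlation:.3f}",
            f"DIC = {fi['DIC']:.2f} (p_D = {fi['p_D']:.2f}); "
            f"WAIC = {fi['WAIC']:.2f} (p_WAIC = {fi['p_WAIC']:.2f})",
        ]
        return "\n".join(lines)
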