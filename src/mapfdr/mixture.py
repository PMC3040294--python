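"""Tri-level hierarchical Bayesian mixture models for areal relative risks.

The model stacks three levels:

1. Likelihood: Y_i ~ Poisson(E_i * theta_i).
2. Mixture on the log relative risk: log(theta_i) = r_i * mu0 + (1 - r_i) * mu1_i,
   with a point mass at mu0 = 0 under the null (pure Poisson variability) and
   an over-dispersed alternative component:
   * PG  variant: exp(mu1_i) ~ Gamma(k, nu), with exponential hyperpriors on
     k and nu (Clayton-Kaldor shrinkage toward the general mean);
   * BYM variant: mu1_i = u_i + v_i, u_i ~ Normal(0, precision lam_u)
     unstructured heterogeneity, v ~ intrinsic CAR with conditional law
     v_i | v_(-i) ~ Normal(mean of neighbours, precision lam_v * n_i)
     (shrinkage toward the local mean), Gamma hyperpriors on both precisions.
3. Null membership: r_i ~ Bernoulli(pi_i), pi_i ~ Beta(c, d), exchangeable
   across areas (or a single shared pi when ``pi_sharing='common'``).

The per-area posterior mean of r_i is the *classification probability*
Prob(r_i = 1 | Y) of belonging to the null set; its complement is the
posterior inclusion probability.  Because the prior mass at the null enters
the probability model explicitly, these probabilities are adjusted for
multiple testing in the local-FDR sense.

Sampling is Metropolis-within-Gibbs.  r_i has a two-point full conditional
(no trans-dimensional moves are needed: the alternative parameters persist,
and are refreshed from their prior/full conditional while an area sits at the
null, keeping the chain irreducible).  pi is conjugate Beta.  The PG
alternative is conjugate Gamma given (k, nu); k and nu move by random-walk
Metropolis on the log scale.  BYM random effects move by componentwise
random-walk Metropolis (exact Gibbs where the likelihood is inactive), with
v updated over a graph colouring so each sweep is a valid scan, re-centred to
sum zero for identifiability; the precisions are conjugate.  All mixture odds
are computed on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

from .areal import AdjacencyMap, AreaTable

__all__ = [
    "MixtureModelSpec",
    "McmcConfig",
    "MixtureDraws",
    "PosteriorSummary",
    "fit_mixture",
    "classification_probabilities",
    "summarize_posterior",
    "gelman_rubin",
    "effective_sample_size",
    "beta_prior_summary",
    "icar_conditional",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class MixtureModelSpec:
    """Model variant and prior settings.

    Parameters
    ----------
    variant : 'pg' or 'bym'
    mu0 : null log relative risk (point mass; 0 unless deliberately moved).
    c, d : Beta(c, d) hyperprior shapes for the null probability pi_i.  The
        default Beta(9.7, 0.3) has mean 0.97, encoding a prior belief that
        around 3% of areas diverge.
    pi_sharing : 'area' for exchangeable area-specific pi_i (default) or
        'common' for a single shared pi.
    k_rate, nu_rate : rates of the exponential hyperpriors on the PG shape k
        and rate nu.
    prec_shape, prec_rate : Gamma hyperprior for the BYM precisions lam_u,
        lam_v.
    fixed_k, fixed_nu, fixed_pi, fixed_lam_u, fixed_lam_v : hold a
        hyperparameter at a known value instead of sampling it (used for
        conjugacy checks and prior studies; ``fixed_pi=0`` disables the null
        component entirely).
    """

    variant: str = "pg"
    mu0: float = 0.0
    c: float = 9.7
    d: float = 0.3
    pi_sharing: str = "area"
    k_rate: float = 0.1
    nu_rate: float = 0.1
    prec_shape: float = 0.5
    prec_rate: float = 0.0005
    fixed_k: float | None = None
    fixed_nu: float | None = None
    fixed_pi: float | None = None
    fixed_lam_u: float | None = None
    fixed_lam_v: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("pg", "bym"):
            raise ValueError(f"variant must be 'pg' or 'bym', got {self.variant!r}")
        if self.pi_sharing not in ("area", "common"):
            raise ValueError("pi_sharing must be 'area' or 'common'")
        if self.c <= 0 or self.d <= 0:
            raise ValueError("Beta hyperprior shapes must be positive")
        for name in ("k_rate", "nu_rate", "prec_shape", "prec_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fixed_pi is not None and not 0.0 <= self.fixed_pi <= 1.0:
            raise ValueError("fixed_pi must lie in [0, 1]")


@dataclass(frozen=True)
class McmcConfig:
    """Chains, iteration counts and seeding.

    Defaults follow common practice for these models (2 chains, long burn-in,
    large stored sample); analyses at test scale use far smaller values and
    verify convergence through the Gelman-Rubin diagnostic instead.
    """

    n_chains: int = 2
    n_burnin: int = 100_000
    n_store: int = 1_000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44
    adapt_batch: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_store < 1:
            raise ValueError("n_store must be >= 1")
        if self.thin < 1 or self.n_burnin < 0:
            raise ValueError("invalid iteration counts")


def icar_conditional(v, neighbour_idx, lam_v: float):
    """Full-conditional mean and precision of each ICAR term.

    mean_i is the average of the current neighbour values and the precision
    is lam_v * n_i.  Islands (no neighbours) get mean 0 and precision 0
    (their conditional is improper; the sampler pins them at 0 instead).
    """
    v = np.asarray(v, dtype=float)
    mean = np.zeros_like(v)
    prec = np.zeros_like(v)
    for i, nbrs in enumerate(neighbour_idx):
        if len(nbrs):
            mean[i] = v[nbrs].mean()
            prec[i] = lam_v * len(nbrs)
    return mean, prec


class _StepAdapter:
    """Batch adaptation of random-walk scales toward a target acceptance rate.

    Active only during burn-in; scales are frozen afterwards so the recorded
    chain satisfies detailed balance.
    """

    def __init__(self, shape, target: float, batch: int):
        self.log_step = np.zeros(shape)
        self.target = target
        self.batch = batch
        self.acc = np.zeros(shape)
        self.n = 0
        self.n_batches = 0
        self.frozen = False

    @property
    def step(self):
        return np.exp(self.log_step)

    def update(self, accepted) -> None:
        if self.frozen:
            return
        self.acc += accepted
        self.n += 1
        if self.n >= self.batch:
            rate = self.acc / self.n
            delta = min(0.25, (self.n_batches + 1) ** -0.5)
            self.log_step += np.where(rate > self.target, delta, -delta)
            self.acc[...] = 0.0
            self.n = 0
            self.n_batches += 1


def _null_logodds(y, e, theta1, pi, mu0):
    """log odds of r_i = 1 (null) vs r_i = 0 given current mu1 and pi."""
    theta0 = math.exp(mu0)
    with np.errstate(divide="ignore"):
        logit_pi = np.log(pi) - np.log1p(-pi)
    return logit_pi + y * (np.log(theta0) - np.log(theta1)) - e * (theta0 - theta1)


def _sample_r(rng, y, e, theta1, pi, mu0, prior_only):
    if prior_only:
        p1 = pi
    else:
        p1 = expit(_null_logodds(y, e, theta1, pi, mu0))
    return (rng.random(y.shape[0]) < p1).astype(np.int8)


def _sample_pi(rng, r, spec: MixtureModelSpec, m: int):
    if spec.fixed_pi is not None:
        return np.full(m, spec.fixed_pi)
    if spec.pi_sharing == "common":
        s = int(r.sum())
        return np.full(m, rng.beta(spec.c + s, spec.d + m - s))
    return rng.beta(spec.c + r, spec.d + 1 - r)


def _run_chain_pg(table, spec, cfg, rng, prior_only):
    y, e, m = table.y.astype(float), table.e, table.m
    k = spec.fixed_k if spec.fixed_k is not None else 1.0
    nu = spec.fixed_nu if spec.fixed_nu is not None else 1.0
    theta1 = np.clip((y + 0.5) / e, 1e-6, None)
    pi = np.full(m, spec.c / (spec.c + spec.d)) if spec.fixed_pi is None else np.full(m, spec.fixed_pi)
    r = _sample_r(rng, y, e, theta1, pi, spec.mu0, prior_only)

    # (log k, log nu, joint ridge move): k and nu are strongly correlated a
    # posteriori (their ratio is the prior mean), so a joint rescaling move
    # along the ridge is added to the componentwise random walks
    adapt = _StepAdapter(3, cfg.target_accept, cfg.adapt_batch)

    def hyper_logpost(k_, nu_, n_act, sum_log_t, sum_t):
        return (n_act * (k_ * math.log(nu_) - gammaln(k_)) + (k_ - 1.0) * sum_log_t
                - nu_ * sum_t - spec.k_rate * k_ - spec.nu_rate * nu_)

    n_iter = cfg.n_burnin + cfg.n_store * cfg.thin
    out = {"r": np.empty((cfg.n_store, m), dtype=np.int8),
           "theta": np.empty((cfg.n_store, m)),
           "mu1": np.empty((cfg.n_store, m)),
           "pi": np.empty((cfg.n_store, m)),
           "k": np.empty(cfg.n_store), "nu": np.empty(cfg.n_store),
           "sum_r": np.empty(cfg.n_store)}
    stored = 0
    for it in range(n_iter):
        if it >= cfg.n_burnin:
            adapt.frozen = True
        # (iii) alternative RR where the area is divergent: conjugate Gamma
        active = (r == 0) & (not prior_only)
        theta1 = np.where(active,
                          rng.gamma(k + y, 1.0 / (nu + e)),
                          theta1)
        theta1 = np.clip(theta1, 1e-300, None)
        # hyper level, partially collapsed: (k, nu) are updated given the
        # active areas' theta1 only — the null areas' values are pure prior
        # draws and are marginalized out, otherwise they pin the hyper
        # conditional and stall mixing.  nu | k is conjugate Gamma under the
        # Exp hyperprior; k moves by random-walk Metropolis on the log scale
        # plus a joint rescaling move along the (k, nu) posterior ridge.
        # Several refreshes per sweep are cheap (fixed sufficient statistics).
        if spec.fixed_k is None or spec.fixed_nu is None:
            n_act = int(active.sum())
            sum_log_t = float(np.log(theta1[active]).sum())
            sum_t = float(theta1[active].sum())
            for _ in range(5):
                step = adapt.step
                acc = np.zeros(3)
                if spec.fixed_nu is None:
                    nu = rng.gamma(1.0 + n_act * k, 1.0 / (spec.nu_rate + sum_t))
                if spec.fixed_k is None:
                    k_prop = k * math.exp(step[0] * rng.standard_normal())
                    log_a = (hyper_logpost(k_prop, nu, n_act, sum_log_t, sum_t)
                             - hyper_logpost(k, nu, n_act, sum_log_t, sum_t)
                             + math.log(k_prop) - math.log(k))
                    if math.log(rng.random()) < log_a:
                        k = k_prop
                        acc[0] = 1.0
                    scale = math.exp(step[2] * rng.standard_normal())
                    k_prop = k * scale
                    nu_prop = nu * scale if spec.fixed_nu is None else nu
                    jac = 2.0 * math.log(scale) if spec.fixed_nu is None else math.log(scale)
                    log_a = (hyper_logpost(k_prop, nu_prop, n_act, sum_log_t, sum_t)
                             - hyper_logpost(k, nu, n_act, sum_log_t, sum_t) + jac)
                    if math.log(rng.random()) < log_a:
                        k, nu = k_prop, nu_prop
                        acc[2] = 1.0
                adapt.update(acc)
        # prior refresh of mu1 for areas at the null (keeps the chain
        # irreducible; drawn from the freshly updated hyper level)
        theta1 = np.where(active, theta1, rng.gamma(k, 1.0 / nu, size=m))
        theta1 = np.clip(theta1, 1e-300, None)
        # (i) null membership, (ii) conjugate pi
        r = _sample_r(rng, y, e, theta1, pi, spec.mu0, prior_only)
        pi = _sample_pi(rng, r, spec, m)
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            out["r"][stored] = r
            out["mu1"][stored] = np.log(theta1)
            out["theta"][stored] = np.where(r == 1, math.exp(spec.mu0), theta1)
            out["pi"][stored] = pi
            out["k"][stored] = k
            out["nu"][stored] = nu
            out["sum_r"][stored] = r.sum()
            stored += 1
    return out


def _colour_classes(neighbour_idx, m):
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for i, nbrs in enumerate(neighbour_idx):
        g.add_edges_from((i, int(j)) for j in nbrs)
    colours = nx.greedy_color(g, strategy="largest_first")
    classes: dict[int, list[int]] = {}
    for node, col in colours.items():
        classes.setdefault(col, []).append(node)
    return [np.array(sorted(nodes), dtype=np.int64) for nodes in classes.values()]


def _run_chain_bym(table, neighbour_idx, spec, cfg, rng, prior_only):
    y, e, m = table.y.astype(float), table.e, table.m
    n_i = np.array([len(nb) for nb in neighbour_idx], dtype=float)
    islands = n_i == 0
    non_isl = ~islands
    classes = [c[n_i[c] > 0] for c in _colour_classes(neighbour_idx, m)]
    classes = [c for c in classes if c.size]
    # rank of the ICAR precision on the non-island subgraph
    g = nx.Graph()
    g.add_nodes_from(np.flatnonzero(non_isl).tolist())
    edges = [(i, int(j)) for i, nbrs in enumerate(neighbour_idx) for j in nbrs if i < j]
    g.add_edges_from(edges)
    icar_rank = max(int(non_isl.sum()) - nx.number_connected_components(g), 0) if non_isl.any() else 0
    edge_a = np.array([a for a, _ in edges], dtype=np.int64)
    edge_b = np.array([b for _, b in edges], dtype=np.int64)

    lam_u = spec.fixed_lam_u if spec.fixed_lam_u is not None else 10.0
    lam_v = spec.fixed_lam_v if spec.fixed_lam_v is not None else 10.0
    u = np.zeros(m)
    v = np.zeros(m)
    pi = np.full(m, spec.c / (spec.c + spec.d)) if spec.fixed_pi is None else np.full(m, spec.fixed_pi)
    r = np.ones(m, dtype=np.int8)

    adapt_u = _StepAdapter(m, cfg.target_accept, cfg.adapt_batch)
    adapt_v = _StepAdapter(m, cfg.target_accept, cfg.adapt_batch)
    adapt_u.log_step[:] = math.log(0.5)
    adapt_v.log_step[:] = math.log(0.5)

    def loglik(mu1, idx):
        # Poisson log-likelihood term for divergent areas only, up to constants
        active = (r[idx] == 0) & (not prior_only)
        lam = e[idx] * np.exp(np.clip(mu1, -500, 500))
        return np.where(active, y[idx] * mu1 - lam, 0.0)

    n_iter = cfg.n_burnin + cfg.n_store * cfg.thin
    out = {"r": np.empty((cfg.n_store, m), dtype=np.int8),
           "theta": np.empty((cfg.n_store, m)),
           "mu1": np.empty((cfg.n_store, m)),
           "pi": np.empty((cfg.n_store, m)),
           "lam_u": np.empty(cfg.n_store), "lam_v": np.empty(cfg.n_store),
           "sum_r": np.empty(cfg.n_store)}
    stored = 0
    all_idx = np.arange(m)
    for it in range(n_iter):
        if it >= cfg.n_burnin:
            adapt_u.frozen = adapt_v.frozen = True
        # unstructured heterogeneity u: conditionally independent across areas
        free = (r == 1) | prior_only
        u_gibbs = rng.standard_normal(m) / math.sqrt(lam_u)
        u_prop = u + adapt_u.step * rng.standard_normal(m)
        log_a = (loglik(u_prop + v, all_idx) - loglik(u + v, all_idx)
                 - 0.5 * lam_u * (u_prop ** 2 - u ** 2))
        acc = np.log(rng.random(m)) < log_a
        u = np.where(free, u_gibbs, np.where(acc, u_prop, u))
        adapt_u.update(np.where(free, (rng.random(m) < cfg.target_accept), acc).astype(float))
        # clustering v: colour-class scan so each conditional sees fixed neighbours
        sweep_acc = np.zeros(m)
        for cls in classes:
            vbar = np.array([v[neighbour_idx[i]].mean() for i in cls])
            prec = lam_v * n_i[cls]
            free_c = free[cls]
            v_gibbs = vbar + rng.standard_normal(cls.size) / np.sqrt(prec)
            v_prop = v[cls] + adapt_v.step[cls] * rng.standard_normal(cls.size)
            log_a = (loglik(u[cls] + v_prop, cls) - loglik(u[cls] + v[cls], cls)
                     - 0.5 * prec * ((v_prop - vbar) ** 2 - (v[cls] - vbar) ** 2))
            acc_c = np.log(rng.random(cls.size)) < log_a
            v[cls] = np.where(free_c, v_gibbs, np.where(acc_c, v_prop, v[cls]))
            sweep_acc[cls] = np.where(free_c, rng.random(cls.size) < cfg.target_accept, acc_c)
        adapt_v.update(sweep_acc)
        v[islands] = 0.0
        # sum-to-zero identifiability: shift the level into u (u+v invariant)
        if non_isl.any():
            shift = v[non_isl].mean()
            v[non_isl] -= shift
            u[non_isl] += shift
        # conjugate precision updates
        if spec.fixed_lam_u is None:
            lam_u = rng.gamma(spec.prec_shape + 0.5 * m,
                              1.0 / (spec.prec_rate + 0.5 * float(u @ u)))
        if spec.fixed_lam_v is None and icar_rank > 0:
            ssq = float(((v[edge_a] - v[edge_b]) ** 2).sum())
            lam_v = rng.gamma(spec.prec_shape + 0.5 * icar_rank,
                              1.0 / (spec.prec_rate + 0.5 * ssq))
        mu1 = u + v
        theta1 = np.exp(np.clip(mu1, -300, 300))
        r = _sample_r(rng, y, e, theta1, pi, spec.mu0, prior_only)
        pi = _sample_pi(rng, r, spec, m)
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            out["r"][stored] = r
            out["mu1"][stored] = mu1
            out["theta"][stored] = np.where(r == 1, math.exp(spec.mu0), theta1)
            out["pi"][stored] = pi
            out["lam_u"][stored] = lam_u
            out["lam_v"][stored] = lam_v
            out["sum_r"][stored] = r.sum()
            stored += 1
    return out


@dataclass
class MixtureDraws:
    """Posterior draw store: per-area arrays are (chains, draws, areas),
    monitored scalars are (chains, draws)."""

    ids: list[str]
    spec: MixtureModelSpec
    config: McmcConfig
    per_area: dict[str, np.ndarray]
    scalars: dict[str, np.ndarray]

    @property
    def n_chains(self) -> int:
        return next(iter(self.per_area.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.per_area.values())).shape[1]

    @property
    def m(self) -> int:
        return len(self.ids)

    def pooled(self, key: str) -> np.ndarray:
        """Draws pooled across chains: (chains*draws, areas) or (chains*draws,)."""
        a = self.per_area[key] if key in self.per_area else self.scalars[key]
        return a.reshape(-1, *a.shape[2:])


def fit_mixture(
    table: AreaTable,
    adj: AdjacencyMap | None = None,
    spec: MixtureModelSpec | None = None,
    cfg: McmcConfig | None = None,
    prior_only: bool = False,
) -> MixtureDraws:
    """Fit the tri-level mixture by MCMC and return the posterior draw store.

    The BYM variant requires an adjacency covering the table's areas; the PG
    variant ignores adjacency.  ``prior_only`` drops every likelihood
    contribution, so the chain samples the prior (used to validate the
    hierarchy: the long-run mean of pi_i must return c/(c+d)).

    Reproducibility: the full draw store is a deterministic function of
    ``cfg.seed``; chains receive independent child seeds.
    """
    spec = spec or MixtureModelSpec()
    cfg = cfg or McmcConfig()
    if spec.variant == "bym":
        if adj is None:
            raise ValueError("the BYM variant requires an adjacency map")
        neighbour_idx = adj.neighbour_indices(table)
        n_islands = sum(1 for nb in neighbour_idx if len(nb) == 0)
        if n_islands:
            import warnings

            warnings.warn(f"{n_islands} area(s) have no neighbours; their "
                          "spatial term is pinned at 0", stacklevel=2)
    ss = np.random.SeedSequence(cfg.seed)
    chains = []
    for child in ss.spawn(cfg.n_chains):
        rng = np.random.default_rng(child)
        if spec.variant == "pg":
            chains.append(_run_chain_pg(table, spec, cfg, rng, prior_only))
        else:
            chains.append(_run_chain_bym(table, neighbour_idx, spec, cfg, rng, prior_only))
    per_area_keys = ["r", "theta", "mu1", "pi"]
    scalar_keys = [k for k in chains[0] if k not in per_area_keys]
    per_area = {k: np.stack([c[k] for c in chains]) for k in per_area_keys}
    scalars = {k: np.stack([c[k] for c in chains]) for k in scalar_keys}
    return MixtureDraws(list(table.ids), spec, cfg, per_area, scalars)


def classification_probabilities(draws: MixtureDraws) -> tuple[np.ndarray, np.ndarray]:
    """Per-area Prob(r_i = 1 | Y) (classification) and its complement
    (inclusion), estimated by the across-draw mean of r_i pooled over chains."""
    r = draws.pooled("r")
    if r.size == 0:
        raise ValueError("empty draw store")
    p_null = r.mean(axis=0)
    return p_null, 1.0 - p_null


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one scalar across >= 2 chains.

    Classic between/within form: with W the mean within-chain variance and
    B/n the variance of the chain means, PSRF = sqrt(((n-1)/n W + B/n) / W).
    Values near 1 indicate convergence.
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = a.shape[1]
    if n < 2:
        raise ValueError("need >= 2 draws per chain")
    w = a.var(axis=1, ddof=1).mean()
    b_over_n = a.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else math.inf
    var_plus = (n - 1) / n * w + b_over_n
    # floored at 1: values below 1 are estimation noise, not anti-convergence
    return float(max(math.sqrt(var_plus / w), 1.0))


def effective_sample_size(chains) -> float:
    """Effective number of draws via Geyer's initial monotone sequence,
    computed per chain on FFT autocorrelations and summed."""
    a = np.atleast_2d(np.asarray(chains, dtype=float))
    total = 0.0
    for x in a:
        n = x.size
        x = x - x.mean()
        var = float(x @ x) / n
        if var == 0.0 or n < 4:
            total += n
            continue
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(x, nfft)
        acf = np.fft.irfft(f * np.conjugate(f))[:n].real / (var * n)
        # sums of adjacent pairs; truncate at first negative, enforce monotone
        pair = acf[: (n // 2) * 2].reshape(-1, 2).sum(axis=1)
        s = 0.0
        prev = np.inf
        for g in pair:
            if g < 0:
                break
            g = min(g, prev)
            s += g
            prev = g
        tau = max(2.0 * s - 1.0, 1.0)
        total += n / tau
    return total


@dataclass
class PosteriorSummary:
    """Per-area posterior summaries plus convergence diagnostics."""

    frame: pd.DataFrame
    psrf: dict[str, float]
    ess: dict[str, float]
    level: float

    @property
    def max_psrf(self) -> float:
        return max(self.psrf.values()) if self.psrf else float("nan")


def summarize_posterior(draws: MixtureDraws, level: float = 0.95) -> PosteriorSummary:
    """Posterior mean/median relative risks, equal-tailed credible intervals,
    classification/inclusion probabilities and Gelman-Rubin diagnostics."""
    if not 0 < level < 1:
        raise ValueError("credible level must lie in (0, 1)")
    theta = draws.pooled("theta")
    if theta.size == 0:
        raise ValueError("empty draw store")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    p_null, p_incl = classification_probabilities(draws)
    frame = pd.DataFrame({
        "area_id": draws.ids,
        "rr_mean": theta.mean(axis=0),
        "rr_median": np.median(theta, axis=0),
        # ECDF quantiles: invariant under pooling identical chains
        "rr_low": np.quantile(theta, lo_q, axis=0, method="inverted_cdf"),
        "rr_high": np.quantile(theta, hi_q, axis=0, method="inverted_cdf"),
        "prob_null": p_null,
        "prob_divergent": p_incl,
        "pi_mean": draws.pooled("pi").mean(axis=0),
    })
    psrf: dict[str, float] = {}
    ess: dict[str, float] = {}
    if draws.n_chains >= 2 and draws.n_draws >= 2:
        for key, arr in draws.scalars.items():
            psrf[key] = gelman_rubin(arr)
            ess[key] = effective_sample_size(arr)
        mean_mu1 = draws.per_area["mu1"].mean(axis=2)
        psrf["mean_mu1"] = gelman_rubin(mean_mu1)
        ess["mean_mu1"] = effective_sample_size(mean_mu1)
    return PosteriorSummary(frame, psrf, ess, level)


def beta_prior_summary(c: float, d: float, quantiles=(0.10, 0.25, 0.50, 0.75, 0.90)) -> dict:
    """Mean and quantiles of the Beta(c, d) hyperprior on the null probability.

    Returned at full precision; round to 2 decimals for display.  Useful for
    eliciting (c, d) from a prior belief about the fraction of divergent
    areas: Beta(9.7, 0.3) has mean 0.97 and concentrates pi near 1.
    """
    if c <= 0 or d <= 0:
        raise ValueError("Beta shapes must be positive")
    dist = stats.beta(c, d)
    return {"mean": float(dist.mean()),
            "quantiles": {float(q): float(dist.ppf(q)) for q in quantiles}}


@dataclass
class SweepResult:
    """Posterior summaries per Beta(c, d) hyperprior, with ordered
    classification probabilities for quantile-quantile comparison."""

    priors: list[tuple[float, float]]
    summaries: dict[tuple[float, float], PosteriorSummary]
    prob_null: dict[tuple[float, float], np.ndarray]

    def qq_pairs(self, prior_a, prior_b) -> np.ndarray:
        """(n, 2) array of sorted classification probabilities under the two
        priors; same ranking puts points on the bisector."""
        a = np.sort(self.prob_null[tuple(prior_a)])
        b = np.sort(self.prob_null[tuple(prior_b)])
        return np.column_stack([a, b])

    def rank_correlation(self, prior_a, prior_b) -> float:
        rho = stats.spearmanr(self.prob_null[tuple(prior_a)],
                              self.prob_null[tuple(prior_b)]).statistic
        return float(rho)


def sensitivity_sweep(
    table: AreaTable,
    adj: AdjacencyMap | None,
    spec: MixtureModelSpec,
    cd_pairs,
    cfg: McmcConfig,
) -> SweepResult:
    """Refit the model under each Beta(c, d) hyperprior with the same data and
    MCMC seed, for sensitivity analysis of the classification probabilities."""
    summaries = {}
    probs = {}
    priors = [tuple(map(float, p)) for p in cd_pairs]
    for c, d in priors:
        draws = fit_mixture(table, adj, replace(spec, c=c, d=d), cfg)
        s = summarize_posterior(draws)
        summaries[(c, d)] = s
        probs[(c, d)] = s.frame["prob_null"].to_numpy()
    return SweepResult(priors, summaries, probs)
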