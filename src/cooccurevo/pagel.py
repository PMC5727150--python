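"""Correlated evolution of two binary traits on a phylogeny.

Implements the classic likelihood test of correlated (discrete) character
evolution: two binary traits evolve along a rooted tree as a continuous-time
Markov chain over the joint state space {00, 01, 10, 11}.  Under the
*independent* model each trait has its own gain and loss rate (4 parameters);
under the *dependent* model the transition rate of each trait may depend on
the current state of the other (8 parameters).  Double transitions (both
traits changing in one instant) have rate zero in both models.

Model support is compared by Bayes factors: each model's marginal
likelihood is estimated by stepping-stone sampling over power posteriors,
with independent exponential priors on all rates (mean configurable,
default 10, matching the common "priorAll exp 10" choice), and

    BF = 2 * (log Z_dependent - log Z_independent)

is reported with the conventional interpretation bands: < 2 weak evidence,
2-5 positive, 5-10 strong, > 10 very strong.  A likelihood-ratio test
(chi-square, df = 4) of the maximized likelihoods is reported alongside as
a fast frequentist cross-check.

State indexing convention: state s = 2*x + y, i.e. (00, 01, 10, 11).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats

from .traits import TraitMatrix
from .trees import Phylogeny, PruningArrays

__all__ = [
    "RateParamsIndependent",
    "RateParamsDependent",
    "MCMCConfig",
    "MLFit",
    "MCMCSamples",
    "MarginalLik",
    "PagelResult",
    "rate_matrix",
    "transition_probs",
    "pruning_loglik",
    "fit_ml",
    "mcmc_sample",
    "marginal_loglik",
    "compute_bf",
    "pagel_test",
    "stationary_distribution",
]

STATE_LABELS = ("00", "01", "10", "11")

_RATE_LO, _RATE_HI = 1e-8, 1e3


def _check_rates(vals, names) -> None:
    for v, name in zip(vals, names):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"rate {name} must be finite and nonnegative, got {v}")


@dataclass(frozen=True)
class RateParamsIndependent:
    """Four rates: each trait its own two-state chain.

    ``ax``/``bx`` are the gain (0->1) and loss (1->0) rates of trait x,
    ``ay``/``by`` those of trait y, per unit branch length.
    """

    ax: float
    bx: float
    ay: float
    by: float

    def __post_init__(self) -> None:
        _check_rates(self.as_vector(), self.names())

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("ax", "bx", "ay", "by")

    def as_vector(self) -> np.ndarray:
        return np.array([self.ax, self.bx, self.ay, self.by], dtype=float)

    @classmethod
    def from_vector(cls, v) -> "RateParamsIndependent":
        return cls(*map(float, v))

    def embed(self) -> "RateParamsDependent":
        """The same process expressed in the 8-rate dependent parameterization."""
        return RateParamsDependent(
            q00_10=self.ax, q01_11=self.ax,
            q10_00=self.bx, q11_01=self.bx,
            q00_01=self.ay, q10_11=self.ay,
            q01_00=self.by, q11_10=self.by,
        )


@dataclass(frozen=True)
class RateParamsDependent:
    """Eight rates q[s -> s'] over state pairs differing in exactly one trait."""

    q00_10: float
    q00_01: float
    q10_00: float
    q10_11: float
    q01_00: float
    q01_11: float
    q11_10: float
    q11_01: float

    def __post_init__(self) -> None:
        _check_rates(self.as_vector(), self.names())

    @staticmethod
    def names() -> tuple[str, ...]:
        return (
            "q00_10", "q00_01", "q10_00", "q10_11",
            "q01_00", "q01_11", "q11_10", "q11_01",
        )

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.q00_10, self.q00_01, self.q10_00, self.q10_11,
             self.q01_00, self.q01_11, self.q11_10, self.q11_01],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, v) -> "RateParamsDependent":
        return cls(*map(float, v))


RateParams = RateParamsIndependent | RateParamsDependent

# (from-state, to-state) for each dependent rate, in RateParamsDependent order;
# state index is 2*x + y.
_DEP_EDGES = (
    (0, 2), (0, 1), (2, 0), (2, 3),
    (1, 0), (1, 3), (3, 2), (3, 1),
)


def n_params(model_flavor: str) -> int:
    if model_flavor == "independent":
        return 4
    if model_flavor == "dependent":
        return 8
    raise ValueError(f"unknown model flavor {model_flavor!r}")


def params_from_vector(v, model_flavor: str) -> RateParams:
    if model_flavor == "independent":
        return RateParamsIndependent.from_vector(v)
    return RateParamsDependent.from_vector(v)


def rate_matrix(params: RateParams) -> np.ndarray:
    """4x4 generator over (00, 01, 10, 11); double transitions have rate 0."""
    if isinstance(params, RateParamsIndependent):
        params = params.embed()
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(params.as_vector(), _DEP_EDGES):
        Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t): a stochastic matrix (rows sum to 1)."""
    if t < 0:
        raise ValueError("branch length t must be nonnegative")
    P = linalg.expm(np.asarray(Q, dtype=float) * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0, from the null space of Q^T."""
    w, v = np.linalg.eig(np.asarray(Q, dtype=float).T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    s = pi.sum()
    if s == 0:
        raise ValueError("could not extract stationary distribution")
    return pi / s


def _batch_transition_probs(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """expm(Q t) for a whole vector of branch lengths at once.

    Uses one eigendecomposition of Q when it is well conditioned, falling
    back to per-branch Pade expm otherwise.  Rows are clipped to [0, inf)
    and renormalized to absorb round-off.
    """
    ts = np.asarray(ts, dtype=float)
    P = None
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            E = np.exp(np.outer(ts, w))  # (B, 4)
            P = np.einsum("ij,bj,jk->bik", V, E, Vinv).real
            if not np.all(np.isfinite(P)) or P.min() < -1e-7:
                P = None
    except np.linalg.LinAlgError:
        P = None
    if P is None:
        P = np.stack([linalg.expm(Q * t) for t in ts])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _resolve_root_prior(root_prior, Q: np.ndarray) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            return np.full(4, 0.25)
        if root_prior == "stationary":
            return stationary_distribution(Q)
        raise ValueError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (4,) or np.any(pi < 0) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("root prior must be a length-4 probability vector")
    return pi


class PruningLikelihood:
    """Felsenstein pruning over the 4-state joint chain, set up once per dataset.

    Precomputes postorder index arrays and tip partials so repeated
    likelihood evaluations (optimization, MCMC) cost one batched matrix
    exponential plus a postorder sweep.  Per-node rescaling keeps the
    computation stable on large trees.
    """

    def __init__(self, tree: Phylogeny | PruningArrays, traits: TraitMatrix,
                 root_prior="uniform"):
        self.arrays = tree.as_arrays() if isinstance(tree, Phylogeny) else tree
        traits.validate_against(self.arrays.tip_labels)
        self._tip_partials = traits.tip_partials(self.arrays.tip_labels)
        self._root_prior_spec = root_prior
        # group internal nodes into levels (all children strictly below),
        # so the postorder sweep runs as a few batched einsums per level
        arr = self.arrays
        level = np.zeros(arr.n_nodes, dtype=int)
        for k, nid in enumerate(arr.postorder_internal):
            c1, c2 = arr.children[k]
            level[nid] = max(level[c1], level[c2]) + 1
        self._levels = []
        ids_all = arr.postorder_internal
        for lv in range(1, level.max() + 1):
            mask = level[ids_all] == lv
            ids = ids_all[mask]
            ch = arr.children[mask]
            self._levels.append((ids, ch[:, 0], ch[:, 1]))

    def loglik_from_Q(self, Q: np.ndarray) -> float:
        arr = self.arrays
        P = _batch_transition_probs(Q, arr.branch_lengths)
        partials = np.zeros((arr.n_nodes, 4))
        partials[: arr.n_tips] = self._tip_partials
        logscale = 0.0
        for ids, c1, c2 in self._levels:
            p = (np.einsum("nij,nj->ni", P[c1], partials[c1])
                 * np.einsum("nij,nj->ni", P[c2], partials[c2]))
            m = p.max(axis=1)
            if np.any(m <= 0) or not np.all(np.isfinite(m)):
                return -np.inf
            partials[ids] = p / m[:, None]
            logscale += float(np.log(m).sum())
        pi = _resolve_root_prior(self._root_prior_spec, Q)
        site = float(pi @ partials[arr.root])
        if site <= 0:
            return -np.inf
        return math.log(site) + logscale

    def loglik(self, params: RateParams) -> float:
        return self.loglik_from_Q(rate_matrix(params))

    def loglik_vector(self, v: np.ndarray, model_flavor: str) -> float:
        return self.loglik(params_from_vector(v, model_flavor))


def pruning_loglik(tree: Phylogeny | PruningArrays, traits: TraitMatrix,
                   Q: np.ndarray, root_prior="uniform") -> float:
    """Log-likelihood of the trait data under generator ``Q``.

    Tip partials are indicator vectors (all-ones for a missing trait);
    internal partials combine children through the branch transition
    matrices; the root is summed against ``root_prior`` ("uniform",
    "stationary", or an explicit length-4 vector).
    """
    return PruningLikelihood(tree, traits, root_prior).loglik_from_Q(np.asarray(Q, float))


@dataclass
class MLFit:
    """Maximum-likelihood fit of one model flavor."""

    model_flavor: str
    rates: RateParams
    loglik: float
    converged: bool
    n_starts: int


def fit_ml(tree: Phylogeny | PruningArrays, traits: TraitMatrix,
           model_flavor: str, n_starts: int = 5, seed: int = 0,
           root_prior="uniform", fixed_rates: dict[str, float] | None = None) -> MLFit:
    """Box-constrained ML estimation of the rates (bounds [1e-8, 1e3]).

    Optimizes over log-rates with L-BFGS-B from ``n_starts`` starting
    points (a fixed moderate-rate start plus draws from a unit-mean
    exponential); the best converged optimum is returned.  ``fixed_rates``
    pins named rates at constants (excluded from optimization).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    like = PruningLikelihood(tree, traits, root_prior)
    vm = _VectorModel(model_flavor, fixed_rates)
    k = vm.k
    if k == 0:
        raise ValueError("all rates fixed; nothing to optimize")
    rng = np.random.default_rng(seed)

    def neg(theta):
        ll = vm.loglik(like, np.exp(theta))
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(math.log(_RATE_LO), math.log(_RATE_HI))] * k
    starts = [np.full(k, math.log(0.5))]
    while len(starts) < n_starts:
        starts.append(np.log(np.clip(rng.exponential(1.0, size=k), _RATE_LO, _RATE_HI)))
    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"ML optimization failed on all {n_starts} starts for "
            f"{model_flavor} model"
        )
    return MLFit(
        model_flavor=model_flavor,
        rates=params_from_vector(vm.full_vector(np.exp(best.x)), model_flavor),
        loglik=-float(best.fun),
        converged=bool(any_ok),
        n_starts=n_starts,
    )


@dataclass
class MCMCConfig:
    """Settings for the Metropolis sampler and stepping-stone estimator.

    ``prior_mean`` is the mean of the exponential prior placed on every
    rate (default 10).  ``chain_length``/``burn_in``/``thinning`` apply to
    each chain run (each power-posterior rung reuses them).  ``n_stones``
    is the number of stepping-stone rungs between prior and posterior.
    """

    prior_mean: float = 10.0
    chain_length: int = 2000
    burn_in: int = 500
    thinning: int = 1
    n_stones: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_mean <= 0:
            raise ValueError("prior_mean must be positive")
        if self.n_stones < 4:
            raise ValueError("n_stones must be >= 4")
        if self.chain_length <= self.burn_in:
            raise ValueError("chain_length must exceed burn_in")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class MCMCSamples:
    """Posterior (or power-posterior) samples of the natural-scale rates."""

    model_flavor: str
    rates: np.ndarray  # (n_samples, n_params)
    logliks: np.ndarray  # (n_samples,)
    acceptance_rate: float
    ess: np.ndarray  # (n_params,)
    param_names: tuple[str, ...]


def _ess(x: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


class _VectorModel:
    """Maps a vector of free rates into the model's full rate vector.

    ``fixed_rates`` pins named rates at constants; only the free rates are
    sampled/integrated and carry a prior.
    """

    def __init__(self, model_flavor: str, fixed_rates: dict[str, float] | None = None):
        self.model_flavor = model_flavor
        names = (RateParamsIndependent.names() if model_flavor == "independent"
                 else RateParamsDependent.names())
        fixed_rates = fixed_rates or {}
        unknown = set(fixed_rates) - set(names)
        if unknown:
            raise ValueError(f"unknown rate names in fixed_rates: {sorted(unknown)}")
        self.template = np.zeros(len(names))
        self.free_idx = []
        self.free_names = []
        for i, n in enumerate(names):
            if n in fixed_rates:
                v = float(fixed_rates[n])
                if v < 0 or not np.isfinite(v):
                    raise ValueError(f"fixed rate {n} must be finite and nonnegative")
                self.template[i] = v
            else:
                self.free_idx.append(i)
                self.free_names.append(n)
        self.free_idx = np.asarray(self.free_idx, dtype=np.intp)
        self.k = len(self.free_idx)

    def full_vector(self, free: np.ndarray) -> np.ndarray:
        v = self.template.copy()
        v[self.free_idx] = free
        return v

    def loglik(self, like: "PruningLikelihood", free: np.ndarray) -> float:
        return like.loglik_vector(self.full_vector(free), self.model_flavor)


def _log_target(theta: np.ndarray, loglik: float, beta: float, prior_mean: float) -> float:
    # density over theta = log(q): exp prior on q plus the log-scale Jacobian
    q = np.exp(theta)
    return beta * loglik + float(-q.sum() / prior_mean + theta.sum())


def _run_chain(like: PruningLikelihood, vm: _VectorModel, config: MCMCConfig,
               rng: np.random.Generator, beta: float = 1.0,
               theta0: np.ndarray | None = None, step0: float = 0.5):
    """Adaptive random-walk Metropolis on log-rates at inverse temperature beta.

    Returns (theta samples, loglik samples, acceptance rate, final theta,
    final step).  Step size adapts toward ~30% acceptance during burn-in
    only, so the recorded chain is a valid (fixed-kernel) Markov chain.
    """
    k = vm.k
    if theta0 is None:
        theta0 = np.log(rng.exponential(config.prior_mean, size=k))
    theta = np.clip(theta0, math.log(_RATE_LO), math.log(_RATE_HI))
    ll = vm.loglik(like, np.exp(theta))
    lp = _log_target(theta, ll, beta, config.prior_mean)
    step = step0
    n_keep = (config.chain_length - config.burn_in) // config.thinning
    thetas = np.empty((n_keep, k))
    lls = np.empty(n_keep)
    kept = 0
    accepted_post = 0
    post_steps = 0
    window_acc = 0
    for it in range(config.chain_length):
        prop = theta + step * rng.standard_normal(k)
        if np.all(prop >= math.log(_RATE_LO)) and np.all(prop <= math.log(_RATE_HI)):
            ll_p = vm.loglik(like, np.exp(prop))
            lp_p = _log_target(prop, ll_p, beta, config.prior_mean)
            if math.log(rng.random()) < lp_p - lp:
                theta, ll, lp = prop, ll_p, lp_p
                window_acc += 1
                if it >= config.burn_in:
                    accepted_post += 1
        if it < config.burn_in:
            if (it + 1) % 25 == 0:
                rate = window_acc / 25.0
                step = float(np.clip(step * math.exp(0.6 * (rate - 0.3)), 1e-3, 10.0))
                window_acc = 0
        else:
            post_steps += 1
            if (it - config.burn_in) % config.thinning == 0 and kept < n_keep:
                thetas[kept] = theta
                lls[kept] = ll
                kept += 1
    acc = accepted_post / max(post_steps, 1)
    return thetas[:kept], lls[:kept], acc, theta, step


def mcmc_sample(tree: Phylogeny | PruningArrays, traits: TraitMatrix,
                model_flavor: str, config: MCMCConfig,
                root_prior="uniform",
                fixed_rates: dict[str, float] | None = None) -> MCMCSamples:
    """Posterior sampling of the rates under exponential(prior_mean) priors.

    ``fixed_rates`` pins named rates at constants (they are excluded from
    sampling and carry no prior); the returned samples cover the free
    rates only, in ``param_names`` order.
    """
    like = PruningLikelihood(tree, traits, root_prior)
    vm = _VectorModel(model_flavor, fixed_rates)
    if vm.k == 0:
        raise ValueError("all rates fixed; nothing to sample")
    rng = np.random.default_rng(config.seed)
    thetas, lls, acc, _, _ = _run_chain(like, vm, config, rng)
    rates = np.exp(thetas)
    ess = np.array([_ess(rates[:, j]) for j in range(rates.shape[1])])
    return MCMCSamples(
        model_flavor=model_flavor, rates=rates, logliks=lls,
        acceptance_rate=acc, ess=ess, param_names=tuple(vm.free_names),
    )


@dataclass
class MarginalLik:
    """Stepping-stone marginal-likelihood estimate with its MC standard error."""

    model_flavor: str
    logz: float
    se: float
    betas: np.ndarray
    rung_logratios: np.ndarray
    rung_se: np.ndarray
    acceptance_rates: np.ndarray


def _rung_logmeanexp(logw: np.ndarray, n_eff: float) -> tuple[float, float]:
    """log mean exp of the rung weights, with a delta-method standard error."""
    m = logw.max()
    u = np.exp(logw - m)
    mean_u = u.mean()
    val = m + math.log(mean_u)
    if len(u) > 1 and mean_u > 0:
        se = float(u.std(ddof=1) / (mean_u * math.sqrt(max(n_eff, 1.0))))
    else:
        se = 0.0
    return float(val), se


def marginal_loglik(tree: Phylogeny | PruningArrays, traits: TraitMatrix,
                    model_flavor: str, config: MCMCConfig,
                    root_prior="uniform",
                    fixed_rates: dict[str, float] | None = None) -> MarginalLik:
    """Stepping-stone estimate of the log marginal likelihood.

    Rungs run from the prior (beta = 0, sampled i.i.d.) to the posterior
    along beta_k = (k / K)^(1/0.3) — the quantiles of a Beta(0.3, 1)
    distribution, which concentrates rungs near the prior where the
    integrand varies fastest.  Chains at successive rungs are warm-started.

    ``fixed_rates`` pins named rates: they carry no prior and are not
    integrated over.  With every rate fixed the model has no free
    parameters and logZ equals the log-likelihood exactly (se = 0).
    """
    like = PruningLikelihood(tree, traits, root_prior)
    vm = _VectorModel(model_flavor, fixed_rates)
    rng = np.random.default_rng(config.seed)
    K = config.n_stones
    if vm.k == 0:
        ll = vm.loglik(like, np.empty(0))
        return MarginalLik(model_flavor=model_flavor, logz=float(ll), se=0.0,
                           betas=np.array([0.0, 1.0]),
                           rung_logratios=np.array([ll]),
                           rung_se=np.array([0.0]),
                           acceptance_rates=np.array([np.nan]))
    betas = (np.arange(K + 1) / K) ** (1.0 / 0.3)
    n_prior = max((config.chain_length - config.burn_in) // config.thinning, 2)

    logratios = np.empty(K)
    rung_se = np.empty(K)
    acc_rates = np.full(K, np.nan)

    # rung 0: exact i.i.d. prior draws
    q0 = rng.exponential(config.prior_mean, size=(n_prior, vm.k))
    ll0 = np.array([vm.loglik(like, q) for q in q0])
    if not np.all(np.isfinite(ll0)):
        bad = int(np.sum(~np.isfinite(ll0)))
        raise RuntimeError(f"non-finite likelihood at {bad} prior draws (rung 0)")
    d = betas[1] - betas[0]
    logratios[0], rung_se[0] = _rung_logmeanexp(d * ll0, float(len(ll0)))

    theta = np.log(np.clip(q0[int(np.argmax(ll0))], _RATE_LO, _RATE_HI))
    step = 0.5
    for k in range(1, K):
        thetas, lls, acc, theta, step = _run_chain(
            like, vm, config, rng, beta=betas[k], theta0=theta, step0=step
        )
        if len(lls) == 0 or not np.all(np.isfinite(lls)):
            raise RuntimeError(f"non-finite likelihoods at rung {k} (beta={betas[k]:.4f})")
        acc_rates[k] = acc
        d = betas[k + 1] - betas[k]
        logw = d * lls
        n_eff = _ess(logw) if np.var(logw) > 0 else float(len(logw))
        logratios[k], rung_se[k] = _rung_logmeanexp(logw, n_eff)

    return MarginalLik(
        model_flavor=model_flavor,
        logz=float(logratios.sum()),
        se=float(np.sqrt((rung_se ** 2).sum())),
        betas=betas,
        rung_logratios=logratios,
        rung_se=rung_se,
        acceptance_rates=acc_rates,
    )


_BF_BANDS = ("weak", "positive", "strong", "very strong")


def compute_bf(logz_dep: float, logz_ind: float) -> tuple[float, str]:
    """Bayes factor 2*(logZ_dep - logZ_ind) and its interpretation band.

    Bands follow the conventional scale: < 2 weak evidence, 2-5 positive,
    5-10 strong, > 10 very strong.
    """
    if not (np.isfinite(logz_dep) and np.isfinite(logz_ind)):
        raise ValueError("log marginal likelihoods must be finite")
    bf = 2.0 * (logz_dep - logz_ind)
    if bf < 2:
        band = "weak"
    elif bf < 5:
        band = "positive"
    elif bf <= 10:
        band = "strong"
    else:
        band = "very strong"
    return float(bf), band


@dataclass
class PagelResult:
    """Full output of the correlated-evolution test."""

    logl_ml_ind: float
    logl_ml_dep: float
    lrt_stat: float
    lrt_p: float
    rates_ind: RateParamsIndependent
    rates_dep: RateParamsDependent
    logz_ind: float
    logz_dep: float
    logz_ind_se: float
    logz_dep_se: float
    bf: float
    bf_band: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.logl_ml_dep < self.logl_ml_ind - 1e-6:
            warnings.warn(
                "dependent ML log-likelihood below independent one beyond "
                "tolerance; optimizer may not have converged"
            )

    def to_dict(self) -> dict:
        return {
            "logL_ml_independent": self.logl_ml_ind,
            "logL_ml_dependent": self.logl_ml_dep,
            "lrt_stat": self.lrt_stat,
            "lrt_p": self.lrt_p,
            "rates_independent": dict(zip(self.rates_ind.names(),
                                          self.rates_ind.as_vector().tolist())),
            "rates_dependent": dict(zip(self.rates_dep.names(),
                                        self.rates_dep.as_vector().tolist())),
            "logZ_independent": self.logz_ind,
            "logZ_dependent": self.logz_dep,
            "logZ_independent_se": self.logz_ind_se,
            "logZ_dependent_se": self.logz_dep_se,
            "bayes_factor": self.bf,
            "bf_band": self.bf_band,
            "diagnostics": self.diagnostics,
        }


def pagel_test(tree: Phylogeny | PruningArrays, traits: TraitMatrix,
               config: MCMCConfig | None = None, n_starts: int = 3,
               root_prior="uniform") -> PagelResult:
    """Run the full test: ML fits, LRT, stepping-stone marginals, Bayes factor."""
    config = config or MCMCConfig()
    ml_ind = fit_ml(tree, traits, "independent", n_starts=n_starts,
                    seed=config.seed, root_prior=root_prior)
    ml_dep = fit_ml(tree, traits, "dependent", n_starts=n_starts,
                    seed=config.seed + 1, root_prior=root_prior)
    # the independent model is nested in the dependent one: polish the
    # dependent fit from the embedded independent optimum as an extra start
    like = PruningLikelihood(tree, traits, root_prior)
    emb = ml_ind.rates.embed().as_vector()
    res = optimize.minimize(
        lambda th: -like.loglik_vector(np.exp(th), "dependent"),
        np.log(np.clip(emb, _RATE_LO, _RATE_HI)),
        method="L-BFGS-B",
        bounds=[(math.log(_RATE_LO), math.log(_RATE_HI))] * 8,
    )
    if np.isfinite(res.fun) and -res.fun > ml_dep.loglik:
        ml_dep = MLFit("dependent", RateParamsDependent.from_vector(np.exp(res.x)),
                       -float(res.fun), True, ml_dep.n_starts + 1)
    lrt = max(2.0 * (ml_dep.loglik - ml_ind.loglik), 0.0)
    lrt_p = float(stats.chi2.sf(lrt, df=4))

    mz_ind = marginal_loglik(tree, traits, "independent", config, root_prior)
    cfg_dep = MCMCConfig(prior_mean=config.prior_mean,
                         chain_length=config.chain_length, burn_in=config.burn_in,
                         thinning=config.thinning, n_stones=config.n_stones,
                         seed=config.seed + 10007)
    mz_dep = marginal_loglik(tree, traits, "dependent", cfg_dep, root_prior)
    bf, band = compute_bf(mz_dep.logz, mz_ind.logz)
    return PagelResult(
        logl_ml_ind=ml_ind.loglik,
        logl_ml_dep=ml_dep.loglik,
        lrt_stat=lrt,
        lrt_p=lrt_p,
        rates_ind=ml_ind.rates,
        rates_dep=ml_dep.rates,
        logz_ind=mz_ind.logz,
        logz_dep=mz_dep.logz,
        logz_ind_se=mz_ind.se,
        logz_dep_se=mz_dep.se,
        bf=bf,
        bf_band=band,
        diagnostics={
            "ml_converged_independent": ml_ind.converged,
            "ml_converged_dependent": ml_dep.converged,
            "ss_acceptance_independent": mz_ind.acceptance_rates.tolist(),
            "ss_acceptance_dependent": mz_dep.acceptance_rates.tolist(),
        },
    )
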