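"""Hierarchical Bayesian p1 model for matched resistant/parental networks.

The undirected p1 exponential random graph model gives every dyad (i, j)
an independent Bernoulli edge with

    log Pr(Y_ij1 = 1) = lambda_ij + theta + alpha_i + alpha_j
    log Pr(Y_ij0 = 1) = lambda_ij

where ``theta`` is a global density parameter, ``alpha_i`` the propensity
of gene i to form edges, and ``lambda_ij = -log(1 + exp(eta))`` the
normalizer, so the edge probability is the logistic function of
``eta = theta + alpha_i + alpha_j``.

Both condition networks are modelled jointly: each condition has its own
theta (normal prior with Gamma-distributed precision) and each gene a
pair of propensities ``(alpha_i^R, alpha_i^P)`` with a shared bivariate
normal prior whose inverse covariance carries a Wishart prior.  The
non-conjugate logistic blocks (theta and each alpha pair) are updated by
random-walk Metropolis within Gibbs; the precision and inverse-covariance
blocks have conjugate Gamma / Wishart full conditionals.  After each
post-burn-in sweep one network per condition is drawn from the current
edge probabilities; the reported posterior edge probability is the
fraction of those sampled networks containing the dyad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .ggr import DyadTable

CONDS = ("R", "P")


@dataclass
class PriorSpec:
    """Hyperparameters of the hierarchy."""

    a0: float = 0.001  # Gamma shape for the theta precision
    b0: float = 0.001  # Gamma rate for the theta precision
    wishart_df: float = 2.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(2))


@dataclass
class MCMCConfig:
    n_iter: int = 15_000
    burn_in: int = 10_000
    seed: int = 0
    thin: int = 1
    step_theta: float = 0.2
    step_alpha: float = 0.5
    adapt: bool = True
    shared_theta: bool = False  # one theta for both conditions

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")


@dataclass
class P1State:
    """One point in parameter space (used for density checks and tests)."""

    theta: np.ndarray  # (2,) for (R, P)
    tau: np.ndarray  # (2,) precisions of theta
    alpha: np.ndarray  # (n_genes, 2)
    sigma: np.ndarray  # (2, 2) covariance of the alpha pairs


def edge_probability(theta: float, alpha_i: float, alpha_j: float) -> float:
    """Logistic edge probability exp(eta)/(1+exp(eta)), eta=theta+ai+aj."""
    return float(expit(theta + alpha_i + alpha_j))


def _softplus(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def log_joint(state: P1State, dyads: DyadTable, priors: PriorSpec) -> float:
    """Unnormalized log posterior density of ``state`` given the dyads."""
    sign, logdet = np.linalg.slogdet(state.sigma)
    if sign <= 0:
        raise ValueError("sigma must be positive definite")
    n = len(dyads.genes)
    gene_index = {g: k for k, g in enumerate(dyads.genes)}
    i_idx = np.array([gene_index[a] for a, _ in dyads.pairs])
    j_idx = np.array([gene_index[b] for _, b in dyads.pairs])
    total = 0.0
    for c, u in zip((0, 1), (dyads.u_r, dyads.u_p)):
        eta = state.theta[c] + state.alpha[i_idx, c] + state.alpha[j_idx, c]
        total += float(np.sum(u * eta - _softplus(eta)))
        total += float(
            stats.norm.logpdf(state.theta[c], 0.0, 1.0 / np.sqrt(state.tau[c]))
        )
        total += float(
            stats.gamma.logpdf(state.tau[c], priors.a0, scale=1.0 / priors.b0)
        )
    sigma_inv = np.linalg.inv(state.sigma)
    quad = np.einsum("ik,kl,il->i", state.alpha, sigma_inv, state.alpha)
    total += float(-0.5 * np.sum(quad) - 0.5 * n * (logdet + 2 * np.log(2 * np.pi)))
    total += float(
        stats.wishart.logpdf(sigma_inv, priors.wishart_df, priors.wishart_scale)
    )
    return total


@dataclass
class P1Fit:
    """Posterior summaries and posterior-predictive edge frequencies."""

    genes: list[str]
    pairs: list[tuple[str, str]]
    n_samples: int
    edge_freq: dict[str, np.ndarray]  # condition -> sampled-network frequency
    prob_mean: dict[str, np.ndarray]  # posterior mean of analytic edge prob
    theta_chain: dict[str, np.ndarray]
    tau_chain: dict[str, np.ndarray]
    alpha_mean: np.ndarray  # (n_genes, 2)
    alpha_sd: np.ndarray
    sigma_mean: np.ndarray
    acceptance: dict[str, float]
    seed: int

    def theta_summary(self, cond: str) -> tuple[float, float]:
        chain = self.theta_chain[cond]
        return float(chain.mean()), float(chain.std(ddof=1))

    def mc_se(self, cond: str) -> np.ndarray:
        p = self.edge_freq[cond]
        return np.sqrt(p * (1 - p) / self.n_samples)


def fit(
    dyads: DyadTable,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> P1Fit:
    """Metropolis-within-Gibbs fit of the joint two-condition p1 model.

    Sweep structure: random-walk Metropolis updates for each theta and for
    each gene's propensity pair, the conjugate Gamma draw for each theta
    precision, and the conjugate Wishart draw for the inverse covariance
    of the propensity pairs.  Proposal scales adapt toward ~0.44
    acceptance during burn-in and are then frozen.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    if len(dyads) == 0:
        raise ValueError("empty dyad table")
    rng = np.random.default_rng(config.seed)
    genes = dyads.genes
    n = len(genes)
    gene_index = {g: k for k, g in enumerate(genes)}
    i_idx = np.array([gene_index[a] for a, _ in dyads.pairs])
    j_idx = np.array([gene_index[b] for _, b in dyads.pairs])
    n_dyads = len(dyads)
    u = np.column_stack([dyads.u_r, dyads.u_p]).astype(float)  # (D, 2)

    # incidence: for each gene, its dyad rows and the partner gene index
    inc_rows: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    inc_partner: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    order = np.arange(n_dyads)
    for g in range(n):
        rows = order[(i_idx == g) | (j_idx == g)]
        inc_rows[g] = rows
        inc_partner[g] = np.where(i_idx[rows] == g, j_idx[rows], i_idx[rows])
    u_inc = [u[inc_rows[g]] for g in range(n)]  # (deg, 2) each
    u_sum_inc = [ui.sum(axis=0) for ui in u_inc]

    # initialization: theta at the logit of the observed density, alpha 0
    dens = np.clip(u.mean(axis=0), 1e-3, 1 - 1e-3)
    theta = np.log(dens / (1 - dens))
    if config.shared_theta:
        theta[:] = theta.mean()
    tau = np.ones(2)
    alpha = np.zeros((n, 2))
    sigma = np.eye(2)
    sigma_inv = np.eye(2)
    asum = alpha[i_idx] + alpha[j_idx]  # (D, 2)

    step_theta = np.full(2, config.step_theta)
    step_alpha = np.full(n, config.step_alpha)
    acc_theta = np.zeros(2)
    try_theta = np.zeros(2)
    acc_alpha = np.zeros(n)
    try_alpha = np.zeros(n)
    win_acc_t = np.zeros(2)
    win_acc_a = np.zeros(n)
    adapt_window = 50

    n_keep = config.n_iter - config.burn_in
    edge_counts = np.zeros((n_dyads, 2))
    prob_sum = np.zeros((n_dyads, 2))
    theta_chain = np.empty((n_keep, 2))
    tau_chain = np.empty((n_keep, 2))
    alpha_sum = np.zeros((n, 2))
    alpha_sq = np.zeros((n, 2))
    sigma_sum = np.zeros((2, 2))
    kept = 0

    wishart_df = priors.wishart_df + n
    prior_scale_inv = np.linalg.inv(priors.wishart_scale)

    for it in range(config.n_iter):
        in_burn = it < config.burn_in

        # --- theta blocks (random-walk Metropolis)
        if config.shared_theta:
            prop = theta[0] + step_theta[0] * rng.standard_normal()
            eta_old = theta[0] + asum
            eta_new = prop + asum
            dloglik = float(
                np.sum(u) * (prop - theta[0])
                - np.sum(_softplus(eta_new) - _softplus(eta_old))
            )
            # a shared theta sits in both conditions' normal priors
            dlogpri = -0.5 * float(tau.sum()) * (prop**2 - theta[0] ** 2)
            try_theta += 1
            if np.log(rng.random()) < dloglik + dlogpri:
                theta[:] = prop
                acc_theta += 1
                win_acc_t += 1
        else:
            for c in range(2):
                prop = theta[c] + step_theta[c] * rng.standard_normal()
                eta_old = theta[c] + asum[:, c]
                eta_new = prop + asum[:, c]
                dloglik = float(
                    u[:, c].sum() * (prop - theta[c])
                    - np.sum(_softplus(eta_new) - _softplus(eta_old))
                )
                dlogpri = -0.5 * tau[c] * (prop**2 - theta[c] ** 2)
                try_theta[c] += 1
                if np.log(rng.random()) < dloglik + dlogpri:
                    theta[c] = prop
                    acc_theta[c] += 1
                    win_acc_t[c] += 1

        # --- theta precisions (conjugate Gamma full conditional)
        for c in range(2):
            shape = priors.a0 + 0.5
            rate = priors.b0 + 0.5 * theta[c] ** 2
            tau[c] = rng.gamma(shape, 1.0 / rate)

        # --- propensity pairs, one Metropolis block per gene
        for g in range(n):
            prop = alpha[g] + step_alpha[g] * rng.standard_normal(2)
            partners = alpha[inc_partner[g]]  # (deg, 2)
            eta_old = theta + alpha[g] + partners
            eta_new = theta + prop + partners
            dloglik = float(
                u_sum_inc[g] @ (prop - alpha[g])
                - np.sum(_softplus(eta_new) - _softplus(eta_old))
            )
            dlogpri = -0.5 * float(
                prop @ sigma_inv @ prop - alpha[g] @ sigma_inv @ alpha[g]
            )
            try_alpha[g] += 1
            if np.log(rng.random()) < dloglik + dlogpri:
                delta = prop - alpha[g]
                alpha[g] = prop
                asum[inc_rows[g]] += delta
                acc_alpha[g] += 1
                win_acc_a[g] += 1

        # --- inverse covariance (conjugate Wishart full conditional)
        scale = np.linalg.inv(prior_scale_inv + alpha.T @ alpha)
        sigma_inv = stats.wishart.rvs(df=wishart_df, scale=scale, random_state=rng)
        sigma = np.linalg.inv(sigma_inv)

        # --- adaptation during burn-in only
        if config.adapt and in_burn and (it + 1) % adapt_window == 0:
            rate_t = win_acc_t / adapt_window
            step_theta *= np.exp(np.clip(rate_t - 0.44, -0.5, 0.5))
            rate_a = win_acc_a / adapt_window
            step_alpha *= np.exp(np.clip(rate_a - 0.44, -0.5, 0.5))
            win_acc_t[:] = 0
            win_acc_a[:] = 0
            acc_theta[:] = 0
            try_theta[:] = 0
            acc_alpha[:] = 0
            try_alpha[:] = 0

        # --- posterior-predictive network draw after burn-in
        if not in_burn and (it - config.burn_in) % config.thin == 0:
            p = expit(theta + asum)  # (D, 2)
            edge_counts += rng.random((n_dyads, 2)) < p
            prob_sum += p
            theta_chain[kept] = theta
            tau_chain[kept] = tau
            alpha_sum += alpha
            alpha_sq += alpha**2
            sigma_sum += sigma
            kept += 1

    theta_chain = theta_chain[:kept]
    tau_chain = tau_chain[:kept]
    freq = edge_counts / kept
    prob_mean = prob_sum / kept
    alpha_mean = alpha_sum / kept
    alpha_var = np.maximum(alpha_sq / kept - alpha_mean**2, 0.0)
    acceptance = {
        "theta_R": float(acc_theta[0] / max(try_theta[0], 1)),
        "theta_P": float(acc_theta[1] / max(try_theta[1], 1)),
        "alpha": float(acc_alpha.sum() / max(try_alpha.sum(), 1)),
    }
    for block, rate in acceptance.items():
        if not 0.05 <= rate <= 0.95:
            warnings.warn(
                f"acceptance rate for block {block} is {rate:.3f}, outside "
                "[0.05, 0.95]; inspect trace summaries",
                RuntimeWarning,
                stacklevel=2,
            )
    return P1Fit(
        genes=genes,
        pairs=dyads.pairs,
        n_samples=kept,
        edge_freq={"R": freq[:, 0], "P": freq[:, 1]},
        prob_mean={"R": prob_mean[:, 0], "P": prob_mean[:, 1]},
        theta_chain={"R": theta_chain[:, 0], "P": theta_chain[:, 1]},
        tau_chain={"R": tau_chain[:, 0], "P": tau_chain[:, 1]},
        alpha_mean=alpha_mean,
        alpha_sd=np.sqrt(alpha_var),
        sigma_mean=sigma_sum / kept,
        acceptance=acceptance,
        seed=config.seed,
    )


def posterior_edge_probabilities(fit_result: P1Fit) -> pd.DataFrame:
    """Per-dyad posterior-predictive edge probabilities with MC errors."""
    return pd.DataFrame(
        {
            "gene_a": [a for a, _ in fit_result.pairs],
            "gene_b": [b for _, b in fit_result.pairs],
            "p_R": fit_result.edge_freq["R"],
            "p_P": fit_result.edge_freq["P"],
            "mc_se_R": fit_result.mc_se("R"),
            "mc_se_P": fit_result.mc_se("P"),
        }
    )


def fit_summary(fit_result: P1Fit) -> dict:
    """JSON-ready posterior summary of a fit."""
    out: dict = {"n_samples": fit_result.n_samples, "seed": fit_result.seed}
    for c in CONDS:
        mean, sd = fit_result.theta_summary(c)
        out[f"theta_{c}_mean"] = mean
        out[f"theta_{c}_sd"] = sd
        out[f"tau_{c}_mean"] = float(fit_result.tau_chain[c].mean())
    out["sigma_mean"] = fit_result.sigma_mean.tolist()
    out["acceptance"] = fit_result.acceptance
    return out
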