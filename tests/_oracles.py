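"""Independent brute-force oracles used by the test suite only."""

import numpy as np

from steptraj.lcmm import (SeriesSet, class_mean, marginal_cov, prior_probs)


def random_instance(rng, n_max=5, t_max=6, g_max=3):
    """A small random model + data set for likelihood-oracle checks."""
    from steptraj.lcmm import LcmmParams

    n = int(rng.integers(1, n_max + 1))
    G = int(rng.integers(1, g_max + 1))
    beta = rng.normal(0.0, 5.0, size=(G, 3))
    gamma = np.concatenate([rng.normal(0.0, 1.0, size=G - 1), [0.0]])
    sigma_u = float(rng.uniform(0.0, 3.0))
    sigma_eps = float(rng.uniform(0.5, 3.0))
    params = LcmmParams(beta=beta, gamma=gamma, sigma_u=sigma_u,
                        sigma_eps=sigma_eps)
    ids, weeks, values = [], [], []
    for i in range(n):
        T = int(rng.integers(1, t_max + 1))
        w = np.sort(rng.choice(np.arange(1, 9), size=T,
                               replace=False)).astype(float)
        y = rng.normal(0.0, 8.0, size=T)
        ids.append(f"S{i}")
        weeks.append(w)
        values.append(y)
    series = SeriesSet(ids, weeks, values)
    return params, series


def dense_class_loglik(params, g, weeks, values):
    """Independent oracle: dense multivariate-normal log density."""
    from scipy.stats import multivariate_normal

    w = np.asarray(weeks, float)
    y = np.asarray(values, float)
    mu = np.atleast_1d(class_mean(params.beta[g], w))
    cov = marginal_cov(params.sigma_u, params.sigma_eps, len(w))
    return float(multivariate_normal(mean=mu, cov=cov).logpdf(y))


def dense_marginal_and_posterior(params, series):
    """Brute-force mixture loglik and responsibilities, term by term
    (log-scale accumulation so tiny densities cannot underflow)."""
    from scipy.special import logsumexp

    pis = prior_probs(params.gamma)
    G = params.n_classes
    total = 0.0
    post = np.zeros((series.n, G))
    for i, (w, y) in enumerate(zip(series.weeks, series.values)):
        log_terms = np.array([
            np.log(pis[g]) + dense_class_loglik(params, g, w, y)
            for g in range(G)
        ])
        lse = logsumexp(log_terms)
        total += lse
        post[i] = np.exp(log_terms - lse)
    return total, post
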