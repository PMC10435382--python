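"""Bridges from inferred topics to genetic analyses.

Association testing itself (GWAS) is out of scope; this module prepares the
quantitative traits (logit-transformed topic weights), mixes topic-level
polygenic risk scores into code-level scores, and reproduces the toy power
calculation showing why combining independently associated diseases into one
binary trait loses per-SNP significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "logit_transform",
    "export_plink_pheno",
    "combine_prs",
    "logistic_wald",
    "gwas_power_sim",
]


def logit_transform(theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """log(theta' / (1 - theta')) with theta' = clamp(theta, eps, 1 - eps).

    Topic weights live on [0, 1], where a linear association model is
    ill-specified; the logit makes them unbounded.  Exact 0/1 weights are
    clamped by ``eps`` before transforming.
    """
    if not (0 < eps < 0.5):
        raise ValueError("eps must be in (0, 0.5)")
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta entries must lie in [0, 1]")
    t = np.clip(theta, eps, 1 - eps)
    return np.log(t / (1 - t))


def export_plink_pheno(theta: np.ndarray, individual_ids, path,
                       eps: float = 1e-6, exclude_healthy=None) -> pd.DataFrame:
    """Write logit-transformed topic weights as a PLINK phenotype table
    (FID, IID, topic1..topicK; missing = NA).

    ``exclude_healthy`` is an optional boolean mask of individuals with no
    diagnoses; their disease-topic traits are set missing, which raises
    association power downstream.
    """
    y = logit_transform(theta, eps=eps)
    cols = {f"topic{k + 1}": y[:, k] for k in range(y.shape[1])}
    df = pd.DataFrame({"FID": individual_ids, "IID": individual_ids, **cols})
    if exclude_healthy is not None:
        mask = np.asarray(exclude_healthy, dtype=bool)
        df.loc[mask, list(cols)] = np.nan
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df


def combine_prs(prs_topics: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Code-level polygenic scores from topic-level ones:
    PRS_ds = sum_t PRS_dt * phi_ts — each disease's risk decomposed over the
    topic 'pathways' weighted by the disease's probability in each topic."""
    prs_topics = np.asarray(prs_topics, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if prs_topics.shape[1] != phi.shape[0]:
        raise ValueError("topic dimension mismatch between PRS table and phi")
    return prs_topics @ phi


def logistic_wald(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                  tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression (Newton-Raphson with an
    intercept) returning coefficients and two-sided Wald p-values for the
    non-intercept terms.  Raises ``FloatingPointError`` on (quasi-)complete
    separation, detected as diverging coefficients or a singular Hessian."""
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        Wdiag = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * Wdiag[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise FloatingPointError("singular Hessian in logistic fit") from e
        beta = beta + step
        if np.abs(beta).max() > 30:
            raise FloatingPointError("separation in logistic fit")
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    H = (X * (p * (1 - p))[:, None]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * norm.sf(np.abs(zstat))
    return beta[1:], pvals[1:]


@dataclass
class PowerSimResult:
    proportion: float
    n_reps: int
    n_separation_retries: int


def gwas_power_sim(n: int = 20_000, geno_maf: float = 0.1, b1: float = 0.1,
                   n_snps: int = 5, reps: int = 1000,
                   alpha_level: float = 0.05, seed=None) -> PowerSimResult:
    """Power loss when independently associated diseases are merged.

    Per replicate: simulate ``n_snps`` independent binary genotypes
    g ~ Bernoulli(geno_maf); for each, draw a disease
    y ~ Bernoulli(logit^{-1}(b0 + b1 g)) with b0 = log(maf/(1-maf)),
    re-drawing until its own logistic regression is significant at
    ``alpha_level``; then form the union disease (any of the n_snps
    diseases) and fit one logistic regression on all SNPs jointly.  Returns
    the average fraction of SNPs that stay significant for the union trait —
    well below 1 because each SNP's signal is diluted by the other diseases.

    Replicates hitting separation in a fit are re-drawn and counted.
    """
    rng = np.random.default_rng(seed)
    b0 = np.log(geno_maf / (1 - geno_maf))
    fractions = np.empty(reps)
    retries = 0
    for rep in range(reps):
        while True:
            try:
                G = (rng.random((n, n_snps)) < geno_maf).astype(float)
                Y = np.empty((n, n_snps))
                for j in range(n_snps):
                    while True:
                        pr = 1.0 / (1.0 + np.exp(-(b0 + b1 * G[:, j])))
                        yj = (rng.random(n) < pr).astype(float)
                        _, pv = logistic_wald(G[:, [j]], yj)
                        if pv[0] < alpha_level:
                            Y[:, j] = yj
                            break
                combined = (Y.sum(axis=1) > 0).astype(float)
                _, pvals = logistic_wald(G, combined)
                fractions[rep] = float(np.mean(pvals < alpha_level))
                break
            except FloatingPointError:
                retries += 1
                warnings.warn("separation in logistic fit; replicate re-drawn")
    return PowerSimResult(proportion=float(fractions.mean()), n_reps=reps,
                          n_separation_retries=retries)
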