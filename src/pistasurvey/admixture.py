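"""Model-based Bayesian clustering of multilocus genotypes.

A Gibbs sampler for the classic admixture model: each individual i has a
membership vector Q_i over K clusters (Dirichlet(alpha) prior), each cluster
k has independent allele-frequency vectors P_kl per locus (Dirichlet(lambda)
prior), and every allele copy is drawn by first picking a cluster from Q_i,
then an allele from that cluster's frequencies. The sampler alternates

  1. cluster assignments z for every allele copy given (Q, P),
  2. P given z (Dirichlet posterior),
  3. Q given z (Dirichlet posterior),

and summarizes the model evidence for a given K with the standard
moment estimator  lnPD = mean(lnL) - var(lnL)/2  over retained sweeps.
Replicate runs across K feed the Evanno delta-K statistic
|L''(K)| / sd(L(K)), whose peak indicates the number of clusters.

Null (species non-amplifying) and missing calls are treated as missing data.
Cluster labels are non-identifiable across runs; ``align_labels`` permutes
replicates onto a reference before any averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .diversity import GenotypeTable

__all__ = [
    "AdmixtureFit",
    "EvannoTable",
    "encode_genotypes",
    "fit_admixture",
    "evanno_delta_k",
    "align_labels",
    "modal_assignment_accuracy",
]


def encode_genotypes(table: GenotypeTable) -> tuple[np.ndarray, list[np.ndarray]]:
    """Allele-index array X (n, L, 2) with -1 for missing/null, plus the
    per-locus allele value lists defining the index spaces."""
    n, L = table.n_individuals, table.n_loci
    X = np.full((n, L, 2), -1, dtype=np.int64)
    alleles: list[np.ndarray] = []
    for l in range(L):
        a1, a2 = table.a1[:, l], table.a2[:, l]
        typed = a1 >= 0
        vals = np.unique(np.concatenate([a1[typed], a2[typed]])) if typed.any() else np.empty(0, np.int64)
        alleles.append(vals)
        if vals.size:
            X[typed, l, 0] = np.searchsorted(vals, a1[typed])
            X[typed, l, 1] = np.searchsorted(vals, a2[typed])
    return X, alleles


@dataclass
class AdmixtureFit:
    """Posterior summary of one (K, seed) Gibbs run."""

    K: int
    Q: np.ndarray                 # (n, K) posterior-mean memberships
    P: np.ndarray                 # (K, L, Amax) posterior-mean cluster frequencies
    lnpd: float                   # mean(lnL) - var(lnL)/2 over retained sweeps
    loglik_trace: np.ndarray      # retained-sweep log-likelihoods
    seed: int
    n_burnin: int
    n_sweeps: int
    alpha: float
    alleles: list[np.ndarray] = field(default_factory=list)


def fit_admixture(
    table: GenotypeTable | tuple[np.ndarray, list[np.ndarray]],
    K: int,
    n_burnin: int = 500,
    n_sweeps: int = 2000,
    alpha: float = 1.0,
    lam: float = 1.0,
    thin: int = 10,
    seed: int = 0,
) -> AdmixtureFit:
    """Run the admixture Gibbs sampler for one K and one seed.

    Deterministic given (input, K, n_burnin, n_sweeps, alpha, lam, thin, seed).
    """
    if isinstance(table, GenotypeTable):
        X, alleles = encode_genotypes(table)
    else:
        X, alleles = table
    n, L, _ = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of individuals ({n})")
    J = np.array([max(a.size, 1) for a in alleles])
    Amax = int(J.max())
    valid = X >= 0                      # (n, L, 2)
    Xc = np.where(valid, X, 0)
    lgrid = np.arange(L)
    amask = (np.arange(Amax)[None, :] < J[:, None]).astype(float)  # (L, Amax)

    rng = np.random.default_rng(seed)
    Q = np.full((n, K), 1.0 / K)
    P = rng.dirichlet(np.ones(Amax), size=(K, L)) * amask[None]
    P /= P.sum(axis=2, keepdims=True)

    Qsum = np.zeros_like(Q)
    Psum = np.zeros_like(P)
    trace: list[float] = []
    n_total = n_burnin + n_sweeps
    for sweep in range(n_total):
        # 1. allele-copy assignments
        Pg = P[:, lgrid[None, :, None], Xc]          # (K, n, L, 2)
        W = Q.T[:, :, None, None] * Pg
        tot = W.sum(axis=0)
        if not np.all(np.isfinite(tot)):
            raise FloatingPointError("non-finite likelihood in Gibbs sweep")
        lnl = float(np.log(tot[valid]).sum())
        u = rng.random((n, L, 2)) * tot
        z = (np.cumsum(W, axis=0) < u[None]).sum(axis=0)
        z = np.minimum(z, K - 1)

        # 2. cluster allele frequencies
        flat = (z * L + lgrid[None, :, None]) * Amax + Xc
        cnt = np.bincount(flat[valid].ravel(), minlength=K * L * Amax).reshape(K, L, Amax)
        P = rng.gamma(cnt + lam) * amask[None]
        P /= P.sum(axis=2, keepdims=True)

        # 3. individual memberships
        zi = np.broadcast_to(np.arange(n)[:, None, None], z.shape)
        nz = np.bincount(
            (zi[valid] * K + z[valid]).ravel(), minlength=n * K
        ).reshape(n, K)
        Q = rng.gamma(nz + alpha)
        Q /= Q.sum(axis=1, keepdims=True)

        if sweep >= n_burnin and (sweep - n_burnin) % thin == 0:
            trace.append(lnl)
            Qsum += Q
            Psum += P
    m = len(trace)
    tr = np.array(trace)
    var = float(tr.var(ddof=1)) if m > 1 else 0.0
    lnpd = float(tr.mean()) - var / 2.0
    return AdmixtureFit(
        K=K, Q=Qsum / m, P=Psum / m, lnpd=lnpd, loglik_trace=tr,
        seed=seed, n_burnin=n_burnin, n_sweeps=n_sweeps, alpha=alpha,
        alleles=alleles,
    )


def align_labels(fits: Sequence[AdmixtureFit], reference: int = 0) -> list[AdmixtureFit]:
    """Permute cluster labels of replicate fits (same K) onto a reference
    replicate, maximizing summed Q-column agreement (Hungarian assignment)."""
    if len(fits) < 1:
        return []
    K = fits[reference].K
    if any(f.K != K for f in fits):
        raise ValueError("all fits must share K")
    ref = fits[reference]
    out: list[AdmixtureFit] = []
    for f in fits:
        M = ref.Q.T @ f.Q  # (K, K) agreement
        _, perm = linear_sum_assignment(-M)
        out.append(
            AdmixtureFit(
                K=f.K, Q=f.Q[:, perm], P=f.P[perm], lnpd=f.lnpd,
                loglik_trace=f.loglik_trace, seed=f.seed, n_burnin=f.n_burnin,
                n_sweeps=f.n_sweeps, alpha=f.alpha, alleles=f.alleles,
            )
        )
    return out


def modal_assignment_accuracy(Q: np.ndarray, labels: Sequence[int]) -> float:
    """Fraction of individuals whose modal cluster matches their true
    population, after the optimal cluster-to-population relabeling."""
    labels = np.asarray(labels)
    modal = Q.argmax(axis=1)
    K = Q.shape[1]
    npop = int(labels.max()) + 1
    conf = np.zeros((npop, K))
    for lab, m in zip(labels, modal):
        conf[lab, m] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / labels.size)


@dataclass(frozen=True)
class EvannoTable:
    """Per-K replicate summary and delta-K statistic."""

    table: pd.DataFrame  # index K; columns mean_lnpd, sd_lnpd, delta_k
    best_k: int


def evanno_delta_k(runs: Mapping[int, Sequence[float]]) -> EvannoTable:
    """Evanno delta-K from replicate lnPD values per K.

    delta_k(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K only. Requires consecutive K with >= 2 replicates
    each and Kmax >= 3. A zero replicate sd leaves delta_k NaN there.
    """
    Ks = sorted(runs)
    if len(Ks) < 3 or Ks != list(range(Ks[0], Ks[-1] + 1)):
        raise ValueError("need consecutive K values spanning at least 3 levels")
    for K in Ks:
        if len(runs[K]) < 2:
            raise ValueError(f"need >= 2 replicates per K (K={K})")
    mean = {K: float(np.mean(runs[K])) for K in Ks}
    sd = {K: float(np.std(runs[K], ddof=1)) for K in Ks}
    rows = []
    for K in Ks:
        if K == Ks[0] or K == Ks[-1]:
            dk = np.nan
        elif sd[K] == 0.0:
            dk = np.nan
        else:
            dk = abs(mean[K + 1] - 2 * mean[K] + mean[K - 1]) / sd[K]
        rows.append((K, mean[K], sd[K], dk))
    df = pd.DataFrame(rows, columns=["K", "mean_lnpd", "sd_lnpd", "delta_k"]).set_index("K")
    interior = df["delta_k"].dropna()
    if interior.empty:
        raise ValueError("delta-K undefined at every interior K (zero replicate sd)")
    return EvannoTable(table=df, best_k=int(interior.idxmax()))
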