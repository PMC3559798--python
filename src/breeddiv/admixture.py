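"""Bayesian admixture clustering (the Pritchard–Stephens–Donnelly model).

Each individual carries ancestry proportions q over K clusters
(Dirichlet(alpha) prior, alpha shared across clusters and learned by
Metropolis); each allele copy draws its cluster of origin from q and its
allele from that cluster's frequency p_kl.  Two allele-frequency priors
are available:

* ``independent``: p_kl ~ Beta(lambda, lambda) with conjugate Gibbs
  updates (lambda = 1 by default);
* ``correlated`` (the F model): cluster frequencies drift from a shared
  ancestral frequency p_l, p_kl ~ Beta(p_l (1-f_k)/f_k, (1-p_l)(1-f_k)/f_k)
  with per-cluster drift f_k; p_l and f_k are updated by Metropolis with
  reflecting proposals.

ln P(X|K) is the harmonic approximation mean - var/2 of the post-burn-in
log-likelihoods.  Replicates are aligned by optimal assignment over
columns (label switching) and averaged; Evanno's delta-K and the
mean-lnP table support the choice of K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-9
_PCLIP = 1e-6


@dataclass
class AdmixtureReplicate:
    K: int
    Q: np.ndarray  # N×K posterior-mean ancestry
    P_mean: np.ndarray  # K×L posterior-mean allele2 freqs
    alpha_trace: np.ndarray
    loglik_trace: np.ndarray
    lnP: float
    seed: int
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class AlignedAdmixture:
    K: int
    Q_mean: np.ndarray
    permutations: list[tuple]
    similarity: float
    sample_ids: list[str] = field(default_factory=list)


def _loglik(g: np.ndarray, present: np.ndarray, q: np.ndarray, p: np.ndarray) -> float:
    """log P(genotypes | q, p) with copies independent given q."""
    m = np.clip(q @ p, _PCLIP, 1 - _PCLIP)  # N×L expected allele2 prob
    ll = np.where(g == 0, 2 * np.log1p(-m), 0.0)
    ll = np.where(g == 1, np.log(2.0) + np.log(m) + np.log1p(-m), ll)
    ll = np.where(g == 2, 2 * np.log(m), ll)
    return float(ll[present].sum())


def _dirichlet_loglik(alpha: float, q: np.ndarray) -> float:
    N, K = q.shape
    return N * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1) * np.log(
        np.clip(q, _PCLIP, 1)
    ).sum()


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def admixture_gibbs(
    G: GenotypeMatrix,
    snp_set=None,
    K: int = 2,
    burnin: int = 15000,
    reps: int = 35000,
    model: str = "correlated",
    seed: int = 0,
    lambda_prior: float = 1.0,
    alpha_max: float = 10.0,
    alpha_proposal_sd: float = 0.025,
) -> AdmixtureReplicate:
    """One MCMC replicate of the admixture model at a fixed K.

    ``burnin`` sweeps are discarded, ``reps`` sweeps are recorded.  Q and
    P_mean are posterior means over recorded sweeps; traces hold alpha and
    the data log-likelihood at every recorded sweep.  Same seed, same
    input → bitwise-identical traces.
    """
    if model not in ("independent", "correlated"):
        raise ValueError("model must be 'independent' or 'correlated'")
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    if K > sub.n_samples:
        raise ValueError(f"K={K} exceeds number of samples {sub.n_samples}")
    g = sub.calls
    N, L = g.shape
    present = g != MISSING
    gz = np.where(present, g, 0)

    if K == 1:
        # closed form: single cluster, every q = 1
        rng = np.random.default_rng(seed)
        n1 = gz.sum(axis=0).astype(float)
        n0 = (2 * present.sum(axis=0) - n1).astype(float)
        ll_trace = np.empty(reps)
        alpha_trace = np.ones(reps)
        p_sum = np.zeros(L)
        q = np.ones((N, 1))
        for t in range(reps):
            p = rng.beta(lambda_prior + n1, lambda_prior + n0)
            p = np.clip(p, _PCLIP, 1 - _PCLIP)
            p_sum += p
            ll_trace[t] = _loglik(g, present, q, p[None, :])
        lnP = float(ll_trace.mean() - ll_trace.var() / 2)
        return AdmixtureReplicate(
            1, np.ones((N, 1)), (p_sum / reps)[None, :], alpha_trace, ll_trace, lnP,
            seed, sub.sample_ids,
        )

    rng = np.random.default_rng(seed)
    # allele-copy counts per (i, l): c1 = copies of allele2, c0 = copies of allele1
    c1 = np.where(present, g, 0).astype(np.int64)
    c0 = np.where(present, 2 - g, 0).astype(np.int64)

    q = rng.dirichlet(np.ones(K), size=N)
    p = rng.uniform(0.1, 0.9, size=(K, L))
    alpha = 1.0
    if model == "correlated":
        p_anc = rng.uniform(0.1, 0.9, size=L)
        f_drift = np.full(K, 0.1)

    total = burnin + reps
    ll_trace = np.empty(reps)
    alpha_trace = np.empty(reps)
    Q_sum = np.zeros((N, K))
    P_sum = np.zeros((K, L))

    ks = np.arange(K)
    for sweep in range(total):
        # --- sample Z counts: for each (i,l), the c1 allele2 copies and c0
        # allele1 copies each choose a cluster ~ q_i * p / (1-p)
        w1 = q[:, :, None] * p[None, :, :]          # N×K×L
        w0 = q[:, :, None] * (1 - p)[None, :, :]
        w1 /= np.maximum(w1.sum(axis=1, keepdims=True), 1e-300)
        w0 /= np.maximum(w0.sum(axis=1, keepdims=True), 1e-300)
        cum1 = np.cumsum(w1, axis=1)
        cum0 = np.cumsum(w0, axis=1)
        # two potential copies per class; multinomial via two uniforms
        u = rng.random((4, N, L))
        z1a = (u[0][:, None, :] > cum1).sum(axis=1)  # N×L in 0..K-1
        z1b = (u[1][:, None, :] > cum1).sum(axis=1)
        z0a = (u[2][:, None, :] > cum0).sum(axis=1)
        z0b = (u[3][:, None, :] > cum0).sum(axis=1)
        take1b = c1 == 2
        take1a = c1 >= 1
        take0b = c0 == 2
        take0a = c0 >= 1

        n1 = np.zeros((K, L))
        n0 = np.zeros((K, L))
        m = np.zeros((N, K))
        for k in ks:
            s1 = (z1a == k) & take1a
            s2 = (z1b == k) & take1b
            s3 = (z0a == k) & take0a
            s4 = (z0b == k) & take0b
            n1[k] = s1.sum(axis=0) + s2.sum(axis=0)
            n0[k] = s3.sum(axis=0) + s4.sum(axis=0)
            m[:, k] = s1.sum(axis=1) + s2.sum(axis=1) + s3.sum(axis=1) + s4.sum(axis=1)

        # --- q update (conjugate Dirichlet)
        gam = rng.gamma(alpha + m)
        q = gam / gam.sum(axis=1, keepdims=True)
        q = np.clip(q, _PCLIP, None)
        q /= q.sum(axis=1, keepdims=True)

        # --- p update
        if model == "independent":
            p = rng.beta(lambda_prior + n1, lambda_prior + n0)
        else:
            a_par = p_anc[None, :] * ((1 - f_drift) / f_drift)[:, None]
            b_par = (1 - p_anc)[None, :] * ((1 - f_drift) / f_drift)[:, None]
            p = rng.beta(a_par + n1, b_par + n0)
        p = np.clip(p, _PCLIP, 1 - _PCLIP)

        if model == "correlated":
            # Metropolis on ancestral frequencies (per locus, reflecting)
            prop = _reflect(p_anc + rng.normal(0, 0.05, size=L), _PCLIP, 1 - _PCLIP)
            lam = ((1 - f_drift) / f_drift)[:, None]
            logp = np.log(p)
            log1p_ = np.log1p(-p)

            def anc_ll(pa):
                a = pa[None, :] * lam
                b = (1 - pa)[None, :] * lam
                return (
                    gammaln(a + b) - gammaln(a) - gammaln(b)
                    + (a - 1) * logp + (b - 1) * log1p_
                ).sum(axis=0)

            acc = np.log(rng.random(L)) < anc_ll(prop) - anc_ll(p_anc)
            p_anc = np.where(acc, prop, p_anc)
            # Metropolis on per-cluster drift f_k
            propf = _reflect(f_drift + rng.normal(0, 0.01, size=K), 1e-4, 1 - 1e-4)

            def drift_ll(fv):
                lamv = ((1 - fv) / fv)[:, None]
                a = p_anc[None, :] * lamv
                b = (1 - p_anc)[None, :] * lamv
                return (
                    gammaln(a + b) - gammaln(a) - gammaln(b)
                    + (a - 1) * logp + (b - 1) * log1p_
                ).sum(axis=1)

            accf = np.log(rng.random(K)) < drift_ll(propf) - drift_ll(f_drift)
            f_drift = np.where(accf, propf, f_drift)

        # --- alpha update (Metropolis, prior U(0, alpha_max))
        prop_a = alpha + rng.normal(0, alpha_proposal_sd)
        if 0 < prop_a < alpha_max:
            if np.log(rng.random()) < _dirichlet_loglik(prop_a, q) - _dirichlet_loglik(alpha, q):
                alpha = prop_a

        if sweep >= burnin:
            t = sweep - burnin
            ll_trace[t] = _loglik(g, present, q, p)
            alpha_trace[t] = alpha
            Q_sum += q
            P_sum += p

    lnP = float(ll_trace.mean() - ll_trace.var() / 2)
    return AdmixtureReplicate(
        K, Q_sum / reps, P_sum / reps, alpha_trace, ll_trace, lnP, seed, sub.sample_ids
    )


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

def log_prob_of_K(replicates: dict[int, list[AdmixtureReplicate]]) -> pd.DataFrame:
    """Mean and sd of ln P(X|K) across replicates per K, with a flag where
    the gain in mean diminishes while the variance grows."""
    rows = []
    for K in sorted(replicates):
        vals = np.array([r.lnP for r in replicates[K]])
        rows.append(
            {
                "K": K,
                "n_replicates": len(vals),
                "mean_lnP": vals.mean(),
                "sd_lnP": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    flag = np.zeros(len(df), dtype=bool)
    for i in range(1, len(df) - 0):
        if i >= 1 and not np.isnan(df.loc[i, "sd_lnP"]) and i < len(df):
            gain = df.loc[i, "mean_lnP"] - df.loc[i - 1, "mean_lnP"]
            prev_gain = (
                df.loc[i - 1, "mean_lnP"] - df.loc[i - 2, "mean_lnP"] if i >= 2 else np.inf
            )
            sd_prev = df.loc[i - 1, "sd_lnP"]
            flag[i] = gain < prev_gain and not np.isnan(sd_prev) and df.loc[i, "sd_lnP"] > sd_prev
    df["diminishing_gain_flag"] = flag
    return df


def evanno_delta_k(lnp_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno's delta-K = |mean second difference of lnP| / sd(lnP(K)).

    Needs three consecutive K values; sd = 0 rows are flagged undefined.
    """
    df = lnp_table.sort_values("K").reset_index(drop=True)
    out = []
    for i in range(1, len(df) - 1):
        if df.loc[i + 1, "K"] - df.loc[i, "K"] != 1 or df.loc[i, "K"] - df.loc[i - 1, "K"] != 1:
            continue
        second = abs(
            df.loc[i + 1, "mean_lnP"] - 2 * df.loc[i, "mean_lnP"] + df.loc[i - 1, "mean_lnP"]
        )
        sd = df.loc[i, "sd_lnP"]
        if not sd or np.isnan(sd):
            out.append({"K": int(df.loc[i, "K"]), "delta_K": np.nan, "defined": False})
        else:
            out.append({"K": int(df.loc[i, "K"]), "delta_K": second / sd, "defined": True})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# replicate alignment (label switching)
# ---------------------------------------------------------------------------

def align_replicates(Q_list: list[np.ndarray], sample_ids=None) -> AlignedAdmixture:
    """Align replicate Q matrices to the first by optimal column assignment
    (cost = summed squared column differences) and average."""
    ref = np.asarray(Q_list[0], float)
    N, K = ref.shape
    perms = [tuple(range(K))]
    aligned = [ref]
    for Q in Q_list[1:]:
        Q = np.asarray(Q, float)
        if Q.shape != ref.shape:
            raise ValueError(f"shape mismatch: {Q.shape} vs {ref.shape}")
        cost = ((ref[:, :, None] - Q[:, None, :]) ** 2).sum(axis=0)  # ref-col × rep-col
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[rows] = cols
        perms.append(tuple(perm))
        aligned.append(Q[:, perm])
    Q_mean = np.mean(aligned, axis=0)
    Q_mean = Q_mean / Q_mean.sum(axis=1, keepdims=True)
    sim = float(
        np.mean([1 - ((a - ref) ** 2).sum() / max(N, 1) for a in aligned])
    )
    return AlignedAdmixture(K, Q_mean, perms, sim, list(sample_ids or []))


def breed_mean_q(aligned: AlignedAdmixture, populations: list[str]) -> pd.DataFrame:
    """Population means of ancestry, plus the majority cluster and its q."""
    df = pd.DataFrame(aligned.Q_mean, columns=[f"q{k+1}" for k in range(aligned.K)])
    df["population"] = list(populations)
    mean = df.groupby("population", sort=False).mean()
    mean["max_cluster"] = mean.to_numpy().argmax(axis=1) + 1
    mean["max_q"] = mean[[f"q{k+1}" for k in range(aligned.K)]].to_numpy().max(axis=1)
    return mean.reset_index()
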