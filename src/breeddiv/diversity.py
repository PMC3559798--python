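"""Within-population diversity: He, Ho, individual f, and multilocus F_IS.

He uses the small-sample-unbiased estimator (n/(n-1))(1 - p^2 - q^2) with
n the number of non-missing gene copies at the locus.  Individual f is the
method-of-moments inbreeding coefficient from an individual's excess
homozygosity over its Hardy–Weinberg expectation.  F_IS is the
Weir–Cockerham within-population fixation index combined over loci as a
ratio of summed variance components, with a one-sided (excess
homozygosity) permutation test that reshuffles the 2n allele copies among
individuals independently at each locus.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def _pop_calls(G: GenotypeMatrix, population: str, snp_set=None) -> np.ndarray:
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    return sub.calls[sub.pop_mask(population)]


def _freq_and_copies(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    obs = calls != MISSING
    n = 2 * obs.sum(axis=0)
    c2 = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, c2 / np.maximum(n, 1), np.nan)
    return p.astype(float), n


def expected_heterozygosity(
    G: GenotypeMatrix, population: str, snp_set=None
) -> tuple[pd.Series, float]:
    """Per-locus unbiased He and its mean over loci with >= 2 gene copies."""
    calls = _pop_calls(G, population, snp_set)
    p, n = _freq_and_copies(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = np.where(n >= 2, (n / np.maximum(n - 1, 1)) * 2 * p * (1 - p), np.nan)
    n_excl = int((n < 2).sum())
    if n_excl:
        logger.info("He(%s): %d loci with <2 gene copies excluded", population, n_excl)
    ids = G.locus_ids if snp_set is None else list(snp_set.locus_ids)
    # snp_set subsetting reorders to map order; recover that order
    if snp_set is not None:
        ids = G.subset(locus_ids=list(snp_set.locus_ids)).locus_ids
    per_locus = pd.Series(he, index=ids, name="He")
    return per_locus, float(np.nanmean(he))


def observed_heterozygosity(
    G: GenotypeMatrix, population: str, snp_set=None
) -> tuple[pd.Series, float]:
    """Per-locus fraction of non-missing genotypes that are heterozygous."""
    calls = _pop_calls(G, population, snp_set)
    obs = calls != MISSING
    n = obs.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    per_locus = pd.Series(ho, index=sub.locus_ids, name="Ho")
    return per_locus, float(np.nanmean(ho))


def individual_f(
    G: GenotypeMatrix, population: str, snp_set=None, pooled_freqs: bool = False
) -> pd.Series:
    """Method-of-moments inbreeding coefficient per individual.

    f_i = (O(hom)_i - E(hom)_i) / (L_i - E(hom)_i), where E(hom) sums
    1 - 2p(1-p)·n/(n-1) over the individual's non-missing loci.  Reference
    frequencies come from the individual's own population by default
    (``pooled_freqs=True`` uses the whole dataset).
    """
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    mask = sub.pop_mask(population)
    calls = sub.calls[mask]
    ref_calls = sub.calls if pooled_freqs else calls
    p, n = _freq_and_copies(ref_calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_hom_l = np.where(n >= 2, 1 - 2 * p * (1 - p) * n / np.maximum(n - 1, 1), np.nan)
    out = {}
    ids = [s.id for s, m in zip(sub.samples, mask) if m]
    for i, sid in enumerate(ids):
        obs_i = (calls[i] != MISSING) & ~np.isnan(exp_hom_l)
        L = int(obs_i.sum())
        o_hom = int(((calls[i] == 0) | (calls[i] == 2))[obs_i].sum())
        e_hom = float(exp_hom_l[obs_i].sum())
        denom = L - e_hom
        out[sid] = (o_hom - e_hom) / denom if denom > 0 else np.nan
    return pd.Series(out, name="f")


def _wc_fis_components(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham within-population components (b, c).

    b = (n/(n-1)) [p(1-p) - ((2n-1)/(4n)) h];  c = h/2, with n the number
    of genotyped diploids and h the observed heterozygote proportion.
    """
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / np.maximum(2 * n, 1)
        h = (calls == 1).sum(axis=0) / np.maximum(n, 1)
        b = np.where(
            n > 1, (n / np.maximum(n - 1, 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h), np.nan
        )
    c = np.where(n > 0, h / 2, np.nan)
    return b, c


def fis_weir_cockerham(G: GenotypeMatrix, population: str, snp_set=None) -> float:
    """Multilocus F_IS as 1 - sum(c)/sum(b + c) over usable loci."""
    calls = _pop_calls(G, population, snp_set)
    if calls.shape[0] < 2:
        raise ValueError(f"population {population}: need >= 2 samples for F_IS")
    b, c = _wc_fis_components(calls)
    ok = ~np.isnan(b) & ~np.isnan(c)
    denom = (b[ok] + c[ok]).sum()
    if denom == 0:
        logger.warning("F_IS undefined for %s (all loci monomorphic)", population)
        return np.nan
    return float(1 - c[ok].sum() / denom)


def fis_permutation_test(
    G: GenotypeMatrix,
    population: str,
    snp_set=None,
    n_perm: int = 10000,
    seed: int = 0,
    two_sided: bool = False,
    batch: int = 200,
) -> tuple[float, float]:
    """One-sided (excess homozygosity) permutation p-value for F_IS.

    The null reshuffles the 2n allele copies among individuals within the
    population independently at each locus (Hardy–Weinberg within the
    observed allele counts).  p = (1 + #{F_IS_perm >= F_IS_obs})/(1 + n_perm).
    Returns (F_IS_observed, p).

    Missing genotypes are excluded from the observed statistic; for the
    permutation null the copy pool at each locus holds only observed copies,
    permuted within their own locus column.
    """
    calls = _pop_calls(G, population, snp_set)
    obs_fis = _fis_from_copy_matrix_from_calls(calls)
    rng = np.random.default_rng(seed)
    n, L = calls.shape
    # expand to allele copies; keep missing as NaN so pairing skips them
    copies = np.empty((2 * n, L))
    gg = calls.astype(float)
    gg[calls == MISSING] = np.nan
    copies[0::2] = np.where(gg >= 1, 1.0, 0.0)
    copies[1::2] = np.where(gg == 2, 1.0, 0.0)
    copies[0::2][np.isnan(gg)] = np.nan
    copies[1::2][np.isnan(gg)] = np.nan

    count_ge = 0
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        # permute copies independently per locus column, per permutation;
        # NaNs travel with the copies so pairing changes under the null
        order = np.argsort(rng.random((nb, 2 * n, L)), axis=1)
        perm = np.take_along_axis(np.broadcast_to(copies, (nb, 2 * n, L)), order, axis=1)
        g = perm[:, 0::2] + perm[:, 1::2]  # (nb, n, L), NaN where either copy missing
        present = ~np.isnan(g)
        m = present.sum(axis=1).astype(float)  # diploids per (perm, locus)
        with np.errstate(invalid="ignore", divide="ignore"):
            pfreq = np.nansum(g, axis=1) / np.maximum(2 * m, 1)
            h = (g == 1).sum(axis=1) / np.maximum(m, 1)
            b = (m / np.maximum(m - 1, 1)) * (
                pfreq * (1 - pfreq) - (2 * m - 1) / (4 * np.maximum(m, 1)) * h
            )
        c = h / 2
        ok = m > 1
        b = np.where(ok, b, 0.0)
        c = np.where(ok, c, 0.0)
        denom = (b + c).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom != 0, 1 - c.sum(axis=1) / np.where(denom != 0, denom, 1), np.nan)
        valid = ~np.isnan(f)
        if two_sided:
            count_ge += int((np.abs(f[valid]) >= abs(obs_fis)).sum())
        else:
            count_ge += int((f[valid] >= obs_fis).sum())
        done += nb
    p = (1 + count_ge) / (1 + n_perm)
    return obs_fis, float(p)


def _fis_from_copy_matrix_from_calls(calls: np.ndarray) -> float:
    b, c = _wc_fis_components(calls)
    ok = ~np.isnan(b) & ~np.isnan(c)
    denom = (b[ok] + c[ok]).sum()
    return float(1 - c[ok].sum() / denom) if denom != 0 else np.nan


def diversity_table(
    G: GenotypeMatrix,
    snp_sets: dict,
    primary: str = "primary",
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population summary: N, F_IS (+ permutation p on the primary set),
    individual-f min/max/mean, and mean He on every provided SNP set."""
    rows = []
    for pop in G.populations:
        n = int(G.pop_mask(pop).sum())
        row: dict = {"population": pop, "n_samples": n}
        fis, pval = fis_permutation_test(
            G, pop, snp_sets[primary], n_perm=n_perm, seed=seed
        )
        row["Fis"] = fis
        row["Fis_pvalue"] = pval
        f = individual_f(G, pop, snp_sets[primary])
        row.update(f_min=f.min(), f_max=f.max(), f_mean=f.mean())
        for name, ss in snp_sets.items():
            _, he = expected_heterozygosity(G, pop, ss)
            row[f"He_{name}"] = he
        _, ho = observed_heterozygosity(G, pop, snp_sets[primary])
        row["Ho_primary"] = ho
        rows.append(row)
    return pd.DataFrame(rows)
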