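"""Principal component analysis of the genotype matrix.

EIGENSTRAT-style standardisation: missing calls are mean-imputed, each
locus is centred by 2p and scaled by sqrt(2p(1-p)); monomorphic loci are
dropped.  The eigendecomposition is of the sample-by-sample covariance of
the standardised matrix, with a deterministic sign convention (first
sample's coordinate non-negative on every component).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples × PCs, with population column
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray


def standardize_genotypes(G: GenotypeMatrix, snp_set=None) -> np.ndarray:
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    calls = sub.calls.astype(float)
    obs = sub.calls != MISSING
    n_copies = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / np.maximum(n_copies, 1)
    keep = (p > 0) & (p < 1) & (n_copies > 0)
    if (~keep).sum():
        logger.info("standardize: dropped %d monomorphic/empty loci", int((~keep).sum()))
    calls = calls[:, keep]
    obs = obs[:, keep]
    p = p[keep]
    mean = 2 * p
    calls = np.where(obs, calls, mean)  # missing -> locus mean
    return (calls - mean) / np.sqrt(2 * p * (1 - p))


def pca(G: GenotypeMatrix, snp_set=None, n_components: int = 10) -> PcaResult:
    sub = G if snp_set is None else G.subset(locus_ids=list(snp_set.locus_ids))
    if sub.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X = standardize_genotypes(sub)
    n = X.shape[0]
    C = (X @ X.T) / X.shape[1]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    rank = int((evals > 1e-10).sum())
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; truncating", n_components, rank)
        n_components = max(rank, 1)
    evals = evals[:n_components]
    evecs = evecs[:, :n_components]
    coords = evecs * np.sqrt(np.maximum(evals, 0))
    # sign convention: first sample non-negative on every component
    sign = np.where(coords[0] < 0, -1.0, 1.0)
    coords = coords * sign
    total = np.trace(C)
    df = pd.DataFrame(
        coords, index=sub.sample_ids, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    df.insert(0, "population", sub.population_of())
    return PcaResult(
        coordinates=df,
        eigenvalues=evals,
        explained_fraction=evals / total if total > 0 else np.zeros_like(evals),
    )
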