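"""Principal component analysis of the panel (MAF + call-rate SNP set,
no LD pruning, as PCA convention dictates).

Expected pattern: the leading components separate the high-drift breeds;
the split-site samples of breed01 overlap each other; the admixed
population sits between its two source breeds.
"""

import pandas as pd

from _common import load_panel, outdir

from breeddiv import qc
from breeddiv.ordination import pca


def main():
    G = load_panel()
    out = outdir()
    kept = [l.strip() for l in open(out / "kept_samples.txt") if l.strip()]
    G = G.subset(sample_ids=kept)

    cr, _ = qc.filter_call_rate(G, 0.99, 0.0)
    pca_set = qc.filter_maf(G, cr, min_maf=0.05)
    res = pca(G, pca_set, n_components=10)
    res.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {"eigenvalue": res.eigenvalues, "explained": res.explained_fraction}
    ).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False)
    print(f"PCA on {len(pca_set)} SNPs, {G.n_samples} samples")
    for i, frac in enumerate(res.explained_fraction[:4]):
        print(f"  PC{i+1}: {100 * frac:.1f}% of variance")
    centroids = res.coordinates.groupby("population")[["PC1", "PC2"]].mean()
    print("population centroids on PC1/PC2:")
    print(centroids.round(2).to_string())


if __name__ == "__main__":
    main()
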