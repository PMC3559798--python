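"""Among-breed differentiation: pairwise and global Weir–Cockerham theta
with permutation significance, and three-level AMOVA.

Expected pattern: the split-site pair (breed01 vs breed01_siteB, same
gene pool) shows near-zero FST — the analogue of a breed sampled in two
countries — while high-drift breed pairs differentiate strongly; AMOVA
places most variance within individuals.
"""

import json

from _common import load_panel, outdir

from breeddiv.differentiation import amova, fst_matrix, global_fst
from breeddiv.qc import SnpSet


def main():
    G = load_panel()
    out = outdir()
    kept = [l.strip() for l in open(out / "kept_samples.txt") if l.strip()]
    G = G.subset(sample_ids=kept)
    primary = SnpSet.load(out / "snp_set_primary.txt")

    theta, pvals = fst_matrix(G, primary, n_perm=500, seed=4, min_pop_size=8)
    theta.to_csv(out / "fst_matrix.tsv", sep="\t")
    pvals.to_csv(out / "fst_pvalues.tsv", sep="\t")
    pairs = theta.where(~(theta == 0)).stack()
    print(f"pairwise FST over {len(theta)} populations "
          f"(small populations excluded): min {pairs.min():.3f}, "
          f"max {pairs.max():.3f}")
    if "breed01_siteB" in theta.index:
        print(f"split-site pair breed01 vs breed01_siteB: "
              f"FST = {theta.loc['breed01', 'breed01_siteB']:.4f}")

    g = global_fst(G, primary, populations=list(theta.index))
    res = amova(G, primary, populations=list(theta.index), n_perm=200, seed=5)
    print(f"global FST = {g:.4f}")
    print(f"AMOVA: {res.pct_among_pops:.2f}% among populations "
          f"(p = {res.p_among:.3g}), {res.pct_among_ind:.2f}% among "
          f"individuals within populations (p = {res.p_within_pops:.3g}), "
          f"{res.pct_within_ind:.2f}% within individuals "
          f"(p = {res.p_within_ind:.3g})")
    with open(out / "amova.json", "w") as fh:
        json.dump({"global_fst": g, **res.as_dict()}, fh, indent=1)


if __name__ == "__main__":
    main()
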