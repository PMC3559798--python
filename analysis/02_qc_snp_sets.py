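"""Sample QC and construction of the four LD-pruned analysis SNP sets.

Reproduces the pruning ladder: within-breed pi-hat pruning at 0.3, then
ascertainment-aware MAF (treating two high-drift breeds as the array's
discovery panel), call-rate and pooled-MAF filters, and the four LD prunes
(pairwise r2 at 0.1/0.2/0.4 and VIF at 1.11).  Writes the set sizes and
each set's provenance.
"""

import pandas as pd

from _common import load_panel, outdir

from breeddiv import qc


def main():
    G = load_panel()
    out = outdir()

    cr_set, kept = qc.filter_call_rate(G, 0.99, 0.90)
    G = G.subset(sample_ids=kept)
    print(f"after call-rate QC: {G.n_samples} samples")

    removed = []
    for pop in G.populations:
        ids = [s.id for s in G.samples if s.population == pop]
        if len(ids) < 2:
            continue
        sub = G.subset(sample_ids=ids)
        maf_set = qc.filter_maf(sub, min_maf=0.05)
        kin = qc.pihat_matrix(sub.subset(locus_ids=maf_set.locus_ids))
        kept_pop = set(qc.prune_related(kin, 0.3))
        removed += [i for i in ids if i not in kept_pop]
    G = G.subset(sample_ids=[s for s in G.sample_ids if s not in set(removed)])
    print(f"pi-hat pruning removed {len(removed)} samples -> {G.n_samples} remain")

    sets = qc.build_paper_snp_sets(G, discovery_pops=["breed09", "breed10"])
    rows = []
    for name, ss in sets.items():
        rows.append({"snp_set": name, "n_loci": len(ss)})
        ss.save(out / f"snp_set_{name}.txt")
        print(f"  {name}: {len(ss)} loci")
    pd.DataFrame(rows).to_csv(out / "snp_set_sizes.tsv", sep="\t", index=False)
    with open(out / "kept_samples.txt", "w") as fh:
        fh.write("\n".join(G.sample_ids) + "\n")


if __name__ == "__main__":
    main()
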