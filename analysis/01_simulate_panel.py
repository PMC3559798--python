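"""Build the synthetic breed panel and write it as PED/MAP + population TSV.

The panel mimics the structure of a real multi-breed SNP-array study:
12 population labels (10 breeds with drift F from 0.02 to 0.25, one breed
sampled at two locations, one admixed population), one small population
(n = 7), mild inbreeding in some breeds and ~0.5% missing calls.
"""

from _common import make_panel, panel_paths


def main():
    G = make_panel()
    ped, mp, pops = panel_paths()
    print(f"panel: {G.n_samples} samples x {G.n_loci} loci, "
          f"{len(G.populations)} populations")
    for pop in G.populations:
        print(f"  {pop}: n = {int(G.pop_mask(pop).sum())}")
    print(f"written: {ped}, {mp}, {pops}")


if __name__ == "__main__":
    main()
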