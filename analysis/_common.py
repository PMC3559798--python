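"""Shared helpers for the numbered analysis drivers.

The panel is a synthetic 12-population breed panel written to (and reloaded
from) PED/MAP under scratch/, so every driver exercises the same text-format
readers that real array data would go through.
"""

from pathlib import Path

from breeddiv.genotypes import read_ped_map, read_pop_table, write_ped_map
from breeddiv.simulate import paper_like_panel

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "analysis_data"
RESULTS = ROOT / "results" / "analysis"

PANEL_SEED = 20
PANEL_LOCI = 1000


def panel_paths():
    return DATA / "panel.ped", DATA / "panel.map", DATA / "panel.pops.tsv"


def load_panel():
    """Load the analysis panel, generating it first if absent."""
    ped, mp, pops = panel_paths()
    if not ped.exists():
        make_panel()
    return read_ped_map(ped, mp, pop_table=read_pop_table(pops))


def make_panel():
    DATA.mkdir(parents=True, exist_ok=True)
    G = paper_like_panel(seed=PANEL_SEED, n_loci=PANEL_LOCI)
    ped, mp, pops = panel_paths()
    write_ped_map(G, ped, mp)
    with open(pops, "w") as fh:
        for s in G.samples:
            fh.write(f"{s.id}\t{s.population}\n")
    return G


def outdir():
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
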