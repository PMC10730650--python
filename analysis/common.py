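"""Shared paths and loaders for the numbered analysis scripts.

Run the scripts in order from the repository root:

    python analysis/01_simulate_world.py
    python analysis/02_score_colours.py
    ...

Each stage reads its predecessors' outputs from results/ and writes its
own tables there.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
WORLD = RESULTS / "world"


def load_cells():
    return pd.read_csv(WORLD / "cells.csv")


def load_occupancy():
    return pd.read_csv(WORLD / "occupancy.csv")


def load_observations():
    from melanoclime.colour import observations_from_frame
    return observations_from_frame(pd.read_csv(WORLD / "observations.csv"))


def load_wheel():
    from melanoclime.colour import ColourWheel
    return ColourWheel.from_csv(WORLD / "wheel.csv")


def load_tree():
    from melanoclime.phylo import read_newick
    return read_newick(WORLD / "tree.nwk")


def load_species_colour():
    return pd.read_csv(RESULTS / "species_colour.csv")


def load_decomposition():
    return pd.read_csv(RESULTS / "decomposition.csv")


def load_assemblages():
    return pd.read_csv(RESULTS / "assemblages.csv")
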