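"""Generate the synthetic world: environment grid, phylogeny, ranges,
colour observations, activity classes and chytrid severity.

Writes the full input bundle to results/world/ together with a manifest
of the true generating parameters, so every later stage can be checked
against what was planted.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from melanoclime.pipeline import write_world_bundle
from melanoclime.world import WorldConfig, generate_world


def main():
    cfg = WorldConfig()  # the study conditions; master seed 0
    world = generate_world(cfg)
    common.WORLD.mkdir(parents=True, exist_ok=True)
    write_world_bundle(world, common.WORLD)
    m = world.manifest
    print(f"world: {m['n_cells']} cells ({m['n_water_cells']} water-dominated), "
          f"{m['n_species']} species, {m['n_observations']} colour observations "
          f"({m['n_missing_species']} species unsampled)")
    print(f"true betas (lightness per species-SD): {m['true_betas']}")
    print(f"deviation lambda {m['true_lambda']}, clipped fraction "
          f"{m['clipped_fraction']:.3f}")
    print(f"bundle written to {common.WORLD}")


if __name__ == "__main__":
    main()
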