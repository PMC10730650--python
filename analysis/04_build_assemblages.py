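"""Assemble species into grid-cell communities and apply the filters.

Excludes water-dominated cells (>50% water) and assemblages with colour
data for under 33% of their species, then averages raw/P/S colour
across co-occurring species.  Writes results/assemblages.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from melanoclime.grid import (
    assemblage_trait_means,
    attach_cell_environment,
    filter_assemblages,
    filter_cells,
)


def main():
    cells = filter_cells(common.load_cells())
    occupancy = common.load_occupancy()
    traits = common.load_decomposition()

    n_water = int((~cells["included"]).sum())
    occ_inc = occupancy.merge(cells.loc[cells["included"], ["cell_id"]], on="cell_id")
    summaries = filter_assemblages(assemblage_trait_means(occ_inc, traits))
    summaries = attach_cell_environment(summaries, cells)
    summaries.to_csv(common.RESULTS / "assemblages.csv", index=False,
                     float_format="%.10g")

    n_total = len(summaries)
    n_kept = int(summaries["included"].sum())
    reasons = summaries.loc[~summaries["included"], "exclusion_reason"].value_counts()
    print(f"cells: {len(cells)} total, {n_water} excluded as water-dominated")
    print(f"assemblages: {n_kept} of {n_total} retained "
          f"({dict(reasons) if len(reasons) else 'no exclusions'})")
    inc = summaries[summaries["included"]]
    print(f"richness per assemblage: median {inc['n_species_total'].median():.0f}, "
          f"colour coverage median {inc['coverage'].median():.2f}")


if __name__ == "__main__":
    main()
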