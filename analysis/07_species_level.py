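"""Species-level models: families, activity, PGLS and chytrid severity.

Fits the family-interaction models of colour lightness against species'
range-mean environments (families with fewer than 10 species excluded),
an activity-time interaction model, an overall PGLS with lambda
estimated by maximum likelihood, and the colour-by-productivity
chytridiomycosis-severity models (per family, threshold 9, plus an
overall PGLS).  Writes results/family_interactions.csv,
activity_interactions.csv and severity_models.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from melanoclime.grid import filter_cells, species_range_environment
from melanoclime.phylo import pgls_fit
from melanoclime.regression import grouped_interaction_fit, severity_models, zscale

ENV = ["MAT", "elevation", "EVI", "UVB"]


def main():
    sc = common.load_species_colour()
    cells = filter_cells(common.load_cells())
    occupancy = common.load_occupancy()
    tree = common.load_tree()
    world_traits = pd.read_csv(common.WORLD / "taxonomy.csv")  # species_id, genus
    activity = pd.read_csv(common.WORLD / "activity.csv")
    severity = pd.read_csv(common.WORLD / "severity.csv")

    env = species_range_environment(occupancy, cells)
    d = sc.merge(env, on="species_id").merge(activity, on="species_id")
    # family labels live in the severity table's bookkeeping
    fam = severity[["species_id", "family"]].drop_duplicates()
    d = d.merge(fam, on="species_id", how="left")

    # family-interaction models (threshold 10)
    df = d.dropna(subset=["family"])
    fam_fit = grouped_interaction_fit(df["lightness"].to_numpy(), df[ENV],
                                      df["family"], min_group_size=10)
    fam_fit.estimates.to_csv(common.RESULTS / "family_interactions.csv",
                             index=False, float_format="%.6g")
    supp_mat = fam_fit.estimates.query("term == 'MAT' and slope > 0 and p < 0.05")
    supp_evi = fam_fit.estimates.query("term == 'EVI' and slope < 0 and p < 0.05")
    n_fam = fam_fit.estimates["group"].nunique()
    print(f"family models: {n_fam} families retained "
          f"({len(fam_fit.excluded_groups)} below 10 species); "
          f"{supp_mat['group'].nunique()} support temperature, "
          f"{supp_evi['group'].nunique()} support productivity "
          f"(overall R^2 {fam_fit.r_squared:.2f})")

    # activity-time interactions
    act_fit = grouped_interaction_fit(d["lightness"].to_numpy(), d[ENV],
                                      d["activity"], min_group_size=10)
    act_fit.estimates.to_csv(common.RESULTS / "activity_interactions.csv",
                             index=False, float_format="%.6g")
    print(f"activity models: groups {sorted(d['activity'].unique())}, "
          f"R^2 {act_fit.r_squared:.2f}")

    # overall PGLS of colour on z-scaled environment, lambda estimated
    dz, _ = zscale(d.set_index("species_id")[ENV])
    pg = pgls_fit(d.set_index("species_id")["lightness"], dz, tree)
    terms = {t: f"{c:+.2f}" for t, c in zip(pg.terms[1:], pg.coef[1:])}
    print(f"PGLS (lambda {pg.lambda_used:.2f}, R^2 {pg.r_squared:.3f}): {terms}")

    # chytrid severity ~ colour x productivity
    sev = severity.merge(sc, on="species_id").merge(
        env[["species_id", "EVI"]], on="species_id")
    per_family, overall = severity_models(sev, tree=tree)
    per_family.estimates.to_csv(common.RESULTS / "severity_models.csv",
                                index=False, float_format="%.6g")
    pos = per_family.estimates.query("slope > 0 and p < 0.05")
    print(f"severity: {len(pos)} of {len(per_family.estimates)} families show a "
          f"positive colour x productivity interaction; overall PGLS slope "
          f"{overall.coef[1]:+.4f} +/- {overall.se[1]:.4f} "
          f"(lambda {overall.lambda_used:.2f})")


if __name__ == "__main__":
    main()
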