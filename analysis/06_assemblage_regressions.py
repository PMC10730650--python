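"""Assemblage-level trait-environment models.

Fits, for raw colour, its P and S components and colour diversity:
(a) multiple linear regressions on z-scaled MAT, elevation, EVI and UVB;
(b) the same models with a penalized spline trend surface over the cell
coordinates; plus hierarchical partitioning overall and per realm, the
realm-interaction model, and Moran's I correlograms of residuals.
Writes results/table1_summary.csv, hierpart_realms.csv,
realm_interactions.csv and correlograms.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from melanoclime.regression import (
    grouped_interaction_fit,
    hierarchical_partitioning,
    morans_correlogram,
    ols_fit,
    trend_surface_fit,
    zscale,
)

ENV = ["MAT", "elevation", "EVI", "UVB"]


def main():
    summ = common.load_assemblages()
    inc = summ[summ["included"]].reset_index(drop=True)
    ses = pd.read_csv(common.RESULTS / "ses.csv")
    Xz, _ = zscale(inc[ENV])
    coords = inc[["x", "y"]].to_numpy()

    rows, cg_rows = [], []
    fits = {}
    for response, col in [("raw", "mean_raw"), ("P", "mean_P"), ("S", "mean_S")]:
        y = inc[col].to_numpy()
        lm = ols_fit(y, Xz)
        gam = trend_surface_fit(y, Xz, coords)
        fits[response] = (lm, gam)
        for model, res in (("lm", lm), ("gam", gam)):
            for term in ENV:
                info = res.term(term)
                rows.append({"response": response, "model": model, "predictor": term,
                             "slope": info["slope"], "se": info["se"], "t": info["t"],
                             "p": info["p"], "r_squared": res.r_squared})
            cg = morans_correlogram(res.residuals, coords, n_classes=10, max_distance=30)
            for rec in cg.to_frame().to_dict("records"):
                cg_rows.append({"response": response, "model": model, **rec})
        print(f"{response}: LM R^2 {lm.r_squared:.2f} -> GAM R^2 {gam.r_squared:.2f}; "
              f"slopes (MAT, EVI, UVB) = "
              f"({lm.term('MAT')['slope']:+.1f}, {lm.term('EVI')['slope']:+.1f}, "
              f"{lm.term('UVB')['slope']:+.1f})")

    sesm = ses.merge(inc[["cell_id"] + ENV + ["x", "y"]], on="cell_id")
    sesm = sesm[~sesm["degenerate"]]
    Xs, _ = zscale(sesm[ENV])
    lm_d = ols_fit(sesm["ses"].to_numpy(), Xs)
    gam_d = trend_surface_fit(sesm["ses"].to_numpy(), Xs, sesm[["x", "y"]].to_numpy())
    for model, res in (("lm", lm_d), ("gam", gam_d)):
        for term in ENV:
            info = res.term(term)
            rows.append({"response": "diversity", "model": model, "predictor": term,
                         "slope": info["slope"], "se": info["se"], "t": info["t"],
                         "p": info["p"], "r_squared": res.r_squared})
    print(f"diversity: LM R^2 {lm_d.r_squared:.2f} -> GAM R^2 {gam_d.r_squared:.2f}")

    pd.DataFrame(rows).to_csv(common.RESULTS / "table1_summary.csv", index=False,
                              float_format="%.6g")
    pd.DataFrame(cg_rows).to_csv(common.RESULTS / "correlograms.csv", index=False,
                                 float_format="%.6g")

    # hierarchical partitioning: overall and per realm (> 50 assemblages)
    hp_rows = []
    hp = hierarchical_partitioning(inc["mean_raw"].to_numpy(), Xz)
    for p, ic, sh in zip(hp.predictors, hp.independent, hp.shares):
        hp_rows.append({"realm": "global", "predictor": p,
                        "independent_contribution": ic, "share": sh,
                        "full_r_squared": hp.full_r_squared})
    for realm, grp in inc.groupby("realm"):
        if len(grp) <= 50:
            continue
        Xr, _ = zscale(grp[ENV])
        hpr = hierarchical_partitioning(grp["mean_raw"].to_numpy(), Xr)
        for p, ic, sh in zip(hpr.predictors, hpr.independent, hpr.shares):
            hp_rows.append({"realm": realm, "predictor": p,
                            "independent_contribution": ic, "share": sh,
                            "full_r_squared": hpr.full_r_squared})
        print(f"hierpart {realm}: dominant {hpr.ranking()[0]} "
              f"(R^2 {hpr.full_r_squared:.2f})")
    pd.DataFrame(hp_rows).to_csv(common.RESULTS / "hierpart_realms.csv", index=False,
                                 float_format="%.6g")

    realm_fit = grouped_interaction_fit(inc["mean_raw"].to_numpy(), inc[ENV],
                                        inc["realm"], min_group_size=51)
    realm_fit.estimates.to_csv(common.RESULTS / "realm_interactions.csv", index=False,
                               float_format="%.6g")
    print(f"realm-interaction model: R^2 {realm_fit.r_squared:.2f}, "
          f"{inc['realm'].nunique() - len(realm_fit.excluded_groups)} realms retained")


if __name__ == "__main__":
    main()
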