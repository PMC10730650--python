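"""Colour-lightness scoring from wheel-coded patch observations.

Field observations record an individual's dorsal colouration as a short
list of patches, each a colour (a colour-wheel id or an explicit RGB
triple) with a percent coverage estimated in 5% steps.  Colour lightness
is the coverage-weighted mean of the RGB channel means, ranging from
0 (black) to 255 (white).  Species values are unweighted means over
individuals (sexes and morphs pooled).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SATURATION_LEVELS = (10, 40, 70, 100)
N_HUES = 18
COVERAGE_STEP = 0.05
_COVERAGE_TOL = 1e-9


@dataclass(frozen=True)
class WheelEntry:
    colour_id: int
    hue_index: int  # 1..18
    saturation: int  # percent, one of SATURATION_LEVELS
    rgb: tuple[int, int, int]


@dataclass
class ColourWheel:
    """A catalog of 72 reference colours: 18 hues x 4 saturation levels."""

    entries: list[WheelEntry]

    def __post_init__(self) -> None:
        if len(self.entries) != N_HUES * len(SATURATION_LEVELS):
            raise ValueError(f"wheel must have {N_HUES * len(SATURATION_LEVELS)} entries, got {len(self.entries)}")
        pairs = {(e.hue_index, e.saturation) for e in self.entries}
        if len(pairs) != len(self.entries):
            raise ValueError("duplicate (hue, saturation) pair in wheel")
        for e in self.entries:
            if not all(0 <= c <= 255 for c in e.rgb):
                raise ValueError(f"RGB out of range in wheel entry {e.colour_id}")
        self._by_id = {e.colour_id: e for e in self.entries}
        if len(self._by_id) != len(self.entries):
            raise ValueError("duplicate colour_id in wheel")

    def rgb(self, colour_id: int) -> tuple[int, int, int]:
        try:
            return self._by_id[colour_id].rgb
        except KeyError:
            raise KeyError(f"colour_id {colour_id} not in wheel") from None

    def lightness(self, colour_id: int) -> float:
        return patch_lightness(self.rgb(colour_id))

    def lightness_values(self) -> np.ndarray:
        """Sorted unique lightness values of the wheel's colours."""
        return np.unique([patch_lightness(e.rgb) for e in self.entries])

    def max_lightness_gap(self) -> float:
        """Largest gap between consecutive lightness values on the wheel.

        Quantisation error bounds derived from this gap apply to targets
        within the wheel's representable lightness span; a wheel without
        near-black colours cannot represent values below its minimum.
        """
        return float(np.max(np.diff(self.lightness_values())))

    def lightness_span(self) -> tuple[float, float]:
        vals = self.lightness_values()
        return float(vals[0]), float(vals[-1])

    def nearest_by_lightness(self, target: float) -> WheelEntry:
        best = min(self.entries, key=lambda e: (abs(patch_lightness(e.rgb) - target), e.colour_id))
        return best

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"colour_id": e.colour_id, "hue_index": e.hue_index, "saturation": e.saturation,
                 "R": e.rgb[0], "G": e.rgb[1], "B": e.rgb[2]}
                for e in self.entries
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ColourWheel":
        entries = [
            WheelEntry(int(r.colour_id), int(r.hue_index), int(r.saturation),
                       (int(r.R), int(r.G), int(r.B)))
            for r in df.itertuples()
        ]
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "ColourWheel":
        return cls.from_frame(pd.read_csv(path))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ColourWheel):
            return NotImplemented
        return self.entries == other.entries


def build_default_wheel(value_channel: float = 1.0, seed: int = 0) -> ColourWheel:
    """Generate a default 72-colour wheel in HSV space.

    18 equally spaced hues, each at four saturation levels (10, 40, 70,
    100%), converted to RGB at the given HSV value channel.  Deterministic
    for fixed arguments; `seed` is accepted for interface symmetry with
    the stochastic generators but does not affect the output.
    """
    if not 0 < value_channel <= 1:
        raise ValueError("value_channel must be in (0, 1]")
    entries = []
    cid = 1
    for h in range(N_HUES):
        hue = h / N_HUES
        for sat in SATURATION_LEVELS:
            r, g, b = colorsys.hsv_to_rgb(hue, sat / 100.0, value_channel)
            rgb = (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))
            entries.append(WheelEntry(cid, h + 1, sat, rgb))
            cid += 1
    return ColourWheel(entries)


@dataclass(frozen=True)
class ColourPatch:
    """One patch of an individual's dorsal surface.

    `colour` is a wheel colour_id (int) or an explicit RGB triple;
    `coverage` is the patch's fraction of the surface, a multiple of 0.05.
    """

    colour: int | tuple[float, float, float]
    coverage: float

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        steps = self.coverage / COVERAGE_STEP
        if abs(steps - round(steps)) > 1e-6:
            raise ValueError(f"coverage {self.coverage} is not a multiple of {COVERAGE_STEP}")


@dataclass
class ColourObservation:
    species_id: str
    individual_id: str
    observer_id: str
    patches: list[ColourPatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patches:
            raise ValueError("observation needs at least one patch")
        total = sum(p.coverage for p in self.patches)
        if abs(total - 1.0) > _COVERAGE_TOL:
            raise ValueError(f"coverages sum to {total}, expected 1.0")


@dataclass(frozen=True)
class SpeciesColour:
    species_id: str
    lightness: float
    n_individuals: int


def patch_lightness(rgb) -> float:
    """Mean of the R, G, B channels: 0 (black) to 255 (white)."""
    r, g, b = rgb
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ValueError(f"channel {c} outside [0, 255]")
    return (r + g + b) / 3.0


def _resolve_rgb(colour, wheel: ColourWheel | None):
    if isinstance(colour, (int, np.integer)):
        if wheel is None:
            raise ValueError("colour_id patch requires a wheel")
        return wheel.rgb(int(colour))
    return colour


def observation_lightness(obs: ColourObservation, wheel: ColourWheel | None = None) -> float:
    """Coverage-weighted mean of patch lightness values."""
    return float(
        sum(p.coverage * patch_lightness(_resolve_rgb(p.colour, wheel)) for p in obs.patches)
    )


def species_lightness(
    observations: list[ColourObservation], wheel: ColourWheel | None = None
) -> list[SpeciesColour]:
    """Per-species unweighted mean over individuals; species order is sorted.

    Species with zero observations are simply absent from the output.
    """
    per_species: dict[str, list[float]] = {}
    for obs in observations:
        per_species.setdefault(obs.species_id, []).append(observation_lightness(obs, wheel))
    return [
        SpeciesColour(sp, float(np.mean(vals)), len(vals))
        for sp, vals in sorted(per_species.items())
    ]


def species_lightness_frame(observations, wheel=None) -> pd.DataFrame:
    rows = species_lightness(observations, wheel)
    return pd.DataFrame(
        {"species_id": [r.species_id for r in rows],
         "lightness": [r.lightness for r in rows],
         "n_individuals": [r.n_individuals for r in rows]}
    )


@dataclass(frozen=True)
class ObserverCalibration:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n: int

    def apply(self, estimates) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(estimates, dtype=float)


def observer_calibration(paired) -> ObserverCalibration:
    """OLS of observer B's estimates on observer A's, for aligning observers.

    `paired` is a sequence of (estimate_a, estimate_b).  Requires n >= 3
    and a non-constant predictor.
    """
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (a, b) pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0:
        raise ValueError("constant predictor: calibration is undefined")
    n = len(a)
    X = np.column_stack([np.ones(n), a])
    beta, *_ = np.linalg.lstsq(X, b, rcond=None)
    resid = b - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    sigma2 = rss / (n - 2) if n > 2 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return ObserverCalibration(
        slope=float(beta[1]), intercept=float(beta[0]),
        slope_se=float(np.sqrt(cov[1, 1])), r_squared=r2, n=n,
    )


# ---------------------------------------------------------------------------
# CSV interchange (long format: one row per patch)

def observations_to_frame(observations: list[ColourObservation]) -> pd.DataFrame:
    rows = []
    for obs in observations:
        for k, p in enumerate(obs.patches, start=1):
            row = {"species_id": obs.species_id, "individual_id": obs.individual_id,
                   "observer_id": obs.observer_id, "patch_index": k,
                   "coverage_percent": round(p.coverage * 100)}
            if isinstance(p.colour, (int, np.integer)):
                row.update(colour_id=int(p.colour), R=np.nan, G=np.nan, B=np.nan)
            else:
                row.update(colour_id=np.nan, R=p.colour[0], G=p.colour[1], B=p.colour[2])
            rows.append(row)
    return pd.DataFrame(rows)


def observations_from_frame(df: pd.DataFrame) -> list[ColourObservation]:
    out = []
    for (sp, ind, obsr), grp in df.groupby(["species_id", "individual_id", "observer_id"], sort=True):
        patches = []
        for r in grp.sort_values("patch_index").itertuples():
            if pd.notna(r.colour_id):
                colour = int(r.colour_id)
            else:
                colour = (float(r.R), float(r.G), float(r.B))
            patches.append(ColourPatch(colour, r.coverage_percent / 100.0))
        out.append(ColourObservation(str(sp), str(ind), str(obsr), patches))
    return out
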