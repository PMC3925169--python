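"""Sheet-structured synthetic specimens and disc images.

No public archive of raw veneer measurements exists, so this module
generates tables with the same structure: S source sheets, each
contributing n discs whose three properties (dry weight in g, moisture
absorption in %, mode skewness) scatter around a sheet-specific latent
mean. Sheet means are drawn from a global Gaussian (between-sheet
variation); discs add independent Gaussian noise (within-sheet
variation). Dry weights and moisture values are kept positive by
resampling rather than clipping, so means are not materially distorted.

Defaults emulate a plantation-pine veneer study: a 60 mm x 1 mm disc of
density ~0.45 g/cm^3 weighs about 1.3 g dry; equilibrium moisture uptake
after days at 28 degC / 80 % RH sits near 15 % of dry weight; discs are
mostly pale (earlywood-dominated), hence a negative mean mode skewness.
Between-sheet spread is set at three times the within-sheet spread in
every dimension, giving sheets that are distinguishable but overlapping.

:func:`simulate_disc_image` renders a synthetic photograph — a circular
disc of alternating concentric pale (earlywood) and dark (latewood)
bands on a near-black background — for exercising the image pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ParameterError
from .measurements import Specimen, write_specimens

DEFAULT_GLOBAL_MEANS = (1.3, 15.0, -0.5)
DEFAULT_WITHIN_SD = (0.025, 0.5, 0.1)
DEFAULT_BETWEEN_SD = tuple(3 * s for s in DEFAULT_WITHIN_SD)


@dataclass
class SheetSimConfig:
    """Parameters of the hierarchical Gaussian sheet model."""

    n_sheets: int = 10
    discs_per_sheet: int = 50
    global_means: tuple = DEFAULT_GLOBAL_MEANS
    between_sheet_sd: tuple = DEFAULT_BETWEEN_SD
    within_sheet_sd: tuple = DEFAULT_WITHIN_SD
    seed: int | None = 0

    def __post_init__(self):
        if self.n_sheets < 1 or self.discs_per_sheet < 1:
            raise ParameterError("n_sheets and discs_per_sheet must be >= 1")
        for name in ("global_means", "between_sheet_sd", "within_sheet_sd"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (3,):
                raise ParameterError(f"{name} must be a 3-vector")
            setattr(self, name, tuple(vec))
        if any(s < 0 for s in self.between_sheet_sd + self.within_sheet_sd):
            raise ParameterError("standard deviations must be non-negative")


def _positive_normal(rng, mean, sd, min_value=0.0, max_tries=1000):
    """Draw Normal(mean, sd) truncated above ``min_value`` by resampling."""
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > min_value or sd == 0:
            return max(x, min_value) if sd == 0 else x
    raise ParameterError(
        f"could not draw a value above {min_value} from N({mean}, {sd}^2)"
    )


def simulate_specimens(config: SheetSimConfig) -> list[Specimen]:
    """Generate the full specimen list for a simulated veneer study.

    Sheet s gets a latent mean vector ~ N(global_means, between_sd^2);
    each disc adds N(0, within_sd^2) noise per property. Dry weight and
    moisture are resampled if non-positive/negative. Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mu = np.asarray(config.global_means)
    tau = np.asarray(config.between_sheet_sd)
    sigma = np.asarray(config.within_sheet_sd)
    width = len(str(config.n_sheets))
    dwidth = len(str(config.discs_per_sheet))
    specimens = []
    for s in range(config.n_sheets):
        sheet_id = f"S{s + 1:0{width}d}"
        sheet_mean = rng.normal(mu, tau)
        for d in range(config.discs_per_sheet):
            dry = _positive_normal(rng, sheet_mean[0], sigma[0], min_value=0.0)
            moist = _positive_normal(rng, sheet_mean[1], sigma[1], min_value=0.0)
            skew = rng.normal(sheet_mean[2], sigma[2])
            specimens.append(
                Specimen(
                    specimen_id=f"{sheet_id}-D{d + 1:0{dwidth}d}",
                    sheet_id=sheet_id,
                    dry_weight=dry,
                    wet_weight=dry * (1 + moist / 100.0),
                    moisture_absorption=moist,
                    mode_skewness=skew,
                )
            )
    return specimens


def write_specimen_table(config: SheetSimConfig, path: str | Path) -> list[Specimen]:
    """Simulate specimens and write them in the CSV schema the
    measurements module reads; returns the specimens."""
    specimens = simulate_specimens(config)
    write_specimens(specimens, path)
    return specimens


def simulate_disc_image(
    diameter_px: int = 240,
    earlywood_level: int = 190,
    latewood_level: int = 80,
    ring_width_px: int = 12,
    noise_sd: float = 4.0,
    seed: int | None = None,
    background_level: int = 10,
    earlywood_fraction: float = 0.7,
) -> np.ndarray:
    """Render a synthetic disc photograph as an 8-bit grayscale array.

    Concentric rings alternate between a pale earlywood band (occupying
    ``earlywood_fraction`` of each ``ring_width_px`` period) and a dark
    latewood band. Gaussian pixel noise of ``noise_sd`` is added to the
    disc only and clipped to [0, 255]; the background stays below the
    standard intensity cutoff so it is removed downstream.
    """
    if diameter_px < 4:
        raise ParameterError("diameter_px must be at least 4")
    if min(earlywood_level, latewood_level) < 60:
        raise ParameterError("band levels must be >= 60 to survive the cutoff")
    if max(earlywood_level, latewood_level) > 255:
        raise ParameterError("band levels must be <= 255")
    if not 0 <= background_level < 60:
        raise ParameterError("background level must be below 60")
    if ring_width_px < 1:
        raise ParameterError("ring_width_px must be >= 1")
    if not 0.0 < earlywood_fraction < 1.0:
        raise ParameterError("earlywood_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    n = diameter_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    disc = r <= n / 2.0
    phase = (r % ring_width_px) / ring_width_px
    bands = np.where(phase < earlywood_fraction, earlywood_level, latewood_level)
    img = np.full((n, n), float(background_level))
    img[disc] = bands[disc] + rng.normal(0.0, noise_sd, size=int(disc.sum()))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def write_disc_image(path: str | Path, **kwargs) -> np.ndarray:
    """Render a synthetic disc and save it as PNG; returns the array."""
    img = simulate_disc_image(**kwargs)
    Image.fromarray(img, mode="L").save(path)
    return img
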