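"""Synthetic inputs with known ground truth.

Because no raw micrographs, contact-angle readings or kinetic traces are
deposited alongside the adhesion study this package models, every analysis
stage is exercised against generated inputs whose truth is known exactly:

* micrographs: disk/ellipse "cells" placed until a target coverage is
  reached, rendered with configurable intensities, an optional linear
  illumination gradient and additive Gaussian noise — the ground-truth mask
  and its exact realized coverage are returned with the image;
* contact-angle sets: forward-modelled from known surface-energy components
  with truncated-normal reading noise;
* kinetic traces: a line with Gaussian absorbance noise.

Each generator is a pure function of its spec plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coverage import Micrograph
from .energetics import (
    ContactAngleMeasurement,
    SurfaceEnergyComponents,
    forward_contact_angle,
)
from .enzymology import KineticTrace
from .liquids import TestLiquid

__all__ = [
    "MicrographSpec",
    "gen_micrograph",
    "gen_replicate_micrographs",
    "gen_contact_angles",
    "gen_kinetic_trace",
]

#: default between-image coverage sd for replicate sets; adhesion studies of
#: this kind report replicate-micrograph standard deviations of a few percent
#: of area (2-11%), so a mid-band 5% is the stated world for one condition
DEFAULT_BETWEEN_IMAGE_SD = 0.05

_MAX_PLACEMENT_ATTEMPTS = 100_000


@dataclass(frozen=True)
class MicrographSpec:
    """Stated world of a synthetic adhesion micrograph.

    Defaults emulate a bright-field view of yeast settled on a polymer
    coupon: a 512x512 8-bit field, background ~200 grey levels, cells ~80,
    cell radius 6 +/- 1.5 px, additive noise sd 8.  Overlap is allowed by
    default (settled yeast cluster); ``overlap_policy='forbid'`` gives
    disjoint cells for clean unit tests.
    """

    width: int = 512
    height: int = 512
    true_coverage: float = 0.3
    cell_radius_mean: float = 6.0
    cell_radius_sd: float = 1.5
    cell_intensity: float = 80.0
    background_intensity: float = 200.0
    noise_sd: float = 8.0
    illumination_gradient: float = 0.0
    overlap_policy: str = "allow"  # "allow" | "forbid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_coverage < 1.0:
            raise ValueError("true_coverage must be in (0, 1)")
        if min(self.width, self.height) < 64:
            raise ValueError("image must be at least 64x64")
        if self.overlap_policy not in ("allow", "forbid"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")


def gen_micrograph(
    spec: MicrographSpec,
    image_id: str = "synthetic",
    condition_id: str = "synthetic",
) -> tuple[Micrograph, np.ndarray, float]:
    """Render a synthetic micrograph.

    Returns (micrograph, ground-truth boolean mask, realized coverage).
    Cells are placed until mask coverage first reaches ``true_coverage``;
    the realized coverage is the exact foreground fraction of the returned
    mask, so it can overshoot the target by at most one cell's area.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    total = h * w
    target_px = spec.true_coverage * total

    covered = 0
    attempts = 0
    while covered < target_px:
        attempts += 1
        if attempts > _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not reach coverage {spec.true_coverage} after "
                f"{_MAX_PLACEMENT_ATTEMPTS} placement attempts"
            )
        r = max(2.0, rng.normal(spec.cell_radius_mean, spec.cell_radius_sd))
        # mild eccentricity, random orientation: yeast are ovoid
        ecc = rng.uniform(0.8, 1.0)
        phi = rng.uniform(0, math.pi)
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        # rasterize only within the cell's bounding box
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        cell = (u / r) ** 2 + (v / (r * ecc)) ** 2 <= 1.0
        window = mask[y0:y1, x0:x1]
        if spec.overlap_policy == "forbid" and np.any(window & cell):
            continue
        covered += int(np.count_nonzero(cell & ~window))
        window |= cell

    realized = float(mask.sum()) / total

    img = np.full((h, w), spec.background_intensity, dtype=float)
    img[mask] = spec.cell_intensity
    if spec.illumination_gradient != 0.0:
        ramp = np.linspace(
            1.0 - spec.illumination_gradient / 2.0,
            1.0 + spec.illumination_gradient / 2.0,
            w,
        )
        img = img * ramp[np.newaxis, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 255.0).astype(np.uint8)

    return (
        Micrograph(pixels=img, image_id=image_id, condition_id=condition_id),
        mask,
        realized,
    )


def gen_replicate_micrographs(
    mean_coverage: float,
    n_images: int,
    between_image_sd: float = DEFAULT_BETWEEN_IMAGE_SD,
    seed: int = 0,
    condition_id: str = "synthetic",
    **spec_overrides,
) -> list[tuple[Micrograph, np.ndarray, float]]:
    """Generate a replicate image set for one assay condition.

    Real replicate micrographs of the same coupon differ in local cell
    density; each image's target coverage is therefore drawn from a normal
    around ``mean_coverage`` (sd ``between_image_sd``, clipped to (0.01,
    0.99)) before rendering.  ``between_image_sd=0`` reproduces identical
    targets.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        target = mean_coverage
        if between_image_sd > 0:
            target = float(
                np.clip(rng.normal(mean_coverage, between_image_sd), 0.01, 0.99)
            )
        spec = MicrographSpec(
            true_coverage=target,
            seed=int(rng.integers(0, 2**31 - 1)),
            **spec_overrides,
        )
        out.append(
            gen_micrograph(
                spec, image_id=f"{condition_id}_{i:03d}", condition_id=condition_id
            )
        )
    return out


def gen_contact_angles(
    components: SurfaceEnergyComponents,
    liquids: list[TestLiquid],
    noise_sd_deg: float = 0.0,
    n_readings: int = 10,
    seed: int = 0,
) -> list[ContactAngleMeasurement]:
    """Forward-model noisy contact-angle measurements from known components.

    Per liquid, draws ``n_readings`` angles as the exact forward angle plus
    normal noise truncated to [0, 180] deg, then reports the reading mean
    and sample sd.  ``noise_sd_deg=0`` reproduces the exact forward angles.
    """
    rng = np.random.default_rng(seed)
    out = []
    for liq in liquids:
        try:
            theta = forward_contact_angle(components, liq)
        except ValueError as exc:
            raise ValueError(f"forward angle undefined for {liq.name}: {exc}") from exc
        if noise_sd_deg == 0:
            out.append(ContactAngleMeasurement(liq, theta, 0.0, n_readings))
            continue
        readings = np.clip(
            rng.normal(theta, noise_sd_deg, size=n_readings), 0.0, 180.0
        )
        sd = float(readings.std(ddof=1)) if n_readings > 1 else 0.0
        out.append(
            ContactAngleMeasurement(liq, float(readings.mean()), sd, n_readings)
        )
    return out


def gen_kinetic_trace(
    true_slope: float,
    intercept: float = 0.05,
    duration: float = 100.0,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    reaction_volume: float = 0.0251,
    debris_mass: float = 0.05,
    path_length: float = 1.0,
) -> KineticTrace:
    """Linear absorbance trace with Gaussian noise.

    Defaults emulate the p-nitrophenyl-laurate assay: 100 s window, 25.1 mL
    reaction volume (25 mL substrate + 0.1 mL debris suspension), 1 cm
    path.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    a = intercept + true_slope * t
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=n_points)
    return KineticTrace(
        times=t,
        absorbance=a,
        reaction_volume=reaction_volume,
        debris_mass=debris_mass,
        path_length=path_length,
    )
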