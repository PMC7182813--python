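"""Acid-base (van Oss-Chaudhury-Good) surface-energy decomposition of solids.

Given sessile-drop contact angles of (at least) three probe liquids, of which
at least two are polar, the solid's Lifshitz-van der Waals and Lewis
acid/base surface-energy components follow from the Young-Good-Girifalco-
Fowkes relation, one equation per liquid *i* on solid *j*::

    (1 + cos(theta_i)) * gamma_i = 2 * ( sqrt(gamma_i^LW) * x
                                       + sqrt(gamma_i^-)  * y
                                       + sqrt(gamma_i^+)  * z )

with unknowns ``x = sqrt(gamma_j^LW)``, ``y = sqrt(gamma_j^+)``,
``z = sqrt(gamma_j^-)``.  Three liquids give a square linear system; more
give an ordinary least-squares problem in the same sqrt-space.

The solve can legitimately return *negative* roots (a well-known feature of
the method on weakly acidic polymer surfaces such as PET).  We store the
squared magnitude, flag the sign, and retain the signed root internally so
that forward-modelling angles from the solved components is an exact
round-trip.

Hydrophobicity is classified from the water contact angle after Rijnaarts:
< 20 deg hydrophilic, 20-50 deg intermediately hydrophobic, >= 50 deg
hydrophobic (boundaries assigned to the upper class).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .liquids import TestLiquid

__all__ = [
    "ContactAngleMeasurement",
    "SurfaceEnergyComponents",
    "HydrophobicityClass",
    "UncertaintyResult",
    "ConditioningError",
    "solve_components",
    "forward_contact_angle",
    "acid_base_component",
    "total_energy",
    "classify_hydrophobicity",
    "propagate_uncertainty",
    "apolar_lw_diagnostic",
]

#: condition-number cap above which the liquid triplet is rejected
DEFAULT_CONDITION_CAP = 1e6
#: condition number above which a degeneracy warning is emitted
_CONDITION_WARN = 1e3


class ConditioningError(ValueError):
    """Raised when the liquid set yields a near-singular sqrt-space system."""


class HydrophobicityClass(enum.Enum):
    HYDROPHILIC = "hydrophilic"
    INTERMEDIATELY_HYDROPHOBIC = "intermediately_hydrophobic"
    HYDROPHOBIC = "hydrophobic"


@dataclass(frozen=True)
class ContactAngleMeasurement:
    """Averaged sessile-drop contact angle for one probe liquid (degrees)."""

    liquid: TestLiquid
    theta_mean: float
    theta_sd: float = 0.0
    n_readings: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_mean <= 180.0:
            raise ValueError(
                f"theta_mean={self.theta_mean} outside [0, 180] deg "
                f"({self.liquid.name})"
            )
        if self.theta_sd < 0:
            raise ValueError("theta_sd must be >= 0")
        if self.n_readings < 1:
            raise ValueError("n_readings must be >= 1")


@dataclass(frozen=True)
class SurfaceEnergyComponents:
    """Solved solid surface-energy components (magnitudes, mJ/m^2).

    ``root_signs`` carries the signs of the solved sqrt-space roots
    (sqrt(gLW), sqrt(g+), sqrt(g-)); ``negative_root_flags`` marks the
    components whose root came out negative.  ``gamma_ab`` and
    ``gamma_total`` are exact identities on the unrounded magnitudes.
    """

    surface_name: str
    gamma_lw: float
    gamma_plus: float
    gamma_minus: float
    root_signs: tuple[int, int, int] = (1, 1, 1)
    negative_root_flags: tuple[bool, bool, bool] = field(init=False)

    def __post_init__(self) -> None:
        for name in ("gamma_lw", "gamma_plus", "gamma_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} magnitude must be >= 0")
        object.__setattr__(
            self, "negative_root_flags", tuple(s < 0 for s in self.root_signs)
        )

    @property
    def gamma_ab(self) -> float:
        return acid_base_component(self.gamma_plus, self.gamma_minus)

    @property
    def gamma_total(self) -> float:
        return total_energy(self.gamma_lw, self.gamma_ab)

    @property
    def signed_roots(self) -> tuple[float, float, float]:
        """(sqrt(gLW), sqrt(g+), sqrt(g-)) with solve signs retained."""
        return (
            self.root_signs[0] * math.sqrt(self.gamma_lw),
            self.root_signs[1] * math.sqrt(self.gamma_plus),
            self.root_signs[2] * math.sqrt(self.gamma_minus),
        )


def acid_base_component(gamma_plus: float, gamma_minus: float) -> float:
    """Lewis acid-base energy ``2*sqrt(gamma_plus * gamma_minus)`` (mJ/m^2)."""
    if gamma_plus < 0 or gamma_minus < 0:
        raise ValueError("Lewis components must be >= 0")
    return 2.0 * math.sqrt(gamma_plus * gamma_minus)


def total_energy(gamma_lw: float, gamma_ab: float) -> float:
    """Total surface energy as the sum of apolar and acid-base parts."""
    if not (math.isfinite(gamma_lw) and math.isfinite(gamma_ab)):
        raise ValueError("components must be finite")
    return gamma_lw + gamma_ab


def classify_hydrophobicity(theta_water: float) -> HydrophobicityClass:
    """Rijnaarts classification of a surface by its water contact angle.

    < 20 deg -> hydrophilic; [20, 50) -> intermediately hydrophobic;
    >= 50 deg -> hydrophobic.  Boundaries belong to the upper class.
    """
    if not 0.0 <= theta_water <= 180.0:
        raise ValueError(f"water contact angle {theta_water} outside [0, 180]")
    if theta_water < 20.0:
        return HydrophobicityClass.HYDROPHILIC
    if theta_water < 50.0:
        return HydrophobicityClass.INTERMEDIATELY_HYDROPHOBIC
    return HydrophobicityClass.HYDROPHOBIC


def _design_matrix(liquids: list[TestLiquid]) -> np.ndarray:
    # rows: [sqrt(gLW_i), sqrt(gminus_i), sqrt(gplus_i)] for unknowns (x, y, z)
    return np.array(
        [
            [
                math.sqrt(liq.gamma_lw),
                math.sqrt(liq.gamma_minus),
                math.sqrt(liq.gamma_plus),
            ]
            for liq in liquids
        ]
    )


def solve_components(
    angles: list[ContactAngleMeasurement],
    surface_name: str = "surface",
    condition_cap: float = DEFAULT_CONDITION_CAP,
) -> SurfaceEnergyComponents:
    """Solve the three-liquid Young-Good-Girifalco-Fowkes system.

    Parameters
    ----------
    angles
        Contact-angle measurements for at least three distinct liquids, at
        least two of them polar.  With exactly three liquids the square
        system is solved directly; with more, by ordinary least squares in
        sqrt-space.
    surface_name
        Label carried into the result.
    condition_cap
        Maximum allowed condition number of the sqrt-space design matrix.

    Returns
    -------
    SurfaceEnergyComponents
        Squared magnitudes with negative roots flagged, never zeroed.

    Raises
    ------
    ValueError
        Fewer than three liquids, duplicate liquids, or fewer than two
        polar liquids.
    ConditioningError
        Design-matrix condition number above ``condition_cap``.
    """
    if len(angles) < 3:
        raise ValueError("need contact angles for at least three liquids")
    liquids = [a.liquid for a in angles]
    names = [liq.name for liq in liquids]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate liquids in {names}")
    n_polar = sum(1 for liq in liquids if not liq.is_apolar)
    if n_polar < 2:
        raise ValueError(
            f"at least two polar liquids required, got {n_polar} among {names}"
        )

    A = _design_matrix(liquids)
    cond = np.linalg.cond(A)
    if cond > condition_cap:
        raise ConditioningError(
            f"liquid set {names} is degenerate in sqrt-space "
            f"(condition number {cond:.3g} > cap {condition_cap:.3g})"
        )
    if cond > _CONDITION_WARN:
        warnings.warn(
            f"liquid set {names} poorly conditioned (condition number {cond:.3g})",
            stacklevel=2,
        )

    theta = np.radians([a.theta_mean for a in angles])
    b = (1.0 + np.cos(theta)) * np.array([liq.gamma_total for liq in liquids]) / 2.0
    if len(angles) == 3:
        roots = np.linalg.solve(A, b)
    else:
        roots, *_ = np.linalg.lstsq(A, b, rcond=None)

    signs = tuple(1 if r >= 0 else -1 for r in roots)
    return SurfaceEnergyComponents(
        surface_name=surface_name,
        gamma_lw=float(roots[0] ** 2),
        gamma_plus=float(roots[1] ** 2),
        gamma_minus=float(roots[2] ** 2),
        root_signs=signs,
    )


def forward_contact_angle(
    components: SurfaceEnergyComponents, liquid: TestLiquid
) -> float:
    """Contact angle (degrees) of a probe liquid on a solid with known
    components, by inverting the Young-Good-Girifalco-Fowkes relation.

    Uses the *signed* sqrt-space roots, so composing with
    :func:`solve_components` round-trips exactly even when a root is
    negative.
    """
    x, y, z = components.signed_roots
    cos_theta = -1.0 + 2.0 * (
        x * math.sqrt(liquid.gamma_lw)
        + y * math.sqrt(liquid.gamma_minus)
        + z * math.sqrt(liquid.gamma_plus)
    ) / liquid.gamma_total
    # guard against 1-ulp excursions from exact wetting
    if not -1.0 <= cos_theta <= 1.0:
        if abs(cos_theta) - 1.0 < 1e-12:
            cos_theta = max(-1.0, min(1.0, cos_theta))
        else:
            raise ValueError(
                f"implied cos(theta) = {cos_theta:.6f} outside [-1, 1] for "
                f"{liquid.name} on {components.surface_name}"
            )
    return math.degrees(math.acos(cos_theta))


def residuals(
    components: SurfaceEnergyComponents, angles: list[ContactAngleMeasurement]
) -> np.ndarray:
    """Relative back-substitution residuals of each liquid equation."""
    x, y, z = components.signed_roots
    out = []
    for a in angles:
        liq = a.liquid
        lhs = (1.0 + math.cos(math.radians(a.theta_mean))) * liq.gamma_total
        rhs = 2.0 * (
            x * math.sqrt(liq.gamma_lw)
            + y * math.sqrt(liq.gamma_minus)
            + z * math.sqrt(liq.gamma_plus)
        )
        out.append((lhs - rhs) / max(abs(lhs), 1.0))
    return np.array(out)


def apolar_lw_diagnostic(
    angles: list[ContactAngleMeasurement],
) -> dict[str, float]:
    """Per-liquid implied apolar gamma^LW, a column-integrity diagnostic.

    Treating each liquid as if it were the sole apolar probe, the relation
    collapses to ``gamma_j^LW = ((1+cos theta)*gamma_i)^2 / (4*gamma_i^LW)``.
    Comparing these implied values against a published gamma^LW reveals
    transposed or mislabelled angle columns: the implied value from the true
    apolar liquid should match the published one, values from polar liquids
    generally should not.
    """
    out = {}
    for a in angles:
        liq = a.liquid
        if liq.gamma_lw <= 0:
            continue
        num = (1.0 + math.cos(math.radians(a.theta_mean))) * liq.gamma_total
        out[liq.name] = num * num / (4.0 * liq.gamma_lw)
    return out


@dataclass(frozen=True)
class UncertaintyResult:
    """Monte-Carlo uncertainty propagation summary (magnitudes, mJ/m^2)."""

    mean: dict[str, float]
    sd: dict[str, float]
    negative_root_fraction: dict[str, float]
    failure_fraction: float
    n_draws: int


def propagate_uncertainty(
    angles: list[ContactAngleMeasurement],
    n_draws: int = 10_000,
    seed: int = 0,
) -> UncertaintyResult:
    """Propagate contact-angle measurement noise through the solve.

    Each draw resamples every liquid's angle from an independent normal
    truncated to [0, 180] deg (truncation keeps the draw count
    deterministic), solves the system, and accumulates component
    magnitudes.  Draws whose solve fails (conditioning, domain) are counted
    as failures; more than 50% failures aborts.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if all(a.theta_sd == 0 for a in angles):
        comp = solve_components(angles)
        point = {
            "gamma_lw": comp.gamma_lw,
            "gamma_plus": comp.gamma_plus,
            "gamma_minus": comp.gamma_minus,
            "gamma_ab": comp.gamma_ab,
            "gamma_total": comp.gamma_total,
        }
        return UncertaintyResult(
            mean=point,
            sd={k: 0.0 for k in point},
            negative_root_fraction={
                k: float(f)
                for k, f in zip(
                    ("gamma_lw", "gamma_plus", "gamma_minus"),
                    comp.negative_root_flags,
                )
            },
            failure_fraction=0.0,
            n_draws=n_draws,
        )
    rng = np.random.default_rng(seed)
    keys = ("gamma_lw", "gamma_plus", "gamma_minus", "gamma_ab", "gamma_total")
    draws: dict[str, list[float]] = {k: [] for k in keys}
    neg_counts = np.zeros(3)
    failures = 0

    sampled = []
    for a in angles:
        if a.theta_sd == 0:
            sampled.append(np.full(n_draws, a.theta_mean))
        else:
            lo = (0.0 - a.theta_mean) / a.theta_sd
            hi = (180.0 - a.theta_mean) / a.theta_sd
            sampled.append(
                stats.truncnorm.rvs(
                    lo, hi, loc=a.theta_mean, scale=a.theta_sd,
                    size=n_draws, random_state=rng,
                )
            )

    for i in range(n_draws):
        try:
            comp = solve_components(
                [
                    ContactAngleMeasurement(a.liquid, float(col[i]), 0.0, 1)
                    for a, col in zip(angles, sampled)
                ]
            )
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        draws["gamma_lw"].append(comp.gamma_lw)
        draws["gamma_plus"].append(comp.gamma_plus)
        draws["gamma_minus"].append(comp.gamma_minus)
        draws["gamma_ab"].append(comp.gamma_ab)
        draws["gamma_total"].append(comp.gamma_total)
        neg_counts += np.array(comp.negative_root_flags, dtype=float)

    fail_frac = failures / n_draws
    if fail_frac > 0.5:
        raise RuntimeError(
            f"{fail_frac:.0%} of Monte-Carlo draws failed to solve"
        )
    n_ok = n_draws - failures
    return UncertaintyResult(
        mean={k: float(np.mean(v)) for k, v in draws.items()},
        sd={k: float(np.std(v, ddof=1)) if n_ok > 1 else 0.0 for k, v in draws.items()},
        negative_root_fraction={
            "gamma_lw": float(neg_counts[0] / n_ok),
            "gamma_plus": float(neg_counts[1] / n_ok),
            "gamma_minus": float(neg_counts[2] / n_ok),
        },
        failure_fraction=fail_frac,
        n_draws=n_draws,
    )
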