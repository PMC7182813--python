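"""Probe-liquid surface-tension components for sessile-drop surface energetics.

A test liquid is characterised by its total surface tension ``gamma_total``
and its Lifshitz-van der Waals (apolar), electron-acceptor (Lewis acid,
``gamma_plus``) and electron-donor (Lewis base, ``gamma_minus``) components,
all in mJ/m^2.  The polar part combines as ``gamma_ab = 2*sqrt(g+ * g-)`` and
``gamma_total ~= gamma_lw + gamma_ab``.

The package ships the canonical three-liquid set used for acid-base surface
energy decomposition — water, formamide and methylene iodide (diiodomethane)
— loadable via :func:`default_liquids`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "TestLiquid",
    "WATER",
    "FORMAMIDE",
    "METHYLENE_IODIDE",
    "default_liquids",
    "load_liquids",
]

#: tolerance (mJ/m^2) for the gamma_total == gamma_lw + gamma_ab consistency check
_CONSISTENCY_TOL = 0.5


@dataclass(frozen=True)
class TestLiquid:
    """Surface-tension components of a probe liquid (mJ/m^2)."""

    __test__ = False  # "Test" here means probe liquid, not a pytest class

    name: str
    gamma_total: float
    gamma_lw: float
    gamma_plus: float
    gamma_minus: float

    def __post_init__(self) -> None:
        if self.gamma_total <= 0:
            raise ValueError(f"{self.name}: gamma_total must be > 0")
        for field in ("gamma_lw", "gamma_plus", "gamma_minus"):
            if getattr(self, field) < 0:
                raise ValueError(f"{self.name}: {field} must be >= 0")
        if abs(self.gamma_total - (self.gamma_lw + self.gamma_ab)) > _CONSISTENCY_TOL:
            raise ValueError(
                f"{self.name}: gamma_total={self.gamma_total} inconsistent with "
                f"gamma_lw + 2*sqrt(g+ g-) = {self.gamma_lw + self.gamma_ab:.3f}"
            )

    @property
    def gamma_ab(self) -> float:
        """Lewis acid-base component, 2*sqrt(gamma_plus * gamma_minus)."""
        return 2.0 * math.sqrt(self.gamma_plus * self.gamma_minus)

    @property
    def is_apolar(self) -> bool:
        """True when both Lewis components vanish (e.g. methylene iodide)."""
        return self.gamma_plus == 0.0 and self.gamma_minus == 0.0


WATER = TestLiquid("water", 72.8, 21.8, 25.5, 25.5)
FORMAMIDE = TestLiquid("formamide", 58.0, 39.0, 2.28, 39.6)
METHYLENE_IODIDE = TestLiquid("methylene iodide", 50.8, 50.8, 0.0, 0.0)


def default_liquids() -> list[TestLiquid]:
    """Return the shipped water / formamide / methylene iodide triplet."""
    with resources.as_file(
        resources.files("adhesurf.data") / "test_liquids.csv"
    ) as path:
        return load_liquids(path)


def load_liquids(path) -> list[TestLiquid]:
    """Load probe liquids from a CSV with columns
    ``name,gamma_total,gamma_lw,gamma_ab,gamma_plus,gamma_minus``.

    The ``gamma_ab`` column is informational; the acid-base component is
    recomputed from ``gamma_plus``/``gamma_minus`` and checked for consistency.
    """
    df = pd.read_csv(path)
    required = {"name", "gamma_total", "gamma_lw", "gamma_plus", "gamma_minus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"liquid table missing columns: {sorted(missing)}")
    return [
        TestLiquid(
            name=row["name"],
            gamma_total=float(row["gamma_total"]),
            gamma_lw=float(row["gamma_lw"]),
            gamma_plus=float(row["gamma_plus"]),
            gamma_minus=float(row["gamma_minus"]),
        )
        for _, row in df.iterrows()
    ]
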