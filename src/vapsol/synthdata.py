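"""Packaged fixture tables and a synthetic descriptor/target generator.

The fixtures carry exactly what is printed in the source tables of the
underlying study — the training-set composition (61 small organic
molecules across nine chemical families), the sixteen polymer repeating
elements with their structures, the fifteen-name descriptor registry, the
published coefficient registry, and the two ΔHvap range anchors
(8.19 kJ/mol for methane, 69.00 kJ/mol for heptanoic acid). Per-molecule
experimental ΔHvap values were published only in an appendix and are NOT
fabricated here; everything beyond the printed tables is exercised with
synthetic data instead.

The generator emulates a descriptor table at the study's scale: n rows by
p columns whose magnitudes cycle through three archetypes — small
non-negative integers (count descriptors), non-negative continuous values
of order 1-15 (E-state sums), and quantum-chemical magnitudes (an
AE-like column of order -5 and gap-like columns of order 0.3) — with a
linear target plus Gaussian noise. Generation is versioned ("pcg64-v1",
numpy's default PCG64 generator) and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

GENERATOR_VERSION = "pcg64-v1"

_EXPECTED_TRAINING_TOTAL = 61
_EXPECTED_RE_COUNT = 16
_EXPECTED_DESCRIPTOR_COUNT = 15
_EXPECTED_COEFFICIENT_COUNT = 13  # plus intercept


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureTables:
    """Validated in-memory copies of the packaged fixture tables."""

    training_composition: pd.DataFrame
    repeating_elements: pd.DataFrame
    descriptor_registry: tuple[str, ...]
    coefficient_registry: dict[str, str]  # name -> printed decimal string
    range_anchors: pd.DataFrame

    @property
    def training_total(self) -> int:
        return int(self.training_composition["count"].sum())

    def coefficient(self, name: str) -> float:
        try:
            return float(self.coefficient_registry[name])
        except KeyError:
            raise FixtureError(f"no published coefficient for {name!r}") from None


def _read_csv(filename: str, **kwargs) -> pd.DataFrame:
    path = resources.files("vapsol") / "data" / filename
    with path.open() as fh:
        return pd.read_csv(fh, **kwargs)


def load_fixtures() -> FixtureTables:
    """Load the packaged tables, enforcing their shape invariants."""
    composition = _read_csv("training_composition.csv")
    res = _read_csv("repeating_elements.csv")
    registry = tuple(_read_csv("descriptor_registry.csv")["name"])
    coeffs_raw = _read_csv("published_coefficients.csv", dtype=str)
    anchors = _read_csv("range_anchors.csv")

    total = int(composition["count"].sum())
    if total != _EXPECTED_TRAINING_TOTAL:
        raise FixtureError(
            f"training composition sums to {total}, expected {_EXPECTED_TRAINING_TOTAL}"
        )
    if len(res) != _EXPECTED_RE_COUNT:
        raise FixtureError(
            f"repeating-element table has {len(res)} rows, expected {_EXPECTED_RE_COUNT}"
        )
    if len(registry) != _EXPECTED_DESCRIPTOR_COUNT:
        raise FixtureError(
            f"descriptor registry has {len(registry)} names, "
            f"expected {_EXPECTED_DESCRIPTOR_COUNT}"
        )
    coeffs = dict(zip(coeffs_raw["name"], coeffs_raw["coefficient"]))
    if "intercept" not in coeffs:
        raise FixtureError("coefficient registry lacks an intercept")
    n_desc = len(coeffs) - 1
    if n_desc != _EXPECTED_COEFFICIENT_COUNT:
        raise FixtureError(
            f"coefficient registry has {n_desc} descriptor coefficients, "
            f"expected {_EXPECTED_COEFFICIENT_COUNT}"
        )
    unknown = set(coeffs) - set(registry) - {"intercept"}
    if unknown:
        raise FixtureError(f"coefficients for unregistered descriptors: {sorted(unknown)}")
    if len(anchors) != 2:
        raise FixtureError("range-anchor table must have exactly two rows")
    return FixtureTables(
        training_composition=composition,
        repeating_elements=res,
        descriptor_registry=registry,
        coefficient_registry=coeffs,
        range_anchors=anchors,
    )


# ---------------------------------------------------------------------------
# synthetic regression data


class RegressionData(NamedTuple):
    X: np.ndarray
    y: np.ndarray
    coefficients: np.ndarray
    intercept: float
    names: tuple[str, ...]


#: per-archetype column scale used to balance default coefficients
_ARCHETYPES = ("count", "estate", "quantum_large", "quantum_small")
_ARCHETYPE_SCALE = {"count": 3.0, "estate": 5.0, "quantum_large": 5.0, "quantum_small": 0.3}


def _draw_column(rng: np.random.Generator, archetype: str, n: int) -> np.ndarray:
    if archetype == "count":
        return rng.poisson(3.0, size=n).astype(float)
    if archetype == "estate":
        return np.abs(rng.normal(5.0, 3.0, size=n))
    if archetype == "quantum_large":  # atomization-energy-like magnitude
        return rng.normal(-5.0, 1.5, size=n)
    return rng.normal(0.3, 0.1, size=n)  # frontier-orbital-gap-like


def generate_regression_data(
    n: int,
    p: int,
    coefficients=None,
    intercept: float = 10.0,
    sigma: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> RegressionData:
    """Synthetic descriptor table with a linear signal plus Gaussian noise.

    Columns cycle through the archetype scales; the default coefficient
    vector is drawn once from the generator and scaled inversely to the
    column magnitude so every descriptor contributes comparably to the
    target. ``y = X theta + theta0 + N(0, sigma^2)``.
    """
    if not (n > p >= 1):
        raise ValueError(f"need n > p >= 1, got n={n}, p={p}")
    if sigma < 0:
        raise ValueError(f"noise level must be >= 0, got {sigma}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    archetypes = [_ARCHETYPES[j % len(_ARCHETYPES)] for j in range(p)]
    X = np.column_stack([_draw_column(rng, a, n) for a in archetypes])
    if coefficients is None:
        theta = np.array(
            [rng.normal(0.0, 2.0) / _ARCHETYPE_SCALE[a] for a in archetypes]
        )
    else:
        theta = np.asarray(coefficients, dtype=float)
        if theta.shape != (p,):
            raise ValueError(f"coefficient vector must have shape ({p},), got {theta.shape}")
    y = X @ theta + intercept + rng.normal(0.0, sigma, size=n)
    names = tuple(f"{a}_{j}" for j, a in enumerate(archetypes))
    return RegressionData(X=X, y=y, coefficients=theta, intercept=float(intercept), names=names)
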