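"""Grid point-count reduction, gonadosomatic index and tubule geometry.

Volume densities come from a 441-intersection ocular grid scored over 15
random fields (6,615 points/animal). Treating 1 g of testis as 1 cm^3 of
tissue (specific gravity 1.0, configurable), the seminiferous tubule volume
per gram is the parenchymal volume (capsule excluded) times the tubular
volume density; dividing by the cross-sectional area pi*(d/2)^2 of an average
round tubule profile turns that volume into a tubule length.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional

from .core import (
    Biometry,
    TubuleMorphometry,
    UnitMismatchWarning,
    ValidationError,
    VolumeDensityTable,
)

__all__ = [
    "gsi",
    "volume_densities",
    "tubule_length_per_gram",
    "tubule_length_total",
]

#: 1 cm^3 expressed in um^3.
_CM3_IN_UM3 = 1.0e12
#: Plausible mammalian GSI window (percent) for the unit-mismatch heuristic.
_GSI_PLAUSIBLE = (0.01, 15.0)


def gsi(biometry: Biometry) -> float:
    """Gonadosomatic index: combined testis mass as percent of body mass.

    The magnitudes are sanity-checked: a GSI outside [0.01%, 15%] almost
    always means testis mass was given in grams (or body mass in mg) and a
    :class:`UnitMismatchWarning` is emitted, but the value is returned
    unconverted — the caller owns the units.
    """
    total_testis_g = biometry.n_testes * biometry.testis_weight_g
    value = 100.0 * total_testis_g / biometry.body_weight_g
    if not _GSI_PLAUSIBLE[0] <= value <= _GSI_PLAUSIBLE[1]:
        warnings.warn(
            f"GSI of {value:.4g}% is outside the plausible mammalian range; "
            "check that testis weight is in mg and body weight in g",
            UnitMismatchWarning,
            stacklevel=2,
        )
    return value


def volume_densities(
    point_counts: Mapping[str, float],
    albuginea_points: Optional[float] = None,
) -> VolumeDensityTable:
    """Reduce grid point counts to a :class:`VolumeDensityTable`.

    ``point_counts`` maps the seven parenchymal leaf components (tunica
    propria, seminiferous epithelium, lumen, Leydig cells, blood vessels,
    lymphatic space, other) to points scored on them. ``albuginea_points``,
    when given, are points scored on the tunica albuginea of the same grid
    sample; the albuginea fraction is then points/(all points) on the whole
    testis while component fractions are referred to the parenchymal points
    only. Aggregate components (tubular compartment, intertubular) are derived
    from the leaves, so the hierarchy is consistent by construction.
    """
    counts = {k: float(v) for k, v in point_counts.items()}
    for k, v in counts.items():
        if v < 0:
            raise ValidationError(f"negative point count for component {k!r}")
    parenchyma_total = sum(counts.values())
    if parenchyma_total <= 0:
        raise ValidationError("total point count must be positive")
    alb = 0.0 if albuginea_points is None else float(albuginea_points)
    if alb < 0:
        raise ValidationError("negative albuginea point count")
    grand_total = parenchyma_total + alb
    fractions = {k: v / parenchyma_total for k, v in counts.items()}
    return VolumeDensityTable(components=fractions, albuginea_fraction=alb / grand_total)


def tubule_length_per_gram(
    vd: VolumeDensityTable,
    tm: TubuleMorphometry,
    specific_gravity: float = 1.0,
) -> float:
    """Seminiferous tubule length in metres contained in one gram of testis.

    One gram of testis occupies 1/specific_gravity cm^3; the capsule
    (albuginea) is removed and the remainder scaled by the tubular volume
    density before dividing by the tubule cross-sectional area. Length scales
    as diameter^-2.
    """
    if specific_gravity <= 0:
        raise ValidationError("specific gravity must be positive")
    volume_um3 = (
        (_CM3_IN_UM3 / specific_gravity)
        * (1.0 - vd.albuginea_fraction)
        * vd["tubule_compartment"]
    )
    radius = tm.diameter_um / 2.0
    length_um = volume_um3 / (math.pi * radius * radius)
    return length_um * 1.0e-6


def tubule_length_total(per_gram_m: float, biometry: Biometry) -> float:
    """Total tubule length (m) in one testis: per-gram length x testis grams."""
    if per_gram_m < 0:
        raise ValidationError("per-gram tubule length must be >= 0")
    return per_gram_m * biometry.testis_weight_g
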