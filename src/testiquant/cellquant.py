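"""Corrected cell counts, Sertoli/Leydig quantification and sperm production.

Counting nuclear profiles in a section of thickness T overcounts objects of
diameter D by the factor (T+D)/T, because any object whose centre lies within
D of the section is cut by it. The Abercrombie correction N*T/(T+D) removes
that bias. Corrected stage-VIII counts give the meiotic index (round
spermatids per pachytene spermatocyte; 4 is the theoretical lossless yield of
meiosis) and the Sertoli cell efficiency (round spermatids per Sertoli cell,
counted via their single nucleolus). Sertoli cells, being a stable
population evenly distributed along the tubule, scale per-section counts to
whole-testis numbers through the total tubule length, and daily sperm
production follows as

    DSP = Sertoli cells/testis x round spermatids per Sertoli cell
          x stage VIII frequency / stage VIII duration (days)

which reduces algebraically to Sertoli cells x efficiency / cycle length.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

from .core import Biometry, ValidationError

__all__ = [
    "abercrombie_correct",
    "meiotic_index",
    "meiotic_loss",
    "sertoli_efficiency",
    "sertoli_per_testis",
    "dsp",
    "dsp_per_gram",
    "leydig_nuclear_volume",
    "leydig_cell_volume",
    "leydig_numbers",
]

_CM3_IN_UM3 = 1.0e12


def abercrombie_correct(raw_count: float, section_thickness_um: float, object_diameter_um: float) -> float:
    """Correct a per-section profile count for section-spanning objects.

    Returns raw * T / (T + D); always <= raw, with equality only for
    point-like objects (D = 0).
    """
    if section_thickness_um <= 0:
        raise ValidationError("section thickness must be positive")
    if object_diameter_um < 0:
        raise ValidationError("object diameter must be >= 0")
    if raw_count < 0:
        raise ValidationError("raw count must be >= 0")
    return raw_count * section_thickness_um / (section_thickness_um + object_diameter_um)


def meiotic_index(round_spermatids_corr: float, pachytene_corr: float) -> float:
    """Corrected round spermatids per pachytene primary spermatocyte."""
    if pachytene_corr <= 0:
        raise ValidationError("pachytene count must be positive")
    if round_spermatids_corr < 0:
        raise ValidationError("round spermatid count must be >= 0")
    return round_spermatids_corr / pachytene_corr


def meiotic_loss(index: float) -> float:
    """Germ-cell loss during meiosis, percent shortfall from the 4x yield.

    Two meiotic divisions turn one pachytene spermatocyte into at most four
    round spermatids, so loss = 100 * (1 - index/4). An index above 4 is
    supra-theoretical and triggers a warning (the negative loss is returned
    as computed).
    """
    if index < 0:
        raise ValidationError("meiotic index must be >= 0")
    if index > 4:
        warnings.warn(
            f"meiotic index {index} exceeds the theoretical yield of 4",
            UserWarning,
            stacklevel=2,
        )
    return 100.0 * (1.0 - index / 4.0)


def sertoli_efficiency(round_spermatids_corr: float, sertoli_nucleoli_corr: float) -> float:
    """Corrected round spermatids per Sertoli cell (nucleolus) at stage VIII."""
    if sertoli_nucleoli_corr <= 0:
        raise ValidationError("Sertoli nucleoli count must be positive")
    if round_spermatids_corr < 0:
        raise ValidationError("round spermatid count must be >= 0")
    return round_spermatids_corr / sertoli_nucleoli_corr


def sertoli_per_testis(
    sertoli_nucleoli_corr_per_section: float,
    tubule_length_total_m: float,
    section_thickness_um: float,
) -> float:
    """Sertoli cells in one testis.

    The total tubule length divided by the section thickness is the number of
    disjoint cross-sections the tubules contain; each holds the corrected
    per-section number of Sertoli cells.
    """
    if sertoli_nucleoli_corr_per_section < 0:
        raise ValidationError("corrected nucleoli per section must be >= 0")
    if tubule_length_total_m < 0:
        raise ValidationError("tubule length must be >= 0")
    if section_thickness_um <= 0:
        raise ValidationError("section thickness must be positive")
    n_sections = tubule_length_total_m * 1.0e6 / section_thickness_um
    return sertoli_nucleoli_corr_per_section * n_sections


def dsp(
    sertoli_per_testis_count: float,
    efficiency: float,
    freq_viii: float,
    duration_viii_days: float,
) -> float:
    """Daily sperm production per testis (spermatozoa/day).

    ``freq_viii`` is the stage VIII frequency as a fraction and
    ``duration_viii_days`` its duration; when the duration equals
    frequency x cycle length the formula is exactly Sertoli cells x
    efficiency / cycle length. Round spermatids stand in for the final sperm
    output (no appreciable loss occurs during spermiogenesis).
    """
    if duration_viii_days <= 0:
        raise ValidationError("stage VIII duration must be positive")
    if not 0.0 <= freq_viii <= 1.0:
        raise ValidationError("stage VIII frequency must be a fraction in [0, 1]")
    return sertoli_per_testis_count * efficiency * freq_viii / duration_viii_days


def dsp_per_gram(dsp_per_testis: float, biometry: Biometry) -> float:
    """Daily sperm production per gram of testis (spermatogenic efficiency)."""
    if dsp_per_testis < 0:
        raise ValidationError("DSP must be >= 0")
    return dsp_per_testis / biometry.testis_weight_g


def leydig_nuclear_volume(nuclear_diameter_um: float) -> float:
    """Leydig nuclear volume (um^3) from the sphere formula 4/3 pi R^3."""
    if nuclear_diameter_um <= 0:
        raise ValidationError("nuclear diameter must be positive")
    r = nuclear_diameter_um / 2.0
    return 4.0 / 3.0 * math.pi * r**3


def leydig_cell_volume(nuclear_volume_um3: float, nucleus_point_fraction: float) -> float:
    """Whole Leydig cell volume (um^3) from the nucleus:cell point fraction.

    With a fraction p of grid points over Leydig cells falling on nuclei,
    cell volume = nuclear volume / p; the cytoplasm is the difference.
    """
    if nuclear_volume_um3 <= 0:
        raise ValidationError("nuclear volume must be positive")
    if not 0.0 < nucleus_point_fraction < 1.0:
        raise ValidationError("nucleus point fraction must be in (0, 1)")
    return nuclear_volume_um3 / nucleus_point_fraction


def leydig_numbers(
    leydig_volume_density: float,
    cell_volume_um3: float,
    biometry: Biometry,
    albuginea_fraction: float,
    specific_gravity: float = 1.0,
) -> tuple[float, float]:
    """Leydig cells per gram of testis and per testis.

    The Leydig volume in one gram of testis is the parenchymal volume
    (capsule excluded) times the Leydig volume density; dividing by the
    individual cell volume counts the cells.
    """
    if cell_volume_um3 <= 0:
        raise ValidationError("cell volume must be positive")
    if not 0.0 <= leydig_volume_density < 1.0:
        raise ValidationError("Leydig volume density must be a fraction of parenchyma")
    if not 0.0 <= albuginea_fraction < 1.0:
        raise ValidationError("albuginea fraction must be a fraction of testis")
    if specific_gravity <= 0:
        raise ValidationError("specific gravity must be positive")
    leydig_volume_per_gram = (
        (_CM3_IN_UM3 / specific_gravity) * (1.0 - albuginea_fraction) * leydig_volume_density
    )
    per_gram = leydig_volume_per_gram / cell_volume_um3
    per_testis = per_gram * biometry.testis_weight_g
    return per_gram, per_testis
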