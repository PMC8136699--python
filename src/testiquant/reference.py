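"""Packaged published species-mean values and pseudo-observations from them.

The reference file carries the printed species means (and SEMs) for the four
cricetid rodents. ``species_mean_observations`` rebuilds an observation set
whose values are exactly those means — a one-animal "average" dataset useful
for checking that the pipeline reproduces the published derived quantities
from the published primary ones.
"""

from __future__ import annotations

from functools import lru_cache

from .core import (
    Biometry,
    LabelingObservation,
    LeydigMorphometry,
    SPECIES,
    Stage,
    StageVIIICounts,
    ValidationError,
    load_packaged_yaml,
)
from .io import ObservationSet

__all__ = ["load_reference", "species_reference", "species_mean_observations"]

_GRID_POINTS = 6615.0


@lru_cache(maxsize=1)
def load_reference() -> dict:
    return load_packaged_yaml("species_reference.yaml")


def species_reference(species: str) -> dict:
    ref = load_reference()
    if species not in ref:
        raise ValidationError(f"unknown species {species!r}; known: {sorted(ref)}")
    return ref[species]


def species_mean_observations(species: str) -> ObservationSet:
    """Observation set whose raw values equal the published species means."""
    ref = species_reference(species)

    bio = Biometry(
        body_weight_g=ref["biometry"]["body_weight_g"]["mean"],
        testis_weight_mg=ref["biometry"]["testis_weight_mg"]["mean"],
    )

    vd = ref["volume_density_percent"]
    leaf = {
        k: vd[k] / 100.0
        for k in (
            "tunica_propria",
            "seminiferous_epithelium",
            "lumen",
            "leydig",
            "blood_vessels",
            "lymphatic",
            "other",
        )
    }
    total_leaf = sum(leaf.values())
    point_counts = {k: _GRID_POINTS * v / total_leaf for k, v in leaf.items()}
    alb = ref["albuginea_percent"] / 100.0
    albuginea_points = _GRID_POINTS * alb / (1.0 - alb)

    tallies = {
        Stage.from_label(s): 2.5 * p for s, p in ref["stage_frequencies_percent"].items()
    }

    lab = ref["labeling"]
    first = lab["animals"][0]
    labeling = (
        LabelingObservation(0.0, lab["one_hour_cell_class"], Stage.from_label(lab["one_hour_stage"])),
        LabelingObservation(
            first["interval_days"], first["cell_class"], Stage.from_label(first["stage"])
        ),
    )

    s8 = ref["stage8"]
    ratios = ref["cell_ratios"]
    thickness = s8["section_thickness_um"]
    sert_corr = s8["sertoli_corrected_per_section"]
    round_corr = sert_corr * ratios["sertoli_efficiency"]["mean"]
    pach_corr = round_corr / ratios["meiotic_index"]["mean"]

    def inflate(corr, diameter):
        return corr * (thickness + diameter) / thickness

    stage8 = StageVIIICounts(
        n_sections=10,
        pachytene_raw=inflate(pach_corr, s8["pachytene_diameter_um"]),
        round_spermatid_raw=inflate(round_corr, s8["round_spermatid_diameter_um"]),
        sertoli_nucleoli_raw=inflate(sert_corr, s8["sertoli_nucleolus_diameter_um"]),
        section_thickness_um=thickness,
        pachytene_diameter_um=s8["pachytene_diameter_um"],
        round_spermatid_diameter_um=s8["round_spermatid_diameter_um"],
        sertoli_nucleolus_diameter_um=s8["sertoli_nucleolus_diameter_um"],
    )

    ley = ref["leydig"]
    leydig = LeydigMorphometry(
        nuclear_diameter_um=ley["nuclear_diameter_um"]["mean"],
        nucleus_point_fraction=ley["nucleus_volume_um3"]["mean"] / ley["cell_volume_um3"]["mean"],
    )

    return ObservationSet(
        animal_id=f"{species}_mean",
        species=species,
        biometry=bio,
        point_counts=point_counts,
        albuginea_points=albuginea_points,
        tubule_diameters_um=(ref["tubule"]["diameter_um"]["mean"],),
        epithelium_heights_um=(ref["tubule"]["epithelium_height_um"]["mean"],),
        stage_tallies=tallies,
        labeling=labeling,
        stage8=stage8,
        leydig=leydig,
    )


def all_species() -> tuple[str, ...]:
    return SPECIES
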