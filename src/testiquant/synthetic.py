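"""Ground-truth synthetic animal generator.

Every observation table the pipeline consumes can be generated from a known
parameter set, so each estimator is testable by parameter recovery without
any external data. Noise models are the minimal ones implied by the sampling
design: multinomial for grid point counts and stage tallies, Poisson for
per-section cell counts (inflated by the Abercrombie factor (T+D)/T so the
correction recovers the truth), Gaussian for calipered lengths, binomial for
the Leydig nucleus:cytoplasm points. Label transport is deterministic: the
cohort moves around the stage clock at 1/cycle-length cycles per day.

Packaged truths for the four species are the published species means, with
between-animal SDs back-calculated as SEM * sqrt(n).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import cellquant, kinetics, stereology
from .core import (
    Biometry,
    GermCellLadder,
    LabelingObservation,
    LeydigMorphometry,
    Stage,
    STAGES,
    StageFrequencyTable,
    StageVIIICounts,
    TubuleMorphometry,
    ValidationError,
    make_stage_table,
)
from .io import ObservationSet
from .reference import species_reference

__all__ = [
    "TruthParams",
    "SyntheticAnimal",
    "generate_grid_counts",
    "generate_tubule_profiles",
    "generate_stage_tallies",
    "generate_labeling",
    "generate_stage8_counts",
    "generate_leydig",
    "generate_animal",
]

_LEAVES = (
    "tunica_propria",
    "seminiferous_epithelium",
    "lumen",
    "leydig",
    "blood_vessels",
    "lymphatic",
    "other",
)


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters for one synthetic animal."""

    species: str
    body_weight_g: float
    testis_weight_mg: float
    leaf_fractions: dict[str, float]
    albuginea_fraction: float
    tubule_diameter_um: float
    tubule_diameter_sd_um: float
    epithelium_height_um: float
    epithelium_height_sd_um: float
    stage_frequencies: StageFrequencyTable
    cycle_length_days: float
    chase_days: float
    one_hour_stage: Stage
    pachytene_corr_per_section: float
    round_spermatid_corr_per_section: float
    sertoli_corr_per_section: float
    section_thickness_um: float
    pachytene_diameter_um: float
    round_spermatid_diameter_um: float
    sertoli_nucleolus_diameter_um: float
    leydig_nuclear_diameter_um: float
    leydig_nuclear_diameter_sd_um: float
    leydig_nucleus_fraction: float
    leydig_density: float

    def __post_init__(self):
        if set(self.leaf_fractions) != set(_LEAVES):
            raise ValidationError("leaf_fractions must cover the seven parenchymal components")
        total = sum(self.leaf_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"leaf fractions must sum to 1, got {total}")
        for name in (
            "body_weight_g",
            "testis_weight_mg",
            "tubule_diameter_um",
            "epithelium_height_um",
            "cycle_length_days",
            "chase_days",
            "section_thickness_um",
            "leydig_nuclear_diameter_um",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.leydig_nucleus_fraction < 1.0:
            raise ValidationError("leydig_nucleus_fraction must be in (0, 1)")
        object.__setattr__(self, "one_hour_stage", Stage.from_label(self.one_hour_stage))

    @classmethod
    def for_species(cls, species: str) -> "TruthParams":
        """Packaged truth: published species means; SD = SEM * sqrt(n)."""
        ref = species_reference(species)
        n = ref["n_animals"]
        sqrt_n = math.sqrt(n)
        vd = ref["volume_density_percent"]
        leaf = {k: vd[k] for k in _LEAVES}
        total = sum(leaf.values())
        ratios = ref["cell_ratios"]
        s8 = ref["stage8"]
        sert = s8["sertoli_corrected_per_section"]
        rnd = sert * ratios["sertoli_efficiency"]["mean"]
        ley = ref["leydig"]
        return cls(
            species=species,
            body_weight_g=ref["biometry"]["body_weight_g"]["mean"],
            testis_weight_mg=ref["biometry"]["testis_weight_mg"]["mean"],
            leaf_fractions={k: v / total for k, v in leaf.items()},
            albuginea_fraction=ref["albuginea_percent"] / 100.0,
            tubule_diameter_um=ref["tubule"]["diameter_um"]["mean"],
            tubule_diameter_sd_um=ref["tubule"]["diameter_um"]["sem"] * sqrt_n,
            epithelium_height_um=ref["tubule"]["epithelium_height_um"]["mean"],
            epithelium_height_sd_um=ref["tubule"]["epithelium_height_um"]["sem"] * sqrt_n,
            stage_frequencies=make_stage_table(ref["stage_frequencies_percent"]),
            cycle_length_days=ref["cycle_length_days"]["mean"],
            chase_days=ref["labeling"]["animals"][0]["interval_days"],
            one_hour_stage=Stage.from_label(ref["labeling"]["one_hour_stage"]),
            pachytene_corr_per_section=rnd / ratios["meiotic_index"]["mean"],
            round_spermatid_corr_per_section=rnd,
            sertoli_corr_per_section=sert,
            section_thickness_um=s8["section_thickness_um"],
            pachytene_diameter_um=s8["pachytene_diameter_um"],
            round_spermatid_diameter_um=s8["round_spermatid_diameter_um"],
            sertoli_nucleolus_diameter_um=s8["sertoli_nucleolus_diameter_um"],
            leydig_nuclear_diameter_um=ley["nuclear_diameter_um"]["mean"],
            leydig_nuclear_diameter_sd_um=ley["nuclear_diameter_um"]["sem"] * sqrt_n,
            leydig_nucleus_fraction=(
                ley["nucleus_volume_um3"]["mean"] / ley["cell_volume_um3"]["mean"]
            ),
            leydig_density=vd["leydig"] / total,
        )

    # --- noiseless propagation of the truth through the estimator formulas ---

    @property
    def biometry(self) -> Biometry:
        return Biometry(self.body_weight_g, self.testis_weight_mg)

    def true_volume_densities(self):
        from .core import VolumeDensityTable

        return VolumeDensityTable(
            components=dict(self.leaf_fractions), albuginea_fraction=self.albuginea_fraction
        )

    def true_gsi(self) -> float:
        return stereology.gsi(self.biometry)

    def true_tubule_length_per_gram(self) -> float:
        tm = TubuleMorphometry(self.tubule_diameter_um, self.epithelium_height_um)
        return stereology.tubule_length_per_gram(self.true_volume_densities(), tm)

    def true_tubule_length_total(self) -> float:
        return stereology.tubule_length_total(self.true_tubule_length_per_gram(), self.biometry)

    def true_sertoli_per_testis(self) -> float:
        return cellquant.sertoli_per_testis(
            self.sertoli_corr_per_section,
            self.true_tubule_length_total(),
            self.section_thickness_um,
        )

    def true_dsp_per_testis(self) -> float:
        efficiency = self.round_spermatid_corr_per_section / self.sertoli_corr_per_section
        return self.true_sertoli_per_testis() * efficiency / self.cycle_length_days

    def true_leydig_cell_volume(self) -> float:
        nuc = cellquant.leydig_nuclear_volume(self.leydig_nuclear_diameter_um)
        return cellquant.leydig_cell_volume(nuc, self.leydig_nucleus_fraction)

    def to_json(self) -> str:
        rec = dataclasses.asdict(self)
        rec["one_hour_stage"] = self.one_hour_stage.roman
        rec["stage_frequencies"] = {
            s.roman: f for s, f in self.stage_frequencies.freq.items()
        }
        return json.dumps(rec, indent=2, sort_keys=True)


def generate_grid_counts(
    truth: TruthParams,
    n_fields: int = 15,
    grid_points: int = 441,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, int]:
    """Multinomial grid point counts over the whole testis.

    The default 15 fields x 441 intersections give 6,615 points. Points fall
    on the albuginea with its whole-testis fraction and on each parenchymal
    leaf with (1 - albuginea) x leaf fraction; the returned dict includes an
    ``albuginea`` entry.
    """
    rng = np.random.default_rng() if rng is None else rng
    total = n_fields * grid_points
    a = truth.albuginea_fraction
    labels = ("albuginea",) + _LEAVES
    probs = [a] + [(1.0 - a) * truth.leaf_fractions[k] for k in _LEAVES]
    draws = rng.multinomial(total, probs)
    return {k: int(v) for k, v in zip(labels, draws)}


def generate_tubule_profiles(
    truth: TruthParams,
    n_profiles: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian diameters and epithelium heights of round tubule profiles."""
    rng = np.random.default_rng() if rng is None else rng
    d = rng.normal(truth.tubule_diameter_um, truth.tubule_diameter_sd_um, n_profiles)
    h = rng.normal(truth.epithelium_height_um, truth.epithelium_height_sd_um, n_profiles)
    return np.abs(d), np.abs(h)


def generate_stage_tallies(
    truth: TruthParams,
    n_tubules: int = 250,
    rng: Optional[np.random.Generator] = None,
) -> dict[Stage, int]:
    """Multinomial stage tallies of ``n_tubules`` random cross-sections."""
    rng = np.random.default_rng() if rng is None else rng
    probs = [truth.stage_frequencies.fraction(s) for s in STAGES]
    draws = rng.multinomial(n_tubules, probs)
    return {s: int(c) for s, c in zip(STAGES, draws)}


def _position_to_observation(
    position: float,
    ladder: GermCellLadder,
    sft: StageFrequencyTable,
    interval_days: float,
) -> LabelingObservation:
    """Map a continuous cycle position to the (cell class, stage) it occupies.

    ``position`` is measured in cycles from the start of stage I of the
    cohort's cycle 0 row. The returned observation carries the true
    within-stage fraction.
    """
    ordinal = int(math.floor(position + 1e-12))
    frac = position - ordinal
    release = ladder.max_ordinal + sft.cumulative_through(ladder.release_stage)
    if position > release + 1e-12:
        raise ValidationError(
            "cohort released: chase extends beyond spermiation of the labeled cohort"
        )
    stage = Stage.XII
    for s in STAGES:
        if frac <= sft.cumulative_through(s) + 1e-12:
            stage = s
            break
    before = sft.cumulative_before(stage)
    width = sft.fraction(stage)
    within = 0.0 if width == 0 else min(1.0, max(0.0, (frac - before) / width))
    cell_class = ladder.cell_class_at(ordinal, stage)
    return LabelingObservation(
        interval_days=interval_days,
        cell_class=cell_class,
        stage=stage,
        within_stage_fraction=within,
    )


def generate_labeling(
    truth: TruthParams,
    chase_days: Optional[float] = None,
    ladder: Optional[GermCellLadder] = None,
) -> tuple[LabelingObservation, LabelingObservation]:
    """Deterministic pulse-chase observation pair.

    The 1-hour anchor is Pl/L at the end of the species' labeling stage; the
    chase observation is the anchor position advanced by chase/cycle-length
    cycles, mapped through the germ-cell ladder. Both carry their true
    within-stage fraction. Raises if the chase outruns spermiation of the
    cohort ("cohort released").
    """
    if chase_days is None:
        chase_days = truth.chase_days
    if chase_days <= 0:
        raise ValidationError("chase_days must be positive")
    if ladder is None:
        ladder = GermCellLadder.for_species(truth.species)
    sft = truth.stage_frequencies
    start_pos = sft.cumulative_through(truth.one_hour_stage)
    end_pos = start_pos + chase_days / truth.cycle_length_days
    start = LabelingObservation(
        interval_days=0.0,
        cell_class="Pl/L",
        stage=truth.one_hour_stage,
        within_stage_fraction=1.0,
    )
    end = _position_to_observation(end_pos, ladder, sft, chase_days)
    return start, end


def generate_stage8_counts(
    truth: TruthParams,
    n_sections: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> StageVIIICounts:
    """Poisson raw stage-VIII counts, inflated by the Abercrombie factor.

    The expected raw count per section is the true (corrected) count times
    (T+D)/T, so applying the correction recovers the truth in expectation.
    """
    rng = np.random.default_rng() if rng is None else rng
    t = truth.section_thickness_um

    def raw_mean(corr, diameter):
        total = rng.poisson(n_sections * corr * (t + diameter) / t)
        return total / n_sections

    return StageVIIICounts(
        n_sections=n_sections,
        pachytene_raw=raw_mean(truth.pachytene_corr_per_section, truth.pachytene_diameter_um),
        round_spermatid_raw=raw_mean(
            truth.round_spermatid_corr_per_section, truth.round_spermatid_diameter_um
        ),
        sertoli_nucleoli_raw=raw_mean(
            truth.sertoli_corr_per_section, truth.sertoli_nucleolus_diameter_um
        ),
        section_thickness_um=t,
        pachytene_diameter_um=truth.pachytene_diameter_um,
        round_spermatid_diameter_um=truth.round_spermatid_diameter_um,
        sertoli_nucleolus_diameter_um=truth.sertoli_nucleolus_diameter_um,
    )


def generate_leydig(
    truth: TruthParams,
    n_nuclei: int = 30,
    n_points: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> LeydigMorphometry:
    """Gaussian nuclear diameters and binomial nucleus:cytoplasm points."""
    rng = np.random.default_rng() if rng is None else rng
    diameters = rng.normal(
        truth.leydig_nuclear_diameter_um, truth.leydig_nuclear_diameter_sd_um, n_nuclei
    )
    nucleus_points = rng.binomial(n_points, truth.leydig_nucleus_fraction)
    fraction = min(max(nucleus_points / n_points, 1e-6), 1.0 - 1e-6)
    return LeydigMorphometry(
        nuclear_diameter_um=float(np.mean(np.abs(diameters))),
        nucleus_point_fraction=float(fraction),
    )


@dataclass
class SyntheticAnimal:
    """One generated animal: all observation tables plus the embedded truth."""

    animal_id: str
    truth: TruthParams
    seed: int
    grid_counts: dict[str, int]
    tubule_diameters_um: np.ndarray
    epithelium_heights_um: np.ndarray
    stage_tallies: dict[Stage, int]
    labeling: tuple[LabelingObservation, LabelingObservation]
    stage8: StageVIIICounts
    leydig: LeydigMorphometry

    def to_observations(self) -> ObservationSet:
        counts = {k: v for k, v in self.grid_counts.items() if k != "albuginea"}
        return ObservationSet(
            animal_id=self.animal_id,
            species=self.truth.species,
            biometry=self.truth.biometry,
            point_counts=counts,
            albuginea_points=self.grid_counts.get("albuginea", 0),
            tubule_diameters_um=tuple(float(v) for v in self.tubule_diameters_um),
            epithelium_heights_um=tuple(float(v) for v in self.epithelium_heights_um),
            stage_tallies=dict(self.stage_tallies),
            labeling=self.labeling,
            stage8=self.stage8,
            leydig=self.leydig,
        )


def generate_animal(
    truth: TruthParams,
    seed: int,
    n_fields: int = 15,
    grid_points: int = 441,
    n_profiles: int = 30,
    n_tubules: int = 250,
    n_sections: int = 10,
    n_nuclei: int = 30,
    n_leydig_points: int = 1000,
    animal_id: Optional[str] = None,
) -> SyntheticAnimal:
    """Generate one full synthetic animal; identical seed, identical animal."""
    rng = np.random.default_rng(seed)
    diameters, heights = generate_tubule_profiles(truth, n_profiles, rng)
    return SyntheticAnimal(
        animal_id=animal_id or f"{truth.species}_seed{seed}",
        truth=truth,
        seed=seed,
        grid_counts=generate_grid_counts(truth, n_fields, grid_points, rng),
        tubule_diameters_um=diameters,
        epithelium_heights_um=heights,
        stage_tallies=generate_stage_tallies(truth, n_tubules, rng),
        labeling=generate_labeling(truth),
        stage8=generate_stage8_counts(truth, n_sections, rng),
        leydig=generate_leydig(truth, n_nuclei, n_leydig_points, rng),
    )
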