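"""Observation-table readers/writers and the end-to-end analysis.

One animal's observations are a set of small CSV tables (one directory per
study): ``biometry.csv``, ``morphometry.csv`` (grid point counts),
``tubules.csv`` (per-profile diameter and epithelium height),
``stage_tallies.csv``, ``labeling.csv``, ``stage8_counts.csv`` and
``leydig.csv``. ``analyze`` reduces them to per-animal results and
per-species mean +/- SEM summaries mirroring the printed tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cellquant, kinetics, stereology
from .core import (
    AnimalResult,
    Biometry,
    GermCellLadder,
    LabelingObservation,
    LeydigMorphometry,
    Stage,
    STAGES,
    StageVIIICounts,
    TubuleMorphometry,
    ValidationError,
    make_stage_table,
)

__all__ = [
    "AnalysisConfig",
    "ObservationSet",
    "read_observations",
    "write_observations",
    "analyze_animal",
    "analyze",
    "write_tables",
]

logger = logging.getLogger("testiquant")

_LEAF_COMPONENTS = (
    "tunica_propria",
    "seminiferous_epithelium",
    "lumen",
    "leydig",
    "blood_vessels",
    "lymphatic",
    "other",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Conventions of the analysis, overridable from YAML.

    ``sertoli_correction`` selects the object diameter used to correct
    Sertoli counts: the counted profile is the nucleolus, but whether the
    published correction used nucleolar or nuclear diameter is not stated,
    so both are supported and the choice is echoed into result metadata.
    """

    n_testes: int = 2
    specific_gravity: float = 1.0
    section_thickness_um: float = 4.0
    boundary_convention: str = "end"
    n_spermatogenic_cycles: float = 4.5
    sertoli_correction: str = "nucleolus"
    ladder_file: Optional[str] = None
    template_file: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.boundary_convention not in ("start", "end", "midpoint"):
            raise ValidationError(f"unknown boundary convention {self.boundary_convention!r}")
        if self.sertoli_correction not in ("nucleolus", "nucleus"):
            raise ValidationError(f"unknown sertoli_correction {self.sertoli_correction!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ObservationSet:
    """All raw observations for one animal (missing tables are None)."""

    animal_id: str
    species: str
    biometry: Optional[Biometry] = None
    point_counts: Optional[dict[str, float]] = None
    albuginea_points: float = 0.0
    tubule_diameters_um: Optional[tuple[float, ...]] = None
    epithelium_heights_um: Optional[tuple[float, ...]] = None
    stage_tallies: Optional[dict[Stage, float]] = None
    labeling: Optional[tuple[LabelingObservation, LabelingObservation]] = None
    stage8: Optional[StageVIIICounts] = None
    leydig: Optional[LeydigMorphometry] = None


def _err(path, row, message):
    raise ValidationError(f"{path}: row {row}: {message}")


def _num(value):
    """Preserve integer-valued counts as ints so CSV round trips verbatim."""
    f = float(value)
    return int(f) if f.is_integer() else f


def _read_csv(path: Path) -> Optional[pd.DataFrame]:
    if not path.exists():
        return None
    return pd.read_csv(path, float_precision="round_trip")


def read_observations(directory) -> dict[str, ObservationSet]:
    """Read and validate one directory of observation CSVs.

    Returns a mapping animal_id -> :class:`ObservationSet`. Violations are
    reported with file and row. Missing files simply leave the corresponding
    observations absent.
    """
    directory = Path(directory)
    sets: dict[str, ObservationSet] = {}

    def get(animal_id, species=None):
        obs = sets.get(animal_id)
        if obs is None:
            obs = ObservationSet(animal_id=str(animal_id), species=species or "")
            sets[animal_id] = obs
        if species and not obs.species:
            obs.species = species
        return obs

    path = directory / "biometry.csv"
    df = _read_csv(path)
    if df is not None:
        for i, row in df.iterrows():
            try:
                bio = Biometry(
                    body_weight_g=row["body_weight_g"],
                    testis_weight_mg=row["testis_weight_mg"],
                    n_testes=int(row.get("n_testes", 2)),
                )
            except (ValidationError, KeyError) as exc:
                _err(path.name, i, exc)
            get(row["animal_id"], row.get("species")).biometry = bio

    path = directory / "morphometry.csv"
    df = _read_csv(path)
    if df is not None:
        for i, row in df.iterrows():
            counts = {}
            for comp in _LEAF_COMPONENTS:
                col = f"points_{comp}"
                if col not in row:
                    _err(path.name, i, f"missing column {col}")
                if row[col] < 0:
                    _err(path.name, i, f"negative point count in {col}")
                counts[comp] = _num(row[col])
            alb = _num(row.get("points_albuginea", 0))
            if alb < 0:
                _err(path.name, i, "negative point count in points_albuginea")
            obs = get(row["animal_id"], row.get("species"))
            obs.point_counts = counts
            obs.albuginea_points = alb

    path = directory / "tubules.csv"
    df = _read_csv(path)
    if df is not None:
        for animal_id, group in df.groupby("animal_id", sort=False):
            if (group["diameter_um"] <= 0).any() or (group["epithelium_height_um"] <= 0).any():
                _err(path.name, int(group.index[0]), "non-positive tubule measurement")
            obs = get(animal_id)
            obs.tubule_diameters_um = tuple(float(v) for v in group["diameter_um"])
            obs.epithelium_heights_um = tuple(float(v) for v in group["epithelium_height_um"])

    path = directory / "stage_tallies.csv"
    df = _read_csv(path)
    if df is not None:
        for animal_id, group in df.groupby("animal_id", sort=False):
            tallies = {}
            for i, row in group.iterrows():
                stage = Stage.from_label(row["stage"])
                if row["count"] < 0:
                    _err(path.name, i, f"negative tally for stage {stage.roman}")
                tallies[stage] = _num(row["count"])
            get(animal_id).stage_tallies = tallies

    path = directory / "labeling.csv"
    df = _read_csv(path)
    if df is not None:
        for animal_id, group in df.groupby("animal_id", sort=False):
            rows = []
            for i, row in group.iterrows():
                frac = row.get("within_stage_fraction")
                if frac is not None and pd.isna(frac):
                    frac = None
                try:
                    rows.append(
                        LabelingObservation(
                            interval_days=float(row["interval_days"]),
                            cell_class=str(row["cell_class"]),
                            stage=Stage.from_label(row["stage"]),
                            within_stage_fraction=frac,
                        )
                    )
                except ValidationError as exc:
                    _err(path.name, i, exc)
            if len(rows) != 2:
                _err(path.name, int(group.index[0]), "expected exactly two labeling rows (1-h anchor and chase)")
            rows.sort(key=lambda o: o.interval_days)
            get(animal_id).labeling = (rows[0], rows[1])

    path = directory / "stage8_counts.csv"
    df = _read_csv(path)
    if df is not None:
        for i, row in df.iterrows():
            try:
                s8 = StageVIIICounts(
                    n_sections=int(row["n_sections"]),
                    pachytene_raw=float(row["pachytene_raw"]),
                    round_spermatid_raw=float(row["round_spermatid_raw"]),
                    sertoli_nucleoli_raw=float(row["sertoli_nucleoli_raw"]),
                    section_thickness_um=float(row.get("section_thickness_um", 4.0)),
                    pachytene_diameter_um=float(row.get("pachytene_diameter_um", 10.0)),
                    round_spermatid_diameter_um=float(row.get("round_spermatid_diameter_um", 6.0)),
                    sertoli_nucleolus_diameter_um=float(row.get("sertoli_nucleolus_diameter_um", 2.5)),
                )
            except ValidationError as exc:
                _err(path.name, i, exc)
            get(row["animal_id"]).stage8 = s8

    path = directory / "leydig.csv"
    df = _read_csv(path)
    if df is not None:
        for i, row in df.iterrows():
            try:
                ley = LeydigMorphometry(
                    nuclear_diameter_um=float(row["nuclear_diameter_um"]),
                    nucleus_point_fraction=float(row["nucleus_point_fraction"]),
                )
            except ValidationError as exc:
                _err(path.name, i, exc)
            get(row["animal_id"]).leydig = ley

    logger.info("read %d animals from %s", len(sets), directory)
    return sets


def write_observations(directory, observations: Sequence[ObservationSet]) -> None:
    """Write observation sets back to the CSV schema (inverse of reading)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def frame(records):
        return pd.DataFrame(records)

    bio, morph, tub, tal, lab, s8, ley = [], [], [], [], [], [], []
    for obs in observations:
        if obs.biometry:
            bio.append(
                dict(
                    animal_id=obs.animal_id,
                    species=obs.species,
                    body_weight_g=obs.biometry.body_weight_g,
                    testis_weight_mg=obs.biometry.testis_weight_mg,
                    n_testes=obs.biometry.n_testes,
                )
            )
        if obs.point_counts:
            rec = dict(animal_id=obs.animal_id, species=obs.species)
            rec.update({f"points_{k}": v for k, v in obs.point_counts.items()})
            rec["points_albuginea"] = obs.albuginea_points
            morph.append(rec)
        if obs.tubule_diameters_um:
            for j, (d, h) in enumerate(zip(obs.tubule_diameters_um, obs.epithelium_heights_um)):
                tub.append(
                    dict(animal_id=obs.animal_id, profile=j, diameter_um=d, epithelium_height_um=h)
                )
        if obs.stage_tallies:
            for stage in STAGES:
                tal.append(
                    dict(animal_id=obs.animal_id, stage=stage.roman, count=obs.stage_tallies.get(stage, 0))
                )
        if obs.labeling:
            for o in obs.labeling:
                lab.append(
                    dict(
                        animal_id=obs.animal_id,
                        interval_days=o.interval_days,
                        cell_class=o.cell_class,
                        stage=o.stage.roman,
                        within_stage_fraction=o.within_stage_fraction,
                    )
                )
        if obs.stage8:
            rec = dict(animal_id=obs.animal_id)
            rec.update(dataclasses.asdict(obs.stage8))
            s8.append(rec)
        if obs.leydig:
            ley.append(
                dict(
                    animal_id=obs.animal_id,
                    nuclear_diameter_um=obs.leydig.nuclear_diameter_um,
                    nucleus_point_fraction=obs.leydig.nucleus_point_fraction,
                )
            )
    for name, records in [
        ("biometry.csv", bio),
        ("morphometry.csv", morph),
        ("tubules.csv", tub),
        ("stage_tallies.csv", tal),
        ("labeling.csv", lab),
        ("stage8_counts.csv", s8),
        ("leydig.csv", ley),
    ]:
        if records:
            frame(records).to_csv(directory / name, index=False)


def analyze_animal(
    obs: ObservationSet,
    config: AnalysisConfig = AnalysisConfig(),
    ladder: Optional[GermCellLadder] = None,
) -> AnimalResult:
    """Run the full pipeline on one animal's observations.

    Observation tables that are absent leave the dependent result fields as
    None (partial results are explicit, never silently imputed).
    """
    result = AnimalResult(animal_id=obs.animal_id, species=obs.species)
    meta = result.metadata

    if obs.biometry is not None:
        result.gsi_percent = stereology.gsi(obs.biometry)

    vd = None
    if obs.point_counts is not None:
        vd = stereology.volume_densities(obs.point_counts, obs.albuginea_points or None)
        meta["volume_density_percent"] = {k: 100.0 * v for k, v in vd.components.items()}
        meta["albuginea_percent"] = 100.0 * vd.albuginea_fraction

    tm = None
    if obs.tubule_diameters_um:
        tm = TubuleMorphometry(
            diameter_um=float(np.mean(obs.tubule_diameters_um)),
            epithelium_height_um=float(np.mean(obs.epithelium_heights_um)),
        )
        meta["tubule_diameter_um"] = tm.diameter_um
        meta["epithelium_height_um"] = tm.epithelium_height_um

    if vd is not None and tm is not None:
        result.tubule_length_per_gram_m = stereology.tubule_length_per_gram(
            vd, tm, config.specific_gravity
        )
        if obs.biometry is not None:
            result.tubule_length_total_m = stereology.tubule_length_total(
                result.tubule_length_per_gram_m, obs.biometry
            )

    sft = None
    if obs.stage_tallies is not None:
        sft = make_stage_table({s.roman: c for s, c in obs.stage_tallies.items()})
        meta["stage_frequencies_percent"] = {s.roman: p for s, p in sft.as_percent().items()}

    if sft is not None and obs.labeling is not None:
        if ladder is None:
            ladder = GermCellLadder.for_species(obs.species, path=config.ladder_file)
        start, end = obs.labeling
        result.cycles_traversed = kinetics.cycles_traversed(
            start, end, sft, ladder, boundary=config.boundary_convention
        )
        result.cycle_length_days = kinetics.cycle_length(
            end.interval_days - start.interval_days, result.cycles_traversed
        )
        result.spermatogenesis_days = kinetics.spermatogenesis_duration(
            result.cycle_length_days, config.n_spermatogenic_cycles
        )

    if obs.stage8 is not None:
        s8 = obs.stage8
        thickness = s8.section_thickness_um
        pach = cellquant.abercrombie_correct(s8.pachytene_raw, thickness, s8.pachytene_diameter_um)
        rnd = cellquant.abercrombie_correct(
            s8.round_spermatid_raw, thickness, s8.round_spermatid_diameter_um
        )
        sert_diam = s8.sertoli_nucleolus_diameter_um
        meta["sertoli_correction"] = config.sertoli_correction
        sert = cellquant.abercrombie_correct(s8.sertoli_nucleoli_raw, thickness, sert_diam)
        result.meiotic_index = cellquant.meiotic_index(rnd, pach)
        result.meiotic_loss_percent = cellquant.meiotic_loss(result.meiotic_index)
        result.sertoli_efficiency = cellquant.sertoli_efficiency(rnd, sert)
        if result.tubule_length_total_m is not None:
            result.sertoli_per_testis = cellquant.sertoli_per_testis(
                sert, result.tubule_length_total_m, thickness
            )
            if obs.biometry is not None:
                result.sertoli_per_gram = result.sertoli_per_testis / obs.biometry.testis_weight_g
            if sft is not None and result.cycle_length_days is not None:
                freq_viii = sft.fraction(Stage.VIII)
                duration_viii = kinetics.stage_duration(Stage.VIII, sft, result.cycle_length_days)
                result.dsp_per_testis = cellquant.dsp(
                    result.sertoli_per_testis,
                    result.sertoli_efficiency,
                    freq_viii,
                    duration_viii,
                )
                if obs.biometry is not None:
                    result.dsp_per_gram = cellquant.dsp_per_gram(
                        result.dsp_per_testis, obs.biometry
                    )

    if obs.leydig is not None:
        ley = obs.leydig
        nuc_vol = cellquant.leydig_nuclear_volume(ley.nuclear_diameter_um)
        result.leydig_nuclear_volume_um3 = nuc_vol
        result.leydig_cell_volume_um3 = cellquant.leydig_cell_volume(
            nuc_vol, ley.nucleus_point_fraction
        )
        density = ley.leydig_volume_density
        if density is None and vd is not None:
            density = vd["leydig"]
        if density is not None and obs.biometry is not None and vd is not None:
            result.leydig_per_gram, result.leydig_per_testis = cellquant.leydig_numbers(
                density,
                result.leydig_cell_volume_um3,
                obs.biometry,
                vd.albuginea_fraction,
                config.specific_gravity,
            )
    return result


_NUMERIC_COLUMNS = [
    "gsi_percent",
    "tubule_length_per_gram_m",
    "tubule_length_total_m",
    "cycles_traversed",
    "cycle_length_days",
    "spermatogenesis_days",
    "meiotic_index",
    "meiotic_loss_percent",
    "sertoli_efficiency",
    "sertoli_per_gram",
    "sertoli_per_testis",
    "dsp_per_gram",
    "dsp_per_testis",
    "leydig_nuclear_volume_um3",
    "leydig_cell_volume_um3",
    "leydig_per_gram",
    "leydig_per_testis",
]


def analyze(
    observations: Mapping[str, ObservationSet] | Sequence[ObservationSet],
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze a set of animals and aggregate per species.

    Returns ``(per_animal, per_species)`` frames. The species summary is the
    arithmetic mean of per-animal values with SEM = SD/sqrt(n) (sample SD),
    the mean +/- SEM convention of morphometric tables; SEM is null for a
    single animal, and ratios are averaged per animal, never recomputed from
    averaged counts.
    """
    if isinstance(observations, Mapping):
        observations = list(observations.values())
    results = [analyze_animal(obs, config) for obs in observations]
    records = []
    for r in results:
        rec = {"animal_id": r.animal_id, "species": r.species}
        rec.update({c: getattr(r, c) for c in _NUMERIC_COLUMNS})
        records.append(rec)
    per_animal = pd.DataFrame(records)
    logger.info("analyzed %d animals", len(per_animal))

    rows = []
    for species, group in per_animal.groupby("species", sort=False):
        for col in _NUMERIC_COLUMNS:
            values = group[col].dropna()
            n = len(values)
            if n == 0:
                continue
            mean = float(values.mean())
            sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else None
            rows.append(dict(species=species, parameter=col, mean=mean, sem=sem, n=n))
    per_species = pd.DataFrame(rows)
    return per_animal, per_species


_TABLE_LAYOUT = {
    "table1.csv": [
        "gsi_percent",
        "tubule_length_per_gram_m",
        "tubule_length_total_m",
    ],
    "table3.csv": ["cycles_traversed", "cycle_length_days", "spermatogenesis_days"],
    "table4.csv": [
        "meiotic_index",
        "sertoli_efficiency",
        "sertoli_per_gram",
        "sertoli_per_testis",
        "dsp_per_gram",
        "dsp_per_testis",
        "meiotic_loss_percent",
    ],
    "table5.csv": [
        "leydig_nuclear_volume_um3",
        "leydig_cell_volume_um3",
        "leydig_per_gram",
        "leydig_per_testis",
    ],
}


def write_tables(directory, per_animal: pd.DataFrame, per_species: pd.DataFrame) -> None:
    """Write per-animal and per-species outputs mirroring the printed tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    per_animal.to_csv(directory / "per_animal.csv", index=False)
    for name, columns in _TABLE_LAYOUT.items():
        subset = per_species[per_species["parameter"].isin(columns)]
        subset.to_csv(directory / name, index=False)
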