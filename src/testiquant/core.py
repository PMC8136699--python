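"""Domain types shared by the whole pipeline.

Unit conventions
----------------
Lengths are micrometres unless the field name says otherwise (``*_m`` metres,
``*_g`` grams, ``*_mg`` milligrams). Public constructors accept frequencies
and volume densities in percent, as printed in morphometric tables, and store
them as fractions of 1; outputs that mirror a published table are reported
back in percent. Stages of the seminiferous epithelium cycle (SEC) are the
closed Roman-numeral enumeration I-XII with modular arithmetic, because the
cycle is periodic: the stage after XII is I.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "ValidationError",
    "UnitMismatchWarning",
    "Stage",
    "STAGES",
    "CELL_CLASSES",
    "SPECIES",
    "Biometry",
    "StageFrequencyTable",
    "make_stage_table",
    "VolumeDensityTable",
    "TubuleMorphometry",
    "LadderEntry",
    "GermCellLadder",
    "LabelingObservation",
    "StageVIIICounts",
    "LeydigMorphometry",
    "AnimalResult",
    "load_packaged_yaml",
]


class ValidationError(ValueError):
    """An observation or parameter violates a domain invariant."""


class UnitMismatchWarning(UserWarning):
    """A magnitude heuristic suggests values were given in the wrong unit."""


_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")

#: Germ-cell classes in developmental order: type A, intermediate and type B
#: spermatogonia; preleptotene through diplotene primary spermatocytes;
#: secondary spermatocytes/meiotic divisions; round and elongating/elongated
#: spermatids.
CELL_CLASSES = ("A", "In", "B", "Pl", "Pl/L", "L", "L/Z", "Z", "P", "D", "MII", "R", "E")

#: Species labels with packaged reference data.
SPECIES = ("a_cursor", "a_montensis", "n_lasiurus", "o_nigripes")


class Stage(enum.IntEnum):
    """SEC stage, a periodic 12-stage clock."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5
    VI = 6
    VII = 7
    VIII = 8
    IX = 9
    X = 10
    XI = 11
    XII = 12

    @classmethod
    def from_label(cls, label) -> "Stage":
        if isinstance(label, Stage):
            return label
        if isinstance(label, int):
            try:
                return cls(label)
            except ValueError:
                raise ValidationError(f"stage number out of range 1-12: {label!r}") from None
        name = str(label).strip().upper()
        if name in _ROMAN:
            return cls(_ROMAN.index(name) + 1)
        raise ValidationError(f"unknown SEC stage: {label!r}")

    @property
    def roman(self) -> str:
        return _ROMAN[self.value - 1]

    def advance(self, n: int = 1) -> "Stage":
        """Stage reached after ``n`` steps around the cycle (stage after XII is I)."""
        return Stage((self.value - 1 + n) % 12 + 1)


STAGES: tuple[Stage, ...] = tuple(Stage)


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0 or not math.isfinite(value):
        raise ValidationError(f"{name} must be a positive finite number, got {value!r}")
    return value


@dataclass(frozen=True)
class Biometry:
    """Body and gonad mass of one animal.

    ``testis_weight_mg`` is the mass of a single testis in milligrams; the
    gonadosomatic index uses ``n_testes`` times that value.
    """

    body_weight_g: float
    testis_weight_mg: float
    n_testes: int = 2

    def __post_init__(self):
        _positive("body_weight_g", self.body_weight_g)
        _positive("testis_weight_mg", self.testis_weight_mg)
        if self.n_testes not in (1, 2):
            raise ValidationError(f"n_testes must be 1 or 2, got {self.n_testes!r}")

    @property
    def testis_weight_g(self) -> float:
        """Mass of one testis in grams."""
        return self.testis_weight_mg / 1000.0


@dataclass(frozen=True)
class StageFrequencyTable:
    """Relative frequencies of stages I-XII, stored as fractions summing to 1.

    Because a tubule cross-section's stage advances at constant speed around
    the cycle, the stage frequencies are the time axis: the cumulative
    frequency up to a point of the cycle is the fraction of one cycle length
    elapsed since the start of stage I.
    """

    freq: Mapping[Stage, float]
    original_total: float = 100.0

    def __post_init__(self):
        freq = {Stage.from_label(k): float(v) for k, v in self.freq.items()}
        if set(freq) != set(STAGES):
            missing = [s.roman for s in STAGES if s not in freq]
            raise ValidationError(f"stage frequency table missing stages: {missing}")
        for stage, f in freq.items():
            if f < 0 or not math.isfinite(f):
                raise ValidationError(f"negative frequency for stage {stage.roman}: {f!r}")
        total = sum(freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions must sum to 1 (got {total}); use make_stage_table")
        object.__setattr__(self, "freq", dict(sorted(freq.items())))

    def fraction(self, stage) -> float:
        return self.freq[Stage.from_label(stage)]

    def cumulative_before(self, stage) -> float:
        """Fraction of the cycle elapsed at the *start* of ``stage``."""
        stage = Stage.from_label(stage)
        return sum(self.freq[s] for s in STAGES if s < stage)

    def cumulative_through(self, stage) -> float:
        """Fraction of the cycle elapsed at the *end* of ``stage``."""
        stage = Stage.from_label(stage)
        return sum(self.freq[s] for s in STAGES if s <= stage)

    def as_percent(self) -> dict[Stage, float]:
        return {s: 100.0 * f for s, f in self.freq.items()}


def make_stage_table(percentages: Mapping) -> StageFrequencyTable:
    """Build a :class:`StageFrequencyTable` from per-stage percentages.

    Accepts the twelve stage frequencies as printed (percent, or raw
    cross-section tallies: any non-negative values with a positive sum) and
    normalizes them to fractions. The pre-normalization sum is retained in
    ``original_total`` as a diagnostic (a well-formed percent column sums to
    ~100).
    """
    parsed: dict[Stage, float] = {}
    for key, value in percentages.items():
        stage = Stage.from_label(key)
        if stage in parsed:
            raise ValidationError(f"duplicate entry for stage {stage.roman}")
        value = float(value)
        if value < 0 or not math.isfinite(value):
            raise ValidationError(f"negative value for stage {stage.roman}: {value!r}")
        parsed[stage] = value
    missing = [s.roman for s in STAGES if s not in parsed]
    if missing:
        raise ValidationError(f"stage frequency table missing stages: {missing}")
    total = sum(parsed.values())
    if total <= 0:
        raise ValidationError("stage frequencies sum to zero")
    return StageFrequencyTable({s: v / total for s, v in parsed.items()}, original_total=total)


_PARENCHYMA_LEAVES = (
    "tunica_propria",
    "seminiferous_epithelium",
    "lumen",
    "leydig",
    "blood_vessels",
    "lymphatic",
    "other",
)
_TUBULE_LEAVES = ("tunica_propria", "seminiferous_epithelium", "lumen")


@dataclass(frozen=True)
class VolumeDensityTable:
    """Volume fractions of testis components from grid point counting.

    ``components`` holds the seven mutually exclusive leaf components as
    fractions of the testis *parenchyma* (they sum to 1), plus the derived
    aggregates ``tubule_compartment`` (= tunica propria + epithelium + lumen)
    and ``intertubular`` (the rest). ``albuginea_fraction`` is the fibrous
    capsule as a fraction of the *whole testis*, which is excluded from the
    parenchyma.
    """

    components: Mapping[str, float]
    albuginea_fraction: float = 0.0

    def __post_init__(self):
        comps = {k: float(v) for k, v in self.components.items()}
        missing = [k for k in _PARENCHYMA_LEAVES if k not in comps]
        if missing:
            raise ValidationError(f"volume density table missing components: {missing}")
        for k in _PARENCHYMA_LEAVES:
            if comps[k] < 0:
                raise ValidationError(f"negative volume density for {k}")
        leaf_total = sum(comps[k] for k in _PARENCHYMA_LEAVES)
        if abs(leaf_total - 1.0) > 1e-6:
            raise ValidationError(f"leaf volume densities must sum to 1, got {leaf_total}")
        tubule = sum(comps[k] for k in _TUBULE_LEAVES)
        inter = leaf_total - tubule
        if "tubule_compartment" in comps and abs(comps["tubule_compartment"] - tubule) > 1e-6:
            raise ValidationError(
                "tubule_compartment inconsistent with tunica propria + epithelium + lumen"
            )
        if "intertubular" in comps and abs(comps["intertubular"] - inter) > 1e-6:
            raise ValidationError("intertubular inconsistent with its leaf components")
        comps["tubule_compartment"] = tubule
        comps["intertubular"] = inter
        if not 0.0 <= self.albuginea_fraction < 0.2:
            raise ValidationError(
                f"albuginea fraction out of plausible range [0, 0.2): {self.albuginea_fraction}"
            )
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "albuginea_fraction", float(self.albuginea_fraction))

    def __getitem__(self, key: str) -> float:
        return self.components[key]


@dataclass(frozen=True)
class TubuleMorphometry:
    """Mean diameter and epithelium height of round tubule profiles (um)."""

    diameter_um: float
    epithelium_height_um: float

    def __post_init__(self):
        _positive("diameter_um", self.diameter_um)
        _positive("epithelium_height_um", self.epithelium_height_um)
        if 2.0 * self.epithelium_height_um >= self.diameter_um:
            raise ValidationError(
                "epithelium height inconsistent with diameter: "
                f"2 x {self.epithelium_height_um} >= {self.diameter_um}"
            )


@dataclass(frozen=True)
class LadderEntry:
    """One cell-class span of the germ-cell ladder."""

    cell_class: str
    stages: tuple[Stage, ...]
    cycle_ordinal: int

    @property
    def last_stage(self) -> Stage:
        return self.stages[-1]


class GermCellLadder:
    """Map from (germ-cell class, stage) to position along spermatogenesis.

    Each entry states which cell class a cohort labeled at Pl/L (cycle
    ordinal 0) has become when it sits in a given stage of a given later
    cycle. Rows tile the twelve stages of each cycle without overlap; the
    final row ends at the spermiation stage, where the cohort leaves the
    epithelium.
    """

    def __init__(self, entries: Iterable[LadderEntry]):
        entries = list(entries)
        if not entries:
            raise ValidationError("empty germ-cell ladder")
        ordinals = [e.cycle_ordinal for e in entries]
        if ordinals != sorted(ordinals):
            raise ValidationError("ladder cycle ordinals must be non-decreasing")
        if not any(e.cell_class == "Pl/L" and e.cycle_ordinal == 0 for e in entries):
            raise ValidationError("ladder must anchor Pl/L at cycle ordinal 0")
        for e in entries:
            if e.cell_class not in CELL_CLASSES:
                raise ValidationError(f"unknown germ-cell class in ladder: {e.cell_class!r}")
        self.entries = entries
        self._index: dict[tuple[str, Stage], LadderEntry] = {}
        by_row: dict[int, set[Stage]] = {}
        for e in entries:
            row = by_row.setdefault(e.cycle_ordinal, set())
            for s in e.stages:
                if s in row:
                    raise ValidationError(
                        f"ladder row {e.cycle_ordinal} covers stage {s.roman} twice"
                    )
                row.add(s)
                key = (e.cell_class, s)
                if key in self._index:
                    raise ValidationError(
                        f"ambiguous ladder entry for ({e.cell_class}, {s.roman})"
                    )
                self._index[key] = e
        last = max(by_row)
        for ordinal, row in by_row.items():
            if ordinal != last and row != set(STAGES):
                raise ValidationError(f"ladder row {ordinal} does not tile stages I-XII")

    def lookup(self, cell_class: str, stage) -> LadderEntry:
        stage = Stage.from_label(stage)
        try:
            return self._index[(cell_class, stage)]
        except KeyError:
            raise ValidationError(
                f"germ-cell class {cell_class!r} does not occur in stage {stage.roman} "
                "of this ladder"
            ) from None

    def position_key(self, cell_class: str, stage) -> tuple[int, int]:
        """Sort key giving a strict weak ordering of ladder positions."""
        stage = Stage.from_label(stage)
        entry = self.lookup(cell_class, stage)
        return (entry.cycle_ordinal, stage.value)

    @property
    def max_ordinal(self) -> int:
        return self.entries[-1].cycle_ordinal

    @property
    def release_stage(self) -> Stage:
        """Last stage of the final row: spermiation of the labeled cohort."""
        return max(s for e in self.entries if e.cycle_ordinal == self.max_ordinal for s in e.stages)

    def cell_class_at(self, cycle_ordinal: int, stage) -> str:
        stage = Stage.from_label(stage)
        for e in self.entries:
            if e.cycle_ordinal == cycle_ordinal and stage in e.stages:
                return e.cell_class
        raise ValidationError(
            f"no ladder entry for cycle {cycle_ordinal}, stage {stage.roman} "
            "(cohort released)"
        )

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "GermCellLadder":
        entries = []
        for rec in records:
            first = Stage.from_label(rec["stages"][0])
            last = Stage.from_label(rec["stages"][-1])
            if last < first:
                raise ValidationError(f"inverted stage span in ladder record: {rec!r}")
            span = tuple(Stage(v) for v in range(first.value, last.value + 1))
            entries.append(LadderEntry(rec["cell_class"], span, int(rec["cycle_ordinal"])))
        return cls(entries)

    @classmethod
    def for_species(cls, species: str, path=None) -> "GermCellLadder":
        """Packaged ladder for one of the four species (or from a YAML file)."""
        data = load_packaged_yaml("germ_cell_ladder.yaml") if path is None else _load_yaml(path)
        try:
            variant = data["species_variant"][species]
        except KeyError:
            raise ValidationError(f"no germ-cell ladder for species {species!r}") from None
        return cls.from_records(data[variant])


@dataclass(frozen=True)
class LabelingObservation:
    """One pulse-chase record: where the most advanced labeled cell sits.

    ``interval_days`` is the chase time net of the 1-hour baseline; the 1-hour
    anchor observation carries 0. ``within_stage_fraction``, when present, is
    the cohort's position inside its stage (0 = stage start, 1 = stage end),
    resolved in practice from pachytene nuclear size; absent for published
    table rows, in which case a boundary convention applies.
    """

    interval_days: float
    cell_class: str
    stage: Stage
    within_stage_fraction: Optional[float] = None

    def __post_init__(self):
        if self.interval_days < 0 or not math.isfinite(self.interval_days):
            raise ValidationError(f"interval_days must be >= 0, got {self.interval_days!r}")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(f"unknown germ-cell class: {self.cell_class!r}")
        object.__setattr__(self, "stage", Stage.from_label(self.stage))
        if self.within_stage_fraction is not None:
            f = float(self.within_stage_fraction)
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"within_stage_fraction must be in [0, 1], got {f}")
            object.__setattr__(self, "within_stage_fraction", f)


@dataclass(frozen=True)
class StageVIIICounts:
    """Raw (uncorrected) mean counts per stage-VIII tubule cross-section."""

    n_sections: int
    pachytene_raw: float
    round_spermatid_raw: float
    sertoli_nucleoli_raw: float
    section_thickness_um: float = 4.0
    pachytene_diameter_um: float = 10.0
    round_spermatid_diameter_um: float = 6.0
    sertoli_nucleolus_diameter_um: float = 2.5

    def __post_init__(self):
        if self.n_sections <= 0:
            raise ValidationError("n_sections must be positive")
        for name in ("pachytene_raw", "round_spermatid_raw", "sertoli_nucleoli_raw"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        _positive("section_thickness_um", self.section_thickness_um)
        for name in (
            "pachytene_diameter_um",
            "round_spermatid_diameter_um",
            "sertoli_nucleolus_diameter_um",
        ):
            _positive(name, getattr(self, name))


@dataclass(frozen=True)
class LeydigMorphometry:
    """Leydig nuclear diameter and nucleus:cytoplasm point fraction."""

    nuclear_diameter_um: float
    nucleus_point_fraction: float
    leydig_volume_density: Optional[float] = None

    def __post_init__(self):
        _positive("nuclear_diameter_um", self.nuclear_diameter_um)
        if not 0.0 < self.nucleus_point_fraction < 1.0:
            raise ValidationError(
                f"nucleus_point_fraction must be in (0, 1), got {self.nucleus_point_fraction}"
            )
        if self.leydig_volume_density is not None and not 0.0 <= self.leydig_volume_density < 1.0:
            raise ValidationError("leydig_volume_density must be a fraction of parenchyma")


@dataclass
class AnimalResult:
    """All derived quantities for one animal (None where inputs were absent)."""

    animal_id: str = ""
    species: str = ""
    gsi_percent: Optional[float] = None
    tubule_length_per_gram_m: Optional[float] = None
    tubule_length_total_m: Optional[float] = None
    cycles_traversed: Optional[float] = None
    cycle_length_days: Optional[float] = None
    spermatogenesis_days: Optional[float] = None
    meiotic_index: Optional[float] = None
    meiotic_loss_percent: Optional[float] = None
    sertoli_efficiency: Optional[float] = None
    sertoli_per_gram: Optional[float] = None
    sertoli_per_testis: Optional[float] = None
    dsp_per_gram: Optional[float] = None
    dsp_per_testis: Optional[float] = None
    leydig_nuclear_volume_um3: Optional[float] = None
    leydig_cell_volume_um3: Optional[float] = None
    leydig_per_gram: Optional[float] = None
    leydig_per_testis: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cycle_length_days is not None and self.spermatogenesis_days is not None:
            if self.spermatogenesis_days < 0 or self.cycle_length_days < 0:
                raise ValidationError("durations must be non-negative")


def _load_yaml(path):
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_packaged_yaml(name: str):
    """Load a YAML data file shipped inside the package."""
    ref = resources.files("testiquant.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
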