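"""SEC cycle-length estimation from pulse-chase labeling.

The stage-frequency table doubles as the cycle's clock face: cumulative stage
frequency equals elapsed fraction of one cycle. A cohort labeled at S phase
(Pl/L spermatocytes) moves deterministically around that clock, changing
germ-cell class as it crosses ladder rows. Comparing the cohort's cycle
position at 1 hour and after a chase of several weeks yields the number of
cycles traversed; chase time divided by cycles traversed is the cycle length
in days. The whole spermatogenic process takes ~4.5 cycles.
"""

from __future__ import annotations

from typing import Optional

from .core import (
    GermCellLadder,
    LabelingObservation,
    Stage,
    StageFrequencyTable,
    STAGES,
    ValidationError,
)

__all__ = [
    "phase_frequencies",
    "cycle_position",
    "cycles_traversed",
    "cycle_length",
    "spermatogenesis_duration",
    "stage_duration",
    "CYCLES_TO_COMPLETE_SPERMATOGENESIS",
]

#: Cycles needed to complete spermatogenesis from the spermatogonial phase.
CYCLES_TO_COMPLETE_SPERMATOGENESIS = 4.5

_PRE_MEIOTIC = (Stage.VIII, Stage.IX, Stage.X, Stage.XI)
_MEIOTIC = (Stage.XII,)
_POST_MEIOTIC = tuple(s for s in STAGES if s <= Stage.VII)

_BOUNDARIES = ("start", "end", "midpoint")


def phase_frequencies(sft: StageFrequencyTable) -> dict[str, float]:
    """Percent frequencies of the three phases of the cycle.

    Pre-meiotic: after spermiation, before metaphase (stages VIII-XI);
    meiotic: meiosis I through II (stage XII); post-meiotic: after meiosis
    until spermiation (stages I-VII). The three percents sum to the table's
    total (100 for a normalized table).
    """
    pct = sft.as_percent()
    return {
        "pre_meiotic": sum(pct[s] for s in _PRE_MEIOTIC),
        "meiotic": sum(pct[s] for s in _MEIOTIC),
        "post_meiotic": sum(pct[s] for s in _POST_MEIOTIC),
    }


def cycle_position(
    stage,
    boundary: str,
    sft: StageFrequencyTable,
    within_stage_fraction: Optional[float] = None,
) -> float:
    """Fraction of one cycle elapsed at a point of ``stage``.

    ``boundary`` is "start", "end" or "midpoint" of the stage; an explicit
    ``within_stage_fraction`` (0 = start, 1 = end) overrides it. Stage I
    start is position 0; stage XII end is position 1.
    """
    stage = Stage.from_label(stage)
    before = sft.cumulative_before(stage)
    if within_stage_fraction is not None:
        return before + within_stage_fraction * sft.fraction(stage)
    if boundary not in _BOUNDARIES:
        raise ValidationError(f"boundary must be one of {_BOUNDARIES}, got {boundary!r}")
    if boundary == "start":
        return before
    if boundary == "end":
        return sft.cumulative_through(stage)
    return before + 0.5 * sft.fraction(stage)


def _observation_position(
    obs: LabelingObservation,
    sft: StageFrequencyTable,
    ladder: GermCellLadder,
    boundary: str,
) -> tuple[int, float]:
    entry = ladder.lookup(obs.cell_class, obs.stage)
    frac = cycle_position(obs.stage, boundary, sft, obs.within_stage_fraction)
    return entry.cycle_ordinal, frac


def cycles_traversed(
    start: LabelingObservation,
    end: LabelingObservation,
    sft: StageFrequencyTable,
    ladder: GermCellLadder,
    boundary: str = "end",
) -> float:
    """Number of cycles the labeled cohort moved between two observations.

    The integer part comes from the germ-cell ladder (how many cycle rows
    separate the two cell classes); the fractional part is the difference of
    within-cycle positions, read off the cumulative stage frequencies. The
    default boundary convention places the most advanced labeled cell at the
    end of its stage at both times; observations carrying an explicit
    within-stage fraction use it instead.
    """
    start_ord, start_frac = _observation_position(start, sft, ladder, boundary)
    end_ord, end_frac = _observation_position(end, sft, ladder, boundary)
    if (end_ord, end_frac) < (start_ord, start_frac):
        raise ValidationError(
            f"end observation ({end.cell_class} at {end.stage.roman}) precedes "
            f"start observation ({start.cell_class} at {start.stage.roman}) on the ladder"
        )
    total = (end_ord - start_ord) + (end_frac - start_frac)
    if total <= 0:
        raise ValidationError("observations give zero cycles traversed")
    return total


def cycle_length(interval_days: float, cycles: float) -> float:
    """Cycle length in days: chase interval / cycles traversed."""
    if cycles <= 0:
        raise ValidationError(f"cycles traversed must be positive, got {cycles!r}")
    if interval_days <= 0:
        raise ValidationError(f"chase interval must be positive, got {interval_days!r}")
    return interval_days / cycles


def spermatogenesis_duration(
    cycle_length_days: float,
    n_cycles: float = CYCLES_TO_COMPLETE_SPERMATOGENESIS,
) -> float:
    """Total duration of spermatogenesis: ~4.5 cycle lengths."""
    if cycle_length_days <= 0:
        raise ValidationError("cycle length must be positive")
    return n_cycles * cycle_length_days


def stage_duration(stage, sft: StageFrequencyTable, cycle_length_days: float) -> float:
    """Duration of one stage in days: its frequency times the cycle length.

    Summed over the twelve stages this returns the cycle length exactly
    (frequencies sum to 1).
    """
    if cycle_length_days < 0:
        raise ValidationError("cycle length must be >= 0")
    return sft.fraction(stage) * cycle_length_days
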