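"""Stage assignment for tubule cross-sections from quantitative descriptors.

Stages are recognised from the acrosome system and spermatid nucleus
morphology: the acrosome vesicle appears at stage II, flattens into a cap
whose angle over the nuclear surface widens monotonically from stage III to
IX, spermiation at stage VII leaves a single spermatid generation from VIII
on, nuclear elongation starts at IX (quantified from stage X as the printed
shortest:longest axis descriptor of the spermatid head), and meiotic figures
are pathognomonic for stage XII.

The classifier first filters candidate stages by the boolean flags, then
picks the surviving stage whose numeric template (angle or elongation
descriptor) is nearest in z-score units; ties resolve to the earlier stage
and are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core import Stage, STAGES, ValidationError, load_packaged_yaml

__all__ = [
    "TubuleFeatures",
    "StageTemplate",
    "StageTemplateSet",
    "StageAssignment",
    "assign_stage",
    "sample_features",
]


@dataclass(frozen=True)
class TubuleFeatures:
    """Observable descriptors of one tubule cross-section.

    Any feature may be absent (None); at least one discriminative feature is
    required for assignment. ``elongation_ratio`` is the printed
    shortest:longest longitudinal axis descriptor, stored as printed
    (values >= 1).
    """

    n_spermatid_generations: Optional[int] = None
    acrosome_angle: Optional[float] = None
    elongation_ratio: Optional[float] = None
    meiotic_figures: Optional[bool] = None
    elongated_at_lumen: Optional[bool] = None
    acrosome_vesicle: Optional[bool] = None
    spermatids_elongating: Optional[bool] = None

    def __post_init__(self):
        if self.n_spermatid_generations not in (None, 1, 2):
            raise ValidationError(
                f"n_spermatid_generations must be 1 or 2, got {self.n_spermatid_generations!r}"
            )
        if self.acrosome_angle is not None and not 0.0 <= self.acrosome_angle <= 180.0:
            raise ValidationError(f"acrosome angle out of [0, 180]: {self.acrosome_angle}")
        if self.elongation_ratio is not None and self.elongation_ratio < 1.0:
            raise ValidationError(
                f"elongation descriptor below 1 (stored as printed): {self.elongation_ratio}"
            )
        if all(
            getattr(self, f) is None
            for f in (
                "n_spermatid_generations",
                "acrosome_angle",
                "elongation_ratio",
                "meiotic_figures",
                "acrosome_vesicle",
                "spermatids_elongating",
            )
        ):
            raise ValidationError("no discriminative feature present")


@dataclass(frozen=True)
class StageTemplate:
    """Expected descriptors for one stage of one species."""

    stage: Stage
    n_generations: Optional[int] = None
    angle_mean: Optional[float] = None
    angle_sd: Optional[float] = None
    ratio_mean: Optional[float] = None
    ratio_sd: Optional[float] = None
    acrosome_vesicle: Optional[bool] = None
    spermatids_elongating: Optional[bool] = None
    meiotic_figures: bool = False


class StageTemplateSet:
    """Per-species stage templates with validity checks.

    The acrosome-angle means must increase strictly from stage III through IX
    within each species — the angle is a monotone developmental clock.
    """

    def __init__(self, templates: Mapping[str, Mapping[Stage, StageTemplate]]):
        self.templates = {sp: dict(tmpl) for sp, tmpl in templates.items()}
        for sp, tmpl in self.templates.items():
            angles = [
                tmpl[s].angle_mean
                for s in STAGES
                if s in tmpl and tmpl[s].angle_mean is not None
            ]
            if any(b <= a for a, b in zip(angles, angles[1:])):
                raise ValidationError(f"angle means not strictly increasing for {sp!r}")

    def species(self) -> tuple[str, ...]:
        return tuple(self.templates)

    def for_species(self, species: str) -> dict[Stage, StageTemplate]:
        try:
            return self.templates[species]
        except KeyError:
            raise ValidationError(f"no stage templates for species {species!r}") from None

    @classmethod
    def from_mapping(cls, data: Mapping) -> "StageTemplateSet":
        parsed: dict[str, dict[Stage, StageTemplate]] = {}
        for sp, stages in data.items():
            tmpl = {}
            for label, rec in stages.items():
                stage = Stage.from_label(label)
                angle = rec.get("angle")
                ratio = rec.get("ratio")
                tmpl[stage] = StageTemplate(
                    stage=stage,
                    n_generations=rec.get("n_generations"),
                    angle_mean=None if angle is None else float(angle["mean"]),
                    angle_sd=None if angle is None else float(angle["sd"]),
                    ratio_mean=None if ratio is None else float(ratio["mean"]),
                    ratio_sd=None if ratio is None else float(ratio["sd"]),
                    acrosome_vesicle=rec.get("acrosome_vesicle"),
                    spermatids_elongating=rec.get("spermatids_elongating"),
                    meiotic_figures=bool(rec.get("meiotic_figures", False)),
                )
            parsed[sp] = tmpl
        return cls(parsed)

    @classmethod
    def packaged(cls, path=None) -> "StageTemplateSet":
        if path is None:
            data = load_packaged_yaml("stage_templates.yaml")
        else:
            with open(path, "r", encoding="utf-8") as fh:
                import yaml

                data = yaml.safe_load(fh)
        return cls.from_mapping(data)


@dataclass(frozen=True)
class StageAssignment:
    """Result of classifying one cross-section."""

    stage: Stage
    score: float
    tied: bool = False
    runner_up: Optional[Stage] = None


def _flag_consistent(features: TubuleFeatures, tmpl: StageTemplate) -> bool:
    if features.meiotic_figures is not None and features.meiotic_figures != tmpl.meiotic_figures:
        return False
    if (
        features.n_spermatid_generations is not None
        and tmpl.n_generations is not None
        and features.n_spermatid_generations != tmpl.n_generations
    ):
        return False
    for name in ("acrosome_vesicle", "spermatids_elongating"):
        fv = getattr(features, name)
        tv = getattr(tmpl, name)
        if fv is not None and tv is not None and fv != tv:
            return False
    return True


def assign_stage(
    features: TubuleFeatures,
    templates: StageTemplateSet,
    species: str,
) -> StageAssignment:
    """Assign an SEC stage to one tubule cross-section.

    Flags restrict the candidate stages (meiotic figures force stage XII; a
    two-generation tubule can only be pre-spermiation, I-VII; and so on);
    among the survivors the numeric descriptor nearest its template mean in
    z-score units wins, score = -|z|. Ties between adjacent stages resolve
    to the earlier stage and are flagged. Contradictory flags (meiotic
    figures in a claimed two-generation tubule) raise an error.
    """
    tmpl = templates.for_species(species)
    if features.meiotic_figures and features.n_spermatid_generations == 2:
        raise ValidationError(
            "contradictory features: meiotic figures imply stage XII, which has a "
            "single spermatid generation, but two generations were claimed"
        )
    candidates = [s for s in STAGES if s in tmpl and _flag_consistent(features, tmpl[s])]
    if not candidates:
        raise ValidationError("no stage is consistent with the given flags")

    scored: list[tuple[float, Stage]] = []
    if features.acrosome_angle is not None:
        angle_stages = [s for s in candidates if tmpl[s].angle_mean is not None]
        if angle_stages:
            for s in angle_stages:
                z = abs(features.acrosome_angle - tmpl[s].angle_mean) / tmpl[s].angle_sd
                scored.append((-z, s))
    if not scored and features.elongation_ratio is not None:
        ratio_stages = [s for s in candidates if tmpl[s].ratio_mean is not None]
        if ratio_stages:
            for s in ratio_stages:
                z = abs(features.elongation_ratio - tmpl[s].ratio_mean) / tmpl[s].ratio_sd
                scored.append((-z, s))

    if scored:
        best = max(score for score, _ in scored)
        # scores within 1e-9 z-units are indistinguishable: report a tie
        winners = sorted(s for score, s in scored if best - score <= 1e-9)
        others = sorted(
            (sc, s) for sc, s in scored if s not in winners
        )
        runner_up = others[-1][1] if others else (winners[1] if len(winners) > 1 else None)
        return StageAssignment(
            stage=winners[0],
            score=best,
            tied=len(winners) > 1,
            runner_up=runner_up,
        )

    # Flag-only assignment: pick the earliest consistent stage; a unique
    # survivor (e.g. meiotic figures -> XII, vesicle flags for I/II) scores 0.
    winners = sorted(candidates)
    return StageAssignment(
        stage=winners[0],
        score=0.0,
        tied=len(winners) > 1,
        runner_up=winners[1] if len(winners) > 1 else None,
    )


def sample_features(
    stage,
    templates: StageTemplateSet,
    species: str,
    rng: Optional[np.random.Generator] = None,
) -> TubuleFeatures:
    """Sample plausible cross-section features from a stage's template.

    Numeric descriptors are drawn from the template's Gaussian (angle clipped
    to [0, 180], elongation descriptor to >= 1); flags are taken from the
    template. Used by the synthetic generator and for Monte-Carlo confusion
    checks of :func:`assign_stage`.
    """
    rng = np.random.default_rng() if rng is None else rng
    stage = Stage.from_label(stage)
    tmpl = templates.for_species(species)[stage]
    angle = ratio = None
    if tmpl.angle_mean is not None:
        angle = float(np.clip(rng.normal(tmpl.angle_mean, tmpl.angle_sd), 0.0, 180.0))
    if tmpl.ratio_mean is not None:
        ratio = float(max(1.0, rng.normal(tmpl.ratio_mean, tmpl.ratio_sd)))
    return TubuleFeatures(
        n_spermatid_generations=tmpl.n_generations,
        acrosome_angle=angle,
        elongation_ratio=ratio,
        meiotic_figures=tmpl.meiotic_figures,
        acrosome_vesicle=tmpl.acrosome_vesicle,
        spermatids_elongating=tmpl.spermatids_elongating,
    )
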