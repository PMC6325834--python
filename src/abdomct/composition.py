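"""Threshold-set catalogue and per-subject composition panels.

A :class:`ThresholdSet` bundles the HU intervals for fat, lean tissue, bone
mineral and all tissue.  The recommended ("final") set is fat −250/−25,
lean −25/150, bone 150/2000, all tissue −250/2000: the three tissue classes
exactly tile the all-tissue interval, so their volumes partition the total.
The catalogue also carries the trialled variants and the prior literature
ranges (canine, human, feline) used for comparison, with the documented
exclusion reasons attached where a range was dropped from further analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .imaging_io import CTVolume
from .segmentation import GLOBAL_CEILING, SlabVOI, ThresholdRange, apply_threshold

TISSUES = ("fat", "lean", "bone", "all_tissue")

#: documented reasons a range was excluded from further analysis
EXCLUSION_REASONS = {
    "cortical_bone_excluded": "excluded: manual inspection revealed that cortical bone "
    "was excluded from the threshold range",
    "no_difference_upper": "excluded: values did not differ from the -250/2000 HU threshold",
    "fat_included": "excluded: manual inspection revealed a large volume of fat was "
    "included within the threshold range",
    "identical_to_150_2000": "excluded: the volumes calculated were exactly the same as "
    "the 150/2000 HU threshold range",
}


@dataclass(frozen=True)
class ThresholdSet:
    """Named bundle of per-tissue HU ranges; members may be absent for
    partial literature sets (e.g. a fat-only canine range)."""

    name: str
    fat: Optional[ThresholdRange] = None
    lean: Optional[ThresholdRange] = None
    bone: Optional[ThresholdRange] = None
    all_tissue: Optional[ThresholdRange] = None
    annotation: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if all(getattr(self, t) is None for t in TISSUES):
            raise ValueError(f"{self.name}: threshold set has no members")

    @property
    def tiling(self) -> bool:
        """True when fat/lean/bone abut and exactly cover the all-tissue range."""
        if any(getattr(self, t) is None for t in TISSUES):
            return False
        return (
            self.fat.lo == self.all_tissue.lo
            and self.fat.hi == self.lean.lo
            and self.lean.hi == self.bone.lo
            and self.bone.hi == self.all_tissue.hi
        )

    def members(self) -> dict[str, ThresholdRange]:
        return {t: getattr(self, t) for t in TISSUES if getattr(self, t) is not None}


def _r(label: str, lo: int, hi: int) -> ThresholdRange:
    return ThresholdRange(label=label, lo=lo, hi=hi)


_FINAL = dict(
    fat=_r("fat", -250, -25),
    lean=_r("lean", -25, 150),
    bone=_r("bone", 150, 2000),
    all_tissue=_r("all_tissue", -250, 2000),
)


def final_threshold_set() -> ThresholdSet:
    """The recommended set: fat −250/−25, lean −25/150, bone 150/2000,
    all tissue −250/2000."""
    return ThresholdSet(name="final", **_FINAL, source="recommended")


def builtin_threshold_sets() -> dict[str, ThresholdSet]:
    """Catalogue of named threshold sets: the final set, single-range trialled
    variants (the final set with one member substituted), and the literature
    comparison sets for dogs, people and cats.

    Excluded ranges stay in the catalogue but carry their exclusion reason as
    an annotation, so reports reproduce the comparison with its caveats.
    """
    sets: dict[str, ThresholdSet] = {"final": final_threshold_set()}

    def trial(tissue: str, lo: int, hi: int, annotation: str | None = None) -> None:
        members = dict(_FINAL)
        members[tissue] = _r(tissue, lo, hi)
        key = f"trial_{tissue}_{lo}/{hi}"
        sets[key] = ThresholdSet(name=key, **members, annotation=annotation, source="trialled")

    # trialled variants (union of the trialled enumeration and the rows the
    # comparison table actually reports)
    trial("fat", -250, -5)
    trial("lean", -5, 150)
    trial("lean", -105, 150, EXCLUSION_REASONS["fat_included"])
    trial("lean", 0, 100)
    trial("lean", -29, 150)
    trial("bone", 150, 1500)
    trial("bone", 150, 3000, EXCLUSION_REASONS["identical_to_150_2000"])
    trial("all_tissue", -250, 1500)
    trial("all_tissue", -250, 3000, EXCLUSION_REASONS["no_difference_upper"])
    trial("all_tissue", -190, 1000, EXCLUSION_REASONS["cortical_bone_excluded"])
    trial("all_tissue", -190, 2000)

    sets["dogs"] = ThresholdSet(
        name="dogs",
        fat=_r("fat", -135, -105),
        annotation="prior canine literature fat range",
        source="literature:dogs",
    )
    sets["people"] = ThresholdSet(
        name="people",
        fat=_r("fat", -190, -30),
        lean=_r("lean", -29, 150),
        bone=_r("bone", 152, 1000),
        annotation="human literature ranges; bone 152/1000 " + EXCLUSION_REASONS["cortical_bone_excluded"],
        source="literature:people",
    )
    sets["cats"] = ThresholdSet(
        name="cats",
        fat=_r("fat", -250, -5),
        lean=_r("lean", -5, 150),
        annotation="feline literature ranges",
        source="literature:cats",
    )
    return sets


@dataclass(frozen=True)
class CompositionPanel:
    """Per-tissue volumes (L) and percentages of all tissue inside a VOI."""

    threshold_set: str
    volumes: dict[str, float]
    voxel_counts: dict[str, int]
    percentages: Optional[dict[str, float]]
    tiling: bool
    voi_summary: dict = field(default_factory=dict)
    annotation: Optional[str] = None

    def to_rows(self, subject: str, sets: dict[str, ThresholdSet] | None = None) -> pd.DataFrame:
        """Tabular form: one row per tissue, keyed by (subject, set name)."""
        catalogue = sets or builtin_threshold_sets()
        ts = catalogue.get(self.threshold_set)
        rows = []
        for tissue, vol in self.volumes.items():
            rng = ts.members().get(tissue) if ts else None
            rows.append(
                {
                    "subject": subject,
                    "set": self.threshold_set,
                    "tissue": tissue,
                    "lo": rng.lo if rng else np.nan,
                    "hi": rng.hi if rng else np.nan,
                    "voxel_count": self.voxel_counts[tissue],
                    "volume_l": vol,
                    "percent": (self.percentages or {}).get(tissue, np.nan),
                    "annotation": self.annotation or "",
                }
            )
        return pd.DataFrame(rows)


def measure_composition(
    volume: CTVolume,
    voi: SlabVOI,
    threshold_set: ThresholdSet,
    *,
    ceiling: int = GLOBAL_CEILING,
) -> CompositionPanel:
    """Segment every member range of the set inside the VOI and derive
    percentages against the all-tissue volume.

    Raises :class:`DegenerateInputError` when the set defines an all-tissue
    range but its volume is zero (percentages undefined — e.g. a VOI of air).
    """
    volumes: dict[str, float] = {}
    counts: dict[str, int] = {}
    for tissue, rng in threshold_set.members().items():
        res = apply_threshold(volume, voi, rng, ceiling=ceiling)
        volumes[tissue] = res.volume_litres
        counts[tissue] = res.voxel_count

    percentages: Optional[dict[str, float]] = None
    if "all_tissue" in volumes:
        total = volumes["all_tissue"]
        if total == 0:
            raise DegenerateInputError(
                f"set {threshold_set.name!r}: all-tissue volume is zero; percentages undefined"
            )
        percentages = {t: 100.0 * v / total for t, v in volumes.items()}

    return CompositionPanel(
        threshold_set=threshold_set.name,
        volumes=volumes,
        voxel_counts=counts,
        percentages=percentages,
        tiling=threshold_set.tiling,
        voi_summary={
            "cranial_index": voi.cranial_index,
            "caudal_index": voi.caudal_index,
            "candidate_voxels": voi.candidate_count,
        },
        annotation=threshold_set.annotation,
    )


# ---------------------------------------------------------------------------
# Validation row specifications (the shape of the published comparison table)
# ---------------------------------------------------------------------------

#: DXA component keys used throughout: total body mass, fat mass, lean tissue
#: mass, bone mineral content.
COMPONENTS = ("total", "fat", "lean", "bmc")

#: tissue label (segmentation side) for each DXA component
COMPONENT_TISSUE = {"total": "all_tissue", "fat": "fat", "lean": "lean", "bmc": "bone"}


@dataclass(frozen=True)
class ValidationRowSpec:
    """One evaluated (DXA component, HU range) pairing, with exclusion status."""

    component: str
    range: ThresholdRange
    excluded: bool = False
    annotation: Optional[str] = None

    @property
    def range_label(self) -> str:
        return str(self.range)


def validation_rows() -> list[ValidationRowSpec]:
    """Every (component, range) row of the published CT↔DXA comparison,
    including the excluded rows with their documented reasons."""
    R = EXCLUSION_REASONS
    rows = [
        ValidationRowSpec("total", _r("all_tissue", -250, 1500)),
        ValidationRowSpec("total", _r("all_tissue", -250, 2000)),
        ValidationRowSpec("total", _r("all_tissue", -190, 2000)),
        ValidationRowSpec("total", _r("all_tissue", -190, 1000), True, R["cortical_bone_excluded"]),
        ValidationRowSpec("total", _r("all_tissue", -250, 3000), True, R["no_difference_upper"]),
        ValidationRowSpec("fat", _r("fat", -250, -5)),
        ValidationRowSpec("fat", _r("fat", -250, -25)),
        ValidationRowSpec("fat", _r("fat", -190, -30)),
        ValidationRowSpec("fat", _r("fat", -135, -105), annotation="prior canine literature fat range"),
        ValidationRowSpec("lean", _r("lean", 0, 100)),
        ValidationRowSpec("lean", _r("lean", -5, 150)),
        ValidationRowSpec("lean", _r("lean", -25, 150)),
        ValidationRowSpec("lean", _r("lean", -29, 150)),
        ValidationRowSpec("lean", _r("lean", -105, 150), True, R["fat_included"]),
        ValidationRowSpec("bmc", _r("bone", 152, 1000), True, R["cortical_bone_excluded"]),
        ValidationRowSpec("bmc", _r("bone", 150, 1500)),
        ValidationRowSpec("bmc", _r("bone", 150, 2000)),
        ValidationRowSpec("bmc", _r("bone", 150, 3000), True, R["identical_to_150_2000"]),
    ]
    return rows


def final_validation_rows() -> list[ValidationRowSpec]:
    """Only the recommended (final-set) rows, one per DXA component."""
    final = final_threshold_set()
    return [
        ValidationRowSpec(comp, final.members()[COMPONENT_TISSUE[comp]])
        for comp in COMPONENTS
    ]


def serialize_threshold_sets(sets: Iterable[ThresholdSet]) -> str:
    """Plain-text config: one ``name<TAB>tissue<TAB>lo<TAB>hi`` line per range."""
    lines = []
    for ts in sets:
        for tissue, rng in ts.members().items():
            lines.append(f"{ts.name}\t{tissue}\t{rng.lo}\t{rng.hi}")
    return "\n".join(lines) + "\n"


def parse_threshold_sets(text: str) -> dict[str, ThresholdSet]:
    """Inverse of :func:`serialize_threshold_sets`."""
    grouped: dict[str, dict[str, ThresholdRange]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, tissue, lo, hi = line.split("\t")
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r} in threshold config")
        grouped.setdefault(name, {})[tissue] = _r(tissue, int(lo), int(hi))
    return {name: ThresholdSet(name=name, **members) for name, members in grouped.items()}
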