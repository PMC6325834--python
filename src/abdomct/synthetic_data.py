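"""Synthetic CT phantoms and simulated CT↔DXA cohorts.

Two generators make every pipeline stage testable without scanner data:

* **Phantoms** — voxel grids with nested axis-aligned compartments (outer
  fat shell, lean core, bone rod) on an air background.  Compartment voxel
  membership is determined by index arithmetic, so per-compartment ground
  truth (counts and litres) is exact, independent of the HU draw.  HU are
  drawn per compartment from a normal distribution whose mean sits at least
  five standard deviations inside the compartment's recommended threshold
  range, making per-voxel misclassification probability below 1e-6.

* **Cohorts** — dog-level paired records of abdominal tissue volumes (L)
  and DXA component masses (kg).  Total abdominal volume is drawn
  log-uniformly over the range implied by a 5.1–60 kg body-weight interval
  through the total-mass calibration line; tissue shares of the total come
  from a Dirichlet distribution; each DXA mass is its component's published
  calibration line plus Gaussian noise whose SD is calibrated analytically
  so the population r² matches the published value per component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .imaging_io import CTVolume, round_half_away
from .segmentation import GLOBAL_CEILING
from .composition import COMPONENTS, COMPONENT_TISSUE, final_threshold_set

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "DXARecord",
    "SimulatedDog",
    "CohortParams",
    "generate_phantom",
    "simulate_cohort",
    "default_cohort_params",
    "default_phantom_spec",
    "cohort_to_frame",
    "cohort_frames_for_validation",
]

#: published calibration lines, mass (kg) = slope * volume (L) + intercept,
#: for the recommended threshold ranges per DXA component
TABLE_CALIBRATION = {
    "total": (3.46, 0.02),
    "fat": (1.70, 1.35),
    "lean": (5.22, -2.80),
    "bmc": (2.64, 0.08),
}

#: published coefficients of determination for the same rows
TABLE_R2 = {"total": 0.985, "fat": 0.981, "lean": 0.972, "bmc": 0.900}

#: body-weight interval of the study cohort (kg)
WEIGHT_RANGE_KG = (5.1, 60.0)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # [lo, hi) per axis


def _box_mask(shape: tuple[int, int, int], box: Box) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def _box_inside(inner: Box, outer: Box) -> bool:
    return all(o0 <= i0 and i1 <= o1 for (i0, i1), (o0, o1) in zip(inner, outer))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU parameters of a nested-box abdominal phantom.

    Boxes are half-open voxel-index ranges per axis; the fat compartment is
    ``outer_box`` minus ``lean_box``, lean is ``lean_box`` minus
    ``bone_box``, bone is ``bone_box``.  ``hu_params`` maps compartment →
    (mean, sd) in HU; each mean must sit at least ``margin_sd`` standard
    deviations inside the compartment's recommended threshold interval.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (1.0, 1.0, 0.75)
    outer_box: Box = ((8, 56), (8, 56), (4, 36))
    lean_box: Box = ((16, 48), (16, 48), (8, 32))
    bone_box: Box = ((28, 36), (28, 36), (8, 32))
    hu_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"fat": (-100.0, 15.0), "lean": (60.0, 12.0), "bone": (700.0, 100.0)}
    )
    background_hu: int = -1000
    seed: int = 0
    margin_sd: float = 5.0

    def __post_init__(self) -> None:
        if not _box_inside(self.bone_box, self.lean_box) or not _box_inside(self.lean_box, self.outer_box):
            raise ValueError("phantom compartments must be nested: bone ⊂ lean ⊂ outer")
        for (x0, x1), n in zip(self.outer_box, self.shape):
            if not (0 <= x0 < x1 <= n):
                raise ValueError(f"outer box {self.outer_box} exceeds grid shape {self.shape}")
        ranges = {t: (r.lo, r.hi) for t, r in final_threshold_set().members().items()}
        ranges["bone"] = (ranges["bone"][0], GLOBAL_CEILING)
        for comp, (mean, sd) in self.hu_params.items():
            lo, hi = ranges[comp]
            if sd < 0:
                raise ValueError(f"{comp}: negative HU sd")
            if sd > 0 and not (lo + self.margin_sd * sd <= mean <= hi - self.margin_sd * sd):
                raise ValueError(
                    f"{comp}: HU mean {mean} not {self.margin_sd} sd inside [{lo}, {hi}] at sd {sd}"
                )

    def compartment_masks(self) -> dict[str, np.ndarray]:
        outer = _box_mask(self.shape, self.outer_box)
        lean = _box_mask(self.shape, self.lean_box)
        bone = _box_mask(self.shape, self.bone_box)
        return {"fat": outer & ~lean, "lean": lean & ~bone, "bone": bone}


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth: per-compartment voxel counts and volumes (L)."""

    voxel_counts: dict[str, int]
    volumes_l: dict[str, float]

    def to_json(self) -> str:
        return json.dumps({"voxel_counts": self.voxel_counts, "volumes_l": self.volumes_l}, indent=2)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render the phantom to a CT volume and return it with its ground truth.

    Deterministic given ``spec.seed``.  Ground truth is computed from the
    compartment index masks, never from the drawn HU.
    """
    rng = np.random.default_rng(spec.seed)
    masks = spec.compartment_masks()
    grid = np.full(spec.shape, spec.background_hu, dtype=np.int16)
    for comp in ("fat", "lean", "bone"):  # fixed order for determinism
        mean, sd = spec.hu_params[comp]
        m = masks[comp]
        draws = rng.normal(mean, sd, size=int(m.sum())) if sd > 0 else np.full(int(m.sum()), mean)
        grid[m] = np.clip(round_half_away(draws), -1024, 4000).astype(np.int16)

    vox_mm3 = float(np.prod(spec.spacing))
    counts = {c: int(m.sum()) for c, m in masks.items()}
    counts["all_tissue"] = sum(counts.values())
    volumes = {c: n * vox_mm3 * 1e-6 for c, n in counts.items()}
    volume = CTVolume(voxels=grid, spacing=spec.spacing, meta={"phantom_seed": spec.seed})
    return volume, PhantomTruth(voxel_counts=counts, volumes_l=volumes)


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    return PhantomSpec(seed=seed)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DXARecord:
    """Reference body-composition masses, in kg."""

    total_mass: float
    fat_mass: float
    lean_mass: float
    bmc: float

    def __post_init__(self) -> None:
        for name in ("total_mass", "fat_mass", "lean_mass", "bmc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def fat_pct(self) -> float:
        return 100.0 * self.fat_mass / self.total_mass

    @property
    def lean_pct(self) -> float:
        return 100.0 * self.lean_mass / self.total_mass

    @property
    def bmc_pct(self) -> float:
        return 100.0 * self.bmc / self.total_mass

    def mass(self, component: str) -> float:
        return {"total": self.total_mass, "fat": self.fat_mass, "lean": self.lean_mass, "bmc": self.bmc}[component]


@dataclass(frozen=True)
class SimulatedDog:
    """One simulated subject: true abdominal tissue volumes plus DXA panel."""

    subject: str
    volumes_l: dict[str, float]  # keys: total, fat, lean, bmc (bmc = bone volume)
    dxa: DXARecord

    @property
    def implied_body_mass_kg(self) -> float:
        """Body mass implied by the total-mass calibration line (no noise)."""
        slope, intercept = TABLE_CALIBRATION["total"]
        return slope * self.volumes_l["total"] + intercept


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for a simulated CT↔DXA cohort.

    ``total_volume_range_l`` is the log-uniform support of the total
    abdominal volume; ``fraction_alpha`` the Dirichlet concentration of the
    (fat, lean, bone) shares; ``linear_maps`` the per-component calibration
    lines; ``noise_sd`` the per-component residual SD in kg.
    """

    n: int = 22
    total_volume_range_l: tuple[float, float] = (1.0, 18.0)
    fraction_alpha: tuple[float, float, float] = (22.2, 34.8, 3.0)
    linear_maps: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(TABLE_CALIBRATION))
    noise_sd: dict[str, float] = field(default_factory=lambda: {c: 0.0 for c in COMPONENTS})
    seed: int = 0
    mass_floor_kg: float = 0.01
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("cohort size must be >= 3")
        a, b = self.total_volume_range_l
        if not (0 < a < b):
            raise ValueError(f"invalid volume range {self.total_volume_range_l}")
        if any(al <= 0 for al in self.fraction_alpha):
            raise ValueError("Dirichlet concentrations must be positive")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")


def _loguniform_moments(a: float, b: float) -> tuple[float, float]:
    """(E[V], E[V²]) for V log-uniform on [a, b]."""
    L = np.log(b / a)
    m1 = (b - a) / L
    m2 = (b * b - a * a) / (2.0 * L)
    return m1, m2


def _component_volume_sd(params_alpha: Sequence[float], vol_range: tuple[float, float],
                         component: str) -> float:
    """Analytic SD of a component's volume under the generative model.

    The component volume is ``f·V`` with ``f`` a Dirichlet share independent
    of the log-uniform total ``V`` (``f ≡ 1`` for the total itself).
    """
    m1, m2 = _loguniform_moments(*vol_range)
    if component == "total":
        return float(np.sqrt(m2 - m1 * m1))
    idx = {"fat": 0, "lean": 1, "bmc": 2}[component]
    alpha = np.asarray(params_alpha, dtype=float)
    a0 = alpha.sum()
    ef = alpha[idx] / a0
    ef2 = alpha[idx] * (alpha[idx] + 1) / (a0 * (a0 + 1))
    var = ef2 * m2 - (ef * m1) ** 2
    return float(np.sqrt(var))


def noise_sd_for_r2(slope: float, volume_sd: float, r2: float) -> float:
    """Residual SD giving population r² for ``mass = slope·vol + noise``.

    From the variance decomposition r² = s²·Var(V) / (s²·Var(V) + σ²):
    σ = |slope|·sd(V)·sqrt((1−r²)/r²).
    """
    if not (0 < r2 <= 1):
        raise ValueError(f"r² must be in (0, 1], got {r2}")
    return float(abs(slope) * volume_sd * np.sqrt((1.0 - r2) / r2))


def default_cohort_params(seed: int = 0, *, n: int = 22,
                          r2_targets: Optional[dict[str, float]] = None) -> CohortParams:
    """Cohort parameters encoding the published study conditions.

    The total-volume support is the 5.1–60 kg weight interval inverted
    through the total-mass line; per-component noise SDs are derived
    analytically so each component's population r² matches its published
    value.
    """
    r2 = dict(TABLE_R2)
    if r2_targets:
        r2.update(r2_targets)
    slope_t, icpt_t = TABLE_CALIBRATION["total"]
    vol_range = ((WEIGHT_RANGE_KG[0] - icpt_t) / slope_t, (WEIGHT_RANGE_KG[1] - icpt_t) / slope_t)
    alpha = (22.2, 34.8, 3.0)
    noise = {
        comp: noise_sd_for_r2(
            TABLE_CALIBRATION[comp][0], _component_volume_sd(alpha, vol_range, comp), r2[comp]
        )
        for comp in COMPONENTS
    }
    return CohortParams(
        n=n,
        total_volume_range_l=vol_range,
        fraction_alpha=alpha,
        linear_maps=dict(TABLE_CALIBRATION),
        noise_sd=noise,
        seed=seed,
    )


def simulate_cohort(params: CohortParams) -> list[SimulatedDog]:
    """Draw a cohort of simulated dogs; deterministic given ``params.seed``.

    Each DXA component mass is generated independently from its own
    calibration line (mirroring that the published rows are separate
    regressions), so the component masses need not close to the total.
    Non-positive masses are redrawn up to ``max_redraws`` times.
    """
    rng = np.random.default_rng(params.seed)
    a, b = params.total_volume_range_l
    dogs = []
    for i in range(params.n):
        total_v = float(np.exp(rng.uniform(np.log(a), np.log(b))))
        shares = rng.dirichlet(params.fraction_alpha)
        volumes = {
            "total": total_v,
            "fat": float(shares[0] * total_v),
            "lean": float(shares[1] * total_v),
            "bmc": float(shares[2] * total_v),
        }
        masses = {}
        for comp in COMPONENTS:
            slope, intercept = params.linear_maps[comp]
            line = slope * volumes[comp] + intercept
            sd = params.noise_sd.get(comp, 0.0)
            for _ in range(params.max_redraws + 1):
                mass = line + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                if mass > params.mass_floor_kg:
                    break
            else:
                raise SimulationError(
                    f"subject {i}: could not draw a positive {comp} mass in "
                    f"{params.max_redraws} attempts (line value {line:.3f} kg, sd {sd:.3f})"
                )
            masses[comp] = float(mass)
        dogs.append(
            SimulatedDog(
                subject=f"dog{i + 1:02d}",
                volumes_l=volumes,
                dxa=DXARecord(
                    total_mass=masses["total"],
                    fat_mass=masses["fat"],
                    lean_mass=masses["lean"],
                    bmc=masses["bmc"],
                ),
            )
        )
    return dogs


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: Sequence[SimulatedDog]) -> pd.DataFrame:
    """Wide per-dog table: volumes (L) and DXA masses (kg)."""
    return pd.DataFrame(
        [
            {
                "subject": d.subject,
                "volume_total_l": d.volumes_l["total"],
                "volume_fat_l": d.volumes_l["fat"],
                "volume_lean_l": d.volumes_l["lean"],
                "volume_bone_l": d.volumes_l["bmc"],
                "dxa_total_kg": d.dxa.total_mass,
                "dxa_fat_kg": d.dxa.fat_mass,
                "dxa_lean_kg": d.dxa.lean_mass,
                "dxa_bmc_kg": d.dxa.bmc,
            }
            for d in cohort
        ]
    )


def cohort_frames_for_validation(cohort: Sequence[SimulatedDog]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (volumes, dxa) frames for :func:`abdomct.method_stats.validate_thresholds`.

    Volumes are labelled with the recommended HU range per component, since
    the generator's tissue volumes correspond to the final threshold set.
    """
    final = final_threshold_set()
    vol_rows, dxa_rows = [], []
    for d in cohort:
        for comp in COMPONENTS:
            rng = final.members()[COMPONENT_TISSUE[comp]]
            vol_rows.append(
                {"subject": d.subject, "component": comp, "range": str(rng), "volume_l": d.volumes_l[comp]}
            )
            dxa_rows.append({"subject": d.subject, "component": comp, "mass_kg": d.dxa.mass(comp)})
    return pd.DataFrame(vol_rows), pd.DataFrame(dxa_rows)


def params_to_json(params: CohortParams) -> str:
    return json.dumps(asdict(params), indent=2, sort_keys=True)


def params_from_json(text: str) -> CohortParams:
    raw = json.loads(text)
    raw["total_volume_range_l"] = tuple(raw["total_volume_range_l"])
    raw["fraction_alpha"] = tuple(raw["fraction_alpha"])
    raw["linear_maps"] = {k: tuple(v) for k, v in raw["linear_maps"].items()}
    return CohortParams(**raw)
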