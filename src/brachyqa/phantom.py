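"""Seeded synthetic cohort of pelvic phantoms with a point-source dose engine.

Each phantom plan is a parametric pelvis: an ellipsoidal HR-CTV at the
grid center, a bladder anterior to it, a rectal tube posterior, a sigmoid
tube superior-posterior, and a small-intestine blob cluster superior.
Organ standoff gaps from the HR-CTV surface are randomized per plan, which
makes the near-target ring volumes vary across the cohort and — because
dose falls off with distance from the dwell positions inside the HR-CTV —
induces the positive volume-dose relationship the prediction model learns.

Dose is a bare inverse-square point-source kernel summed over a
tandem-and-ovoid dwell layout, then scaled so D90(HR-CTV) equals the
prescription exactly, as a planner would normalize coverage.  This keeps
the geometric dose gradients of an Ir-192 implant without radial dose
function or anisotropy corrections.

The small-intestine standoff is coupled negatively to bladder size (a
fuller bladder lifts bowel closer to the superior dose region in this
anatomy), reproducing the clinically observed positive correlation
between bladder volume and small-intestine dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dosimetry import (
    DEFAULT_PRESCRIPTION_GY,
    DoseGrid,
    PlanDoseMetrics,
    cumulative_dvh,
    dose_to_fraction,
    plan_metrics,
)
from .geometry import FeatureVector, build_feature_vector, derive_rings, sub_oar_volumes
from .structures import HRCTV, OAR_NAMES, StructureError, StructureSet


class PhantomError(RuntimeError):
    pass


@dataclass
class PhantomConfig:
    """Cohort-level generation parameters (all lengths in mm).

    The defaults define the study conditions: 200 plans on an 80^3 lattice
    at 2.5 mm, HR-CTV semi-axes 18-28 mm, organ standoff gaps of a few mm
    up to ~18 mm, 7 Gy prescription to D90.
    """

    n_plans: int = 200
    shape: tuple[int, int, int] = (80, 96, 80)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    #: HR-CTV center as a fraction of the grid extent (shifted posterior so
    #: the anterior bladder fits inside the lattice)
    center_frac: tuple[float, float, float] = (0.5, 0.4, 0.5)
    #: HR-CTV mean semi-axis range; per-axis deviation is +/- hrctv_aspect_mm
    #: around the drawn mean so overall size (not shape) dominates variation
    hrctv_semiaxes_mm: tuple[float, float] = (19.0, 27.0)
    hrctv_aspect_mm: float = 2.0
    center_jitter_mm: float = 3.0
    # per-organ (size_lo, size_hi, gap_lo, gap_hi) in mm
    bladder_radius_mm: tuple[float, float] = (28.0, 42.0)
    bladder_gap_mm: tuple[float, float] = (1.0, 12.0)
    rectum_radius_mm: tuple[float, float] = (10.0, 16.0)
    rectum_gap_mm: tuple[float, float] = (0.5, 10.0)
    sigmoid_radius_mm: tuple[float, float] = (8.0, 14.0)
    sigmoid_gap_mm: tuple[float, float] = (1.0, 12.0)
    intestine_radius_mm: tuple[float, float] = (13.0, 17.0)
    #: height of the bowel-cluster center above the HR-CTV center (mm).
    #: Absolute (not riding on the target surface): a larger HR-CTV closes
    #: the bowel-target gap, as in real pelvic anatomy.
    intestine_height_mm: tuple[float, float] = (42.0, 52.0)
    #: mm of extra intestine standoff per mm of bladder radius below its
    #: midpoint (negative coupling: big bladder -> bowel closer)
    intestine_bladder_coupling: float = 1.2
    n_tandem_dwells: int = 5
    ovoid_offset_mm: float = 12.0
    weight_jitter: float = 0.05
    r_min_mm: float = 1.0
    d_prescription: float = DEFAULT_PRESCRIPTION_GY
    max_retries: int = 20
    seed: int = 20160529

    def plan_rng(self, plan_index: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, plan_index])


@dataclass
class DwellSet:
    """Dwell positions (physical mm) and nonnegative weights."""

    positions: np.ndarray  # (n, 3)
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.positions) < 1:
            raise PhantomError("at least one dwell position required")
        if (self.weights < 0).any() or not self.weights.any():
            raise PhantomError("weights must be >= 0 and not all zero")


# ---------------------------------------------------------------------------
# geometry primitives


def _coords(shape, spacing):
    axes = [spacing[i] * np.arange(shape[i]) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xx, yy, zz, center, semiaxes) -> np.ndarray:
    return (
        ((xx - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((zz - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _tube_z(xx, yy, zz, cx, cy, radius, z_lo, z_hi) -> np.ndarray:
    """Cylinder along z between z_lo and z_hi."""
    return (
        ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2)
        & (zz >= z_lo)
        & (zz <= z_hi)
    )


def generate_structures(cfg: PhantomConfig, plan_seed: int) -> StructureSet:
    """One deterministic pelvic phantom for a given plan index/seed.

    Organ placement uses per-plan standoff gaps from the HR-CTV surface;
    if a jittered placement overlaps the HR-CTV it is rejected and
    redrawn, up to ``cfg.max_retries`` times.
    """
    rng = cfg.plan_rng(plan_seed)
    shape, spacing = cfg.shape, cfg.spacing
    xx, yy, zz = _coords(shape, spacing)
    extent = [spacing[i] * (shape[i] - 1) for i in range(3)]
    center = np.array(extent) * np.array(cfg.center_frac) + rng.uniform(
        -cfg.center_jitter_mm, cfg.center_jitter_mm, size=3
    )

    a_mean = rng.uniform(*cfg.hrctv_semiaxes_mm)
    a = a_mean + rng.uniform(-cfg.hrctv_aspect_mm, cfg.hrctv_aspect_mm, size=3)
    hrctv = _ellipsoid(xx, yy, zz, center, a)

    def draw(lo_hi):
        return rng.uniform(*lo_hi)

    for attempt in range(cfg.max_retries):
        masks = {HRCTV: hrctv}
        # bladder: anterior (+y) ellipsoid, mildly flattened
        rb = draw(cfg.bladder_radius_mm)
        gb = draw(cfg.bladder_gap_mm)
        b_center = center + [
            rng.uniform(-5, 5),
            a[1] + gb + rb,
            rng.uniform(-8, 8),
        ]
        masks["bladder"] = _ellipsoid(
            xx, yy, zz, b_center, (rb, rb, 0.8 * rb)
        )
        # rectum: posterior (-y) tube along z
        rr = draw(cfg.rectum_radius_mm)
        gr = draw(cfg.rectum_gap_mm)
        masks["rectum"] = _tube_z(
            xx,
            yy,
            zz,
            center[0] + rng.uniform(-4, 4),
            center[1] - (a[1] + gr + rr),
            rr,
            center[2] - 55.0,
            center[2] + 25.0,
        )
        # sigmoid colon: superior-posterior tube
        rs = draw(cfg.sigmoid_radius_mm)
        gs = draw(cfg.sigmoid_gap_mm)
        u = np.array([0.0, -0.55, 0.835])  # unit posterior-superior
        support = float(np.sqrt(np.sum((a * u) ** 2)))  # ellipsoid extent along u
        s_center = center + u * (support + gs + rs)
        masks["sigmoid_colon"] = _tube_z(
            xx,
            yy,
            zz,
            s_center[0] + rng.uniform(-4, 4),
            s_center[1],
            rs,
            s_center[2] - 5.0,
            s_center[2] + 55.0,
        )
        # small intestine: blob cluster at an absolute height above the
        # pelvis; a fuller bladder lifts bowel closer to the dose region
        # (coupling reproduces the V_bladder correlation)
        ri = draw(cfg.intestine_radius_mm)
        b_mid = sum(cfg.bladder_radius_mm) / 2.0
        height = draw(cfg.intestine_height_mm) + cfg.intestine_bladder_coupling * (
            b_mid - rb
        )
        height = max(height, a[2] + ri + 1.0)  # keep clear of the HR-CTV
        blob = np.zeros(shape, dtype=bool)
        base = center + [0.0, 0.0, height]
        for _ in range(4):
            c = base + [
                rng.uniform(-6, 6),
                rng.uniform(-6, 6),
                rng.uniform(0, 10),
            ]
            blob |= _ellipsoid(xx, yy, zz, c, (ri, ri, ri))
        masks["small_intestine"] = blob
        try:
            return StructureSet(masks=masks, spacing=spacing)
        except StructureError:
            continue
    raise PhantomError(
        f"no overlap-free organ placement after {cfg.max_retries} retries"
    )


# ---------------------------------------------------------------------------
# dose engine


def make_dwells(
    cfg: PhantomConfig, structures: StructureSet, rng: np.random.Generator
) -> DwellSet:
    """Tandem-and-ovoid dwell layout scaled to the HR-CTV extent."""
    hrctv = structures.masks[HRCTV]
    idx = np.argwhere(hrctv)
    spacing = np.asarray(structures.spacing)
    center = idx.mean(axis=0) * spacing
    z_half = (idx[:, 2].max() - idx[:, 2].min()) / 2.0 * spacing[2]
    positions = []
    # tandem: dwells along the z axis through the HR-CTV center
    for t in np.linspace(-0.7, 0.7, cfg.n_tandem_dwells):
        positions.append(center + [0.0, 0.0, t * z_half])
    # ovoids: lateral pair at the inferior end
    for sx in (-1.0, 1.0):
        positions.append(
            center + [sx * cfg.ovoid_offset_mm, 0.0, -0.7 * z_half]
        )
    n = len(positions)
    weights = rng.uniform(1 - cfg.weight_jitter, 1 + cfg.weight_jitter, n)
    return DwellSet(positions=np.array(positions), weights=weights)


def compute_dose(
    dwells: DwellSet,
    shape,
    spacing,
    r_min_mm: float = 1.0,
    origin=(0.0, 0.0, 0.0),
) -> DoseGrid:
    """Inverse-square point-source dose: sum_i w_i / max(r_i, r_min)^2."""
    xx, yy, zz = _coords(shape, spacing)
    dose = np.zeros(shape, dtype=float)
    for pos, w in zip(dwells.positions, dwells.weights):
        r2 = (xx - pos[0]) ** 2 + (yy - pos[1]) ** 2 + (zz - pos[2]) ** 2
        np.maximum(r2, r_min_mm**2, out=r2)
        dose += w / r2
    return DoseGrid(dose=dose, spacing=tuple(spacing), origin=tuple(origin))


def normalize_to_prescription(
    dose: DoseGrid,
    structures: StructureSet,
    d_prescription: float = DEFAULT_PRESCRIPTION_GY,
) -> DoseGrid:
    """Scale the dose grid so D90(HR-CTV) equals the prescription exactly."""
    dvh = cumulative_dvh(dose, structures.masks[HRCTV])
    d90 = dose_to_fraction(dvh, 0.90)
    if d90 <= 0:
        raise PhantomError("zero dose in HR-CTV; cannot normalize")
    return DoseGrid(
        dose=dose.dose * (d_prescription / d90),
        spacing=dose.spacing,
        origin=dose.origin,
    )


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class PlanRecord:
    """One synthetic plan: metrics and per-organ features (volumes are
    dropped unless the cohort was generated with ``keep_volumes``)."""

    plan_id: int
    metrics: PlanDoseMetrics
    features: dict[str, FeatureVector]
    structures: StructureSet | None = None
    dose: DoseGrid | None = None


def generate_plan(
    cfg: PhantomConfig, plan_index: int, keep_volumes: bool = False
) -> PlanRecord:
    """Generate structures, dose, metrics and features for one plan."""
    structures = generate_structures(cfg, plan_index)
    rng = np.random.default_rng([cfg.seed, plan_index, 1])  # dwell stream
    dwells = make_dwells(cfg, structures, rng)
    dose = compute_dose(
        dwells, cfg.shape, cfg.spacing, r_min_mm=cfg.r_min_mm
    )
    dose = normalize_to_prescription(dose, structures, cfg.d_prescription)
    metrics = plan_metrics(dose, structures, cfg.d_prescription)
    rings = derive_rings(structures)
    features = {
        organ: build_feature_vector(
            sub_oar_volumes(rings, structures, organ), structures, organ
        )
        for organ in OAR_NAMES
    }
    return PlanRecord(
        plan_id=plan_index,
        metrics=metrics,
        features=features,
        structures=structures if keep_volumes else None,
        dose=dose if keep_volumes else None,
    )


def generate_cohort(
    cfg: PhantomConfig, keep_volumes: bool = False
) -> list[PlanRecord]:
    """The full synthetic cohort, deterministic given ``cfg.seed``."""
    return [
        generate_plan(cfg, i, keep_volumes=keep_volumes)
        for i in range(cfg.n_plans)
    ]


def cohort_to_frame(records: list[PlanRecord]):
    """Long-format table: one row per plan per organ with the six feature
    columns, D2cm3 and the D2cm3/Dprescription target."""
    import pandas as pd

    rows = []
    for rec in records:
        for organ, fv in rec.features.items():
            row = {
                "plan_id": rec.plan_id,
                "organ": organ,
                "V_global_cm3": fv.values[0],
                "d2cm3_Gy": rec.metrics.d2cm3[organ],
                "d_prescription_Gy": rec.metrics.d_prescription,
                "ratio": rec.metrics.ratio[organ],
            }
            for k in range(1, 6):
                row[f"v{k}_cm3"] = fv.values[k]
            rows.append(row)
    cols = [
        "plan_id",
        "organ",
        "V_global_cm3",
        "v1_cm3",
        "v2_cm3",
        "v3_cm3",
        "v4_cm3",
        "v5_cm3",
        "d2cm3_Gy",
        "d_prescription_Gy",
        "ratio",
    ]
    return pd.DataFrame(rows)[cols]
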