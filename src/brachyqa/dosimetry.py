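"""DVH-derived dose metrics: D2cm3, D90, EQD2 and per-fraction constraints.

Dose-volume metrics are computed bin-free from the exact multiset of voxel
doses: voxel doses are sorted descending, voxel volumes accumulated, and
the dose at a volume criterion read off with linear interpolation between
steps of the cumulative curve.  All doses are Gy per fraction unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import StructureSet, StructureError

#: per-fraction D2cm3 limits (Gy), strict '<'
CONSTRAINTS_GY = {
    "bladder": 5.2,
    "rectum": 4.7,
    "sigmoid_colon": 4.7,
    "small_intestine": 4.7,
}

DEFAULT_PRESCRIPTION_GY = 7.0


class DosimetryError(ValueError):
    pass


@dataclass
class DoseGrid:
    """3D dose array (Gy/fraction) on the same lattice as a StructureSet."""

    dose: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if (self.dose < 0).any():
            raise DosimetryError("negative dose values")

    def matches(self, structures: StructureSet) -> bool:
        return (
            self.dose.shape == structures.shape
            and np.allclose(self.spacing, structures.spacing)
        )


def cumulative_dvh(
    dose: DoseGrid, mask: np.ndarray, spacing=None
) -> np.ndarray:
    """Cumulative DVH as an (n, 2) array of (dose_Gy, volume_cm3 >= dose).

    One row per distinct voxel dose, ascending in dose; the volume column
    is monotone non-increasing and starts at the full organ volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if spacing is None:
        spacing = dose.spacing
    if dose.dose.shape != mask.shape:
        raise DosimetryError(
            f"lattice mismatch: dose {dose.dose.shape} vs mask {mask.shape}"
        )
    if not mask.any():
        raise DosimetryError("empty structure")
    vox_cm3 = float(np.prod(spacing)) / 1000.0
    doses = np.sort(dose.dose[mask].ravel())
    levels, counts = np.unique(doses, return_counts=True)
    # volume receiving >= level = total - volume strictly below
    below = np.concatenate([[0], np.cumsum(counts)[:-1]])
    vol_ge = (len(doses) - below) * vox_cm3
    return np.column_stack([levels, vol_ge])


def dose_at_volume(dvh: np.ndarray, v_cm3: float = 2.0) -> float:
    """Largest dose D such that the volume receiving >= D is >= v_cm3.

    Linear interpolation between steps of the cumulative curve; the
    minimum dose to the hottest ``v_cm3`` of the organ (D2cm3 for the
    default criterion).
    """
    dvh = np.asarray(dvh, dtype=float)
    levels, vols = dvh[:, 0], dvh[:, 1]
    total = vols[0]
    if total < v_cm3:
        raise DosimetryError(
            f"organ smaller than volume criterion ({total:.3f} < {v_cm3} cm^3)"
        )
    if v_cm3 <= vols[-1]:  # the hottest level alone covers v
        return float(levels[-1])
    # vols descends with level; interpolate dose as a function of volume
    return float(np.interp(v_cm3, vols[::-1], levels[::-1]))


def dose_to_fraction(dvh: np.ndarray, fraction: float = 0.90) -> float:
    """Dose received by the given fraction of the organ volume (D90 etc.)."""
    if not 0 < fraction <= 1:
        raise DosimetryError(f"fraction must be in (0, 1], got {fraction}")
    total = float(np.asarray(dvh)[0, 1])
    return dose_at_volume(dvh, fraction * total)


@dataclass
class EQD2Params:
    """Linear-quadratic fractionation parameters.

    alpha_beta is 10 Gy for targets and 3 Gy for the organs at risk.
    """

    n_fractions: int
    d_per_fraction: float
    alpha_beta: float

    def __post_init__(self) -> None:
        if self.n_fractions <= 0:
            raise DosimetryError("n_fractions must be positive")
        if self.d_per_fraction < 0:
            raise DosimetryError("dose per fraction must be >= 0")
        if self.alpha_beta <= 0:
            raise DosimetryError("alpha/beta must be positive")


def eqd2(p: EQD2Params) -> float:
    """Equivalent dose in 2 Gy fractions: n*d*(d + a/b) / (2 + a/b)."""
    return (
        p.n_fractions
        * p.d_per_fraction
        * (p.d_per_fraction + p.alpha_beta)
        / (2.0 + p.alpha_beta)
    )


@dataclass
class PlanDoseMetrics:
    """Per-plan dose summary: D90 of the HR-CTV, per-organ D2cm3 and the
    dimensionless D2cm3/Dprescription ratios."""

    d_prescription: float
    d90_hrctv: float
    d2cm3: dict[str, float]
    ratio: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ratio:
            self.ratio = {
                o: d / self.d_prescription for o, d in self.d2cm3.items()
            }


def plan_metrics(
    dose: DoseGrid,
    structures: StructureSet,
    d_prescription: float = DEFAULT_PRESCRIPTION_GY,
    organs=None,
) -> PlanDoseMetrics:
    """Compute D90(HR-CTV) and D2cm3 for each organ of a plan."""
    if not dose.matches(structures):
        raise DosimetryError("dose and structures on different lattices")
    hr_dvh = cumulative_dvh(dose, structures.masks["hrctv"])
    d90 = dose_to_fraction(hr_dvh, 0.90)
    d2 = {}
    for organ in organs or structures.organ_names():
        dvh = cumulative_dvh(dose, structures.masks[organ])
        d2[organ] = dose_at_volume(dvh, 2.0)
    return PlanDoseMetrics(
        d_prescription=d_prescription, d90_hrctv=d90, d2cm3=d2
    )


def check_constraints(m: PlanDoseMetrics) -> dict[str, str]:
    """Per-fraction D2cm3 limits: bladder < 5.2 Gy, others < 4.7 Gy.

    Strict inequality; organs absent from the metrics are reported as
    ``"missing"`` rather than passing silently.
    """
    verdict = {}
    for organ, limit in CONSTRAINTS_GY.items():
        if organ not in m.d2cm3:
            verdict[organ] = "missing"
        else:
            verdict[organ] = "pass" if m.d2cm3[organ] < limit else "fail"
    return verdict
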