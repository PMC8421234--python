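"""Voxel dose grids, EQD2 conversion, and dose-volume metrics.

The equivalent dose in 2-Gy fractions (EQD2) expresses a fractionated dose
distribution on the scale of conventional 2 Gy/fraction radiotherapy using
the linear-quadratic model:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

where ``D`` is the total dose a voxel receives, ``d`` the dose per fraction
at that voxel, and alpha/beta (Gy) the tissue's fractionation sensitivity
(3 Gy for the thyroid, a late-reacting tissue). Conversion is performed
voxel-by-voxel with ``d_v = D_v / n_fractions`` (a uniform fraction count
across the grid); at exactly 2 Gy/fraction the conversion is the identity.

Dose-volume metrics (Dmin/Dmax/Dmean, Vx = % of structure volume receiving
at least x Gy) are computed on the raw masked voxel doses, never from the
binned DVH curve, so they carry no binning bias.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseKind",
    "RadiobiologyParams",
    "FractionationScheme",
    "DoseGrid",
    "StructureMask",
    "DVHCurve",
    "DoseMetrics",
    "DEFAULT_VX_LEVELS",
    "eqd2_voxel",
    "convert_to_eqd2",
    "cumulative_dvh",
    "dose_metrics",
]

#: Vx reporting levels (Gy) used throughout the package.
DEFAULT_VX_LEVELS = (10, 20, 30, 40, 45, 50, 60, 70)


class DoseKind(str, enum.Enum):
    """Whether a grid holds physical dose or EQD2-converted dose."""

    PHYSICAL = "physical"
    EQD2 = "eqd2"


@dataclass(frozen=True)
class RadiobiologyParams:
    """Linear-quadratic parameters. ``alpha_beta`` in Gy, must be > 0."""

    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha_beta) or self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be finite and > 0, got {self.alpha_beta}")


@dataclass(frozen=True)
class FractionationScheme:
    """Uniform fraction count of a treatment course."""

    n_fractions: int

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError(f"n_fractions must be an integer >= 1, got {self.n_fractions}")


@dataclass
class DoseGrid:
    """A 3-D lattice of per-voxel dose (Gy) with geometry metadata.

    Voxel indices are 0-based; physical coordinates refer to voxel centers,
    with ``origin`` the coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dose_kind: DoseKind = DoseKind.PHYSICAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("dose grid must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("all dose values must be finite and >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if len(self.origin) != 3:
            raise ValueError("origin must have three components (mm)")
        self.dose_kind = DoseKind(self.dose_kind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class StructureMask:
    """Binary mask congruent with a :class:`DoseGrid`."""

    include: np.ndarray
    name: str = "structure"

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 3:
            raise ValueError("mask must be a 3-D boolean array")
        if not self.include.any():
            raise ValueError(f"mask '{self.name}' selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())

    def volume_cc(self, grid: DoseGrid) -> float:
        """Structure volume in cc on the grid's lattice."""
        _check_congruent(grid, self)
        return self.n_voxels * grid.voxel_volume_mm3 / 1000.0


def _check_congruent(grid: DoseGrid, mask: StructureMask) -> None:
    if grid.values.shape != mask.include.shape:
        raise ValueError(
            f"grid shape {grid.values.shape} != mask shape {mask.include.shape}"
        )


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: % volume at-or-above each dose edge."""

    dose_edges: np.ndarray
    cum_volume_pct: np.ndarray
    structure: str = "structure"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_gy": self.dose_edges, "cum_volume_pct": self.cum_volume_pct}
        )


@dataclass
class DoseMetrics:
    """Dose-volume summary of one structure on one grid."""

    d_min: float
    d_max: float
    d_mean: float
    volume_cc: float
    v: dict[int, float] = field(default_factory=dict)
    fractionated_dose: float | None = None
    dose_kind: DoseKind = DoseKind.EQD2
    structure: str = "structure"

    def as_dict(self) -> dict:
        out = {
            "structure": self.structure,
            "dose_kind": self.dose_kind.value,
            "d_min_gy": self.d_min,
            "d_max_gy": self.d_max,
            "d_mean_gy": self.d_mean,
            "volume_cc": self.volume_cc,
            "fx_dose_gy": self.fractionated_dose,
        }
        out.update({f"v{x}": self.v[x] for x in sorted(self.v)})
        return out


def eqd2_voxel(total_dose, fraction_dose, params: RadiobiologyParams = RadiobiologyParams()):
    """EQD2 of a total dose ``D`` delivered at ``d`` Gy/fraction.

    Accepts scalars or arrays (broadcast). Identity when ``fraction_dose == 2``.
    """
    D = np.asarray(total_dose, dtype=float)
    d = np.asarray(fraction_dose, dtype=float)
    if np.any(~np.isfinite(D)) or np.any(D < 0):
        raise ValueError("total_dose must be finite and >= 0")
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("fraction_dose must be finite and >= 0")
    ab = params.alpha_beta
    out = D * (d + ab) / (2.0 + ab)
    return float(out) if out.ndim == 0 else out


def convert_to_eqd2(
    grid: DoseGrid,
    scheme: FractionationScheme,
    params: RadiobiologyParams = RadiobiologyParams(),
) -> DoseGrid:
    """Pixel-by-pixel EQD2 conversion of a physical dose grid.

    The per-voxel fraction dose is ``d_v = D_v / n_fractions``. Converting an
    already-converted grid is refused (double conversion is meaningless).
    """
    if grid.dose_kind is not DoseKind.PHYSICAL:
        raise ValueError("grid is already EQD2; refusing double conversion")
    d = grid.values / scheme.n_fractions
    values = eqd2_voxel(grid.values, d, params)
    return DoseGrid(values=values, spacing=grid.spacing, origin=grid.origin,
                    dose_kind=DoseKind.EQD2)


def cumulative_dvh(grid: DoseGrid, mask: StructureMask, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of the masked voxels.

    At each dose edge x the curve holds ``100 * #(dose >= x) / #voxels``;
    edges run from 0 to just past the structure Dmax in ``bin_width`` steps.
    """
    _check_congruent(grid, mask)
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    doses = grid.values[mask.include]
    d_max = float(doses.max())
    n_edges = int(np.floor(d_max / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    # vectorized threshold count: doses sorted, searchsorted per edge
    sorted_doses = np.sort(doses)
    n_below = np.searchsorted(sorted_doses, edges, side="left")
    cum_pct = 100.0 * (doses.size - n_below) / doses.size
    return DVHCurve(dose_edges=edges, cum_volume_pct=cum_pct, structure=mask.name)


def dose_metrics(
    grid: DoseGrid,
    mask: StructureMask,
    scheme: FractionationScheme | None = None,
    vx_levels: tuple[int, ...] = DEFAULT_VX_LEVELS,
    physical_d_mean: float | None = None,
) -> DoseMetrics:
    """Dmin/Dmax/Dmean, Vx, volume, and fractionated dose for one structure.

    All statistics come from the raw masked voxel doses. Vx uses the
    inclusive convention (dose >= x Gy). The fractionated-dose metric is
    the mean *physical* dose per fraction: taken from the grid itself when
    it is physical, or from ``physical_d_mean`` when the grid is EQD2 (it
    cannot be recovered from converted voxel values).
    """
    _check_congruent(grid, mask)
    doses = grid.values[mask.include]
    v = {int(x): 100.0 * int(np.count_nonzero(doses >= x)) / doses.size
         for x in vx_levels}
    fx = None
    if scheme is not None:
        if grid.dose_kind is DoseKind.PHYSICAL:
            fx = float(doses.mean() / scheme.n_fractions)
        elif physical_d_mean is not None:
            fx = float(physical_d_mean / scheme.n_fractions)
    return DoseMetrics(
        d_min=float(doses.min()),
        d_max=float(doses.max()),
        d_mean=float(doses.mean()),
        volume_cc=mask.volume_cc(grid),
        v=v,
        fractionated_dose=fx,
        dose_kind=grid.dose_kind,
        structure=mask.name,
    )
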