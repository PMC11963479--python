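"""Reduction of raw hydraulic / physiological measurements to the
summary quantities used downstream.

Covers: pressure-driven rock conductivity from timed mass collections,
gravimetric porosity, root hydraulic conductivity and leaf-normalised
conductance, relative electrolyte leakage, relative growth rates, and
plant-available water content derived from a retention curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constitutive import RHO_WATER, VGMBimodalParams, water_content
from .errors import MeasurementError

__all__ = [
    "FlowRecord",
    "RootMeasurement",
    "LeakageRecord",
    "GrowthRecord",
    "RockConductivityResult",
    "rock_conductivity",
    "gravimetric_porosity",
    "root_conductivity",
    "leaf_normalized_conductance",
    "relative_electrolyte_leakage",
    "growth_summaries",
    "available_water_content",
    "read_flow_records",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise MeasurementError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class FlowRecord:
    """One timed water-mass collection from a perfused sample.

    Attributes
    ----------
    delta_m: collected water mass over the interval (kg)
    delta_t: collection interval (s)
    t_start: start of the interval, seconds since the session began
    L: sample length along the flow direction (m)
    A: sample cross-sectional area (m2)
    P: applied pressure (MPa)
    sample_id: optional grouping key for per-sample statistics
    """

    delta_m: float
    delta_t: float
    t_start: float
    L: float
    A: float
    P: float
    sample_id: str | None = None

    def __post_init__(self) -> None:
        _require_positive(
            delta_m=self.delta_m, delta_t=self.delta_t, L=self.L, A=self.A, P=self.P
        )
        if self.t_start < 0:
            raise MeasurementError("t_start must be >= 0")

    @property
    def conductivity(self) -> float:
        """Per-record conductivity (delta_m * L) / (delta_t * A * P)."""
        return (self.delta_m * self.L) / (self.delta_t * self.A * self.P)


@dataclass(frozen=True)
class RootMeasurement:
    """Whole-root-system hydraulics plus the scan-derived normalisers."""

    K: float  # root hydraulic conductance, kg s-1 MPa-1
    L_root: float  # total root length, m
    A_root: float  # root surface area, m2
    A_leaf: float  # total leaf area, m2

    def __post_init__(self) -> None:
        _require_positive(
            K=self.K, L_root=self.L_root, A_root=self.A_root, A_leaf=self.A_leaf
        )


@dataclass(frozen=True)
class LeakageRecord:
    """Electrical-conductivity pair of the electrolyte-leakage assay."""

    EC_i: float  # initial conductivity, uS cm-1
    EC_f: float  # final conductivity after freeze-thaw, uS cm-1

    def __post_init__(self) -> None:
        if not self.EC_i > 0:
            raise MeasurementError("EC_i must be > 0 (bathed tissue conducts)")
        if self.EC_f < self.EC_i:
            raise MeasurementError("EC_f must be >= EC_i")


@dataclass(frozen=True)
class GrowthRecord:
    """Paired initial/final size and biomass measurements of one sapling."""

    h0: float
    h1: float
    d0: float
    d1: float
    mass_above: float  # dry above-ground biomass, g
    mass_below: float  # dry below-ground biomass, g

    def __post_init__(self) -> None:
        _require_positive(
            h0=self.h0,
            h1=self.h1,
            d0=self.d0,
            d1=self.d1,
            mass_above=self.mass_above,
            mass_below=self.mass_below,
        )


@dataclass(frozen=True)
class RockConductivityResult:
    """Summary of a rock-conductivity session.

    ``sd_records`` is the standard deviation across retained individual
    collection intervals; ``sd_samples`` (if sample ids were provided)
    is the standard deviation across per-sample means — both views are
    reported because summary statistics in the literature rarely state
    which was used.
    """

    mean: float
    sd_records: float
    n_retained: int
    values: tuple[float, ...]
    sample_means: dict[str, float] | None = None
    sd_samples: float | None = None


def rock_conductivity(
    records: Iterable[FlowRecord], stabilization_s: float = 1800.0
) -> RockConductivityResult:
    """Saturated rock hydraulic conductivity from timed collections.

    Each retained record yields ``k = (delta_m * L) / (delta_t * A * P)``
    (kg m-1 s-1 MPa-1); records starting before ``stabilization_s``
    (default 30 min) are discarded as flow-stabilisation transient.
    """
    records = list(records)
    retained = [r for r in records if r.t_start >= stabilization_s]
    if not retained:
        raise MeasurementError(
            f"no records at or after the {stabilization_s:.0f} s "
            "stabilization cut-off"
        )
    values = np.array([r.conductivity for r in retained])
    sample_means = None
    sd_samples = None
    ids = {r.sample_id for r in retained}
    if ids != {None}:
        groups: dict[str, list[float]] = {}
        for r in retained:
            groups.setdefault(str(r.sample_id), []).append(r.conductivity)
        sample_means = {k: float(np.mean(v)) for k, v in groups.items()}
        if len(sample_means) > 1:
            sd_samples = float(np.std(list(sample_means.values()), ddof=1))
    return RockConductivityResult(
        mean=float(values.mean()),
        sd_records=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_retained=len(retained),
        values=tuple(values),
        sample_means=sample_means,
        sd_samples=sd_samples,
    )


def gravimetric_porosity(
    m_sat: float, m_dry: float, V: float, rho_w: float = RHO_WATER
) -> float:
    """Porosity (%) from saturated/dry masses of a sample of volume V (m3).

    The pore volume is the mass of imbibed water divided by the water
    density: ``100 * ((m_sat - m_dry) / rho_w) / V``.
    """
    if V <= 0:
        raise MeasurementError("sample volume must be > 0")
    if m_sat < m_dry:
        raise MeasurementError("saturated mass below dry mass")
    porosity = 100.0 * ((m_sat - m_dry) / rho_w) / V
    if porosity > 100.0 + 1e-9:
        raise MeasurementError(f"implied porosity {porosity:.1f}% exceeds 100%")
    return porosity


def root_conductivity(m: RootMeasurement) -> float:
    """Root hydraulic conductivity k_root = K * L_root / A_root
    (kg s-1 m-1 MPa-1), normalising whole-system conductance by the
    mean path length per unit absorbing surface."""
    return m.K * m.L_root / m.A_root


def leaf_normalized_conductance(m: RootMeasurement) -> float:
    """Leaf-area-normalised root conductance K_root = K / A_leaf
    (kg s-1 m-2 MPa-1)."""
    return m.K / m.A_leaf


def relative_electrolyte_leakage(r: LeakageRecord) -> float:
    """Relative electrolyte leakage REL = 100 * EC_i / EC_f (%).

    100% means the initial bath already carried every electrolyte the
    tissue can release (fully disrupted membranes)."""
    return 100.0 * r.EC_i / r.EC_f


def growth_summaries(g: GrowthRecord) -> dict[str, float]:
    """Relative growth rates (%) in height and basal diameter, plus the
    below/above-ground dry-biomass ratio."""
    return {
        "RGRH": 100.0 * (g.h1 - g.h0) / g.h0,
        "RGRD": 100.0 * (g.d1 - g.d0) / g.d0,
        "root_shoot": g.mass_below / g.mass_above,
    }


def available_water_content(
    params: VGMBimodalParams,
    psi_fc: float = -0.033,
    psi_pwp: float = -1.5,
    bulk_density: float = 1.08,
) -> float:
    """Plant-available water content (g water per g dry soil).

    Difference between the volumetric water content at field capacity
    (default -0.033 MPa) and at the permanent wilting point (-1.5 MPa),
    converted to a gravimetric basis with the soil bulk density
    (g cm-3); water density is taken as 1 g cm-3.
    """
    if not psi_pwp < psi_fc < 0:
        raise MeasurementError(
            f"require psi_pwp < psi_fc < 0, got psi_fc={psi_fc}, psi_pwp={psi_pwp}"
        )
    if bulk_density <= 0:
        raise MeasurementError("bulk_density must be > 0")
    dtheta = water_content(psi_fc, params) - water_content(psi_pwp, params)
    return dtheta / bulk_density


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

FLOW_COLUMNS = ("delta_m_kg", "delta_t_s", "t_start_s", "L_m", "A_m2", "P_MPa")


def read_flow_records(path) -> list[FlowRecord]:
    """Read a CSV of flow records.

    Required columns: ``delta_m_kg, delta_t_s, t_start_s, L_m, A_m2,
    P_MPa``; optional ``sample_id``.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementError(f"flow-record table missing columns: {missing}")
    has_id = "sample_id" in df.columns
    return [
        FlowRecord(
            delta_m=row.delta_m_kg,
            delta_t=row.delta_t_s,
            t_start=row.t_start_s,
            L=row.L_m,
            A=row.A_m2,
            P=row.P_MPa,
            sample_id=str(row.sample_id) if has_id else None,
        )
        for row in df.itertuples()
    ]


def cylinder_volume(length_m: float, diameter_m: float) -> float:
    """Volume (m3) of a cylindrical core sample."""
    _require_positive(length_m=length_m, diameter_m=diameter_m)
    return length_m * math.pi * (diameter_m / 2.0) ** 2
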