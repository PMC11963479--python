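"""Bimodal van Genuchten–Mualem constitutive relations for variably
saturated flow.

Water retention and unsaturated hydraulic conductivity follow the
bimodal (two pore-size mode) form of Durner, closed with the Mualem
conductivity model:

    Se(psi)  = sum_i w_i [1 + (alpha_i |psi|)^{n_i}]^{-m_i},   m_i = 1 - 1/n_i
    theta    = theta_r + (theta_s - theta_r) Se
    k(psi)   = Ks * Se^tau
               * [sum_i w_i alpha_i (1 - (1 - Se_i^{1/m_i})^{m_i})]^2
               / [sum_i w_i alpha_i]^2

Conventions: water potential ``psi`` is in MPa and is <= 0 in the
unsaturated range (0 at saturation); conductivities are carried in
kg m-1 s-1 MPa-1 throughout, the unit natural to plant-hydraulics
instrumentation.  Setting ``w1 = 1`` recovers the classical unimodal
van Genuchten–Mualem model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import CalibrationError, DomainError, ParameterError

__all__ = [
    "VGMBimodalParams",
    "effective_saturation",
    "water_content",
    "capacity",
    "unsaturated_conductivity",
    "calibrate",
    "psi_to_pF",
    "VGMMaterial",
    "ConstantKMaterial",
    "LinearMaterial",
]

#: density of water (kg m-3) used in unit conversions
RHO_WATER = 1000.0
#: gravitational acceleration (m s-2) used in the pF conversion
GRAVITY = 9.81


@dataclass(frozen=True)
class VGMBimodalParams:
    """Parameter set of the bimodal retention/conductivity model for one
    material.

    Attributes
    ----------
    theta_r, theta_s:
        Residual and saturated volumetric water content (m3 m-3).
    w1, w2:
        Weights of the two pore-size modes; must sum to 1.
    alpha1, alpha2:
        Inverse air-entry values of the modes (MPa-1).
    n1, n2:
        Shape exponents (> 1); ``m_i = 1 - 1/n_i`` is implied.
    Ks:
        Saturated hydraulic conductivity (kg m-1 s-1 MPa-1).
    tau:
        Mualem tortuosity/connectivity exponent (default 0.5).
    label:
        Material name, carried through for reporting.
    """

    theta_r: float
    theta_s: float
    w1: float
    w2: float
    alpha1: float
    alpha2: float
    n1: float
    n2: float
    Ks: float
    tau: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_r < self.theta_s <= 1.0:
            raise ParameterError(
                f"require 0 <= theta_r < theta_s <= 1, got "
                f"theta_r={self.theta_r}, theta_s={self.theta_s}"
            )
        if self.w1 < 0 or self.w2 < 0 or abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ParameterError(
                f"modal weights must be non-negative and sum to 1, got "
                f"w1={self.w1}, w2={self.w2}"
            )
        for name in ("alpha1", "alpha2"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("n1", "n2"):
            if getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be > 1")
        if self.Ks <= 0:
            raise ParameterError("Ks must be > 0")

    @property
    def m1(self) -> float:
        return 1.0 - 1.0 / self.n1

    @property
    def m2(self) -> float:
        return 1.0 - 1.0 / self.n2


def _check_psi(psi: np.ndarray) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0):
        raise DomainError("water potential must be <= 0 MPa in the unsaturated range")
    return psi


def _modal_se(psi: np.ndarray, alpha: float, n: float) -> np.ndarray:
    """Effective saturation of a single van Genuchten mode."""
    m = 1.0 - 1.0 / n
    return (1.0 + (alpha * np.abs(psi)) ** n) ** (-m)


def effective_saturation(psi, params: VGMBimodalParams):
    """Effective saturation Se(psi) in [0, 1].

    ``psi`` may be a scalar or array of water potentials (MPa, <= 0).
    """
    psi = _check_psi(psi)
    se = params.w1 * _modal_se(psi, params.alpha1, params.n1) + params.w2 * _modal_se(
        psi, params.alpha2, params.n2
    )
    return se if se.ndim else float(se)


def water_content(psi, params: VGMBimodalParams):
    """Volumetric water content theta(psi) (m3 m-3)."""
    se = effective_saturation(psi, params)
    return params.theta_r + (params.theta_s - params.theta_r) * se


def capacity(psi, params: VGMBimodalParams):
    """Specific moisture capacity C = d(theta)/d(psi) (MPa-1), analytic.

    Positive for psi < 0 (theta increases with psi) and zero at
    saturation for n > 1.
    """
    psi = _check_psi(psi)
    h = np.abs(psi)
    c = np.zeros_like(h)
    for w, alpha, n in (
        (params.w1, params.alpha1, params.n1),
        (params.w2, params.alpha2, params.n2),
    ):
        if w == 0.0:
            continue
        m = 1.0 - 1.0 / n
        ah = alpha * h
        c = c + w * m * n * alpha * ah ** (n - 1.0) * (1.0 + ah**n) ** (-m - 1.0)
    c = (params.theta_s - params.theta_r) * c
    return c if c.ndim else float(c)


def _mualem_factor(se: np.ndarray, m: float) -> np.ndarray:
    """Mualem pore-connectivity factor 1 - (1 - Se^{1/m})^m per mode."""
    # clip guards the Se -> 1 branch against round-off above 1
    se = np.clip(se, 0.0, 1.0)
    return 1.0 - (1.0 - se ** (1.0 / m)) ** m


def unsaturated_conductivity(psi, params: VGMBimodalParams):
    """Unsaturated hydraulic conductivity k(psi) (kg m-1 s-1 MPa-1)."""
    psi = _check_psi(psi)
    se1 = _modal_se(psi, params.alpha1, params.n1)
    se2 = _modal_se(psi, params.alpha2, params.n2)
    se = params.w1 * se1 + params.w2 * se2
    num = params.w1 * params.alpha1 * _mualem_factor(se1, params.m1) + (
        params.w2 * params.alpha2 * _mualem_factor(se2, params.m2)
    )
    den = params.w1 * params.alpha1 + params.w2 * params.alpha2
    k = params.Ks * se**params.tau * (num / den) ** 2
    return k if k.ndim else float(k)


def psi_to_pF(psi) -> float:
    """Convert water potential (MPa, < 0) to pF = log10(|psi| in cm head).

    1 MPa corresponds to 1e6 / (rho_w g) m of water head; -1.5 MPa gives
    pF 4.18, the conventional permanent-wilting-point line.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi >= 0):
        raise DomainError("pF is defined for strictly negative water potential")
    head_cm = np.abs(psi) * 1e6 / (RHO_WATER * GRAVITY) * 100.0
    pf = np.log10(head_cm)
    return pf if pf.ndim else float(pf)


# ---------------------------------------------------------------------------
# calibration from summary anchors
# ---------------------------------------------------------------------------


def _validate_anchors(anchors: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    anchors = [(float(p), float(t)) for p, t in anchors]
    if len(anchors) < 1:
        raise CalibrationError("at least one anchor (psi, theta) is required")
    if any(p > 0 for p, _ in anchors):
        raise CalibrationError("anchor water potentials must be <= 0 MPa")
    anchors.sort(key=lambda pt: abs(pt[0]))
    for (p0, t0), (p1, t1) in zip(anchors, anchors[1:]):
        if abs(p1) > abs(p0) and t1 > t0 + 1e-12:
            raise CalibrationError(
                f"anchors not monotone: theta({p1}) = {t1} exceeds "
                f"theta({p0}) = {t0} at a drier potential"
            )
        if abs(p1) == abs(p0):
            raise CalibrationError(f"duplicate anchor potential psi = {p0}")
    return anchors


def _se_from_theta(theta: float, theta_r: float, theta_s: float) -> float:
    se = (theta - theta_r) / (theta_s - theta_r)
    if not 0.0 < se < 1.0:
        raise CalibrationError(
            f"anchor theta = {theta} outside the open interval "
            f"({theta_r}, {theta_s}) set by theta_r/theta_s"
        )
    return se


def _alpha_for(se: float, h: float, n: float) -> float:
    """Inverse air entry making a unimodal mode pass through (h, Se)."""
    m = 1.0 - 1.0 / n
    return (se ** (-1.0 / m) - 1.0) ** (1.0 / n) / h


def calibrate(
    anchors: Sequence[tuple[float, float]],
    Ks: float,
    *,
    theta_r: float = 0.0,
    theta_s: float | None = None,
    porosity_cap: float | None = None,
    n_default: float = 2.0,
    fixed_mode2: tuple[float, float, float] | None = None,
    tau: float = 0.5,
    label: str = "",
    anchor_tol: float = 1e-3,
) -> VGMBimodalParams:
    """Fit a (bi)modal retention parameter set through summary anchors.

    Stands in for a laboratory retention-curve fit when only summary
    values (saturated conductivity, water content at a few potentials)
    are available.

    Parameters
    ----------
    anchors:
        ``(psi, theta_v)`` pairs, psi in MPa (<= 0).  An anchor at
        psi = 0 pins ``theta_s``.  theta must be non-increasing in |psi|.
    Ks:
        Saturated conductivity, reproduced exactly.
    theta_r, theta_s:
        Fixed residual content and (if no psi = 0 anchor) saturated
        content.  ``porosity_cap`` may supply theta_s instead.
    n_default:
        Shape exponent used when a single interior anchor leaves the
        shape free (the anchor then determines alpha in closed form).
    fixed_mode2:
        Optional ``(w2, alpha2, n2)`` pinning the second (slow) pore
        mode; the first mode is then solved through the anchors.  Used
        when the late-draining matrix mode is known or chosen a priori
        and only the macropore mode needs fitting.

    Returns
    -------
    VGMBimodalParams reproducing every anchor within ``anchor_tol`` in
    theta and ``Ks`` exactly.
    """
    if Ks <= 0:
        raise CalibrationError("Ks must be > 0")
    anchors = _validate_anchors(anchors)

    sat = [t for p, t in anchors if p == 0.0]
    interior = [(p, t) for p, t in anchors if p < 0.0]
    if sat:
        theta_s_eff = sat[0]
    elif theta_s is not None:
        theta_s_eff = float(theta_s)
    elif porosity_cap is not None:
        theta_s_eff = float(porosity_cap)
    else:
        raise CalibrationError(
            "theta_s is undetermined: provide a psi = 0 anchor, theta_s, "
            "or porosity_cap"
        )
    if porosity_cap is not None and theta_s_eff > porosity_cap + 1e-12:
        raise CalibrationError(
            f"theta_s = {theta_s_eff} exceeds porosity cap {porosity_cap}"
        )
    if not interior:
        raise CalibrationError("at least one anchor with psi < 0 is required")

    se_targets = [
        (abs(p), _se_from_theta(t, theta_r, theta_s_eff)) for p, t in interior
    ]

    def unimodal(alpha: float, n: float) -> VGMBimodalParams:
        return VGMBimodalParams(
            theta_r=theta_r,
            theta_s=theta_s_eff,
            w1=1.0,
            w2=0.0,
            alpha1=alpha,
            alpha2=alpha,
            n1=n,
            n2=n,
            Ks=Ks,
            tau=tau,
            label=label,
        )

    params: VGMBimodalParams | None = None
    if fixed_mode2 is not None:
        w2, alpha2, n2 = fixed_mode2
        if not 0.0 < w2 < 1.0:
            raise CalibrationError("fixed mode-2 weight must be in (0, 1)")
        m2 = 1.0 - 1.0 / n2
        hs = np.array([h for h, _ in se_targets])
        ses = np.array([s for _, s in se_targets])
        se2 = (1.0 + (alpha2 * hs) ** n2) ** (-m2)

        def resid1(x: np.ndarray) -> np.ndarray:
            a1, n1 = np.exp(x[0]), 1.0 + np.exp(x[1])
            m1 = 1.0 - 1.0 / n1
            se1 = (1.0 + (a1 * hs) ** n1) ** (-m1)
            return (1.0 - w2) * se1 + w2 * se2 - ses

        x0 = np.array([np.log(1.0 / hs.min()), 0.0])
        sol = optimize.least_squares(resid1, x0, method="lm", max_nfev=20000)
        params = VGMBimodalParams(
            theta_r=theta_r,
            theta_s=theta_s_eff,
            w1=1.0 - w2,
            w2=w2,
            alpha1=float(np.exp(sol.x[0])),
            alpha2=float(alpha2),
            n1=1.0 + float(np.exp(sol.x[1])),
            n2=float(n2),
            Ks=Ks,
            tau=tau,
            label=label,
        )
    elif len(se_targets) == 1:
        h, se = se_targets[0]
        params = unimodal(_alpha_for(se, h, n_default), n_default)
    elif len(se_targets) == 2:
        # exact 2x2 solve: alpha follows from the wetter anchor for any n,
        # a 1D root in n matches the drier one
        (h1, se1), (h2, se2) = se_targets

        def resid(n: float) -> float:
            alpha = _alpha_for(se1, h1, n)
            m = 1.0 - 1.0 / n
            return (1.0 + (alpha * h2) ** n) ** (-m) - se2

        ns = np.linspace(1.02, 12.0, 400)
        vals = np.array([resid(n) for n in ns])
        sign = np.sign(vals)
        idx = np.where(np.diff(sign) != 0)[0]
        if idx.size:
            n_fit = optimize.brentq(resid, ns[idx[0]], ns[idx[0] + 1], xtol=1e-12)
            params = unimodal(_alpha_for(se1, h1, n_fit), n_fit)

    if params is None:
        # general case: bimodal least squares in transformed coordinates
        hs = np.array([h for h, _ in se_targets])
        ses = np.array([s for _, s in se_targets])

        def model(x: np.ndarray) -> np.ndarray:
            w1 = 1.0 / (1.0 + np.exp(-x[0]))
            a1, a2 = np.exp(x[1]), np.exp(x[2])
            n1, n2 = 1.0 + np.exp(x[3]), 1.0 + np.exp(x[4])
            m1, m2 = 1.0 - 1.0 / n1, 1.0 - 1.0 / n2
            return w1 * (1.0 + (a1 * hs) ** n1) ** (-m1) + (1.0 - w1) * (
                1.0 + (a2 * hs) ** n2
            ) ** (-m2)

        x0 = np.array([0.0, np.log(1.0 / hs.min()), np.log(1.0 / hs.max()), 0.0, 0.0])
        sol = optimize.least_squares(
            lambda x: model(x) - ses, x0, method="lm", max_nfev=20000
        )
        w1 = 1.0 / (1.0 + np.exp(-sol.x[0]))
        params = VGMBimodalParams(
            theta_r=theta_r,
            theta_s=theta_s_eff,
            w1=w1,
            w2=1.0 - w1,
            alpha1=float(np.exp(sol.x[1])),
            alpha2=float(np.exp(sol.x[2])),
            n1=1.0 + float(np.exp(sol.x[3])),
            n2=1.0 + float(np.exp(sol.x[4])),
            Ks=Ks,
            tau=tau,
            label=label,
        )

    for p, t in anchors:
        err = abs(water_content(p, params) - t)
        if err > anchor_tol:
            raise CalibrationError(
                f"calibrated curve misses anchor (psi={p}, theta={t}) "
                f"by {err:.2e} (> {anchor_tol})"
            )
    return params


# ---------------------------------------------------------------------------
# material wrappers consumed by the flow solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VGMMaterial:
    """Hydraulic material closing the Richards equation with the bimodal
    van Genuchten–Mualem relations."""

    params: VGMBimodalParams

    @property
    def theta_r(self) -> float:
        return self.params.theta_r

    @property
    def theta_s(self) -> float:
        return self.params.theta_s

    def water_content(self, psi):
        return water_content(psi, self.params)

    def capacity(self, psi):
        return capacity(psi, self.params)

    def conductivity(self, psi):
        return unsaturated_conductivity(psi, self.params)


@dataclass(frozen=True)
class ConstantKMaterial(VGMMaterial):
    """Material with potential-independent conductivity.

    Used for root tissue: a single measured root conductivity is carried
    across the whole potential range, while retention follows the
    wrapped parameter set (typically near-rigid, so the root stores
    negligible water).  Swap in a plain :class:`VGMMaterial` to make the
    root conductivity potential-dependent.
    """

    def conductivity(self, psi):
        psi = np.asarray(psi, dtype=float)
        k = np.full_like(psi, self.params.Ks)
        return k if k.ndim else float(k)


@dataclass(frozen=True)
class LinearMaterial:
    """Idealized medium with constant conductivity and linear retention,
    for which the Richards equation reduces to linear diffusion.

    Used to verify the numerical solver against closed-form series
    solutions; not meant to represent a physical soil.
    """

    k: float
    c: float  # d(theta)/d(psi), MPa-1
    theta_at_zero: float
    theta_r: float = 0.0
    theta_s: float = 1.0

    def water_content(self, psi):
        psi = np.asarray(psi, dtype=float)
        th = self.theta_at_zero + self.c * psi
        return th if th.ndim else float(th)

    def capacity(self, psi):
        psi = np.asarray(psi, dtype=float)
        c = np.full_like(psi, self.c)
        return c if c.ndim else float(c)

    def conductivity(self, psi):
        psi = np.asarray(psi, dtype=float)
        k = np.full_like(psi, self.k)
        return k if k.ndim else float(k)


def as_material(obj, *, constant_k: bool = False):
    """Coerce a parameter set or material object to the material protocol."""
    if isinstance(obj, VGMBimodalParams):
        return ConstantKMaterial(obj) if constant_k else VGMMaterial(obj)
    if hasattr(obj, "water_content") and hasattr(obj, "conductivity"):
        return obj
    raise ParameterError(f"cannot interpret {obj!r} as a hydraulic material")
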