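"""Closed-form physics of the coflow viscometer chip.

The chip carries a test fluid (blood) and a reference fluid (1x PBS) side by
side through a shallow rectangular channel.  Treating the coflow interface as
a rigid "virtual wall" splits the channel into two parallel resistive
conduits with a common pressure drop, which yields a closed-form expression
for the test-fluid viscosity from the normalized interface position alpha_b,
the two delivered flow rates, and an empirical correction factor Cf(alpha_b)
that absorbs the virtual-wall model error.

Canonical internal units: mm for lengths, s for time, cP for viscosity.
Flow rates are accepted in mL/h at the API boundary and converted to mm^3/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: 1 mL/h expressed in mm^3/s.
ML_H_TO_MM3_S = 1000.0 / 3600.0


class DomainError(ValueError):
    """An input lies outside the physically/empirically valid domain."""


class DegenerateFlowError(ValueError):
    """A flow configuration that makes the requested quantity undefined."""


class OutOfRangeError(ValueError):
    """No interface position inside the correction-factor domain matches."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Roi:
    """Half-open pixel rectangle, 0-based, origin at the top-left corner.

    Rows run across the channel width (the cross-channel, "vertical"
    direction); columns run along the flow direction.
    """

    top: int
    bottom: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.bottom > self.top >= 0 and self.right > self.left >= 0):
            raise ValueError(f"degenerate ROI {self}")

    @property
    def rows(self) -> slice:
        return slice(self.top, self.bottom)

    @property
    def cols(self) -> slice:
        return slice(self.left, self.right)

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def area_px(self) -> int:
        return self.height * self.width

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.rows, self.cols]

    def within(self, shape: tuple[int, int]) -> bool:
        return self.bottom <= shape[0] and self.right <= shape[1]


@dataclass(frozen=True)
class Segment:
    """One straight rectangular channel segment of the resistance network."""

    length_mm: float
    width_mm: float
    depth_mm: float

    def __post_init__(self) -> None:
        if min(self.length_mm, self.width_mm, self.depth_mm) <= 0:
            raise DomainError(f"non-positive segment dimension: {self}")


#: Blood path of the default chip: narrow inlet channel, main chamber,
#: narrow connector, wide channel (lengths/widths in mm, uniform depth).
DEFAULT_BLOOD_SEGMENTS: tuple[Segment, ...] = (
    Segment(4.9, 0.1, 0.05),
    Segment(3.0, 1.0, 0.05),
    Segment(8.8, 0.1, 0.05),
    Segment(14.5, 1.0, 0.05),
)


@dataclass(frozen=True)
class ChipGeometry:
    """Channel dimensions, tubing, pixel scale and the three analysis ROIs.

    Defaults describe a chip with 1 mm wide chambers of uniform 0.05 mm
    depth, 0.1 mm narrow connectors, and 1.8 mm^2 ROIs imaged at 5 um/px
    (200 px across the channel, 360 px along it).
    """

    width_mm: float = 1.0
    depth_mm: float = 0.05
    narrow_width_mm: float = 0.1
    segments: tuple[Segment, ...] = DEFAULT_BLOOD_SEGMENTS
    tubing_id_mm: float = 0.25
    tubing_length_mm: float = 300.0
    pixel_scale_um: float = 5.0
    frame_shape: tuple[int, int] = (760, 400)
    roi_mc: Roi = field(default_factory=lambda: Roi(40, 240, 20, 380))
    roi_ac: Roi = field(default_factory=lambda: Roi(280, 480, 20, 380))
    roi_vc: Roi = field(default_factory=lambda: Roi(520, 720, 20, 380))

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "narrow_width_mm",
                     "tubing_id_mm", "tubing_length_mm", "pixel_scale_um"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.depth_mm > self.width_mm:
            raise DomainError("low-aspect assumption requires depth <= width")
        for roi in (self.roi_mc, self.roi_ac, self.roi_vc):
            if not roi.within(self.frame_shape):
                raise DomainError(f"ROI {roi} outside frame {self.frame_shape}")

    @property
    def width_px(self) -> int:
        """Channel width expressed in pixels."""
        return int(round(self.width_mm * 1000.0 / self.pixel_scale_um))

    @property
    def cross_section_mm2(self) -> float:
        return self.width_mm * self.depth_mm


@dataclass(frozen=True)
class FluidProperties:
    """Viscosities of the reference fluid and, when known, the test fluid."""

    mu_r_cP: float = 1.0
    mu_b_cP: float | None = None

    def __post_init__(self) -> None:
        if self.mu_r_cP <= 0 or (self.mu_b_cP is not None and self.mu_b_cP <= 0):
            raise DomainError("viscosities must be > 0")


@dataclass(frozen=True)
class FlowState:
    """Delivered and branch flow rates (mL/h); enforces Qvc = Qb - Qac."""

    q_b: float
    q_r: float
    q_mc: float
    q_ac: float
    q_vc: float

    def __post_init__(self) -> None:
        if min(self.q_b, self.q_r, self.q_mc, self.q_ac, self.q_vc) < 0:
            raise DomainError("flow rates must be >= 0")
        if abs(self.q_vc - (self.q_b - self.q_ac)) > 1e-12:
            raise DomainError("Qvc must equal Qb - Qac")


@dataclass(frozen=True)
class CorrectionFactorModel:
    """Empirical quartic Cf(alpha_b) compensating the virtual-wall error.

    The default coefficients were calibrated for a 1 mm x 0.05 mm channel.
    The polynomial is a fit and extrapolates badly, so evaluation outside
    ``domain`` raises instead of clamping.
    """

    coefficients: tuple[float, float, float, float, float] = (
        -12.038, 26.171, -20.770, 7.156, 0.014)
    domain: tuple[float, float] = (0.05, 0.95)

    def __call__(self, alpha_b: float) -> float:
        return correction_factor(alpha_b, self)


DEFAULT_CF = CorrectionFactorModel()


@dataclass(frozen=True)
class ResistanceNetwork:
    """Equivalent branch resistances at the ac/vc junction (cP * mm^-3)."""

    r_ac_branch: float
    r_vc_branch: float

    def __post_init__(self) -> None:
        if self.r_ac_branch <= 0 or self.r_vc_branch <= 0:
            raise DomainError("branch resistances must be > 0")


def network_from_split_fraction(ac_fraction: float) -> ResistanceNetwork:
    """Network whose current divider sends ``ac_fraction`` of Qb into ac."""
    if not 0 < ac_fraction < 1:
        raise DomainError("split fraction must lie in (0, 1)")
    return ResistanceNetwork(r_ac_branch=1.0 - ac_fraction,
                             r_vc_branch=ac_fraction)


#: Default junction split: 5% of the delivered blood enters the
#: aggregation-sensing channel (the measured split for blood in this chip).
DEFAULT_NETWORK = network_from_split_fraction(0.05)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def rectangular_channel_resistance(length_mm: float, width_mm: float,
                                   depth_mm: float, viscosity_cP: float) -> float:
    """Hydraulic resistance of a shallow rectangular channel.

    Single-term aspect-corrected form R = 12 mu L / (w h^3 (1 - 0.63 h/w)),
    accurate to <1% for h/w <= 0.05.  Units: cP * mm^-3 for flow in mm^3/s.
    """
    if min(length_mm, width_mm, depth_mm, viscosity_cP) <= 0:
        raise DomainError("all resistance inputs must be > 0")
    if depth_mm > width_mm:
        raise DomainError("formula assumes depth <= width")
    aspect = 1.0 - 0.63 * depth_mm / width_mm
    return 12.0 * viscosity_cP * length_mm / (width_mm * depth_mm**3 * aspect)


def segment_resistance(segments, viscosity_cP: float) -> float:
    """Series resistance of a list of :class:`Segment`."""
    return sum(rectangular_channel_resistance(s.length_mm, s.width_mm,
                                              s.depth_mm, viscosity_cP)
               for s in segments)


def correction_factor(alpha_b: float,
                      model: CorrectionFactorModel = DEFAULT_CF) -> float:
    """Evaluate Cf(alpha_b) with the model's stored quartic coefficients."""
    lo, hi = model.domain
    if not lo <= alpha_b <= hi:
        raise DomainError(
            f"alpha_b={alpha_b:g} outside correction-factor domain [{lo}, {hi}]")
    c4, c3, c2, c1, c0 = model.coefficients
    return ((((c4 * alpha_b) + c3) * alpha_b + c2) * alpha_b + c1) * alpha_b + c0


def blood_viscosity(alpha_b: float, q_r: float, q_b: float, q_ac: float,
                    mu_r: float, model: CorrectionFactorModel = DEFAULT_CF) -> float:
    """Test-fluid viscosity from the coflow interface position.

    mu_b = mu_r * alpha_b/(1 - alpha_b) * Qr/(Qb - Qac) * Cf(alpha_b),
    with all flow rates in the same (arbitrary) units.
    """
    if mu_r <= 0 or q_r <= 0:
        raise DomainError("mu_r and Qr must be > 0")
    if q_b - q_ac <= 0:
        raise DegenerateFlowError("Qb must exceed Qac for a blood stream to exist")
    cf = correction_factor(alpha_b, model)
    if not 0 < alpha_b < 1:
        raise DomainError("alpha_b must lie strictly inside (0, 1)")
    return mu_r * (alpha_b / (1.0 - alpha_b)) * (q_r / (q_b - q_ac)) * cf


def _interface_gain(alpha_b: float, model: CorrectionFactorModel) -> float:
    """g(alpha) = alpha/(1-alpha) * Cf(alpha); strictly increasing on the domain."""
    return (alpha_b / (1.0 - alpha_b)) * correction_factor(alpha_b, model)


def interface_from_viscosity(mu_b: float, mu_r: float, q_r: float,
                             q_blood: float,
                             model: CorrectionFactorModel = DEFAULT_CF,
                             tol: float = 1e-10) -> float:
    """Invert the viscosity formula: the alpha_b that yields ``mu_b``.

    Solves g(alpha) = mu_b * Q_blood / (mu_r * Qr) by bisection on the
    correction-factor domain; the monotonicity of g makes the root unique.
    ``q_blood`` is the blood-stream flow in the sensing channel (Qb - Qac).
    """
    if min(mu_b, mu_r, q_r, q_blood) <= 0:
        raise DomainError("all inverse-model inputs must be > 0")
    target = mu_b * q_blood / (mu_r * q_r)
    lo, hi = model.domain
    f_lo = _interface_gain(lo, model) - target
    f_hi = _interface_gain(hi, model) - target
    if f_lo > 0 or f_hi < 0:
        raise OutOfRangeError(
            f"viscosity ratio unreachable at these flow rates: need g(alpha)="
            f"{target:g}, attainable range is [{f_lo + target:g}, {f_hi + target:g}]"
            f" on alpha in [{lo}, {hi}]; adjust Qr to relocate the interface")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _interface_gain(mid, model) - target
        if abs(f_mid) < tol * max(abs(target), 1.0) and (hi - lo) < 1e-12:
            return mid
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) < 1e-16:
            break
    return 0.5 * (lo + hi)


def shear_rate_rect(q_ml_h: float, width_mm: float, depth_mm: float) -> float:
    """Wall shear rate of a low-aspect rectangular channel: 6Q/(w h^2), s^-1."""
    if width_mm <= 0 or depth_mm <= 0:
        raise DomainError("channel dimensions must be > 0")
    if q_ml_h < 0:
        raise DomainError("flow rate must be >= 0")
    q = q_ml_h * ML_H_TO_MM3_S
    return 6.0 * q / (width_mm * depth_mm**2)


def shear_rate_viscosity_channel(q_b: float, q_ac: float, alpha_b: float,
                                 width_mm: float, depth_mm: float) -> float:
    """Shear rate of the blood stream in the viscosity-sensing channel.

    The blood stream of flow Qb - Qac occupies the fraction alpha_b of the
    channel width, so this is ``shear_rate_rect`` on the reduced width.
    """
    if not 0 < alpha_b <= 1:
        raise DomainError("alpha_b must lie in (0, 1]")
    if q_b <= q_ac or q_ac < 0:
        raise DegenerateFlowError("requires Qb > Qac >= 0")
    return shear_rate_rect(q_b - q_ac, alpha_b * width_mm, depth_mm)


def flow_split(network: ResistanceNetwork, q_b: float) -> tuple[float, float]:
    """Split Qb between the aggregation and viscosity branches.

    Current divider at the junction: Qac = Qb * Rvc / (Rac + Rvc).
    Returns (Qac, Qvc) with Qac + Qvc == Qb exactly.
    """
    if q_b < 0:
        raise DomainError("Qb must be >= 0")
    total = network.r_ac_branch + network.r_vc_branch
    if total <= 0:
        raise DegenerateFlowError("zero total branch resistance")
    q_ac = q_b * network.r_vc_branch / total
    return q_ac, q_b - q_ac


def transit_time(tubing_id_mm: float, tubing_length_mm: float,
                 q_ml_h: float) -> float:
    """Plug-flow transit time through the inlet tubing, in seconds."""
    if tubing_id_mm <= 0 or tubing_length_mm < 0:
        raise DomainError("tubing dimensions must be positive")
    if q_ml_h <= 0:
        raise DegenerateFlowError("no flow: transit time is infinite")
    volume_mm3 = math.pi * (tubing_id_mm / 2.0) ** 2 * tubing_length_mm
    return volume_mm3 / (q_ml_h * ML_H_TO_MM3_S)
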