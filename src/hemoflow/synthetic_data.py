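"""Ground-truthed synthetic timelapse renderer for the coflow chip.

Renders burst stacks of three horizontal channel bands — the main chamber
(mc), the aggregation-sensing chamber (ac) and the viscosity-sensing coflow
channel (vc) — under continuous, waiting-time, and on-off delivery
schedules.  The physics driving each trigger is the forward chain

    delivered Hct(t)  ->  phantom viscosity mu_b  ->  interface alpha_b
    (via the inverse coflow model)  ->  plug velocities  ->  rendered frames,

so every dataset ships with a ground-truth manifest against which the full
analysis pipeline can be checked in closed loop.

What is emulated: syringe sedimentation raising the delivered hematocrit
(faster while the pump is off), aggregation-induced intensity deficits in
the low-shear chamber, interface motion tracking viscosity, dark tracer
speckle advected between the two frames of each burst, and additive Gaussian
camera noise.  What is not: optical PSFs, individual cells, in-chip settling.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .chip_model import (
    ChipGeometry,
    CorrectionFactorModel,
    DEFAULT_CF,
    ML_H_TO_MM3_S,
    ResistanceNetwork,
    network_from_split_fraction,
    flow_split,
    interface_from_viscosity,
    shear_rate_rect,
    DomainError,
    OutOfRangeError,
)


class GenerationError(RuntimeError):
    """The requested scenario cannot be rendered consistently."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticBloodModel:
    """Phantom blood: hematocrit, aggregability and sedimentation behaviour.

    ``sed_amplitude`` is the asymptotic fractional rise of the delivered
    hematocrit; ``sed_tau_s`` its time constant; ``stasis_kappa`` the factor
    by which the sedimentation clock accelerates while delivery is off.
    ``fixed_viscosity_cP`` overrides the hematocrit-based phantom viscosity
    (used for Newtonian surrogate fluids such as glycerin).
    """

    hct0: float = 0.5
    cdex_mg_ml: float = 20.0
    aggregability: float = 1.0
    sed_amplitude: float = 0.2
    sed_tau_s: float = 600.0
    stasis_kappa: float = 4.0
    medium_slope_cP_per_mg_ml: float = 0.075
    fixed_viscosity_cP: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.hct0 < 0.8:
            raise DomainError("hct0 must lie in (0, 0.8)")
        if self.sed_amplitude < 0 or self.sed_tau_s <= 0:
            raise DomainError("sed_amplitude >= 0 and sed_tau_s > 0 required")
        if not 0 <= self.aggregability <= 1:
            raise DomainError("aggregability must lie in [0, 1]")
        if self.stasis_kappa < 1:
            raise DomainError("stasis_kappa must be >= 1")

    def medium_viscosity(self) -> float:
        """Suspension-medium viscosity, linear in dextran concentration."""
        return 1.0 + self.medium_slope_cP_per_mg_ml * self.cdex_mg_ml


@dataclass(frozen=True)
class SyntheticScenario:
    """Delivery schedule and acquisition timing for one synthetic run.

    ``schedule`` is an ordered list of ("on" | "off", duration_s) phases; an
    initial "off" phase models a no-delivery waiting time, alternating
    phases model pump on-off operation.  Triggers fire every
    ``trigger_period_s``; each captures ``burst_frames`` frames spaced
    ``burst_dt_s`` apart.  The seed is mandatory.
    """

    q_b_ml_h: float = 0.4
    q_r_ml_h: float = 1.8
    schedule: tuple[tuple[str, float], ...] = (("on", 60.0),)
    trigger_period_s: float = 1.0
    burst_frames: int = 2
    burst_dt_s: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise DomainError("an integer seed is mandatory")
        if self.q_b_ml_h <= 0 or self.q_r_ml_h <= 0:
            raise DomainError("flow rates must be > 0")
        if self.burst_frames < 2 or self.burst_dt_s <= 0:
            raise DomainError("bursts need >= 2 frames at positive spacing")
        for state, dur in self.schedule:
            if state not in ("on", "off"):
                raise DomainError(f"unknown schedule state {state!r}")
            if dur <= 0:
                raise DomainError("schedule durations must be positive")

    @property
    def duration_s(self) -> float:
        return sum(dur for _, dur in self.schedule)

    @property
    def n_triggers(self) -> int:
        return int(math.floor(self.duration_s / self.trigger_period_s))


@dataclass(frozen=True)
class RenderSettings:
    """Photometric and seeding parameters of the renderer.

    ``background_i0``: bright-field background level (8-bit).
    ``hct_attenuation``: intensity removed per unit hematocrit fraction.
    ``particle_density_mm2``: tracer speckle per mm^2 of channel area, dense
    enough for ~4+ tracers per 13 px interrogation window.
    """

    background_i0: float = 220.0
    hct_attenuation: float = 120.0
    particle_density_mm2: float = 1000.0
    particle_sigma_px: float = 1.2
    particle_amplitude: float = 40.0
    noise_sigma: float = 0.0
    stasis_agg_tau_s: float = 30.0

    def __post_init__(self) -> None:
        if self.background_i0 <= 0 or not 0 <= self.background_i0 <= 255:
            raise DomainError("background must lie in (0, 255]")
        if self.particle_density_mm2 < 0 or self.particle_sigma_px <= 0:
            raise DomainError("invalid particle settings")
        if self.noise_sigma < 0:
            raise DomainError("noise sigma must be >= 0")


@dataclass(frozen=True)
class TriggerState:
    """Ground truth for one trigger, consumed by :func:`render_burst`."""

    t_s: float
    delivering: bool
    hct: float
    mu_b_cP: float
    alpha_b: float
    u_mc_mm_s: float
    u_ac_mm_s: float
    ai_target: float
    mc_stasis_deficit: float = 0.0


@dataclass
class GroundTruthManifest:
    """Per-trigger ground truth plus a config echo; serialises to JSON."""

    seed: int
    config: dict
    records: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "config": self.config,
                       "records": self.records}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(seed=raw["seed"], config=raw["config"],
                   records=raw["records"])


# ---------------------------------------------------------------------------
# Forward physics
# ---------------------------------------------------------------------------


def _schedule_state(t: float, schedule) -> str:
    """Delivery state at time t; past the schedule end the last state holds."""
    elapsed = 0.0
    state = schedule[-1][0]
    for st, dur in schedule:
        if t < elapsed + dur:
            return st
        elapsed += dur
    return state


def _sedimentation_clock(t: float, schedule, kappa: float) -> float:
    """Effective settling time: rate 1 while delivering, ``kappa`` while off."""
    s = 0.0
    elapsed = 0.0
    for st, dur in schedule:
        span = min(dur, max(0.0, t - elapsed))
        if span <= 0:
            break
        s += span * (1.0 if st == "on" else kappa)
        elapsed += dur
    if t > elapsed:  # beyond schedule: last state persists
        s += (t - elapsed) * (1.0 if schedule[-1][0] == "on" else kappa)
    return s


def delivered_hematocrit(t: float, schedule, model: SyntheticBloodModel) -> float:
    """Hematocrit delivered at the chip inlet at time t.

    Syringe sedimentation concentrates the aspirated layer, so
    Hct(t) = Hct0 * (1 + a*A*(1 - exp(-s(t)/tau))) with the clock s(t)
    accelerated during no-delivery phases; capped at 0.8.
    """
    if t < 0:
        raise DomainError("t must be >= 0")
    s = _sedimentation_clock(t, schedule, model.stasis_kappa)
    rise = model.aggregability * model.sed_amplitude * (1.0 - math.exp(-s / model.sed_tau_s))
    return min(0.8, model.hct0 * (1.0 + rise))


def phantom_viscosity(hct: float, cdex_mg_ml: float,
                      medium_slope: float = 0.075) -> float:
    """Phantom suspension viscosity, cP.

    Krieger-Dougherty-type divergence in hematocrit on top of a medium
    viscosity linear in dextran concentration:
    mu = mu_medium(Cdex) * (1 - Hct/0.98)^(-2.5).
    """
    if hct < 0 or hct >= 0.98:
        raise DomainError("hct must lie in [0, 0.98)")
    if cdex_mg_ml < 0:
        raise DomainError("dextran concentration must be >= 0")
    mu_medium = 1.0 + medium_slope * cdex_mg_ml
    return mu_medium * (1.0 - hct / 0.98) ** (-2.5)


def phantom_aggregation_deficit(hct: float, cdex_mg_ml: float, a: float,
                                shear_s1: float, gain: float = 0.6) -> float:
    """Fractional intensity deficit in the aggregation chamber, in [0, 0.5].

    delta = gain * a * f_dex(Cdex) * (1 - Hct) * g(shear) with a unimodal
    dextran response peaking at 15 mg/mL and a deficit that decays with
    shear (aggregates break up at high shear; half-decay at 100 s^-1).
    """
    if not 0 <= a <= 1 or hct < 0 or cdex_mg_ml < 0 or shear_s1 < 0:
        raise DomainError("deficit inputs out of range")
    c_peak = 15.0
    f_dex = 0.0 if cdex_mg_ml == 0 else \
        (cdex_mg_ml / c_peak) * math.exp(1.0 - cdex_mg_ml / c_peak)
    g_shear = 1.0 / (1.0 + shear_s1 / 100.0)
    return float(np.clip(gain * a * f_dex * (1.0 - hct) * g_shear, 0.0, 0.5))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _channel_band(roi, frame_width: int) -> tuple[slice, int]:
    """Full-width channel band for a ROI: same rows, all columns."""
    return slice(roi.top, roi.bottom), frame_width


def _draw_particles(img: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                    amp: float, sigma: float, row0: int, row1: int) -> None:
    """Subtract Gaussian tracer blobs at float positions; x wraps periodically."""
    w = img.shape[1]
    r = int(math.ceil(3.0 * sigma))
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for x, y in zip(xs, ys):
        cx = int(math.floor(x))
        cy = int(math.floor(y))
        y0 = max(row0, cy - r)
        y1 = min(row1, cy + r + 1)
        if y1 <= y0:
            continue
        col_idx = np.arange(cx - r, cx + r + 1)
        gx = np.exp(-((col_idx - x) ** 2) * inv2s2)
        row_idx = np.arange(y0, y1)
        gy = np.exp(-((row_idx - y) ** 2) * inv2s2)
        img[np.ix_(row_idx, col_idx % w)] -= amp * np.outer(gy, gx)


def render_burst(state: TriggerState, geometry: ChipGeometry,
                 settings: RenderSettings, rng: np.random.Generator,
                 burst_frames: int = 2, burst_dt_s: float = 0.001) -> np.ndarray:
    """Render one burst of frames for a trigger.

    Chamber bands are drawn at I0 - beta*Hct with dark tracer speckle
    advected by u * dt between frames; the aggregation band (tracers
    included) is scaled by (1 - deficit); the coflow band is split at row
    round(alpha_b * w_px) between blood and reference-fluid intensities.
    Intensities are clipped to [0, 255] and returned as uint8.
    """
    h, w = geometry.frame_shape
    px_mm = geometry.pixel_scale_um / 1000.0  # mm per pixel
    i0 = settings.background_i0
    blood_i = i0 - settings.hct_attenuation * state.hct
    mc_rows, _ = _channel_band(geometry.roi_mc, w)
    ac_rows, _ = _channel_band(geometry.roi_ac, w)
    vc_rows, _ = _channel_band(geometry.roi_vc, w)
    return _render_burst_frames(state, geometry, settings, rng,
                                mc_rows, ac_rows, vc_rows, blood_i, i0, px_mm,
                                burst_frames, burst_dt_s)


def _render_burst_frames(state, geometry, settings, rng, mc_rows, ac_rows,
                         vc_rows, blood_i, i0, px_mm,
                         burst_frames: int = 2, burst_dt_s: float = 0.001):
    h, w = geometry.frame_shape
    dt = burst_dt_s
    disp_mc_px = state.u_mc_mm_s * dt / px_mm
    disp_ac_px = state.u_ac_mm_s * dt / px_mm
    if max(disp_mc_px, disp_ac_px) * (burst_frames - 1) > 6.5:
        warnings.warn("particle displacement exceeds half an interrogation "
                      "window; PIV will alias", RuntimeWarning, stacklevel=2)

    band_h_px = mc_rows.stop - mc_rows.start
    band_area_mm2 = band_h_px * w * px_mm**2
    n_part = int(round(settings.particle_density_mm2 * band_area_mm2))

    def sample(rows):
        xs = rng.uniform(0, w, size=n_part)
        ys = rng.uniform(rows.start + 1.0, rows.stop - 1.0, size=n_part)
        return xs, ys

    mc_x, mc_y = sample(mc_rows)
    ac_x, ac_y = sample(ac_rows)

    w_px = geometry.width_px
    blood_rows = int(round(state.alpha_b * w_px))
    frames = np.empty((burst_frames, h, w), dtype=np.uint8)
    for k in range(burst_frames):
        img = np.full((h, w), float(i0))
        img[mc_rows, :] = blood_i
        img[ac_rows, :] = blood_i
        img[vc_rows, :] = i0
        img[vc_rows.start:vc_rows.start + blood_rows, :] = blood_i
        if n_part:
            _draw_particles(img, (mc_x + disp_mc_px * k), mc_y,
                            settings.particle_amplitude,
                            settings.particle_sigma_px,
                            mc_rows.start, mc_rows.stop)
            _draw_particles(img, (ac_x + disp_ac_px * k), ac_y,
                            settings.particle_amplitude,
                            settings.particle_sigma_px,
                            ac_rows.start, ac_rows.stop)
        # aggregation deficit scales the whole chamber content (cells and
        # aggregates darken together); stasis aggregation darkens mc too
        img[ac_rows, :] *= (1.0 - state.ai_target)
        if state.mc_stasis_deficit > 0:
            img[mc_rows, :] *= (1.0 - state.mc_stasis_deficit)
        if settings.noise_sigma > 0:
            img += rng.normal(0.0, settings.noise_sigma, size=img.shape)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return frames


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(scenario: SyntheticScenario,
                     blood: SyntheticBloodModel,
                     geometry: ChipGeometry | None = None,
                     settings: RenderSettings | None = None,
                     mu_r_cP: float = 1.0,
                     network: ResistanceNetwork | None = None,
                     cf_model: CorrectionFactorModel = DEFAULT_CF,
                     ) -> tuple[np.ndarray, GroundTruthManifest]:
    """Render a full burst stack plus its ground-truth manifest.

    Page order is trigger-major then burst frame.  Deterministic for a
    fixed scenario seed.  Raises :class:`GenerationError` if the interface
    leaves the correction-factor domain at any trigger.
    """
    geometry = geometry or ChipGeometry()
    settings = settings or RenderSettings()
    network = network or network_from_split_fraction(0.05)
    rng = np.random.default_rng(scenario.seed)

    cross_section = geometry.cross_section_mm2  # mm^2
    manifest = GroundTruthManifest(
        seed=scenario.seed,
        config={"scenario": _as_config(scenario), "blood": asdict(blood),
                "render": asdict(settings), "mu_r_cP": mu_r_cP,
                "pixel_scale_um": geometry.pixel_scale_um})

    n_triggers = scenario.n_triggers
    frames_out = np.empty(
        (n_triggers * scenario.burst_frames, *geometry.frame_shape), np.uint8)

    alpha_prev: float | None = None
    off_since: float | None = None
    for i in range(n_triggers):
        t = i * scenario.trigger_period_s
        delivering = _schedule_state(t, scenario.schedule) == "on"
        hct = delivered_hematocrit(t, scenario.schedule, blood)
        mu_b = (blood.fixed_viscosity_cP if blood.fixed_viscosity_cP is not None
                else phantom_viscosity(hct, blood.cdex_mg_ml,
                                       blood.medium_slope_cP_per_mg_ml))
        q_ac, q_vc = flow_split(network, scenario.q_b_ml_h)
        if delivering:
            off_since = None
            try:
                alpha_b = interface_from_viscosity(
                    mu_b, mu_r_cP, scenario.q_r_ml_h, q_vc, cf_model)
            except (OutOfRangeError, DomainError) as exc:
                raise GenerationError(
                    f"trigger {i} (t={t:g}s): {exc}") from exc
            alpha_prev = alpha_b
            u_mc = scenario.q_b_ml_h * ML_H_TO_MM3_S / cross_section
            u_ac = q_ac * ML_H_TO_MM3_S / cross_section
            shear_ac = shear_rate_rect(q_ac, geometry.width_mm, geometry.depth_mm)
            mc_deficit = 0.0
        else:
            if off_since is None:
                off_since = t
            if alpha_prev is None:
                # chip pre-filled before delivery starts: static interface at
                # the equilibrium position for the initial viscosity
                try:
                    alpha_prev = interface_from_viscosity(
                        mu_b, mu_r_cP, scenario.q_r_ml_h, q_vc, cf_model)
                except (OutOfRangeError, DomainError) as exc:
                    raise GenerationError(
                        f"trigger {i} (t={t:g}s): {exc}") from exc
            alpha_b = alpha_prev
            u_mc = u_ac = 0.0
            shear_ac = 0.0
            # stasis aggregation slowly darkens the stationary mc content
            t_off = t - off_since
            mc_deficit = (phantom_aggregation_deficit(
                hct, blood.cdex_mg_ml, blood.aggregability, 0.0)
                * (1.0 - math.exp(-t_off / settings.stasis_agg_tau_s)))
            q_ac = q_vc = 0.0
        deficit = phantom_aggregation_deficit(
            hct, blood.cdex_mg_ml, blood.aggregability, shear_ac) \
            if delivering else 0.0

        state = TriggerState(t_s=t, delivering=delivering, hct=hct,
                             mu_b_cP=mu_b, alpha_b=alpha_b,
                             u_mc_mm_s=u_mc, u_ac_mm_s=u_ac,
                             ai_target=deficit, mc_stasis_deficit=mc_deficit)
        burst = _render_burst_frames(
            state, geometry, settings, rng,
            slice(geometry.roi_mc.top, geometry.roi_mc.bottom),
            slice(geometry.roi_ac.top, geometry.roi_ac.bottom),
            slice(geometry.roi_vc.top, geometry.roi_vc.bottom),
            settings.background_i0 - settings.hct_attenuation * hct,
            settings.background_i0, geometry.pixel_scale_um / 1000.0,
            scenario.burst_frames, scenario.burst_dt_s)
        frames_out[i * scenario.burst_frames:(i + 1) * scenario.burst_frames] = burst
        manifest.records.append({
            "trigger": i, "t_s": t, "state": "on" if delivering else "off",
            "hct": hct, "mu_b_cP": mu_b, "alpha_b": alpha_b,
            "u_mc_mm_s": u_mc, "u_ac_mm_s": u_ac,
            "q_ac_ml_h": q_ac, "q_vc_ml_h": q_vc, "ai_target": deficit})
    return frames_out, manifest


def _as_config(scenario: SyntheticScenario) -> dict:
    cfg = asdict(scenario)
    cfg["schedule"] = [list(p) for p in scenario.schedule]
    return cfg


def save_dataset(stack: np.ndarray, manifest: GroundTruthManifest,
                 tiff_path, manifest_path) -> None:
    """Write the stack as an 8-bit multi-page TIFF and the manifest as JSON."""
    import tifffile

    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    manifest.to_json(manifest_path)
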