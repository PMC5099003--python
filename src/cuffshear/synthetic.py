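"""Synthetic pulsatile wall-shear-stress fields for cuffed and control vessels.

This module generates the study conditions of the carotid-cuff mouse model
at desk scale: paired instrumented/control straight tubes (~0.6 mm diameter,
10 mm long), a cuff whose lumen tapers from 500 to 250 um, an 8 Hz cardiac
cycle discretized at 300 steps with every 10th step exported (30 instants),
and a parametric time-varying vortex downstream of the cuff that produces
flow reversal and multidirectional shear.

Wall shear stress is closed with a quasi-steady Poiseuille law: at each
instant the wall shear magnitude is the steady fully developed value for the
instantaneous flow rate, |tau|(s, t) = 4*mu*Q(t) / (pi*R(s)^3).  At Reynolds
numbers around 40 and Womersley numbers of 2-3 this captures amplitude-level
behaviour without solving the Navier-Stokes equations.  Spatial log-normal
heterogeneity emulates the node-to-node spread of time-averaged WSS seen in
real vessels, which the threshold calibration relies on.

Units: geometry mm, diameters um, velocity mm/s, time s, stress Pa.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .mesh import (
    CenterlineFrame,
    RegionLabels,
    TriSurfaceMesh,
    build_tube_mesh,
    control_regions,
    parameterize,
    segment_regions,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluidProps:
    """Newtonian blood: viscosity 3.5 mPa*s, density 1050 kg/m^3."""

    viscosity_pa_s: float = 3.5e-3
    density_kg_m3: float = 1050.0

    def __post_init__(self) -> None:
        if self.viscosity_pa_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class DisturbanceSpec:
    """Parametric surrogate for the time-varying vortex downstream of the cuff.

    ``reversal_amplitude`` is the fraction of the local axial WSS reversed at
    the envelope peak (values above 0.5 produce instantaneous reversal);
    ``circ_amplitude`` scales the added circumferential component;
    ``vortex_frequency_multiplier`` sets the vortex frequency as a multiple
    of the cardiac frequency.
    """

    recirc_length_mm: float = 2.5
    reversal_amplitude: float = 1.0
    circ_amplitude: float = 0.5
    vortex_frequency_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if min(self.recirc_length_mm, self.reversal_amplitude,
               self.circ_amplitude, self.vortex_frequency_multiplier) < 0:
            raise ValueError("disturbance parameters must be non-negative")

    @classmethod
    def none(cls) -> "DisturbanceSpec":
        return cls(recirc_length_mm=0.0, reversal_amplitude=0.0,
                   circ_amplitude=0.0, vortex_frequency_multiplier=0.0)


@dataclass(frozen=True)
class VesselSpec:
    """Geometry, inflow and discretization of one synthetic carotid artery.

    Defaults are the instrumented (cuffed) left carotid: inlet diameter
    622 um, mean inlet velocity 112.8 mm/s, cuff spanning 5.0-6.2 mm with a
    500 -> 250 um lumen taper, heart rate 8 Hz, 300 steps per cycle with
    every 10th exported.
    """

    inlet_diameter_um: float = 622.0
    vessel_length_mm: float = 10.0
    has_cuff: bool = True
    cuff_start_mm: float = 5.0
    cuff_end_mm: float = 6.2
    cuff_inlet_diameter_um: float = 500.0
    cuff_outlet_diameter_um: float = 250.0
    taper_transition_mm: float = 0.3
    mean_inlet_velocity_mm_s: float = 112.8
    heart_rate_hz: float = 8.0
    n_steps_per_cycle: int = 300
    export_every: int = 10
    disturbance: DisturbanceSpec = field(default_factory=DisturbanceSpec)
    heterogeneity_sigma_log: float = 0.2
    n_axial: int = 121
    n_circ: int = 32

    def __post_init__(self) -> None:
        if self.inlet_diameter_um <= 0 or self.vessel_length_mm <= 0:
            raise ValueError("vessel dimensions must be positive")
        if self.mean_inlet_velocity_mm_s <= 0 or self.heart_rate_hz <= 0:
            raise ValueError("velocity and heart rate must be positive")
        if self.n_steps_per_cycle % self.export_every != 0:
            raise ValueError("n_steps_per_cycle must be divisible by export_every")
        if self.heterogeneity_sigma_log < 0:
            raise ValueError("heterogeneity_sigma_log must be >= 0")
        if self.has_cuff:
            if not (0 < self.cuff_start_mm < self.cuff_end_mm
                    < self.vessel_length_mm):
                raise ValueError("cuff interval must lie inside the vessel")
            if min(self.cuff_inlet_diameter_um,
                   self.cuff_outlet_diameter_um) <= 0:
                raise ValueError("cuff diameters must be positive")
            tail = self.vessel_length_mm - self.cuff_end_mm
            if self.disturbance.recirc_length_mm > tail + 1e-9:
                raise ValueError("recirculation zone exceeds the vessel")

    @property
    def period_s(self) -> float:
        return 1.0 / self.heart_rate_hz

    @property
    def n_export(self) -> int:
        return self.n_steps_per_cycle // self.export_every

    @classmethod
    def default_instrumented(cls) -> "VesselSpec":
        return cls()

    @classmethod
    def default_control(cls) -> "VesselSpec":
        # contralateral right carotid: 594 um, 153.4 mm/s, no cuff
        return cls(inlet_diameter_um=594.0, has_cuff=False,
                   mean_inlet_velocity_mm_s=153.4,
                   disturbance=DisturbanceSpec.none())


def radius_profile(spec: VesselSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Lumen radius R(s) in mm for a vessel spec.

    Cuffed vessels are piecewise linear: the vessel radius ramps to the cuff
    inlet radius over ``taper_transition_mm`` before the cuff, tapers
    linearly inside the cuff, and ramps back after the cuff exit.
    """
    r_vessel = spec.inlet_diameter_um / 2000.0  # um -> mm radius
    if not spec.has_cuff:
        return lambda s: np.full_like(np.asarray(s, dtype=float), r_vessel)
    r_in = spec.cuff_inlet_diameter_um / 2000.0
    r_out = spec.cuff_outlet_diameter_um / 2000.0
    t = spec.taper_transition_mm
    xp = np.array([
        0.0,
        max(spec.cuff_start_mm - t, 0.0),
        spec.cuff_start_mm,
        spec.cuff_end_mm,
        min(spec.cuff_end_mm + t, spec.vessel_length_mm),
        spec.vessel_length_mm,
    ])
    fp = np.array([r_vessel, r_vessel, r_in, r_out, r_vessel, r_vessel])
    return lambda s: np.interp(np.asarray(s, dtype=float), xp, fp)


@dataclass
class VelocityWaveform:
    """Inlet velocity over one cardiac cycle on the full time grid."""

    times: np.ndarray     # (n_steps,) s, uniform over [0, T)
    velocity: np.ndarray  # (n_steps,) mm/s, strictly positive
    period: float         # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if np.any(self.velocity <= 0):
            raise ValueError("inlet velocity must stay positive (no bulk reversal)")


def make_waveform(
    spec: VesselSpec,
    a1: float = 0.4,
    a2: float = 0.15,
    phi: float = np.pi / 4,
) -> VelocityWaveform:
    """Two-harmonic pulsatile inlet waveform with exact mean velocity.

    U(t) = U*(1 + a1*sin(2*pi*t/T) + a2*sin(4*pi*t/T + phi)), rescaled so
    the sample mean equals the spec's mean inlet velocity exactly.
    """
    T = spec.period_s
    n = spec.n_steps_per_cycle
    t = np.arange(n) * (T / n)
    u = 1.0 + a1 * np.sin(2 * np.pi * t / T) + a2 * np.sin(4 * np.pi * t / T + phi)
    if np.any(u <= 0):
        raise ValueError("waveform amplitudes drive the inlet velocity negative")
    u = u * (spec.mean_inlet_velocity_mm_s / u.mean())
    return VelocityWaveform(times=t, velocity=u, period=T)


@dataclass
class WSSFieldSeries:
    """Per-node WSS 3-vectors (Pa) at the exported instants of one cycle."""

    vectors: np.ndarray        # (n_nodes, n_export, 3) Pa
    times: np.ndarray          # (n_export,) s
    period: float              # s
    mesh: Optional[TriSurfaceMesh] = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_nodes, n_export, 3)")
        if self.vectors.shape[1] != len(self.times):
            raise ValueError("time axis mismatch between vectors and times")

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_export(self) -> int:
        return self.vectors.shape[1]

    def copy(self) -> "WSSFieldSeries":
        return WSSFieldSeries(self.vectors.copy(), self.times.copy(),
                              self.period, self.mesh)


def _axial_tangent(mesh: TriSurfaceMesh, axis: np.ndarray) -> np.ndarray:
    """Unit axial direction projected into each node's tangent plane.

    WSS is tangent to the wall, so on tapered segments the axial direction
    is tilted by the local cone angle.
    """
    n = mesh.normals
    t = axis[None, :] - (n @ axis)[:, None] * n
    norms = np.linalg.norm(t, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("surface normal parallel to the vessel axis")
    return t / norms[:, None]


def quasi_steady_wss(
    mesh: TriSurfaceMesh,
    frame: CenterlineFrame,
    radius_fn: Callable[[np.ndarray], np.ndarray],
    waveform: VelocityWaveform,
    fluid: FluidProps,
    spec: VesselSpec,
) -> WSSFieldSeries:
    """Quasi-steady Poiseuille WSS on the exported time grid.

    Mass conservation fixes the flow rate Q(t) = U(t)*pi*R_inlet^2 from the
    inlet waveform; the wall shear magnitude at axial position s is then
    |tau|(s, t) = 4*mu*Q(t)/(pi*R(s)^3), directed along the axial tangent.
    """
    R = np.asarray(radius_fn(frame.axial), dtype=float)
    if np.any(R <= 0):
        raise ValueError("radius must be positive at every node")
    r_inlet = float(np.asarray(radius_fn(np.array([0.0]))).ravel()[0])
    idx = slice(None, None, spec.export_every)
    u_t = waveform.velocity[idx]
    times = waveform.times[idx]
    q_t = u_t * np.pi * r_inlet**2                       # mm^3/s
    mag = 4.0 * fluid.viscosity_pa_s * q_t[None, :] / (np.pi * R[:, None] ** 3)
    direction = _axial_tangent(mesh, frame.axis)
    vectors = mag[:, :, None] * direction[:, None, :]
    return WSSFieldSeries(vectors=vectors, times=times,
                          period=waveform.period, mesh=mesh)


def apply_downstream_disturbance(
    field: WSSFieldSeries,
    frame: CenterlineFrame,
    spec: VesselSpec,
) -> WSSFieldSeries:
    """Impose the time-varying downstream vortex on a quasi-steady field.

    Within cuff_end < s <= cuff_end + recirc_length, with envelope
    w(s) = sin^2(pi*(s - cuff_end)/recirc_length), the axial WSS component
    is multiplied by 1 - A_rev*w*(1 + sin(2*pi*m*t/T + theta)) (reversing at
    the peak when A_rev > 0.5) and a circumferential component
    A_circ*w*|tau_axial|*cos(2*pi*m*t/T + 2*theta) is added.  Nodes outside
    the zone are untouched.
    """
    d = spec.disturbance
    out = field.copy()
    if d.recirc_length_mm == 0 or (
        d.reversal_amplitude == 0 and d.circ_amplitude == 0
    ):
        return out
    zone_end = spec.cuff_end_mm + d.recirc_length_mm
    if zone_end > frame.length + 1e-9:
        raise ValueError("recirculation zone extends beyond the mesh")
    s = frame.axial
    zone = (s > spec.cuff_end_mm) & (s <= zone_end)
    if not np.any(zone):
        return out
    mesh = field.mesh
    if mesh is None:
        raise ValueError("field carries no mesh; cannot build local axes")

    w = np.sin(np.pi * (s[zone] - spec.cuff_end_mm) / d.recirc_length_mm) ** 2
    theta = frame.angular[zone]
    u_ax = _axial_tangent(mesh, frame.axis)[zone]
    u_circ = np.cross(mesh.normals[zone], u_ax)
    u_circ /= np.linalg.norm(u_circ, axis=1)[:, None]

    tau = out.vectors[zone]                                  # (nz, k, 3)
    ax_comp = np.einsum("nki,ni->nk", tau, u_ax)             # (nz, k)
    residual = tau - ax_comp[:, :, None] * u_ax[:, None, :]

    m = d.vortex_frequency_multiplier
    phase = 2 * np.pi * m * field.times[None, :] / field.period  # (1, k)
    factor = 1.0 - d.reversal_amplitude * w[:, None] * (
        1.0 + np.sin(phase + theta[:, None])
    )
    circ_mag = (
        d.circ_amplitude * w[:, None] * np.abs(ax_comp)
        * np.cos(phase + 2.0 * theta[:, None])
    )
    out.vectors[zone] = (
        residual
        + (factor * ax_comp)[:, :, None] * u_ax[:, None, :]
        + circ_mag[:, :, None] * u_circ[:, None, :]
    )
    return out


def apply_spatial_heterogeneity(
    field: WSSFieldSeries,
    sigma_log: float,
    seed: int,
) -> WSSFieldSeries:
    """Scale each node's WSS history by a log-normal factor exp(g),
    g ~ Normal(-sigma_log^2/2, sigma_log), so the per-node TAWSS spread is
    log-normal with unit mean factor.  Direction and time structure are
    unchanged."""
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    out = field.copy()
    if sigma_log == 0:
        return out
    rng = np.random.default_rng(seed)
    g = rng.normal(-0.5 * sigma_log**2, sigma_log, size=field.n_nodes)
    out.vectors *= np.exp(g)[:, None, None]
    return out


# ---------------------------------------------------------------------------
# Paired vessels and cohorts
# ---------------------------------------------------------------------------

@dataclass
class VesselData:
    """One synthetic vessel: geometry, parameterization, field and regions."""

    spec: VesselSpec
    mesh: TriSurfaceMesh
    frame: CenterlineFrame
    field: WSSFieldSeries
    labels: RegionLabels


@dataclass
class MouseDataset:
    """Paired instrumented and contralateral control vessels of one mouse."""

    mouse_id: str
    instrumented: VesselData
    control: VesselData
    fluid: FluidProps
    seed: int

    def vessels(self):
        return {"instrumented": self.instrumented, "control": self.control}


def _build_vessel(spec: VesselSpec, fluid: FluidProps, het_seed: int) -> tuple:
    rp = radius_profile(spec)
    mesh = build_tube_mesh(rp, spec.vessel_length_mm, spec.n_axial, spec.n_circ)
    frame = parameterize(mesh)
    waveform = make_waveform(spec)
    fld = quasi_steady_wss(mesh, frame, rp, waveform, fluid, spec)
    if spec.has_cuff:
        fld = apply_downstream_disturbance(fld, frame, spec)
    fld = apply_spatial_heterogeneity(fld, spec.heterogeneity_sigma_log,
                                      het_seed)
    return mesh, frame, fld


def synth_mouse(
    spec_instrumented: VesselSpec,
    spec_control: VesselSpec,
    seed: int,
    fluid: FluidProps = FluidProps(),
    plaque_extent: float = 1.6,
    mouse_id: str = "mouse_00",
) -> MouseDataset:
    """Generate one mouse: a cuffed instrumented vessel with downstream
    disturbance plus a uniform contralateral control, both with spatial
    heterogeneity, with regions attached (control regions anchored to the
    distal end)."""
    if not spec_instrumented.has_cuff:
        raise ValueError("instrumented spec must carry a cuff")
    ss = np.random.SeedSequence(seed)
    het_i, het_c = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))

    mesh_i, frame_i, field_i = _build_vessel(spec_instrumented, fluid, het_i)
    labels_i = segment_regions(frame_i, spec_instrumented.cuff_start_mm,
                               spec_instrumented.cuff_end_mm, plaque_extent)
    mesh_c, frame_c, field_c = _build_vessel(spec_control, fluid, het_c)
    labels_c = control_regions(frame_c, labels_i, frame_i)

    return MouseDataset(
        mouse_id=mouse_id,
        instrumented=VesselData(spec_instrumented, mesh_i, frame_i, field_i,
                                labels_i),
        control=VesselData(spec_control, mesh_c, frame_c, field_c, labels_c),
        fluid=fluid,
        seed=seed,
    )


def synth_cohort(
    n_mice: int,
    base_instrumented: Optional[VesselSpec] = None,
    base_control: Optional[VesselSpec] = None,
    seed: int = 0,
    fluid: FluidProps = FluidProps(),
    plaque_extent: float = 1.6,
) -> list:
    """Cohort of paired vessels with mild (+/-10%) per-mouse jitter.

    Jitter applies to the mean inlet velocities, the heterogeneity spread
    and the downstream disturbance amplitudes, giving every metric nonzero
    between-mouse variance.  Per-mouse seeds derive deterministically from
    the master seed.
    """
    if n_mice < 2:
        raise ValueError("a cohort needs at least 2 mice")
    base_i = base_instrumented or VesselSpec.default_instrumented()
    base_c = base_control or VesselSpec.default_control()
    children = np.random.SeedSequence(seed).spawn(n_mice)
    cohort = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        jv_i, jv_c, jh, jd = rng.uniform(0.9, 1.1, size=4)
        spec_i = dataclasses.replace(
            base_i,
            mean_inlet_velocity_mm_s=base_i.mean_inlet_velocity_mm_s * jv_i,
            heterogeneity_sigma_log=base_i.heterogeneity_sigma_log * jh,
            disturbance=dataclasses.replace(
                base_i.disturbance,
                reversal_amplitude=base_i.disturbance.reversal_amplitude * jd,
                circ_amplitude=base_i.disturbance.circ_amplitude * jd,
            ),
        )
        spec_c = dataclasses.replace(
            base_c,
            mean_inlet_velocity_mm_s=base_c.mean_inlet_velocity_mm_s * jv_c,
            heterogeneity_sigma_log=base_c.heterogeneity_sigma_log * jh,
        )
        mouse_seed = int(rng.integers(2**31))
        cohort.append(
            synth_mouse(spec_i, spec_c, mouse_seed, fluid=fluid,
                        plaque_extent=plaque_extent, mouse_id=f"mouse_{k:02d}")
        )
    return cohort
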