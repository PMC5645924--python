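"""Mechanism phantom: synthetic recordings with analytic ground truth.

The phantom emulates an instrumental swallowing model built from two classic
mechanisms: an in-line slider-crank whose reciprocating slider stands in for
hyoid excursion, and a belt-pulley drive whose follower rotation stands in
for epiglottic tilt.  Both admit closed-form position/velocity laws, so a
simulated recording comes with exact ground truth for end-to-end validation
of the analysis pipeline.

Scene layout (millimetres, anatomical-like axes: y up the cervical axis, x
anterior/image-left): C4 at the origin, C2 straight above, the slider moving
along the y-axis at a fixed anterior offset, the epiglottis arm rotating about
a fixed base, and a 24 mm calibration coin.  The scene is rendered to pixels
(v increases downward) at ``px_per_mm`` and i.i.d. Gaussian marking noise of
``noise_sigma_px`` is added to every marker coordinate, seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import EventLog, FrameAnnotation, PixelPoint, Recording

__all__ = [
    "PhantomConfig",
    "PhantomGroundTruth",
    "slider_position",
    "slider_velocity",
    "pulley_angle",
    "pulley_angular_velocity",
    "simulate_recording",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, drive and rendering parameters of the simulated mechanism."""

    crank_radius_r: float = 10.0      # mm
    rod_length_l: float = 50.0        # mm, must exceed crank_radius_r
    angular_speed_omega: float = math.pi  # rad/s of the crank / driver pulley
    crank_phase_theta0: float = 0.0   # rad
    pulley_ratio: float = 0.5         # driver radius / follower radius
    epiglottis_arm_mm: float = 25.0   # base->tip distance
    follower_phase_phi0_deg: float = 0.0
    fps: float = 30.0
    duration: float = 2.0             # s
    noise_sigma_px: float = 0.0       # marking-jitter SD
    seed: int = 0
    px_per_mm: float = 4.0
    c2_c4_drift: float = 0.0          # rigid scene drift amplitude, mm
    slide_axis_angle_deg: float = 0.0 # rotation of the slide axis off +y

    def __post_init__(self):
        if not (self.rod_length_l > self.crank_radius_r > 0):
            raise ValueError("need rod_length_l > crank_radius_r > 0 (mechanism locks)")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if self.noise_sigma_px < 0:
            raise ValueError("noise_sigma_px must be >= 0")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if self.pulley_ratio <= 0:
            raise ValueError("pulley_ratio must be positive")


@dataclass
class PhantomGroundTruth:
    """Noise-free analytic kinematics sampled at the recording's frame times."""

    t: np.ndarray
    slider_displacement_mm: np.ndarray   # d(t) - d(t_0), along the slide axis
    slider_velocity_mmps: np.ndarray
    follower_angle_deg: np.ndarray       # phi(t) - phi(t_0)
    angular_velocity_degps: np.ndarray
    peaks: dict[str, float] = field(default_factory=dict)


def slider_position(theta: float | np.ndarray, r: float, l: float):
    """In-line slider-crank displacement along the slide axis.

    d(theta) = r cos(theta) + sqrt(l^2 - r^2 sin^2(theta)); d ranges from
    l - r (bottom dead center, theta = pi) to l + r (top dead center, 0).
    """
    if not l > r >= 0:
        raise ValueError("mechanism locks: need l > r >= 0")
    theta = np.asarray(theta, dtype=float)
    return r * np.cos(theta) + np.sqrt(l**2 - (r * np.sin(theta)) ** 2)


def slider_velocity(
    t: float | np.ndarray, r: float, l: float, omega: float, theta0: float = 0.0
):
    """Analytic derivative of slider_position with theta(t) = theta0 + omega t.

    d'(t) = -r omega sin(theta) [1 + r cos(theta) / sqrt(l^2 - r^2 sin^2 theta)].
    """
    if not l > r >= 0:
        raise ValueError("mechanism locks: need l > r >= 0")
    t = np.asarray(t, dtype=float)
    theta = theta0 + omega * t
    root = np.sqrt(l**2 - (r * np.sin(theta)) ** 2)
    return -r * omega * np.sin(theta) * (1.0 + r * np.cos(theta) / root)


def pulley_angle(
    t: float | np.ndarray, ratio: float, omega: float, phi0_deg: float = 0.0
):
    """Follower angle under rigid belt transmission, degrees.

    phi(t) = phi0 + ratio * omega * t; the follower turns at the constant
    rate (driver radius / follower radius) times the driver speed.
    """
    if ratio <= 0:
        raise ValueError("pulley_ratio must be positive")
    t = np.asarray(t, dtype=float)
    return phi0_deg + np.degrees(ratio * omega * t)


def pulley_angular_velocity(ratio: float, omega: float) -> float:
    """Constant follower angular velocity, degree/s."""
    return math.degrees(ratio * omega)


# fixed scene geometry (mm, anatomical axes), chosen to keep structures
# separated in the rendered image
_C4 = np.array([0.0, 0.0])
_C2 = np.array([0.0, 50.0])
_SLIDER_X_OFFSET = 20.0
_EPI_BASE = np.array([35.0, 15.0])
_COIN_CENTER = np.array([-30.0, 70.0])
_COIN_DIAMETER_MM = 24.0
_IMAGE_ORIGIN_PX = (400.0, 500.0)  # pixel (u, v) of scene origin


def _scene_to_pixel(xy: np.ndarray, px_per_mm: float) -> tuple[float, float]:
    u0, v0 = _IMAGE_ORIGIN_PX
    return (u0 - px_per_mm * xy[0], v0 - px_per_mm * xy[1])


def simulate_recording(cfg: PhantomConfig) -> tuple[Recording, PhantomGroundTruth]:
    """Render the mechanism into a marker Recording plus analytic ground truth.

    Per frame: hyoid at the slider position along the slide axis, epiglottis
    base fixed with the tip at ``epiglottis_arm_mm`` along the follower
    direction, static (or rigidly drifting) C2/C4, and the calibration coin.
    Noise is i.i.d. Gaussian per marker coordinate, from ``cfg.seed``; the
    ground truth is noise-free.  ``c2_c4_drift`` translates the *whole scene*
    rigidly (a slow sinusoidal sway), which the moving anatomical frame must
    cancel exactly.
    """
    n = int(round(cfg.duration * cfg.fps)) + 1
    t = np.arange(n) / cfg.fps
    theta = cfg.crank_phase_theta0 + cfg.angular_speed_omega * t
    d = np.asarray(slider_position(theta, cfg.crank_radius_r, cfg.rod_length_l))
    d_vel = np.asarray(
        slider_velocity(
            t, cfg.crank_radius_r, cfg.rod_length_l,
            cfg.angular_speed_omega, cfg.crank_phase_theta0,
        )
    )
    phi = np.asarray(
        pulley_angle(t, cfg.pulley_ratio, cfg.angular_speed_omega, cfg.follower_phase_phi0_deg)
    )
    ang_vel = pulley_angular_velocity(cfg.pulley_ratio, cfg.angular_speed_omega)

    beta = math.radians(cfg.slide_axis_angle_deg)
    slide_dir = np.array([-math.sin(beta), math.cos(beta)])  # +y default

    rng = np.random.default_rng(cfg.seed)
    coin_half = np.array([_COIN_DIAMETER_MM / 2.0, 0.0])
    frames: list[FrameAnnotation] = []
    for i in range(n):
        # rigid whole-scene drift (head sway); anatomical analysis cancels it
        drift = cfg.c2_c4_drift * np.array(
            [math.sin(2.0 * math.pi * 0.25 * t[i]), math.cos(2.0 * math.pi * 0.25 * t[i])]
        )
        phi_rad = math.radians(phi[i])
        tip_dir = np.array([-math.sin(phi_rad), math.cos(phi_rad)])  # posterior-positive tilt
        scene = {
            "c4": _C4 + drift,
            "c2": _C2 + drift,
            "hyoid": np.array([_SLIDER_X_OFFSET, 0.0]) + d[i] * slide_dir + drift,
            "epiglottis_base": _EPI_BASE + drift,
            "epiglottis_tip": _EPI_BASE + cfg.epiglottis_arm_mm * tip_dir + drift,
            "coin_a": _COIN_CENTER - coin_half + drift,
            "coin_b": _COIN_CENTER + coin_half + drift,
        }
        markers = {}
        for name, xy in scene.items():
            u, v = _scene_to_pixel(xy, cfg.px_per_mm)
            if cfg.noise_sigma_px > 0:
                u += rng.normal(0.0, cfg.noise_sigma_px)
                v += rng.normal(0.0, cfg.noise_sigma_px)
            markers[name] = PixelPoint(u, v)
        frames.append(FrameAnnotation(frame=i, markers=markers))

    rec = Recording(
        fps=cfg.fps,
        frames=frames,
        events=EventLog(),
        meta={
            "generator": "deglukin.phantom",
            "seed": str(cfg.seed),
            "noise_sigma_px": repr(cfg.noise_sigma_px),
            "px_per_mm": repr(cfg.px_per_mm),
        },
    )

    disp = d - d[0]
    rel_phi = phi - phi[0]
    truth = PhantomGroundTruth(
        t=t,
        slider_displacement_mm=disp,
        slider_velocity_mmps=d_vel,
        follower_angle_deg=rel_phi,
        angular_velocity_degps=np.full(n, ang_vel),
        peaks={
            "slider_peak_displacement_mm": float(disp[np.argmax(np.abs(disp))]),
            "slider_peak_velocity_mmps": float(d_vel[np.argmax(np.abs(d_vel))]),
            "follower_peak_angle_deg": float(rel_phi[np.argmax(np.abs(rel_phi))]),
            "angular_velocity_degps": float(ang_vel),
        },
    )
    return rec, truth


def config_grid(seed: int = 0) -> list[PhantomConfig]:
    """A spread of phantom configurations spanning small-to-large linear
    amplitudes (peak-to-peak 2r of roughly 6-49 mm) and angular sweeps of
    roughly 10-160 degrees, mirroring a bench validation series."""
    crank_radii = np.linspace(3.1, 24.3, 16)  # 2r in ~[6.2, 48.6] mm
    sweeps_deg = np.linspace(10.0, 160.0, 16)
    configs = []
    for i, (r, sweep) in enumerate(zip(crank_radii, sweeps_deg)):
        omega = math.pi  # half a crank turn per second
        duration = 1.0   # exactly one full sweep of the slider
        ratio = math.radians(sweep) / (omega * duration)
        configs.append(
            PhantomConfig(
                crank_radius_r=float(r),
                rod_length_l=float(2.2 * r + 30.0),
                angular_speed_omega=omega,
                pulley_ratio=ratio,
                fps=30.0,
                duration=duration,
                seed=seed + i,
            )
        )
    return configs
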