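"""Synthetic phantoms and radial k-space acquisition with system imperfections.

The phantom is a union of uniform balls ("compartments") whose 3D Fourier
transform is known in closed form, so single-coil k-space can be sampled
grid-free at arbitrary coordinates. System imperfections are modeled
minimally but to the point:

* a direction-odd zeroth-order phase per spoke, ``psi = c . d`` for start
  direction ``d`` — the spatially constant phase offset (e.g. from B0 eddy
  currents) that flips sign when the readout direction reverses;
* per-axis gradient delays (plus a global delay) that displace the effective
  sampling locations along the spoke by ``(tau_axis + global) * d_axis``
  readout samples per axis, i.e. an anisotropic shift of the realized
  trajectory.

The corruption moves where the data were *actually* sampled while the
reconstruction keeps using the nominal coordinates — exactly the mismatch
that produces the artifacts under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .bssfp import SequenceParams, Tissue, bssfp_signal
from .trajectory import SpokeSet, TrajectoryConfig
from . import _gridding

__all__ = [
    "Compartment",
    "PhantomSpec",
    "ImperfectionModel",
    "KSpaceData",
    "analytic_ball_transform",
    "corrupt_spokes",
    "simulate_acquisition",
    "bssfp_contrast_weights",
    "rasterize_phantom",
    "gaussian_coil_profiles",
    "soft_ball",
    "salt_water_ball",
    "vial_phantom",
    "simulate_phase_cycled_series",
]


@dataclass(frozen=True)
class Compartment:
    """Uniform ball: center/radius in voxel units of the target matrix."""

    center: tuple
    radius: float
    amplitude: complex = 1.0 + 0j
    tissue: Optional[Tissue] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("compartment radius must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3


@dataclass(frozen=True)
class PhantomSpec:
    """Collection of (possibly overlapping) ball compartments.

    Either no compartment carries tissue parameters (amplitude mode) or all
    do (contrast mode for phase-cycled bSSFP simulation).
    """

    compartments: tuple

    def __post_init__(self) -> None:
        comps = tuple(self.compartments)
        if not comps:
            raise ValueError("phantom needs at least one compartment")
        with_tissue = [c.tissue is not None for c in comps]
        if any(with_tissue) and not all(with_tissue):
            raise ValueError("tissue parameters must be set on all compartments or none")
        object.__setattr__(self, "compartments", comps)

    @property
    def has_tissue(self) -> bool:
        return self.compartments[0].tissue is not None

    @property
    def dc_magnitude(self) -> float:
        """|k-space center| of the phantom, used to scale the noise level."""
        return abs(sum(c.amplitude * c.volume for c in self.compartments))

    def with_amplitudes(self, amplitudes: Sequence[complex]) -> "PhantomSpec":
        comps = tuple(replace(c, amplitude=complex(a))
                      for c, a in zip(self.compartments, amplitudes))
        return PhantomSpec(compartments=comps)


@dataclass(frozen=True)
class ImperfectionModel:
    """Parametric forward model of the acquisition imperfections.

    ``phase_coeffs`` (rad per direction component) generate the
    direction-odd zeroth-order phase ``c . d``; ``delays`` and
    ``global_delay`` are per-axis / isotropic gradient delays in readout
    sample units; ``noise_sigma`` is the complex-Gaussian noise level
    relative to the phantom's k-space-center magnitude.
    """

    phase_coeffs: tuple = (0.0, 0.0, 0.0)
    delays: tuple = (0.0, 0.0, 0.0)
    global_delay: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        pc = tuple(float(v) for v in self.phase_coeffs)
        dl = tuple(float(v) for v in self.delays)
        if len(pc) != 3 or len(dl) != 3:
            raise ValueError("phase_coeffs and delays must have 3 components")
        if not all(np.isfinite(pc + dl + (self.global_delay, self.noise_sigma))):
            raise ValueError("imperfection parameters must be finite")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        object.__setattr__(self, "phase_coeffs", pc)
        object.__setattr__(self, "delays", dl)

    @property
    def is_identity(self) -> bool:
        return (self.phase_coeffs == (0.0, 0.0, 0.0)
                and self.delays == (0.0, 0.0, 0.0)
                and self.global_delay == 0.0 and self.noise_sigma == 0.0)


IDENTITY_MODEL = ImperfectionModel()


@dataclass
class KSpaceData:
    """Acquired radial samples with nominal and effective coordinates.

    ``samples`` has shape (spokes, readout samples, coils). The nominal
    coordinates are what the reconstruction believes was sampled; the
    effective coordinates are where the simulator actually evaluated the
    object spectrum.
    """

    samples: np.ndarray
    nominal_coords: np.ndarray
    effective_coords: np.ndarray
    spoke_set: SpokeSet
    center_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s, m, _ = self.samples.shape
        if self.nominal_coords.shape != (s, m, 3):
            raise ValueError("nominal_coords shape mismatch")
        if self.effective_coords.shape != (s, m, 3):
            raise ValueError("effective_coords shape mismatch")
        if len(self.spoke_set) != s:
            raise ValueError("spoke_set length mismatch")

    @property
    def n_spokes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]

    @property
    def config(self) -> TrajectoryConfig:
        return self.spoke_set.config

    def subset(self, index) -> "KSpaceData":
        return KSpaceData(
            samples=self.samples[index],
            nominal_coords=self.nominal_coords[index],
            effective_coords=self.effective_coords[index],
            spoke_set=self.spoke_set.subset(index),
            center_index=self.center_index,
            meta=dict(self.meta),
        )

    def with_samples(self, samples: np.ndarray) -> "KSpaceData":
        return KSpaceData(
            samples=samples,
            nominal_coords=self.nominal_coords,
            effective_coords=self.effective_coords,
            spoke_set=self.spoke_set,
            center_index=self.center_index,
            meta=dict(self.meta),
        )


def analytic_ball_transform(compartment: Compartment, k: np.ndarray) -> np.ndarray:
    """Closed-form 3D Fourier transform of a uniform ball at points ``k``.

    ``F(k) = A * V * 3*(sin u - u cos u)/u^3 * exp(-2j*pi*k.center)`` with
    ``u = 2*pi*|k|*radius`` and ``V`` the ball volume; the ``u -> 0`` limit
    is evaluated by series.
    """
    k = np.asarray(k, dtype=float)
    kn = np.linalg.norm(k, axis=-1)
    u = 2.0 * np.pi * kn * compartment.radius
    small = u < 1e-4
    form = np.empty_like(u)
    us = u[small]
    form[small] = 1.0 - us ** 2 / 10.0 + us ** 4 / 280.0
    ub = u[~small]
    form[~small] = 3.0 * (np.sin(ub) - ub * np.cos(ub)) / ub ** 3
    phase = np.exp(-2j * np.pi * (k @ np.asarray(compartment.center)))
    return compartment.amplitude * compartment.volume * form * phase


def _phantom_transform(phantom: PhantomSpec, k: np.ndarray) -> np.ndarray:
    out = np.zeros(k.shape[:-1], dtype=complex)
    for comp in phantom.compartments:
        out += analytic_ball_transform(comp, k)
    return out


def corrupt_spokes(spoke_set: SpokeSet, model: ImperfectionModel):
    """Effective sample coordinates and per-spoke additive phase.

    The per-axis k-space displacement is
    ``dk_axis = (tau_axis + global_delay) * d_axis * delta_k`` (constant
    along the readout), subtracted from the nominal coordinates; the
    additive constant phase is ``c . d``, odd in the spoke direction. An
    isotropic delay reduces to a pure along-readout shift of that many
    samples for every spoke.
    """
    cfg = spoke_set.config
    nominal = spoke_set.sample_positions()
    d = spoke_set.directions
    tau = np.asarray(model.delays) + model.global_delay
    dk = (tau[None, :] * d) * cfg.delta_k  # (S, 3)
    effective = nominal - dk[:, None, :]
    phase = d @ np.asarray(model.phase_coeffs)
    return effective, phase


def soft_ball(center=(0.0, 0.0, 0.0), radius: float = 10.0, order: int = 6,
              amplitude: complex = 1.0, tissue: Optional[Tissue] = None,
              max_radius: float = 20.0) -> tuple:
    """Nested-shell approximation of a ball with a smooth (super-Gaussian) edge.

    Returns compartments whose summed radial profile approximates
    ``amplitude * exp(-(r/radius)^order)``, sampled in 1-voxel shells. The
    soft edge keeps the object's spectral energy concentrated at low
    spatial frequencies, so that at desk-scale spoke counts coverage
    streaks do not mask the trajectory-dependent phase artifacts under
    study; a real salt-water ball edge also spans a finite width through
    partial-volume averaging, if a narrower one.
    """
    profile = lambda r: np.exp(-(r / radius) ** order)
    comps = []
    for shell in np.arange(1.0, max_radius + 1.0):
        amp = profile(shell - 0.5) - profile(shell + 0.5)
        if abs(amp) > 1e-6:
            comps.append(Compartment(center=center, radius=float(shell),
                                     amplitude=amplitude * amp, tissue=tissue))
    return tuple(comps)


def salt_water_ball(radius: float = 10.0, order: int = 6) -> PhantomSpec:
    """Canonical homogeneous spherical phantom used in the artifact studies."""
    return PhantomSpec(compartments=soft_ball(radius=radius, order=order))


def vial_phantom(tissues: Sequence[Tissue], ring_radius: float = 12.0,
                 vial_radius: float = 5.0, order: int = 6) -> PhantomSpec:
    """Ring of soft-edged tissue vials for T1/T2 mapping experiments.

    Vials are placed on a circle of ``ring_radius`` voxels in the central
    transverse plane, emulating the compartment layout of an MRI system
    phantom at desk scale.
    """
    comps = []
    n = len(tissues)
    for i, tissue in enumerate(tissues):
        ang = 2.0 * np.pi * i / n
        center = (ring_radius * np.cos(ang), ring_radius * np.sin(ang), 0.0)
        comps.extend(soft_ball(center=center, radius=vial_radius, order=order,
                               tissue=tissue, max_radius=vial_radius + 4))
    return PhantomSpec(compartments=tuple(comps))


def rasterize_phantom(phantom: PhantomSpec, matrix: int) -> np.ndarray:
    """Complex amplitude volume of the phantom on a centered voxel grid."""
    x = np.arange(matrix) - matrix // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    vol = np.zeros((matrix, matrix, matrix), dtype=complex)
    for comp in phantom.compartments:
        cx, cy, cz = comp.center
        inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= comp.radius ** 2
        vol[inside] += comp.amplitude
    return vol


def gaussian_coil_profiles(n_coils: int, matrix: int,
                           rel_width: float = 0.9) -> np.ndarray:
    """Synthetic smooth coil sensitivities, shape (coils, matrix^3 grid).

    Gaussian-weighted fields centered on a ring around the volume; no claim
    of resembling a specific physical array.
    """
    x = np.arange(matrix) - matrix // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    sigma = rel_width * matrix / 2.0
    angles = 2.0 * np.pi * np.arange(n_coils) / max(n_coils, 1)
    r0 = 0.6 * matrix / 2.0
    coils = []
    for i, ang in enumerate(angles):
        cx, cy = r0 * np.cos(ang), r0 * np.sin(ang)
        cz = 0.3 * matrix / 2.0 * np.sin(3 * ang)
        g = np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
                     / (2 * sigma ** 2)))
        coils.append(g * np.exp(1j * (0.5 * ang + 2.0 * np.pi * 0.1 * i)))
    return np.asarray(coils)


def simulate_acquisition(
    phantom: PhantomSpec,
    spoke_set: SpokeSet,
    model: ImperfectionModel = IDENTITY_MODEL,
    coil_profiles: Optional[np.ndarray] = None,
    seed: int = 0,
    seq: Optional[SequenceParams] = None,
    phase_increment_deg: Optional[float] = None,
) -> KSpaceData:
    """Simulate the radial acquisition of ``phantom`` along ``spoke_set``.

    Single-coil mode (``coil_profiles=None``) samples the analytic ball
    transform at the *effective* (corrupted) coordinates, applies the
    direction-odd spoke phase, and adds seeded complex Gaussian noise.
    Multi-coil mode evaluates a discrete non-uniform forward transform of
    the sensitivity-weighted rasterized phantom at the same coordinates.
    Nominal coordinates are stored for reconstruction, which must not see
    the effective ones.

    In tissue (contrast) mode pass ``seq`` and ``phase_increment_deg``; the
    compartment amplitudes are replaced by their bSSFP signal first.
    """
    if phantom.has_tissue:
        if seq is None or phase_increment_deg is None:
            raise ValueError("tissue-mode phantom requires seq and phase_increment_deg")
        phantom = bssfp_contrast_weights(phantom, seq, phase_increment_deg)

    cfg = spoke_set.config
    nominal = spoke_set.sample_positions()
    effective, phase = corrupt_spokes(spoke_set, model)
    spoke_factor = np.exp(1j * phase)

    if coil_profiles is None:
        clean = _phantom_transform(phantom, effective)
        data = (clean * spoke_factor[:, None])[:, :, None]
    else:
        coil_profiles = np.asarray(coil_profiles)
        matrix = coil_profiles.shape[1]
        vol = rasterize_phantom(phantom, matrix)
        flat = effective.reshape(-1, 3)
        coils = []
        for prof in coil_profiles:
            vals = _gridding.grid_forward(vol * prof, flat)
            coils.append(vals.reshape(effective.shape[:2]) * spoke_factor[:, None])
        data = np.stack(coils, axis=-1)

    if model.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sigma_abs = model.noise_sigma * phantom.dc_magnitude
        noise = rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        data = data + noise * (sigma_abs / np.sqrt(2.0))

    return KSpaceData(
        samples=data,
        nominal_coords=nominal,
        effective_coords=effective,
        spoke_set=spoke_set,
        center_index=cfg.center_index,
        meta={
            "seed": seed,
            "phase_coeffs": model.phase_coeffs,
            "delays": model.delays,
            "global_delay": model.global_delay,
            "noise_sigma": model.noise_sigma,
        },
    )


def simulate_phase_cycled_series(
    phantom: PhantomSpec,
    spoke_set: SpokeSet,
    seq: SequenceParams,
    model: ImperfectionModel = IDENTITY_MODEL,
    seed: int = 0,
) -> list:
    """Simulate one acquisition per RF phase increment of ``seq``.

    Equivalent to calling :func:`simulate_acquisition` per increment, but the
    per-compartment unit transforms are evaluated once and recombined with
    the increment-dependent bSSFP amplitudes, which makes a full
    phase-cycled series cheap. Single-coil only. Noise is seeded per
    increment from ``seed``.
    """
    if not phantom.has_tissue:
        raise ValueError("phase-cycled series requires a tissue-mode phantom")
    cfg = spoke_set.config
    nominal = spoke_set.sample_positions()
    effective, phase = corrupt_spokes(spoke_set, model)
    spoke_factor = np.exp(1j * phase)[:, None]
    units = [analytic_ball_transform(replace(c, amplitude=1.0 + 0j), effective)
             for c in phantom.compartments]
    series = []
    for i, inc in enumerate(seq.rf_phase_increments_deg):
        weighted = bssfp_contrast_weights(phantom, seq, inc)
        data = np.zeros(effective.shape[:2], dtype=complex)
        for unit, comp in zip(units, weighted.compartments):
            data += comp.amplitude * unit
        data = (data * spoke_factor)[:, :, None]
        if model.noise_sigma > 0:
            rng = np.random.default_rng(seed + i)
            sigma_abs = model.noise_sigma * weighted.dc_magnitude
            noise = rng.standard_normal(data.shape) \
                + 1j * rng.standard_normal(data.shape)
            data = data + noise * (sigma_abs / np.sqrt(2.0))
        series.append(KSpaceData(
            samples=data, nominal_coords=nominal, effective_coords=effective,
            spoke_set=spoke_set, center_index=cfg.center_index,
            meta={"seed": seed, "phase_increment_deg": float(inc),
                  "phase_coeffs": model.phase_coeffs, "delays": model.delays,
                  "global_delay": model.global_delay,
                  "noise_sigma": model.noise_sigma},
        ))
    return series


def bssfp_contrast_weights(phantom: PhantomSpec, seq: SequenceParams,
                           phase_increment_deg: float) -> PhantomSpec:
    """Set compartment amplitudes to their bSSFP signal at one increment.

    The steady-state signal of each compartment's tissue replaces its
    amplitude, scaled by the compartment's geometric amplitude fraction so
    that soft-edged (nested-shell) compartments keep their spatial profile.
    """
    if not phantom.has_tissue:
        raise ValueError("phantom compartments carry no tissue parameters")
    amps = [
        c.amplitude
        * complex(bssfp_signal(c.tissue, seq, increments_deg=[phase_increment_deg])[0])
        for c in phantom.compartments
    ]
    return phantom.with_amplitudes(amps)
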