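"""3D radial spiral phyllotaxis trajectory generation.

A 3D radial acquisition samples straight lines ("spokes") through the center
of k-space. In the spiral phyllotaxis scheme the spoke start directions are
placed on the unit sphere with the azimuth advancing by the golden angle
``pi*(3 - sqrt(5))`` from one spoke index to the next, while the polar angle
follows a design-specific linear schedule:

``original``
    the polar angle grows from the pole to the equator, so every spoke starts
    in the upper hemisphere;
``pole_to_pole``
    the polar angle sweeps all the way from one pole to the other, so spokes
    start from both hemispheres and nearly opposing spoke pairs occur
    throughout the scan;
``continuous``
    the polar angle traverses the full circle ``[0, 2*pi)``, returning to the
    starting pole at the end of the scan, which shrinks the k-space jump
    between the end of one interleave and the start of the next.

Spokes are acquired in ``K`` interleaves of ``J`` spokes each; the spoke with
phyllotaxis index ``n`` is the ``j``-th spoke of interleave ``k`` through
``n = k + (j - 1) * K``. When ``K`` is a Fibonacci number consecutive spokes
of one interleave have nearly equal azimuths, giving a smooth trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "GOLDEN_ANGLE",
    "ConfigurationError",
    "TrajectoryConfig",
    "SpokeSet",
    "azimuthal_angle",
    "polar_angle_original",
    "polar_angle_pole_to_pole",
    "polar_angle_continuous",
    "interleave_order",
    "spoke_direction",
    "build_spoke_set",
    "sample_positions",
]

#: Golden-angle azimuthal increment in radians, ``pi * (3 - sqrt(5))``.
GOLDEN_ANGLE: float = float(np.pi * (3.0 - np.sqrt(5.0)))

Design = Literal["original", "pole_to_pole", "continuous"]
DESIGNS = ("original", "pole_to_pole", "continuous")
SI_SPOKE_MODES = ("formula", "replace_with_z")


class ConfigurationError(ValueError):
    """Raised for inconsistent trajectory configurations."""


@dataclass(frozen=True)
class TrajectoryConfig:
    """Parametric description of one phyllotaxis trajectory.

    Parameters
    ----------
    n_spokes:
        Total number of spokes ``N``; must equal
        ``n_interleaves * spokes_per_interleave``.
    n_interleaves:
        Number of interleaves ``K`` (one interleave is a contiguous shot,
        e.g. one heartbeat).
    design:
        One of ``original``, ``pole_to_pole``, ``continuous``.
    golden_angle:
        Azimuthal increment in radians; defaults to ``pi*(3 - sqrt(5))``.
    samples_per_spoke:
        Number of readout samples per spoke. Odd counts place one sample
        exactly at the k-space center (recommended; the center-phase
        diagnostics rely on it).
    k_max:
        Radial k-space extent in cycles/voxel; 0.5 is the Nyquist limit of
        an isotropic matrix.
    si_spoke_mode:
        ``formula`` leaves the first spoke of each interleave where the
        phyllotaxis formulas put it; ``replace_with_z`` overwrites it with an
        exact superior-inferior spoke along +z (the self-gating convention).
    """

    n_spokes: int
    n_interleaves: int
    design: Design = "original"
    golden_angle: float = GOLDEN_ANGLE
    samples_per_spoke: int = 49
    k_max: float = 0.5
    si_spoke_mode: str = "formula"

    def __post_init__(self) -> None:
        if self.n_spokes < 1 or self.n_interleaves < 1:
            raise ConfigurationError("n_spokes and n_interleaves must be positive")
        if self.n_spokes % self.n_interleaves:
            raise ConfigurationError(
                f"n_spokes={self.n_spokes} is not a multiple of "
                f"n_interleaves={self.n_interleaves}"
            )
        if not 0.0 < self.golden_angle < 2.0 * np.pi:
            raise ConfigurationError("golden_angle must lie in (0, 2*pi)")
        if self.samples_per_spoke < 3:
            raise ConfigurationError("samples_per_spoke must be >= 3")
        if self.k_max <= 0:
            raise ConfigurationError("k_max must be positive")
        if self.design not in DESIGNS:
            raise ConfigurationError(f"unknown design {self.design!r}")
        if self.si_spoke_mode not in SI_SPOKE_MODES:
            raise ConfigurationError(f"unknown si_spoke_mode {self.si_spoke_mode!r}")
        if self.design == "pole_to_pole" and self.n_spokes % 2:
            raise ConfigurationError("pole_to_pole requires an even number of spokes")
        if self.design == "continuous" and self.n_spokes % 4:
            raise ConfigurationError("continuous requires n_spokes divisible by 4")

    @property
    def spokes_per_interleave(self) -> int:
        """Spokes per interleave ``J = N / K``."""
        return self.n_spokes // self.n_interleaves

    @property
    def center_index(self) -> int:
        """Readout index of the sample closest to the k-space center."""
        return (self.samples_per_spoke - 1) // 2 if self.samples_per_spoke % 2 \
            else self.samples_per_spoke // 2

    @property
    def delta_k(self) -> float:
        """Spacing between consecutive readout samples in cycles/voxel."""
        return 2.0 * self.k_max / (self.samples_per_spoke - 1)

    def replace(self, **kwargs) -> "TrajectoryConfig":
        return replace(self, **kwargs)


def _check_spoke_index(n: np.ndarray, n_spokes: int) -> np.ndarray:
    n = np.asarray(n)
    if np.any(n < 1) or np.any(n > n_spokes):
        raise IndexError(f"spoke index out of range 1..{n_spokes}")
    return n


def azimuthal_angle(n, cfg: TrajectoryConfig):
    """Azimuth of spoke ``n`` (1-based): ``(n * golden_angle) mod 2*pi``."""
    n = _check_spoke_index(n, cfg.n_spokes)
    return np.mod(n * cfg.golden_angle, 2.0 * np.pi)


def polar_angle_original(n, n_spokes: int):
    """Original-design polar angle ``(pi/2) * n / N``, pole to equator."""
    n = _check_spoke_index(n, n_spokes)
    return (np.pi / 2.0) * (n / n_spokes)


def polar_angle_pole_to_pole(n, n_spokes: int):
    """Pole-to-pole polar schedule over ``[0, pi]``.

    First half descends from the +z pole to the equator at twice the original
    rate, second half continues to the −z pole; both branches meet at
    ``pi/2`` for ``n = N/2``.
    """
    if n_spokes % 2:
        raise ConfigurationError("pole_to_pole schedule requires even N")
    n = _check_spoke_index(n, n_spokes)
    n = np.asarray(n, dtype=float)
    first = (np.pi / 2.0) * (2.0 * n / n_spokes)
    second = np.pi - (np.pi / 2.0) * (2.0 * (n_spokes - n) / n_spokes)
    return np.where(n < n_spokes / 2, first, second)


def polar_angle_continuous(n, n_spokes: int):
    """Continuous polar schedule over the full circle ``[0, 2*pi]``.

    Four linear segments meeting at ``pi/2``, ``pi`` and ``3*pi/2`` at
    ``n = N/4``, ``N/2`` and ``3N/4``; ``n = N`` maps to ``2*pi``, i.e. back
    to the +z pole after direction conversion.
    """
    if n_spokes % 4:
        raise ConfigurationError("continuous schedule requires N divisible by 4")
    n = _check_spoke_index(n, n_spokes)
    n = np.asarray(n, dtype=float)
    N = float(n_spokes)
    seg1 = (np.pi / 2.0) * (4.0 * n / N)
    seg2 = np.pi - (np.pi / 2.0) * (4.0 * (N / 2.0 - n) / N)
    seg3 = np.pi + (np.pi / 2.0) * (4.0 * (n - N / 2.0) / N)
    seg4 = 2.0 * np.pi - (np.pi / 2.0) * (4.0 * (N - n) / N)
    out = np.select(
        [n < N / 4, n < N / 2, n < 3 * N / 4],
        [seg1, seg2, seg3],
        default=seg4,
    )
    return out


def interleave_order(j, k, cfg: TrajectoryConfig):
    """Phyllotaxis index of the ``j``-th spoke of interleave ``k``.

    ``n(j, k) = k + (j - 1) * K`` with 1-based ``j`` and ``k``.
    """
    j = np.asarray(j)
    k = np.asarray(k)
    if np.any(j < 1) or np.any(j > cfg.spokes_per_interleave):
        raise IndexError(f"j out of range 1..{cfg.spokes_per_interleave}")
    if np.any(k < 1) or np.any(k > cfg.n_interleaves):
        raise IndexError(f"k out of range 1..{cfg.n_interleaves}")
    return k + (j - 1) * cfg.n_interleaves


def spoke_direction(theta, phi):
    """Unit vector ``(sin t cos p, sin t sin p, cos t)`` for polar/azimuth angles.

    Polar angles beyond ``pi`` (continuous design) are evaluated literally,
    which is equivalent to polar ``2*pi - theta`` with azimuth ``phi + pi``
    and realizes the pole-crossing path.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack(
        [st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1
    )


_POLAR_SCHEDULES = {
    "original": polar_angle_original,
    "pole_to_pole": polar_angle_pole_to_pole,
    "continuous": polar_angle_continuous,
}


@dataclass
class SpokeSet:
    """Ordered set of spokes in chronological acquisition order.

    Arrays are stored interleave-major (interleave 1 first, its spokes in
    within-interleave order), which is the order the scanner plays them out.
    ``n`` is the 1-based phyllotaxis index entering the angle formulas.
    """

    config: TrajectoryConfig
    n: np.ndarray            # (S,) phyllotaxis index, 1-based
    interleave: np.ndarray   # (S,) k, 1-based
    within: np.ndarray       # (S,) j, 1-based
    theta: np.ndarray        # (S,) polar angle [rad]
    phi: np.ndarray          # (S,) azimuth [rad] in [0, 2*pi)
    directions: np.ndarray   # (S, 3) unit start directions
    is_si_spoke: np.ndarray  # (S,) bool, first spoke of each interleave

    def __len__(self) -> int:
        return self.n.size

    @property
    def upper_mask(self) -> np.ndarray:
        """True where the spoke starts in the upper hemisphere (z >= 0)."""
        return self.directions[:, 2] >= 0.0

    @property
    def start_hemisphere(self) -> np.ndarray:
        """Per-spoke label ``'upper'``/``'lower'`` from the start z-sign."""
        return np.where(self.upper_mask, "upper", "lower")

    def subset(self, index) -> "SpokeSet":
        """New SpokeSet restricted to ``index`` (bool mask or int indices)."""
        return SpokeSet(
            config=self.config,
            n=self.n[index],
            interleave=self.interleave[index],
            within=self.within[index],
            theta=self.theta[index],
            phi=self.phi[index],
            directions=self.directions[index],
            is_si_spoke=self.is_si_spoke[index],
        )

    def sample_positions(self) -> np.ndarray:
        """Readout sample coordinates, shape ``(S, M, 3)`` in cycles/voxel."""
        return sample_positions(self.directions, self.config)


def build_spoke_set(cfg: TrajectoryConfig) -> SpokeSet:
    """Generate all spokes of ``cfg`` in chronological acquisition order."""
    J, K = cfg.spokes_per_interleave, cfg.n_interleaves
    kk = np.repeat(np.arange(1, K + 1), J)
    jj = np.tile(np.arange(1, J + 1), K)
    n = interleave_order(jj, kk, cfg)
    phi = azimuthal_angle(n, cfg)
    theta = np.asarray(_POLAR_SCHEDULES[cfg.design](n, cfg.n_spokes), dtype=float)
    dirs = spoke_direction(theta, phi)
    is_si = jj == 1
    if cfg.si_spoke_mode == "replace_with_z":
        dirs = dirs.copy()
        dirs[is_si] = (0.0, 0.0, 1.0)
        theta = theta.copy()
        theta[is_si] = 0.0
    return SpokeSet(
        config=cfg, n=n, interleave=kk, within=jj,
        theta=theta, phi=phi, directions=dirs, is_si_spoke=is_si,
    )


def sample_positions(directions, cfg: TrajectoryConfig) -> np.ndarray:
    """Sample coordinates along full spokes.

    ``M = cfg.samples_per_spoke`` equally spaced samples from
    ``+k_max * d`` (start point) to ``-k_max * d`` inclusive; with odd ``M``
    the center sample lies exactly at the origin.

    ``directions`` may be a single 3-vector or an ``(S, 3)`` array; the
    result has shape ``(M, 3)`` or ``(S, M, 3)``.
    """
    d = np.asarray(directions, dtype=float)
    radii = np.linspace(cfg.k_max, -cfg.k_max, cfg.samples_per_spoke)
    return d[..., None, :] * radii[:, None]
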