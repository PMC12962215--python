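"""Opposing-spoke phase compensation and gradient-delay correction.

Both corrections exploit that a pole-to-pole (or continuous) trajectory
acquires, for every spoke, a nearly antipodal partner:

* the **constant-phase correction** transfers the k-space-center phase of
  the closest opposing spoke onto each spoke as a constant per-coil phase
  factor. A direction-odd zeroth-order phase error takes opposite values on
  a spoke and its partner, so the transferred phase cancels the
  inconsistency (spoke and partner end up carrying twice the direction-even
  component, which is spatially smooth and harmless to the magnitude);
* the **gradient-delay correction** compares each spoke's 1D projection
  (inverse FT along the readout) with its partner's reversed projection,
  fits a line to the unwrapped phase difference where the projection has
  signal, and removes half of the fitted slope+intercept per spoke so that
  both members of a pair move symmetrically. The slope maps to the sample
  shift induced by gradient delays; the intercept carries the zeroth-order
  phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import KSpaceData
from .trajectory import SpokeSet

__all__ = [
    "CenterPhaseTable",
    "OpposingPairMap",
    "DelayFit",
    "extract_center_phase",
    "split_hemispheres",
    "find_opposing",
    "opposing_phase_correction",
    "gradient_delay_correction",
]


@dataclass
class CenterPhaseTable:
    """k-space-center phase per retained spoke and coil, in (-pi, pi].

    ``valid`` is False where the center sample magnitude is exactly zero
    (phase undefined); such entries are NaN rather than silently zero.
    """

    phase: np.ndarray        # (S, C)
    valid: np.ndarray        # (S, C) bool
    theta: np.ndarray        # (S,)
    phi: np.ndarray          # (S,)
    directions: np.ndarray   # (S, 3)
    n: np.ndarray            # (S,) phyllotaxis index
    interleave: np.ndarray   # (S,)
    within: np.ndarray       # (S,)


@dataclass
class OpposingPairMap:
    """Per spoke: position of the nearest opposing spoke and the angular gap.

    ``partner`` indexes positions within the same KSpaceData/SpokeSet; the
    partner always starts in the opposite hemisphere. ``gap`` is the angle
    between ``d_i`` and ``-d_partner(i)`` in [0, pi].
    """

    partner: np.ndarray      # (S,) int
    gap: np.ndarray          # (S,) rad
    upper: np.ndarray        # (S,) bool, hemisphere of spoke i


@dataclass
class DelayFit:
    """Per-spoke linear fit of the opposing-projection phase difference.

    ``slope`` is in radians per projection bin, ``intercept`` in radians;
    ``delay_samples`` maps the slope to the implied per-spoke readout shift
    in sample units. ``fitted`` is False where the fit region was empty.
    """

    slope: np.ndarray
    intercept: np.ndarray
    delay_samples: np.ndarray
    fitted: np.ndarray
    partner: np.ndarray
    mask_fraction: np.ndarray
    meta: dict = field(default_factory=dict)


def extract_center_phase(kspace: KSpaceData) -> CenterPhaseTable:
    """Phase of the k-space-center sample for every spoke and coil."""
    center = kspace.samples[:, kspace.center_index, :]
    mag = np.abs(center)
    valid = mag > 0
    phase = np.where(valid, np.angle(center), np.nan)
    ss = kspace.spoke_set
    return CenterPhaseTable(
        phase=phase, valid=valid, theta=ss.theta, phi=ss.phi,
        directions=ss.directions, n=ss.n,
        interleave=ss.interleave, within=ss.within,
    )


def split_hemispheres(kspace: KSpaceData):
    """Partition the data into upper- and lower-hemisphere starting spokes.

    Each subset is a standalone KSpaceData usable for reconstruction (a
    hemisphere-only reconstruction reproduces the single-hemisphere artifact
    of the original design). Raises for the original design, which has a
    single hemisphere.
    """
    if kspace.config.design == "original":
        raise ValueError("original design has a single start hemisphere")
    upper = kspace.spoke_set.upper_mask
    return kspace.subset(upper), kspace.subset(~upper)


def find_opposing(spoke_set: SpokeSet) -> OpposingPairMap:
    """Nearest opposing spoke for every spoke, by exhaustive search.

    For spoke ``i`` the partner is the spoke from the opposite start
    hemisphere minimizing the angle between ``d_i`` and ``-d_j``; ties are
    broken by the lower phyllotaxis index ``n``.
    """
    upper = spoke_set.upper_mask
    if not upper.any() or upper.all():
        raise ValueError("opposing-spoke search requires spokes in both hemispheres")
    d = spoke_set.directions
    n_idx = spoke_set.n
    pos = np.arange(len(spoke_set))
    partner = np.empty(len(spoke_set), dtype=int)
    gap = np.empty(len(spoke_set))
    for hemi_mask in (upper, ~upper):
        cand_pos = pos[~hemi_mask]
        cand_d = d[~hemi_mask]
        cand_n = n_idx[~hemi_mask]
        # cos of angle between d_i and -d_j
        dots = d[hemi_mask] @ (-cand_d.T)
        for row, i in enumerate(pos[hemi_mask]):
            best = dots[row].max()
            ties = np.flatnonzero(dots[row] >= best)
            if ties.size > 1:
                ties = ties[np.argsort(cand_n[ties], kind="stable")]
            j = ties[0]
            partner[i] = cand_pos[j]
            gap[i] = np.arccos(np.clip(dots[row, j], -1.0, 1.0))
    return OpposingPairMap(partner=partner, gap=gap, upper=upper)


def opposing_phase_correction(kspace: KSpaceData, pairs: OpposingPairMap,
                              table: CenterPhaseTable):
    """Constant-phase compensation from the opposing spoke's center phase.

    Every sample of spoke ``i`` and coil ``c`` is multiplied by the
    unit-magnitude phase factor of the partner's center sample so that the
    direction-odd phase inconsistency between the pair cancels (see module
    docstring for the sign convention). Magnitudes are unchanged exactly.
    Spokes whose partner phase is undefined are left uncorrected and
    reported in the returned list.
    """
    if table.phase.shape[0] != kspace.n_spokes:
        raise ValueError("center-phase table inconsistent with k-space data")
    partner_phase = table.phase[pairs.partner]   # (S, C)
    partner_valid = table.valid[pairs.partner]
    factor = np.where(partner_valid, np.exp(1j * partner_phase), 1.0)
    corrected = kspace.samples * factor[:, None, :]
    uncorrected = np.flatnonzero(~partner_valid.all(axis=1))
    out = kspace.with_samples(corrected)
    out.meta["opposing_phase_corrected"] = True
    out.meta["uncorrected_spokes"] = uncorrected.tolist()
    return out, uncorrected


def _ifft_readout(samples: np.ndarray) -> np.ndarray:
    """Centered inverse FT along the readout, samples ordered +k -> -k."""
    inc = samples[:, ::-1, :]  # increasing k
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(inc, axes=1), axis=1), axes=1)


def _fft_readout(proj: np.ndarray) -> np.ndarray:
    inc = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(proj, axes=1), axis=1), axes=1)
    return inc[:, ::-1, :]


def gradient_delay_correction(
    kspace: KSpaceData,
    pairs: OpposingPairMap,
    apply: str = "half",
    coil_mode: str = "complex",
    magnitude_threshold: float = 0.1,
):
    """Opposing-projection gradient-delay (and phase-offset) correction.

    Per spoke: (a) inverse FT along the readout; (b) the partner's
    projection is reversed because opposing spokes traverse the same line in
    opposite directions; (c) the per-coil phase differences are combined —
    by a magnitude-weighted complex sum (``coil_mode='complex'``) or a plain
    sum of angles (``'sum'``); (d) the unwrapped phase difference is fitted
    linearly against the projection bin where the combined projection
    magnitude exceeds ``magnitude_threshold`` of its maximum; (e) half the
    fitted line (``apply='half'``) is removed from every spoke, moving both
    members of a pair symmetrically, or the full line from upper-hemisphere
    spokes only (``apply='full'``).

    Returns the corrected KSpaceData and a :class:`DelayFit` report.
    """
    if apply not in ("half", "full"):
        raise ValueError("apply must be 'half' or 'full'")
    if coil_mode not in ("complex", "sum"):
        raise ValueError("coil_mode must be 'complex' or 'sum'")
    M = kspace.n_samples
    if M < 16:
        raise ValueError("gradient-delay fit needs at least 16 readout samples")
    if M % 2 == 0:
        raise ValueError("gradient-delay correction requires an odd sample count")

    proj = _ifft_readout(kspace.samples)      # (S, M, C), bin x = idx - M//2
    x = np.arange(M) - M // 2
    S = kspace.n_spokes
    slope = np.zeros(S)
    intercept = np.zeros(S)
    fitted = np.zeros(S, dtype=bool)
    mask_frac = np.zeros(S)

    proj_rev = proj[pairs.partner][:, ::-1, :]     # partner at -x
    cross = proj * np.conj(proj_rev)               # (S, M, C)
    if coil_mode == "complex":
        combined = cross.sum(axis=2)
        weight = np.abs(combined)
        delta_all = np.angle(combined)
    else:
        delta_all = np.angle(cross).sum(axis=2)
        weight = np.abs(cross).sum(axis=2)

    for i in range(S):
        w = weight[i]
        wmax = w.max()
        if wmax <= 0:
            warnings.warn(f"spoke {i}: all-zero projection, left uncorrected")
            continue
        mask = np.sqrt(w) > magnitude_threshold * np.sqrt(wmax)
        if mask.sum() < 2:
            warnings.warn(f"spoke {i}: fit region empty, left uncorrected")
            continue
        xm = x[mask]
        dm = np.unwrap(delta_all[i][mask])
        wm = w[mask]
        a, b = np.polyfit(xm, dm, 1, w=np.sqrt(wm))
        slope[i], intercept[i] = a, b
        fitted[i] = True
        mask_frac[i] = mask.mean()

    factor = 0.5 if apply == "half" else 1.0
    correct_mask = fitted if apply == "half" else (fitted & pairs.upper)
    line = slope[:, None] * x[None, :] + intercept[:, None]
    phase = np.where(correct_mask[:, None], factor * line, 0.0)
    proj_corr = proj * np.exp(-1j * phase)[:, :, None]
    corrected = _fft_readout(proj_corr)

    # pair-difference slope = 4*pi*delta_k_shift per bin; per-spoke shift is
    # half of that, and one projection bin spans 1/(M*delta_k) voxels.
    delay_samples = slope * M / (4.0 * np.pi)
    out = kspace.with_samples(corrected)
    out.meta["gradient_delay_corrected"] = apply
    fit = DelayFit(
        slope=slope, intercept=intercept, delay_samples=delay_samples,
        fitted=fitted, partner=pairs.partner, mask_fraction=mask_frac,
        meta={"apply": apply, "coil_mode": coil_mode,
              "magnitude_threshold": magnitude_threshold},
    )
    return out, fit
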