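"""Kaiser-Bessel gridding primitives (3D non-uniform <-> Cartesian).

Implements the standard convolution-gridding pair: samples at arbitrary
k-space locations are spread onto (adjoint) or gathered from (forward) an
oversampled Cartesian grid with a finite-support Kaiser-Bessel kernel, FFTs
move between k-space and image space, and the image is divided by the
kernel's continuous Fourier transform (deapodization).

Conventions
-----------
* k coordinates are in cycles/voxel, in ``[-0.5, 0.5]``.
* image coordinates are integer voxel offsets centered on ``matrix // 2``.
* the adjoint computes ``f(x) = sum_i s_i exp(+2j*pi*k_i.x)`` (up to the
  controlled gridding approximation error), the forward its exact transpose
  ``s(k_i) = sum_x f(x) exp(-2j*pi*k_i.x)``.

The kernel shape parameter follows Beatty's minimal-aliasing rule
``beta = pi * sqrt(W^2/os^2 * (os - 0.5)^2 - 0.8)``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import i0


def kernel_beta(width: int, oversampling: float) -> float:
    return float(np.pi * np.sqrt((width / oversampling) ** 2
                                 * (oversampling - 0.5) ** 2 - 0.8))


def grid_size(matrix: int, oversampling: float) -> int:
    g = int(round(matrix * oversampling))
    return g + (g % 2)  # even grids keep the center bin unambiguous


def kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel on ``|u| <= width/2``, else 0."""
    u = np.asarray(u, dtype=float)
    arg = 1.0 - (2.0 * u / width) ** 2
    inside = arg > 0
    out = np.zeros_like(u)
    out[inside] = i0(beta * np.sqrt(arg[inside]))
    return out


@lru_cache(maxsize=32)
def _apodization_1d(matrix: int, gsize: int, width: int,
                    beta_key: int) -> np.ndarray:
    """Continuous FT of the kernel at the cropped image positions.

    ``a(x) = int_{-W/2}^{W/2} C(u) cos(2*pi*u*x/G) du`` evaluated by
    Simpson quadrature for ``x`` on the centered matrix grid.
    """
    from scipy.integrate import simpson

    beta = beta_key / 1e9
    x = np.arange(matrix) - matrix // 2
    u = np.linspace(-width / 2.0, width / 2.0, 2049)
    c = kb_kernel(u, width, beta)
    integrand = c[None, :] * np.cos(2.0 * np.pi * u[None, :] * x[:, None] / gsize)
    return simpson(integrand, x=u, axis=1)


def apodization_1d(matrix: int, gsize: int, width: int, beta: float) -> np.ndarray:
    return _apodization_1d(matrix, gsize, width, int(round(beta * 1e9)))


def _tap_indices(coords: np.ndarray, gsize: int, width: int, beta: float):
    """Per-axis grid indices and kernel weights for every sample.

    Returns ``idx`` (3, P, W) wrapped integer indices and ``wts`` (3, P, W).
    """
    u = coords * gsize + gsize / 2.0  # (P, 3)
    first = np.floor(u - width / 2.0).astype(np.int64) + 1  # (P, 3)
    offs = np.arange(width)
    idx = first[..., None] + offs  # (P, 3, W)
    wts = kb_kernel(idx - u[..., None], width, beta)
    idx = np.mod(idx, gsize)
    return np.moveaxis(idx, 1, 0), np.moveaxis(wts, 1, 0)


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if np.any(np.abs(coords) > 0.5 + 1e-9):
        raise ValueError("k-space coordinates must lie within +-0.5 cycles/voxel")
    return coords


def grid_adjoint(coords: np.ndarray, values: np.ndarray, matrix: int,
                 oversampling: float = 1.5, width: int = 5) -> np.ndarray:
    """Adjoint gridding of complex ``values`` at ``coords`` onto ``matrix^3``."""
    coords = _check_coords(coords)
    values = np.asarray(values).reshape(-1)
    if values.size != coords.shape[0]:
        raise ValueError("values and coords disagree in length")
    G = grid_size(matrix, oversampling)
    beta = kernel_beta(width, oversampling)
    idx, wts = _tap_indices(coords, G, width, beta)

    grid_r = np.zeros(G * G * G)
    grid_i = np.zeros(G * G * G)
    vr, vi = values.real, values.imag
    for a in range(width):
        ia, wa = idx[0][:, a], wts[0][:, a]
        for b in range(width):
            iab = (ia * G + idx[1][:, b])
            wab = wa * wts[1][:, b]
            for c in range(width):
                flat = iab * G + idx[2][:, c]
                w = wab * wts[2][:, c]
                grid_r += np.bincount(flat, weights=w * vr, minlength=G ** 3)
                grid_i += np.bincount(flat, weights=w * vi, minlength=G ** 3)
    grid = (grid_r + 1j * grid_i).reshape(G, G, G)

    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))) * G ** 3
    lo = G // 2 - matrix // 2
    img = img[lo:lo + matrix, lo:lo + matrix, lo:lo + matrix]
    apod = apodization_1d(matrix, G, width, beta)
    img /= apod[:, None, None] * apod[None, :, None] * apod[None, None, :]
    return img


def grid_forward(image: np.ndarray, coords: np.ndarray,
                 oversampling: float = 1.5, width: int = 5) -> np.ndarray:
    """Sample the DFT of ``image`` at non-uniform ``coords`` (type-2 transform)."""
    image = np.asarray(image)
    matrix = image.shape[0]
    if image.shape != (matrix, matrix, matrix):
        raise ValueError("image must be a cube")
    coords = _check_coords(coords)
    G = grid_size(matrix, oversampling)
    beta = kernel_beta(width, oversampling)
    apod = apodization_1d(matrix, G, width, beta)
    pre = image / (apod[:, None, None] * apod[None, :, None] * apod[None, None, :])

    padded = np.zeros((G, G, G), dtype=complex)
    lo = G // 2 - matrix // 2
    padded[lo:lo + matrix, lo:lo + matrix, lo:lo + matrix] = pre
    grid = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))

    idx, wts = _tap_indices(coords, G, width, beta)
    flat_grid = grid.reshape(-1)
    out = np.zeros(coords.shape[0], dtype=complex)
    for a in range(width):
        ia, wa = idx[0][:, a], wts[0][:, a]
        for b in range(width):
            iab = ia * G + idx[1][:, b]
            wab = wa * wts[1][:, b]
            for c in range(width):
                flat = iab * G + idx[2][:, c]
                out += (wab * wts[2][:, c]) * flat_grid[flat]
    return out


def adjoint_dft_reference(coords: np.ndarray, values: np.ndarray,
                          matrix: int, chunk: int = 4096) -> np.ndarray:
    """Naive O(P * matrix^3) adjoint DFT, ``sum_i s_i exp(+2j*pi*k_i.x)``.

    Exact (no kernel approximation); used as the gridding oracle at small
    matrix sizes.
    """
    coords = _check_coords(coords)
    values = np.asarray(values).reshape(-1)
    x = np.arange(matrix) - matrix // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    pos = np.stack([X, Y, Z], axis=-1).reshape(-1, 3).astype(float)
    img = np.zeros(pos.shape[0], dtype=complex)
    for start in range(0, coords.shape[0], chunk):
        ks = coords[start:start + chunk]
        vs = values[start:start + chunk]
        img += np.exp(2j * np.pi * (pos @ ks.T)) @ vs
    return img.reshape(matrix, matrix, matrix)
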