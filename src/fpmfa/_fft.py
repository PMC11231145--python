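"""Centered FFT helpers shared by the simulator and the reconstruction.

All spectra in this package live on DC-at-center grids.  The ``norm="forward"``
convention (forward transform divides by the pixel count, inverse does not)
is used on both the low- and high-resolution grids so that cropping a spectral
window and inverse-transforming it needs no extra scale factor: a unit field
has a DC sample of exactly 1 on either grid.
"""

from __future__ import annotations

import numpy as np


def fft2c(x: np.ndarray) -> np.ndarray:
    """Forward 2-D FFT to a DC-at-center spectrum (spatial origin at corner)."""
    return np.fft.fftshift(np.fft.fft2(x, norm="forward"))


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.ifft2(np.fft.ifftshift(x), norm="forward")


def window_slices(hr_shape: tuple[int, int], lr_shape: tuple[int, int],
                  offset: tuple[int, int]) -> tuple[slice, slice]:
    """Slices selecting a low-res spectral window inside the high-res grid.

    ``offset`` is the window-center displacement from the high-res DC sample,
    in spectral samples (row, col).  Raises ``ValueError`` when the window
    would leave the grid.
    """
    sl = []
    for n_hr, n_lr, off in zip(hr_shape, lr_shape, offset):
        start = n_hr // 2 - n_lr // 2 + int(off)
        if start < 0 or start + n_lr > n_hr:
            raise ValueError(
                f"spectral window offset {offset} leaves the {hr_shape} grid")
        sl.append(slice(start, start + n_lr))
    return tuple(sl)
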