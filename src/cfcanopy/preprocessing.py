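"""Image loading and standardization for fluorescence canopy analysis.

Canopy images arrive as 8-bit PNG/TIFF, grayscale or RGB.  Every
downstream stage (histogram thresholding, cooccurrence statistics)
operates on a single-channel 0-255 intensity grid at a fixed frame
size, so this module collapses colour, resizes to the analysis frame,
and exposes the [0, 1] normalization used by the clustering stage.

Intensities stay 0-255 integers through the histogram/threshold stages;
``normalize`` is applied only immediately before K-means, mirroring the
pipeline ordering.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from skimage.transform import resize

#: Default analysis frame as (width, height).
DEFAULT_FRAME = (1388, 1038)

#: Rec. 601 luminance weights used to collapse RGB to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def load_image(path) -> np.ndarray:
    """Load an 8-bit PNG/TIFF as a 2-D uint8 intensity array.

    RGB(A) input is collapsed to grayscale with the Rec. 601 luminance
    weighting (the fluorescence channels carry nearly identical
    information, so the exact weighting is low-impact).

    Parameters
    ----------
    path : str or Path
        Image file to read.

    Returns
    -------
    numpy.ndarray
        2-D uint8 array, intensities in 0-255.

    Raises
    ------
    OSError
        If the file cannot be read as an image.
    ValueError
        If the image bit depth is not 8-bit.
    """
    with Image.open(path) as im:
        if im.mode in ("I;16", "I", "F"):
            raise ValueError(
                f"unsupported bit depth (mode {im.mode!r}); 8-bit images required"
            )
        if im.mode == "L":
            return np.asarray(im, dtype=np.uint8)
        rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
    gray = rgb @ np.asarray(LUMA_WEIGHTS)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) RGB array to uint8 luminance (Rec. 601)."""
    gray = np.asarray(rgb, dtype=np.float64) @ np.asarray(LUMA_WEIGHTS)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def standardize(img: np.ndarray, frame: tuple[int, int] = DEFAULT_FRAME,
                *, is_mask: bool = False) -> np.ndarray:
    """Resize an image (or binary mask) to the analysis frame.

    Images are resampled bilinearly; masks use nearest-neighbour so the
    labels stay binary.  Already-conforming input is returned unchanged.

    Parameters
    ----------
    img : numpy.ndarray
        2-D intensity grid or binary mask.
    frame : (int, int)
        Target (width, height); default 1388 x 1038.
    is_mask : bool
        Use nearest-neighbour interpolation and preserve label values.
    """
    width, height = frame
    if width <= 0 or height <= 0:
        raise ValueError(f"frame must have positive area, got {frame}")
    img = np.asarray(img)
    if img.shape == (height, width):
        return img
    order = 0 if is_mask else 1
    out = resize(img.astype(np.float64), (height, width), order=order,
                 preserve_range=True, anti_aliasing=False)
    if is_mask:
        return out.astype(img.dtype)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def normalize(img: np.ndarray) -> np.ndarray:
    """Map 0-255 intensities onto [0, 1] by division by 255.

    Monotone: pixel ordering is preserved.  Applied once, immediately
    before the K-means stage.
    """
    return np.asarray(img, dtype=np.float64) / 255.0
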