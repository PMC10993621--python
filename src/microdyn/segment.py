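"""Preprocessing and segmentation: projections to binary masks and soma records.

Everything downstream of this module operates on binary masks (values in
{0, 1}) and soma centroid records in physical micrometre coordinates. Real
two-photon data typically arrives as grayscale maximum projections; the
functions here provide a deterministic path (denoise -> register -> threshold
-> morphology) from such projections to the mask/centroid representation.
Externally produced masks (e.g. from a trained pixel classifier) can be fed in
directly and pass through `binarize` unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology
from skimage.registration import phase_cross_correlation


class DegenerateImageError(ValueError):
    """Raised when an image has no usable intensity structure (e.g. constant)."""


@dataclass
class TimeLapse:
    """An ordered set of 2D frames on a shared pixel grid.

    Parameters
    ----------
    frames : ndarray, shape (t, h, w)
        Frame stack, time first.
    pixel_size_um : float
        Physical size of one pixel side, micrometres.
    timestamps_min : ndarray, shape (t,)
        Acquisition time of each frame in minutes; strictly increasing.
    binary : bool
        Whether frames are binary masks (values restricted to {0, 1}).
    registration_shifts_px : ndarray or None
        (t, 2) integer shifts applied during registration, if any.
    flagged_frames : list of int
        Frames whose registration shift exceeded the configured limit.
    """

    frames: np.ndarray
    pixel_size_um: float
    timestamps_min: np.ndarray | None = None
    binary: bool = False
    registration_shifts_px: np.ndarray | None = None
    flagged_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (t, h, w), got shape {self.frames.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.timestamps_min is None:
            self.timestamps_min = np.arange(self.frames.shape[0], dtype=float)
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        if self.timestamps_min.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.timestamps_min) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.binary and not _is_binary(self.frames):
            raise ValueError("binary=True but frames contain values outside {0, 1}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])


@dataclass
class SomaRecord:
    """Per-timepoint soma centroids with stable integer labels.

    Coordinates are physical (x_um, y_um), with x along image columns and y
    along rows; centroids are centers of mass of pixel centers, 0-based.
    """

    session: str
    labels: np.ndarray
    xy_um: np.ndarray
    pixel_size_um: float = 1.0
    animal_id: str = ""
    area_range_um2: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.xy_um = np.asarray(self.xy_um, dtype=float).reshape(-1, 2)
        if self.labels.shape[0] != self.xy_um.shape[0]:
            raise ValueError("labels and coordinates must have matching length")
        if len(set(self.labels.tolist())) != len(self.labels):
            raise ValueError("soma labels must be unique")

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal_id,
                "session": self.session,
                "label": self.labels,
                "x_um": self.xy_um[:, 0],
                "y_um": self.xy_um[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pixel_size_um: float = 1.0) -> "SomaRecord":
        return cls(
            session=str(df["session"].iloc[0]) if len(df) else "",
            labels=df["label"].to_numpy(),
            xy_um=df[["x_um", "y_um"]].to_numpy(),
            pixel_size_um=pixel_size_um,
            animal_id=str(df["animal"].iloc[0]) if len(df) else "",
        )


def _is_binary(arr: np.ndarray) -> bool:
    return bool(np.isin(np.unique(arr), (0, 1)).all())


def preprocess(
    stack: TimeLapse,
    median_radius_px: int = 1,
    gaussian_sigma_px: float = 1.0,
    register: bool = False,
    max_shift_fraction: float = 0.25,
) -> TimeLapse:
    """Denoise (median then Gaussian) and optionally register a grayscale stack.

    Registration is translation-only: each frame is shifted by the integer
    pixel displacement maximizing cross-correlation with the first frame,
    padding uncovered edges with zeros. Frames whose shift exceeds
    ``max_shift_fraction`` of the smaller field dimension are flagged (and a
    warning is recorded) but still shifted.
    """
    frames = stack.frames.astype(float)
    out = np.empty_like(frames)
    footprint = morphology.disk(median_radius_px) if median_radius_px > 0 else None
    for t, frame in enumerate(frames):
        g = frame
        if footprint is not None:
            g = filters.median(g, footprint=footprint)
        if gaussian_sigma_px > 0:
            g = filters.gaussian(g, sigma=gaussian_sigma_px, preserve_range=True)
        out[t] = g

    shifts = None
    flagged: list[int] = []
    if register and stack.n_frames > 1:
        shifts = np.zeros((stack.n_frames, 2), dtype=int)
        limit = max_shift_fraction * min(stack.shape)
        ref = out[0]
        for t in range(1, stack.n_frames):
            shift, _, _ = phase_cross_correlation(ref, out[t])
            shift = np.round(shift).astype(int)
            shifts[t] = shift
            if np.hypot(*shift.astype(float)) > limit:
                flagged.append(t)
                warnings.warn(
                    f"frame {t}: registration shift {tuple(shift)} px exceeds "
                    f"{max_shift_fraction:.0%} of the field", stacklevel=2,
                )
            out[t] = ndi.shift(out[t], shift, order=0, cval=0.0)

    return TimeLapse(
        frames=out,
        pixel_size_um=stack.pixel_size_um,
        timestamps_min=stack.timestamps_min.copy(),
        binary=False,
        registration_shifts_px=shifts,
        flagged_frames=flagged,
    )


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a single 2D image to a {0, 1} mask.

    Already-binary input is returned unchanged (idempotence), so masks
    produced elsewhere flow through the pipeline untouched. ``method`` is
    ``"otsu"`` (threshold from the histogram) or ``"fixed"`` (requires
    ``threshold``; pixels >= threshold map to 1).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("binarize expects a single 2D image")
    if _is_binary(image):
        return image.astype(np.uint8)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        return (image >= threshold).astype(np.uint8)
    if method == "otsu":
        if np.all(image == image.flat[0]):
            raise DegenerateImageError("constant image: Otsu threshold undefined")
        t = filters.threshold_otsu(image)
        # threshold_otsu returns the lower class's upper edge: keep > t
        return (image > t).astype(np.uint8)
    raise ValueError(f"unknown method {method!r}")


def binarize_stack(stack: TimeLapse, method: str = "otsu", threshold: float | None = None) -> TimeLapse:
    """Apply :func:`binarize` frame-wise."""
    frames = np.stack([binarize(f, method=method, threshold=threshold) for f in stack.frames])
    return replace(stack, frames=frames, binary=True)


def extract_somas(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 20.0,
    max_area_um2: float = 400.0,
    opening_radius_um: float = 2.0,
    session: str = "",
    animal_id: str = "",
) -> SomaRecord:
    """Locate soma centroids in a binary population mask.

    Morphological opening with a disk of radius ``opening_radius_um`` removes
    thin processes; remaining connected components with area inside
    ``[min_area_um2, max_area_um2]`` are counted as somas. Centroids are
    component centers of mass in micrometres; labels are assigned in raster
    order (top-to-bottom, then left-to-right) of the centroids.
    """
    mask = np.asarray(mask)
    if not _is_binary(mask):
        raise ValueError("extract_somas expects a binary mask")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    m = mask.astype(bool)
    r_px = int(round(opening_radius_um / pixel_size_um))
    if r_px > 0:
        m = morphology.opening(m, morphology.disk(r_px))
    lab = measure.label(m, connectivity=2)
    px_area = pixel_size_um**2
    centroids = []
    for rp in measure.regionprops(lab):
        area = rp.area * px_area
        if min_area_um2 <= area <= max_area_um2:
            row, col = rp.centroid
            centroids.append((row, col))
    centroids.sort()  # raster order: by row, then column
    xy = np.array([(c * pixel_size_um, r * pixel_size_um) for r, c in centroids]).reshape(-1, 2)
    return SomaRecord(
        session=session,
        labels=np.arange(1, len(centroids) + 1),
        xy_um=xy,
        pixel_size_um=pixel_size_um,
        animal_id=animal_id,
        area_range_um2=(min_area_um2, max_area_um2),
    )
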