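"""Fluorescence co-culture plate analysis.

A co-culture plaque assay seeds a soft-agar lawn with two differentially
fluorescent host strains.  A phage that kills only the red-labelled host
leaves a fluorescence deficit in the red channel, a phage of the
green-labelled host leaves one in the green channel, and a plasmid-dependent
phage (which infects both hosts through the plasmid-encoded pilus) ablates
both signals, producing a dark plaque.  This module reads the two channel
images, rescales exposure, merges them into the red/blue display composite,
detects plaques as relative fluorescence deficits against the local lawn,
and classifies each plaque by its two-channel deficit phenotype.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

__all__ = [
    "PlaqueClass",
    "ChannelImage",
    "PlateImage",
    "PlaqueCall",
    "VisionParams",
    "read_channel_image",
    "write_channel_image",
    "rescale_exposure",
    "compose_disco_image",
    "estimate_lawn_background",
    "find_plate_disk",
    "detect_plaques",
    "classify_plaque",
    "count_plaques_by_class",
    "analyze_plate",
    "calls_to_frame",
]


class PlaqueClass(str, enum.Enum):
    """Fluorescence phenotype of a plaque in the two-host co-culture lawn."""

    RED_HOST_PHAGE = "RED_HOST_PHAGE"        # kills the red-labelled host only
    GREEN_HOST_PHAGE = "GREEN_HOST_PHAGE"    # kills the green-labelled host only
    PLASMID_DEPENDENT = "PLASMID_DEPENDENT"  # kills both hosts (dark plaque)
    ARTIFACT = "ARTIFACT"                    # below threshold in both channels

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three phage phenotypes (ARTIFACT excluded).
PHAGE_CLASSES = (
    PlaqueClass.RED_HOST_PHAGE,
    PlaqueClass.GREEN_HOST_PHAGE,
    PlaqueClass.PLASMID_DEPENDENT,
)


@dataclass
class ChannelImage:
    """A single grayscale fluorescence channel.

    Parameters
    ----------
    data:
        2-D array of nonnegative intensities (integer counts or floats in
        [0, 1] after rescaling).
    channel:
        ``"red"`` or ``"green"``.
    bit_depth:
        Bit depth of the source raster; 0 for float data.
    """

    data: np.ndarray
    channel: str = "red"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(
                f"channel image must be 2-D grayscale, got shape {self.data.shape}; "
                "split color images into channels first"
            )
        if not np.all(np.isfinite(self.data.astype(float))):
            raise ValueError("channel image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class PlateImage:
    """Two registered fluorescence channels plus the assay metadata needed
    to turn plaque counts into titers."""

    red: ChannelImage
    green: ChannelImage
    plated_volume_ml: float = 0.1
    dilution_exponent: int = 0
    sample: str = ""

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channels are not registered: red {self.red.shape} vs green {self.green.shape}"
            )
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be positive")
        if self.dilution_exponent < 0:
            raise ValueError("dilution exponent must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass
class PlaqueCall:
    """One detected plaque and its fluorescence-phenotype classification."""

    plaque_id: int
    coords: np.ndarray            # (k, 2) array of (row, col) pixel indices
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    deficit_red: float
    deficit_green: float
    plaque_class: PlaqueClass


@dataclass
class VisionParams:
    """Tunable parameters of the detection/classification pipeline.

    ``theta_d`` is the relative-deficit threshold used both for the
    candidate-pixel mask and for the per-plaque classification rule;
    ``r_bg`` is the radius (px) of the structuring disk used to estimate
    the lawn background by grayscale closing and must exceed the largest
    expected plaque radius.
    """

    p_lo: float = 0.5
    p_hi: float = 99.5
    r_bg: int = 48
    theta_d: float = 0.4
    a_min: int = 20
    connectivity: int = 2  # scikit-image convention: 2 == 8-neighbour
    watershed_split: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_lo < self.p_hi <= 100):
            raise ValueError("percentiles must satisfy 0 <= p_lo < p_hi <= 100")
        if not (0 < self.theta_d < 1):
            raise ValueError("theta_d must lie in (0, 1)")
        if self.a_min < 1:
            raise ValueError("a_min must be >= 1")
        if self.r_bg <= 0:
            raise ValueError("r_bg must be positive")


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def read_channel_image(path: str | Path, channel: str = "red") -> ChannelImage:
    """Read a single-channel grayscale TIFF/PNG losslessly.

    Color (multi-channel) rasters are rejected: the assay's channels are
    acquired separately and must be supplied as separate files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(
            f"{path} is not single-channel grayscale (shape {data.shape}); "
            "split the color image and pass one channel file at a time"
        )
    bit_depth = data.dtype.itemsize * 8 if np.issubdtype(data.dtype, np.integer) else 0
    return ChannelImage(data=data, channel=channel, bit_depth=bit_depth)


def write_channel_image(img: ChannelImage, path: str | Path) -> None:
    """Write a channel to TIFF or PNG, preserving integer intensities."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img.data)


# ---------------------------------------------------------------------------
# exposure rescale and display composite
# ---------------------------------------------------------------------------

def rescale_exposure(img: ChannelImage, p_lo: float = 0.5, p_hi: float = 99.5) -> ChannelImage:
    """Linearly rescale intensities so the ``p_lo`` percentile maps to 0 and
    the ``p_hi`` percentile maps to 1, clipping to [0, 1].

    A constant image (degenerate percentile span) maps to all zeros.
    """
    if not (0 <= p_lo < p_hi <= 100):
        raise ValueError("percentiles must satisfy 0 <= p_lo < p_hi <= 100")
    data = np.asarray(img.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(data, [p_lo, p_hi])
    if hi <= lo:
        scaled = np.zeros_like(data)
    else:
        scaled = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return ChannelImage(data=scaled, channel=img.channel, bit_depth=0)


def compose_disco_image(red: ChannelImage, green: ChannelImage) -> np.ndarray:
    """Merge the two rescaled channels into the display composite.

    The red fluorescence channel is shown as red and the green channel is
    remapped to blue for contrast, so lawn regions where both hosts grow
    appear magenta and dark plaques (both hosts killed) appear black.
    """
    if red.shape != green.shape:
        raise ValueError("channel shapes differ")
    out = np.zeros(red.shape + (3,), dtype=float)
    out[..., 0] = red.data
    out[..., 2] = green.data
    return out


# ---------------------------------------------------------------------------
# background, plate disk, detection
# ---------------------------------------------------------------------------

def estimate_lawn_background(img: ChannelImage, r_bg: int) -> np.ndarray:
    """Estimate the local lawn intensity by grayscale morphological closing
    with a disk of radius ``r_bg``.

    Closing fills dark features smaller than the disk, so as long as
    ``r_bg`` exceeds the largest plaque radius the result tracks the lawn
    through uneven illumination; it is pointwise >= the input.
    """
    if r_bg <= 0:
        raise ValueError("r_bg must be positive")
    footprint = morphology.disk(r_bg, decomposition="sequence")
    return morphology.closing(np.asarray(img.data, dtype=float), footprint)


def find_plate_disk(red: ChannelImage, green: ChannelImage) -> np.ndarray:
    """Locate the plate (lawn) disk as the largest bright connected region
    of the channel sum after Otsu thresholding, with holes (plaques) filled."""
    total = np.asarray(red.data, dtype=float) + np.asarray(green.data, dtype=float)
    if total.max() <= total.min():
        return np.zeros(total.shape, dtype=bool)
    mask = total > threshold_otsu(total)
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros(total.shape, dtype=bool)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndi.binary_fill_holes(labels == largest)


@dataclass
class _PlateAnalysis:
    """Internal per-plate cache: rescaled channels, plate mask and the
    per-pixel relative deficit in each channel."""

    deficit_red: np.ndarray
    deficit_green: np.ndarray
    plate_mask: np.ndarray


def _analyze_channels(plate: PlateImage, params: VisionParams) -> _PlateAnalysis:
    red = rescale_exposure(plate.red, params.p_lo, params.p_hi)
    green = rescale_exposure(plate.green, params.p_lo, params.p_hi)
    plate_mask = find_plate_disk(red, green)

    deficits = []
    for chan in (red, green):
        bg = estimate_lawn_background(chan, params.r_bg)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(bg > 1e-9, (bg - chan.data) / bg, 0.0)
        deficits.append(np.clip(d, 0.0, 1.0))
    return _PlateAnalysis(deficits[0], deficits[1], plate_mask)


def detect_plaques(plate: PlateImage, params: VisionParams | None = None) -> list[PlaqueCall]:
    """Detect candidate plaque regions and classify each one.

    Candidate pixels are those inside the plate disk whose relative deficit
    ``(background - intensity) / background`` exceeds ``theta_d`` in at
    least one channel.  Candidates are grouped by 8-connectivity, regions
    smaller than ``a_min`` pixels are discarded, and each surviving region
    is classified by its mean per-channel deficit.  With
    ``watershed_split=True``, touching plaques are separated by a
    distance-transform watershed before grouping.
    """
    params = params or VisionParams()
    analysis = _analyze_channels(plate, params)
    dmax = np.maximum(analysis.deficit_red, analysis.deficit_green)
    candidate = (dmax >= params.theta_d) & analysis.plate_mask

    if params.watershed_split and candidate.any():
        distance = ndi.distance_transform_edt(candidate)
        # seeds: local maxima of the distance map, one marker per plaque core
        peaks = morphology.local_maxima(distance) & (distance > 1)
        markers = label(peaks, connectivity=params.connectivity)
        labels = watershed(-distance, markers, mask=candidate)
    else:
        labels = label(candidate, connectivity=params.connectivity)

    calls: list[PlaqueCall] = []
    for region in regionprops(labels):
        if region.area < params.a_min:
            continue
        coords = region.coords
        call = _classify_coords(
            len(calls), coords, region.centroid, analysis, params
        )
        calls.append(call)
    return calls


def _classify_coords(
    plaque_id: int,
    coords: np.ndarray,
    centroid: tuple[float, float],
    analysis: _PlateAnalysis,
    params: VisionParams,
) -> PlaqueCall:
    rows, cols = coords[:, 0], coords[:, 1]
    dr = float(analysis.deficit_red[rows, cols].mean())
    dg = float(analysis.deficit_green[rows, cols].mean())
    if dr >= params.theta_d and dg >= params.theta_d:
        cls = PlaqueClass.PLASMID_DEPENDENT
    elif dr >= params.theta_d:
        cls = PlaqueClass.RED_HOST_PHAGE
    elif dg >= params.theta_d:
        cls = PlaqueClass.GREEN_HOST_PHAGE
    else:
        cls = PlaqueClass.ARTIFACT
    return PlaqueCall(
        plaque_id=plaque_id,
        coords=coords,
        centroid=(float(centroid[0]), float(centroid[1])),
        area_px=int(coords.shape[0]),
        deficit_red=dr,
        deficit_green=dg,
        plaque_class=cls,
    )


def classify_plaque(
    coords: np.ndarray, plate: PlateImage, params: VisionParams | None = None
) -> PlaqueCall:
    """Classify one pixel region of a plate by its mean two-channel deficit.

    The decision rule: both deficits >= ``theta_d`` -> plasmid-dependent
    (dark plaque); red only -> phage of the red-labelled host (plaque shows
    the remaining green host, displayed blue); green only -> phage of the
    green host (plaque shows red); neither -> artifact.
    """
    coords = np.asarray(coords)
    if coords.size == 0:
        raise ValueError("empty region")
    params = params or VisionParams()
    analysis = _analyze_channels(plate, params)
    centroid = (coords[:, 0].mean(), coords[:, 1].mean())
    return _classify_coords(0, coords, centroid, analysis, params)


def count_plaques_by_class(
    plate: PlateImage, params: VisionParams | None = None
) -> dict[PlaqueClass, int]:
    """Detect and classify plaques, returning counts per class.

    All four classes are present as keys; ARTIFACT regions are counted
    separately and must not be added to phage totals.
    """
    calls = detect_plaques(plate, params)
    counts = {cls: 0 for cls in PlaqueClass}
    for call in calls:
        counts[call.plaque_class] += 1
    return counts


# ---------------------------------------------------------------------------
# tabular output / end-to-end convenience
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Sequence[PlaqueCall]) -> pd.DataFrame:
    """Tabulate plaque calls (one row per plaque) for CSV export."""
    return pd.DataFrame(
        {
            "plaque_id": [c.plaque_id for c in calls],
            "centroid_y": [c.centroid[0] for c in calls],
            "centroid_x": [c.centroid[1] for c in calls],
            "area_px": [c.area_px for c in calls],
            "deficit_red": [c.deficit_red for c in calls],
            "deficit_green": [c.deficit_green for c in calls],
            "class": [c.plaque_class.value for c in calls],
        }
    )


def analyze_plate(
    red_path: str | Path,
    green_path: str | Path,
    meta: dict | str | Path,
    params: VisionParams | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """File-level entry point: read the two channel images and metadata,
    detect and classify plaques, and optionally write the call table
    (CSV) and the red/blue display composite (PNG) to ``out_dir``."""
    if not isinstance(meta, dict):
        meta = json.loads(Path(meta).read_text())
    plate = PlateImage(
        red=read_channel_image(red_path, "red"),
        green=read_channel_image(green_path, "green"),
        plated_volume_ml=float(meta.get("plated_volume_ml", 0.1)),
        dilution_exponent=int(meta.get("dilution_exponent", 0)),
        sample=str(meta.get("sample", "")),
    )
    params = params or VisionParams()
    calls = detect_plaques(plate, params)
    table = calls_to_frame(calls)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "plaque_calls.csv", index=False)
        red = rescale_exposure(plate.red, params.p_lo, params.p_hi)
        green = rescale_exposure(plate.green, params.p_lo, params.p_hi)
        rgb = (compose_disco_image(red, green) * 255).astype(np.uint8)
        import imageio.v3 as iio

        iio.imwrite(out_dir / "overlay.png", rgb)
    return table
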