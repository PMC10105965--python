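"""Anatomical tracing quantification.

Retrograde maps: thresholded label area per anatomical ROI normalized to the
starter-region label area (connectivity ratio), plus soma counting and
GABA co-localization.  Anterograde volumes: threshold → 26-connected
component labeling → per-object voxel volumes summed and normalized by ROI
volume and starter-cell density.

Conventions: voxel indices are 0-based; ROI masks are boolean arrays
congruent with the image; bounding boxes are half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, segmentation

log = logging.getLogger(__name__)

__all__ = [
    "LabeledVolume",
    "RoiMask",
    "ConnectivityResult",
    "ProjectionDensityResult",
    "threshold_channel",
    "connectivity_ratio",
    "colocalization_fraction",
    "count_cells",
    "reconstruct_processes_3d",
]

SECTION_THICKNESS_UM = 40.0
SECTION_INTERVAL = 6  # every sixth section quantified


@dataclass
class LabeledVolume:
    """Voxel grid (z, y, x) with named fluorescence channels."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]  # (z, y, x)
    section_interval: int = SECTION_INTERVAL

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not present")
        return self.channels[name]


@dataclass
class RoiMask:
    """Named anatomical region as a boolean mask congruent with the volume."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def require_fits(self, volume: LabeledVolume) -> None:
        if self.mask.shape != volume.shape:
            raise ValueError(
                f"ROI {self.name!r} shape {self.mask.shape} does not fit volume {volume.shape}"
            )

    def area_um2(self, pixel_size_um: tuple[float, float]) -> float:
        return float(self.mask.sum()) * pixel_size_um[0] * pixel_size_um[1]

    def volume_um3(self, voxel_size_um: tuple[float, float, float]) -> float:
        return float(self.mask.sum()) * float(np.prod(voxel_size_um))


@dataclass
class ConnectivityResult:
    per_region_area_um2: dict[str, float]
    starter_area_um2: float
    ratios: dict[str, float]
    ranking: pd.DataFrame = field(repr=False, default=None)
    undefined: bool = False


@dataclass
class ProjectionDensityResult:
    object_count: int
    object_volumes_um3: np.ndarray
    summed_volume_um3: float
    roi_volume_um3: float
    starter_cell_density: float | None
    normalized_density: float | None
    unnormalized_flag: bool = False

    def __post_init__(self) -> None:
        if self.object_count and not np.isclose(
            self.summed_volume_um3, float(np.sum(self.object_volumes_um3))
        ):
            raise ValueError("summed volume must equal sum of object volumes")


def threshold_channel(
    image: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    percentile: float = 99.0,
) -> tuple[np.ndarray, float]:
    """Binary mask of suprathreshold voxels plus the threshold used.

    Methods: ``otsu`` (default), ``fixed`` (requires ``value``), and
    ``percentile``.  A constant-intensity channel yields an empty mask with
    a warning.
    """
    image = np.asarray(image)
    if image.min() == image.max():
        warnings.warn("constant-intensity channel: empty mask")
        return np.zeros(image.shape, dtype=bool), float(image.max())
    if method == "otsu":
        thr = float(filters.threshold_otsu(image))
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a value")
        thr = float(value)
    elif method == "percentile":
        thr = float(np.percentile(image, percentile))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    log.info("threshold_channel: method=%s threshold=%.4g", method, thr)
    return image > thr, thr


def connectivity_ratio(
    mcherry_mask: np.ndarray,
    rois: list[RoiMask],
    starter_roi: RoiMask,
    pixel_size_um: tuple[float, float],
) -> ConnectivityResult:
    """Per-region thresholded label area normalized to starter-region area.

    Areas are summed over all sampled sections (axis 0 of a stack) in
    physical µm².  A zero starter area makes all ratios undefined.
    """
    px_area = pixel_size_um[0] * pixel_size_um[1]
    starter_area = float((mcherry_mask & starter_roi.mask).sum()) * px_area
    per_region = {
        r.name: float((mcherry_mask & r.mask).sum()) * px_area for r in rois
    }
    if starter_area <= 0:
        log.warning("zero starter area: connectivity ratios undefined")
        return ConnectivityResult(
            per_region_area_um2=per_region,
            starter_area_um2=0.0,
            ratios={},
            undefined=True,
        )
    ratios = {k: v / starter_area for k, v in per_region.items()}
    ranking = (
        pd.DataFrame(
            {"region": list(ratios), "area_um2": list(per_region.values()),
             "connectivity_ratio": list(ratios.values())}
        )
        .sort_values("connectivity_ratio", ascending=False)
        .reset_index(drop=True)
    )
    return ConnectivityResult(
        per_region_area_um2=per_region,
        starter_area_um2=starter_area,
        ratios=ratios,
        ranking=ranking,
    )


def detect_somata(
    channel: np.ndarray,
    pixel_size_um: tuple[float, float],
    min_diameter_um: float = 8.0,
    threshold_method: str = "otsu",
) -> np.ndarray:
    """Label somata as blobs: threshold → distance-transform watershed split.

    Returns an integer label image (0 = background).  Touching blobs are
    split at the watershed line between distance-transform maxima, so two
    spheres touching at one voxel count as two.
    """
    mask, _ = threshold_channel(channel, method=threshold_method)
    if not mask.any():
        return np.zeros(channel.shape, dtype=np.int32)
    min_radius_px = 0.5 * min_diameter_um / float(np.mean(pixel_size_um))
    distance = ndimage.distance_transform_edt(mask)
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        distance,
        min_distance=max(1, int(round(min_radius_px))),
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(channel.shape, dtype=np.int32)
    for i, c in enumerate(coords, start=1):
        markers[tuple(c)] = i
    labels = segmentation.watershed(-distance, markers, mask=mask)
    # discard specks below the minimum diameter footprint
    min_area = np.pi * min_radius_px**2 * 0.25
    out = np.zeros_like(labels)
    nxt = 1
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            out[labels == region.label] = nxt
            nxt += 1
    return out


def colocalization_fraction(
    mcherry: np.ndarray,
    gaba: np.ndarray,
    pixel_size_um: tuple[float, float],
    min_diameter_um: float = 8.0,
    soma_labels: np.ndarray | None = None,
) -> dict:
    """Fraction of label-positive somata also positive in the GABA channel.

    A soma is GABA+ iff the mean GABA intensity within its footprint exceeds
    the GABA channel's Otsu threshold.  Zero detected somata leaves the
    fraction undefined.
    """
    if soma_labels is None:
        soma_labels = detect_somata(mcherry, pixel_size_um, min_diameter_um)
    n_somata = int(soma_labels.max())
    if n_somata == 0:
        return {"n_mcherry": 0, "n_colocalized": 0, "fraction": None, "undefined": True}
    if gaba.min() == gaba.max():
        # no GABA signal at all: nothing can be positive
        return {"n_mcherry": n_somata, "n_colocalized": 0, "fraction": 0.0, "undefined": False}
    gaba_thr = float(filters.threshold_otsu(gaba))
    n_pos = 0
    means = ndimage.mean(gaba, labels=soma_labels, index=np.arange(1, n_somata + 1))
    n_pos = int(np.sum(np.asarray(means) > gaba_thr))
    return {
        "n_mcherry": n_somata,
        "n_colocalized": n_pos,
        "fraction": n_pos / n_somata,
        "undefined": False,
    }


def count_cells(
    channel: np.ndarray,
    roi: RoiMask,
    pixel_size_um: tuple[float, float],
    min_diameter_um: float = 8.0,
    section_thickness_um: float = SECTION_THICKNESS_UM,
) -> dict:
    """Blob count within an ROI and the density count/(ROI area × thickness)."""
    if not roi.mask.any():
        raise ValueError(f"ROI {roi.name!r} is empty")
    labels = detect_somata(channel, pixel_size_um, min_diameter_um)
    count = 0
    for region in measure.regionprops(labels):
        cz = tuple(int(round(c)) for c in region.centroid)
        if roi.mask[cz]:
            count += 1
    area = roi.area_um2(pixel_size_um)
    return {
        "count": count,
        "density": count / (area * section_thickness_um),
        "roi_area_um2": area,
    }


def reconstruct_processes_3d(
    volume: LabeledVolume,
    hilus_roi: RoiMask,
    channel: str = "YFP",
    threshold: float | None = None,
    threshold_method: str = "otsu",
    starter_cell_density: float | None = None,
    min_object_voxels: int = 1,
) -> ProjectionDensityResult:
    """Threshold → 26-connected components → summed volume → normalization.

    ``threshold`` fixes a batch-standardized threshold shared across
    genotypes; otherwise the configured method computes one (logged).  The
    normalized projection density is summed object volume / hilus ROI
    volume / starter-cell density; a missing density yields the
    unnormalized value with a flag.
    """
    hilus_roi.require_fits(volume)
    img = volume.channel(channel)
    if threshold is not None:
        mask, thr = threshold_channel(img, method="fixed", value=threshold)
    else:
        mask, thr = threshold_channel(img, method=threshold_method)
    mask &= hilus_roi.mask

    labels = measure.label(mask, connectivity=3)  # 26-connectivity in 3D
    counts = np.bincount(labels.ravel())[1:]  # per-object voxel counts
    counts = counts[counts >= min_object_voxels]
    vox = volume.voxel_volume_um3
    object_volumes = counts.astype(float) * vox
    summed = float(object_volumes.sum())
    roi_volume = hilus_roi.volume_um3(volume.voxel_size_um)

    density = summed / roi_volume if roi_volume > 0 else 0.0
    if starter_cell_density is None or starter_cell_density <= 0:
        log.warning("missing starter-cell density: emitting unnormalized density")
        return ProjectionDensityResult(
            object_count=len(counts),
            object_volumes_um3=object_volumes,
            summed_volume_um3=summed,
            roi_volume_um3=roi_volume,
            starter_cell_density=None,
            normalized_density=density,
            unnormalized_flag=True,
        )
    return ProjectionDensityResult(
        object_count=len(counts),
        object_volumes_um3=object_volumes,
        summed_volume_um3=summed,
        roi_volume_um3=roi_volume,
        starter_cell_density=starter_cell_density,
        normalized_density=density / starter_cell_density,
        unnormalized_flag=False,
    )
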