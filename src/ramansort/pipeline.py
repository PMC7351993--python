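"""Real-time image-analysis chain: detect, frame, mask, decompose, gate.

The chain mirrors the on-instrument processing order: threshold-trigger
events on the forward-scatter trace, cut a fixed-length multi-color frame per
event, normalize to square pixels, build a binary cell mask from one selected
color (background correction -> Gaussian -> top-hat -> Canny -> contour
closing -> convex hull), unmix the frame into constituent images, extract
per-constituent statistics over the mask, and apply a 2-D gate to make the
sort/unsort decision.  Events with empty masks are never sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature as skfeature
from skimage import morphology as skmorph

from .flowsim import AcquisitionConfig, FSCTrace, LineScanStream
from .spectral import SpectralBasis, unmix_image


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the masking chain; defaults sized for ~3-10 um cells.

    ``canny_low_frac``/``canny_high_frac`` are hysteresis thresholds relative
    to the maximum of the filtered image.  ``tophat_radius`` should exceed
    the specimen scale along at least one axis so the top-hat acts as a
    background flattener without eroding the cell.  ``min_area_px`` discards
    noise-born micro-components.
    """

    gaussian_sigma: float = 1.0
    tophat_radius: int = 15
    canny_sigma: float = 1.0
    canny_low_frac: float = 0.1
    canny_high_frac: float = 0.3
    close_radius: int = 2
    spur_neighbor_min: int = 5
    min_area_px: int = 20
    margin_rows: int = 5


@dataclass(frozen=True)
class EventFrame:
    event_id: int
    trigger_time: float
    raw: np.ndarray          # (frame_lines, n_lateral, n_colors)
    aborted: bool = False


@dataclass(frozen=True)
class CellMask:
    pixels: np.ndarray       # bool, normalized grid
    area_px: int
    area_um2: float

    @property
    def empty(self) -> bool:
        return self.area_px == 0


@dataclass(frozen=True)
class FeatureVector:
    """Per-event features: area plus within-mask intensity statistics.

    ``features`` maps names like ``"PMMA_density"`` to values; per
    constituent the suffixes are ``_total``, ``_mean``, ``_max``, ``_sd`` and
    ``_density`` (total intensity divided by mask area in um^2 — the
    per-area intensity used for gating).  ``empty`` flags events whose mask
    closed on nothing; such records carry no intensity features.
    """

    event_id: int
    area_um2: float
    features: dict[str, float] = field(default_factory=dict)
    empty: bool = False


@dataclass(frozen=True)
class Gate:
    """A sort region in a 2-D feature plane (boundary inclusive).

    ``region`` is either a rectangle ``(xmin, xmax, ymin, ymax)`` or a
    polygon given as a sequence of ``(x, y)`` vertices.
    """

    x_feature: str
    y_feature: str
    region: tuple
    label: str = "sort"

    def __post_init__(self) -> None:
        region = self.region
        if len(region) == 4 and np.isscalar(region[0]):
            xmin, xmax, ymin, ymax = region
            if not (xmin < xmax and ymin < ymax):
                raise ValueError("degenerate rectangle gate")
        else:
            if len(region) < 3:
                raise ValueError("polygon gate needs at least 3 vertices")

    def contains(self, x: float, y: float) -> bool:
        region = self.region
        if len(region) == 4 and np.isscalar(region[0]):
            xmin, xmax, ymin, ymax = region
            return bool(xmin <= x <= xmax and ymin <= y <= ymax)
        from shapely.geometry import Point, Polygon

        return bool(Polygon(list(region)).covers(Point(x, y)))

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        is_rect = len(self.region) == 4 and np.isscalar(self.region[0])
        payload = {
            "type": "rectangle" if is_rect else "polygon",
            "x_feature": self.x_feature,
            "y_feature": self.y_feature,
            "label": self.label,
            ("rectangle" if is_rect else "vertices"): (
                list(self.region) if is_rect
                else [list(v) for v in self.region]
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "Gate":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        if payload["type"] == "rectangle":
            region = tuple(payload["rectangle"])
        else:
            region = tuple(tuple(v) for v in payload["vertices"])
        return cls(payload["x_feature"], payload["y_feature"], region,
                   payload.get("label", "sort"))


def detect_events(
    trace: FSCTrace,
    threshold: float,
    refractory: float,
) -> list[tuple[int, float]]:
    """Threshold-trigger: one event per upward crossing, with dead time.

    Returns ``(event_id, trigger_time)`` pairs in time order, IDs from 0.
    Crossings within ``refractory`` seconds of the previous accepted trigger
    are suppressed.
    """
    values = np.asarray(trace.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty FSC trace")
    above = values > threshold
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    events: list[tuple[int, float]] = []
    last = -np.inf
    for idx in crossings:
        t = float(trace.line_times[idx])
        if t - last >= refractory:
            events.append((len(events), t))
            last = t
    return events


def frame_event(
    stream: LineScanStream,
    trigger_time: float,
    config: AcquisitionConfig,
    acquisition_delay: float = 0.0,
) -> EventFrame:
    """Cut ``frame_lines`` consecutive lines starting at trigger + delay.

    Frames that would extend beyond either end of the stream are returned
    with ``aborted=True`` and a zero-filled raw array.
    """
    t0 = float(stream.line_times[0])
    if trigger_time < t0:
        raise ValueError("trigger precedes the stream start")
    start = int(round((trigger_time + acquisition_delay - t0) * config.line_rate))
    n = config.frame_lines
    shape = (n, config.n_lateral_pixels, stream.samples.shape[2])
    if start < 0 or start + n > stream.n_lines:
        return EventFrame(-1, trigger_time, np.zeros(shape), aborted=True)
    return EventFrame(-1, trigger_time, stream.samples[start:start + n].copy())


def normalize_square(
    frame: np.ndarray,
    flow_fov: float,
    lateral_fov: float,
) -> np.ndarray:
    """Resample the lateral axis so pixels become square.

    The flow-direction pitch ``flow_fov / n_lines`` is kept; the lateral axis
    is linearly interpolated to ``round(lateral_fov / pitch)`` columns
    (rounding half up), so a 122 x 24 frame with a 33 x 24 um field of view
    becomes 122 x 89.  Accepts ``(lines, lateral)`` or
    ``(lines, lateral, colors)`` arrays.
    """
    if flow_fov <= 0 or lateral_fov <= 0:
        raise ValueError("fields of view must be positive")
    arr = np.asarray(frame, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    n_lines, width, n_ch = arr.shape
    if n_lines == 0 or width == 0:
        raise ValueError("zero-size frame")
    pitch = flow_fov / n_lines
    new_width = int(np.floor(lateral_fov / pitch + 0.5))
    if new_width == width:
        out = arr.copy()
    else:
        # Linear interpolation between pixel centres as a (sparse) matrix so
        # all rows and channels resample in one matmul.
        x_old = (np.arange(width) + 0.5) / width
        x_new = (np.arange(new_width) + 0.5) / new_width
        x_new = np.clip(x_new, x_old[0], x_old[-1])
        hi = np.clip(np.searchsorted(x_old, x_new), 1, width - 1)
        lo = hi - 1
        w_hi = (x_new - x_old[lo]) / (x_old[hi] - x_old[lo])
        weights = np.zeros((new_width, width))
        weights[np.arange(new_width), lo] = 1.0 - w_hi
        weights[np.arange(new_width), hi] += w_hi
        out = np.einsum("lwc,nw->lnc", arr, weights)
    return out[:, :, 0] if squeeze else out


def _background_correct(image: np.ndarray, margin_rows: int) -> np.ndarray:
    """Subtract the per-column median of the first and last margin rows."""
    m = margin_rows
    margins = np.concatenate([image[:m], image[-m:]], axis=0)
    return image - np.median(margins, axis=0, keepdims=True)


def _trim_spurs(mask: np.ndarray, neighbor_min: int) -> np.ndarray:
    """Drop pixels with fewer than ``neighbor_min`` of 8 neighbours set.

    The Canny ring straddles the true boundary by up to half a pixel; the
    contour fill therefore over-counts by roughly a one-pixel shell at small
    radii.  A single majority pass removes the weakly connected outer-shell
    pixels without the full one-pixel bite of a morphological erosion.
    """
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    neighbors = ndimage.convolve(mask.astype(int), kernel, mode="constant")
    return mask & (neighbors >= neighbor_min)


def segment(image: np.ndarray, params: SegmentationParams | None = None,
            pixel_area_um2: float = 1.0) -> CellMask:
    """Build a binary cell mask from one normalized single-channel image.

    Chain: background correction, Gaussian smoothing, white top-hat, Canny
    edge detection with hysteresis thresholds relative to the filtered
    maximum, contour closing (dilation, hole fill, erosion), spur trimming,
    then the convex hull of the largest connected component followed by a
    final spur trim.  The trailing trim keeps the disk-area convention
    centred on the true boundary; it may peel single boundary-layer pixels
    off the exact hull, so the mask is convex up to one boundary pixel.  An
    empty mask is a valid outcome (blank frames, unclosed contours, or
    components below ``min_area_px``).
    """
    p = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    empty = CellMask(np.zeros(img.shape, dtype=bool), 0, 0.0)

    img = _background_correct(img, p.margin_rows)
    img = ndimage.gaussian_filter(img, p.gaussian_sigma)
    footprint = skmorph.disk(p.tophat_radius, decomposition="sequence")
    img = skmorph.white_tophat(img, footprint)
    peak = img.max()
    if peak <= 0:
        return empty
    edges = skfeature.canny(
        img,
        sigma=p.canny_sigma,
        low_threshold=p.canny_low_frac * peak,
        high_threshold=p.canny_high_frac * peak,
    )
    if not edges.any():
        return empty
    closing = skmorph.disk(p.close_radius)
    closed = ndimage.binary_dilation(edges, structure=closing)
    filled = ndimage.binary_fill_holes(closed)
    mask = ndimage.binary_erosion(filled, structure=closing)
    mask = _trim_spurs(mask, p.spur_neighbor_min)
    labels, n = ndimage.label(mask)
    if n == 0:
        return empty
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    if largest.sum() < p.min_area_px:
        return empty
    hull = _trim_spurs(skmorph.convex_hull_image(largest), p.spur_neighbor_min)
    area = int(hull.sum())
    if area < p.min_area_px:
        return empty
    return CellMask(hull, area, area * pixel_area_um2)


def extract_features(
    decomposed: np.ndarray,
    mask: CellMask,
    pixel_area_um2: float,
    constituent_names: Sequence[str],
    event_id: int = -1,
    clip_negative: bool = False,
) -> FeatureVector:
    """Within-mask statistics per constituent, plus per-area densities.

    ``decomposed`` is a ``(lines, width, n_constituents)`` stack on the same
    grid as the mask.  ``clip_negative`` zeroes negative unmixing
    coefficients before computing the statistics (display-stage convention);
    by default coefficients are used as-is.
    """
    decomposed = np.asarray(decomposed, dtype=float)
    if decomposed.shape[:2] != mask.pixels.shape:
        raise ValueError(
            f"decomposed grid {decomposed.shape[:2]} does not match "
            f"mask grid {mask.pixels.shape}"
        )
    if mask.empty:
        return FeatureVector(event_id=event_id, area_um2=0.0, empty=True)
    area_um2 = mask.area_px * pixel_area_um2
    feats: dict[str, float] = {"area_um2": area_um2, "area_px": float(mask.area_px)}
    for i, name in enumerate(constituent_names):
        vals = decomposed[:, :, i][mask.pixels]
        if clip_negative:
            vals = np.maximum(vals, 0.0)
        total = float(vals.sum())
        feats[f"{name}_total"] = total
        feats[f"{name}_mean"] = float(vals.mean())
        feats[f"{name}_max"] = float(vals.max())
        feats[f"{name}_sd"] = float(vals.std())
        feats[f"{name}_density"] = total / area_um2
    return FeatureVector(event_id=event_id, area_um2=area_um2, features=feats)


def decide(features: FeatureVector, gate: Gate) -> bool:
    """Sort iff the event's feature point lies inside the gate (inclusive).

    Events with empty masks are never sorted.
    """
    if features.empty:
        return False
    for name in (gate.x_feature, gate.y_feature):
        if name not in features.features:
            raise KeyError(f"feature {name!r} not present in this feature vector")
    return gate.contains(
        features.features[gate.x_feature], features.features[gate.y_feature]
    )


def process_frame(
    raw: np.ndarray,
    basis: SpectralBasis,
    config: AcquisitionConfig,
    seg_params: SegmentationParams | None = None,
    event_id: int = -1,
    mask_channel: int | None = None,
    clip_negative: bool = False,
) -> FeatureVector:
    """Normalize, mask, decompose and featurize one raw event frame.

    The mask channel defaults to the constituent with the largest total
    frame signal after decomposition.
    """
    norm = normalize_square(raw, config.flow_fov, config.lateral_fov)
    decomposed = unmix_image(norm, basis)
    if mask_channel is None:
        mask_channel = int(np.argmax(decomposed.sum(axis=(0, 1))))
    mask = segment(decomposed[:, :, mask_channel], seg_params,
                   pixel_area_um2=config.pixel_area_um2)
    return extract_features(
        decomposed, mask, config.pixel_area_um2, basis.constituent_names,
        event_id=event_id, clip_negative=clip_negative,
    )


def default_acquisition_delay(config: AcquisitionConfig) -> float:
    """Delay that centres a specimen in its frame when the FSC spot and the
    imaging line coincide (the simulator's geometry): half a frame back."""
    return -(config.frame_lines // 2) * config.line_period


def process_stream(
    stream: LineScanStream,
    fsc: FSCTrace,
    basis: SpectralBasis,
    config: AcquisitionConfig,
    gate: Gate | None = None,
    seg_params: SegmentationParams | None = None,
    threshold: float = 1.0,
    refractory: float = 2e-4,
    acquisition_delay: float | None = None,
    mask_channel: int | None = None,
) -> pd.DataFrame:
    """Run the full chain over a stream; one row per detected event.

    Columns: event_id, trigger_time, aborted, empty_mask, every feature, and
    (when a gate is given) the sort decision.  Detected events are conserved:
    every trigger yields exactly one row, aborted frames included.
    """
    if acquisition_delay is None:
        acquisition_delay = default_acquisition_delay(config)
    rows = []
    for event_id, t in detect_events(fsc, threshold, refractory):
        frame = frame_event(stream, t, config, acquisition_delay)
        row: dict[str, object] = {
            "event_id": event_id,
            "trigger_time": t,
            "aborted": frame.aborted,
        }
        if frame.aborted:
            row["empty_mask"] = True
            if gate is not None:
                row["sort"] = False
        else:
            fv = process_frame(frame.raw, basis, config, seg_params,
                               event_id=event_id, mask_channel=mask_channel)
            row["empty_mask"] = fv.empty
            row.update(fv.features)
            if gate is not None:
                row["sort"] = decide(fv, gate)
        rows.append(row)
    return pd.DataFrame(rows)
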