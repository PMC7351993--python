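"""Synthetic line-scan flow acquisitions with ground truth.

Emulates the acquisition geometry of a line-focusing SRS flow imager: cells
arrive as a Poisson stream, cross a 1-D focal line of ``n_lateral_pixels``
detector pixels, and the instrument records one multi-color line per line
period plus a scalar forward-scatter (FSC) trace used for event detection.

Specimens are rendered as uniform disks (optionally carrying brighter
internal droplets, emulating e.g. lipid droplets) in (time x lateral)
coordinates.  The flow direction is sampled at ``flow_speed / line_rate``
micrometres per line; with the defaults (0.04 m/s, 48 kHz) that is 0.833 um
per line, while the lateral pixel pitch is ``lateral_fov / n_lateral_pixels``
= 1 um.  Downstream square-pixel normalization is a separate, configurable
step (:func:`ramansort.pipeline.normalize_square`).

All randomness flows through one seeded :class:`numpy.random.Generator` per
run, so identical seeds and configs give bit-identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral import SpectralBasis

#: Default concentration templates: species label -> per-constituent
#: concentration vector (signal units per unit basis response).  "target"
#: mimics the PMMA-like constituent, "nontarget" the PS-like one.
DEFAULT_TEMPLATES: dict[str, tuple[float, ...]] = {
    "target": (0.0, 1.0),
    "nontarget": (1.0, 0.0),
}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and noise settings.

    Defaults reproduce the instrument's printed operating point: a 48 kHz
    line rate over 24 lateral detector pixels at four colors, 122-line event
    frames nominally covering a 33 x 24 um field of view, and a flow speed of
    0.04 m/s.  ``noise_sigma`` is the per-pixel additive Gaussian noise in
    the same signal units as the rendered intensities; with unit peak signal
    the default corresponds to SNR ~ 30.
    """

    line_rate: float = 48_000.0          # lines / s
    n_lateral_pixels: int = 24
    n_colors: int = 4
    lateral_fov: float = 24.0            # um
    flow_fov: float = 33.0               # um, nominal frame coverage
    frame_lines: int = 122
    flow_speed: float = 0.04             # m / s
    noise_sigma: float = 1.0 / 30.0      # signal units
    fsc_pulse_width: float = 0.0         # s, extra boxcar widening of FSC pulses
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("line_rate", "n_lateral_pixels", "n_colors", "lateral_fov",
                     "flow_fov", "frame_lines", "flow_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0 or self.fsc_pulse_width < 0:
            raise ValueError("noise_sigma and fsc_pulse_width must be non-negative")

    @property
    def line_period(self) -> float:
        """Seconds per line."""
        return 1.0 / self.line_rate

    @property
    def line_period_us(self) -> int:
        """Line period rounded to whole microseconds (48 kHz -> 21 us)."""
        return round(1e6 / self.line_rate)

    @property
    def lateral_pitch(self) -> float:
        """Lateral pixel pitch in um."""
        return self.lateral_fov / self.n_lateral_pixels

    @property
    def flow_pitch(self) -> float:
        """Flow-direction travel per line in um (flow_speed / line_rate)."""
        return self.flow_speed * 1e6 / self.line_rate

    @property
    def normalized_pitch(self) -> float:
        """Square-pixel pitch used by normalization: flow_fov / frame_lines (um)."""
        return self.flow_fov / self.frame_lines

    @property
    def normalized_width(self) -> int:
        """Lateral width after square-pixel normalization (rounds half up)."""
        return int(np.floor(self.lateral_fov / self.normalized_pitch + 0.5))

    @property
    def pixel_area_um2(self) -> float:
        """Area of one normalized square pixel in um^2."""
        return self.normalized_pitch**2


@dataclass(frozen=True)
class Droplet:
    """Internal texture element: a sub-disk of boosted concentration."""

    flow_offset_um: float
    lateral_offset_um: float
    radius_um: float
    multiplier: float = 3.0


@dataclass(frozen=True)
class Specimen:
    species: str
    center_time: float        # s, at the interrogation line
    lateral_offset: float     # um from channel center
    radius: float             # um
    texture: tuple[Droplet, ...] = ()

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("specimen radius must be positive")


@dataclass(frozen=True)
class LineScanStream:
    """Raw multi-color acquisition: (n_lines, n_lateral, n_colors) + times."""

    samples: np.ndarray
    line_times: np.ndarray

    def __post_init__(self) -> None:
        if self.samples.shape[0] != self.line_times.shape[0]:
            raise ValueError("one line time per acquired line required")
        dt = np.diff(self.line_times)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("line times must increase with constant pitch")

    @property
    def n_lines(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class FSCTrace:
    """Forward-scatter intensity per line time (non-negative)."""

    values: np.ndarray
    line_times: np.ndarray


@dataclass(frozen=True)
class GroundTruth:
    specimens: tuple[Specimen, ...]
    r: float                  # target fraction
    rate: float               # events / s
    duration: float           # s

    def __post_init__(self) -> None:
        times = [s.center_time for s in self.specimens]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("specimen arrival times must be sorted")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("target fraction r must lie in [0, 1]")

    @property
    def arrival_times(self) -> np.ndarray:
        return np.array([s.center_time for s in self.specimens])

    @property
    def is_target(self) -> np.ndarray:
        return np.array([s.species == "target" for s in self.specimens])

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "event_id": i,
                "time_s": s.center_time,
                "species": s.species,
                "is_target": s.species == "target",
                "radius_um": s.radius,
                "lateral_offset_um": s.lateral_offset,
            }
            for i, s in enumerate(self.specimens)
        ]
        pd.DataFrame(
            rows,
            columns=[
                "event_id", "time_s", "species", "is_target",
                "radius_um", "lateral_offset_um",
            ],
        ).to_csv(path, index=False)


def simulate_arrivals(
    rate: float,
    r: float,
    duration: float,
    seed: int,
    *,
    radius_range: tuple[float, float] = (2.5, 5.0),
    lateral_jitter: float = 1.5,
    droplet_species: Mapping[str, int] | None = None,
) -> GroundTruth:
    """Draw a Poisson stream of labeled specimens.

    Inter-arrival times are exponential with mean ``1/rate``; each arrival is
    independently a target with probability ``r``.  Radii are uniform over
    ``radius_range`` (um) and lateral offsets Gaussian with SD
    ``lateral_jitter`` um, truncated so specimens stay inside the lateral
    field of view of the default geometry.  ``droplet_species`` optionally
    maps a species label to a number of internal droplets to attach.
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    specimens: list[Specimen] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        species = "target" if rng.random() < r else "nontarget"
        radius = rng.uniform(*radius_range)
        offset = float(np.clip(rng.normal(0.0, lateral_jitter), -6.0, 6.0))
        texture: tuple[Droplet, ...] = ()
        if droplet_species and species in droplet_species:
            drops = []
            for _ in range(droplet_species[species]):
                dr = rng.uniform(0.2, 0.4) * radius
                rho = rng.uniform(0.0, radius - dr)
                phi = rng.uniform(0.0, 2 * np.pi)
                drops.append(
                    Droplet(rho * np.cos(phi), rho * np.sin(phi), dr, 3.0)
                )
            texture = tuple(drops)
        specimens.append(Specimen(species, t, offset, radius, texture))
    return GroundTruth(tuple(specimens), r=r, rate=rate, duration=duration)


def _concentration_templates(
    basis: SpectralBasis,
    templates: Mapping[str, Sequence[float]] | None,
) -> dict[str, np.ndarray]:
    raw = templates if templates is not None else DEFAULT_TEMPLATES
    out = {}
    for species, c in raw.items():
        c = np.asarray(c, dtype=float)
        if c.shape != (basis.n_constituents,):
            raise ValueError(
                f"template for {species!r} has {c.size} entries, "
                f"basis has {basis.n_constituents} constituents"
            )
        out[species] = c
    return out


def _paint_specimen(
    samples: np.ndarray,
    fsc: np.ndarray,
    line_times: np.ndarray,
    spec: Specimen,
    c: np.ndarray,
    basis: SpectralBasis,
    config: AcquisitionConfig,
    line0_time: float,
) -> None:
    """Add one disk specimen (plus droplets) to samples/fsc in place."""
    half_fov = config.lateral_fov / 2.0
    if abs(spec.lateral_offset) + spec.radius > half_fov:
        raise ValueError(
            f"specimen at lateral offset {spec.lateral_offset} um with radius "
            f"{spec.radius} um exceeds the {config.lateral_fov} um lateral FOV"
        )
    v_um = config.flow_speed * 1e6  # um / s
    half_span = spec.radius / v_um  # s
    i0 = max(0, int(np.ceil((spec.center_time - half_span - line0_time) * config.line_rate)))
    i1 = min(
        samples.shape[0],
        int(np.floor((spec.center_time + half_span - line0_time) * config.line_rate)) + 1,
    )
    if i0 >= i1:
        return
    y = (line_times[i0:i1] - spec.center_time) * v_um          # flow offsets, um
    x = (np.arange(config.n_lateral_pixels) + 0.5) * config.lateral_pitch - half_fov
    dx = x[None, :] - spec.lateral_offset                      # (lines, lateral)
    dy = y[:, None]
    r2 = dx**2 + dy**2
    inside = r2 <= spec.radius**2
    conc = inside[..., None] * c[None, None, :]
    for drop in spec.texture:
        din = (dx - drop.lateral_offset_um) ** 2 + (dy - drop.flow_offset_um) ** 2 \
            <= drop.radius_um**2
        boost = np.where(din & inside, drop.multiplier, 1.0)
        conc = conc * boost[..., None]
    samples[i0:i1] += np.einsum("ij,xyj->xyi", basis.responses, conc)
    # FSC: amplitude proportional to the occluded chord length at each line.
    chord = 2.0 * np.sqrt(np.maximum(spec.radius**2 - y**2, 0.0))
    fsc[i0:i1] += chord


def render_stream(
    truth: GroundTruth,
    basis: SpectralBasis,
    config: AcquisitionConfig,
    templates: Mapping[str, Sequence[float]] | None = None,
) -> tuple[LineScanStream, FSCTrace]:
    """Render a ground-truth stream into line scans plus an FSC trace.

    Every specimen is painted as a disk whose temporal extent is
    ``2 * radius / flow_speed``; in-support pixels carry
    ``responses @ c(species)``.  Zero-mean Gaussian noise with SD
    ``config.noise_sigma`` is added to every sample of the line-scan stream;
    the FSC trace is noiseless (the event-detection channel of the instrument
    is high-SNR by design) and proportional to the occluded chord length.
    """
    tmpl = _concentration_templates(basis, templates)
    n_lines = max(1, int(np.ceil(truth.duration * config.line_rate)))
    line_times = np.arange(n_lines) / config.line_rate
    samples = np.zeros((n_lines, config.n_lateral_pixels, basis.n_colors))
    fsc = np.zeros(n_lines)
    for spec in truth.specimens:
        if spec.species not in tmpl:
            raise ValueError(f"no concentration template for species {spec.species!r}")
        _paint_specimen(samples, fsc, line_times, spec, tmpl[spec.species],
                        basis, config, 0.0)
    if config.fsc_pulse_width > 0:
        k = max(1, int(round(config.fsc_pulse_width * config.line_rate)))
        fsc = np.convolve(fsc, np.ones(k), mode="same")
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        samples += rng.normal(0.0, config.noise_sigma, samples.shape)
    return (
        LineScanStream(samples=samples, line_times=line_times),
        FSCTrace(values=np.maximum(fsc, 0.0), line_times=line_times),
    )


def render_frame(
    specimen: Specimen,
    basis: SpectralBasis,
    config: AcquisitionConfig,
    templates: Mapping[str, Sequence[float]] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one specimen centred in a single event frame.

    Returns a raw ``(frame_lines, n_lateral_pixels, n_colors)`` array with
    additive noise drawn from ``rng`` (or a generator seeded from the
    config).  Convenience path for large per-event experiments where a full
    continuous stream would be needlessly heavy.
    """
    tmpl = _concentration_templates(basis, templates)
    if specimen.species not in tmpl:
        raise ValueError(f"no concentration template for species {specimen.species!r}")
    n = config.frame_lines
    line_times = np.arange(n) / config.line_rate
    center = replace(specimen, center_time=line_times[n // 2])
    samples = np.zeros((n, config.n_lateral_pixels, basis.n_colors))
    fsc = np.zeros(n)
    _paint_specimen(samples, fsc, line_times, center, tmpl[specimen.species],
                    basis, config, 0.0)
    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        samples += rng.normal(0.0, config.noise_sigma, samples.shape)
    return samples


def write_stream(stream: LineScanStream, tiff_path: str | Path,
                 times_path: str | Path) -> None:
    """Write samples as a multi-page TIFF and line times as CSV."""
    import tifffile

    tifffile.imwrite(
        tiff_path, stream.samples.astype(np.float32), photometric="minisblack"
    )
    pd.DataFrame({"line_time_s": stream.line_times}).to_csv(times_path, index=False)


def read_stream(tiff_path: str | Path, times_path: str | Path) -> LineScanStream:
    import tifffile

    samples = np.asarray(tifffile.imread(tiff_path), dtype=float)
    line_times = pd.read_csv(times_path)["line_time_s"].to_numpy(dtype=float)
    return LineScanStream(samples=samples, line_times=line_times)
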