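"""Fluorescence particle quantification and thermography traces.

Two assays share one pipeline. In the morphology assay, Bodipy stains neutral
lipid (whole adipocytes and free lipid droplets) and Hoechst stains nuclei;
a Bodipy particle containing nuclear signal is counted as an adipocyte, one
without as a free lipid droplet. In the live/dead assay, Calcein marks live
cytoplasm, EthD-1 marks dead-cell DNA and Hoechst marks all nuclei; each
channel is quantified as total particle area.

The pipeline per channel: despeckle (median filter) → intensity threshold →
distance-transform watershed to split touching particles → per-particle area
in µm². A small helper extracts mean-temperature-vs-time traces from infrared
frame stacks, with convenience flags at 1 °C and 5 °C rises (tissue heating
stays under 1 °C for treatment voltages at or below 6 V; resistive heating
beyond 5 °C appears around 10 V).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

CHANNEL_NAMES = ("bodipy", "hoechst", "calcein", "ethd1")


@dataclass
class ChannelProjection:
    """Single-channel maximum-intensity projection with a µm-per-px scale."""

    intensities: np.ndarray
    channel_name: str
    scale_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("channel projection must be a 2-D raster")
        if not np.all(np.isfinite(self.intensities)) or self.intensities.min() < 0:
            raise ValueError("intensities must be finite and nonnegative")
        if self.channel_name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.channel_name!r}; expected one of {CHANNEL_NAMES}")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")


@dataclass
class Particle:
    id: int
    area_um2: float
    centroid_rc: tuple[float, float]
    bbox: tuple[int, int, int, int]


@dataclass
class ParticleSet:
    """Labeled particles (0 = background) with per-particle areas."""

    labels: np.ndarray
    particles: list[Particle] = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def total_area_um2(self) -> float:
        return float(sum(p.area_um2 for p in self.particles))


@dataclass
class CellCounts:
    n_adipocytes: int
    n_lipid_droplets: int
    per_particle_class: dict[int, str] = field(default_factory=dict)


@dataclass
class SignalAreaSummary:
    channel_name: str
    total_area_um2: float
    n_particles: int
    annotation: str = ""


@dataclass
class TemperatureTrace:
    times_s: np.ndarray
    mean_temp_C: np.ndarray
    max_rise_C: float
    exceeds_1C: bool = False
    exceeds_5C: bool = False


def denoise(channel: ChannelProjection, radius_px: int = 1) -> ChannelProjection:
    """Despeckle with a median filter of the given radius (3×3 at radius 1)."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    size = 2 * radius_px + 1
    out = ndi.median_filter(channel.intensities, size=size)
    return ChannelProjection(out, channel.channel_name, channel.scale_um_per_px)


def threshold_channel(channel: ChannelProjection, threshold: float) -> np.ndarray:
    """Binary mask of pixels at or above the intensity threshold."""
    return channel.intensities >= threshold


def watershed_split(mask: np.ndarray, min_seed_separation_px: int = 5,
                    scale_um_per_px: float = 1.0) -> ParticleSet:
    """Split touching blobs with a Euclidean-distance-transform watershed.

    Seeds are local maxima of the distance transform at least
    ``min_seed_separation_px`` apart; watershed lines are drawn along ridges
    of the inverted distance map. Every foreground pixel receives exactly one
    positive label.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return ParticleSet(labels=np.zeros(mask.shape, dtype=np.int32))
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_seed_separation_px, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    if len(peaks) > 0:
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # peak suppression is global: guarantee a seed in every connected component
    comp, n_comp = ndi.label(mask, structure=np.ones((3, 3)))
    seeded = set(np.unique(comp[markers > 0]))
    next_id = int(markers.max()) + 1
    for c in range(1, n_comp + 1):
        if c not in seeded:
            flat = np.argmax(np.where(comp == c, dist, -1))
            markers.flat[flat] = next_id
            next_id += 1
    labels = watershed(-dist, markers=markers, mask=mask, connectivity=2)
    # relabel consecutively: basins can merge or labels go unused
    return particle_areas(labels, scale_um_per_px)


def particle_areas(labels: np.ndarray, scale_um_per_px: float = 1.0) -> ParticleSet:
    """Populate per-particle areas (px count × scale²) from a label raster.

    Labels are renumbered to consecutive positive integers sorted by original
    label id.
    """
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=np.int32)
    particles: list[Particle] = []
    for new_id, rp in enumerate(regionprops(labels.astype(np.int32)), start=1):
        out[labels == rp.label] = new_id
        particles.append(
            Particle(
                id=new_id,
                area_um2=float(rp.area * scale_um_per_px**2),
                centroid_rc=tuple(float(c) for c in rp.centroid),
                bbox=tuple(int(b) for b in rp.bbox),
            )
        )
    return ParticleSet(labels=out, particles=particles)


def classify_cells(lipid_particles: ParticleSet, nuclear_mask: np.ndarray,
                   min_overlap_px: int = 1) -> CellCounts:
    """Adipocyte vs lipid-droplet call by nuclear colocalization.

    A lipid particle is an adipocyte when at least ``min_overlap_px`` pixels
    of the nuclear mask fall inside its label region; otherwise it is a free
    lipid droplet.
    """
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    if nuclear_mask.shape != lipid_particles.labels.shape:
        raise ValueError("nuclear mask and lipid labels must share shape")
    overlap = ndi.sum_labels(nuclear_mask, lipid_particles.labels,
                             index=[p.id for p in lipid_particles.particles])
    classes = {}
    for p, ov in zip(lipid_particles.particles, np.atleast_1d(overlap)):
        classes[p.id] = "adipocyte" if ov >= min_overlap_px else "droplet"
    n_adipo = sum(1 for v in classes.values() if v == "adipocyte")
    return CellCounts(
        n_adipocytes=n_adipo,
        n_lipid_droplets=len(classes) - n_adipo,
        per_particle_class=classes,
    )


def quantify_channel(channel: ChannelProjection, threshold: float,
                     denoise_radius: int = 1,
                     min_seed_separation_px: int = 5) -> tuple[ParticleSet, SignalAreaSummary]:
    """denoise → threshold → watershed → particle areas for one channel."""
    den = denoise(channel, denoise_radius)
    mask = threshold_channel(den, threshold)
    pset = watershed_split(mask, min_seed_separation_px, channel.scale_um_per_px)
    summary = SignalAreaSummary(
        channel_name=channel.channel_name,
        total_area_um2=pset.total_area_um2,
        n_particles=pset.n_particles,
    )
    return pset, summary


def live_dead_summary(calcein: ChannelProjection, hoechst: ChannelProjection,
                      ethd1: ChannelProjection, thresholds: dict[str, float],
                      denoise_radius: int = 1) -> list[SignalAreaSummary]:
    """Total signal areas for the Calcein / Hoechst / EthD-1 channels.

    Live cells are Calcein-positive; Hoechst marks all nuclei and EthD-1 dead
    nuclei, so Hoechst-minus-EthD-1 indicates live cells. That interpretation
    is attached as an annotation only; the numbers reported are per-channel
    particle areas.
    """
    shapes = {c.intensities.shape for c in (calcein, hoechst, ethd1)}
    if len(shapes) != 1:
        raise ValueError("channels must share shape")
    out = []
    notes = {
        "calcein": "live cytoplasm",
        "hoechst": "all nuclei (may include collagen SHG)",
        "ethd1": "dead-cell nuclei; Hoechst minus EthD-1 ~ live",
    }
    for ch in (calcein, hoechst, ethd1):
        _, summary = quantify_channel(ch, thresholds[ch.channel_name], denoise_radius)
        summary.annotation = notes[ch.channel_name]
        out.append(summary)
    return out


def suppress_elongated(nuclear_mask: np.ndarray, max_aspect_ratio: float = 3.0) -> np.ndarray:
    """Drop fibril-shaped components (major/minor axis ratio above cutoff).

    Collagen second-harmonic signal bleeds into the nuclear imaging channel as
    elongated fibrils; nuclei are round. Off by default in the pipeline.
    """
    labeled, _ = ndi.label(np.asarray(nuclear_mask, dtype=bool))
    out = np.zeros_like(nuclear_mask, dtype=bool)
    for rp in regionprops(labeled):
        minor = rp.axis_minor_length
        ratio = rp.axis_major_length / minor if minor > 0 else np.inf
        if ratio <= max_aspect_ratio:
            out[labeled == rp.label] = True
    return out


def roi_temperature_trace(frames: np.ndarray, times_s: np.ndarray,
                          roi: tuple[int, int, int, int]) -> TemperatureTrace:
    """Mean ROI temperature per frame and the maximum rise over the first frame.

    ``roi`` is (row_start, row_end, col_start, col_end), half-open. Flags are
    set when the rise exceeds 1 °C and 5 °C.
    """
    frames = np.asarray(frames, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if frames.ndim != 3 or frames.shape[0] != times_s.size:
        raise ValueError("frames must be T×H×W matching times")
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("times must be strictly increasing")
    r0, r1, c0, c1 = roi
    if r1 <= r0 or c1 <= c0 or r0 < 0 or c0 < 0 or r1 > frames.shape[1] or c1 > frames.shape[2]:
        raise ValueError("ROI empty or outside frames")
    means = frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    rise = float(means.max() - means[0])
    return TemperatureTrace(
        times_s=times_s,
        mean_temp_C=means,
        max_rise_C=rise,
        exceeds_1C=rise > 1.0,
        exceeds_5C=rise > 5.0,
    )
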