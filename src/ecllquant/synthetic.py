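"""Synthetic ground-truth generators for every pipeline input.

No tissue images or assay spreadsheets are deposited with this package, so
each stage is validated against synthetic data with known truth: dye-stained
cross-section photographs with two colored pH bands, fluorescence channel
fields of disk-shaped cells, monitored current traces, thermal frame stacks,
and potassium/glycerol assay readouts generated from a known lysed fraction
and saponified fraction. Every generator is deterministic per seed
(numpy PCG64 via ``default_rng``) and returns its truth record alongside the
data; ``write_truth_sidecar`` serializes the truth as key=value text.

What the generators emulate — and what they do not: band geometry is
rectangular (constant width with depth) although real fronts taper; cells are
perfect disks with uniform staining; assay noise is multiplicative Gaussian.
Recovery of truth here demonstrates the pipeline's numerics, not robustness
to every artifact of real tissue photography or microscopy.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import dosimetry as dosi
from .fluorescence import ChannelProjection
from .ph_mapping import CalibratedImage, lab_to_rgb

#: Package LAB constants for the dye colors: acid front (orange, ~pH 5),
#: base front (blue, ~pH 8) and unstained tissue background.
LAB_ANODE = (62.0, 35.0, 55.0)
LAB_CATHODE = (45.0, 0.0, -45.0)
LAB_BACKGROUND = (72.0, 14.0, 16.0)

GLYCEROL_POSITIVE_MGL = 72.0  # complete-saponification yield of 1 cm³ tissue
GLYCEROL_BACKGROUND_MGL = 1.4


@dataclass
class PhMapTruth:
    """Ground truth of a synthetic pH-map photograph."""

    anode_width_mm: float = 2.0
    cathode_width_mm: float = 3.0
    colors: dict = field(default_factory=lambda: {
        "background": LAB_BACKGROUND, "anode": LAB_ANODE, "cathode": LAB_CATHODE,
    })
    noise_sd: float = 2.0
    scale_mm_per_px: float = 0.05
    electrode_spacing_mm: float = 3.0
    seed: int = 0


@dataclass
class FluorFieldTruth:
    """Ground truth of a synthetic fluorescence field."""

    n_adipocytes: int = 30
    n_droplets: int = 20
    cell_radius_px: tuple[int, int] = (8, 14)
    nucleus_radius_px: int = 3
    live_fraction: float = 1.0
    noise_scale: float = 0.02
    seed: int = 0
    centroids: list = field(default_factory=list)
    radii: list = field(default_factory=list)
    nucleated: list = field(default_factory=list)
    alive: list = field(default_factory=list)


@dataclass
class AssayTruth:
    """Ground truth behind synthetic potassium and glycerol readouts."""

    true_lysed_fraction: float = 0.146
    true_saponified_fraction: float = 0.40
    noise_cv: float = 0.0
    seed: int = 0


def make_ph_image(truth: PhMapTruth, image_size: tuple[int, int] = (240, 400)
                  ) -> tuple[CalibratedImage, PhMapTruth]:
    """Render a dye-stained cross-section with two vertical pH bands.

    The anode (orange) and cathode (blue) bands are centered on two electrode
    positions ``electrode_spacing_mm`` apart around the image center, each of
    the specified physical width, on a tissue-colored background. I.i.d.
    Gaussian noise of SD ``noise_sd`` is added in LAB space before conversion
    to sRGB.
    """
    h, w = image_size
    scale = truth.scale_mm_per_px
    rng = np.random.default_rng(truth.seed)

    colors = {k: np.asarray(v, dtype=float) for k, v in truth.colors.items()}
    seps = [np.linalg.norm(colors[a] - colors[b])
            for a, b in (("background", "anode"), ("background", "cathode"), ("anode", "cathode"))]
    if truth.noise_sd > 0 and min(seps) < 5 * truth.noise_sd:
        warnings.warn("color separation < 5× noise SD: bands may be unresolvable",
                      stacklevel=2)

    half_gap_px = truth.electrode_spacing_mm / 2 / scale
    cx = w / 2
    x_anode, x_cathode = cx - half_gap_px, cx + half_gap_px
    half_a = truth.anode_width_mm / 2 / scale
    half_c = truth.cathode_width_mm / 2 / scale
    if x_anode + half_a >= x_cathode - half_c:
        raise ValueError("pH bands overlap: widths too large for electrode spacing")
    cols = np.arange(w)
    in_anode = np.abs(cols - x_anode) < half_a
    in_cathode = np.abs(cols - x_cathode) < half_c
    if in_anode.sum() == 0 or in_cathode.sum() == 0 or (x_anode - half_a) < 0 or (x_cathode + half_c) > w:
        raise ValueError("bands do not fit inside the image at this scale")

    lab = np.empty((h, w, 3))
    lab[:] = colors["background"]
    lab[:, in_anode] = colors["anode"]
    lab[:, in_cathode] = colors["cathode"]
    lab += rng.normal(0.0, truth.noise_sd, size=lab.shape)
    rgb = np.clip(lab_to_rgb(lab), 0.0, 1.0)
    return CalibratedImage(rgb, scale_mm_per_px=scale), truth


def make_recovery_ph_truth(anode_width_mm: float, cathode_width_mm: float,
                           seed: int, noise_sd: float = 2.0,
                           scale_mm_per_px: float = 0.05,
                           margin_mm: float = 1.0) -> PhMapTruth:
    """Truth with electrode spacing widened just enough to resolve both bands.

    Fronts wider than the electrode spacing physically merge where acid meets
    base; the width metric is defined for resolved bands, so width-recovery
    experiments place the electrodes ``margin_mm`` beyond the touching
    distance whenever the default 3 mm spacing would make the bands overlap.
    """
    spacing = max(3.0, (anode_width_mm + cathode_width_mm) / 2 + margin_mm)
    return PhMapTruth(anode_width_mm=anode_width_mm, cathode_width_mm=cathode_width_mm,
                      noise_sd=noise_sd, scale_mm_per_px=scale_mm_per_px,
                      electrode_spacing_mm=spacing, seed=seed)


def default_ph_rois(truth: PhMapTruth, image_size: tuple[int, int] = (240, 400)
                    ) -> tuple[tuple[int, int, int, int], tuple[int, int, int, int]]:
    """ROIs centered inside each band (half the band width, mid-depth rows)."""
    h, w = image_size
    scale = truth.scale_mm_per_px
    cx = w / 2
    half_gap = truth.electrode_spacing_mm / 2 / scale
    rois = []
    for x_c, width_mm in ((cx - half_gap, truth.anode_width_mm),
                          (cx + half_gap, truth.cathode_width_mm)):
        half = max(2, int(width_mm / 2 / scale * 0.5))
        rois.append((h // 4, 3 * h // 4, int(x_c - half), int(x_c + half) + 1))
    return tuple(rois)


def _draw_disk(img: np.ndarray, center: tuple[int, int], radius: float, value: float) -> None:
    r0, c0 = center
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value


def make_fluor_field(truth: FluorFieldTruth, image_size: tuple[int, int] = (256, 256),
                     scale_um_per_px: float = 1.0,
                     max_place_attempts: int = 20000
                     ) -> tuple[dict[str, ChannelProjection], FluorFieldTruth]:
    """Render the four fluorescence channels for a field of disk cells.

    Bodipy: every cell as a filled disk. Hoechst: nuclear dots inside the
    nucleated (adipocyte) subset. Calcein: the live fraction of cells.
    EthD-1: nuclear dots of dead nucleated cells. Disks are placed without
    overlap by rejection sampling; Poisson photon noise plus Gaussian read
    noise is added to each channel. The placed centroids/radii and the
    nucleated/alive flags are recorded in the returned truth.
    """
    h, w = image_size
    rng = np.random.default_rng(truth.seed)
    n_total = truth.n_adipocytes + truth.n_droplets
    rmin, rmax = truth.cell_radius_px

    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    attempts = 0
    while len(centers) < n_total:
        attempts += 1
        if attempts > max_place_attempts:
            raise ValueError("cannot place disks without overlap: field too crowded")
        r = int(rng.integers(rmin, rmax + 1))
        cr = int(rng.integers(r + 1, h - r - 1))
        cc = int(rng.integers(r + 1, w - r - 1))
        if all((cr - pr) ** 2 + (cc - pc) ** 2 > (r + prr + 2) ** 2
               for (pr, pc), prr in zip(centers, radii)):
            centers.append((cr, cc))
            radii.append(r)

    nucleated = [i < truth.n_adipocytes for i in range(n_total)]
    alive = list(rng.random(n_total) < truth.live_fraction)

    bodipy = np.zeros((h, w))
    hoechst = np.zeros((h, w))
    calcein = np.zeros((h, w))
    ethd1 = np.zeros((h, w))
    for i, (ctr, r) in enumerate(zip(centers, radii)):
        _draw_disk(bodipy, ctr, r, 1.0)
        if nucleated[i]:
            _draw_disk(hoechst, ctr, truth.nucleus_radius_px, 1.0)
            if not alive[i]:
                _draw_disk(ethd1, ctr, truth.nucleus_radius_px, 1.0)
        if alive[i]:
            _draw_disk(calcein, ctr, r, 1.0)

    channels = {}
    photons = 200.0
    for name, img in (("bodipy", bodipy), ("hoechst", hoechst),
                      ("calcein", calcein), ("ethd1", ethd1)):
        noisy = rng.poisson(img * photons) / photons
        noisy = noisy + rng.normal(0.0, truth.noise_scale, size=img.shape)
        channels[name] = ChannelProjection(np.clip(noisy, 0, None), name, scale_um_per_px)

    out_truth = FluorFieldTruth(**{**asdict(truth),
                                   "centroids": centers, "radii": radii,
                                   "nucleated": nucleated, "alive": alive})
    return channels, out_truth


def make_current_trace(mean_current_A: float, duration_s: float,
                       noise_cv: float = 0.0, seed: int = 0) -> dosi.CurrentTrace:
    """Current monitored at 1 Hz with multiplicative Gaussian noise.

    The expected trapezoidal integral equals ``mean_current_A * duration_s``.
    """
    if mean_current_A <= 0 or duration_s <= 0:
        raise ValueError("current and duration must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 1e-12, 1.0)
    if times.size < 2 or times[-1] < duration_s:
        times = np.linspace(0.0, duration_s, max(2, times.size))
    current = mean_current_A * (1.0 + rng.normal(0.0, noise_cv, size=times.size))
    return dosi.CurrentTrace(times, np.clip(current, 0.0, None))


def make_thermal_stack(n_frames: int, rise_C: float, baseline_C: float = 20.0,
                       noise_sd: float = 0.0, shape: tuple[int, int] = (32, 32),
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Frame stack with a linear programmed temperature ramp plus pixel noise."""
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames, dtype=float)
    ramp = baseline_C + rise_C * times / max(1, n_frames - 1)
    frames = ramp[:, None, None] + rng.normal(0.0, noise_sd, size=(n_frames, *shape))
    return frames, times


def make_assay_readouts(truth: AssayTruth,
                        tissue_volume_uL: float = dosi.DEFAULT_TISSUE_VOLUME_UL,
                        n_electrodes: int = dosi.DEFAULT_N_ELECTRODES,
                        sample_volume_uL: float = dosi.DEFAULT_SAMPLE_VOLUME_UL,
                        intracellular_mM: float = dosi.DEFAULT_INTRACELLULAR_K_MM,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, AssayTruth]:
    """Potassium and glycerol readout tables from known lysis/saponification.

    K⁺ released = lysed fraction × intracellular [K⁺] × (1+ε); glycerol of the
    treated sample = saponified fraction × positive-control yield × treated
    volume fraction × (1+ε), ε ~ N(0, noise_cv). Positive and negative control
    rows are included in both tables.
    """
    rng = np.random.default_rng(truth.seed)

    def noisy(x: float) -> float:
        return float(x * (1.0 + rng.normal(0.0, truth.noise_cv))) if truth.noise_cv > 0 else x

    k_released = noisy(truth.true_lysed_fraction * intracellular_mM)
    k_df = pd.DataFrame([
        {"sample_id": "treated", "condition": "treated", "conc_released_mM": k_released},
        {"sample_id": "negative", "condition": "negative_control", "conc_released_mM": 0.0},
        {"sample_id": "positive", "condition": "positive_control",
         "conc_released_mM": intracellular_mM},
    ])

    per_electrode_uL = truth.true_lysed_fraction * tissue_volume_uL / n_electrodes
    volume_fraction = per_electrode_uL / sample_volume_uL
    g_treated = noisy(truth.true_saponified_fraction * GLYCEROL_POSITIVE_MGL * volume_fraction)
    g_df = pd.DataFrame([
        {"sample_id": "treated", "condition": "treated", "conc_mgL": g_treated},
        {"sample_id": "untreated", "condition": "negative_control",
         "conc_mgL": GLYCEROL_BACKGROUND_MGL},
        {"sample_id": "positive", "condition": "positive_control",
         "conc_mgL": GLYCEROL_POSITIVE_MGL},
    ])
    return k_df, g_df, truth


def write_truth_sidecar(truth, path) -> None:
    """Serialize a truth dataclass as flat key=value text."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in asdict(truth).items():
            fh.write(f"{key}={value!r}\n")
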