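"""Synthetic photoactivated-localization (PALM) movies with ground truth.

The acquisition protocol is the pulsed scheme used for mEos2: blocks of
short imaging frames (33 ms) at the readout laser, each block paired with
one 405 nm activation pulse, repeated until the fluorophore pool is
exhausted (a few thousand frames).  Activation is sparse by design so that
at most ~one emitter is on per diffraction-limited region per frame, and
each activated molecule bleaches irreversibly within its imaging block.

Photophysics model: off -> (pulse, probability p) -> on for a geometric
number of frames, capped at the block length -> bleached.  Camera model:
Poisson photon noise on the pixel-integrated Gaussian PSF plus a Poisson
background, a multiplicative EM gain, and additive Gaussian read noise.
The full EMCCD gain-register cascade (excess-noise factor ~sqrt(2)) is not
modelled.

Also provides a synthetic brightfield image of a rod-shaped cell
(spherocylinder, the fission-yeast morphology) for exercising the
automation chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "AcquisitionConfig",
    "EmitterSet",
    "FrameStack",
    "generate_schedule",
    "simulate_movie",
    "simulate_brightfield_cell",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    frame_time_ms: float = 33.0
    frames_per_imaging_block: int = 10
    activation_pulses: int = 500     # 500 pulses x 10 frames fills max_frames
    max_frames: int = 5000           # imaging frames
    detector_shape: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 100.0
    psf_sigma_nm: float = 130.0
    emccd_gain: float = 50.0         # counts per photoelectron
    read_noise_e: float = 1.0        # photon-equivalent rms, post-gain
    camera_offset: float = 100.0     # counts
    background_photons_per_px: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.frames_per_imaging_block < 1:
            raise ValueError("frames_per_imaging_block must be >= 1")
        if min(self.detector_shape) < 1:
            raise ValueError("detector_shape must be positive")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be positive")
        if self.activation_pulses < 0 or self.max_frames < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EmitterSet:
    """Ground-truth fluorophores: positions, photon yield, photophysics."""

    x_nm: np.ndarray
    y_nm: np.ndarray
    photon_budget: float = 300.0          # expected photons per on-frame
    activation_prob: float = 0.02         # per pulse, per inactive emitter
    mean_on_frames: float = 2.0           # mean of the geometric on-time
    cluster: np.ndarray | None = None     # integer cluster labels

    def __post_init__(self):
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        if self.cluster is None:
            self.cluster = np.zeros(self.x_nm.size, dtype=int)
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")

    def __len__(self) -> int:
        return self.x_nm.size

    @classmethod
    def two_clusters(cls, centers_nm, n_per_cluster: int = 30,
                     scatter_nm: float = 120.0, seed: int = 0,
                     **kw) -> "EmitterSet":
        """Two compact puncta, like a pair of separated centromeric foci."""
        rng = np.random.default_rng(seed)
        xs, ys, labels = [], [], []
        for ci, (cx, cy) in enumerate(centers_nm):
            xs.append(rng.normal(cx, scatter_nm, n_per_cluster))
            ys.append(rng.normal(cy, scatter_nm, n_per_cluster))
            labels.append(np.full(n_per_cluster, ci))
        return cls(np.concatenate(xs), np.concatenate(ys),
                   cluster=np.concatenate(labels), **kw)


@dataclass
class FrameStack:
    """Detector frames, the pulse schedule, and the ground-truth table."""

    frames: np.ndarray                     # (n_frames, H, W) uint16 counts
    config: AcquisitionConfig
    ground_truth: pd.DataFrame             # frame, emitter, x_nm, y_nm, photons, crowded
    annotations: list = field(default_factory=list)  # ("activation"|"imaging", idx)

    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.frames)


def generate_schedule(config: AcquisitionConfig) -> list[tuple[str, int | None]]:
    """Pulse/imaging event sequence, truncated at ``max_frames`` frames.

    Each activation pulse is followed by ``frames_per_imaging_block``
    imaging frames; ``("imaging", i)`` carries the imaging-frame index.
    """
    config.validate()
    events: list[tuple[str, int | None]] = []
    frame = 0
    for _ in range(config.activation_pulses):
        if frame >= config.max_frames:
            break
        events.append(("activation", None))
        for _ in range(config.frames_per_imaging_block):
            if frame >= config.max_frames:
                break
            events.append(("imaging", frame))
            frame += 1
    return events


def integrated_gaussian(shape: tuple[int, int], x_px: float, y_px: float,
                        sigma_px: float, window_sigmas: float = 6.0) -> np.ndarray:
    """Unit-mass 2D Gaussian integrated over pixels (sparse support)."""
    h, w = shape
    out = np.zeros(shape)
    r = int(np.ceil(window_sigmas * sigma_px)) + 1
    x0, x1 = max(int(x_px) - r, 0), min(int(x_px) + r + 2, w)
    y0, y1 = max(int(y_px) - r, 0), min(int(y_px) + r + 2, h)
    if x0 >= x1 or y0 >= y1:
        return out
    s = sigma_px * np.sqrt(2.0)
    ex = 0.5 * (erf((np.arange(x0, x1 + 1) - 0.5 - x_px) / s))
    ey = 0.5 * (erf((np.arange(y0, y1 + 1) - 0.5 - y_px) / s))
    out[y0:y1, x0:x1] = np.outer(np.diff(ey), np.diff(ex))
    return out


def simulate_movie(emitters: EmitterSet, config: AcquisitionConfig,
                   seed: int | None = None) -> FrameStack:
    """Render the movie for ``emitters`` under ``config``.

    Each on-emitter contributes an expected ``photon_budget`` photons per
    imaging frame as a pixel-integrated Gaussian; shot noise is applied per
    pixel together with the background, then gain, read noise, offset and
    16-bit quantisation.  The ground-truth table records every (frame,
    emitter) emission with its expected photon count; ``crowded`` flags
    frames where another active emitter sits within 4 PSF sigma.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    events = generate_schedule(config)
    n_frames = sum(1 for kind, _ in events if kind == "imaging")
    h, w = config.detector_shape
    px = config.pixel_size_nm
    sigma_px = config.psf_sigma_nm / px

    n = len(emitters)
    activated = np.zeros(n, dtype=bool)
    frames_left = np.zeros(n, dtype=int)

    frames = np.zeros((n_frames, h, w), dtype=np.uint16)
    gt_rows = []
    for kind, fidx in events:
        if kind == "activation":
            candidates = ~activated
            fire = candidates & (rng.random(n) < emitters.activation_prob)
            activated |= fire
            k = int(fire.sum())
            if k:
                on = rng.geometric(1.0 / emitters.mean_on_frames, size=k)
                frames_left[fire] = np.minimum(on, config.frames_per_imaging_block)
            continue
        active = np.flatnonzero(frames_left > 0)
        mu = np.full((h, w), float(config.background_photons_per_px))
        for i in active:
            xp, yp = emitters.x_nm[i] / px, emitters.y_nm[i] / px
            mu += emitters.photon_budget * integrated_gaussian(
                (h, w), xp, yp, sigma_px)
        counts = rng.poisson(mu) * config.emccd_gain
        counts = counts + rng.normal(
            0.0, config.read_noise_e * config.emccd_gain, size=(h, w))
        frames[fidx] = np.clip(np.round(counts + config.camera_offset),
                               0, 65535).astype(np.uint16)
        for i in active:
            near = [j for j in active if j != i and
                    np.hypot(emitters.x_nm[j] - emitters.x_nm[i],
                             emitters.y_nm[j] - emitters.y_nm[i])
                    < 4 * config.psf_sigma_nm]
            gt_rows.append({"frame": fidx, "emitter": int(i),
                            "x_nm": emitters.x_nm[i], "y_nm": emitters.y_nm[i],
                            "photons": emitters.photon_budget,
                            "cluster": int(emitters.cluster[i]),
                            "crowded": bool(near)})
        frames_left[active] -= 1

    gt = pd.DataFrame(gt_rows, columns=["frame", "emitter", "x_nm", "y_nm",
                                        "photons", "cluster", "crowded"])
    return FrameStack(frames=frames, config=config, ground_truth=gt,
                      annotations=events)


def simulate_brightfield_cell(length_um: float, diameter_um: float = 4.0,
                              orientation_deg: float = 0.0,
                              center_px: tuple[float, float] | None = None,
                              shape: tuple[int, int] = (512, 512),
                              pixel_size_um: float = 0.1,
                              background: float = 1000.0,
                              contrast: float = 400.0,
                              noise: float = 10.0,
                              defocus_px: float = 0.0,
                              seed: int = 0):
    """Brightfield image of a rod-shaped cell in a basin-like field.

    The cell is a spherocylinder of the given long-axis length and
    diameter (fission-yeast cells are ~4 um across and 7–14 um long over
    the cycle), rendered dark on a bright background with soft edges, two
    faint basin-wall shadows, and Gaussian noise.  Returns ``(image,
    truth)`` with the ground-truth pose in ``truth``.
    """
    if not length_um >= diameter_um > 0:
        raise ValueError("need length_um >= diameter_um > 0")
    h, w = shape
    cy, cx = center_px if center_px is not None else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    theta = np.deg2rad(orientation_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    dx, dy = xx - cx, yy - cy
    half_core = max((length_um - diameter_um) / 2 / pixel_size_um, 0.0)
    t = np.clip(dx * ux + dy * uy, -half_core, half_core)
    dist = np.hypot(dx - t * ux, dy - t * uy)

    radius_px = diameter_um / 2 / pixel_size_um
    edge = max(1.0, defocus_px + 1.0)
    soft = 1.0 / (1.0 + np.exp((dist - radius_px) / edge))

    img = np.full(shape, background, dtype=float)
    # faint shadows of the basin side walls
    wall = background * 0.05 * (np.exp(-((xx - w * 0.08) / 3.0) ** 2)
                                + np.exp(-((xx - w * 0.92) / 3.0) ** 2))
    img -= wall
    img -= contrast * soft
    if noise > 0:
        img += np.random.default_rng(seed).normal(0.0, noise, shape)
    truth = {"center_px": (cy, cx), "length_um": length_um,
             "diameter_um": diameter_um, "orientation_deg": orientation_deg % 180}
    return img, truth
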