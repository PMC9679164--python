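"""Combined ring-and-wedge retinotopic mapping protocol.

The protocol presents a simultaneous expanding/contracting ring and rotating
wedge, one aperture position per 1-s TR.  The ring traverses eccentricity
with logarithmic scaling over 48-s cycles (6 cycles per run); the 20-deg
wedge rotates through 360 deg in 36 s (8 cycles per run).  Three 20-s
fixation baselines are embedded at the start, mid-point and end, giving a
348-frame (348 s) run at a maximum stimulated eccentricity of 8.6 deg.

Only the binary apertures are modelled: the pRF forward model is driven by
aperture/receptive-field overlap, so the checkerboard carrier inside the
aperture is irrelevant here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolConfig",
    "ApertureSequence",
    "ring_eccentricity_schedule",
    "wedge_angle_schedule",
    "compose_run",
]


@dataclass(frozen=True)
class ProtocolConfig:
    max_eccentricity: float = 8.6  # deg
    tr_s: float = 1.0
    ring_cycles: int = 6
    ring_period_s: float = 48.0
    wedge_cycles: int = 8
    wedge_period_s: float = 36.0
    wedge_width_deg: float = 20.0
    baseline_s: float = 20.0
    grid_resolution: float = 4.0  # pixels per degree
    ring_min_eccentricity: float = 0.5  # deg
    ring_width_ratio: float = 0.5  # annulus width as a fraction of centre ecc

    def __post_init__(self) -> None:
        for name in (
            "max_eccentricity",
            "tr_s",
            "ring_cycles",
            "ring_period_s",
            "wedge_cycles",
            "wedge_period_s",
            "wedge_width_deg",
            "baseline_s",
            "grid_resolution",
            "ring_min_eccentricity",
            "ring_width_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ring_stim_s != self.wedge_stim_s:
            raise ValueError(
                "inconsistent protocol: ring and wedge stimulation durations "
                f"differ ({self.ring_stim_s} s vs {self.wedge_stim_s} s)"
            )

    @property
    def ring_stim_s(self) -> float:
        return self.ring_cycles * self.ring_period_s

    @property
    def wedge_stim_s(self) -> float:
        return self.wedge_cycles * self.wedge_period_s

    @property
    def total_duration_s(self) -> float:
        return self.ring_stim_s + 3 * self.baseline_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s / self.tr_s))

    @property
    def n_stim_frames(self) -> int:
        return int(round(self.ring_stim_s / self.tr_s))


def ring_eccentricity_schedule(
    config: ProtocolConfig, expanding: bool = True
) -> np.ndarray:
    """Per-stimulation-frame (inner, outer) ring radii in degrees.

    Within each cycle the ring *centre* eccentricity is log-spaced from
    ``ring_min_eccentricity`` up to the value at which the outer edge reaches
    ``max_eccentricity``; the annulus width scales proportionally with the
    centre (width = ring_width_ratio x centre), so the last frame of an
    expanding cycle touches the stimulus edge exactly.
    """
    frames_per_cycle = int(round(config.ring_period_s / config.tr_s))
    centre_max = config.max_eccentricity / (1.0 + config.ring_width_ratio / 2.0)
    centre = np.geomspace(config.ring_min_eccentricity, centre_max, frames_per_cycle)
    if not expanding:
        centre = centre[::-1]
    centre = np.tile(centre, config.ring_cycles)
    half_width = 0.5 * config.ring_width_ratio * centre
    return np.column_stack([centre - half_width, centre + half_width])


def wedge_angle_schedule(
    config: ProtocolConfig, clockwise: bool = True, start_deg: float = 0.0
) -> np.ndarray:
    """Per-stimulation-frame wedge centre angle in [0, 360) degrees.

    The wedge advances 360 / period degrees per TR (10 deg/s for a 36-s
    cycle).  Angles follow the mathematical convention (0 deg = right
    horizontal meridian, counter-clockwise positive); ``clockwise`` negates
    the increment.
    """
    step = 360.0 / config.wedge_period_s * config.tr_s
    if clockwise:
        step = -step
    t = np.arange(config.n_stim_frames)
    return (start_deg + step * t) % 360.0


@dataclass(frozen=True)
class ApertureSequence:
    """Per-TR binary visual-field masks on a square grid spanning +/-max_ecc."""

    frames: np.ndarray  # (T, H, W) bool
    baseline_flags: np.ndarray  # (T,) bool
    coords: np.ndarray  # (H,) pixel-centre coordinates in deg (shared by x, y)
    frame_table: pd.DataFrame  # frame, time_s, ring_inner, ring_outer, wedge_angle

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_xy(self) -> tuple:
        x, y = np.meshgrid(self.coords, self.coords)
        return x, y

    def flat_frames(self) -> np.ndarray:
        """(T, P) float view used by the pRF forward model."""
        return self.frames.reshape(self.n_frames, -1).astype(float)

    def save(self, stem: str | Path) -> None:
        """Write <stem>.npz (masks) and <stem>_frames.csv (frame table)."""
        stem = Path(stem)
        np.savez_compressed(
            stem.with_suffix(".npz"),
            frames=self.frames,
            baseline_flags=self.baseline_flags,
            coords=self.coords,
        )
        self.frame_table.to_csv(stem.parent / f"{stem.name}_frames.csv", index=False)

    @classmethod
    def load(cls, stem: str | Path) -> "ApertureSequence":
        stem = Path(stem)
        with np.load(stem.with_suffix(".npz")) as z:
            frames = z["frames"]
            flags = z["baseline_flags"]
            coords = z["coords"]
        table = pd.read_csv(stem.parent / f"{stem.name}_frames.csv")
        return cls(frames, flags, coords, table)


def _grid_coords(config: ProtocolConfig) -> np.ndarray:
    n = int(round(2 * config.max_eccentricity * config.grid_resolution))
    if n % 2 == 0:
        n += 1  # odd pixel count so a pixel centre sits at fixation
    half = n / (2.0 * config.grid_resolution)
    return (np.arange(n) + 0.5) / config.grid_resolution - half


def compose_run(
    config: ProtocolConfig = ProtocolConfig(),
    ring_expanding: bool = True,
    wedge_clockwise: bool = True,
) -> ApertureSequence:
    """Full run: union of ring and wedge masks with three embedded baselines.

    Baselines (all-off frames) occupy the first and last ``baseline_s``
    seconds and an equal block at the mid-point, splitting the stimulation
    frames into two equal halves.
    """
    ring = ring_eccentricity_schedule(config, expanding=ring_expanding)
    wedge = wedge_angle_schedule(config, clockwise=wedge_clockwise)
    n_stim = config.n_stim_frames
    n_base = int(round(config.baseline_s / config.tr_s))
    if ring.shape[0] != n_stim or wedge.shape[0] != n_stim:
        raise ValueError("ring and wedge schedules have inconsistent lengths")

    coords = _grid_coords(config)
    x, y = np.meshgrid(coords, coords)
    r = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    in_field = r <= config.max_eccentricity
    half_wedge = config.wedge_width_deg / 2.0

    n_total = config.n_frames
    frames = np.zeros((n_total, coords.size, coords.size), dtype=bool)
    baseline = np.zeros(n_total, dtype=bool)
    half_stim = n_stim // 2
    stim_to_frame = np.concatenate(
        [
            n_base + np.arange(half_stim),
            2 * n_base + half_stim + np.arange(n_stim - half_stim),
        ]
    )
    baseline[:] = True
    baseline[stim_to_frame] = False

    table = pd.DataFrame(
        {
            "frame": np.arange(n_total),
            "time_s": np.arange(n_total) * config.tr_s,
            "ring_inner": np.nan,
            "ring_outer": np.nan,
            "wedge_angle": np.nan,
            "baseline": baseline,
        }
    )
    for s, f in enumerate(stim_to_frame):
        inner, outer = ring[s]
        theta = wedge[s]
        ring_mask = (r >= inner) & (r <= outer)
        # half-open wedge [theta - w/2, theta + w/2) to avoid double counting
        dang = (ang - (theta - half_wedge)) % 360.0
        wedge_mask = dang < config.wedge_width_deg
        frames[f] = (ring_mask | wedge_mask) & in_field
        table.loc[f, ["ring_inner", "ring_outer", "wedge_angle"]] = (
            inner,
            outer,
            theta,
        )
    return ApertureSequence(frames, baseline, coords, table)
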