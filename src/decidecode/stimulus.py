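"""Circular drifting-grating stimulus.

The task stimulus is a radially drifting (expanding or contracting) circular
grating.  Pixel intensity is produced in two steps: a radial blending value

    a(x, y) = 1/2 + 1/2 * sin(pi * (d(x, y) - s) / (2 r))

where ``d`` is the pixel's eccentricity (degrees from screen centre), ``s``
the current drift phase (degrees) and ``r`` the spatial parameter setting the
grating's spatial frequency (period ``4 r`` degrees); and a blend of two
grayscale levels straddling mid-gray at the requested Michelson contrast c:

    l(x, y) = a * (0.5 - c/2) + (1 - a) * (0.5 + c/2)

so intensities span [0.5 - c/2, 0.5 + c/2] and the rendered Michelson
contrast (max-min)/(max+min) outside the inner annulus equals c.  Pixels
inside the inner annulus are uniform mid-gray (0.5).  Iso-intensity contours
satisfy d - s = const, so advancing the phase at ``drift_speed`` degrees per
second drifts the rings radially at exactly that speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusSpec", "render_frame", "advance_phase", "michelson_contrast"]


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and dynamics of the circular grating (degrees of visual angle)."""

    spatial_param_r: float = 0.75      # sets spatial frequency; period = 4 r
    drift_speed: float = 4.0 / 3.0     # deg / s
    annulus_radius: float = 1.5        # inner uniform-gray disk
    truncation_radius: float = 11.3    # visible extent (screen border)
    frame_rate: float = 60.0           # Hz
    direction: str = "expand"          # {"expand", "contract"}
    pixels_per_degree: float = 25.0

    def __post_init__(self):
        if self.spatial_param_r <= 0 or self.annulus_radius <= 0 or self.truncation_radius <= 0:
            raise ValueError("all radii and the spatial parameter must be positive")
        if self.annulus_radius >= self.truncation_radius:
            raise ValueError("annulus_radius must be smaller than truncation_radius")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.direction not in ("expand", "contract"):
            raise ValueError("direction must be 'expand' or 'contract'")

    @property
    def direction_sign(self) -> int:
        return 1 if self.direction == "expand" else -1


def _blend(spec: StimulusSpec, d: np.ndarray, phase_s: float, contrast: float) -> np.ndarray:
    a = 0.5 + 0.5 * np.sin(np.pi * (d - phase_s) / (2.0 * spec.spatial_param_r))
    return a * (0.5 - contrast / 2.0) + (1.0 - a) * (0.5 + contrast / 2.0)


def render_frame(
    spec: StimulusSpec,
    contrast: float,
    phase_s: float,
    grid_size: int | None = None,
) -> np.ndarray:
    """Render one stimulus frame as a 2-D intensity field in [0, 1].

    Parameters
    ----------
    contrast : Michelson contrast of the grating, in [0, 1].
    phase_s : current drift phase in degrees.
    grid_size : number of pixels per side; defaults to cover the truncation
        radius at ``spec.pixels_per_degree``.
    """
    if not np.isfinite(phase_s):
        raise ValueError("phase_s must be finite")
    if not np.isfinite(contrast) or not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast must lie in [0, 1], got {contrast!r}")
    if grid_size is None:
        grid_size = int(np.ceil(2 * spec.truncation_radius * spec.pixels_per_degree)) + 1
    half = (grid_size - 1) / 2.0
    px = (np.arange(grid_size) - half) / (grid_size - 1) * (2 * spec.truncation_radius)
    x, y = np.meshgrid(px, px)
    d = np.hypot(x, y)
    frame = _blend(spec, d, phase_s, contrast)
    frame[d < spec.annulus_radius] = 0.5
    return frame


def advance_phase(spec: StimulusSpec, phase_s: float, n_frames: int) -> float:
    """Advance the drift phase by ``n_frames`` frames.

    Increment = direction_sign * drift_speed * n_frames / frame_rate, so the
    iso-intensity contours move radially at ``drift_speed`` degrees/second
    (outward for expansion, inward for contraction).
    """
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    return phase_s + spec.direction_sign * spec.drift_speed * n_frames / spec.frame_rate


def michelson_contrast(
    frame: np.ndarray, spec: StimulusSpec, grid_extent_deg: float | None = None
) -> float:
    """Michelson contrast (max-min)/(max+min) over the visible grating.

    Only pixels with eccentricity between the inner annulus and the
    truncation radius enter (the uniform central disk and off-screen corners
    are excluded).
    """
    n = frame.shape[0]
    extent = 2 * spec.truncation_radius if grid_extent_deg is None else grid_extent_deg
    half = (n - 1) / 2.0
    px = (np.arange(n) - half) / (n - 1) * extent
    x, y = np.meshgrid(px, px)
    d = np.hypot(x, y)
    sel = (d >= spec.annulus_radius) & (d <= spec.truncation_radius)
    vmax, vmin = frame[sel].max(), frame[sel].min()
    return (vmax - vmin) / (vmax + vmin)
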