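"""Render spheroid states into anisotropic 3D fluorescence stacks.

Each labelled nucleus becomes a 3D Gaussian blob whose spatial scale is
the nucleus radius broadened by the point-spread function
(σ_eff = sqrt((r/2)² + psf_sigma²), per axis in µm), evaluated on the
anisotropic voxel grid (default 1×1×2 µm, 121 z-planes).  Optional
exponential intensity attenuation with imaging depth emulates the loss
of signal in the lower hemisphere of thick samples.  Noise is a Poisson
(shot) term on the signal plus additive Gaussian background noise.

Stacks are unsigned 16-bit with axis order (z, y, x); world coordinates
place the spheroid centre at the field centre, with z index 0 the top
slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpheroidState

__all__ = ["RenderParams", "ImagingProtocol", "render"]


@dataclass(frozen=True)
class RenderParams:
    """Imaging geometry and noise model.

    voxel_size: (dz, dy, dx) µm; n_z z-planes; field_px in-plane width
    (square field).  background is the camera offset (intensity units),
    noise_sd the Gaussian read-noise SD; shot_noise toggles the Poisson
    term on the signal.  depth_attenuation (µm) is the 1/e decay length
    of intensity with depth, or None for no attenuation.
    """

    voxel_size: tuple[float, float, float] = (2.0, 1.0, 1.0)
    n_z: int = 121
    field_px: int = 256
    psf_sigma: float = 0.8  # µm
    amplitude: float = 3000.0
    background: float = 100.0
    noise_sd: float = 20.0
    shot_noise: bool = True
    depth_attenuation: float | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.n_z < 1 or self.field_px < 1:
            raise ValueError("stack dimensions must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.depth_attenuation is not None and self.depth_attenuation <= 0:
            raise ValueError("depth_attenuation must be positive or None")

    @property
    def field_um(self) -> float:
        return self.field_px * self.voxel_size[1]

    @property
    def depth_um(self) -> float:
        return self.n_z * self.voxel_size[0]


@dataclass(frozen=True)
class ImagingProtocol:
    """Time-lapse schedule: one stack every ``frame_interval`` minutes
    from t = 0 to ``duration`` hours (inclusive start)."""

    frame_interval: float = 84.0  # min
    duration: float = 48.0  # h
    start_offset: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def frame_times(self) -> np.ndarray:
        """Frame times in hours (t = 0 included, last frame ≤ duration)."""
        n = int(np.floor(self.duration * 60.0 / self.frame_interval)) + 1
        return self.start_offset + np.arange(n) * self.frame_interval / 60.0


def render(
    state: SpheroidState,
    params: RenderParams = RenderParams(),
    rng: np.random.Generator | None = None,
    allow_clip: bool = False,
) -> np.ndarray:
    """Render one state into a (n_z, ny, nx) uint16 stack.

    With ``rng=None`` the render is noise-free (no shot noise, flat
    background).  Raises if the spheroid exceeds the field unless
    ``allow_clip`` is set.
    """
    dz, dy, dx = params.voxel_size
    ny = nx = params.field_px
    nz = params.n_z
    signal = np.zeros((nz, ny, nx), dtype=np.float64)

    if state.n_cells:
        # world coordinates: spheroid centre at field centre
        cx = cy = params.field_um / 2.0
        cz = params.depth_um / 2.0
        pos = state.positions + np.array([cx, cy, cz])
        half_extent = np.abs(state.positions).max(axis=0) + state.radii.max()
        if not allow_clip:
            if (
                half_extent[0] > cx
                or half_extent[1] > cy
                or half_extent[2] > cz
            ):
                raise ValueError(
                    "spheroid exceeds the rendering field; enlarge field_px/n_z "
                    "or pass allow_clip=True"
                )
        zc = (np.arange(nz) + 0.5) * dz
        yc = (np.arange(ny) + 0.5) * dy
        xc = (np.arange(nx) + 0.5) * dx
        for k in range(state.n_cells):
            x, y, z = pos[k]
            r = state.radii[k]
            s = float(np.hypot(r / 2.0, params.psf_sigma))
            amp = params.amplitude
            if params.depth_attenuation is not None:
                amp *= np.exp(-z / params.depth_attenuation)
            cut = 4.0 * s
            iz = np.searchsorted(zc, [z - cut, z + cut])
            iy = np.searchsorted(yc, [y - cut, y + cut])
            ix = np.searchsorted(xc, [x - cut, x + cut])
            if iz[0] >= iz[1] or iy[0] >= iy[1] or ix[0] >= ix[1]:
                continue
            wz = np.exp(-((zc[iz[0] : iz[1]] - z) ** 2) / (2 * s * s))
            wy = np.exp(-((yc[iy[0] : iy[1]] - y) ** 2) / (2 * s * s))
            wx = np.exp(-((xc[ix[0] : ix[1]] - x) ** 2) / (2 * s * s))
            signal[iz[0] : iz[1], iy[0] : iy[1], ix[0] : ix[1]] += (
                amp * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
            )

    if rng is None:
        out = signal + params.background
    else:
        if params.shot_noise:
            # Poisson shot noise on the photon-like signal term
            out = rng.poisson(signal).astype(np.float64)
        else:
            out = signal.copy()
        out += rng.normal(params.background, params.noise_sd, size=signal.shape)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)
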