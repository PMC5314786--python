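"""Acquisition and tracking configuration objects.

Defaults reproduce the stroboscopic single-particle-tracking conditions used
throughout the package: 1-ms excitation pulses inside 5-ms camera frames, a
7-pixel (~0.67 um) field of view per PSF, and a per-axis single-localization
error of 40 nm (sigma = 0.08 um in the sigma = 2s convention, see
:mod:`trnatrack.diffusion`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class ImagingConfig:
    """Camera, illumination and photophysics parameters.

    Parameters
    ----------
    frame_interval : float
        Camera frame time in seconds (default 5 ms).
    strobe_duration : float
        Excitation pulse length in seconds (default 1 ms); must not exceed
        ``frame_interval``.
    pixel_size : float
        Object-plane pixel pitch in um/pixel. The default 0.67/7 um follows
        from the 7 px ~ 0.67 um linking-window equivalence.
    psf_sigma : float
        Gaussian PSF standard deviation in um.
    photons_per_strobe : float
        Expected detected photons per emitter per excitation pulse.
    background_rate : float
        Background photons per pixel per frame.
    em_gain : float
        Camera counts per detected photon.
    read_noise : float
        RMS read noise in camera counts.
    loc_error_axis : float
        Per-axis single-localization error s in um (default 0.04, i.e.
        sigma = 2 s = 0.08 um).
    """

    frame_interval: float = 0.005
    strobe_duration: float = 0.001
    pixel_size: float = 0.67 / 7.0
    psf_sigma: float = 0.13
    photons_per_strobe: float = 90.0
    background_rate: float = 2.0
    em_gain: float = 20.0
    read_noise: float = 15.0
    loc_error_axis: float = 0.04

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        if self.strobe_duration > self.frame_interval:
            raise ConfigError("strobe_duration must not exceed frame_interval")
        for name in ("frame_interval", "strobe_duration", "photons_per_strobe",
                     "background_rate", "em_gain", "read_noise", "loc_error_axis"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        return cls(**d)


@dataclass(frozen=True)
class TrackingConfig:
    """Trajectory-linking parameters.

    ``max_link_distance`` is the displacement window for consecutive-frame
    links (7 px ~ 0.67 um by default, which links >= 98% of steps of a single
    species with apparent D = 4 um^2/s at 5 ms). ``memory_frames`` lets a
    track survive transient disappearance (blinking / missed localization)
    for that many frames. ``gap_window_scale``: displacements bridged across
    a gap of g frames must satisfy ``max_link_distance * gap_window_scale**g``
    (default sqrt(2) per skipped frame, since step variance grows with lag).
    """

    max_link_distance: float = 0.67
    memory_frames: int = 1
    min_steps_for_D: int = 4
    gap_window_scale: float = 2.0 ** 0.5

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ConfigError("max_link_distance must be > 0")
        if self.memory_frames < 0:
            raise ConfigError("memory_frames must be >= 0")
        if self.min_steps_for_D < 1:
            raise ConfigError("min_steps_for_D must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingConfig":
        return cls(**d)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for downstream analysis stages."""

    mobility_threshold: float = 1.0   # um^2/s; below = slow diffusing
    n_steps_for_D: int = 4
    periphery_cutoff: float = 0.5     # on the normalized short axis
    short_cell_bin: tuple = (1.7, 2.9)  # um
    long_cell_bin: tuple = (3.1, 4.3)   # um

    def to_dict(self) -> dict:
        d = asdict(self)
        d["short_cell_bin"] = list(self.short_cell_bin)
        d["long_cell_bin"] = list(self.long_cell_bin)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("short_cell_bin", "long_cell_bin"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# Apparent diffusion coefficient of the assembled ribosome, used as the
# constrained slow species in two-species mixture fits (um^2/s).
RIBOSOME_D_APP = 0.5

# Apparent diffusion coefficient of the ternary complex (aa-tRNA:EF-Tu:GTP),
# used as the intermediate constrained species in three-species fits (um^2/s).
TERNARY_COMPLEX_D_APP = 2.4
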