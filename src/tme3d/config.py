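"""Acquisition geometry and channel optics.

Defaults reflect a Bessel-type light-sheet microscope: an sCMOS camera with
6.5 μm pixels behind an overall ×11.1 magnification gives 0.59 μm
object-space pixels over a 2048×1024 field; planes are stepped at 2 μm; each
optical section covers ~300 μm of depth and the z stage advances 250 μm
between sections, leaving a 16.7% overlap for post-hoc stitching.  The
illumination sheet has a 3.5 μm axial extent (FWHM), and excitation
penetration depth grows with wavelength (~660/780/900 μm at 488/532/637 nm).
"""

from __future__ import annotations

import math

from pydantic import BaseModel, Field, model_validator

#: Excitation wavelength (nm) -> 1/e penetration depth (μm) in cleared tissue.
PENETRATION_DEPTH_UM: dict[int, float] = {488: 660.0, 532: 780.0, 637: 900.0}

#: Light-sheet axial extent (thickness), FWHM, μm.
SHEET_THICKNESS_UM = 3.5

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # ≈ 1/2.355


class ChannelSpec(BaseModel):
    """One fluorescence channel: marker label, excitation and PSF model."""

    name: str
    excitation_nm: float = 488.0
    attenuation_length_um: float | None = None
    psf_sigma_xy_um: float = 1.0
    # Sheet thickness is quoted as FWHM; σ_z defaults to FWHM/2.355.
    psf_sigma_z_um: float = Field(default=SHEET_THICKNESS_UM * _FWHM_TO_SIGMA)

    @model_validator(mode="after")
    def _check(self) -> "ChannelSpec":
        if self.attenuation_length_um is None:
            key = int(round(self.excitation_nm))
            object.__setattr__(
                self, "attenuation_length_um", PENETRATION_DEPTH_UM.get(key, 780.0)
            )
        if self.attenuation_length_um <= 0:
            raise ValueError("attenuation_length_um must be > 0")
        if self.psf_sigma_z_um < self.psf_sigma_xy_um:
            raise ValueError(
                "psf_sigma_z_um must be >= psf_sigma_xy_um "
                "(light-sheet axial resolution is worse than lateral)"
            )
        return self


class AcquisitionConfig(BaseModel):
    """Light-sheet acquisition geometry."""

    lateral_pixel_um: float = 0.59
    plane_step_um: float = 2.0
    tile_shape_px: tuple[int, int] = (2048, 1024)
    section_depth_um: float = 300.0
    z_stage_step_um: float = 250.0
    channels: list[ChannelSpec] = Field(default_factory=list)
    camera_pixel_um: float = 6.5
    magnification: float = 11.1
    bit_depth: int = 16

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionConfig":
        for name in ("lateral_pixel_um", "plane_step_um", "section_depth_um",
                     "z_stage_step_um", "camera_pixel_um", "magnification"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.z_stage_step_um > self.section_depth_um:
            raise ValueError(
                "z_stage_step_um exceeds section_depth_um: z tiling would "
                "leave unimaged gaps"
            )
        return self

    @property
    def overlap_fraction(self) -> float:
        """Fraction of each optical section shared with the next z tile."""
        return (self.section_depth_um - self.z_stage_step_um) / self.section_depth_um

    @property
    def object_pixel_um(self) -> float:
        """Object-space pixel pitch implied by camera pitch and magnification."""
        return self.camera_pixel_um / self.magnification

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        """(dz, dy, dx) of the rendered/acquired grid."""
        return (self.plane_step_um, self.lateral_pixel_um, self.lateral_pixel_um)

    def channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"channel {name!r} not in acquisition config")


def magnification_from_optics(
    objective_mag: float = 10.0,
    tube_lens_mm: float = 200.0,
    reference_tube_lens_mm: float = 180.0,
) -> float:
    """Overall magnification of an objective used with a non-native tube lens.

    A 10× objective designed for a 180 mm reference tube lens, used with a
    200 mm tube lens, yields 10 × 200/180 ≈ ×11.1.
    """
    return objective_mag * tube_lens_mm / reference_tube_lens_mm
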