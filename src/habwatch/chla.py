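"""OC-2 chlorophyll-a retrieval from blue/green surface reflectance.

The OC-2 algorithm is an empirical two-band ocean-color model: chlorophyll-a
(mg/m³) is ten raised to a fourth-order polynomial in the base-10 log of the
blue:green remote-sensing reflectance ratio,

    Chl-a = 10^(a0 + a1·R + a2·R² + a3·R³ + a4·R⁴),
    R = log10(Rrs_blue / Rrs_green),

with the blue band (~482 nm) standing in for Rrs(490) and the green band
(~560 nm) for Rrs(555). Level-2 surface reflectance is fed in directly as
Rrs (a scalar ``rrs_factor`` is exposed for sensitivity studies). Because
the output is a power of ten it is strictly positive, and on R ∈ [−1, 1]
the exponent is strictly decreasing in R: chlorophyll falls as the
blue:green ratio rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import GridTransform
from .scene_io import RadiometricMetadata, RasterField, Scene

__all__ = [
    "Oc2Coefficients",
    "DEFAULT_OC2",
    "dn_to_reflectance",
    "band_ratio_R",
    "oc2_chla",
    "retrieve_chla",
]


@dataclass(frozen=True)
class Oc2Coefficients:
    """Polynomial coefficients of the OC-2 base-10 exponent."""

    a0: float = 0.2511
    a1: float = -2.0853
    a2: float = 1.5035
    a3: float = -3.1747
    a4: float = 0.3383

    def exponent(self, r):
        """Evaluate the polynomial exponent at log-ratio ``r`` (Horner)."""
        r = np.asarray(r, dtype=np.float64)
        return self.a0 + r * (self.a1 + r * (self.a2 + r * (self.a3 + r * self.a4)))

    def exponent_derivative(self, r):
        r = np.asarray(r, dtype=np.float64)
        return self.a1 + r * (2 * self.a2 + r * (3 * self.a3 + r * 4 * self.a4))


DEFAULT_OC2 = Oc2Coefficients()


def dn_to_reflectance(
    band: np.ndarray,
    meta: RadiometricMetadata,
    *,
    mask: np.ndarray | None = None,
    role: str = "reflectance",
    transform: GridTransform | None = None,
    crs_id: str = "",
) -> RasterField:
    """Rescale quantized surface-reflectance counts to reflectance.

    value = dn × refl_scale + refl_offset. Pixels whose reflectance comes
    out ≤ 0 are marked invalid rather than clipped — the log-ratio is
    undefined there and clipping would fabricate blooms.
    """
    band = np.asarray(band)
    values = band.astype(np.float64) * meta.refl_scale + meta.refl_offset
    valid = values > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    return RasterField(
        values=values, mask=valid, role=role,
        transform=transform or GridTransform.identity(), crs_id=crs_id,
    )


def band_ratio_R(rrs_blue: RasterField, rrs_green: RasterField) -> RasterField:
    """Base-10 log of the blue:green reflectance ratio, per pixel."""
    if rrs_blue.shape != rrs_green.shape:
        raise ValueError(
            f"grid mismatch: {rrs_blue.shape} vs {rrs_green.shape}"
        )
    valid = rrs_blue.mask & rrs_green.mask
    valid &= (rrs_blue.values > 0) & (rrs_green.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, rrs_blue.values / np.where(valid, rrs_green.values, 1.0), 1.0)
        values = np.log10(ratio)
    return RasterField(
        values=values, mask=valid, role="log-ratio",
        transform=rrs_blue.transform, crs_id=rrs_blue.crs_id,
    )


def oc2_chla(R: RasterField, coef: Oc2Coefficients = DEFAULT_OC2) -> RasterField:
    """Chlorophyll-a (mg/m³) from the log band ratio via the OC-2 polynomial."""
    values = np.power(10.0, coef.exponent(R.values))
    return RasterField(
        values=values, mask=R.mask.copy(), role="chla",
        transform=R.transform, crs_id=R.crs_id,
    )


def retrieve_chla(
    scene: Scene,
    coef: Oc2Coefficients = DEFAULT_OC2,
    rrs_factor: float = 1.0,
) -> RasterField:
    """Full per-pixel Chl-a retrieval from a scene's blue and green bands.

    Composition of DN→reflectance, band ratio, and the OC-2 polynomial; the
    output mask is the conjunction of all stage masks. ``rrs_factor``
    rescales reflectance to Rrs before the ratio (default 1: surface
    reflectance used as-is); being a common factor it cancels in the ratio
    unless band-specific handling is added upstream.
    """
    blue = dn_to_reflectance(
        scene.band("blue"), scene.meta, mask=scene.band_mask("blue"),
        transform=scene.transform, crs_id=scene.crs_id,
    )
    green = dn_to_reflectance(
        scene.band("green"), scene.meta, mask=scene.band_mask("green"),
        transform=scene.transform, crs_id=scene.crs_id,
    )
    if rrs_factor != 1.0:
        blue.values *= rrs_factor
        green.values *= rrs_factor
    return oc2_chla(band_ratio_R(blue, green), coef)
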