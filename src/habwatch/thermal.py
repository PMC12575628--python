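"""Mono-window lake-surface-air-temperature retrieval from band 10.

The chain converts quantized thermal counts to at-sensor radiance
(Lλ = ML·QCal + A_L), radiance to brightness temperature through the
Planck-form inversion (Tb = K2 / ln(K1/Lλ + 1) − 273.15, in °C), estimates
surface emissivity from NDVI through the proportional-vegetation fraction
(Pv = ((NDVI − NDVImin)/(NDVImax − NDVImin))², ε = 0.004·Pv + 0.986), and
applies the single-channel correction

    LSAT = Tb10 / (1 + (λ·Tb10/ρ)·ln ε)

with λ the band-10 effective wavelength and ρ = h·c/σ ≈ 1.4388×10⁻² m·K.

Two temperature-unit modes are provided for the correction term. The
default ``"celsius"`` mode feeds Tb10 in °C straight into the correction,
reproducing workflows that convert to Celsius before the mono-window step;
``"kelvin"`` applies the correction on the Kelvin scale (the physically
conventional form) and converts back. The numerical difference is small for
ε near 1 but is surfaced, not hidden: pick a mode explicitly when comparing
against external products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .chla import dn_to_reflectance
from .geo import GridTransform
from .scene_io import RadiometricMetadata, RasterField, Scene

__all__ = [
    "NdviStats",
    "dn_to_radiance",
    "radiance_to_bt",
    "bt_to_radiance",
    "ndvi",
    "proportional_vegetation",
    "emissivity",
    "mono_window_lsat",
    "invert_mono_window",
    "retrieve_lsat",
]

logger = logging.getLogger(__name__)

TempMode = Literal["celsius", "kelvin"]

_ZERO_C = 273.15


@dataclass(frozen=True)
class NdviStats:
    """NDVI extremes anchoring the proportional-vegetation rescaling.

    ``source`` records whether the extremes were computed from the scene's
    own valid pixels (``"per-scene"``) or supplied as fixed values for
    cross-scene reproducibility (``"fixed"``).
    """

    ndvi_min: float
    ndvi_max: float
    source: str = "fixed"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ndvi_min <= self.ndvi_max <= 1.0):
            raise ValueError(
                f"need -1 <= ndvi_min <= ndvi_max <= 1, got "
                f"({self.ndvi_min}, {self.ndvi_max})"
            )


def dn_to_radiance(
    tir10: np.ndarray,
    meta: RadiometricMetadata,
    *,
    mask: np.ndarray | None = None,
    transform: GridTransform | None = None,
    crs_id: str = "",
) -> RasterField:
    """At-sensor spectral radiance from quantized band-10 counts.

    value = ml × QCal + al, in W·m⁻²·sr⁻¹·µm⁻¹.
    """
    tir10 = np.asarray(tir10)
    values = tir10.astype(np.float64) * meta.ml + meta.al
    valid = np.ones(values.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    return RasterField(
        values=values, mask=valid, role="radiance",
        transform=transform or GridTransform.identity(), crs_id=crs_id,
    )


def radiance_to_bt(radiance: RasterField, meta: RadiometricMetadata) -> RasterField:
    """Brightness temperature (°C) via the Planck-form inversion.

    value = K2 / ln(K1/Lλ + 1) − 273.15; non-positive radiance is masked.
    """
    valid = radiance.mask & (radiance.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe = np.where(valid, radiance.values, 1.0)
        values = meta.k2 / np.log(meta.k1 / safe + 1.0) - _ZERO_C
    return RasterField(
        values=np.where(valid, values, 0.0), mask=valid, role="bt",
        transform=radiance.transform, crs_id=radiance.crs_id,
    )


def bt_to_radiance(bt_celsius, meta: RadiometricMetadata):
    """Closed-form inverse of :func:`radiance_to_bt` (scalar or array, °C in)."""
    t_kelvin = np.asarray(bt_celsius, dtype=np.float64) + _ZERO_C
    return meta.k1 / (np.exp(meta.k2 / t_kelvin) - 1.0)


def ndvi(red: RasterField, nir: RasterField) -> RasterField:
    """Normalized difference vegetation index (NIR − RED)/(NIR + RED)."""
    if red.shape != nir.shape:
        raise ValueError(f"grid mismatch: {red.shape} vs {nir.shape}")
    total = nir.values + red.values
    valid = red.mask & nir.mask & (total != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(valid, (nir.values - red.values) / np.where(valid, total, 1.0), 0.0)
    return RasterField(
        values=values, mask=valid, role="ndvi",
        transform=red.transform, crs_id=red.crs_id,
    )


def proportional_vegetation(ndvi_field: RasterField, stats: NdviStats) -> RasterField:
    """Squared, rescaled NDVI: the fraction of the pixel emitting as vegetation.

    Clamped to [0, 1] so fixed stats tighter than the scene's NDVI range
    cannot push Pv out of bounds; a degenerate range (max = min) yields
    Pv = 0 everywhere.
    """
    span = stats.ndvi_max - stats.ndvi_min
    if span == 0:
        values = np.zeros(ndvi_field.shape)
    else:
        scaled = (ndvi_field.values - stats.ndvi_min) / span
        values = np.clip(scaled, 0.0, 1.0) ** 2
    return RasterField(
        values=values, mask=ndvi_field.mask.copy(), role="pv",
        transform=ndvi_field.transform, crs_id=ndvi_field.crs_id,
    )


def emissivity(pv: RasterField) -> RasterField:
    """Surface emissivity as an affine function of Pv: ε = 0.004·Pv + 0.986."""
    values = 0.004 * pv.values + 0.986
    return RasterField(
        values=values, mask=pv.mask.copy(), role="emissivity",
        transform=pv.transform, crs_id=pv.crs_id,
    )


def _correction_denominator(t, eps_values, meta: RadiometricMetadata):
    return 1.0 + (meta.lambda10 * t / meta.rho) * np.log(eps_values)


def mono_window_lsat(
    bt: RasterField,
    eps: RasterField,
    meta: RadiometricMetadata,
    temp_mode: TempMode = "celsius",
) -> RasterField:
    """Single-channel LSAT (°C) from brightness temperature and emissivity.

    ε = 1 gives LSAT = Tb10 exactly. Pixels where the correction
    denominator is non-positive are masked invalid and counted in a
    diagnostics log entry.
    """
    if bt.shape != eps.shape:
        raise ValueError(f"grid mismatch: {bt.shape} vs {eps.shape}")
    valid = bt.mask & eps.mask & (eps.values > 0) & (eps.values <= 1)
    if temp_mode == "celsius":
        t = bt.values
        denom = _correction_denominator(t, np.where(valid, eps.values, 1.0), meta)
        values = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0), 0.0)
    elif temp_mode == "kelvin":
        t = bt.values + _ZERO_C
        denom = _correction_denominator(t, np.where(valid, eps.values, 1.0), meta)
        values = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0) - _ZERO_C, 0.0)
    else:
        raise ValueError(f"unknown temp_mode {temp_mode!r}")
    bad = valid & (denom <= 0)
    if bad.any():
        logger.warning("mono_window_lsat: %d pixels with non-positive denominator masked", int(bad.sum()))
    return RasterField(
        values=values, mask=valid & (denom > 0), role="lsat",
        transform=bt.transform, crs_id=bt.crs_id,
    )


def invert_mono_window(
    lsat_celsius,
    eps_values,
    meta: RadiometricMetadata,
    temp_mode: TempMode = "celsius",
):
    """Brightness temperature (°C) that the mono-window step maps to ``lsat``.

    Closed form: Tb = LSAT / (1 − LSAT·(λ/ρ)·ln ε) on the working scale.
    """
    ln_eps = np.log(np.asarray(eps_values, dtype=np.float64))
    c = meta.lambda10 / meta.rho
    if temp_mode == "celsius":
        t = np.asarray(lsat_celsius, dtype=np.float64)
        return t / (1.0 - t * c * ln_eps)
    t = np.asarray(lsat_celsius, dtype=np.float64) + _ZERO_C
    return t / (1.0 - t * c * ln_eps) - _ZERO_C


def retrieve_lsat(
    scene: Scene,
    stats: NdviStats | Literal["auto"] = "auto",
    temp_mode: TempMode = "celsius",
) -> RasterField:
    """Full mono-window LSAT retrieval from red, nir and tir10 bands.

    ``stats="auto"`` derives NDVImin/NDVImax from the scene's own valid
    pixels (after any AOI mask); pass fixed :class:`NdviStats` for
    reproducibility across scenes.
    """
    radiance = dn_to_radiance(
        scene.band("tir10"), scene.meta, mask=scene.band_mask("tir10"),
        transform=scene.transform, crs_id=scene.crs_id,
    )
    bt = radiance_to_bt(radiance, scene.meta)

    red = dn_to_reflectance(
        scene.band("red"), scene.meta, mask=scene.band_mask("red"),
        role="red-reflectance", transform=scene.transform, crs_id=scene.crs_id,
    )
    nir = dn_to_reflectance(
        scene.band("nir"), scene.meta, mask=scene.band_mask("nir"),
        role="nir-reflectance", transform=scene.transform, crs_id=scene.crs_id,
    )
    ndvi_field = ndvi(red, nir)
    if stats == "auto":
        if not ndvi_field.mask.any():
            raise ValueError("all NDVI pixels invalid; cannot auto-derive NDVI stats")
        valid = ndvi_field.valid_values()
        stats = NdviStats(float(valid.min()), float(valid.max()), source="per-scene")
    pv = proportional_vegetation(ndvi_field, stats)
    eps = emissivity(pv)
    return mono_window_lsat(bt, eps, scene.meta, temp_mode=temp_mode)
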