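"""Paired-raster accuracy assessment.

Mirrors the standard satellite-product validation recipe: co-register the
reference product onto the estimate grid (nearest neighbour — reference
products are typically coarser, e.g. 300 m or 1 km against 30 m), draw a
seeded random sample of 500–1000 jointly valid pixels, and report R²,
RMSE, MSE and MAE together with the fitted regression line. Raw values are
compared, never normalized.

R² is reported as the squared Pearson correlation of the paired sample —
the quantity that accompanies a fitted regression line on a scatter plot.
The one-to-one-line variant (1 − SSres/SStot against the identity) is also
computed and carried as ``r2_identity`` for users who need agreement rather
than association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .scene_io import RasterField

__all__ = ["PairedSample", "ValidationReport", "coregister", "sample_pairs", "compute_metrics"]

logger = logging.getLogger(__name__)


@dataclass
class PairedSample:
    """Co-located estimate/reference values drawn from a raster pair."""

    estimates: np.ndarray
    references: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=np.float64)
        self.references = np.asarray(self.references, dtype=np.float64)
        if self.estimates.shape != self.references.shape:
            raise ValueError("estimate and reference lengths differ")
        if self.n != len(self.estimates):
            raise ValueError("n does not match sample length")
        if self.n < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.isfinite(self.estimates).all() and np.isfinite(self.references).all()):
            raise ValueError("sample contains non-finite values")


@dataclass
class ValidationReport:
    """Accuracy metrics for a paired sample; units follow the compared role."""

    r2: float
    rmse: float
    mse: float
    mae: float
    slope: float
    intercept: float
    n: int
    r2_identity: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "mse": self.mse, "mae": self.mae,
            "slope": self.slope, "intercept": self.intercept, "n": self.n,
            "r2_identity": self.r2_identity,
        }


def coregister(reference: RasterField, target: RasterField) -> RasterField:
    """Resample ``reference`` onto the ``target`` grid by nearest neighbour.

    Each target pixel center is located in the reference grid; the nearest
    reference pixel supplies the value. The result is invalid wherever the
    target pixel falls outside the reference footprint or either source
    pixel is invalid. Raises on empty overlap.
    """
    rows, cols = target.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = target.transform.xy(rr, cc)
    fr, fc = reference.transform.rowcol(x, y)
    ri = np.floor(fr).astype(int)
    ci = np.floor(fc).astype(int)
    inside = (ri >= 0) & (ci >= 0) & (ri < reference.shape[0]) & (ci < reference.shape[1])
    if not inside.any():
        raise ValueError("reference and target footprints do not overlap")
    ri_safe = np.clip(ri, 0, reference.shape[0] - 1)
    ci_safe = np.clip(ci, 0, reference.shape[1] - 1)
    values = reference.values[ri_safe, ci_safe]
    mask = inside & reference.mask[ri_safe, ci_safe] & target.mask
    return RasterField(
        values=np.where(mask, values, 0.0), mask=mask, role=reference.role,
        transform=target.transform, crs_id=target.crs_id,
    )


def sample_pairs(a: RasterField, b: RasterField, n: int, seed: int) -> PairedSample:
    """Draw ``n`` jointly valid pixels uniformly without replacement.

    ``n`` is clipped to the number of jointly valid pixels (clipping is
    logged); the draw is deterministic for a given seed.
    """
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    joint = a.mask & b.mask
    available = int(joint.sum())
    if available < 2:
        raise ValueError(f"only {available} jointly valid pixels; need at least 2")
    if n > available:
        logger.warning("requested %d samples but only %d jointly valid pixels; clipping", n, available)
        n = available
    flat = np.flatnonzero(joint)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    return PairedSample(
        estimates=a.values.ravel()[chosen],
        references=b.values.ravel()[chosen],
        n=n, seed=seed,
    )


def compute_metrics(sample: PairedSample) -> ValidationReport:
    """Error metrics and regression fit for a paired sample.

    MSE is the mean squared difference, RMSE its square root, MAE the mean
    absolute difference. R² is the squared Pearson correlation; the slope
    and intercept come from the ordinary least-squares fit of estimates on
    references. A zero-variance reference leaves R²/slope/intercept
    undefined (NaN) while the error metrics stay finite.
    """
    est, ref = sample.estimates, sample.references
    diff = est - ref
    mse = float(np.mean(diff**2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(diff)))
    if np.var(ref) == 0:
        return ValidationReport(
            r2=float("nan"), rmse=rmse, mse=mse, mae=mae,
            slope=float("nan"), intercept=float("nan"), n=sample.n,
        )
    fit = _sps.linregress(ref, est)
    r2 = float(fit.rvalue**2)
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2_identity = float(1.0 - np.sum(diff**2) / ss_tot)
    return ValidationReport(
        r2=r2, rmse=rmse, mse=mse, mae=mae,
        slope=float(fit.slope), intercept=float(fit.intercept),
        n=sample.n, r2_identity=r2_identity,
    )


def scatter_plot(sample: PairedSample, report: ValidationReport, path) -> None:
    """Estimate-vs-reference scatter with the fitted regression line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(sample.references, sample.estimates, s=6, alpha=0.5)
    if np.isfinite(report.slope):
        xs = np.linspace(sample.references.min(), sample.references.max(), 2)
        ax.plot(xs, report.slope * xs + report.intercept, "r-",
                label=f"fit: y = {report.slope:.3f}x + {report.intercept:.3f}\nR² = {report.r2:.3f}")
        ax.legend()
    ax.set_xlabel("reference")
    ax.set_ylabel("estimate")
    ax.set_title(f"n = {report.n}, RMSE = {report.rmse:.3f}, MAE = {report.mae:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
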