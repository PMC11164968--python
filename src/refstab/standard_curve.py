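"""Standard-curve fitting and amplification-efficiency estimation.

A qPCR standard curve regresses Ct on log10 template concentration over a
serial dilution.  Under exponential amplification with per-cycle fold factor
1 + E the slope is k = -1 / log10(1 + E), so

    E = 10**(-1/k) - 1

A perfectly doubling reaction (E = 1, i.e. 100%) gives the textbook slope of
-3.32 cycles per decade.  Curves with E outside [0.9, 1.1] or R^2 below 0.98
are accepted but flagged, mirroring common assay-QC practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_model import ValidationError

__all__ = ["StandardCurve", "CurveQualityWarning", "fit_standard_curve",
           "efficiency_from_slope"]

EFFICIENCY_RANGE = (0.9, 1.1)
R2_MIN = 0.98


class CurveQualityWarning(UserWarning):
    """Standard-curve fit falls outside the usual QC range."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10 relative concentration for one gene."""

    gene_id: str
    slope: float          # cycles per log10 concentration unit; negative
    intercept: float      # cycles at the top (log10 conc = 0) point
    r2: float
    efficiency: float     # fraction; 1.0 = 100%

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10**(-1/k) - 1 from a curve slope k.

    Only negative slopes are meaningful (more template -> earlier Ct).
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValidationError(
            f"slope must be negative for a valid standard curve, got {slope}"
        )
    return float(10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    gene_id: str = "",
    warn: bool = True,
) -> StandardCurve:
    """Fit a standard curve from (log10 relative concentration, Ct) points.

    Ordinary least squares of Ct on log10 concentration; needs at least 3
    points over at least 2 distinct concentrations.  A non-negative fitted
    slope is an error (efficiency undefined).  QC warnings fire when the
    derived efficiency leaves [0.9, 1.1] or R^2 drops below 0.98.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be (log10_conc, ct) pairs")
    if pts.shape[0] < 3:
        raise ValidationError(f"need >= 3 dilution points, got {pts.shape[0]}")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValidationError("all concentrations identical; cannot fit a slope")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope >= 0:
        raise ValidationError(
            f"fitted slope {slope:.4g} is non-negative; efficiency undefined "
            f"(gene {gene_id!r})"
        )
    ss_res = float(np.sum((y - (fit.intercept + slope * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    eff = efficiency_from_slope(slope)
    if warn:
        lo, hi = EFFICIENCY_RANGE
        if not (lo <= eff <= hi):
            warnings.warn(
                f"gene {gene_id!r}: efficiency {eff * 100:.1f}% outside "
                f"[{lo * 100:.0f}%, {hi * 100:.0f}%]",
                CurveQualityWarning, stacklevel=2,
            )
        if r2 < R2_MIN:
            warnings.warn(
                f"gene {gene_id!r}: R^2 = {r2:.4f} below {R2_MIN}",
                CurveQualityWarning, stacklevel=2,
            )
    return StandardCurve(
        gene_id=gene_id, slope=slope, intercept=float(fit.intercept),
        r2=r2, efficiency=eff,
    )
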