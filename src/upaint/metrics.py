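"""Reconstruction-quality metrics: RMSE, piecewise PSNR, global SSIM.

The evaluation protocol maps intensities to [0, 255] and compares a
reconstruction (OP) against its ground truth (GT):

    RMSE = sqrt(mean((GT - OP)^2))
    PSNR = 100                 if RMSE = 0
         = 20 * log10(255/RMSE)  otherwise  (capped at 100)
    SSIM = [2*mu_GT*mu_OP + c1] * [2*cov(GT,OP) + c2]
           / ([mu_GT^2 + mu_OP^2 + c1] * [sd_GT^2 + sd_OP^2 + c2])

SSIM here is global (whole-image moments, no sliding window), with the
standard small stabilizing constants c1 = (0.01*255)^2, c2 = (0.03*255)^2.
The doubled covariance term makes SSIM exactly 1 for identical images; a
``numerator="printed"`` mode with the bare [cov + c2] term is retained for
comparison with sources that state the formula that way.  SSIM is bounded
above by 1 but can go negative for anti-correlated images.

Model-level comparison uses the two-independent-sample t-test on per-image
metric values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ContractError

__all__ = [
    "DEFAULT_C1",
    "DEFAULT_C2",
    "MetricsReport",
    "GroupComparison",
    "map_to_255",
    "rmse",
    "psnr",
    "ssim",
    "evaluate_pair",
    "summarize_reports",
    "compare_groups",
]

DEFAULT_C1 = (0.01 * 255.0) ** 2
DEFAULT_C2 = (0.03 * 255.0) ** 2


@dataclass(frozen=True)
class MetricsReport:
    """Metric triplet for one (output, ground-truth) pair, with the
    constants it was computed under."""

    rmse: float
    psnr: float
    ssim: float
    c1: float
    c2: float
    n_pixels: int


@dataclass(frozen=True)
class GroupComparison:
    """Two-independent-sample t-test between per-image metric values."""

    group_a: tuple
    group_b: tuple
    statistic: float
    p_value: float


def map_to_255(image: np.ndarray, declared_range: tuple[float, float] | None = None
               ) -> np.ndarray:
    """Affine map of the declared intensity range onto [0, 255].

    [0, 1]-normalized tiles simply scale by 255.  Without a declared range
    the image's own (min, max) is used, which is ambiguous for a constant
    image — that case raises.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ContractError("image contains non-finite intensities")
    if declared_range is None:
        lo, hi = float(img.min()), float(img.max())
        if hi == lo:
            raise ContractError(
                "constant image with undeclared range: the [0,255] map is ambiguous"
            )
    else:
        lo, hi = map(float, declared_range)
        if hi <= lo:
            raise ContractError("declared_range must have max > min")
    return (img - lo) * (255.0 / (hi - lo))


def _check_pair(gt, op):
    gt = np.asarray(gt, dtype=np.float64)
    op = np.asarray(op, dtype=np.float64)
    if gt.shape != op.shape:
        raise ContractError(f"shape mismatch: {gt.shape} vs {op.shape}")
    return gt, op


def rmse(gt: np.ndarray, op: np.ndarray) -> float:
    """Root of the mean squared pixel difference, on the [0, 255] scale."""
    gt, op = _check_pair(gt, op)
    return float(np.sqrt(np.mean((gt - op) ** 2)))


def psnr(gt: np.ndarray, op: np.ndarray) -> float:
    """Piecewise peak signal-to-noise ratio: 100 for an exact match,
    20*log10(255/RMSE) otherwise."""
    r = rmse(gt, op)
    if r == 0.0:
        return 100.0
    return float(20.0 * np.log10(255.0 / r))


def ssim(gt: np.ndarray, op: np.ndarray, c1: float = DEFAULT_C1,
         c2: float = DEFAULT_C2, numerator: str = "doubled",
         sample_moments: bool = False) -> float:
    """Global structural similarity on the [0, 255] scale.

    Population moments by default (``sample_moments=True`` switches to the
    n-1 convention for variance/covariance).  ``numerator="doubled"`` uses
    the standard 2*cov term so identical images score exactly 1;
    ``"printed"`` uses the bare cov term.
    """
    gt, op = _check_pair(gt, op)
    if c1 <= 0 or c2 <= 0:
        raise ContractError("c1 and c2 must be positive")
    if numerator not in ("doubled", "printed"):
        raise ContractError(f"unknown numerator mode {numerator!r}")
    ddof = 1 if sample_moments else 0
    mu_g, mu_o = gt.mean(), op.mean()
    var_g = gt.var(ddof=ddof)
    var_o = op.var(ddof=ddof)
    n = gt.size
    cov = float(((gt - mu_g) * (op - mu_o)).sum() / (n - ddof))
    cov_term = 2.0 * cov if numerator == "doubled" else cov
    num = (2.0 * mu_g * mu_o + c1) * (cov_term + c2)
    den = (mu_g ** 2 + mu_o ** 2 + c1) * (var_g + var_o + c2)
    return float(num / den)


def evaluate_pair(gt: np.ndarray, op: np.ndarray, c1: float = DEFAULT_C1,
                  c2: float = DEFAULT_C2,
                  declared_range: tuple[float, float] | None = (0.0, 1.0)
                  ) -> MetricsReport:
    """Map both images to [0, 255] and compute all three metrics.

    ``declared_range`` defaults to (0, 1), the scale of normalized training
    tiles; pass None to use each image's own range, or another range for
    images already on a different scale.
    """
    gt255 = map_to_255(gt, declared_range) if declared_range != (0.0, 255.0) else np.asarray(gt, float)
    op255 = map_to_255(op, declared_range) if declared_range != (0.0, 255.0) else np.asarray(op, float)
    gt255, op255 = _check_pair(gt255, op255)
    return MetricsReport(
        rmse=rmse(gt255, op255),
        psnr=psnr(gt255, op255),
        ssim=ssim(gt255, op255, c1, c2),
        c1=c1,
        c2=c2,
        n_pixels=int(gt255.size),
    )


def summarize_reports(reports) -> dict:
    """Mean and standard deviation per metric over a batch of reports."""
    out = {}
    for name in ("rmse", "psnr", "ssim"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                     if len(vals) > 1 else 0.0, "n": len(vals)}
    return out


def compare_groups(a, b) -> GroupComparison:
    """Two-independent-sample t-test (two-sided) between metric groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant and equal: no evidence of difference
        stat, p = 0.0, 1.0
    else:
        stat = float(res.statistic)
    return GroupComparison(tuple(a), tuple(b), stat, p)
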