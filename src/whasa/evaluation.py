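"""Agreement statistics between automated and reference segmentations:
Similarity Index (Dice), two-way mixed single-measures ICC, ordinary
least-squares volume regression, and Bland-Altman analysis with optional
magnitude-dependent bias and limits of agreement.

Bland-Altman: with D = Seg - Ref and A = (Seg + Ref) / 2, the constant
model reports bias = mean(D) and limits mean(D) +/- 1.96 SD(D).  When the
regression of D on A is significant (p <= 0.05) the bias becomes the fitted
line D^(A); if additionally |residuals| regress significantly on A, the
limits become D^(A) +/- 1.96 sqrt(pi/2) R^(A) (the absolute-residual method
for magnitude-dependent spread), else D^(A) +/- 1.96 SD(residuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask, GridMismatchError

__all__ = [
    "similarity_index",
    "icc_two_way_mixed_single",
    "bland_altman",
    "BlandAltmanResult",
    "AgreementReport",
    "evaluate_suite",
]


def similarity_index(seg: BinaryMask, ref: BinaryMask) -> float:
    """Dice similarity index 2|seg & ref| / (|seg| + |ref|).

    Two empty masks are perfectly similar by convention (SI = 1)."""
    if seg.shape != ref.shape:
        raise GridMismatchError(
            f"masks on different grids: {seg.shape} vs {ref.shape}")
    ns, nr = seg.count(), ref.count()
    if ns == 0 and nr == 0:
        warnings.warn("both masks empty: SI defined as 1.0", stacklevel=2)
        return 1.0
    inter = int((seg.data & ref.data).sum())
    return 2.0 * inter / (ns + nr)


def icc_two_way_mixed_single(x, y, kind: str = "consistency") -> float:
    """Two-way mixed single-measures intraclass correlation between two
    raters.

    ``kind="consistency"`` gives ICC(3,1) = (MSR - MSE)/(MSR + (k-1) MSE);
    ``kind="absolute"`` additionally penalises systematic offsets between
    raters.  Computed from the two-way ANOVA decomposition with k = 2.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("ICC requires at least 3 paired measurements")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite measurements")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_subjects = k * ((subj_means - grand) ** 2).sum()
    ss_raters = n * ((rater_means - grand) ** 2).sum()
    ss_error = ss_total - ss_subjects - ss_raters
    msr = ss_subjects / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    denom_c = msr + (k - 1) * mse
    if denom_c <= 0 or np.isclose(msr, 0):
        warnings.warn("zero between-subject variance: ICC reported as 0",
                      stacklevel=2)
        return 0.0
    if kind == "consistency":
        return float((msr - mse) / denom_c)
    if kind == "absolute":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        return float((msr - mse) / denom)
    raise ValueError(f"unknown ICC kind {kind!r}")


@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement between two paired measurement series.

    ``bias``/``loa_low``/``loa_high`` are the uniform-variability estimates
    (always reported).  ``mode`` records which model the significance tests
    selected; for magnitude-dependent modes the line coefficients are given
    as (intercept, slope) pairs in ``bias_line`` and ``spread_line``.
    """

    n: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    mode: str  # "constant" | "bias-varies" | "bias-and-spread-vary"
    d_on_a_pvalue: float = None
    bias_line: tuple = None
    spread_line: tuple = None
    resid_on_a_pvalue: float = None
    sd_resid: float = None

    def limits_at(self, a):
        """Evaluate the (possibly magnitude-dependent) 95% limits at mean
        values ``a``."""
        a = np.asarray(a, dtype=np.float64)
        if self.mode == "constant":
            return (np.full_like(a, self.loa_low),
                    np.full_like(a, self.loa_high))
        b0, b1 = self.bias_line
        center = b0 + b1 * a
        if self.mode == "bias-and-spread-vary":
            c0, c1 = self.spread_line
            half = 1.96 * np.sqrt(np.pi / 2.0) * (c0 + c1 * a)
        else:
            half = 1.96 * self.sd_resid
        return center - half, center + half


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman analysis of y (test) against x (reference), D = y - x.

    The relation of D to the average A is tested for significance at
    ``alpha`` (p <= alpha, inclusive); significant trends switch to a fitted
    bias line, and a significant |residual|-on-A regression additionally
    makes the limits magnitude-dependent.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("Bland-Altman analysis requires at least 4 pairs")
    d = y - x
    a = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    res = BlandAltmanResult(
        n=n, bias=bias, sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        mode="constant")
    if np.isclose(sd, 0.0) or np.isclose(a.std(), 0.0):
        # degenerate: all differences equal, or no spread of magnitudes
        return res
    lr = stats.linregress(a, d)
    res.d_on_a_pvalue = float(lr.pvalue)
    if lr.pvalue > alpha:
        return res
    res.mode = "bias-varies"
    res.bias_line = (float(lr.intercept), float(lr.slope))
    resid = d - (lr.intercept + lr.slope * a)
    res.sd_resid = float(np.sqrt((resid ** 2).sum() / (n - 2)))
    absr = np.abs(resid)
    if np.isclose(absr.std(), 0.0):
        return res
    lr2 = stats.linregress(a, absr)
    res.resid_on_a_pvalue = float(lr2.pvalue)
    if lr2.pvalue <= alpha:
        res.mode = "bias-and-spread-vary"
        res.spread_line = (float(lr2.intercept), float(lr2.slope))
    return res


@dataclass
class AgreementReport:
    """Per-case and pooled agreement between segmentations and references."""

    per_case: pd.DataFrame = field(repr=False)
    mean_si: float
    sd_si: float
    icc: float
    slope: float
    intercept: float
    r_squared: float
    bland_altman: BlandAltmanResult

    def to_dict(self) -> dict:
        d = {
            "mean_si": self.mean_si,
            "sd_si": self.sd_si,
            "icc": self.icc,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "per_case": self.per_case.to_dict(orient="records"),
        }
        if self.bland_altman is not None:
            ba = asdict(self.bland_altman)
            d["bland_altman"] = {k: v for k, v in ba.items() if v is not None}
        else:
            d["bland_altman"] = None
        return d


def evaluate_suite(cases) -> AgreementReport:
    """Evaluate a list of (segmentation, reference) mask pairs.

    Per-case SI and volumes (mL); pooled ICC (consistency), OLS regression
    of segmented on reference volumes, and Bland-Altman of the volume
    differences (Seg - Ref).  Requires at least 3 cases; Bland-Altman is
    omitted (None) when fewer than 4 cases are available.
    """
    cases = list(cases)
    if len(cases) < 3:
        raise ValueError("evaluate_suite requires at least 3 cases")
    rows = []
    for i, (seg, ref) in enumerate(cases):
        rows.append({
            "case": i,
            "seg_volume_ml": seg.volume_ml(),
            "ref_volume_ml": ref.volume_ml(),
            "si": similarity_index(seg, ref),
        })
    df = pd.DataFrame(rows)
    segv = df["seg_volume_ml"].to_numpy()
    refv = df["ref_volume_ml"].to_numpy()
    icc = icc_two_way_mixed_single(refv, segv)
    if np.isclose(refv.std(), 0.0):
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        lr = stats.linregress(refv, segv)
        slope, intercept, r2 = float(lr.slope), float(lr.intercept), \
            float(lr.rvalue ** 2)
    ba = bland_altman(refv, segv) if len(cases) >= 4 else None
    return AgreementReport(
        per_case=df,
        mean_si=float(df["si"].mean()),
        sd_si=float(df["si"].std(ddof=1)),
        icc=icc,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        bland_altman=ba,
    )
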