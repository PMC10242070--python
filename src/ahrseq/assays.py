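"""Wet-lab quantification statistics: qPCR relative expression and ELISA
four-parameter-logistic calibration.

Quantitative PCR expression is normalized to two housekeeping genes by the
delta-delta-Cq method with amplification efficiency fixed at 2, and treated
vs vehicle-control groups are compared with a two-sided unpaired Student
t-test on the log2 relative values (Welch optional).  ELISA optical
densities are blank-subtracted and calibrated with the 4PL curve
y = d + (a - d) / (1 + (x / c)^b) fitted by damped (Levenberg-Marquardt)
least squares; sample concentrations come from the algebraic inverse, with
no extrapolation beyond the asymptotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "QpcrMeasurement",
    "ElisaCurve",
    "relative_expression",
    "fit_4pl",
    "four_pl",
    "interpolate_concentration",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR replicate: target and two housekeeper quantification cycles."""

    sample_id: str
    cq_target: float
    cq_hk1: float
    cq_hk2: float

    @property
    def delta_cq(self) -> float:
        """Cq_target minus the arithmetic mean of the housekeeper Cq values
        (equivalently, geometric-mean normalization of expression)."""
        for v in (self.cq_target, self.cq_hk1, self.cq_hk2):
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite Cq in {self.sample_id}")
        return self.cq_target - 0.5 * (self.cq_hk1 + self.cq_hk2)


def relative_expression(
    treated: list[QpcrMeasurement],
    control: list[QpcrMeasurement],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Housekeeper-normalized expression ratio of treated over control with a
    two-sided unpaired t-test.

    Per replicate the relative value is 2^(-delta Cq); the ratio is the mean
    of treated relative values over the mean of control ones, and the test
    is run on the log2 relative values (i.e. on -delta Cq), Student by
    default, Welch with ``equal_var=False``.
    """
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("both groups need >= 2 replicates for the t-test")
    rel_t = np.array([2.0 ** -m.delta_cq for m in treated])
    rel_c = np.array([2.0 ** -m.delta_cq for m in control])
    ratio = float(rel_t.mean() / rel_c.mean())
    t_res = stats.ttest_ind(np.log2(rel_t), np.log2(rel_c), equal_var=equal_var)
    return ratio, float(t_res.pvalue)


def four_pl(x, a: float, d: float, c: float, b: float):
    """4PL response: y = d + (a - d) / (1 + (x / c)^b); a is the zero-dose
    asymptote, d the infinite-dose asymptote, c the inflection concentration
    and b the slope."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class ElisaCurve:
    a: float
    d: float
    c: float
    b: float
    rss: float

    def predict(self, x):
        return four_pl(x, self.a, self.d, self.c, self.b)


def fit_4pl(
    standards: list[tuple[float, float]],
    blank: float = 0.0,
    max_iter: int = 500,
) -> ElisaCurve:
    """Fit the 4PL calibration curve to (concentration, OD) standards.

    ODs are reduced by the mean blank before fitting.  Initialization:
    a = minimum OD, d = maximum OD, c = the standard concentration nearest
    half-maximal OD, b = 1; refinement by Levenberg-Marquardt least squares.
    A flat dose-response (a ~ d) is flagged with a warning.
    """
    conc = np.array([s[0] for s in standards], dtype=float)
    od = np.array([s[1] for s in standards], dtype=float) - blank
    if len(np.unique(conc)) < 5:
        raise ValueError("4PL calibration needs >= 5 distinct standard concentrations")
    if np.ptp(od) == 0:
        warnings.warn("all ODs identical: no dose response; degenerate flat fit returned")
        return ElisaCurve(float(od[0]), float(od[0]), float(np.median(conc)), 1.0, 0.0)
    a0, d0 = float(od.min()), float(od.max())
    half = (a0 + d0) / 2.0
    c0 = float(conc[np.argmin(np.abs(od - half))])
    if c0 <= 0:
        c0 = float(np.median(conc[conc > 0]))
    x0 = np.array([a0, d0, c0, 1.0])

    def resid(theta):
        return four_pl(conc, *theta) - od

    rss0 = float((resid(x0) ** 2).sum())
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=max_iter * len(x0),
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    rss = float((sol.fun**2).sum())
    if not np.isfinite(sol.x).all() or rss > rss0 + 1e-12:
        raise RuntimeError(f"4PL fit did not improve on the heuristic start (best RSS {rss:.4g})")
    a, d, c, b = (float(v) for v in sol.x)
    if abs(a - d) < 1e-6 * max(1.0, abs(d)):
        warnings.warn("degenerate 4PL fit: asymptotes nearly equal (no dose response)")
    return ElisaCurve(a, d, c, b, rss)


def interpolate_concentration(curve: ElisaCurve, sample_od: float, blank: float = 0.0) -> float:
    """Invert the calibration curve at a blank-subtracted sample OD.

    x = c * ((a - d)/(y - d) - 1)^(1/b).  The OD must lie strictly between
    the fitted asymptotes; saturated or sub-baseline readings raise an
    out-of-range error rather than extrapolating.
    """
    y = sample_od - blank
    lo, hi = sorted((curve.a, curve.d))
    if not lo < y < hi:
        raise ValueError(
            f"OD {y:.4g} outside the open calibration range ({lo:.4g}, {hi:.4g})"
        )
    x = curve.c * ((curve.a - curve.d) / (y - curve.d) - 1.0) ** (1.0 / curve.b)
    return float(x)


def qpcr_from_frame(df: pd.DataFrame, target: str, hk1: str, hk2: str) -> list[QpcrMeasurement]:
    """Build measurements from a long qPCR table with columns sample, gene, cq."""
    wide = df.pivot(index="sample", columns="gene", values="cq")
    out = []
    for sample, row in wide.iterrows():
        out.append(QpcrMeasurement(str(sample), row[target], row[hk1], row[hk2]))
    return out
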