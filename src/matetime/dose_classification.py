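"""Hill dose-response fitting and promoter timing-class assignment.

Pheromone-responsive promoters fall into three kinetic classes relative to the
early reference promoter (pAGA1-like): *early* promoters respond with paired
response-time differences centered at zero and stay on the x = y correlation
diagonal; *late* promoters are delayed by at least 15 min and deviate strongly
from the diagonal; everything in between is *intermediate*.  Late promoters
are also switch-like in dose (Hill coefficient near 3, half-activation around
300 nM pheromone) while early promoters respond gradedly (Hill coefficient
near 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .expression_timing import DelaySet


def hill(c: np.ndarray, base: float, amplitude: float, ec50: float, n: float) -> np.ndarray:
    """Hill dose-response E(c) = base + amplitude * c^n / (ec50^n + c^n)."""
    c = np.asarray(c, dtype=float)
    out = np.full_like(c, base, dtype=float)
    pos = c > 0
    cn = np.power(c[pos], n)
    out[pos] = base + amplitude * cn / (np.power(ec50, n) + cn)
    return out


@dataclass
class DoseResponse:
    """Fitted Hill parameters of mean expression output vs dose."""

    doses: np.ndarray
    mean_output: np.ndarray
    sd_output: np.ndarray | None
    base: float
    amplitude: float
    ec50: float
    hill_n: float
    residual: float  # sum of squared residuals of the best fit
    converged: bool  # False when the response is degenerate/unidentifiable

    def predict(self, c) -> np.ndarray:
        return hill(np.asarray(c, dtype=float), self.base, self.amplitude, self.ec50, self.hill_n)


def hill_fit(
    doses: np.ndarray,
    outputs: np.ndarray,
    sd: np.ndarray | None = None,
    weighted: bool = False,
) -> DoseResponse:
    """Least-squares Hill fit of mean expression output versus dose.

    Multi-start: initial Hill coefficients {0.5, 1, 2, 4} crossed with EC50
    starts at the positive-dose quartiles; the best fit by residual wins.
    A zero-dose control enters as c = 0 (E = base).  ``weighted=True`` uses
    per-dose sd as sigma (off by default: per-dose cell counts are usually
    similar and unweighted fits are more robust to a single tight dose).
    """
    doses = np.asarray(doses, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if doses.shape != outputs.shape:
        raise ValueError("doses and outputs differ in length")
    if not np.all(np.isfinite(outputs)):
        raise ValueError("non-finite outputs")
    pos = np.unique(doses[doses > 0])
    if pos.size < 4:
        raise ValueError("need at least 4 distinct positive doses")

    span = outputs.max() - outputs.min()
    if span == 0:
        warnings.warn("constant outputs: amplitude ~ 0, Hill n unidentifiable")
        return DoseResponse(
            doses=doses, mean_output=outputs, sd_output=sd,
            base=float(outputs[0]), amplitude=0.0, ec50=float(np.median(pos)),
            hill_n=1.0, residual=0.0, converged=False,
        )

    sigma = np.asarray(sd, dtype=float) if (weighted and sd is not None) else None
    lo = [-np.inf, 0.0, pos.min() / 100.0, 0.05]
    hi = [np.inf, np.inf, pos.max() * 100.0, 10.0]
    ec50_starts = np.quantile(pos, [0.25, 0.5, 0.75])
    best = None
    for n0 in (0.5, 1.0, 2.0, 4.0):
        for ec0 in ec50_starts:
            p0 = [float(outputs.min()), float(span), float(ec0), n0]
            try:
                popt, _ = curve_fit(
                    hill, doses, outputs, p0=p0, sigma=sigma,
                    bounds=(lo, hi), maxfev=20000, xtol=1e-14, ftol=1e-14,
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((hill(doses, *popt) - outputs) ** 2))
            if best is None or ssr < best[1]:
                best = (popt, ssr)
    if best is None:
        raise RuntimeError(
            "Hill fit failed to converge from every start; "
            f"doses={doses.tolist()}, outputs={outputs.tolist()}"
        )
    popt, ssr = best
    converged = popt[1] > 0.05 * span  # amplitude collapsed => unidentifiable n
    return DoseResponse(
        doses=doses, mean_output=outputs, sd_output=sd,
        base=float(popt[0]), amplitude=float(popt[1]),
        ec50=float(popt[2]), hill_n=float(popt[3]),
        residual=ssr, converged=bool(converged),
    )


class PromoterClass(str, Enum):
    EARLY = "early"
    INTERMEDIATE = "intermediate"
    LATE = "late"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Numeric cut-offs operationalizing the three kinetic classes.

    Only the 15-min late-delay bound is a fixed, established value; the
    early-delay bound and the significant-offset fractions are package
    defaults needed to turn the qualitative definition into a rule.
    """

    late_delay_min: float = 15.0
    early_delay_min: float = 5.0
    late_significant_fraction: float = 0.5
    early_significant_fraction: float = 0.25
    significance_p: float = 1e-3


@dataclass
class PromoterClassification:
    promoter: str
    klass: PromoterClass | None
    median_delta: float
    sign_test_p: float | None
    fraction_significant_offsets: float | None
    unclassifiable: bool = False
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)


def classify_promoter(
    delay_set: DelaySet,
    offset_series: pd.DataFrame | None,
    promoter: str = "",
    thresholds: ClassificationThresholds | None = None,
    sign_test_p: float | None = None,
    stimulation_time: float = 0.0,
) -> PromoterClassification:
    """Assign early/intermediate/late from paired delays and diagonal offsets.

    * late: median delay >= 15 min AND offsets significant (p < 1e-3) at >= 50%
      of post-stimulus time points;
    * early: |median delay| < 5 min AND offsets significant at < 25% of
      post-stimulus time points;
    * otherwise intermediate.

    ``offset_series`` needs columns time and p (see
    :func:`matetime.covariation.offset_test_series`).  If it is ``None`` the
    rule falls back to delays alone (late iff median >= 15, early iff
    |median| < 5), with the significant fraction reported as ``None``.
    """
    th = thresholds or ClassificationThresholds()
    if delay_set.empty:
        return PromoterClassification(
            promoter=promoter, klass=None, median_delta=math.nan,
            sign_test_p=sign_test_p, fraction_significant_offsets=None,
            unclassifiable=True, thresholds=th,
        )
    med = delay_set.median
    if offset_series is not None:
        post = offset_series[offset_series["time"] > stimulation_time]
        if len(post) == 0:
            raise ValueError("offset series has no post-stimulus time points")
        frac_sig = float((post["p"] < th.significance_p).mean())
        if med >= th.late_delay_min and frac_sig >= th.late_significant_fraction:
            klass = PromoterClass.LATE
        elif abs(med) < th.early_delay_min and frac_sig < th.early_significant_fraction:
            klass = PromoterClass.EARLY
        else:
            klass = PromoterClass.INTERMEDIATE
    else:
        frac_sig = None
        if med >= th.late_delay_min:
            klass = PromoterClass.LATE
        elif abs(med) < th.early_delay_min:
            klass = PromoterClass.EARLY
        else:
            klass = PromoterClass.INTERMEDIATE
    return PromoterClassification(
        promoter=promoter, klass=klass, median_delta=float(med),
        sign_test_p=sign_test_p, fraction_significant_offsets=frac_sig,
        thresholds=th,
    )
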