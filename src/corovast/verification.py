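"""Solution-verification and diagnostic-statistics utilities.

Two unrelated toolboxes a simulation study needs around the solver proper:

* ASME V&V-style solution verification: Richardson extrapolation and the
  Grid Convergence Index (GCI) from three systematically refined grids, and
  the root-sum-square combination of numerical, input and experimental
  uncertainties into a validation uncertainty.
* Agreement of a computed index against an invasive reference: Pearson
  correlation with Fisher-z 95% CI, Bland–Altman bias and limits of
  agreement, and confusion-matrix diagnostics (sensitivity, specificity,
  PPV, NPV, accuracy) at the clinical cut-offs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GridStudy", "ValidationUncertainty", "PairedComparison",
    "DiagnosticResult", "richardson_gci", "validation_uncertainty",
    "diagnostic_performance",
]


@dataclass(frozen=True)
class GridStudy:
    """Result of a three-grid Richardson/GCI convergence study.

    ``U_num = GCI_fine / 1.25`` converts the banded index into a standard
    uncertainty (the safety factor removed); the divisor is configurable
    through :func:`richardson_gci`.
    """

    phi_fine: float
    phi_medium: float
    phi_coarse: float
    r: float
    p: float | None
    phi_ext: float | None
    GCI_fine: float
    U_num: float
    oscillatory: bool = False

    def __post_init__(self) -> None:
        if not self.r > 1:
            raise ValueError("refinement factor must exceed 1")
        if self.GCI_fine < 0:
            raise ValueError("GCI must be non-negative")


@dataclass(frozen=True)
class ValidationUncertainty:
    """RSS combination U_val = sqrt(U_num² + U_inp² + U_exp²)."""

    U_num: float
    U_inp: float
    U_exp: float
    U_val: float = field(init=False)

    def __post_init__(self) -> None:
        for u in (self.U_num, self.U_inp, self.U_exp):
            if u < 0:
                raise ValueError("uncertainty components must be >= 0")
        object.__setattr__(
            self, "U_val",
            math.sqrt(self.U_num ** 2 + self.U_inp ** 2 + self.U_exp ** 2))


def richardson_gci(phi: Sequence[float], r: float,
                   safety: float = 1.25,
                   standard_uncertainty_divisor: float = 1.25) -> GridStudy:
    """Richardson extrapolation and GCI from (fine, medium, coarse) values.

    Apparent order ``p = ln|(φ3−φ2)/(φ2−φ1)| / ln r`` with φ1 the fine
    grid; ``φ_ext = φ1 + (φ1−φ2)/(r^p − 1)``;
    ``GCI_fine = safety·|(φ2−φ1)/φ1| / (r^p − 1)``.

    Oscillatory convergence (sign change between successive differences) is
    flagged and the GCI is computed from absolute differences.  Identical
    successive values give GCI 0 with the order undefined.
    """
    if len(phi) != 3:
        raise ValueError("phi must be (fine, medium, coarse)")
    if not r > 1:
        raise ValueError("refinement factor r must exceed 1")
    f, m, c = (float(x) for x in phi)
    e21 = m - f
    e32 = c - m
    if e21 == 0.0 or e32 == 0.0:
        warnings.warn("zero successive difference; grid-converged, "
                      "order undefined", stacklevel=2)
        return GridStudy(f, m, c, r, None, f if e21 == 0 else None,
                         0.0, 0.0)
    oscillatory = (e21 * e32) < 0
    if oscillatory:
        warnings.warn("oscillatory grid convergence; GCI from absolute "
                      "differences", stacklevel=2)
    p = math.log(abs(e32 / e21)) / math.log(r)
    denom = r ** p - 1.0
    phi_ext = f + (f - m) / denom if not oscillatory else None
    gci = safety * abs(e21 / f) / denom
    return GridStudy(f, m, c, r, p, phi_ext, gci,
                     gci / standard_uncertainty_divisor, oscillatory)


def validation_uncertainty(U_num: float, U_inp: float,
                           U_exp: float) -> float:
    """Validation uncertainty: root-sum-square of the three components."""
    return ValidationUncertainty(U_num, U_inp, U_exp).U_val


@dataclass
class PairedComparison:
    """Per-vessel method values paired with invasive reference FFR.

    A vessel counts as hemodynamically significant (positive) when its
    index is at or below the cut-off — FFR semantics — for method and
    reference alike.  The reference cut-off defaults to the clinical 0.80.
    """

    method: np.ndarray
    reference: np.ndarray
    method_cutoff: float
    reference_cutoff: float = 0.80

    def __post_init__(self) -> None:
        self.method = np.asarray(self.method, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.method.shape != self.reference.shape or self.method.ndim != 1:
            raise ValueError("method and reference must be equal-length 1D")
        if len(self.method) < 3:
            raise ValueError("need at least 3 pairs for a correlation study")
        for arr, label in ((self.method, "method"),
                           (self.reference, "reference")):
            if np.any((arr <= 0) | (arr >= 1.5)):
                raise ValueError(f"{label} values must lie in (0, 1.5)")


@dataclass
class DiagnosticResult:
    """Confusion counts, diagnostic rates (%), correlation and agreement."""

    TP: int
    FP: int
    FN: int
    TN: int
    sensitivity: float | None
    specificity: float | None
    PPV: float | None
    NPV: float | None
    accuracy: float
    pearson_r: float
    r_CI95: tuple[float, float]
    bland_altman_bias: float
    loa: tuple[float, float]

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def summary(self) -> str:
        def pct(x: float | None) -> str:
            return "undefined" if x is None else f"{x:.1f}%"
        lo, hi = self.r_CI95
        return (
            f"n = {self.n} vessels "
            f"(TP {self.TP}, FP {self.FP}, FN {self.FN}, TN {self.TN})\n"
            f"specificity {pct(self.specificity)}, "
            f"sensitivity {pct(self.sensitivity)}, "
            f"PPV {pct(self.PPV)}, NPV {pct(self.NPV)}, "
            f"accuracy {pct(self.accuracy)}\n"
            f"Pearson r = {self.pearson_r:.4f} "
            f"(95% CI {lo:.4f} to {hi:.4f})\n"
            f"Bland–Altman bias = {self.bland_altman_bias:+.4f}, "
            f"limits of agreement {self.loa[0]:+.4f} to {self.loa[1]:+.4f}"
        )


def _rate(num: int, den: int, what: str) -> float | None:
    if den == 0:
        warnings.warn(f"{what} undefined: empty denominator class",
                      stacklevel=3)
        return None
    return 100.0 * num / den


def confusion_rates(TP: int, FP: int, FN: int, TN: int
                    ) -> dict[str, float | None]:
    """Diagnostic rates (%) from confusion counts."""
    if min(TP, FP, FN, TN) < 0:
        raise ValueError("counts must be non-negative")
    n = TP + FP + FN + TN
    if n == 0:
        raise ValueError("empty confusion matrix")
    return {
        "sensitivity": _rate(TP, TP + FN, "sensitivity"),
        "specificity": _rate(TN, TN + FP, "specificity"),
        "PPV": _rate(TP, TP + FP, "PPV"),
        "NPV": _rate(TN, TN + FN, "NPV"),
        "accuracy": 100.0 * (TP + TN) / n,
    }


def _fisher_ci(r: float, n: int, level: float = 0.95
               ) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return (math.tanh(z - zc * se), math.tanh(z + zc * se))


def diagnostic_performance(pc: PairedComparison) -> DiagnosticResult:
    """Full diagnostic comparison of a method against invasive FFR.

    Confusion counts at the two cut-offs, the five diagnostic rates as
    percentages, Pearson r with a Fisher-z 95% CI, and Bland–Altman bias
    with ±1.96·SD limits of agreement.  An all-one-class reference leaves
    the affected rates as None (flagged with a warning) rather than 0.
    """
    m_pos = pc.method <= pc.method_cutoff
    r_pos = pc.reference <= pc.reference_cutoff
    TP = int(np.sum(m_pos & r_pos))
    FP = int(np.sum(m_pos & ~r_pos))
    FN = int(np.sum(~m_pos & r_pos))
    TN = int(np.sum(~m_pos & ~r_pos))
    rates = confusion_rates(TP, FP, FN, TN)

    if np.ptp(pc.method) == 0 or np.ptp(pc.reference) == 0:
        r = float("nan")
        ci = (float("nan"), float("nan"))
        warnings.warn("constant series: correlation undefined", stacklevel=2)
    else:
        r = float(stats.pearsonr(pc.method, pc.reference).statistic)
        ci = _fisher_ci(r, len(pc.method))

    diff = pc.method - pc.reference
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)

    return DiagnosticResult(
        TP=TP, FP=FP, FN=FN, TN=TN,
        sensitivity=rates["sensitivity"], specificity=rates["specificity"],
        PPV=rates["PPV"], NPV=rates["NPV"], accuracy=rates["accuracy"],
        pearson_r=r, r_CI95=ci, bland_altman_bias=bias, loa=loa)
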