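"""Retention-index prediction from the Abraham solvation model and
concordance of predicted vs observed GC×GC elution spaces.

The Abraham linear free-energy relationship (LFER)

    log k = c + e*E + s*S + a*A + b*B + l*L

relates a solute's descriptors (E: excess molar refraction, S: dipolarity/
polarizability, A/B: hydrogen-bond acidity/basicity, L: log gas–hexadecane
partition coefficient) to its retention factor on a stationary phase with
system coefficients (c, e, s, a, b, l). Retention is then expressed on the
Kováts scale by interpolating log k between the bracketing n-alkanes, whose
L descriptors form the calibration ladder (an n-alkane has E=S=A=B=0).

The predicted GC×GC elution space plots the first-dimension index I1 against
the transformed second-dimension parameter u2 = base**(ΔI/100) with
ΔI = I2 − I1 (base 1.6 by default; ΔI is scaled to carbon-number units by
``delta_scale`` before exponentiation). Concordance with the observed
(rt1, rt2) configuration is quantified by Procrustes disparity and
per-dimension Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "AbrahamSolute",
    "PhaseSystem",
    "ElutionPoint",
    "ConcordanceReport",
    "RIComparison",
    "lfer_log_k",
    "kovats_index",
    "predict_elution_point",
    "procrustes_concordance",
    "ri_rmse",
]


@dataclass(frozen=True)
class AbrahamSolute:
    """Abraham solute descriptors; ``provenance`` records whether they are
    experimental or estimated (the two are analysed separately downstream)."""

    E: float
    S: float
    A: float
    B: float
    L: float
    provenance: str = "estimated"

    def __post_init__(self):
        if not np.isfinite(self.L):
            raise ValueError("L descriptor must be finite")
        if self.provenance not in ("experimental", "estimated"):
            raise ValueError(f"provenance must be experimental|estimated, got {self.provenance!r}")


@dataclass
class PhaseSystem:
    """A stationary phase: LFER system coefficients plus the n-alkane
    calibration ladder (carbon number -> L descriptor)."""

    name: str
    c: float
    e: float
    s: float
    a: float
    b: float
    l: float
    alkane_l: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.l <= 0:
            raise ValueError("phase coefficient l must be > 0")
        if self.alkane_l:
            ns = sorted(self.alkane_l)
            if ns != list(range(ns[0], ns[-1] + 1)):
                raise ValueError("alkane calibration carbon numbers must be contiguous")

    def alkane_log_k(self) -> tuple[np.ndarray, np.ndarray]:
        """(carbon numbers, log k) of the calibration alkanes on this phase."""
        ns = np.array(sorted(self.alkane_l))
        logk = self.c + self.l * np.array([self.alkane_l[n] for n in ns])
        return ns, logk


@dataclass
class ElutionPoint:
    """Predicted GC×GC coordinates: (I1, u2) with u2 = base**(ΔI/delta_scale)."""

    I1: float
    I2: float
    u2: float
    base: float = 1.6

    def __post_init__(self):
        if not 1.0 <= self.base <= 2.0:
            raise ValueError("base must lie in [1, 2]")
        if self.u2 <= 0:
            raise ValueError("u2 must be positive")


@dataclass
class ConcordanceReport:
    """Procrustes disparity and per-dimension correlations between a
    predicted and an observed two-dimensional configuration."""

    procrustes_disparity: float
    r1: float
    r2: float
    n: int


@dataclass
class RIComparison:
    """Calculated vs reference retention index for one compound;
    ``dI = calculated - reference``."""

    compound: str
    calculated: float
    reference: float

    @property
    def dI(self) -> float:
        return self.calculated - self.reference


def lfer_log_k(solute: AbrahamSolute, phase: PhaseSystem) -> float:
    """Abraham LFER retention factor: c + eE + sS + aA + bB + lL."""
    return (
        phase.c
        + phase.e * solute.E
        + phase.s * solute.S
        + phase.a * solute.A
        + phase.b * solute.B
        + phase.l * solute.L
    )


def kovats_index(solute: AbrahamSolute, phase: PhaseSystem) -> float:
    """Kováts retention index of ``solute`` on ``phase``.

    log k is bracketed between consecutive calibration alkanes and linearly
    interpolated: I = 100 n + 100 (log k − log k_n)/(log k_{n+1} − log k_n).
    Outside the calibration range the end segment is extrapolated and a
    warning is logged. By construction an n-alkane returns exactly 100 n.
    """
    if not phase.alkane_l:
        raise ValueError(f"phase {phase.name!r} has no alkane calibration")
    ns, logk = phase.alkane_log_k()
    if np.any(np.diff(logk) <= 0):
        raise ValueError("degenerate alkane bracket: log k not strictly increasing")
    x = lfer_log_k(solute, phase)
    if x < logk[0] or x > logk[-1]:
        logger.warning(
            "log k %.3f outside alkane calibration [%0.3f, %0.3f] on %s; extrapolating",
            x, logk[0], logk[-1], phase.name,
        )
    i = int(np.clip(np.searchsorted(logk, x, side="right") - 1, 0, len(ns) - 2))
    return 100.0 * ns[i] + 100.0 * (x - logk[i]) / (logk[i + 1] - logk[i])


def predict_elution_point(
    solute: AbrahamSolute,
    phase1: PhaseSystem,
    phase2: PhaseSystem,
    base: float = 1.6,
    delta_scale: float = 100.0,
) -> ElutionPoint:
    """Predict the (I1, u2) elution coordinates of a solute on a
    phase1 × phase2 column combination."""
    i1 = kovats_index(solute, phase1)
    i2 = kovats_index(solute, phase2)
    u2 = base ** ((i2 - i1) / delta_scale)
    return ElutionPoint(I1=i1, I2=i2, u2=u2, base=base)


def procrustes_concordance(predicted, observed) -> ConcordanceReport:
    """Procrustes disparity plus per-dimension Pearson correlations.

    Both configurations (lists of (x, y), matched by compound) are centred,
    scaled to unit norm and optimally rotated; the disparity is the residual
    sum of squares. Pearson r is computed dimension-wise on the raw
    coordinates (it is invariant to the Procrustes standardisation).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed configurations differ in shape")
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("need >= 3 matched 2-D points")
    _, _, disparity = _scipy_procrustes(p, o)
    r1 = float(pearsonr(p[:, 0], o[:, 0])[0])
    r2 = float(pearsonr(p[:, 1], o[:, 1])[0])
    return ConcordanceReport(float(disparity), r1, r2, n=p.shape[0])


def ri_rmse(comparisons, exclude=frozenset()) -> float:
    """Root-mean-square of dI over the non-excluded comparisons."""
    di = [c.dI for c in comparisons if c.compound not in exclude]
    if not di:
        raise ValueError("no comparisons left after exclusion")
    return float(np.sqrt(np.mean(np.square(di))))
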