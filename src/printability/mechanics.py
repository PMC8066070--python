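"""Tensile and oscillatory-shear analysis of film substrates.

Tensile curves are analyzed in the engineering convention: stress is force
over the *initial* cross-section area and strain is grip displacement over
the *initial* gauge length.  From a force-displacement trace the module
derives

* tensile strength ``TS = max(F) / A`` (MPa),
* elongation at break ``EB = 100 * dL_break / L0`` (%), with the break
  point detected as the first post-peak sample where the force drops below
  a configurable fraction (default 50%) of the peak force,
* Young's modulus ``YM`` as the least-squares slope of stress on strain
  restricted to the initial linear region.

The complex modulus from an oscillatory frequency sweep is the element-wise
magnitude ``|G*| = sqrt(G'^2 + G''^2)``; a sweep is summarized to a single
G* either as the mean over frequencies (default) or as the value at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AnalysisError, StatisticsError, ValidationError

__all__ = [
    "TensileCurve",
    "OscillatorySweep",
    "TensileResult",
    "tensile_analysis",
    "complex_modulus",
    "summarize_g_star",
    "ts_ym_correlation",
    "DEFAULT_YM_STRAIN_WINDOW",
]

#: default strain window for the Young's-modulus fit (strain fractions,
#: i.e. 0.05%-0.25% extension), the conventional initial linear region for
#: thin-film tensile testing
DEFAULT_YM_STRAIN_WINDOW = (0.0005, 0.0025)


@dataclass
class TensileCurve:
    """Force-displacement trace with specimen geometry.

    ``displacement`` (mm) must start at 0 and be non-decreasing; ``force``
    (N) has the same length.  ``l0`` is the initial gauge length (mm) and
    ``area`` the initial cross-section (mm^2), so stress = force/area is in
    MPa and strain = displacement/l0 is dimensionless.
    """

    displacement: np.ndarray
    force: np.ndarray
    l0: float
    area: float

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.ndim != 1 or self.force.ndim != 1:
            raise ValidationError("displacement and force must be 1-D")
        if self.displacement.size != self.force.size:
            raise ValidationError("displacement and force lengths differ")
        if self.displacement.size < 3:
            raise ValidationError("tensile curve needs at least 3 points")
        if self.l0 <= 0 or self.area <= 0:
            raise ValidationError("l0 and area must be positive")
        if self.displacement[0] != 0:
            raise ValidationError("displacement must start at 0")
        if np.any(np.diff(self.displacement) < 0):
            raise ValidationError("displacement must be non-decreasing")

    @property
    def strain(self) -> np.ndarray:
        return self.displacement / self.l0

    @property
    def stress(self) -> np.ndarray:
        """Engineering stress in MPa (N/mm^2)."""
        return self.force / self.area


@dataclass
class OscillatorySweep:
    """Frequency-indexed storage/loss modulus pairs (MPa), 0.1-10 Hz."""

    frequency: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.g_prime = np.asarray(self.g_prime, dtype=float)
        self.g_double_prime = np.asarray(self.g_double_prime, dtype=float)
        n = self.frequency.size
        if n == 0:
            raise ValidationError("sweep must be non-empty")
        if self.g_prime.size != n or self.g_double_prime.size != n:
            raise ValidationError("sweep arrays must have equal length")
        if np.any(self.g_prime < 0) or np.any(self.g_double_prime < 0):
            raise ValidationError("moduli must be non-negative")
        if n > 1 and np.any(np.diff(self.frequency) <= 0):
            raise ValidationError("frequencies must be strictly increasing")


@dataclass
class TensileResult:
    ts: float      # MPa
    eb: float      # %
    ym: float      # MPa
    break_index: int


def tensile_analysis(
    curve: TensileCurve,
    ym_strain_window: tuple = DEFAULT_YM_STRAIN_WINDOW,
    break_drop_fraction: float = 0.5,
) -> TensileResult:
    """Derive TS, EB and YM from a tensile force-displacement curve.

    The break point is the first sample after the force maximum whose force
    falls below ``break_drop_fraction`` of the maximum (the last point if
    the force never drops that far).  The Young's-modulus fit uses the
    samples whose strain lies in ``ym_strain_window``, or the first 10% of
    points when those are more numerous (a guard for coarsely sampled
    curves whose second point already exceeds the window).
    """
    stress = curve.stress
    strain = curve.strain

    i_peak = int(np.argmax(curve.force))
    ts = float(curve.force[i_peak]) / curve.area

    post = np.nonzero(
        curve.force[i_peak + 1:] < break_drop_fraction * curve.force[i_peak])[0]
    break_index = (i_peak + 1 + int(post[0])) if post.size else curve.force.size - 1
    eb = 100.0 * float(curve.displacement[break_index]) / curve.l0

    lo, hi = ym_strain_window
    if not (0 <= lo < hi):
        raise AnalysisError(f"invalid YM strain window ({lo}, {hi})")
    in_window = np.nonzero((strain >= lo) & (strain <= hi))[0]
    n_head = max(2, curve.force.size // 10)
    idx = in_window if in_window.size >= n_head else np.arange(
        min(n_head, curve.force.size))
    if idx.size < 2 or np.ptp(strain[idx]) == 0:
        raise AnalysisError(
            f"YM window contains {idx.size} point(s); need >= 2 with distinct strain")
    slope = float(np.polyfit(strain[idx], stress[idx], 1)[0])
    return TensileResult(ts=ts, eb=eb, ym=max(slope, 0.0), break_index=break_index)


def complex_modulus(sweep: OscillatorySweep) -> np.ndarray:
    """Element-wise complex-modulus magnitude |G*| = sqrt(G'^2 + G''^2)."""
    return np.hypot(sweep.g_prime, sweep.g_double_prime)


def summarize_g_star(sweep: OscillatorySweep, reduction: str = "mean") -> float:
    """Reduce a sweep to a single G* value.

    ``reduction``: "mean" averages |G*| over the sweep; "at_1hz" linearly
    interpolates |G*| at 1 Hz (clamped to the sweep's frequency range).
    """
    g = complex_modulus(sweep)
    if reduction == "mean":
        return float(np.mean(g))
    if reduction == "at_1hz":
        return float(np.interp(1.0, sweep.frequency, g))
    raise ValidationError(f"unknown G* reduction {reduction!r}")


def ts_ym_correlation(panel) -> dict:
    """Pearson correlation of tensile strength vs Young's modulus.

    Uses the records where both values are present; returns
    ``{"pearson_r": r, "r_squared": r**2, "n": n}``.
    """
    pairs = [(r.ts, r.ym) for r in panel if r.ts is not None and r.ym is not None]
    if len(pairs) < 3:
        raise StatisticsError(
            f"TS-YM correlation needs >= 3 complete pairs, have {len(pairs)}")
    ts, ym = map(np.asarray, zip(*pairs))
    if np.ptp(ts) == 0 or np.ptp(ym) == 0:
        raise StatisticsError("TS-YM correlation undefined: zero variance")
    r = float(stats.pearsonr(ts, ym).statistic)
    return {"pearson_r": r, "r_squared": r * r, "n": len(pairs)}
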