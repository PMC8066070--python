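"""Disintegration-time comparison and dissolution-profile metrics.

Orodispersible substrates must disintegrate fast (the compendial limit for
orodispersible tablets, 180 s by default here, is the compliance
reference), and printing cycles should not change the disintegration time.
The before/after comparison is a two-sided paired Student t-test on
per-sample mean disintegration times.  Dissolution profiles (cumulative %
drug released vs time) are summarized by the earliest time a release level
is attained, with linear interpolation between sampling points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import StatisticsError, SubstratePanel, ValidationError

__all__ = [
    "DissolutionProfile",
    "PairedTestResult",
    "paired_ttest",
    "dt_paired_test",
    "dissolution_metrics",
    "dt_compliance",
]


@dataclass
class DissolutionProfile:
    """Cumulative release profile: time (min) vs % of dose released.

    ``released`` may overshoot 100% slightly (analytical error tolerated up
    to 110%).  Small non-monotonic dips from sampling noise can be removed
    with :meth:`cleaned`, which applies least-squares isotonic regression.
    """

    time: np.ndarray
    released: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if self.time.size == 0 or self.time.size != self.released.size:
            raise ValidationError("time and released must be equal-length, non-empty")
        if self.time[0] < 0 or (self.time.size > 1 and np.any(np.diff(self.time) <= 0)):
            raise ValidationError("time must be strictly increasing and start >= 0")
        if np.any(self.released < 0) or np.any(self.released > 110):
            raise ValidationError("released fraction must lie in [0, 110]%")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.size != self.time.size:
                raise ValidationError("sd length must match time")

    def cleaned(self) -> "DissolutionProfile":
        """Isotonic (pool-adjacent-violators) cleanup of noise-induced dips."""
        from sklearn.isotonic import IsotonicRegression
        iso = IsotonicRegression(increasing=True)
        rel = iso.fit_transform(self.time, self.released)
        return DissolutionProfile(self.time, rel, sd=self.sd)


@dataclass
class PairedTestResult:
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float  # seconds, after - before
    degenerate: bool = False

    def __post_init__(self):
        if self.df < 1:
            raise StatisticsError("paired t-test needs df >= 1 (n >= 2 pairs)")
        if not (0 <= self.p_value <= 1):
            raise StatisticsError("p-value must lie in [0, 1]")


def paired_ttest(before, after) -> PairedTestResult:
    """Two-sided paired Student t-test on (after - before) differences.

    If the differences have zero variance the t statistic is undefined
    (0/0 or +-inf); the result is flagged ``degenerate`` with p = 1 when
    the constant difference is zero and p = 0 otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValidationError("before/after must have equal length")
    n = before.size
    if n < 2:
        raise StatisticsError("paired t-test needs >= 2 pairs")
    d = after - before
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0.0:
        return PairedTestResult(
            t_statistic=0.0 if mean_d == 0 else float(np.sign(mean_d)) * np.inf,
            df=df, p_value=1.0 if mean_d == 0 else 0.0,
            mean_difference=mean_d, degenerate=True)
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(t_statistic=float(t), df=df, p_value=p,
                            mean_difference=mean_d)


def dt_paired_test(panel: SubstratePanel) -> PairedTestResult:
    """Paired t-test of disintegration time before vs after printing.

    Pairs the per-sample mean disintegration times of every record with
    both values present (samples that disintegrated during printing have
    no after-value and drop out).  A warning is emitted when a flagged
    suspect after-printing value enters the test.
    """
    recs = [r for r in panel if r.dt_before is not None and r.dt_after is not None]
    if len(recs) < 2:
        raise StatisticsError(
            f"need >= 2 complete DT pairs, have {len(recs)}")
    suspects = [r.sample_id for r in recs if "dt_after_suspect" in r.flags]
    if suspects:
        warnings.warn(
            f"suspect after-printing disintegration value(s) for {suspects} "
            "enter the paired test; see the panel's documented correction",
            UserWarning, stacklevel=2)
    return paired_ttest([r.dt_before for r in recs], [r.dt_after for r in recs])


def dissolution_metrics(profile: DissolutionProfile, level: float) -> dict:
    """Earliest time (min) at which cumulative release reaches ``level`` %.

    Linear interpolation between the bracketing sampling points; returns
    ``{"t_level": float | None, "reached": bool}``.
    """
    if not (0 < level <= 100):
        raise ValidationError(f"level must lie in (0, 100], got {level}")
    rel = profile.released
    t = profile.time
    hit = np.nonzero(rel >= level)[0]
    if hit.size == 0:
        return {"t_level": None, "reached": False}
    i = int(hit[0])
    if i == 0:
        return {"t_level": float(t[0]), "reached": True}
    # interpolate on the segment [i-1, i]; rel[i-1] < level <= rel[i]
    frac = (level - rel[i - 1]) / (rel[i] - rel[i - 1])
    return {"t_level": float(t[i - 1] + frac * (t[i] - t[i - 1])), "reached": True}


def dt_compliance(panel: SubstratePanel | None, limit: float = 180.0) -> dict:
    """Per-sample compliance flags against a disintegration-time limit (s).

    A sample complies when its before-printing DT is within the limit and
    its after-printing DT (when measured) is too.  The default 180 s is
    the compendial orodispersible-tablet disintegration limit.
    """
    if limit <= 0:
        raise ValidationError("limit must be positive")
    out = {}
    for r in (panel or ()):
        ok = (r.dt_before is not None and r.dt_before <= limit
              and (r.dt_after is None or r.dt_after <= limit))
        out[r.sample_id] = bool(ok)
    return out
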