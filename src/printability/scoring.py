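"""Printability scoring: 0-100% parameter transforms, radar-chart relative
area, and substrate ranking.

Eight characterization parameters enter the score: porosity (POR),
thickness (TH), elongation at break (EB), tensile strength (TS), Young's
modulus (YM), complex modulus (G*), drug load (DL) and printed pattern
appearance (PPA).  Each is transformed onto a 0-100% scale where 100% is
favorable:

* POR, TH, G*, DL - proportional to the panel maximum (the highest value
  scores 100%); higher porosity/thickness mean more ink uptake, higher G*
  more resistance to repeated printing cycles;
* EB - saturating at a flexibility target (default 10%): enough
  stretch to fold through the printer, no bonus beyond it;
* TS - saturating at a strength target (default 2 MPa);
* YM - linearly penalized toward a stiffness bound (default 430 MPa)
  above which films are too rigid; scores clamp at 0 beyond the bound;
* PPA - ordinal 0/5/10 marks (none/one/two pluses for color uniformity
  and edge definition) mapped linearly to 0/50/100%.

A substrate's composite printability is the area of its octagonal radar
polygon relative to the full-score octagon; the relative area depends on
which scores are angular neighbors, so the axis order is part of the
configuration, and a small calibration utility (:func:`convention_search`)
scores documented convention variants against externally reported areas.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import SubstratePanel, TransformError, ValidationError

logger = logging.getLogger("printability")

__all__ = [
    "AXES",
    "TransformConfig",
    "PrintabilityScoreVector",
    "encode_ppa",
    "transform_scores",
    "radar_area",
    "rank_substrates",
    "convention_search",
    "default_convention_grid",
    "radar_chart_svg",
]

#: the eight score axes in the default (methods-listing) order
AXES = ("POR", "TH", "EB", "TS", "YM", "G*", "DL", "PPA")

#: alternative order grouping the figure-label axes (POR, TH, DL, PPA)
FIGURE_LABEL_ORDER = ("POR", "TH", "DL", "PPA", "EB", "TS", "YM", "G*")

#: record fields behind the max-normalized axes
_MAX_AXES = {"POR": "porosity_exp", "TH": "thickness", "G*": "g_star", "DL": "drug_load"}


@dataclass(frozen=True)
class TransformConfig:
    """Convention knobs for the 0-100% transform and the radar area.

    ``max_scope`` chooses whether the POR/TH/G*/DL maxima are taken over
    the whole panel ("global", allowing cross-subset comparison) or within
    each subset ("per_subset").  ``ym_mode`` selects the stiffness
    penalty: "linear" gives ``100 * (ym_bound - YM) / ym_bound`` clamped
    to [0, 100]; "min_over" gives ``100 * min(ym_bound / YM, 1)``.
    """

    eb_target: float = 10.0        # % elongation considered fully flexible
    ts_target: float = 2.0         # MPa tensile strength considered sufficient
    ym_bound: float = 430.0        # MPa stiffness bound (unfavorable above)
    max_scope: str = "global"      # "global" | "per_subset"
    axis_order: tuple = AXES
    ppa_map: dict = field(default_factory=lambda: {0: 0.0, 5: 50.0, 10: 100.0})
    ym_mode: str = "linear"        # "linear" | "min_over"
    por_source: str = "porosity_exp"   # record field behind the POR axis
    g_star_reduction: str = "mean"     # sweep reduction used upstream

    def __post_init__(self):
        if self.eb_target <= 0 or self.ts_target <= 0 or self.ym_bound <= 0:
            raise ValidationError("transform targets must be positive")
        if sorted(self.axis_order) != sorted(AXES):
            raise ValidationError(
                f"axis_order must be a permutation of {AXES}, got {self.axis_order}")
        if self.max_scope not in ("global", "per_subset"):
            raise ValidationError(f"unknown max_scope {self.max_scope!r}")
        if self.ym_mode not in ("linear", "min_over"):
            raise ValidationError(f"unknown ym_mode {self.ym_mode!r}")

    def replace(self, **kw) -> "TransformConfig":
        return replace(self, **kw)

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        d["ppa_map"] = {str(k): v for k, v in self.ppa_map.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TransformConfig":
        d = json.loads(text)
        if "axis_order" in d:
            d["axis_order"] = tuple(d["axis_order"])
        if "ppa_map" in d:
            d["ppa_map"] = {int(k): float(v) for k, v in d["ppa_map"].items()}
        return cls(**d)


@dataclass
class PrintabilityScoreVector:
    """Transformed 0-100% scores on the eight axes plus the relative area."""

    sample_id: str
    scores: dict                 # axis label -> score in [0, 100]
    relative_area: float         # % of the full-score octagon area
    subset: str = ""

    def __post_init__(self):
        missing = [a for a in AXES if a not in self.scores]
        if missing:
            raise ValidationError(f"{self.sample_id}: missing axis scores {missing}")
        for a, s in self.scores.items():
            if not (0.0 <= s <= 100.0):
                raise ValidationError(
                    f"{self.sample_id}: score {a}={s} outside [0, 100]")
        if not (0.0 <= self.relative_area <= 100.0):
            raise ValidationError("relative_area outside [0, 100]")


def encode_ppa(color_ok: str, edges_ok: str) -> int:
    """Ordinal printed-pattern-appearance value from the two marks.

    0, 5 or 10 for none, one or two "+" marks (color uniformity and edge
    definition), order-symmetric.
    """
    for v in (color_ok, edges_ok):
        if v not in ("+", "-"):
            raise ValidationError(f"PPA mark must be '+' or '-', got {v!r}")
    return 5 * ((color_ok == "+") + (edges_ok == "+"))


def _axis_score(record, axis: str, config: TransformConfig, maxima: dict) -> float:
    if axis == "EB":
        s = 100.0 * min(record.eb / config.eb_target, 1.0)
    elif axis == "TS":
        s = 100.0 * min(record.ts / config.ts_target, 1.0)
    elif axis == "YM":
        if config.ym_mode == "linear":
            s = 100.0 * max(0.0, (config.ym_bound - record.ym) / config.ym_bound)
        else:
            s = 100.0 * min(config.ym_bound / record.ym, 1.0) if record.ym > 0 else 100.0
    elif axis == "PPA":
        s = float(config.ppa_map[encode_ppa(record.ppa_color, record.ppa_edges)])
    else:
        fname = config.por_source if axis == "POR" else _MAX_AXES[axis]
        s = 100.0 * getattr(record, fname) / maxima[axis]
    return float(min(max(s, 0.0), 100.0))


def _required_fields(config: TransformConfig):
    return (config.por_source, "thickness", "eb", "ts", "ym", "g_star",
            "drug_load", "ppa_color", "ppa_edges")


def _scorable(panel, config):
    included, excluded = [], {}
    for r in panel:
        missing = [f for f in _required_fields(config) if getattr(r, f) is None]
        if missing:
            excluded[r.sample_id] = f"missing {', '.join(missing)}"
            logger.warning("excluding %s from scoring: missing %s",
                           r.sample_id, ", ".join(missing))
        else:
            included.append(r)
    return included, excluded


def _maxima(records, config: TransformConfig) -> dict:
    out = {}
    for axis, fname in (("POR", config.por_source), ("TH", "thickness"),
                        ("G*", "g_star"), ("DL", "drug_load")):
        m = max(getattr(r, fname) for r in records)
        if m <= 0:
            raise TransformError(f"scope maximum for axis {axis} is {m}; "
                                 "max-normalized score undefined")
        out[axis] = m
    return out


def transform_scores(panel: SubstratePanel, config: TransformConfig | None = None):
    """Transform every scorable record onto the eight 0-100% axes.

    Records missing any of the eight parameters are excluded with a logged
    warning.  Returns a list of :class:`PrintabilityScoreVector` in panel
    order; the POR/TH/G*/DL maxima are taken over the scorable records of
    the configured scope.
    """
    config = config or TransformConfig()
    included, _ = _scorable(panel, config)
    if not included:
        raise TransformError("no scorable records in panel")
    vectors = []
    if config.max_scope == "global":
        scope_maxima = {None: _maxima(included, config)}
    else:
        scope_maxima = {}
        for r in included:
            if r.subset not in scope_maxima:
                scope_maxima[r.subset] = _maxima(
                    [q for q in included if q.subset == r.subset], config)
    for r in included:
        maxima = scope_maxima[None if config.max_scope == "global" else r.subset]
        scores = {a: _axis_score(r, a, config, maxima) for a in AXES}
        vectors.append(PrintabilityScoreVector(
            sample_id=r.sample_id, subset=r.subset, scores=scores,
            relative_area=radar_area(scores, config.axis_order)))
    return vectors


def radar_area(scores, axis_order=AXES) -> float:
    """Relative radar-polygon area (%) of an axis-score vector.

    With n equally spaced axes and radii r_i (the scores in ``axis_order``),
    the polygon area is ``A = 1/2 sin(2*pi/n) * sum_i r_i r_{i+1}``
    (cyclic); the relative area is 100 * A / A_max with A_max the same
    polygon at full score 100 on every axis.  The factor sin(2*pi/n)/2
    cancels, leaving ``100 * sum r_i r_{i+1} / (n * 100^2)``.
    """
    if isinstance(scores, dict):
        r = np.array([scores[a] for a in axis_order], dtype=float)
    else:
        r = np.asarray(scores, dtype=float)
    n = r.size
    if n != len(axis_order):
        raise ValidationError("scores length must match axis_order")
    if np.any(r < 0) or np.any(r > 100):
        raise ValidationError("scores must lie in [0, 100]")
    return 100.0 * float(np.dot(r, np.roll(r, -1))) / (n * 100.0 ** 2)


_EXCLUSION_FLAGS = {
    "drug_recrystallization": "drug recrystallization observed on substrate",
    "excessive_brittleness": "excessive brittleness",
    "disintegrated_during_printing": "sample disintegrated during printing",
}


def rank_substrates(panel: SubstratePanel, config: TransformConfig | None = None,
                    exclude_flagged: bool = True):
    """Rank substrates by descending relative radar area.

    Records carrying quality-exclusion flags (observed drug
    recrystallization, excessive brittleness, disintegration during
    printing) are dropped before scoring when ``exclude_flagged``; records
    missing any score parameter are always dropped.  Ties (equal area) are
    broken by sample_id lexicographic order and reported as tied.

    Returns ``(ranking, exclusions)``: ``ranking`` is a list of
    ``(sample_id, relative_area, tied)`` tuples, ``exclusions`` a dict
    sample_id -> reason.
    """
    config = config or TransformConfig()
    exclusions = {}
    records = []
    for r in panel:
        bad = [f for f in r.flags if f in _EXCLUSION_FLAGS] if exclude_flagged else []
        if bad:
            exclusions[r.sample_id] = "; ".join(_EXCLUSION_FLAGS[f] for f in bad)
        else:
            records.append(r)
    if not records:
        raise TransformError("no scorable records after exclusions")
    sub = SubstratePanel(records, provenance=panel.provenance)
    _, missing = _scorable(sub, config)
    exclusions.update(missing)
    vectors = transform_scores(sub, config)
    vectors.sort(key=lambda v: (-v.relative_area, v.sample_id))
    areas = [v.relative_area for v in vectors]
    ranking = [(v.relative_area in areas[:i] + areas[i + 1:])
               for i, v in enumerate(vectors)]
    return ([(v.sample_id, v.relative_area, tied)
             for v, tied in zip(vectors, ranking)], exclusions)


def default_convention_grid():
    """The documented convention variants for :func:`convention_search`.

    Enumerates max scope (global / per-subset), stiffness bound (430 from
    the recommended boundary vs the 400 MPa phrasing), the YM inversion
    (linear-to-bound vs min-over-value) and the two documented axis orders.
    """
    grid = []
    for scope in ("global", "per_subset"):
        for bound in (430.0, 400.0):
            for ym_mode in ("linear", "min_over"):
                for order in (AXES, FIGURE_LABEL_ORDER):
                    grid.append(TransformConfig(
                        max_scope=scope, ym_bound=bound, ym_mode=ym_mode,
                        axis_order=order))
    return grid


def convention_search(panel: SubstratePanel, printed_areas: dict, grid=None):
    """Score transform-convention variants against reported relative areas.

    For each config in ``grid`` computes the relative areas of the samples
    named in ``printed_areas`` (a dict sample_id -> %) and the residuals
    (computed - reported).  Returns ``(best_config, report)`` where
    ``report`` is a list of ``{"config", "residuals", "max_abs_residual"}``
    in grid order and ``best_config`` minimizes the maximum absolute
    residual (first in grid order on ties).  The best config is reported,
    never silently adopted as a default.
    """
    if not printed_areas:
        raise ValidationError("printed_areas must be non-empty")
    if grid is None:
        grid = default_convention_grid()
    grid = list(grid)
    if not grid:
        raise ValidationError("convention grid must be non-empty")
    report = []
    for cfg in grid:
        vectors = {v.sample_id: v for v in transform_scores(panel, cfg)}
        residuals = {}
        for sid, target in printed_areas.items():
            if sid not in vectors:
                raise ValidationError(f"sample {sid} not scorable under {cfg}")
            residuals[sid] = vectors[sid].relative_area - target
        report.append({
            "config": cfg,
            "residuals": residuals,
            "max_abs_residual": max(abs(v) for v in residuals.values()),
        })
    best = min(range(len(report)), key=lambda i: report[i]["max_abs_residual"])
    return grid[best], report


# ---------------------------------------------------------------------------
# Radar chart rendering (presentational only; the area statistic above
# never depends on this)
# ---------------------------------------------------------------------------

def radar_chart_svg(vectors, config: TransformConfig | None = None,
                    title: str = "", size: int = 420) -> str:
    """Render score vectors as an SVG radar chart (one polygon each).

    Axes sit at equal angles starting at 12 o'clock and proceed clockwise
    in the configured axis order; rings mark 25/50/75/100%.
    """
    config = config or TransformConfig()
    order = config.axis_order
    n = len(order)
    cx = cy = size / 2
    rmax = size / 2 - 40

    def xy(axis_i: int, radius_pct: float):
        ang = math.pi / 2 - 2 * math.pi * axis_i / n  # clockwise from 12 o'clock
        rr = rmax * radius_pct / 100.0
        return cx + rr * math.cos(ang), cy - rr * math.sin(ang)

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" '
             f'height="{size + 30}" viewBox="0 0 {size} {size + 30}">']
    if title:
        parts.append(f'<text x="{cx:.1f}" y="16" text-anchor="middle" '
                     f'font-size="14">{title}</text>')
    for ring in (25, 50, 75, 100):
        pts = " ".join(f"{x:.1f},{y:.1f}" for x, y in (xy(i, ring) for i in range(n)))
        parts.append(f'<polygon points="{pts}" fill="none" stroke="#ccc"/>')
    for i, label in enumerate(order):
        x, y = xy(i, 100)
        lx, ly = xy(i, 112)
        parts.append(f'<line x1="{cx:.1f}" y1="{cy:.1f}" x2="{x:.1f}" y2="{y:.1f}" '
                     'stroke="#ccc"/>')
        parts.append(f'<text x="{lx:.1f}" y="{ly:.1f}" text-anchor="middle" '
                     f'font-size="11">{label}</text>')
    palette = ["#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e",
               "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]
    for k, v in enumerate(vectors):
        pts = " ".join(f"{x:.2f},{y:.2f}" for x, y in
                       (xy(i, v.scores[a]) for i, a in enumerate(order)))
        color = palette[k % len(palette)]
        parts.append(f'<polygon points="{pts}" fill="{color}" fill-opacity="0.15" '
                     f'stroke="{color}" stroke-width="1.5"/>')
        parts.append(f'<text x="{12 + k * 90}" y="{size + 14}" font-size="11" '
                     f'fill="{color}">'
                     f'{v.sample_id} ({v.relative_area:.1f}%)</text>')
    parts.append("</svg>")
    return "\n".join(parts)
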