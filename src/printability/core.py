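"""Domain data model for printing-substrate characterization panels.

A *panel* is an ordered collection of substrate records, one per candidate
printing substrate (cast polymer film or commercial wafer edible sheet).
Each record carries the characterization values the downstream statistics
and the printability scoring consume: uniformity (weight, thickness),
porosity by two methods, drug load after repeated printing cycles, printed
pattern appearance marks, disintegration times before/after printing, and
mechanical parameters (elongation at break, tensile strength, Young's
modulus, complex modulus).

Missing measurements are represented as ``None`` (empty cells in CSV),
never as sentinel numbers, so that a substrate that e.g. disintegrated
during printing cannot contaminate panel statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "PipelineError",
    "FormatError",
    "ValidationError",
    "AnalysisError",
    "StatisticsError",
    "TransformError",
    "SpecError",
    "SubstrateRecord",
    "SubstratePanel",
    "load_panel",
    "write_panel",
    "reference_panel",
    "S2_DT_AFTER_CORRECTED",
    "PANEL_COLUMNS",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file could not be parsed into the expected schema."""


class ValidationError(PipelineError):
    """An input value violates a physical or structural invariant."""


class AnalysisError(PipelineError):
    """A curve/image analysis cannot be performed on the given data."""


class StatisticsError(PipelineError):
    """Too little (or degenerate) data for the requested statistic."""


class TransformError(PipelineError):
    """The score transform is undefined for the given panel/config."""


class SpecError(PipelineError):
    """A synthetic-data specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Record / panel types
# ---------------------------------------------------------------------------

#: measured fields that may carry a standard deviation of the same units
_MEASURED = (
    "weight", "thickness", "drug_load", "porosity_exp", "porosity_img",
    "dt_before", "dt_after", "eb", "ts", "ym", "g_star",
)

_SIGNS = ("+", "-")


@dataclass
class SubstrateRecord:
    """One substrate's full characterization row.

    Units: weight mg/cm^2, thickness um, drug_load ug, porosities %,
    disintegration times s, eb %, ts/ym/g_star MPa.  ``ppa_color`` and
    ``ppa_edges`` are visual-inspection marks, "+" (acceptable) or "-"
    (poor).  Any measured field may be ``None`` (not determined).
    ``flags`` carries free-text quality flags (e.g. observed drug
    recrystallization) that drive downstream exclusion rules.
    """

    sample_id: str
    subset: str = "I"
    weight: float | None = None
    thickness: float | None = None
    drug_load: float | None = None
    porosity_exp: float | None = None
    porosity_img: float | None = None
    ppa_color: str | None = None
    ppa_edges: str | None = None
    dt_before: float | None = None
    dt_after: float | None = None
    eb: float | None = None
    ts: float | None = None
    ym: float | None = None
    g_star: float | None = None
    sd: dict = field(default_factory=dict)
    flags: tuple = ()

    def validate(self) -> "SubstrateRecord":
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        for name in ("thickness", "weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{self.sample_id}: {name} must be > 0, got {v}")
        for name in ("drug_load", "eb", "ts", "ym", "g_star", "dt_before", "dt_after"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.sample_id}: {name} must be >= 0, got {v}")
        for name in ("porosity_exp", "porosity_img"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{self.sample_id}: {name} must lie in [0, 100], got {v}")
        for name in ("ppa_color", "ppa_edges"):
            v = getattr(self, name)
            if v is not None and v not in _SIGNS:
                raise ValidationError(
                    f"{self.sample_id}: {name} must be '+' or '-', got {v!r}")
        return self

    def replace(self, **kw) -> "SubstrateRecord":
        return replace(self, **kw)


#: canonical CSV column order (sd columns are interleaved as <name>_sd)
PANEL_COLUMNS = [
    "sample_id", "subset", "weight_mg_cm2", "thickness_um", "drug_load_ug",
    "porosity_exp_pct", "porosity_img_pct", "ppa_color", "ppa_edges",
    "dt_before_s", "dt_after_s", "eb_pct", "ts_mpa", "ym_mpa", "gstar_mpa",
]

_COL2FIELD = {
    "sample_id": "sample_id", "subset": "subset",
    "weight_mg_cm2": "weight", "thickness_um": "thickness",
    "drug_load_ug": "drug_load", "porosity_exp_pct": "porosity_exp",
    "porosity_img_pct": "porosity_img", "ppa_color": "ppa_color",
    "ppa_edges": "ppa_edges", "dt_before_s": "dt_before",
    "dt_after_s": "dt_after", "eb_pct": "eb", "ts_mpa": "ts",
    "ym_mpa": "ym", "gstar_mpa": "g_star",
}
_FIELD2COL = {v: k for k, v in _COL2FIELD.items()}


@dataclass
class SubstratePanel:
    """Ordered, non-empty collection of :class:`SubstrateRecord`."""

    records: list
    provenance: str = ""

    def __post_init__(self):
        if not self.records:
            raise ValidationError("panel must contain at least one record")
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s) in panel: {dup}")
        for r in self.records:
            r.validate()

    def __iter__(self) -> Iterator[SubstrateRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> SubstrateRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset_panel(self, subset: str) -> "SubstratePanel":
        recs = [r for r in self.records if r.subset == subset]
        if not recs:
            raise ValidationError(f"no records in subset {subset!r}")
        return SubstratePanel(recs, provenance=f"{self.provenance} [subset {subset}]")

    @property
    def subsets(self) -> list:
        out = []
        for r in self.records:
            if r.subset not in out:
                out.append(r.subset)
        return out

    # -- tabular views ------------------------------------------------------

    def to_dataframe(self, with_sd: bool = True) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {}
            for col, fname in _COL2FIELD.items():
                row[col] = getattr(r, fname)
            if with_sd:
                for fname, sd in r.sd.items():
                    row[_FIELD2COL[fname] + "_sd"] = sd
            rows.append(row)
        df = pd.DataFrame(rows)
        base = [c for c in PANEL_COLUMNS if c in df.columns]
        extra = [c for c in df.columns if c not in base]
        return df[base + sorted(extra)]

    def to_json(self) -> str:
        def enc(r: SubstrateRecord) -> dict:
            d = {f.name: getattr(r, f.name) for f in fields(r) if f.name != "flags"}
            d["flags"] = list(r.flags)
            return d
        return json.dumps(
            {"provenance": self.provenance, "records": [enc(r) for r in self.records]},
            indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubstratePanel":
        obj = json.loads(text)
        recs = []
        for d in obj["records"]:
            d = dict(d)
            d["flags"] = tuple(d.get("flags", ()))
            d["sd"] = dict(d.get("sd", {}))
            recs.append(SubstrateRecord(**d))
        return cls(recs, provenance=obj.get("provenance", ""))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_panel(path, delimiter: str = ",") -> SubstratePanel:
    """Read a substrate panel from a delimited text file.

    Header names follow :data:`PANEL_COLUMNS`; any measured column may be
    accompanied by a ``<name>_sd`` column.  Empty cells become ``None``
    (absent), never zeros.  Decimal separator is always ``.``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as e:
        raise ValidationError(f"{path}: file has no data") from e
    unknown = [c for c in df.columns
               if c not in _COL2FIELD and not (
                   c.endswith("_sd") and c[:-3] in _COL2FIELD)]
    if unknown:
        raise FormatError(f"{path}: unrecognized column(s) {unknown}")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if len(df) == 0:
        raise ValidationError(f"{path}: data section is empty")

    def cell(raw, col):
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        raw = str(raw).strip()
        if raw == "" or raw.lower() in ("na", "n/a", "nan"):
            return None
        if col in ("sample_id", "subset", "ppa_color", "ppa_edges"):
            return raw
        try:
            v = float(raw)
        except ValueError as e:
            raise FormatError(f"{path}: unparseable value {raw!r} in column {col}") from e
        return v

    records = []
    for _, row in df.iterrows():
        kw, sd = {}, {}
        for col in df.columns:
            v = cell(row[col], col)
            if col.endswith("_sd"):
                if v is not None:
                    sd[_COL2FIELD[col[:-3]]] = v
            else:
                kw[_COL2FIELD[col]] = v
        kw.setdefault("subset", "I")
        if kw.get("subset") is None:
            kw["subset"] = "I"
        records.append(SubstrateRecord(sd=sd, **kw))
    return SubstratePanel(records, provenance=str(path))


def write_panel(panel: SubstratePanel, path, delimiter: str = ",") -> None:
    """Write a panel to CSV (or JSON when the path ends in ``.json``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(panel.to_json())
        return
    panel.to_dataframe().to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Bundled reference dataset
# ---------------------------------------------------------------------------

#: documented correction for the suspect S2 after-printing disintegration
#: time: the published table prints 2.2 s against 32.5 s before printing,
#: inconsistent with the accompanying no-change conclusion; 32.2 s is the
#: value consistent with it.  The verbatim panel keeps 2.2 and flags it.
S2_DT_AFTER_CORRECTED = 32.2

# sample_id, subset, weight(sd), thickness(sd), drug_load(sd),
# porosity_exp(sd), porosity_img, ppa_color, ppa_edges,
# dt_before(sd), dt_after(sd), eb(sd), ts(sd), ym(sd), g_star(sd), flags
_REFERENCE_ROWS = [
    ("S1", "I", (13.2, 1.1), (124, 5), (197.5, 0.2), (1.3, 0.1), 2.5, "-", "-",
     (27.0, 2.0), (26.7, 1.0), (272.91, 0.00), (0.43, 0.00), (2.99, 0.00),
     (0.58, 0.06), ()),
    ("S2", "I", (16.2, 0.6), (121, 2), (181.5, 0.4), (1.8, 0.2), 3.1, "+", "+",
     (32.5, 0.8), (2.2, 1.8), (21.14, 1.07), (8.26, 0.36), (146.25, 0.07),
     (0.73, 0.12), ("dt_after_suspect",)),
    ("S3", "I", (13.6, 0.4), (78, 4), (54.2, 2.6), (0.8, 0.1), 0.5, "+", "-",
     (41.7, 0.9), (41.5, 2.0), (2.50, 0.37), (53.63, 6.67), (3498.00, 173.09),
     (90.35, 4.34), ("drug_recrystallization", "excessive_brittleness")),
    ("S4", "I", (8.4, 0.4), (69, 4), None, (0.8, 0.1), 0.3, None, None,
     (3.5, 0.5), None, None, None, None, None,
     ("disintegrated_during_printing",)),
    ("S5", "II", (31.1, 0.7), (396, 22), (437.1, 2.5), (8.2, 0.5), 31.8, "+", "+",
     (28.2, 1.9), (28.8, 1.6), (11.31, 1.66), (1.52, 0.16), (182.67, 8.95),
     (433.12, 15.34), ()),
    ("S6", "II", (26.5, 0.7), (309, 12), (97.8, 4.9), (3.0, 0.6), 9.8, "-", "+",
     (52.5, 1.4), (53.1, 1.6), (28.77, 8.43), (1.07, 0.13), (111.86, 13.33),
     (642.98, 16.12), ()),
    ("S7", "II", (30.9, 1.0), (481, 18), (294.2, 0.0), (6.3, 0.5), 31.5, "-", "+",
     (46.0, 1.3), (46.5, 2.1), (11.27, 0.52), (4.11, 0.31), (403.67, 36.18),
     (467.63, 28.98), ()),
    ("S8", "III", (8.6, 0.0), (264, 6), (217.3, 4.1), (6.9, 0.2), 33.8, "-", "+",
     (17.2, 1.2), (17.0, 0.9), (1.86, 0.21), (3.81, 0.66), (300.45, 0.64),
     (0.35, 0.06), ()),
    ("S9", "III", (12.4, 0.2), (369, 6), (333.2, 1.0), (9.7, 0.2), 41.1, "+", "+",
     (20.8, 0.7), (20.5, 1.0), (1.49, 0.31), (1.14, 0.53), (105.49, 16.84),
     (2.65, 0.07), ()),
    ("S10", "III", (18.6, 0.2), (502, 7), (151.0, 5.6), (6.1, 0.4), 30.4, "+", "+",
     (129.3, 2.5), (129.3, 1.4), (0.67, 0.18), (1.66, 0.38), (290.20, 22.77),
     (601.29, 0.08), ()),
]


def reference_panel(corrected_dt: bool = False) -> SubstratePanel:
    """The bundled ten-substrate reference panel.

    Subset I are single-polymer orodispersible thin films, subset II
    structured orodispersible film templates (polymer-blend SOFTs), and
    subset III commercial wafer edible sheets.  S4 disintegrated on first
    ink contact and therefore has no drug load, pattern-appearance marks,
    after-printing disintegration time or mechanical characterization.

    S2's after-printing disintegration time is stored verbatim (2.2 s) and
    flagged ``dt_after_suspect``; pass ``corrected_dt=True`` for the
    documented corrected variant (:data:`S2_DT_AFTER_CORRECTED`).
    """
    records = []
    names = ("weight", "thickness", "drug_load", "porosity_exp")
    for (sid, sub, w, th, dl, pe, pi, pc, pedge, dtb, dta,
         eb, ts, ym, g, flg) in _REFERENCE_ROWS:
        sd = {}
        vals = {}
        for name, pair in zip(
                names + ("dt_before", "dt_after", "eb", "ts", "ym", "g_star"),
                (w, th, dl, pe, dtb, dta, eb, ts, ym, g)):
            if pair is None:
                vals[name] = None
            else:
                vals[name], s = pair
                sd[name] = s
        records.append(SubstrateRecord(
            sample_id=sid, subset=sub, porosity_img=float(pi),
            ppa_color=pc, ppa_edges=pedge, sd=sd, flags=tuple(flg), **vals))
    if corrected_dt:
        for i, r in enumerate(records):
            if r.sample_id == "S2":
                records[i] = r.replace(
                    dt_after=S2_DT_AFTER_CORRECTED,
                    flags=tuple(f for f in r.flags if f != "dt_after_suspect")
                    + ("dt_after_corrected",))
    tag = "corrected S2 DT-after" if corrected_dt else "verbatim"
    return SubstratePanel(records, provenance=f"bundled reference panel ({tag})")
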