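"""Synthetic raw-measurement generator with known ground truth.

Every raw input the pipeline consumes can be generated here with exact
target parameters, so that analysis code can be validated by parameter
recovery:

* tensile force-displacement curves with a linear elastic region of slope
  YM, a smooth quadratic yield-to-peak blend reaching stress TS exactly at
  strain EB/100, and a near-vertical post-peak failure drop;
* oscillatory frequency sweeps whose storage/loss moduli realize a target
  complex-modulus magnitude at a fixed phase angle;
* binary-contrast pore images (bright ellipses on a dark background) with
  the exactly realized bright-pixel fraction reported back;
* first-order dissolution profiles ``Q(t) = 100 (1 - exp(-k t))`` with
  optional truncated-Gaussian triplicate noise.

All randomness flows through ``numpy.random.default_rng(seed)`` (the
PCG64 generator), so identical seeds give identical data on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from .core import (SpecError, SubstratePanel, SubstrateRecord, ValidationError,
                   write_panel)
from .dispersal import DissolutionProfile
from .mechanics import (OscillatorySweep, TensileCurve, summarize_g_star,
                        tensile_analysis)
from .porosity import PoreImage, porosity_image

__all__ = [
    "SubstrateTargets",
    "SynthSpec",
    "make_tensile_curve",
    "make_sweep",
    "make_pore_image",
    "make_dissolution_profile",
    "make_panel",
]


@dataclass
class SubstrateTargets:
    """Ground-truth parameters for one synthetic substrate."""

    ts: float            # MPa
    eb: float            # %
    ym: float            # MPa
    g_star: float        # MPa
    porosity: float      # %
    thickness: float     # um
    drug_load: float     # ug
    ppa_pluses: int = 2  # 0, 1 or 2
    dt_before: float = 30.0   # s
    dt_after: float = 30.0    # s
    k_dissolution: float = 0.2  # 1/min first-order release rate
    weight: float = 20.0        # mg/cm^2

    def validate(self):
        for name in ("ts", "eb", "ym", "g_star", "porosity", "thickness",
                     "drug_load", "dt_before", "dt_after", "k_dissolution",
                     "weight"):
            if getattr(self, name) < 0:
                raise SpecError(f"target {name} must be non-negative")
        if self.ppa_pluses not in (0, 1, 2):
            raise SpecError("ppa_pluses must be 0, 1 or 2")
        if self.ym * self.eb / 100.0 < self.ts:
            raise SpecError(
                f"inconsistent targets: YM*(EB/100) = {self.ym * self.eb / 100.0:.4g} "
                f"< TS = {self.ts:.4g}; the elastic line cannot reach peak stress")
        return self


@dataclass
class SynthSpec:
    """A reproducible multi-substrate synthetic study."""

    seed: int
    targets: dict = field(default_factory=dict)  # sample_id -> SubstrateTargets
    noise: dict = field(default_factory=dict)    # measurement type -> relative sd

    def __post_init__(self):
        if not self.targets:
            raise ValidationError("SynthSpec needs at least one substrate")
        for t in self.targets.values():
            t.validate()

    def noise_for(self, kind: str) -> float:
        return float(self.noise.get(kind, 0.0))


def make_tensile_curve(ts: float, eb: float, ym: float, *, noise: float = 0.0,
                       seed: int = 0, n_points: int = 400, area: float = 1.0,
                       l0: float = 50.0, knee_fraction: float = 0.9) -> TensileCurve:
    """Generate a tensile curve with exact target TS (MPa), EB (%), YM (MPa).

    Shape: linear elastic rise at slope YM up to the yield knee at stress
    ``knee_fraction * TS``, then a quadratic blend ``s(u) = u (2 - u)``
    (zero slope at the peak) reaching TS exactly at strain EB/100, then two
    near-vertical drop points to 30% of peak force so break detection at
    the 50% criterion lands at the peak strain.  Gaussian noise of relative
    standard deviation ``noise`` (fraction of peak force) is added to force
    only.  Recovery of YM by the default strain-window fit requires the
    knee strain ``knee_fraction*TS/YM`` to exceed the window's upper edge.
    """
    targets = SubstrateTargets(ts=ts, eb=eb, ym=ym, g_star=0, porosity=0,
                               thickness=1, drug_load=0)
    targets.validate()
    if not (0 < knee_fraction < 1):
        raise SpecError("knee_fraction must lie in (0, 1)")
    eps_peak = eb / 100.0
    eps_knee = min(knee_fraction * ts / ym, knee_fraction * eps_peak) if ym > 0 \
        else knee_fraction * eps_peak
    sigma_knee = ym * eps_knee

    n_lin = max(3, n_points // 3)
    n_blend = max(3, n_points - n_lin)
    e_lin = np.linspace(0.0, eps_knee, n_lin)
    s_lin = ym * e_lin
    u = np.linspace(0.0, 1.0, n_blend)[1:]
    e_blend = eps_knee + u * (eps_peak - eps_knee)
    s_blend = sigma_knee + (ts - sigma_knee) * u * (2.0 - u)
    # near-vertical failure: force collapses within 0.01% extra strain
    e_drop = eps_peak * np.array([1.0 + 5e-5, 1.0 + 1e-4])
    s_drop = ts * np.array([0.3, 0.05])

    strain = np.concatenate([e_lin, e_blend, e_drop])
    stress = np.concatenate([s_lin, s_blend, s_drop])
    force = stress * area
    if noise > 0:
        rng = np.random.default_rng(seed)
        force = np.clip(force + rng.normal(0.0, noise * ts * area, force.size),
                        0.0, None)
    return TensileCurve(displacement=strain * l0, force=force, l0=l0, area=area)


def make_sweep(g_star: float, *, noise: float = 0.0, seed: int = 0,
               n_points: int = 15, phase_deg: float = 15.0) -> OscillatorySweep:
    """Frequency sweep (0.1-10 Hz, log-spaced) realizing |G*| = ``g_star``.

    G' and G'' are set from a constant phase angle (default 15 deg, a
    predominantly elastic film), so the magnitude equals the target at
    every frequency and any sweep reduction recovers it exactly at zero
    noise.
    """
    if g_star < 0:
        raise SpecError("g_star target must be non-negative")
    freq = np.logspace(np.log10(0.1), np.log10(10.0), n_points)
    delta = np.deg2rad(phase_deg)
    gp = np.full(n_points, g_star * np.cos(delta))
    gpp = np.full(n_points, g_star * np.sin(delta))
    if noise > 0:
        rng = np.random.default_rng(seed)
        gp = np.clip(gp * (1 + rng.normal(0, noise, n_points)), 0, None)
        gpp = np.clip(gpp * (1 + rng.normal(0, noise, n_points)), 0, None)
    return OscillatorySweep(frequency=freq, g_prime=gp, g_double_prime=gpp)


def make_pore_image(width: int, height: int, pore_fraction: float, *,
                    seed: int = 0, pore_value: int = 230, solid_value: int = 25):
    """Bright-ellipse pore image with exactly known realized pore fraction.

    Ellipses (random centers, semi-axes 2-8% of the smaller dimension) are
    painted onto a dark background until the bright-pixel fraction first
    meets or exceeds ``pore_fraction`` %.  Returns ``(PoreImage,
    realized_fraction_pct)``; thresholding midway between the two gray
    levels recovers the realized fraction exactly.
    """
    if not (0 <= pore_fraction <= 100):
        raise ValidationError("pore_fraction must lie in [0, 100]")
    if width <= 0 or height <= 0:
        raise ValidationError("image dimensions must be positive")
    px = np.full((height, width), solid_value, dtype=np.uint8)
    total = px.size
    target_px = pore_fraction / 100.0 * total
    rng = np.random.default_rng(seed)
    lo = max(2, int(0.02 * min(width, height)))
    hi = max(lo + 1, int(0.08 * min(width, height)))
    guard = 0
    while np.count_nonzero(px == pore_value) < target_px:
        r, c = rng.uniform(0, height), rng.uniform(0, width)
        ra, rc = rng.uniform(lo, hi), rng.uniform(lo, hi)
        rr, cc = ellipse(r, c, ra, rc, shape=px.shape)
        px[rr, cc] = pore_value
        guard += 1
        if guard > 100 * total:  # pragma: no cover - unreachable safeguard
            raise RuntimeError("pore painting failed to converge")
    realized = 100.0 * np.count_nonzero(px == pore_value) / total
    return PoreImage(px), realized


def make_dissolution_profile(k: float, times, *, noise: float = 0.0,
                             seed: int = 0, n_replicates: int = 3
                             ) -> DissolutionProfile:
    """First-order release profile Q(t) = 100 (1 - exp(-k t)), k in 1/min.

    With ``noise`` > 0, ``n_replicates`` noisy realizations (truncated to
    [0, 110]%) are averaged and their standard deviation reported per time
    point, emulating triplicate sampling.
    """
    times = np.asarray(times, dtype=float)
    if k <= 0:
        raise ValidationError("release rate k must be positive")
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValidationError("times must be strictly increasing and non-negative")
    q = 100.0 * (1.0 - np.exp(-k * times))
    if noise <= 0:
        return DissolutionProfile(time=times, released=q,
                                  sd=np.zeros_like(times))
    rng = np.random.default_rng(seed)
    reps = np.clip(q[None, :] + rng.normal(0.0, noise * 100.0,
                                           (n_replicates, times.size)),
                   0.0, 110.0)
    return DissolutionProfile(time=times, released=reps.mean(axis=0),
                              sd=reps.std(axis=0, ddof=1))


_PPA_MARKS = {0: ("-", "-"), 1: ("+", "-"), 2: ("+", "+")}

_DISSOLUTION_TIMES = np.array([1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0])


def make_panel(spec: SynthSpec, out_dir=None):
    """End-to-end synthetic study: a characterized panel plus raw data.

    For each substrate the raw measurements (tensile curve, frequency
    sweep, pore image, dissolution profile) are generated from the spec
    targets and immediately re-analyzed by the pipeline operations; the
    panel rows therefore contain *pipeline-derived* values, which recover
    the targets within noise-scaled tolerances.  When ``out_dir`` is
    given, the raw files, the panel CSV and a ground-truth manifest JSON
    are written there.

    Returns ``(panel, raw, manifest)`` where ``raw`` maps sample_id to the
    in-memory raw objects and ``manifest`` records the ground truth.
    """
    import json
    from pathlib import Path

    rng = np.random.default_rng(spec.seed)
    records, raw, manifest = [], {}, {"seed": spec.seed, "substrates": {}}
    for sid, t in spec.targets.items():
        seeds = {kind: int(rng.integers(0, 2 ** 31 - 1))
                 for kind in ("tensile", "sweep", "image", "dissolution")}
        curve = make_tensile_curve(t.ts, t.eb, t.ym,
                                   noise=spec.noise_for("tensile"),
                                   seed=seeds["tensile"])
        sweep = make_sweep(t.g_star, noise=spec.noise_for("sweep"),
                           seed=seeds["sweep"])
        image, realized = make_pore_image(256, 256, t.porosity,
                                          seed=seeds["image"])
        profile = make_dissolution_profile(
            t.k_dissolution, _DISSOLUTION_TIMES,
            noise=spec.noise_for("dissolution"), seed=seeds["dissolution"])

        tens = tensile_analysis(curve)
        color, edges = _PPA_MARKS[t.ppa_pluses]
        records.append(SubstrateRecord(
            sample_id=sid, subset="I",
            weight=t.weight, thickness=t.thickness, drug_load=t.drug_load,
            porosity_exp=t.porosity,
            porosity_img=porosity_image(image, threshold=127),
            ppa_color=color, ppa_edges=edges,
            dt_before=t.dt_before, dt_after=t.dt_after,
            eb=tens.eb, ts=tens.ts, ym=tens.ym,
            g_star=summarize_g_star(sweep)))
        raw[sid] = {"curve": curve, "sweep": sweep, "image": image,
                    "profile": profile, "realized_pore_fraction": realized}
        manifest["substrates"][sid] = {
            "targets": t.__dict__, "seeds": seeds,
            "realized_pore_fraction": realized}

    panel = SubstratePanel(records, provenance=f"synthetic (seed={spec.seed})")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(panel, out / "panel.csv")
        for sid, bundle in raw.items():
            c, s, p = bundle["curve"], bundle["sweep"], bundle["profile"]
            np.savetxt(out / f"{sid}_tensile.csv",
                       np.column_stack([c.displacement, c.force]),
                       delimiter=",", header="displacement_mm,force_n", comments="")
            np.savetxt(out / f"{sid}_sweep.csv",
                       np.column_stack([s.frequency, s.g_prime, s.g_double_prime]),
                       delimiter=",",
                       header="frequency_hz,gprime_mpa,gdoubleprime_mpa", comments="")
            np.savetxt(out / f"{sid}_dissolution.csv",
                       np.column_stack([p.time, p.released, p.sd]),
                       delimiter=",", header="time_min,released_pct,sd_pct",
                       comments="")
            bundle["image"].save(out / f"{sid}_pores.png")
            (out / f"{sid}_geometry.json").write_text(json.dumps(
                {"l0_mm": c.l0, "area_mm2": c.area}))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return panel, raw, manifest
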