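"""EMSA titration analysis: band table -> fractional saturation -> Hill plot.

Quantified gel lanes (one intensity per band species, species ``k`` = number
of repressor molecules bound) are reduced to fractional saturation — by
default the mean fraction of sites occupied,

    Y = sum_k k * I_k / (n * sum_k I_k),

which for a single-site probe is simply bound/total.  Replicates at each
concentration are averaged, and the Hill transform

    theta = Y / (1 - Y),   plot log10(theta) vs log10([protein])

yields the Hill coefficient n_H as the slope at log10(theta) = 0 and the
dissociation constant as Kd = 10^(x-intercept).  n_H < 1 indicates negative
cooperativity (here: independent sites of descending affinity), n_H > 1
positive cooperativity, n_H = 1 none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    EmptyLaneError,
    InputError,
    InsufficientDataError,
    PathologicalFitError,
    SingularFitError,
)

__all__ = [
    "Lane",
    "BandTable",
    "SaturationPoint",
    "SaturationCurve",
    "HillPoint",
    "HillResult",
    "band_table_to_saturation",
    "hill_transform",
    "hill_fit",
    "classify_cooperativity",
]

#: Y values within EPS of 0 or 1 are excluded before the log transform.
EPS = 1e-6


@dataclass(frozen=True)
class Lane:
    """One gel lane: protein concentration (µM) and intensity per band species 0..n."""

    concentration: float
    intensities: tuple[float, ...]
    replicate_id: int = 1

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.intensities)
        object.__setattr__(self, "intensities", vals)
        if self.concentration < 0 or not math.isfinite(self.concentration):
            raise InputError(f"lane concentration must be >= 0, got {self.concentration}")
        if any(v < 0 or not math.isfinite(v) for v in vals):
            raise InputError(f"band intensities must be finite and >= 0: {vals}")


@dataclass(frozen=True)
class BandTable:
    """Quantified EMSA titration: a list of lanes sharing a band-species layout.

    Must contain at least one zero-protein lane (the normalization lane run
    on every gel).
    """

    lanes: tuple[Lane, ...]

    def __post_init__(self) -> None:
        lanes = tuple(self.lanes)
        object.__setattr__(self, "lanes", lanes)
        if not lanes:
            raise InputError("band table must contain at least one lane")
        widths = {len(ln.intensities) for ln in lanes}
        if len(widths) != 1:
            raise InputError(f"lanes disagree on band-species count: {sorted(widths)}")
        if not any(ln.concentration == 0 for ln in lanes):
            raise InputError("band table must include a zero-protein lane")

    @property
    def n_species(self) -> int:
        return len(self.lanes[0].intensities)


@dataclass(frozen=True)
class SaturationPoint:
    concentration: float
    y: float
    sem: float = 0.0
    n_replicates: int = 1


@dataclass(frozen=True)
class SaturationCurve:
    """Fractional saturation vs concentration, aggregated over replicates."""

    points: tuple[SaturationPoint, ...]

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        concs = [p.concentration for p in pts]
        if any(c < 0 for c in concs):
            raise InputError("concentrations must be >= 0")
        if any(concs[i] >= concs[i + 1] for i in range(len(concs) - 1)):
            raise InputError("concentrations must be strictly increasing after aggregation")
        if any(not 0 <= p.y <= 1 for p in pts):
            raise InputError("Y must lie in [0, 1]")


@dataclass(frozen=True)
class HillPoint:
    """One point of the Hill plot: (log10 conc, log10 theta), both finite."""

    log_conc: float
    log_theta: float


@dataclass(frozen=True)
class HillResult:
    """Hill-plot line fit: slope n_H, x-intercept, Kd = 10^x_intercept."""

    n_h: float
    x_intercept: float
    kd: float
    n_points_used: int
    r_squared: float
    classification: str
    n_points_excluded: int = 0


def band_table_to_saturation(
    table: BandTable, weighting: str = "occupancy"
) -> SaturationCurve:
    """Reduce lanes to fractional saturation, averaging replicates per concentration.

    ``weighting="occupancy"`` (default) weights each band species by its
    stoichiometry: Y = sum_k k*I_k / (n * sum_k I_k), the mean fraction of
    sites occupied.  This is the quantity whose Hill plot exposes negative
    cooperativity on multi-operator probes; for a single-site gel it reduces
    to bound/total.  ``weighting="any_bound"`` instead counts every shifted
    species equally: Y = sum_{k>=1} I_k / sum_k I_k, the fraction of probe
    molecules with at least one protein bound — on heterogeneous multisite
    probes this is dominated by the tightest site and its Hill slope stays
    near 1 regardless of the affinity spread.

    The standard error of the mean is reported where a concentration was run
    in replicate.
    """
    if weighting not in ("occupancy", "any_bound"):
        raise InputError(f"unknown weighting {weighting!r}")
    n_bound_max = table.n_species - 1
    per_conc: dict[float, list[float]] = {}
    for i, lane in enumerate(table.lanes):
        total = sum(lane.intensities)
        if total <= 0:
            raise EmptyLaneError(f"lane {i} (conc={lane.concentration} µM) has zero total intensity")
        if weighting == "occupancy" and n_bound_max > 0:
            y = sum(k * v for k, v in enumerate(lane.intensities)) / (n_bound_max * total)
        else:
            y = sum(lane.intensities[1:]) / total
        y = min(max(y, 0.0), 1.0)
        per_conc.setdefault(lane.concentration, []).append(y)
    points = []
    for conc in sorted(per_conc):
        ys = np.array(per_conc[conc])
        sem = float(ys.std(ddof=1) / math.sqrt(len(ys))) if len(ys) > 1 else 0.0
        points.append(
            SaturationPoint(
                concentration=conc,
                y=float(ys.mean()),
                sem=sem,
                n_replicates=len(ys),
            )
        )
    return SaturationCurve(points=tuple(points))


class HillPoints(list):
    """List of :class:`HillPoint` that remembers how many points were excluded."""

    n_excluded: int = 0


def hill_transform(curve: SaturationCurve, eps: float = EPS) -> HillPoints:
    """Map usable points to (log10 conc, log10 Y/(1-Y)); degenerate points dropped.

    Points at zero concentration or with Y within ``eps`` of 0 or 1 carry no
    finite Hill coordinate and are excluded, not errors; the count of
    exclusions is reported on the returned list so filtering is auditable.
    """
    points = HillPoints()
    excluded = 0
    for p in curve.points:
        if p.concentration <= 0 or p.y <= eps or p.y >= 1.0 - eps:
            excluded += 1
            continue
        theta = p.y / (1.0 - p.y)
        points.append(HillPoint(math.log10(p.concentration), math.log10(theta)))
    points.n_excluded = excluded
    if len(points) < 2:
        raise InsufficientDataError(
            f"only {len(points)} usable Hill points (need >= 2); "
            "titration may be entirely unsaturated or saturated"
        )
    return points


def hill_fit(points: list[HillPoint], window: float = 1.0) -> HillResult:
    """Fit the Hill line near half-saturation and extract n_H and Kd.

    Ordinary least squares over points with ``|log10 theta| <= window``
    (default 1, i.e. Y roughly in [0.09, 0.91]); if the window holds fewer
    than 2 points, the 4 points nearest log10(theta) = 0 are used instead.
    ``Kd = 10^x_intercept`` with ``x_intercept = -intercept/slope``.
    """
    if len(points) < 2:
        raise InsufficientDataError("need >= 2 Hill points")
    pts = sorted(points, key=lambda p: (p.log_conc, p.log_theta))
    sel = [p for p in pts if abs(p.log_theta) <= window]
    if len(sel) < 2:
        sel = sorted(pts, key=lambda p: abs(p.log_theta))[:4]
    x = np.array([p.log_conc for p in sel])
    t = np.array([p.log_theta for p in sel])
    if np.ptp(x) == 0:
        raise SingularFitError("all selected Hill points share one concentration")
    slope, intercept = np.polyfit(x, t, 1)
    if slope <= 0:
        raise PathologicalFitError(
            f"Hill slope {slope:.4g} <= 0: saturation does not increase with concentration"
        )
    ss_res = float(np.sum((t - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    x_int = -intercept / slope
    result = HillResult(
        n_h=float(slope),
        x_intercept=float(x_int),
        kd=10.0 ** float(x_int),
        n_points_used=len(sel),
        r_squared=r2,
        classification="",
        n_points_excluded=len(points) - len(sel),
    )
    return replace(result, classification=classify_cooperativity(result))


def classify_cooperativity(result: HillResult, tol: float = 0.10) -> str:
    """Label a Hill coefficient: negative (< 1-tol), positive (> 1+tol), else non-cooperative."""
    if result.n_h < 1.0 - tol:
        return "negative"
    if result.n_h > 1.0 + tol:
        return "positive"
    return "non-cooperative"
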