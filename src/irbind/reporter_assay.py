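"""Miller-unit analysis of kinetic β-galactosidase plate reads.

Reporter activity is measured as the kinetic rate of ONPG hydrolysis:
the OLS slope of OD420 over time (per minute), scaled by cell density,

    Miller units (mU) = slope(OD420/min) * 5000 / OD600(first time point).

Per-condition activities are then normalized to a vector-only control, and
autoregulation is summarized as the repression ratio of induced over
uninduced activity (ratio < 1 means the induced protein represses its own
promoter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError, InsufficientDataError

__all__ = [
    "KineticPlateRead",
    "MillerResult",
    "miller_units",
    "aggregate_replicates",
    "normalize_activity",
    "repression_ratio",
]

MILLER_SCALE = 5000.0


@dataclass(frozen=True)
class KineticPlateRead:
    """One well's kinetic read: OD420 series over time plus the initial OD600.

    ``times`` are minutes, strictly increasing (typical design: every 90 s
    for one hour).  Condition labels identify promoter construct, antitoxin
    plasmid and IPTG induction state.
    """

    well_id: str
    times: tuple[float, ...]
    od420: tuple[float, ...]
    od600_first: float
    construct: str = ""
    antitoxin: str = ""
    iptg: bool = False
    replicate_id: int = 1

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.times)
        a = tuple(float(v) for v in self.od420)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od420", a)
        if len(t) < 3:
            raise InsufficientDataError("need >= 3 time points for a kinetic slope")
        if len(t) != len(a):
            raise InputError("times and od420 must have equal length")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise InputError("times must be strictly increasing")
        if not all(map(math.isfinite, t + a)):
            raise InputError("times and od420 must be finite")
        if not (self.od600_first > 0 and math.isfinite(self.od600_first)):
            raise InputError(f"od600_first must be > 0, got {self.od600_first}")


@dataclass(frozen=True)
class MillerResult:
    """Miller units for one condition, with optional replicate spread and normalization."""

    label: str
    mu: float
    slope: float
    sd: float = 0.0
    normalized_mu: float | None = None
    normalized_sd: float | None = None
    n_replicates: int = 1
    negative_slope: bool = False


def miller_units(
    read: KineticPlateRead,
    window: tuple[float, float] | None = None,
    label: str | None = None,
) -> MillerResult:
    """Convert one kinetic read to Miller units.

    The slope is the OLS slope of OD420 vs time in minutes over the full
    series, or over ``window = (t_min, t_max)`` for wells that saturate.
    A negative slope is returned as computed and flagged.
    """
    t = np.array(read.times)
    a = np.array(read.od420)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 3:
            raise InsufficientDataError("window leaves < 3 time points")
        t, a = t[mask], a[mask]
    slope = float(np.polyfit(t, a, 1)[0])
    mu = slope * MILLER_SCALE / read.od600_first
    if label is None:
        label = " ".join(
            x for x in (read.construct, read.antitoxin, "+IPTG" if read.iptg else "-IPTG") if x
        ) or read.well_id
    return MillerResult(
        label=label, mu=mu, slope=slope, n_replicates=1, negative_slope=slope < 0
    )


def aggregate_replicates(results: list[MillerResult], label: str | None = None) -> MillerResult:
    """Mean ± sd of Miller units across replicate wells of one condition."""
    if not results:
        raise InputError("no replicates to aggregate")
    labels = {r.label for r in results}
    if label is None:
        if len(labels) > 1:
            raise InputError(f"refusing to aggregate mixed conditions: {sorted(labels)}")
        label = results[0].label
    mus = np.array([r.mu for r in results])
    sd = float(mus.std(ddof=1)) if len(mus) > 1 else 0.0
    return MillerResult(
        label=label,
        mu=float(mus.mean()),
        slope=float(np.mean([r.slope for r in results])),
        sd=sd,
        n_replicates=len(results),
        negative_slope=bool(np.mean(mus) < 0),
    )


def normalize_activity(
    samples: list[MillerResult], control_label: str
) -> list[MillerResult]:
    """Normalize each condition's activity to the named control (control -> 1.0).

    The sd of the ratio is propagated by the delta method assuming
    independent errors, using each condition's replicate sd and the standard
    error of the control mean:

        sd(r) ≈ |r| * sqrt((sd_s/mu_s)^2 + (sem_c/mu_c)^2).
    """
    controls = [r for r in samples if r.label == control_label]
    if not controls:
        raise InputError(f"control {control_label!r} not found")
    control = controls[0]
    if control.mu == 0:
        raise InputError("control Miller units are zero; cannot normalize")
    sem_c = control.sd / math.sqrt(control.n_replicates)
    out = []
    for r in samples:
        ratio = r.mu / control.mu
        sem_s = r.sd / math.sqrt(r.n_replicates)
        if r.mu != 0:
            nsd = abs(ratio) * math.sqrt((sem_s / r.mu) ** 2 + (sem_c / control.mu) ** 2)
        else:
            nsd = sem_s / abs(control.mu)
        out.append(replace(r, normalized_mu=ratio, normalized_sd=nsd))
    return out


def repression_ratio(induced: MillerResult, uninduced: MillerResult) -> float:
    """Fold change of induced over uninduced activity; < 1 indicates repression."""
    if uninduced.mu <= 0:
        raise InputError(f"uninduced Miller units must be > 0, got {uninduced.mu}")
    return induced.mu / uninduced.mu
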