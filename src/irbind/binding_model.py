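"""Equilibrium statistical-thermodynamic model of a repressor binding *n* operator sites.

The promoter is described by an ordered list of operator sites (here, inverted
repeats), each with its own dissociation constant ``kd`` in µM, plus optional
pairwise coupling factors ``omega``.  At free repressor concentration ``c`` the
statistical weight of a binding configuration ``S`` (a subset of occupied
sites) is

    w(S) = prod_{i in S} (c / kd_i) * prod_{i<j in S} omega_ij

and configuration probabilities follow by normalizing over all ``2^n``
configurations.  With all ``omega = 1`` the sites are independent and the
number of occupied sites follows a Poisson-binomial distribution with
per-site occupancies ``p_i = c / (c + kd_i)``; heterogeneous affinities then
produce an apparent Hill coefficient below one (negative apparent
cooperativity) even though no site-site interaction exists.

Concentrations are in µM throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InvalidModelError, NonIdentifiableError

__all__ = [
    "SiteModel",
    "PromoterBindingModel",
    "ConfigurationDistribution",
    "BandDistribution",
    "FitResult",
    "configuration_distribution",
    "band_distribution",
    "fractional_saturation",
    "apparent_hill_coefficient",
    "fit_single_site",
    "fit_multisite",
]

MAX_SITES = 8


@dataclass(frozen=True)
class SiteModel:
    """A single operator site with its dissociation constant in µM."""

    site_id: str
    kd: float

    def __post_init__(self) -> None:
        if not (self.kd > 0 and math.isfinite(self.kd)):
            raise InvalidModelError(
                f"site {self.site_id!r}: kd must be positive and finite, got {self.kd}"
            )


@dataclass(frozen=True)
class PromoterBindingModel:
    """Ordered operator sites plus optional pairwise coupling factors.

    ``coupling`` maps unordered site-id pairs to omega > 0; unspecified pairs
    default to 1 (independent sites).  ``omega > 1`` models positive
    cooperativity (the AbiEi-like case), ``omega < 1`` destabilizes joint
    occupancy.
    """

    sites: tuple[SiteModel, ...]
    coupling: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sites = tuple(self.sites)
        object.__setattr__(self, "sites", sites)
        if len(sites) > MAX_SITES:
            raise InvalidModelError(
                f"model must have at most {MAX_SITES} sites, got {len(sites)}"
            )
        # zero sites is permitted: it is the product of knocking out every
        # operator (polyC replacement of all repeats), a probe that never shifts
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise InvalidModelError(f"duplicate site ids: {ids}")
        norm: dict[frozenset, float] = {}
        for pair, omega in dict(self.coupling).items():
            key = frozenset(pair)
            if len(key) != 2 or not key <= set(ids):
                raise InvalidModelError(f"coupling pair {set(pair)} not among site ids")
            if not (omega > 0 and math.isfinite(omega)):
                raise InvalidModelError(f"omega for {set(pair)} must be > 0, got {omega}")
            if key in norm and norm[key] != omega:
                raise InvalidModelError(f"conflicting omega values for {set(pair)}")
            norm[key] = omega
        object.__setattr__(self, "coupling", norm)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    @property
    def kds(self) -> np.ndarray:
        return np.array([s.kd for s in self.sites], dtype=float)

    def omega(self, id_a: str, id_b: str) -> float:
        return self.coupling.get(frozenset((id_a, id_b)), 1.0)

    @classmethod
    def from_kds(
        cls,
        kds,
        site_ids=None,
        coupling: dict | None = None,
    ) -> "PromoterBindingModel":
        """Build a model from plain Kd values (µM), auto-naming sites S1..Sn."""
        kds = list(kds)
        if site_ids is None:
            site_ids = [f"S{i + 1}" for i in range(len(kds))]
        sites = tuple(SiteModel(sid, kd) for sid, kd in zip(site_ids, kds))
        return cls(sites=sites, coupling=coupling or {})


@dataclass(frozen=True)
class ConfigurationDistribution:
    """Probability of each of the ``2^n`` occupancy configurations at one concentration.

    Configuration ``k`` occupies site ``i`` iff bit ``i`` of ``k`` is set
    (site order as in the model).
    """

    probs: np.ndarray
    concentration: float
    site_ids: tuple[str, ...]

    def prob_of(self, occupied) -> float:
        """Probability of the configuration occupying exactly the given site ids."""
        occupied = set(occupied)
        idx = 0
        for i, sid in enumerate(self.site_ids):
            if sid in occupied:
                idx |= 1 << i
        unknown = occupied - set(self.site_ids)
        if unknown:
            raise InvalidModelError(f"unknown site ids {sorted(unknown)}")
        return float(self.probs[idx])


@dataclass(frozen=True)
class BandDistribution:
    """Probability that exactly ``k`` sites are bound, k = 0..n (gel band species)."""

    probs: np.ndarray
    concentration: float

    @property
    def n_sites(self) -> int:
        return len(self.probs) - 1

    def mean_occupancy(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)


@dataclass(frozen=True)
class FitResult:
    """Recovered dissociation constants (µM, ascending) and fit diagnostics."""

    kds: tuple[float, ...]
    residual: float
    n_evaluations: int

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.kds):
            raise InvalidModelError(f"fitted kds must be positive: {self.kds}")
        if self.residual < 0:
            raise InvalidModelError("residual must be >= 0")


def _check_conc(conc: float) -> float:
    conc = float(conc)
    if conc < 0 or not math.isfinite(conc):
        raise DomainError(f"concentration must be finite and >= 0, got {conc}")
    return conc


def _log_weights(model: PromoterBindingModel, conc: float) -> np.ndarray:
    """Log statistical weight of every configuration (bit-indexed)."""
    n = model.n_sites
    kds = model.kds
    with np.errstate(divide="ignore"):
        log_ratio = np.log(conc) - np.log(kds) if conc > 0 else np.full(n, -np.inf)
    ids = model.site_ids
    log_omega = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        log_omega[i, j] = math.log(model.omega(ids[i], ids[j]))
    logw = np.empty(2**n)
    for cfg in range(2**n):
        members = [i for i in range(n) if cfg >> i & 1]
        w = sum(log_ratio[i] for i in members)
        w += sum(log_omega[i][j] for i, j in itertools.combinations(members, 2))
        logw[cfg] = w
    return logw


def configuration_distribution(
    model: PromoterBindingModel, conc: float
) -> ConfigurationDistribution:
    """Equilibrium probability of every occupancy configuration at ``conc`` µM.

    Exhaustive enumeration of all ``2^n`` configurations; weights are handled
    in log space so extreme concentration/Kd ratios cannot overflow.
    """
    conc = _check_conc(conc)
    logw = _log_weights(model, conc)
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    return ConfigurationDistribution(
        probs=probs, concentration=conc, site_ids=model.site_ids
    )


def band_distribution(model: PromoterBindingModel, conc: float) -> BandDistribution:
    """Distribution of the number of occupied sites: the gel band species 0..n."""
    cfg = configuration_distribution(model, conc)
    n = model.n_sites
    counts = np.array([bin(k).count("1") for k in range(2**n)])
    probs = np.bincount(counts, weights=cfg.probs, minlength=n + 1)
    return BandDistribution(probs=probs, concentration=conc)


def fractional_saturation(model: PromoterBindingModel, conc: float) -> float:
    """Mean per-site occupancy Y = E[k]/n in [0, 1]; 0 at zero ligand, -> 1 at saturation."""
    if model.n_sites == 0:
        _check_conc(conc)
        return 0.0
    return band_distribution(model, conc).mean_occupancy() / model.n_sites


def _log10_theta(model: PromoterBindingModel, log10_conc: float) -> float:
    y = fractional_saturation(model, 10.0**log10_conc)
    return math.log10(y / (1.0 - y))


def apparent_hill_coefficient(model: PromoterBindingModel, y_tol: float = 1e-10) -> float:
    """Hill-plot slope d log10(Y/(1-Y)) / d log10(conc) at half saturation.

    The half-saturation concentration is located by bisection on log10
    concentration over ``[min(kd)/1e4, max(kd)*1e4]`` (Y is continuous and
    strictly increasing, so the root is bracketed), then the slope is taken
    by a central finite difference with step 1e-4 in log10 space.
    """
    if model.n_sites == 0:
        raise InvalidModelError("zero-site model has no half-saturation point")
    kds = model.kds
    lo = math.log10(kds.min()) - 4.0
    hi = math.log10(kds.max()) + 4.0
    f_lo = fractional_saturation(model, 10.0**lo) - 0.5
    f_hi = fractional_saturation(model, 10.0**hi) - 0.5
    # widen until bracketed (strong coupling can push c* outside the default window)
    while f_lo > 0:
        lo -= 4.0
        f_lo = fractional_saturation(model, 10.0**lo) - 0.5
    while f_hi < 0:
        hi += 4.0
        f_hi = fractional_saturation(model, 10.0**hi) - 0.5
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = fractional_saturation(model, 10.0**mid) - 0.5
        if abs(f_mid) < y_tol:
            break
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
    h = 1e-4
    return (_log10_theta(model, mid + h) - _log10_theta(model, mid - h)) / (2.0 * h)


def _multistart_log_kd(lo: float, hi: float, per_decade: float = 5.0) -> np.ndarray:
    """Deterministic log-spaced grid of starting log10-Kd values, ~5 per decade."""
    span = max(hi - lo, 1.0)
    n = max(5, int(math.ceil(per_decade * span)) + 1)
    return np.linspace(lo, hi, n)


def fit_single_site(curve) -> FitResult:
    """Least-squares fit of the one-site isotherm Y = c/(c + Kd) to a saturation curve.

    Kd is parameterized on a log10 scale; a deterministic multi-start grid of
    initial values spanning the titrated concentration range (±1 decade)
    guards against local minima.  Curves that never leave Y≈0 or Y≈1 are
    rejected as non-identifiable.
    """
    conc = np.asarray([p.concentration for p in curve.points], dtype=float)
    y = np.asarray([p.y for p in curve.points], dtype=float)
    if np.any(conc < 0):
        raise DomainError("concentrations must be >= 0")
    eps = 1e-9
    informative = (y > eps) & (y < 1.0 - eps) & (conc > 0)
    if informative.sum() < 3:
        raise NonIdentifiableError(
            "need >= 3 points with 0 < Y < 1 at positive concentration to fit Kd"
        )
    pos = conc > 0

    def resid(x: np.ndarray) -> np.ndarray:
        kd = 10.0 ** x[0]
        return conc[pos] / (conc[pos] + kd) - y[pos]

    lo = math.log10(conc[pos].min()) - 1.0
    hi = math.log10(conc[pos].max()) + 1.0
    best = None
    n_eval = 0
    for x0 in _multistart_log_kd(lo, hi):
        sol = least_squares(resid, x0=[x0], xtol=1e-15, ftol=1e-15, gtol=1e-15)
        n_eval += sol.nfev
        cost = float(np.sum(sol.fun**2))
        key = (cost, 10.0 ** sol.x[0])
        if best is None or key < best[0]:
            best = (key, sol)
    cost, sol = best[0][0], best[1]
    return FitResult(kds=(10.0 ** sol.x[0],), residual=cost, n_evaluations=n_eval)


def _independent_band_probs(kds: np.ndarray, conc: float) -> np.ndarray:
    """Band probabilities for omega = 1 via per-site occupancy convolution.

    Mathematically identical to :func:`band_distribution` on an uncoupled
    model (the enumeration is tested against this identity) but O(n^2)
    instead of O(2^n); used inside the fitting loop.
    """
    p = conc / (conc + kds)
    probs = np.array([1.0])
    for pi in p:
        probs = np.convolve(probs, [1.0 - pi, pi])
    return probs


def fit_multisite(table, n_sites: int) -> FitResult:
    """Global fit of per-site Kds to observed band fractions across a titration.

    Fits the independent-site (omega = 1) band distribution to the per-lane
    band fractions of a quantified gel by least squares over log10 Kds.
    The returned Kd multiset is sorted ascending (site labels are not
    identifiable from band counts alone).  Starts are a deterministic ladder
    of center x spread combinations in log space; ties broken by lowest
    residual, then lexicographically smallest sorted Kds.
    """
    lanes = table.lanes
    if not lanes or len(lanes[0].intensities) != n_sites + 1:
        raise NonIdentifiableError(
            f"table must have {n_sites + 1} band columns for an {n_sites}-site fit"
        )
    concs = np.array([ln.concentration for ln in lanes], dtype=float)
    n_distinct = len(np.unique(concs[concs > 0]))
    if n_distinct < 2 * n_sites:
        raise NonIdentifiableError(
            f"need >= {2 * n_sites} distinct positive concentrations, got {n_distinct}"
        )
    fracs = []
    use = []
    for ln in lanes:
        tot = float(np.sum(ln.intensities))
        if tot <= 0:
            continue
        use.append(ln.concentration)
        fracs.append(np.asarray(ln.intensities, dtype=float) / tot)
    use = np.array(use)
    fracs = np.array(fracs)

    def resid(x: np.ndarray) -> np.ndarray:
        kds = 10.0**x
        pred = np.array([_independent_band_probs(kds, c) for c in use])
        return (pred - fracs).ravel()

    pos = use > 0
    lo = math.log10(use[pos].min())
    hi = math.log10(use[pos].max())
    centers = np.linspace(lo, hi, 5)
    spreads = (0.0, 0.5, 1.0, 1.5, 2.0)
    best = None
    n_eval = 0
    for c0 in centers:
        for sp in spreads:
            x0 = c0 + (
                np.linspace(-sp, sp, n_sites) if n_sites > 1 else np.array([0.0])
            )
            sol = least_squares(resid, x0=x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
            n_eval += sol.nfev
            cost = float(np.sum(sol.fun**2))
            kds = tuple(sorted(10.0 ** sol.x))
            key = (cost, kds)
            if best is None or key < best[0]:
                best = (key, kds, cost)
    _, kds, cost = best
    return FitResult(kds=kds, residual=cost, n_evaluations=n_eval)
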