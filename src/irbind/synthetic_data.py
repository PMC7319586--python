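"""Seeded generators for every input the analysis pipeline consumes.

No raw gels or plate reads accompany the underlying study, so this module
is the package's data source: EMSA band tables sampled from a
:class:`~irbind.binding_model.PromoterBindingModel`, polyC-mutant probe
variants (site knockouts), promoter sequences with planted inverted
repeats, and kinetic reporter reads driven by promoter occupancy.

Noise models are explicit and seeded: band intensities receive independent
multiplicative lognormal factors (densitometry error keeps intensities
positive; default sigma 0.05, matching the few-percent spread of triplicate
gel quantification), OD420 time series receive additive Gaussian noise
(plate-reader error).  Identical seeds reproduce identical outputs
bit-for-bit, and every generator returns its ground truth alongside the
data so downstream tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding_model import PromoterBindingModel, band_distribution
from .errors import DesignError, InputError
from .hill_analysis import BandTable, Lane
from .ir_scanner import PromoterSequence, reverse_complement
from .reporter_assay import KineticPlateRead

__all__ = [
    "NoiseModel",
    "TitrationDesign",
    "simulate_emsa",
    "mutate_probe",
    "PlantedRepeat",
    "plant_inverted_repeats",
    "simulate_reporter",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal band noise with optional additive background.

    ``multiplicative_sigma`` is the standard deviation of the underlying
    normal, so each intensity is multiplied by exp(N(0, sigma^2)).
    """

    multiplicative_sigma: float = 0.05
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sigma < 0:
            raise InputError("multiplicative_sigma must be >= 0")
        if self.background < 0:
            raise InputError("background must be >= 0")


@dataclass(frozen=True)
class TitrationDesign:
    """Lane concentrations (µM, must include 0), replicate count and probe intensity."""

    concentrations: tuple[float, ...]
    replicates: int = 3
    total_probe_intensity: float = 1000.0

    def __post_init__(self) -> None:
        concs = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", concs)
        if 0.0 not in concs:
            raise InputError("design must include a zero-protein lane")
        if len(set(concs)) != len(concs):
            raise InputError("concentrations must be distinct")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if not self.total_probe_intensity > 0:
            raise InputError("total_probe_intensity must be > 0")

    @classmethod
    def log_spaced(
        cls,
        center_kd: float,
        decades: float = 2.0,
        n_lanes: int = 12,
        replicates: int = 3,
        total_probe_intensity: float = 1000.0,
    ) -> "TitrationDesign":
        """Zero lane plus ``n_lanes`` log-spaced concentrations spanning
        ``center_kd * 10^±decades`` (default: four decades around the Kd)."""
        concs = np.logspace(
            math.log10(center_kd) - decades, math.log10(center_kd) + decades, n_lanes
        )
        return cls(
            concentrations=(0.0, *concs),
            replicates=replicates,
            total_probe_intensity=total_probe_intensity,
        )


def simulate_emsa(
    model: PromoterBindingModel, design: TitrationDesign, noise: NoiseModel
) -> BandTable:
    """Sample a quantified EMSA titration from the occupancy model.

    Expected band intensities per lane are ``total_probe_intensity`` times
    the model's band distribution at that concentration; each intensity is
    then scaled by an independent lognormal factor and offset by the
    background.  With zero sigma and background the lane fractions equal
    the model distribution exactly.
    """
    rng = np.random.default_rng(noise.seed)
    lanes = []
    for conc in design.concentrations:
        expected = design.total_probe_intensity * band_distribution(model, conc).probs
        for rep in range(1, design.replicates + 1):
            factors = np.exp(rng.normal(0.0, noise.multiplicative_sigma, size=expected.shape)) \
                if noise.multiplicative_sigma > 0 else np.ones_like(expected)
            intensities = expected * factors + noise.background
            lanes.append(Lane(concentration=conc, intensities=tuple(intensities), replicate_id=rep))
    return BandTable(lanes=tuple(lanes))


def mutate_probe(model: PromoterBindingModel, knocked_out_sites: list[str]) -> PromoterBindingModel:
    """polyC-mutant probe: remove the named sites (their binding is ablated).

    Replacing an inverted repeat by a cytosine tract removes its binding
    event entirely, so knockouts are modeled as site deletion.  Order of
    the remaining sites and their couplings are preserved; knocking out
    every site yields a zero-site probe that never shifts.
    """
    ko = set(knocked_out_sites)
    unknown = ko - set(model.site_ids)
    if unknown:
        raise InputError(f"unknown site ids: {sorted(unknown)}")
    kept = tuple(s for s in model.sites if s.site_id not in ko)
    coupling = {
        pair: omega
        for pair, omega in model.coupling.items()
        if not (pair & ko)
    }
    return PromoterBindingModel(sites=kept, coupling=coupling)


@dataclass(frozen=True)
class PlantedRepeat:
    """Ground truth for one planted pair (1-based inclusive coordinates)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    arm_length: int
    spacer: int
    mutations: int


@dataclass(frozen=True)
class PlantPlan:
    arm_length: int
    spacer: int
    position: int  # 1-based left_start
    mutations: int = 0


def plant_inverted_repeats(
    length: int,
    plan: list[PlantPlan | dict],
    seed: int = 0,
    seq_id: str = "synthetic",
) -> tuple[PromoterSequence, list[PlantedRepeat]]:
    """Random promoter sequence with inverted-repeat pairs planted at known positions.

    Background bases are uniform-random; each planted pair writes a random
    left arm, the stated spacer, and the reverse complement of the left arm
    with the stated number of point mutations applied at distinct random
    positions of the right arm.  Placements may not overlap.  Returns the
    sequence and the ground-truth coordinates.
    """
    rng = np.random.default_rng(seed)
    plans = [p if isinstance(p, PlantPlan) else PlantPlan(**p) for p in plan]
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    occupied: list[tuple[int, int]] = []
    truth = []
    for p in plans:
        i0 = p.position - 1
        end0 = i0 + 2 * p.arm_length + p.spacer - 1
        if i0 < 0 or end0 >= length:
            raise DesignError(f"plan {p} does not fit in a {length} bp sequence")
        if any(i0 <= b and a <= end0 for a, b in occupied):
            raise DesignError(f"plan {p} overlaps a previous placement")
        occupied.append((i0, end0))
        left = rng.choice(bases, size=p.arm_length)
        right = np.array(list(reverse_complement("".join(left))))
        if p.mutations:
            pos = rng.choice(p.arm_length, size=p.mutations, replace=False)
            for q in pos:
                alternatives = [b for b in "ACGT" if b != right[q]]
                right[q] = alternatives[rng.integers(3)]
        seq[i0 : i0 + p.arm_length] = left
        j0 = i0 + p.arm_length + p.spacer
        seq[j0 : j0 + p.arm_length] = right
        truth.append(
            PlantedRepeat(
                left_start=i0 + 1,
                left_end=i0 + p.arm_length,
                right_start=j0 + 1,
                right_end=j0 + p.arm_length,
                arm_length=p.arm_length,
                spacer=p.spacer,
                mutations=p.mutations,
            )
        )
    return PromoterSequence(id=seq_id, sequence="".join(seq)), truth


def simulate_reporter(
    model: PromoterBindingModel,
    repressor_conc: float,
    basal_slope: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
    od600_first: float | None = None,
    times: tuple[float, ...] | None = None,
    well_id: str = "A1",
    **labels,
) -> KineticPlateRead:
    """Kinetic reporter read whose rate is gated by promoter occupancy.

    Transcription requires a fully unbound promoter, so the OD420 ramp is
    ``basal_slope * P(0 sites bound at repressor_conc)`` per minute, sampled
    at the plate-reader cadence (every 90 s for one hour by default) with
    additive Gaussian noise; OD600 at the first time point is drawn near 0.5.
    """
    if basal_slope < 0:
        raise InputError("basal_slope must be >= 0")
    rng = np.random.default_rng(seed)
    if times is None:
        times = tuple(np.arange(0.0, 60.0 + 1e-9, 1.5))  # minutes, 90 s cadence
    if model.n_sites:
        p_unbound = float(band_distribution(model, repressor_conc).probs[0])
    else:
        p_unbound = 1.0
    activity = basal_slope * p_unbound
    t = np.asarray(times)
    od420 = activity * t
    if noise_sd > 0:
        od420 = od420 + rng.normal(0.0, noise_sd, size=t.shape)
    od420 = np.maximum(od420, 0.0) if noise_sd == 0 else od420
    if od600_first is None:
        od600_first = float(rng.uniform(0.4, 0.6))
    return KineticPlateRead(
        well_id=well_id,
        times=tuple(t),
        od420=tuple(od420),
        od600_first=od600_first,
        **labels,
    )
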