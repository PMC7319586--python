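"""Reference parameter sets for the studied antitoxin-operator systems.

The Mycobacterium tuberculosis antitoxin Rv2827c represses its own
rv2827c-rv2826c operon through four tandem 23 bp inverted repeats (IR1-IR4)
upstream of the start codon; mutant-probe EMSA titrations place their
dissociation constants across almost three orders of magnitude, which is
what makes occupancy build up in ordered, ever-weaker steps (apparent
negative cooperativity).  The Streptococcus agalactiae homolog AbiEi
instead binds its two repeats with positive cooperativity, emulated here
with a coupling factor omega > 1.
"""

from __future__ import annotations

from .binding_model import PromoterBindingModel, SiteModel

__all__ = ["RV2827C_IR_KDS_UM", "rv2827c_promoter_model", "abiei_like_model"]

#: Per-repeat dissociation constants (µM) of Rv2827c for its four operators,
#: from single-repeat mutant-probe titrations; affinity order IR1 > IR4 > IR2 > IR3.
RV2827C_IR_KDS_UM: dict[str, float] = {
    "IR1": 0.0205,
    "IR2": 0.862,
    "IR3": 11.0,
    "IR4": 0.121,
}


def rv2827c_promoter_model() -> PromoterBindingModel:
    """Four independent operators (omega = 1) with the Rv2827c per-repeat affinities."""
    return PromoterBindingModel(
        sites=tuple(SiteModel(sid, kd) for sid, kd in RV2827C_IR_KDS_UM.items())
    )


def abiei_like_model(kd: float = 0.05, omega: float = 50.0) -> PromoterBindingModel:
    """Two equal operators with positive coupling: the positively cooperative contrast case."""
    return PromoterBindingModel(
        sites=(SiteModel("IR1", kd), SiteModel("IR2", kd)),
        coupling={frozenset(("IR1", "IR2")): omega},
    )
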