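"""Glycan derived traits: sums of relative abundances sharing a structural feature.

Sixteen traits summarize a glycan profile:

* ``man`` — oligomannose glycans (Man5-Man9; paucimannose is excluded);
* ``g0/g1/g2`` — neutral complex glycans with 0 / 1 / >=2 galactoses
  (sialylated glycans are implicitly galactosylated and hybrid hexoses are
  ambiguous between mannose and galactose, so both are excluded);
  ``g_total = g1 + g2`` (the galactosylated fraction);
* ``f_neutral/f_sialo/f_total`` — fucosylated glycans split by sialylation;
* ``b_neutral/b_sialo/b_total`` — bisecting-GlcNAc glycans split likewise;
* ``s1..s4`` — glycans carrying exactly k sialic acids; ``s_total`` their sum.

The trait groups overlap (one glycan can be simultaneously agalactosylated,
bisected and fucosylated), so traits are not a partition of 100%.  Each trait
is linear in the abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, Mapping, Sequence

import pandas as pd

from .glycan_core import GlycanAnnotation
from .spectra import GlycanProfile

__all__ = ["TraitProfile", "TRAIT_NAMES", "compute_traits", "traits_to_frame"]

TRAIT_NAMES = (
    "man", "g0", "g1", "g2", "g_total",
    "f_neutral", "f_sialo", "f_total",
    "b_neutral", "b_sialo", "b_total",
    "s1", "s2", "s3", "s4", "s_total",
)


@dataclass(frozen=True)
class TraitProfile:
    sample_id: str
    man: float
    g0: float
    g1: float
    g2: float
    g_total: float
    f_neutral: float
    f_sialo: float
    f_total: float
    b_neutral: float
    b_sialo: float
    b_total: float
    s1: float
    s2: float
    s3: float
    s4: float
    s_total: float

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "sample_id"}


def compute_traits(profile: GlycanProfile, annotations: Mapping[str, GlycanAnnotation]) -> TraitProfile:
    """Sum abundances into the sixteen derived traits.

    Every key present in the profile must have an annotation; an unknown key
    raises ``KeyError`` naming it.
    """
    t = {name: 0.0 for name in TRAIT_NAMES}
    for key, abundance in profile.abundances.items():
        if key not in annotations:
            raise KeyError(f"no structural annotation for glycan {key!r}")
        ann = annotations[key]
        c = ann.composition
        if ann.glycan_class == "oligomannose":
            t["man"] += abundance
        if 1 <= c.neu5ac <= 4:
            t[f"s{c.neu5ac}"] += abundance
        if c.neu5ac >= 1:
            t["s_total"] += abundance
        if c.dhex >= 1:
            t["f_sialo" if c.neu5ac >= 1 else "f_neutral"] += abundance
        if ann.bisected:
            t["b_sialo" if c.neu5ac >= 1 else "b_neutral"] += abundance
        if ann.glycan_class == "complex" and c.neu5ac == 0:
            if ann.galactoses == 0:
                t["g0"] += abundance
            elif ann.galactoses == 1:
                t["g1"] += abundance
            else:
                t["g2"] += abundance
    t["g_total"] = t["g1"] + t["g2"]
    t["f_total"] = t["f_neutral"] + t["f_sialo"]
    t["b_total"] = t["b_neutral"] + t["b_sialo"]
    return TraitProfile(sample_id=profile.sample_id, **t)


def traits_to_frame(traits: Sequence[TraitProfile]) -> pd.DataFrame:
    """Samples x traits matrix."""
    return pd.DataFrame([t.as_dict() for t in traits], index=[t.sample_id for t in traits])
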