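"""Glycan composition parsing, structural classification and mass computation.

Serum N-glycan compositions are written as compact keys such as ``H5N4S2F1``:
counts of hexose (H), N-acetylhexosamine (N), N-acetylneuraminic acid /
sialic acid (S) and deoxyhexose / fucose (F).  One key may cover several
structural isomers; structural attributes (oligomannose vs hybrid vs complex,
antenna count, bisecting GlcNAc, galactose count) are therefore carried in a
:class:`GlycanAnnotation`, either curated from a library table or inferred
from the composition with conservative fallback rules.

Masses are monoisotopic.  Sialylated glycans are assumed to be methylamidated
(each carboxyl group -COOH converted to -CONHCH3, i.e. -OH replaced by
-NHCH3) before MALDI analysis, which adds a fixed mass shift per sialic acid
and renders the glycans neutral and stable in positive-ion mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "GlycanComposition",
    "GlycanAnnotation",
    "MassConfig",
    "parse_composition",
    "render_composition",
    "neutral_mass",
    "theoretical_mz",
    "classify_structure",
    "MONOISOTOPIC_RESIDUES",
    "WATER_MASS",
    "PROTON_MASS",
    "SODIUM_MASS",
    "ELECTRON_MASS",
    "METHYLAMIDATION_SHIFT",
]

# Monoisotopic residue masses (Da), i.e. the monosaccharide minus one water,
# from CODATA/IUPAC atomic masses: H 1.00782503207, C 12, N 14.0030740048,
# O 15.9949146196.
MONOISOTOPIC_RESIDUES: Mapping[str, float] = {
    "hex": 162.0528234187,      # C6H10O5
    "hexnac": 203.0793725197,   # C8H13NO5
    "dhex": 146.0579087991,     # C6H10O4
    "neu5ac": 291.0954165068,   # C11H17NO8
}

WATER_MASS = 18.0105646837
PROTON_MASS = 1.00727646688
SODIUM_MASS = 22.9897692809
ELECTRON_MASS = 0.00054857990907

# -OH -> -NHCH3 on each sialic acid carboxyl: +(N + C + 4H) - (O + H).
METHYLAMIDATION_SHIFT = 13.0316344814


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan composition."""

    hex: int = 0
    hexnac: int = 0
    neu5ac: int = 0
    dhex: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "neu5ac", "dhex"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")

    @property
    def key(self) -> str:
        return render_composition(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


@dataclass(frozen=True)
class GlycanAnnotation:
    """Structural attributes attached to a composition.

    ``glycan_class`` is one of ``oligomannose``, ``hybrid``, ``complex`` or
    ``other`` (paucimannose and compositions that fit no class).  ``source``
    records whether the annotation came from a curated library (``curated``)
    or from the composition-based fallback rules (``inferred``).
    """

    composition: GlycanComposition
    glycan_class: str
    antennae: int = 0
    bisected: bool = False
    galactoses: int = 0
    source: str = "inferred"

    def __post_init__(self) -> None:
        if self.glycan_class not in ("oligomannose", "hybrid", "complex", "other"):
            raise ValueError(f"unknown glycan class {self.glycan_class!r}")
        if self.glycan_class == "oligomannose":
            c = self.composition
            if c.neu5ac or c.dhex or self.antennae or self.bisected:
                raise ValueError(f"invalid oligomannose annotation for {c.key}")
        if self.bisected and (self.glycan_class != "complex" or self.composition.hexnac < 5):
            raise ValueError(f"bisection requires a complex glycan with >=5 HexNAc ({self.composition.key})")
        if self.glycan_class == "complex" and self.galactoses > self.antennae:
            raise ValueError(f"galactoses exceed antennae for {self.composition.key}")

    @property
    def key(self) -> str:
        return self.composition.key

    @property
    def is_sialylated(self) -> bool:
        return self.composition.neu5ac > 0

    @property
    def is_fucosylated(self) -> bool:
        return self.composition.dhex > 0


@dataclass(frozen=True)
class MassConfig:
    """Derivatization and adduct settings for theoretical m/z computation.

    The default reflects the profiling workflow: methylamidated sialic acids,
    singly sodiated ions ([M+Na]+) in positive reflector mode.  The adduct
    mass subtracts one electron mass for a singly charged cation; the
    difference (~0.0005 Da) is far below matching tolerances but the
    convention is explicit and tested.
    """

    derivatization: str = "methylamidation"
    adduct: str = "sodium"
    residue_masses: Mapping[str, float] = field(default_factory=lambda: dict(MONOISOTOPIC_RESIDUES))
    water_mass: float = WATER_MASS
    methylamidation_shift: float = METHYLAMIDATION_SHIFT

    def __post_init__(self) -> None:
        if self.derivatization not in ("none", "methylamidation"):
            raise ValueError(f"unknown derivatization {self.derivatization!r}")
        if self.adduct not in ("proton", "sodium"):
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if any(m <= 0 for m in self.residue_masses.values()) or self.water_mass <= 0:
            raise ValueError("residue and water masses must be positive")

    @property
    def adduct_mass(self) -> float:
        base = SODIUM_MASS if self.adduct == "sodium" else PROTON_MASS
        if self.adduct == "sodium":
            base -= ELECTRON_MASS
        # PROTON_MASS is already the H+ cation mass (electron excluded).
        return base


_KEY_RE = re.compile(r"([HNSF])(\d+)")


def parse_composition(key: str) -> GlycanComposition:
    """Parse a composition key like ``H5N4S2F1`` into monosaccharide counts.

    Letters may appear in any order; omitted letters mean a count of zero.
    H (hexose) and N (HexNAc) are required.  Raises ``ValueError`` naming the
    offending token on malformed input.
    """
    if not isinstance(key, str) or not key.strip():
        raise ValueError(f"empty composition key: {key!r}")
    s = key.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _KEY_RE.finditer(s):
        if m.start() != pos:
            raise ValueError(f"malformed composition key {key!r}: unexpected token {s[pos:m.start()]!r}")
        letter = m.group(1)
        if letter in counts:
            raise ValueError(f"malformed composition key {key!r}: duplicate letter {letter!r}")
        counts[letter] = int(m.group(2))
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"malformed composition key {key!r}: unexpected token {s[pos:]!r}")
    if "H" not in counts or "N" not in counts:
        raise ValueError(f"malformed composition key {key!r}: H and N counts are required")
    return GlycanComposition(
        hex=counts["H"],
        hexnac=counts["N"],
        neu5ac=counts.get("S", 0),
        dhex=counts.get("F", 0),
    )


def render_composition(c: GlycanComposition) -> str:
    """Canonical key ``H{h}N{n}[S{s}][F{f}]``, omitting zero terms for S/F."""
    out = f"H{c.hex}N{c.hexnac}"
    if c.neu5ac:
        out += f"S{c.neu5ac}"
    if c.dhex:
        out += f"F{c.dhex}"
    return out


def neutral_mass(c: GlycanComposition, cfg: MassConfig = MassConfig()) -> float:
    """Monoisotopic neutral mass (Da) of the (optionally derivatized) glycan."""
    r = cfg.residue_masses
    mass = (
        c.hex * r["hex"]
        + c.hexnac * r["hexnac"]
        + c.dhex * r["dhex"]
        + c.neu5ac * r["neu5ac"]
        + cfg.water_mass
    )
    if cfg.derivatization == "methylamidation":
        mass += c.neu5ac * cfg.methylamidation_shift
    return mass


def theoretical_mz(c: GlycanComposition, cfg: MassConfig = MassConfig()) -> float:
    """m/z of the singly charged adduct ion ([M+Na]+ by default)."""
    return neutral_mass(c, cfg) + cfg.adduct_mass


def classify_structure(
    c: GlycanComposition,
    curated: Optional[Mapping[str, GlycanAnnotation]] = None,
) -> GlycanAnnotation:
    """Assign a structural annotation to a composition.

    A curated table (key -> annotation) always wins.  Otherwise fallback
    rules are applied:

    * oligomannose: two core GlcNAcs, >=5 hexoses, no sialic acid or fucose;
    * hybrid: exactly three HexNAc and >=5 hexoses (one processed antenna
      plus unprocessed mannose arm);
    * paucimannose / unclassifiable two-HexNAc compositions -> ``other``;
    * everything else is complex.  A bisecting GlcNAc is inferred when the
      HexNAc count exceeds what the hexoses could plausibly decorate
      (hexnac >= 5 and hex - 3 < hexnac - 2); antennae = hexnac - 2 minus the
      bisecting residue; galactoses = min(max(hex - 3, 0), antennae).

    Bisection is not decidable from composition alone, so curated entries
    (structures confirmed by orthogonal LC-MS/MS evidence) should be supplied
    for any glycan where the inference matters.
    """
    key = render_composition(c)
    if curated and key in curated:
        ann = curated[key]
        if ann.composition != c:
            raise ValueError(f"curated annotation for {key} has mismatched composition")
        return ann if ann.source == "curated" else replace(ann, source="curated")
    if c.hexnac < 2:
        raise ValueError(f"{key} is not an N-glycan (needs >=2 HexNAc for the chitobiose core)")
    if c.hexnac == 2:
        if c.hex >= 5 and c.neu5ac == 0 and c.dhex == 0:
            return GlycanAnnotation(c, "oligomannose")
        # paucimannose (H3N2/H4N2) or decorated two-HexNAc oddities
        return GlycanAnnotation(c, "other")
    if c.hexnac == 3 and c.hex >= 5:
        return GlycanAnnotation(c, "hybrid", antennae=1)
    bisected = c.hexnac >= 5 and (c.hex - 3) < (c.hexnac - 2)
    antennae = c.hexnac - 2 - (1 if bisected else 0)
    galactoses = min(max(c.hex - 3, 0), antennae)
    return GlycanAnnotation(c, "complex", antennae=antennae, bisected=bisected, galactoses=galactoses)
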