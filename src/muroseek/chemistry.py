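"""Muropeptide structure grammar and monoisotopic mass calculation.

Muropeptides are named in gm-notation: each disaccharide subunit is written
as a ``gm-`` prefix (g = GlcNAc, m = MurNAc) followed by the one-letter codes
of its peptide stem, cross-linked subunits are joined with ``=``, and
structure-level modifications are appended as ``(Anh)`` (1,6-anhydroMurNAc)
and ``(-Ac)`` (sugar deacetylation).  Examples::

    gm-AEJA                  disaccharide-tetrapeptide monomer
    gm-AEJ_NH2=gm-A          1-3 cross-linked dimer with a single-Ala donor
    gm-AEJA=gm-AEJA (Anh)    dimer carrying one anhydroMurNAc chain terminus

Masses are neutral monoisotopic masses in Da.  MurNAc residues are assumed
borohydride-reduced (muramitol, +2 H) except where an anhydro ring replaces
the reduction; this matches the standard sample preparation in which soluble
muropeptides are reduced before LC-MS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

__all__ = [
    "WATER",
    "PROTON",
    "AMIDATION_DELTA",
    "DEACETYLATION_DELTA",
    "REDUCTION_DELTA",
    "ANHYDRO_DELTA",
    "ADDUCT_DELTAS",
    "RESIDUE_MASSES",
    "GLYCAN_MASSES",
    "X_ALPHABET",
    "GlycanUnit",
    "Subunit",
    "Muropeptide",
    "MuropeptideParseError",
    "parse_muropeptide",
    "canonical_name",
    "monoisotopic_mass",
    "stem_fragment_masses",
]

# -- mass constants (monoisotopic, Da) --------------------------------------

WATER = 18.010565
PROTON = 1.007276
#: COOH -> CONH2 on the meso-DAP side chain.
AMIDATION_DELTA = -0.984016
#: loss of the N-acetyl group (ketene, C2H2O) from GlcNAc or MurNAc.
DEACETYLATION_DELTA = -42.010565
#: reduction of MurNAc to muramitol (+2 H) by sodium borohydride.
REDUCTION_DELTA = 2.015650
#: 1,6-anhydro ring: loss of water relative to non-reduced MurNAc.
ANHYDRO_DELTA = -WATER
#: replacing H by the metal cation on a neutral molecule.
ADDUCT_DELTAS = {"Na": 21.981944, "K": 37.955882}

#: Residue (dehydrated) monoisotopic masses.  J is meso-diaminopimelic acid;
#: J_NH2 its side-chain amidated form; E denotes iso-glutamic acid
#: (gamma-linked) which is mass-identical to Glu.
RESIDUE_MASSES: Dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
    "J": 172.084793,
}
RESIDUE_MASSES["J_NH2"] = RESIDUE_MASSES["J"] + AMIDATION_DELTA

#: Glycan residue (dehydrated) monoisotopic masses.
GLYCAN_MASSES = {"GlcNAc": 203.079373, "MurNAc": 275.100502}

#: Default expansion of an "X" (any amino acid) stem position: the 19
#: standard residues distinguishable by mass (Leu is isobaric with Ile and
#: therefore not listed separately).
X_ALPHABET: Tuple[str, ...] = tuple(
    c for c in "ACDEFGHIKMNPQRSTVWY"
)

#: Codes accepted in stems but normalized at parse time.
_ALIASES = {"Z": "J_NH2"}

_DAP_CODES = frozenset({"J", "J_NH2"})


class MuropeptideParseError(ValueError):
    """Raised when a gm-notation name cannot be parsed."""


@dataclass(frozen=True)
class GlycanUnit:
    """One glycan residue of a disaccharide subunit.

    ``reduced`` marks borohydride-reduced MurNAc (muramitol); ``anhydro``
    the 1,6-anhydro ring found at glycan chain termini.  The two are
    mutually exclusive and anhydro occurs on MurNAc only.
    """

    kind: str  # "GlcNAc" | "MurNAc"
    reduced: bool = False
    anhydro: bool = False
    deacetylated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in GLYCAN_MASSES:
            raise ValueError(f"unknown glycan kind {self.kind!r}")
        if self.reduced and self.anhydro:
            raise ValueError("a glycan unit cannot be both reduced and anhydro")
        if self.anhydro and self.kind != "MurNAc":
            raise ValueError("1,6-anhydro ring occurs on MurNAc only")

    @property
    def mass(self) -> float:
        m = GLYCAN_MASSES[self.kind]
        if self.reduced:
            m += REDUCTION_DELTA
        if self.anhydro:
            m += ANHYDRO_DELTA
        if self.deacetylated:
            m += DEACETYLATION_DELTA
        return m


@dataclass(frozen=True)
class Subunit:
    """A disaccharide (GlcNAc-MurNAc) carrying one peptide stem."""

    stem: Tuple[str, ...]
    glycans: Tuple[GlycanUnit, ...] = field(
        default=(GlycanUnit("GlcNAc"), GlycanUnit("MurNAc", reduced=True))
    )

    def __post_init__(self) -> None:
        if not self.stem:
            raise ValueError("peptide stem must be non-empty")
        for code in self.stem:
            if code not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue code {code!r}")


@dataclass(frozen=True)
class Muropeptide:
    """A parsed muropeptide: up to three cross-linked disaccharide-peptides.

    Modifications are recorded at the whole-structure level ("Anh", "DeAc"),
    as the notation does not localize them to a subunit; mass is identical
    for any placement.  At most one anhydro ring per structure (it marks a
    chain terminus), replacing the reduced MurNAc of one subunit.
    """

    subunits: Tuple[Subunit, ...]
    modifications: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 1 <= len(self.subunits) <= 3:
            raise ValueError("a muropeptide has 1 to 3 subunits")
        bad = set(self.modifications) - {"Anh", "DeAc"}
        if bad:
            raise ValueError(f"unknown modifications: {sorted(bad)}")

    @property
    def crosslink_count(self) -> int:
        return len(self.subunits) - 1

    @property
    def level(self) -> str:
        return ("monomer", "dimer", "trimer")[len(self.subunits) - 1]

    @property
    def amidated(self) -> bool:
        return any("J_NH2" in su.stem for su in self.subunits)

    @property
    def name(self) -> str:
        return canonical_name(self)


def _tokenize_stem(text: str, context: str) -> Tuple[str, ...]:
    tokens = []
    i = 0
    while i < len(text):
        if text.startswith("J_NH2", i):
            tokens.append("J_NH2")
            i += 5
            continue
        c = text[i]
        if c in _ALIASES:
            tokens.append(_ALIASES[c])
        elif c in RESIDUE_MASSES:
            tokens.append(c)
        else:
            raise MuropeptideParseError(
                f"unknown residue code {text[i:]!r} in {context!r}"
            )
        i += 1
    return tuple(tokens)


def parse_muropeptide(name: str) -> Muropeptide:
    """Parse a gm-notation name into a :class:`Muropeptide`.

    ``=`` separates cross-linked subunits; trailing ``(Anh)`` / ``(-Ac)``
    set structure-level modification flags; ``Z`` is accepted as an alias
    for amidated meso-DAP (``J_NH2``).
    """
    if not name or not name.strip():
        raise MuropeptideParseError("empty muropeptide name")
    text = " ".join(name.split())
    mods = set()
    changed = True
    while changed:
        changed = False
        for suffix, mod in ((" (Anh)", "Anh"), (" (-Ac)", "DeAc"),
                            ("(Anh)", "Anh"), ("(-Ac)", "DeAc")):
            if text.endswith(suffix):
                if mod in mods:
                    raise MuropeptideParseError(
                        f"duplicate modification {mod!r} in {name!r}"
                    )
                mods.add(mod)
                text = text[: -len(suffix)].rstrip()
                changed = True
    parts = text.split("=")
    if len(parts) > 3:
        raise MuropeptideParseError(
            f"{name!r} has {len(parts)} subunits; at most 3 are supported"
        )
    subunits = []
    for part in parts:
        part = part.strip()
        lowered = part[:3].lower()
        if lowered != "gm-":
            raise MuropeptideParseError(
                f"malformed glycan prefix in subunit {part!r} "
                "(expected 'gm-')"
            )
        stem_text = part[3:]
        if not stem_text:
            raise MuropeptideParseError(f"empty peptide stem in {part!r}")
        subunits.append(Subunit(stem=_tokenize_stem(stem_text, part)))
    return Muropeptide(subunits=tuple(subunits), modifications=frozenset(mods))


def canonical_name(m: Muropeptide) -> str:
    """Serialize a muropeptide back to its canonical gm-notation name."""
    body = "=".join("gm-" + "".join(su.stem) for su in m.subunits)
    if "Anh" in m.modifications:
        body += " (Anh)"
    if "DeAc" in m.modifications:
        body += " (-Ac)"
    return body


def monoisotopic_mass(m: Muropeptide) -> float:
    """Neutral monoisotopic mass of a muropeptide, in Da.

    Each subunit contributes its glycan and stem residue masses plus one
    water (condensation closure); each cross-link removes one water.  One
    reduced MurNAc per subunit is assumed, except that an ``Anh``
    modification converts one MurNAc to the (non-reduced) 1,6-anhydro form.
    ``DeAc`` removes one acetyl group.
    """
    total = 0.0
    for su in m.subunits:
        total += sum(g.mass for g in su.glycans)
        total += sum(RESIDUE_MASSES[c] for c in su.stem)
        total += WATER
    total -= m.crosslink_count * WATER
    if "Anh" in m.modifications:
        # reduced MurNAc -> 1,6-anhydroMurNAc
        total += ANHYDRO_DELTA - REDUCTION_DELTA
    if "DeAc" in m.modifications:
        total += DEACETYLATION_DELTA
    return total


def mass_of(name: str) -> float:
    """Convenience: parse a name and return its monoisotopic mass."""
    return monoisotopic_mass(parse_muropeptide(name))


def stem_fragment_masses(stem: Sequence[str]) -> Dict[str, float]:
    """Singly protonated b/y fragment ion masses of a peptide stem.

    For a stem of n residues returns the 2(n-1) fragments ``b1..b(n-1)``
    and ``y1..y(n-1)``: b_i is the N-terminal acylium series (residue sum +
    proton), y_i the C-terminal series (residue sum + water + proton).
    A stem shorter than two residues yields no fragments.
    """
    stem = tuple(stem)
    for code in stem:
        if code not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue code {code!r}")
    n = len(stem)
    if n < 2:
        return {}
    frags: Dict[str, float] = {}
    for i in range(1, n):
        frags[f"b{i}"] = sum(RESIDUE_MASSES[c] for c in stem[:i]) + PROTON
        frags[f"y{i}"] = sum(RESIDUE_MASSES[c] for c in stem[-i:]) + WATER + PROTON
    return frags
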