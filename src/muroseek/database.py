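"""Theoretical search-space construction.

Three stages mirror the two-step muropeptide search strategy:

1. :func:`enumerate_monomer_space` produces the candidate monomer stems a
   tandem-MS validation step would score (positional residue constraints,
   ``X`` wildcard positions).
2. :func:`load_monomer_db` reads a curated monomer database (DB0) of
   validated structures from CSV.
3. :func:`build_multimers` dynamically generates dimers and trimers from
   DB0 monomers under configurable cross-link chemistry (4-3, 3-3 and the
   non-canonical 1-3 bond whose donor is a single-alanine stem), plus
   anhydro / deacetyl modification variants.

Cross-link chemistry encoded here: the acceptor of every bond is the
side-chain amine of a meso-DAP (J or J_NH2) at stem position 3.  The bond
forms from a donor carboxyl that must be C-terminal in the cross-linked
product, so donors are exactly tetrapeptide stems (4-3, via position-4
D-Ala), tripeptide stems with unamidated DAP (3-3; amidation occupies the
bonding carboxyl), or the lone alanine of a single-residue stem (1-3).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import chemistry
from .chemistry import (
    Muropeptide,
    MuropeptideParseError,
    Subunit,
    X_ALPHABET,
    canonical_name,
    monoisotopic_mass,
    parse_muropeptide,
)

__all__ = [
    "TheoreticalEntry",
    "CrosslinkRules",
    "MonomerDBError",
    "enumerate_monomer_space",
    "gluconobacter_monomer_space",
    "load_monomer_db",
    "build_multimers",
    "build_database",
    "write_database",
    "read_database",
]

CROSSLINK_TYPES = ("4-3", "3-3", "1-3")

#: isobaric grouping width, Da
_MERGE_TOL = 1e-4


@dataclass(frozen=True)
class TheoreticalEntry:
    """One searchable mass of the theoretical database.

    Isobaric structures (masses within 1e-4 Da) are grouped under a single
    entry; ``names`` retains every gm-notation name, ``name`` the first.
    """

    names: Tuple[str, ...]
    mass: float
    level: str  # monomer | dimer | trimer
    crosslink_types: FrozenSet[str] = frozenset()
    anhydro: bool = False
    deacetyl: bool = False
    amidated: bool = False
    warning: Optional[str] = None

    @property
    def name(self) -> str:
        return self.names[0]


@dataclass(frozen=True)
class CrosslinkRules:
    """Which multimer chemistry to enumerate.

    ``restrict_1_3_to_gmA`` limits 1-3 donors to the plain ``gm-A``
    monomer (no glycan modifications), the conservative setting used when
    probing a peptidoglycan for heterologously introduced 1-3 activity.
    """

    enabled: FrozenSet[str] = frozenset(CROSSLINK_TYPES)
    restrict_1_3_to_gmA: bool = False
    max_level: int = 3

    def __post_init__(self) -> None:
        bad = set(self.enabled) - set(CROSSLINK_TYPES)
        if bad:
            raise ValueError(f"unknown cross-link types: {sorted(bad)}")
        if self.max_level not in (1, 2, 3):
            raise ValueError("max_level must be 1, 2 or 3")


class MonomerDBError(ValueError):
    """Raised when a monomer CSV cannot be loaded."""


# ---------------------------------------------------------------------------
# candidate monomer enumeration


def enumerate_monomer_space(
    position_choices: Mapping[int, Sequence[str]],
    lengths: Iterable[int],
    x_alphabet: Sequence[str] = X_ALPHABET,
    penta_cterm: Optional[Sequence[str]] = None,
) -> List[Muropeptide]:
    """Enumerate candidate disaccharide-peptide monomers.

    Parameters
    ----------
    position_choices
        Allowed residue codes per stem position (1-based).  The wildcard
        ``"X"`` expands to ``x_alphabet``.
    lengths
        Stem lengths to emit (subset of 1..5).
    x_alphabet
        Expansion of the ``X`` wildcard; must be non-empty if used.
    penta_cterm
        Optional override for positions 4-5 of pentapeptides, e.g.
        ``["A", "X"]`` for stems ending in an Ala-X dipeptide.

    Returns
    -------
    list of Muropeptide
        Unique gm- monomers in deterministic enumeration order.
    """

    def expand(codes: Sequence[str]) -> List[str]:
        out: List[str] = []
        for c in codes:
            if c == "X":
                if not x_alphabet:
                    raise ValueError("empty alphabet for an X position")
                out.extend(x_alphabet)
            else:
                out.append("J_NH2" if c == "Z" else c)
        # dedupe, preserve order
        return list(dict.fromkeys(out))

    seen = set()
    result: List[Muropeptide] = []
    for length in sorted(set(lengths)):
        if not 1 <= length <= 5:
            raise ValueError(f"stem length {length} outside 1..5")
        per_pos: List[List[str]] = []
        ok = True
        for pos in range(1, length + 1):
            if penta_cterm is not None and length == 5 and pos >= 4:
                per_pos.append(expand([penta_cterm[pos - 4]]))
                continue
            choices = position_choices.get(pos)
            if not choices:
                ok = False
                break
            per_pos.append(expand(choices))
        if not ok:
            continue
        stems = [()]
        for choices in per_pos:
            stems = [s + (c,) for s in stems for c in choices]
        for stem in stems:
            m = Muropeptide(subunits=(Subunit(stem=stem),))
            key = canonical_name(m)
            if key not in seen:
                seen.add(key)
                result.append(m)
    return result


def gluconobacter_monomer_space() -> List[Muropeptide]:
    """The candidate monomer space used for G. oxydans B58.

    Mono- to pentapeptide stems with Ala in position 1, Glu/Gln in
    position 2, meso-DAP or amidated meso-DAP in position 3, any amino acid
    in position 4, and pentapeptides ending in an Ala-X dipeptide.
    """
    return enumerate_monomer_space(
        {1: ["A"], 2: ["E", "Q"], 3: ["J", "Z"], 4: ["X"]},
        lengths=range(1, 6),
        penta_cterm=["A", "X"],
    )


# ---------------------------------------------------------------------------
# curated monomer databases


def _entry_from_muropeptide(
    m: Muropeptide,
    crosslink_types: FrozenSet[str] = frozenset(),
    warning: Optional[str] = None,
) -> TheoreticalEntry:
    return TheoreticalEntry(
        names=(canonical_name(m),),
        mass=monoisotopic_mass(m),
        level=m.level,
        crosslink_types=crosslink_types,
        anhydro="Anh" in m.modifications,
        deacetyl="DeAc" in m.modifications,
        amidated=m.amidated,
        warning=warning,
    )


def load_monomer_db(path: str | Path) -> List[TheoreticalEntry]:
    """Load a curated monomer database from CSV.

    Expected columns: ``Structure`` (gm-notation name, required) and
    optionally ``Mass``.  Masses are always recomputed from the structure;
    if a supplied mass disagrees by more than 1e-3 Da the entry is loaded
    with a ``warning`` attached.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MonomerDBError(f"{path}: empty file (header required)")
        cols = {c.strip().lower(): i for i, c in enumerate(header)}
        if "structure" not in cols:
            raise MonomerDBError(f"{path}: missing required column 'Structure'")
        s_i = cols["structure"]
        m_i = cols.get("mass")
        entries: List[TheoreticalEntry] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            name = row[s_i].strip()
            try:
                m = parse_muropeptide(name)
            except MuropeptideParseError as exc:
                raise MonomerDBError(f"{path}:{lineno}: {exc}") from exc
            if m.crosslink_count:
                raise MonomerDBError(
                    f"{path}:{lineno}: {name!r} is not a monomer"
                )
            warning = None
            if m_i is not None and m_i < len(row) and row[m_i].strip():
                try:
                    stated = float(row[m_i])
                except ValueError:
                    raise MonomerDBError(
                        f"{path}:{lineno}: non-numeric mass {row[m_i]!r}"
                    )
                computed = monoisotopic_mass(m)
                if abs(stated - computed) > 1e-3:
                    warning = (
                        f"stated mass {stated:.4f} disagrees with computed "
                        f"{computed:.4f}"
                    )
            entries.append(_entry_from_muropeptide(m, warning=warning))
    return entries


# ---------------------------------------------------------------------------
# dynamic multimer generation


def _strip_modifications(m: Muropeptide) -> Muropeptide:
    return replace(m, modifications=frozenset())


def _donor_types(m: Muropeptide, rules: CrosslinkRules) -> FrozenSet[str]:
    """Cross-link types a monomer can donate under the given rules."""
    stem = m.subunits[0].stem
    types = set()
    if "1-3" in rules.enabled and stem == ("A",):
        if not (rules.restrict_1_3_to_gmA and canonical_name(m) != "gm-A"):
            types.add("1-3")
    # The donating carboxyl must be the stem's C-terminus, so donors are
    # exactly tripeptides (3-3) or tetrapeptides (4-3).  Amidation (J_NH2)
    # occupies the DAP carboxyl, so only unamidated J can donate a 3-3 bond.
    if "3-3" in rules.enabled and len(stem) == 3 and stem[2] == "J":
        types.add("3-3")
    if "4-3" in rules.enabled and len(stem) == 4:
        types.add("4-3")
    return frozenset(types)


def _is_acceptor(m: Muropeptide) -> bool:
    stem = m.subunits[0].stem
    return len(stem) >= 3 and stem[2] in ("J", "J_NH2")


def _merge_isobars(entries: List[TheoreticalEntry]) -> List[TheoreticalEntry]:
    """Group entries whose masses coincide within 1e-4 Da."""
    entries = sorted(entries, key=lambda e: (e.mass, e.name))
    merged: List[TheoreticalEntry] = []
    for e in entries:
        if merged and abs(e.mass - merged[-1].mass) <= _MERGE_TOL:
            prev = merged[-1]
            names = prev.names + tuple(n for n in e.names if n not in prev.names)
            merged[-1] = TheoreticalEntry(
                names=names,
                mass=prev.mass,
                level=prev.level,
                crosslink_types=prev.crosslink_types | e.crosslink_types,
                anhydro=prev.anhydro or e.anhydro,
                deacetyl=prev.deacetyl or e.deacetyl,
                amidated=prev.amidated or e.amidated,
                warning=prev.warning or e.warning,
            )
        else:
            merged.append(e)
    return merged


def _mod_variants(m: Muropeptide, modifications: FrozenSet[str]
                  ) -> List[Muropeptide]:
    """The structure itself plus its enabled modification variants."""
    out = [m]
    if "Anh" in modifications and "Anh" not in m.modifications:
        out.append(replace(m, modifications=m.modifications | {"Anh"}))
    if "DeAc" in modifications and "DeAc" not in m.modifications:
        out.extend(
            replace(v, modifications=v.modifications | {"DeAc"}) for v in list(out)
        )
    return out


def build_multimers(
    monomers: Sequence[Muropeptide | str],
    rules: CrosslinkRules,
    modifications: FrozenSet[str] = frozenset({"Anh", "DeAc"}),
) -> List[TheoreticalEntry]:
    """Generate the dimer/trimer search space from a set of monomers.

    Multimers are assembled from the unmodified core of each input monomer;
    modification variants (at most one anhydro ring and one deacetylation
    per structure) are then emitted per ``modifications``.  Names are
    written acceptor-first (``acceptor=donor``, the rightmost subunit being
    the donor); trimers chain two bonds through a middle subunit that both
    accepts and donates.  Isobaric products are merged into single entries.
    """
    parsed = [
        parse_muropeptide(m) if isinstance(m, str) else m for m in monomers
    ]
    # unmodified building blocks, deduplicated; keep original (possibly
    # modified) forms too for 1-3 donor restriction checks
    bases: Dict[str, Muropeptide] = {}
    for m in parsed:
        b = _strip_modifications(m)
        bases.setdefault(canonical_name(b), b)
    blocks = list(bases.values())

    entries: List[TheoreticalEntry] = []
    if rules.max_level < 2:
        return entries

    acceptors = [b for b in blocks if _is_acceptor(b)]
    donors = [(b, _donor_types(b, rules)) for b in blocks]
    donors = [(b, t) for b, t in donors if t]

    dimers: List[Tuple[Muropeptide, FrozenSet[str], Muropeptide, Muropeptide]] = []
    for acc in acceptors:
        for don, types in donors:
            dimer = Muropeptide(subunits=acc.subunits + don.subunits)
            dimers.append((dimer, types, acc, don))

    for dimer, types, _, _ in dimers:
        for variant in _mod_variants(dimer, modifications):
            entries.append(
                _entry_from_muropeptide(variant, crosslink_types=types)
            )

    if rules.max_level >= 3:
        # X=Y=Z: Y accepts from Z and donates to X; no branching (one DAP
        # accepts at most one bond).
        mid_donors = {canonical_name(d): t for d, t in donors if _is_acceptor(d)}
        for outer in acceptors:
            for mid_name, mid_types in mid_donors.items():
                mid = bases[mid_name]
                for don, dtypes in donors:
                    trimer = Muropeptide(
                        subunits=outer.subunits + mid.subunits + don.subunits
                    )
                    for variant in _mod_variants(trimer, modifications):
                        entries.append(
                            _entry_from_muropeptide(
                                variant, crosslink_types=mid_types | dtypes
                            )
                        )

    return _merge_isobars(entries)


def build_database(
    monomers: Sequence[TheoreticalEntry | Muropeptide | str],
    rules: CrosslinkRules,
    modifications: FrozenSet[str] = frozenset({"Anh", "DeAc"}),
) -> List[TheoreticalEntry]:
    """Full search database: monomers, their modification variants, and the
    dynamically generated multimers."""
    structures: List[Muropeptide] = []
    for m in monomers:
        if isinstance(m, TheoreticalEntry):
            structures.extend(parse_muropeptide(n) for n in m.names)
        elif isinstance(m, str):
            structures.append(parse_muropeptide(m))
        else:
            structures.append(m)
    entries: List[TheoreticalEntry] = []
    seen = set()
    for m in structures:
        for variant in _mod_variants(m, modifications):
            name = canonical_name(variant)
            if name not in seen:
                seen.add(name)
                entries.append(_entry_from_muropeptide(variant))
    entries = _merge_isobars(entries)
    entries.extend(build_multimers(structures, rules, modifications))
    return entries


# ---------------------------------------------------------------------------
# database CSV round-trip

_DB_HEADER = ["Structure", "Mass", "Level", "CrosslinkTypes", "Flags"]


def write_database(entries: Sequence[TheoreticalEntry], path: str | Path) -> None:
    """Export a generated database as CSV (isobaric names pipe-joined)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_DB_HEADER)
        for e in entries:
            flags = "|".join(
                f for f, on in (("Anh", e.anhydro), ("DeAc", e.deacetyl),
                                ("Amidated", e.amidated)) if on
            )
            w.writerow([
                "|".join(e.names),
                f"{e.mass:.6f}",
                e.level,
                "|".join(sorted(e.crosslink_types)),
                flags,
            ])


def read_database(path: str | Path) -> List[TheoreticalEntry]:
    """Read a database CSV written by :func:`write_database`."""
    path = Path(path)
    entries: List[TheoreticalEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "Structure" not in reader.fieldnames:
            raise MonomerDBError(f"{path}: not a database CSV")
        for lineno, row in enumerate(reader, start=2):
            names = tuple(row["Structure"].split("|"))
            flags = set((row.get("Flags") or "").split("|")) - {""}
            xl = frozenset((row.get("CrosslinkTypes") or "").split("|")) - {""}
            try:
                mass = float(row["Mass"])
            except (TypeError, ValueError):
                raise MonomerDBError(f"{path}:{lineno}: bad mass {row.get('Mass')!r}")
            entries.append(TheoreticalEntry(
                names=names,
                mass=mass,
                level=row.get("Level") or parse_muropeptide(names[0]).level,
                crosslink_types=frozenset(xl),
                anhydro="Anh" in flags,
                deacetyl="DeAc" in flags,
                amidated="Amidated" in flags,
            ))
    return entries
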