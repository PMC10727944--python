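"""Relative abundances and compositional indices of a peptidoglycan sample.

All percentages are computed over *identified* structures only (the
unidentified intensity pool is excluded from the denominator), matching how
published muropeptide composition tables are normalized.

Indices:

* cross-linking index = 0.5 * (% dimers) + 0.33 * (% trimers).  The
  weights are the fraction of cross-linked stems per muropeptide: half the
  stems of a dimer and (by the same published convention, printed as 0.33
  rather than 1/3) a third of the stems of a trimer are acceptors.
* glycan chain length = 1 / (f_anh_mono + 0.5 * f_anh_dimer + 0.33 *
  f_anh_trimer) in disaccharide units, where the f are *fractions*
  (percent / 100) of anhydroMurNAc-carrying structures.  AnhydroMurNAc
  marks glycan chain termini, so its weighted frequency is the reciprocal
  of the average chain length.
* 1-3 content = % of dimers containing a single-alanine donor stem (the
  hallmark of 1-3 transpeptidation); 1-3 containing trimers are tallied
  separately, not folded in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import math

from .chemistry import Muropeptide, parse_muropeptide

__all__ = [
    "Classification",
    "SummaryMetrics",
    "classify_for_summary",
    "relative_abundance",
    "crosslink_index",
    "glycan_chain_length",
    "summarize",
]

AbundanceInput = Union[Mapping[str, float], Iterable[Tuple[str, float]]]


@dataclass(frozen=True)
class Classification:
    """Summary categories of one structure."""

    level: str  # monomer | dimer | trimer
    anhydro: bool
    deacetyl: bool
    amidated: bool
    #: a subunit stem is exactly [A]: evidence of 1-3 transpeptidation
    single_ala_donor: bool
    #: monomer with a stem of <= 2 residues (includes the lone-Ala monomer)
    dipeptide_monomer: bool
    #: monomer with a stem of exactly 2 residues
    strict_dipeptide_monomer: bool


def classify_for_summary(structure: Union[str, Muropeptide]) -> Classification:
    """Classify a structure for compositional summaries."""
    m = parse_muropeptide(structure) if isinstance(structure, str) else structure
    stems = [su.stem for su in m.subunits]
    is_monomer = len(stems) == 1
    # a lone-Ala stem marks a 1-3 donor only when actually cross-linked
    single_a = not is_monomer and any(stem == ("A",) for stem in stems)
    return Classification(
        level=m.level,
        anhydro="Anh" in m.modifications,
        deacetyl="DeAc" in m.modifications,
        amidated=m.amidated,
        single_ala_donor=single_a,
        dipeptide_monomer=is_monomer and len(stems[0]) <= 2,
        strict_dipeptide_monomer=is_monomer and len(stems[0]) == 2,
    )


@dataclass(frozen=True)
class SummaryMetrics:
    """Per-sample compositional summary (percentages on the 0-100 scale)."""

    pct_monomers: float
    pct_dimers: float
    pct_trimers: float
    pct_anh_monomers: float
    pct_anh_dimers: float
    pct_anh_trimers: float
    crosslink_index: float
    glycan_chain_length: Optional[float]  # None when no anhydro structures
    pct_1_3_dimers: float
    pct_1_3_trimers: float
    pct_dipeptide_monomers: float
    pct_strict_dipeptide_monomers: float

    def as_dict(self) -> Dict[str, Optional[float]]:
        return dict(self.__dict__)


def _pairs(abundances: AbundanceInput) -> List[Tuple[str, float]]:
    if isinstance(abundances, Mapping):
        return list(abundances.items())
    return list(abundances)


def relative_abundance(intensities: AbundanceInput) -> List[Tuple[str, float]]:
    """Convert per-structure intensities to percent of identified total."""
    pairs = _pairs(intensities)
    total = sum(v for _, v in pairs)
    if total <= 0:
        raise ValueError("total identified intensity is zero")
    return [(name, v / total * 100.0) for name, v in pairs]


def crosslink_index(pct_dimers: float, pct_trimers: float) -> float:
    """0.5 * (% dimers) + 0.33 * (% trimers), percentages on 0-100."""
    return 0.5 * pct_dimers + 0.33 * pct_trimers


def glycan_chain_length(
    pct_anh_monomers: float,
    pct_anh_dimers: float,
    pct_anh_trimers: float,
) -> Optional[float]:
    """Average glycan chain length in disaccharide units.

    ``1 / (f_mono + 0.5 * f_di + 0.33 * f_tri)`` with f = percent / 100.
    Returns None (undefined) when no anhydro structures were observed.
    """
    denom = (pct_anh_monomers + 0.5 * pct_anh_dimers
             + 0.33 * pct_anh_trimers) / 100.0
    if denom <= 0:
        return None
    return 1.0 / denom


def summarize(abundances: AbundanceInput) -> SummaryMetrics:
    """Compute all compositional indices from (structure, %) abundances.

    Abundances are used as given (they are expected to sum to ~100 over the
    identified structures; use :func:`relative_abundance` first when
    starting from raw intensities).  Duplicate names (retention-time
    isomers) are allowed and all contribute.
    """
    totals = {"monomer": 0.0, "dimer": 0.0, "trimer": 0.0}
    anh = {"monomer": 0.0, "dimer": 0.0, "trimer": 0.0}
    one_three = {"dimer": 0.0, "trimer": 0.0}
    dipeptide = 0.0
    strict_dipeptide = 0.0
    for name, pct in _pairs(abundances):
        if math.isnan(pct):
            continue
        # isobaric groups arrive pipe-joined; classify by the first name
        c = classify_for_summary(name.split("|")[0] if isinstance(name, str)
                                 else name)
        totals[c.level] += pct
        if c.anhydro:
            anh[c.level] += pct
        if c.single_ala_donor and c.level in one_three:
            one_three[c.level] += pct
        if c.dipeptide_monomer:
            dipeptide += pct
        if c.strict_dipeptide_monomer:
            strict_dipeptide += pct
    return SummaryMetrics(
        pct_monomers=totals["monomer"],
        pct_dimers=totals["dimer"],
        pct_trimers=totals["trimer"],
        pct_anh_monomers=anh["monomer"],
        pct_anh_dimers=anh["dimer"],
        pct_anh_trimers=anh["trimer"],
        crosslink_index=crosslink_index(totals["dimer"], totals["trimer"]),
        glycan_chain_length=glycan_chain_length(
            anh["monomer"], anh["dimer"], anh["trimer"]),
        pct_1_3_dimers=one_three["dimer"],
        pct_1_3_trimers=one_three["trimer"],
        pct_dipeptide_monomers=dipeptide,
        pct_strict_dipeptide_monomers=strict_dipeptide,
    )
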