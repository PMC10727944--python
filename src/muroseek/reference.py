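"""Bundled reference dataset: the published muropeptide composition of
*Gluconobacter oxydans* B58 peptidoglycan.

The table lists 61 identified structures with their relative abundances
(percent of total identified intensity) in the wild type at exponential and
stationary phase and in two L,D-transpeptidase insertion mutants, together
with mean retention times, theoretical monoisotopic masses and observed ppm
errors.  It serves three purposes here: a ground-truth surface for the mass
calculator, a realistic composition for the synthetic-data generator, and
the input for recomputing compositional indices (cross-linking index,
1-3 content, glycan chain length).

Abundance columns may be empty where a structure was not detected (ND).
Two rows share the name ``gm-AEJA=gm-AEJA (Anh)``: they are chromatographic
isomers with distinct retention times.
"""

from __future__ import annotations

from importlib.resources import files
from typing import List, Tuple

import pandas as pd

__all__ = [
    "load_composition",
    "abundance_pairs",
    "db0_monomers",
    "SAMPLE_COLUMNS",
]

#: abundance columns of the composition table, one per sample.
SAMPLE_COLUMNS = ("wt_expo_pct", "wt_stat_pct", "ldt_go1_pct", "ldt_go2_pct")

_CSV = "gluconobacter_b58_composition.csv"


def load_composition() -> pd.DataFrame:
    """Load the bundled G. oxydans B58 composition table."""
    with files("muroseek.data").joinpath(_CSV).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def abundance_pairs(sample: str, table: pd.DataFrame | None = None
                    ) -> List[Tuple[str, float]]:
    """(structure, abundance %) pairs for one sample column, ND rows dropped.

    Duplicate structure names (retention-time isomers) are kept as separate
    pairs so their abundances both count.
    """
    if table is None:
        table = load_composition()
    if sample not in SAMPLE_COLUMNS:
        raise ValueError(f"unknown sample column {sample!r}; "
                         f"expected one of {SAMPLE_COLUMNS}")
    sub = table.loc[table[sample].notna(), ["structure", sample]]
    return list(sub.itertuples(index=False, name=None))


def db0_monomers(table: pd.DataFrame | None = None) -> List[str]:
    """The curated monomer database (DB0) for G. oxydans B58.

    These are the MS/MS-validated monomer structures of the composition
    table (the 28 entries without a cross-link), from which the dimer and
    trimer search space is generated dynamically.
    """
    if table is None:
        table = load_composition()
    return [s for s in table["structure"] if "=" not in s]
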