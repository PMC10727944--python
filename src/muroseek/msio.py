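"""Readers and writers for deconvoluted LC-MS feature lists and result tables.

A *feature* is one deconvoluted observation: neutral monoisotopic mass (Da),
retention time (minutes) and summed intensity (ion counts).  Two input
dialects are supported: ``csv`` (comma-separated, columns ``mass,rt,
intensity`` plus optional ``id``) and ``ftrs`` (tab-separated with the same
columns under common deconvolution-tool aliases).  Column-name matching is
case-insensitive; anything else should be pre-converted by the user rather
than guessed at.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

__all__ = [
    "Feature",
    "FeatureTable",
    "FeatureTableError",
    "read_features",
    "write_features",
    "write_results",
]


class FeatureTableError(ValueError):
    """Raised when a feature file cannot be parsed."""


@dataclass(frozen=True)
class Feature:
    """One deconvoluted LC-MS observation."""

    id: int
    neutral_mass: float  # Da
    rt: float  # minutes
    intensity: float  # arbitrary units

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"feature {self.id}: mass must be positive")
        if self.intensity < 0:
            raise ValueError(f"feature {self.id}: negative intensity")
        if self.rt < 0:
            raise ValueError(f"feature {self.id}: negative retention time")


@dataclass
class FeatureTable:
    sample_id: str
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FeatureTableError(f"duplicate feature ids: {dup}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def total_intensity(self) -> float:
        return sum(f.intensity for f in self.features)


# column-name aliases, all lowercase with separators stripped
_MASS_ALIASES = {"mass", "neutralmass", "monoisotopicmass", "theomass", "mwmonoisotopic"}
_RT_ALIASES = {"rt", "rtmin", "retentiontime", "apexrt"}
_INT_ALIASES = {"intensity", "sumintensity", "intensitysum", "maxintensity", "xic"}
_ID_ALIASES = {"id", "featureid", "index"}


def _norm(col: str) -> str:
    return "".join(c for c in col.lower() if c.isalnum())


def _find(columns: Sequence[str], aliases: set, what: str,
          path: Path, required: bool = True) -> Optional[str]:
    for col in columns:
        if _norm(col) in aliases:
            return col
    if required:
        raise FeatureTableError(
            f"{path}: missing required column for {what} "
            f"(accepted names e.g. {sorted(aliases)[:3]})"
        )
    return None


def read_features(
    path: str | Path,
    dialect: str = "csv",
    sample_id: Optional[str] = None,
    rt_seconds: bool = False,
) -> FeatureTable:
    """Read a deconvoluted feature list.

    Parameters
    ----------
    dialect
        ``"csv"`` (comma-separated) or ``"ftrs"`` (tab-separated).
    rt_seconds
        If True, retention times in the file are seconds and are converted
        to minutes.
    """
    path = Path(path)
    if dialect not in ("csv", "ftrs"):
        raise FeatureTableError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FeatureTableError(f"{path}: empty file (header required)")
    mass_c = _find(df.columns, _MASS_ALIASES, "mass", path)
    rt_c = _find(df.columns, _RT_ALIASES, "retention time", path)
    int_c = _find(df.columns, _INT_ALIASES, "intensity", path)
    id_c = _find(df.columns, _ID_ALIASES, "id", path, required=False)

    features: List[Feature] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            mass = float(rec[mass_c])
            rt = float(rec[rt_c])
            intensity = float(rec[int_c])
            fid = int(rec[id_c]) if id_c else row_no - 2
        except (TypeError, ValueError) as exc:
            raise FeatureTableError(f"{path}: row {row_no}: {exc}")
        if rt_seconds:
            rt /= 60.0
        try:
            features.append(Feature(fid, mass, rt, intensity))
        except ValueError as exc:
            raise FeatureTableError(f"{path}: row {row_no}: {exc}")
    return FeatureTable(sample_id=sample_id or path.stem, features=features)


def write_features(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table in the simple-csv dialect (masses to 1e-6 Da)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "mass", "rt", "intensity"])
        for f in table.features:
            w.writerow([f.id, f"{f.neutral_mass:.6f}", f"{f.rt:.4f}",
                        repr(f.intensity)])


_RESULT_COLUMNS = [
    "Structure", "RT (min)", "RT sd", "Theoretical Mass (Da)",
    "Observed Mass (Da)", "Dppm", "Intensity", "Abundance (%)",
]


def write_results(consolidated: pd.DataFrame, path: str | Path) -> None:
    """Write a consolidated result table as CSV.

    Expects the frame produced by :func:`muroseek.search.consolidate`,
    optionally with an ``abundance_pct`` column.  Masses are printed with 4
    decimals and abundances with 3, matching conventional reporting.
    """
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_RESULT_COLUMNS)
        for row in consolidated.itertuples(index=False):
            rt_sd = getattr(row, "rt_sd", None)
            abundance = getattr(row, "abundance_pct", None)
            w.writerow([
                row.structure,
                f"{row.rt_mean:.2f}",
                "" if rt_sd is None or pd.isna(rt_sd) else f"{rt_sd:.2f}",
                f"{row.theoretical_mass:.4f}",
                f"{row.obs_mass_mean:.4f}",
                f"{row.ppm_mean:.2f}",
                repr(float(row.intensity_mean)),
                "" if abundance is None else f"{abundance:.3f}",
            ])
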