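"""Matching of observed features to theoretical muropeptide masses.

The search proceeds in three stages:

1. *Direct matching*: every feature is compared with every database entry;
   a match is accepted when the absolute ppm error is within tolerance
   (inclusive).  A feature matching several non-isobaric entries keeps all
   matches, but only the lowest-|ppm| one (the *primary*) receives its
   intensity, so abundance sums never double-count.
2. *Cleanup*: unidentified features whose mass equals a matched entry plus
   an adduct delta (Na, K) or minus an in-source substructure loss
   (GlcNAc, disaccharide), and whose retention time lies within the cleanup
   window of that match, are satellite signals of the parent ion; their
   intensity is merged into the parent.
3. *Consolidation*: per-replicate results are combined into per-structure
   mean intensity, mean +/- sd retention time, mean observed mass and mean
   ppm error.

Total intensity is conserved throughout: assigned + unidentified always
equals the input total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .chemistry import ADDUCT_DELTAS, GLYCAN_MASSES
from .database import CrosslinkRules, TheoreticalEntry
from .msio import Feature, FeatureTable

__all__ = [
    "SearchConfig",
    "MatchResult",
    "SearchResult",
    "ppm_diff",
    "match_features",
    "cleanup",
    "consolidate",
    "load_config",
]

#: neutral mass removed by in-source loss of a glycan substructure
INSOURCE_LOSSES = {
    "GlcNAc": GLYCAN_MASSES["GlcNAc"],
    "disaccharide": GLYCAN_MASSES["GlcNAc"] + GLYCAN_MASSES["MurNAc"],
}

# relative guard so that a feature constructed at exactly the tolerance
# boundary is accepted despite float rounding
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters.  Defaults: 10 ppm tolerance, 0.5 min cleanup
    window, Na/K adducts and both in-source losses enabled."""

    ppm_tolerance: float = 10.0
    cleanup_window: float = 0.5  # minutes
    adducts: FrozenSet[str] = frozenset({"Na", "K"})
    insource_losses: FrozenSet[str] = frozenset({"GlcNAc", "disaccharide"})

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")
        if self.cleanup_window < 0:
            raise ValueError("cleanup_window must be non-negative")
        bad = set(self.adducts) - set(ADDUCT_DELTAS)
        if bad:
            raise ValueError(f"unknown adducts: {sorted(bad)}")
        bad = set(self.insource_losses) - set(INSOURCE_LOSSES)
        if bad:
            raise ValueError(f"unknown in-source losses: {sorted(bad)}")


@dataclass(frozen=True)
class MatchResult:
    """One feature <-> entry pairing.

    ``provenance`` is ``direct`` for a mass match, or ``adduct-merged`` /
    ``insource-merged`` for a satellite folded into the parent during
    cleanup.  ``primary`` marks the single match per feature that carries
    the feature's intensity.
    """

    feature: Feature
    entry: TheoreticalEntry
    ppm_error: float
    intensity_assigned: float
    provenance: str = "direct"
    primary: bool = True


@dataclass
class SearchResult:
    """Matches plus the pool of unidentified features (intensity retained)."""

    matches: List[MatchResult]
    unidentified: List[Feature]
    config: SearchConfig

    @property
    def assigned_intensity(self) -> float:
        return sum(m.intensity_assigned for m in self.matches)

    @property
    def unidentified_intensity(self) -> float:
        return sum(f.intensity for f in self.unidentified)


def ppm_diff(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def _within(ppm: float, tolerance: float) -> bool:
    return abs(ppm) <= tolerance * (1.0 + _BOUNDARY_EPS)


def match_features(
    table: FeatureTable,
    db: Sequence[TheoreticalEntry],
    cfg: SearchConfig = SearchConfig(),
) -> SearchResult:
    """Match every feature against the theoretical database.

    Tolerance comparison is inclusive of the boundary.  Ties between
    equal-|ppm| candidates break on entry name for determinism.
    """
    if not db:
        raise ValueError("theoretical database is empty")
    masses = np.array([e.mass for e in db])
    order = np.argsort(masses)
    sorted_masses = masses[order]

    matches: List[MatchResult] = []
    unidentified: List[Feature] = []
    for f in table.features:
        # window on absolute mass difference; generous bound then exact test
        half = f.neutral_mass * cfg.ppm_tolerance * 1e-6 * 1.001 + 1e-9
        lo = np.searchsorted(sorted_masses, f.neutral_mass - half, side="left")
        hi = np.searchsorted(sorted_masses, f.neutral_mass + half, side="right")
        cands = []
        for idx in order[lo:hi]:
            e = db[idx]
            ppm = ppm_diff(f.neutral_mass, e.mass)
            if _within(ppm, cfg.ppm_tolerance):
                cands.append((abs(ppm), e.name, ppm, e))
        if not cands:
            unidentified.append(f)
            continue
        cands.sort(key=lambda c: (c[0], c[1]))
        for rank, (_, _, ppm, e) in enumerate(cands):
            matches.append(MatchResult(
                feature=f,
                entry=e,
                ppm_error=ppm,
                intensity_assigned=f.intensity if rank == 0 else 0.0,
                provenance="direct",
                primary=rank == 0,
            ))
    return SearchResult(matches=matches, unidentified=unidentified, config=cfg)


def cleanup(result: SearchResult) -> SearchResult:
    """Merge adduct and in-source satellite signals into their parents.

    An unidentified feature is a satellite of a directly matched entry when
    its mass equals (entry mass + adduct delta) or (entry mass - loss)
    within the ppm tolerance and its retention time is within the cleanup
    window of the parent feature.  Each satellite merges into at most one
    parent (nearest retention time, then lowest |ppm|).  Cleanup never
    creates matches for structures without direct evidence.
    """
    cfg = result.config
    deltas: List[Tuple[str, float]] = []
    for a in sorted(cfg.adducts):
        deltas.append(("adduct-merged", ADDUCT_DELTAS[a]))
    for l in sorted(cfg.insource_losses):
        deltas.append(("insource-merged", -INSOURCE_LOSSES[l]))
    if not deltas:
        return result

    parents = [m for m in result.matches if m.primary and m.provenance == "direct"]
    new_matches = list(result.matches)
    remaining: List[Feature] = []
    for f in result.unidentified:
        best = None  # (rt_dist, abs_ppm, name, provenance, ppm, parent)
        for p in parents:
            rt_dist = abs(f.rt - p.feature.rt)
            if rt_dist > cfg.cleanup_window:
                continue
            for provenance, delta in deltas:
                expected = p.entry.mass + delta
                if expected <= 0:
                    continue
                ppm = ppm_diff(f.neutral_mass, expected)
                if not _within(ppm, cfg.ppm_tolerance):
                    continue
                key = (rt_dist, abs(ppm), p.entry.name, provenance, ppm, p)
                if best is None or key[:4] < best[:4]:
                    best = key
        if best is None:
            remaining.append(f)
        else:
            _, _, _, provenance, ppm, parent = best
            new_matches.append(MatchResult(
                feature=f,
                entry=parent.entry,
                ppm_error=ppm,
                intensity_assigned=f.intensity,
                provenance=provenance,
                primary=False,
            ))
    return SearchResult(matches=new_matches, unidentified=remaining, config=cfg)


def _per_replicate_rows(result: SearchResult) -> pd.DataFrame:
    """One row per structure for one replicate (intensity-weighted stats
    when several chromatographic isomers match the same structure)."""
    rows: Dict[str, Dict[str, float]] = {}
    for m in result.matches:
        if m.intensity_assigned <= 0 and not m.primary:
            continue
        key = "|".join(m.entry.names)
        r = rows.setdefault(key, {
            "structure": key,
            "theoretical_mass": m.entry.mass,
            "intensity": 0.0,
            "_w_rt": 0.0, "_w_mass": 0.0, "_w_ppm": 0.0, "_w": 0.0,
        })
        r["intensity"] += m.intensity_assigned
        if m.provenance == "direct" and m.primary:
            w = max(m.intensity_assigned, 1e-12)
            r["_w_rt"] += w * m.feature.rt
            r["_w_mass"] += w * m.feature.neutral_mass
            r["_w_ppm"] += w * m.ppm_error
            r["_w"] += w
    recs = []
    for r in rows.values():
        w = r["_w"] or 1.0
        recs.append({
            "structure": r["structure"],
            "theoretical_mass": r["theoretical_mass"],
            "intensity": r["intensity"],
            "rt": r["_w_rt"] / w,
            "obs_mass": r["_w_mass"] / w,
            "ppm": r["_w_ppm"] / w,
        })
    return pd.DataFrame(
        recs, columns=["structure", "theoretical_mass", "intensity",
                       "rt", "obs_mass", "ppm"],
    )


def consolidate(replicates: Sequence[SearchResult]) -> pd.DataFrame:
    """Combine per-replicate search results into one table.

    Structures absent from a replicate contribute nothing to that
    replicate's totals; means are taken over the replicates in which the
    structure was detected.  Retention-time sd uses the n-1 denominator and
    is NaN for a single observation.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    frames = [_per_replicate_rows(r) for r in replicates]
    allrows = pd.concat(frames, ignore_index=True)
    if allrows.empty:
        return pd.DataFrame(columns=[
            "structure", "theoretical_mass", "n_replicates",
            "intensity_mean", "rt_mean", "rt_sd", "obs_mass_mean", "ppm_mean",
        ])
    g = allrows.groupby("structure", sort=True)
    out = pd.DataFrame({
        "theoretical_mass": g["theoretical_mass"].first(),
        "n_replicates": g["intensity"].size(),
        "intensity_mean": g["intensity"].mean(),
        "rt_mean": g["rt"].mean(),
        "rt_sd": g["rt"].std(ddof=1),
        "obs_mass_mean": g["obs_mass"].mean(),
        "ppm_mean": g["ppm"].mean(),
    }).reset_index()
    return out


def load_config(path: str | Path) -> Tuple[SearchConfig, CrosslinkRules, FrozenSet[str]]:
    """Load a YAML key-value configuration file.

    Recognized keys: ``ppm_tolerance``, ``cleanup_window_min``, ``adducts``,
    ``insource_losses``, ``crosslinks``, ``modifications``,
    ``restrict_1_3_to_gmA``, ``max_level``.  Missing keys take the
    defaults.  Returns (search config, cross-link rules, modifications).
    """
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a key-value mapping")

    def as_set(value, default):
        if value is None:
            return frozenset(default)
        if isinstance(value, str):
            value = [v.strip() for v in value.split(",") if v.strip()]
        return frozenset(value)

    cfg = SearchConfig(
        ppm_tolerance=float(raw.get("ppm_tolerance", 10.0)),
        cleanup_window=float(raw.get("cleanup_window_min", 0.5)),
        adducts=as_set(raw.get("adducts"), {"Na", "K"}),
        insource_losses=as_set(raw.get("insource_losses"),
                               {"GlcNAc", "disaccharide"}),
    )
    rules = CrosslinkRules(
        enabled=as_set(raw.get("crosslinks"), {"4-3", "3-3", "1-3"}),
        restrict_1_3_to_gmA=bool(raw.get("restrict_1_3_to_gmA", False)),
        max_level=int(raw.get("max_level", 3)),
    )
    mods = as_set(raw.get("modifications"), {"Anh", "DeAc"})
    return cfg, rules, mods
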