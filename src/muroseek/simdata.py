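"""Synthetic deconvoluted feature lists with known ground truth.

The generator emulates what a deconvolution step hands to the search
engine: one neutral-mass feature per muropeptide with multiplicative
(ppm-scale, Gaussian) mass error, retention-time jitter, optional sodium /
potassium adduct and in-source fragment satellites that siphon a fraction
of the parent intensity, and decoy features at masses constructed to lie
well outside tolerance of every true mass.

It deliberately does not simulate chromatographic peak shapes, isotope
envelopes or charge states — those live upstream of the deconvoluted
feature list this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import csv
import math

import numpy as np
import pandas as pd

from .chemistry import ADDUCT_DELTAS, mass_of
from .msio import Feature, FeatureTable
from .search import INSOURCE_LOSSES

__all__ = ["SimSpec", "simulate_features", "write_truth"]


@dataclass(frozen=True)
class SimSpec:
    """Specification of one synthetic LC-MS run.

    Parameters
    ----------
    composition
        Structure name -> relative abundance in percent; must sum to 100.
    total_intensity
        Total ion intensity shared among the true structures.
    ppm_noise_sd
        Gaussian sd of the multiplicative mass error, in ppm.
    rt_map
        Structure -> retention time (minutes).  When omitted, structures
        are spread uniformly over 5-15 min in composition order.
    rt_jitter_sd
        Gaussian sd of retention-time jitter, minutes.
    satellite_rates
        Per-feature probability of emitting each satellite type
        (keys among Na, K, GlcNAc, disaccharide).
    satellite_intensity_frac
        Fraction of the parent intensity diverted to each emitted
        satellite (the parent keeps the remainder, so total intensity is
        conserved and cleanup can restore the true composition).
    n_decoys, decoy_mass_range, decoy_exclusion_ppm
        Number of decoy features, the mass range they are drawn from, and
        the minimum ppm distance a decoy must keep from every true or
        satellite mass (resampled until satisfied, never emitted closer).
    seed
        Seed of the pseudo-random stream; a fixed seed gives
        byte-identical output.
    """

    composition: Mapping[str, float]
    total_intensity: float = 1e9
    ppm_noise_sd: float = 3.0
    rt_map: Optional[Mapping[str, float]] = None
    rt_jitter_sd: float = 0.02
    satellite_rates: Mapping[str, float] = field(
        default_factory=lambda: {"Na": 0.3, "K": 0.1, "GlcNAc": 0.15}
    )
    satellite_intensity_frac: float = 0.1
    n_decoys: int = 20
    decoy_mass_range: Tuple[float, float] = (400.0, 2500.0)
    decoy_exclusion_ppm: float = 30.0
    decoy_intensity: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(f"composition sums to {total}, expected 100")
        bad = set(self.satellite_rates) - set(ADDUCT_DELTAS) - set(INSOURCE_LOSSES)
        if bad:
            raise ValueError(f"unknown satellite types: {sorted(bad)}")
        if not 0 <= self.satellite_intensity_frac < 1:
            raise ValueError("satellite_intensity_frac must be in [0, 1)")


def _satellite_delta(kind: str) -> float:
    if kind in ADDUCT_DELTAS:
        return ADDUCT_DELTAS[kind]
    return -INSOURCE_LOSSES[kind]


def simulate_features(
    spec: SimSpec,
    sample_id: str = "synthetic",
    exclusion_masses: Optional[Sequence[float]] = None,
) -> Tuple[FeatureTable, pd.DataFrame]:
    """Generate one synthetic feature table plus its ground truth.

    ``exclusion_masses`` extends the set of masses decoys must avoid
    (e.g. every entry of the database that will be searched); the true and
    satellite masses of the run are always avoided.

    Returns
    -------
    (FeatureTable, DataFrame)
        The feature table and a tidy ground-truth frame with columns
        ``Structure`` and ``TrueAbundance``.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.composition)
    theo = {name: mass_of(name) for name in names}

    if spec.rt_map is not None:
        rt_of = dict(spec.rt_map)
        missing = [n for n in names if n not in rt_of]
        if missing:
            raise ValueError(f"rt_map missing structures: {missing[:3]}")
    else:
        if len(names) == 1:
            rt_of = {names[0]: 10.0}
        else:
            rt_of = {n: 5.0 + 10.0 * i / (len(names) - 1)
                     for i, n in enumerate(names)}

    features: List[Feature] = []
    fid = 0

    def emit(mass: float, rt: float, intensity: float) -> None:
        nonlocal fid
        eps = rng.normal(0.0, spec.ppm_noise_sd) * 1e-6
        jitter = rng.normal(0.0, spec.rt_jitter_sd)
        features.append(Feature(
            id=fid,
            neutral_mass=mass * (1.0 + eps),
            rt=max(rt + jitter, 0.0),
            intensity=intensity,
        ))
        fid += 1

    protected: List[float] = list(theo.values())
    for name in names:
        intensity = spec.total_intensity * spec.composition[name] / 100.0
        rt = rt_of[name]
        kept = intensity
        for kind, rate in sorted(spec.satellite_rates.items()):
            if rng.random() < rate:
                sat_mass = theo[name] + _satellite_delta(kind)
                if sat_mass <= 0:
                    continue
                sat_int = intensity * spec.satellite_intensity_frac
                kept -= sat_int
                emit(sat_mass, rt, sat_int)
                protected.append(sat_mass)
        emit(theo[name], rt, kept)

    if exclusion_masses is not None:
        protected.extend(exclusion_masses)
    avoid = np.array(sorted(protected))

    lo, hi = spec.decoy_mass_range
    for _ in range(spec.n_decoys):
        for _attempt in range(1000):
            mass = rng.uniform(lo, hi)
            # nearest protected mass in ppm
            i = int(np.searchsorted(avoid, mass))
            near = [avoid[j] for j in (i - 1, i) if 0 <= j < len(avoid)]
            if all(abs(mass - t) / t * 1e6 > spec.decoy_exclusion_ppm
                   for t in near):
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not place a decoy away from true masses")
        emit(mass, rng.uniform(4.0, 16.0), spec.decoy_intensity)

    truth = pd.DataFrame({
        "Structure": names,
        "TrueAbundance": [spec.composition[n] for n in names],
    })
    return FeatureTable(sample_id=sample_id, features=features), truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the ground-truth sidecar CSV (``Structure,TrueAbundance``)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["Structure", "TrueAbundance"])
        for row in truth.itertuples(index=False):
            w.writerow([row.Structure, repr(float(row.TrueAbundance))])
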