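# Methods

This note records the model behind `muroseek`, the default parameters and
why they were chosen, and the numerical decisions that affect results.

## Mass model

A muropeptide is 1–3 subunits, each a GlcNAc–MurNAc disaccharide with a
peptide stem. The neutral monoisotopic mass is

```
mass = Σ over subunits [ Σ(glycan masses) + Σ(stem residue masses) + water ]
       − crosslink_count × water
```

with residue masses in the dehydrated (residue) convention and one water of
condensation removed per cross-link. Constants (Da): water 18.010565,
proton 1.007276, GlcNAc 203.079373, MurNAc 275.100502, borohydride
reduction +2.015650 (applied to the MurNAc of every subunit by default,
because samples are reduced before LC-MS), amidation −0.984016,
de-N-acetylation −42.010565. A 1,6-anhydroMurNAc replaces the *reduced*
MurNAc and is one water lighter than the non-reduced form, i.e.
−20.026215 relative to the reduced default. Anh and reduction are mutually
exclusive on one glycan; at most one Anh per muropeptide.

Additivity — `mass(multimer) = Σ(monomer masses) − (n−1)·water` — is a
structural consequence of this formula and is enforced by the test suite
to 1e-6 Da over the whole generated database. All 61 bundled reference
masses are reproduced within ±0.0015 Da (worst case ≈0.0004 Da).

## Database generation

The search space is built dynamically from a curated monomer list (DB0):

1. **Monomers**: each DB0 structure, plus modification variants
   ({Anh}, {DeAc}, {Anh, DeAc}) when enabled.
2. **Dimers/trimers**: acceptor × donor combinations under the enabled
   cross-link rules, with modification variants applied at the multimer
   level (one Anh maximum).

Acceptor: any stem of length ≥ 3 with DAP (amidated or not) at position 3.
Donor, by chemistry:

- **4-3**: stem of exactly 4 residues (the position-4 D-Ala carboxyl
  donates);
- **3-3**: stem of exactly 3 residues ending in *unamidated* DAP;
- **1-3**: stem of exactly one alanine (the gm-A moiety). An optional
  restriction (`--restrict-gmA`) limits 1-3 donors to the plain `gm-A`
  monomer, for organisms where only that donor is plausible.

Two deliberate design decisions narrow the combinatorics relative to a
naive "any stem long enough can donate" reading:

- **Amidated DAP cannot donate a 3-3 bond.** Amidation occupies the very
  carboxyl that would form the bond, so `gm-AEJ_NH2` is an acceptor but
  never a 3-3 donor.
- **Donor stems must terminate at the donating residue** (lengths exactly
  4 / 3 / 1, not ≥). In transpeptidation the donor bond is made at the
  stem's C-terminal carboxyl; a longer stem would place the donating
  residue internally.

Both decisions are chemically motivated, and both also matter numerically:
they remove near-isobaric phantom candidates that would otherwise sit
4–6 ppm from genuine low-abundance structures and randomly steal their
intensity. With the bundled 28-monomer DB0 and all rules enabled the
database holds 522 mass entries and contains every one of the 61 reference
structures.

Entries closer than 1e-4 Da are merged into one isobar group whose name is
the pipe-joined list of member names; matching cannot distinguish them, so
reporting them as one entry is honest. Summary classification of a merged
group uses its first name.

## Matching and cleanup

ppm error is `(observed − theoretical)/theoretical × 1e6`; a feature
matches an entry when |ppm| ≤ tolerance (default **10 ppm**, the standard
setting for well-calibrated orbitrap data at these masses). The comparison
is inclusive with a 1e-9 relative epsilon so that features exactly at the
boundary are not lost to floating-point rounding. When several entries
match one feature, all matches are reported but only the lowest-|ppm| one
(ties broken by name) is *primary* and receives the feature intensity —
intensity is never double-counted.

Cleanup then re-examines unmatched features: one that sits at a matched
entry's mass ± a known delta (Na +21.981944, K +37.955882, in-source loss
of GlcNAc −203.079373 or of a full disaccharide −478.179875) within the
ppm tolerance *and* within ±0.5 min retention time (default window) of
the parent feature is merged into the parent, adding its intensity.
Candidate parents are ranked by RT proximity, then |ppm|. Cleanup never
invents identifications: satellites only merge into structures already
matched directly. Total intensity (assigned + unidentified) is conserved
exactly through matching and cleanup.

Replicates are consolidated per structure: intensity-weighted observed
mass and ppm, mean RT with between-replicate sd (ddof = 1, undefined for a
single replicate), mean intensity over the replicates in which the
structure appears (absence contributes nothing, not a zero).

## Compositional indices

Percent abundances are normalized over *identified* intensity only.

- **Cross-linking index** = 0.5 × %dimers + 0.33 × %trimers. The weights
  are the fraction of acceptor stems per oligomer; 0.33 is used literally
  (not 1/3) to match the published convention.
- **Glycan chain length** = 1 / (f_anh_mono + 0.5·f_anh_di + 0.33·f_anh_tri)
  in disaccharide units, f = percent/100; anhydroMurNAc marks chain ends.
  Undefined (None) when no anhydro structure is observed.
- **1-3 content** = % of dimers containing a single-Ala donor stem
  (1-3-containing trimers are tallied separately).
- **Dipeptide monomers** = monomers with stems of ≤ 2 residues (the
  lone-Ala monomer included; a strict ==2 variant is also reported).

Recomputing these from the bundled wild-type composition columns gives a
cross-linking index of 19.9 (stationary phase) and 15.9 (exponential) and
a 1-3 dimer fraction of 16.6% (stationary) — the values checked by
`scripts/acceptance.py` and the acceptance tests. The recomputed glycan
chain lengths (≈21 and ≈22 disaccharides) are consistent with, but not
numerically pinned to, values quoted alongside such tables, whose rounding
provenance is not reconstructible; the chain-length formula itself is
verified by analytic toy cases instead.

## Synthetic data generator

`muroseek.simdata` emulates what a deconvolution step hands to the search
engine, so the whole pipeline can be validated against a known truth:

- one neutral-mass feature per structure, multiplicative Gaussian mass
  error (default sd **3 ppm**, a realistic calibrated-instrument spread
  well inside the 10 ppm tolerance), RT jitter sd 0.02 min;
- stochastic Na/K adduct and in-source GlcNAc-loss satellites (defaults
  0.3/0.1/0.15 per feature) that each divert 10% of the parent intensity,
  so cleanup can restore the true composition and total intensity is
  conserved by construction;
- decoy features (default 20 at 1e5 intensity) drawn uniformly over
  400–2500 Da and resampled until ≥ 30 ppm from every true, satellite and
  (optionally) database mass — so decoys are unmatchable by construction
  and any decoy identification is a pipeline bug;
- a fixed seed gives byte-identical output (`numpy.random.default_rng`).

It deliberately does not simulate chromatographic peak shape, isotope
envelopes, charge states or detector saturation — those live upstream of
the deconvoluted feature list this package consumes.

End-to-end, a composition at the bundled reference proportions is
recovered within 0.5 percentage points per structure at 3 ppm noise, with
zero decoy matches (enforced by the acceptance tests over several seeds).

## Limitations

- Identification is by intact monoisotopic mass only; isobaric structures
  (e.g. amidation + deacetylation combinations, Q/K vs E/J exchanges)
  cannot be distinguished and are reported as merged groups. MS/MS-level
  validation is out of scope; `chemistry.stem_fragment_masses` provides
  b/y stem fragment masses to support manual inspection.
- Trimers are modelled as linear chains (middle subunit both accepts and
  donates); branched trimers are not generated.
- The cleanup step only merges satellites into structures with direct
  evidence in the same run; co-eluting genuine structures at an adduct
  spacing would be merged incorrectly if the true parent were absent from
  the database.
- Quantification is by summed deconvoluted intensity and assumes equal
  response factors across muropeptides, as is conventional for relative
  (percent) composition.
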