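# muroseek

Muropeptide identification and quantification from deconvoluted LC-MS
feature lists, with dynamic theoretical-database generation covering 4-3,
3-3 and 1-3 peptidoglycan cross-links.

## Background

Peptidoglycan, the bacterial cell-wall polymer, is digested by muramidase
into soluble muropeptides: GlcNAc–MurNAc disaccharides carrying short
peptide stems, optionally cross-linked into dimers and trimers. LC-MS of
the (borohydride-reduced) digest yields a list of neutral monoisotopic
masses with retention times and intensities. Identifying those masses
requires a theoretical database of candidate structures — and because
cross-linked multimers explode combinatorially, the database is generated
*dynamically* from a small curated monomer list (DB0) plus a set of
cross-link rules.

`muroseek` implements this workflow with first-class support for the
unusual **1-3 cross-link** (donor stem a single alanine, acceptor the
*meso*-DAP of position 3), alongside the canonical 4-3 and 3-3 chemistries.
It ships the published muropeptide composition of *Gluconobacter oxydans*
B58 as a bundled reference dataset, used for validation and as a realistic
ground truth for the synthetic-data generator.

## Structure notation

Structures are written in gm-notation:

- `g` = GlcNAc, `m` = MurNAc (reduced to muramitol unless marked anhydro);
- stem residues follow a hyphen: `A` alanine, `E` isoglutamic acid,
  `J` *meso*-diaminopimelic acid (DAP), `J_NH2` (alias `Z`) amidated DAP,
  plus the standard one-letter amino acids;
- `=` joins cross-linked subunits: `gm-AEJ_NH2=gm-A` is the major 1-3
  dimer;
- trailing `(Anh)` marks a 1,6-anhydroMurNAc (glycan chain terminus),
  `(-Ac)` a de-N-acetylated glycan.

## Command-line workflow

```sh
# 1. Generate the theoretical database from a curated monomer CSV
muroseek build-db db0.csv --out db.csv
# INFO wrote 522 entries (28 monomer masses in) to db.csv

# 2. (Validation) simulate replicate runs at a known composition
muroseek simulate composition.csv --out run1.csv --seed 1
muroseek simulate composition.csv --out run2.csv --seed 2

# 3. Search the feature lists (several files = replicates)
muroseek search run1.csv run2.csv --db db.csv --out results.csv
# INFO run1.csv: 91 features, 48 direct matches, 20 unidentified
# INFO run2.csv: 90 features, 49 direct matches, 20 unidentified
# INFO cross-linking index: 19.9
```

`results.csv` holds the consolidated identifications:

```
Structure,RT (min),RT sd,Theoretical Mass (Da),Observed Mass (Da),Dppm,Intensity,Abundance (%)
gm-A,7.34,0.01,569.2432,569.2433,0.22,13849723.005539889,1.384
gm-AE,5.23,0.00,698.2858,698.2860,0.36,105177896.44207117,10.514
...
```

and `results.summary.csv` the compositional indices (cross-linking index,
glycan chain length, 1-3 content, dipeptide monomers). A JSON manifest
records inputs, configuration and a database fingerprint for every search.

Useful options: `--ppm` (tolerance, default 10), `--cleanup-min`
(adduct/in-source cleanup RT window, default 0.5 min), `--config` (YAML),
`--dialect ftrs`, `--rt-seconds`; for `build-db`: `--crosslinks 4-3,3-3,1-3`
(or `none`), `--restrict-gmA` (limit 1-3 donors to plain gm-A), `--mods`,
`--max-level`.

## Library example

```python
from muroseek.chemistry import mass_of
from muroseek.database import CrosslinkRules, build_database
from muroseek import reference
from muroseek.metrics import summarize

mass_of("gm-AEJ_NH2=gm-A")          # 1420.6194 (the major 1-3 dimer)
db = build_database(reference.db0_monomers(), CrosslinkRules())
len(db)                              # 522 mass entries

summary = summarize(reference.abundance_pairs("wt_stat_pct"))
round(summary.crosslink_index, 1)    # 19.9
```

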