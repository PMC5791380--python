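# confdiv

Structural bioinformatics pipeline for comparing the **conformational
diversity** of proteins crystallized in **aqueous (A)** versus
**non-aqueous/organic (O)** media.

Many proteins have several deposited crystal structures ("conformers" of an
identical sequence). When some of those structures were obtained in organic
solvents — ethanol, DMF, trifluoroethanol, MPD, ... — the ensemble can be
split into conformer pairs by crystallization environment: **AA** (both
aqueous), **AO** (mixed) and **OO** (both non-aqueous). Comparing the
maximum Cα RMSD pair of each subgroup, together with a panel of structural
descriptors, probes whether non-aqueous media kinetically trap proteins in
a narrower region of their native ensemble.

## What the package computes

- **Environment label** per conformer: O iff the crystal contains a HET
  group on an editable organic-solvent lexicon (`confdiv/data/solvents.txt`),
  read from the PDB HETATM records.
- **Pairing**: quality control (resolution < 4 Å, no mutations), grouping by
  100% sequence identity, bound-state matching (cognate-ligand triage by HET
  code), all AA/AO/OO pairs, and the maximum-RMSD pair per subgroup —
  RMSD from Kabsch least-squares superposition over common resolved Cα.
- **Metric panel** per conformer: Shrake–Rupley accessible surface area
  (absolute, relative to extended ALA-X-ALA references, buried fraction at
  the 25% threshold), three-state secondary structure from Kabsch–Sander
  backbone H-bond energies, geometric hydrogen-bond counts, mass-weighted
  radius of gyration, intrinsically disordered regions (≥ 5 consecutive
  missing residues outside the 20-residue termini), and grid-based interior
  cavities with B-factor flexibility scores.
- **Statistics**: per-subgroup means/medians, two-sample Kolmogorov–Smirnov
  tests for each subgroup pairing, one-way ANOVA, D'Agostino–Pearson
  normality, significance at α = 0.05.
- **Synthetic studies**: a seeded generator builds conformer ensembles with
  prescribed per-subgroup RMSD structure, injected solvents/ligands, missing
  regions and B-factor fields, so the whole pipeline is testable without any
  downloads.

## Worked example

Simulate a study and analyze it:

```bash
confdiv simulate -o study --n-proteins 10 --seed 3
confdiv run study -o results_dir
```

The report (`results_dir/report.txt`) summarizes each metric per subgroup.
For the RMSD of the maximum pairs this prints:

```
rmsd
  subgroup       n        mean      median
  AA            10       0.857       0.846
  AO            10       0.969       0.967
  OO            10       0.619       0.595
  KS AA_vs_AO  : D=0.400 p=0.418
  KS AA_vs_OO  : D=0.800 p=0.00206 *
  KS AO_vs_OO  : D=0.800 p=0.00206 *
  ANOVA: F=14.959 p=4.24e-05 *
```

meaning the OO pairs span a significantly narrower conformational range
than AA and AO pairs (starred comparisons), while AA and AO are
statistically indistinguishable — the signature of conformational
restriction in non-aqueous media that the pipeline is built to detect.

The library surface mirrors the CLI: `confdiv.parse_pdb`,
`confdiv.label_environment`, `confdiv.pair_rmsd`, `confdiv.asa`,
`confdiv.assign_ss`, `confdiv.count_hbonds`, `confdiv.detect_cavities`,
`confdiv.compare_subgroups`, `confdiv.make_benchmark`, and so on.

A real-data check on human Ras conformers (PDB 1xd2, 4dls, 1p2s, 4nym,
3rs5) is included in the test suite; coordinate files are not redistributed,
so fetch those entries into `tests/data/ras/` to run it.

## Layout

| Module | Role |
|---|---|
| `confdiv.io` / `confdiv.model` | PDB parsing/writing (gemmi-backed), structure model, missing-residue detection |
| `confdiv.environment` | solvent lexicon, A/O labeling, QC, grouping, pairing, max-pair selection |
| `confdiv.superpose` | Kabsch superposition, pairwise Cα RMSD |
| `confdiv.sasa` | Shrake–Rupley ASA, ALA-X-ALA references, buried fraction |
| `confdiv.secondary` | Kabsch–Sander H-bond energies, H/E/L assignment, per-element RMSD |
| `confdiv.hbonds` | geometric hydrogen-bond counting |
| `confdiv.metrics` | radius of gyration, IDRs, active-site metrics, pair deltas |
| `confdiv.cavities` | grid flood-fill cavity detection, flexibility |
| `confdiv.stats` | KS / ANOVA / normality, subgroup comparison report |
| `confdiv.synth` | seeded synthetic ensembles with prescribed RMSD structure |
| `confdiv.pipeline` / `confdiv.cli` | orchestration, tables, report, CLI |

See `docs/methods.md` for the scientific details and design choices.
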