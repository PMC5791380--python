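# Methods

This note documents the models, parameter choices and numerical decisions
behind `confdiv`, and what the synthetic-data tests do and do not establish
about real crystallographic data.

## Environment classification

A conformer is labeled **non-aqueous (O)** exactly when its HETATM records
contain at least one residue code on the organic-solvent lexicon; otherwise
**aqueous (A)**. This is a deliberately transparent heuristic: deposited PDB
headers rarely state solvent concentrations, so the presence of the solvent
molecule in the refined crystal is the usable evidence. Consequences to keep
in mind:

- the verdict is only as good as the lexicon. The shipped list
  (`confdiv/data/solvents.txt`, ~40 codes) is an editable policy file, and
  borderline cryoprotectants are a genuine judgment call: **GOL (glycerol)
  and the PEG/EDO family sit on the additive list by default**, while MPD
  and ethylene-glycol-as-solvent (EGL) sit on the solvent list. Move codes
  between the two files to change the policy; results that depend on lexicon
  composition should be reported together with the lexicon used.
- a solvent molecule must have been ordered enough to refine; weakly bound
  solvent is invisible, so A labels are noisier than O labels.

**Bound-state triage.** A conformer counts as ligand-bound when a HET code
survives after removing waters, lexicon solvents and the additive list
(ions, buffers, cryoprotectants). This separates cognate-ligand effects
(e.g. GTP, with its Mg²⁺ excluded as an ion) from solvent effects; only
bound–bound and unbound–unbound pairs are compared. The triage has no
notion of biological relevance beyond the code lists — a genuinely novel
ligand code is treated as cognate, an unlisted buffer as a ligand.

## Quality control and pairing

Structures need a resolution strictly below 4.0 Å and an unset mutation
flag (the flag is input metadata: detecting mutations requires a reference
sequence, which is upstream curation, not structure content). Conformers
group by exact sequence identity; when SEQRES is absent, sequences carry a
`-` per missing residue and identity ignores gap positions, so the same
crystal form with different disorder is never split. Within a group, every
same-bound-state pair gets a subgroup tag from its two labels, and per
subgroup only the **maximum-RMSD pair** is kept — the ensemble's diversity
summary. Ties resolve lexicographically on conformer ids for determinism.

## Structural metrics

**Superposition/RMSD.** Kabsch least-squares superposition (SVD of the
cross-covariance, reflection corrected to det +1) over the Cα atoms of
residues resolved in *both* conformers, paired by residue identifier —
sequences are identical by construction, so no alignment step exists to
disagree about. Residues missing in either conformer are excluded from the
superposition, the per-site deviations and the per-element means; this is
the only well-defined common-set policy. Collinear point sets are flagged
but still produce a result.

**ASA.** Shrake–Rupley sampling with 960 Fibonacci-lattice points per atom,
probe 1.4 Å, Bondi vdW radii (editable in `confdiv/data/vdw_radii.txt`),
heavy atoms only; waters always excluded, other HET groups excluded from
surface and occlusion by default (an `include_het` flag makes them
occluders). At 960 points the isolated-sphere error is < 0.5% and doubling
the point count moves global ASA by < 0.5%. Relative ASA divides a
residue's ASA by that residue type's ASA in an extended (φ=ψ=180°)
ALA-X-ALA tripeptide, computed once per type from ideal geometry with the
central side chain grafted from biotite's ideal residue templates — the
reference table is therefore consistent with the pipeline's own radii and
sampling rather than copied from another program (values differ from
published tables by a few percent; relative comparisons are unaffected).
Residues under 25% relative ASA count as buried; exactly 25% is exposed.

**Secondary structure.** Backbone N–H···O=C bonds are scored with the
Kabsch–Sander energy E = 0.084·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)·332
kcal/mol, amide H placed 1 Å from N anti to the preceding carbonyl
(prolines and chain starts donate nothing); a bond is E < −0.5. Two
consecutive i→i+k turns (k = 3, 4, 5) mark helix H; parallel/antiparallel
bridge patterns (intra- or inter-chain) mark strand E; everything else is
loop L. Helix wins where patterns overlap, and residues with an incomplete
backbone are forced L. This is a three-state reduction, not a full
eight-state reproduction. Per-element RMSD uses the class assignment of the
pair's first conformer (lexicographically smaller id) and Cα deviations.

**Hydrogen bonds.** Backbone donors use the placed amide H with criteria
D–A ≤ 3.9 Å, H–A ≤ 2.5 Å, D-H-A ≥ 90°; side-chain donors carry no modeled
hydrogens and use heavy-atom criteria (D–A ≤ 3.5 Å, antecedent-D-A ≥ 90°).
Waters and HET groups never participate; covalent neighbors (same residue,
backbone N(i)–O(i−1)) are excluded. Absolute counts are criterion-dependent
and will differ from hydrogen-resolved programs; differences and orderings
between conformers are the analysis surface. An ideal 12-residue α-helix
yields exactly its 8 i→i+4 bonds under these criteria.

**Disorder.** Missing residues come from REMARK 465 when present (the
authoritative source), else from numbering gaps between resolved residues —
never both, which would double-count; gaps spanning insertion codes are not
inferred. An intrinsically disordered region is a run of ≥ 5 consecutive
missing residues after clipping away the first and last 20 positions of the
chain (positions in SEQRES indexing, so renumbering offsets are harmless).
Missing-residue differences between conformers are reported both as raw
counts and as fractions of chain length.

**Cavities.** The structure is rasterized at 0.8 Å; points inside any
(r_vdw + 1.4 Å)-expanded atom are occupied, free space is segmented
(6-connectivity) and components reachable from the box boundary are
exterior. What remains are *fully enclosed voids*; open surface pockets are
deliberately not counted. Components below 30 Å³ are grid noise and
discarded. Volumes converge to < 10% under spacing halving and are stable
to < 5% under rigid rotation, but absolute volumes are method-dependent —
alpha-sphere or Voronoi detectors partition space differently — so only
counts, orderings and differences are compared across conformers. Cavity
flexibility is the mean of min–max-normalized B-factors (normalized over
the conformer's protein atoms) of the lining atoms, pooled over cavities;
it lives in [0, 1] and degenerates to 0 with constant B-factors.

## Statistics

Maximum pairs per subgroup are compared metric-wise: n/mean/median per
subgroup, two-sample Kolmogorov–Smirnov for AA–AO, AA–OO, AO–OO, and
one-way ANOVA across the three; significance at α = 0.05, deliberately
without multiple-testing correction, with both means and medians reported.
scipy.stats provides the machinery (exact KS p for small samples,
asymptotic otherwise); the test suite pins the small-sample p to an
exhaustive permutation enumeration and the KS type-I error at n = 50 to
[3.5%, 6.5%]. D'Agostino–Pearson refuses n < 20, where its z-transforms are
invalid.

## Synthetic studies: what they emulate and what they don't

The generator builds ideal-geometry poly-ALA backbones (N, Cα, C, O, Cβ)
with per-segment dihedrals (H: −57/−47, E: −119/113, coil randomized in the
β/PPII basin) and displaces conformers along smooth low-frequency chain
modes, orthogonalized against rigid-body motion, so per-site deviation
profiles are spatially coherent like real conformational change — not
i.i.d. noise. Subgroup structure is geometric: the two aqueous conformers
sit t_AA apart along mode 1, the organic cluster sits on mode 1 at the
offset that makes the widest AO pair equal t_AO, and the two organic
conformers differ by t_OO along an orthogonal mode. Amplitudes are
calibrated against measured post-superposition RMSDs (nonlinearity of the
rotational refit makes a one-shot scaling insufficient).

Default targets are AA 0.97 Å, AO 0.94 Å, OO 0.68 Å with a 0.15 Å
per-protein spread — aqueous pairs roughly 1.4× as diverse as non-aqueous
ones — at 50 proteins, 64 residues, 2 + 2 conformers; these are the study
conditions every statistical check runs under. One geometric constraint is
worth knowing: the widest AO pair can never be smaller than
√((t_AA/2)² + t_OO²), so sampled t_AO below that floor is raised to it,
biasing recovered AO means slightly upward (~5% under the defaults).

Passing tests on synthetic data establish that the *pipeline* recovers
prescribed effects (labels, subgroup RMSD structure, loop-localized change,
injected disorder) with correct statistics. They do not establish anything
about real crystals: poly-ALA backbones have no packed hydrophobic core
(buried fractions are a few percent, not ~45%), no real sheets-in-context,
usually no enclosed cavities, and solvent molecules are placed, not
observed. The one real-data check is the Ras worked example in the test
suite (PDB 1xd2/4dls/1p2s/4nym/3rs5; maximum pairs AA 3.14 Å, AO 3.01 Å,
OO 0.82 Å, tolerance ±0.15 Å covering superposition-method differences);
coordinates are not redistributed, so it runs only after fetching those
entries into `tests/data/ras/`.

## Numerical details and edge cases

- Altlocs: highest occupancy wins, ties prefer altloc 'A'; model 1 only.
- PDB writing is fixed-column v3.3; coordinates outside the field range are
  a hard error; parse∘write is identity on atoms, HET codes and missing
  runs (B-factors to the format's 0.01 precision).
- Unknown elements get a 1.80 Å default radius with a warning; unknown
  residue types have no relative-ASA reference and drop out of buried
  fraction (logged).
- Cavity grids exceeding a point budget coarsen with a warning.
- Empty subgroups or sub-minimum samples make that comparison absent
  ("n/a" in the rendered report), never an exception.
- Determinism: all generator randomness flows from one integer seed through
  numpy SeedSequence spawning; analysis outputs are bitwise-stable for a
  fixed input and config.

## Known limitations

- The A/O split inherits every bias of deposited HET content.
- Relative-ASA references from backbone-grafted ideal side chains differ by
  a few percent from NACCESS-style tables; buried-fraction thresholds are
  therefore not bit-comparable to other programs.
- Three-state SS and geometric H-bond criteria approximate, not reproduce,
  DSSP/HBPLUS.
- Tunnel analysis (length/number between surface and active site) is out of
  scope; only enclosed cavities are measured.
- Dataset-scale conclusions require a real multi-protein corpus (e.g. a
  conformational-diversity database); this package provides the measurement
  and comparison machinery plus synthetic validation, not the corpus.
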