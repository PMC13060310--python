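# Methods

This note documents the models, parameter choices and numerical decisions
behind `burialcode`, and what the synthetic benchmark does and does not
emulate.

## Structure model and input handling

Structures are single protein chains of ordered residues with heavy atoms
only. Parsing (via biotite) keeps the first model, resolves alternate
locations to the highest occupancy, strips hydrogens/waters/unmappable
hetero groups, and maps common non-standard residues (MSE, SEC, SEP, ...)
to their parent standard type. Residues are re-indexed 0..N−1 in file
order — all analyses work in sequence-ordinal space — with original PDB
numbers and insertion codes kept only as metadata.

Target/model pairs from prediction experiments typically differ by a few
residues at the termini. `align_and_trim` globally aligns the two
sequences (BLOSUM62; affine gaps, open −10, extend −0.5, the first gap
position charged open+extend) and trims terminal overhangs so lengths
match exactly. A pair whose *optimal* alignment needs interior gaps is
rejected: positional correspondence for per-residue labels would be
ambiguous, and only end-length differences are in scope.

Atomic radii come from an element-based table (C 1.70, N 1.55, O 1.52,
S 1.80 Å, default 1.80 Å) that can be overridden per (residue, atom) via a
JSON config. The radii set is a documented stand-in — published radii sets
differ at the few-percent level — and every SASA-derived quantity is
computed self-consistently against whatever table is active, so swapping
tables does not bias rSASA systematically.

## SASA, rSASA and core identity

Per-atom SASA uses the Shrake–Rupley construction: test points on each
probe-expanded sphere (probe 1.4 Å, the standard water-sized probe), a
point counted accessible iff outside every other expanded sphere. Points
are placed by a deterministic golden-section spiral, so results are
bit-reproducible with no RNG; the default budget of 960 points/atom keeps
the discretization error under ~1% (verified against the analytic sphere
and two-sphere cap formulas, and by 960-vs-3840-point convergence).

rSASA divides a residue's SASA by its area in an extended Gly-X-Gly host
built at run time **in the same representation and with the same radii,
probe and point budget** as the query structure. This self-consistent
reference was chosen over a fixed literature table so that rSASA stays
calibrated when the radii table or the coarse side-chain representation
changes; the Tien et al. (2013) theoretical max-ASA table ships as a
loadable override for users who want a fixed literature normalization.
Backbone atoms are included in both numerator and denominator. rSASA is
clamped to [0, 1.5]: conformations can slightly exceed the extended
reference, and such values are legal and always non-core.

Core identity is b_i = 1 iff rSASA_i < 0.1, strict at the boundary. The
0.1 default is the strictest burial definition that still tracks model
quality well; `cutoff_scan` recomputes ρ and the core fraction over a
cutoff grid to expose this sensitivity directly.

## Label channels

* **Contacts** — c_ij = 1 iff the Cα–Cα distance is strictly below 8 Å.
  The default applies no sequence-separation filter (all N(N−1)/2 pairs);
  a named preset (Cβ atoms, |i−j| > 6) matches the convention used when
  evaluating sequence-model contact predictions. Pair labels are always
  flattened in row-major upper-triangle order.
* **H-bond satisfaction** — backbone N–H···O=C bonds under the
  Kabsch–Sander electrostatic energy (coupling 27.888 kcal·Å/mol, cutoff
  −0.5 kcal/mol) with amide hydrogens rebuilt on the external bisector of
  C(i−1)–N–CA at 1.01 Å. Candidates require |i−j| ≥ 3: in an isolated
  ideal extended chain the i→i±2 geometry sits right at the energy
  threshold, and excluding it keeps "satisfied" meaning a genuine
  helix/turn/sheet partner. Proline and the N-terminus never donate.
* **Secondary structure** — a simplified three-state assignment from the
  H-bond graph: H for runs of ≥2 consecutive i→i+4 bonds, E for
  parallel/antiparallel bridge patterns, C otherwise. This is a
  deliberately reduced re-implementation, not a DSSP clone; 8-state parity
  is a non-goal and the channel is secondary to burial and contacts.
* **External alphabets** — any per-residue string over a declared alphabet
  (e.g. 3Di, predicted burial) ingests into the same LabelSet container
  and flows through φ and the information analysis unchanged.

## Agreement scores

φ is the Matthews correlation coefficient: determinant form for two
classes, the k-class R_K generalization otherwise (the two agree to
1e-12 on 2×2 inputs, which the tests enforce). A zero margin — e.g. a
model predicting no core at all — makes φ undefined; it is reported as 0
with a `degenerate` flag, matching the "no correlation" reading and
keeping downstream rank correlations well-defined.

Cα-LDDT uses inclusion radius 15 Å, thresholds {0.5, 1, 2, 4} Å, minimum
sequence separation 1 (i = j excluded only), strict inequalities on both
the inclusion and preservation tests, per-residue averaging over that
residue's reference pairs and a global mean over residues with at least
one reference pair. The target defines the reference pair set, so the
score is deliberately asymmetric in (target, model). All constants are
configurable because published LDDT variants differ in these details.

## Flattened bootstrap Spearman

Decoy sets are heavily skewed toward low-quality models, which lets the
low-LDDT mass dominate a plain rank correlation. All reported ρ values
therefore use a flattened bootstrap: LDDT is cut into 20 equal-width bins
on [0, 1]; each replicate draws an equal number of samples with
replacement from every non-empty bin (the smallest non-empty bin count,
so flattening is exact); the median Spearman over 1000 replicates is
reported. Ties get average ranks; a replicate with zero rank variance
contributes 0; an input whose φ values are all tied returns 0 with a
warning.

## Information accounting

Outcome probabilities p(x) are pooled frequencies over the native label
sets of the corpus (for benchmarks: the targets' own channels). Outcomes
never observed receive a Jeffreys pseudo-count of 0.5 so ι = −log₂ p stays
finite. Restraint subsampling selects, per target, a uniform random subset
of positions of the requested fraction (rounded half-up, minimum 1);
φ per decoy is computed over selected positions only, and
I = Σ ι(native label)/N is normalized per target and then averaged over
targets (a pooled-ΣN variant is available behind a flag; the difference is
negligible for similar-length targets). φ is computed per decoy — each
decoy is one point in the ρ computation — because LDDT is a per-decoy
quantity.

ρ-vs-I curves repeat each fraction `n_repeats` times (default 25); beyond
25 repeats the loop may stop early once the running mean of I moves by
less than 1% between repeats. Each fraction draws from an independent seed
stream spawned from the master seed, so fractions are reproducible in any
order. I* interpolates linearly between the two curve points bracketing
the ρ threshold (default 0.9) and is reported absent when the curve never
crosses — channel summaries sort by I* with absent entries last.

## Label-noise robustness and hydrophobicity

`flip_labels` flips each native core label independently with probability
p (decoy labels are never touched — the perturbation models errors in
knowledge of the *native* core). The robustness curve reports mean ± sd of
ρ over repeats per p, plus the realized flip fraction; externally
predicted native labels enter as single (f_flip, ρ) points via the same
machinery.

Core hydrophobicity is ℋ = (1/N) Σ h_i b_i with h_i from a named
per-residue scale; Δℋ = ℋ_native − ℋ_model, so Δℋ < 0 means the model
buried a more hydrophobic set than the native. The default scale is the
Eisenberg et al. (1984) normalized consensus scale, with Kyte–Doolittle
(1982) as a shipped alternate; the package's tests use a synthetic scale
so no literature values affect correctness. Per-type base rates use
H = −p_c log₂ p_c − p_s log₂ p_s with 0·log 0 := 0.

## Synthetic benchmark

`make_benchmark` stands in for an external target/model corpus. Targets
are idealized backbones: N/CA/C/O placed by natural-extension-reference-
frame construction from ideal bond geometry, helix (φ,ψ) = (−57°,−47°),
strand (−120°,120°), coil torsions sampled from four Ramachandran basins
(α, β, PPII, left-handed α). Side chains are a single volume-scaled sphere
at the idealized Cβ position (radius from the Zamyatnin residue volume
beyond glycine; glycine gets none): burial, contacts and LDDT only need
heavy-atom occupancy at roughly correct volume, and the rSASA reference is
computed in the same representation, so the coarse model is internally
consistent. Chains are rejection-sampled against Cα self-clashes
(non-bonded pairs < 3.2 Å) and then greedily compacted — single coil
torsions are resampled and accepted when the radius of gyration shrinks
without clashes — because an uncollapsed random chain buries almost
nothing and the burial channel would be vacuous. Typical generated targets
reach Rg ≈ 9–11 Å at N ≈ 40–60 with core fractions of 0.1–0.2.

Decoys add iid Gaussian noise to every atom over a ladder of sigmas
(0.05–2.8 Å, 4 decoys each by default, 40 per target), giving an LDDT
spread covering ~[0.25, 1.0] and ≥10 of the 20 flattening bins; a
geometry-preserving `segment_rotate` mode (rigid rotation of a random
contiguous segment) is available where covalent geometry matters. LDDT
against the native is computed for every decoy at generation time. All
randomness flows from one master seed through named substreams.

The default study conditions used by the test suite — 3 targets × 40
decoys, lengths 40–60 — were chosen once as the smallest benchmark that
exercises every pipeline stage with a well-spread LDDT distribution while
keeping a full suite run on one CPU in minutes.

**What the synthetic data does not emulate:** real side-chain packing and
rotamer detail, realistic secondary-structure composition and β-sheet
topology, the error correlations of actual structure predictors (Gaussian
noise is spatially uncorrelated; real model errors are not), and corpus
base rates — so ι values and ρ magnitudes on the synthetic benchmark
characterize the machinery, not any real proteome. Passing tests
demonstrate the correctness of the computations and the qualitative
structure of the results (burial and contact φ track LDDT; information
curves rise; noise degrades ρ monotonically), not quantitative agreement
with any real-data study.

## Known limitations

* PDB only (no mmCIF); single chains; first NMR model only.
* The Shrake–Rupley loop is pure numpy per atom — fine for chains of a
  few hundred residues, not tuned for proteome-scale scans.
* The three-state secondary structure detector is intentionally minimal;
  do not expect per-residue agreement with DSSP on edge cases (bulges,
  π-helices, bifurcated bonds).
* The ESM2/3Di encoders themselves are out of scope: external label
  strings are ingested, never generated.
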