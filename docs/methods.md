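# Methods

## Torsion-angle entropy by compressibility

The conformational order of a peptide chain over an ensemble is summarized
by the entropy of its torsion-angle time series. Each dihedral series
(degrees, IUPAC sign convention, range (−180°, +180°]) is discretized into
fixed-width bins — `symbol = floor((angle + 180)/w)`, +180° mapping into
the last bin — and the entropy of the symbol stream is estimated from its
compressed size:

    bits/symbol = 8 · (compressed_bytes − baseline_bytes) / n_symbols

where `baseline_bytes` is the compressed size of an empty payload (header
correction). The estimate therefore reflects the *entropy rate* of the
stream, not just its marginal frequencies: a deterministic period-2
alternation compresses to ~0.001 bits/symbol although a frequency-counting
estimator reports 1 bit. This is the reason compression, not counting, is
the primary estimator; the plug-in estimator (Shannon entropy of empirical
frequencies with the Miller–Madow correction (K−1)/(2N ln 2)) is kept as
an independent cross-check valid for memoryless streams.

**Bin width** defaults to 10° (36 bins): fine enough to separate
side-chain rotamer wells (~120° apart) and the α/β backbone basins, coarse
enough that desk-scale streams (10³–10⁵ frames) populate the occupied bins
well. Because S_tors depends on it, the bin width is echoed in all outputs.

**Compressor.** The estimator needs a general-purpose lossless compressor
whose per-symbol cost tracks the source entropy. zstd at its maximum level
(22) is the default: its finite-state-entropy coding stage stays within a
few percent of the plug-in estimate across planted entropies 0–5.17 bits
at N = 10⁵, whereas whole-bit Huffman coding (zlib) and LZMA's
match-biased modelling overshoot by 10–25% on skewed small alphabets. The
compressor is pluggable (`scoring.COMPRESSORS`; lzma and zlib are also
registered) and recorded in output provenance. Streams shorter than 1000
symbols trigger an "unreliable" warning; n_bins > 256 is rejected because
symbols are serialized one byte each.

**Angle sets.** Set I contains only φ, ψ, ω (backbone conformation);
Set II adds side-chain χ₁–χ₄ per a packaged plain-text table of IUPAC atom
quadruples (`confens/data/chi_atoms.tsv`, user-extensible). ω(i) is
assigned to the residue C-terminal to the peptide bond
(CA(i−1)-C(i−1)-N(i)-CA(i)); conventions differ, so this is stated.
Proline φ is included. χ angles with 2-fold-symmetric terminal groups
(Asp χ₂, Glu χ₃, Phe χ₂, Tyr χ₂) are folded into (−90°, +90°] by default
so that chemically identical orientations are not counted as two states —
this lowers S_tors and is configurable, since whether such folding should
precede entropy estimation is a genuine judgment call. Chain-terminal
angles whose defining quadruple does not exist are omitted, never padded;
consecutive residues with C–N > 2.5 Å are treated as a chain break.

## Model scoring and Pareto ranking

S_tors = mean of per-record compression entropies (each record compressed
independently, matching "average entropy over angles"; joint compression
of concatenated streams is possible but not the default because it mixes
inter-angle redundancy into a per-angle average). Its spread is the RMSD
across records. E_glob mean/spread are computed over the per-frame energy
series after discarding the first 10% of frames as equilibration (no
standard value exists; 10% is conservative for equilibrated inputs and
configurable). The energy series must match the frame count one-to-one.

Ranking uses Pareto dominance under (minimize S_tors, minimize E_glob).
If exactly one model is non-dominated it is reported as best; otherwise
the non-dominated front is reported without forcing a total order, and
front members within a configurable tolerance on both axes are co-reported
as ties. The report is invariant under adding a constant to all energies.
Spread bars are RMSDs across angle records (entropy) and frames (energy);
with replicate trajectories one point per replica is the intended usage.

## RMSF and mobility-region calling

Every frame is rigid-body fitted (Kabsch, SVD form with the reflection
branch corrected to det +1) on the Cα selection onto the ensemble-mean
structure, refined iteratively: fit to frame 0, take the mean, re-fit to
the mean, twice. RMSF(i) = √⟨|x_i − ⟨x_i⟩|²⟩. The mean-structure reference
with two refinement rounds is common practice; the selection is
configurable because whether to exclude flexible termini from the fit is a
study-level choice.

A small systematic bias is inherent to fitting: the rigid-body fit absorbs
6 of the 3R fluctuation degrees of freedom, shrinking RMSF by roughly
√(1 − 6/(3R)) — ~3% for R = 30 residues, <1% for R = 100. Recovery tests
therefore use chains of ≥100 residues.

Mobility calls compare mean RMSF profiles between conditions on the
intersection of their residue keys (a truncated mutant is handled
naturally). Residue i is *elevated* when Δ(i) = mean_alt − mean_ref
exceeds max(abs_floor, k · pooled inter-replica SD). Defaults:
abs_floor = 0.2 Å, k = 1.0, min_len = 4 residues, gap_tol = 1. Rationale:
the regions of interest in comparative deletion studies are ~5–20 residues
with Δ of a few tenths of an Å; 0.2 Å sits well above inter-replica noise
at a few hundred frames per replica while keeping such regions callable,
min_len = 4 suppresses single-residue excursions, and one tolerated gap
merges regions split by a single quiet residue. No numeric criterion
exists in the literature for "reproducibly increased mobility", so the
call's `reproducibility` field makes the criterion explicit: the fraction
of (ref, alt) replica pairs whose run-mean Δ is positive. Calling is
one-sided (increases only) by default, matching the usual question; a
two-sided mode exists behind a flag. The empirical null false-call rate
at these defaults is ≤5% over 20 generator repetitions.

## GROMOS clustering

All-pairs post-fit RMSD on the selection, then repeatedly: the frame with
the most neighbors within the cutoff becomes a center; it and its
neighbors are removed. Ties on neighbor count go to the lowest frame
index; cluster ids are relabelled by decreasing size. The implementation
is tested for exact agreement with an independent exhaustive
implementation over all distinct cutoffs of random ensembles.

## Structural features

**Hydrogen bonds** (site analysis): donors/acceptors are N/O heavy atoms.
With hydrogens present: D–A ≤ 3.5 Å and D–H···A ≥ 150° (30° deviation
from linear); without: distance only, each pair reported once. Pairs
within one residue and the trivially close peptide-bond pair
N(i+1)···O(i) are excluded. This geometric criterion is deliberately
distinct from the energetic criterion inside secondary-structure
assignment, because "hydrogen bond" is used loosely in site analysis but
precisely in DSSP-style assignment.

**Secondary structure**: Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond iff
E < −0.5; amide H reconstructed 1.0 Å from N opposite the preceding
carbonyl when absent, so crystal-style heavy-atom inputs work. n-turns
(3/4/5) give G/H/I via two consecutive turns; bridges (parallel and
antiparallel patterns) chain into ladders (E), isolated bridges B;
H-bonded turns T; bends (Cα angle > 70°) S. Priority
H > E > G > I > B > T > S > '-'. Helix runs are ≥4 by construction.

**β-turns**: residues i..i+3 with Cα(i)–Cα(i+3) ≤ 7 Å and the central
residues not both helical; types from the central (φ, ψ) against canonical
values (I: −60,−30/−90,0; II: −60,120/80,0; primed mirrors; VIII:
−60,−30/−120,120) at ±30° with one 45° allowance, else "other". Occupancy
is the exact fraction of frames in which the turn is present; stable iff
≥ 0.5. The 0.5 threshold for "stable"/"strong" (also used for H-bonds) is
a reported, configurable convention — the field labels features stable
without a number.

**Stacking**: ring centroids and SVD plane normals for Phe/Tyr/Trp/His;
contact iff centroid distance ≤ 5.5 Å and interplanar angle ≤ 30°
(parallel) or ≥ 60° (T-shaped); intermediate angles are not counted. The
reported class is the majority over frames present.

**Disulfides**: CYS Sγ–Sγ pairs within 2.3 Å (a covalent S–S bond is
~2.05 Å; the margin absorbs coordinate noise). Each cysteine joins at most
one bond; if several partners are in range the shortest wins with a
warning.

## Synthetic data: what it emulates and what it does not

The generator stands in for long explicit-solvent MD trajectories, which
are far outside desk scale. Each generator emulates exactly one property
with known truth:

* `gen_symbol_stream` — i.i.d. symbols with *exactly* the requested
  entropy: support size k = ⌈2^H⌉ (the smallest uniform support reaching
  the target, keeping the distribution minimally skewed) with a point
  mass on symbol 0 whose weight is solved by bisection.
* `gen_harmonic_ensemble` — reference + per-residue isotropic Gaussian
  displacement (expected RMSF σ√3) plus a random per-frame rigid motion,
  on by default so superposition is actually exercised by tests.
* `gen_mobility_pair` — replicate harmonic ensembles with extra σ planted
  in a residue range; replica seeds derived by SeedSequence spawning.
* `gen_ranking_pair` — chains rebuilt per frame from helix dihedrals with
  narrow (σ = 4°) versus wide (σ = 40°) wells, energy logs drawn around
  −15000 versus −14000 kJ/mol (σ = 100): entropy and energy orderings are
  both planted, mirroring an ordered-versus-molten model comparison at a
  magnitude plausible for a small protein globule.
* `gen_canonical_ss` — poly-ALA backbones built by sequential
  internal-coordinate placement with ideal geometry (N–CA 1.458, CA–C
  1.525, C–N 1.329 Å): helix (−57°, −47°), isolated strand (−139°, 135°),
  type-I turn, and a two-strand antiparallel hairpin. The hairpin uses
  fully extended flat strands (φ = ψ = 180°) related by a dyad about the
  sheet normal, with spacing and registration chosen by a deterministic
  scan maximizing inter-strand Kabsch–Sander bonds under a steric filter —
  twisted strand geometries cannot be paired by a rigid copy over a
  useful length.
* `gen_hbond_toggle` — a planted N–H···O=C bond present in an exact
  fraction of frames.

Randomness is NumPy PCG64 (`default_rng`) throughout; identical
`GeneratorSpec`s produce byte-identical outputs.

What passing tests on these fixtures shows: the estimators, detectors and
callers recover planted truth under their stated assumptions. What it does
not show: behavior on real trajectories, where fluctuations are
anisotropic and correlated, torsion streams are autocorrelated (compression
legitimately reports a lower entropy rate than the marginal entropy),
secondary structure is imperfect, and energy series drift. The analysis
code is agnostic to the provenance of its PDB/XVG inputs; only the
fixtures are idealized.

## Numerical choices and degenerate inputs

* Dihedral range (−180°, +180°]; −180° is mapped to +180°. Collinear
  triples raise an undefined-dihedral error.
* Kabsch requires ≥3 non-collinear points (second singular value test);
  reflection branch corrected via the determinant sign.
* Superposition weights, when given, are normalized internally.
* Occupancies are exact rational counts (present/total), so TSV outputs
  are bitwise reproducible.
* Altloc policy: highest occupancy, tie → first record. Insertion codes
  are rejected rather than silently misordered. Hydrogens are read when
  present, never required.
* Frame indexing is 0-based internally; residues are always identified by
  author numbering (chain_id, res_seq), so literature residue numbers are
  usable verbatim.
* PDB coordinates round-trip at the format's 3-decimal precision.

## Problem sizes

Defaults used by the test suite and acceptance script: entropy streams
N = 10⁵; RMSF recovery 5000 frames × 100 residues; mobility calling 3+3
replicas × 300 frames × 80 residues with 20 null repetitions; clustering
8 frames × 10 seeds at all distinct cutoffs; ranking pairs 2 × 1200
frames × 20 residues. These sizes put sampling noise well below the
tolerances being tested while keeping a full run to a few minutes on one
CPU.

## Known limitations

* mmCIF and binary trajectory formats are not read (the Ensemble contract
  would admit them later).
* No rotamer repacking after alanine substitution — coordinates are kept,
  side chain truncated at CB; repacking is an external-tool step.
* Potential energies are consumed, never computed: there is no force
  field here.
* DSSP-style assignment implements the Kabsch–Sander core (turns,
  bridges/ladders, bends) but not PP-helix detection or the full
  bulge-ladder merging of mature DSSP implementations.
* The β-turn/DSSP "T" distinction matters when a single residue is said
  to be "in a β-turn conformation": the package reports both 4-residue
  turns and per-residue T codes, covering both readings.
* Nucleic-acid torsions and improper dihedrals are out of scope.
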