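# Methods

## Palindrome definition and enumeration

A hit is a window *w* of a chain's one-letter sequence with
*w = reverse(w)*, length ≥ `min_len` (default 5) and ≤ `max_len` (default
9). Enumeration slides every allowed length one residue at a time; the
classical probe/target formulation (invert the probe, search the sequence
for the target) reports each self-palindromic window twice with the roles
swapped, so the enumerator emits each window exactly once and the test
suite checks equivalence against a literal probe/target implementation.
The scanned sequence is derived from ATOM records, not SEQRES: every
annotation downstream is structural, so palindromes must correspond to
residues with coordinates. SEQRES is still parsed for reference.

Design points that were genuinely open:

* **Self-palindromes only.** The probe/target machinery also finds inverted
  pairs at two distinct locations; those are a different object (inverted
  peptides) and are out of scope. A hit here always has probe position =
  target position.
* **Co-centred sub-palindromes are reported** (a 9-mer palindrome contains
  a co-centred 7-mer and 5-mer). Both readings occur in practice; a
  `maximal_only` flag suppresses nested windows for users who want only the
  outermost ones. Off by default.
* **CARP = all residues identical** (strictest reading). Two-letter
  repeats such as `ALALA` are legitimate palindromes and are kept.
* **'X' never matches itself.** Nonstandard residues (MSE, PTR, …) map to
  'X' and can never appear inside a hit; this is conservative and keeps
  modified residues from matching each other spuriously.
* **Completeness filter.** A residue is complete when all heavy atoms of
  its chemical component definition are present (hydrogens and OXT
  ignored); any window touching an incomplete residue is excluded, since
  its solvent accessibility and contacts would be understated.

Control windows ("non-PALINs") are drawn uniformly at random, with
replacement across the chain set, one per hit at the hit's length, rejecting
palindromic windows, windows failing the completeness filter and windows
positionally identical to a hit. Sampling is governed by a single integer
seed; a bounded number of retries (10,000) guards against degenerate chain
sets. The sampling scheme itself (uniform over valid placements) is a
choice; nothing in the survey protocol prescribes one.

## Secondary structure

The built-in assigner follows the hydrogen-bond-pattern approach of
Kabsch & Sander. The amide hydrogen is reconstructed 1.0 Å from N along
the C(i−1)→O(i−1) direction reversed (prolines and chain starts have no
donor); an H-bond between CO(i) and NH(j) exists when the electrostatic
energy `0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)` is below −0.5
kcal/mol (pairs closer than 0.5 Å count as bonded). n-turns (n = 3, 4, 5)
give G/H helices (two consecutive 4-turns mark residues i…i+3 as H),
bridges give E (laddered) or B (isolated), remaining turn spans are T,
CA-trace bends above 70° are S, and everything else is C. Residues missing
any backbone atom are '-'. All chains of a model are pooled so inter-chain
sheets register through bridges. Assembly priority is H, E, B, G, T, S.
This is a deliberately compact re-derivation, not a full DSSP reimplementation
(no π-helix, no sheet-label bookkeeping); on ideal-geometry fixtures it
agrees exactly with mdtraj's DSSP implementation, which the test suite
asserts. On real, irregular structures the two can differ at boundaries —
which is why precomputed DSSP files, when supplied (`--dssp-dir`), take
precedence, with '-' for residues absent from the file and 'C' for a blank
structure column.

The whole-window category uses a strict majority (> 50%) of H for helix
and of E for strand, helix checked first (both majorities cannot hold
simultaneously), coil only when every residue is C, otherwise irregular.
Whether G counts toward helix and B toward strand, and the majority
fraction itself, are parameters of `SSCategoryRule`: survey literature is
not uniform here, and the defaults are the strictest reading.

## Solvent accessibility

Shrake–Rupley sampling with a deterministic golden-spiral point set
(default 960 points) on each heavy atom's solvent-expanded sphere; a point
is buried if inside any neighbour's expanded sphere. Radii: C 1.7, N 1.55,
O 1.52, S 1.8 Å (plus a table for common hetero elements; unknown elements
fall back to 1.8 Å with a warning); probe 1.4 Å. The occlusion context is
all chains plus het groups; crystallographic waters are excluded by default
because their presence varies arbitrarily between entries and would bury
surfaces inconsistently (a flag restores them). Per-residue values are sums
over the residue's atoms; a window's value is the arithmetic mean over its
residues. The quadrature is deterministic given `n_points`; total-structure
SASA changes by < 1% from 960 to 3840 points and is rotation-invariant to
about 0.1% at 3840 points (asserted in tests). An independent cross-check
against Bio.PDB's Shrake–Rupley on the same file is part of the suite.
Published survey values computed with other programs (surface-point methods,
unstated radii) are expected to agree only within a few percent, so per-entry
comparisons use a ±10% or ±2 Å² band, whichever is larger.

## Contacts and functional interactions

A contact is a polymer residue outside the window, on any chain, with at
least one heavy atom within 3.2 Å of any window atom; each such residue
counts once no matter how many atom pairs qualify. Hydrogens and het groups
are excluded from the count by default (`include_h`/`include_het` flags
exist because legacy contact programs differ in their atom selections); het
groups instead feed the interaction flags. Interaction flags use a 3.9 Å
threshold (a typical heavy-atom contact distance in structure-annotation
databases): *ligand* for non-water, non-metal het atoms, *metal* for metal
elements, *site_or_catalytic* when a window residue appears in a SITE
record or a user-supplied catalytic list or contacts such a residue, and
*disulphide* when a window cysteine SG lies within 2.3 Å of another SG.
Unresolvable catalytic-list entries warn rather than fail.

## Hydropathy and sequence profiles

Kyte–Doolittle values, unweighted mean over the window, reported to two
decimals. The mean is invariant under reversal, so a palindrome's value is
direction-free by construction; all values lie in [−4.5, 4.5] (the scale's
extremes). Position frequency matrices are raw counts (L × 20); for a
palindrome-only input column i must equal column L−1−i exactly, a property
the tests enforce by recount. Consensus is the per-column argmax with
lexicographic tie-break (alphabetical first); logo rendering tools may
resolve ties differently, which only matters for exactly tied columns.
Exports are FASTA (60-column wrap) and TSV, one pair per (length,
category) group.

## Superposition

Kabsch superposition via SVD with reflection correction (det = +1
enforced); backbone atom set N, CA, C, O (CA-only available through the
`atoms` argument). Side-chain divergence applies the backbone transform
and reports per-position RMSD over the intersection of side-chain heavy-atom
names (coverage reported when atoms are missing); glycines have no
side-chain atoms and are skipped. The divergence threshold of 1.0 Å
operationalizes "different rotamer" and is configurable; it is a reporting
threshold, not a statistical claim. The test oracle is a direct numerical
minimization over rotation vectors with restarts.

## Synthetic data

The sequence generator draws background residues i.i.d. from configurable
frequencies (uniform by default — real proteomes are non-uniform, but
uniformity makes the accidental-palindrome rate analytic: a length-5 window
is palindromic with probability (1/20)², which the tests verify by
simulation against exact enumeration). Planted windows overwrite the
background at stated positions; ground truth and accidental background
palindromes are both recorded.

The structure builder places N, CA, C, O (and CB from the standard
L-configuration frame) by sequential internal-coordinate construction:
N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°. Conformers: helix (−57, −47),
strand (−139, 135), or custom per-residue φ/ψ; recomputed dihedrals match
the request to < 0.1°. The β-hairpin fixture joins two strands with a
two-residue turn whose dihedrals (strand −103.96/101.15, turn
62.43/−90.53 and −116.83/0) were refined once, offline, to make all narrow-
pair cross-strand hydrogen bonds strong (energies ≈ −3 kcal/mol); the
values are frozen constants, so the fixture is deterministic and builds in
milliseconds.

What the fixtures do **not** emulate: full side chains beyond CB,
imperfect experimental geometry, alternate conformations in the same file
coexisting with modified residues, crystal packing, or realistic residue
composition. Passing tests on synthetic data therefore demonstrate
correctness of the algorithms under controlled geometry, not calibration
against experimental structures; the per-entry published spot checks exist
for the latter and require the named PDB files on disk.

## Pipeline and reporting

`run_pipeline` processes entries independently; a failing entry is logged,
recorded in a failure manifest and skipped (the CLI exits non-zero only
when every entry fails). Every excluded window is logged with its reason
(CARP / missing atoms / nonstandard / duplicate / missing secondary
structure), and the exclusion table is written alongside the hit table so
counts are auditable. Output intervals are author-numbered, 1-based,
inclusive ("167–171" style); internal indices are 0-based half-open. All
outputs are TSV with a header row; rows are sorted on stable keys and all
randomness flows from the single configured seed, so reruns are
byte-identical.

Problem sizes in the test suite and acceptance script (1,000-sequence scan
comparisons, 1,000 planted chains of length 80, four-structure synthetic
surveys, 960-point quadrature) were chosen to exercise every code path at
desk scale; the pipeline itself streams entry by entry and has no
structural limit on dataset size.
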