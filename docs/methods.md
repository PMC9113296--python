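# Methods

This note documents the models, conventions and numerical choices behind
`naworm`, and what its synthetic test data does and does not establish.

## Pseudo-torsion model

Each nucleotide *i* is described by two pseudo-torsion angles spanning its
backbone neighbourhood:

* eta(i) = torsion(C4'(i−1), P(i), C4'(i), P(i+1))
* theta(i) = torsion(P(i), C4'(i), P(i+1), C4'(i+1))

and the primed pair eta'(i)/theta'(i) with C1' in place of C4'.  The torsion
kernel uses the IUPAC sign convention (cis = 0°, trans = 180°; positive for
clockwise rotation looking down the central bond) and reports angles on
[0, 360) — negative torsions have 360 added — matching the axis convention
of the 2-D plots and the worm CSVs.  A single function (`geometry.wrap360`)
owns this range choice.  The kernel agrees with biotite and MDAnalysis to
1e−6° on random quadruples, and with an independently written normal-vector
atan2 oracle in the test suite.  Note that the IUPAC-signed torsion is
*invariant* under reversal of the atom order (a chain read 3'→5' gives the
same signed angles); mirroring through a plane negates it.

Degenerate geometry — zero-length bond vectors, collinear atom triples,
flat sugar rings — yields *undefined* angles, never exceptions, so one
malformed residue cannot abort a whole-database build.  Undefined angles
never compare equal to any number and serialize as the explicit sentinel
`NA`.

### Definedness and chain breaks

eta(i) requires residues i−1, i, i+1 to exist and be backbone-connected;
theta(i) requires i and i+1.  Hence the first residue of a chain has eta
undefined, and the last residue has both angles undefined (theta(N) needs
C4'(N+1), and eta(N) needs P(N+1)).  Consecutive residues count as bonded
when the O3'(i)–P(i+1) distance is ≤ 2.0 Å if both atoms exist, falling
back to P(i)–P(i+1) ≤ 10.0 Å for coarse-grained models without O3'.  A
break makes exactly the spanning angles undefined.  Records are emitted for
*every* nucleotide, terminals included, so worm positions map 1:1 onto
sequence positions.

## Sugar pucker

The pucker label comes from the Altona–Sundaralingam pseudorotation phase
of the five endocyclic ring torsions nu0..nu4:

    tan P = (nu4 + nu1 − nu3 − nu0) / (2 nu2 (sin 36° + sin 72°))

evaluated with atan2, so nu2 = 0 needs no special case and the quadrant is
fixed by the sign of nu2.  Classification is the minimal binary North/South
split: P ∈ [270°, 360°) ∪ [0°, 90°) → C3'-endo, P ∈ [90°, 270°) →
C2'-endo; the half-open boundaries make twist states deterministic.  An
unphysically flat ring (all nu ≈ 0) or any missing ring atom gives an
undefined phase and the label `unknown`.  The full ten-state
envelope/twist taxonomy and the pucker amplitude are deliberately out of
scope: downstream consumers (plot markers, worm CSVs) only use the binary
label.

## Helical window

The helical/non-helical flag is a reporting convention, not a physical
constant: a nucleotide is "helical" when its (eta, theta) falls inside a
rectangular window in angle space, with periodic containment so the window
may wrap through 0/360.  The factory default is centered on the mean
interior (eta, theta) of the package's own ideal A-form fixture
(89.42°, 286.29°) with ±25° half-widths; both center and half-widths are
plain configuration (`helical_*` keys in the TOML config, or
`HelicalWindow` in code) because the synthetic fixture is a geometric
construction, not a literature A-form helix, and real-data users should
re-center the window on their reference helix of choice.  In C1'-only mode
the flag is derived from (eta', theta') against the same window.

## Worms, databases and motif search

A worm stores (position, author seq_id, residue name, eta, theta, pucker)
per nucleotide; CSVs carry a leading comment line recording the source id
and the angle mode (`c4` or `c1`), because a database stores exactly one
mode and probe/database mode mismatches must fail loudly rather than
silently compare eta with eta'.  Angles are printed with 3 decimals;
database builds process files in sorted-filename order, so rebuilding over
the same inputs is byte-identical.

Search scores a probe of length L against every length-L window with the
per-position periodic Euclidean distance

    delta_i = sqrt( d(eta_p, eta_w)² + d(theta_p, theta_w)² ),
    d(a, b) = min(|a − b|, 360 − |a − b|),

aggregated by the mean over comparable positions (sum is available as
explicit configuration).  Positions where any of the four angles is
undefined are incomparable; a window whose incomparable fraction exceeds a
threshold (default 0) is skipped, because terminal residues always carry
one undefined angle and zero-filling would bias scores toward chain ends.
Hits are ranked ascending, ties broken by (source id, window start), and
the top 20 returned by default; no score cutoff is applied.  The
implementation vectorizes all windows of a worm at once via numpy stride
tricks; the test suite checks full ranked-list equality against a plain
loop-based rescorer, plus invariance of all scores under a global rotation
of every angle.

## Synthetic fixtures

The generator builds idealized single-chain helices by applying one frozen
rise/twist step (32.7°/2.81 Å for the "A-form" RNA template, 36°/3.38 Å
for the "B-form" DNA template) to a template nucleotide constructed
geometrically:

* the furanose ring is a regular pentagon (≈1.42 Å edges) with an
  out-of-plane displacement pattern calibrated by deterministic scan so its
  pseudorotation phase hits the target (North ≈18° / South ≈162°);
* the phosphate is placed on the sphere |step(P) − C3'| = 3.02 Å nearest
  C5', and O3' on the C3'→P(i+1) line at 1.42 Å, making every O3'–P(i+1)
  distance exactly 1.60 Å — the chain is unbroken by construction;
* RNA templates carry O2', DNA templates do not, which also exercises the
  polymer-type classifier.

Because each residue is a rigid copy of its predecessor, all interior
pseudo-torsions are identical up to the 3-decimal coordinate rounding used
when writing PDB/mmCIF (observed spread ≲ 0.15°).  The fixtures are
self-consistent but not biophysically accurate: bases are absent, bond
geometry beyond the constraints above is schematic, and the eta/theta
values are not literature A-/B-form values.  All angle expectations in the
tests are therefore expressed relative to the fixture's own
oracle-recomputed values.  Passing tests demonstrate correctness of the
geometry pipeline, serialization and search machinery — not agreement with
any particular experimental structure, and not robustness to disorder,
missing density or altloc pathologies beyond the cases explicitly
constructed.

Decoy worms for search tests draw angles uniformly on [0, 360) from a
seeded generator (numpy PCG64), optionally overwriting a seeded random
window of one worm with a planted probe motif; identical arguments always
reproduce identical worms.

## Parsing decisions

Structure reading is backed by gemmi with content sniffing, so PDB and
mmCIF yield identical chain models.  Residues qualify as nucleotides via
gemmi's tabulated chemistry, with an atom-content fallback (sugar atoms
present, no lone alpha-carbon) for nonstandard names; modified nucleotides
are kept whenever the backbone atoms exist, since base identity is
irrelevant to the math.  Residues lacking all of P/C4'/C1' are dropped
with a warning and without renumbering survivors.  Alternate locations
resolve to the highest-occupancy conformer (tie → alphabetically first
altloc); hydrogens and anisotropic records are ignored.  Multi-model files
default to the first model, selectable by flag.  Both primed (`C4'`) and
starred (`C4*`) atom-name dialects are accepted and normalized to primed.
Polymer-type labels (RNA/DNA/unknown) come from a majority vote over
residue names and O2'/C2' content and affect only reporting, never the
angle math.

## Problem sizes

The default test-and-acceptance workload uses a 12-nt RNA helix, a 2×10-nt
DNA duplex, 8–20 decoy worms of length 50–60 (≈500–1000 windows per
search), and 10⁴ random quadruples for kernel validation; these sizes fully
exercise every code path while keeping the complete suite under ten
seconds.

## Known limitations

* The helical window default is fixture-derived; applying it to real
  structures without re-centering labels only geometries close to the
  synthetic helix as helical.
* No gapped or variable-length worm alignment; probes match only
  equal-length windows.
* No significance model for search scores — ranking only.
* Classical backbone torsions (alpha..zeta, chi) and suite classification
  are out of scope.
* Plot images are not pixel-tested; the sidecar tables are the contract.
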