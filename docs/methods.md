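# Methods

This note documents the models, conventions and numerical choices behind
`decoytools`, what the synthetic generators do and do not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Containers and numbering

All residue numbering is 1-based and inclusive, expressed in *reference*
numbering: letter *i* (0-based) of a stored string corresponds to position
`shift + i`, where `shift` comes from the chain's attached
`ReferenceSequence` (default 1). Selection expressions (`"43-64"`,
comma-separated unions, hyphen or en-dash) and region slices operate in
this numbering, and slicing preserves labels rather than renumbering — so
`slice_region(21, 56)` twice is the identity on the first slice, and a
mutation at position 46 is reported as `P46G` regardless of slicing.

`DesignTable` subclasses `pandas.DataFrame`; references ride in
`_metadata` and survive ordinary pandas operations (sorting, boolean
selection, `head`). Casting to and from a plain frame preserves every
cell, which is what makes the CSV/JSON round-trips exact.

Conventions chosen where the design was genuinely open:

- **Re-adding a reference replaces it** (last write wins).
- **Gap characters count as mutations** against a reference letter, and
  are **excluded from frequency normalisation** by default (a position
  observed only as gaps yields an all-zero row, flagged in
  `empty_positions`); an optional gap column can be requested.
- **Residue-constrained selection** (`get_sequence_with`) thresholds the
  *fraction* of matching (position, letter) pairs with `>=` confidence; no
  rounding of `confidence × len(pairs)` to a count is performed.
  `invert=True` is the exact complement, so `confidence = 1/len(pairs)`
  with `invert` means "contains none of the listed residues".
- **Quantile filtering** uses the linear-interpolation quantile and a
  strict inequality (`score < q(0.05)` for lower-is-better), so an
  all-equal column selects nothing — the documented edge case of a strict
  percentile rule.
- **Variant enumeration** is the full Cartesian product of the per-position
  option sets; the template letter participates only if listed. The
  template combination therefore appears exactly once when every template
  letter is among its options, and is flagged in the boolean
  `is_template` column rather than deduplicated away.
- **Duplicate decoy identifiers** are kept on parse with a warning;
  `deduplicate_identifiers` renames repeats (`_r2`, `_r3`, ...) on request,
  since design reruns commonly repeat names.
- **Resfile dialect**: header line (default `NATAA`), `start`, then one
  `<resnum> <chain> PIKAA <newAA>` line per mutation relative to the
  reference.

## Sequence statistics

Frequencies are per-position relative counts over non-gap observations.
Enrichment is the cellwise difference between the top-fraction matrix and
the whole-population matrix (rows sum to 0 by construction); the
overrepresentation rule selects positions whose maximal difference exceeds
a threshold (0.20 by default) and reports the argmax letter.

Information content follows the Schneider–Stephens logo convention:
`bits(i) = log2(20) − H(i)` with `H` the Shannon entropy over non-zero
cells; letter heights are `f(i,a) · bits(i)` and stacks are drawn in
ascending frequency order. No small-sample correction is applied by
default; passing the population size enables the standard
`(s−1)/(2 ln2 · n)` correction. A raw-frequency height mode is provided
because the community is split on the convention for design populations.

Per-residue substitution scoring is a positional lookup
`M[design_i, reference_i]` with no alignment and no gap penalties; gaps and
non-standard letters yield undefined cells that break the plotted line.
BLOSUM62 (and the other standard matrices) come from Biopython's bundled
`substitution_matrices` data, which ships the canonical published tables.

## Geometry

Torsions use the IUPAC sign convention,
`atan2(((b1×b2)×(b2×b3))·b̂2, (b1×b2)·(b2×b3))`, with results in
(−180°, 180°]; degenerate (collinear) configurations return NaN rather
than raising, because real structures contain them. Backbone dihedrals are
undefined at segment termini; a chain break is declared on a residue
numbering gap or a Cα–Cα distance above 4.5 Å, and residues missing any of
N/CA/C are flagged incomplete, undefining every dihedral they touch.

Ramachandran flavours are assigned with the precedence
PRO > PRE-PRO > GLY > GENERAL (a glycine immediately before proline is
PRE-PRO). The plotted background regions are deliberately coarse embedded
polygons around the canonical basins — orientation aids, not statistical
contours. The secondary-structure call from φ/ψ alone (broad α and β
boxes) is likewise approximate and labelled as such; it is not a
hydrogen-bond based assignment.

Kabsch superposition is the standard SVD construction with the determinant
sign correction, so reflections are never returned; for degenerate point
sets the RMSD is still optimal but the rotation may be non-unique.

Fragment quality: each fragment instance carries only dihedrals, so its
backbone is rebuilt by forward kinematics (NeRF) with ideal covalent
geometry — bond lengths N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω from the file — and its Cα
trace superposed onto the query window `[p, p+k−1]`. Because the rebuild
assumes ideal geometry, absolute RMSDs against experimentally determined
structures are approximate; orderings between fragment sets (the quantity
the profiles are read for) are meaningful. A window rebuilt from a
structure's own dihedrals reproduces those dihedrals to better than 1e−6°
(float64 round-trip, verified in the suite), so self-comparisons sit at
numerical zero. Frames whose query window is incomplete or spans a break
get NaN quality and drop out of profiles.

## File formats

The silent parser commits to the *score subset*: the first `SCORE:` line
is the header (ending in `description`), later `SCORE:` lines are rows,
`ANNOTATED_SEQUENCE:` lines attach sequences with `[...]` annotation
suffixes stripped, and every other line type is skipped. Rows with the
wrong field count are skipped with a warning and counted in
`table.attrs["skipped_rows"]`. The bundled silent *writer* exists to make
round-trips testable, not to produce coordinate-bearing files. Score-JSON
is one object per line with the union of keys as columns. All text readers
accept gzip input transparently.

PDB backbones are read through Biopython's permissive parser: first model
only, first altLoc kept, insertion codes preserved, HETATM ignored.
Clustal blocks are parsed by a small dedicated reader (full first token as
the identifier, conservation lines ignored, no consensus line required)
so that ragged alignments can be reported with the offending identifier.

CD and SPR have no standard interchange format, so this project defines
plain CSV dialects: CD as `wavelength,ellipticity,temperature` (strictly
monotone wavelengths per series) and SPR as
`time,response,series,concentration` with `series ∈ {measured, fitted}`
(monotone non-decreasing time per series). The reference-domain loader is
a generic CSV reader (`id,length,score,...`) with a length-window filter;
it makes no assumption about where the table came from.

## Synthetic generators

All generators are pure functions of `FixtureConfig` (numpy
`default_rng((seed, stream))`, no global state): the same config yields
byte-identical files. The default configuration is the condition set the
test suite measures: 1000 decoys of 60 residues, planted enrichment at
positions 34/35/46/47 with margin 0.30 over a background enriched-letter
frequency of 0.30, top fraction 5%, 9-mer fragments with 200 neighbors,
and a helix–loop–strand–loop–helix backbone.

The population generator plants the signal deterministically: it draws
scores from a normal model, identifies the top-q rows by the same strict
quantile rule the selection operation uses, and sets the *count* of
enriched-letter carriers in the top and non-top groups to
`round(p·n_group)` with `p_top − p_rest = margin/(1−q)`, so the realised
top-vs-all frequency difference equals the margin up to rounding rather
than relying on sampling luck. An RMSD-like column correlated with score
is included so score-vs-rms scatter shows the funnel shape used in
refolding analysis. What this does **not** emulate: physical energies,
covariation between positions, indels, or any relationship between a
decoy's sequence and its score beyond the planted positions — so passing
tests demonstrate the statistics and bookkeeping are correct, not that any
particular design protocol works.

CD traces follow a two-state helix–coil melt (sigmoidal helix fraction
around `melt_tm`, Gaussian-basis helix and coil spectra, additive noise);
SPR traces follow 1:1 Langmuir association/dissociation kinetics with
noise on the measured series only. Both are shape-realistic stand-ins for
instrument output, not instrument models.

## Problem sizes

The shipped suite and the acceptance script run at deliberately modest
sizes chosen as the package's own defaults: populations of 40–1000
decoys, 60-residue backbones, fragment libraries of 5–200 neighbors,
1000-transform invariance sweeps, 20-set SO(3) oracle comparisons and
200-population conservation sweeps. All scale linearly if larger runs are
wanted.

## Known limitations

- No alignment anywhere: sequence comparisons are positional, so indels
  require pre-aligned input (gaps are honoured but never introduced).
- The silent dialect covers score tables only; binary/coordinate silent
  variants and HMMER output parsing are out of scope.
- Fragment-quality values are ideal-geometry approximations (see above).
- The CLI is a thin veneer; anything beyond its flags is meant to be done
  through the library.
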