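# Methods

`pfvmkit` predicts conformational *ensembles* for a protein from its
bare sequence, using a discrete structural alphabet rather than an
energy function or a learned model. This note records the model, its
assumptions, the parameters that matter, and the limits of what the
synthetic test bed can show.

## The fold alphabet

The elementary folding unit is a window of five consecutive residues —
the shortest stretch of backbone that carries two consecutive dihedral
environments. The window's Cα geometry is summarised by three internal
descriptors:

* `tau1` — pseudo-torsion of Cα(i), Cα(i+1), Cα(i+2), Cα(i+3);
* `tau2` — pseudo-torsion of Cα(i+1) … Cα(i+4);
* `theta` — bend angle at Cα(i+2) spanned by Cα(i), Cα(i+2), Cα(i+4).

Torsions follow the IUPAC right-handed convention in (−180°, 180°];
angles are in [0°, 180°]. Each descriptor is quantized into three bins,
so the descriptor cube has 3 × 3 × 3 = 27 cells, mapped bijectively onto
26 letters plus `$`:

* `A` — the cell holding the canonical α-helix window geometry,
  measured once on the noise-free ideal generator and frozen:
  (τ1, τ2, θ) = (51.51°, 51.51°, 71.67°);
* `B` — the canonical β-strand cell, from (178.71°, 178.71°, 179.99°);
* `$` — the degenerate cell (near-zero torsions, near-straight bend:
  where collinear traces land), merged with the undefined symbol that
  also marks windows with missing Cα atoms or chain breaks;
* `C`–`Z` — the remaining 24 cells in lexicographic cell order.

Symbols are classed as helix (1), alike-helix (the 5 valid cells one
bin step from the helix cell), strand (1), alike-strand (6), irregular
(13) and undefined (1). Classes drive report styling and alignment
weights.

### Bin boundaries

Boundaries are configuration (`QuantizerConfig`), not constants.
Pseudo-torsions are periodic, so tau bins are defined by three *cyclic*
cut points; the defaults are cuts at (−130°, −10°, 110°) for both taus
and edges at 40° and 140° for theta. These were chosen from the
measured jitter response of the ideal generator: 5° Gaussian jitter on
(φ, ψ) spreads the helix bend angle over roughly [49°, 95°] and the
strand pseudo-torsion over roughly [151°, 203°] (wrapping ±180°), so
every canonical descriptor sits at least ~9° from its nearest cut and
the encoding of a canonical segment is stable under that noise level.
A boundary at ±180° would cut straight through the strand torsion,
which is why the tau bins are cyclic. The quantizer refuses any
configuration in which the helix, strand and degenerate cells are not
three distinct cells.

The encoder is deterministic, idempotent, and — because all descriptors
are internal coordinates — invariant under rigid motion. A chain of N
residues encodes to exactly N − 4 symbols; perturbing one Cα can change
at most the 5 windows containing it.

## Pentamer database and the fold-variation matrix

Every window of every corpus chain contributes one observation
(pentamer sequence → fold code). Records rank codes by raw count,
descending, ties broken lexicographically; no source weighting is
applied. Windows encoding `$` and pentamers containing non-standard
residues are excluded.

20⁵ = 3,200,000 pentamer sequences exist and a desk-scale corpus covers
a sliver of them, so queries for unseen pentamers return the
corpus-wide *background* ranking truncated to `k_backoff` (default 5)
codes, flagged `synthetic`. This statistical backoff is the package's
substitute for running molecular dynamics on unseen pentamers, which is
out of scope here; synthetic columns are marked in every report so that
conclusions can be traced to observation or to backoff.

The protein folding variation matrix (PFVM) of a sequence has one
ranked column per sliding window (|sequence| − 4 columns). Treating
each column as an independent categorical distribution with
probabilities proportional to counts gives:

* `PFVM-01` — the rank-1 code of every column, the single most
  favoured conformation string;
* an exact conformation count — the big-integer product of column
  depths (for real proteins an astronomical number; for the published
  P53 DNA-binding-domain matrix ~1.33 × 10¹⁵⁰);
* a log-probability score for any contained string, the sum of
  per-column log frequencies.

Ensemble strings are generated either by single-column substitution of
`PFVM-01` (ranks 2..`max_rank`) or as the exact top-k of the product
distribution. Because columns are independent, sweeping columns while
keeping the k best partial strings is exact, not heuristic. No
compatibility constraint is imposed between adjacent overlapping
windows at this stage; overlap coherence is resolved downstream by
fragment search against real geometry.

## Alignment score

Two conformation strings are compared position by position (equal
lengths) or by global alignment with affine gaps (Gotoh recursion;
defaults gap open −0.5, extend −0.1). Aligned symbols weigh: identical
1.0; same class 0.8; a typical fold vs its "alike" class 0.5; anything
else 0.0. The undefined symbol weighs 0.0 against any *different*
symbol, but identical symbols always weigh 1.0 — this keeps the
identity endpoint exact (self-alignment = 1.00) even for strings
containing `$` windows, which complete structures can legitimately
produce through the degenerate cell. The score is the mean weight over
the alignment, normalized by the longer length when lengths differ, so
it lives in [0, 1]; 0.70 is the downstream acceptance threshold for
conformational homologs. The 1.0/0.8/0.5/0.0 ladder is this package's
calibration; only the endpoints (identity 1.00, acceptance 0.70) are
fixed contracts.

## Fragment search and model assembly

A structure library stores each chain with its fold string, indexed by
8-gram. Query strings are cut into spans of `target_len` 45 residues
with 4-residue overlap (one encoder window) — whole chains rarely find
a full-length homolog above 0.70, fragments of 40–50 residues do. Every
k-gram of the query fragment votes for candidate source windows, each
candidate is scored positionwise, and hits strictly above the threshold
are ranked by score, source id, position. When a span finds nothing the
threshold relaxes down a ladder (0.70 → 0.60 → 0.50); a member whose
span is empty at the floor is dropped with a logged reason.

Fragments are spliced left to right: each incoming fragment is rigidly
superposed (least-squares, Kabsch) onto the growing model over the
shared overlap residues and its new residues appended. Junction RMSDs
are reported, never enforced; junction geometry is not energy-checked
and no loop closure or clash resolution is attempted. Models are
Cα traces only.

Note the k-gram seeding is a recall heuristic: a source window scoring
above threshold with no exact shared 8-gram would be missed. On
realistic fragments (31+ windows at score > 0.70) shared exact runs are
essentially always present; the test suite checks equality with an
exhaustive window scan on its corpus.

## Synthetic test bed

The generator grows N–Cα–C backbones from (φ, ψ) torsions (helix
−57°/−47°, strand −139°/+135°, coil uniform over φ ∈ [−160°, −45°],
ψ ∈ [−80°, 170°]) with ideal bond geometry and trans peptides, giving
the ~3.8 Å Cα virtual bond, then keeps the Cα trace. Gaussian jitter on
the torsions (library default 2°) emulates thermal/experimental spread.
Libraries of 10 mixed-segment chains of 30–120 residues, with
sequences drawn from a reduced 8-letter alphabet in the tests so that
pentamers recur across chains — the recurrence regime a full-PDB corpus
reaches with the real 20-letter alphabet.

What this test bed does *not* emulate: real Ramachandran statistics
(coil is uniform, not basin-weighted), sequence-dependent fold
propensity (fixture sequences are independent of geometry, so observed
pentamer→fold associations are arbitrary though reproducible),
side-chain packing, and the scale of the real database. Passing tests
therefore demonstrate the *mechanics* — encoding laws, count
conservation, containment, exact optimality, retrieval and splicing
round trips — not predictive accuracy on real proteins.

## Numerical choices and degenerate inputs

* Collinear point runs: torsion undefined → 0.0 by convention, bend
  180°; the window lands in the degenerate cell → `$`.
* Chain breaks: consecutive Cα distance outside [2.0, 4.5] Å; windows
  spanning a break encode `$`. Residues are renumbered 1-based by
  ordinal, because matrix columns are defined on sequence ordinals.
* Alternate locations: highest occupancy wins, then smallest altloc id.
* All ties everywhere (pattern ranks, variant ordering, hit ranking)
  break lexicographically, making every stage deterministic; two runs
  with identical inputs produce byte-identical artifacts (manifests
  carry no timestamps).
* Conformation counts use exact big integers; no floating-point
  overflow at any matrix size.
* Superposition needs ≥ 3 paired points; assembly refuses overlaps
  shorter than 3 residues.

## Known limitations

* The letter-to-geometry assignment is this package's own frozen
  convention; strings are not interchangeable with encodings produced
  by other structural-alphabet software.
* Retrieval ambiguity: repetitive fold strings (long helix runs) can
  recur verbatim in a library; any tied source is an equally valid
  homolog, so exact coordinate round-trips are only guaranteed for
  unambiguous queries.
* Reproducing the published P53 conformation count requires the
  published matrix itself (a journal supplementary file, not
  redistributable); converted to the PFVM TSV interchange format at
  `data/p53_dbd_pfvm.tsv` it is picked up by the acceptance suite.
* Models are unrefined Cα traces; no molecular-dynamics polishing, no
  all-atom reconstruction.
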