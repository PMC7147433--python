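# Methods

## Model of the molecule

A plastome is treated as a circle of length `L` over the IUPAC nucleotide
alphabet carrying exactly one long inverted-repeat pair: two disjoint arcs
of equal length whose sequences are reverse complements of each other
(possibly with scattered interior mismatches), separated by two unequal
single-copy arcs. The linearization observed in a file is an arbitrary
rotation of this circle on an arbitrary strand. Curation is therefore a
pure rotation of the input string or of its reverse complement; base
content is conserved exactly, which is asserted as an invariant.

## Detection

**Windows.** The circle is tiled with non-overlapping windows of
`window_size` bp starting at 0, w, 2w, …; when `L` is not a multiple of
`w` the final window wraps across the origin (up to `w−1` bases near the
origin are covered twice, which is harmless because matches are deduplicated
positionally). Windows whose fraction of non-ACGT characters exceeds
`max_ambiguous_fraction` (default 0.1) are excluded from matching; runs of
Ns therefore cannot seed matches, but can still be bridged by the merge
step.

**Matching.** Each clean window is searched, as an exact string, against
the reverse complement of the whole circle at *every* offset (implemented
as substring search over the doubled sequence). Grid-to-grid matching
would be wrong: the second repeat copy is grid-aligned with the first only
when `a + b + ℓ ≡ 0 (mod w)` for copy starts `a`, `b` and length `ℓ`,
which almost never holds for an arbitrary rotation.

**Anti-diagonal clustering.** If base `p` of one copy pairs with base
`c − 1 − p (mod L)` of the other, then every matched window pair `(i, j)`
satisfies `i + j + w ≡ c (mod L)` exactly. Substitution-type noise never
changes `c`; only an indel between the copies does. Matches are grouped by
`c`, consecutive windows form runs, and mirror runs (the same repeat seen
from the other copy's windows) are unified through the reflection
`p ↦ c − 1 − p`.

**Gapped-palindrome repair.** Interior mismatch patches fragment the
match runs. All fragments sharing a pairing constant (within
`ir_discrepancy_tolerance` of the dominant one, default 500 bp) are merged
by taking the hull from the outermost extremes; only the extremes define
the repeat, interior disagreement is counted in `mismatches`, never
corrected. A fragment whose constant differs by more than the tolerance
implies copies of different lengths (an indel-style misassembly); if its
territory overlaps the chosen repeat the record fails with
`multiple_candidate_pairs_unresolved` rather than guessing. Other
non-overlapping repeats are legitimate (plastomes contain short dispersed
repeats) and are merely counted in `n_candidate_pairs_considered`; the
longest pair wins, ties broken by smaller circular start.

**Boundary refinement.** Starting from the window-resolution extremes
(always inside the true repeat), each edge is extended outward base by
base while the complement pairing holds. A mismatch run of up to 50 bp is
stepped over only when followed by at least 12 consecutive exact pairings.
The continuation length is set by a chance-match argument, not by tuning:
in unrelated single-copy flanking sequence a base pairs by chance with
probability 1/4, so a false 12-base continuation occurs with probability
4^-12 ≈ 6·10⁻⁸ per boundary — negligible across the whole test volume —
while genuine scattered substitutions near a repeat end (the realistic
noise mode) are skipped and counted as interior mismatches. After
extension each edge retracts to the outermost exactly-pairing base, so on
clean sequence the reported boundaries are the maximal exact palindrome,
which the generator certifies to coincide with the planted truth.
Consequences worth knowing: two mismatches within 12 bp of each other, or
a mismatch within 12 bp of the true boundary, stop the extension early and
yield a conservatively short repeat — visible in the robustness experiment
as small boundary errors at low divergence.

## Partition and canonical rewrite

The two arcs between the copies are labelled LSC (longer) and SSC
(shorter); equal arcs or adjacent copies are biologically aberrant and
fail the record. "IRb" is positional: the copy that follows the LSC in
the output reading sense — inputs without annotations must still curate,
so gene content is never consulted.

The same molecule admits exactly two canonical linearizations, one per
strand, each starting at its LSC's first base. The emitted one is the
lexicographically smaller of the two candidate strings. This rule is
arbitrary but total, deterministic, and strand/rotation-invariant, which
gives the key property: all linearizations of the same molecule, on either
strand, produce byte-identical output, and curation is idempotent. (A
"canonical SSC sense" cannot be chosen independently of the whole-molecule
strand without editing the sequence, which would break base conservation;
the lex rule fixes both at once.)

`--orient` replaces the lex choice by batch consensus: the first curated
record is the reference, and every other record keeps or swaps its strand
candidate according to which LSC shares more 15-mers with the reference
LSC. Stranded (non-canonicalized) k-mers are used deliberately — a k-mer
set closed under reverse complement is identical for both orientations and
carries no signal.

## Annotation liftover

The coordinate transform is the affine circular map `out = (p − anchor)
mod L` (forward) or `out = (anchor − p) mod L` with complementation
(flipped). Feature sub-intervals are mapped piecewise, split only at the
output origin, merged when they become adjacent, and strand labels flip
with the molecule. The fidelity contract — extracting a lifted feature
from the curated sequence reproduces the input feature's sequence exactly,
including multi-exon, minus-strand and origin-wrapping features — is
asserted for every feature in the test fixtures.

## Synthetic data

The generator draws i.i.d. bases at GC 0.37 (plastome-like; composition
does not affect any contract), builds LSC + IRb + SSC + rc(IRb), and
enforces two certificates before emitting: (i) a brute-force 40-mer scan
proves no inverted match exists off the planted pairing, so the planted
repeat is the unique answer at any detection window ≥ 40 bp; (ii) the
bases flanking the repeat boundaries do not extend the palindrome, so the
planted boundaries are base-exact truth. The molecule is then linearized
at one of nine cut positions (conventional start, two inside the LSC, the
IRb start, mid-IRb, the SSC start, mid-SSC, the IRa start, mid-IRa — the
mid-IR cuts split a repeat across the sequence ends) and optionally
strand-flipped. Default sizes are LSC 8,500 / IR 2,500 / SSC 1,800 bp,
one order of magnitude below real plastomes so sweeps of thousands of
curations run in seconds; a full-scale profile with the region sizes of
the *Arabidopsis thaliana* chloroplast (LSC 84,170 / IR 26,264 /
SSC 17,780 bp) is provided for the robustness experiment. What the
generator does **not** emulate: indels and rearrangements, sequencing-read
noise outside the IRs, gene content, and the biased composition of real
intergenic spacers — passing tests demonstrate the geometric and
coordinate contracts, not base-caller realism.

## Robustness experiment

`round(level × IR length)` positions inside one IR copy are substituted to
a different base, uniformly without replacement, so the planted count
equals the number of inter-copy mismatching positions. Eleven divergence
levels are spaced geometrically over 0.01%–5.31%. A replicate is scored
*correct* only when all four detected boundary positions equal the truth
exactly (tolerance 0 by default). Per-replicate seeds derive from the
master seed via `numpy` SeedSequence spawning, making the whole report a
pure function of the configuration. On the desk-scale substrate with
window 250 the recovery rate is 100% at zero alterations and decays
monotonically (Spearman ρ ≈ −0.97 at 100 replicates/level); on the
Arabidopsis-scale substrate with the default window of 1000 and 22 planted
alterations, recovery stays above 90%.

## Defaults and numerical choices

| parameter | default | why |
|---|---|---|
| `window_size` | 1000 bp | matches one IR window even in small repeats; larger = specific, smaller = sensitive |
| `min_ir_length` | = window size | at least one full window must match |
| `ir_discrepancy_tolerance` | 500 bp | below one window: gross copy-length disagreement fails loudly but small indels merge |
| `max_ambiguous_fraction` | 0.1 | N-runs excluded from seeding, bridgeable by repair |
| refinement skip / continuation | 50 / 12 bp | chance-continuation probability 4⁻¹² (see above) |
| GC of synthetic bases | 0.37 | plastome-like composition |
| scaled region sizes | 8.5 k / 2.5 k / 1.8 k | 10× scale-down of typical plastome regions for fast sweeps |

Test and acceptance problem sizes (200 molecules × 18 linearizations,
100 replicates per divergence level, 50 repair runs) are the package's
own desk-scale choices: large enough that every certified invariant is
exercised across all cut classes and strands with zero tolerated failures.

## Known limitations

- Only substitution-type noise is modelled; an indel *inside* one IR copy
  shifts the pairing constant mid-repeat and, beyond the discrepancy
  tolerance, fails the record rather than producing a repaired pair.
- Plastomes genuinely lacking IRs (many gymnosperms, some parasitic
  plants) are reported as `no_ir_found` — by design, not detected as a
  different structure.
- Boundary refinement is conservative near repeat ends (see above); with
  dense noise the reported repeat shrinks instead of guessing.
- The batch driver is single-process; at ~100 ms per full-size plastome a
  4,500-record batch is minutes of work, so parallelism is not worth its
  complexity here.
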