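# Methods

This note documents the models and numerical choices behind `repsel`: the
pairwise identity measure, the clustering that defines candidate seeds
and the search set, the iterative profile with its E-value statistics,
the two recognition engines, the unrecognized-member taxonomy, the
embedding, and the synthetic data the tests rest on.

## Pairwise alignment and percent identity

All identity values come from Needleman–Wunsch global alignment with
BLOSUM62 substitution scores and affine gap penalties (open 11, extend 1,
so a gap of length *k* costs 11 + *k*). Terminal gaps are penalized in
the DP. Traceback ties are broken deterministically — diagonal, then up
(gap in the second sequence), then left — so equal-scoring optima always
resolve to the same alignment.

Percent identity is `100 · identical pairs / aligned columns`, where
columns under a *terminal* gap in either row are excluded from the
denominator (internal gap columns count) and `X` never counts as
identical. The terminal-gap exclusion is deliberate: a fragment that
matches part of a long member still shows high identity, and flagging
fragments is the job of the partial-domain classifier, not the identity
measure. The DP kernels are verified against an exhaustive move-sequence
enumeration oracle on small instances.

Sequence input maps the ambiguity codes B, Z, J, U, O to `X`; `X` scores
as the background-average residue everywhere (0-bit PSSM column,
never identical, hydropathy 0).

## Clustering

Greedy incremental clustering in order of decreasing length (ties by
id): each sequence joins the first cluster whose representative it
matches at ≥ the threshold, else founds a new cluster. Because input is
length-sorted, each representative is its cluster's longest member, and
representatives are pairwise below the threshold by construction. At 25%
this yields the candidate seeds (one per cluster); at 50% the
non-redundant search set used for profile construction and as the
reference set for the divergence ratio. No alignment-coverage constraint
is imposed on cluster membership: only the identity threshold is
specified by the protocol, and adding one would be an undeclared extra
parameter.

## PSSM construction

Profiles live in the seed's coordinate system: every accepted hit is
globally re-aligned to the seed and projected onto seed positions
(seed-gap columns dropped). This keeps the profile width fixed and the
merge step reproducible, at the cost of ignoring insertions relative to
the seed — an accepted simplification, since the representative concept
is seed-centric.

Per column, sequences get Henikoff position-based weights (gaps and X do
not contribute). With weighted frequencies *f*, background *g* (Robinson
& Robinson), pseudocount weight *b* = 5 and *N*<sub>eff</sub> = mean
number of distinct residue types per column:

    f' = (N_eff · f + b · g) / (N_eff + b)
    score = log2(f' / g)   [bits]

Zero-frequency cells at *b* = 0 are floored at −10 bits to keep the DP
finite. This background blend is simpler than data-dependent pseudocount
schemes but is documented, testable in closed form, and monotone in the
evidence. Empty (all-gap) columns fall back to background and score 0.

## E-value calibration

Rather than fixed Karlin–Altschul constants (which do not exist for
arbitrary PSSMs with these gap settings), each profile is calibrated
against its own decoys: `n_decoys` (default 200, minimum 50)
residue-shuffled copies of search-set sequences are scored by
Smith–Waterman local alignment of the PSSM (affine 11/1, bit units), and
the best-score sample is fitted to a Gumbel distribution by maximum
likelihood (scipy). With fitted location μ and scale β:

    λ = 1 / (β ln 2)          [per bit]
    k = n_db · e^(μ/β) / (L_profile · N_db)
    E(S) = k · L_profile · N_db · 2^(−λS)

so that E(μ) equals the number of database sequences, as expected for a
score at the decoy mode. Calibration is deterministic given its RNG
seed; a degenerate (zero-variance) decoy score distribution raises an
error rather than producing a fake fit. Parameter recovery is tested on
simulated Gumbel data (scale recovered within 10% at n = 2000).

## Iterative profile search

Round one scores the search set with the single-sequence PSSM of the
seed; hits at E ≤ 10⁻³ are re-aligned and merged; the PSSM is rebuilt
and the search repeated, up to three rounds. Included hits accumulate
(a hit once included is kept), so alignment size is non-decreasing and
early convergence — no new hits — ends the loop. The final profile is
rebuilt and recalibrated from the final alignment.

Enrichment runs one additional search-and-rebuild round against the
*full* family instead of the non-redundant set. It is triggered when the
winning candidate's coverage is below 90%, and the better of the
original and enriched profiles is kept (coverage can fail to improve, so
the comparison is essential; ties keep the original).

## Recognition engines

**Profile engine.** A member is recognized iff its best local-alignment
E-value against the BRP is ≤ 10⁻². The seed always recognizes itself.

**Motif engine.** Column conservation is the normalized-entropy
complement `1 − H(f')/log2 20`, computed with a light dedicated
pseudocount (*b* = 0.1) rather than the scoring blend: the scoring
pseudocount is deliberately heavy for small alignments and would cap
conservation of an invariant single-sequence column near 0.1, making
every threshold unreachable. Maximal runs of columns with conservation
≥ 0.6 and length ≥ 5 become motifs; runs longer than 40 columns are
split into near-equal adjacent blocks, because a single very wide
ungapped motif is destroyed by one indel whereas a chain of moderate
blocks with order and spacing constraints keeps both robustness and
specificity. At most 10 motifs are kept (best mean conservation,
re-sorted by start).

A query is assigned iff (a) at least ⌈⅔ · n_motifs⌉ motifs are found
(a motif is found when its best ungapped window scores ≥ 0.5 bits per
column), (b) found motifs occur in family order, and (c) each
consecutive found pair's start-to-start distance is within ±50% of the
family's. This explicit rule set replaces a trained combiner whose
weights were never published; it covers the same feature list (motif
count, order, distance, conservation) and is reproducible. Circular
permutations and discontinuous domains are out of scope; order is
strict.

## BRS selection

Per engine, the candidate with maximum coverage wins; ties break by
higher mean bit score over recognized members, then longer seed, then
lexicographically smallest id (an invented but deterministic chain). The
seed counts in its own coverage numerator and denominator — it is a
family member, self-recognition is guaranteed, and the convention shifts
all candidates equally. The agreement flag records whether both engines
picked the same seed.

## Unrecognized-member taxonomy

Members missed by both engines are classified by a first-match
precedence rule, so the categories partition the unrecognized set the
way a survivor-style accounting does (each sequence gets exactly one
label; all five measurements are stored so the label can be re-derived):

1. **partial** — length < 0.60 × family mean length;
2. **low_complexity** — > 0.30 of residues inside SEG-style segments.
   Segments come from windowed Shannon entropy (window 12): windows with
   K2 ≤ 2.2 trigger, extension spans contiguous windows with K2 ≤ 2.5,
   overlapping segments merge, segments < 10 residues are dropped. The
   final entropy-minimization refinement of the original SEG algorithm
   is omitted — it moves boundaries marginally and only the covered
   fraction is used;
3. **composition_bias** — ≥ 1 transmembrane-like stretch (Kyte–Doolittle
   hydropathy, window 19, sliding mean > 1.6, runs closer than half a
   window merged — a declared heuristic stand-in for dedicated TM
   predictors, which are external binaries; the category only needs a
   deterministic, testable proxy) or polar fraction > 0.75 over the
   polar set {D,E,K,R,H,N,Q,S,T,Y,C};
4. **outlier** — divergence ratio < 0.8, where the ratio is the member's
   mean identity to the other members of the 50% set divided by that
   set's mean pairwise identity (pairs involving the member excluded).
   The boundary is strict: exactly 0.8 is not an outlier;
5. **unexplained** otherwise.

## Embedding

The "family dispersion plot" is classical (Torgerson) MDS on
*d* = 1 − identity/100 over the 50% set: double-center the squared
distances, take the top three eigenpairs, truncate negative eigenvalues
to zero. PCA proper would need a feature matrix that the identity data
does not define; classical MDS on the identity-derived distance is the
standard equivalent with the same visual semantics. Axes are ordered by
eigenvalue, and each axis's first nonzero coordinate is made positive so
output is reproducible across input orderings. Exactly embeddable
distance matrices are reproduced to < 10⁻⁶.

## Synthetic families

The generator simulates a star topology: an ancestor drawn from
background frequencies; members derived by per-site substitution at
`mutation_rate` with BLOSUM62-conditional exchange probabilities (so
identity–score relationships resemble real divergence) and per-site
single-residue deletions at `indel_rate`. With *k* subgroups,
intermediate ancestors are evolved at twice the member rate. Member 0
("center") stays identical to the ancestor; because insertions are not
modelled, the center is always the unique longest member and its id
sorts first, which pins the planted best representative under the
longest-member candidate rule. Planted anomalies overwrite labelled
members: fragments (contiguous truncation to 20–50% of ancestor length),
low-complexity contaminants (poly-Q/E/S/T run of 0.6× the member length
inserted at a random position — long enough that the run exceeds the 30%
classification threshold after insertion), hydrophobic 25-mers
(overwritten in place), and outliers (full replacement with a
uniform-random sequence). Everything is deterministic given `rng_seed`.

What the generator does **not** emulate: insertions, indel-length
distributions, rate heterogeneity across sites, realistic domain
architecture, or real low-complexity sequence structure beyond
homopolymers. Tests passing on this data show the machinery implements
its definitions and recovers planted structure under controlled
divergence; they do not certify recognition sensitivity on real PFAM
families.

## Problem sizes and defaults

Default study conditions used by the tests and the acceptance script:
planted-center recovery on 20 families of 40 members × 150 residues at
mutation rate 0.35; taxonomy recovery on 10 two-subgroup families of 40
members with 10% fragments, 10% homopolymer contaminants and 10%
outliers; SEG oracle agreement on 200 mixed-composition random
sequences; alignment oracle agreement on all pairs from a pool of every
1–2-mer plus seeded 3–6-mers over a 4-letter sub-alphabet; dual-engine
checks at mutation rate 0.2 (where conserved motifs exist) with 100
shuffled decoys per engine. These sizes keep a full run in the tens of
seconds on one CPU while leaving every rate estimate with a meaningful
denominator.

## Known limitations

- E-values are per-profile empirical calibrations; they are comparable
  within a profile's searches, not across profiles.
- The motif engine reports coverage 0 for families with no column run
  above the conservation threshold (very diverged families); the profile
  engine is the primary coverage instrument there.
- Greedy clustering depends on the length-sorted processing order; it
  does not reproduce any particular external clustering tool's output,
  only the representative-separation property.
- The identity denominator convention (terminal gaps excluded) is a
  declared choice; other tools' conventions differ.
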