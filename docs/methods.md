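# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic-data generators do and do not emulate, and
the design decisions taken where more than one convention was defensible.

## Nucleosome coordinate frame

The wrapped DNA is indexed 0-based over `length_bp` (default 147) with the
dyad at index 73. Superhelical locations are linear in base-pair position:

    SHL(pos) = (centroid − dyad) / bp_per_shl,
    centroid = motif_start + (motif_len − 1)/2

with `bp_per_shl = 73/7 ≈ 10.43`, chosen so the 147-bp frame spans SHL −7
to +7 exactly at its edges. This single linear convention reproduces the
conventional fractional SHL labels (+5.8, −6.2, …) from integer motif
starts. Real nucleosomal DNA twist varies along the wrap; we deliberately
do not model sequence-dependent periodicity. An even-length motif can
never have its centroid exactly on the dyad base pair, so a 6-bp motif
"at SHL 0" is necessarily half a base pair off.

The rotational phase angle `360·frac(|SHL|)` is reported as an annotation
only. Whether a given phase faces solvent or histones depends on a cutoff
that is not standardised; classification is left to the user.

`shl_to_pos` inverts the map by nearest integer start, breaking exact ties
away from the dyad, and round-trips exactly for every valid start.

## SeEN-seq

**Library design.** The 10-bp cassette (core CACGTG within GGCACGTGTC) is
substituted at every start in `[0, L−10]` of a backbone that must be free
of the core on both strands (the core is its own reverse complement, so
one scan covers the duplex). A substitution junction can recreate a
second core; such variants are excluded with a warning rather than kept,
since they would be ambiguous in any downstream assignment. Constructs
are modelled as `adapter + GATATC + variant + GATATC + adapter`; blunt
EcoRV cleavage (GAT^ATC) leaves `ATC + variant + GAT`, hence the 153-bp
fragment for a 147-bp tiling region. Tiling spans the wrapped 147 bp; the
extra 6 bp are restriction-site remnants, which reconciles tiling "across
the entire" backbone with the longer construct length.

**Read assignment.** Reads are assigned by exact match of a variant's
discriminating window — the cassette ± `min_overlap` (default 8) bp of
backbone context, clipped at construct ends — on either strand. The
window is the minimal subsequence that distinguishes tiling neighbours;
window uniqueness is checked at library build time and a collision is a
library-design error. Since every window contains the cassette exactly
once, candidate lookups are anchored at cassette occurrences in the read,
which makes assignment O(read length) rather than O(#variants).
Ambiguous and non-matching reads are counted unassigned; reads identical
to the spike-in competitor are tallied separately. Assignment conserves
reads: assigned + unassigned + spike-in = input.

**Enrichment.** Per replicate, `e_i = ((b_i+p)/Σ(b+p)) / ((u_i+p)/Σ(u+p))`
with pseudocount `p = 0` by default; a zero unbound count then yields an
undefined (NaN) position, never ±inf. Spike-in and unassigned reads are
excluded from library-size totals by default. Replicates are paired by id
and combined by arithmetic mean. Max-normalisation divides every defined
value by the maximum of the replicate mean and is idempotent. Enrichment
is invariant to uniform scaling of either fraction's counts.

## Structural register scanning

**Superposition.** Rigid-body least squares via Kabsch (SVD with
determinant correction, so reflections are never returned). Anchors are
backbone phosphate positions of both strands over the scanned window
(C1' as fallback), the convention register-scanning tools use; at least
three non-collinear pairs are required. The tests cross-check RMSDs
against an independent Horn quaternion-method implementation.

**Clash score.** For each 1-bp register where the probe window fits, the
probe DNA anchors are superposed onto the nucleosomal anchors and the
TF *protein* atoms (probe DNA excluded — it is superposed onto
nucleosomal DNA; hydrogens absent from typical X-ray/EM models) are
counted if strictly closer than `threshold_A` (default 1.0 Å) to any
nucleosome atom, histone or DNA. The KD-tree nearest-neighbour query is
an acceleration only: counts equal brute-force all-pairs counting exactly,
and are invariant under a global rigid motion applied jointly to both
models. Clash counts are non-decreasing in the threshold.

**Interface area.** Shrake–Rupley SASA on a deterministic golden-section
spiral lattice (default 960 points/atom, Bondi van-der-Waals radii,
probe 1.4 Å, configurable fallback radius for unknown elements with a
warning). Buried area = `(SASA(a) + SASA(b) − SASA(a∪b))/2`, symmetric in
the two groups, zero beyond interaction distance, and bit-reproducible
for a fixed point count. Two lattice densities are compared in the tests
(480 vs 4000 points agree within 5%; the two-sphere case matches the
closed-form spherical-cap area within 2%). Deposited-structure interface
conventions (PISA-style) can differ from the SASA-difference definition
by roughly 15%; values should be read with that tolerance.

**Overlay.** Clash profiles join enrichment profiles by
`position = register + offset` (identity under default frames); a
Spearman correlation between −clash and enrichment is attached, NaN with
a log message when either side is constant.

## Fragment profiles (V-plots, DNaseI cut sites)

Fragments are 0-based half-open `[start, end)`; the midpoint of an
even-length fragment is half-integer, and bins are half-open `[x, x+bin)`
so no fragment is counted twice. Each (fragment, same-reference anchor)
pair within the offset range increments one bin at
`(midpoint − centre, length)`, sign-flipped for minus-strand anchors.
A fragment contains the motif iff `|offset| ≤ (length − motif_len)/2`
(boundary inclusive); fragments shorter than the motif are always outside.
When reading alignments, fragments are paired-end template spans (TLEN
semantics); secondary/supplementary records are skipped.

DNaseI cut sites are read start positions binned at 1 bp. Each replicate
is downsampled without replacement to a fixed depth (default 100,000)
using a per-replicate-index substream of one run seed, so identical
conditions subsample identically and their difference profile is exactly
zero; the condition difference is mean(A) − mean(B). A replicate smaller
than the requested depth is an error naming the replicate.

## Single-molecule footprinting

**Chemistry encoded in the calls.** M.CviPI methylates cytosines in
accessible GpC dinucleotides; bisulfite converts unmethylated C to T.
At a GCH position (GpC not followed by G, avoiding CpG confounding), a
read C therefore means methylated = accessible = 0, a read T means
protected = 1; anything else is missing. This C/T→0/1 mapping is forced
by the chemistry.

**Reference conversion** is per-cytosine by context classification, not
sequential string replacement, so overlapping GC/CG contexts are
well-defined: HCH→T (always converted), GCH/HCG/GCG→Y (pyrimidine;
methylation-dependent). G positions and the bottom strand are untouched.

**Alignment.** Biopython's `PairwiseAligner` under the linear scheme
match/mismatch/gap = 1.0/−0.2/−0.5, with a substitution matrix in which
degenerate targets (Y = C/T, R = A/G) score as matches against compatible
bases and N matches nothing. The final score is the total score divided
by the alignment length, so it never exceeds 1.0. Primer prefix checks
are global over the common prefix length; read-to-amplicon mapping is
semi-global (target end overhangs free), and the final-score denominator
counts only the columns spanning the query — otherwise a perfect 250-nt
read against a 437-nt amplicon could never pass threshold. Both
thresholds ("higher than" 0.8 for primers, 0.7 for mapping) are strict
inequalities, guarded against float noise at the exact boundary.

**Merging, dedup, depth.** In the mate overlap the base with the strictly
higher quality wins, ties to mate 1; uncovered reference positions are
padded as missing (a warning flags internal gaps). PCR duplicates are
molecules with identical reconstructed sequences (no UMIs); each sample
is then downsampled without replacement to a common depth, by default the
unique-molecule count of the poorest sample, with per-sample substreams.

**Clustering.** "Binary matrix decomposition" is implemented as masked
alternating minimisation: rows are hard-assigned to one of k prototype
rows in [0,1]^p minimising the squared error over observed entries;
prototypes update as masked means; empty clusters are re-seeded from the
worst-fit row. The objective is non-increasing within a restart and the
best of `restarts` seeded initialisations is kept, so results are
deterministic for a fixed seed. This is a documented stand-in for the
published algorithm of that name, whose internals are not specified in
the methods we follow; cluster boundaries need not coincide. k is a user
parameter (7 clusters in the motivating locus). Per-cluster % protection
is `100 · mean(call = 1 over non-missing)` per replicate, summarised as
mean ± s.e.m. across replicates; all-missing positions are excluded from
a replicate's mean with a log note.

## Curve fits

**Damped cosine.** `y = m·x + c + A·e^(−k·x)·cos(2π(x − phase)/period)`.
The division by the period is required dimensionally. Fitting is
trust-region nonlinear least squares with bounds A ≥ 0, k ≥ 0,
period > 0; initialisation is linear detrend → Lomb–Scargle periodogram
peak (sampling-agnostic) → two-half envelope regression for A and k →
coarse phase grid. Phase is reported modulo the period in [0, period); a
trace whose detrended residual is numerically zero returns the linear
trend with oscillation parameters zeroed and flagged unidentifiable. The
half-life is reported both as 1/k (the convention used alongside this
equation) and as ln2/k (`half_life_ln2`, the standard exponential
definition); they differ by ln 2.

**Detection filters.** Keep iff PSF width ≤ 400 nm AND offset ≤ 250 nm
AND intensity ≤ 5000 counts: "exceeding" is read as strictly greater, so
boundaries are kept. Filtering is a subset operation and idempotent.

**Dwell-time mixtures.** The empirical complementary CDF (survival) at
the sorted dwells, `S(t_i) = 1 − (i − ½)/n`, is fitted unweighted with
`Σ w_i·e^(−t/τ_i)`, weights on a softmax simplex and τ in log space, by
seeded multi-start least squares. The component count (2 or 3) is the
caller's choice. Time constants closer than two-fold are flagged
degenerate — they are not resolvable from a survival curve. Fits below
~50 dwells warn. Fitting the CCDF unweighted, rather than a weighted or
ML variant, is a documented choice.

**One-site binding.** `y = x/(Kd + x)` with Bmax fixed at 1, so
y(Kd) = 0.5 identically and Kd scales with the concentration units.
Titrations with no curvature (all saturated or all baseline) raise an
unidentifiability error instead of returning a boundary value.

## Synthetic data: what it emulates, and what it does not

All generators draw from named substreams of one top-level seed
(CRC-keyed `SeedSequence`), so outputs are bit-for-bit reproducible and
adding a generator never perturbs existing fixtures. Each returns a
`TruthBundle` sufficient for its module's recovery test.

* **Backbone/reads (SeEN-seq).** Uniform random motif-free DNA stands in
  for the real positioning sequence; real nucleosome positioning strength
  is not modelled. Unbound pools are uniform over variants plus the
  competitor at 30:1 (competitor:pool, mirroring the assay's spike
  excess); bound pools are profile-weighted with no competitor (it
  carries no motif). Sequencing error is a uniform per-base substitution
  (default 0.001), not a platform error spectrum.
* **Toy structures.** DNA anchors on an ideal superhelix (radius 41.9 Å,
  pitch 25.9 Å, 1.65 turns scaled to the toy length), a random
  histone-proxy core, and a straight ideal B-helix probe with a compact
  TF pseudo-atom cloud. Geometry is cartoon-level; the point is exact
  brute-force clash truth per register, not realism.
* **Fragments.** Cut sites fall uniformly in the unprotected linker on
  each side of a sampled architecture (nucleosome + edge TF, TF-only,
  …); MNase sequence bias is reduced to this protection model. The
  nucleosome+edge-TF class concentrates inside-V mass above 150 bp and
  the TF-only class below 100 bp, reproducing the qualitative V-plot
  signatures.
* **SMF reads.** Full forward model: per-molecule footprint class →
  accessible-GCH methylation (efficiency, default 0.95) → bisulfite
  conversion (default 0.995) → primered 250-bp read pairs with qualities,
  substitution errors (errored bases get low quality) and PCR duplicates.
  The synthetic amplicon's first/last 25 bases carry no top-strand C, so
  primer sequences are conversion-invariant, as real bisulfite primers
  are designed to be. Endogenous CpG methylation is not modelled. With
  error rate 0 and efficiency/conversion 1, every molecule of a class is
  identical, so deduplication collapses each class to one molecule — the
  exact-recovery test operates at that depth.
* **Traces/dwells.** Direct forward models of the damped cosine and the
  exponential mixture with Gaussian/exponential noise.

Passing tests on these generators demonstrates correctness of the
computational procedures under their stated statistical assumptions; they
do not validate performance on real sequencing error spectra, mapping
artefacts, chromatin heterogeneity or optical aberrations.

## Problem sizes and tolerances used in the test suite

Recovery tests run at the depths the statistics require and the suite
executes in about a minute: SeEN-seq at 10^5 reads per fraction (recovery
judged at 3 binomial SEs on the log scale, the correct error model for a
ratio of binomial proportions); clash oracles on ≤ 500-atom toys at
thresholds 0.5/1/2 Å; alignment scoring against an exhaustive-enumeration
oracle over all 4-mer pairs; SMF exact recovery error-free plus ARI ≥ 0.9
at 10% call-flip noise (k = 2, 80 discriminating positions); damped-cosine
period recovery within ±0.2 h at 5% noise over 100 seeds; mixture τ within
10% at n = 10^4.

## Known limitations

* The SHL map is linear; no sequence-dependent twist.
* Interface areas use the SASA-difference convention; PISA-like numbers
  can differ by ~15%.
* The binary-matrix clustering is a stand-in (see above); only its
  documented properties (masked objective, monotone descent, seeded
  determinism) are guaranteed.
* Alignment of bisulfite reads assumes the amplicon's top strand; the
  complementary-strand read family of post-bisulfite PCR is represented
  only through reverse-complemented mates.
* `shl_to_pos` returns a single nearest start; callers needing all
  equally-near starts must enumerate.
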