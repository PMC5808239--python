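# Methods

## Problem and approach

Bulk immune-repertoire sequencing tags every receptor RNA molecule with a
random molecular identifier (MID, 12 nt by default) during reverse
transcription, so each molecule can be tracked through PCR and sequencing.
Three error processes corrupt the naive "one MID = one molecule" picture:

1. **MID collisions** — two distinct molecules draw the same MID by chance.
   Building one consensus per MID then fuses two receptor sequences into a
   chimera.
2. **Errors on the payload** — PCR and sequencing substitutions scatter
   reads around the true sequence.
3. **Errors on the MID itself** — a substitution inside the barcode creates
   a *satellite* MID group that inflates the molecule count.

`midseq` addresses (1) by splitting each MID group into edit-distance
sub-clusters, (2) by quality-weighted consensus within each sub-cluster plus
a one-edit neighbor collapse across clonotypes, and (3) by removing, within
each clonotype, MID entries whose read support falls below 20% of that
clonotype's per-MID maximum.

## Processing chain

**Preprocessing.** Only reads containing an exact occurrence of the
constant-region anchor are kept; kept reads are trimmed to a 150-nt payload
starting at the anchor (the read tail beyond this is the most error-prone
part of the read and never enters consensus building). Reads with an N
inside the MID cannot be grouped and are rejected; an N in the payload is
tolerated and votes with weight 0. Reads whose post-anchor payload is
shorter than `min_payload` (100 nt) are rejected. No quality trimming is
performed before the cut. Accepted + rejected always equals parsed.

**Sub-clustering.** Within one MID group, reads are clustered greedily: the
unassigned read with the highest summed quality (ties: smallest read id)
seeds a cluster of all unassigned reads within
`round(0.15 × seed payload length)` Levenshtein edits (22 for 150 nt);
repeat until no reads remain. The published method names quality threshold
clustering without fixing seed choice or assignment order; the greedy
scheme is a deterministic, near-linear choice that coincides with it
whenever molecules sharing an MID differ by more than twice the threshold —
which the clone-separation analysis below makes the operating regime.
Clusters with fewer than 2 reads are discarded (a singleton cannot be
distinguished from an error), and a 2-read cluster is kept only if both
reads are identical.

**Consensus.** Per position, the base maximizing the summed Phred quality
of the reads carrying it wins; ties break by the fixed order A<C<G<T.
Members whose length differs from the cluster's modal length do not vote —
indel-aware multiple alignment is deliberately out of scope, as
substitutions dominate the targeted error processes and length-discordant
reads are rare.

**Clonotypes and filters.** Identical consensus sequences merge into
clonotypes; the molecule count is the number of surviving sub-clusters
(same-MID duplicates remain distinct countable entries). Filters run in the
order: non-functional flagging, one-edit neighbor collapse, MID read-count
filter.

* *Non-functional flagging* uses an in-frame stop codon relative to the
  constant-region reading frame (`frame_offset`). Full V/J junction
  productivity calling is out of scope; the stop-codon proxy is the
  documented substitute. Flagged clonotypes stay in the raw output and are
  excluded from productive tallies only.
* *Neighbor collapse* removes a clonotype at Levenshtein distance exactly 1
  from a clonotype with strictly more molecules. Decisions are evaluated
  against the pre-filter state in a single pass: ties survive, and genuine
  1-edit clone pairs are never chain-collapsed. Candidate pairs are found
  with a prefix/suffix half-key screen (a single edit leaves either the
  first or the last half of the shorter sequence intact) and verified with
  a banded alignment, keeping the step near-linear.
* *MID read-count filter* removes, within a clonotype, MID entries with
  fewer than 20% of the maximum per-MID read count. The 20%-of-maximum rule
  is the operating filter; a two-component negative-binomial mixture fit
  (EM, deterministic initialisation at the 10th/90th count percentiles,
  dispersion M-steps by bounded 1-D likelihood maximisation) is provided as
  the diagnostic that separates true from erroneous MIDs and can supply an
  absolute crossover threshold instead.

## Models

With M possible MIDs and N tagged molecules, per-MID occupancy is
Poisson(N/M):

    P_k = (N/M)^k e^(-N/M) / k!

and the fraction of *occupied* MIDs that need sub-clustering is

    F(k>1) = [1 - e^(-N/M) - (N/M) e^(-N/M)] / (1 - e^(-N/M)),

which is nearly linear in N for N/M ≲ 0.3 (for 12-nt MIDs, up to ~5 million
molecules). Identical molecules sharing an MID are uncorrectable even in
principle; the expected fractional undercount of n identical molecules is
(n − E[distinct])/n with E[distinct] = M(1 − (1 − 1/M)^n). The companion
per-molecule probability 1 − (1 − 1/M)^(n−1) is also reported; the headline
bound uses the undercount form.

Clone sizes x_i (cells per clone) follow a discrete power law
f(x) ∝ x^(-alpha); each cell contributes a constant m transcript molecules,
so clone i holds m·x_i of the N = m·Σx_i molecules. Sampling n molecules
without replacement detects clone i unless all its molecules are missed,
giving

    E(D) = K − Σ_i C(N − m·x_i, n) / C(N, n),    P(D) = E(D)/K,

evaluated via log-gamma differences (N up to ~1e7 would overflow
factorials). The per-cell copy number is estimated by integer least
squares: for each candidate m, clone sizes are drawn from the fitted power
law (one shared seed across candidates, so residuals reflect m alone),
model coverages are computed at each input fraction and rescaled by the
model coverage at the 90% reference fraction, and the m with the smallest
summed squared residual wins (smallest m on ties, flagged). Observed
coverages must be scaled the same way before fitting.

The exponent alpha is fitted by discrete maximum likelihood
(Hurwitz-zeta-normalised) over candidate lower cutoffs, selecting the
cutoff with the smallest Kolmogorov–Smirnov distance between empirical and
fitted tails; both CDFs are compared right-continuously at the observed
atoms. A log-log size-frequency regression slope (bins with ≥5
observations) is available as the cross-check estimator; the MLE route is
the default. No default alpha is baked in — it must be supplied or fitted.

Fold expansion of a clone is (clone_cells / population_cells) /
precursor_frequency.

## Synthetic data generator

The simulator emulates exactly the processes the pipeline corrects, with
full ground truth (clone table, molecule→clone and molecule→MID maps,
read→molecule map):

* **Clones** — random stop-free payloads (codon-sampled) behind the shared
  anchor; an optional fraction receives one in-frame stop (non-productive).
  Pairwise Levenshtein separation ≥ 25 edits is verified (with regeneration
  and bounded retries) for repertoires up to 3,000 clones; beyond that the
  check is skipped, since the edit distance of independent 100+-nt random
  sequences concentrates far above the threshold and exhaustive pairwise
  verification would dominate run time. The 25-edit default keeps the
  22-edit clustering threshold cleanly inside the separability regime, so
  pipeline tests measure algorithm correctness rather than biological
  ambiguity; smaller separations can be configured for stress tests.
* **Molecules and MIDs** — exactly m molecules per cell; each molecule
  draws an independent uniform MID. Spike-ins are appended with exact copy
  numbers.
* **PCR** — the amplicon pool is never materialised (it would be ~2^cycles
  per molecule); instead the genealogy of the *sampled reads* is simulated.
  Each read is assigned to one of 2^s founder lineages (s = 3 founder
  cycles by default); founder lineages carry Poisson(s·eff·L·rate) early
  substitutions shared by all their reads — these are what create
  erroneous-MID satellite groups with ≥2 reads, and, when they hit the
  payload, shared-error consensus candidates for the neighbor collapse —
  while the remaining (cycles − s) duplications contribute private
  Poisson-distributed substitutions per read. Reads are assigned to
  founders uniformly, which ignores the size bias of sampling from a grown
  pool; the satellite-generation phenomenology (satellite frequency rising
  with cycle number and depth, satellite read counts a ~1/2^s share of the
  molecule's reads) is preserved. Errors hit MID and payload bases alike.
  Substitution-only by default, consistent with the alignment-free
  consensus.
* **Sequencing** — Poisson read coverage per molecule, per-base
  substitutions, and qualities from a declining positional profile
  (Q38→Q26 with integer noise, clipped to [2, 40]); qualities are not
  coupled to the simulated errors, which keeps the quality-weighted
  consensus unbiased but means quality-aware error correction cannot be
  validated against the simulator.

What passing tests on this generator do **not** show about real data:
primer bias and V-gene-dependent capture efficiency, indels and homopolymer
errors, sequencer-specific quality/error coupling, genuine V(D)J sequence
similarity structure (real clones can sit closer than 25 edits), and
RNA-capture losses upstream of tagging (the fitted m absorbs capture
efficiency, which is why a per-cell estimate of 3 coexists with ~10 copies
by digital PCR).

## Problem sizes used in the checks

Simulation-backed checks run at deliberately moderate scale: end-to-end
recovery and saturation analyses use a few hundred clones (~1,200–1,800
molecules, ~30x coverage); the chimera analysis shortens the MID to 7 nt so
that ~8% of MIDs collide at ~2,700 molecules (with 12-nt MIDs the same
collision rate needs ~1.7 million molecules); the spike-in sensitivity
analysis uses 20 seeded libraries of ~1e5 background molecules at ~6x
coverage with 17,000 clones capped at 1,000 cells each (the cap bounds the
heavy-tail variance of the library size). Monte-Carlo oracles use 1e5
replicates; parameter-recovery sweeps use 1e5 clones (alpha) and 1e4 clones
x 20 replicates (copy number).

## Known limitations

* Consensus is alignment-free; indel-rich data would need an aligner-based
  consensus and an indel-aware simulator.
* The non-functional filter sees only the payload window, not the full
  junction; out-of-frame junctions without a payload stop are not flagged.
* The NB mixture diagnostic assumes exactly two components; heavily
  multimodal read-count distributions will fit poorly (flagged via
  boundary/degenerate indicators rather than guessed at).
* `estimate_copy_number` reports a point estimate with a residual profile,
  not an uncertainty interval; non-integer m is out of scope.
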