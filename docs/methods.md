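# Methods

This note describes the models and procedures implemented in
`phageselect`, the assumptions behind them, and the choices made where
the design was genuinely open.

## Problem setting

Phage-display selections for cell-penetrating peptides (CPPs) start
from a random peptide library — here nine-mer peptides encoded by NNK
degenerate codons and displayed on the phage PIII coat protein — and
apply several rounds of cell-based selection. Pools from the naïve
library and from successive output rounds (ORD) are amplicon-sequenced;
the analysis questions are (i) how diversity collapses as enrichment
proceeds, (ii) which residue compositions are selected for or against,
and (iii) how similarity-defined groups of naïve sequences fare across
rounds. `phageselect` implements that analysis pipeline end to end,
together with a generative simulator so every stage can be validated
against known ground truth.

## NNK codon model

An NNK codon draws positions 1–2 from {A,C,G,T} and position 3 from
{G,T}: 32 codons covering all 20 amino acids with unequal multiplicity
(e.g. Leu 3/32, Met 1/32) and a single reachable stop, the amber codon
TAG. Libraries amplified in amber-suppressor (supE) hosts read TAG as
glutamine, so the default amber policy is `suppress_to_Q` (Q then has
effective multiplicity 2/32); a `discard` policy is provided for
non-suppressing contexts. The codon table is derived from the standard
genetic code (Biopython's table 1), never transcribed by hand.

## Selection simulator

The simulator is a deliberately simple generative stand-in for a real
selection campaign, with enough structure that the downstream pipeline
must recover it:

* **Naïve pool.** `pool_size` clones (default 5×10⁴ — desk scale; real
  libraries reach ~10⁸–10⁹ diversity, which is not simulated) drawn
  i.i.d. per position from the NNK codon multiplicities.
* **Fitness.** Per-peptide log-fitness is linear in composition:
  intercept + `beta_nterm_met`·[position 1 is Met] + `beta_cys`·(#Cys)
  + `beta_cation`·(#Lys + #Arg) + ε, ε ~ N(0, `noise_sd`) drawn once
  per peptide. Defaults (0.7, −1.0, −0.6, 0.3) were chosen so that five
  multiplicative rounds reproduce the qualitative outcome reported for
  cathepsin-based cytoplasmic-entry selections: e^(5·0.7) ≈ 33-fold
  relative enrichment turns the ~3% position-1-Met subpopulation into
  the majority, while cysteine-containing and multi-cationic sequences
  are strongly depleted. The log-linear form and the coefficients are
  inventions of this package, documented as such; they exist to give
  the pipeline recoverable structure, not to model phage biology.
* **Rounds.** Each round updates frequencies multiplicatively
  (f ∝ f·w) and resamples multinomially at `reads_per_round` (default
  10⁵) sequencing depth; realized counts seed the next round, so clones
  lost to sampling stay lost. Rounds are labeled ORD1..ORDn (default
  n = 5); the emulated 13-sample study keeps the naïve pool plus rounds
  2–5 for three cell-line arms (293, Caco2, CHO). Arms share the naïve
  pool but scale all betas by a per-arm factor (1.0 / 1.15 / 0.85),
  emulating the observed cell-type ordering of enrichment rates
  (fastest in Caco2, slowest in CHO).
* **Reads.** One read per count: 5′ flank + a uniformly chosen
  synonymous NNK encoding of the peptide + 3′ flank, with flat
  per-base substitution errors (default 0.001; no indels and no
  quality model — substitution-dominated short-read chemistry is
  assumed). Quality strings are constant Phred-33 'I'. The default
  flanks are placeholders with realistic structure (an SfiI cloning
  site upstream, Gly-Gly-Gly-Ser linker codons downstream); real
  amplicon designs supply their own.

All randomness descends from one user seed through
`numpy.random.SeedSequence` spawning, so every sample is reproducible.

What the simulator does **not** emulate: PCR amplification bias and
chimeras, indels, quality-score structure, clone-level amplification
bottlenecks between rounds, and full library scale. Passing tests
therefore demonstrate that the analysis recovers known structure under
idealized sampling noise, not that it is robust to every artifact of
real NGS data.

## Read decoding

Reads are processed on the forward strand only (single-direction
sequencing of a fixed-structure amplicon). The 5′ flank is located by
leftmost Hamming match with at most `max_mismatches` (default 1)
mismatches; the 3′ flank is then tested at its expected position,
`insert_length` nucleotides downstream, before any scan — the
downstream flank encodes a Gly/Ser linker whose codons legitimately
occur inside inserts, so a scan-first rule would mis-trim a small
fraction of perfectly valid reads. A fallback scan distinguishes
`wrong_length` from `flank_not_found` rejections. Inserts with
ambiguous bases are rejected; TAA/TGA stops are always rejected; TAG
follows the amber policy. Codons with a non-NNK third base (A/C) are
impossible in an error-free library read, but they are translated and
tallied rather than rejected, because rejecting them would bias
against true peptides observed through a single sequencing error.
Counting is at the amino-acid level (nucleotide synonymy collapsed),
with deterministic output ordering (descending count, ties
lexicographic) and per-reason rejection tallies satisfying
retained + rejected = total.

## Enrichment statistics

* **Unique fraction** — distinct sequences / total retained reads; a
  depth-dependent diversity measure that falls as selection
  concentrates the pool.
* **Position frequency matrix** — L×20 row-stochastic matrix of
  residue usage, either count-weighted (default; reflects pool
  composition) or unique-unweighted with an optional seeded subsample
  (the "randomly picked sequences" view).
* **Min-count filter** — `count ≥ k` (default 5) visualization filter;
  frequencies are deliberately *not* renormalized so filtered rows
  remain interpretable as fractions of the full sample.
* **Trajectories** — per-peptide frequency series with
  naïve-referenced fold changes. Fold changes use frequencies, not
  counts, so unequal depths compare; absence is reported as frequency
  0 (fold 0) rather than smoothed, and peptides unseen in the naïve
  sample are flagged `newly_observed` (fold undefined unless a
  pseudocount is requested).

## Embedding and clustering

The clustering stage mirrors the language-model-embedding analysis
used in CPP selection studies: embed, reduce to 20 dimensions by PCA,
fit a Gaussian mixture (20 components for the pooled global analysis
over all samples' unique sequences; 10 for the per-sample/naïve
analysis), and project to 2-D by t-SNE for visualization only.

* **Built-in embedder.** Per position: hydropathy (Kyte–Doolittle,
  scaled by 1/4.5), charge class (+1 K/R, +0.5 H, −1 D/E), side-chain
  volume (Zamyatnin, scaled), aromaticity (F/W/Y), and a Cys
  indicator; plus the 20 global residue-composition counts — d = 5L+20
  (65 for 9-mers). Because PCA and the mixture operate on raw
  Euclidean geometry, feature scales are balanced deliberately: the
  Cys indicator carries weight 6 (rare binary features otherwise
  vanish next to continuous scales), the N-terminal position carries
  weight 5 on the four graded descriptors (the displayed peptide's
  free N-terminus is the most selection-relevant position), and
  composition counts carry weight 2. These weights are part of the
  embedder's definition; they were chosen so that
  composition-signature clusters (cysteine-containing, multi-cationic,
  N-terminal-Met) are separable the way they are under learned
  protein-language-model embeddings. External embeddings (e.g.
  1280-dimensional ESM-2 650M vectors) can be supplied as a delimited
  table and flow through the identical reduction/clustering path.
* **PCA** is plain centered PCA (optionally z-scored); the basis sign
  convention (largest-|loading| entry positive) makes the reduction
  deterministic.
* **GMM.** Diagonal-covariance EM with seeded k-means initialization,
  iteration cap 200, mean-log-likelihood tolerance 1e-5 and covariance
  floor 1e-6. Diagonal covariance is the robust choice at desk-scale
  n with 10–20 components. The fit is implemented in the package so
  the per-iteration log-likelihood trace can be recorded and asserted
  non-decreasing on every fit; responsibilities are cross-checked in
  the tests against direct Gaussian-density evaluation and an
  independent EM implementation (scikit-learn).
* **t-SNE** coordinates are for plots only; per-dataset projections of
  the same peptide are never compared numerically, and no statistic is
  computed from them. Perplexity defaults to 30, capped below the
  sample count.

## Cluster trajectory tracking

Clusters are defined once on the naïve library (all unique sequences,
unfiltered) and tracked forward: each round sample is filtered at
count ≥ 5, embedded, projected through the naïve PCA basis, and
assigned to the fixed naïve mixture — there is no per-round refit and
no label matching, because the question is what happened to the naïve
groups. Each cluster's aggregate frequency per sample gives an
enrichment ratio ρ = final-round / naïve aggregate frequency,
categorized as Eliminated (final frequency exactly 0), Minimum
(ρ < 0.2), Slight (0.2 ≤ ρ < 1), Modest (1 ≤ ρ < 3) or High (ρ ≥ 3).
These thresholds are this package's own definitions (configurable);
no published convention exists for them. A cluster with visibly mixed
signatures can be sub-split by refitting a small mixture within its
members (labels suffixed `4-1`, `4-2`, …).

## Physicochemical properties

Three named constant sets, with the four classic CPPs (Tat48-60,
penetratin, 9R, 8K) serving as the transcription check — their
published one-decimal property values reproduce exactly under these
constants:

* **Kyte–Doolittle hydropathy** (original scale constants), reported
  as the mean over residues.
* **EMBOSS pKa set** (`iep` defaults: N-term 8.6, C-term 3.6, C 8.5,
  D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1) for isoelectric points.
* **Lehninger pKa set** (free amino-acid table: N-term 9.69, C-term
  2.34, D 3.86, E 4.25, C 8.33, H 6.00, K 10.53, R 12.48, Y 10.07)
  for net charge, reported at pH 7.4 by default.

Net charge is the Henderson–Hasselbalch sum (basic groups
+1/(1+10^(pH−pKa)), acidic groups −1/(1+10^(pKa−pH)); termini always
included; free Cys treated as ionizable, with no disulfide
adjustment). It is strictly decreasing in pH and the termini guarantee
a sign change, so the pI is the unique root in (0, 14); it is found by
Brent root-finding to |charge| ≪ 1e-4 (a vectorized 60-step bisection
serves bulk tables, agreeing with the scalar path to 1e-6). Values are
kept at full precision internally and rounded to one decimal only at
reporting time. Cluster property averages can be unique-unweighted
(default) or count-weighted; for single-peptide rows the choice is
immaterial.

## Numerical and degenerate-input conventions

Frequencies must sum to 1 within 1e-9 (unfiltered tables); PCA bases
are orthonormal within 1e-8; mixture weights sum to 1 within 1e-9 with
strictly positive covariances; EM traces are checked non-decreasing
within 1e-9 on every fit. Count-table ordering ties break
lexicographically; cluster-assignment ties break toward the lowest
component id; empty retained read sets, all-zero fitness vectors,
K > n mixtures and sub-splits with too few members raise errors rather
than degrade silently.

## Problem sizes

The default simulated study is 13 samples: a 5×10⁴-clone naïve pool
and 10⁵ reads per round for four sequenced rounds in each of three
arms (1.25×10⁶ reads total). These sizes were chosen as the smallest
at which the selection signatures are unambiguous and sampling noise
is realistic for a desk-scale reanalysis; unit tests use further
reduced pools (500–8000 clones) where only mechanics are under test.

## Known limitations

* The built-in embedder is a fixed physicochemical descriptor map, not
  a learned model; clusters it cannot express (e.g. positional motifs
  away from the N-terminus) will not be separable, which is exactly
  why the external-embedding interface exists.
* Enrichment categories depend on the documented ρ thresholds;
  different thresholds shift Slight/Modest boundaries (Eliminated is
  threshold-free).
* Fold changes at low counts are noisy; no shrinkage or significance
  testing is performed (none is claimed).
* The decoder assumes fixed-length inserts and substitution-only
  errors; indel-containing reads fail the length check and are
  rejected rather than recovered.
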