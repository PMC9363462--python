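# Methods

## Scope and model

`tgprofile` analyses single-round activity-based display selections of short
peptides. One round of selection takes a degenerate library (a fixed backbone
peptide with NNK codons at chosen positions), exposes it to an enzyme that
covalently marks reactive peptides (for transglutaminase: biotinylation of
peptides carrying an accessible acyl-donor glutamine), and captures the
marked fraction on streptavidin beads. Both the original and the captured
pool are sequenced; the analysis compares the two samples.

The central statistic is the enrichment factor

    EF(x) = (c_after(x) / N_after) / (c_before(x) / N_before)

for any sequence class `x`: a single peptide, or "residue `a` at
Gln-relative position `rel`". Counts are normalized to each sample's total,
and EF > 1 means the class was preferentially captured. The orientation
(after over before) is fixed throughout the package and stated on the API.

Coordinates follow the field convention of counting relative to the
reactive glutamine: the residue immediately N-terminal is −1, the following
ones +1, +2, +3. Internally everything is 0-based; `rel_to_abs` is the only
crossing point. Two presets ship with the package: `Lib4` (positions −1, +1,
+2, +3 randomized around a fixed reactive Gln) and `LibQ` (only the reactive
position randomized, before/after samples distinguished by in-read 10-nt
tags). The T26 backbone's first seven residues (HQSYVDP) follow the
published template peptide; the remaining five residues and all anchor/tag
DNA in the presets are synthetic stand-ins, because the full construct
sequence is not available in machine-readable form. No algorithm depends on
them; they are config inputs.

## Read processing

Per read pair: optional 3'-adapter trimming (longest read suffix matching
an adapter prefix, ≥ 5 nt overlap, ≤ 20% mismatches) → mean-Phred quality
filter (default threshold 25, inclusive; both mates must pass; the named
tool's average-quality semantics, since the upstream method states only the
tool and the threshold) → tag demultiplexing when the design defines tags
(leading 10 nt, ≤ 1 substitution, ties → unassigned) → anchor-based
extraction of the coding DNA (read 1 authoritative, reverse-complemented
read 2 as fallback; ≤ 1 substitution per anchor, no indels, no pair
merging) → translation (standard genetic code, stops in-band as `*`) →
design filters. The reactive-Gln filter applies only where the design fixes
that position (Lib4), not where it is itself randomized (LibQ); stop codons
are rejected anywhere; backbone variants at non-randomized positions are
retained. Every pair lands in exactly one bucket, so
`accepted + Σ rejections = input pairs` is an invariant, tested on every
fixture and simulation.

Trimming is plain 3'-overlap trimming, not palindromic pair-aware trimming;
for these short single-amplicon constructs the anchor search makes the
distinction irrelevant.

## Enrichment statistics

Peptides with `c_before = 0` have no defined EF; they are flagged
(`zero_before`) and excluded from ranking rather than reported as infinite.
An optional pseudocount (suggested 0.5) is available for exploratory use.
Ranking drops peptides with `c_after` below a count threshold (default 100,
inclusive at the boundary), sorts by EF descending with deterministic tie
breaks (higher `c_after`, then lexicographic), and reports 1-based ranks.
The position-EF matrix is computed over all accepted reads (not only ranked
peptides — the larger n; configurable upstream by filtering the count
table). The heatmap consensus takes the per-position argmax with
alphabetical tie-breaking and an explicit tie flag. `logo_matrix` exports
per-position frequencies for any peptide set (columns sum to 1); rendering
logos is out of scope.

## Selection simulator

The simulator is first-class, tested code: it is the source of ground truth
for every recovery test. Library sampling draws each randomized codon
uniformly from the 32 NNK codons (so residue frequencies follow codon
multiplicities, e.g. Leu 3/32, Gln 1/32, amber stop 1/32). Capture is one
Bernoulli trial per molecule:

    p(x) = β + (1 − β) · σ(b0 + Σ_rel W[rel, x(rel)])

with logistic σ, applied only when the reactive position carries Gln;
otherwise — and for any peptide with a stop at a scored position — capture
happens at the background rate β alone. An optional artifact rule adds
capture probability to peptides containing a motif, modelling
streptavidin-binding false positives (His/Trp-rich sequences). The logistic
additive form is the simplest monotone link between per-position effects
and a probability; the real capture kinetics are unknown and not claimed.
A single round is simulated, matching the experimental design.

Sequencing emits each sample's reads multinomially from its molecule
counts, builds `[tag] + upstream anchor + coding DNA + downstream anchor`,
applies substitution errors at a uniform per-base rate, and samples Phred
scores from a clipped normal (mean 35, sd 3). Read 2 is the reverse
complement with independent errors. There are no indels, no quality decay
by cycle, no PCR bias or chimeras — the extraction step is anchor-based and
substitution-tolerant, so these are the error modes the pipeline actually
distinguishes. Consequences: passing recovery tests shows correctness of
the counting and statistics under the stated noise model, not robustness
to indel-heavy or length-variable real data.

Defaults of the planted model: W[−1,Q] = +2.0, W[+3,I] = W[+3,V] = +1.0,
W[+2,F] = −1.5, b0 = −2, β = 0.002. The weights encode the qualitative
substrate preference the pipeline is meant to recover; b0 and β are
exercise parameters (the wet-lab capture efficiency and background are not
quantified anywhere) chosen to give a realistic ~12% specific capture rate
over a ~0.2% nonspecific floor.

`true_position_ef` is the analytic oracle: the expected position-EF matrix
computed by exact enumeration over the NNK-induced residue distribution
(20^k weighted combinations), conditioned by default on the read-processing
filters (no stop at a randomized site), which is what the empirical matrix
estimates. Fixed-backbone weights enter as constant offsets so the oracle
composes with any design.

## Statistical analysis

Peptides with defined positive EF are one-hot encoded over the randomized
positions (20 indicators per position, positions ascending then residues
alphabetical). A Random-Forest regressor predicts EF under k-fold CV
(default k = 10); permutation importance is the increase in held-out MSE
when one column is shuffled, averaged over folds × repeats (default 10).
The implementation batches all feature × repeat permutations of a fold into
one prediction call; it is verified in the test suite against
scikit-learn's `permutation_importance` on the same fold. Signs come from
the Pearson correlation of each raw indicator with EF; zero-variance
columns get no sign. The response is raw EF by default (log transform
opt-in), matching how enrichment is reported downstream.

Hyperparameter search (`hypertune`) is a seeded randomized search over tree
depth, features-per-split and leaf size scored by CV MSE; default budget is
desk-scale (25 iterations) with the full budget reachable through config.

At desk scale the per-peptide EF is count-noisy (before-counts of 1–2
reads), so the shipped *scaled analysis configuration* — used by the
recovery tests and the acceptance script — stabilizes the response by
requiring `c_before ≥ 3`, takes a seeded random subsample of 4000 peptides
(a top-by-count cut would condition on count noise and bias the
importances), and regularizes the trees (`max_depth 12`,
`min_samples_leaf 20`, `max_features 0.5`). These are pipeline options with
library defaults unchanged (all defined-EF peptides, unregularized trees).

Group comparisons use two-sided Welch t-tests at α = 0.01, reported raw
(a Bonferroni column can be added downstream). Hydrophobic set
{A,V,L,I,M,F,W,C}; polar set {S,T,Y,N,Q,C,D,E,K,R,H}. Cys deliberately
belongs to both: a small borderline-polar residue with a hydrophobic thiol.
Both sets are arguments, not constants. Degenerate groups (n < 2, or an
empty polar/nonpolar side) are skipped with a notice. The zero-variance
Welch convention is p = 1 for equal constant samples and p = 0 otherwise.

## Reproducibility and numerics

Every stochastic stage derives its seed as
`sha256(master_seed : stage_name) mod 2^31`, so one master seed fixes the
whole run while stages stay decorrelated. FASTQ emission is byte-identical
under a fixed seed (gzip members are written with mtime 0). All tables are
sorted deterministically before writing; ranking and consensus ties have
stated deterministic rules. The run manifest records the config hash, input
checksums, per-stage record counts and wall times; wall times are the one
intentionally non-reproducible field, so determinism contracts are stated
over the data tables.

Problem sizes used by the recovery tests and the acceptance script:
2×10^5 library molecules, 2.5×10^5 read pairs per sample, 0.5% per-base
error, ten fixed replicate seeds. At this pool size the binomial capture
step leaves irreducible ~2–3% sampling noise in a position-EF cell
(relative standard error ≈ sqrt((1−p̄)/(p̄·n_cell))), which is why
agreement with the analytic oracle is assessed as the mean absolute
relative deviation over well-populated cells (before- and after-counts
≥ 8000) with a 5% bound, rather than as a per-cell maximum that sampling
theory puts at the bound itself.

## Known limitations

- Substitution-only error model; indel-containing reads fail anchor
  extraction and are tallied, not rescued.
- No modelling of PCR amplification bias, bead saturation, or acyl-acceptor
  (lysine-side) chemistry.
- Single selection round; composing rounds is a loop the API supports but
  ships untested.
- NNK is the only degeneracy scheme exercised; the design type admits
  others but they are untested.
- The statistical analysis ranks positional effects and assigns signs; it
  does not estimate causal effect sizes.
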