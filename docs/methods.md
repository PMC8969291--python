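# Methods

## Scope and model

`psmrescore` post-processes the output of any shotgun-proteomics database
search.  Its premise is that a PSM can be judged from evidence computable
without the search engine: the cross-correlation between the experimental
spectrum and the theoretical b/y fragment spectrum, the statistics of
annotated fragment ions, and basic descriptors of the peptide and precursor.
A linear SVM trained on each experiment's own target/decoy PSMs then
combines this evidence into a data-dependent score, and identifications are
controlled by target-decoy FDR.

## XCorr

The experimental spectrum is square-root transformed (compressing the
dynamic range), binned at `bin_width` (default 0.02 Da, appropriate for
high-resolution MS/MS; a low-resolution preset would use ~1.0005 Da), and
normalised in 10 equal m/z windows so each window's maximum becomes 50.
With processed bins `y` and unit theoretical bins `t`,

    XCorr = 0.005 · ( Σ_j t_j·y_j − (1/150) Σ_{τ=−75..75, τ≠0} Σ_j t_j·y_{j+τ} )

computed in one pass by subtracting from each bin the mean of its ±75-bin
neighbourhood before the dot product.  The test suite verifies this fast
form against explicit lag enumeration to 1e-6.  Theoretical ions cover the b
and y series at fragment charges 1..max(1, z−1); modifications travel with
the fragment containing the modified residue; monoisotopic masses throughout
(proton 1.007276 Da, water 18.010565 Da).  No deisotoping, neutral losses,
a-ions or precursor-peak removal are applied; these would shift absolute
XCorr values but not the rescoring architecture.

## Features

Twenty-five named features per PSM (32 numeric entries after one-hot
expansion of charge class and enzymatic state):

| group | features | notes |
|---|---|---|
| match quality | `xcorr`, `delta_xcorr` | `delta_xcorr` = own XCorr minus the best among *other* candidates for the same (file, scan, charge); 0 for a singleton group, since most exported tables carry one row per spectrum |
| basic | `charge` (capped at 6), `pep_len`, `tryptic` (2 fully / 1 N-term / 0 C-term / none), `n_missed_cleavages` | trypsin rule: cut after K/R, blocked before P; `'-'` flanks denote protein termini and conform |
| mass | `precursor_m`, `cal_pep_m`, `mass_diff`, `abs_mass_diff` | `mass_diff` optionally snapped to the nearest of {−1, 0, +1, +2} × 1.00335 Da, because searches routinely allow 13C isotope errors; configurable off |
| annotation | `sum/frac/max_intensity` (all/y/b), `seq_cover_y/b`, `num_consecutive_y/b`, `mean/sd_frag_mass_err`, `n_anno_peaks` | greedy nearest-peak matching within `frag_tol` (default 0.02 Da); each theoretical ion claims ≤1 peak, ties to the more intense peak |

Numerical conventions for degenerate cases: intensity logs are log10(1 + x)
so absent matches map to 0; intensity fractions are 0 when TIC is 0; the
mass-error mean is 0 with no matches and the sd is 0 with fewer than two;
`num_consecutive` is the length of the longest run of matched ordinals (a
defensible alternative is the count of adjacent pairs; both are monotone in
match quality).  The "none" enzymatic state expands to an all-zero one-hot
rather than claiming one of the three coded states.

## Target-decoy q-values

PSMs are sorted by decreasing score, decoys first on ties (conservative);
the FDR estimate above each cutoff is `#decoys / max(1, #targets)` (the +1
numerator correction is available as an option) and q-values are the running
minimum from the worst prefix upward.  A PSM set at FDR α is the targets
with q ≤ α; decoys are never reported.  The implementation is checked
against brute-force prefix enumeration on a thousand random instances.

## Iterative SVM

Iteration 1 selects positives as targets with q ≤ `fdr_train` (default
0.01) under XCorr, negatives as random decoys — at most 10,000 of each,
uniformly sampled, since a linear model does not need millions of training
rows.  Features are standardised with training-sample statistics each
iteration (constant features get a unit divisor — necessary because masses
in hundreds of Da sit next to fractions in [0,1]).  A linear SVM
(liblinear primal solver, deterministic; cost C configurable, default 1)
is fitted, all PSMs re-scored, q-values recomputed, and from iteration 2 the
current SVM score drives positive selection.  The loop runs up to 10
iterations, stopping early when the accepted-target count changes by less
than 0.1% relative; the final result uses the iteration whose model accepted
the most targets at `fdr_train`, so the final count never falls below
iteration 1.  The final model scores all PSMs including those used in
training; no cross-validation split is applied — the 10k/10k subsampling
limits overfitting, and the ground-truth calibration benchmark (below)
confirms the realised FDP stays within the nominal level under the
generator's conditions.  Pass-through tool scores, when supplied, are
appended to the feature matrix untransformed (take logarithms of e-value-like
scores before export).

## Synthetic data generator

Real search results cannot ship with the package, so every stage is
exercised on generated data with known ground truth.  A pool of tryptic
peptides (~2,500) is digested from 60 random protein sequences of length 360
drawn with roughly protein-like residue frequencies; carbamidomethyl is
fixed on Cys and Met oxidation applied to 30% of Met peptides.  Each PSM is
one of:

- **correct target** — spectrum built from the assigned peptide's own b/y
  ions, each kept with probability drawn per PSM from uniform(0.05, 0.65)
  (centre 0.35 ± 0.30), plus 40 noise peaks and lognormal intensities;
- **incorrect target** — a genuine spectrum of a *different* pool peptide
  whose mass lies within ±2 Da of the assigned peptide's, so wrong matches
  resemble real random hits rather than pure noise;
- **decoy** — generated exactly like an incorrect target but assigned a
  pseudo-reversed peptide (C-terminal residue kept, modifications remapped)
  with the decoy accession prefix.

Precursor m/z is derived from the assigned peptide with ~3 ppm jitter in
all three classes, so the mass-difference features carry no class signal and
decoys remain exchangeable with incorrect targets — the assumption that
makes decoy counts estimate false matches.  With `auxiliary_signal` on
(default), correct PSMs get fragment m/z jitter of sd 0.0015 Da while
accidental matches show tolerance-limited uniform errors (sd ≈ 0.0115 Da):
class signal in the mass-error features that XCorr, insensitive below its
0.02 Da bin, cannot exploit.  The wide coverage spread makes the
correct/incorrect XCorr distributions overlap the way published
target/decoy distributions do, leaving genuine headroom for the learned
score.  Default sizes are 3,000 correct + 2,000 incorrect targets and 5,000
decoys (5,000 targets at 60% correct).

What the generator does **not** emulate: realistic fragment intensity
patterns, retention time, chimeric spectra, charge-state errors, shared
peptides across proteins, and sequence homology between targets and decoys.
Passing benchmarks therefore demonstrate the correctness and calibration of
the machinery under the stated statistical structure, not performance on
real instrument data.

## Benchmarks and problem sizes

The standard evaluation runs the full pipeline on 20 independent datasets of
10,000 PSMs (the acceptance test suite) and reports per seed the XCorr-only
baseline count at 1% FDR, the SVM count, and the ground-truth FDP among
accepted PSMs; `scripts/acceptance.py` reports the same quantities over 10
seeds plus the two oracle-agreement checks.  Typical results: mean FDP
≈ 0.005 (nominal 0.01), SVM gain ≈ 13% over the baseline, gain ≥ 5% in every
seed.  A full seed evaluates in ~10 s on one CPU.

## Known limitations

- Only b/y series and CID/HCD-style fragmentation; no ETD c/z support.
- One spectrum lookup key per MGF (SCANS, else TITLE); duplicate keys are
  rejected rather than disambiguated.
- The SVM is linear by design (following the Percolator lineage); nonlinear
  kernels and cross-validated scoring are out of scope.
- Peptide-level and protein-level FDR are not computed.
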