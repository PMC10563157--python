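# Methods

This note documents the models, parameter choices and known limitations of
varipept in enough detail to reproduce or audit any number the package
computes.

## Variant database construction

Variants are single-nucleotide substitutions given in 1-based transcript
cDNA coordinates with a minor allele frequency (MAF). A variant is applied
only when its stated reference allele matches the cDNA (anything else is an
input-consistency error), its MAF exceeds the threshold (default 0.01,
i.e. "common" variants), and it falls inside the annotated main open
reading frame (mORF). The substituted mORF is translated with the standard
genetic code; a synonymous product, or a stop before the first codon
completes, yields no entry. Transcripts without an mORF annotation are
skipped with a warning. **Premature stop codons truncate the protein at
the stop** — the truncated product is kept and digested normally; this is
a design choice (one could equally drop truncating variants), made because
a truncated protein still contributes real tryptic peptides upstream of
the stop. Only substitutions are supported; indels and stop-loss variants
are out of scope.

Digestion follows the standard trypsin convention: cleavage C-terminal to
K/R, suppressed when the next residue is P; up to 2 missed cleavages;
peptides of 8–40 residues (all configurable). The length filter is applied
last, after missed-cleavage concatenation.

### Decoys

Decoys are pseudo-reversed targets generated per protein. The sequence is
cut at its fully-specific tryptic sites; within each fragment the K, R and
P residues keep their positions and the remaining residues are reversed.
Because every residue that can create or suppress a cleavage site stays in
place, re-digestion of the decoy reproduces exactly the target's fragment
boundary structure, and each decoy fragment is a permutation of the
corresponding target fragment. Consequently the multiset of
tryptic-peptide residue compositions — and therefore peptide masses, at
every missed-cleavage level — is preserved per protein. (A whole-sequence
reversal with cleavage-site swapping does not have this guarantee when
proline-suppressed sites are present; preserving peptide masses is the
property that makes decoys valid score competitors, so we enforce it by
construction.) Decoy peptides that collide with any target peptide are
re-shuffled (same fixed positions, shuffled free residues, seeded RNG) up
to 20 times; remaining collisions are logged and kept. Decoy accessions
carry the prefix `DECOY_`.

### Peptide labeling

Labels are assigned at the **sequence level**: a peptide equal to any
canonical-database peptide is `canonical`, even if it is also reachable
through a variant entry; a peptide reachable only through variant entries
is `variant`; peptides found only in decoys are `decoy`. Contaminant
entries never produce `variant` labels. Sequence-level labeling is the
conservative choice for coincidental collisions — a spectrum matching such
a peptide cannot be claimed as evidence for the variant.

## Predictors

The pipeline treats RT and fragment-intensity prediction as an exchange
format, not a model: tab-separated adapters
(`peptide_key, rt_predicted` and
`peptide_key, series, ordinal, fragment_charge, mz, intensity`) accept
exports from external deep-learning predictors, and built-in surrogates
fill in when no file is supplied. The surrogates are pure functions:

- **RT**: an additive hydrophobicity model, `120 + 18·Σ coef(aa) + 2·len`
  seconds, with fixed residue coefficients spanning −2.5 (K) to 11.0 (W).
  The absolute scale is irrelevant because predictions are always
  recalibrated (below).
- **Fragments**: all b/y ions at fragment charges 1–2; m/z from
  monoisotopic residue masses (b = prefix + proton, y = suffix + water +
  proton, modification deltas attributed to the containing fragment);
  intensities follow a smooth positional bump (peaking mid-sequence) with
  y weighted 2× over b and charge 2 weighted 0.3× over charge 1,
  normalized to unit sum.

The surrogates make no claim of predictive accuracy on real data; they
exist so that the feature and rescoring mathematics can be exercised and
validated independently of any predictor download. With real data, use the
adapters.

The modified-peptide join key is `PEPTIDE|pos:delta,...|charge`, written
with 10 significant digits so mass deltas round-trip.

## RT apex and calibration

The elution apex is extracted from MS1 scans: intensity within 10 ppm of
the precursor m/z is summed per scan over a ±60 s window around the MS2
time, smoothed with a centered 3-point moving average, and the RT of the
maximum is taken (earliest on ties). If no MS1 point qualifies, the MS2
time is used (`ms2_fallback`); in that case the measured-RT-to-apex
feature is 0 by construction. The smoothing window, tolerance and
tie-break are our choices — the upstream tooling this emulates does not
document its parameters — and all are configurable.

Calibration maps the predictor scale onto the chromatogram: ordinary least
squares of apex RT on predicted RT, fitted on targets confident
(q ≤ 0.01) in a rescoring pass that uses only the standard features. If
fewer than two confident PSMs exist (e.g. on very poor data), the 50
top-scoring targets are used instead, with a warning; a degenerate fit
(constant predictions) falls back to the identity map with a warning
rather than aborting the run.

## Feature schemas

**Standard (18)**: engine score; delta score to the next-best candidate;
precursor mass error in ppm and its absolute value; peptide length; missed
cleavages; charge indicators (z = 2, 3, 4, ≥ 5); enzymatic N/C terminus;
number of variable modifications; number of matched fragments; fraction of
matched fragment intensity; precursor m/z; precursor neutral mass; and
ln of the candidate count for the spectrum. The exact composition of a
"standard" Percolator feature set varies between tools; this default is a
representative 18-name schema and is configurable.

**Extended (40)** adds 22 features: the four RT error metrics
(|Δ|, Δ², ln(1+|Δ|) with Δ = apex − calibrated prediction, and
|RT_MS2 − apex|); the five agreement metrics × three ion groups (b, y,
all); the consecutive matched b-ordinal run from the N terminus and
y-ordinal run from the C terminus; and the matched-peak count over all
ions.

Peak matching uses greedy unique assignment within a relative tolerance
(default 10 ppm): candidate (predicted ion, observed peak) pairs are taken
in order of increasing ppm error (ties: lower ordinal), each observed
peak and each predicted ion used at most once. The agreement metrics
operate on intensity vectors indexed by the predicted ions of the group:
predicted intensities and matched observed intensities (0 where
unmatched), each normalized to unit sum (an all-zero observed vector is
left as zeros). Then

- `pct_matched` = |matched| / |predicted| · 100,
- `cosine` = dot/(‖obs‖‖pred‖), 0/0 defined as 0,
- `angular` = 1 − arccos(cosine)/π ∈ [0.5, 1], exactly 0.5 when nothing
  matches,
- `log_distance` = mean |ln(obs + ε) − ln(pred + ε)|,
- `cross_entropy` = −Σ obs · ln(pred + ε), in the observed→predicted
  direction (the symmetrized variant is a possible alternative; we fix
  this direction and document it),

with ε = 10⁻⁶ as the logarithm floor. The RT "logarithmic distance" is
defined as ln(1 + |Δ|): symmetric in sign, zero at zero, finite
everywhere. PSMs with zero matched peaks keep their floor-valued features
and stay in the analysis; they are not dropped.

## Rescoring

A semi-supervised linear rescorer with the same contract as Percolator
(which can also be used externally via the PIN export). PSMs are split
into 3 folds by a salted hash of the spectrum id. Per fold: features are
standardized on the training split; the starting direction is the single
feature (and sign) maximizing targets at q ≤ 0.01; then for 10 iterations,
positives are the targets currently at q ≤ 0.01, negatives all decoys,
and an L2-regularized logistic model (regularization strength 1.0) is
refitted. The held-out fold is scored by the final model; per-fold scores
are standardized against the training decoys before merging, and the
merged scores are z-scored. With a single feature there is nothing to
learn and the feature itself is the score. Folds whose training split
yields fewer than 10 confident positives are merged into a neighbor; if
no feature separates anything at the training threshold, scoring falls
back to the engine score (this is what makes the procedure safe on
null-only data: nothing is learned, and essentially nothing reaches a
confident q-value).

q-values use target-decoy competition with the conservative +1 decoy
correction, FDR̂(s) = (#decoys ≥ s + 1)/max(1, #targets ≥ s), and the
running-minimum (q = min over thresholds at or below the score, capped at
1); tied scores share a q-value. Peptide-level q-values take the best PSM
per peptide sequence and re-run the competition on those representatives;
whether a peptide roll-up or a dedicated peptide model is preferable is an
open design question, and the best-PSM roll-up is the simple, common
choice.

## Synthetic data

The generator emulates the statistical structure of a proteogenomic
search at desk scale, not instrument physics. Defaults (one seed drives
everything; identical seeds give byte-identical outputs):

- 30 proteins of 100–160 residues built from tryptic-friendly segments
  (6–11 plain residues + K/R), reverse-translated to cDNA with UTRs and an
  annotated mORF; 30 missense variants with MAF ∈ [0.05, 0.5].
- 400 correct PSMs (15% on variant peptides) and 200 random PSMs (half
  matched to decoy peptides, half to wrong targets).
- Correct spectra are the surrogate prediction with multiplicative
  log-normal intensity noise (CV 0.2), 3 ppm m/z jitter, 15% peak dropout
  and 40 uniform chemical-noise peaks scaled to the signal median — so a
  substantial share of observed intensity is unexplained, as in real
  spectra. Measured RT is the true elution time (surrogate RT mapped onto
  a 150–1650 s gradient) plus Gaussian noise (σ = 5 s); MS1 scans every
  3 s carry a triangular XIC (half-width 30 s) around each true apex.
- 30% of correct PSMs are *hard*: 40–80% peak dropout and an engine score
  drawn from the random-match distribution. These model low-abundance
  peptides whose engine-level evidence is weak and which only predictor
  agreement can rescue — the population responsible for the
  extended-vs-standard identification gain.
- Random PSMs record, as the spectrum's precursor, the wrong peptide's
  theoretical m/z with the same ppm jitter (a search engine only reports
  candidates whose precursor matches), and 35% of them have 10–80% of the
  wrong peptide's ion m/z values planted into the spectrum with
  uncorrelated intensities — random matches that fool counting features
  but not the intensity-pattern or RT metrics. Engine scores: correct
  ~N(2.5, 1), random ~N(0, 1).

What passing tests on this generator do **not** show: robustness to real
predictor error (surrogates are exact for correct PSMs up to noise),
charge-state envelopes, chromatographic tailing, co-eluting isobaric
peptidoforms, or modification localization. The generator's role is to
verify the mathematics and the qualitative structure (decoy/target
feature separation, FDR control, gain from predictor features), not to
benchmark absolute identification rates.

## Numerical and scale choices

- Test-suite problem sizes: the distributional panel uses 10 seeds of the
  default configuration (600 PSMs each); FDR calibration uses 20 null
  replicates of 300 random PSMs. These sizes give stable properties while
  keeping the whole suite under a minute of compute.
- At 1% FDR, runs with fewer than ~100 decoys cannot resolve q ≤ 0.01 at
  all (the +1 correction makes (d+1)/t > 0.01 until t ≥ 100); very small
  demonstration runs therefore legitimately accept nothing.
- mzML support is a minimal subset (64-bit/32-bit float arrays,
  no-compression or zlib, ms level, scan start time, selected ion) read
  with lxml directly; MGF I/O uses pyteomics. Retention times are seconds
  everywhere; mzML minute units are converted on read.
- Apex grid quantization: with MS1 scans every 3 s, apex RT (and hence RT
  residuals) is quantized to the scan grid; "zero" RT error in noiseless
  tests means < 5 s.
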