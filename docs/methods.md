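# Methods

## Cross-link identification model

The pipeline consumes spectrum-level identifications of BS³ cross-linked
peptides. A record is either a peptide *pair* (two peptides, one linked
lysine each) or a *looped* peptide (one peptide carrying both linked
lysines). Absolute residue coordinates are 1-based; a link position `i` in a
peptide starting at offset `s` maps to residue `s + i − 1`. When the source
table supplies claimed absolute residues (as the printed summary tables do),
the claim is cross-checked against the computed coordinate whenever the
protein sequence is available, and is used to disambiguate peptides that
occur at multiple offsets. The bundled summary-table fixtures are processed
in claimed-residue mode — the full construct sequences are not part of the
tables, and inventing them would add nothing the audit below does not
already check — with the in-peptide position verified to be a lysine in
every row.

**Curation.** A record is kept iff all of:

* E-value strictly below 0.001 (the FDR < 0.05 working point of the search);
* each cross-linked peptide shows ≥ 4 *consecutive* matched ordinals within
  its b series or within its y series (series are not mixed — this is the
  reading adopted for "4 consecutive b or y ions");
* strictly more than half of the spectrum peaks are assigned ("majority of
  ions assigned" is quantified as fraction > 0.5; configurable).

Records lacking ion annotations can be retained behind a permissive flag and
are reported separately as uncurated.

**Classification and collapse.** Loop if single-peptide, inter if the two
proteins differ, intra otherwise; the classes are exhaustive and mutually
exclusive, so class counts always partition the collapsed set. Uniqueness is
at the residue-pair level with canonical ordering (so (A, ra, B, rb) and
(B, rb, A, ra) merge); loop links key on their unordered position pair.
Replicate support is the set of replicate labels over retained evidence; a
link is drawn bold when supported by ≥ 2 biological replicates, and the flag
is monotone under added evidence.

**Offset audit.** Each (residue, position) claim implies a peptide start
offset; all rows sharing a (protein, peptide) key must imply a single start.
Overlapping but distinct peptides (e.g. a peptide and its missed-cleavage
extension) legitimately imply different starts. The shipped tables audit
clean. One transcription oddity is preserved as printed: one intramolecular
row lists under a PBX1 label a peptide that elsewhere belongs to MEIS1; the
audit keys on (protein, peptide), so the implied starts remain internally
consistent.

## Digestion model

Trypsin cleaves C-terminal to K/R, blocked before proline by default (the
common search-engine default; configurable). Glu-C cleaves C-terminal to E,
with cleavage after D behind a flag (buffer-dependent specificity).
Cross-linker-modified lysines are uncleavable (`blocked_sites`) — required
to produce peptides such as `KTVLSIR` carrying a linked N-terminal lysine.
Peptides with k missed cleavages are exactly the merges of k + 1 adjacent
fully-cleaved peptides (property-tested against an independent merge
oracle); the search maximum of five missed cleavages is enforced.

## Heptad registers

A heptad assignment fixes the letter of the first residue and cycles
a–g with period 7; `hydrophobic_face` reports the residues on any letter
subset, typically {a, d}. Domain boundaries for the three proteins are only
fragmentarily published, so the default domain table brackets the printed
hydrophobic stretches and is flagged approximate; it drives display and
domain-pair summaries only, never residue mapping.

## One-site binding fit

Model: `y = baseline + Bmax·x/(Kd + x)`, doses in nM. By default
`baseline = 0` (the plain one-site model); a flag adds a fitted baseline.
For each candidate Kd on a 25-point log grid spanning the positive dose
range widened 100× on both sides, the linear parameters have an exact
linear-least-squares solution; the best candidate seeds a trust-region
least-squares polish. The accepted solution never has a larger residual sum
of squares than any multistart seed (asserted in tests). `se_kd` is the
asymptotic standard error from the Jacobian; a Kd outside dose-span × [10⁻²,
10²] is flagged extrapolated. Simulated titrations use 10 log-spaced doses
over 0.23–500 nM (the ELISA titration range) with unit-mean multiplicative
log-normal noise, CV 5% by default — an immunoassay-like noise model chosen
because the source assay reports none.

## Plate-immunoassay statistics

Signals are averaged per (construct, experiment), divided by that
experiment's wild-type signal (wild-type ≡ 1 by construction; the
normalization is invariant to rescaling any single experiment), and
summarized across experiments with the population standard deviation
(ddof = 0, mirroring spreadsheet `STDEV.P`). Mutants are compared to
wild-type with a pooled-variance two-sample t-test, one-tailed in the
mutant < wild-type direction (the loss-of-binding hypothesis). With zero
pooled variance the test is degenerate: p = 0.5 for equal means, else 0 or 1
by direction. Stars: p < 0.05 `*`, < 0.025 `**`, < 0.01 `***`, < 0.005
`****`, < 0.001 `*****`, strict inequalities, `ns` otherwise.

## Image quantification

**Rolling-ball background.** The background is the grayscale morphological
opening of the image with a non-flat ball structuring element (the
definition of the rolling-ball background): erosion then dilation with ball
heights, nearest-edge padding. It is anti-extensive, so the corrected image
is non-negative and a constant image corrects to zero. For radii above
16 px the image is block-minimum downscaled by `radius // 16`, opened at the
reduced radius, and the background is bilinearly upscaled and clipped below
the image — the classic large-radius approximation; the exact small-radius
path is what the brute-force opening oracle verifies. A radius exceeding the
image size degrades to a global-minimum background with a warning.

**Thresholds.** Otsu maximizes between-class variance of the `g ≤ t` /
`g > t` split over the intensity histogram; Huang minimizes the fuzzy
entropy `Σ h(g)·S(u(g))` with membership `u(g) = 1/(1 + |g − μ_class|/C)`,
`C = g_max − g_min`, and `S(u) = −u ln u − (1−u) ln(1−u)`. Integer images
use one histogram bin per gray level (so candidates are the actual levels);
float images use 256 equal-width bins. Ties resolve to the lowest candidate;
foreground is strictly above the threshold; constant images raise a
degenerate-input error. Both implementations equal exhaustive-search oracles
on random 8-bit images.

**Find Maxima.** ImageJ-style noise-tolerance semantics: a regional maximum
of value v is accepted iff no path to a strictly higher pixel stays at or
above v − tolerance throughout (8-connectivity). Equal-valued plateaus
report a single point — the plateau pixel nearest its center of mass, ties
broken by smallest row then column. Implementation: a descending-level
union-find sweep; a candidate is killed when its component acquires a
strictly higher summit while the sweep level is still within its tolerance
band, and accepted once the level falls below it. Two equal maxima joined
above both tolerance floors are both reported (neither sees a *strictly*
higher summit). Verified against a per-definition brute-force oracle.

**Nucleus segmentation.** Rolling-ball removal → Gaussian blur → Huang
(PLA) or Otsu (confocal) threshold → 8-connected components → hole filling
→ minimum-area filter; labels renumbered in raster order. Defaults: radius
50 px, σ = 2 px, min area 200 px² — the source plugins publish no values, so
these are fixed once at scales typical for cultured-cell nuclei at ~0.3
µm/px. Background removal is applied both before nucleus detection and
before foci detection.

**Foci counting and N/C ratio.** A focus is nuclear iff the label raster is
positive at its pixel; nuclear + cytoplasmic counts always partition the
detections. The N/C ratio is the mean background-removed GFP over the
nucleus divided by the mean over the cell's cytoplasm region — hand-drawn
masks when available, else an automatic dilation ring around the nucleus
excluding all nuclei. Per-condition ratios are normalized by the reference
(wild-type) condition's median (configurable to the mean).

## Synthetic data

All generators are pure functions of (parameters, seed). Protein pairs
default to 344 and 308 residues (the lengths of the C-terminally truncated
constructs used for cross-linking) with 14 lysines each, regenerated until
every digestion peptide of length ≥ 5 occurs at a unique offset. Planted
links draw E-values log-uniformly from [10⁻⁸, 10⁻⁴] and decoys from
[10⁻³, 1] (invented, configurable); decoys cycle through exactly one
violated curation rule each (E-value, broken ion run, minority assignment),
and their residue pairs are disjoint from the planted set so precision and
recall are well defined. PLA fields are 192 × 192 px with 3 non-overlapping
elliptical nuclei, Gaussian foci (σ = 1.5 px, amplitude 80, pairwise
separation ≥ 15 px), a linear background gradient and Gaussian noise
(σ = 2). These sizes keep the full recovery suites inside a desktop test
run while leaving dozens of resolvable foci per field.

What the generators do *not* emulate: real MS/MS fragmentation and decoy
score distributions (decoys violate rules by construction rather than by
rescoring), optical point-spread functions beyond Gaussian spots, uneven
illumination beyond a linear gradient, touching nuclei, and cell-shape
variability. Passing recovery tests therefore demonstrate the correctness
of the pipeline's logic under its stated assumptions, not its robustness to
every artefact of real acquisitions.

## Numerical choices and limitations

* E-value comparison is strict `<`; star thresholds are strict `<`.
* Low-SNR foci detection (spot amplitude ~4× noise sd) applies a σ = 1 px
  Gaussian matched filter before Find Maxima with tolerance 3; at high SNR
  detection runs unsmoothed with tolerance 20.
* The one-site fit assumes free-ligand ≈ total-ligand (no depletion) and
  homoscedastic residuals; Hill/cooperative models are out of scope.
* Cross-links at protein N-terminal α-amines (BS³ chemistry) are accepted
  behind a flag, default off; only lysine–lysine links are modelled.
* The linear SVG map is a display artefact: arc height scales with sequence
  distance, bold strokes mark both-replicate support; no 3-D distance
  validation is attempted (no structure of these complexes exists).
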