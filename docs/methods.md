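# Methods

## Coordinates and genome model

All internal coordinates are 0-based half-open `[start, end)`. GFF3 input
(1-based inclusive) and the 1-based summary peak-table dialect are converted
at the I/O boundary only; MACS-style narrowPeak is already half-open, with
the summit stored as an offset from the peak start. IUPAC ambiguity codes
are collapsed to `N` on read; any other character is a parse error naming
the record.

The intergenic complement is constructed per contig by merging all gene
intervals (strand ignored; overlapping or abutting genes are unioned) and
complementing against the contig span, so coding length + intergenic length
equals the contig length exactly. Which feature types count as "coding" is
configurable (`read_annotation(feature_types=...)`); the default is `gene`
features only, since structural RNA annotation conventions vary between
genomes.

AT fractions exclude `N` bases from the denominator; an all-`N` interval
yields `nan`, which propagates as missing rather than as zero. Pooled AT
over an interval set sums base counts before dividing (length-weighted),
while per-region AT returns one value per interval; the two differ for
unequal interval lengths, and both are exposed because the comparison
statistics need the per-region form.

## Summit-window classification

The enrichment-summit window spans 30 bp upstream through 30 bp downstream
of the peak summit. Two readings of that phrase differ by one base; the
package uses the half-open `[summit-30, summit+30)`, exactly 60 bp with the
summit base as the first downstream base, matching the "60-bp region around
the summit" label; an inclusive 61-bp variant is available via
`inclusive_window=True`. Windows are clipped at contig edges.

A window is called **intergenic** iff strictly more than 30 bp of it
overlap the intergenic set; exactly 30 bp (or fewer) is **coding**. This
strict inequality is deliberate and tested at the boundary. The
`window_fully_in_context` flag marks windows lying entirely inside their
called context (the asterisk convention of the published top-20 table).
The fold-enrichment filter is inclusive (FE ≥ 2 belongs to the "FE ≥ 2"
class). Top-k/bottom-k selection sorts by FE with deterministic (contig,
start) tie-breaking.

## AT-enrichment testing

Summit-window AT fractions are partitioned by called context and compared
with the matching genomic background. Two background constructions are
offered because the sampling unit of such comparisons is a genuine modeling
choice: `per_region` (default) uses one AT value per genomic
intergenic/merged-coding interval; `matched_windows` draws length-matched
(60-bp) windows from the background, equalizing measurement variance with
the peak windows. The method tag is recorded in every output row.

Welch's unequal-variance t test is the default "unpaired t test" because
the group variances differ by construction (60-bp windows versus whole
regions); Student's pooled variant is selectable, and both are verified
against hand-computed closed forms to 1e-10. The seeded permutation test
uses the add-one estimator p = (1 + k)/(n_perm + 1), so its smallest
attainable p is 1/(n_perm + 1) — n_perm must exceed 999 to reject at
α = 0.001. Significance is flagged at p < 0.001 with no multiple-testing
correction, mirroring the single-comparison convention of the analysis this
package reproduces. Cells with fewer than two windows are marked
not-computable instead of raising.

## Subpeak merging and correlation

Peaks separated by at most `max_gap_bp` (default 200 bp) on one contig are
grouped into a parent region; members are lettered a, b, c, … by start
position and the region inherits the maximum member fold enrichment. The
grouping is a parameterized reconstruction — the upstream peak caller's
internal subpeak logic is not public — and makes no claim of reproducing
any original lettering. The width–enrichment relation is summarized by the
Pearson correlation with its least-squares line; fewer than three peaks or
zero variance in either variable raises a degenerate-input error (CLI exit
code 4).

## EMSA isotherm fitting

Fraction bound per lane is 1 − free/total, clipped to [0, 1]. The default
binding model is the single-site hyperbola θ = [P]/(K_D + [P]) on protein
monomer concentration, fit by least squares in log K_D with a multistart
over seven log-spaced initial values spanning 0.1× the smallest to 10× the
largest positive concentration; the Hill variant adds a free cooperativity
exponent bounded to [0.1, 10]. Fits are labelled *apparent*: ladder-like
multi-dimer binding violates the single-site assumption, so K_D is simply
the concentration at half-maximal binding. Non-convergence sets
`converged=False` with diagnostics instead of raising. The fit is
scale-consistent (scaling all concentrations by c scales K_D by c), which
the tests assert.

## AFM quantification

Topographs are leveled by subtracting a least-squares background plane
(approximating instrument-software leveling; scar correction is out of
scope). Complexes are 8-connected components above a height threshold
(default 1.0 nm above the leveled background) with area ≥ 4 px. Per
complex, the maximum height is binned into [0,2), [2,4), [4,6), > 6 nm —
percentages over a non-empty population sum to 100 — plus the percentage
above a tall-complex cutoff (default 12 nm). Foci are regional maxima with
prominence ≥ 0.5 nm (h-maxima transform) whose pairwise separation is
≥ 5 px after greedy suppression in height order; every detected complex
reports ≥ 1 focus. All parameters are exposed because the inclusion
criteria of such analyses are instrument- and preparation-specific.

## Synthetic data: what it emulates, and what not

The generator defines the study conditions the tests run under.

- **Genome** (`GenomeSpec`): one 400-kb contig, 240 genes of 600–1400 bp,
  coding AT 53%, intergenic AT 62%. Bases are drawn independently within a
  region; composition is heterogeneous between regions — each gene draws
  its own AT target (sd 0.02; codon structure keeps real coding DNA
  relatively homogeneous) and intergenic sequence draws one target per
  500-bp block (sd 0.05), producing the sub-kilobase AT-rich islands that
  nonspecific AT-favouring occupancy centers on while keeping the
  genome-wide class means on target. Gap lengths follow a symmetric
  Dirichlet(0.3) partition of the non-coding space with a 30-bp minimum,
  giving a heavy-tailed gap distribution with occasional kilobase-scale
  intergenic islands. The resulting intergenic fraction (~35–40%) is larger
  than in a typical archaeal genome; it buys enough intergenic peaks per
  simulation for stable category statistics at this genome size. No
  dinucleotide structure, operon structure or replication-strand bias is
  modelled, so passing tests demonstrate correct recovery of
  composition-driven occupancy, not robustness to those real-genome
  features.
- **Occupancy** (`OccupancySpec`): expected fold enrichment is
  baseline + α · logistic((AT_w − m)/s) of the 500-bp moving AT fraction,
  with α = 3.5, m = 0.65, s = 0.02. The logistic link bounds enrichment
  (maxima land in the 3–5× range of the strongest observed peaks) and its
  midpoint sits above the intergenic mean so that enrichment discriminates
  among intergenic islands rather than saturating on all of them — the
  generator's expression of "enrichment zones centered preferentially on
  AT-rich intergenic windows". α = 0 is the null: a flat track.
- **Coverage**: IP depth ~ Poisson(depth · E(x)/mean E), input ~
  Poisson(depth), default 50× in triplicate. The master seed is split with
  `SeedSequence.spawn`, one child stream per replicate track, so adding a
  replicate never perturbs earlier streams. No read-length, fragment-size
  or crosslinking model.
- **Toy peak caller**: replicate-averaged, depth-normalized, moving-average
  smoothed (IP+1)/(input+1); maximal runs ≥ cutoff (default 1.5), gaps
  ≤ 200 bp merged, width ≥ 100 bp; summit = leftmost argmax, peak FE = mean
  over the peak. It segments simulated tracks only and is not a substitute
  for a real peak caller.
- **EMSA/AFM**: hyperbolic titrations with Gaussian noise clipped to
  [0, 1]; topographs as chains of equal-amplitude Gaussian bumps (one per
  focus, 3.1σ spacing, σ = 2.5 px) whose geometry guarantees each complex
  stays one connected component with recoverable foci, with complex
  clearance preventing merges — ground truth is returned alongside.

Problem sizes used by the test suite and the acceptance script — a 400-kb
genome, single simulations per condition, 100 seeded K_D fits, 200 seeded
null t tests, 12–14 AFM complexes — were chosen so the statistical checks
are well-powered at comfortably interactive runtimes.

## Numerical and design notes

- Identity/similarity of a pairwise protein alignment counts identical
  (and, for similarity, same-class) residue pairs over all alignment
  columns by default, gaps counting as mismatch; the alternative
  ungapped-column denominator is selectable and the choice is recorded in
  the result, since published values rarely state it. The residue classes
  default to basic (K, R, H), acidic (D, E), polar uncharged (S, T, N, Q),
  hydrophobic (A, V, I, L, M, F, Y, W) and special (C, G, P).
- Identical constant samples in the t test return t = 0, p = 1 by
  convention rather than 0/0.
- Permutation p-values tolerate 1e-15 float noise when comparing permuted
  to observed differences, so exact ties count as extreme.
- The exactly-6-nm AFM edge case falls in the top ("> 6") bin so the bins
  partition the height axis.
- Known limitations: no multi-contig occupancy coupling (tracks are
  per-contig), no replicate-level peak reconciliation beyond averaging in
  the toy caller (the reproducibility criterion of real multi-replicate
  peak sets is recorded in output metadata, not inferred), and no gel or
  instrument-file parsing — the package starts from lane-intensity tables
  and height matrices.
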