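# Methods

## Model and procedure

`backfold` treats a coding sequence as an RNA that can fold back on itself
and asks whether its realized arrangement of synonymous codons is unusual
in how much structure it forms. The pipeline is: (1) fold the original ORF
and obtain per-position base-pairing probabilities; (2) sample alternative
ORFs (aORFs) that encode the same peptide under a null model; (3) fold the
aORFs identically and rank the original's mean pairedness (DBF) within the
sample; (4) aggregate ranks over many genes into a 101-bin score
distribution and quantify enrichment of the extremes.

The rank score is `(j + k/2) / (i + j + k)` with i/j/k the counts of
aORFs folding more / less / equally strongly. Ties contribute half so that
the all-tied case gives exactly 0.5. Ties are declared at `tie_epsilon =
1e-12` on DBF values; because DBFs are means of folding probabilities,
exact ties essentially only arise from identical sequences (model 2 on
short or low-diversity ORFs), which the implementation detects by
sequence identity and folds only once.

## Folding engines

**Built-in engine.** A McCaskill-style inside–outside dynamic program over
pseudoknot-free structures with a purely additive per-pair energy model:
Boltzmann weights `exp(E/kT)` with defaults E(GC) = 3, E(AU) = 2,
E(GU) = 1 (units of kT, kT = 1) and a minimum hairpin of 3 unpaired
bases. No stacking or loop terms. This model was chosen because (a) an
exhaustive enumeration oracle stays exact and cheap, so the dynamic
program is verifiable to numerical precision (the suite checks agreement
to 1e-9 on hundreds of random sequences), and (b) every downstream
statistic is *comparative* — the oORF is ranked against aORFs folded under
the same model — so the ordering, not the absolute probability scale, is
what matters. Numerical scaling: unpaired positions carry a factor 1/s and
pairs w/s²; the driver retries along a small ladder of scales when a long
or GC-rich sequence over- or underflows the partition function. Kernels
are numba-compiled; a batched entry point folds the ~100 equal-length
sequences of one scoring step in a single call.

**Local (windowed) mode.** Sequences of at least `local_threshold` (100 nt,
equal to the window) are folded in a sliding window of 100 nt with step 1;
the probability of a pair is its mean over all windows fully containing
it, i.e. exactly the RNAplfold averaging convention, and pairs spanning
more than the window have probability 0. Dividing by the per-pair window
count (rather than the sequence-wide window count) avoids deflating
positions near the sequence ends. A consequence worth stating plainly:
because different pairs average over different numbers of windows, the
per-position sums of windowed probabilities are a weighted mixture and can
exceed 1 (we observed up to ~3.6 on random 1.5-kb sequences, and verified
the same behaviour in RNAplfold's own output). Windowed matrices are
therefore flagged, and the [0, 1] bound on pairedness profiles is enforced
only for global-mode matrices. The windowed "DBF" is thus a pairing load
rather than a true fraction; all uses of it here are comparative (ranks
within a null sample, ratios between groups), which the mixture scaling
leaves intact.

**Thermodynamic adapter.** Where the ViennaRNA python bindings are
installed, `backfold.vienna.ViennaRNAEngine` provides full Turner-model
probabilities (RNAfold partition function globally, RNAplfold windows
locally) behind the same matrix contract, plus parsers for RNAplfold
`_basepairs` and `_dp.ps` files. The adapter is the preferred engine for
the fold-change simulations, whose reference values derive from
thermodynamic folding; it is not a pip-installable dependency and the
package degrades gracefully without it.

## Null models and reproducibility

Models 0/1/2 are described in the README. Stop codons form a family like
any other (three members; model 2 shuffles within the usually singleton
stop family, a no-op) — treating them uniformly keeps the samplers simple
and leaves model 2 unaffected. Random streams are derived per
(seed, CRC32(record id), model, replicate) via `SeedSequence`, so outputs
are bit-identical across runs, processing orders and worker counts.

## Score distribution and selection fraction

Bin assignment is `round(score × 100)` half-away-from-zero with a 1e-9
nudge absorbing binary representation error; with n = 100 aORFs raw
scores live on a half-percent grid and midpoints round up. Bin Z-scores
standardize the bin *fraction* by the mean and the population (not n−1)
standard deviation over the 101 bin fractions; the enrichment excess
subtracts the neutral expectation 1/101 per significant bin. The fraction
(not the count) is used in the excess term for dimensional consistency —
subtracting 1/101 from a count would mix units. Only bins 0–4 and 96–100
can contribute, each gated at Z ≥ 1.96; no multiple-testing correction is
applied across bins (the fixed per-bin threshold is part of the method's
definition).

## Calibration harnesses and what they show

**Null uniformity.** `null_scores` draws random ORFs (ATG + uniform sense
codons + uniform stop; 25 codons by default), replaces each "oORF" by a
fresh model-2 shuffle of itself, and ranks it against 100 further
shuffles. By exchangeability the rank is uniform over the 101 grid values
— note that this exactness requires n = 100 aORFs: with n = 50 the score
grid has only 51 points and a 101-bin histogram cannot be uniform. The
acceptance suite checks a 5000-record corpus by χ² (p > 0.01) and a
±3-binomial-SD bound per bin. 25 codons is the smallest size at which the
shuffle space is effectively tie-free while folding stays fast; this is a
package choice, stated here for reproducibility.

**Recovery.** Implants are random ORFs whose oORF is the most structured
of 200 model-2 shuffles, emulating strong selection for high structure;
mixed into the null corpus at 2/5/10% they should be — and are — recovered
by S to within 1.5 percentage points. The recovery is slightly below the
implanted fraction by construction: the 1/101 neutral share is deducted
per enriched bin, and implant mass landing in bins whose Z stays below
1.96 is not counted.

**What the synthetic data do not show.** Generated ORFs have i.i.d.
uniform codon usage and no compositional autocorrelation, repeats, or
length/GC heterogeneity; real transcriptomes have all of these. Passing
calibration shows the statistic is unbiased and the machinery correct
under the stated null, not that any particular genome's S value is
reproduced.

## Codon-set and amino-acid-set experiments

Within every multi-codon synonymous family, codons sorted by (G+C count,
then third-position base C > G > T > A) descending split into a high-GC
half ("set 2", associated with high structure) and a low-GC half
("set 1"); methionine and tryptophan, having one codon, carry no
codon-level signal and belong to neither codon set. Amino acids split
10 + 10 by mean codon G+C (ties broken alphabetically), M and W included.
The third-position order follows the long-standing observation of
C-ending codon preference in highly expressed genes; any fixed order
would do for reproducibility. An empirical derivation from composition
trends across several datasets (strict low<mid<high increase votes a
codon into set 2, majority across datasets decides, unresolved codons
fall back to the GC rule) is provided and converges to the GC-rank
partition when structure is GC-driven. The rank-sum comparison of mean
codon GC share between the two amino-acid sets gives p < 0.001,
matching the direction and significance reported for this contrast.

The fold-change experiments draw random peptides (methionine first,
then i.i.d. uniform residues), encode each peptide once with set-1-only
and once with set-2-only codons (codon experiment) or draw independent
peptides from the set-1-only and set-2-only amino-acid alphabets with
uniform codon choice (amino-acid experiment), fold every ORF, and report
each group's mean paired-base fraction relative to the pooled mean of
both groups. With equal group sizes the two ratios sum to exactly 2 —
an algebraic identity of the pooled mean. The default scale is 200
peptides of length 500 per group (the per-group length-500 condition is
kept; the peptide count is a package choice that leaves the group means
stable to well under 0.01). A `pooling` switch selects per-ORF or
per-base weighting of the pooled mean; the two coincide whenever both
groups share one ORF length, as they do here.

## Degenerate inputs and numeric edge cases

Sequences with ambiguity codes are rejected at the door (pairing
probabilities are undefined for them). ORFs shorter than 6 nt, out of
frame, or with internal stops are rejected with machine-readable reasons;
terminal stops are retained and folded. Empty aORF samples, empty
profiles and out-of-range scores raise. The enumeration oracle refuses
sequences longer than 25 nt. Local folding of a sequence shorter than
the window falls back to global with a warning; a window-length sequence
has exactly one window and reproduces global folding identically.

## Known limitations

The built-in energy model ignores stacking, loop entropies and
temperature, so its absolute probabilities are not thermodynamic;
replication-grade numbers require the ViennaRNA adapter. No pseudoknots.
Only the standard genetic code is wired in (the code table is a single
module-level constant, straightforward to generalize). The amino-acid-set
fold changes depend on which 10 + 10 amino-acid split is used; the GC-rank
split is a principled default, but other defensible splits shift the
ratios by a few hundredths.
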