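# Methods

`mirdrought` re-implements, as a tested library, the computational chain used
in early Illumina-era plant small-RNA studies to find drought-responsive
miRNAs from one control (CK) and one stressed (DS) library: read cleaning and
collapsing, exact-match genome mapping, removal of ncRNA- and known-miRNA-
derived tags, novel miRNA discovery by hairpin folding with miRNA* support,
and a conditional Poisson test on normalized counts. This note records the
models, the defaults and why, the numerical choices, and what the synthetic
data can and cannot demonstrate.

## Preprocessing

Reads are 3'-adapter-ligated inserts. Trimming finds the leftmost exact
occurrence of an adapter prefix (>= 6 nt, configurable) extending to the
read's 3' end; reads without such a match are discarded as "null adapter",
mirroring the cleaning rules of the original pipelines. Inserts are kept when
18-30 nt (the size range selected during library construction) and when their
A-fraction is <= 0.8; the polyA rule is stated qualitatively in the source
protocols, so the 0.8 threshold is this package's choice, exposed in config.
Only 3' trimming is implemented: sequencing starts after the 5' adapter, so
inserts are assumed 5'-adapter-free. Quality scores are never used; the
filters are length/adapter/polyA only. All sequences are held internally as
DNA (ACGT) and rendered as RNA (lowercase, U) in reports.

Collapsing produces unique tags with exact per-library multiplicities; count
conservation through collapse is asserted by tests. Library statistics
(primary/clean/unique/mapped counts, length histograms, common/specific
fractions) reproduce the shape of the usual "statistics of sRNA sequences"
table.

## Mapping

Tags are aligned to the genome by exact full-length match only, the policy
the original studies applied ("mismatches were not allowed"). A k-mer index
(k = 12 by default; tags are always >= 18 nt) over the forward strand is
probed with the tag and its reverse complement; hits are reported as 1-based
inclusive loci with strand. The 1-based inclusive convention is fixed by the
published location strings, whose end - start + 1 reproduces the printed
precursor lengths. Multi-mapping tags keep all loci, each carrying the full
tag count; fractional assignment is deliberately not the default because the
per-locus reporting convention of the reference tables is one row per locus.
An O(nm) naive scan serves as the correctness oracle in tests.

## Annotation

ncRNA removal (rRNA/tRNA/snRNA/snoRNA) is exact substring matching against a
user-supplied FASTA: an sRNA tag is a fragment of its parent ncRNA, so
substring (not equality) is the default. Known-miRNA assignment is exact
full-sequence matching against a mature-miRNA FASTA by default; a templated
isomiR mode (<= 2 nt end shifts, configurable mismatches) exists but is off,
which is the most conservative reading of an exact-match pipeline. Ties are
broken lexicographically by miRNA id so assignment is deterministic. Family
names are parsed from ids (mtr-miR399a -> miR399); the conserved/
non-conserved label comes from a packaged, user-editable list of deeply
conserved plant families — conservation is a curation fact, not a
computation.

## Folding

The folding engine is a Zuker-style dynamic program over nested structures:
hairpin loops >= 3 nt, stacks, bulges, internal loops (size capped at 30),
and multiloops under the standard linear model, with a traceback that breaks
energy ties toward fewer pairs in a fixed scan order. Energies are carried as
integer deci-kcal/mol, making results bit-reproducible across platforms; the
DP tables are filled by numba-compiled kernels so that 300-nt windows fold in
tens of milliseconds.

The energy model (packaged as `data/stack_energies.tsv`) is a simplified
nearest-neighbour parameterisation: one-decimal stacking energies for the six
canonical pairs (GU allowed, scored weaker than Watson-Crick), tabulated loop
penalties with 1.1*ln(n/n0) extrapolation, multiloop cost a + b*branches, and
a 0.5 kcal/mol penalty per AU/GU helix end. It provides a consistent
free-energy scale on which real pre-miRNA hairpins score roughly -40 to -110
kcal/mol — the same working range as the published mfold values — but it does
not reproduce mfold/Turner energies number-for-number, and published MFE
values are treated as fixture data, never as recomputation targets. The -30
kcal/mol acceptance threshold is therefore a calibrated default on the
internal scale, exposed in config.

Correctness is established against an exhaustive enumerator for sequences
<= 18 nt: every admissible nested structure is generated and scored with the
same loop-decomposition evaluator, and the DP optimum must match on hundreds
of seeded random sequences. The evaluator defines the model; the DP and the
enumerator are two independent searches over it.

## Discovery

Unannotated tags of mature length (20-22 nt; the reference tables contain
only 21/22-nt matures) and with >= 3 summed raw counts are candidate seeds.
The count gate is this package's addition: candidate selection needs some
expression support, and without it every 20-22-nt degradation fragment would
be folded at great cost and no scientific benefit. For each locus, genomic
windows of total length 80-320 nt in 20-nt steps are excised with the tag
near the 5' end, near the 3' end, and centered — the window plan is the
largest gap left by the source protocols; the range covers the published
86-315-nt precursor span with margin.

Each window is folded and the annotation criteria are applied to the hairpin
component enclosing the mature: the outermost pair bracketing the mature and
everything nested inside it. Side structure elsewhere in the excised flanks
is ignored — an 80-320-nt window of real (or realistic synthetic) genome
almost always folds some incidental hairpin in its tails, and fold-and-
inspect pipelines likewise judged the stem-loop containing the candidate, not
the whole excised fragment. The criteria: (a) the component is a single
stem-loop; (b) the mature sits on one arm and does not span the terminal
loop; (c) at most 4 mature bases are unpaired (common plant annotation
practice); (d) component free energy <= -30 kcal/mol; (e) component length
within 80-320 nt. Among passing windows per locus the lowest-MFE component is
kept (ties to the shorter precursor); acceptance is monotone in the MFE
threshold by construction.

The miRNA* interval is predicted from the structure by the Dicer-duplex
geometry: drop the mature's 2-nt 3' overhang, take the pairing partners of
the rest, and extend 2 nt at the star's own 3' end. On a perfect duplex this
construction is an involution (the star of the star is the mature), which is
frozen in tests. Because a handful of mature bases can pair spuriously
outside the duplex, the partner set is first reduced to its densest cluster
spanning at most one mature length. Sequenced star support is any collapsed
tag matching the predicted interval with up to 2 nt of independent end
variation; a single read counts, following the source literature's position
that no star-count minimum is required. Candidates whose precursor contains a
known mature (either strand) are the known miRNA's star arm and are dropped.
Overlapping candidate precursors collapse to the most abundant mature,
ignoring strand, because a palindromic stem maps its tags onto both strands
of one interval; within one tag's own overlapping loci, the orientation with
sequenced star support wins. Candidates are classified as a new member of a
known family when within 3 mismatches of a known mature (length differences
scored at best overlap), else as new miRNAs.

## Differential expression

Counts are normalized to CPM (count / total clean reads * 1e6). Entries below
1 CPM in both libraries are removed; the both-below reading is deliberate,
since the stricter either-below rule would delete exactly the
condition-specific miRNAs a stress study reports. The effect size is
log2(DS/CK) of normalized values; a zero side is displayed with a 0.01-CPM
pseudo-value and flagged, but the p-value always uses raw counts and needs no
pseudo-count.

Significance uses the Audic-Claverie conditional test generalized to unequal
depths: given x counts at depth N1, the count y at depth N2 follows
P(Y=y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)), a negative binomial
with x+1 successes and success probability N1/(N1+N2), evaluated through
scipy's regularized incomplete-beta tails. The two-sided p doubles the
smaller inclusive tail, min(1, 2*min(P(Y<=y), P(Y>=y))), capped at 1 —
conservative for discrete counts (measured type-I level 0.034-0.049 over the
relevant count range at the 5% nominal level). The statistic treats the
libraries as an unordered pair: tails are evaluated in a canonical argument
order, so swapping the libraries returns the bit-identical p-value, and
x = y at equal depths returns exactly 1 (both tails are exactly 1/2 by a
rational-arithmetic identity). An exact-rational summation oracle
(`poisson_p_oracle`) validates the implementation to ~1e-10 relative.

Calls follow the study's thresholds: up when DS/CK > 1.5 and p <= 0.05, down
symmetrically, with tiers "*" for 0.01 < p <= 0.05 and "**" for p <= 0.01. No
multiple-testing correction by default, matching the per-miRNA reporting
convention of single-pair DGE studies; Benjamini-Hochberg is available behind
a flag.

## Synthetic data

The generator emulates the study design at desk scale: a random genome
(default 100 kb; 400 kb in the recovery study) with planted hairpin
precursors at recorded non-overlapping loci on both strands, two libraries of
adapter-ligated reads, and a truth table of loci, rates and fold changes.

A planted precursor is flank5 + mature arm + loop + star arm + flank3 with
flank3 the reverse complement of flank5, so the construct folds into a single
long stem that pairs every mature base; the star arm is the reverse
complement of the mature with 0-3 point changes to non-pairing bases, placed
so the mature/star duplex carries 2-nt 3' overhangs. Each construct is
fold-validated at build time and redrawn (same RNG stream) if random loop or
flank bases create an alternative minimum-energy structure — the generator
guarantees its own postcondition rather than assuming it. Mature counts per
library are Poisson(rate); star counts are Poisson(rate/50), the 1:50 default
reflecting the low star counts of published tables and exposed in config.
Background reads are genome-derived fragments (so they map, exercising the
mapper and the exclusion steps realistically) with a length distribution
peaked at 24 nt then 21 nt, the canonical plant sRNA profile; a configurable
fraction comes from planted ncRNA sequences and a further set of planted
"known" miRNA hairpins exercises annotation. A 5% noise fraction of reads get
corrupted adapters to exercise the null-adapter filter. Reads are emitted as
36-nt FASTQ records with constant quality "I"; counts are Poisson rather than
negative binomial because the downstream test assumes Poisson sampling (an NB
option exists for robustness experiments).

What passing tests show — and what they do not: the synthetic data
demonstrates that the pipeline's logic recovers planted signal (>= 90% of 50
planted miRNAs at >= 500 expected reads recovered with star support, >= 95%
of 4-fold changes called in the correct direction) under the stated noise
model. Real libraries additionally contain sequencing errors, untemplated
additions, heterogeneous Dicer processing, RNA editing and expression-
dependent biases, none of which are modelled; conclusions about absolute
sensitivity on real data do not follow.

## Problem sizes and runtime

Default test and validation sizes were chosen so the whole suite runs in a
few minutes on one core: 500 sequences for the DP-vs-enumeration sweep, a
100-kb genome and 100 tags for the mapper oracle, 1000 null miRNAs for test
calibration, and a 50-miRNA / 2x90k-read recovery study. All are configurable
upward; sensitivity and calibration results were stable when spot-checked at
larger sizes.

## Known limitations

- The energy model is internally consistent but not Turner-accurate; MFE
  values are comparable within this package only.
- Exact-match mapping cannot place tags across assembly errors or SNVs.
- One library per condition: the Poisson test captures counting noise only,
  not biological dispersion; calls are "drought-responsive" in the same
  operational sense as in single-pair DGE studies.
- The discovery step reports one candidate per locus and does not model
  read-stack patterns beyond the mature/star pair.
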