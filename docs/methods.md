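# Methods

This note documents the models and procedures implemented in `arlnc`, the
assumptions behind them, the parameters that matter, and what validation
on the synthetic study does and does not demonstrate.

## Coordinate and sequence conventions

All genomic intervals are 0-based half-open internally; GTF files on disk
are 1-based inclusive and the shift happens only in `io_formats`. Strand
is required for every transcript (unstranded records are rejected)
because every classification rule is strand-semantic. T and U are
interchangeable; sequences are canonicalized to RNA inside the duplex
screen and to DNA in the ORF scanner. Transcript length always means
spliced (exonic) length, not genomic span.

## Identification cascade

Candidates are filtered in a fixed order, and a removed transcript is
charged to the first rule that triggered, so the report satisfies
`input = retained + Σ removed` exactly:

1. *Annotated match* — same chromosome and strand with an identical
   intron chain (single-exon: reciprocal exonic overlap ≥ 50%). Matches
   to annotated noncoding models are retained directly as annotated
   lncRNAs; matches to coding models are removed. Annotated lncRNAs skip
   the later filters: they are curated models, and re-filtering them on
   the simulated expression would conflate annotation status with
   abundance.
2. *Class code* — novel transcripts must be `u` (no overlap with any
   annotated gene span), `x` (exonic overlap on the opposite strand,
   ≥ 1 bp) or `i` (entirely within one intron of any isoform, either
   strand). Same-strand exonic overlap, or partial span overlap matching
   none of these, is removed.
3. *Length* — spliced length < 150 nt removed (149 nt fails, 150 passes).
4. *Abundance* — TPM_max < 1, where the maximum is over all
   timepoint × replicate samples (not over timepoint means).
5. *Coding potential* — see below.

### Coding-potential stand-in

Reference coding-potential classifiers depend on external SVM models and
alignment databases; `arlnc` instead uses a self-contained, deterministic
score. A transcript is coding when its longest ATG→stop ORF reaches 100
codons, **or** covers ≥ 50% of the transcript with a positive in-frame
hexamer log-odds. The hexamer tables (log2 coding/noncoding frequency
ratios, +1 pseudocounts) are trained once at import time on a fixed-seed
synthetic fixture: 120 codon-biased coding-like sequences (strong
position-specific nucleotide bias, internal stops rejected) versus 120
uniform sequences. The strong training bias keeps the score of random
ORFs clearly negative: measured on uniform 300-nt sequences, ≤ 1% are
called coding. The residual false-positive rate is real and intended —
on a default synthetic study the cascade occasionally (≈ 1 in 50)
removes a genuine lncRNA whose random sequence happens to contain a
half-covering, well-scoring ORF, just as the original cascade removed a
small number of candidates as coding.

## Genomic-location classification

Priority: *antisense* (≥ 1 bp exonic overlap with a coding gene on the
opposite strand) over *intronic* (full containment in a single intron of
any isoform, either strand, no exon overlap) over *intergenic*.
*Divergent* (head-to-head: the two 5′ ends face each other within the
window without span overlap) and *convergent* (tail-to-tail 3′ ends) are
non-exclusive flags against coding genes on the opposite strand, so
category proportions may sum past 100%. The window default of 1,000 bp is
the conventional promoter-proximal distance and is configurable
(`window_bp`).

## sORF detection and the ribosome release score

The sORF scan enumerates ATG→stop spans in the three forward frames of
the spliced sequence (antisense ORFs are out of scope), reporting one
call per stop at its 5′-most ATG, with peptide length ≥ 10 aa (coding
span ≥ 30 nt, stop excluded). The release score is implemented in the
bounded form

  RRS = d_ORF / (d_ORF + d_down),  RRS ∈ [0, 1],

where d_ORF is the mean footprint depth over [start, stop) and d_down
the mean over a window (default 100 nt, minimum 10 nt) after the stop
codon; 0/0 defines RRS = 0. The bounded form is a deliberate design
choice: the unbounded density-ratio form has no natural 0.9 threshold,
whereas on this scale 0.9 means ORF density nine times the downstream
density, a meaningful operating point for translation termination. RRS
is invariant under uniform scaling of coverage. A lncRNA is a
ribo-lncRNA when mean footprint coverage ≥ 1 read/nt; an sORF call with
RRS ≥ 0.9 marks it sORF-encoding. sRNA precursors require ≥ 20 sRNA
reads with ≥ 50% at 21–22 nt. The ribo and sRNA labels are
non-exclusive; *canonical* means neither.

## Differential expression over the lifespan

Counts are normalized with median-of-ratios size factors computed over
all samples (falling back to total-count ratios, with a warning, when no
transcript is observed everywhere). Each contrast window —
growth→maturation 4→18 d, maturation→senescence 16→30 d (the windows
overlap by design, matching the phenology), and whole-lifespan 4→30 d —
is tested between its endpoint timepoints: group means of normalized
counts with a 0.5 pseudo-count, a per-transcript NB dispersion by method
of moments pooled over the two endpoint groups (floor 1e−8), a
delta-method standard error for log2FC, and a two-sided normal Wald
p-value. BH adjustment is applied within each contrast; the AR set is
the union over contrasts of transcripts with |log2FC| ≥ 1 and
p_adj ≤ 0.05.

Calibration caveat: with two replicates per endpoint the per-transcript
dispersion estimate is extremely noisy and the raw test is
anti-conservative (measured null p ≤ 0.05 rate ≈ 0.18 at n = 2,
declining to ≈ 0.07 by n = 8). Cross-transcript dispersion shrinkage,
which large-scale DE packages use to repair exactly this, is
deliberately out of scope. What the pipeline's AR call actually relies
on is the joint gate — BH adjustment *and* the effect-size threshold —
which controls the realized null false-AR proportion to ≈ 2% at n = 2
(measured over 400,000 null transcripts), while planted 8-fold changes
are recovered at essentially full power. Endpoint contrast (not a
full-course likelihood-ratio test) is a documented design choice.

## Temporal clustering

Profiles are replicate-mean TPM with a 0.5 pseudo-count, log2-ratioed to
the first timepoint, z-scored per transcript, and clustered with k-means
(k = 6, 50 restarts, fixed seed). Cluster names are a pure function of
the centroids computed in the original profile space: direction from the
sign of the terminal value (U vs D), order within a direction from the
first timepoint at which the centroid passes half its terminal value
(earliest change → U1/D1). Constant profiles cannot be standardized and
are reported `unclustered`.

## Neighbor pairs, ceRNA sets, localization

Pair geometry is evaluated on per-gene merged exon units; a gene's
expression profile is the sum of its isoforms' replicate-mean TPM.
"Adjacent" for IPP/ILP means the single nearest non-overlapping neighbor
by gap distance (ties toward the smaller coordinate); DLP's "common
promoter region" is operationalized as TSS–TSS ≤ window on opposite
strands. Random pairs are uniform lncRNA × coding-gene draws (seeded) and
are not purged of qualifying-category pairs. Rank-sum comparisons use
the exact two-tailed Mann–Whitney distribution when both groups have
n ≤ 20 without ties, otherwise the tie-corrected normal approximation
without continuity correction (so self-comparisons give p = 1).

ceRNA candidates are all lncRNA–mRNA pairs sharing ≥ 1 targeting miRNA;
the junction significance is the upper-tail hypergeometric probability
with the universe N = all distinct miRNAs in the merged table
(configurable; union semantics). Retention requires raw p < 0.05 — no
multiple-testing correction across candidate pairs by default, matching
the screening semantics; a BH option exists — and *positive*
co-expression PCC > 0.7. Note that among candidate pairs the apparent
null detection rate exceeds 5% (≈ 12% at default table densities): that
is a selection effect of conditioning on sharing at least one miRNA, not
miscalibration; over all tested pairs the null rate is ≈ 1%.

Nuclear/cytosolic calls compare fraction TPMs directly; the tie goes to
cytosolic (documented arbitrary break), and transcripts absent from both
fractions are excluded.

## Duplex screen and its energy model

The screen finds ungapped antiparallel duplexes: exact Watson–Crick
6-mer seeds located through a k-mer index of the mRNA (G:U does not
seed), extension along the seed's diagonal under an additive per-pair
model — GC −2.2, AU −1.1, GU −0.6 kcal/mol, mismatch +1.0 — and
reporting gates E < −16 kcal/mol with ≥ 15 paired (non-mismatch)
positions, then a final |PCC| ≥ 0.9 co-expression filter. "Interaction
length" counts paired bases, not span length. The constants are
calibrated so the −16 gate sits exactly at a 15-nt A:U-only perfect
duplex (15 × −1.1 = −16.5); bulges and intramolecular accessibility are
out of scope.

`scan_pair` refines all extensions sharing a diagonal to that diagonal's
exact minimum-energy span (a vectorized minimum-subarray sweep — the
limit of x-drop extension with unbounded drop), then merges candidates
overlapping on both molecules keeping the best energy. The per-seed
x-drop walk (stop a direction when the running energy exceeds its best
prefix by 3.0 kcal/mol) is available as `extend_duplex`. Consequently the
reported best energy equals the global ungapped optimum whenever any
Watson–Crick 6-mer lies on the optimal diagonal — in particular for
every planted complementary segment ≥ 15 nt — and the screen is sound
(never reports an unachievable energy); spans on diagonals with no WC
6-mer are invisible to any seeded screen by construction.

Two properties of this simple model deserve emphasis. First, with G:U at
−0.6 the expected energy of a random paired diagonal is only mildly
positive, so at gene-length scales (hundreds × thousands of nt) random
sequence pairs routinely contain spans passing the −16/15 gates; the
screen's specificity in practice comes from the stringent |PCC| ≥ 0.9
filter, and reported call counts (e.g. ~10⁴ on the default synthetic
study) should be read accordingly. Second, because TPM is compositional,
transcripts with flat counts share a systematic downward trend whenever
many transcripts are upregulated late in life, which inflates baseline
correlations (visible in the Random pair category); planted effects are
validated *against* those baselines, not against zero.

## The synthetic study

The generator lays out gene blocks sequentially with 3–6 kb margins so
no positional arrangement arises by accident: multi-exon coding genes
(2–5 exons, alternating strands, a quarter with a second isoform),
coding–coding APP/DPP/CPP baseline pairs, and lncRNAs placed to satisfy
exactly one intended category (antisense inside a host exon, intronic
centered in an enlarged intron, divergent/convergent with 100–800 bp
offsets, intergenic isolated). Every placement is post-validated with
the production classifier and the run aborts if any label would not
recover — placement correctness is enforced, not hoped for.

Expression: counts are NB with mean `baseline × 2^log2FC(archetype, day)
× library size`, lognormal baselines (median ≈ 120 counts), lognormal
library sizes (σ = 0.1), and a shared dispersion of 0.02 — a biological
CV of ≈ 14%, typical of controlled-environment replicate plant time
courses, and the operating point at which planted co-expression
(PCC > 0.7 for ceRNA partners, ≥ 0.9 for duplex partners) is reliably
recoverable from two replicates; at dispersion 0.1 the TPM-space
correlation of same-archetype pairs frequently drops below those gates.
The six archetypes are piecewise-linear log2FC trajectories relative to
day 4 with amplitude 3 (8-fold): U1/D1 complete by day 10, U2/D2 by day
18, U3/D3 ramp from day 16 — so each window's endpoint contrast sees at
least the full amplitude in the matching archetypes, and half-change
times order the clusters unambiguously. 65% of lncRNAs are planted AR;
antisense hosts, ceRNA mRNA partners and duplex mRNA partners inherit
their lncRNA partner's archetype (the co-expression signal), drawn from
still-flat coding genes so signals never collide.

Footprints: translated sORFs (ATG + 24 sense codons + TAA, placed in the
5′ part with ≥ 90 nt downstream) receive Poisson(12)/nt inside the ORF
over Poisson(0.2)/nt background (RRS ≈ 0.98); everything else gets the
background only, below the 1 read/nt ribo gate. sRNA precursors get 200
reads with 80% at 21–22 nt; others get shallow (Poisson mean 9)
length-uniform noise below the depth gate. Target tables plant
4-miRNA junctions (with 2–3 extra private targets each) over uniform
background assignments of 1–5 (lncRNA) or 1–8 (mRNA) miRNAs from a
universe of 100. Duplex pairs carry exact reverse-complementary 20-nt
segments with GC ≥ 0.5 (planted energy ≤ −33 kcal/mol).

What passing on this generator shows — and what it does not: recovery
rates demonstrate the internal consistency of each stage against its own
assumptions (NB counts with shared dispersion, uniform background
sequence, exactly planted geometry). Real data add features the
generator deliberately omits: overdispersion heterogeneity, GC and
length biases, alignment and assembly artifacts, correlated biological
programs that produce high PCC without shared regulation, and structured
(non-uniform) sequence background. Thresholds validated here are
operating points, not guarantees about false-discovery rates on real
tissue.

## Determinism and problem sizes

Every stochastic step draws from a `numpy` Generator seeded from the
study seed (stage offsets +1…+4); iteration orders are sorted; outputs
are written with fixed float formatting — the same seed reproduces every
file byte for byte. Default sizes (110 coding genes, 54 lncRNAs, 14
timepoints × 2 replicates, 100 miRNAs) are chosen so a full run completes
in well under a minute while leaving every stage's statistics
non-trivial; null calibrations in the test suite use 2,000 transcripts ×
200 replicates, the scale at which binomial margins on a 5% rate are
informative.

## Known limitations

- The coding-potential score is trained on a synthetic fixture, not on
  curated coding/noncoding sets; it reproduces the *shape* of the filter,
  not a benchmarked classifier.
- The NB Wald endpoint test without dispersion shrinkage is
  anti-conservative at two replicates (see above); its raw p-values
  should not be interpreted marginally, only through the BH + effect-size
  gate.
- The duplex energy model ignores stacking context, bulges and
  accessibility; its absolute energies are comparable only within the
  model, and background hit rates at transcriptome scale are high before
  the co-expression filter.
- Localization and stress-response inputs are consumed as given tables;
  the pipeline does not model fractionation efficiency or stress-course
  kinetics.
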