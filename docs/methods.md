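# Methods

`sdrscan` reproduces, as code, the manual curation protocol used to
characterize copies of tyrosine-recombinase (DIRS-order) retrotransposons
of the VIPER/TATE type in kinetoplastid genomes.  These elements do not
end in LTRs: their hallmark is a set of **split direct repeats (SDRs)** —
one unit (A1) at the 5′ end of the element and its partner (A2) at the 3′
end, normally interleaved with a second pair (B1/B2).  The canonical 3′
order is `B1, A2, B2`; a variant `B1, B2, A2` occurs, and some copies show
only an A pair.  Internally the elements carry up to three long ORFs: a
poorly conserved gag-like ORF (sometimes bearing a CX₂CX₄HX₄C zinc-knuckle,
the CH-box), a tyrosine recombinase (YR), and a reverse transcriptase /
RNase H ORF (RT/RH) that typically overlaps the YR ORF in a different
reading frame.

## Copy model and classification

A candidate copy is a genomic locus (the element plus flanking sequence,
8 kb by convention).  The pipeline runs four stages in order:

1. **ORF annotation.** Six-frame discovery of maximal ATG→stop ORFs
   (nested ATGs collapsed to the longest per frame/stop, mirroring common
   ORF-finder defaults; non-ATG starts are not considered).  Roles are
   assigned by local-alignment similarity (BLOSUM62, affine gaps, BLAST
   gap convention `open + k·extend`, default 11/1) against a role-labeled
   reference protein panel; gag-like, which has no reliable homology
   signal, is assigned *positionally* — an otherwise-unassigned ORF
   immediately upstream of, or overlapping, the YR ORF and longer than its
   size threshold.  Two same-strand ORFs in shifted frames whose panel
   hits tile adjacent regions of the same reference protein are linked as
   one frameshifted gene.  A single ORF with strong hits in two or more
   role classes is flagged as a single-ORF layout.
2. **SDR detection.** Self-comparison of the locus: on each diagonal of
   the (sequence × sequence) comparison, maximal *anchored* intervals —
   intervals that begin and end with `seed_len` exact matches and whose
   overall mismatch fraction is at most `max_mismatch_frac` — are
   reported as ungapped direct-repeat pairs.  Anchoring makes exact
   k-mer seeding complete (every reportable repeat contains a seed) and
   stops extension from wandering into flanks on chance agreements.
   Pairs whose two units overlap (match longer than its own offset) are
   the signature of a tandem array and drive segmentation of the locus at
   every period multiple; only disjoint pairs are considered for terminal
   labeling.  Terminal windows are measured from the element, not the
   retrieved locus: when role ORFs exist they anchor the windows
   (repeats within `terminal_window_bp` upstream of the first ORF or
   downstream of the last), otherwise the sequence ends are used.  The
   pair reaching nearest the 5′ terminus is labeled A, the remaining pair
   reaching nearest the 3′ terminus is labeled B; ties prefer the pair
   maximizing length × identity.  A pair whose units exceed the terminal
   window in length is element-scale similarity (e.g. between neighboring
   copies in one merged locus), not a terminal repeat, and is never
   labeled.  Element boundaries span the labeled units (confidence
   `sdr`), or the role-ORF span when no repeats are found (confidence
   `orf_only`).
3. **Copy status.**  *putative_autonomous* = three role ORFs above their
   size thresholds (strictly >300 aa gag-like, >250 aa YR, >600 aa RT/RH)
   **plus** labeled direct repeats; *potentially_encoding* = the three
   ORFs without repeats; *sire_like_remnant* = matches only the terminal
   A2+B2 region of a full-length template with no internal coding region;
   *inconclusive* = a long N-run (≥ `n_run_min_len`, default 50 bp)
   overlaps the annotated features, or the copy/locus abuts a contig end
   (window `contig_end_window_bp`, default 500 bp) — including the case
   where the retrieved locus itself was clipped by the contig, since part
   of the evidence may then lie off-contig (a deliberately conservative
   rule: a copy whose flank was clipped is never called degenerate, as
   the missing flank could conceal the difference between a decayed copy
   and a broken complete one); otherwise *degenerate*.
   Positive evidence wins: a fully supported copy near a contig end is
   still autonomous.  An ORF interrupted by a long N-run, frameshift-linked,
   or lacking a terminal stop never counts toward the encoding columns.
4. **Divergence.**  Pairwise global alignments (nucleotide 2/−3 with
   gap 7+2k; protein BLOSUM62 with gap 12+1k); percent identity is
   computed only over confidently aligned columns — columns inside any
   5-column window whose gap-column fraction exceeds 50% are masked, and
   the post-mask length is reported with every identity so summaries read
   "(n, alignment length)".  Distances are observed difference proportions,
   optionally Poisson-corrected (d = −ln(1−p), the multiple-hit
   correction).  Trees are Saitou–Nei neighbor joining with the standard
   Q-criterion, ties broken by input label order, negative branch-length
   estimates clamped to zero and counted; with two clusters left the final
   edge is split at its midpoint, giving a conventional rooted rendering
   of the unrooted tree.  The redundancy filter collapses every maximal
   monophyletic clade whose leaves share one species and whose maximum
   pairwise distance is strictly below the threshold (default 0.35,
   applied to p-distances; a switch selects corrected distances) to its
   longest sequence, and iterates collapse + tree rebuild to a fixed
   point so the operation is idempotent.  A CD-HIT-style greedy
   length-ranked pre-deduplication at a configurable identity threshold
   (default 0.95) can thin a set before tree building.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `flank_bp` | 8000 | flank retrieved around each candidate locus |
| `min_aa` | 300/250/600 | role size thresholds (strict >), gag/YR/RT-RH |
| `orf_scan_min_aa` | 100 | discovery floor for six-frame ORF scan |
| `panel_score_floor` | 60 | minimum local-alignment score for a role hit |
| `seed_len` | 12 | exact-match anchor/seed length (bp) |
| `min_repeat_len` | 50 | shortest reportable repeat unit (bp) |
| `max_mismatch_frac` | 0.1 | mismatch budget over a repeat pair |
| `terminal_window_bp` | 1000 | window in which repeats count as terminal |
| `gap_warn_bp` | 1000 | ORF↔repeat distance that triggers a flag |
| `tandem_min_len` | 1000 | minimum period/match for tandem segmentation |
| `contig_end_window_bp` | 500 | contig-end proximity window |
| `n_run_min_len` | 50 | N-run length treated as missing data |
| `redundancy_threshold` | 0.35 | same-species collapse threshold |

SDR defaults were chosen to cover the 57–414 bp, 81–100 % identity range
reported for these elements while rejecting chance matches (a random
12-mer agreement has probability 4⁻¹²); the panel score floor of 60 was
calibrated so unrelated random ~300-aa proteins essentially never reach
it (BLOSUM62 local scores for random pairs of that size run far below),
while true homologs — even fragments — score in the hundreds.

## The synthetic generator

`simulate` builds elements to specification: three stop-free ORFs of the
requested lengths (default 492/338/948 aa, matching a well-conserved
reference copy set), a YR↔RT/RH overlap of 100 bp realized with both
frames stop-free through the overlap, an optional CH-box embedded in the
gag-like protein, and repeat units of the requested architecture, lengths
(default A=173 bp, B=219 bp) and pair identities (default 100 %/100 %).
Codon content is uniform over synonymous codons; background is i.i.d.
nucleotide sequence at configurable GC.  Each element emits its own
translated ORFs as the role-labeled reference panel.  Degradation applies
substitutions, indels, targeted frameshift insertions, N-runs and
truncations, and recomputes the expected status by applying the
classifier's rules to the planted features — including emulating the ORF
caller (longest ATG→stop fragment over the planted interval in the
planted frame).  `plant_genome` inserts elements (optionally as
head-to-tail tandem arrays, in a GGGTTA telomeric hexamer context, or cut
by contig breaks, which makes the affected copies inconclusive) and
returns a truth manifest; `extract_loci` reproduces the hit-plus-flank
retrieval convention, recording contig coordinates in FASTA headers.

Two harness conventions make exact recovery a fair test rather than a
coin flip: planted repeat-pair mismatches avoid the first/last `seed_len`
bases of each unit (so anchored seeding cannot trivially fail), and the
bases immediately flanking each planted unit (and each planted element
edge) are forced to mismatch their partner positions — otherwise chance
single-base agreements legitimately extend an ungapped repeat past the
true boundary about half the time.

What the generator does *not* emulate: real kinetoplastid base
composition and codon usage, low-complexity/satellite background,
nested/chimeric insertions, or gapped repeat divergence (indels between
repeat partners).  Passing the planted-truth suites therefore shows the
pipeline implements its own rules exactly on structurally realistic
material, not that it is robust to every artifact of real assemblies.

## Numerical and procedural choices

- Internal coordinates are 0-based half-open; GFF3 output is 1-based
  inclusive; conversion is bijective and tested via re-parsing with
  gffutils.
- Co-optimal alignments are resolved by the alignment engine's
  deterministic enumeration order; scores are unique, so identities can
  differ only marginally in column layout.
- `smith_waterman` returns score 0 with empty spans when no positive-
  scoring local alignment exists.
- Repeat-pair ties during A/B labeling use length × identity, then
  position; all orderings in the pipeline are explicit, making runs a
  pure function of (inputs, config).
- Degenerate inputs: empty loci files yield an all-zero summary; copies
  without panel support fall back to positional gag and threshold-only
  "encoding" counts (panel support is tallied in a separate column);
  an undefined identity (nothing confidently aligned) is reported as
  `na`, never as 0 %.
- Pipeline truth emulation does not model frameshift-pair linking; a
  frameshift so close to an ORF's 3′ end that the long fragment still
  clears the role threshold is reported as encoding by both the
  classifier and the truth only when linking fails, so status agreement
  on such borderline plants is not guaranteed to be exact (the planted
  scenarios in the test suites use mid-ORF frameshifts, where both
  routes agree).

## Problem sizes used in the shipped checks

The property suites run on: all two-letter strings up to 12 bp plus
2,000 random four-letter strings up to 30 bp (repeat-detector oracle
equivalence), 1,000 random 200-mers with planted 60–65 bp repeats,
exhaustive path-enumeration alignment oracles on ≤10-mers, 100 intact
and 100 degraded planted genomes (~22 kb each, 2 kb flanks), NJ additive
recovery for 4–8 leaves (all three 4-taxon topologies; 25 random trees
per larger size), and a 13-copy family at 5 % planted mean pairwise
divergence for the identity summary.  These sizes exercise every rule at
full fidelity while keeping the whole suite around a minute.
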