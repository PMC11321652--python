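# Methods

`abescan` models the computational arc of a library-assisted adenine base
editor (ABE) engineering campaign: enumerate a deaminase variant library,
screen it with a fluorescence-coupled reporter, and quantify the editing
behaviour of candidate editors at therapeutic loci from amplicon sequencing.
This note records the models, parameter choices and numerical conventions,
and what the synthetic data do and do not establish.

## Coordinate model

All positions are 1-based protospacer coordinates on the protospacer
strand: the 20-nt protospacer spans +1..+20 (5'→3'), the PAM occupies
+21..+23, and bases 5' of the protospacer are negative with −1 adjacent to
+1 (no position 0). `ProtospacerSpec` owns the strand convention: for a
reverse-orientation amplicon the reference is reverse-complemented exactly
once, and every edit call is reported on the protospacer strand (an
apparent T>C on the sequenced strand is an A>G edit). This matches how
per-position A>G frequencies are conventionally reported regardless of
which strand was sequenced.

## Library enumeration

Three deterministic sub-library rules over the deaminase active-site region
(residues 106–157):

- **Range scan** — every single substitution to each of the 20 canonical
  amino acids at each position. Identity pairs (amino acid equals the
  parent residue) collapse to a single wild-type entry, so an L-position
  scan yields 19·L + 1 distinct variants (989 for L = 52). The wild type is
  always retained: it anchors enrichment normalisation.
- **Site saturation** — the full 20^k Cartesian product over chosen
  positions (111, 119, 149 by default). A position assigned its parent
  residue contributes no substitution, so the 20^k tuples map one-to-one
  onto distinct substitution sets (8,000 for k = 3).
- **Charge swap** — at selected residues, one variant per other member of
  the residue's charge/polarity class. Default partition: positive {K,R,H},
  negative {D,E}, polar-uncharged {S,T,N,Q,C,Y}, nonpolar
  {A,V,L,I,P,F,M,W,G}. "Same charge" is only unambiguous for charged
  residues; the polar/nonpolar split is a documented, configurable choice.

The counts are verified against brute-force enumeration oracles rather than
the closed forms.

**Ancestral back-mutation**: for each single-substitution screen hit, the
two nearest residues where the modern deaminase differs from its ancestor
(scanning outward, within a flank of 10 residues, ties toward the lower
index) are reverted singly and jointly, giving up to three variants per
seed; duplicates across seeds are emitted once. Three seeds with two
differing neighbours each yield nine variants.

The shipped `tada8e_synthetic.fasta` / `tada710_synthetic.fasta` are
**synthetic stand-in sequences**, not the published deaminases: a common
167-residue scaffold carrying the residue identities the rules reference
(F84, V106, S109, R111, N119, N122, D147, Y149, P152 in the modern
sequence) and differing at exactly six positions within 106–157. All
enumeration arithmetic depends only on these identities.

**Oligos** are the parent CDS with substituted codons chosen by rank from a
human codon-usage policy; if a codon completes the BsmBI/Esp3I recognition
site (CGTCTC, either strand) in context, the next-ranked codon is used, and
variants whose every codon fails are returned as explicit rejection
records. Translating every emitted oligo reproduces its variant's protein
(tested as a round-trip property).

## Reporter and sort-seq screen

The reporter is a defective EGFP with a 27-nt insert between the start
codon and the EGFP ORF. The insert carries an in-frame TGA whose editable
adenine sits at protospacer +7; the A>G edit converts TGA→TGG (Trp),
removing the stop. `egfp_state` is *on* iff the edited insert, read in
frame from the ATG, contains no stop codon and keeps EGFP in frame; it is
verified against a codon-by-codon translate-and-scan oracle over all 81
single-base substitutions of the insert.

Enrichment of a variant v between input and sorted pools:

    score(v) = log2[(s_v + c) / (S + c·n)] − log2[(i_v + c) / (I + c·n)]

with pseudocount c = 0.5 (config-exposed), pool totals S, I and variant
universe size n. The screen's readout specifies sorting and sequencing but
no statistic, so this minimal log-ratio of pseudocounted relative
frequencies is the package's choice; ranks descend by score with ties
broken by higher sorted count, then variant id. `rank_aggregate` unions
per-replicate top-k hits (k = 10 by default) and reports per-variant
support; union aggregation is the only rule consistent with triplicate
top-ten lists producing more than ten candidates. A frequency-only ranking
mode (`rank_by="frequency"`) is provided because the original analysis may
have ranked by sorted-pool abundance alone.

## Amplicon quantification

The quantifier is deliberately ungapped. Amplicon reads sit at a fixed (or
nearly fixed) offset on their reference, so each read is anchored at the
offset minimising Hamming distance within ±5 of the nominal start; reads
whose length differs from the expected span are discarded as
indel-bearing (base editors produce few indels and only substitutions are
quantified — the discard counters preserve auditability). Substitutions
inside the quantification window (default −3..+12, wide enough for the −1
and +12 bystanders seen at therapeutic loci) become edit calls; each
passing read contributes exactly one *combo* (its set of in-window calls),
making the allele table an exact joint distribution over edit combinations.
Substitutions outside the window count against a mismatch budget (default
5) and are never called as edits; reads over budget are discarded as
off-amplicon. Read conservation (passing + discarded = input) holds by
construction and is asserted in tests. Base qualities are parsed but unused
by default; the depositing study gives no evidence of quality filtering, so
it is off and config-exposed.

Per-position frequencies divide by **all passing reads** (not edited
reads), consistent with how editing efficiency is reported with unedited
reads diluting the percentage; integer hit counts are accumulated and
divided once, so frequencies equal the brute-force marginalisation oracle
exactly. Positions whose reference base is not the queried from-base are
flagged not-applicable rather than reported as 0.

The **editing window** at threshold fraction t is the maximal contiguous
run of applicable positions with frequency ≥ t × peak, containing the
5'-most peak. This is the standard fraction-of-peak definition; raising t
never widens the window (property-tested). Default t = 0.3.

## Outcome classification

A locus is described by its editable adenine positions, a designated
therapeutic target among them and per-position codon consequences
(standard genetic code via Biopython; *corrective* is assigned only to the
designated target, *noncoding* is available for intronic positions).
Reads partition exactly into:

- **precise** — edited at the target position and nowhere else,
- **bystander_missense** — any combination containing a missense or
  nonsense position,
- **other_edited** — edited combinations whose bystanders are all benign
  (synonymous/noncoding), kept as an explicit fourth category because the
  three-way chart is not exhaustive for loci with synonymous bystanders,
- **wild_type** — unedited.

The four fractions sum to 1 exactly. A `three_way()` view folds
other_edited into the missense slice to recover the three-category chart.
`classify_outcomes` refuses combos touching positions absent from the locus
description; `project_allele_table` is the explicit preparatory step that
projects noisy tables onto the locus's editable A>G positions (the CLI
applies it by default). Purity ratios are focal/(focal+competing) between
two combination fractions — e.g. single-target vs dual
target-plus-bystander — and are undefined (None) when both are zero.

Shipped locus fixtures are synthetic amplicons honouring published
protospacer layouts, not genomic sequence: `hfe_c282y` (editable +1/+5/+8,
target +5, codons ACG→GCG / TAC→TGC / CAG→CGG), `hbb_s` (target +7,
synonymous bystanders +9/+12 at codon third positions), `pcsk9_intron1`
(target +6, noncoding bystander −1), `stop_egfp_reporter`, and a generic
`aavs1_like` purity site (adenines +4/+6/+7).

## Off-target comparison

A site is summarised by its maximum per-position A>G frequency (one number
per site, matching per-site bar charts; a specific position can be selected
instead). Untreated-control background is subtracted by default
(net = max(freq − control, 0)) and recorded in output metadata. The
specificity ratio net_on/(net_on + Σ net_OT) is 1 when no off-target
editing is detected, undefined when nothing is edited, and monotone
decreasing in every off-target frequency.

## Synthetic data

`simulate_amplicon_reads` draws each read's combo from an explicit joint
distribution (edits co-occur on molecules, so the generator is
parameterised by whole-allele probabilities), applies the substitutions to
the reference, then i.i.d. uniform substitution errors (default 0.001 per
base, within plausible Illumina amplicon range; the depositing study
reports no error figures) and a constant Q40 quality. An optional
`indel_rate` truncates/extends reads by one base solely to exercise the
indel discard path. `simulate_screen_pools` assigns cells to variants
multinomially, draws fluorescence = activity + Gaussian noise (default sd
0.1) and sorts the top `gate_fraction` (default 0.05, the screen's 5%
gate). Both generators are deterministic given their seed (byte-identical
outputs, tested).

What the simulations do **not** model: PCR/duplicate bias, position- or
context-dependent error, paired-end structure, quality-score variation,
lentiviral copy number, or any window structure inside the screen
simulator (fluorescence is a scalar readout; window behaviour is exercised
through read simulation). Passing round-trip and recovery tests therefore
establishes internal correctness of the estimators under these generative
assumptions — not performance on real sequencing artefacts.

## Problem sizes and statistical checks

Default test/verification sizes, chosen to give tight multinomial error
while keeping runs quick: read simulations n = 20,000; generator→quantifier
round trip checked at a fixed seed within 3σ multinomial on the generating
combos, and across 50 seeds by χ² goodness of fit at α = 0.001 on counts
projected onto the generating positions and conditioned on the generating
support (with sequencing error a ~1.5% minority of reads carries an error
call elsewhere in the window; the error-free exact-recovery property is
tested separately). Because 50 independent tests at α = 0.001 have a ~5%
family-wise false-alarm rate, the repeated check allows at most one
rejection (under a correct generator P(≥2) ≈ 1e-3). The screen-recovery
check uses 1,000 variants with 10 planted at activity 0.9 vs 0.05
background, 10^6 cells, 5% gate, noise 0.1 — conditions under which all
planted variants must appear in every replicate's enrichment top 20 and in
the aggregated top-10 union.

## Known limitations

- Ungapped anchoring cannot place reads with true indels; they are counted
  and discarded, not resolved.
- The enrichment statistic is a design choice, not inferred from data; with
  very low input counts the pseudocount dominates.
- Consequence annotation requires caller-supplied codon context (no
  reading-frame inference from genome annotation); fixtures know their
  frame by construction.
- The commercial library's printed total (23,393 sequences) is not
  recomposable from the stated rules; the package reports its own counts
  and never asserts that total.
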