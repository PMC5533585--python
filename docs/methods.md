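# Methods

## PSM filtering and protein inference

A peptide-spectrum match is retained when every criterion holds, all
boundaries inclusive: peptide length ≥ 7 aa; fully tryptic; DeltCn ≥ 0.08;
XCorr ≥ 1.8 (charge 1), 2.5 (charge 2), 3.5 (charge ≥ 3 — the published
thresholds name only triply-charged spectra, so higher charges share that
floor); Sp rank ≤ 10. *Fully tryptic* means the residue preceding the
peptide is K/R (or the peptide sits at the protein N-terminus, flank `-`)
and the peptide ends in K/R (or sits at the protein C-terminus). No
proline-suppression rule is applied by default since the filter it mirrors
states none; a flag enables it. Rows with a missing score or charge < 1
are rejected with a logged reason rather than raising — malformed rows in
large search outputs are routine.

Protein inference keeps proteins with ≥ 2 distinct retained peptides or
one peptide with ≥ 2 spectra, then removes proteins whose retained-peptide
set is a strict subset of another's. Proteins with *equal* peptide sets
are indistinguishable on the evidence; all are kept and annotated with a
canonical joint identifier (sorted, semicolon-joined) rather than
arbitrarily dropping one. Decoy entries flow through filtering and
inference exactly like targets so that the FDR statistics
(spectral = 2·shuffled/total·100, protein = shuffled/total·100) are
meaningful on the output. Runs are pooled within one replicate before the
two-peptide rule, never across replicates.

## dNSAF

Shared-peptide spectra are distributed proportionally to unique spectral
counts; when every parent has zero unique counts the proportional rule is
0/0 and the spectra are split equally — the symmetric choice that keeps
column totals exactly conserved (Σ dSpC = Σ shared spectra). Distributed
counts are kept at full floating precision; nothing is rounded before
normalization. dSAF_k = (uSpC_k + dSpC_k)/L_k is normalized over detected
**target** proteins only: decoys are excluded from the denominator because
every downstream use (bait-vs-control ratios) is target-only, and a
decoy-dependent denominator would couple the two channels' decoy
contamination into the enrichment estimates. `include_decoys=True`
restores the alternative. Whether the normalization should span
targets+decoys is genuinely underdetermined by the published description;
this choice is flagged here deliberately.

`dnsaf_from_count_table` is an algebraically identical vectorized path for
experiments without shared-peptide structure (the tests assert equality
with the general path); large simulation studies use it.

## Enrichment and hit calling

Averages use only replicates with non-zero dNSAF (all-zero → 0); the
t-test, by contrast, uses **all** replicate values including zeros — the
two rules are stated separately in the procedure this implements and are
kept separate here. The t-test is the equal-variance (Student) form, on
raw rather than log dNSAF; both are configurable (`equal_var`, and the
caller can transform inputs). Degenerate inputs: two constant equal groups
give p = 1; constant different groups give the smallest representable
positive double (the statistic diverges), so downstream strict `p < 0.05`
comparisons behave sensibly.

Fold enrichment avg_bait/avg_control uses sentinels: control 0 with bait
positive → +∞ (passes any fold threshold — the protein was simply never
seen in the control); 0/0 → NaN (never a hit). The hit rule is strict on
all three thresholds (fold > 3, p < 0.05, average raw bait spectral count
> 2), with decoys excluded. The average spectral count uses raw
(undistributed) bait counts over all replicates; configurable since the
published rule does not specify the variant. The two-tier proximity map is
the one place the fold boundary is inclusive (high: fold ≥ 3; mid:
2 ≤ fold < 3; both at p < 0.05), mirroring the published tier legend as
opposed to the hit rule's strict > 3.

Volcano export writes (log₂ fold, −log₁₀ p, hit flag); +∞ fold rows are
plotted at one unit above the largest finite log₂ fold and flagged
`capped` — hit logic upstream already consumed the exact sentinel.

## Dataset comparison

Contrasting labels each protein with the exact subset of datasets
containing it; the cells partition the union exactly. CT-specific sets
subtract the union of *all* NT datasets from each activator's CT set. The
pairwise-overlap table counts proteins shared by **exactly** two datasets
(exclusive mode, the published table's stated convention — overlap
involving a third activator "is not shown"); an inclusive mode is provided
for exploration. Percentages divide by the *column* dataset's input n —
verified arithmetically against four independent printed cells
(44/87 → 50.6, 44/92 → 47.8, 27/74 → 36.5, 14/37 → 37.8) — and round
half-up to one decimal, which matches every printed cell where banker's
rounding would not. Network export writes a bipartite dataset/protein
graph (SIF + GraphML) with family, terminus, cross-family and 3-family
annotations; filtering to proteins with recognized gene names is left to
an optional caller-supplied id filter.

## Candidate screen and alignment

The screen's ratio criterion takes the maximum bait/control dNSAF ratio
over the pooled datasets (whether the published screen used per-dataset or
pooled-maximum ratios is unstated; maximum is the inclusive reading), and
presence requires non-zero dNSAF in ≥ 3 of 4 replicates of at least one
single dataset — replicates are never pooled across datasets. Coiled-coil
eligibility needs one annotated interval ≥ 100 aa (inclusive); proteins
without annotation count as length 0. Exclusion lists (nuclear proteins,
dynein/dynactin subunits, entirely-coiled-coil proteins) are plain-text
inputs.

Global alignment wraps a Needleman–Wunsch aligner with affine gaps under
BLOSUM62, gap open 10, extend 0.5 — the cited alignment tool's documented
defaults — with end gaps unpenalized. The gap convention is open for the
first gapped position and extend for each subsequent one. Identity counts
identical columns and similarity positive-scoring columns, both against
the full alignment length including gap columns. Scores are unique;
identity/similarity of co-optimal alignments can differ, and the first
enumerated alignment is used. The test suite checks scores against an
independently written Gotoh dynamic program (itself validated by
exhaustive alignment enumeration on tiny sequences, including the
degenerate open = extend case).

## Motility

Classification is a two-threshold excursion test computed from running
extrema in one pass: *diffusive* requires excursions > 600 nm in both
directions (a rise above the running minimum and a drop below the running
maximum); *processive* requires |net displacement| > 600 nm with the
opposing excursion ≤ 600 nm. The published processive definition states no
displacement floor; 600 nm is adopted — symmetric with the reversal
threshold — so the three classes partition all events; it is a parameter
(`reversal_nm`). Classification is invariant to position offsets and sign
flips.

Segmentation at behavior changes is deliberately simple and deterministic:
local speed per frame is the magnitude of the least-squares slope over a
centered 5-frame window; frames are labeled motile above 50 nm/s (≈ 4
standard errors of a noise-only slope at 20 nm localization noise and
0.5 s frames); labels pass a 3-point majority filter iterated to a fixed
point; and runs shorter than 20 frames (10 s) are absorbed into their
longer neighbor, because a genuine behavior change must persist — without
the persistence rule a diffusive stretch, whose local speed flickers
across any threshold, shatters into fragments. Every construction here is
symmetric under time reversal, so boundaries of a reversed track mirror
exactly (runs partition the frames; the cut falls between frames). An
earlier design using directional hysteresis was rejected for breaking that
symmetry.

Velocities are least-squares slopes of position against time (an
endpoint-displacement mode is provided), computed only for processive
events spanning strictly more than five frame intervals; diffusive and
non-motile events never enter velocity statistics. Summaries report the
mean ± SD of velocity *magnitudes* — direction belongs to the individual
event, and pooling signed velocities from a direction-symmetric experiment
would average to zero.

## Synthetic data

The count generator emulates quadruplicate bait-vs-control streptavidin
purifications: per protein and replicate, unique spectral counts are
Poisson with a common baseline rate (default 10 expected spectra), and
planted proximal proteins multiply the baseline in the bait channel only.
Replicate-to-replicate dispersion of real spectral counts is not
documented for the design this emulates; Poisson is the minimal stand-in
and real data are over-dispersed, so passing recovery tests here bounds
statistical, not biochemical, performance. Shared peptides pair proteins
deterministically (two parents each, keeping worked examples tractable) at
a rate equal to the mean of the parents' rates; decoys are id-prefixed
(`shuffled_`) and drawn like targets. Protein lengths are uniform on the
configured interval — lengths matter only through dNSAF normalization.

The PSM generator produces rows with known retain/reject truth: retained
rows satisfy every criterion (a quarter exactly at the inclusive
boundaries), rejected rows violate exactly one criterion each, cycling
through all five reasons. The track generator draws per-track classes from
the mixture; processive tracks drift at N(800, 100) nm/s with random sign,
diffusive tracks are Gaussian random walks (300 nm per-frame step SD), and
non-motile tracks are pure 20 nm localization noise, all sampled at 0.5 s.
These defaults are well-separated on the 600 nm scale: a processive track
covers micrometres while noise stays within tens of nm. Real kymograph
tracks have pauses, photobleaching gaps, and mixed behaviors within one
trajectory; the generators emulate none of that, so classifier recovery
numbers characterize the decision rules, not tracking robustness.

## Problem sizes

The test suite and acceptance script use: 1000 randomized 20-protein /
50-peptide instances for the dNSAF oracle; 100 seeds of 2000-protein
4-vs-4 experiments (40 planted at multipliers 8 and 16) for hit-caller
recovery, and the same for the null calibration; exhaustive alignment
pairs over a two-letter alphabet up to length 6 plus 300 sampled pairs up
to length 12; and 500–1000 simulated tracks for motility recovery. These
sizes make the Monte-Carlo standard errors small against every margin
tested while keeping a full run in the low minutes on one core.
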