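# Methods

This note documents the analysis model, the numerical conventions, the
synthetic-data generator, and the design decisions taken where the procedure
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All genomic coordinates are 0-based half-open (`[start, end)`), the BED
convention, applied at read time to every input; chromosome names pass
through a configurable alias map and are compared string-exactly afterwards.
Features are strandless. Blacklist handling is whole-record removal: any
overlap ≥ 1 bp with a blacklisted region (centromere/telomere) drops the
record — conservative, and the only reading under which "bins overlapping
centromeres were removed" is unambiguous. Interchromosomal loop and domain
records are dropped in the readers, with counts logged so that
records-in = records-out + dropped holds for every reader.

## Compartments

Per sample, the raw 1 Mb eigenvector is z-scored genome-wide over retained
bins (sample SD, `ddof=1`). Orientation follows: per chromosome, if the
Pearson correlation between the sample's values and the gene-density track
is negative, the chromosome's signs are flipped; bins with oriented value
> 0 are A, < 0 are B, exactly 0 unassigned. Z-scoring before orientation is
an ordering choice — the two operations commute for labeling purposes except
through the genome-wide mean shift, which is small for approximately
centered PC1 tracks; the order is fixed and documented here. An exactly zero
or undefined correlation is an error rather than a silent guess, because the
orientation would be arbitrary.

Replicate labels are merged by **majority vote**; bins without a strict
majority are unassigned and excluded from switch classification (logged).
Majority vote is the least-assumption merge rule and is exactly testable.
Switch classes are a pure function of the (sham, condition) label pair.
Transcripts map to the bin containing their locus midpoint — at 1 Mb
resolution this avoids double counting without measurable loss.

## TADs

Within a condition, a TAD is reproducible iff every replicate contains a
domain with both boundaries within ±20 kb (the consensus tolerance).
Matching within each replicate is greedy by smallest total boundary
displacement, each replicate domain usable once; the consensus interval
takes the **first replicate's coordinates** (a fixed reference replicate is
deterministic; the tolerance guarantees any choice differs by ≤ 20 kb per
end) and the mean of matched replicate boundary scores.

Condition-versus-sham comparison builds all pairs with min(reciprocal
overlap) ≥ 0.8 and matches one-to-one, greedily by descending min-RO with
genomic-position tie-breaks (leftmost sham domain first). One-to-one
cardinality prevents a single sham domain from absorbing several condition
domains, which would corrupt gained/lost counts. Matched pairs are stable
when both displacements are ≤ 10 kb, else shifted; unmatched condition
domains are gained, unmatched sham domains lost.

Fusion/fission runs afterwards at ±40 kb and only on gained/lost domains,
so replicate jitter is never promoted to architectural reorganization. The
covering predicate is: partner overlaps the ±40 kb-extended interval by
≥ 1 bp **and** its midpoint lies inside the extension — midpoint containment
excludes grazing neighbors, which a pure-overlap rule at ±40 kb would count.
A gained domain covering ≥ 2 sham domains is merged; a lost sham domain
covering ≥ 2 condition domains is split, and those condition domains (the
fission products, themselves gained) carry a separate `derived_from_split`
flag rather than a category2 label, keeping "split" attached to the parent
while still making split-derived gains countable.

Length strata cut at 100 kb and 400 kb with the intermediate class closed on
the left (`100 kb ≤ length < 400 kb`); the source ranges are open-ended, so
the edge assignment is a documented choice. Boundary strength is strong iff
the z-score is strictly above 1.

## Loops

Loop identity is the exact anchor-coordinate 5-tuple after canonical
ordering (`anchor1.start ≤ anchor2.start`); no fuzzy cross-condition anchor
matching is attempted, by design. A replicate call passes when some context
(BL, Donut, H, V) has adjusted p < 0.05 with observed count ≥ 3; a loop is
reproducible when present and passing in **every** replicate. The consensus
loop carries the first replicate's per-context statistics, from which
strength is classified (strong / weak / intermediate per the thresholds in
the README table; intermediate is everything satisfying neither definition).
Length is short/long at 200 kb on the anchor-start span.

Differential status over the union of reproducible keys, strict mode:
gained_6h (present 6 h, absent sham), gained_24h (present 24 h, absent sham
and 6 h), lost (sham-only, absent at both timepoints), stable (in sham and
≥ 1 timepoint). A key absent in sham but present at both timepoints is
labeled by first appearance (gained_6h); per-timepoint presence flags
(`lost_6h`, `lost_24h`, `in_*`) are carried on every record so the
alternative per-timepoint reading of "lost" remains computable without
re-running. TAD context uses anchor **midpoints** (inside / outside /
one_anchor / inter_tad, with a mapping onto the three-way
inside/outside/cross-boundary view); midpoints give each 10 kb anchor a
single deterministic membership even when it straddles a domain edge.

## Statistics

*Fisher exact test.* The two-sided p-value is computed by exact integer
hypergeometric enumeration: tables with the observed margins whose
probability numerator does not exceed the observed one are summed as Python
integers and divided once. Ties at the observed probability are therefore
resolved exactly rather than to a floating-point tolerance. The odds ratio
is the sample cross-product `ad/bc`, with the Haldane–Anscombe +0.5 applied
to all four cells iff any cell is zero; the 95% CI is Woolf's log-normal
interval on the (corrected) cells. Woolf was chosen over a conditional-MLE
interval because it is closed-form, testable, and matches the symmetric-on-
log-scale form of reported intervals.

*BH-FDR.* Step-up adjustment delegates to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")` behind a
validating wrapper; one family = one timepoint × one architecture layer.

*Wilcoxon rank-sum.* Delegates to `scipy.stats.mannwhitneyu`, exact
enumeration when the combined sample is ≤ 12 with no ties, otherwise the
normal approximation with tie and continuity corrections.

*Enrichment universe.* 2×2 tables are built over all transcripts located in
the layer under test (`all_located`, default) or all expressed transcripts
(`all_expressed`), a config switch; transcripts with several loop
memberships count once per stratum. For flow tables a transcript's single
loop status takes gained over lost when both memberships exist — an
arbitrary but deterministic precedence, logged and documented.

## Synthetic-data generator

The generator emulates the emulated study's design — three conditions (sham,
6 h, 24 h reperfusion) × three replicates, 1 Mb compartment bins, 10 kb
TAD/loop resolution — on a 2-chromosome × 20 Mb genome with the first 1 Mb
bin of each chromosome blacklisted as a stand-in centromere. Scene sizes
(~48–54 TADs and 265–300 loops per condition, ~3,000 transcripts) are chosen
so the full pipeline runs in seconds while every planted event class is
populated.

*Compartments.* Switch-class fractions default to the published proportions
(6 h: A→B 29%, B→A 29%, StableA 21%, StableB 21%; 24 h: 25/26/26/23),
apportioned to integer bin counts per chromosome by largest remainder with
consistent sham marginals. The 24 h switch set is nested within the 6 h set
(or vice versa when larger), emulating partial normalization; ever-switching
bins get weak eigenvalue magnitudes (0.10–0.30) and never-switching bins
strong ones (0.9–1.6), which is biologically sensible (switching bins sit
near the A/B interface) and keeps the per-chromosome gene-density
correlation sign-determinate for every sample even at 58% switching. Each
sample's track is rebalanced to exactly zero mean per chromosome by scaling
A-mass against B-mass — a sign-preserving normalization mimicking the
approximately centered character of real PC1 — so genome-wide z-scoring
cannot move any bin across zero and label recovery is exact by construction,
not by luck. A random per-chromosome sign flip per sample exercises the
orientation step.

*TADs.* Each chromosome is tiled with non-overlapping event slots separated
by ≥ 60 kb (beyond the ±40 kb fusion tolerance): pair slots (two sham
domains that either stay stable or fuse into one merged gained domain),
single slots (stable / shifted by 30–50 kb at one end / lost / split into
two gained children around a 40 kb gap), empty slots (de-novo gained domains
of 100–390 kb, the intermediate lengths reported for gains), and decoy slots
holding domains displaced by 25 kb in replicate 2 — beyond tolerance, hence
planted as non-reproducible. Replicates 2–3 jitter boundaries by
N(0, 2 kb) truncated at ±5 kb; replicate 1 carries planted coordinates,
matching the pipeline's reference-replicate convention so recovery can be
exact. Boundary scores are drawn ≥ 0.15 away from the strong/weak threshold
so score noise (SD 0.03) cannot flip the class.

*Loops.* A universe of ~410 unique keys is drawn on a pool of globally
unique 10 kb anchor bins (anchors never overlap, so every transcript has
exactly one loop membership) with presence patterns over
(sham, 6 h, 24 h) fixed by config counts. Per-context statistics are
generated constructively to guarantee the intended pass/strength label — the
artifact tests classification logic, not Hi-C physics — and adjusted p
values are drawn directly rather than simulated from an FDR procedure.
Decoy loops exercise the reproducibility filter: "partial" decoys are absent
from one replicate, "failing" decoys have observed = 2 in all contexts of
one replicate. Routing loops are placed with their first anchor inside
planted gained/lost TADs of each timepoint so that every loop→TAD flow path
is populated.

*Transcripts.* Three sub-populations: (1) routed transcripts distributed
over loop→TAD paths by a multinomial with weights 46/33/14/11
(gained→gained, lost→gained, gained→lost, lost→lost), placed inside routing
anchors; (2) an enrichment population with a planted odds ratio (default 2)
for the class "upregulated noncoding" being in a lost loop, realized by
Bernoulli draws whose stratum odds are OR × base odds, placed on lost-loop
versus stable-loop anchors; (3) unstructured non-significant background off
every anchor. The manifest records each transcript's realized loop/TAD/
compartment path, so flow tables and the enrichment 2×2 are checkable
exactly against the pipeline's output.

*What the generator does not emulate:* contact matrices and their
normalization, distance-dependent signal decay, overlapping or nested TADs,
anchor sharing between loops, assembly gaps, and expression-level noise
structure beyond the planted classes. Passing tests therefore demonstrate
the correctness of the classification, matching and integration logic under
the stated conventions — not robustness to upstream caller artifacts.

Determinism: everything derives from one `numpy.random.default_rng(seed)`
consumed in a fixed order, and all writers format floats explicitly, so the
same (config, seed) reproduces byte-identical files; the pipeline itself has
no randomness.

## Degenerate inputs and tie-breaks

Zero-variance eigenvector tracks, zero/undefined orientation correlations,
NaN eigenvalues, overlapping bins, all-zero contingency tables and invalid
p-values raise errors naming the offender; off-resolution loop anchors warn
(chromosome-terminal anchors are legitimate). All matchers break ties by
genomic position (leftmost first), making every result invariant to input
order. Empty flow strata are emitted as warnings, not errors.

## Known limitations

Exact-anchor loop identity makes differential loop calls sensitive to
one-bin anchor shifts between conditions; this is faithful to the method
being implemented, and a tolerance-based matcher is deliberately out of
scope. Interval matching is quadratic per chromosome in the worst case,
ample for feature-call workloads (10²–10⁴ records) but not for base-pair
tiling. The Fisher p-value enumerates the hypergeometric support with exact
big-integer arithmetic, which is O(min margin) per table and comfortable up
to universes of ~10⁴ transcripts.
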