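# Methods

## Overview

`kinophos` analyses the phosphorylation-site landscape of a protein
kinome from file-based inputs: a kinase catalog (sequence, family,
catalytic-domain and disordered-region intervals), a phosphosite table
with detection-evidence counts, a missense-mutation table, and per-family
multiple sequence alignments. Four analyses are chained: detection-
evidence ranking, family conservation scoring, in-silico tryptic
digestion, and positional classification relative to the kinase domain.
All coordinates are 1-based and intervals are inclusive on both ends,
matching the residue-letter-plus-position convention used for sites such
as Y419.

## Evidence classes and predominance ranking

Each site carries `ht_count` (number of high-throughput MS datasets
detecting it) and `lt_count` (number of targeted low-throughput studies).
A site is LT+HT when both are positive, HT-only or LT-only otherwise; a
site with neither is rejected as unobserved.

Within a kinase, sites are ranked descending by `ht_count`, ties broken
descending by `lt_count`, remaining ties ascending by position. The
primary key is HT frequency because predominance is defined by detection
frequency across high-throughput datasets, with targeted studies as
supporting evidence rather than part of a weighted sum; the positional
tie-break exists purely to make reports deterministic. The top ten
ranked sites are the kinase's *predominant* set (the cut `k = 10` is
configurable) and the first is its representative site. Sites with no
curated functional association (activation, inhibition, activity
alteration, localization, stability, degradation, conformation,
interaction) are *orphans*. External machine-learned functional scores in
[0, 1] can be joined by (kinase, position); out-of-range entries are
rejected and logged.

## Conservation score

For a site at position `p` with window half-width `w` (default 5, so an
11-residue window), the site is mapped to its alignment column and the
`2w + 1` columns centred there are each scored against the characters of
the other family members at that column (`n` = members − 1; the query is
excluded because a self-match would put a two-member family's floor at
0.5 instead of 0). At each column, among the `n` comparison characters
we count exact matches, property matches (different residue, same
physicochemical group) and gaps, and combine them as

    score_j = clamp(w_exact · exact/n + w_property · property/n + w_gap · gaps/n, 0, 1)

with defaults `w_exact = 1.0`, `w_property = 0.5`, `w_gap = 0.0`. Under
these defaults gaps contribute nothing, which penalizes gapped columns by
dilution while keeping every column's maximum at 1; `w_gap` may be set
negative for a harsher penalty (the clamp keeps the column score in
[0, 1]). A gap as the *query's* character scores 0 — there is no residue
to conserve. The total score is the mean over the `2w + 1` columns, so
it lies in [0, 1] and equals exactly 1 for an interior site in a family
of identical sequences. Window positions that fall beyond the sequence
or alignment edge are gap-padded and score 0; edge sites are therefore
attenuated by construction, which we accept as the faithful consequence
of gap padding.

The property groups (hydrophobic AVLIM, aromatic FWY, polar STNQC,
positive KRH, negative DE, special GP) are a conventional six-class
partition of the 20 amino acids and are swappable in `ScoringWeights`.

Thresholds, applied to the normalized total: ≥ 0.75 highly conserved,
≤ 0.25 less conserved, strictly below 0.1 additionally *family-unique* —
a candidate for kinase-specific regulation. Families with a single
member are excluded (nothing to compare against).

## Tryptic digestion

Trypsin cleaves after K or R except when the next residue is P (the
canonical rule; the method is named but not parameterized further, so
the standard rule is adopted). With zero missed cleavages the fragments
tile the sequence exactly; up to two missed cleavages emit all
concatenations of adjacent fragments. Peptides are binned into < 8,
8–15, and > 15 residues — 8–15 aa (≈ 500–2000 Da) being the band MS
detects best — and monoisotopic masses (residue masses + one water) are
computed via pyteomics. Phosphorylation mass (+79.9663 Da per site) is
*not* added by default, since the detectability band is conventionally
quoted for unmodified peptides; a parameter exposes it.

## Positional classification

A site is inside the kinase domain iff it falls in any domain interval
(inclusive). Kinases are categorized from the placement of their top-3
ranked sites: all inside → PiKD, all outside → PoKD, mixed → PaKD; with
fewer than two ranked sites no call is possible → PeKD (enigmatic).
Kinases with exactly two sites are classified by the same
all-in/all-out/mixed rule on the pair — the minimal extension of the
top-3 rule, since the enigmatic category is reserved for kinases where
placement cannot be assessed. Domain coverage is the summed domain
length over protein length: ≥ 0.70 high, [0.50, 0.70) mid, < 0.50 less
(mid is half-open at the top so the strata partition). Disorder overlap
uses the same interval test against disordered segments; mutation
co-location requires exact position equality and tallies pairs inside
vs outside the domain.

## Synthetic kinome generator

The generator stands in for database exports with a bundle in the exact
formats the readers consume, plus planted ground truth. Families are
evolved star-wise from a uniform-random ancestor: a configurable
fraction of columns (default 0.5) is conserved and never substituted,
the rest substitute independently per member with probability 0.5.
Phosphoacceptor columns are planted in both strata — three conserved and
three variable per family by default — with ±3 flanking columns forced
into the same stratum, so a planted-conserved site sits in a conserved
motif the way functional phosphosites sit in conserved substrate
context. There are no indels by default, making the true alignment the
column-identity alignment; an optional per-column deletion mode exists
only to stress the alignment reader.

Default conditions and why:

- families: 12; members per family 3–8 (typical curated kinase families
  hold a handful of paralogs); sequence length 300–700 aa (the range of
  most kinases).
- HT counts: zipf with exponent 2, so one or two sites dominate each
  kinase — emulating real phosphoproteomes where a single activation-loop
  site may appear in a third of all datasets while its regulatory partner
  appears in a tenth. With probability 0.08 a site is HT-undetected
  (LT-only), matching the small minority of sites known only from
  targeted work; LT support is present with probability 0.2.
- function tags: present with probability 0.4, leaving orphans as the
  largest class, as in curated resources.
- domain coverage fractions cycle through {0.8, 0.6, 0.3} so all three
  coverage strata occur; disorder covers 15% of each sequence; mutations
  land on 10% of site positions.

The generator records, by construction, which sites were planted
conserved/variable and each kinase's expected positional category
(derived inline from the planted counts and intervals, independent of
the classifier module). What it does **not** emulate: tree-structured
phylogeny (star topology only), indel-rich alignments, compositional
bias, correlated detection across tissues, or isoform ambiguity — so
passing recovery tests demonstrates correctness of the scoring and
classification logic under known truth, not robustness to real-data
artifacts such as alignment error or snapshot-dependent counts.

## Numerical and degenerate-input choices

- Ranking and all reports are deterministic; every random draw flows
  from a single integer seed through per-family child generators, and a
  fixed config reproduces the bundle byte-for-byte.
- Malformed data rows (interval past the sequence end, residue mismatch,
  unknown kinase) are rejected, logged with row number, and counted in
  the run summary; duplicate kinase IDs and ragged alignments abort.
- A kinase with no observed sites is valid and classifies as PeKD; an
  empty site table yields an all-PeKD kinome and zero conservation rows.
- Conservation for families without a supplied alignment is skipped and
  noted in the summary unless the built-in star-alignment fallback
  (BLOSUM62 pairwise to the longest member) is enabled; the fallback is
  a convenience for small tests, not a replacement for a progressive
  aligner.

## Problem sizes in the test suite

The acceptance-style checks run at: 10^4 random windows for the
position-score oracle, 500 random sequences for digestion, 300 random
site sets for ranking, a 22-family (~120-kinase) bundle for positional
recovery, and 32 families for the planted-conservation separation —
sizes at which every stochastic check is far from its decision boundary
while the whole suite completes in seconds.

## Known limitations

- The per-position score algebra and the gap term admit more than one
  reading in the source material conventions for this statistic; the
  multiplicative-weight, clamp-to-[0,1], mean-normalized reading adopted
  here is documented above and configurable, not asserted as the only
  one.
- Conservation is computed against a supplied alignment; alignment
  quality bounds score quality.
- Kinome-wide headline counts depend on licensed database snapshots and
  are out of scope; the pipeline reports whatever its frozen inputs
  contain.
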