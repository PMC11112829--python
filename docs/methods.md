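# Methods

This note documents the models, numerical choices and known limitations of
the package; the README gives the user-facing overview.

## Pairwise alignment and the network score

All pairwise alignments (local for network edges, global for reference
anchoring, identity and redundancy) use BLOSUM62 with affine gap penalties:
the first residue of a gap costs 11, each extension 1.  The network edge
statistic is an expectation-style alignment score

    AS = m · n · s · 2^(−bits),   bits = (λ·S − ln K) / ln 2

with S the raw Smith–Waterman score, λ = 0.267 and K = 0.041 (the standard
gapped-BLOSUM62 Karlin–Altschul parameters), m, n the sequence lengths and
s a configurable search-space scale (default 1).  Lower AS means stronger
similarity.  Because deep alignments drive AS below double-precision range
(identical 770-mers reach ~10⁻⁴⁷⁰), edges carry `log10_score` as the exact
value; the linear `score` field is floored at 10⁻³⁰⁰.  All cut-off
comparisons use the log form.

Web tools computing similar expectation scores use their own (unpublished)
parameterisations, so absolute AS values and the exact cut-off at which a
given family separates are tool-specific.  What this module supports — and
what the tests pin down — is the *behaviour*: edges are computed once at a
loose threshold, sweeps are pure graph filtering, components only split as
the cut-off decreases, and nested family structure separates outermost
first.  The optional k-mer prefilter (skip pairs sharing no 4-mer) is off
by default and unused in every shipped test.

## Reference anchoring and the five curation criteria

Queries are anchored by full global alignment to an annotated reference
(end gaps penalized, so truncations are visible as missing coverage).
Biopython's deterministic enumeration of co-optimal alignments provides the
tie-break (highest score, then its fixed traversal order).  A query whose
alignment identity — matches over aligned columns, dual-gap columns
excluded — falls below 20 % is "unanchorable": unrelated equal-length
proteins reach ~16–17 % under this scoring, so the floor separates noise
from the ≥ 45 % identity of genuine family members.  Criteria read query
residues at mapped reference positions:

* catalytic His and heme Met/His: the mapped residue must be H (M) exactly;
  a gapped landmark fails the criterion.
* Rossmann motif: the regex `G.G..G` must occur in the query interval
  aligned to the reference motif ± 15 columns (the window is configurable;
  the criterion is a *local* motif, not a global one).
* N-terminal Cyt domain: ≥ 60 % of the reference Cyt-region columns must
  map to query positions that precede the mapped DH start.  The 60 % floor
  is this package's operationalisation of "contains an N-terminal Cyt
  domain"; no numeric rule exists in the literature for this check.
* signal peptide: a built-in n/h/c heuristic (below), overridable by an
  external predictor's tabular calls.

The signal-peptide heuristic requires, within the first 30 residues: a
7-residue window starting no later than position 12 with mean
Kyte–Doolittle hydropathy ≥ 1.8 (h-region), a non-negatively charged
prefix (n-region), and a small residue (A/G/S) within 12 residues after
the hydrophobic stretch (c-region cleavage context).  It is a structural
filter, not a statistical model: it recovers the generator's planted
leaders essentially perfectly, but on real proteomes a dedicated predictor
is more accurate — hence the adapter that consumes external predictions
and overrides the heuristic.

The packaged reference is **synthetic**: a deterministic, seeded random
protein of 770 residues with the canonical annotation coordinates planted
exactly (Met65, His163, His689, YDY at 238, GxGxxG at 246, Cyt 19–215, DH
230–770) and with the motif search windows scrubbed of accidental matches.
It exercises the full anchoring machinery with known truth; users working
with real data supply their own annotated reference.

Redundancy reduction is greedy first-fit in input order at a global
identity threshold (default 0.99): deterministic, order-dependent by
design, and verified against all-pairs identity on small sets.  Column
trimming removes columns with gap fraction ≥ 0.9 (inclusive).  Sequence
logos are star alignments on reference columns: each record is anchored
independently and column *p* of the logo collects residues aligned to
reference position *p*; information content is R = log₂20 − H per column
with no small-sample correction (the planted-frequency tests would absorb
the correction into their tolerance, so it stays off by default).

## Domain split and clade selection

The DH domain starts 8 residues before the first YDY occurrence within
± 20 query positions of the mapped reference YDY; if none is found, the
split falls back to the query position aligned to the reference DH start
and the result is flagged.  Sub-clades are cut from a Newick tree (branch
lengths required) by severing every edge whose cumulative root-to-node
distance first exceeds the threshold (default 0.4); leaves never crossing
the threshold form one residual clade.  Cumulative root distance is one of
several defensible readings of an "evolutionary distance threshold"
(pairwise leaf distance and subtree height being the others); it is the
one that makes clade count non-increasing in the threshold, which the
property tests rely on.  Candidate selection is per-clade, preferring
records flagged with the priority lifestyle ("plant-associated" by
default), ties broken by accession order.

## Construct design

Domestication removes every occurrence (both strands) of the SacI, PmeI,
AscI, BbsI and BsaI recognition sequences by synonymous codon exchange:
single-codon exchanges are tried before pairs; a candidate is accepted only
if the global site count strictly decreases (so an edit cannot silently
create a new site); among minimal edits the codon most frequent in the
configurable usage table wins (uniform default → alphabetical).  A site
overlapping only Met/Trp codons has no synonymous escape and raises.

Fragmentation models a standard golden-gate grammar.  Cut points fall on
codon boundaries at the SP|Cyt and Cyt|DH protein splits; payloads whose
synthesized form would exceed 900 bp are subdivided into balanced
codon-multiple parts.  Each synthesized fragment is
`adapter5 + payload + fusion + adapter3 [+ spacer]`, where the adapters
carry inward-pointing BsaI sites (cut geometry 1/5, 4-nt 5′ overhangs) and
`fusion` is the first 4 nt of the *next* payload — so the digested sticky
ends are exactly the junction 4-mers of the CDS.  Junction cuts shift by
whole codons (up to ±30 bp) until every overhang is unique and
non-palindromic.  Fragments under 300 bp get a deterministic neutral 3′
spacer, generated greedily and screened against all five sites; spacers
sit outside the cut sites and vanish in the reaction.  The stop module
contributes `TAAGCTT` (TAA stop + fusion tail) and ends in a fixed
acceptor-side overhang.  `validate_assembly` digests every fragment
textually, chains pieces purely by overhang matching (input order is
irrelevant), requires a unique linear chain, and compares the product with
the domesticated CDS + stop payload, reporting the first divergent
position on mismatch.

## Biochemical calculators

Units: absorbances AU, ε in mM⁻¹cm⁻¹ (except ε₂₈₀ from sequence, reported
in M⁻¹cm⁻¹ as is conventional), path cm, time min, activity U = µmol
min⁻¹.  Volumetric activity is `slope/(ε·d) × dilution / sample_fraction`;
the slope comes from an ordinary least-squares fit over the whole trace
(window selection is a config option), R² below 0.95 warns, negative
slopes clip to zero with a warning.  Traces are represented with positive
slope magnitudes regardless of whether the physical signal rises or falls.
The limit of quantification is 10 × the n−1 standard deviation of blank
activities (≥ 3 blanks).

Purification tables compute total protein = concentration × volume,
specific activity, yield % and purification factor per assay relative to a
reference step, at full precision; rounding happens only in the display
formatter.  Below-detection-limit is a distinct state (None/NaN → rendered
"b.d.l."), never coerced to zero.

ε₂₈₀ = 5500·nTrp + 1490·nTyr + 125·⌊nCys/2⌋ (all-cystine default,
all-reduced optional).  FAD occupancy: [FAD] = A₄₅₀/ε_FAD,450 (default
11.3 mM⁻¹cm⁻¹) from the TCA-released flavin; protein from the native A₂₈₀
iteratively corrected for the flavin's own 280-nm absorbance,
P ← (A₂₈₀ − [FAD]·ε_FAD,280)/ε_prot,280 to 10⁻⁹ (with the default
ε_FAD,280 = 0 this reduces to the single-step estimate).  The fixed-point
scheme and its constants are this package's documented definition of the
"iterative calculation" — the protocols cited in the experimental
literature are not reproduced verbatim here.  Occupancy clips to [0, 1.05]
and warns above 1.  Normalisation to 100 % FAD loading divides the
specific activity by the occupancy; supplied standard deviations propagate
in quadrature.

Spectral features: band maxima are grid maxima refined by 3-point
quadratic interpolation, accepted only as *interior* local maxima of their
window — Soret 400–440 nm per state, α 548–570 nm and β 520–545 nm on the
reduced spectrum.  A flat or monotone window (e.g. the flavin shoulder of
a heme-free DH domain) therefore yields "no Soret band" rather than a
spurious edge peak.  RZ is A₄₂₀/A₂₈₀ of the oxidized spectrum
(interpolated); the difference spectrum is reduced − oxidized on the
common grid.

## The synthetic-data generators

`generate_family` plants a class structure: class ancestors diverge from a
shared root, members from their class ancestor, with per-copy mutation
counts solved from the identity targets including a collision correction
(2k − (20/19)k²/M mismatches expected for two copies mutated at k of M
mutable positions) so realized pairwise identities land within ±3
percentage points of target.  Substitutions are uniform exchanges — no
rate variation, no empirical exchangeabilities — which is sufficient for
identity-controlled planting but means the families lack the compositional
signal of real evolution; passing tests demonstrate recovery of planted
structure, not performance on real proteomes.  Feature columns *and* the
motif search windows are excluded from random mutation, so a planted
ablation (single-point changes: the three Rossmann glycines → A, catalytic
H → A, heme M/H → A, YDY → YAY, h-region → DDEE…) is the sole determinant
of the corresponding criterion.  Members get individually sampled
secretion leaders by default (M + 1–2 K/R + 9–12 hydrophobics + small-
residue c-region); this is disabled for ≥ 99 %-identity redundancy
scenarios where the leader would dominate the divergence budget.  Defaults
(within 0.90, between 0.60, reference root of 770 aa) describe a closely
related family; the shipped test scenarios use 300-aa random-root families
for clustering (4 classes × 20 members) and reference-root families for
curation (200 members), sizes chosen so the full validation runs in tens
of seconds.  Indels default off so planted coordinates stay exact; the
indel-enabled mode is deliberately out of scope of the shipped scenarios.

`generate_tree` builds random bifurcating subtrees per planted clade
(within-depth budget, default 0.05) joined to the root by edges of
separation/2 (default 0.5), so any threshold between the two scales
recovers the planted clades.  `generate_cds` reverse-translates with
seeded codon sampling and embeds each requested recognition site by
constraining the overlapped codons to synonymous choices (raising if the
protein cannot host the site at that offset); chance sites from random
codon choice are recorded in the truth.  The assay, spectrum and
purification simulators invert the corresponding calculators exactly at
zero noise; their truth objects store the realized (noisy) values so
closed-form agreement is testable under noise too.

## Known limitations

* AS values are not comparable across tools; only separation behaviour is
  portable.
* The curation criteria assume the query aligns colinearly to the
  reference; heavily rearranged or chimeric sequences would need manual
  review.
* The signal-peptide heuristic is tuned to canonical Sec leaders; lipoprotein
  or Tat-style signals are out of scope.
* The golden-gate grammar models one assembly level with fixed adapters;
  vendor-specific overhang sets can be configured but multi-level
  hierarchies cannot.
* Kinetic modelling (Michaelis–Menten), pH profiles and mass-spectrometric
  analyses are out of scope.
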