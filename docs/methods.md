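# Methods

This note documents the models, algorithmic choices and defaults behind
`barcodelim`, and what the simulation-based tests do and do not demonstrate.

## Distance models

Sites are compared under **pairwise deletion**: a site enters a pair's
comparison only if both sequences carry an unambiguous A/C/G/T there.
Ambiguity codes (including N) and gaps are treated as missing at that site,
not as partial matches — deterministic and conservative, and it preserves
the number of compared sites under ragged N content.

The **K2P distance** is the closed form
d = −½ ln[(1 − 2P − Q)√(1 − 2Q)] with P = ts/n, Q = tv/n over the n compared
sites.  When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 (substitutional saturation) the
pair is *undefined*: it is recorded in the matrix's `undefined_pairs`,
carried as NaN, excluded from summaries with a logged count, and makes
tree building refuse loudly rather than propagate NaN.  The **p-distance**
is (ts + tv)/n.  The correction only inflates: K2P ≥ p on every defined
pair, with equality exactly at distance zero.

Distances are stored as **proportions** everywhere; per-cent values with two
decimals appear only in rendered report tables.  One canonical unit avoids
100-fold mistakes when numbers cross module boundaries.

The **rank-wise divergence summary** partitions pairs into disjoint sets:
conspecific (same species label), congeneric (same genus, different
species), confamilial (same family, different genus).  SE is defined as the
sample standard deviation of the pair distances divided by √(number of
pairs) — the standard error of the mean over pairwise comparisons.  Pairs
are not independent (they share sequences), so this SE is interpretable
only as a descriptive scale, which is how such tables are conventionally
read.  A level with a single pair reports SE 0; a level with no pairs
reports undefined statistics.

The **barcode-gap report** gives, per species, the maximum intraspecific
distance (undefined for singletons) and the nearest-neighbor (NN) distance,
the minimum over all pairs crossing the species boundary.  A species has a
gap iff NN exceeds its maximum intraspecific distance.  The dataset *overlaps*
iff the overall minimum interspecific distance does not exceed the overall
maximum intraspecific distance.

## Neighbor-joining and bootstrap

Saitou–Nei agglomeration with the Studier–Keppler criterion
Q(i,j) = (n−2)d(i,j) − r_i − r_j.  Determinism is part of the contract: Q is
evaluated in an exactly symmetric floating-point form, and ties (within a
relative tolerance of 1e−12) are broken by the lexicographically smallest
pair of representative labels, where an internal node is represented by the
smallest leaf label beneath it.  Negative branch-length estimates are
clamped to zero for output (standard practice; keeps Newick consumers
sane); the pre-clamp estimate is retained on every node and the clamp count
logged.  On additive matrices the generating topology and pre-clamp branch
lengths are recovered exactly — the test suite checks this exhaustively for
all unrooted topologies on 4–6 taxa.

Bootstrap supports come from resampling alignment columns with replacement,
recomputing the distance matrix and NJ tree per replicate, and annotating
each internal edge of the original tree with the percentage of replicates
containing the same bipartition (canonically encoded, so the value is
invariant to input order and rooting).  One seeded generator produces all
draws up front; replicate r consumes row r, making results independent of
evaluation order.  Replicates with an undefined pair are discarded; more
than 10% discards aborts.  The default of 100 replicates matches common NJ
practice and keeps a 400-sequence bootstrap around a minute.

**Cluster extraction** reads OTUs off the bootstrapped tree: clusters are
maximal unrooted clades (either side of an internal edge) with edge support
≥ 97 and maximum within-clade pairwise distance ≤ 0.02; qualifying clades
are accepted largest-first, and leaves in none become singletons.  Working
with edge sides rather than rooted subtrees matters: the final NJ join can
land inside a species, in which case that species is not a rooted-subtree
clade at all.  The 97% support floor is the survey convention for counting
clusters; the 2% cap is near the species-scale threshold used by barcode
repositories.  Both are exposed on the CLI.  How exactly a survey "reads
clusters off" an NJ topology is never fully specified in the field; this
two-threshold rule is this package's documented surrogate.

A taxon is **monophyletic** iff some edge of the unrooted tree bipartitions
exactly its leaf set; single-leaf taxa are trivially monophyletic.

## ABGD-style gap discovery

The prior p is a ceiling on intraspecific divergence.  Given ranked
pairwise distances d₍₁₎ ≤ … ≤ d₍ₘ₎ and gaps gᵢ = d₍ᵢ₊₁₎ − d₍ᵢ₎:

* a gap is *eligible* iff its upper end exceeds p **and** its midpoint
  (the candidate threshold) is at least p — distances below the prior are
  intraspecific by assumption, so a threshold below the prior would be
  self-contradictory;
* the *local slope* before gap i is the mean of the previous
  w = max(3, ⌈0.1·m⌉) gaps; a gap with no predecessors is never significant
  on its own;
* gap i is the barcode gap iff gᵢ > X·slope and gᵢ > X·G, where G is the
  largest gap lying inside the prior region and X is the relative gap width
  (default 1.2, the common web-interface setting);
* the threshold is the band midpoint (symmetric, stable under small
  perturbations); partitioning joins pairs with d < threshold into
  connected components; recursion re-applies the detector inside every
  group to a fixpoint (guarded at 20 rounds).

This gap-significance rule is this package's operationalization of
ABGD-style detection; the published algorithm's exact slope estimator is not
restated anywhere in reproducible detail, so constructed two-band distance
sets (an intra band, an empty band, an inter band) serve as the correctness
oracle: any sound detector must place its threshold inside the empty band.
The sweep evaluates n geometrically spaced priors over [0.001, 0.1]
(defaults; the geometric ladder matches the web-interface convention) and
returns an initial and a recursive partition per prior.  Note a wording trap
in the surrounding literature: the prior range is sometimes described as
"interspecific divergence"; ABGD's prior is a maximum *intra*specific
divergence, which is what is implemented here.

At very small priors the recursive partitions oversplit (every discrete
distance step can look like a gap) and at priors above the species-level
band the detector either finds nothing or latches onto deeper structure —
both are authentic ABGD behaviors.  The single reported ABGD answer is
therefore the recursive partition at the smallest prior whose group count
is modal across the whole sweep (ties toward the smaller count).

## BIN-proxy OTUs

Barcode repositories assign Barcode Index Numbers via RESL on uncorrected
p-distances; its refinement stage is unpublished in reproducible detail.
The proxy here is the documented seed step only: single-linkage connected
components at p < 0.022.  It is labelled a proxy throughout.  Its semantics
deliberately coincide with the ABGD component partition at the same
threshold, and the two are implemented as independent code paths
(scipy sparse-graph components vs a hand-rolled union-find) that the test
suite requires to agree exactly.

## Quality screening

COI is protein-coding, so genuine barcodes have a stop-free reading frame.
Each gap-stripped sequence is translated in frames 0/1/2 under the
**vertebrate mitochondrial code** (stops TAA, TAG, AGA, AGG — the standard
code would miscall AGA/AGG in fishes); the frame with fewest stops wins,
ties to the lowest frame.  Codons containing ambiguity codes are skipped,
not counted as stops.  A record passes iff its best frame has zero stops
and the alignment length equals the expected amplicon (626 bp default).
With pre-aligned uniform-length input, true indels manifest as internal
gaps, which are counted into `n_ambiguous`.  QC failures do not halt the
pipeline by default — failing records are excluded with a logged warning,
mirroring survey practice of dropping poor-quality sequences — and a strict
mode aborts instead.  Which genetic-code table repository pipelines apply
is not published; this policy is a documented stand-in.

## The simulator

The generator emulates the statistical structure of a delta-wide barcode
inventory: a balanced nested hierarchy in which every level is a **star
tree** with a fixed stem depth (expected substitutions per site):
individuals at 0.003 below their species, species at 0.03 below their
genus, genera at 0.08 below their family, families at 0.06 below the root.
Star shapes, rather than birth–death topologies, give direct analytic
control of the divergence bands the gap logic needs: conspecific pairs sit
at ~2×0.003 (≈0.6% mean, matching the sub-2% intraspecific band of real
fish surveys), congeners at ~2×0.033 (≈6–8%), confamilials at ~20%.  The
family stem exists so that families are genuine clades — without it family
monophyly would be unattainable even in principle.  Sequences evolve
site-wise under K80 (equal base frequencies, ts/tv rate ratio κ = 4,
mid-range for fish COI) with rates normalized so a stem of depth t yields t
expected substitutions per site; K2P is the consistent estimator of that
branch length, which the tests verify by Monte Carlo.  Codon-aware
rejection sampling redraws any codon that would become an in-frame stop, so
synthetic datasets pass QC by construction.  The default amplicon is 626 bp;
the generator builds whole stop-free codons and trims, so the trailing
partial codon is simply never translated.

The optional **cryptic split** plants two lineages inside one nominal
species, separated by 2×`split_depth` (default 0.006, i.e. ≈1.2%) at the
lineage ancestors.  The scenario used in tests sets `intra_depth` = 0.0005
so that intraspecific distances stay ≤ ~0.3% — the deep-conspecific
configuration in which a 2.2% threshold merges the pair while gap-based
recursion at priors below the split depth can separate it.

Default scale is 20 species × 5 sequences (a desk-scale survey slice that
keeps the full test suite in minutes); `SimConfig.survey_scale()` provides
the inventory-sized preset (100 species, 1–8 specimens each, ~450
sequences), which the end-to-end runtime test drives through the whole
pipeline with 100 bootstrap replicates in about a minute on one CPU.

What the simulator does **not** emulate: indels, rate heterogeneity across
sites, selection, coalescent structure within species, unbalanced
taxonomies, contamination, or sequencing error.  Passing recovery tests on
these data therefore demonstrates correctness of the algorithms under the
model's assumptions, not performance on real surveys — where paraphyly,
introgression and uneven sampling make delimiter disagreement the norm.

## Numerical and determinism choices

* One root seed; named substreams for taxonomy sampling, root-sequence
  generation and evolution, so outputs are byte-identical per seed and
  independent of evaluation order.
* NJ tie-breaks and group renumbering (first-seen id order) are fully
  deterministic; report bundles regenerate byte-for-byte from their
  manifest, which deliberately contains nothing time- or host-dependent.
* MEGA distance files are written lower-left at 6 decimals (the layout the
  classic ABGD web tool consumes) and refuse matrices with undefined pairs,
  since the dialect has no missing-value convention.
* Newick output quarantines reserved characters by rejection rather than
  quoting.

## Known limitations

* The NJ-cluster surrogate (support ≥ 97 plus 2% cap) is sensitive to
  bootstrap support sitting exactly at the threshold: on simulated default
  surveys roughly one dataset in six contains a species whose true support
  is within a point of 97, so per-dataset species recovery by this rule is
  ~85–90%, while ABGD and threshold OTUs recover the truth essentially
  always.  This mirrors real surveys, where NJ cluster counts at a 97%
  floor routinely differ from named-species counts.
* The BIN proxy omits RESL's refinement; datasets where refinement would
  re-split merged seeds will disagree with repository BIN counts.
* K2P variance is not propagated (no delta-method standard errors on
  distances), and no other substitution models are offered.
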