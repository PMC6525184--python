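# barcodelim

Distance-based species delimitation from aligned COI DNA barcodes.

Biodiversity surveys routinely barcode hundreds of specimens with a ~650 bp
fragment of the mitochondrial *COI* gene and then ask: how many molecular
species (OTUs) are in the sample, do the named species each form their own
cluster, and is there a *barcode gap* — a separation between intraspecific
and interspecific divergence — that makes distance-based identification
reliable?  `barcodelim` implements that entire analysis surface as a tested,
reproducible library and command-line tool, aimed at researchers analysing
fish (or any animal) barcode inventories and at methodologists who want the
delimitation steps under unit-test control rather than behind a web portal.

## What it computes

**Distances.** Pairwise Kimura two-parameter distances under pairwise
deletion,

d = −½ ln[(1 − 2P − Q) · √(1 − 2Q)],

with P and Q the observed transition (A↔G, C↔T) and transversion
proportions, plus uncorrected p-distances (p = ts+tv over compared sites).
Saturated pairs are reported as undefined, never silently zeroed.

**Trees.** Saitou–Nei neighbor-joining with the Studier–Keppler Q-criterion,
deterministic tie-breaking, non-parametric bootstrap supports from column
resampling, cluster extraction (maximal clades with support ≥ 97% and
within-clade distance ≤ 2%), and monophyly assessment per taxon.

**Delimitation.** Automatic Barcode Gap Discovery: ranked pairwise
distances, detection of the first significant gap beyond a prior
intraspecific limit (relative gap width X, default 1.2), single-linkage
partitioning below the implied threshold, recursive refinement, and a sweep
over geometrically spaced priors (0.001–0.1).  A BIN-style OTU proxy applies
single linkage at 2.2% p-distance (the published RESL seed threshold — the
proprietary refinement stage is deliberately out of scope).

**Reports.** Rank-wise divergence tables (min/mean/max/SE within species,
genus, family, in percent), per-species barcode-gap records (maximum
intraspecific vs nearest-neighbor distance), cross-method OTU comparisons
with split/merged flags, and QC screening for in-frame stop codons under the
vertebrate mitochondrial code.

**Simulation.** A K80 sequence simulator over a nested
family/genus/species/individual star hierarchy with codon-aware rejection
sampling (no lineage ever carries an in-frame stop), including an optional
cryptic split inside one nominal species — so every stage of the pipeline is
exercisable and testable without downloading any data.

## Worked example

```python
import barcodelim as bl
from barcodelim.abgd import AbgdConfig, abgd_sweep
from barcodelim.distances import summary_frame
from barcodelim.otu import choose_abgd_partition, compare_partitions

aln, tax, truth = bl.simulate_dataset(bl.SimConfig(seed=1))   # 20 species x 5 seqs
dk = bl.distance_matrix(aln, "K2P")
print(summary_frame(bl.rank_divergence_summary(dk, tax)).to_string(index=False))

tree = bl.bootstrap_support(aln, replicates=100, seed=1)
nj_part = bl.extract_nj_clusters(tree, dk)
abgd_part = choose_abgd_partition(abgd_sweep(dk, AbgdConfig()))
otu_part = bl.threshold_otus(bl.distance_matrix(aln, "P_DIST"))
cmp = compare_partitions({"nj": nj_part, "abgd": abgd_part, "otu_2.2pct": otu_part}, tax)
print("OTU counts:", cmp.counts)
```

prints

```
         level  n_pairs  min_divergence_pct  mean_divergence_pct  max_divergence_pct  se_divergence_pct
within_species      200                0.00                 0.64                1.62               0.02
  within_genus      250                4.28                 6.24                8.49               0.07
 within_family      500               16.60                21.19               24.36               0.09
OTU counts: {'nj': 20, 'abgd': 20, 'otu_2.2pct': 20}
```

Divergence rises with taxonomic rank (0.64% within species, 6.24% within
genera, 21.19% within families), the intra/inter bands do not overlap, and
all three delimiters — NJ clusters at ≥97% bootstrap, ABGD's modal
partition, and 2.2% threshold OTUs — recover the 20 true species exactly.

The same analysis is available from the shell:

```sh
barcodelim simulate --out data/
barcodelim run --config pipeline.yaml          # QC -> distances -> NJ -> ABGD -> OTUs
barcodelim abgd data/sequences.fasta data/taxonomy.tsv --pmin 0.001 --pmax 0.1 --out parts.csv
```

`run` writes a complete report bundle (CSV tables, Newick tree, MEGA-format
distance matrix) plus a `manifest.json` from which the bundle can be
regenerated byte-for-byte.

## Layout

```
src/barcodelim/
  records.py    alignment + distance-matrix containers
  io.py         FASTA/TSV, MEGA distance, Newick
  qc.py         stop-codon / length screening
  distances.py  K2P, p-distance, divergence summaries, barcode gap
  nj.py         neighbor-joining, bootstrap, clusters, monophyly
  abgd.py       gap detection, threshold partitioning, prior sweep
  otu.py        BIN-proxy OTUs, cross-method comparison
  simulate.py   K80 hierarchical barcode simulator
  pipeline.py   end-to-end orchestration + manifests
  cli.py        command-line interface
```

See `docs/methods.md` for the scientific background, parameter defaults and
known limitations.
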