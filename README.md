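# eck — enzyme complexity kit

`eck` is a toolkit for quantifying how complex enzymes are, working from
mechanism-level enzyme records (the kind curated in mechanism databases such
as MACiE, joined with sequence, EC and CATH domain annotations). It answers
three questions for structural bioinformaticians and enzymologists:

1. **Which residues do the catalysis?** Catalytic propensities per EC class —
   for residue type *r* and class *C*,

   `P(r, C) = (n_cat(r, C) / n_cat(C)) / (n_bg(r, C) / n_bg(C))`

   the share of the catalytic toolkit contributed by *r*, normalized by its
   background abundance (1 = no enrichment), plus seven-category functional
   role profiles (activation, steric, stabilization, proton / H-radical /
   electron shuttling, covalent catalysis, with hydride shuttling reserved to
   organic cofactors) across residues, metal ions and organic cofactors.
2. **How many times did each reaction evolve?** Evolutionary families per EC
   node, estimated from sequences (global-alignment percent identity →
   threshold graph → single-linkage clustering → profile-based singleton
   merging; an upper bound) and from structures (canonical CATH H-level
   domain-combination keys refined by a permissive sequence-identity floor;
   a lower bound).
3. **How are active sites packaged into proteins?** Domain role labels
   (catalytic = furnishes ≥ 1 catalytic residue; binding = ≥ 3 binding
   residues), catalytic-unit extraction, canonical architecture signatures
   ("A\*", "A\*B", "A\*A\*", ...), a configuration census and domain→EC
   promiscuity tables.

Because the original database snapshots are not redistributable, `eck` ships
a first-class synthetic data generator that plants known family structure,
propensity multipliers, role assignments and architectures, so every
analysis stage can be validated against ground truth.

## Worked example

Generate a 6-node synthetic dataset and run the full pipeline:

```python
from eck.report import run_pipeline
report = run_pipeline({"generator": {"n_ec_nodes": 6, "rng_seed": 5}},
                      out_dir="eck_output")
```

or equivalently `eck --seed 5 --out-dir eck_output run` with the generator
section in a config file. The printed report (abridged):

```json
{
 "n_records": 28,
 "sequence_families": {"n_nodes": 6, "mean_raw": 1.67, "mean_merged": 1.67,
                       "singleton_node_fraction": 0.667},
 "structural_families": {"n_nodes": 6, "mean": 1.33,
                         "singleton_node_fraction": 0.667},
 "architecture": {"census_total": 28, "single_domain_fraction": 0.607,
                  "n_catalytic_codes": 7},
 "recovery": {"exact_match_rate": 1.0, "mean_bias": 0.0, "n_nodes": 6}
}
```

Reading: the 28 generated records fall into on average 1.67 sequence
families per EC node (1.33 at the structural level, computed over the
records flagged as having a structure), two-thirds of nodes are covered by a
single family, 61% of enzymes are truly single-domain, and the clustering
recovered the planted family count of every node exactly. Per-node tables
(`node_counts.tsv`, `census.tsv`, `propensity.tsv`, ...) are written next to
`report.json`, and every mean in the report is recomputable from them.

The estimator classes compose in the scikit-learn style:

```python
from eck import GeneratorConfig, generate, select_complete_ec
from eck import SequenceFamilyClusterer, PropensityAnalyzer

dataset, truth = generate(GeneratorConfig(n_ec_nodes=20, rng_seed=11))
clusterer = SequenceFamilyClusterer(identity_threshold=30.0).fit(select_complete_ec(dataset))
clusterer.counts_          # per-node raw/merged family counts
PropensityAnalyzer().fit(dataset).table_.values  # residue x EC-class matrix
```

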