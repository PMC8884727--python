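# clonotrace

Analysis toolkit for cellular-barcoding lineage tracing of hematopoietic
stem and progenitor cells (HSPCs), with a single-cell companion arm for
calling treatment-responder cells. It is written for experiments in which
lentivirally barcoded progenitors are transplanted into mice, mature
lineages (erythroid E, myeloid M, B-lymphoid B, optionally dendritic cells
or megakaryocyte progenitors) are sorted and sequenced, and the question is
how a perturbation — here ex vivo erythropoietin (EPO) exposure — changes
the *output balance* of individual clones.

## What it computes

**Barcode arm.**

1. **Extraction** (`barcode_extract`): amplicon reads are parsed against a
   read template (index + constant + 20-nt barcode segments) with *no*
   mismatch tolerance, demultiplexed by index, and filtered against the
   barcode reference list. Everything else is tallied with a rejection
   reason; assigned + rejected always equals input.
2. **QC cascade** (`clonal_filter`): samples with <5000 reads are dropped;
   each sample is normalized to 10⁵ reads; technical replicates are merged
   only if their Pearson correlation (over the union of detected barcodes)
   is ≥0.9, with barcodes seen in a single replicate zeroed and the
   replicate mean taken; merged samples with <10 barcodes are dropped;
   low-abundance barcodes shared between mice of one transduction batch
   across sequencing runs are zeroed until cross-run sharing is no larger
   than within-run sharing; each surviving mouse becomes a barcode ×
   lineage `CloneMatrix`. A mouse is excluded whenever any of its lineage
   samples fails.
3. **Bias classification** (`bias_classify`): a clone's class is the set
   of lineages receiving strictly more than a threshold *t* (default 10%)
   of its normalized output — MBE (balanced), ME / MB / BE (biased),
   M / B / E (restricted), plus DC-only / MkP-only for auxiliary
   compartments. Derived outputs: class frequencies, class × lineage
   contribution percentages, ternary (triangle-plot) coordinates, and
   progenitor-compartment overlap splits.
4. **Permutation testing** (`perm_test`): for a per-mouse statistic (e.g.
   "% of the E lineage produced by ME-biased clones"), the observed
   |Δ of group means| is compared against all C(n_A+n_B, n_A) regroupings
   of the mice (exhaustively when feasible, Monte Carlo with the add-one
   rule otherwise): p = #{regroupings with effect ≥ observed} / #regroupings.

**Single-cell arm** (`sc_responder`): gene/cell QC (Gm…, …Rik, Rps/Rpl
gene discard; <1000 detected genes; mitochondrial fraction), library-size
log-normalization (`log1p(count/total·10⁴)`), logistic-regression
differential expression (per-gene likelihood-ratio test, Bonferroni),
a DEG-count permutation null, signature **module scores** (mean expression
of the gene set minus expression-bin-matched random control genes),
a composite up-minus-down response score, responder calling at the
treated group's 90th percentile, and kNN mapping of query cells onto a
reference atlas (project into the reference's 10-PC space, average the
embedding coordinates of the 10 nearest reference cells).

**Synthetic data** (`synthdata`): generators for both arms with complete
ground-truth ledgers — clone classes and weights, designed read totals,
planted cross-run contaminants, responder cell ids and shifted gene
programs — so every stage is testable without any external download.

## Worked example

Simulate a control cohort and an EPO-like cohort whose clone-class mixture
shifts toward ME-biased clones, run the QC cascade, classify, and test the
ME-class contribution to the erythroid lineage:

```python
from clonotrace import FilterParams, permutation_test, run_cascade
from clonotrace.bias_classify import class_contributions, classify_matrix
from clonotrace.synthdata import ExperimentDesign, gen_clonal_experiment

def me_to_e(design):
    table, _ = gen_clonal_experiment(design)
    matrices, _ = run_cascade(table, FilterParams())
    out = {}
    for mouse, cm in matrices.items():
        labels = classify_matrix(cm.abundance)
        out[mouse] = float(class_contributions(cm.abundance, labels).loc["ME", "E"])
    return out

ctrl = ExperimentDesign(groups=("control",), n_mice_per_group=5, n_clones_per_mouse=60,
                        class_mixture={"MBE": .4, "ME": .2, "MB": .2, "E": .1, "M": .05, "B": .05},
                        weight_concentration=150.0, clone_size_sigma=0.4,
                        depth_per_sample=30_000, contamination_rate=0.0, seed=1)
epo = ExperimentDesign(groups=("EPO",), n_mice_per_group=5, n_clones_per_mouse=60,
                       class_mixture={"MBE": .2, "ME": .5, "MB": .1, "E": .1, "M": .05, "B": .05},
                       weight_concentration=150.0, clone_size_sigma=0.4,
                       depth_per_sample=30_000, contamination_rate=0.0, seed=2)

a, b = me_to_e(ctrl), me_to_e(epo)
res = permutation_test(list(a.values()), list(b.values()))
print(res.observed_effect, res.p_value, res.n_permutations)
```

This prints per-mouse ME-to-E contributions of 20.4–45.9% for control mice
and 55.5–76.6% for EPO mice; the observed |difference of group means| is
31.0 percentage points and the exhaustive permutation test over all 252
regroupings of the ten mice gives p = 0.0079. In other words, the shift in
which clones produce the erythroid lineage is far larger than any shift
obtainable by relabeling mice at random.

A command-line interface mirrors the library:

```bash
clonotrace simulate clonal --mice-per-group 2 --clones 30 --seed 5 --out cohort/
clonotrace filter --counts cohort/counts.tsv --samples cohort/samples.tsv --out filtered/
clonotrace classify --matrix filtered/control_m1.clone_matrix.tsv --threshold 0.10 --out classes/
clonotrace permtest --stat-file stats.tsv --n-perm 10000 --seed 1 --out permtest.tsv
clonotrace sc responders --matrix-dir sc_counts/ --min-genes 1000 --out responders/
```

## Layout

```
src/clonotrace/
  synthdata.py        generators + ground-truth ledgers
  barcode_extract.py  read-template parsing, reference filtering, count tables
  clonal_filter.py    the QC cascade -> per-mouse clone matrices
  bias_classify.py    bias classes, frequencies, contributions, ternary, overlap
  perm_test.py        exhaustive / Monte-Carlo permutation tests
  sc_responder.py     single-cell QC, DE, module scores, responders, kNN mapping
  cli.py              `clonotrace` command-line interface
docs/methods.md       model, parameter and design documentation
tests/                pytest suite (unit, property and end-to-end tests)
```
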