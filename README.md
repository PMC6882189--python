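# equihap

Phylogeography of the horse mitochondrial control region from short
hypervariable fragments.

Maternal-lineage studies of domestic horses type a short hypervariable
segment of the mitochondrial control region (by default NPS
15,494–15,740, 247 bp) across thousands of animals, assign each
fragment to a backbone haplogroup, and compare haplogroup composition
across geographic cohorts. `equihap` implements that workflow as a
tested, reusable Python library and CLI for population geneticists and
archaeogeneticists working with horse (or analogous) mtDNA surveys:

* **Variant profiling** — aligned fragments are reduced to canonical
  variant calls against a reference window (bare position = transition,
  base suffix = transversion, `d` = deletion, `+` = insertion; `N`
  positions are treated as missing data, as expected for degraded
  ancient-DNA fragments).
* **Motif-based haplogroup classification** — a haplogroup's *motif* is
  the set of variants exclusively shared by all of its members inside
  the window. Fragments are assigned by exact or near-matching: the
  score of haplogroup *h* is the fraction of its motif sites (among
  those readable in the fragment) present in the profile, and a call
  requires `score >= min_fraction` plus a margin over the runner-up.
  Haplogroups with no motif inside the window can never be called from
  the fragment alone.
* **Haplotype networks** — unique haplotypes are connected by a minimum
  spanning tree under Hamming distance (number of mismatching variant
  labels), with a deterministic Kruskal tie-break, plus cohort
  summaries: unique-haplotype counts, the F% statistic
  (100 · n_unique / n_haplotypes per haplogroup and cohort), dominant
  haplotypes, and ranked candidate ancestral haplotypes.
* **Population genetics** — Nei's haplotype diversity
  h = n/(n−1)·(1−Σp²), nucleotide diversity π, pairwise
  Φ<sub>ST</sub> from two-population AMOVA, island-model gene flow
  Nm = (1−Φ<sub>ST</sub>)/(2Φ<sub>ST</sub>) for a maternally inherited
  haploid marker, hierarchical AMOVA
  (Φ<sub>CT</sub>/Φ<sub>SC</sub>/Φ<sub>ST</sub>) with permutation
  P-values, and Pearson χ² cohort tests on haplogroup counts.
* **Frequency-table PCA** — population × haplogroup percentage tables
  and their principal components; the packaged world survey
  (59 populations × 10 haplogroups) reproduces the published variance
  structure.
* **Synthetic data** — a generator that plants haplogroup founders with
  exclusive motifs, star-shaped within-haplogroup radiation,
  region-specific haplogroup frequencies and missing-data dropout, so
  every stage can be validated against known truth.

## Worked example

```python
import equihap as eq

# 1. The world-survey PCA on the packaged frequency table
table = eq.load_world_frequency_table()           # 59 populations x 10 haplogroups
res = eq.run_pca(table, standardization="correlation", cases="haplogroups")
for i in range(3):
    print(f"PC{i+1}: {res.component_variance_percent[i]:5.2f}%"
          f"  (cumulative {res.cumulative_percent[i]:5.2f}%)")

# 2. A synthetic two-cohort study with planted truth
cfg = eq.default_config(seed=42, n_per_population=50)
ds = eq.simulate_samples(cfg)
motifs = eq.infer_motifs([(p, ds.truth[p.sample_id]) for p in ds.profiles],
                         window=ds.window)
calls, _ = eq.classify_dataset(ds.profiles, motifs)
acc = sum(c.haplogroup == ds.truth[c.sample_id] for c in calls) / len(calls)
print(f"classification accuracy vs planted truth: {acc:.3f}")
```

prints

```
PC1: 44.54%  (cumulative 44.54%)
PC2: 18.88%  (cumulative 63.42%)
PC3:  9.69%  (cumulative 73.12%)
classification accuracy vs planted truth: 1.000
```

The first line says 44.54% of the variance in the world haplogroup-
frequency table lies on a single axis (the east–west cline), another
18.88% on the second (the north–south contrast within East Asia); the
synthetic study confirms that motif inference and near-matching recover
every planted label when fragments are complete.

The same stages are available from the shell:

```sh
equihap simulate --seed 42 --out sim/
equihap run --config run.yaml --out results/
equihap pca --freq-table table.csv --mode correlation --out pca.json
```

`equihap run` executes the whole chain (profiles → motifs →
classification → haplotype network → AMOVA/χ²/Φ<sub>ST</sub>/Nm →
frequency table → PCA) and writes a manifest with a SHA-256 hash per
artifact; reruns with the same inputs and seed are byte-identical.

## Layout

```
src/equihap/
  window.py     reference window, variant calling, Hamming distance
  motifs.py     motif inference and (near-)matching classification
  network.py    minimum-spanning haplotype networks, F%, ancestral ranking
  popgen.py     diversity, AMOVA, Phi_ST, Nm, chi-squared cohort tests
  pca.py        frequency tables and PCA (packaged world table in data/)
  simulate.py   synthetic haplogroup-structured datasets
  pipeline.py   end-to-end orchestration with hashed manifests
  cli.py        click-based command line (`equihap`)
docs/methods.md  models, conventions, parameter defaults, limitations
```
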