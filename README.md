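# ligandscape

Quantitative analysis of HLA class I immunopeptidomes from SILAC
experiments: which presented peptides does an ER aminopeptidase (such as
ERAP2) destroy, which does it create, and which sequence submotifs do
those peptides share?

The package is written for immunopeptidomics analysts who have a peptide
quantification table (heavy = peptidase-proficient WT, light = knockout)
from an MS search engine and want the downstream statistics:

1. **Quality filtering** — drop records with disqualifying search-engine
   flags (`InconsistentlyLabeled`, `NoQuanValues`, `Redundant`,
   `IndistinguishableChannels`) and peptides outside the 8–11-mer window;
   replicate overlap as Jaccard similarity.
2. **Moderated differential abundance** — per peptide, replicate ratios
   x = log2(KO/WT) are tested with an empirical-Bayes moderated t:
   the sample variance s² (d residual df) is shrunk toward a prior
   (d0, s0²) fitted to all peptides by the moments method on log s²,
   giving s̃² = (d0·s0² + d·s²)/(d0 + d) and t = x̄ / √(s̃²/n) on d + d0
   df. FDR calibration uses Storey q-values (smoothed π0). Peptides with
   q < 0.01 are classified **sensitive** (log2FC > 0: destroyed by the
   peptidase, enriched in KO) or **dependent** (log2FC < 0).
3. **Motif deconvolution** — mixed ligand sets (cross-reactive
   immunopurification) are split into motif clusters by annealed Gibbs
   sampling over PSSM mixtures with an inter-cluster similarity penalty
   λ, solutions per cluster number, and a trash class for outliers.
4. **Allele models and binding scores** — PSSMs with log-odds
   log2((c+βb)/(n+β)/b); the binding score of a peptide is the
   percentile rank of its summed log-odds in a seeded background
   population (scores in [0,1]; > 0.6 good, > 0.8 strong binder).
5. **Submotif landscapes** — pairwise peptide distances
   d(a,b) = Σ_p w_p·R[a_p,b_p] with a BLOSUM62-derived residue
   dissimilarity R and entropy weights w_p = 1 − H_p/log2(20); 2-D
   non-metric MDS (Kruskal stress-1, 10 ordinations, least stress kept);
   DBSCAN at the k-distance elbow.
6. **Enrichment statistics** — per-position per-residue exact Fisher
   tests (Bonferroni × 20), χ² for sensitive/dependent balance per
   cluster (Bonferroni × clusters), GRAVY (Kyte–Doolittle), and
   Kruskal–Wallis with Dunn post-hoc comparisons.

A first-class synthetic-data module generates SILAC peptidomes with known
allele motifs, planted submotifs and planted effect classes, so every
stage is testable against ground truth without any download.

## Worked example

The numbered scripts under `analysis/` run the full story on synthetic
data; outputs land in `results/analysis/`.

```bash
python analysis/01_simulate_experiment.py
python analysis/02_filter_quantify.py
python analysis/03_differential_abundance.py
```

`01` simulates 5,000 9-mers from an A29-like motif (2 replicates,
planted: 500 sensitive at +1.5 log2 units, 500 dependent at −1.5,
Gaussian ratio noise sd 0.4, 5% flagged records). `02` keeps 9,487 of
10,000 records (the rest removed per flag) and reports a replicate
Jaccard similarity of 0.903. `03` then prints:

```
tested 4501 peptides with >= 2 replicate ratios
variance prior: d0 = 13.31, s0^2 = 0.1436; pi0 = 0.664
calls at q<0.01: {'sensitive': 434, 'dependent': 439, 'unaffected': 3628}
realized false-discovery proportion among calls: 0.0046
fraction of planted effects recovered: 0.966
```

meaning: the moderated test called 873 peptides at 1% FDR, 0.46% of the
calls were actually null (the FDR held), and 96.6% of the planted effects
were recovered. The remaining scripts deconvolute a two-allele mixture
(`04`, adjusted Rand index 1.000 against the planted families), map the
submotif landscape of a single allele (`05`, both planted submotifs —
P2-F/Y and P7-L — recovered as 100%-pure DBSCAN clusters), compute the
positional and cluster enrichment statistics (`06`, e.g. P7-L in
sensitive peptides at Padj = 1.3e-89), and screen a synthetic proteome
for allele-restricted 9-mers (`07`).

The same stages are scriptable through one config:

```bash
ligandscape run-all --config config.yaml --seed 1 --outdir out/
```

with a YAML config holding either a `synthetic:` block or `inputs:`
paths (quantification TSV, FASTA, per-allele training sets); see
`ligandscape.pipeline.normalize_config` for all fields and defaults.

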