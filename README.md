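# cofracnet

Inference of protein–protein interaction networks from co-fractionation mass
spectrometry (CF-MS), built around the two-cell-state design used to map the
human mitochondrial interactome of NTera2 embryonal carcinoma stem cells
(ECSCs) and their retinoic-acid-differentiated neuronal-like cells (DNLCs):
mitochondrial extracts are separated by size-exclusion (SEC) and ion-exchange
(IEC) chromatography in duplicate, proteins in the same complex co-elute, and
the pairwise co-elution evidence is integrated into per-state networks whose
differences expose interaction rewiring during neuronal differentiation.

The package is organised as an analysis project: every computation lives in
the library under `src/cofracnet/`, and the numbered scripts under
`analysis/` drive the simulated study end to end, writing their tables to
`results/`. Because the pipeline is exercised on synthetic elution profiles
with planted ground truth, every stage can be benchmarked against a known
answer.

## The method

For each state and technique, proteins passing the ≥ 2-distinct-peptide
filter are scored pairwise on replicate-concatenated elution profiles with
three complementary measures:

* **PCC** — Pearson correlation of the two profiles;
* **WCC** — weighted cross-correlation,
  `max over |s| ≤ S of (1 − |s|/(S+1)) · cos(x, shift(y, s))`, tolerant of
  small elution offsets (default `S = 2`);
* **co-apex** — the fraction of experiments in which both proteins peak in
  the same fraction.

Each (technique, metric) evidence source is converted to a log-likelihood
score against a reference complex catalog (CORUM-like):

    LLS(bin) = ln [ (pos_bin / neg_bin) / (pos_total / neg_total) ]

with equal-frequency bins over the positive score range and a pseudocount
keeping every bin finite. A pair's **ΣLLS** is the sum over its available
evidence; the per-state static network retains pairs above a stringent
cutoff chosen on the ROC against the reference (AUC-reported, 5-fold
cross-validated at the complex level). The **differential (DF) network**
scores each pair by `FC = ΣLLS_DNLC / ΣLLS_ECSC`; log2 FC is standardised
over all scored pairs and an edge is called rewired when `|Z| ≥ 1.96`
(two-sided p ≤ 0.05) and `FC ≥ 2` or `≤ 1/2`. Complexes are discovered with
Markov clustering, ClusterONE-style cohesiveness growth
(`f(S) = w_in / (w_in + w_bound + penalty)`) and a core-attachment method,
and matched to the reference by the overlap score
`ω(A,B) = |A∩B|² / (|A|·|B|)` at the conventional ω ≥ 0.25. Phosphosites
are retained when the localization Ascore is ≥ 13 (≈ 95% confidence,
`confidence = 1 − 10^(−Ascore/10)`) and the site is detected in ≥ 2 of 3
replicates or is a known site.

## Worked example

```sh
python analysis/01_simulate_study.py    # 50 complexes, 200 background, 20% rewired
python analysis/02_score_pairs.py
python analysis/03_integrate_networks.py
python analysis/04_differential_network.py
python analysis/05_discover_complexes.py
```

On the default study (seed 0) step 03 prints

```
state    auc  cv_auc_min  cv_auc_max  threshold  edges top20_cocomplex_p bottom20_cocomplex_p
 ECSC 0.9990      0.9958         1.0     -0.205   2369                 0                    1
 DNLC 0.9981      0.9962         1.0     -5.164   2469                 0                    1
```

i.e. ΣLLS separates planted co-complex pairs from catalog negatives almost
perfectly (held-out AUC ≥ 0.996 in every fold), and the top 20th ΣLLS
percentile is overwhelmingly co-complex while the bottom is not. Step 04
reports that 69 of the 72 planted rewired pairs fall in the significant,
≥ 2-fold tails of the DF network, and step 05 shows all three clustering
algorithms recovering ≥ 45 of the 50 planted complexes at ω ≥ 0.25, with
within-complex interaction profiles far more correlated (mean r = 0.91)
than between-complex ones (r = −0.01).

A `cofracnet` console command exposes the same stages
(`simulate`, `score`, `integrate`, `differential`, `complexes`, `enrich`)
for use on external TSV matrices and GMT catalogs.

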