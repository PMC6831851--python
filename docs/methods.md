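# Methods

## Scope and model

`cofracnet` implements the inference chain of a two-state co-fractionation
MS (CF-MS) interactome study: pairwise elution-profile scoring per
separation technique, naive-additive log-likelihood integration against a
reference complex catalog, ROC-based network thresholding with complex-level
cross-validation, a differential network with Z/fold-change rewiring calls,
three complex-discovery algorithms with ω-based benchmarking,
hypergeometric/BH enrichment statistics, and phosphosite retention rules.
All stages run end to end on synthetic elution profiles with planted ground
truth, so recovery can be measured exactly.

## Synthetic elution model

The generator starts at the protein × fraction distinct-peptide-count
matrix — the representation CF-MS pipelines work from after peptide-spectrum
matching — and emulates the study design: two cell states, SEC and IEC
separations, duplicate replicates. Defaults (fixed as the study conditions
for all tests and the acceptance run): 50 planted complexes with uniform
sizes 2–10, 200 background monomer proteins, 20% of complexes rewired
between states, SEC = 80 and IEC = 95 fractions per replicate.

* **Apexes.** Each complex receives one apex fraction per technique. SEC
  apexes are evenly spaced in order of decreasing summed member mass (a
  log-normal per-protein mass proxy), encoding that larger assemblies elute
  earlier; IEC apexes are drawn uniformly *without replacement*, since
  assemblies of different composition carry different net charge and
  resolve into different fractions. Apex layouts are replicate- and
  state-independent: replicates of one experiment share their signal, and a
  one-member rewiring edit does not displace the elution of unrelated
  complexes (an early rank-based layout did exactly that, smearing spurious
  differential co-elution over the whole matrix).
* **Peaks and counts.** Every member elutes as a discretized Gaussian
  (s.d. 1.0 fraction) around its complex apex with a per-protein log-normal
  amplitude (median 30 counts); observed counts are Poisson draws around
  the intensity with a per-(protein, replicate) log-normal amplitude jitter
  (s.d. 0.25, the count-dispersion knob). The 1.0-fraction peak width is
  chosen so that 50 assemblies are chromatographically resolvable in 80–95
  fractions, mirroring the premise that distinct complexes separate across
  the collected gradient.
* **Monomers, dropout, rewiring.** Background proteins (and members
  removed by rewiring) elute as independent monomer peaks; complex members
  additionally carry a half-amplitude monomer peak with probability 0.1 (a
  partially unassembled pool). Dropout zeroes a protein's whole row in a
  replicate with probability 0.05, exercising the both-replicates
  co-detection rule downstream. Rewiring edits a selected complex in the
  second state by removing one member (size > 2) or swapping one member for
  an unused background protein; `rewired_pairs` is recomputed as the exact
  symmetric difference of co-complex pairs between states.

What the generator does **not** emulate: peptide-level identification noise,
correlated contamination across neighbouring fractions, abundance-dependent
detection efficiency, shared subunits between complexes (planted complexes
are disjoint), and technique-specific peak asymmetry. Passing tests
therefore demonstrate correctness of the inference machinery under a clean,
resolvable co-elution signal — not performance on real chromatograms, where
score distributions are broader and reference catalogs are incomplete.

## Scoring

Cells with fewer than 2 distinct peptides are zeroed and proteins detected
in fewer than 2 fractions are dropped (a one-fraction profile has no
co-elution information). A pair is scored for a technique only if both
proteins survive in **both** replicates; PCC and WCC are computed on
replicate-concatenated profiles — WCC shifts never cross the replicate
boundary — and co-apex across the technique's replicate experiments, with
apex ties broken to the earliest fraction. WCC uses
`w(s) = 1 − |s|/(max_shift+1)` with default `max_shift = 2` and negative
values floored at 0. Undefined scores (zero variance, never co-detected)
are recorded as missing, never as 0.

## LLS integration

`LLS(bin) = ln[((pos_b + c)/(neg_b + c)) / (pos_tot/neg_tot)]` with
pseudocount `c = 1` on the bin counts and the prior odds from raw totals.
Bins are equal-frequency (default 10) over the **positive** reference
scores: negatives outnumber positives by orders of magnitude, so pooled
quantiles would spend every bin on the noise region and collapse all
informative scores into one bin; anchoring the bins on the positives puts
resolution where evidence discriminates. Reference positives are co-complex
pairs of the catalog restricted to the scored universe; negatives are
catalog proteins that never share a complex. ΣLLS is the sum over available
evidence; missing evidence contributes 0.

Thresholding reports the ROC AUC over the labeled pairs and either imposes
a fixed cutoff (default 1.45, the stringent published-scale threshold,
read as *retain ΣLLS > 1.45*) or maximises Youden's J, nudged strictly
below the chosen ROC threshold so the network invariant "every edge has
ΣLLS > threshold" holds with inclusive ROC semantics. Cross-validation
splits at the **complex** level (all pairs of a complex share a fold;
negatives are assigned uniformly) because co-complex pairs are exchangeable
within a complex and pair-level splits leak.

## Differential network

`FC = ΣLLS_DNLC / ΣLLS_ECSC` over **all scored pairs**; the Z null is the
empirical mean/sd of log2 FC across the scored data (no robust estimator,
matching the two-standard-deviations rule). A missing or nonpositive state
score is replaced by a small positive floor (default: the minimum positive
ΣLLS among the compared pairs); a pair with no positive evidence in either
state sits at FC = 1. Restricting the domain to thresholded network edges
was tried and rejected: it packs the distribution tails with
one-technique coincidental co-eluters and inflates the sd until genuine
rewiring is no longer two sd from the mean. Significant edges
(|Z| ≥ 1.96) with FC ≥ 2 (≤ 1/2) are labeled DNLC- (ECSC-) specific;
significance gates the label.

## Complex discovery

* **MCL**: dense column-stochastic iteration (self-loops 1.0, expansion 2,
  inflation 2.0, prune 1e−6) to a 1e−8 fixed point; clusters are attractor
  rows, overlapping ones merged; non-convergence raises with the residual
  trace.
* **Cohesiveness growth**: seeds in decreasing weighted-degree order
  (lexicographic ties), single best add/remove move while
  `f(S) = w_in/(w_in + w_bound + penalty)` strictly improves (penalty 2),
  grown sets merged at ω ≥ 0.8 to a fixed point.
* **Core-attachment**: cores grown greedily from the heaviest untouched
  edge while induced unweighted density stays ≥ 0.7; outside proteins
  adjacent to ≥ 0.5 of a core's members attach.

All three are deterministic; minimum complex size is 2 (heterodimers are
legitimate). Predictions are matched to the reference by maximum ω;
recovery uses ω ≥ 0.25. The per-algorithm selection p-value is a
hypergeometric over the pooled predictions of all algorithms (population =
all predictions, successes = all recovered, draws = this algorithm's
predictions): "recovered vs total" admits several populations, and pooling
makes the comparison a proper enrichment among peers. Ties break by
recovery rate, then name.

## Enrichment and phosphosites

Hypergeometric tests are upper-tail only (the analyses never test
depletion); BH step-up q-values are order-preserving. Marker assignment
gives each entity the minimum-p marker class if p ≤ 1 − confidence
(default 95%). Ascore follows the −10·log10(p) convention
(`confidence = 1 − 10^(−A/10)`); the integer threshold for a confidence
level is reported to the nearest integer, under which 95% ↔ 13. Retention
in a state requires Ascore ≥ 13 **and** detection in ≥ 2 of that state's 3
replicates, or a known site with ≥ 1 detection — a catalog entry alone,
with no detection in the state, is not called in that state. Retained
sites partition exactly into state-specific and shared sets with per-residue
(pS/pT/pY) tallies.

## Numerical and interface choices

Pairs are unordered, serialized lexicographically; writers sort output so
identical inputs give byte-identical files; readers reject structural
errors (duplicate ids, negative or malformed counts) rather than repairing
them. All randomness flows through numpy Generators keyed by named,
CRC-derived substreams of one base seed, so every artifact is reproducible
bit for bit from (seed, parameters). Simulation sizes used throughout the
tests and the acceptance run — 50 complexes, ~480 proteins, 4 experiments
per state — complete the full pipeline in well under a minute on one CPU.

## Known limitations

The reference catalog used for LLS fitting on simulated data is the planted
truth itself (as CORUM is for the real study); with an incomplete or biased
catalog the LLS calibration degrades gracefully but the reported AUCs do
not account for catalog error. The additive ΣLLS treats the three metrics
per technique as independent evidence although they are strongly
correlated; this over-counts confidence for pairs that co-elute in a single
technique, which is why the differential null is computed over all scored
pairs. Monomer-apex collisions between background proteins can produce
spurious edges near the threshold; they affect network precision against
the full universe, not against the catalog-labeled reference.
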