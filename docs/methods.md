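# Methods

## The model the generator implements

The simulator emulates a selfing metapopulation sampled in geographic
clusters. Its statistical core is the drift-covariance model that the
differentiation scan assumes:

* **Population tree → Ω.** A random bifurcating ultrametric tree over the
  P populations is drawn with join heights uniform on (0, `tree_depth`).
  Ω[i,j] is the branch length shared by tips i and j from the root, so
  diag(Ω) = `tree_depth` and Ω is positive definite. `tree_depth` is in
  variance units of the scaled frequency deviation (an F_ST-like scale);
  the default 0.1 represents strong but not extreme differentiation among
  island populations.
* **Allele frequencies.** Per SNV, the ancestral frequency is
  π ~ U(0.05, 0.95) and the population vector is
  p = π·1 + sqrt(π(1−π))·MVN(0, Ω), clipped to [0.001, 0.999]. Clipping
  (rather than redrawing) keeps draws O(1); the induced bias is only
  appreciable when π is near the interval ends.
* **Adaptive loci.** A planted locus coupled to covariate z (standardized
  across populations) has mean logistic(logit(π) + β·z) per population,
  with β = `adaptive_effect` (default 1.5) a logit-slope per covariate SD.
* **Environment.** Covariates are drawn once per population from a
  multivariate normal with the configured correlation target (default: a
  single altitude-gradient factor making elevation and the two
  temperatures near-collinear, |r| ≳ 0.95) and are **constant within a
  population** — the analysis operates on cluster-level covariate means,
  so within-cluster environmental variation is deliberately ignored.
* **Genotypes.** Each sample draws one founder allele per SNV (selfing:
  homozygous), with a fraction 1 − `selfing_rate` (default 0.5%) of calls
  emitted heterozygous. Depth is Poisson(27); PLs come from the standard
  diploid binomial likelihood with 1% base error. Site annotations pass
  the QC filters except a configurable fraction (default 5%) that draw one
  deliberately failing annotation; these feed the filter tests.
* **Hyper-divergent blocks.** Within each block every sample carries one of
  two haplotype classes (each at ~50% frequency); all block SNVs are
  class-defining, and extra class-defining SNVs are inserted at 4× the
  background density, raising windowed π well over four-fold — emulating
  the high-diversity blocks maintained by balancing selection in selfing
  Caenorhabditis.

What the generator does **not** emulate: recombination and background LD
(blocks and finite sampling are the only LD sources), migration beyond the
tree-shaped covariance, within-cluster environmental gradients, and a
coalescent site-frequency spectrum (see limitations).

## Analysis choices

* **Polarization.** PL triplets give the log10 likelihood ratio between the
  homozygotes as (PL_alt − PL_ref)/10; |LLR| > 2 converts a heterozygote to
  the favoured homozygote; missing PL leaves the call unchanged with a
  warning.
* **QC thresholds are boundary-exclusive** exactly as written (DP > 5 keeps
  DP = 6). Per-call depth masking runs before the site-level missingness
  and heterozygosity rules, so those fractions see the post-depth calls.
* **Isotypes.** Concordance = identical non-missing dosages / jointly
  non-missing sites (the denominator is a documented choice). Grouping is
  by connected components: the pairwise >0.9997 rule is not transitive, so
  chains are resolved by transitive closure; each isotype is represented by
  its lexicographically smallest strain.
* **Diversity.** Diploid haplotype convention (n = 2 × samples) even though
  samples are near-homozygous, matching the conventional VCF-based
  computation. Windows start at position 1 per chromosome; the terminal
  partial window uses its true length as denominator. Tajima's D uses the
  1989 constants with n taken as the median haplotype count over
  segregating sites in the window; windows with S = 0, or n < 4, are NaN.
* **Spatial clustering** is average-linkage on haversine distances
  (spherical Earth, R = 6,371 km; ellipsoidal corrections ≤ 0.5% are
  irrelevant at a 3 km cut), with labels canonicalized by minimum sample
  id so they are order-stable.
* **Fisher's exact test** uses the minlike two-sided rule (sum of all
  tables no more probable than the observed); odds ratios are sample ORs
  with Haldane's 0.5 correction on zero cells. Dunn's z uses the
  tie-corrected rank variance; Bonferroni multiplies within one variable's
  family of pairwise comparisons.
* **LD pruning** follows the plink windowed scheme: within each 50-marker
  window any pair with dosage r² above the cut loses its lower-MAF member
  (ties → later position), then the window advances by `step`. The removal
  rule is underdetermined by common usage; this one is fixed and the
  retained set is verified against an exhaustive post-check in tests.
  The PCA marker set uses (50, 10, r² 0.1); the GEA set (50, 1, r² 0.8,
  MAF ≥ 0.1).
* **PCA** normalizes by sqrt(2p̂(1−p̂)), drops monomorphic markers, and
  tests eigenvalues with the Tracy–Widom statistic using the
  moment-matched effective marker count; the TW1 tail is evaluated through
  a shifted-gamma approximation (accurate to ~1e-2 in CDF). Outlier
  iterations remove samples > 6 SD along any of the top 10 PCs
  (smartpca-like defaults). PC signs are canonicalized (largest-magnitude
  loading positive).
* **Ω estimation** replaces MCMC with a moment estimator: Ω̂ is the average
  of a aᵀ over a random SNV subset (default 5,000), shrunk toward its
  diagonal by the smallest weight that brings the condition number to
  ≤ 1e6. Because the ancestral frequency is estimated by the
  weighted cross-population mean, the deviation vectors lie in a
  (P−1)-dimensional subspace and the neutral XtX mean is ≈ P−1 to P; the
  calibration tests bound it within 10% of P. Ω̂ also absorbs the binomial
  sampling noise of finite cluster sizes — the scan statistics remain
  calibrated because the same Ω̂ whitens the same deviations.
* **Bayes factors** use the conjugate Zellner g-prior with g = P after
  whitening both the deviation vector and the standardized covariate by
  chol(Ω̂): BF = (1+g)^(−1/2)·(1 − g/(1+g)·R²)^(−P/2), reported in
  decibans. "BF > 20" is read as 20 dB (BF > 100, the decisive cutoff).
* **LMM GWA** estimates the variance ratio once per chromosome by REML on
  the eigendecomposed intercept-only model (log10 grid [−5, 5], 101
  points, golden-section refinement), then applies per-marker GLS Wald
  tests (t, n − 2 df) with the LOCO kinship. With K = I this reduces
  exactly to per-marker OLS. Phenotypes are per-isotype environmental
  values. Significance is 0.05 / Meff with the Li–Ji rule on the marker
  correlation eigenvalues (eigenvalues rounded to 10 decimals before the
  floor step, which is discontinuous at integers).
* **Regions.** "Within 1 kb" is inclusive (gap ≤ 1000 bp). The 150-marker
  flank counts *tested* markers. XtX regions are built with the same
  gap/flank algorithm from the top-0.1% markers. Overlap is ≥ 1 bp
  (bedtools semantics), coordinates are 1-based inclusive internally and
  0-based half-open in BED export (round-trip lossless).

## Problem sizes

The default simulation — 13 populations × 11 samples, 20,000 SNVs on six
1-Mb chromosomes, 20 planted loci at logit-effect 1.5, six 20-kb
hyper-divergent blocks — is the configuration all calibration and
end-to-end numbers refer to. Null calibrations use 20,000 neutral SNVs
(XtX, BF) and 5,000 markers (LMM uniformity); Ω recovery uses 10,000 SNVs;
the consensus study averages 20 seeds.

## Known limitations

* **Site-frequency spectrum.** Truncating π to [0.05, 0.95] removes rare
  variants entirely, so genome-wide Tajima's D on simulated data is
  strongly positive by construction (every site has high pairwise
  diversity relative to S/a1). The D implementation is validated against
  an independent reimplementation on arbitrary genotype configurations,
  but the generator cannot produce the near-zero genome-wide D of a
  neutral coalescent sample. Passing tests therefore validate the D
  computation, not coalescent realism of the simulated spectrum.
* **Region-level false discoveries at desk scale.** With 20,000 markers a
  ±150-marker flank makes each region ~1.5% of the marker space; the
  top-0.1% XtX track alone covers a substantial genome fraction, so chance
  triple overlaps (BayPass ∩ GWA ∩ XtX) are far more common than they
  would be at millions of markers, and spatially structured covariates
  (latitude, longitude) retain residual mixed-model inflation with only 13
  populations even though noise phenotypes are well calibrated. The
  20-seed consensus study reports both the planted-locus recovery and the
  neutral-region rate so this geometry effect is visible rather than
  hidden.
* Clipped (not redrawn) truncation of frequency draws biases deviations at
  extreme π; the Ω recovery tests quantify the consequence (entrywise
  correlation with truth ≥ 0.99 at the default depth).
* The CLI wraps the library thinly; orchestration is single-process by
  design, with provenance carried by the SHA-256 manifest rather than a
  workflow engine.
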