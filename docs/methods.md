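# Methods

## The classification problem

Antioxidant proteins counter damage from reactive oxygen species; verifying
antioxidant activity in vitro is slow, so sequence-based classifiers are used
to triage candidates. The signal exploited here is not the raw sequence but
two per-protein profiles computed from it:

* a **position-specific scoring matrix (PSSM)** — an L×20 matrix of
  substitution log-odds scores from an iterative profile search, encoding
  evolutionary conservation; and
* a **secondary-structure profile** — a per-residue state in {H helix,
  E strand, C coil} plus three state probabilities, as printed in
  PSI-PRED-style `.ss2` files (probability columns ordered C, H, E).

The package consumes these profile files directly; it never runs the
profile-generating tools themselves.

## The 473-feature descriptor

Each protein of length L contributes 473 features in a fixed block order
(positions are 1-based):

1. **Weighted n-grams of the consensus sequence** (1–420). The frequency
   matrix `2^(p[i,n] · bf[n])` exponentiates each PSSM score weighted by the
   background frequency `bf[n]` of residue n; the **consensus sequence**
   takes the row-wise argmax letter (ties to the first letter in the order
   `ARNDCQEGHILKMFPSTWYV`). 1-gram frequencies `O(a)/L` and overlapping
   2-gram frequencies `O(ab)/(L−1)` of that consensus are then rescaled by
   20/420 and 400/420 so the 420 values sum to 1 whenever each raw block
   does.
2. **PSSM column means** (421–440): `f_n = (1/L) Σ_i p[i,n]`, the average
   substitution score toward each residue, A first, V last.
3. **Secondary-structure sequence scores** (441–446), in the order
   (F_H, F_C, F_E, F_Max_H, F_Max_E, F_βαβ): position-weighted state scores
   `F_X = (Σ 1-based positions of X) / (L(L−1))`; longest-run fractions
   `Max_Length / L` for H and E; and the βαβ motif frequency. The **segment
   sequence** collapses maximal H runs to α and E runs to β, dropping coils
   (`EECCCHHHEEECHHHEECCEE → βαβαββ`); βαβ occurrences are counted with
   overlap and divided by L−2.
4. **Probability features** (447–473): the L×3 state-probability matrix is
   split into λ = 8 contiguous row blocks with sizes differing by at most
   one (larger blocks first); each block contributes its three column means
   (C, H, E), followed by the three global column means.

Numerical notes, all deliberate:

* The position scores F_H/F_E/F_C are implemented exactly as defined even
  though their L(L−1) denominator lets an all-coil sequence exceed 0.5
  (F_C = (L+1)/(2(L−1))); the closed form is pinned in tests.
* The denominators of the longest-run and βαβ features are the protein
  length L (and L−2), not the segment-sequence length.
* The local-probability blocks precede the global triple in the vector.
* λ is configurable (`--lambda`); values other than 8 change the descriptor
  length to 446 + 3λ + 3 and are supported but non-standard.
* Background frequencies default to the Robinson–Robinson composition (the
  standard profile-search background) and can be overridden with a 20-value
  file in alphabet order.
* A PSSM or `.ss2` file whose residue string or length disagrees with the
  FASTA record is an error, not a warning: a profile computed for a
  different sequence silently corrupts every block.

## MRMD feature selection

Each feature column `f_i` gets a score `RV_i + DV_i`:

* `RV_i = PCC(f_i, c)`, the Pearson correlation with the 0/1 label vector
  (signed as defined; `--abs-relevance` gives the |PCC| variant; constant
  columns score 0);
* `DV_i = (1/M) Σ_j ED(f_i, f_j)`, the mean Euclidean distance from column
  i to all M feature columns (the self term contributes 0). The distance
  sum runs over the M feature vectors and is divided by M — that is the
  only reading under which the quantity is a mean over the objects it is
  defined on.

Columns are min-max scaled to [0, 1] before scoring by default
(`--no-normalize` disables); without it the distance term is dominated by
feature scale, and with it the scores are invariant to per-feature affine
rescaling (a tested property). Features are sorted by descending score,
ties broken by original index.

The optimal subset is the best prefix of that ranking: prefixes
[f′1], [f′1,f′2], … are each scored by pooling stratified k-fold (default
k = 10) held-out predictions of a 100-tree random forest (unlimited depth,
√M feature subsampling, seed 1) and computing F1 (configurable to
accuracy or MCC) on the pooled confusion counts; the best value wins,
smallest prefix on ties. `max_subset_size` caps the largest prefix
examined, which is how large runs are kept tractable; k-fold rather than
leave-one-out is used here because the search evaluates up to M prefixes.

## SVM, tuning, and evaluation

The classifier is an RBF-kernel SVM. The hyperparameter grid enumerates
log2 C from −5 to 15 in steps of 0.5 and log2 γ from 3 down to −15 in steps
of −0.5 (41 × 37 = 1517 pairs), scored by F1 under the jackknife
(leave-one-out) test; ties go to smaller C, then larger γ. The full score
surface is returned for audit. Class imbalance can be countered with
per-class penalty multipliers on C (e.g. negative:positive = 1:6).

Evaluation metrics from the pooled held-out confusion counts:
Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc, F1 (harmonic precision–recall mean)
and MCC; any metric with a zero denominator returns 0 so reports stay
total. AUC is the rank statistic — the probability that a random positive
outscores a random negative, ties counted half — computed on the pooled
held-out decision values (no probability calibration); the ROC curve is the
threshold sweep plotted as (1−Sp, Sn).

By default the pipeline fits selection once on the full table and then
jackknifes the final model on the chosen columns — the conventional
protocol for this method family, which leaks selection information into the
reported numbers. `nested=True` re-runs ranking, prefix search and tuning
inside every leave-one-out fold; it is the honest but far more expensive
variant, and the report records which protocol produced it.

## Synthetic study conditions

The generator emulates the two profile types so the whole pipeline is
testable without external tools:

* sequences drawn from the Robinson–Robinson composition, lengths uniform
  on [50, 120];
* PSSM scores: integer-rounded Gaussians (sd 2.5) clipped to the typical
  log-odds range [−8, 12], mean −1 off-diagonal and +3 on the column
  matching the sequence residue; positives get their means shifted by
  `effect_size` (default 4) on five designated columns;
* states from a 3-state Markov chain with realistic run persistence;
  positives' transition rows are mixed toward helix by `ss_bias`
  (default 0.3);
* probabilities rounded to three decimals with the sampled state always
  maximal, mimicking the file format's rounding.

The default 10 positives / 60 negatives preset keeps the 1:6 class
imbalance of the curated antioxidant benchmark this method family is
trained on, at a size where a full jackknife is cheap. Every protein is
generated from its own `(seed, label, index)` random stream, so datasets
are order-independent and byte-reproducible; at `effect_size = 0` and
`ss_bias = 0` the two classes share identical generating parameters.

What the generator does **not** emulate: real antioxidant sequence motifs,
homology structure between proteins, database-dependent PSSM pseudo-counts,
or redundancy filtering. Passing the recovery tests therefore shows that
the pipeline detects and localizes class-dependent profile signal under the
stated noise — not that it reproduces real-data benchmark accuracy.

## Problem sizes and known limitations

* Tests and the acceptance script run the preset at 70 samples, cap the
  prefix search at 48 features with 5-fold evaluation, and tune on a
  16-pair sub-grid; these are the package's default desk-scale settings —
  the full 1517-pair grid under full jackknife remains available and is the
  documented default of `grid_search` itself.
* Pooled leave-one-out AUC is pessimistically biased on signal-free data
  with imbalanced classes (excluding a rare positive shifts that fold's
  model, anti-correlating held-out scores with labels); the null-condition
  checks use the mean over several seeds and a wide band for this reason.
* `grid_search` under full jackknife costs O(N × 1517) SVM fits; use
  `folds` for anything beyond a few hundred samples.
* Feature extraction is exact arithmetic on small matrices; no tolerance
  parameters exist outside the tests' own comparisons (oracle equivalence
  at 1e−9, Mann–Whitney identity at 1e−12).
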