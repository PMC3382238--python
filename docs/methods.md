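# Methods

`amylostretch` predicts amyloidogenic (fibril-forming) residues in protein
sequences from their *context*: instead of scoring short hexapeptides in
isolation, every residue is judged on the 27-residue window centered on it,
because the fibril-forming ability of a short stretch depends cooperatively
on the stretches 6–10 residues away on either side. Two engines implement
this idea and can be combined:

1. a coarse-grained **β-strand–turn–β-strand energy model** scored directly
   on the window sequence, and
2. a **feature-selection + classification pipeline** (mRMR ranking,
   incremental feature selection, nearest-neighbor or random-forest
   classifiers, jackknife evaluation) over per-residue sequence descriptors,
   optionally augmented with the energy.

## Residue windows

A protein of length *n* yields exactly *n* windows of length `2j+1`
(default flank `j = 13`, window 27; configurable 2–15 to scan window sizes
5–31). Windows at the termini are padded with the unknown symbol `X` rather
than truncated, so per-residue prediction is total. `X` is given neutral
behavior everywhere: the mean over the 20 amino acids in the energy tables,
and the per-attribute dataset mean in feature providers. All coordinates in
APIs and output files are 1-based and inclusive.

## The motif energy model

A window is threaded onto two 6-residue β-strands (A and B) joined by a
flexible turn of 0–15 residues, in parallel or antiparallel registration.
For a 27-residue window this admits 136 placements per orientation
(Σ<sub>L=0..15</sub>(16−L)); all are scored and the minimum total is
assigned to the window:

    E = E_inter + E_intra + E_desol

* **E_inter** — stacking against the adjacent, identical chain in the
  fibril: amyloid chains stack in register, so residue *i* of one chain
  contacts residue *i* of the next, and the term is the sum of the diagonal
  (self-contact) energies e(r, r) over the 12 strand residues. One adjacent
  chain is counted (no factor of two).
* **E_intra** — cross-strand contacts between A and B within the chain. The
  contact set is the standard β-arch geometry: the 6 facing pairs plus one
  diagonal per rung, 11 terms (antiparallel: (a_i, b_{7−i}) and
  (a_i, b_{6−i}); parallel: (a_i, b_i) and (a_i, b_{i+1})). The set is
  injectable through the config for experimentation.
* **E_desol** — desolvation penalty for burying side chains at the
  sheet–sheet interface, summed over the residues selected by the buried
  rule (default: all 12 strand residues; an alternating inward-face rule is
  available). The 20 per-residue penalties are fixed constants of the
  method (Gly 0, Ala 30, Val −16, Ile 9, Leu 33, Ser 8, Thr −3, Asp 50,
  Asn 44, Glu 44, Gln 36, Lys 50, Arg 50, Cys 50, Met 34, Phe −5, Tyr 6,
  Trp 20, His 20, Pro 0); the low/negative values single out V, F, T, I as
  the residues cheap to bury. Re-optimizing them is a non-goal.

A residue is called amyloidogenic when its window minimum is **strictly**
below the cutoff, default **−54.0** (a tie at exactly −54.0 is negative).
Ties between equal-energy placements resolve to the first in the
deterministic enumeration order (linker ascending, start ascending,
parallel before antiparallel). Windows too short to host the motif
(< 12 residues) get a +∞ sentinel and are never called positive.

### Contact table and units

The pairwise contact energies ship as a clearly labelled **synthetic
surrogate** table (`data/contact_energies_synthetic.tsv`): an additive
hydropathy form e(a,b) = −(0.15 + 0.05·(h_a + h_b)) over the Kyte–Doolittle
scale, symmetric, with hydrophobic self-contacts most favorable — the
qualitative structure of knowledge-based contact potentials, not a
published matrix. Any 20×20 symmetric matrix (full or lower-triangle, with
a one-letter header) can be dropped in via `contact_matrix` in the config.

Because the desolvation penalties (−16…50) and the cutoff (−54.0) live on a
~10× coarser scale than typical contact-energy units, every contact term is
multiplied by `contact_scale` (default 10). This calibration was fixed once
at design time so the three terms are commensurate and the cutoff is
discriminative: a poly-Gly 27-mer scores ≈ −25 (not amyloidogenic), a
poly-Val 27-mer ≈ −323 (strongly amyloidogenic), and a random uniform
27-mer ≈ +70. Absolute units are therefore internal to the package; only
orderings and the cutoff crossing carry meaning.

## Featurization

Each window row is encoded position-major: for every window position, each
provider contributes its per-residue attributes for the residue at that
position. The default schema has 34 attributes per residue — 20 PSSM
columns, 5 physicochemical scales (Kyte–Doolittle hydropathy, Zamyatnin
volume, Chou–Fasman β and helix propensities, Grantham polarity; shipped as
package data), 1 disorder score, 3 secondary-structure class scores,
1 solvent accessibility, and 4 conservation attributes — giving
27 × 34 = **918** columns, and **945** after appending one minimized window
energy per position. External predictors (sequence profilers, disorder and
secondary-structure tools) are *not* invoked; their outputs enter through
the tabular provider interface (`protein_id, position, v1..vk` TSV), with
missing entries mean-imputed under a warning. Features are used
unstandardized by default (`zscore_columns` exists for distance-based
classifiers). Column order is a pure function of the flank and provider
list, so rebuilds are bit-identical.

## Feature selection and evaluation

Continuous columns are discretized into three bins at mean ± one population
standard deviation, with inclusive boundaries (so binary columns keep two
states); constant columns collapse to a single bin. Mutual information is
the plug-in estimate from the empirical joint distribution, computed and
reported in bits.

* **MaxRel** sorts features by MI with the label, descending.
* **mRMR** uses the MID (difference) criterion: greedy forward selection
  starting from the MaxRel top, each next feature maximizing
  MI(f; y) − mean<sub>s∈S</sub> MI(f; s). An optional `top_k` truncates the
  O(d²) greedy search and appends the remainder in MaxRel order.
* Ties everywhere break toward the smallest column index, making both
  rankings deterministic and row-order invariant.

**IFS** evaluates the classifier on the first k ranked features for each k
and reports three rates per point — positive-class, negative-class and
overall accuracy (in percent) — choosing the smallest k that attains the
maximum overall accuracy. The "features that increase the accuracy" along
the curve are exposed as `improving_ks`, and the selected set can be
summarized as per-window-position counts and per-category enrichment
against the selected/total reference ratio.

Classifiers: 1-nearest-neighbor under Euclidean distance (cosine optional),
with exact distance ties resolved to the smallest training-row index; and a
random forest (500 bootstrap trees, √d features per split, mandatory seed)
wrapped from scikit-learn. No class reweighting is applied by default: with
~8% positive residues the negative rate dominates the overall rate, which
is a property of the task the evaluation intentionally preserves (an
optional balanced mode is out of scope).

**Evaluation** is jackknife (leave-one-out) cross-validation with confusion
counts aggregated over the n rounds. For Euclidean 1-NN the jackknife is
computed exactly via a masked pairwise-distance matrix. A true jackknife of
a 500-tree forest refits the forest n times per curve point, which is not
affordable at thousands of windows on one CPU; for that regime the
evaluator slot accepts a stratified 5-fold evaluator (a grouped jackknife:
every sample still predicted exactly once by a model that never saw it),
and the IFS grid can be capped (`max_k`). Exact LOO remains the default and
is used wherever it is affordable.

## Synthetic data

The generator emulates the structure of a curated fibril-site dataset
without shipping one:

* **Sequences.** Random proteins (default 20 proteins of 80–120 residues,
  uniform composition; SwissProt-like frequencies optional). Positive sites
  are planted as *pairs* of contiguous 6–10 residue stretches from
  {V, I, T, F} separated by a 0–5 residue gap — two plantable β-strands and
  a turn, so a 27-residue window over a site can actually fill both strands
  of the motif and cross the −54 cutoff (a lone 6–10mer never can, since
  the second strand would sit on background sequence). Stretch residues are
  labeled 1; gap residues stay 0. Sites are planted until the labeled
  fraction reaches `positive_fraction` (default 0.08, the class balance of
  curated residue datasets).
* **Features.** All 34 attributes are unit Gaussian noise; `n_informative`
  attributes (default 5: disorder, pssm_C, pssm_H, cons_ppi, ss_strand)
  additionally carry a class-conditional mean shift of `effect_size`
  (default 3) at labeled residues and half that in the two bands 6–9
  residues away, reproducing the three-region contribution pattern
  (center + N-side + C-side) in window space.
* **Toy proteomes.** Plain random sequences (50–300 residues) for the scan
  path.

What passing tests on this data do **not** show: real fibril sites are not
composed purely of V/I/T/F, real descriptors are correlated across
attributes and positions (PSSMs come from alignments, not noise), and the
true operating point of the energy cutoff on experimental data cannot be
validated without the original curated dataset and external predictor
outputs. The synthetic results validate the machinery — recovery of planted
signal, correct accounting, determinism — not clinical accuracy.

## Problem sizes used in the shipped checks

The end-to-end recovery check runs ~2000 windows (20 proteins × ~100
residues), a 945-column matrix, mRMR truncated at 30, and an IFS grid of
k = 1..20 under the 5-fold evaluator with 500-tree forests; the acceptance
script uses the same sizes plus a 30-protein toy-proteome scan. These sizes
were chosen as the smallest at which the planted-signal and null behaviors
separate cleanly.

## Known limitations

* The 11-term cross-strand contact set is a documented geometric choice;
  the engine accepts alternatives but none is fitted to structures here.
* The contact table is a synthetic surrogate; results depend on it only
  through orderings, but any quantitative comparison to fibril
  thermodynamics requires substituting a real statistical potential.
* Whether E_inter should count one or both neighboring chains is a
  convention (one is used); changing it rescales E_inter by 2 and would
  require re-calibrating the cutoff.
* The energy-vs-cutoff classifier is deliberately asymmetric on imbalanced
  data (it optimizes exclusion of false positives); its positive rate on
  real sequences is bounded by how often both strands of a true site fall
  inside one window.
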