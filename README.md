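# amylostretch

Context-dependent prediction of amyloidogenic segments in protein sequences.

Short peptide stretches (classically hexapeptides) can nucleate amyloid
fibril formation, but whether a stretch actually drives its host protein
into fibrils depends on the surrounding sequence. `amylostretch` scores each
residue on the **27-residue window** centered on it, combining two engines:

* a coarse-grained **β-strand–turn–β-strand energy model**: the window is
  threaded onto two six-residue β-strands joined by a flexible turn of up to
  15 residues (parallel or antiparallel), every placement is scored as
  `E = E_inter + E_intra + E_desol` (inter-chain stacking + cross-strand
  contacts + desolvation penalties for buried side chains), and the minimum
  over all placements is assigned to the window. Residues whose window
  energy falls strictly below **−54.0** are called amyloidogenic.
* a **feature pipeline**: windows are encoded as 918 features (34
  per-residue attributes × 27 positions: PSSM, physicochemical scales,
  disorder, secondary structure, accessibility, conservation — all via a
  pluggable provider interface), optionally augmented with 27 per-position
  energies (945 columns); features are ranked by **mRMR** (mutual
  information, MID criterion), and **incremental feature selection** with
  jackknife-evaluated nearest-neighbor or random-forest classifiers finds
  the accuracy-optimal feature set, reporting positive / negative / overall
  accuracy rates.

It is intended for structural bioinformaticians studying aggregation-prone
regions: per-residue profiles of single proteins, proteome-wide "amylome"
scans, and method experiments on the selection pipeline itself.

## Worked example (library)

```python
from amylostretch import default_energy_config, window_energy, classify_energy

cfg = default_energy_config()   # strands of 6, linker <= 15, cutoff -54.0
for name, seg in [
    ("poly-Gly", "G" * 27),
    ("poly-Val", "V" * 27),
    ("VITF pair in background", "QERGVITFVIPNGTFVITFDKQERAGE"),
]:
    e = window_energy(seg, cfg)
    print(name, round(e.total, 1), classify_energy(e, cfg), e.placement)
```

prints (abridged):

```
poly-Gly                 total= -25.3  desol=   0.0  call=0  (start 1, linker 0, parallel)
poly-Val                 total=-323.1  desol=-192.0  call=1  (start 1, linker 0, parallel)
VITF pair in background  total=-142.4  desol= -45.0  call=1  (start 5, linker 3, parallel)
```

Poly-Gly buries nothing (Gly penalty 0) but stays above the cutoff; poly-Val
is dominated by its negative burial penalties; in the third window the
search itself finds the planted geometry — strand A on `VITFVI` (positions
5–10), a 3-residue turn (`PNG`), strand B on `TFVITF` — and calls the
residue amyloidogenic. Windows shorter than 12 residues cannot host the
motif and are never called.

## Worked example (CLI)

```sh
amylostretch simulate -o fixture --seed 5 --n-proteins 6 \
    --length-min 50 --length-max 70
amylostretch featurize fixture/proteins.fasta --labels fixture/labels.tsv \
    --providers-dir fixture/providers --energy -o matrix.tsv
amylostretch select-evaluate matrix.tsv -o selection --classifier rf \
    --n-trees 200 --seed 4 --top-k 15 --max-k 15 --evaluator kfold
amylostretch scan fixture/proteins.fasta -o scan
```

prints:

```
wrote fixture bundle to fixture
wrote 365 x 945 feature matrix to matrix.tsv
best k=3: acc_pos=97.14 acc_neg=100.0 acc_overall=99.73
scanned 6 proteins / 365 residues: 17.81% residues amyloidogenic, 33.33% proteins with >=1 call
```

The six synthetic proteins (365 residues) yield a 945-column matrix; three
mRMR-ranked features already classify the planted sites nearly perfectly
(97% of positive residues, 100% of negatives); the energy-only scan calls
17.8% of residues — the planted strand-turn-strand sites plus their
immediate surroundings — and both a residue-level and a protein-level
percentage are reported because "fraction of amyloidogenic segments" is
ambiguous between the two. `scan/profile.tsv` holds the per-residue energy
breakdown, call, and best placement (1-based positions throughout);
`selection/` holds the MaxRel/mRMR rankings, the IFS curve, and the
position-contribution and category-enrichment tables for the optimal set.

Labels are two-column TSV `protein_id <TAB> 1-based-position` rows listing
positive residues (`0` lists an all-negative protein); externally computed
per-residue features (sequence profiles, disorder, secondary structure)
enter as `protein_id, position, v1..vk` TSVs — no external predictor is ever
invoked by the package.

## Scope notes

The curated experimental fibril-site dataset used to develop the method is
not redistributable and is replaced here by the synthetic generator
(`amylostretch.synthetic_data`); the shipped contact table is a clearly
labelled synthetic surrogate for a published statistical potential and can
be overridden from a plain-text matrix file. See `docs/methods.md` for the
model, its assumptions, parameter defaults, and known limitations.
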