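# archaeotype

Whole-cell MALDI-TOF mass-spectral fingerprinting for archaea, as an open,
tested pipeline.

Halophilic and methanogenic archaea are hard to identify by 16S rRNA genes
alone — haloarchaea in particular carry divergent intragenomic rRNA operon
copies — so identification by intact-protein mass fingerprints is the
practical alternative. A linear-positive-mode spectrum over m/z 2,000–20,000
(singly charged ions, so m/z ≈ molecular mass in Da) is a strain's
fingerprint; matching it against a curated library of reference spectra
identifies the organism in minutes.

`archaeotype` implements that workflow end to end:

- **Preprocessing** — Savitzky–Golay smoothing (width 5 m/z, 1 cycle),
  morphological top-hat baseline correction, robust noise estimation, and
  centroid peak detection (S/N ≥ 3, peak width 5 m/z, at most 100 peaks).
- **Reference spectra (MSPs)** — built from 10–24 replicate acquisitions;
  replicates whose proportion of reproducible peaks is not higher than 0.6
  are rejected, and surviving peaks are merged into per-strain consensus
  peaks carrying mean m/z, mean intensity, and replicate frequency.
- **Identification** — the three-value log score. For candidate *C* and
  reference *R*:

  - *v₁* = fraction of reference peaks with a matching partner in *C*,
  - *v₂* = fraction of candidate peaks with a matching partner in *R*,
  - *v₃* = intensity symmetry of the matched pairs (rank correlation mapped
    to [0, 1]),

  score = log₁₀(1000 · v₁ · v₂ · v₃), at most 3 (= log 1000). Scores of
  2.30–3.00 read as highly probable species identification, 2.00–2.29 as
  secure genus / probable species.
- **Clustering** — MSP dendrograms from distance level
  (1 − s)·1000 with s the symmetrized three-value product, average linkage,
  Newick export, and a strains × m/z-bin "gel view" matrix.
- **Biomarkers** — protein average mass (residue-mass sum + one water, the
  standard pI/Mw convention), database search within a 1% mass window, and
  truncation scans that locate the terminal fragment explaining an
  observed signal. A FASTA of published archaeal biomarker peptides is
  packaged.
- **Synthetic data** — a ground-truthed generator of replicate spectra and
  planted genus/species/strain panels, so every stage is testable without
  proprietary instrument files.

## Worked example

Build a library for ten synthetic strains (two planted genera) and identify
a fresh replicate of one of them (`examples/02_build_library_and_identify.py`):

```
library: 10 reference spectra, 29-30 peaks each

unknown is truly: G1.sp1.st1

rank  strain        score  band
   1  G1.sp1.st1    2.878  highly probable species
   2  G1.sp1.st2    2.814  highly probable species
   3  G1.sp1.st3    2.812  highly probable species
   6  G2.sp1.st1    0.714  not reliable

triplicate re-identification of G1.sp1.st1: 2.815 ± 0.116 (mean ± sample sd over 3 replicates)
```

The unknown's own reference ranks first inside the species band; strains of
the same planted species score close behind (they share 90% of their
peaks), while the other genus collapses to an unreliable score. The other
examples cover peak picking against ground truth, dendrograms/gel views,
and biomarker mass search:

```sh
python examples/01_simulate_and_preprocess.py
python examples/03_dendrogram_and_gel_view.py
python examples/04_biomarker_search.py
```

The same workflow is available from the shell:

```sh
archaeotype simulate --panel 2x1x5 --replicates 10 --seed 7 --out panel/
archaeotype build-msp --replicates panel/G1.sp1.st1 --strain-id G1.sp1.st1 --out lib.json
archaeotype identify --library lib.json --candidate peaks.csv
archaeotype dendrogram --library lib.json --out tree.nwk --gel-view gel.csv
archaeotype biomarker --observed 6148.08 --db proteins.fasta --window 1.0
```

Exit codes: 0 success, 2 configuration error, 3 input error, 4 QC failure.

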