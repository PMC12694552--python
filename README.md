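# milletct

Micro-CT grain-structure phenotyping and QTL mapping for foxtail millet
(*Setaria italica*), built as a fully synthetic, testable re-implementation
of a seed-phenomics study pipeline.

Foxtail millet grains are small (~3 mm³) and structurally complex: a hull
(lemma + palea) encloses an air gap — the *cavity* — around the caryopsis,
which is itself split into embryo and endosperm. These internal traits
matter for water uptake at germination, but they are invisible to surface
imaging. Micro-CT resolves them in 3D; linking the resulting traits to a
biparental RIL (recombinant inbred line) population lets one map the loci
that control grain structure, and intersecting those loci with
differentially expressed genes nominates candidates.

The package implements every stage of that pipeline on synthetic data:

1. **Phantoms & simulation** (`milletct.phantom`, `milletct.popsim`) —
   nested-ellipsoid grain phantoms with voxel-exact ground-truth labels;
   RIL genotypes as a two-state Markov chain (Haldane map function,
   F∞ correction R = 2r/(1+2r)) with planted additive QTLs at a target
   heritability; DEG tables with planted candidates.
2. **Segmentation** (`milletct.segmentation`) — Otsu global threshold,
   per-slice Canny edges as growth barriers, deterministic 3D region
   growing with a running-mean similarity criterion, pooling of regions
   into the four tissues by intensity rank, topology checks, manual-style
   intensity-range overrides.
3. **Morphometry** (`milletct.morphometry`) — the 15 structural traits:
   volumes (mm³) and marching-cubes surface areas (mm²) of whole grain (K),
   embryo (EM), endosperm (EN), cavity (C) and hull (H); mean hull
   thickness H-A-T (µm) via the distance-transform/medial-axis estimator;
   and the four volume ratios (which sum to exactly 1 by construction).
4. **Trait statistics** (`milletct.traitstats`) — min/max/mean/SD,
   CV = 100·SD/mean, bias-corrected skewness G1 / excess kurtosis G2,
   Shapiro–Wilk, and the |skew| < 3 & |kurtosis| < 10 screening rule;
   Pearson correlation matrix with t-test p-values.
5. **QTL mapping** (`milletct.qtl`) — inclusive composite interval mapping
   (ICIM-ADD): stepwise cofactor selection at entry threshold PIN = 0.01,
   then a 1 cM Haley–Knott scan of the cofactor-adjusted phenotype with
   LOD = (n/2)·log₁₀(RSS₀/RSS₁), loci called above LOD 2.5 with 2-LOD-drop
   intervals, PVE and additive effects, and genome-wide permutation
   thresholds.
6. **Candidate genes** (`milletct.candidates`) — DEG thresholding
   (|log₂FC| ≥ 1, p < 0.05) and closed-interval intersection with QTL
   physical intervals.

## Worked example

The `analysis/` scripts run a complete synthetic study (40 RILs imaged at
3 µm, one planted grain-size locus at 50 cM on chromosome 2, seven
candidate genes planted at 19–21 Mb):

```bash
python analysis/01_simulate.py
python analysis/02_segment_and_measure.py
python analysis/03_trait_statistics.py
python analysis/04_qtl_scan.py
python analysis/05_candidate_genes.py
```

Output from one run (seed fixed in `analysis/study_config.py`):

```
per-tissue Dice vs ground truth (5% noise):
   tissue  median_dice  min_dice
   EMBRYO     0.998034  0.996260
ENDOSPERM     0.999724  0.999435
   CAVITY     0.998621  0.998124
     HULL     0.998136  0.997645

called loci (planted locus: chromosome 2, 50 cM = 20 Mb):
 QTL  Chromosome Physical Interval (Mb)   Traits   LOD  PVE (%)   Add
qKV2           2          18.400-21.600 K-Volume 3.744   35.016 0.001

candidate (gene, QTL) pairs: 7
```

Reading: segmentation recovers every tissue at Dice ≥ 0.996 under 5%
noise; the scan calls a single locus, `qKV2`, whose 2-LOD-drop physical
interval (18.4–21.6 Mb) brackets the planted position (20 Mb) and whose
PVE reflects the simulated heritability at n = 40; all 7 planted DEGs fall
inside the interval and are returned as candidates.

The same stages are available as a CLI
(`milletct simulate|segment|traits|stats|qtl|candidates|run`).

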