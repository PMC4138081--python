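# mirforge

Genome-wide microRNA discovery from multi-library small RNA-seq, with the
genomic-context and phylostratigraphic expression analytics used in
invertebrate miRNA surveys — plus a ground-truthed synthetic-data
generator that makes every step of the pipeline testable end to end.

The package is built around the annotation standard used for
deep-sequencing miRNA surveys (here in its oyster-survey form, over a
21-library design of developmental stages and adult organs). A candidate
hairpin precursor is accepted only if it meets six criteria:

1. the precursor sequence maps to a **single genomic locus**;
2. the precursor secondary structure folds with **MFE below
   −21 kcal/mol**;
3. the 5′ ends of the major mapped reads are **consistent** on both arms
   (modal 5′-end fraction ≥ 0.8);
4. mature reads come from **both arms**, with ≥ 50 reads combined over
   all libraries;
5. the two mature sequences share **≥ 16 complementary positions**;
6. the mature is **conserved in widely diverged taxa**, or the duplex
   shows the Dicer-signature **2-nt 3′ overhang** at both ends.

Downstream of discovery the package computes: intronic/intergenic
location classes against gene models; a 79-bp contiguous-window null
model with a Pearson χ² contrast and 0/500/1000/2000-bp flank extension
profiles; 10-kb precursor clusters; guide/star assignment by the >5-fold
read-ratio rule with a 50-read retention floor; RPM expression, CV, and
5×/⅕ specificity screens (with mantle-library merging); seed-anchored
phylostratum assignment (seed 2–8 identical, identity ≥ 0.8); host-gene
co-expression (Pearson r > 0.8, P < 10⁻⁴); and the **miRNA profile age
index**

    miRPAI(stage) = Σᵢ psᵢ·eᵢ / Σᵢ eᵢ ,

the expression-weighted mean phylostratum psᵢ of the miRNAs expressed at
that stage (eᵢ = read count; higher = younger profile).

Secondary structure comes from a built-in nested-pairing dynamic
programme with pair pseudo-energies (G:C −3, A:U −2, G:U −1 kcal/mol,
minimum loop 3); ViennaRNA's RNAfold can be plugged in as an alternative
backend with the identical contract.

## Worked example

The `analysis/` scripts run the whole study on synthetic data with known
ground truth: 40 true precursors (intronic, intergenic and clustered,
with phylostratum-structured expression across the 21 libraries) and 60
decoy hairpins, ten violating each criterion.

```bash
python analysis/01_simulate_study.py   --seed 1
python analysis/02_discover_mirnas.py  --seed 1
python analysis/03_genomic_context.py
python analysis/04_expression_analysis.py --seed 1
```

prints

```
planted 100 precursors (...) and wrote 46964 reads across 21 libraries under scratch/study
46071/46964 reads passed QC; 2650 tags; 1380 retained alignments
accepted 40/40 true precursors; rejected 60/60 decoys (60 with the exact planted criterion recorded)
40 precursors: 14 intragenic (35%) vs 16% of 79-bp windows; chi-square 10.5, P = 1.18e-03
38 precursors (95%) fall in 8 clusters (gap <= 10 kb)
80 matures from accepted precursors; 51 kept for expression analysis (>= 50 reads)
miRPAI peaks at s05.D (5.06): the developmental profile is youngest around mid-development, as designed into the simulator
mean expression CV 0.67; 2 specifically-high and 43 specifically-low calls
```

Reading the numbers: every planted true precursor is recovered and every
decoy is rejected with the correct criterion recorded; accepted
precursors are intragenic far more often than length-matched genome
windows (χ² contrast); the miRPAI curve peaks at the mid-developmental
stage where the generator placed young-miRNA expression; and the two
designed organ markers (mantle and adductor muscle) are the two
specifically-high calls. Tables land under `results/`, intermediate data
under `scratch/study/`.

The same run is available as one command (`mirforge run --seed 1
--outdir out/`), and each stage separately as `mirforge
simulate|qc|map|discover|context|express`.

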