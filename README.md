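# cofkit

Analysis toolkit for CofC/CofD-type guanylyltransferases — the enzymes
that activate a C3 phospho-acid (2-phospho-L-lactate, phosphoenolpyruvate,
or 3-phospho-D-glycerate) with GTP during biosynthesis of the microbial
redox cofactor F420 and its derivative 3PG-F420.

It is written for structural biologists and enzymologists characterizing
substrate specificity in this family, and covers four analyses plus the
synthetic data needed to exercise them end to end:

- **Binding-site geometry** (`cofkit.structgeom`): parse PDB coordinate
  models; enumerate ligand hydrogen bonds on heavy atoms; quantify H-bond
  quality as the *out-of-π-plane distortion* — the distance `|(p − c)·n̂|`
  of the H-bond partner atom `p` from the total-least-squares plane
  (centroid `c`, unit normal `n̂`) of the sp2 group it bonds to
  (carboxylate or peptide amide); build chain-averaged contact tables with
  water/Mg²⁺ bridges; superpose structures by the Kabsch algorithm;
  measure the carboxylate rotation between two ligand poses about the
  axis through the carboxylate oxygens, and the displacement of any group;
  audit metal coordination shells.
- **Diagnostic-residue screening** (`cofkit.alignscreen`): map a reference
  residue number (e.g. the serine whose backbone conformation selects
  3-PG) to its alignment column, classify homologs as 3-PG-tolerant
  (Ser/Thr in that column) or not, and compute Needleman–Wunsch global
  alignments and percent identity.
- **Assay quantification** (`cofkit.assayquant`): the combined CofC/D
  activity assay chain — extracted ion chromatogram (XIC) at a target
  m/z → trapezoidal peak area (AUC) → per-replicate normalization →
  least-squares formation rate over the linear 0–20 min range → relative
  turnover `rᵢ = 100·kᵢ/Σⱼkⱼ` per substrate, with mean ± SD over
  biological replicates.
- **Thermal-shift binding** (`cofkit.dsfbind`): two-state unfolding with
  ligand linkage for nano-DSF melting curves,
  `f_u = 1/(1 + exp(ΔG_app/RT))` with
  `ΔG_app = ΔH_u(1 − T/T_m) + RT ln(1 + [L]/K_D)`, fitted across a ligand
  titration to estimate K_D, plus an RSS feasibility grid over
  (φ, K_D,GTP, K_D,GPPG) for protein that co-purifies with tightly bound
  product.
- **Synthetic data** (`cofkit.synthdata`): seeded generators with
  machine-readable ground truth — toy pockets with planted π-plane
  offsets, ligand-pose pairs at known rotation angles, homolog sets with
  a planted diagnostic column, chromatogram time courses with known
  rates, melting curves with known K_D.

## Worked example

Simulate a competitive triplicate assay in which the enzyme converts
3-PG, 2-PL and PEP at a 65 : 26.5 : 8.5 rate ratio (2 % noise), then run
the full quantification chain:

```sh
$ cofsynth assay --seed 1 --noise-cv 0.02 --out demo
$ cofassay quantify --csv demo/assay.csv
{
  "n_replicates": 3,
  "mean_percent": {
    "2-PL": 26.49,
    "3-PG": 64.94,
    "PEP": 8.57
  },
  "sd_percent": {
    "2-PL": 0.32,
    "3-PG": 0.33,
    "PEP": 0.06
  }
}
```

The pipeline recovers the planted substrate preference: ~65 % of total
turnover goes to 3-PG, with sub-half-point SD across the three
replicates. Geometry works the same way — plant two H-bond donors 0.74 Å
out of the carboxylate plane and measure them back:

```sh
$ cofsynth pocket --seed 3 --offsets 0.74,0.74 --out demo
$ cofgeom hbonds --pdb demo/pocket.pdb --ligand A:CBX:501
{
  "n_hbonds": 2,
  ...
  "average_pi_distortion_A": 0.74
}
```

Both donors are found at 2.9 Å heavy-atom distance and the mean
out-of-π-plane distortion equals the planted 0.74 Å exactly.

The same operations run on real coordinate files
(`cofgeom hbonds --pdb 7p97.pdb --ligand A:<LIG>:<NUM>`), alignments
(`cofscreen map/classify/identity`) and melting-curve CSVs
(`cofdsf fit/grid`).

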