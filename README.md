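# protolra

Ensemble pKa estimation for conformational ensembles, plus GPCR
activation-state geometry metrics.

The package implements the analysis chain used to estimate the macroscopic
pKa of a buried titratable site (e.g. the conserved Asp2.50 of class A
GPCRs) from two fixed-protonation molecular-dynamics ensembles:

1. **titration** — equilibrium protonation of interacting titratable sites
   in a single conformation, from an intrinsic-pKa + pairwise-coupling model
   (exact enumeration over all microstates, or Metropolis Monte Carlo with
   single- and paired-site flips), and per-conformation half-titration
   points (pK_half).
2. **lra** — pooling of per-frame titration curves, the
   Henderson–Hasselbalch transform into pH-dependent ensemble pKa curves,
   the two-endpoint linear-response average of the protonated (P) and
   deprotonated (D) ensembles, the y = x intersection giving the
   macroscopic pKa, delete-one jackknife standard errors, and two-way
   (high/low) splitting of bimodal pK_half series.
3. **geometry** — activation metrics on structures addressed through a
   Ballesteros–Weinstein residue map: TM3–TM6 / TM3–TM7 Cα distances,
   NPxxY backbone RMSD after superposition, the five-distance A100
   activation index with inactive/intermediate/active classification,
   transmission-switch distances, Na⁺-pocket and hydrophobic-lock triangle
   areas (Heron's formula on side-chain centres of mass), side-chain COM
   distances, and chi2 torsions.
4. **synthetic** — generators for conformational-titration ensembles with
   known ground truth (Markov-switching conformational substates, per-frame
   intrinsic-pKa noise, coupled neighbour sites) including an exact
   joint-partition-function oracle, bimodal pK_half time series, and toy
   structures with analytically known geometry.
5. **io / pipeline / cli** — plain-text formats (JSON-lines frames, TSV
   curves and tables, JSON reports, YAML configuration), the end-to-end
   workflow, and the `protolra` command line tool.

## Command line

```bash
# generate a synthetic two-substate system (P/D frame files + ground truth)
protolra simulate --config spec.yaml --seed 1 --out sim/

# per-frame titration curves on the default pH grid (-10..20, step 0.25)
protolra titrate --frames sim/frames_P.jsonl --method exact --out curves/

# per-frame pK_half table, then split it into high/low populations
protolra pkhalf --frames sim/frames_P.jsonl --ensemble P --out pkhalf.tsv
protolra split --series pkhalf.tsv --method kmeans2 --out split.json

# macroscopic pKa with jackknife error (optionally restricted to the
# high-pK_half population of the protonated ensemble)
protolra lra --prot sim/frames_P.jsonl --deprot sim/frames_D.jsonl \
             --population high --out lra_out/

# activation metrics, one row per trajectory frame
protolra metrics --topology top.pdb --trajectory traj.xtc \
                 --bw-map bw.yaml --reference inactive.pdb \
                 --a100-config a100.yaml --out metrics.tsv

# everything from one YAML configuration
protolra run --config run.yaml
```

Frame files are JSON-lines, one object per conformation:

```json
{"frame_id": "P:rep1:0", "replicate": "rep1", "time_ps": 0.0, "ensemble": "P",
 "sites": [{"id": "Asp2.50", "pkint": 7.1, "polarity": "anionic"}],
 "w": [[0, 1, 0.8]]}
```

`w` holds sparse upper-triangle couplings in pK units. The BW map and A100
index configuration are YAML; note that the five A100 distance pairs and
coefficients are receptor calibration data and must be supplied explicitly
(only the classification thresholds, 0 and 55, have defaults).

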