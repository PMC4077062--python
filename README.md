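# ureakit

Structure–function analysis toolkit for urea/H⁺ membrane transporters of
the sodium:solute symporter (SSS) superfamily, built around the fungal
high-affinity urea permease UreA (*Aspergillus nidulans*) as the reference
system.

## Who this is for

Groups dissecting a membrane transporter by combining comparative sequence
analysis, a homology model and radiotracer uptake assays. The toolkit
covers the desk side of that programme:

1. **Conservation-contrast residue prioritization.** Residues important for
   transport should be conserved across functionally characterized
   *orthologues* (urea transporters of other species: ScDUR3, CaDUR3,
   AtDUR3, PiDUR3, OsDUR3) but *not* in within-genome *paralogues* whose
   specificity has diverged. Columns of a labelled alignment are classified
   as `family_conserved`, `orthologue_specific`, `reference_specific` or
   `unconserved`, and candidate residues (the Y106/A110/N275/… tier) are
   read off the `orthologue_specific` set.
2. **Topology annotation.** Reference positions are mapped to membrane
   segments (TMS1–15, loops, the intracellular helix ICH3/4) from a
   topology TSV; a 15-TMS fixture consistent with the published per-residue
   locations ships with the package.
3. **Structural filters** on a supplied 3D model (PDB): Shrake–Rupley
   solvent accessible surface area with a configurable probe (default
   2.0 Å, the cavity-surface probe; 1.4 Å water probe available), relative
   sidechain exposure, sidechain polarity, facing residue pairs across a
   cavity (the Y106–Y437 gate geometry) and salt-bridge detection (the
   R141–E123 interaction).
4. **Uptake kinetics.** Initial rates from time courses (2-min linear
   window), Michaelis–Menten fits (v = V·S/(Km+S)), competitive-inhibition
   IC50 fits (v = V₀/(1+I/IC50)), the Cheng–Prusoff conversion
   Ki = IC50/(1+L/Km), wild-type normalization with deletion-strain
   background subtraction (V%), and censored reporting (">3000 µM") for
   constants beyond the assayed range.
5. **Phenotype classification.** A rule-based decision list combining V%,
   kinetic constants and subcellular localization (membrane vs ER
   retention) into discrete classes: `wt_like`, `transport_null_membrane`,
   `trafficking_defective`, `partial_transport`, `selectivity_altered`,
   `truncation_null`.

A synthetic-data module generates labelled alignments with planted
conservation classes, uptake datasets drawn from the kinetic models at the
study's assay design (0.5–50 µM saturation, 1.0 µM tracer, 0.5–3000 µM
competition, 3 replicates, <20% replicate SD), and toy structures with
analytically known accessibility — so every stage is testable against
exact ground truth without downloads.

## Worked example

Simulate a wild-type saturation assay (Km 26 µM, V 100), fit it, then fit
an acetamide competition series and convert to Ki:

```python
from ureakit.datasets import kinetic_truth_for
from ureakit.synthetic import gen_saturation, gen_competition
from ureakit.kinetics import fit_michaelis_menten, fit_ic50

truth = kinetic_truth_for("wt", seed=42)      # Km=26 µM, Vmax=100, CV 15%
res = fit_michaelis_menten(gen_saturation(truth))
print(res.summary())

comp = fit_ic50(gen_competition(truth, "acetamide"))
print(f"Ki = {comp.ki(truth.Km):.1f} uM")
```

```
Michaelis-Menten saturation fit
===============================
  n observations : 30
  tested range   : 0.5-50 uM
  Km   :      24.68 +/- 2.6 uM
  Vmax :      93.91 +/- 7.02
  residual norm  : 21.86
  converged      : True
  reliable       : True
Ki = 204.0 uM
```

One noisy 30-point assay recovers Km = 24.7 ± 2.6 µM against the
generating 26 µM; the acetamide Ki of 204 µM scatters around the
generating 237 µM (averaging over seeds centres it — see the acceptance
script). The same objects drive the CLI:

```sh
ureakit simulate --out demo --seed 3          # synthetic inputs + truth tables
ureakit conserve --alignment demo/alignment.fasta --groups demo/groups.tsv --out cands.tsv
ureakit kinetics --table demo/saturation_wt.tsv --kind saturation
ureakit classify                              # packaged allele table
ureakit run-all --config pipeline.yaml        # full config-driven pipeline
```

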