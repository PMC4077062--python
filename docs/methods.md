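# Methods

This note records the models, conventions and open design choices behind
each stage, what the synthetic generators do and do not emulate, and the
numerical tolerances in use.

## Conservation-contrast classification

A labelled alignment partitions sequences into one *reference*, ≥1
*orthologues* (transporters with the reference's function in other
species) and *paralogues* (within-genome homologues with diverged
specificity). Columns are mapped to 1-based positions on the ungapped
reference — the numbering residues are named by (Y106, S446) — and
classified by a closed, mutually exclusive decision table:

* `family_conserved`: every orthologue and paralogue matches the reference
  residue;
* `orthologue_specific`: every orthologue matches and the paralogue
  non-conservation predicate holds;
* `reference_specific`: no orthologue matches;
* `unconserved`: everything else.

Matching defaults to strict identity. An optional *similarity* mode treats
the fixed physicochemical groups {ILVM} {FWY} {KRH} {DE} {ST} {NQ} {AG}
{C} {P} as matches, because published alignment shadings often mark
"structurally conserved" columns without defining the criterion. Gaps
never match; a reference-gap column has no reference numbering and is
reported separately rather than classified. The paralogue predicate
defaults to "not all paralogues carry the reference residue"; the stricter
"no paralogue carries it" is available (`paralogue_rule="none"`). These
two choices — identity vs similarity, and the paralogue predicate — are
genuinely open in the source material; the defaults are the most
conservative readings and are configurable everywhere they matter.

## Topology

Topology is consumed, never predicted. Segments are inclusive 1-based
ranges (label, start, end, compartment), validated for inversion and
overlap. The shipped urea-transporter fixture places W82 in TMS2,
Y106/A110 in TMS3, T133/R141 in ICH3/4, A163/G168 in TMS4, N275/D286 in
TMS7, A374/Y388 in TMS9, Y437/S446 in TMS11, W480 at the end of TMS12 and
P639 in the C-terminal region. Only these memberships are constrained by
the published locations; the boundary integers themselves are a package
choice and carry no significance.

## Solvent accessibility and the pathway filter

SASA is Shrake–Rupley: each atom's van der Waals sphere (Bondi radii:
C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å) is inflated by the
probe radius and sampled with a deterministic golden-spiral point set
(default 960 points); the accessible fraction times the expanded-sphere
area gives the per-atom SASA. The default probe is 2.0 Å, matching the
probe used for the published cavity-surface renderings of the reference
model; the conventional 1.4 Å water probe is one argument away. Unknown
elements either fail or fall back to 1.70 Å with a warning, configurably.

Per-residue sidechain SASA is normalized by a constant
maximum-accessibility table (Tien et al. 2013 theoretical Gly-X-Gly
maxima minus the glycine backbone contribution). With the 2.0 Å probe,
relative values can modestly exceed 1 because the reference maxima are
water-probe quantities; this does not affect thresholding. Glycine has no
sidechain and is judged on its Cα area against a Cα reference. A residue
counts as *cavity/solvent exposed* when its relative sidechain
accessibility is ≥ 0.15 (configurable; the source material gives no
number, and 0.15 is the conventional buried/exposed boundary).

The substrate-pathway candidate set intersects three filters: (i) family
conservation (from the alignment stage), (ii) exposure as above, and
(iii) sidechain hydrogen-bonding capability (polar set S T C Y N Q D E K
R H W — tryptophan included for its indole NH). Positions outside the
modelled residue range are reported as unevaluable rather than dropped.

"Facing" residue pairs are operationalized geometrically, since the
relationship is only ever stated qualitatively: sidechain centroids
within 8 Å and each Cα→centroid vector pointing at the partner centroid
within 60°. Salt bridges are basic-sidechain-N / acidic-sidechain-O pairs
(Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2) with
minimum atom distance ≤ 4.0 Å, each residue pair reported once.

## Uptake kinetics

*Initial rates* are per-replicate least-squares slopes of accumulated
signal over the linear window (default 2 min, where uptake velocity is
linear), averaged across replicates with the SE from the replicate
spread.

*V%* is 100·(rate_mutant − rate_background)/(rate_wt − rate_background),
floored at zero; the background is the carrier-deletion strain. Values
under the resolution bound (2% of wild type — the loss-of-function
criterion) are displayed as "<2".

*Saturation fits* minimize least squares of v = Vmax·S/(Km+S) with
positivity bounds, started from a Hanes–Woolf linearization. The default
objective uses relative-error weighting (σᵢ ∝ |yᵢ|): the assay's
replicate noise is multiplicative (SD proportional to the mean), so
relative weighting is the correctly specified variance model. This
matters at the edge of the design: for a parameter set whose Km (92 µM)
lies above the top tested concentration (50 µM), unweighted raw-signal
fitting yields a heavy-tailed Km estimator whose mean is ~19% high, while
the weighted fit keeps the mean within ~6%. Unweighted fitting remains
available (`weighting=None`). Fits whose Km lands more than ten-fold
outside the tested range, or which fail to converge, are flagged
unreliable.

*Competition fits* use the competitive form v(I) = V₀/(1 + I/IC50) with
the Hill slope fixed at 1 — competitive inhibition of a Michaelis–Menten
carrier at fixed tracer concentration implies unit slope — with a
free-slope variant as a diagnostic. An IC50 fitted beyond the maximum
tested concentration (including a flat, uninhibited response) is censored
and reported "> max"; censoring propagates through the Cheng–Prusoff
conversion Ki = IC50/(1 + L/Km) at the same assay bound, matching the
reporting convention for constants like ">3000 µM". Standard errors come
from the Jacobian at the optimum scaled by replicate-level residual
variance; printed ± values are standard errors. Convergence tolerances
are 1e-14 (scipy trf); noiseless closed-loop recovery is asserted at
1e-6 relative.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the study conditions: saturation grids spanning
0.5–50 µM, competition grids 0.5–3000 µM plus the I = 0 anchor at a
1.0 µM tracer, three replicates per point, and multiplicative Gaussian
noise truncated at zero with CV 0.15 (the source states only that
replicate SD stayed below 20%; 0.15 respects that bound, and the
distributional form is a package choice since none is stated). Time
courses are linear over the measurement window and approach a plateau
exponentially afterwards (time constant = window length) — the plateau
shape is unconstrained by any data and only the linear window is ever
fitted. Per-allele generating parameters come from the packaged
characterization table; each allele's Vmax is anchored so its initial
rate at the 1.0 µM tracer equals its tabulated V% of the wild type
(wild-type Vmax = 100 on an arbitrary linear count scale).

Planted-alignment columns satisfy their class definitions exactly, and
background columns are redrawn whenever they would classify as
`family_conserved` or `orthologue_specific`, making "the selectors return
exactly the planted sets" an exact contract. Planting an `unconserved`
column requires ≥2 orthologues (with one orthologue the class is
unreachable). All generators take explicit seeds and are byte-identical
under identical arguments.

What passing on synthetic data does **not** show: real assays have
between-experiment (day) variance, counting statistics at low signal, and
quench/efficiency drifts that the i.i.d. multiplicative model ignores;
real alignments have indels, rate heterogeneity and phylogenetic
correlation that uniform background columns ignore; toy structures probe
the geometry engines, not the quality of any homology model. Wet-lab
observables (growth plates, Westerns, microscopy) are never simulated —
localization and growth scores enter only as categorical inputs.

## Phenotype classification

First-match-wins decision list: ER retention → `trafficking_defective`;
V% ≤ 2 at the membrane → `transport_null_membrane`; premature stop →
`truncation_null`; V% ≥ 90 with every shared constant within 1.5-fold of
wild type → `wt_like`; any constant shifted ≥ 1.5-fold with V% > 2 →
`selectivity_altered`; otherwise `partial_transport`. The 1.5-fold
threshold is the smallest shift treated as meaningful in the reference
system (a ~1.6× Km change) and is configurable. Censored constants are
compared at their bounds; two constants censored at the same bound count
as unshifted. A V%-null record lacking localization (and not a stop
allele) is classified on V% alone and flagged `needs_review` rather than
rejected. Growth scores are carried, never used.

## Problem sizes and determinism

The recovery runs in `scripts/acceptance.py` use 200 simulated assays per
Km target, 100 per Ki target and 200 per V% target — enough that the
mean's Monte-Carlo error is well under each quantity's reported
uncertainty, while the whole script completes in seconds. Per-run seeds
derive from the single `--seed` argument via `numpy.random.SeedSequence`
spawning, so every number is reproducible end to end.

## Known limitations

* The conservation stage assumes the alignment is correct; no aligner is
  wrapped, and column-level alignment errors propagate to the classes.
* Relative accessibility with a non-water probe is normalized against
  water-probe maxima (values may exceed 1; thresholding is unaffected).
* The facing/salt-bridge geometry uses fixed cutoffs on a static model and
  cannot capture conformational rearrangement between inward- and
  outward-facing states.
* Proton-coupling energetics and protonophore inhibition are out of
  scope; the kinetics module treats transport as a Michaelis–Menten
  carrier with competitive inhibitors.
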