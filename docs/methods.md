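# Methods

This note records the models, conventions and numerical choices behind
`cleavemap`, and what the synthetic-data generators do and do not
emulate.

## Mass arithmetic and conventions

Positions are 1-based; fragment spans are inclusive at both ends, so
"1–12" covers twelve residues. The neutral monoisotopic mass of a span
is the sum of the standard residue (dehydrated monomer) masses plus one
water (18.010565 Da); the reported ion mass is the singly protonated
species, `[M+H]+ = M + 1.007276` Da. The residue table is the standard
monoisotopic set at 5-decimal precision (anchor: Gly = 57.02146 Da) and
can be overridden from JSON, e.g. to fold a fixed modification into a
residue. Cysteine is treated as a free thiol; no variable modifications,
isotope envelopes, multiple charging or non-proton adducts are modeled.
An average-mass mode exists for completeness but plays no role in the
matching pipeline.

On the packaged Ex4C reference digest table, recomputing the `[M+H]+`
mass of every reported span reproduces all 17 reported theoretical
masses within ±0.001 Da (largest deviation 0.0002 Da), which fixes the
interpretation of that table's mass column as singly protonated
monoisotopic — the convention used throughout.

D-amino acids are mass-identical to their L-enantiomers and carried as a
per-residue flag, serialized as lowercase one-letter codes. This FASTA
dialect is intentional and parsed symmetrically; it exists because the
D-substituted analogs (TSME-7/8) differ from L-analogs only in
chirality, which masses cannot see but proteases can.

## Digestion model

A protease is a declarative rule: cut after any residue in
`cleave_after` unless the following residue is in `blocked_by_next`.
Defaults: trypsin K/R blocked by P; chymotrypsin F/Y/W/L; elastase
A/V/L/I/G/S. The chymotrypsin and elastase sets are standard broad
specificities on purpose — rule-based digestion is a candidate
generator, while the evidence-based caller (`infer_cleavage_sites`)
decides which sites are real. D-residues are invisible to all rules by
default (`d_residue_immune`), reflecting the stereospecificity of
protease active sites; the flag can be disabled.

Partial digests enumerate every span bounded by termini or cut sites
with at most `max_missed` interior sites, ordered by (start, end).
Resistance uses a two-state complete-digestion limit model: at assay
endpoint, a peptide with ≥1 predicted site is fully hydrolyzed (0%
intact), a site-free peptide is untouched (100%). No kinetic model is
attempted — the inputs carry no rate constants — so intermediate intact
fractions (partially resistant analogs plateauing at 75–95%) are outside
this model by construction.

## Peak assignment

Candidates are, by default, *all* contiguous subpeptides of the parent
(n(n+1)/2 spans), matched on absolute Da tolerance (default 0.05 Da) or
ppm. The default tolerance covers 16 of the 17 packaged reference peaks;
one elastase peak carries an apparent error of 0.085 Da and needs the
per-run override (0.1 Da) — that override exists precisely because real
apparent masses can drift beyond the nominal window. Best match =
smallest |error|, ties broken by (start, end). Two reference peaks sit
on exact composition-permutation ties (spans 6–21 vs 7–22, and 21–25 vs
22–26, each pair containing the same residue multiset): mass matching
cannot distinguish them even in principle, so both candidates are
returned and the peak is flagged ambiguous rather than resolved by fiat.

When the digesting enzyme is known, `candidate_spans` restricts matching
to protease-consistent spans (e.g. a partial digest list). This sharply
reduces degenerate ambiguity — short fragments such as a lone Gly
otherwise match every occurrence of that residue — and is what makes
exact end-to-end cut-set recovery provable in the synthetic pipeline
(see below). The default remains the unrestricted scan.

Retention time is carried through reports but never scored.

## Site inference

Each matched fragment implies up to two cut candidates: after its last
residue, and after the residue preceding its first. Tallying gives
end-side and start-side support; the default caller requires both-sided
support, which on the packaged data yields trypsin {12, 20, 27} and
chymotrypsin {6, 21, 22, 25} while rejecting the coverage-edge boundary
after position 39. One-sided mode exists for sensitivity analysis: the
elastase evidence {19, 21, 26} only surfaces there, because elastase
fragments rarely overlap on both flanks of a cut. Note the packaged
elastase fragments evidence a cut after Leu26 (fragment 22–26) and none
after Lys27; an external description of the same data lists Lys27 — the
caller reports what the fragments support and leaves such discrepancies
visible in the report rather than harmonizing them.

`observed_terminus` declares the last residue covered by any fragment
(39 for Ex4C, whose C-terminal Cys40 never appears in a fragment);
boundaries at or beyond it are suppressed as coverage artifacts, not
cleavages. Support is a plain count — no probabilistic or
intensity-weighted scoring is attempted, as the inputs are peak lists
without usable intensities.

## Analog design

`enumerate_analogs` takes per-site candidate lists and emits the full
Cartesian product (every site substituted; deterministic order; count =
product of list sizes). Candidates may be D-enantiomers. Two screens
follow:

* **resistance** — an analog is resistant iff the rule predicts zero
  sites in it;
* **binding energy** — analogs at or below a threshold (default −42 on
  the ingested kcal/mol-scale score; lower = more stable
  ligand-receptor complex) are retained, preserving input order.

All structure-based numbers (per-mutation stability scores, per-analog
binding energies) are input data transcribed into packaged CSV/JSON
fixtures; computing them (Rosetta-style ΔΔG, MD, MM-GBSA) is explicitly
out of scope. Two packaged candidate sets exist: the top-3 stabilizing
substitutions per site (3×3×3 = 27 analogs) and an extended set taking
the union of residues observed across the packaged L-type analogs
(3×4×4 = 48, which contains all six L-type TSME sequences).

## Pharmacology

"Three-parameter" means {baseline, Emax, EC50} with Hill slope fixed at
1; a four-parameter variant frees the slope. Fitting is least squares
on the log-concentration scale (the grid spans five orders of
magnitude, and log-EC50 is the natural parameter), initialized at
baseline = min response, Emax = max response, EC50 = geometric mean
concentration. A flat response or failed optimization returns a result
flagged `converged=False` rather than raising mid-pipeline. Standard
errors come from the curvature of the least-squares fit; the EC50
standard error is delta-method-transformed from log scale.

AUC is the trapezoidal rule over the observed window only — no C0
back-extrapolation and no terminal-phase extrapolation — because the
intended sampling designs are fixed windows (an IPGTT's −30…120 min
glucose course, a 0…12 h plasma profile), and the same arithmetic
serves both. Relative bioavailability is the dose-normalized AUC ratio.
As a worked example, plasma AUCs of 0.56 (oral, 2.12 mg/kg) and 3.17
ng·h/mL (injected, 0.11 mg/kg) give F_rel = 0.917%; note that arithmetic
on rounded printed AUCs can differ from a value computed on unrounded
data by several percent of itself, so such published figures are treated
as worked examples, not equality targets.

## Synthetic-data generators

The generators provide inputs with the statistical structure each stage
assumes, so the whole pipeline is testable without instrument data.

* **Digest peaks** — true fragment `[M+H]+` masses from a complete or
  partial in-silico digest, plus additive Gaussian mass error (absolute
  Da, not ppm, mirroring the few-mDa-to-tens-of-mDa discrepancies seen
  in real apparent masses), Bernoulli dropout, and spurious peaks
  uniform over a configurable mass window (real chromatograms contain
  unassigned peaks). Ground truth is returned alongside. Default
  conditions are noise-free and dropout-free.
* **Dose-response** — logistic mean plus i.i.d. Gaussian noise on a
  10-step 5-fold dilution grid from 250 nM, the design of the reference
  reporter assay; the default noise level used in recovery tests is 5%
  of Emax with 3 replicates.
* **PK profiles** — a one-compartment first-order absorption Bateman
  curve `C(t) = A(e^(−ke·t) − e^(−ka·t))` with additive noise clipped at
  zero, sampled at 0–12 h. This is the simplest generator with the
  observed rise-and-decay shape; it is a stand-in for testing the AUC
  arithmetic, not a pharmacokinetic claim.

What the generators do **not** emulate: ionization efficiency and
intensity structure, retention-time behavior, correlated or
heteroscedastic assay noise, multi-compartment kinetics, and
between-animal variability. Passing recovery tests therefore
demonstrates correctness of the computational chain under the stated
noise models, not robustness to every failure mode of real instruments.

All generators take an explicit integer seed and are bit-reproducible
under it.

## Verified end-to-end property

With zero dropout and zero mass error, assigning simulated digest peaks
against protease-consistent candidate spans (keeping all tied
candidates) and splicing the matches recovers the generator's true cut
set *exactly*: every match necessarily lands on a true fragment span, so
all support falls on true cut positions, and every true cut has support
from its two flanking fragments. This holds on 100/100 random
peptide/rule draws in the test suite (and is provable, not empirical).
With the unrestricted all-span scan the same recovery fails for peptides
with repeated short fragments — which is the scientific reason the
candidate restriction exists.

## Problem sizes in the test suite

Property tests use peptides up to 40 residues, 100-seed recovery loops,
and a 200-replicate EC50 recovery study at 5% noise; the full suite runs
in well under a minute on one CPU. These sizes were chosen as the
smallest that exercise every degeneracy the methods must handle
(permutation ties, proline blocks, D-residues, coverage edges).

## Known limitations

* The complete-digestion limit model cannot represent partial
  resistance; analogs between 0% and 100% intact are outside it.
* Mass matching cannot distinguish composition permutations; such peaks
  are reported ambiguous and need protease context (candidate
  restriction) or orthogonal evidence (MS/MS) to resolve.
* Binding-energy screening is only as good as the ingested scores; the
  package deliberately contains no structural scoring of its own.
* The per-residue chirality flag covers D-substitution but no other
  backbone or side-chain chemistry (no PTMs, staples, or non-natural
  residues).
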