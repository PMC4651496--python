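# parvmap

Antibody epitope mapping on parvalbumin-like antigens: an integrated,
tested pipeline for the four computational analyses used to localise a
conformational antibody epitope on a small protein antigen and rationalise
cross-reactivity across a protein family.

Fish allergy is driven by IgE against β-parvalbumins, small (~12 kDa,
~109-residue) EF-hand calcium-binding proteins whose conserved surfaces make
patients react to many fish species at once. Mapping where a cross-reactive
antibody (e.g. an scFv fragment) binds such an antigen combines several
lines of evidence, each of which this package implements as a library module
with a thin CLI:

- **NMR chemical shift perturbation (CSP)** — comparing ¹H-¹⁵N HSQC amide
  shifts of the free and antibody-bound antigen, per residue:

  `CSP = |ΔδH| + 0.1·|ΔδN|`

  Residues with CSP strictly above a significance threshold (default
  0.028 ppm) form the CSP-derived epitope; peaks that vanish on complex
  formation (exchange broadening) are reported as a separate *disappeared*
  class. Epitope residues are summarised per sequence region (N-terminus,
  AB/CD axis, CD site, around residue 80, C-terminus).
- **¹⁵N relaxation** — mono-exponential fits `I(t) = I₀·e^(−R·t)` of R1 and
  R2 decay series; the R2/R1 ratio tracks rotational correlation time and
  confirms complex formation (an antigen bound in a larger complex tumbles
  more slowly, raising R2/R1).
- **Docking contact frequency** — over an ensemble of rigid-body
  antigen–antibody docking poses (2000 by default), an antigen residue
  counts as contacting a pose when any of its heavy atoms lies within 5 Å
  (inclusive) of any heavy atom of the antibody CDR region; the per-residue
  contact frequency across the ensemble profiles the docking-predicted
  epitope. Optionally only the best-scoring fraction of poses is counted.
- **Accessibility & conservation** — Shrake–Rupley solvent-accessible
  surface area with Gly-X-Gly-normalised relative accessibility, and
  Clustal-style conservation symbols (`*` invariant, `:` strong group,
  `.` weak group) over a family alignment, with epitope-to-column mapping
  and overlap statistics against published IgE-epitope intervals.

A first-class **synthetic data generator** produces every input the pipeline
consumes — shift tables, decay series, a toy antigen structure, a pose
ensemble, a family alignment — with a JSON manifest of the planted ground
truth (epitope residues, relaxation rates, per-pose contact sets, conserved
columns), so the entire pipeline is testable for parameter recovery without
any external data.

## Worked example

Generate a synthetic bundle with a planted 29-residue epitope and run the
full analysis:

```sh
parvmap simulate --out demo --seed 3 --n-poses 100
parvmap csp --free demo/free.tsv --bound demo/bound_70uM.tsv --out demo/csp.tsv
parvmap pipeline --config demo/pipeline.yaml --out demo/run
```

prints

```
synthetic bundle written to demo
29 significant residues (CSP > 0.028 ppm), 0 disappeared
report written to demo/run/report.json: 29 CSP-epitope residues, Jaccard(csp, docking) = 1.0
```

The CSP step recovered exactly the 29 planted epitope residues (every CSP
above 0.028 ppm is a planted residue and vice versa), and the
docking-derived epitope (contact frequency ≥ 0.5) coincides with the
CSP-derived one, giving a Jaccard agreement of 1.0. `demo/run/report.json`
holds the machine-readable report: epitope sets with provenance, per-region
counts (5 N-terminal, 16 CD-loop-proximal, 5 around residue 80, 3
C-terminal), the per-residue table joining CSP, contact frequency, relative
accessibility and conservation symbol, and the R2/R1 summaries showing the
roughly three-fold ratio increase of the complex over the free antigen.

Individual stages are also available as `parvmap csp`, `relax`, `sasa`,
`contacts`, `conserve` and `report`; run any with `--help` for its options.

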