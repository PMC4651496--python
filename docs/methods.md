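# Methods

This note documents the models, parameter choices, numerical details and
known limitations behind each `parvmap` stage, and what the synthetic
benchmark does and does not establish about real data.

## Chemical shift perturbation

Amide CSP is the weighted city-block distance between free and bound
¹H/¹⁵N shifts, `CSP = |ΔδH| + w·|ΔδN|` with `w = 0.1` by default. The
0.1 weight compensates the ~10-fold wider ¹⁵N dispersion; no
glycine-specific weight is applied. Significance uses a **strict**
inequality, `CSP > threshold`, with a default threshold of 0.028 ppm;
a residue sitting exactly at the threshold is not significant. The
threshold is treated as a fixed, user-configurable input rather than being
derived from the CSP distribution (e.g. mean + SD), since practice varies.

Peaks present in the free spectrum but absent from the bound one are
classified *disappeared* — typically intermediate-exchange broadening at
the interface. They are strong binding evidence, but since no shift can be
measured they are never given an imputed CSP and never merged into the
significant set; they travel through the pipeline as a separate list.
Residues absent from the free table (prolines, unassigned positions — no
amide peak in an HSQC) are excluded from all denominator statistics.

With multiple titration points, CSP is computed per point and the headline
epitope uses the highest antigen concentration (the strongest bound
fraction); per-point significant sets are retained in the report.

The default region scheme for summarising epitope location on a
~109-residue parvalbumin is `n_terminus` 1–15, `ab_cd_axis` 28–45,
`cd_site` 51–62, `around_80` 75–85, `c_terminus` 95–109 — inclusive,
non-overlapping, configurable. The "CD-loop-proximal" summary used in
reports is the union of `ab_cd_axis` and `cd_site`.

## Relaxation fitting

Each R1/R2 decay is fit as `I(t) = I₀·e^(−R·t)` by nonlinear least squares
(trust-region reflective, parameter/function tolerances 1e-8), initialised
from the log-linear regression of ln I on t. At least three positive
intensities are required; non-converged fits are flagged and excluded from
summaries with a warning. The R2/R1 ratio is reported per residue and as a
per-state mean; its increase on complex formation is the diagnostic, not
its absolute value (no model-free analysis is attempted).

## Solvent accessibility

Shrake–Rupley with a 1.4 Å probe and a 960-point Fibonacci (golden-spiral)
quadrature per atom; the point set is deterministic, so SASA outputs are
exactly reproducible. Van der Waals radii: C 1.7, N 1.55, O 1.52, S 1.8 Å;
unknown elements fall back to 1.8 Å with a warning. For an isolated atom
the quadrature is exact (every point accessible), and doubling the point
count changes total SASA on test structures by < 1%. Relative accessibility
divides residue SASA by the theoretical Gly-X-Gly maximum (Tien et al.
2013 theoretical values); residues are called exposed at relative
accessibility ≥ 0.2, a common convention. Only the first model of an NMR
ensemble is used, matching how such ensembles are used for docking.

## Docking contacts

The contact criterion is heavy-atom to heavy-atom distance ≤ 5.0 Å between
an antigen residue and the antibody CDR region, read as **inclusive** at
exactly 5.0 Å; hydrogens are ignored on both sides. CDR residues are
supplied explicitly (residue numbers per antibody chain) rather than
inferred from Chothia/Kabat numbering — antibody libraries with randomised
CDR3 loops do not number reliably, and the definition is an input, not a
prediction. The KDTree implementation is verified in the test suite
against a brute-force all-pairs distance scan.

Score handling: a score table must cover all poses or none (a partially
scored ensemble is rejected rather than silently subset). Filtering to the
best-scoring `⌈fraction·n⌉` poses is available but **off by default** —
an ensemble's score distribution is often too flat to trust, and the
default analysis is purely geometric. Lower score = better (docking energy
convention). Frequencies are raw per-residue fractions of kept poses; both
counts and frequencies are emitted, and no cross-residue normalisation is
applied. The docking-derived epitope uses a frequency threshold of 0.5 by
default (configurable and echoed in the report); the underlying profile is
a colour ramp, so any threshold is a reporting convenience.

## Conservation

Clustal consensus symbols are computed from the frozen strong groups
{STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW} and weak groups
{CSA, ATV, SAG, STNK, STPA, SGND, SDEENK, NDEQHK, NEQHRK, FVLIM, HFY}:
`*` all identical, `:` all in one strong group, `.` all in one weak group,
blank otherwise; any gap in a column blanks it (Clustal convention). The
test suite checks ≥ 95% column agreement against the consensus line of
`mafft --clustalout` on substitution-only toy families; divergences are
confined to columns where gap placement differs between implementations.
Epitope residues given in reference-sequence numbering are mapped to
alignment columns through the reference's gap structure only — no
hard-coded numbering-offset tables between family members.

Packaged literature IgE-epitope intervals (reference numbering of the cod
parvalbumin): 28–45, 95–109, 75–85, 30–40 and 50–60, each tagged with its
mapping study context; users may substitute their own interval TSV.
Overlap is reported as intersection counts plus the Jaccard index
|E∩I| / |E∪I| per interval.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

| parameter | default | rationale |
|---|---|---|
| `n_residues` | 109 | β-parvalbumin length (C-terminus runs to residue 109) |
| planted epitope | 29 residues | conformational epitope (7, 8, 11, 12, 15, 29–33, 36, 108) extended so the region breakdown is 5/16/5/3 across N-terminus / CD-loop-proximal / around-80 / C-terminus |
| `csp_effect` | 0.05 ppm | well above the 0.028 ppm threshold, typical of a direct-contact residue |
| `csp_noise_sigma` | 0.002 ppm | HSQC peak-position reproducibility |
| titration | bound fractions 0.5, 1.0 at 40, 70 µM (2:1, 1:1) | fast-exchange titration toward saturation |
| `n_poses` | 2000 | independent rigid-body docking solutions |
| `p_contact_in` / `p_contact_out` | 0.9 / 0.05 | planted vs background contact probability per pose |
| `n_sequences` / `substitution_rate` | 6 / 0.2 | parvalbumin-family-like divergence |
| decay noise | 1% of I₀ | typical relaxation-series intensity error |
| free rates | R1 ∈ [1.2, 1.8], R2 ∈ [7, 9] s⁻¹; complex R2 = 3× free, R1 = 0.8× free | ~12 kDa free antigen vs ~40 kDa complex tumbling |

Shift tables: free shifts uniform over δH 7.5–9.5 / δN 105–130 ppm; the
planted effect is split 60% into δH and (after 0.1-weighting) 40% into δN
and scales with the bound fraction — the fast-exchange picture, which makes
per-residue CSP non-decreasing across titration points. Optionally a
configured subset of residues is dropped from every bound table to emulate
disappeared peaks.

Poses: the toy antigen is an extended Cα+Cβ pseudo-chain at 3.8 Å spacing
(idealised geometry, no force field — downstream operators consume only
coordinates and identities). Each pose samples its contact set
independently per residue, then realises it geometrically: one probe heavy
atom is placed 4.0 Å from each touched residue's Cα, which satisfies the
5 Å criterion for that residue alone (nearest-neighbour Cα/Cβ are ≥ 5.5 Å
from the probe atom). The manifest records every per-pose contact set, so
the contact operator can be checked pose by pose. Scores are
−(#planted contacts) + N(0, 0.5), correlating better (lower) scores with
planted-epitope engagement.

Alignment: homologs mutate each non-epitope site independently
(substitution to a different residue, or a gap at 2% rate); planted epitope
columns are copied verbatim, so the planted epitope is perfectly conserved
— the cross-reactivity scenario.

Every generator is a pure function of `(seed, parameters)`: identical
seeds give byte-identical files. The acceptance script and the test suite
run the ensemble at 2000 and at reduced pose counts respectively; pose
count only narrows the frequency estimates' sampling error, and the
reported problem sizes accompany every number.

**What passing recovery tests does not show:** real HSQC data have peak
overlap, exchange-regime-dependent lineshapes and assignment ambiguities;
real docking ensembles have spatially correlated (not per-residue
independent) contacts and rugged score landscapes; real families have
indels and rate heterogeneity. The benchmark validates the bookkeeping and
the estimators under clean planted conditions, not robustness to these
effects.

## Pipeline & determinism

Stages run in dependency order (CSP → relaxation → accessibility →
contacts → annotation → conservation → joined report); a missing optional
input (structure, poses, decays, alignment) skips its stage with a warning
and leaves a null field in the report, keeping the schema stable. A residue
numbering mismatch between shift table and structure is a hard, listed
error. TSV floats are formatted to 6 significant digits and the JSON report
is key-sorted, so a fixed input directory reproduces byte-identical outputs;
wall-clock timestamps appear only in `run.log`. The Jaccard index between
the CSP- and docking-derived epitopes is a repo-defined agreement metric
(no standard joint statistic exists) and is labelled as such in the report.

## Known limitations

- No exchange-regime modelling: CSP assumes fast exchange; intermediate
  exchange only surfaces as disappeared peaks.
- SASA is single-conformer; no ensemble averaging over NMR models.
- Conservation symbols are computed on the user-supplied alignment; the
  package never aligns sequences itself.
- The B-factor annotation channel clamps scores to the PDB field range
  [-99.99, 999.99] and stores them at 2 decimals — round-tripping scores
  through an annotated PDB is exact only at that precision.
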