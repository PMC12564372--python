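# Methods

This note records the models and procedures implemented in `il18design`,
the conventions and defaults chosen where the underlying workflow left
them open, and what the synthetic data does and does not emulate.

## Variant model

A mutation is `<wt><position><mut>` in one-letter code with 1-based
mature-IL-18 numbering (Tyr1 = 1); a variant is a set of mutations at
pairwise-distinct positions, the empty set being wild type (`WT`).
Canonical labels sort mutations by ascending position and join with `+`;
parsing accepts any token order, and variants compare by mutation set,
not by string.  Ambiguity codes (B, Z, X) and silent substitutions
(`E6E`) are rejected.  Labels carry no chain identifier — the chain is
structural metadata, supplied separately where structures are read.

Saturation mutagenesis emits exactly 19 variants per site (never the
identity).  Combination of single mutants enumerates all size-k subsets
whose mutations occupy distinct positions; for the five IL-18 singles
E6M, K129M, R131K, N111S, R131G this position-clash rule yields 9
doubles, 7 triples and 2 quadruples (R131K and R131G never co-occur).
Output order is lexicographic by canonical label, hence deterministic.

## Interface energetics

Input is a per-residue decomposition of the complex's binding energy
into total, electrostatic, van der Waals and desolvation terms
(kcal/mol), as produced by FFT-docking decomposition tools.
Classification: favorable if the total is < 0, unfavorable if > 0,
exactly 0 is neither.  Hotspot ("key") residues are those at or below a
configurable threshold, default −1.0 kcal/mol, *inclusive* — the
workflow's own borderline hotspot lists are most consistent with an
inclusive bound, and the boundary convention is explicit and
configurable.  Receptor-epitope site membership (I/II/III) comes from
the crystal-structure literature, so it is an annotation column in the
input, never derived.

## Activity calibration

Relative activity is mutant % over wild-type % (wild type = 100).  Each
ΔΔG type is regressed by ordinary least squares on x = ln(% activity) —
the direction that yields an energy *prediction* from an activity — with
the Pearson correlation and a two-sided p-value from the t distribution
with n − 2 degrees of freedom (`scipy.stats.linregress`).  Degenerate
inputs (n < 3, zero-variance x or y) are rejected.  Activity prediction
inverts the fitted line: x̂ = (ΔΔG − b)/a.

Scoring weights are the three correlations rounded to three decimals,
half away from zero; applied to the published panel correlations
(−0.7019, −0.7443, −0.5770) this reproduces the published weight vector
(−0.702, −0.744, −0.577) exactly.  The 17-mutant activity panel behind
those correlations is an *optional* input file (TSV `variant
activity_pct`): its values are not bundled, so calibration from raw
activities is exercised on synthetic panels, and the published
correlations are shipped as constants for scoring.

## Scoring, ranking, selection

The mutation score is the weighted sum of the ΔΔG triple; it is linear,
so flipping all weight signs negates every score and exactly reverses a
ranking.  Ranking sorts by descending score with deterministic
tie-breaks: ascending ΔΔG_binding first (binding affinity is the primary
design objective), then label.  Two selection rules are provided, since
the workflow's own candidate set is not strictly consistent with either:
`strict_all_negative` (all three ΔΔG < 0) and `top_n` by rank.  Scores
are displayed to 2 decimals; full precision is kept internally.

Recomputing scores from the shipped one-decimal panel reproduces the
published two-decimal scores within ±0.10 for every candidate row (and
within ±0.05 for 21 of 24) — the residual spread is what one-decimal
rounding of the inputs produces.  Control rows can deviate further
(E6K: 1.61 recomputed vs 1.95 published), indicating the published
scores used unrounded ΔΔG values; the package flags this by keeping the
published column for comparison but always recomputing.

Multi-mutant ΔΔG triples are inputs (the upstream tools compute them
non-additively); `additive_approximation` sums single-mutant triples as
an explicitly flagged fallback.

## Trajectory metrics

Interchange format is (multi-model) PDB via biotite; coordinates in Å,
1-based residue numbering, insertion codes rejected.  PDB's 3-decimal
coordinate field is the acknowledged round-trip tolerance.

* **Superposition** — closed-form Kabsch fit (SVD with determinant
  correction, proper rotations only), default selection the backbone
  N/CA/C/O atoms; degenerate (< 3 atoms, collinear) sets rejected.
* **RMSD series** — per-frame post-superposition RMSD, with mean ± sd
  over an analysis window and a boolean quality marker at the
  conventional 3 Å acceptability bound (a flag, not an error).
* **Per-residue RMSD** — residue-wise backbone deviation per frame after
  a *global* backbone alignment (no per-residue refit).
* **RMSF** — per-residue sqrt of the mean squared displacement about the
  trajectory-average position, on CA atoms by default.  Alignment to the
  reference is applied by default but can be skipped for pre-aligned
  trajectories, since the fitted rigid motion slightly and unevenly
  absorbs fluctuation (largest at the extremities of elongated chains).
* **Distance pattern** — per residue, the mean over frames of the
  distance of the N/C/CA/O geometric center from the origin of the
  reference frame, after alignment; residues missing any of the four
  atoms are excluded.
* **Hydrogen bonds** — donor–acceptor distance ≤ 3.5 Å and D–H···A angle
  ≥ 150° (measured at the hydrogen, 180° linear), both inclusive.
  Donors are N/O with a covalently bound hydrogen, inferred by a
  < 1.2 Å distance rule when no topology is given; acceptors are all
  N/O.  Structures without hydrogens are rejected with an instruction to
  protonate.  Mean counts over the analysis window are reported at full
  precision (round to integer for table-style reporting).
* **Contacts** — group-centroid distances per frame with classes:
  ≤ 5 Å within the favorable electrostatic/π range (≤ 4 Å reported as
  the strong subset, since the convention is a 4–5 Å band), > 6 Å
  long-range electrostatic, otherwise neither.  Group conventions:
  Asp/Glu carboxylate-oxygen midpoint, Lys NZ, Arg CZ, His imidazole
  centroid; aromatic rings (Phe/Tyr/Trp/His) by ring-atom centroid.
  Standard salt-bridge/π conventions; the upstream workflow does not
  specify them.

The default analysis window discards the leading 60 % of frames
(equilibration by MD convention, e.g. keeping the last 1000 of 2500
snapshots) and is configurable everywhere.

## Synthetic data

Generators are deterministic per seed (one `numpy` Generator per call)
and return planted ground truth alongside the data.

* **Energy tables** — favorable totals strictly negative (some beyond
  the −1 hotspot bound), unfavorable strictly positive, default 30 %
  unfavorable; electrostatic + van der Waals favorable with desolvation
  compensating, and terms summing to the total.  Classification must
  recover the planted labels with zero error.
* **Validation panels** — default n = 17 mutants; activities log-normal
  around the tens-of-percent range (near-dead to enhanced mutants); each
  ΔΔG type follows its published regression line (slopes −0.6046,
  −0.4544, −0.2829; intercepts −0.5622, 0.5580, 0.5701) plus Gaussian
  noise, default σ = 0.5 kcal/mol, independently per type.  Degenerate
  all-equal-activity panels are refused.
* **ΔΔG landscapes** — single-mutant components i.i.d. N(0.5, 1.5²)
  kcal/mol (a mildly destabilizing majority with a favorable minority,
  as in saturation scans); the five best singles are combined into all
  position-compatible subsets of order 2–4, each combination's triple
  being the sum of its singles plus one N(0, σ_epi) coupling per
  component per site pair, default σ_epi = 0.3 kcal/mol.  Ground truth
  is the score argmax of the purely additive landscape.  Ranking the
  epistatic table recovers it reliably only when σ_epi is far below the
  inter-variant score gaps (gaps are typically a few tenths of a score
  unit near the top of the ranking); the low-epistasis regime used in
  tests sets σ_epi = 0.01, ~30-fold below those gaps.
* **Toy structures** — extended chains (3.8 Å residue spacing) with N,
  H, CA, C, O per residue, amide hydrogens pointing away from all
  carbonyl oxygens so that no intra-chain pair meets the H-bond angle
  criterion, plus one water-oxygen acceptor placed at an exactly stated
  donor–acceptor distance and D–H···A angle — the only geometric H-bond
  in the structure, by construction.
* **Trajectories** — per-atom isotropic Gaussian displacements about a
  reference with per-residue amplitude, default 0.5 Å per coordinate,
  multiplied by 3 inside the flexible-loop region (default residues
  106–112); default 1000 frames at 0.06 ns spacing.  Optionally a random
  global rotation + translation per frame, which the alignment step must
  remove exactly.  The analytic check: isotropic σ per coordinate gives
  RMSF = √3·σ; at 1000 frames each residue estimate carries
  ~1/√(6·n_frames) ≈ 1.3 % relative sampling scatter, so the profile
  mean is the quantity compared to the analytic limit.

What the synthetic data does *not* emulate: force-field energetics
(values are scale-realistic only), correlated or anharmonic protein
motions, solvent, side chains beyond the groups needed for contact
tests, and any sequence–structure coupling.  Passing tests therefore
demonstrate the correctness of the statistics and the pipeline's
recovery of planted signals, not predictive accuracy on real proteins.

## Known limitations

* ΔΔG values and per-residue energies are consumed, never computed; the
  pipeline's predictions are only as good as the upstream energetics.
* H-bond donor inference by the 1.2 Å rule requires explicit hydrogens
  and can mispair in severely distorted geometries; supply explicit
  donor pairs when a topology is available.
* Contact classification needs the standard side-chain atom names; no
  support for alternate locations or insertion codes.
* The MD-derived quantities of a real study (mean RMSD/H-bond counts of
  specific systems) depend on the original trajectories and force
  field; this package reproduces the *metrics*, and verifies them
  against analytic limits and exhaustive oracles on synthetic
  trajectories at desk scale (hundreds to 1000 frames, 10–130
  residues).
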