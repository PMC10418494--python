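# Methods

This package determines antibody–antigen binding affinity by two independent
routes — a structure-based linear model over interface descriptors, and a
solution-phase equilibrium analysis of species concentrations measured by
multi-detector size-exclusion chromatography (SEC) — plus a rigid-geometry
analysis of binding stoichiometry. The worked system throughout is the
extracellular HER2 domain (g-eHER2, ~86.4 kDa) binding the IgG antibodies
trastuzumab and pertuzumab (~147 kDa, valence f = 2), at 309 K.

## 1. Structure route: contact/NIS affinity model

**Descriptors.** Two residues, one per binding partner, are an interfacial
contact (IC) when any pair of their heavy atoms lies within 5.5 Å
(inclusive; `contacts.find_contacts`). A contact is counted once per residue
pair. Residues are classified as charged (E, D, K, R), polar
(C, H, N, Q, S, T, W) or apolar (A, F, G, I, L, V, M, P, Y), and contacts
are tallied by unordered class pair. The non-interacting surface (NIS) is
the set of residues of the *complex* with relative SASA ≥ 5% that sit in no
contact pair; %NIS_charged and %NIS_apolar are class shares of that set.

**Model.**

    ΔG = −0.09459·IC_cc − 0.10007·IC_ca + 0.19577·IC_pp − 0.22671·IC_pa
         + 0.18681·%NIS_apolar + 0.13810·%NIS_charged − 15.9433   [kcal/mol]

Charged–polar and apolar–apolar contacts are deliberately absent from the
model. Kd follows as exp(ΔG·1000/(R·T)) with R = 1.987 cal K⁻¹ mol⁻¹;
temperature enters only this conversion. The charged-NIS coefficient
circulates in two printings, +0.13810 and +0.3810; only the former is
consistent with the model's own published predictions (the latter shifts a
typical Fab–antigen complex by ≈ +5 kcal/mol), so +0.13810 is the default
and the +0.3810 variant is retained behind
`QsarCoefficients.printed_variant()` purely to document the discrepancy.

**SASA.** Numerical Shrake–Rupley-style sampling (biotite's deterministic
Fibonacci point set, 960 points, 1.4 Å probe) over a frozen element-wise
Bondi radius table. Relative SASA divides per-residue totals by
extended-tripeptide maxima: a NACCESS-style table by default, the Tien
et al. (2013) theoretical maxima as an option. Single-sphere results match
the closed form 4π(r+1.4)² essentially exactly; rigid-motion variation of
multi-atom surfaces stays below 0.5% at 960 points.

**NIS classification scheme.** Surface characterisation historically uses a
slightly different class table than the contact model (histidine charged;
cysteine and tryptophan apolar; tyrosine polar). Both schemes are
implemented (`Scheme.IC`, `Scheme.NIS`); NIS percentages default to the
surface variant, contacts always use the contact table. The choice is
recorded in every prediction's metadata.

**BSA.** Buried surface area is the total ΔSASA over both sides,
SASA(A) + SASA(B) − SASA(AB); the per-side (halved) convention is available
as a flag. Interface residues are those losing > 0.1 Å² on complexation.

**Ensembles.** Snapshot sets are scored per structure and summarised as
mean ± sample (n−1) standard deviation; failed snapshots are excluded with
a warning and recorded. Crystal structures are read as deposited (first
model, highest-occupancy altloc, heavy protein atoms only; no loop
rebuilding, no glycans), so descriptor counts on entries with unmodelled
loops can differ slightly from values computed on loop-filled models. When
an asymmetric unit holds several antigen–Fab copies,
`select_antigen_fab_copy` scores the alphabetically first copy and records
the selection.

## 2. Solution route: bivalent-antibody equilibrium

From measured total antibody and antigen concentrations (c_a, c_g, mass
units) and the equilibrium free-antigen concentration c_ag, the
reacted-site fraction is

    p = 1 − (c_ag / c_g)^(1/f),            f = 2 for IgG,

and the association constant (per molar) is the bivalent-binder closed form

    K = f·M_a·p / [ 4·c_a·(1−p)·(1 − p·f·c_g·M_a / (2·c_a·M_g)) ].

In molar variables this is K = f·p / [4(1−p)(A − p·f·G/2)] — a site-level
mass-action constant, bonds over free-site concentrations, under random
site reaction. Converting to mole-fraction units (K_a = K·[H₂O], default
55.34 M; the 309 K value ≈ 55.15 changes ΔG by < 0.1%) gives
ΔG = −R·T·ln K_a. The measured study mixtures yield K_a = 2.47×10⁷ and
3.18×10⁷ (mole fraction)⁻¹, i.e. ΔG = −10.45 and −10.61 kcal/mol.

**Mass balance.** The measured mixture rows close the antibody balance but
not the antigen balance (by +18% and +57%); since the chain consumes only
totals and free antigen this does not affect the constants, and the
checker therefore *warns* by default (tolerance 5%, `error` policy
available).

**Forward simulator.** `simulate_equilibrium` generates species from a
known site constant for parameter-recovery studies. Its default model is
the same site-reaction statistics the closed form inverts: p solves the
quadratic K·4(1−p)(A − p·f·G/2) = f·p, free antigen is G(1−p)^f, and bound
antigen is distributed over the two antibody arms by a quasi-chemical
split with weights (1, 2x, ρx²) — ρ = 1 is the independent binomial split,
ρ < 1 penalises and ρ > 1 favours double occupancy (an avidity /
steric-penalty dial that never moves the free-antigen concentration, hence
never the recovered K). Under this model simulate → analyze recovers K to
1e-6 relative for any ρ, which is the designed invariant. An alternative
`model="mass_action"` solves the textbook independent-sites species law
([AbAg] = 2K[Ab][Ag], [AbAg₂] = ρK²[Ab][Ag]²) by bounded root finding;
applied to *that* model the closed-form estimator returns an effective
constant different from the site constant (by ×0.49 at K = 10⁴ M⁻¹ down to
×0.04 at 10⁸ M⁻¹ at the study totals) — a deliberate illustration of
estimator–model mismatch, not a defect. Under 2% multiplicative noise on
all concentrations the estimator recovers K with ≈3% mean relative error
at the study conditions (100 replicates); the error is dominated by the
√(c_ag/c_g) propagation, so single replicates can reach ~7%.

## 3. SEC tetra-detection

Detector responses are modelled as proportional to local mass
concentration times an optical property: RI ∝ c·dn/dc, UV ∝ c·dA/dc,
LS ∝ c·M_w·(dn/dc)², VIS ∝ c·[η]. Calibrating the proportionality
constants on one standard of known mass, M_w and dn/dc (albumin-like,
66.4 kDa, dn/dc 0.185 mL/g, dA/dc 0.66) then gives per peak: injected mass
(RI), absolute molar mass M_w = (A_LS/k_LS)/((A_RI/k_RI)·dn/dc), and
dA/dc from the UV/RI ratio. dA/dc is reported as the absorbance of a
1 mg/mL solution in a 1 cm cell — numerically ε₂₈₀/M_w, which puts an IgG
near 1.4 and serum albumin near 0.66. ε₂₈₀ itself is the Gill–von Hippel
sum 5690·nTrp + 1280·nTyr + 120·ncystine.

**Deconvolution.** The RI trace is fitted by nonlinear least squares
(tolerance 1e-10, ≤ 5000 evaluations) with Gaussian components
(area, center, width; exponentially-modified Gaussian with an extra tail
constant τ as an option); initial centers come from user guesses or from
prominence-ranked local maxima of a lightly smoothed trace, with evenly
spread fallback seeds when fewer maxima than peaks are visible. The fitted
unit-area shapes are transferred to the other detectors, whose component
areas are re-estimated by non-negative linear least squares. Fractions of
total protein are RI-area shares (equal dn/dc across species — the
standard protein assumption).

**Synthetic chromatograms.** The generator places species on a log-linear
retention calibration V = 38.05 − 9.56·log₁₀(M/kDa) (anchored on the
antibody/complex family: 147 kDa → 17.3 mL, 234 → 15.4, 320 → 14.1),
Gaussian peaks of σ = 0.25 mL, 1% multiplicative detector noise by
default, aligned traces (no inter-detector delay), 100 µL injections at
0.5 mL/min. It emulates peak shapes, detector proportionality and noise —
not column physics, band-broadening theory, inter-detector volume delays,
baseline artefacts or non-ideal (e.g. tag-mediated) retention; real
instruments need delay correction and baseline handling before these
routines apply. Recovery tests on such data therefore validate the
quantification chain, not the chromatography. The frozen reference
mixtures reproduce the study compositions: heterodimer/heterotrimer mass
fractions 0.315/0.100 of C_T (trastuzumab-like) and 0.123/0.272
(pertuzumab-like).

**Hydrodynamics.** The Stokes–Einstein relation D = k_B·T/(6πη·r_h)
converts between diffusion coefficient and hydrodynamic radius; with
η = 7.0×10⁻⁴ Pa·s (aqueous buffer near 36 °C, configurable) an IgG-like
D = 5.81×10⁻¹¹ m²/s corresponds to r_h ≈ 5.5 nm. Values are stored in SI
units throughout.

## 4. Rigid stoichiometry analysis

To ask whether a second antigen fits on the free Fab arm of a 1:1 complex,
the (bound antigen + engaged light chain) substructure is copied, its
light-chain backbone (N, CA, C, O of residues shared by number and
insertion code) is superposed onto the free arm's light chain by the
proper-rotation Kabsch fit, and the transformed antigen copy is merged as
a new chain — no minimisation afterwards, by design ("rigid procedure").
Steric feasibility is scored by heavy-atom pairs across the two antigen
copies below 2.5 Å (severe-clash convention, configurable), the minimum
cross distance, and the fraction of atoms with any partner below the
cutoff. On the bundled minimal IgG fixture the C2-symmetric geometry
grafts clash-free into the mirror pose, while a 25°-crowded geometry
yields dozens of clashing pairs — the geometric mechanism by which arm
arrangement can gate 2:1 binding.

## 5. Synthetic data: what it does and does not show

Toy residues are five-atom bodies (backbone + a CB contact carrier);
contact fixtures isolate each intended residue pair in its own spatial
cluster so the realised contact list — self-checked against an independent
O(n²) scan at generation time — equals the specification exactly,
including fixtures that reproduce a full crystal-interface contact
multiset. Random complexes for oracle-equivalence tests draw uniform
residue placements. All generators are integer-seeded and bit-reproducible.
Passing tests on these fixtures demonstrate correctness of the geometric
and numerical machinery; they say nothing about force-field-level realism,
conformational flexibility, or glycosylation, none of which is modelled.

## 6. Numerical choices and degenerate inputs

Root finding uses Brent's method with relative tolerance at machine
precision; the arm-split quadratic is solved in closed form with explicit
handling of ρ = 0 and zero binding. Distance comparisons at the contact
cutoff are inclusive; equality at 5.5 Å counts. Altloc resolution keeps the
highest-occupancy conformer (ties: first). Non-standard residues are kept
in structures but skipped (with a warning and a count) in classification.
Saturated mixtures (free antigen = 0) flag p = 1; over-saturated Goldberg
inputs (non-positive free-site bracket) raise a domain error rather than
returning a negative constant. Empty structures, unknown element radii,
degenerate (< 3 point or collinear) superposition inputs, and zero-signal
calibration runs raise typed errors mapped to distinct CLI exit codes.

## 7. Problem sizes

Default test and analysis workloads are sized for a laptop: 960-point SASA
sampling, 200 random complexes in the contact-oracle battery, 100
replicates in noise-recovery studies, 1200-point chromatogram grids with
4-peak fits. All scale linearly if larger studies are wanted.

## 8. Known limitations

* The crystal-structure pipeline needs the public PDB entries; they are
  fetched on demand (or read from `data/pdb/`) and are not bundled.
* Descriptors are computed on deposited coordinates; no loop rebuilding,
  so entries with unmodelled interface-adjacent loops may count slightly
  differently than loop-filled models.
* The NIS class table and relative-SASA reference reproduce the historical
  surface protocol by construction, not by cross-validation against an
  external service.
* The equilibrium model treats exactly two complex species (1:1 and 2:1);
  higher aggregates and antigen homodimers are out of scope.
* SEC modelling is proportional-response only: no column physics, no
  viscometer bridge model beyond [η]·c, no inter-detector delay.
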