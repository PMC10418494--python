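# abaffinity

Antibody–antigen binding affinity, two independent ways:

1. **Structure route** — a linear model over interfacial contacts (ICs) and
   non-interacting surface (NIS) computed from a crystal structure or
   snapshot ensemble:

       ΔG = −0.09459·IC_cc − 0.10007·IC_ca + 0.19577·IC_pp − 0.22671·IC_pa
            + 0.18681·%NIS_apolar + 0.13810·%NIS_charged − 15.9433  [kcal/mol]

   with contacts defined at a 5.5 Å heavy-atom cutoff and residues classed
   charged/polar/apolar.

2. **Solution route** — species concentrations of an antibody–antigen
   mixture (free antibody, free antigen, 1:1 and 2:1 complexes, e.g. from
   multi-detector SEC) through the bivalent-antibody equilibrium:

       p = 1 − (c_ag/c_g)^(1/f),
       K = f·M_a·p / [4·c_a·(1−p)·(1 − p·f·c_g·M_a/(2·c_a·M_g))],
       K_a = K·[H₂O],    ΔG = −R·T·ln K_a

   with f the antibody valence (2 for IgG) and R = 1.987 cal K⁻¹ mol⁻¹.

The package also quantifies species from synthetic tetra-detector SEC
traces (RI/UV/LS/VIS calibration on a single standard, peak deconvolution,
absolute molar mass from the LS/RI ratio), and probes binding
*stoichiometry* by rigid grafting: superposing a bound antigen onto the
free Fab arm of a 1:1 complex and counting steric clashes.

It is written for biophysicists comparing therapeutic antibodies — the
worked system is the HER2 ectodomain (86.4 kDa) with trastuzumab and
pertuzumab IgGs (≈147 kDa) at 309 K.

## Worked example

```python
>>> from abaffinity import analyze_mixture
>>> from abaffinity.synthetic import TRASTUZUMAB_MIXTURE
>>> r = analyze_mixture(TRASTUZUMAB_MIXTURE)   # totals 4.78/1.46 uM, free antigen 0.08 uM
>>> round(r.p, 4), f"{r.k_a:.3e}", round(r.delta_g, 2)
(0.7659, '2.472e+07', -10.45)
```

Reading: 76.6% of antigen sites are reacted, the mole-fraction association
constant is 2.47×10⁷, and the binding free energy is −10.45 kcal/mol. The
same chain on the pertuzumab mixture gives 3.18×10⁷ and −10.61 kcal/mol —
the slightly tighter binder. On the structure side:

```python
>>> from abaffinity import ContactTally, predict_delta_g
>>> from abaffinity.sasa import NISResult
>>> from abaffinity.tables import Scheme
>>> tally = ContactTally(ic_charged_charged=3, ic_charged_apolar=23,
...                      ic_polar_polar=10, ic_polar_apolar=24)
>>> nis = NISResult(21.0, 42.0, 37.0, {}, 100, 5.0, Scheme.NIS)
>>> round(predict_delta_g(tally, nis), 2)
-12.2
```

— the pertuzumab crystal-interface descriptors evaluate to −12.2 kcal/mol.

The numbered scripts under `analysis/` run the full studies and write
tables under `results/`: `01` the solution-phase affinities, `02` the
descriptor-based predictions (including the charged-NIS coefficient
variant), `03` synthetic SEC quantification (masses back within 1%,
fractions within 0.02), `04` the rigid stoichiometry analysis (open arms
graft clash-free, crowded arms interpenetrate), `05` the crystal-structure
pipeline when 1N8Z/1S78 are available.

A CLI wraps the same library:

```bash
abaffinity predict complex.pdb --antigen C --antibody A,B
abaffinity equilibrium --table species.csv
abaffinity simulate --k-site 5e5 --rho 2.0
abaffinity sec deconvolve --input chromatogram.csv --n-peaks 4
abaffinity graft --structure igg.pdb --antigen-chain G --bound-light L --free-light M
```

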