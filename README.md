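# dnabind

Binding analysis for DNA–intercalator complexes: chemometric estimation of
dissociation constants from UV-VIS titration spectra, construction of
NOE-derived and Watson–Crick distance restraints for restrained molecular
dynamics, sequence cataloguing of palindromic binding sites, and
hydrogen-bond occupancy statistics.

## Who this is for

Spectroscopists and modellers characterizing how planar aromatic ligands
(acridine-type drugs and the like) intercalate into short double-stranded
DNA. The package covers the desk-side computational chain of such a study:

- **Sequence bookkeeping** (`dnabind.seqsteps`): reverse complement,
  palindrome validation, the 10 dinucleotide-step classes of duplex DNA
  under reverse-complement equivalence, and the location of NTAN
  tetranucleotide sites (a central 5′-TA-3′ intercalation cavity with
  variable flanks).
- **Binding model** (`dnabind.binding`): the n-identical-independent-sites
  equilibrium. With total ligand `c`, total duplex `M` and free ligand `L`
  (all µM), the occupancy is ν = (c − L)/M, and the Scatchard relation
  ν/L = (n − ν)/K_d makes the plot of ν/L against ν a line with slope
  −1/K_d and x-intercept n. K_d and n are estimated by piecewise regression
  (binding-regime line plus saturation plateau).
- **Chemometrics** (`dnabind.chemometrics`): titration spectra are centred
  and decomposed into eigenvectors (two-pass PCA); a closed two-species
  system has centred rank 1, the first-component scores are anchored into
  molar fractions of free/bound ligand, and L = x_free·c feeds the
  Scatchard fit.
- **Restraints** (`dnabind.restraints`): NOESY cross-peaks classified
  weak/medium/strong become flat-bottom distance restraints (zero penalty
  between the bounds, 0.5·k·Δ² outside, k = 1000 kJ mol⁻¹ nm⁻² by default);
  Watson–Crick hydrogen bonds contribute 3 restraints per G·C pair and 2
  per A·T pair, terminal pairs excluded by default.
- **Occupancy** (`dnabind.occupancy`): fraction of trajectory frames
  satisfying a geometric hydrogen-bond criterion (distance ≤ 0.35 nm,
  donor–H–acceptor angle ≥ 150° by default).
- **Synthetic data** (`dnabind.synthetic`): two-species Beer–Lambert
  titrations with known ground-truth K_d at the experimental design points
  (10 µM ligand, DNA:ligand ratios 0.25–7), and stochastic hydrogen-bond
  traces — every input the pipeline needs, generated at desk scale.

Two NOE contact tables (23 rows each) and thirteen palindromic study
sequences ship as plain-text fixtures under `dnabind/data`.

## Worked example

Simulate a titration with ground truth K_d = 0.26 µM at the standard design
(10 µM ligand; ratios 0, 0.25, 0.5, 1, 1.5, 2, 3, 5, 7; 0.5 % spectral
noise), then analyse it:

```sh
dnabind simulate-titration --kd 0.26 --noise-sd 0.005 --seed 7 \
    -o spectra.csv --manifest manifest.txt
dnabind analyze-titration spectra.csv --manifest manifest.txt
```

```json
{
  "Kd_uM": 0.24395055537293026,
  "breakpoint_v": null,
  "estimate_flag": false,
  "n_sites": 0.9935842832344063,
  "n_species": 2,
  ...
}
```

The analysis found two spectral species, recovered K_d = 0.244 µM (6 %
from the 0.26 µM ground truth at this noise level) and n ≈ 0.99 sites per
duplex, and did not flag the fit: enough sub-saturation points were
well-determined. `x_free` in the full report shows the free-ligand fraction
collapsing from 1.0 (no DNA) to < 0.01 at ratio 7 — the saturated tail that
is excluded from the regression.

Watson–Crick restraints for the d(CGATATCG)₂ duplex (14 = 3·2 G·C + 2·4 A·T
over the six non-terminal pairs):

```sh
$ dnabind wc-restraints CGATATCG | head -4
atom_i	atom_j	low_nm	up_nm	k_kj_mol_nm2	provenance
A:G2:O6	B:C7:N4	0.27	0.31	1000	wc_hbond
A:G2:N1	B:C7:N3	0.27	0.31	1000	wc_hbond
A:G2:N2	B:C7:O2	0.27	0.31	1000	wc_hbond
```

A 10⁵-frame stochastic hydrogen-bond trace with stationary bonded
probability 0.822 measures back at 0.8217:

```sh
dnabind simulate-trace --p 0.822 --frames 100000 --seed 1 -o trace.tsv
dnabind hbond-occupancy trace.tsv   # -> "occupancy": 0.8217
```

Other subcommands: `steps` (dinucleotide-step TSV from FASTA),
`noe-restraints` (restraints from a contact table, per complex),
`fit-kd` (Scatchard fit from a bare table), `restraint-energy`
(flat-bottom energies and violations).

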