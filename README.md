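# lyase-profile

Comparative sequence/structure profiling of MIO-dependent aromatic amino-acid
ammonia-lyases (PAL, HAL, TAL) — the descriptors used to rationalise why some
family members are thermotolerant and alkalophilic.

Thermophilic enzymes tend to carry dense salt-bridge networks, and
alkalophilic enzymes an excess of acidic residues on the surface.
`lyase-profile` computes, for any set of sequences and homotetrameric
structures, the comparative table that makes those trends visible:

* **Composition columns** — residues per chain, Cys per chain, Asp/Glu/Lys/Arg
  percentages, and the *acid excess* per chain

  `acid excess = (#Asp + #Glu) − (#Lys + #Arg)`

* **Salt bridges** — acidic–basic residue pairs with any side-chain
  oxygen–nitrogen distance ≤ 3.2 Å (Asp OD1/OD2, Glu OE1/OE2 vs Lys NZ,
  Arg NE/NH1/NH2; His optional via `--include-his`). The counting unit is the
  residue pair, and the participation statistic **AA in SB (%)** counts each
  residue once no matter how many bridges it joins.
* **Disulfide candidates** — Cys–Cys pairs with SG–SG distance < 6 Å,
  classified intra- vs inter-subunit on the expanded biological assembly.
* **Family call** — PAL/HAL/TAL classification from the selectivity dyad
  aligned to the Ser83–His84 positions of *P. putida* histidine
  ammonia-lyase (FL → PAL, SH → HAL, HL/HQ → TAL), plus alignment-anchored
  localization of the MIO-forming Ala-Ser-Gly tripeptide.
* **Surface-charge balance** — a declared proxy for electrostatic-surface
  comparison: Shrake–Rupley SASA with an exposure-weighted balance
  `(basic − acidic) / (basic + acidic)` over exposed charged residues,
  in [−1, 1] (−1 = uniformly acidic surface). It is *not* a
  Poisson–Boltzmann potential.

Structures are read from PDB or mmCIF (via gemmi) with biological-assembly
expansion from deposited operators; all statistics are defined on the
functional homotetramer, so expansion is mandatory unless
`--use-asymmetric-unit` is passed explicitly.

A synthetic-data generator (`lyase_profile.synthetic_data`) produces
multimeric toy structures with a *certified* number of planted ion pairs,
decoy pairs just outside the cutoff, and Cys–Cys contacts — plus sequences
with controlled composition and planted motifs — so the entire pipeline is
testable without downloading anything.

## Worked example

Generate a toy homotetramer with 12 planted salt bridges (3 inter-chain), 6
decoy pairs at 3.4–4.0 Å, and 2 disulfide contacts (1 inter-subunit), then
profile it:

```bash
$ lyase-profile synth structure --seed 3 --out-prefix toy
$ lyase-profile structure toy.pdb --use-asymmetric-unit
Source  Enzyme  Residue/chain  CYS/chain  ASP (%)  GLU (%)  LYS (%)  ARG (%)  Acid excess  Salt bridges  AA in SB (%)  SS candidates*  Charge balance*(proxy)
toy             60             0          1.7      3.3      0.0      5.0      0            12            10.0          2               0.005
```

The detector recovers exactly the 12 planted bridges (none of the 6 decoys),
the participation is 10.0% (24 of 240 residues, each counted once), and both
planted Cys–Cys contacts appear under the 6 Å screen. Columns marked `*` are
extensions beyond the classical comparison table; the charge balance is
flagged as a proxy.

Reconstructing a published acid excess from printed percentages:

```python
>>> from lyase_profile import acid_excess_from_percentages
>>> acid_excess_from_percentages(540, 4.8, 8.5, 2.0, 8.3)   # alkalophilic PAL
16
>>> acid_excess_from_percentages(509, 5.1, 5.7, 3.5, 5.3)   # P. putida HAL
10
```

Other entry points: `lyase-profile sequence <fasta> [--classify]`,
`lyase-profile panel <panel.json> [--strict] [--rank-by fraction_in_sb]`,
and `lyase-profile synth sequence --plant ASG@57 --target D=0.2`.

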