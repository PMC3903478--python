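# Methods

## Scope and model

`lyase-profile` implements the descriptor set used to compare MIO-dependent
aromatic amino-acid ammonia-lyases (PAL/HAL/TAL) with respect to
thermotolerance and alkalophilicity. The underlying physical picture: buried
and surface ion pairs stabilise folds at high temperature, and an excess of
acidic residues — particularly solvent-exposed ones — correlates with
activity at strongly basic pH. The package therefore quantifies, per enzyme:
charged-residue composition and net acid excess per chain, the ion-pair
(salt-bridge) network of the functional homotetramer, geometric
disulfide-bridge candidates, family membership from active-site motifs, and
a surface-charge proxy.

## Operational definitions and parameters

| quantity | definition | default | notes |
|---|---|---|---|
| salt bridge | acidic–basic residue pair with any side-chain O–N distance ≤ cutoff | 3.2 Å, **inclusive** | Asp OD1/OD2, Glu OE1/OE2 vs Lys NZ, Arg NE/NH1/NH2 |
| His as basic | ND1/NE2 join the basic set | off | sensitivity flag; the comparative table tabulates only Lys/Arg |
| chain termini | OXT / N-terminal N join the charged sets | off | the criterion is side-chain-defined |
| AA in SB (%) | 100 × (residues in ≥1 bridge, counted once) / (all assembly residues) | — | the count-once rule makes this residue-level |
| disulfide candidate | Cys–Cys SG–SG distance < cutoff | 6.0 Å, **strict** | CB fallback (flagged) when SG is absent; a geometric screen, not a bond assignment |
| acid excess | (#Asp + #Glu) − (#Lys + #Arg) per chain | — | exact integer from counts |
| family dyad | residues aligned to Ser83–His84 of *P. putida* HAL | FL→PAL, SH→HAL, HL/HQ→TAL | other dyads → `ambiguous` |
| anchor identity floor | below this the family call is `non-MIO` | 15% | anchoring below the twilight zone is meaningless |
| alignment | global, affine gaps, BLOSUM62 | open 10, extend 0.5 | EMBOSS-style defaults; gap of length L costs open + (L−1)·extend |
| SASA | Shrake–Rupley, probe 1.4 Å | 960 lattice points/atom | deterministic golden-spiral lattice, no randomness |
| exposure threshold | per-residue SASA above which a residue is "surface" | 5 Å² | configurable |
| surface-charge balance | (basic − acidic)/(basic + acidic) exposed area | — | in [−1, 1]; undefined when no charged residue is exposed |

Cutoff inclusivity is read literally from the defining phrases ("within
3.2 Å" → inclusive; "< 6 Å" → strict). The salt-bridge unit is the residue
pair, not the atomic contact: published counts for ~2,000-residue tetramers
(tens to low hundreds) are consistent with pair counting, and the count-once
participation rule presupposes residue-level semantics.

## Structure handling

Parsing (gemmi) keeps the first coordinate model, excludes waters and
non-amino-acid heteroatoms, retains unknown ATOM-record residue names flagged
`X`, and maps MSE→M. For alternate locations the highest-occupancy conformer
per atom name is kept, ties broken alphabetically — deterministic and
standard practice. Hydrogens are carried but ignored by every distance
criterion and by SASA (heavy-atom definitions). Residue numbers are author
numbering, verbatim from the file; sequence positions are reported 1-based.

Biological assemblies are expanded from deposited operators (REMARK 350 /
mmCIF assembly categories); symmetry copies are renamed `A1, A2, …`
deterministically. Because all tetramer statistics are meaningless on a
monomeric asymmetric unit, there is no silent fallback: analysing deposited
coordinates as-is requires the explicit `--use-asymmetric-unit` flag.
Crystal waters and ions are always stripped before analysis.

## Motif anchoring

The MIO-forming tripeptide is localised by alignment anchoring, not by
leftmost scan: ASG is a common tripeptide, so only the query position aligned
to an annotated reference MIO start counts, and only if the query tripeptide
there is exactly ASG. Family classification aligns the query against every
anchor in the set, takes the highest-identity anchor, and reads the dyad
letters at the query positions aligned to the anchor's dyad. The packaged
anchor set is **synthetic** (generated stand-in sequences with annotated MIO
and dyad sites, labelled as such); it exercises the machinery and supports
testing, while real classification should use anchors built from curated
reference enzymes via `load_anchors`.

Alignment is delegated to Biopython's `PairwiseAligner` (global mode,
affine gaps). When several alignments are co-optimal the aligner's first
traceback is used; this is deterministic for fixed inputs, which is the
property the reports need — the specific diagonal-first tie-break order is
not semantically meaningful, and scores are verified against an independent
three-state dynamic program in the test suite.

## SASA and the surface-charge proxy

Continuum electrostatics is out of scope; the surface comparison is a
declared proxy. SASA uses the Shrake–Rupley construction on a golden-spiral
lattice: points on each probe-expanded atom sphere are tested against all
probe-expanded neighbour spheres, and the accessible fraction scales the
sphere area. The lattice is fixed, so results are exactly reproducible; an
isolated sphere is exact by construction, a two-sphere system agrees with the
closed-form spherical-cap area to well under 2% at 960 points, and
rigid-body motion changes whole-model totals by < 0.5%. Van der Waals radii
are a fixed published set (Bondi; Se 1.9 Å) shipped with the package —
reproducibility was preferred over configurability. Unknown elements raise an
error naming the atom rather than guessing a radius.

The balance (basic − acidic)/(basic + acidic) over exposed charged residues
orders structures by negative surface character. It is validated only on
constructed pairs where the ordering is true by construction (e.g. swapping
exposed Lys→Glu must strictly lower it); no claim is made that it reproduces
rendered electrostatic-potential surfaces, which are not quantitative.

## Synthetic ground truth

The generator lays residues on a wide grid (12 Å spacing, one chain per
row), assigns disjoint residue-pair slots for features, and positions named
side-chain atoms (OD1/OE1, NZ/NH1, SG) so each planted pair realises its
drawn distance exactly: ion pairs at 2.7–3.1 Å, decoys at 3.4–4.0 Å,
disulfide contacts at 2.0–2.2 Å by default. These defaults sit comfortably
inside/outside the 3.2 Å criterion with an enforced ±0.05 Å ambiguity gap
around every cutoff, so detection can never hinge on floating-point noise.
Backbone atoms get a small (±0.3 Å) seeded jitter so local geometry is not
artificially repetitive; planted key atoms stay exact. Before returning, the
generator *certifies* by exhaustive brute force that the planted features are
the only ones present, and raises rather than emitting an ambiguous
instance. Generation is deterministic per seed down to the PDB bytes.

What the toys do not emulate: rotamer realism, clash energies, backbone
connectivity across the grid, crystallographic artifacts (alt-locs,
occupancies < 1, waters), or realistic sequence composition. Passing tests
therefore demonstrate correctness of the *criteria and statistics*, not
agreement with any particular deposited structure; the latter is checked
separately against published tetramer counts when the reference files are
available (see `scripts/fetch_reference_data.py`).

Sequence generation fills a length with a target composition (±1 count per
targeted letter), plants motifs at stated positions, and rejection-samples
the background so each planted motif occurs nowhere else.

## Problem sizes and determinism

Default verification runs use 4-chain × 60-residue toys (240 residues,
~1,300 atoms) and batches of 25–50 random specs — sizes chosen so the whole
suite and the reproduction script complete in seconds on one core while
still exercising multi-chain statistics. All randomness flows through
explicit seeds (numpy `default_rng`); reports embed a config hash, input
checksums and the package version, and repeated runs are byte-identical.

## Known limitations

* Exact reproduction of published per-structure bridge counts depends on the
  original tool's atom selection (His, termini, assembly choice), which is
  why the sensitivity flags exist; two published acid-excess rows are
  internally inconsistent with the printed percentages under the stated
  definition and are carried as documented exceptions rather than fitted.
* The disulfide screen is purely geometric; it proposes candidates, not
  bonds (no redox or stereochemical assessment).
* NMR multi-model files use the first model only; no structure editing or
  writing beyond the synthetic generator's PDB output.
* The family rule covers the PAL/HAL/TAL dyad variants only; aminomutases
  and other MIO enzymes with different dyads will report `ambiguous`.
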