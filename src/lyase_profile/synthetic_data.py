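"""Synthetic structures and sequences with certified ground truth.

Every analysis stage of this package is distance- or motif-based, so it can be
exercised end-to-end on toy inputs whose true feature set is known by
construction: multimeric structures with a planted number of acidic–basic ion
pairs at controlled distances (plus decoy pairs just outside the cutoff),
planted proximal Cys–Cys pairs, and sequences with controlled residue
composition and planted motifs.

Toy structures use a minimal atom set per residue (backbone N, CA, C, O, a CB,
plus the named charged/thiol side-chain atoms) — sufficient because all
implemented criteria reference named atoms; rotamer realism is deliberately
absent.  Residue sites are laid out on a wide grid (one chain per row) so that
the only sub-cutoff contacts are the planted ones, and the generator
*certifies* this by an exhaustive brute-force distance scan before returning;
an ambiguity gap of ±0.05 Å around each cutoff is enforced so that detection
can never hinge on floating-point noise.

Generation is deterministic for a fixed seed, down to the PDB bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import gemmi
import numpy as np

from .bridge_analysis import ACIDIC_ATOMS, BASIC_ATOMS
from .errors import GenerationError
from .structure_io import (
    AtomRecord,
    Chain,
    ChainSequence,
    Residue,
    ResidueRef,
    StructureModel,
)

_SPACING = 12.0  # Å between residue sites; large vs all cutoffs
_SB_CUTOFF = 3.2
_SS_CUTOFF = 6.0
_GAP = 0.05  # ambiguity gap enforced around both cutoffs

#: minimal atom sets; local offsets from the residue site (Å)
_BACKBONE = {
    "N": (-1.2, 0.5, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, 0.5, 0.0),
    "O": (1.3, 1.6, 0.2),
    "CB": (0.0, -1.0, 0.8),
}
_FILLER_NAMES = ("ALA", "SER", "THR", "VAL", "LEU", "PHE")
_ONE = {"ALA": "A", "SER": "S", "THR": "T", "VAL": "V", "LEU": "L", "PHE": "F",
        "ASP": "D", "GLU": "E", "LYS": "K", "ARG": "R", "CYS": "C"}
#: key charged atom placed at the planted distance; trailing atoms sit behind it
_KEY_ATOM = {"ASP": "OD1", "GLU": "OE1", "LYS": "NZ", "ARG": "NH1", "CYS": "SG"}
_TRAILING = {"ASP": ("OD2",), "GLU": ("OE2",), "LYS": (), "ARG": ("NE", "NH2"), "CYS": ()}


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Specification of a toy multimer with planted features."""

    n_chains: int = 4
    residues_per_chain: int = 60
    n_salt_bridges: int = 12
    n_inter_chain_bridges: int = 3
    n_decoys: int = 6
    n_disulfides: int = 2
    n_inter_chain_disulfides: int = 1
    bridge_distance_range: tuple[float, float] = (2.7, 3.1)
    decoy_distance_range: tuple[float, float] = (3.4, 4.0)
    disulfide_distance_range: tuple[float, float] = (2.0, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bridge_distance_range
        if not (0 < lo <= hi <= _SB_CUTOFF - _GAP):
            raise GenerationError(
                f"bridge_distance_range must lie within (0, {_SB_CUTOFF - _GAP}]"
            )
        lo, hi = self.decoy_distance_range
        if not (_SB_CUTOFF + _GAP <= lo <= hi < _SPACING / 2):
            raise GenerationError(
                f"decoy_distance_range must lie within [{_SB_CUTOFF + _GAP}, {_SPACING / 2})"
            )
        lo, hi = self.disulfide_distance_range
        if not (0 < lo <= hi <= _SS_CUTOFF - _GAP):
            raise GenerationError(
                f"disulfide_distance_range must lie within (0, {_SS_CUTOFF - _GAP}]"
            )
        if self.n_inter_chain_bridges > self.n_salt_bridges:
            raise GenerationError("n_inter_chain_bridges exceeds n_salt_bridges")
        if self.n_inter_chain_disulfides > self.n_disulfides:
            raise GenerationError("n_inter_chain_disulfides exceeds n_disulfides")
        if self.n_chains < 1 or self.residues_per_chain < 2:
            raise GenerationError("need at least 1 chain with 2 residues")
        n_inter = self.n_inter_chain_bridges + self.n_inter_chain_disulfides
        if n_inter > 0 and self.n_chains < 2:
            raise GenerationError("inter-chain features require at least 2 chains")


@dataclass(frozen=True)
class PlantedPair:
    first: ResidueRef
    second: ResidueRef
    distance: float
    inter_chain: bool


@dataclass
class SyntheticTruth:
    """Certified ground truth accompanying generated data."""

    planted_ion_pairs: list[PlantedPair] = field(default_factory=list)
    decoy_pairs: list[PlantedPair] = field(default_factory=list)
    planted_disulfides: list[PlantedPair] = field(default_factory=list)
    sequence_plants: list[tuple[str, int]] = field(default_factory=list)
    composition_target: dict[str, float] = field(default_factory=dict)
    chain_sequences: list[str] = field(default_factory=list)


def _chain_id(index: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if index < len(alphabet):
        return alphabet[index]
    return alphabet[index // len(alphabet) - 1] + alphabet[index % len(alphabet)]


def _site(chain: int, i: int) -> np.ndarray:
    return np.array([i * _SPACING, chain * _SPACING, 0.0])


class _Slots:
    """Disjoint residue-pair slots for planting features.

    Intra-chain slots pair residues (i, i+1) with i ≡ 0 (mod 3); inter-chain
    slots pair residue i of adjacent chains with i ≡ 2 (mod 3).  The modular
    classes keep any two slots at least one full grid spacing apart.
    """

    def __init__(self, spec: SyntheticStructureSpec, rng: np.random.Generator):
        self.intra = [
            (c, i, c, i + 1)
            for c in range(spec.n_chains)
            for i in range(0, spec.residues_per_chain - 1, 3)
        ]
        self.inter = [
            (c, i, c + 1, i)
            for c in range(spec.n_chains - 1)
            for i in range(2, spec.residues_per_chain, 3)
        ]
        rng.shuffle(self.intra)
        rng.shuffle(self.inter)
        self._used: set[tuple[int, int]] = set()

    def take(self, kind: str, n: int, what: str):
        pool = self.intra if kind == "intra" else self.inter
        taken = []
        rest = []
        for slot in pool:
            c1, i1, c2, i2 = slot
            if len(taken) < n and not {(c1, i1), (c2, i2)} & self._used:
                taken.append(slot)
                self._used |= {(c1, i1), (c2, i2)}
            else:
                rest.append(slot)
        if len(taken) < n:
            raise GenerationError(
                f"spec unsatisfiable: needs {n} {kind}-chain slots for {what}, "
                f"only {len(taken)} disjoint residue pairs available"
            )
        if kind == "intra":
            self.intra = rest
        else:
            self.inter = rest
        return taken


def _place_feature(residue_types: dict, overrides: dict, slot, kind: str,
                   distance: float, rng: np.random.Generator) -> None:
    """Assign residue types and key-atom positions realising one feature."""
    c1, i1, c2, i2 = slot
    p1, p2 = _site(c1, i1), _site(c2, i2)
    axis = (p2 - p1) / np.linalg.norm(p2 - p1)
    mid = (p1 + p2) / 2.0
    if kind == "disulfide":
        names = ("CYS", "CYS")
    else:
        acid = rng.choice(("ASP", "GLU"))
        base = rng.choice(("LYS", "ARG"))
        names = (acid, base) if rng.random() < 0.5 else (base, acid)
    for (c, i), name, sign in (((c1, i1), names[0], -1.0), ((c2, i2), names[1], +1.0)):
        residue_types[(c, i)] = name
        key_pos = mid + sign * (distance / 2.0) * axis
        positions = {_KEY_ATOM[name]: key_pos}
        for k, trailing in enumerate(_TRAILING[name], start=1):
            positions[trailing] = key_pos + sign * 1.0 * k * axis
        overrides[(c, i)] = positions


def _element_of(atom_name: str) -> str:
    return {"N": "N", "C": "C", "O": "O", "S": "S"}[atom_name[0]]


def _build_model(spec: SyntheticStructureSpec, residue_types: dict, overrides: dict,
                 structure_id: str, rng: np.random.Generator) -> StructureModel:
    model = StructureModel(structure_id=structure_id)
    for c in range(spec.n_chains):
        chain = Chain(chain_id=_chain_id(c))
        for i in range(spec.residues_per_chain):
            name = residue_types[(c, i)]
            ref = ResidueRef(chain_id=chain.chain_id, residue_number=i + 1, residue_name=name)
            site = _site(c, i)
            # small jitter breaks the grid's artificial local-geometry
            # repetition; feature key atoms (placed below) stay exact
            atoms = [
                AtomRecord(name=an, element=_element_of(an),
                           position=site + np.array(off) + rng.uniform(-0.3, 0.3, 3))
                for an, off in _BACKBONE.items()
            ]
            for an, pos in overrides.get((c, i), {}).items():
                atoms.append(AtomRecord(name=an, element=_element_of(an), position=pos))
            chain.residues.append(Residue(ref=ref, one_letter=_ONE[name], atoms=atoms))
        model.chains.append(chain)
    return model


def _ref_pair_key(a: ResidueRef, b: ResidueRef):
    ka = (a.chain_id, a.residue_number)
    kb = (b.chain_id, b.residue_number)
    return (ka, kb) if ka <= kb else (kb, ka)


def _certify(model: StructureModel, truth: SyntheticTruth, spec: SyntheticStructureSpec) -> None:
    """Exhaustive check that planted features are the only ones present."""
    acid, base, thiol = [], [], []
    for res in model.iter_residues():
        for a in res.atoms:
            if res.name in ACIDIC_ATOMS and a.name in ACIDIC_ATOMS[res.name]:
                acid.append((res.ref, a.position))
            elif res.name in BASIC_ATOMS and a.name in BASIC_ATOMS[res.name]:
                base.append((res.ref, a.position))
            elif res.name == "CYS" and a.name == "SG":
                thiol.append((res.ref, a.position))

    found: dict = {}
    for ra, pa in acid:
        for rb, pb in base:
            d = float(np.linalg.norm(pa - pb))
            if abs(d - _SB_CUTOFF) < _GAP:
                raise GenerationError(f"ambiguous O-N distance {d:.3f} near cutoff")
            if d <= _SB_CUTOFF:
                key = _ref_pair_key(ra, rb)
                found[key] = min(d, found.get(key, np.inf))
    planted = {_ref_pair_key(p.first, p.second): p.distance for p in truth.planted_ion_pairs}
    if set(found) != set(planted):
        raise GenerationError("accidental or missing ion pair in generated structure")
    for key, d in found.items():
        if abs(d - planted[key]) > 1e-6:
            raise GenerationError("planted ion-pair distance not realised")

    decoys = {_ref_pair_key(p.first, p.second) for p in truth.decoy_pairs}
    lo, hi = spec.decoy_distance_range
    for p in truth.decoy_pairs:
        if not (lo - 1e-9 <= p.distance <= hi + 1e-9):
            raise GenerationError("decoy outside its distance range")
    if decoys & set(planted):
        raise GenerationError("decoy collides with planted pair")

    found_ss: dict = {}
    for (ra, pa), (rb, pb) in combinations(thiol, 2):
        d = float(np.linalg.norm(pa - pb))
        if abs(d - _SS_CUTOFF) < _GAP:
            raise GenerationError(f"ambiguous SG-SG distance {d:.3f} near cutoff")
        if d < _SS_CUTOFF:
            found_ss[_ref_pair_key(ra, rb)] = d
    planted_ss = {_ref_pair_key(p.first, p.second): p.distance for p in truth.planted_disulfides}
    if set(found_ss) != set(planted_ss):
        raise GenerationError("accidental or missing disulfide in generated structure")


def generate_structure(
    spec: SyntheticStructureSpec,
) -> tuple[StructureModel, SyntheticTruth]:
    """Generate a toy multimer realising ``spec``, with certified truth.

    Returns the coordinate model and a :class:`SyntheticTruth` listing every
    planted ion pair (with its realised minimum O–N distance and inter-chain
    flag), decoy pair and Cys–Cys pair.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    slots = _Slots(spec, rng)

    residue_types: dict = {}
    overrides: dict = {}
    plan: list[tuple[str, tuple, float]] = []

    n_intra_sb = spec.n_salt_bridges - spec.n_inter_chain_bridges
    for slot in slots.take("intra", n_intra_sb, "intra-chain salt bridges"):
        plan.append(("bridge", slot, float(rng.uniform(*spec.bridge_distance_range))))
    for slot in slots.take("inter", spec.n_inter_chain_bridges, "inter-chain salt bridges"):
        plan.append(("bridge", slot, float(rng.uniform(*spec.bridge_distance_range))))
    for slot in slots.take("intra", spec.n_decoys, "decoy pairs"):
        plan.append(("decoy", slot, float(rng.uniform(*spec.decoy_distance_range))))
    n_intra_ss = spec.n_disulfides - spec.n_inter_chain_disulfides
    for slot in slots.take("intra", n_intra_ss, "intra-chain disulfides"):
        plan.append(("disulfide", slot, float(rng.uniform(*spec.disulfide_distance_range))))
    for slot in slots.take("inter", spec.n_inter_chain_disulfides, "inter-chain disulfides"):
        plan.append(("disulfide", slot, float(rng.uniform(*spec.disulfide_distance_range))))

    for kind, slot, distance in plan:
        _place_feature(residue_types, overrides, slot, kind, distance, rng)

    for c in range(spec.n_chains):
        for i in range(spec.residues_per_chain):
            if (c, i) not in residue_types:
                residue_types[(c, i)] = str(rng.choice(_FILLER_NAMES))

    structure_id = f"synthetic-{spec.seed}"
    model = _build_model(spec, residue_types, overrides, structure_id, rng)

    truth = SyntheticTruth(chain_sequences=[
        "".join(res.one_letter for res in chain.residues) for chain in model.chains
    ])
    for kind, slot, distance in plan:
        c1, i1, c2, i2 = slot
        ref1 = model.chains[c1].residues[i1].ref
        ref2 = model.chains[c2].residues[i2].ref
        pair = PlantedPair(first=ref1, second=ref2, distance=distance, inter_chain=c1 != c2)
        if kind == "bridge":
            truth.planted_ion_pairs.append(pair)
        elif kind == "decoy":
            truth.decoy_pairs.append(pair)
        else:
            truth.planted_disulfides.append(pair)

    _certify(model, truth, spec)
    return model, truth


# ---------------------------------------------------------------------------
# PDB output


def to_pdb_string(model: StructureModel) -> str:
    """Serialise a model as PDB text (byte-deterministic for a fixed model)."""
    st = gemmi.Structure()
    st.name = model.structure_id
    g_model = gemmi.Model(1)
    for chain in model.chains:
        g_chain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.ref.residue_number, res.ref.insertion_code or " ")
            for a in res.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = a.name
                g_atom.pos = gemmi.Position(*np.round(a.position, 3))
                g_atom.element = gemmi.Element(a.element)
                g_atom.occ = a.occupancy
                g_atom.b_iso = 0.0
                g_res.add_atom(g_atom)
            g_chain.add_residue(g_res)
        g_model.add_chain(g_chain)
    st.add_model(g_model)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# sequences

_CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


def generate_sequence(
    length: int,
    composition_target: dict[str, float] | None = None,
    plants: list[tuple[str, int]] | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[ChainSequence, SyntheticTruth]:
    """Random sequence with target composition and motifs planted exactly once.

    ``plants`` is a list of ``(motif, 1-based position)``; planted motifs are
    guaranteed to occur at their stated positions and nowhere else (rejection
    sampling of the background).  Residue counts for letters named in
    ``composition_target`` (letter → frequency) match the target within ±1.
    """
    composition_target = composition_target or {}
    plants = list(plants or [])

    occupied: set[int] = set()
    for motif, pos in plants:
        if pos < 1 or pos + len(motif) - 1 > length:
            raise GenerationError(f"plant {motif!r}@{pos} does not fit in length {length}")
        span = set(range(pos - 1, pos - 1 + len(motif)))
        if span & occupied:
            raise GenerationError(f"plant {motif!r}@{pos} overlaps another plant")
        occupied |= span

    planted_letters: dict[str, int] = {}
    for motif, _ in plants:
        for ch in motif:
            planted_letters[ch] = planted_letters.get(ch, 0) + 1

    free = length - len(occupied)
    fill: list[str] = []
    for letter, freq in sorted(composition_target.items()):
        need = round(freq * length) - planted_letters.get(letter, 0)
        fill.extend(letter * max(0, need))
    if len(fill) > free:
        raise GenerationError("composition target exceeds available positions")
    background = [ch for ch in _CANONICAL if ch not in composition_target]

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pad = list(rng.choice(background, size=free - len(fill)))
        pool = fill + pad
        rng.shuffle(pool)
        seq = [""] * length
        for motif, pos in plants:
            seq[pos - 1 : pos - 1 + len(motif)] = list(motif)
        it = iter(pool)
        for i in range(length):
            if not seq[i]:
                seq[i] = next(it)
        text = "".join(seq)
        expected: dict[str, list[int]] = {}
        for motif, pos in plants:
            expected.setdefault(motif, []).append(pos)
        if all(
            [m.start() + 1 for m in _finditer_overlapping(motif, text)] == sorted(positions)
            for motif, positions in expected.items()
        ):
            truth = SyntheticTruth(
                sequence_plants=plants,
                composition_target=dict(composition_target),
                chain_sequences=[text],
            )
            return ChainSequence(source_id=f"synthetic-seq-{seed}", residues=text), truth
    raise GenerationError("could not avoid accidental motif occurrences; "
                          "relax plants or composition target")


def _finditer_overlapping(motif: str, text: str):
    import re

    return re.finditer(f"(?={re.escape(motif)})", text)
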