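"""Reading of PDB/mmCIF structures, biological-assembly expansion and FASTA I/O.

The coordinate model built here is the substrate for all distance-based
analyses (salt-bridge and disulfide-candidate detection, solvent-accessible
surface area).  Parsing is delegated to :mod:`gemmi`; this module reduces the
parsed structure to a plain in-memory model holding, per chain, the ordered
amino-acid residues and their heavy/hydrogen atoms.

Conventions
-----------
* Residue numbers are taken verbatim from the file (author numbering).
* For alternate-location groups only the highest-occupancy conformer of each
  atom is retained; ties are broken by alphabetical alt-loc identifier.
* Waters and non-amino-acid heteroatoms are excluded.  Selenomethionine (MSE)
  maps to ``M``; other non-standard amino acids map to ``X``.
* Only the first model of a multi-model (e.g. NMR) file is read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AssemblyError, FastaError, MalformedInputError

AMINO_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "Residue",
    "Chain",
    "StructureModel",
    "ChainSequence",
    "parse_structure",
    "apply_assembly",
    "extract_sequences",
    "read_fasta",
    "write_fasta",
]


@dataclass(eq=False)
class AtomRecord:
    """A single atom: PDB-convention name, element symbol and position in Å."""

    name: str
    element: str
    position: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Author-numbered residue identifier, e.g. Cys 150 of chain A."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def __str__(self) -> str:  # matches the field's "150C(A)" style loosely
        return f"{self.residue_name} {self.residue_number}{self.insertion_code}({self.chain_id})"


@dataclass
class Residue:
    ref: ResidueRef
    one_letter: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_standard: bool = True

    @property
    def name(self) -> str:
        return self.ref.residue_name

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class _AssemblyOperator:
    """One rigid-body operator of a biological assembly generator."""

    chain_ids: tuple[str, ...] | None  # None = applies to all chains
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3-vector

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=1e-9)
            and np.allclose(self.translation, 0.0, atol=1e-9)
        )


@dataclass
class StructureModel:
    """A parsed multimeric structure: chains → residues → atoms."""

    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    assembly_applied: bool = False
    assembly_label: str = ""
    assemblies: dict[str, list[_AssemblyOperator]] = field(default_factory=dict, repr=False)

    def iter_residues(self):
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self):
        for res in self.iter_residues():
            yield from res.atoms

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def residue_refs(self) -> set[ResidueRef]:
        return {r.ref for r in self.iter_residues()}

    def coordinate_checksum(self) -> float:
        """Order-independent checksum used to verify read-only analyses."""
        return float(sum(np.sum(a.position) for a in self.iter_atoms()))


@dataclass(frozen=True)
class ChainSequence:
    """One-letter amino-acid sequence of a chain or database record.

    ``numbering_offset`` is the author number of the first residue, so the
    1-based sequence position ``i`` corresponds to residue number
    ``numbering_offset + i - 1``.
    """

    source_id: str
    residues: str
    chain_id: str = ""
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_LETTERS
        if bad:
            raise MalformedInputError(
                f"sequence {self.source_id!r}: illegal residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# parsing


def _detect_format(text: str) -> str:
    head = text.lstrip()[:4000]
    if head.startswith("data_") or "_atom_site." in head:
        return "cif"
    return "pdb"


def _one_letter(res_name: str, info: gemmi.ResidueInfo | None) -> tuple[str, bool]:
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code
        if code.strip():
            return code.upper(), code.isupper()
    return "X", False


def _select_alt_locs(raw_atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep, per atom name, the highest-occupancy conformer (tie: alphabetical)."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in raw_atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
            continue
        cur = best[atom.name]
        if (atom.occupancy, -ord(atom.alt_loc or "~")) > (cur.occupancy, -ord(cur.alt_loc or "~")):
            best[atom.name] = atom
    return [best[name] for name in order]


def _subchain_to_chain(model: gemmi.Model) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for chain in model:
        for res in chain:
            if res.subchain:
                mapping.setdefault(res.subchain, chain.name)
    return mapping


def _extract_assemblies(st: gemmi.Structure) -> dict[str, list[_AssemblyOperator]]:
    sub2chain = _subchain_to_chain(st[0]) if len(st) else {}
    assemblies: dict[str, list[_AssemblyOperator]] = {}
    for asm in st.assemblies:
        ops: list[_AssemblyOperator] = []
        for gen in asm.generators:
            chain_ids: tuple[str, ...] | None
            names = [c for c in gen.chains if c and c != "(all)"]
            if not names and gen.subchains:
                seen: list[str] = []
                for sub in gen.subchains:
                    parent = sub2chain.get(sub)
                    if parent and parent not in seen:
                        seen.append(parent)
                names = seen
            chain_ids = tuple(names) if names else None
            for op in gen.operators:
                tr = op.transform
                ops.append(
                    _AssemblyOperator(
                        chain_ids=chain_ids,
                        rotation=np.array(tr.mat.tolist(), dtype=float),
                        translation=np.array(tr.vec.tolist(), dtype=float),
                    )
                )
        if ops:
            assemblies[asm.name] = ops
    return assemblies


def parse_structure(text: str, *, fmt: str | None = None, structure_id: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF document into a :class:`StructureModel`.

    Parameters
    ----------
    text:
        The document content.  The format is auto-detected unless ``fmt``
        (``"pdb"`` or ``"cif"``) is given.
    structure_id:
        Overrides the identifier found in the document.

    Raises
    ------
    MalformedInputError
        If the document contains no polymer (amino-acid) atom records.
    """
    fmt = fmt or _detect_format(text)
    try:
        if fmt == "cif":
            block = gemmi.cif.read_string(text).sole_block()
            st = gemmi.make_structure_from_block(block)
        elif fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            raise MalformedInputError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise MalformedInputError(f"could not parse {fmt} document: {exc}") from exc

    if len(st) == 0:
        raise MalformedInputError("document contains no coordinate model")

    model = StructureModel(structure_id=structure_id or st.name or "structure")
    model.assemblies = _extract_assemblies(st)

    skipped: list[str] = []
    for g_chain in st[0]:
        chain = Chain(chain_id=g_chain.name)
        for g_res in g_chain:
            info = gemmi.find_tabulated_residue(g_res.name)
            is_water = info is not None and info.is_water()
            is_amino = info is not None and info.is_amino_acid()
            # HETATM ligands/ions/waters are excluded; unknown ATOM-record
            # residue names are retained and flagged 'X'.
            if is_water or (not is_amino and g_res.het_flag != "A"):
                skipped.append(f"{g_res.name} {g_res.seqid.num}({g_chain.name})")
                continue
            letter, standard = _one_letter(g_res.name, info)
            ref = ResidueRef(
                chain_id=g_chain.name,
                residue_number=g_res.seqid.num,
                insertion_code=(g_res.seqid.icode or "").strip(),
                residue_name=g_res.name,
            )
            raw = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    alt_loc=a.altloc or "",
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    is_hydrogen=a.element.is_hydrogen,
                )
                for a in g_res
            ]
            chain.residues.append(
                Residue(ref=ref, one_letter=letter, atoms=_select_alt_locs(raw), is_standard=standard)
            )
        if chain.residues:
            model.chains.append(chain)

    if not model.chains:
        detail = f" (only non-polymer records such as {skipped[0]})" if skipped else ""
        raise MalformedInputError(f"document contains no polymer atom records{detail}")
    return model


# ---------------------------------------------------------------------------
# biological assembly


def apply_assembly(model: StructureModel, assembly_label: str) -> StructureModel:
    """Expand ``model`` to the biological assembly named ``assembly_label``.

    Symmetry copies are renamed deterministically as original chain id plus
    1-based copy index (``A`` → ``A1``, ``A2``, ...).  An identity-only
    assembly returns an unrenamed copy with only the flag set.
    """
    if not model.assemblies:
        raise AssemblyError(
            "no assembly transforms present in the source document; "
            "pass --use-asymmetric-unit to analyse the deposited coordinates as-is"
        )
    if assembly_label not in model.assemblies:
        available = ", ".join(sorted(model.assemblies))
        raise AssemblyError(
            f"unknown assembly {assembly_label!r}; available labels: {available}"
        )
    ops = model.assemblies[assembly_label]

    per_chain: dict[str, list[_AssemblyOperator]] = {}
    for chain in model.chains:
        per_chain[chain.chain_id] = [
            op for op in ops if op.chain_ids is None or chain.chain_id in op.chain_ids
        ]

    identity_only = all(
        len(lst) == 1 and lst[0].is_identity for lst in per_chain.values() if lst
    ) and all(len(lst) <= 1 for lst in per_chain.values())

    out = StructureModel(
        structure_id=model.structure_id,
        assembly_applied=True,
        assembly_label=assembly_label,
    )
    for chain in model.chains:
        chain_ops = per_chain[chain.chain_id]
        for k, op in enumerate(chain_ops, start=1):
            new_id = chain.chain_id if identity_only else f"{chain.chain_id}{k}"
            new_chain = Chain(chain_id=new_id)
            for res in chain.residues:
                new_ref = replace(res.ref, chain_id=new_id)
                new_atoms = [
                    AtomRecord(
                        name=a.name,
                        element=a.element,
                        position=op.rotation @ a.position + op.translation,
                        alt_loc=a.alt_loc,
                        occupancy=a.occupancy,
                        is_hydrogen=a.is_hydrogen,
                    )
                    for a in res.atoms
                ]
                new_chain.residues.append(
                    Residue(ref=new_ref, one_letter=res.one_letter, atoms=new_atoms,
                            is_standard=res.is_standard)
                )
            out.chains.append(new_chain)

    ids = [c.chain_id for c in out.chains]
    if len(ids) != len(set(ids)):
        raise AssemblyError(f"assembly expansion produced duplicate chain ids: {ids}")
    return out


# ---------------------------------------------------------------------------
# sequences


def extract_sequences(model: StructureModel) -> list[ChainSequence]:
    """One :class:`ChainSequence` per chain, in model order."""
    out = []
    for chain in model.chains:
        seq = "".join(res.one_letter for res in chain.residues)
        out.append(
            ChainSequence(
                source_id=model.structure_id,
                chain_id=chain.chain_id,
                residues=seq,
                numbering_offset=chain.residues[0].ref.residue_number,
            )
        )
    return out


def read_fasta(text: str) -> list[ChainSequence]:
    """Parse FASTA text; ``chain=`` and ``start=`` description tokens are honoured."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records and text.strip():
        raise FastaError("no FASTA records found (headers must start with '>')")
    out: list[ChainSequence] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"record {rec.id!r} is empty")
        bad = set(seq) - AMINO_LETTERS
        if bad:
            raise FastaError(f"record {rec.id!r}: illegal characters {sorted(bad)}")
        chain_id = ""
        offset = 1
        for token in rec.description.split()[1:]:
            if token.startswith("chain="):
                chain_id = token[len("chain="):]
            elif token.startswith("start="):
                offset = int(token[len("start="):])
        out.append(ChainSequence(source_id=rec.id, residues=seq, chain_id=chain_id,
                                 numbering_offset=offset))
    return out


def write_fasta(seqs: list[ChainSequence]) -> str:
    """Write sequences as 60-column-wrapped FASTA; inverse of :func:`read_fasta`."""
    records = []
    for s in seqs:
        desc = []
        if s.chain_id:
            desc.append(f"chain={s.chain_id}")
        if s.numbering_offset != 1:
            desc.append(f"start={s.numbering_offset}")
        records.append(SeqRecord(Seq(s.residues), id=s.source_id, description=" ".join(desc)))
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
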