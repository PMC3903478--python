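"""Salt-bridge and disulfide-candidate detection on multimeric structures.

A *salt bridge* is operationally defined as an acidic–basic residue pair with
any side-chain oxygen–nitrogen distance within 3.2 Å (inclusive): Asp OD1/OD2
and Glu OE1/OE2 against Lys NZ and Arg NE/NH1/NH2.  Histidine (ND1/NE2) can be
added for sensitivity analysis but is excluded by default, matching the
ionizable-residue columns of the comparative report.  The unit of counting is
the residue pair — a pair with several atomic O–N contacts is one bridge — and
for the participation statistic a residue engaged in several bridges is
counted only once.

A *disulfide candidate* is a Cys–Cys pair with SG–SG distance strictly below
6 Å; pairs across different chains are flagged inter-subunit.  This is a
geometric screen for bridges that *could* form, not an assignment of bonded
disulfides.

Detection is accelerated with a k-d tree; results are identical to an
all-pairs scan (the test-suite enforces this equivalence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError
from .structure_io import Residue, ResidueRef, StructureModel

#: residue → side-chain oxygen atoms carrying the carboxylate charge
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
#: residue → side-chain nitrogen atoms carrying the positive charge
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_ATOMS = {"HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class IonPairConfig:
    """Criteria for the ion-pair (salt-bridge) search."""

    cutoff: float = 3.2  # Å, inclusive
    include_his: bool = False
    include_termini: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def basic_atoms(self) -> dict[str, tuple[str, ...]]:
        table = dict(BASIC_ATOMS)
        if self.include_his:
            table.update(HIS_ATOMS)
        return table


@dataclass(frozen=True)
class IonPair:
    acidic: ResidueRef
    basic: ResidueRef
    min_distance: float
    inter_chain: bool


@dataclass(frozen=True)
class IonPairStats:
    """Aggregate bridge statistics over a whole (assembly) model."""

    n_pairs: int
    n_unique_residues: int
    total_residues: int
    fraction_in_sb: float  # percent of all residues in ≥1 bridge, counted once
    n_inter_chain: int


@dataclass(frozen=True)
class DisulfideConfig:
    cutoff: float = 6.0  # Å, strict <

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class DisulfidePair:
    cys_a: ResidueRef
    cys_b: ResidueRef
    distance: float
    inter_subunit: bool
    fallback_atoms: bool = False  # CB-CB used because an SG was missing


def _sort_key(ref: ResidueRef) -> tuple:
    return (ref.chain_id, ref.residue_number, ref.insertion_code)


def _charged_atom_table(model: StructureModel, table: dict[str, tuple[str, ...]],
                        termini: str | None = None):
    """Collect (residue index, position) rows for the configured charged atoms.

    ``termini`` adds chain-terminal charges: ``"N"`` appends the backbone N of
    each chain's first residue, ``"C"`` the OXT/terminal carboxylate oxygens.
    """
    residues: list[ResidueRef] = []
    coords: list[np.ndarray] = []
    owner: list[int] = []

    def add(res: Residue, atom_names: tuple[str, ...]) -> None:
        found = [a for a in res.atoms if a.name in atom_names and not a.is_hydrogen]
        if not found:
            return
        residues.append(res.ref)
        idx = len(residues) - 1
        for a in found:
            coords.append(a.position)
            owner.append(idx)

    for chain in model.chains:
        for i, res in enumerate(chain.residues):
            names = table.get(res.name)
            extra: tuple[str, ...] = ()
            if termini == "N" and i == 0:
                extra = ("N",)
            elif termini == "C" and i == len(chain.residues) - 1:
                extra = ("OXT",)
            if names or extra:
                add(res, tuple(names or ()) + extra)
    return residues, (np.array(coords) if coords else np.empty((0, 3))), np.array(owner, dtype=int)


def find_salt_bridges(model: StructureModel, config: IonPairConfig | None = None) -> list[IonPair]:
    """All acidic–basic residue pairs with an O–N contact within the cutoff.

    Each qualifying residue pair is reported once with its minimum O–N
    distance, ordered deterministically by (chain, residue number).  A model
    with no acidic or no basic residues yields an empty list.
    """
    config = config or IonPairConfig()
    acid_refs, acid_xyz, acid_owner = _charged_atom_table(
        model, ACIDIC_ATOMS, termini="C" if config.include_termini else None)
    base_refs, base_xyz, base_owner = _charged_atom_table(
        model, config.basic_atoms, termini="N" if config.include_termini else None)
    if len(acid_xyz) == 0 or len(base_xyz) == 0:
        return []

    tree = cKDTree(base_xyz)
    neighbor_lists = tree.query_ball_point(acid_xyz, r=config.cutoff)

    best: dict[tuple[int, int], float] = {}
    for ai, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        a_res = acid_owner[ai]
        a_pos = acid_xyz[ai]
        for bi in neighbors:
            b_res = base_owner[bi]
            key = (a_res, b_res)
            d = float(np.linalg.norm(a_pos - base_xyz[bi]))
            if key not in best or d < best[key]:
                best[key] = d

    pairs = [
        IonPair(
            acidic=acid_refs[ak],
            basic=base_refs[bk],
            min_distance=d,
            inter_chain=acid_refs[ak].chain_id != base_refs[bk].chain_id,
        )
        for (ak, bk), d in best.items()
    ]
    pairs.sort(key=lambda p: (_sort_key(p.acidic), _sort_key(p.basic)))
    return pairs


def ion_pair_stats(pairs: list[IonPair], model: StructureModel) -> IonPairStats:
    """Bridge count and residue-participation statistics with the count-once rule."""
    known = model.residue_refs()
    participants: set[ResidueRef] = set()
    n_inter = 0
    for p in pairs:
        for ref in (p.acidic, p.basic):
            if ref not in known:
                raise ConsistencyError(f"pair residue {ref} not present in model")
        participants.add(p.acidic)
        participants.add(p.basic)
        n_inter += p.inter_chain
    total = model.n_residues
    return IonPairStats(
        n_pairs=len(pairs),
        n_unique_residues=len(participants),
        total_residues=total,
        fraction_in_sb=100.0 * len(participants) / total if total else 0.0,
        n_inter_chain=n_inter,
    )


def find_disulfide_candidates(
    model: StructureModel, config: DisulfideConfig | None = None
) -> list[DisulfidePair]:
    """All Cys–Cys pairs with SG–SG distance strictly below the cutoff.

    When a cysteine lacks its SG atom the CB position is used instead and the
    pair flagged ``fallback_atoms``.  Each unordered pair is reported once,
    with the partner lower in (chain, number) order first.
    """
    config = config or DisulfideConfig()
    refs: list[ResidueRef] = []
    xyz: list[np.ndarray] = []
    fallback: list[bool] = []
    for res in model.iter_residues():
        if res.name != "CYS":
            continue
        atom = res.atom("SG")
        fb = False
        if atom is None:
            atom = res.atom("CB")
            fb = True
        if atom is None:
            continue
        refs.append(res.ref)
        xyz.append(atom.position)
        fallback.append(fb)
    if len(xyz) < 2:
        return []

    arr = np.array(xyz)
    tree = cKDTree(arr)
    out: list[DisulfidePair] = []
    for i, j in sorted(tree.query_pairs(r=config.cutoff)):
        d = float(np.linalg.norm(arr[i] - arr[j]))
        if d >= config.cutoff:  # query_pairs is inclusive; the criterion is strict
            continue
        a, b = sorted((refs[i], refs[j]), key=_sort_key)
        out.append(
            DisulfidePair(
                cys_a=a,
                cys_b=b,
                distance=d,
                inter_subunit=a.chain_id != b.chain_id,
                fallback_atoms=fallback[i] or fallback[j],
            )
        )
    out.sort(key=lambda p: (_sort_key(p.cys_a), _sort_key(p.cys_b)))
    return out


@dataclass(frozen=True)
class BridgeReport:
    """Structure-derived descriptor fragment for one (assembly) model."""

    stats: IonPairStats
    pairs: list[IonPair] = field(repr=False)
    disulfides: list[DisulfidePair] = field(repr=False)
    n_disulfides: int
    n_inter_subunit_disulfides: int
    cys_per_chain: dict[str, int]
    ion_config: IonPairConfig
    ss_config: DisulfideConfig


def bridge_report(
    model: StructureModel,
    ion_config: IonPairConfig | None = None,
    ss_config: DisulfideConfig | None = None,
) -> BridgeReport:
    """Bundle ion-pair statistics, disulfide candidates and Cys counts."""
    ion_config = ion_config or IonPairConfig()
    ss_config = ss_config or DisulfideConfig()
    pairs = find_salt_bridges(model, ion_config)
    stats = ion_pair_stats(pairs, model)
    disulfides = find_disulfide_candidates(model, ss_config)
    cys_per_chain = {
        chain.chain_id: sum(res.name == "CYS" for res in chain.residues)
        for chain in model.chains
    }
    return BridgeReport(
        stats=stats,
        pairs=pairs,
        disulfides=disulfides,
        n_disulfides=len(disulfides),
        n_inter_subunit_disulfides=sum(p.inter_subunit for p in disulfides),
        cys_per_chain=cys_per_chain,
        ion_config=ion_config,
        ss_config=ss_config,
    )
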