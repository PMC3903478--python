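"""Sequence-level descriptors of MIO ammonia-lyases.

Three groups of operations live here:

* **Composition** — per-chain residue counts, the four ionizable-residue
  percentages (Asp, Glu, Lys, Arg), cysteine count and the *acid excess*
  (#Asp + #Glu) − (#Lys + #Arg), a net-acidity index associated with
  alkalophilic enzymes.
* **Alignment** — optimal global (end-to-end) pairwise alignment with an
  affine gap model and a named substitution matrix (default BLOSUM62),
  delegated to :class:`Bio.Align.PairwiseAligner`.
* **Motif calls** — localization of the MIO-forming Ala-Ser-Gly tripeptide by
  alignment anchoring against an annotated reference, and PAL/HAL/TAL family
  classification from the selectivity dyad (the two residues aligned to the
  Ser83-His84 positions of *P. putida* histidine ammonia-lyase): FL → PAL,
  SH → HAL, HL or HQ → TAL.

Anchoring is used rather than a leftmost scan because ASG is a common
tripeptide; only the occurrence aligned to the reference MIO site counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, MalformedInputError
from .structure_io import ChainSequence, read_fasta

ACIDIC_LETTERS = ("D", "E")
BASIC_LETTERS = ("K", "R")

#: dyad → enzyme family (substrate specificity) mapping
DYAD_FAMILIES = {"FL": "PAL", "SH": "HAL", "HL": "TAL", "HQ": "TAL"}


@dataclass(frozen=True)
class CompositionProfile:
    """Residue composition of one chain (the sequence-derived report columns)."""

    source_id: str
    chain_length: int
    counts: dict[str, int]
    cys_count: int
    acid_excess: int

    def percentage(self, letter: str) -> float:
        return 100.0 * self.counts.get(letter, 0) / self.chain_length

    def rounded_percentage(self, letter: str) -> float:
        """1-decimal percentage as printed in comparative tables."""
        return round(self.percentage(letter), 1)


@dataclass(frozen=True)
class AlignmentResult:
    """Global pairwise alignment with per-column position maps (1-based)."""

    aligned_query: str
    aligned_reference: str
    score: float
    percent_identity: float
    query_to_ref: dict[int, int | None] = field(repr=False)
    ref_to_query: dict[int, int | None] = field(repr=False)


@dataclass(frozen=True)
class AnchorReference:
    """A reference sequence annotated with MIO and selectivity-dyad positions."""

    sequence: ChainSequence
    family: str
    mio_start: int  # 1-based position of the A of the ASG tripeptide
    dyad_positions: tuple[int, int]  # 1-based, analogous to Ser83-His84 of PpHAL


@dataclass(frozen=True)
class MotifCall:
    """MIO-motif location and enzyme-family call for a query sequence."""

    mio_start: int | None
    selectivity_pair: str
    family: str  # PAL | HAL | TAL | ambiguous | non-MIO
    anchor_identity: float
    anchor_id: str = ""


# ---------------------------------------------------------------------------
# composition


def composition(seq: ChainSequence) -> CompositionProfile:
    """Count residues and derive the ionizable-composition columns.

    Raises :class:`MalformedInputError` for an empty sequence.  Non-standard
    residues (``X``) are counted in the chain length but contribute to none of
    the charged-residue statistics.
    """
    if len(seq.residues) == 0:
        raise MalformedInputError(f"sequence {seq.source_id!r} is empty")
    counts: dict[str, int] = {}
    for letter in seq.residues:
        counts[letter] = counts.get(letter, 0) + 1
    acid_excess = (
        counts.get("D", 0) + counts.get("E", 0) - counts.get("K", 0) - counts.get("R", 0)
    )
    return CompositionProfile(
        source_id=seq.source_id if not seq.chain_id else f"{seq.source_id}:{seq.chain_id}",
        chain_length=len(seq.residues),
        counts=counts,
        cys_count=counts.get("C", 0),
        acid_excess=acid_excess,
    )


def acid_excess_from_percentages(
    length: int, asp_pct: float, glu_pct: float, lys_pct: float, arg_pct: float
) -> int:
    """Reconstruct the integer acid excess from rounded printed percentages.

    Returns ``length × (Asp% + Glu% − Lys% − Arg%) / 100`` rounded to the
    nearest integer, ties away from zero.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    value = length * (asp_pct + glu_pct - lys_pct - arg_pct) / 100.0
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


# ---------------------------------------------------------------------------
# alignment


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError:
        available = ", ".join(substitution_matrices.load())
        raise ConfigurationError(
            f"unknown substitution matrix {matrix!r}; available: {available}"
        ) from None
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = sub
    # affine gap model: a gap of length L costs gap_open + (L-1)*gap_extend
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    query: ChainSequence,
    reference: ChainSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal end-to-end alignment of ``query`` against ``reference``.

    Percent identity is computed over all alignment columns.  When several
    alignments share the optimal score the first traceback reported by the
    aligner is used, which is deterministic for fixed inputs.
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(query.residues, reference.residues)[0]
    gapped_q, gapped_r = str(alignment[0]), str(alignment[1])

    q_to_r: dict[int, int | None] = {}
    r_to_q: dict[int, int | None] = {}
    qi = ri = 0
    matches = 0
    for cq, cr in zip(gapped_q, gapped_r):
        if cq != "-" and cr != "-":
            qi += 1
            ri += 1
            q_to_r[qi] = ri
            r_to_q[ri] = qi
            if cq == cr:
                matches += 1
        elif cq != "-":
            qi += 1
            q_to_r[qi] = None
        elif cr != "-":
            ri += 1
            r_to_q[ri] = None
    n_columns = len(gapped_q)
    return AlignmentResult(
        aligned_query=gapped_q,
        aligned_reference=gapped_r,
        score=float(alignment.score),
        percent_identity=100.0 * matches / n_columns if n_columns else 0.0,
        query_to_ref=q_to_r,
        ref_to_query=r_to_q,
    )


# ---------------------------------------------------------------------------
# motif calls


def locate_mio_motif(
    query: ChainSequence,
    reference: AnchorReference,
    **align_kwargs,
) -> MotifCall:
    """Locate the ASG tripeptide of ``query`` by anchoring to ``reference``.

    The query position aligned to the reference MIO start is reported if and
    only if the query tripeptide starting there is exactly ``ASG``; a mere
    occurrence of ASG elsewhere never counts.
    """
    aln = global_align(query, reference.sequence, **align_kwargs)
    mio_start = _anchored_mio_start(query, reference, aln)
    return MotifCall(
        mio_start=mio_start,
        selectivity_pair="",
        family="",
        anchor_identity=aln.percent_identity,
        anchor_id=reference.sequence.source_id,
    )


def _anchored_mio_start(query: ChainSequence, reference: AnchorReference,
                        aln: AlignmentResult) -> int | None:
    pos = aln.ref_to_query.get(reference.mio_start)
    if pos is None:
        return None
    if query.residues[pos - 1 : pos + 2] == "ASG":
        return pos
    return None


def classify_family(
    query: ChainSequence,
    anchors: list[AnchorReference],
    identity_threshold: float = 15.0,
    **align_kwargs,
) -> MotifCall:
    """PAL/HAL/TAL family call from the anchored selectivity dyad.

    The query is aligned against every anchor; the anchor with the highest
    percent identity supplies the dyad and MIO anchoring.  A query with no
    anchored ASG tripeptide, or whose best anchor identity falls below
    ``identity_threshold`` (anchoring below the twilight zone is meaningless),
    is called ``non-MIO``.
    """
    if not anchors:
        raise ConfigurationError("anchor reference set is empty")

    best: AnchorReference | None = None
    best_aln: AlignmentResult | None = None
    for anchor in anchors:
        aln = global_align(query, anchor.sequence, **align_kwargs)
        if best_aln is None or aln.percent_identity > best_aln.percent_identity:
            best, best_aln = anchor, aln
    assert best is not None and best_aln is not None

    mio_start = _anchored_mio_start(query, best, best_aln)
    p1, p2 = best.dyad_positions
    q1 = best_aln.ref_to_query.get(p1)
    q2 = best_aln.ref_to_query.get(p2)
    dyad = (query.residues[q1 - 1] if q1 else "-") + (query.residues[q2 - 1] if q2 else "-")

    if mio_start is None or best_aln.percent_identity < identity_threshold:
        family = "non-MIO"
        mio_start = None
    else:
        family = DYAD_FAMILIES.get(dyad, "ambiguous")
    return MotifCall(
        mio_start=mio_start,
        selectivity_pair=dyad,
        family=family,
        anchor_identity=best_aln.percent_identity,
        anchor_id=best.sequence.source_id,
    )


def load_default_anchors() -> list[AnchorReference]:
    """Load the packaged *synthetic* anchor set.

    These anchors are synthetic stand-in sequences with annotated MIO and dyad
    positions; they exercise the anchoring machinery but are not database
    sequences.  For real classification supply anchors built from curated
    reference enzymes via :func:`load_anchors`.
    """
    data = resources.files("lyase_profile") / "data"
    return load_anchors(
        (data / "synthetic_anchors.fasta").read_text(),
        (data / "synthetic_anchors.json").read_text(),
    )


def load_anchors(fasta_text: str, annotation_json: str) -> list[AnchorReference]:
    """Build an anchor set from FASTA plus a JSON annotation map.

    The JSON maps record id → ``{"family", "mio_start", "dyad_positions"}``
    with 1-based sequence positions.
    """
    annotations = json.loads(annotation_json)
    anchors = []
    for seq in read_fasta(fasta_text):
        ann = annotations.get(seq.source_id)
        if ann is None:
            raise ConfigurationError(f"anchor {seq.source_id!r} has no annotation entry")
        mio = int(ann["mio_start"])
        if seq.residues[mio - 1 : mio + 2] != "ASG":
            raise ConfigurationError(
                f"anchor {seq.source_id!r}: annotated MIO start {mio} is not an ASG site"
            )
        anchors.append(
            AnchorReference(
                sequence=seq,
                family=str(ann["family"]),
                mio_start=mio,
                dyad_positions=(int(ann["dyad_positions"][0]), int(ann["dyad_positions"][1])),
            )
        )
    return anchors
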