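"""Panel orchestration: comparative descriptor rows over sequences/structures.

A *panel* is a JSON document listing entries, each naming a sequence file and
optionally a structure file with an assembly label.  For every entry a
:class:`DescriptorRow` is computed: the sequence-derived columns (chain
length, Cys count, ionizable percentages, acid excess), and — when a structure
is given — the salt-bridge statistics, disulfide-candidate count and the
surface-charge balance proxy.  Output is TSV with report rounding (1-decimal
percentages) or JSON with full precision; rows embed provenance (config hash,
input checksums, package version) so every number is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bridge_analysis import DisulfideConfig, IonPairConfig, bridge_report
from .errors import ConfigurationError, LyaseProfileError
from .sequence_profile import AnchorReference, classify_family, composition
from .structure_io import (
    ChainSequence,
    StructureModel,
    apply_assembly,
    extract_sequences,
    parse_structure,
    read_fasta,
)
from .surface_charge import compute_sasa, surface_charge_summary

#: column → (header label, TSV formatter); starred headers mark extensions
#: beyond the classical comparative table; the charge balance is additionally
#: marked as an electrostatics proxy.
_COLUMNS: dict[str, tuple[str, str]] = {
    "label": ("Source", "s"),
    "family": ("Enzyme", "s"),
    "chain_length": ("Residue/chain", "d"),
    "cys_per_chain": ("CYS/chain", "d"),
    "asp_pct": ("ASP (%)", ".1f"),
    "glu_pct": ("GLU (%)", ".1f"),
    "lys_pct": ("LYS (%)", ".1f"),
    "arg_pct": ("ARG (%)", ".1f"),
    "acid_excess": ("Acid excess", "d"),
    "n_salt_bridges": ("Salt bridges", "d"),
    "fraction_in_sb": ("AA in SB (%)", ".1f"),
    "n_disulfide_candidates": ("SS candidates*", "d"),
    "surface_charge_balance": ("Charge balance*(proxy)", ".3f"),
}


@dataclass
class DescriptorRow:
    """One comparative-report row; structural columns are None when absent."""

    label: str
    family: str = ""
    chain_length: int | None = None
    cys_per_chain: int | None = None
    asp_pct: float | None = None
    glu_pct: float | None = None
    lys_pct: float | None = None
    arg_pct: float | None = None
    acid_excess: int | None = None
    n_salt_bridges: int | None = None
    fraction_in_sb: float | None = None
    n_disulfide_candidates: int | None = None
    surface_charge_balance: float | None = None
    error: str = ""
    provenance: dict = field(default_factory=dict)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def config_hash(config: dict) -> str:
    return _sha256(json.dumps(config, sort_keys=True, default=str).encode())[:16]


def profile_sequence(
    seq: ChainSequence,
    label: str | None = None,
    anchors: list[AnchorReference] | None = None,
) -> DescriptorRow:
    """Sequence-only descriptor row; family via anchor classification if given."""
    prof = composition(seq)
    row = DescriptorRow(
        label=label or prof.source_id,
        chain_length=prof.chain_length,
        cys_per_chain=prof.cys_count,
        asp_pct=prof.percentage("D"),
        glu_pct=prof.percentage("E"),
        lys_pct=prof.percentage("K"),
        arg_pct=prof.percentage("R"),
        acid_excess=prof.acid_excess,
    )
    if anchors:
        call = classify_family(seq, anchors)
        row.family = call.family
        row.provenance["anchor_id"] = call.anchor_id
        row.provenance["anchor_identity"] = round(call.anchor_identity, 2)
        if call.mio_start is not None:
            row.provenance["mio_start"] = call.mio_start
    return row


def profile_structure(
    model: StructureModel,
    label: str | None = None,
    ion_config: IonPairConfig | None = None,
    ss_config: DisulfideConfig | None = None,
    compute_surface: bool = True,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    exposure_threshold: float = 5.0,
    anchors: list[AnchorReference] | None = None,
) -> DescriptorRow:
    """Full descriptor row for a (pre-expanded) structure model.

    Sequence columns are computed from the first chain; bridge statistics are
    over the whole model, so the model should already be the intended
    biological assembly.
    """
    seq = extract_sequences(model)[0]
    row = profile_sequence(seq, label=label or model.structure_id, anchors=anchors)
    rep = bridge_report(model, ion_config, ss_config)
    row.n_salt_bridges = rep.stats.n_pairs
    row.fraction_in_sb = rep.stats.fraction_in_sb
    row.n_disulfide_candidates = rep.n_disulfides
    row.provenance.update(
        {
            "assembly_applied": model.assembly_applied,
            "assembly_label": model.assembly_label,
            "saltbridge_cutoff": rep.ion_config.cutoff,
            "include_his": rep.ion_config.include_his,
            "ss_cutoff": rep.ss_config.cutoff,
            "n_chains": len(model.chains),
            "n_inter_chain_bridges": rep.stats.n_inter_chain,
            "n_inter_subunit_ss": rep.n_inter_subunit_disulfides,
        }
    )
    if compute_surface:
        sasa = compute_sasa(model, probe_radius, n_sphere_points)
        summary = surface_charge_summary(model, sasa, exposure_threshold)
        row.surface_charge_balance = summary.surface_charge_balance
        row.provenance["surface_charge_is_proxy"] = True
    return row


def run_panel(
    panel: dict,
    base_dir: Path | str = ".",
    anchors: list[AnchorReference] | None = None,
    compute_surface: bool = True,
) -> list[DescriptorRow]:
    """Compute descriptor rows for every panel entry, in panel order.

    Entries with unreadable inputs yield a row whose ``error`` field is set;
    remaining entries are still processed.  Panel schema::

        {"entries": [{"label": ..., "sequence": "a.fasta",
                      "structure": "a.pdb", "assembly": "1",
                      "use_asymmetric_unit": false, "family": "PAL"}, ...],
         "options": {"saltbridge_cutoff": 3.2, "ss_cutoff": 6.0,
                     "include_his": false}}
    """
    base = Path(base_dir)
    options = panel.get("options", {})
    ion_config = IonPairConfig(
        cutoff=float(options.get("saltbridge_cutoff", 3.2)),
        include_his=bool(options.get("include_his", False)),
    )
    ss_config = DisulfideConfig(cutoff=float(options.get("ss_cutoff", 6.0)))
    chash = config_hash(panel)

    rows: list[DescriptorRow] = []
    for entry in panel.get("entries", []):
        label = entry.get("label", entry.get("sequence", entry.get("structure", "?")))
        try:
            rows.append(
                _run_entry(entry, base, label, ion_config, ss_config, anchors, compute_surface)
            )
        except (LyaseProfileError, OSError, ValueError) as exc:
            rows.append(DescriptorRow(label=label, error=str(exc)))
        rows[-1].provenance["config_hash"] = chash
        rows[-1].provenance["version"] = __version__
    return rows


def _run_entry(entry, base, label, ion_config, ss_config, anchors, compute_surface):
    checksums = {}
    model = None
    seq = None
    if entry.get("structure"):
        spath = base / entry["structure"]
        text = spath.read_text()
        checksums[str(entry["structure"])] = _sha256(text.encode())
        model = parse_structure(text, structure_id=label)
        if entry.get("assembly"):
            model = apply_assembly(model, str(entry["assembly"]))
        elif model.assemblies and not entry.get("use_asymmetric_unit"):
            label_first = sorted(model.assemblies)[0]
            model = apply_assembly(model, label_first)
    if entry.get("sequence"):
        qpath = base / entry["sequence"]
        text = qpath.read_text()
        checksums[str(entry["sequence"])] = _sha256(text.encode())
        seq = read_fasta(text)[0]

    if model is not None:
        row = profile_structure(
            model, label=label, ion_config=ion_config, ss_config=ss_config,
            compute_surface=compute_surface, anchors=anchors,
        )
        if seq is not None:
            seq_row = profile_sequence(seq, label=label, anchors=anchors)
            for col in ("chain_length", "cys_per_chain", "asp_pct", "glu_pct",
                        "lys_pct", "arg_pct", "acid_excess", "family"):
                setattr(row, col, getattr(seq_row, col))
            row.provenance.update(seq_row.provenance)
    elif seq is not None:
        row = profile_sequence(seq, label=label, anchors=anchors)
    else:
        raise ConfigurationError(f"panel entry {label!r} names neither sequence nor structure")

    if not row.family and entry.get("family"):
        row.family = str(entry["family"])
    row.provenance["inputs"] = checksums
    return row


def rank_rows(rows: list[DescriptorRow], key: str) -> list[DescriptorRow]:
    """Stable descending sort by a numeric column; ties keep panel order."""
    numeric = [c for c, (_, f) in _COLUMNS.items() if f != "s"]
    if key not in numeric:
        raise ConfigurationError(f"unknown sort key {key!r}; numeric columns: {', '.join(numeric)}")
    absent = [r for r in rows if getattr(r, key) is None]
    present = [r for r in rows if getattr(r, key) is not None]
    return sorted(present, key=lambda r: -getattr(r, key)) + absent


def to_tsv(rows: list[DescriptorRow]) -> str:
    """TSV report with table rounding (starred headers mark extensions)."""
    lines = ["\t".join(header for header, _ in _COLUMNS.values())]
    for row in rows:
        cells = []
        for col, (_, fmt) in _COLUMNS.items():
            value = getattr(row, col)
            if value is None:
                cells.append("")
            elif fmt == "s":
                cells.append(str(value))
            else:
                cells.append(format(value, fmt))
        if row.error:
            cells[-1] = cells[-1] + f"\t# ERROR: {row.error}"
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def to_json(rows: list[DescriptorRow]) -> str:
    """Full-precision JSON report (machine-exact companion to the TSV)."""
    return json.dumps([dataclasses.asdict(r) for r in rows], indent=2, sort_keys=True)
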