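"""Published comparison panel of MIO ammonia-lyases.

These are the printed per-chain composition and salt-bridge figures for the
panel of aromatic amino-acid ammonia-lyases used in comparative analyses of
thermotolerance and alkalophilicity: chain length, cysteines per chain, the
four ionizable-residue percentages (1 decimal, as printed), the printed acid
excess, and — where a homotetrameric 3-D structure was available — the printed
salt-bridge count and participation percentage.

They serve as *inputs* for desk-scale reconstruction checks (e.g. recovering
the integer acid excess from the rounded percentages); the structural counts
are tied to specific deposited tetramers or undeposited homology models, noted
in ``structure_source``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PanelRow:
    label: str
    organism: str
    family: str
    chain_length: int
    cys_per_chain: int
    asp_pct: float
    glu_pct: float
    lys_pct: float
    arg_pct: float
    acid_excess: int
    n_salt_bridges: int
    aa_in_sb_pct: float
    structure_source: str
    #: the printed acid excess is consistent with (#D+#E)−(#K+#R) reconstructed
    #: from the rounded percentages; False marks documented exceptions
    acid_excess_consistent: bool = True


REFERENCE_PANEL: tuple[PanelRow, ...] = (
    PanelRow("RxPAL", "Rubrobacter xylanophilus", "PAL", 540, 9, 4.8, 8.5, 2.0, 8.3,
             16, 285, 23.1, "homology model (undeposited)"),
    PanelRow("PlPAL", "Photorhabdus luminescens", "PAL", 532, 7, 4.5, 6.2, 5.1, 3.9,
             9, 220, 16.0, "homology model (undeposited)"),
    PanelRow("PpHAL", "Pseudomonas putida", "HAL", 509, 7, 5.1, 5.7, 3.5, 5.3,
             10, 128, 11.4, "PDB 1GKM"),
    PanelRow("PcPAL", "Petroselinum crispum", "PAL", 716, 9, 3.8, 7.7, 5.6, 5.6,
             12, 148, 9.1, "PDB 1W27", acid_excess_consistent=False),
    PanelRow("RtPAL", "Rhodosporidium toruloides", "PAL", 716, 4, 4.2, 5.7, 4.0, 4.9,
             7, 137, 8.0, "PDB 1Y2M"),
    PanelRow("RsTAL", "Rhodobacter sphaeroides", "TAL", 523, 8, 5.5, 4.2, 1.0, 8.8,
             0, 98, 8.2, "PDB 2O7E", acid_excess_consistent=False),
    PanelRow("AvPAL", "Anabaena variabilis", "PAL", 567, 6, 5.5, 3.4, 3.2, 4.4,
             7, 74, 5.9, "PDB 3CZO"),
    PanelRow("NpPAL", "Nostoc punctiforme", "PAL", 569, 7, 5.6, 3.9, 3.1, 4.4,
             11, 68, 5.3, "PDB 2NYF"),
)


def panel_row(label: str) -> PanelRow:
    for row in REFERENCE_PANEL:
        if row.label == label:
            return row
    raise KeyError(f"no panel row labelled {label!r}")
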