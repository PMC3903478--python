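#!/usr/bin/env python
"""Download the reference inputs used by the accession/structure checks.

Fetches the UniProt sequences (Q1AV79, Q7N4T3, P21310) and the deposited
biological assemblies of the comparison tetramers (1GKM, 3CZO, 1W27, 2O7E,
1Y2M, 2NYF) into ``data/reference/``.  Requires network access; the analysis
itself never does.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

UNIPROT = ("Q1AV79", "Q7N4T3", "P21310")
PDB_ASSEMBLIES = ("1gkm", "3czo", "1w27", "2o7e", "1y2m", "2nyf")

OUT = Path(__file__).resolve().parent.parent / "data" / "reference"


def fetch(url: str, dest: Path) -> None:
    print(f"  {url} -> {dest}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    for acc in UNIPROT:
        fetch(f"https://rest.uniprot.org/uniprotkb/{acc}.fasta", OUT / f"{acc}.fasta")
    for pdb_id in PDB_ASSEMBLIES:
        # deposited biological assembly 1, uncompressed PDB format
        fetch(
            f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb1",
            OUT / f"{pdb_id}_assembly1.pdb",
        )
    print("done")
    return 0


if __name__ == "__main__":
    sys.exit(main())
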