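#!/usr/bin/env python
"""Download the worked-example PDB entries into scratch/pdb (network needed).

Enables the optional real-structure tests in tests/test_acceptance.py:
3HBX (D3 hexamer engaging three interface types), 1A99 (non-isomorphic
dimer lattice, monomer call) and 2VCO (open heterologous lattice, monomer
call).
"""

import urllib.request
from pathlib import Path

ENTRIES = ["3hbx", "1a99", "2vco"]
DEST = Path(__file__).resolve().parent.parent / "scratch" / "pdb"


def main():
    DEST.mkdir(parents=True, exist_ok=True)
    for pdb_id in ENTRIES:
        out = DEST / f"{pdb_id}.cif"
        if out.exists():
            print(f"{out} already present")
            continue
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
        print(f"fetching {url}")
        urllib.request.urlretrieve(url, out)
    print("done")


if __name__ == "__main__":
    main()
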