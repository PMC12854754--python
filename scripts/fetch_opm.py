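"""Download the OPM-oriented reference structures used by the test suite.

The structural-radius acceptance checks compare against membrane-oriented
PDB files from the Orientations of Proteins in Membranes (OPM) database,
which cannot be redistributed with the package.  Run this script once with
network access::

    python scripts/fetch_opm.py

It places 6kr8.pdb, 2rh1.pdb and 4hkr.pdb under data/opm/.
"""

import urllib.request
from pathlib import Path

OPM_URL = "https://opm-assets.storage.googleapis.com/pdb/{pdb_id}.pdb"
PDB_IDS = ("6kr8", "2rh1", "4hkr")


def main() -> None:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "opm"
    out_dir.mkdir(parents=True, exist_ok=True)
    for pdb_id in PDB_IDS:
        target = out_dir / f"{pdb_id}.pdb"
        if target.exists():
            print(f"{target} already present")
            continue
        url = OPM_URL.format(pdb_id=pdb_id)
        print(f"fetching {url}")
        with urllib.request.urlopen(url, timeout=60) as resp:
            target.write_bytes(resp.read())
        print(f"wrote {target} ({target.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
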