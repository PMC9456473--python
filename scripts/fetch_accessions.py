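#!/usr/bin/env python
"""Fetch the four Bletilla plastome accessions from NCBI (network required).

This is a convenience script outside the tested surface: the test suite and
acceptance script never download anything. Usage:

    python scripts/fetch_accessions.py [--out data/accessions]
"""

import argparse
import time
import urllib.request
from pathlib import Path

ACCESSIONS = ("OP104328", "OP104329", "OP104330", "MT806143")
EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text"
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="data/accessions")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = out / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} exists, skipping")
            continue
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as fh:
            dest.write_bytes(fh.read())
        time.sleep(0.5)
    print(f"records under {out}/; run scripts/verify_published.py next")


if __name__ == "__main__":
    main()
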