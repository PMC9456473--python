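#!/usr/bin/env python
"""Check the recomputed comparative values against the reference table values
for the four deposited accessions (fetch them first; see fetch_accessions.py)."""

import argparse
import json
import sys

from plastcomp.published import verify_published


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dir", default="data/accessions")
    args = ap.parse_args()
    checks = verify_published(args.dir)
    print(json.dumps(checks, indent=1, default=str))
    bad = [k for k, v in checks.items() if not v["ok"]]
    if bad:
        print(f"FAILED: {bad}", file=sys.stderr)
        sys.exit(1)
    print(f"all {len(checks)} checks passed")


if __name__ == "__main__":
    main()
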