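#!/usr/bin/env python
"""Download the deposited coordinate files used for validation runs.

This is the only network-touching script in the repository; the library
itself never fetches anything.  Files land as mmCIF under
``structures/`` (or ``--dest``).

Accessions:

* 3K4X — the X-ray-derived eukaryotic clamp (PCNA) bound to a 10-bp
  duplex (named in the study).
* 1PLQ — S. cerevisiae PCNA alone (molecular-replacement search model,
  named in the study).
* 3GLF — E. coli clamp-loader (gamma-complex) bound to primer-template
  DNA; 1SXJ — yeast RFC bound to closed PCNA; 3BEP — E. coli beta clamp
  bound to primer-template DNA.  These three are identified in the
  study only by citation; the accessions here are the corresponding
  deposited entries — verify against the cited publications before
  relying on them.

Usage::

    python scripts/fetch_structures.py [--dest structures/]
"""

import argparse
import urllib.request
from pathlib import Path

ACCESSIONS = ["3K4X", "1PLQ", "3GLF", "1SXJ", "3BEP"]
URL = "https://files.rcsb.org/download/{}.cif"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("structures"))
    parser.add_argument("--accessions", nargs="*", default=ACCESSIONS)
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for acc in args.accessions:
        target = args.dest / f"{acc.upper()}.cif"
        if target.exists():
            print(f"{target} already present, skipping")
            continue
        print(f"fetching {acc} ...")
        urllib.request.urlretrieve(URL.format(acc.upper()), target)
        print(f"  -> {target} ({target.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
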