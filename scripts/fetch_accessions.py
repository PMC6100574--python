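#!/usr/bin/env python
"""Fetch the five published Cynanchum chloroplast accessions from NCBI.

Downloads each accession as FASTA via NCBI E-utilities into
``data/accessions/<accession>.fasta`` (~800 kb total).  Requires network
access; run once, then the published-panel checks in the test suite and in
``scripts/acceptance.py`` pick the files up automatically.

Usage:
    python scripts/fetch_accessions.py [--outdir data/accessions]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.request
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from indeldiag.published import PUBLISHED_ACCESSIONS  # noqa: E402

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=REPO / "data" / "accessions")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for acc in PUBLISHED_ACCESSIONS:
        dest = args.outdir / f"{acc}.fasta"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        url = EFETCH.format(acc=acc)
        print(f"{acc}: fetching ...")
        with urllib.request.urlopen(url, timeout=60) as resp:
            data = resp.read()
        if not data.startswith(b">"):
            print(f"{acc}: unexpected response, skipping", file=sys.stderr)
            return 1
        dest.write_bytes(data)
        time.sleep(0.4)  # NCBI rate-limit etiquette
    print(f"done; files in {args.outdir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
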