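#!/usr/bin/env python
"""One-time download of the 14 published thrips mitogenome GenBank records.

Usage:  python scripts/fetch_genbank.py --out data/genbank

Requires network access to NCBI E-utilities.  The downloaded flat files feed
`mitorder ingest` / the real-data acceptance test; nothing in the library
fetches from the network.
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.request
from pathlib import Path

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nucleotide&id={acc}&rettype=gb&retmode=text"
)

#: taxon id (matching the packaged tree tips) -> GenBank accession(s).
#: S_dorsalis_SA is multipartite: two records, one per chromosome.
#: The printed source table lists MF991901 for both N_samayunkur and T_palmi;
#: T_palmi is mapped here to the adjacent deposit MF991902 — verify on use.
ACCESSIONS: dict[str, tuple[str, ...]] = {
    "F_vespiformis": ("MN072395",),
    "H_indicus": ("MN072397",),
    "R_cruentatus": ("MN072396",),
    "G_uzeli": ("MK940484",),
    "D_minowai": ("MF582634",),
    "N_samayunkur": ("MF991901",),
    "T_palmi": ("MF991902",),
    "A_obscurus": ("KY498001",),
    "S_dorsalis_EA": ("KM349826",),
    "S_dorsalis_SA": ("KM349827", "KM349828"),
    "F_intonsa": ("JQ917403",),
    "F_occidentalis": ("JN835456",),
    "T_imaginis": ("AF335993",),
    "H_aculeatus": ("KP198620",),
}


def fetch(accession: str, timeout: float = 30.0) -> str:
    with urllib.request.urlopen(EFETCH.format(acc=accession), timeout=timeout) as fh:
        return fh.read().decode()


def fetch_all(outdir: Path, timeout: float = 30.0, pause: float = 0.4) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for taxon, accs in ACCESSIONS.items():
        for acc in accs:
            path = outdir / f"{taxon}.{acc}.gb"
            if path.exists():
                written.append(path)
                continue
            text = fetch(acc, timeout=timeout)
            if "FEATURES" not in text:
                raise RuntimeError(f"{acc}: response is not a GenBank flat file")
            path.write_text(text)
            written.append(path)
            time.sleep(pause)  # NCBI rate courtesy
    return written


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("data/genbank"))
    ap.add_argument("--timeout", type=float, default=30.0)
    args = ap.parse_args(argv)
    paths = fetch_all(args.out, timeout=args.timeout)
    print(f"fetched {len(paths)} records into {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
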