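"""Optional, untested convenience: fetch the public datasets this pipeline
was designed around, for full-scale reproduction runs.

Requires network access; nothing in the package or its test suite depends
on this script.  It downloads:

* the processed RNA-Seq count tables of GEO series GSE201506 (total,
  monosome and polysome fractions of human lung fibroblasts with/without
  TGF-beta1), and
* the human NEU3 reference mRNA (RefSeq NM_006656) from NCBI, whose CDS can
  be scanned with ``transreg motif-scan --exact`` to locate the two
  translation-up motif instances.

The proteomics raw files live in MassIVE dataset MSV000089217 and must be
retrieved and searched separately; this script only prints the landing URL.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

GEO_SUPPL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE201nnn/GSE201506/suppl/"
)
NEU3_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=NM_006656&rettype=fasta&retmode=text"
)
MASSIVE_URL = (
    "https://massive.ucsd.edu/ProteoSAFe/dataset.jsp"
    "?task=dd7c4a6aac1145d1bc6ac9ead122f015"
)


def main(outdir: str = "public_data") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    print(f"fetching NEU3 mRNA (NM_006656) -> {out / 'NEU3_NM_006656.fasta'}")
    urllib.request.urlretrieve(NEU3_EFETCH, out / "NEU3_NM_006656.fasta")
    print(f"GEO supplementary listing: {GEO_SUPPL}")
    print("download the count matrices listed there into", out)
    print("proteomics (manual):", MASSIVE_URL)


if __name__ == "__main__":
    main(*sys.argv[1:])
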