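#!/usr/bin/env python
"""Optional online check against the deposited GenBank sequences.

The study's rDNA sequences are deposited under accessions PP768890–PP768902
(28S: PP768890–PP768898; 18S: PP768899–PP768902).  This helper downloads
the 28S isolate sets, aligns each conspecific pair globally, and reports
the maximum intraspecific p-distance — expected ≤ 0.2% (0–2 nt) for both
C. parvus (PP768895–PP768898) and M. truncatus (PP768890–PP768892).

Requires network access and an e-mail address for NCBI Entrez; it is a
documentation/verification aid, not part of the test suite, and nothing in
the package depends on it.

Usage:  python scripts/accession_check.py --email you@example.org
"""

from __future__ import annotations

import argparse
import sys

from Bio import Entrez, SeqIO

from monotax.seqdist import count_differences, global_align

SETS = {
    "C. parvus (28S)": [f"PP7688{n}" for n in range(95, 99)],
    "M. truncatus (28S)": [f"PP7688{n}" for n in range(90, 93)],
}


def fetch(accessions: list[str]) -> list[tuple[str, str]]:
    handle = Entrez.efetch(
        db="nucleotide", id=",".join(accessions), rettype="fasta", retmode="text"
    )
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="Entrez contact e-mail")
    args = parser.parse_args()
    Entrez.email = args.email

    failures = 0
    for label, accs in SETS.items():
        seqs = fetch(accs)
        worst = 0.0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                aln = global_align(seqs[i][1], seqs[j][1])
                d, n = count_differences(aln.aligned1, aln.aligned2)
                worst = max(worst, 100.0 * d / n if n else 0.0)
        ok = worst <= 0.2
        failures += not ok
        print(f"{label}: max intraspecific p-distance {worst:.2f}% "
              f"({'OK' if ok else 'UNEXPECTED'}, threshold 0.2%)")
    sys.exit(1 if failures else 0)


if __name__ == "__main__":
    main()
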