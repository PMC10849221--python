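#!/usr/bin/env python
"""Convert RegulonDB-style gene/UTR dumps into the package's input dialects.

UNTESTED CONVENIENCE PLUMBING: this script documents the conversion from
the public E. coli annotation dumps (a Gene_sequence.txt-style table of CDS
sequences and a UTR_5_3_sequence-style table of first-gene 5'-UTRs, plus an
operon membership table) into the CDS FASTA + operon TSV consumed by
`ribopred`.  It requires files you must download yourself and is not
exercised by the test suite.

Usage:
    python scripts/convert_regulondb.py \
        --gene-sequences Gene_sequence.txt \
        --utr-sequences UTR_5_3_sequence.txt \
        --operons OperonSet.txt \
        --outdir converted/
"""

from __future__ import annotations

import argparse
import csv
from pathlib import Path


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--gene-sequences", required=True, type=Path)
    ap.add_argument("--utr-sequences", required=True, type=Path)
    ap.add_argument("--operons", required=True, type=Path)
    ap.add_argument("--outdir", required=True, type=Path)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # Gene_sequence-style dump: tab-separated, gene name and CDS sequence;
    # comment lines start with '#'.
    cds: dict[str, str] = {}
    with open(args.gene_sequences) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            name, seq = row[0].strip(), row[-1].strip().upper()
            if name and set(seq) <= set("ACGTUN"):
                cds[name] = seq.replace("U", "T")

    # UTR dump: gene name -> 5'-UTR sequence (first genes of TUs).
    utr: dict[str, str] = {}
    with open(args.utr_sequences) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            utr[row[0].strip()] = row[-1].strip().upper().replace("U", "T")

    # Operon membership: operon name + comma-separated ordered gene list.
    with open(args.outdir / "operons.tsv", "w") as out:
        out.write("gene_id\toperon_id\tposition\tutr5\n")
        with open(args.operons) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or len(row) < 2:
                    continue
                operon = row[0].strip()
                genes = [g.strip() for g in row[-1].split(",") if g.strip()]
                for pos, gene in enumerate(genes, start=1):
                    out.write(
                        f"{gene}\t{operon}\t{pos}\t{utr.get(gene, '')}\n"
                    )

    with open(args.outdir / "cds.fasta", "w") as out:
        for name, seq in cds.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i:i + 70] + "\n")

    print(f"wrote {len(cds)} CDSs and operon table to {args.outdir}")


if __name__ == "__main__":
    main()
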