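#!/usr/bin/env python
"""Convert a dbSNP-style VCF into the flat allele-frequency TSV dialect.

Reads a sites VCF whose INFO field carries an allele-frequency key
(CAF-style comma list aligned with REF+ALT, or a plain AF list aligned
with ALT) and writes the five-column table the rarity filter consumes:
chrom, pos, ref, alt, af — one row per alternate allele.

Usage:  python scripts/dbsnp_vcf_to_tsv.py in.vcf out.tsv [--af-key AF]
"""

from __future__ import annotations

import argparse
import sys


def convert(vcf_path: str, tsv_path: str, af_key: str = "CAF") -> int:
    n = 0
    with open(vcf_path) as src, open(tsv_path, "w") as dst:
        for line in src:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                continue
            chrom, pos, _, ref, alt_field, _, _, info = fields[:8]
            alts = alt_field.split(",")
            freqs = None
            for item in info.split(";"):
                if item.startswith(af_key + "="):
                    raw = item.split("=", 1)[1].strip("[]")
                    vals = [None if x in (".", "") else float(x) for x in raw.split(",")]
                    # CAF lists include the reference allele first
                    freqs = vals[1:] if af_key == "CAF" and len(vals) == len(alts) + 1 else vals
                    break
            if freqs is None:
                continue
            for alt, af in zip(alts, freqs):
                if af is None:
                    continue
                dst.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{af}\n")
                n += 1
    return n


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("vcf")
    parser.add_argument("tsv")
    parser.add_argument("--af-key", default="CAF")
    args = parser.parse_args()
    n = convert(args.vcf, args.tsv, args.af_key)
    print(f"wrote {n} allele-frequency rows to {args.tsv}", file=sys.stderr)


if __name__ == "__main__":
    main()
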