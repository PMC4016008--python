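"""Text-format I/O: minimal VCF, BED, and TSV tables.

All interval output is 0-based half-open (BED convention); VCF positions
are 1-based.  Floats are rounded to 6 decimals on write.  Every file
starts with a comment line declaring its coordinate convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exome import VariantRecord
from .ibd import IBDSegment

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_tsv",
    "read_tsv",
]


def write_vcf(variants: list[VariantRecord], samples: list[str], path) -> None:
    """Minimal VCF: GENE, CSQ_CLASS, AF_<panel>, COHORT_AC in INFO, GT calls."""
    panels = sorted({p for v in variants for p in v.panel_mafs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##coordinates=1-based\n")
        chroms = list(dict.fromkeys(v.chrom for v in variants))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Functional class">\n')
        for p in panels:
            fh.write(
                f'##INFO=<ID=AF_{p},Number=1,Type=Float,Description="Panel allele frequency">\n'
            )
        fh.write('##INFO=<ID=COHORT_AC,Number=1,Type=Integer,Description="Control cohort allele count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "FORMAT\t" + "\t".join(samples) + "\n")
        for v in variants:
            info = [f"GENE={v.gene}", f"CSQ_CLASS={v.functional_class}"]
            for p in panels:
                info.append(f"AF_{p}={round(v.panel_mafs.get(p, 0.0), 6)}")
            info.append(f"COHORT_AC={v.cohort_count}")
            gts = []
            for s in samples:
                g = v.genotypes.get(s)
                gts.append({None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}[g])
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.variant_id or ".",
                        v.ref,
                        v.alt,
                        ".",
                        "PASS",
                        ";".join(info),
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )


def read_vcf(path) -> list[VariantRecord]:
    """Read a minimal VCF back into variant records (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for rec in vcf:
        info = dict(rec.INFO)
        panel_mafs = {
            k[3:]: float(v) for k, v in info.items() if k.startswith("AF_")
        }
        genotypes: dict[str, int | None] = {}
        for s, gt in zip(samples, rec.gt_types):
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            genotypes[s] = {0: 0, 1: 1, 2: None, 3: 2}[int(gt)]
        out.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                gene=str(info.get("GENE", "")),
                functional_class=str(info.get("CSQ_CLASS", "other")),
                panel_mafs=panel_mafs,
                cohort_count=int(info.get("COHORT_AC", 0)),
                genotypes=genotypes,
                variant_id=rec.ID,
            )
        )
    return out


def write_bed(segments: list[IBDSegment], path, *, name: str | None = None) -> None:
    """BED (0-based half-open); score = 1000 x mean posterior."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED)\n")
        for seg in segments:
            label = name or "+".join(seg.members) or "segment"
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{label}\t"
                f"{round(1000 * seg.mean_posterior)}\n"
            )


def read_bed(path) -> list[IBDSegment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            members = tuple(fields[3].split("+")) if len(fields) > 3 else ()
            score = float(fields[4]) / 1000 if len(fields) > 4 else 1.0
            out.append(
                IBDSegment(chrom, start, end, members, mean_posterior=min(score, 1.0))
            )
    return out


def write_tsv(df: pd.DataFrame, path, *, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.round(6).to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
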