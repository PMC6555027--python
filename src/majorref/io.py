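"""FASTA and VCF serialization helpers shared across the toolkit.

Reading goes through the standard libraries (pyfaidx for FASTA, pysam for
VCF — see the modules that consume records); writing is done here because
the toolkit emits small, fully controlled files (single-ALT combined VCFs,
normalized genomes) where a line writer keeps the dialect explicit."""

from __future__ import annotations

import os

FASTA_WIDTH = 60


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA into {name: sequence}, preserving soft-mask case."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path, width: int = FASTA_WIDTH,
                index: bool = True) -> None:
    """Write {name: sequence} as FASTA (fixed line width) and emit .fai."""
    path = str(path)
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    if index:
        from pyfaidx import Faidx

        fai = Faidx(path, rebuild=True)
        fai.close()


def write_vcf(path, rows, contig_lengths=None, sample_gts=None,
              extra_headers=()) -> None:
    """Write VCF rows as plain text.

    ``rows``: iterables of (chrom, pos, id, ref, alts, info) with optional
    trailing (qual, filter) elements; ``info`` is a {key: value} dict or a
    preformatted string.  ``sample_gts``: optional {sample: [gt per row]}."""
    lines = ["##fileformat=VCFv4.2"]
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Alternate allele frequency">')
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    symbolic = {
        a.strip("<>") for r in rows for a in r[4]
        if isinstance(a, str) and a.startswith("<")
    }
    for s in sorted(symbolic):
        lines.append(f'##ALT=<ID={s},Description="Symbolic allele">')
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(extra_headers)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    samples = sorted(sample_gts) if sample_gts else []
    if samples:
        cols += ["FORMAT"] + samples
    lines.append("\t".join(cols))
    for i, row in enumerate(rows):
        chrom, pos, vid, ref, alts, info = row[:6]
        qual = row[6] if len(row) > 6 else "."
        filt = row[7] if len(row) > 7 else "."
        if isinstance(info, dict):
            info = ";".join(f"{k}={v}" for k, v in info.items()) or "."
        fields = [str(chrom), str(pos), str(vid), ref, ",".join(alts),
                  str(qual), str(filt), info]
        if samples:
            fields.append("GT")
            fields += [sample_gts[s][i] for s in samples]
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
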