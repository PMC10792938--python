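"""Readers and writers for the pipeline's plain-text formats.

Methylation tracks are bedGraph-like TSV (chrom, start, end, methylation,
coverage) or per-CpG TSV (chrom, pos, methylation, coverage); interval
tracks are BED3+; variants use a minimal VCF subset (CHROM, POS, REF, ALT
and per-sample AF:DP in FORMAT).  All in-memory coordinates are 0-based
half-open; conversion to the 1-based convention is confined to VCF I/O.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import intervals as ivl
from .methylome import MethylomeTrack


class ParseError(ValueError):
    pass


def read_methylation_table(
    path, line_id: str = "", state: str = ""
) -> MethylomeTrack:
    """Read a methylation track, auto-detecting bedGraph-like vs per-CpG TSV.

    A 5-column file is taken as (chrom, start, end, methylation, coverage)
    and the CpG position is the interval start; a 4-column file as
    (chrom, pos, methylation, coverage).  Malformed lines are reported with
    their line number; methylation outside [0, 1] is a parse error.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split("\t") if "\t" in s else s.split()
            try:
                if len(parts) >= 5:
                    chrom, start, _end, meth, cov = parts[:5]
                    pos = int(start)
                elif len(parts) == 4:
                    chrom, p, meth, cov = parts
                    pos = int(p)
                else:
                    raise ValueError("expected 4 or 5 columns")
                meth = float(meth)
                cov = int(float(cov))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed record ({exc})") from exc
            if not 0 <= meth <= 1:
                raise ParseError(
                    f"{path}:{lineno}: methylation {meth} outside [0, 1]"
                )
            rows.append((chrom, pos, meth, cov))
    if not rows:
        warnings.warn(f"{path}: empty methylation table")
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "cov"])
    return MethylomeTrack(line_id=line_id, state=state, records=df)


def write_methylation_table(track: MethylomeTrack, path) -> None:
    """Write a track as bedGraph-like TSV (chrom, start, end, meth, cov)."""
    df = track.records
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 2,
            "meth": df["meth"],
            "cov": df["cov"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_intervals(path) -> dict[str, np.ndarray]:
    """Read a BED3+ file into merged, sorted per-chromosome intervals.

    Track/browser/comment headers are skipped; end <= start is an error.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split("\t") if "\t" in s else s.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            per_chrom.setdefault(chrom, []).append((start, end))
    return {c: ivl.merge(v) for c, v in per_chrom.items()}


def write_intervals(track: Mapping[str, np.ndarray], path, name: str = ".") -> None:
    """Write per-chromosome intervals as BED6 (score 0, strand '.')."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            for s, e in np.asarray(track[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t.\n")


def write_dmrs(dmrs, path) -> None:
    """Extended DMR TSV: BED-like columns plus per-(line, state) means."""
    keys = sorted({k for d in dmrs for k in d.mean_methylation})
    with open(path, "w") as fh:
        cols = ["chrom", "start", "end", "n_cpgs", "direction", "score", "reverting"]
        cols += [f"mean_{ln}_{st}" for ln, st in keys]
        fh.write("\t".join(cols) + "\n")
        for d in dmrs:
            row = [
                d.chrom,
                str(d.start),
                str(d.end),
                str(d.n_cpgs),
                d.direction,
                "NA" if d.reversion_score is None else f"{d.reversion_score:.6g}",
                "NA" if d.reverting is None else str(int(d.reverting)),
            ]
            row += [
                f"{d.mean_methylation[k]:.6g}" if k in d.mean_methylation else "NA"
                for k in keys
            ]
            fh.write("\t".join(row) + "\n")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(variants: pd.DataFrame, path, samples=("parental", "resistant", "P12")) -> None:
    """Write the minimal VCF subset (CHROM, POS 1-based, REF, ALT, AF:DP)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for row in variants.itertuples():
            fields = [
                row.chrom,
                str(row.pos + 1),
                ".",
                row.ref,
                row.alt,
                ".",
                "PASS",
                ".",
                "AF:DP",
            ]
            for s in samples:
                af = getattr(row, f"vaf_{s}")
                dp = getattr(row, f"cov_{s}", 0)
                fields.append(f"{af:.6g}:{int(dp)}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read the minimal VCF subset back into the canonical variant table."""
    samples: list[str] = []
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.rstrip("\n")
            if s.startswith("##") or not s:
                continue
            if s.startswith("#CHROM"):
                samples = s.split("\t")[9:]
                continue
            parts = s.split("\t")
            if len(parts) < 10 or not samples:
                raise ParseError(f"{path}:{lineno}: malformed VCF record")
            fmt = parts[8].split(":")
            rec = {
                "chrom": parts[0],
                "pos": int(parts[1]) - 1,
                "ref": parts[3],
                "alt": parts[4],
            }
            for sample, blob in zip(samples, parts[9:]):
                vals = dict(zip(fmt, blob.split(":")))
                rec[f"vaf_{sample}"] = float(vals.get("AF", "nan"))
                rec[f"cov_{sample}"] = int(vals.get("DP", 0))
            rows.append(rec)
    return pd.DataFrame(rows)


def write_genome_bed(genome, islands_path=None, genes_path=None) -> None:
    """Dump islands as BED6 and genes as BED12."""
    if islands_path is not None:
        write_intervals(genome.islands, islands_path, name="CpG_island")
    if genes_path is not None:
        with open(genes_path, "w") as fh:
            for g in genome.genes.itertuples():
                exons = g.exons
                sizes = ",".join(str(e - s) for s, e in exons)
                starts = ",".join(str(s - g.start) for s, _ in exons)
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
                )


def frame_checksum(df: pd.DataFrame) -> str:
    """Stable content hash of a DataFrame, for run manifests."""
    import hashlib

    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def file_checksum(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
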