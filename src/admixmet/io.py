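"""Standard-format I/O: VCF and dosage TSV genotypes, TSV matrices, JSON.

Missing values are written as the empty string and read back from any of
"", "NA", "NaN". VCF output is a minimal VCFv4.2 subset (CHROM, POS, ID,
REF, ALT, GT) readable by htslib-based tools; reading goes through cyvcf2
and rejects multiallelic records.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_table_tsv",
    "read_table_tsv",
    "load_genotypes",
    "write_json",
]

NA_TOKENS = ["", "NA", "NaN"]


def write_vcf(path: str | Path, dosages: pd.DataFrame, markers: pd.DataFrame) -> None:
    """Write counted-allele dosages as a VCFv4.2 file (GT only).

    ``dosages`` is samples x markers (0/1/2, NaN missing); ``markers``
    supplies chrom, pos, ref, alt per marker id. The counted allele is
    ALT: dosage 2 -> "1/1", 1 -> "0/1", 0 -> "0/0", missing -> "./.".
    """
    path = Path(path)
    samples = [str(s) for s in dosages.index]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    contigs = list(dict.fromkeys(markers["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixmet\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for mid in dosages.columns:
            row = markers.loc[mid]
            vals = dosages[mid].to_numpy(dtype=float)
            gts = "\t".join(
                "./." if np.isnan(v) else gt_map[int(v)] for v in vals
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (dosage DataFrame, marker table).

    Dosage counts the ALT allele; a genotype with any missing allele is
    treated as missing. Multiallelic records are rejected together,
    listed by id.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    multi = []
    for i, var in enumerate(vcf):
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            multi.append(vid)
            continue
        ids.append(vid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = np.array(var.genotypes, dtype=object)
        dos = np.empty(len(samples))
        for s in range(len(samples)):
            a = gt[s][:2]
            if any(x < 0 for x in a):
                dos[s] = np.nan
            else:
                dos[s] = sum(1 for x in a if x == 1)
        rows.append(dos)
    if multi:
        raise ValueError(f"multiallelic records rejected: {multi}")
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=samples, columns=ids,
    )
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="marker_id"),
    )
    return dosages, markers


def write_dosage_tsv(path: str | Path, dosages: pd.DataFrame) -> None:
    out = dosages.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_TOKENS,
                     keep_default_na=False)
    return df.astype(float)


def write_matrix_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    """Samples x metabolites abundance matrix; missing as empty string."""
    out = matrix.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=NA_TOKENS,
                       keep_default_na=False)


def write_table_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", na_rep="")


def read_table_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=NA_TOKENS,
                       keep_default_na=False, **kwargs)


def load_genotypes(path: str | Path, fmt: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load genotypes from VCF or dosage TSV (auto-detected by suffix).

    Returns (dosages, marker table or None for TSV input).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_dosage_tsv(path), None
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
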