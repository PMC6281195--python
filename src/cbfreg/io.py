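"""Readers/writers for the file formats the pipeline touches, and promoter
extraction with explicit coordinate conventions.

Internal coordinates are 0-based half-open; BED is read natively and GFF3
is converted on ingest, so a single convention is used everywhere and ±1
drift cannot creep in.  A gene's "translation start" is the first base of
the start codon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "PromoterSet",
    "read_fasta",
    "write_fasta",
    "extract_promoters",
    "read_bed_models",
    "read_gff3_models",
    "read_leakage_csv",
    "read_de_table",
    "read_annotation_map",
    "read_gene_list",
    "write_results",
]

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: where translation starts and on which strand.

    ``translation_start`` is 1-based, the first base of the start codon on
    the gene's sense strand.
    """

    gene_id: str
    contig: str
    translation_start: int
    strand: str

    def __post_init__(self) -> None:
        if self.translation_start < 1:
            raise ValueError(f"{self.gene_id}: translation_start must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class PromoterSet:
    """Upstream sequences keyed by gene id, 5'→3' on each gene's sense strand.

    ``truncated`` lists genes whose window ran off a contig edge and was
    shortened rather than dropped (dropping would bias motif counts).
    """

    sequences: dict[str, str]
    requested_length: int
    truncated: set[str] = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self) -> None:
        for gid, seq in self.sequences.items():
            bad = set(seq.upper()) - _IUPAC_DNA
            if bad:
                raise ValueError(f"{gid}: non-IUPAC characters {sorted(bad)}")
            if len(seq) > self.requested_length:
                raise ValueError(f"{gid}: sequence longer than requested length")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def ids(self) -> list[str]:
        return list(self.sequences)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id → sequence map (case preserved)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_promoters(
    genome: dict[str, str],
    models: list[GeneModel],
    length: int = 1000,
) -> PromoterSet:
    """Extract the ``length`` bases immediately upstream of each gene's
    translation start.

    For a + strand gene the window is the 1-based closed interval
    [translation_start − length, translation_start − 1] — it ends on the
    base just before the start codon.  For a − strand gene it is the
    reverse complement of [translation_start + 1, translation_start +
    length].  Windows are truncated (and the gene flagged) where they run
    off a contig edge; a window entirely off-contig is an error.
    """
    seqs: dict[str, str] = {}
    truncated: set[str] = set()
    for m in models:
        if m.contig not in genome:
            raise KeyError(f"{m.gene_id}: unknown contig {m.contig!r}")
        contig = genome[m.contig]
        if not 1 <= m.translation_start <= len(contig):
            raise ValueError(
                f"{m.gene_id}: translation_start {m.translation_start} "
                f"outside contig {m.contig!r} (length {len(contig)})"
            )
        t0 = m.translation_start - 1  # 0-based index of the start codon base
        if m.strand == "+":
            lo = t0 - length
            if lo < 0:
                truncated.add(m.gene_id)
                lo = 0
            window = contig[lo:t0]
        else:
            hi = t0 + 1 + length
            if hi > len(contig):
                truncated.add(m.gene_id)
                hi = len(contig)
            window = reverse_complement(contig[t0 + 1:hi])
        if not window:
            raise ValueError(f"{m.gene_id}: promoter window entirely off-contig")
        seqs[m.gene_id] = window
    return PromoterSet(
        sequences=seqs,
        requested_length=length,
        truncated=truncated,
        provenance=f"extract_promoters(length={length}, n_models={len(models)})",
    )


def read_bed_models(path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open).

    Translation start is taken as chromStart for + genes and chromEnd for
    − genes, i.e. the 5' end of the feature on its own strand.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 requires 6 columns")
            contig, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            ts = start + 1 if strand == "+" else end
            models.append(GeneModel(gene_id=name, contig=contig,
                                    translation_start=ts, strand=strand))
    return models


def write_bed(models: list[GeneModel], path) -> None:
    """Write gene models as BED6 start-codon features (0-based half-open),
    the inverse of :func:`read_bed_models`."""
    with open(path, "w") as fh:
        for m in models:
            if m.strand == "+":
                start, end = m.translation_start - 1, m.translation_start + 2
            else:
                start, end = m.translation_start - 3, m.translation_start
            fh.write(f"{m.contig}\t{start}\t{end}\t{m.gene_id}\t0\t{m.strand}\n")


def read_gff3_models(path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed), converting on ingest."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: GFF3 requires 9 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            gid = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gid = item[3:]
            if gid is None:
                raise ValueError(f"{path}: line {lineno}: missing ID attribute")
            ts = int(start) if strand == "+" else int(end)
            models.append(GeneModel(gene_id=gid, contig=contig,
                                    translation_start=ts, strand=strand))
    return models


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")


def read_leakage_csv(path) -> pd.DataFrame:
    """Read replicate-level electrolyte-leakage measurements.

    Required columns: genotype, acclimation, temperature_C, replicate,
    leakage_pct.  Returns a typed DataFrame; use
    :func:`cbfreg.freeze.curves_from_dataframe` for per-group mean curves.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["genotype", "acclimation", "temperature_C",
                          "replicate", "leakage_pct"], path)
    for col in ("temperature_C", "leakage_pct"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col} at line {row}")
        df[col] = coerced
    return df


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression table (TSV).

    Required columns: gene_id, contrast, log2fc.  Optional: q_value,
    fpkm_ref, fpkm_alt — a missing q_value column yields NaN q, which the
    classification stage refuses to threshold without an explicit override.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "contrast", "log2fc"], path)
    for col in ("q_value", "fpkm_ref", "fpkm_alt"):
        if col not in df.columns:
            df[col] = np.nan
    df["log2fc"] = pd.to_numeric(df["log2fc"])
    return df


def read_annotation_map(path) -> dict[str, set[str]]:
    """Read a gene→GO map (TSV: term_id, term_name, gene_id) into
    term_id → gene-id set.  Term names are returned via the paired
    ``.attrs['term_names']`` mapping on use of :func:`read_annotation_table`;
    here only the membership map is built."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["term_id", "gene_id"], path)
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term_id"):
        out[str(term)] = set(grp["gene_id"].astype(str))
    return out


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["term_id", "gene_id"], path)
    if "term_name" not in df.columns:
        df["term_name"] = ""
    return df


def read_gene_list(path) -> set[str]:
    """Read a one-id-per-line gene list (case-normalized to upper)."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  summary: dict | None = None) -> None:
    """Write result tables as TSV plus an optional JSON run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if summary is not None:
        with open(out / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
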