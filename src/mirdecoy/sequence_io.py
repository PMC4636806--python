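"""Readers, writers and canonical records for the plain-text formats of the pipeline.

Sequences travel as FASTA, expression as a genes x samples TSV of log2
intensities, target-site predictions as a four-column TSV, and gene loci as
BED3+name (0-based, half-open).  Gene and sample identifiers are treated as
opaque keys throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import __version__

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

GENOTYPES = ("EU", "TS")
TREATMENTS = ("control", "sponge")


def _tool_header() -> str:
    return f"# mirdecoy {__version__}"


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over a declared alphabet (stored upper-case)."""

    id: str
    sequence: str
    moltype: str = "rna"

    def __post_init__(self) -> None:
        if self.moltype not in ("rna", "dna"):
            raise ValueError(f"moltype must be 'rna' or 'dna', got {self.moltype!r}")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = RNA_ALPHABET if self.moltype == "rna" else DNA_ALPHABET
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal character {sorted(bad)[0]} "
                f"for moltype {self.moltype}"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, moltype: str = "rna") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` s.

    T/U are normalized to the declared ``moltype``; any other alphabet
    violation raises with the offending record named.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seq = seq.replace("T", "U") if moltype == "rna" else seq.replace("U", "T")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq, moltype))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities, backed by a DataFrame."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        coerced = self.data.apply(pd.to_numeric, errors="coerce")
        bad = ~np.isfinite(coerced.to_numpy(dtype=float))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-numeric or missing value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        self.data = coerced.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            gene = df.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric cell at gene {gene!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_tool_header() + "\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene_id")


@dataclass
class SampleMetadata:
    """Per-sample genotype/treatment/batch labels."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "genotype", "treatment", "batch")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"metadata missing columns {sorted(missing)}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad_g = set(self.data["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise ValueError(f"unknown genotype {sorted(bad_g)[0]!r}")
        bad_t = set(self.data["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValueError(f"unknown treatment {sorted(bad_t)[0]!r}")
        self.data = self.data.reset_index(drop=True)

    def for_samples(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Metadata rows aligned to ``sample_ids``; every sample must have one row."""
        indexed = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise ValueError(f"no metadata for sample {missing[0]!r}")
        return indexed.loc[list(sample_ids)]

    def group_sizes(self) -> pd.Series:
        return self.data.groupby(["genotype", "treatment"]).size()


def read_metadata_tsv(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleMetadata(df)


def write_metadata_tsv(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_tool_header() + "\n")
        meta.data.to_csv(fh, sep="\t", index=False)


@dataclass
class PredictionRecord:
    """Predicted target-site counts for one miRNA-gene pair, by conservation class."""

    mirna_id: str
    gene_id: str
    n_sites_conserved: int
    n_sites_nonconserved: int
    n_sites_total: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_sites_conserved < 0 or self.n_sites_nonconserved < 0:
            raise ValueError(
                f"negative site count for {self.mirna_id}/{self.gene_id}"
            )
        self.n_sites_total = self.n_sites_conserved + self.n_sites_nonconserved


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    """Read a TSV of (mirna, gene, conserved, nonconserved) site counts.

    Rows whose total is zero carry no usable site and are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    records: list[PredictionRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        rec = PredictionRecord(
            str(row.mirna), str(row.gene), int(row.conserved), int(row.nonconserved)
        )
        if rec.n_sites_total == 0:
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} prediction row(s) with zero total sites")
    return records


def predictions_frame(records: Iterable[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.mirna_id, r.gene_id, r.n_sites_conserved, r.n_sites_nonconserved, r.n_sites_total)
            for r in records
        ],
        columns=["mirna", "gene", "conserved", "nonconserved", "total"],
    )


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_tool_header() + "\n")
        predictions_frame(records)[["mirna", "gene", "conserved", "nonconserved"]].to_csv(
            fh, sep="\t", index=False
        )


@dataclass
class GeneLocus:
    """A gene's genomic interval, 0-based half-open."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")


def read_bed_loci(path: str | Path) -> list[GeneLocus]:
    """Read BED3+name gene loci; the first locus per gene is kept, later ones warned."""
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected BED3+name")
            chrom, start, end, name = fields[:4]
            locus = GeneLocus(name, chrom, int(start), int(end))
            if name in seen:
                n_dup += 1
                continue
            seen.add(name)
            loci.append(locus)
    if n_dup:
        warnings.warn(f"{n_dup} duplicate gene name(s) in {path}; first kept")
    return loci


def write_bed_loci(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_tool_header() + "\n")
        for loc in loci:
            fh.write(f"{loc.chromosome}\t{loc.start}\t{loc.end}\t{loc.gene_id}\n")
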