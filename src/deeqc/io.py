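"""Readers and writers for FASTA, FASTQ, GTF, TSV tables and the zip bundle.

All other modules do file I/O through here.  Conventions:

* FASTQ quality strings are decoded with a caller-supplied offset
  (33 for Sanger / Illumina 1.9, 64 for Illumina 1.5).
* GTF files are 1-based inclusive on disk and converted to 0-based
  half-open internally.
* TSV tables use a tab separator, a header row, and the literal string
  ``NA`` for missing values.
* Gzip input is detected by magic bytes, never by file extension.
"""

from __future__ import annotations

import gzip
import io as _io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Mate, Reference, SequenceRead, TranscriptModel, merge_intervals

GZIP_MAGIC = b"\x1f\x8b"


class FastqParseError(ValueError):
    pass


class GtfParseError(ValueError):
    pass


class BundleFormatError(ValueError):
    pass


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly-gzipped text file, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(
    path: str | Path,
    offset: int = 33,
    max_reads: int | None = None,
    mate: Mate = Mate.SINGLE,
) -> Iterator[SequenceRead]:
    """Stream reads from a (possibly gzipped) 4-line-record FASTQ file.

    ``max_reads`` truncates the stream, which supports the fixed-size
    samples the QC stages draw (4,000 reads for format checks, 10,000 for
    5'-clip optimisation).
    """
    handle = _open_text(path)
    try:
        index = 0
        for title, seq, qual in FastqGeneralIterator(handle):
            if max_reads is not None and index >= max_reads:
                break
            try:
                quals = tuple(ord(c) - offset for c in qual)
                yield SequenceRead(title.split()[0], seq.upper(), quals, mate)
            except ValueError as err:
                raise FastqParseError(f"record {index}: {err}") from err
            index += 1
    except ValueError as err:
        if isinstance(err, FastqParseError):
            raise
        raise FastqParseError(f"record {index}: {err}") from err
    finally:
        handle.close()


def write_fastq(reads: Iterable[SequenceRead], path: str | Path, offset: int = 33) -> int:
    """Write reads as plain FASTQ; returns the number written."""
    n = 0
    with open(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + offset) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon features of a GTF file into gene models.

    Exons are grouped by ``transcript_id`` then ``gene_id``; input line
    order does not matter.  Coordinates convert from 1-based inclusive to
    0-based half-open.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as err:  # gffutils raises assorted exception types
        raise GtfParseError(f"cannot parse GTF {path}: {err}") from err

    symbols: dict[str, str] = {}
    tx_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    gene_meta: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    for feat in db.all_features():
        if "gene_id" not in feat.attributes:
            raise GtfParseError(f"{feat.featuretype} feature without gene_id at {feat.seqid}:{feat.start}")
        gid = feat.attributes["gene_id"][0]
        if "gene_name" in feat.attributes:
            symbols[gid] = feat.attributes["gene_name"][0]
        if feat.featuretype != "exon":
            continue
        if feat.end < feat.start:
            raise GtfParseError(f"exon with end < start at {feat.seqid}:{feat.start}-{feat.end}")
        if "transcript_id" not in feat.attributes:
            raise GtfParseError(f"exon without transcript_id at {feat.seqid}:{feat.start}")
        tid = feat.attributes["transcript_id"][0]
        tx_exons.setdefault((gid, tid), []).append((feat.start - 1, feat.end))
        prev = gene_meta.setdefault(gid, (feat.seqid, feat.strand))
        if prev != (feat.seqid, feat.strand):
            raise GtfParseError(f"gene {gid}: inconsistent chrom/strand across exons")

    genes: dict[str, GeneModel] = {}
    for (gid, tid), exons in tx_exons.items():
        chrom, strand = gene_meta[gid]
        if gid not in genes:
            genes[gid] = GeneModel(gid, symbols.get(gid, gid), chrom, strand, exons=[])
        genes[gid].transcripts.append(TranscriptModel(tid, gid, sorted(exons)))
    for g in genes.values():
        g.exons = merge_intervals(e for t in g.transcripts for e in t.exons)
        g.transcripts.sort(key=lambda t: t.tx_id)
    return sorted(genes.values(), key=lambda g: g.gene_id)


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "deeqc") -> None:
    """Write gene/transcript/exon features, converting back to 1-based inclusive."""
    with open(path, "wt") as fh:
        for g in genes:
            s, e = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(f"{g.chrom}\t{source}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                ts = min(x for x, _ in t.exons)
                te = max(x for _, x in t.exons)
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.tx_id}"; gene_name "{g.symbol}";'
                fh.write(f"{g.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n")
                for xs, xe in t.exons:
                    fh.write(f"{g.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{tattrs}\n")


def read_reference(fasta_path: str | Path, gtf_path: str | Path) -> Reference:
    return Reference(genome=read_fasta(fasta_path), genes=read_gtf(gtf_path))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(path_or_buf, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False, **kwargs)


def write_table(df: pd.DataFrame, path_or_buf) -> None:
    df.to_csv(path_or_buf, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# The 7-table zip bundle
# ---------------------------------------------------------------------------

#: Default on-disk member names; configurable because live archives may differ.
BUNDLE_MEMBERS = {
    "gene_counts": "GeneCountMatrix.tsv",
    "tx_counts": "TxCountMatrix.tsv",
    "gene_info": "GeneInfo.tsv",
    "tx_info": "TxInfo.tsv",
    "qc_metrics": "QC_summary.tsv",
    "summary_meta": "MetadataSummary.tsv",
    "full_meta": "MetadataFull.tsv",
}


@dataclass
class DatasetBundle:
    """The seven-table archive a processed run set ships as, plus run logs.

    Count matrices are run x feature (runs as rows).  ``logs`` maps run id
    to the verbatim text of its processing log.
    """

    gene_counts: pd.DataFrame
    tx_counts: pd.DataFrame
    gene_info: pd.DataFrame
    tx_info: pd.DataFrame
    qc_metrics: pd.DataFrame
    summary_meta: pd.DataFrame
    full_meta: pd.DataFrame
    logs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # a named columns axis cannot be represented in a TSV member
        for name in BUNDLE_MEMBERS:
            getattr(self, name).columns.name = None

    def validate(self) -> None:
        runs = set(self.gene_counts.index)
        for name in ("tx_counts", "qc_metrics", "summary_meta", "full_meta"):
            other = set(getattr(self, name).index)
            if other != runs:
                raise ValueError(f"run identifiers of {name} differ from gene_counts")
        if (self.gene_counts.values < 0).any() or (self.tx_counts.values < 0).any():
            raise ValueError("negative counts in bundle")
        missing = set(self.gene_counts.columns) - set(self.gene_info.index)
        if missing:
            raise ValueError(f"gene_info does not cover genes: {sorted(missing)[:5]}")


def write_bundle(
    bundle: DatasetBundle,
    path: str | Path,
    members: dict[str, str] = BUNDLE_MEMBERS,
) -> None:
    bundle.validate()

    def _info(name: str) -> zipfile.ZipInfo:
        # fixed timestamp so identical bundles are byte-identical
        zi = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        zi.compress_type = zipfile.ZIP_DEFLATED
        return zi

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for attr, member in members.items():
            buf = _io.StringIO()
            write_table(getattr(bundle, attr), buf)
            zf.writestr(_info(member), buf.getvalue())
        for run, text in bundle.logs.items():
            zf.writestr(_info(f"logs/{run}.log"), text)


def read_bundle(path: str | Path, members: dict[str, str] = BUNDLE_MEMBERS) -> DatasetBundle:
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        absent = [m for m in members.values() if m not in names]
        if absent:
            raise BundleFormatError(f"bundle missing member table(s): {absent}")
        tables = {}
        for attr, member in members.items():
            with zf.open(member) as fh:
                tables[attr] = read_table(_io.TextIOWrapper(fh, "utf-8"))
        logs = {}
        for name in sorted(names):
            if name.startswith("logs/") and name.endswith(".log"):
                logs[Path(name).stem] = zf.read(name).decode("utf-8")
    bundle = DatasetBundle(logs=logs, **tables)
    bundle.validate()
    return bundle
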