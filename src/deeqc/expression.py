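"""Expression-matrix model: Tx2Gene aggregation, RPM normalisation, lengths.

An :class:`ExpressionMatrix` is a features x samples table (genes or
transcripts as rows, runs as columns).  Transcript counts aggregate to the
gene level by summation over parent-gene membership; library-size
normalisation is reads per million (each column rescaled to sum to 1e6).
Feature lengths follow the merged-exon convention: a transcript's length
is the sum of its exon lengths, a gene's length the size of the union of
all exonic intervals across its isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import Reference, merge_intervals


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # features x samples
    level: str  # "gene" or "transcript"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FeatureLengthTable:
    lengths: pd.Series  # feature id -> length (bases)
    method: str  # "merged_exon_union" or "exon_sum"


def tx2gene(tx: ExpressionMatrix, tx_info: dict[str, str]) -> ExpressionMatrix:
    """Sum transcript counts into parent-gene counts; column totals conserved."""
    orphans = [t for t in tx.values.index if t not in tx_info]
    if orphans:
        raise KeyError(f"transcripts without a parent gene: {orphans[:10]}")
    gene_ids = tx.values.index.map(tx_info)
    agg = tx.values.groupby(gene_ids, sort=True).sum()
    agg.index.name = "gene_id"
    return ExpressionMatrix(agg, "gene")


def rpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reads-per-million normalisation: each column rescaled to sum to 1e6."""
    sums = m.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum column(s): {list(zero.index)[:5]}")
    return ExpressionMatrix(m.values * 1e6 / sums, m.level)


def feature_lengths(ref: Reference) -> tuple[FeatureLengthTable, FeatureLengthTable]:
    """(gene, transcript) length tables from the exon models."""
    gene_len, tx_len = {}, {}
    for g in ref.genes:
        if not any(t.exons for t in g.transcripts):
            raise ValueError(f"gene {g.gene_id} has no exons")
        union = merge_intervals(e for t in g.transcripts for e in t.exons)
        gene_len[g.gene_id] = sum(e - s for s, e in union)
        for t in g.transcripts:
            tx_len[t.tx_id] = t.length
    genes = FeatureLengthTable(pd.Series(gene_len, name="length"), "merged_exon_union")
    txs = FeatureLengthTable(pd.Series(tx_len, name="length"), "exon_sum")
    return genes, txs


def gene_info_table(ref: Reference) -> pd.DataFrame:
    """GeneInfo table: accession, symbol, merged-exon length."""
    glens, _ = feature_lengths(ref)
    rows = {g.gene_id: {"symbol": g.symbol, "length": int(glens.lengths[g.gene_id])}
            for g in ref.genes}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


def tx_info_table(ref: Reference) -> pd.DataFrame:
    """TxInfo table: accession, parent gene, symbol, exon-sum length."""
    rows = {}
    for g in ref.genes:
        for t in g.transcripts:
            rows[t.tx_id] = {"parent_gene": g.gene_id, "symbol": g.symbol,
                             "length": t.length}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "tx_id"
    return df
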