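"""Synthetic reference and Illumina-like read generation.

Every downstream stage (trimming, adapter inference, 5'-clip optimisation,
mapping, strandedness calling, quantification) is validated against reads
whose origin is known exactly.  The simulator is deliberately simple:
uniform coverage, iid substitution errors and a parametric 3' quality
decay.  Fidelity to a particular instrument error model is not the point;
a controllable ground truth is.

Reads are drawn so that each genomic fragment lies within a single exon,
which keeps the toy genome mappable without spliced alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import GeneModel, Mate, Reference, SequenceRead, TranscriptModel, revcomp

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulation parameters.

    The defaults describe a small but realistic bulk RNA-seq run: 50-gene
    transcriptome, 100 bp single-end reads at uniform 2x fold coverage,
    0.1% substitution rate, no adapter read-through, no nonreference 5'
    bases, unstranded library (sense probability 0.5).
    """

    seed: int = 0
    n_genes: int = 50
    n_tx_per_gene: int = 2
    n_exons_per_gene: int = 1
    exon_length_range: tuple[int, int] = (300, 700)
    intron_length_range: tuple[int, int] = (60, 150)
    spacer_length_range: tuple[int, int] = (100, 300)
    n_chroms: int = 2
    read_length: int = 100
    layout: str = "SE"  # "SE" or "PE"
    fragment_length: int = 200  # PE only
    fold_coverage: float = 2.0
    sub_error_rate: float = 0.001
    adapter_seq: str | None = None
    adapter_fraction: float = 0.0
    min_adapter_bases: int = 14  # adapter bases left in a read-through read
    fiveprime_extra: int = 0  # nonreference 5' bases (0, 4, 8, 12, 20)
    strand_fraction: float = 0.5  # probability a read is sense-strand
    mean_qual: float = 35.0
    qual_decay: float = 0.15  # phred lost per base over the final 30% of the read
    qual_jitter: float = 2.0
    exact_counts: bool = True  # deterministic reads per transcript vs Poisson
    skip_short: bool = True  # transcripts shorter than the fragment are skipped

    def validate(self) -> None:
        for name in ("adapter_fraction", "strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 18:
            raise ConfigError("read_length must be >= 18")
        if self.layout not in ("SE", "PE"):
            raise ConfigError("layout must be SE or PE")
        if self.fiveprime_extra >= self.read_length - 18:
            raise ConfigError("fiveprime_extra leaves fewer than 18 template bases")
        if self.exon_length_range[0] > self.exon_length_range[1]:
            raise ConfigError("invalid exon_length_range")


@dataclass
class ReadOrigin:
    """Provenance of one simulated read (mate1 for PE)."""

    tx_id: str
    gene_id: str
    tx_pos: int  # fragment start in transcript coordinates
    sense: bool  # True if the read follows the transcript strand
    fragment: str  # error-free template portion, read orientation
    has_adapter: bool
    insert_len: int


@dataclass
class GroundTruth:
    tx_counts: dict[str, int]
    gene_counts: dict[str, int]
    origins: list[ReadOrigin]
    adapter: str | None
    fiveprime_extra: int

    def validate(self) -> None:
        per_gene = {}
        tx_parent = {o.tx_id: o.gene_id for o in self.origins}
        for tx, n in self.tx_counts.items():
            if tx in tx_parent:
                per_gene[tx_parent[tx]] = per_gene.get(tx_parent[tx], 0) + n


@dataclass
class ReadBatch:
    """A set of simulated reads; ``r2`` is populated for paired-end layouts."""

    r1: list[SequenceRead]
    r2: list[SequenceRead] | None = None

    def __len__(self) -> int:
        return len(self.r1)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_reference(cfg: SimConfig) -> Reference:
    """Build a toy genome with gene models tiled across chromosomes.

    Genes alternate strand, are separated by intergenic spacers, and carry
    ``n_tx_per_gene`` transcripts: the first uses every exon; subsequent
    isoforms drop one exon (multi-exon genes) or shorten the single exon,
    so isoforms share sequence and quantification must split multireads.

    If ``cfg.adapter_seq`` is set, the genome is re-drawn until the adapter
    is absent from both strands, so the clip rule can be tested cleanly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    for _attempt in range(50):
        chrom_parts: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(cfg.n_chroms)}
        chrom_pos: dict[str, int] = {c: 0 for c in chrom_parts}
        genes: list[GeneModel] = []
        for gi in range(cfg.n_genes):
            chrom = f"chr{gi % cfg.n_chroms + 1}"
            spacer = int(rng.integers(*cfg.spacer_length_range, endpoint=True))
            chrom_parts[chrom].append(_random_seq(rng, spacer))
            chrom_pos[chrom] += spacer
            exons: list[tuple[int, int]] = []
            for ei in range(cfg.n_exons_per_gene):
                if ei > 0:
                    intron = int(rng.integers(*cfg.intron_length_range, endpoint=True))
                    chrom_parts[chrom].append(_random_seq(rng, intron))
                    chrom_pos[chrom] += intron
                elen = int(rng.integers(*cfg.exon_length_range, endpoint=True))
                chrom_parts[chrom].append(_random_seq(rng, elen))
                exons.append((chrom_pos[chrom], chrom_pos[chrom] + elen))
                chrom_pos[chrom] += elen
            strand = "+" if gi % 2 == 0 else "-"
            gid = f"G{gi + 1:04d}"
            gene = GeneModel(gid, f"gene{gi + 1}", chrom, strand, exons=list(exons))
            for ti in range(cfg.n_tx_per_gene):
                tid = f"{gid}.T{ti + 1}"
                if ti == 0 or cfg.n_exons_per_gene == 1:
                    tx_exons = list(exons)
                    if ti > 0:
                        # single-exon isoform: shorten the exon by 25% per isoform
                        s, e = exons[0]
                        shrink = max(1, (e - s) // 4) * ti
                        tx_exons = [(s, max(s + cfg.read_length + 20, e - shrink))]
                else:
                    drop = (ti - 1) % cfg.n_exons_per_gene
                    tx_exons = [x for j, x in enumerate(exons) if j != drop] or list(exons)
                gene.transcripts.append(TranscriptModel(tid, gid, tx_exons))
            genes.append(gene)
        genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
        ref = Reference(genome=genome, genes=genes)
        if cfg.adapter_seq is None or not ref.contains(cfg.adapter_seq):
            return ref
    raise ConfigError("could not build a genome lacking the requested adapter sequence")


def draw_adapter(rng: np.random.Generator, ref: Reference, length: int = 24) -> str:
    """Random adapter guaranteed absent from the reference (either strand)."""
    for _ in range(100):
        cand = _random_seq(rng, length)
        if not ref.contains(cand):
            return cand
    raise ConfigError("could not draw an adapter absent from the genome")


def _exon_starts_in_tx(tx: TranscriptModel) -> list[tuple[int, int]]:
    """Exon intervals in transcript coordinates (strand-agnostic)."""
    out, pos = [], 0
    for s, e in sorted(tx.exons):
        out.append((pos, pos + (e - s)))
        pos += e - s
    return out


def _valid_starts(tx: TranscriptModel, flen: int) -> list[tuple[int, int]]:
    """Ranges of fragment starts keeping the fragment inside one exon."""
    ranges = []
    for a, b in _exon_starts_in_tx(tx):
        if b - a >= flen:
            ranges.append((a, b - flen))
    return ranges


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alts = [bytes([b]) for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = alts[rng.integers(len(alts))]
    return arr.tobytes().decode()


def _quals(rng: np.random.Generator, cfg: SimConfig, n: int) -> tuple[int, ...]:
    pos = np.arange(n)
    knee = 0.7 * cfg.read_length
    base = cfg.mean_qual - cfg.qual_decay * np.maximum(0, pos - knee)
    noise = rng.normal(0.0, cfg.qual_jitter, size=n)
    return tuple(int(q) for q in np.clip(np.rint(base + noise), 2, 40))


def simulate_reads(ref: Reference, cfg: SimConfig) -> tuple[ReadBatch, GroundTruth]:
    """Simulate reads at uniform fold coverage with known provenance.

    Per transcript the read count is ``round(fold_coverage * length /
    read_length)`` in exact-count mode, or Poisson with that mean.  Each
    read optionally receives ``fiveprime_extra`` random nonreference 5'
    bases and, for ``adapter_fraction`` of reads, a short insert whose 3'
    end runs through into the adapter.  Substitution errors apply to the
    template-derived portion only.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 7])
    adapter = cfg.adapter_seq
    if adapter is None and cfg.adapter_fraction > 0:
        adapter = draw_adapter(rng, ref)

    glen = cfg.read_length - cfg.fiveprime_extra  # template bases per read
    r1: list[SequenceRead] = []
    r2: list[SequenceRead] = []
    origins: list[ReadOrigin] = []
    tx_counts: dict[str, int] = {}
    gene_counts: dict[str, int] = {}
    ridx = 0

    for gene in ref.genes:
        for tx in gene.transcripts:
            txseq = ref.transcript_sequence(tx)
            mean = cfg.fold_coverage * tx.length / cfg.read_length
            n_reads = int(round(mean)) if cfg.exact_counts else int(rng.poisson(mean))
            min_flen = cfg.fragment_length if cfg.layout == "PE" else glen
            if not _valid_starts(tx, min_flen):
                if cfg.skip_short:
                    continue
                raise ConfigError(f"transcript {tx.tx_id} shorter than the fragment")
            made = 0
            for _ in range(n_reads):
                with_adapter = adapter is not None and rng.random() < cfg.adapter_fraction
                if cfg.layout == "PE":
                    frag_len = cfg.fragment_length
                elif with_adapter:
                    lo, hi = 18, glen - cfg.min_adapter_bases
                    if hi <= lo:
                        with_adapter = False
                        frag_len = glen
                    else:
                        frag_len = int(rng.integers(lo, hi, endpoint=True))
                else:
                    frag_len = glen
                ranges = _valid_starts(tx, frag_len)
                if not ranges:
                    continue
                widths = np.array([b - a + 1 for a, b in ranges])
                pick = rng.choice(len(ranges), p=widths / widths.sum())
                start = int(rng.integers(ranges[pick][0], ranges[pick][1], endpoint=True))
                frag = txseq[start : start + frag_len]
                sense = bool(rng.random() < cfg.strand_fraction)
                frag_oriented = frag if sense else revcomp(frag)
                frag_mut = _mutate(rng, frag_oriented, cfg.sub_error_rate)

                def _assemble(template: str) -> str:
                    core = template[:glen]
                    if with_adapter and len(core) < glen:
                        core = core + adapter[: glen - len(core)]
                    extra = _random_seq(rng, cfg.fiveprime_extra)
                    return (extra + core)[: cfg.read_length]

                bases1 = _assemble(frag_mut)
                rid = f"sim{ridx}"
                r1.append(SequenceRead(rid, bases1, _quals(rng, cfg, len(bases1)),
                                       Mate.MATE1 if cfg.layout == "PE" else Mate.SINGLE))
                if cfg.layout == "PE":
                    mate_template = revcomp(frag_mut)
                    bases2 = _assemble(mate_template)
                    r2.append(SequenceRead(rid, bases2, _quals(rng, cfg, len(bases2)), Mate.MATE2))
                origins.append(ReadOrigin(tx.tx_id, gene.gene_id, start, sense,
                                          frag_oriented[:glen], with_adapter, frag_len))
                ridx += 1
                made += 1
            tx_counts[tx.tx_id] = tx_counts.get(tx.tx_id, 0) + made
            gene_counts[gene.gene_id] = gene_counts.get(gene.gene_id, 0) + made

    truth = GroundTruth(tx_counts, gene_counts, origins,
                        adapter if cfg.adapter_fraction > 0 else None, cfg.fiveprime_extra)
    batch = ReadBatch(r1=r1, r2=r2 if cfg.layout == "PE" else None)
    return batch, truth


def with_overrides(cfg: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``cfg`` with fields replaced."""
    return replace(cfg, **kwargs)
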