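"""Pre-mapping read QC stages.

Four decisions are made per run, each from a bounded read sample so cost
does not scale with library size:

1. quality-encoding detection (4,000-read sample, ASCII-range heuristic);
2. 3' quality trimming (drop terminal bases with phred < 10) with an
   18-nucleotide minimum-length filter;
3. 3' adapter inference by k-mer overrepresentation and the clip decision
   (clip only when the candidate is absent from the genome and occurs in
   strictly more than 2.5% of sampled reads);
4. progressive 5' clipping (0, 4, 8, 12, 20 nt) scored by unique mapping
   rate, to remove nonreference 5' bases such as UMIs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import prod

from .models import Mate, Reference, SequenceRead

CLIP_GRID = (0, 4, 8, 12, 20)


class EncodingError(ValueError):
    pass


class UnmappableSampleError(ValueError):
    pass


@dataclass(frozen=True)
class QualityEncoding:
    name: str  # "sanger_33" or "illumina15_64"
    offset: int


SANGER_33 = QualityEncoding("sanger_33", 33)
ILLUMINA15_64 = QualityEncoding("illumina15_64", 64)


@dataclass
class TrimReport:
    reads_in: int
    reads_out: int
    bases_trimmed: int

    @property
    def qc_pass_rate(self) -> float:
        return self.reads_out / self.reads_in if self.reads_in else 0.0


@dataclass
class AdapterCall:
    candidate: str | None
    frequency: float
    in_genome: bool
    decision: str  # "clip" or "no_clip"


@dataclass
class FivePrimeClipResult:
    tested_clips: list[tuple[int, float]]
    chosen_clip: int


def detect_encoding(qual_strings: list[str]) -> QualityEncoding:
    """Infer the phred offset from raw quality characters.

    Any ASCII code below 59 implies the Sanger (+33) encoding; codes all at
    or above 64 with at least one at or above 75 imply Illumina 1.5 (+64).
    Anything else (e.g. every code in the overlap zone 59-63) is reported
    as undetermined so the caller can supply an explicit offset.
    """
    if not qual_strings or all(not q for q in qual_strings):
        raise EncodingError("empty quality sample")
    lo = min(min(ord(c) for c in q) for q in qual_strings if q)
    hi = max(max(ord(c) for c in q) for q in qual_strings if q)
    if lo < 59:
        return SANGER_33
    if lo >= 64 and hi >= 75:
        return ILLUMINA15_64
    raise EncodingError(
        f"undetermined quality encoding (ASCII range {lo}-{hi}); pass an explicit offset"
    )


def trim_3prime(
    read: SequenceRead, qual_threshold: int = 10, min_len: int = 18
) -> SequenceRead | None:
    """Strip low-quality 3' bases; return None when the read drops below min_len.

    Trimming is stepwise from the 3' terminus: the last base is removed
    while its phred score is strictly below the threshold.
    """
    n = len(read)
    while n > 0 and read.quals[n - 1] < qual_threshold:
        n -= 1
    if n < min_len:
        return None
    if n == len(read):
        return read
    return SequenceRead(read.read_id, read.bases[:n], read.quals[:n], read.mate)


def trim_batch(
    reads: list[SequenceRead], qual_threshold: int = 10, min_len: int = 18
) -> tuple[list[SequenceRead], TrimReport]:
    kept: list[SequenceRead] = []
    bases_trimmed = 0
    for r in reads:
        t = trim_3prime(r, qual_threshold, min_len)
        if t is None:
            bases_trimmed += len(r)
        else:
            bases_trimmed += len(r) - len(t)
            kept.append(t)
    return kept, TrimReport(len(reads), len(kept), bases_trimmed)


def trim_pairs(
    r1: list[SequenceRead],
    r2: list[SequenceRead],
    qual_threshold: int = 10,
    min_len: int = 18,
) -> tuple[list[SequenceRead], list[SequenceRead], TrimReport]:
    """Trim both mates; a pair is dropped when either mate fails min_len."""
    k1, k2, trimmed = [], [], 0
    for a, b in zip(r1, r2, strict=True):
        ta = trim_3prime(a, qual_threshold, min_len)
        tb = trim_3prime(b, qual_threshold, min_len)
        if ta is None or tb is None:
            trimmed += len(a) + len(b)
            continue
        trimmed += (len(a) - len(ta)) + (len(b) - len(tb))
        k1.append(ta)
        k2.append(tb)
    return k1, k2, TrimReport(len(r1), len(k1), trimmed)


def _base_composition(reads: list[SequenceRead]) -> dict[str, float]:
    counts: Counter[str] = Counter()
    for r in reads:
        counts.update(r.bases)
    total = sum(counts.values()) or 1
    return {b: counts.get(b, 0) / total for b in "ACGTN"}


def infer_adapter(
    sample: list[SequenceRead],
    genome: Reference | None,
    k: int = 12,
    tail_fraction: float = 1 / 3,
    overrep_factor: float = 10.0,
    min_kmer_count: int = 5,
    freq_threshold: float = 0.025,
) -> AdapterCall:
    """Infer a 3' adapter from k-mer overrepresentation and decide whether to clip.

    Counts k-mers whose start lies in the 3' ``tail_fraction`` of each
    read, takes the k-mer most overrepresented relative to its expectation
    under the sample's base composition, and greedily extends it left and
    right by per-column majority vote over the reads containing it.  The
    clip decision requires the final candidate to occur in strictly more
    than ``freq_threshold`` of sampled reads and to be absent (either
    strand, exact match) from the genome.
    """
    if len(sample) < 1:
        raise ValueError("empty read sample")
    kmer_counts: Counter[str] = Counter()
    n_kmers = 0
    for r in sample:
        lo = max(0, int(len(r) * (1 - tail_fraction)))
        for i in range(lo, len(r) - k + 1):
            kmer_counts[r.bases[i : i + k]] += 1
            n_kmers += 1
    comp = _base_composition(sample)

    best, best_ratio = None, 0.0
    for kmer, count in kmer_counts.items():
        if count < min_kmer_count:
            continue
        expect = n_kmers * prod(max(comp.get(b, 0.0), 1e-9) for b in kmer)
        ratio = count / max(expect, 1e-300)
        if ratio > best_ratio or (ratio == best_ratio and best is not None and kmer < best):
            best, best_ratio = kmer, ratio
    if best is None or best_ratio <= overrep_factor:
        return AdapterCall(None, 0.0, False, "no_clip")

    candidate = _extend_candidate(best, sample)
    n_contain = sum(candidate in r.bases for r in sample)
    frequency = n_contain / len(sample)
    in_genome = genome.contains(candidate) if genome is not None else False
    decision = "clip" if (not in_genome and frequency > freq_threshold) else "no_clip"
    return AdapterCall(candidate, frequency, in_genome, decision)


def _extend_candidate(
    candidate: str,
    sample: list[SequenceRead],
    majority: float = 0.7,
    min_support: int = 3,
    support_floor_frac: float = 0.3,
) -> str:
    """Greedy left/right extension of a seed k-mer by column majority vote."""
    initial = sum(candidate in r.bases for r in sample)
    floor = max(min_support, int(support_floor_frac * initial))
    for direction in (+1, -1):
        while True:
            votes: Counter[str] = Counter()
            for r in sample:
                i = r.bases.find(candidate)
                if i == -1:
                    continue
                j = i + len(candidate) if direction == +1 else i - 1
                if 0 <= j < len(r):
                    votes[r.bases[j]] += 1
            if not votes:
                break
            base, cnt = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            total = sum(votes.values())
            if cnt < floor or cnt / total < majority:
                break
            candidate = candidate + base if direction == +1 else base + candidate
    return candidate


def clip_adapter(
    read: SequenceRead,
    adapter: str,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
    min_len: int = 18,
) -> SequenceRead | None:
    """Remove the longest read-suffix matching an adapter-prefix.

    Returns the read unchanged when no suffix/prefix overlap of at least
    ``min_overlap`` bases fits within the mismatch budget, and None when
    the clipped read falls below ``min_len``.
    """
    best = 0
    max_l = min(len(read), len(adapter))
    for L in range(min_overlap, max_l + 1):
        tail = read.bases[-L:]
        mism = sum(a != b for a, b in zip(tail, adapter[:L]))
        if mism <= max_mismatch_rate * L:
            best = L
    if best == 0:
        return read
    n = len(read) - best
    if n < min_len:
        return None
    return SequenceRead(read.read_id, read.bases[:n], read.quals[:n], read.mate)


def clip_batch(
    reads: list[SequenceRead], adapter: str, **kwargs
) -> tuple[list[SequenceRead], TrimReport]:
    kept, trimmed = [], 0
    for r in reads:
        c = clip_adapter(r, adapter, **kwargs)
        if c is None:
            trimmed += len(r)
        else:
            trimmed += len(r) - len(c)
            kept.append(c)
    return kept, TrimReport(len(reads), len(kept), trimmed)


def optimize_5prime_clip(
    sample: list[SequenceRead],
    index,
    clip_grid: tuple[int, ...] = CLIP_GRID,
    max_mismatch: int = 2,
    margin: float = 0.01,
) -> FivePrimeClipResult:
    """Score progressive 5' clips by unique mapping rate; prefer less clipping.

    The chosen clip is the smallest one whose unique-mapping rate lies
    within ``margin`` of the best rate observed.  Residual nonreference 5'
    bases fail full-length verification outright, so under-clipping scores
    far below the margin; the tolerance only absorbs sampling noise among
    the clips at or beyond the true contamination length.  Reads left
    shorter than the mapper seed after clipping count as unmapped, so
    over-clipping is penalised naturally.
    """
    from . import mapper as _mapper

    if not sample:
        raise ValueError("empty read sample")
    tested: list[tuple[int, float]] = []
    for clip in clip_grid:
        n_unique = 0
        for r in sample:
            if len(r) - clip < index.seed_len:
                continue
            clipped = SequenceRead(r.read_id, r.bases[clip:], r.quals[clip:], r.mate)
            res = _mapper.map_read(clipped, index, max_mismatch=max_mismatch)
            if res.status == "unique":
                n_unique += 1
        tested.append((clip, n_unique / len(sample)))
    if all(rate == 0.0 for _, rate in tested):
        raise UnmappableSampleError("unmappable sample: no clip setting yields unique mappings")
    best = max(rate for _, rate in tested)
    chosen = min(clip for clip, rate in tested if rate >= best - margin)
    return FivePrimeClipResult(tested, chosen)
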