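"""FASTQ handling: quality filtering, pair merging, alignment, clustering.

The processing unit is one amplicon template per read: paired-end mates
are merged on their overlap, the merged read is globally aligned to the
amplicon with affine gap costs, and the alignment's indels are left-
normalized so that junction coordinates are reproducible.  Greedy
same-length clustering (the cd-hit idiom) is provided for the top-variant
report; classification itself operates per merged read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import Align

from .locus import RepeatLocus, revcomp
from .outcomes import IndelEvent

__all__ = [
    "SeqRecord",
    "Alignment",
    "read_fastq",
    "write_fastq",
    "quality_filter",
    "merge_pair",
    "align_to_amplicon",
    "normalize_indels",
    "cluster_reads",
    "Cluster",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeqRecord:
    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.qual)) if self.qual else 0.0


def read_fastq(path: str | Path):
    """Iterate SeqRecords from a plain or gzipped FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield SeqRecord(
                id=header[1:].strip().split()[0],
                seq=seq.upper(),
                qual=tuple(ord(c) - 33 for c in qual),
            )


def write_fastq(records, path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in records:
            fh.write(
                "@%s\n%s\n+\n%s\n" % (r.id, r.seq, "".join(chr(q + 33) for q in r.qual))
            )


# ---------------------------------------------------------------------------
# quality filter and pair merging
# ---------------------------------------------------------------------------

def quality_filter(reads, min_mean_q: float = 5.0):
    """Keep reads whose mean Phred quality is >= ``min_mean_q``
    (boundary inclusive); the discarded count is logged."""
    kept, discarded = [], 0
    for r in reads:
        if r.mean_q >= min_mean_q:
            kept.append(r)
        else:
            discarded += 1
    log.info("quality_filter: kept %d, discarded %d", len(kept), discarded)
    return kept


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def merge_pair(
    r1: SeqRecord,
    r2: SeqRecord,
    min_overlap: int = 20,
    max_overlap_mismatch: float = 0.1,
) -> SeqRecord | None:
    """Merge a read pair on their best ungapped overlap.

    ``r2`` is the reverse-strand mate and is reverse-complemented first.
    Among all ungapped offsets the one maximizing the number of matching
    overlap bases wins; disagreeing bases are resolved to the higher-
    quality base and merged qualities take the max of the two.  Returns
    None (UNMERGED) when the best overlap is shorter than ``min_overlap``
    or its mismatch rate exceeds ``max_overlap_mismatch``.
    """
    s1 = _encode(r1.seq)
    s2 = _encode(revcomp(r2.seq))
    q1 = np.asarray(r1.qual)
    q2 = np.asarray(r2.qual)[::-1]
    n1, n2 = len(s1), len(s2)

    best = None  # (matches, overlap_len, offset)
    # offset = start of s2 relative to s1 (may be negative); visit larger
    # overlaps first so a perfect overlap allows an early exit
    offsets = sorted(
        range(-(n2 - min_overlap), n1 - min_overlap + 1),
        key=lambda off: -(min(n1, off + n2) - max(0, off)),
    )
    for off in offsets:
        lo1, hi1 = max(0, off), min(n1, off + n2)
        ov = hi1 - lo1
        if ov < min_overlap:
            continue
        a = s1[lo1:hi1]
        b = s2[lo1 - off : hi1 - off]
        matches = int(np.count_nonzero(a == b))
        if best is None or matches > best[0]:
            best = (matches, ov, off)
        if matches == ov:
            break  # perfect overlap; smaller overlaps cannot have more matches
    if best is None:
        return None
    matches, ov, off = best
    if (ov - matches) / ov > max_overlap_mismatch:
        return None

    lo1, hi1 = max(0, off), min(n1, off + n2)
    a, b = s1[lo1:hi1], s2[lo1 - off : hi1 - off]
    qa, qb = q1[lo1:hi1], q2[lo1 - off : hi1 - off]
    cons = np.where(qa >= qb, a, b)
    consq = np.maximum(qa, qb)

    parts_seq, parts_q = [], []
    if off > 0:
        parts_seq.append(s1[:lo1]); parts_q.append(q1[:lo1])
    elif off < 0:
        parts_seq.append(s2[: -off]); parts_q.append(q2[: -off])
    parts_seq.append(cons); parts_q.append(consq)
    if off + n2 > n1:
        parts_seq.append(s2[hi1 - off :]); parts_q.append(q2[hi1 - off :])
    elif off + n2 < n1:
        parts_seq.append(s1[hi1:]); parts_q.append(q1[hi1:])
    seq = np.concatenate(parts_seq).tobytes().decode()
    qual = tuple(int(q) for q in np.concatenate(parts_q))
    return SeqRecord(id=r1.id, seq=seq, qual=qual)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A parsed read-vs-amplicon alignment.

    ``ops`` is the ordered operation list ``(kind, length, inserted_seq)``
    with kinds MATCH / MISMATCH / INS / DEL; ``indels`` the derived indel
    events, left-aligned once :func:`normalize_indels` has run.
    """

    read_id: str
    read_seq: str
    score: float
    identity: float
    ref_span: tuple[int, int]
    ops: tuple[tuple, ...]
    indels: tuple[IndelEvent, ...]
    normalized: bool = False


def _make_aligner(match, mismatch, gap_open, gap_extend):
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    # our convention: a gap of length L costs gap_open + L * gap_extend
    a.open_gap_score = gap_open + gap_extend
    a.extend_gap_score = gap_extend
    return a


def align_to_amplicon(
    read: SeqRecord | str,
    locus: RepeatLocus,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -6.0,
    gap_extend: float = -0.5,
    min_identity: float = 0.6,
    _aligner_cache: dict = {},
) -> Alignment | None:
    """Global affine alignment of a read to the amplicon.

    Amplicon reads are primer-defined and span the reference end to end,
    so the alignment is fully global.  Returns None (REJECTED) when the
    identity — matches over all alignment columns — falls below
    ``min_identity``; raises ValueError for non-ACGTN sequences.
    """
    if isinstance(read, str):
        read = SeqRecord(id="read", seq=read.upper(), qual=(30,) * len(read))
    if not read.seq:
        raise ValueError("invalid sequence: empty read")
    if set(read.seq) - set("ACGTN"):
        raise ValueError("invalid sequence: non-ACGTN symbols")
    key = (match, mismatch, gap_open, gap_extend)
    aligner = _aligner_cache.get(key)
    if aligner is None:
        aligner = _aligner_cache[key] = _make_aligner(*key)
    aln = aligner.align(locus.amplicon, read.seq)[0]
    parsed = _parse_alignment(read, locus.amplicon, aln)
    if parsed.identity < min_identity:
        return None
    return parsed


def _parse_alignment(read: SeqRecord, ref: str, aln) -> Alignment:
    t_blocks, q_blocks = aln.aligned
    ops: list[tuple] = []
    indels: list[IndelEvent] = []
    matches = mismatches = 0
    query = read.seq

    prev_t = 0
    prev_q = 0
    for (ts, te), (qs, qe) in zip(t_blocks.tolist(), q_blocks.tolist()):
        if ts > prev_t:
            ops.append(("DEL", ts - prev_t, ""))
            indels.append(IndelEvent("DEL", prev_t, ts, ref[prev_t:ts]))
        if qs > prev_q:
            ops.append(("INS", qs - prev_q, query[prev_q:qs]))
            indels.append(IndelEvent("INS", ts, ts, query[prev_q:qs]))
        a = _encode(ref[ts:te])
        b = _encode(query[qs:qe])
        eq = a == b
        m = int(np.count_nonzero(eq))
        matches += m
        mismatches += len(a) - m
        _append_match_ops(ops, eq)
        prev_t, prev_q = te, qe
    if prev_t < len(ref):
        ops.append(("DEL", len(ref) - prev_t, ""))
        indels.append(IndelEvent("DEL", prev_t, len(ref), ref[prev_t:]))
    if prev_q < len(query):
        ops.append(("INS", len(query) - prev_q, query[prev_q:]))
        indels.append(IndelEvent("INS", len(ref), len(ref), query[prev_q:]))

    # identity is read-centric: matches over read-consuming columns.
    # Reference-consuming deletion columns are excluded so that a read
    # carrying a genuine large deletion (half the amplicon gone) is not
    # rejected, while random sequence still scores well below threshold.
    ins_len = sum(ev.length for ev in indels if ev.kind == "INS")
    columns = matches + mismatches + ins_len
    identity = matches / columns if columns else 0.0
    ref_span = (
        (int(t_blocks[0][0]), int(t_blocks[-1][1])) if len(t_blocks) else (0, 0)
    )
    return Alignment(
        read_id=read.id,
        read_seq=query,
        score=float(aln.score),
        identity=identity,
        ref_span=ref_span,
        ops=tuple(ops),
        indels=tuple(indels),
    )


def _append_match_ops(ops, eq: np.ndarray) -> None:
    # run-length encode the match/mismatch vector
    if not len(eq):
        return
    start = 0
    for i in range(1, len(eq) + 1):
        if i == len(eq) or eq[i] != eq[start]:
            ops.append(("MATCH" if eq[start] else "MISMATCH", i - start, ""))
            start = i


def normalize_indels(aln: Alignment, locus: RepeatLocus) -> Alignment:
    """Shift every indel to its leftmost equivalent placement.

    Left-alignment makes junction coordinates reproducible across
    aligners (a deletion inside a repeat run has many score-equivalent
    placements).  Idempotent.
    """
    if aln.normalized:
        return aln
    ref = locus.amplicon
    out = []
    for ev in aln.indels:
        if ev.kind == "DEL":
            s, e = ev.start, ev.end
            while s > 0 and ref[s - 1] == ref[e - 1]:
                s -= 1
                e -= 1
            out.append(IndelEvent("DEL", s, e, ref[s:e]))
        else:
            p, seq = ev.start, ev.seq
            while p > 0 and ref[p - 1] == seq[-1]:
                seq = seq[-1] + seq[:-1]
                p -= 1
            out.append(IndelEvent("INS", p, p, seq))
    out.sort(key=lambda ev: (ev.start, ev.kind))
    return replace(aln, indels=tuple(out), normalized=True)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    representative: str
    size: int
    n_unique: int


def cluster_reads(
    seqs, min_identity: float = 0.95
) -> list[Cluster]:
    """Greedy abundance-sorted clustering of same-length sequences.

    Unique sequences are visited in decreasing abundance; each joins the
    first existing cluster whose representative has identical length and
    at least ``min_identity`` ungapped (Hamming) identity, else founds a
    new cluster.  The sum of cluster sizes equals the input read count.
    """
    from collections import Counter

    counts = Counter(s.seq if isinstance(s, SeqRecord) else s for s in seqs)
    clusters: list[Cluster] = []
    reps: dict[int, list[tuple[np.ndarray, Cluster]]] = {}
    for seq, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        arr = _encode(seq)
        placed = False
        for rep_arr, cl in reps.get(len(seq), ()):
            ident = np.count_nonzero(rep_arr == arr) / len(seq)
            if ident >= min_identity:
                cl.size += cnt
                cl.n_unique += 1
                placed = True
                break
        if not placed:
            cl = Cluster(representative=seq, size=cnt, n_unique=1)
            clusters.append(cl)
            reps.setdefault(len(seq), []).append((arr, cl))
    clusters.sort(key=lambda c: -c.size)
    return clusters
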