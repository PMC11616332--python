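"""End-to-end classification: FASTQ -> per-read outcomes -> summary.

Ties the stages together in the order the sequencing analysis runs them:
quality filter, pair merging (paired input), global alignment with
identity rejection, indel left-normalization, per-read classification,
and sample summarization.  Identical read sequences are aligned once and
the result reused, which makes error-free simulations nearly free and
deduplicates real data substantially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .locus import RepeatLocus
from .outcomes import OutcomeRecord, OutcomeSummary, classify_read, summarize
from .reads import (
    align_to_amplicon,
    cluster_reads,
    merge_pair,
    normalize_indels,
    quality_filter,
    read_fastq,
)

__all__ = ["ClassifyConfig", "classify_reads", "classify_fastq", "records_to_frame"]


@dataclass(frozen=True)
class ClassifyConfig:
    min_mean_q: float = 5.0
    min_overlap: int = 20
    max_overlap_mismatch: float = 0.1
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -0.5
    min_identity: float = 0.6


def classify_reads(
    reads,
    locus: RepeatLocus,
    guides=(),
    config: ClassifyConfig = ClassifyConfig(),
    pairs=None,
):
    """Run the per-read pipeline on SeqRecords (or pairs).

    Returns ``(records, qc)`` where ``qc`` counts reads kept, discarded
    by the quality filter, unmerged, and rejected by alignment identity.
    Unmerged and rejected reads are excluded from all denominators but
    counted here.
    """
    qc = {"input": 0, "low_quality": 0, "unmerged": 0, "rejected": 0, "classified": 0}
    if pairs is not None:
        merged = []
        for r1, r2 in pairs:
            qc["input"] += 1
            m = merge_pair(
                r1, r2, min_overlap=config.min_overlap,
                max_overlap_mismatch=config.max_overlap_mismatch,
            )
            if m is None:
                qc["unmerged"] += 1
            else:
                merged.append(m)
        reads = merged
    else:
        reads = list(reads)
        qc["input"] = len(reads)

    kept = quality_filter(reads, min_mean_q=config.min_mean_q)
    qc["low_quality"] = len(reads) - len(kept)

    records: list[OutcomeRecord] = []
    kept_seqs: list[str] = []
    aln_cache: dict[str, object] = {}
    rec_cache: dict[str, OutcomeRecord] = {}
    for r in kept:
        if r.seq not in aln_cache:
            aln = align_to_amplicon(
                r, locus,
                match=config.match, mismatch=config.mismatch,
                gap_open=config.gap_open, gap_extend=config.gap_extend,
                min_identity=config.min_identity,
            )
            if aln is not None:
                aln = normalize_indels(aln, locus)
                rec_cache[r.seq] = classify_read(aln, locus, guides)
            aln_cache[r.seq] = aln
        if aln_cache[r.seq] is None:
            qc["rejected"] += 1
            continue
        records.append(replace(rec_cache[r.seq], read_id=r.id))
        kept_seqs.append(r.seq)
    qc["classified"] = len(records)
    return records, qc, kept_seqs


def classify_fastq(
    fastq,
    locus: RepeatLocus,
    guides=(),
    fastq2=None,
    control_fastq=None,
    config: ClassifyConfig = ClassifyConfig(),
    top_n: int = 5,
):
    """Classify a FASTQ sample (optionally paired, optionally with an
    unedited control for stutter correction).

    Returns ``(records, summary, qc, clusters)``.
    """
    if fastq2 is not None:
        pairs = list(zip(read_fastq(fastq), read_fastq(fastq2)))
        if not pairs:
            raise ValueError("empty FASTQ input")
        records, qc, kept_seqs = classify_reads(None, locus, guides, config, pairs=pairs)
    else:
        reads = list(read_fastq(fastq))
        if not reads:
            raise ValueError("empty FASTQ input")
        records, qc, kept_seqs = classify_reads(reads, locus, guides, config)
    if not records:
        raise ValueError("no reads survived filtering/alignment")

    control_records = None
    if control_fastq is not None:
        control_records, _, _ = classify_reads(
            list(read_fastq(control_fastq)), locus, guides, config
        )
    summary = summarize(records, locus, control_records=control_records, top_n=top_n)
    clusters = cluster_reads(kept_seqs)
    return records, summary, qc, clusters


def records_to_frame(records):
    """Per-read records as a tidy DataFrame (one OutcomeRecord per row)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": r.read_id,
            "category": r.category,
            "cag_units": r.cag_units,
            "net_delta": r.net_delta,
            "frameshift": r.frameshift,
            "flank_changed": r.flank_changed,
            "whole_tract_excised": r.whole_tract_excised,
            "mh_seq": r.mh[0],
            "mh_len": r.mh[1],
            "staggered_ins": r.staggered_ins,
            "templated_ins": r.templated_ins[0] if r.templated_ins else "",
        }
        for r in records
    )
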