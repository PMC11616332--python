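"""Per-read CAG-tract genotyping and editing-outcome classification.

This is the analytical core of the package.  Each merged, aligned read is
reduced to an :class:`OutcomeRecord`: its repeat-unit count, net indel
length, one of six headline outcome categories, and repair-pathway
signature flags (microhomology-flanked deletion, whole-tract excision,
staggered-cut +1 insertion, templated insertion).  Samples are then
summarized into category fractions, a repeat-length histogram and a
ranked top-variant table, optionally with a PCR-stutter correction
estimated from an unedited control.

Categories
----------
``UNEDITED``
    the reference sequence, no indels.
``INS_CAG`` / ``DEL_CAG``
    in-frame gain / loss of repeat units (net indel divisible by 3).
``INS`` / ``DEL`` / ``INDEL``
    frameshift outcomes with only insertions, only deletions, or both.
``OTHER_INFRAME``
    internal seventh label for the rare corner of in-frame indels that
    leave the repeat count unchanged (pure-flank in-frame events); kept
    out of the six headline categories so it cannot silently distort them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .locus import Guide, RepeatLocus

__all__ = [
    "IndelEvent",
    "OutcomeRecord",
    "OutcomeSummary",
    "CATEGORIES",
    "count_repeats",
    "classify_read",
    "detect_microhomology",
    "detect_templated_insertion",
    "detect_staggered_ins",
    "estimate_stutter",
    "summarize",
    "deletion_shift_range",
    "insertion_shift_range",
]

CATEGORIES = ("UNEDITED", "INS_CAG", "DEL_CAG", "INS", "DEL", "INDEL")


@dataclass(frozen=True)
class IndelEvent:
    """A single insertion or deletion relative to the amplicon.

    For a DEL, ``[start, end)`` is the deleted amplicon interval and
    ``seq`` the deleted reference bases.  For an INS, ``start == end`` is
    the between-base insertion point and ``seq`` the inserted bases.
    """

    kind: str  # "INS" | "DEL"
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.kind not in ("INS", "DEL"):
            raise ValueError("kind must be INS or DEL")
        if self.kind == "INS" and (self.start != self.end or not self.seq):
            raise ValueError("INS needs start == end and non-empty seq")
        if self.kind == "DEL" and self.end - self.start != len(self.seq):
            raise ValueError("DEL interval must match deleted seq length")

    @property
    def length(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# repeat counting
# ---------------------------------------------------------------------------

def count_repeats(seq: str, motif: str = "CAG") -> tuple[int, tuple[int, int]]:
    """Longest exact tandem run of ``motif`` in ``seq`` (any phase).

    Returns ``(units, (start, end))``; ties broken leftmost; no run at all
    gives ``(0, (0, 0))``.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    best_units, best_iv = 0, (0, 0)
    i = 0
    n = len(seq)
    while i < n:
        if seq[i : i + m] == motif:
            j = i + m
            while seq[j : j + m] == motif:
                j += m
            units = (j - i) // m
            if units > best_units:
                best_units, best_iv = units, (i, j)
            # runs starting strictly inside [i, j) cannot be longer than
            # this one, so resume near the run's tail
            i = max(i + 1, j - m + 1)
        else:
            i += 1
    return best_units, best_iv


# ---------------------------------------------------------------------------
# placement ambiguity (microhomology) helpers
# ---------------------------------------------------------------------------

def deletion_shift_range(amplicon: str, start: int, end: int) -> tuple[int, int]:
    """Maximal left/right shifts of DEL ``[start, end)`` that leave the
    edited sequence unchanged (junction microhomology ambiguity)."""
    left = 0
    while start - left - 1 >= 0 and amplicon[start - left - 1] == amplicon[end - left - 1]:
        left += 1
    right = 0
    while end + right < len(amplicon) and amplicon[start + right] == amplicon[end + right]:
        right += 1
    return left, right


def insertion_shift_range(amplicon: str, pos: int, seq: str) -> tuple[int, int]:
    """Maximal left/right shifts of an insertion at ``pos`` (with cyclic
    rotation of ``seq``) that leave the edited sequence unchanged."""
    left = 0
    s = seq
    p = pos
    while p - 1 >= 0 and amplicon[p - 1] == s[-1] and left < len(amplicon):
        s = s[-1] + s[:-1]
        p -= 1
        left += 1
    right = 0
    s = seq
    p = pos
    while p < len(amplicon) and amplicon[p] == s[0] and right < len(amplicon):
        s = s[1:] + s[0]
        p += 1
        right += 1
    return left, right


def _del_has_placement(amplicon, ev, pred) -> bool:
    l, r = deletion_shift_range(amplicon, ev.start, ev.end)
    return any(pred(ev.start + d, ev.end + d) for d in range(-l, r + 1))


def _ins_has_placement(amplicon, ev, pred) -> bool:
    l, r = insertion_shift_range(amplicon, ev.start, ev.seq)
    return any(pred(ev.start + d) for d in range(-l, r + 1))


# ---------------------------------------------------------------------------
# repair signatures
# ---------------------------------------------------------------------------

def detect_microhomology(
    ev: IndelEvent, amplicon: str, max_len: int = 10
) -> tuple[str, int]:
    """Junction microhomology of a deletion: the longest word (up to
    ``max_len``) repeated at both junctions, checking the left-side
    (``amplicon[start-k:start] == amplicon[end-k:end]``) and right-side
    (``amplicon[start:start+k] == amplicon[end:end+k]``) registers and
    taking the larger.  Returns ``("", 0)`` for unique junctions."""
    if ev.kind != "DEL":
        raise ValueError("microhomology is defined for deletions")
    s, e = ev.start, ev.end
    best = ("", 0)
    for k in range(1, max_len + 1):
        if s - k >= 0 and amplicon[s - k : s] == amplicon[e - k : e]:
            best = (amplicon[s - k : s], k)
    for k in range(1, max_len + 1):
        if e + k <= len(amplicon) and amplicon[s : s + k] == amplicon[e : e + k]:
            if k > best[1]:
                best = (amplicon[s : s + k], k)
    return best


def detect_templated_insertion(
    ev: IndelEvent, amplicon: str, window: int = 25, min_len: int = 4
) -> tuple[int, int] | None:
    """Local donor of an inserted sequence, if any.

    Searches the forward strand within ``window`` nt of the insertion
    point for an exact copy of the inserted sequence (or, failing that,
    of its longest prefix or suffix of at least ``min_len`` nt).  Returns
    the nearest donor interval, or None.  Insertions shorter than
    ``min_len`` are never reported (the 1-nt staggered-cut duplication is
    handled by :func:`detect_staggered_ins`).
    """
    if ev.kind != "INS":
        raise ValueError("templated-insertion search needs an INS event")
    ins = ev.seq
    if len(ins) < min_len:
        return None
    pos = ev.start

    def _search(word: str):
        lo = max(0, pos - window)
        hi = min(len(amplicon), pos + window)
        hits = []
        j = amplicon.find(word, lo)
        while j != -1 and j + len(word) <= hi:
            hits.append((j, j + len(word)))
            j = amplicon.find(word, j + 1)
        if not hits:
            return None
        return min(hits, key=lambda iv: (min(abs(iv[0] - pos), abs(iv[1] - pos)), iv[0]))

    hit = _search(ins)
    if hit:
        return hit
    for L in range(len(ins) - 1, min_len - 1, -1):
        for word in (ins[:L], ins[-L:]):
            hit = _search(word)
            if hit:
                return hit
    return None


def detect_staggered_ins(ev: IndelEvent, guide: Guide, amplicon: str) -> bool:
    """True iff ``ev`` is the single-base duplication expected from a
    staggered Cas9 cut at ``guide``: a 1-nt insertion within 1 nt of the
    blunt cut whose base equals the staggered-donor base."""
    if ev.kind != "INS":
        return False
    return (
        len(ev.seq) == 1
        and abs(ev.start - guide.blunt_cut) <= 1
        and ev.seq == amplicon[guide.staggered_donor]
    )


# ---------------------------------------------------------------------------
# per-read classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeRecord:
    read_id: str
    category: str
    cag_units: int
    net_delta: int
    frameshift: bool
    flank_changed: bool
    whole_tract_excised: bool
    mh: tuple[str, int]
    staggered_ins: bool
    templated_ins: tuple[str, tuple[int, int]] | None
    indels: tuple[IndelEvent, ...] = ()

    @property
    def signature(self) -> tuple:
        """Variant signature: net length change plus junction coordinates
        and inserted sequences — identical templates share a signature."""
        return (
            self.net_delta,
            tuple((ev.kind, ev.start, ev.end, ev.seq) for ev in self.indels),
        )


def _tract_only(ev: IndelEvent, locus: RepeatLocus) -> bool:
    """True iff some equivalent placement of ``ev`` lies entirely inside
    the repeat tract (microhomology-ambiguity grace: left-alignment alone
    would overcall flank changes at the tract's left edge)."""
    s, e = locus.repeat_interval
    if ev.kind == "DEL":
        return _del_has_placement(
            locus.amplicon, ev, lambda a, b: a >= s and b <= e
        )
    return _ins_has_placement(locus.amplicon, ev, lambda p: s < p < e)


def _covers_tract(ev: IndelEvent, locus: RepeatLocus) -> bool:
    if ev.kind != "DEL":
        return False
    s, e = locus.repeat_interval
    return _del_has_placement(locus.amplicon, ev, lambda a, b: a <= s and b >= e)


def _apply_indels(amplicon: str, indels) -> str:
    """Reference sequence with the indel events applied (substitutions
    reverted): the read's inferred template."""
    seq = amplicon
    for ev in sorted(indels, key=lambda e: (-e.start, e.kind != "DEL")):
        if ev.kind == "DEL":
            seq = seq[: ev.start] + seq[ev.end :]
        else:
            seq = seq[: ev.start] + ev.seq + seq[ev.start :]
    return seq


def classify_read(aln, locus: RepeatLocus, guides=()) -> OutcomeRecord:
    """Classify one aligned (and indel-normalized) read.

    ``aln`` must expose ``read_id``, ``read_seq`` and a left-aligned
    ``indels`` tuple (see :mod:`cagrepair.reads`).  The repeat count is
    taken on the read's inferred template (the reference with the
    alignment's indels applied), which makes the call tolerant of
    sequencing substitutions inside the tract — a base error must not
    fragment the exact repeat run and masquerade as a contraction.
    """
    indels = tuple(aln.indels)
    amplicon = locus.amplicon
    net = sum(ev.length if ev.kind == "INS" else -ev.length for ev in indels)
    frameshift = net % 3 != 0
    units, _iv = count_repeats(_apply_indels(amplicon, indels), locus.motif)

    kinds = {ev.kind for ev in indels}
    if not indels:
        category = "UNEDITED"
    elif frameshift:
        if kinds == {"INS"}:
            category = "INS"
        elif kinds == {"DEL"}:
            category = "DEL"
        else:
            category = "INDEL"
    elif units > locus.expected_units:
        category = "INS_CAG"
    elif units < locus.expected_units:
        category = "DEL_CAG"
    else:
        category = "OTHER_INFRAME"

    flank_changed = any(not _tract_only(ev, locus) for ev in indels)
    whole_tract = any(_covers_tract(ev, locus) for ev in indels)

    mh = ("", 0)
    dels = [ev for ev in indels if ev.kind == "DEL"]
    if dels:
        principal = max(dels, key=lambda ev: ev.length)
        mh = detect_microhomology(principal, amplicon)

    ins_events = [ev for ev in indels if ev.kind == "INS"]
    staggered = any(
        detect_staggered_ins(ev, g, amplicon)
        for ev in ins_events
        for g in (guides.values() if isinstance(guides, dict) else guides)
    )
    templated = None
    for ev in sorted(ins_events, key=lambda e: -e.length):
        donor = detect_templated_insertion(ev, amplicon)
        if donor is not None:
            templated = (ev.seq, donor)
            break

    return OutcomeRecord(
        read_id=aln.read_id,
        category=category,
        cag_units=units,
        net_delta=net,
        frameshift=frameshift,
        flank_changed=flank_changed,
        whole_tract_excised=whole_tract,
        mh=mh,
        staggered_ins=staggered,
        templated_ins=templated,
        indels=indels,
    )


# ---------------------------------------------------------------------------
# stutter and sample summaries
# ---------------------------------------------------------------------------

def _inframe_tract_only(rec: OutcomeRecord) -> bool:
    return not rec.frameshift and not rec.flank_changed


def estimate_stutter(control_records) -> dict[int, float]:
    """Empirical distribution of repeat-unit deviation among in-frame,
    tract-only reads of an unedited control sample.

    PCR slippage over the repeat produces whole-unit contractions (and
    rarer expansions) even without editing; this distribution is the
    correction kernel used by :func:`summarize`.
    """
    control_records = list(control_records)
    if not control_records:
        raise ValueError("empty control sample")
    usable = [r for r in control_records if _inframe_tract_only(r)]
    if not usable:
        raise ValueError("no usable reads in control (all frameshift/flank-changed)")
    expected = _infer_expected_units(usable)
    counts = Counter(r.cag_units - expected for r in usable)
    n = sum(counts.values())
    return {d: c / n for d, c in sorted(counts.items())}


def _infer_expected_units(records) -> int:
    # unedited records carry net_delta 0 at the reference repeat count
    for r in records:
        if r.category == "UNEDITED":
            return r.cag_units
    # fall back to the mode
    return Counter(r.cag_units for r in records).most_common(1)[0][0]


@dataclass
class OutcomeSummary:
    n_reads: int
    category_fractions: dict[str, float]
    flank_fraction: float
    length_histogram: dict[tuple[int, bool], float]
    top_variants: list[tuple[tuple, float]]
    whole_tract_fraction: float
    staggered_ins_fraction: float
    stutter_corrected: dict[str, float] | None = None

    def to_dict(self) -> dict:
        """JSON-serializable form."""
        return {
            "n_reads": self.n_reads,
            "category_fractions": self.category_fractions,
            "flank_fraction": self.flank_fraction,
            "length_histogram": [
                {"cag_units": u, "frameshift": fs, "fraction": f}
                for (u, fs), f in sorted(self.length_histogram.items())
            ],
            "top_variants": [
                {"net_delta": sig[0], "events": [list(e) for e in sig[1]], "fraction": f}
                for sig, f in self.top_variants
            ],
            "whole_tract_fraction": self.whole_tract_fraction,
            "staggered_ins_fraction": self.staggered_ins_fraction,
            "stutter_corrected": self.stutter_corrected,
        }


def summarize(
    records,
    locus: RepeatLocus,
    control_records=None,
    top_n: int = 5,
) -> OutcomeSummary:
    """Sample-level summary of per-read outcome records.

    Category fractions are over all classified reads; the flank-change
    fraction is over *edited* reads only (the denominator choice for the
    flank plot); the repeat-length histogram is over all reads stratified
    by frameshift.  If an unedited control is supplied, a stutter-corrected
    category table is added: the control's repeat-deviation kernel, scaled
    by the observed unedited fraction, is subtracted from the in-frame
    tract-only deviation mass with a non-negativity clamp, and the result
    renormalized.  Both raw and corrected tables are reported.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    n = len(records)
    cat = Counter(r.category for r in records)
    category_fractions = {c: cat.get(c, 0) / n for c in CATEGORIES}
    if cat.get("OTHER_INFRAME"):
        category_fractions["OTHER_INFRAME"] = cat["OTHER_INFRAME"] / n

    edited = [r for r in records if r.category != "UNEDITED"]
    flank_fraction = (
        sum(r.flank_changed for r in edited) / len(edited) if edited else 0.0
    )
    hist = Counter((r.cag_units, r.frameshift) for r in records)
    length_histogram = {k: v / n for k, v in hist.items()}

    sig = Counter(r.signature for r in records)
    top_variants = [(s, c / n) for s, c in sig.most_common(top_n)]

    whole_tract_fraction = sum(r.whole_tract_excised for r in records) / n
    staggered_fraction = sum(r.staggered_ins for r in records) / n

    stutter_corrected = None
    if control_records is not None:
        stutter = estimate_stutter(control_records)
        stutter_corrected = _stutter_correct(records, locus, stutter, n)

    return OutcomeSummary(
        n_reads=n,
        category_fractions=category_fractions,
        flank_fraction=flank_fraction,
        length_histogram=length_histogram,
        top_variants=top_variants,
        whole_tract_fraction=whole_tract_fraction,
        staggered_ins_fraction=staggered_fraction,
        stutter_corrected=stutter_corrected,
    )


def _stutter_correct(records, locus, stutter, n) -> dict[str, float]:
    """Subtractive deconvolution of PCR stutter from the in-frame
    tract-only repeat-deviation mass, clamped at zero and renormalized."""
    expected = locus.expected_units
    obs = Counter(
        r.cag_units - expected for r in records if _inframe_tract_only(r)
    )
    obs = {d: c / n for d, c in obs.items()}
    u = obs.get(0, 0.0)  # observed unedited-looking fraction
    if stutter.get(0, 0.0) <= 0:
        raise ValueError("degenerate stutter kernel: no unshifted control mass")
    corrected = {0: u}
    for d, f in obs.items():
        if d != 0:
            corrected[d] = max(0.0, f - u * stutter.get(d, 0.0) / stutter[0])
    cats = Counter(r.category for r in records)
    out = {c: cats.get(c, 0) / n for c in CATEGORIES}
    out["DEL_CAG"] = sum(f for d, f in corrected.items() if d < 0)
    out["INS_CAG"] = sum(f for d, f in corrected.items() if d > 0)
    out["UNEDITED"] = corrected[0]
    total = sum(out.values())
    if total > 0:
        out = {c: f / total for c, f in out.items()}
    return out
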