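"""Synthetic inputs with ground truth for every stage of the pipeline.

The read generator emulates deep amplicon sequencing of a CRISPR-edited
CAG-repeat locus: a ~242-bp amplicon carrying a (CAG)41 tract, 250-bp
reads (merged or paired-end), and a configurable mixture of editing
outcomes — unedited templates, PCR stutter, in-frame repeat contractions
and expansions, microhomology-anchored whole-tract excisions, the
staggered-cut single-base duplication, locally templated insertions,
flank deletions, dual-cut excisions and composite indels.  Each read name
carries its ground-truth label, and a truth table (class, intended
outcome category, repeat units, net indel, signature flags) accompanies
the FASTQ so the classifier can be scored exactly.

Companion generators produce qPCR Cq tables (the analytic inverse of the
resection formula, for round-trip testing), capillary-electrophoresis
peak tables and label-free proteomics intensity matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locus import Guide, RepeatLocus, revcomp
from .outcomes import (
    IndelEvent,
    deletion_shift_range,
    insertion_shift_range,
    _del_has_placement,
    _ins_has_placement,
)
from .reads import SeqRecord, write_fastq

__all__ = [
    "SIM_CLASSES",
    "OutcomeSpec",
    "SimConfig",
    "sample_stutter",
    "simulate_reads",
    "simulate_resection_cq",
    "simulate_lfq",
    "simulate_ce_peaks",
    "LfqTruth",
]

SIM_CLASSES = (
    "UNEDITED",
    "STUTTER",
    "INFRAME_DEL_CAG",
    "INS_CAG",
    "WHOLE_TRACT_MH_DEL",
    "STAGGERED_INS",
    "TEMPLATED_INS",
    "FLANK_DEL",
    "DUAL_CUT_EXCISION",
    "COMPLEX",
)

#: classes whose construction needs at least one located guide
_NEEDS_GUIDE = {"STAGGERED_INS", "TEMPLATED_INS", "FLANK_DEL", "COMPLEX"}


@dataclass(frozen=True)
class OutcomeSpec:
    """A mixture of outcome classes with per-class parameters.

    ``components`` is a list of ``(sim_class, params_dict, probability)``;
    probabilities must sum to 1.
    """

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple(
            (cls, dict(params), float(prob)) for cls, params, prob in self.components
        )
        object.__setattr__(self, "components", comps)
        total = sum(p for _, _, p in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1 (got %g)" % total)
        for cls, params, prob in comps:
            if cls not in SIM_CLASSES:
                raise ValueError("unknown outcome class %r" % cls)
            if prob < 0:
                raise ValueError("negative probability for %s" % cls)

    @classmethod
    def from_dict(cls, fractions: dict, params: dict | None = None) -> "OutcomeSpec":
        params = params or {}
        return cls(
            tuple((c, params.get(c, {}), p) for c, p in fractions.items())
        )


@dataclass(frozen=True)
class SimConfig:
    n_reads: int
    seed: int
    sub_error_rate: float = 0.0
    layout: str = "merged"  # "merged" | "paired"
    read_len: int = 250
    base_quality: int = 30

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not (0 <= self.sub_error_rate < 0.1):
            raise ValueError("sub_error_rate must be in [0, 0.1)")
        if self.read_len > 300:
            raise ValueError("read_len must be <= 300")
        if self.layout not in ("merged", "paired"):
            raise ValueError("layout must be 'merged' or 'paired'")


# ---------------------------------------------------------------------------
# stutter law
# ---------------------------------------------------------------------------

def sample_stutter(
    units: int,
    slip_prob: float,
    rng: np.random.Generator,
    p_geo: float = 0.5,
    contraction_bias: float = 0.9,
) -> int:
    """Draw a stuttered repeat count.

    With probability ``1 - slip_prob`` the template count is returned
    unchanged; otherwise the whole-unit deviation magnitude is geometric
    (``p_geo``) and its sign is negative (contraction) with probability
    ``contraction_bias``.  Results are clamped at zero, and a zero-unit
    template never slips (no repeats to misprime on).  The slip parameters
    are placeholders — real stutter rates are instrument- and
    locus-specific and should be estimated from an unedited control.
    """
    if units < 0:
        raise ValueError("units must be >= 0")
    if not (0 <= slip_prob < 0.5):
        raise ValueError("slip_prob must be in [0, 0.5)")
    if units == 0:
        return 0
    if rng.random() >= slip_prob:
        return units
    mag = int(rng.geometric(p_geo))
    sign = -1 if rng.random() < contraction_bias else 1
    return max(0, units + sign * mag)


# ---------------------------------------------------------------------------
# template construction per class
# ---------------------------------------------------------------------------

def _tract_template(locus: RepeatLocus, units: int) -> tuple[str, list[IndelEvent]]:
    """Template with ``units`` repeat units; the length change expressed
    as a single left-aligned tract-edge indel event."""
    amp = locus.amplicon
    s, e = locus.repeat_interval
    motif = locus.motif
    delta = units - locus.expected_units
    seq = amp[:s] + motif * units + amp[e:]
    if delta == 0:
        return seq, []
    if delta < 0:
        d = -delta * len(motif)
        return seq, [IndelEvent("DEL", s, s + d, amp[s : s + d])]
    return seq, [IndelEvent("INS", s, s, motif * delta)]


def _mh_del_candidates(locus: RepeatLocus, max_flank: int = 10, min_mh: int = 2):
    """All whole-tract deletions [s, e) extending 0..max_flank nt into
    each flank whose junctions carry >= min_mh nt of microhomology."""
    amp = locus.amplicon
    ts, te = locus.repeat_interval
    cands = []
    for a in range(0, max_flank + 1):
        for b in range(0, max_flank + 1):
            s, e = ts - a, te + b
            if s < min_mh or e + min_mh > len(amp):
                continue
            ok = amp[s - min_mh : s] == amp[e - min_mh : e] or amp[s : s + min_mh] == amp[e : e + min_mh]
            if ok:
                cands.append((s, e))
    return cands


def _pick_guide(guides, params) -> Guide:
    if not guides:
        raise ValueError("guide required for this outcome class")
    if isinstance(guides, dict):
        name = params.get("guide")
        return guides[name] if name else next(iter(guides.values()))
    return list(guides)[0]


def _build_template(cls, params, locus, guides, rng):
    """Return (template_seq, events) for one simulated molecule."""
    amp = locus.amplicon
    ts, te = locus.repeat_interval
    exp = locus.expected_units

    if cls == "UNEDITED":
        return amp, []

    if cls == "STUTTER":
        units = sample_stutter(
            exp,
            params.get("slip_prob", 0.1),
            rng,
            params.get("p_geo", 0.5),
            params.get("contraction_bias", 0.9),
        )
        return _tract_template(locus, units)

    if cls == "INFRAME_DEL_CAG":
        max_removed = exp - 1
        k = min(int(rng.geometric(params.get("p_units", 0.15))), max_removed)
        return _tract_template(locus, exp - k)

    if cls == "INS_CAG":
        k = min(int(rng.geometric(params.get("p_units", 0.5))), params.get("max_units", 10))
        return _tract_template(locus, exp + k)

    if cls == "WHOLE_TRACT_MH_DEL":
        cands = _mh_del_candidates(
            locus, params.get("max_flank", 10), params.get("min_mh", 2)
        )
        if not cands:
            raise ValueError("locus has no microhomology-anchored whole-tract deletion")
        s, e = cands[int(rng.integers(len(cands)))]
        return amp[:s] + amp[e:], [IndelEvent("DEL", s, e, amp[s:e])]

    if cls == "STAGGERED_INS":
        g = _pick_guide(guides, params)
        cut, donor = g.blunt_cut, g.staggered_donor
        base = amp[donor]
        return amp[:cut] + base + amp[cut:], [IndelEvent("INS", cut, cut, base)]

    if cls == "TEMPLATED_INS":
        g = _pick_guide(guides, params)
        cut = g.blunt_cut
        L = int(rng.integers(params.get("min_len", 4), params.get("max_len", 12) + 1))
        lo = max(0, cut - 25)
        hi = cut - L
        if hi <= lo:
            raise ValueError("cut too close to amplicon start for templated insertion")
        d = int(rng.integers(lo, hi + 1))
        ins = amp[d : d + L]
        return amp[:cut] + ins + amp[cut:], [IndelEvent("INS", cut, cut, ins)]

    if cls == "FLANK_DEL":
        g = _pick_guide(guides, params)
        cut = g.blunt_cut
        L = int(rng.integers(params.get("min_len", 1), params.get("max_len", 12) + 1))
        if cut <= ts:  # upstream guide: delete into the 5' flank
            s, e = cut - L, cut
        else:  # downstream (or in-tract) guide: delete into the 3' flank
            s, e = max(cut, te), max(cut, te) + L
        if s < 0 or e > len(amp):
            raise ValueError("flank deletion outside amplicon")
        return amp[:s] + amp[e:], [IndelEvent("DEL", s, e, amp[s:e])]

    if cls == "DUAL_CUT_EXCISION":
        if guides is None or len(guides) < 2:
            raise ValueError("guide required: dual-cut excision needs two guides")
        gs = list(guides.values()) if isinstance(guides, dict) else list(guides)
        cuts = sorted(g.blunt_cut for g in gs)
        s, e = cuts[0], cuts[-1]
        return amp[:s] + amp[e:], [IndelEvent("DEL", s, e, amp[s:e])]

    if cls == "COMPLEX":
        # composite lesion: a flank deletion at the cut plus a separate
        # random insertion in the opposite flank.  The two events are kept
        # well apart: a deletion-plus-insert at a single junction next to
        # the repeat tract is not uniquely recoverable by any optimal
        # aligner (the insert is score-equivalently absorbed as
        # mismatches against the elastic repeat), so the composite class
        # is built from separated, individually recoverable events.
        g = _pick_guide(guides, params)
        cut = g.blunt_cut
        dlen = int(rng.integers(params.get("min_del", 4), params.get("max_del", 10) + 1))
        if cut <= ts:
            s, e = max(0, cut - dlen), cut
            ins_pos = (te + len(amp)) // 2
        else:
            s, e = max(cut, te), max(cut, te) + dlen
            ins_pos = ts // 2
        if e > len(amp):
            raise ValueError("flank too short for composite deletion")
        while True:
            ilen = int(rng.integers(params.get("min_ins", 7), params.get("max_ins", 12) + 1))
            if (ilen - (e - s)) % 3 != 0:
                break
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ilen))
        events = sorted(
            [IndelEvent("DEL", s, e, amp[s:e]), IndelEvent("INS", ins_pos, ins_pos, ins)],
            key=lambda ev: ev.start,
        )
        seq = amp
        for ev in sorted(events, key=lambda ev: -ev.start):
            if ev.kind == "DEL":
                seq = seq[: ev.start] + seq[ev.end :]
            else:
                seq = seq[: ev.start] + ev.seq + seq[ev.start :]
        return seq, events

    raise ValueError("unknown outcome class %r" % cls)


def _truth_category(events, locus: RepeatLocus, template: str) -> str:
    """Intended six-category outcome of a constructed edit (same rules as
    the classifier, applied to the generator's exact event list)."""
    from .outcomes import count_repeats

    if not events:
        return "UNEDITED"
    net = sum(ev.length if ev.kind == "INS" else -ev.length for ev in events)
    if net % 3 != 0:
        kinds = {ev.kind for ev in events}
        if kinds == {"INS"}:
            return "INS"
        if kinds == {"DEL"}:
            return "DEL"
        return "INDEL"
    units, _ = count_repeats(template, locus.motif)
    if units > locus.expected_units:
        return "INS_CAG"
    if units < locus.expected_units:
        return "DEL_CAG"
    return "OTHER_INFRAME"


def _truth_flags(events, locus: RepeatLocus):
    s, e = locus.repeat_interval
    amp = locus.amplicon
    flank = False
    whole = False
    for ev in events:
        if ev.kind == "DEL":
            inside = _del_has_placement(amp, ev, lambda a, b: a >= s and b <= e)
            covers = _del_has_placement(amp, ev, lambda a, b: a <= s and b >= e)
            whole = whole or covers
        else:
            inside = _ins_has_placement(amp, ev, lambda p: s < p < e)
        flank = flank or not inside
    return flank, whole


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    locus: RepeatLocus,
    guides,
    spec: OutcomeSpec,
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    prefix: str = "sim",
):
    """Simulate edited amplicon reads with a per-read truth table.

    Returns ``(reads, truth)`` where ``reads`` is a list of SeqRecords
    (merged layout) or ``(r1, r2)`` tuples (paired layout) and ``truth``
    a DataFrame with one row per read.  When ``out_dir`` is given, FASTQ
    file(s) and ``<prefix>_truth.tsv`` are also written; output is
    byte-identical for identical configurations.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = [c for c, _, _ in spec.components]
    probs = np.array([p for _, _, p in spec.components])
    params = {i: pr for i, (_, pr, _) in enumerate(spec.components)}
    for cls in classes:
        if cls in _NEEDS_GUIDE and not guides:
            raise ValueError("guide required for outcome class %s" % cls)

    draws = rng.choice(len(classes), size=cfg.n_reads, p=probs)
    reads, truth_rows = [], []
    staggered_truth_cache = {}
    for i, ci in enumerate(draws):
        cls = classes[ci]
        template, events = _build_template(cls, params[ci], locus, guides, rng)
        net = sum(ev.length if ev.kind == "INS" else -ev.length for ev in events)
        from .outcomes import count_repeats

        units, _ = count_repeats(template, locus.motif)
        category = _truth_category(events, locus, template)
        flank, whole = _truth_flags(events, locus)
        staggered = cls == "STAGGERED_INS"
        rid = "read%06d|class=%s|cag=%d|delta=%d" % (i, cls, units, net)
        truth_rows.append(
            {
                "read_id": rid,
                "class": cls,
                "category": category,
                "cag_units": units,
                "net_delta": net,
                "flank_changed": flank,
                "whole_tract_excised": whole,
                "staggered_ins": staggered,
            }
        )
        reads.append(_template_to_reads(rid, template, cfg, rng))

    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if cfg.layout == "merged":
            write_fastq(reads, out_dir / ("%s.fastq" % prefix))
        else:
            write_fastq((r[0] for r in reads), out_dir / ("%s_R1.fastq" % prefix))
            write_fastq((r[1] for r in reads), out_dir / ("%s_R2.fastq" % prefix))
        truth.to_csv(out_dir / ("%s_truth.tsv" % prefix), sep="\t", index=False)
    return reads, truth


def _add_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if not len(hits):
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def _template_to_reads(rid: str, template: str, cfg: SimConfig, rng):
    q = cfg.base_quality
    if cfg.layout == "merged":
        seq = _add_errors(template, cfg.sub_error_rate, rng)
        return SeqRecord(id=rid, seq=seq, qual=(q,) * len(seq))
    r1 = _add_errors(template[: cfg.read_len], cfg.sub_error_rate, rng)
    r2 = _add_errors(revcomp(template)[: cfg.read_len], cfg.sub_error_rate, rng)
    return (
        SeqRecord(id=rid + "/1", seq=r1, qual=(q,) * len(r1)),
        SeqRecord(id=rid + "/2", seq=r2, qual=(q,) * len(r2)),
    )


# ---------------------------------------------------------------------------
# qPCR, CE and LFQ generators
# ---------------------------------------------------------------------------

def resection_delta_cq(ssdna_pct: float) -> float:
    """Analytic inverse of the restriction-protection resection formula:
    the Cq shift of the digested fraction for a given ssDNA percentage."""
    if ssdna_pct <= 0 or ssdna_pct > 100:
        raise ValueError("ssdna_pct must be in (0, 100]")
    return float(np.log2(100.0 / ssdna_pct - 0.5) + 1.0)


def simulate_resection_cq(
    truth: pd.DataFrame,
    cq_mock_base: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_tech: int = 3,
    n_bio: int = 1,
) -> pd.DataFrame:
    """Cq table realizing given ssDNA percentages per site/timepoint.

    ``truth`` needs columns site, timepoint_h, ssdna_pct (optionally
    distance_bp).  Output rows are one technical replicate each, with
    digested and mock conditions, Gaussian Cq noise of ``noise_sd``.
    At zero noise the table round-trips exactly through the resection
    calculator.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, t in truth.iterrows():
        dcq = resection_delta_cq(float(t["ssdna_pct"]))
        for bio in range(1, n_bio + 1):
            for cond, base in (("mock", cq_mock_base), ("digested", cq_mock_base + dcq)):
                for _tech in range(n_tech):
                    rows.append(
                        {
                            "site": t["site"],
                            "distance_bp": t.get("distance_bp", np.nan),
                            "timepoint_h": t["timepoint_h"],
                            "condition": cond,
                            "replicate": bio,
                            "cq": base + rng.normal(0.0, noise_sd) if noise_sd else base,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class LfqTruth:
    shifted: pd.Series  # bool per protein


def simulate_lfq(
    n_proteins: int,
    n_shifted: int,
    log2_effect: float,
    n_per_group: int = 5,
    missing_mechanism: str | None = None,
    seed: int = 0,
    base_mean: float = 7.0,
    between_sd: float = 0.6,
    within_sd: float = 0.10,
):
    """Two-group LFQ intensity matrix with truth labels.

    Log10 protein means are Normal(``base_mean``, ``between_sd``);
    replicate noise is Normal(0, ``within_sd``) on the log10 scale — a
    ~25% intensity CV, typical of LFQ replicates, at which a log2
    fold change of 1.5 over five replicates per group is comfortably
    detectable (the reference design this generator emulates); the
    first ``n_shifted`` proteins gain ``log2_effect`` (in log2 units) in
    the second group.  ``missing_mechanism="MNAR"`` applies intensity-
    dependent dropout (lower intensity, higher dropout probability).
    Returns ``(matrix_df, groups, LfqTruth)`` with linear-scale
    intensities and NaN for missing values.
    """
    if n_shifted > n_proteins:
        raise ValueError("n_shifted must be <= n_proteins")
    rng = np.random.default_rng(seed)
    proteins = ["P%05d" % i for i in range(n_proteins)]
    samples = ["ctrl_%d" % i for i in range(1, n_per_group + 1)] + [
        "edit_%d" % i for i in range(1, n_per_group + 1)
    ]
    groups = {s: ("ctrl" if s.startswith("ctrl") else "edit") for s in samples}
    mu = rng.normal(base_mean, between_sd, size=n_proteins)
    log10 = rng.normal(0.0, within_sd, size=(n_proteins, 2 * n_per_group)) + mu[:, None]
    shift10 = log2_effect * np.log10(2.0)
    log10[:n_shifted, n_per_group:] += shift10
    if missing_mechanism == "MNAR":
        tau = base_mean - 1.2 * between_sd
        p_miss = 1.0 / (1.0 + np.exp((log10 - tau) / 0.25))
        log10 = np.where(rng.random(log10.shape) < p_miss, np.nan, log10)
    elif missing_mechanism is not None:
        raise ValueError("missing_mechanism must be None or 'MNAR'")
    mat = pd.DataFrame(10.0 ** log10, index=proteins, columns=samples)
    shifted = pd.Series(
        [i < n_shifted for i in range(n_proteins)], index=proteins, name="shifted"
    )
    return mat, groups, LfqTruth(shifted=shifted)


def simulate_ce_peaks(
    fractions: dict[float, float],
    total_area: float = 100000.0,
    max_height: float = 10000.0,
    jitter: float = 0.0,
    seed: int = 0,
    n_noise_peaks: int = 0,
) -> pd.DataFrame:
    """Capillary-electrophoresis peak table for given product-size
    fractions; peak areas are proportional to fractions, heights scaled so
    the largest fraction has ``max_height``.  Optional sub-threshold noise
    peaks (height < 5% of the maximum) can be added."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    fmax = max(fractions.values())
    rows = []
    for size, f in sorted(fractions.items()):
        rows.append(
            {
                "size_bp": size + (rng.normal(0, jitter) if jitter else 0.0),
                "height": max_height * f / fmax,
                "area_bp": total_area * f,
            }
        )
    for _ in range(n_noise_peaks):
        rows.append(
            {
                "size_bp": float(rng.uniform(60, 400)),
                "height": float(rng.uniform(0.001, 0.049)) * max_height,
                "area_bp": float(rng.uniform(0.0001, 0.001)) * total_area,
            }
        )
    return pd.DataFrame(rows)
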