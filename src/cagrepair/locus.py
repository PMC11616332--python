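"""Amplicon / repeat-tract / guide geometry.

Everything downstream (simulation, classification, signature detection)
derives its coordinates from the two types defined here.  Conventions:

* all coordinates are 0-based, half-open intervals on the amplicon's
  forward (plus) strand;
* cut sites are *between-base* indices: ``blunt_cut = i`` means the DNA is
  cut between bases ``i - 1`` and ``i``;
* the SpCas9 blunt cut falls 3 nt 5' of the PAM on the protospacer-bearing
  strand.  The RuvC domain sometimes cuts the non-target strand one base
  further from the PAM (after the 4th nucleotide upstream of the PAM),
  leaving a 1-nt 5' overhang; fill-in of that overhang duplicates the base
  we call the *staggered donor*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "RepeatLocus",
    "Guide",
    "LocusError",
    "locate_guide",
    "default_locus",
    "default_guides",
    "load_locus",
    "revcomp",
]

_RC = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes used for PAM patterns.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_RC)[::-1]


def _matches_pattern(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(seq, pattern)
    )


class LocusError(ValueError):
    """Invalid locus annotation or guide placement."""


@dataclass(frozen=True)
class RepeatLocus:
    """An amplicon reference with a coordinate-annotated tandem-repeat tract.

    ``amplicon[repeat_start:repeat_end]`` must be exactly
    ``motif * expected_units``; the flanks are everything outside that
    interval.
    """

    name: str
    amplicon: str
    repeat_start: int
    repeat_end: int
    motif: str = "CAG"

    def __post_init__(self) -> None:
        amp = self.amplicon.upper()
        object.__setattr__(self, "amplicon", amp)
        if not amp or set(amp) - set("ACGT"):
            raise LocusError("invalid locus: amplicon must be non-empty A/C/G/T")
        if not (0 <= self.repeat_start < self.repeat_end <= len(amp)):
            raise LocusError("invalid locus: repeat interval outside amplicon")
        tract = amp[self.repeat_start : self.repeat_end]
        if len(tract) % len(self.motif):
            raise LocusError("invalid locus: tract length not a multiple of motif")
        if tract != self.motif * (len(tract) // len(self.motif)):
            raise LocusError("invalid locus: repeat interval is not motif-pure")

    @property
    def expected_units(self) -> int:
        return (self.repeat_end - self.repeat_start) // len(self.motif)

    @property
    def repeat_interval(self) -> tuple[int, int]:
        return (self.repeat_start, self.repeat_end)

    def __len__(self) -> int:
        return len(self.amplicon)


@dataclass(frozen=True)
class Guide:
    """A protospacer placement on the amplicon with derived cut geometry.

    ``blunt_cut`` is the between-base index of the RuvC/HNH blunt cut
    (3 nt 5' of the PAM on the protospacer strand).  ``staggered_donor`` is
    the amplicon index of the base duplicated when the RuvC domain cuts the
    non-target strand one nucleotide further from the PAM (the "-4 rule"
    single-base insertion).
    """

    name: str
    protospacer: str
    pam: str
    strand: str  # '+' or '-'
    start: int  # 0-based start of the protospacer match on the plus strand
    blunt_cut: int
    staggered_donor: int
    n_placements: int = 1

    @property
    def donor_base(self) -> str:  # resolved lazily by callers holding the locus
        raise AttributeError("use locus.amplicon[guide.staggered_donor]")


def _placements(amplicon: str, protospacer: str, pam_pattern: str):
    """All (strand, plus-strand start) placements of protospacer+PAM."""
    n, L = len(amplicon), len(protospacer)
    plus_target = protospacer
    minus_target = revcomp(protospacer)
    out = []
    for i in range(n - L + 1):
        if (
            amplicon[i : i + L] == plus_target
            and i + L + 3 <= n
            and _matches_pattern(amplicon[i + L : i + L + 3], pam_pattern)
        ):
            out.append(("+", i))
        if (
            amplicon[i : i + L] == minus_target
            and i - 3 >= 0
            and _matches_pattern(revcomp(amplicon[i - 3 : i]), pam_pattern)
        ):
            out.append(("-", i))
    out.sort(key=lambda p: p[1])
    return out


def locate_guide(
    locus: RepeatLocus,
    protospacer: str,
    pam_pattern: str = "NGG",
    name: str = "guide",
) -> Guide:
    """Place a 20-nt protospacer (+PAM) on either strand of the amplicon.

    Multiple placements are tolerated when the extra copies lie fully
    inside the repeat tract (a repeat-targeting guide genuinely cleaves at
    several registers); the leftmost placement is returned as canonical and
    ``Guide.n_placements`` reports the multiplicity.  More than one
    placement *outside* the tract is ambiguous and raises.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20:
        raise LocusError("protospacer must be 20 nt")
    if pam_pattern not in ("NGG", "NAG"):
        raise LocusError("pam_pattern must be NGG or NAG")
    found = _placements(locus.amplicon, protospacer, pam_pattern)
    if not found:
        raise LocusError("guide not found")
    s, e = locus.repeat_interval
    outside = [p for p in found if not (s <= p[1] and p[1] + 20 <= e)]
    if len(outside) > 1:
        raise LocusError("ambiguous guide: %d placements outside the repeat tract" % len(outside))
    strand, start = found[0]
    if strand == "+":
        blunt_cut = start + 17
        donor = start + 16
        pam = locus.amplicon[start + 20 : start + 23]
    else:
        blunt_cut = start + 3
        donor = start + 3
        pam = revcomp(locus.amplicon[start - 3 : start])
    return Guide(
        name=name,
        protospacer=protospacer,
        pam=pam,
        strand=strand,
        start=start,
        blunt_cut=blunt_cut,
        staggered_donor=donor,
        n_placements=len(found),
    )


# ---------------------------------------------------------------------------
# Bundled synthetic locus
# ---------------------------------------------------------------------------

#: Synthetic 242-bp amplicon: 40-nt flank + (CAG)41 + 79-nt flank.  The
#: flanks are CAG-free and carry three planted guide sites: a minus-strand
#: guide cutting at the tract's 5' boundary (between-base 38, staggered
#: donor base 'A'), a plus-strand in-tract guide with a noncanonical NAG
#: PAM (34 registers), and a plus-strand guide cutting 58 nt downstream of
#: the tract.  Several >=2-nt microhomology pairs (CC, CA, TGG, CCTT)
#: bracket the tract within 10 nt of its ends.
DEFAULT_AMPLICON = (
    "GCTCTTGAGGGACTCGTGGTTCTGGAAGCTGGCCTTCCAT"
    + "CAG" * 41
    + "TACACCTTGGTGTGGTTCTTCCTGGTCTTGTGCTGTTGGTTGTCTTGGAAGTCTGTGTTCGTGGTTGGCTCCTGCTTGT"
)

#: (name, protospacer, pam_pattern) of the three bundled guides.
DEFAULT_GUIDE_SPECS = (
    ("g_upstream", revcomp(DEFAULT_AMPLICON[35:55]), "NGG"),
    ("g_tract", "AGCAGCAGCAGCAGCAGCAG", "NAG"),
    ("g_downstream", DEFAULT_AMPLICON[204:224], "NGG"),
)


def default_locus() -> RepeatLocus:
    """The bundled synthetic (CAG)41 amplicon, total length 242 bp."""
    return RepeatLocus(
        name="synthetic_CAG41",
        amplicon=DEFAULT_AMPLICON,
        repeat_start=40,
        repeat_end=163,
    )


def default_guides(locus: RepeatLocus | None = None) -> dict[str, Guide]:
    """The three bundled guides, located on ``locus`` (default bundled)."""
    locus = locus or default_locus()
    return {
        name: locate_guide(locus, proto, pam, name=name)
        for name, proto, pam in DEFAULT_GUIDE_SPECS
    }


def load_locus(fasta_path: str | Path, config_path: str | Path):
    """Load a locus from FASTA plus a JSON sidecar.

    The sidecar schema is ``{"motif": ..., "repeat_start": ..,
    "repeat_end": .., "guides": [{"name", "protospacer", "pam"}, ...]}``.
    Returns ``(RepeatLocus, {name: Guide})``.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise LocusError("invalid locus: FASTA must contain exactly one record")
    cfg = json.loads(Path(config_path).read_text())
    locus = RepeatLocus(
        name=records[0].id,
        amplicon=str(records[0].seq).upper(),
        repeat_start=int(cfg["repeat_start"]),
        repeat_end=int(cfg["repeat_end"]),
        motif=cfg.get("motif", "CAG"),
    )
    guides = {
        g["name"]: locate_guide(locus, g["protospacer"], g.get("pam", "NGG"), name=g["name"])
        for g in cfg.get("guides", [])
    }
    return locus, guides
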