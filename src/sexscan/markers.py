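"""Stage 4: X/Y haplotype comparison and presence/absence PCR markers.

A global affine-gap alignment of the X and Y copies of a candidate gene
exposes the sex-specific insertions (long gap runs on one haplotype)
that make presence/absence PCR possible: a primer pair sitting entirely
inside a Y-only insertion amplifies male DNA and nothing in females,
and a pair spanning the insertion boundary reports presence as a
product-size shift.  ``insilico_pcr`` predicts amplicons from primer
matches on a template (both orientations; the 3'-terminal base of each
primer must match exactly, mimicking extension chemistry).

Scoring convention: a gap of length L costs ``gap_open + L *
gap_extend`` (the first gapped column pays both the opening and an
extension), with defaults +1/-1/-4/-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedVariant:
    """One difference between the aligned haplotypes.

    ``kind`` is ``snp``, ``insertion_on_Y`` (gap on X) or
    ``insertion_on_X`` (gap on Y); coordinates are half-open on each
    input sequence (zero-length on the gapped side).
    """

    kind: str
    x_start: int
    x_end: int
    y_start: int
    y_end: int

    @property
    def length(self) -> int:
        return max(self.x_end - self.x_start, self.y_end - self.y_start)


@dataclass
class HaplotypeAlignment:
    x_aligned: str
    y_aligned: str
    score: float
    identity: float
    catalogue: list[AlignedVariant] = field(default_factory=list)

    @property
    def x(self) -> str:
        return self.x_aligned.replace("-", "")

    @property
    def y(self) -> str:
        return self.y_aligned.replace("-", "")


def global_align(
    seq_x: str,
    seq_y: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
    max_len: int = 50_000,
) -> HaplotypeAlignment:
    """Optimal global affine-gap alignment of two haplotype sequences.

    Identity = matching columns / aligned columns (dual-gap columns
    cannot occur in a pairwise global alignment).  The variant catalogue
    lists SNP columns and maximal gap runs.
    """
    from Bio import Align

    seq_x, seq_y = seq_x.upper(), seq_y.upper()
    if not seq_x or not seq_y:
        raise ValueError("cannot align empty sequences")
    for name, s in (("x", seq_x), ("y", seq_y)):
        if set(s) - VALID:
            raise ValueError(f"sequence {name} has non-ACGTN characters")
        if len(s) > max_len:
            raise ValueError(f"sequence {name} exceeds length cap {max_len}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # our convention: gap of length L costs open + L*extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_x, seq_y)[0]

    x_aln, y_aln = _gapped_strings(aln, seq_x, seq_y)
    matches = sum(a == b and a != "-" for a, b in zip(x_aln, y_aln))
    identity = matches / len(x_aln)
    catalogue = _variant_catalogue(x_aln, y_aln)
    return HaplotypeAlignment(
        x_aligned=x_aln,
        y_aligned=y_aln,
        score=float(aln.score),
        identity=identity,
        catalogue=catalogue,
    )


def _gapped_strings(aln, seq_x: str, seq_y: str) -> tuple[str, str]:
    """Reconstruct gapped strings from a Bio.Align.Alignment's coordinates."""
    coords = aln.coordinates
    x_parts: list[str] = []
    y_parts: list[str] = []
    for k in range(coords.shape[1] - 1):
        x0, x1 = int(coords[0, k]), int(coords[0, k + 1])
        y0, y1 = int(coords[1, k]), int(coords[1, k + 1])
        if x1 > x0 and y1 > y0:
            x_parts.append(seq_x[x0:x1])
            y_parts.append(seq_y[y0:y1])
        elif x1 > x0:
            x_parts.append(seq_x[x0:x1])
            y_parts.append("-" * (x1 - x0))
        else:
            x_parts.append("-" * (y1 - y0))
            y_parts.append(seq_y[y0:y1])
    return "".join(x_parts), "".join(y_parts)


def _variant_catalogue(x_aln: str, y_aln: str) -> list[AlignedVariant]:
    out: list[AlignedVariant] = []
    xi = yi = 0
    col = 0
    n = len(x_aln)
    while col < n:
        a, b = x_aln[col], y_aln[col]
        if a == "-" or b == "-":
            gap_on_x = a == "-"
            x0, y0 = xi, yi
            while col < n and (
                (x_aln[col] == "-") if gap_on_x else (y_aln[col] == "-")
            ):
                if x_aln[col] != "-":
                    xi += 1
                if y_aln[col] != "-":
                    yi += 1
                col += 1
            out.append(
                AlignedVariant(
                    "insertion_on_Y" if gap_on_x else "insertion_on_X",
                    x0, xi, y0, yi,
                )
            )
            continue
        if a != b:
            out.append(AlignedVariant("snp", xi, xi + 1, yi, yi + 1))
        xi += 1
        yi += 1
        col += 1
    return out


def find_sex_specific_segments(
    alignment: HaplotypeAlignment, min_len: int = 100
) -> list[AlignedVariant]:
    """Maximal gap runs >= min_len: candidate sex-specific insertions."""
    return [
        v
        for v in alignment.catalogue
        if v.kind in ("insertion_on_Y", "insertion_on_X") and v.length >= min_len
    ]


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    """A PCR primer pair; the reverse primer is 5'->3' on the opposite strand."""

    name: str
    forward: str
    reverse: str
    max_product_bp: int = 5000
    allowed_mismatches: int = 0

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for primer in (self.forward, self.reverse):
            if not primer or set(primer) - set("ACGT"):
                raise ValueError(f"{self.name}: primers must be nonempty ACGT")
        if self.max_product_bp < len(self.forward) + len(self.reverse):
            raise ValueError(f"{self.name}: max product below primer footprints")


@dataclass
class Amplicon:
    """Predicted product on a template, half-open [start, end)."""

    start: int
    end: int
    mismatches_forward: int
    mismatches_reverse: int

    @property
    def size(self) -> int:
        return self.end - self.start


def _primer_sites(
    template: np.ndarray, primer: str, allowed: int, three_prime_end: str
) -> list[tuple[int, int]]:
    """(start, mismatches) of primer matches on the template plus strand.

    ``three_prime_end`` is "right" when the primer's 3' base is the last
    base of the site, "left" when it is the first (a reverse primer's
    binding site read on the plus strand).  The 3' base must match
    exactly; N on the template never matches.
    """
    m = len(primer)
    n = len(template)
    if n < m:
        return []
    p = np.frombuffer(primer.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(template, m)
    neq = (windows != p) | (windows == b"N")
    mism = neq.sum(axis=1)
    anchor = neq[:, -1] if three_prime_end == "right" else neq[:, 0]
    hits = np.flatnonzero((mism <= allowed) & ~anchor)
    return [(int(h), int(mism[h])) for h in hits]


def insilico_pcr(template: str, pair: PrimerPair) -> list[Amplicon]:
    """Predict amplicons of a primer pair on a template.

    Both orientations of the pair are searched, so amplifying the
    reverse complement of the template yields the same products with
    mirrored coordinates.  Product size spans both primer footprints
    (half-open end of the reverse site minus start of the forward site).
    """
    template = template.upper()
    if set(template) - VALID:
        raise ValueError("template has non-ACGTN characters")
    arr = np.frombuffer(template.encode(), dtype="S1")
    out: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    for fwd, rev, swap in (
        (pair.forward, pair.reverse, False),
        (pair.reverse, pair.forward, True),
    ):
        f_hits = _primer_sites(arr, fwd, pair.allowed_mismatches, "right")
        r_hits = _primer_sites(arr, revcomp(rev), pair.allowed_mismatches, "left")
        for f_start, f_mm in f_hits:
            for r_start, r_mm in r_hits:
                end = r_start + len(rev)
                if r_start < f_start + len(fwd):
                    continue
                size = end - f_start
                if size > pair.max_product_bp:
                    continue
                key = (f_start, end)
                if key in seen:
                    continue
                seen.add(key)
                mm_f, mm_r = (r_mm, f_mm) if swap else (f_mm, r_mm)
                out.append(Amplicon(f_start, end, mm_f, mm_r))
    return sorted(out, key=lambda a: (a.start, a.end))


# ---------------------------------------------------------------------------
# marker design
# ---------------------------------------------------------------------------

@dataclass
class MarkerCandidate:
    pair: PrimerPair
    #: "within_segment" (class i) or "segment_anchored" (class ii)
    design_class: str
    products_carrier: list[Amplicon]
    products_other: list[Amplicon]


def design_presence_markers(
    alignment: HaplotypeAlignment,
    segments: Sequence[AlignedVariant],
    primer_len: tuple[int, int] = (20, 26),
    product_range: tuple[int, int] = (100, 1000),
) -> list[MarkerCandidate]:
    """Design presence/absence primer pairs over sex-specific insertions.

    For each insertion segment two design classes are attempted: (i)
    both primers inside the segment, amplifying only the carrying
    haplotype; (ii) forward primer inside the segment, reverse in the
    shared flank downstream, giving a carrier-only product anchored to
    one segment primer.  Every candidate is verified by
    :func:`insilico_pcr` on both haplotypes; any candidate producing a
    product on the non-carrying haplotype is discarded.
    """
    import warnings

    lo, hi = primer_len
    plen = min(hi, max(lo, 24))
    out: list[MarkerCandidate] = []
    for k, seg in enumerate(segments):
        if seg.kind == "insertion_on_Y":
            carrier, other = alignment.y, alignment.x
            s_start, s_end = seg.y_start, seg.y_end
        elif seg.kind == "insertion_on_X":
            carrier, other = alignment.x, alignment.y
            s_start, s_end = seg.x_start, seg.x_end
        else:
            continue
        seg_len = s_end - s_start
        if seg_len < plen:
            warnings.warn(
                f"segment {k} shorter than minimum primer length; "
                "no within-segment designs",
                stacklevel=2,
            )
            continue
        fwd = carrier[s_start : s_start + plen]

        # class (i): both primers inside the segment
        if seg_len >= 2 * plen and seg_len >= product_range[0]:
            prod = min(seg_len, product_range[1])
            rev_site = carrier[s_start + prod - plen : s_start + prod]
            out.extend(
                _verified(
                    PrimerPair(
                        f"seg{k}_within", fwd, revcomp(rev_site),
                        max_product_bp=product_range[1],
                    ),
                    "within_segment",
                    carrier,
                    other,
                )
            )

        # class (ii): forward inside the segment, reverse in the shared flank
        fwd2_start = max(s_start, s_end - plen)
        fwd2 = carrier[fwd2_start : fwd2_start + plen]
        for offset in range(50, product_range[1] - plen, 50):
            r_start = s_end + offset
            if r_start + plen > len(carrier):
                break
            size = r_start + plen - fwd2_start
            if size < product_range[0]:
                continue
            if size > product_range[1]:
                break
            rev_site = carrier[r_start : r_start + plen]
            verified = _verified(
                PrimerPair(
                    f"seg{k}_anchored", fwd2, revcomp(rev_site),
                    max_product_bp=product_range[1],
                ),
                "segment_anchored",
                carrier,
                other,
            )
            if verified:
                out.extend(verified)
                break  # one verified anchored design per segment suffices
    return out


def _verified(
    pair: PrimerPair, design_class: str, carrier: str, other: str
) -> list[MarkerCandidate]:
    on_carrier = insilico_pcr(carrier, pair)
    on_other = insilico_pcr(other, pair)
    if not on_carrier or on_other:
        return []
    return [MarkerCandidate(pair, design_class, on_carrier, on_other)]


# ---------------------------------------------------------------------------
# packaged fixtures: the published cephx1 primer pairs and synthetic
# templates mirroring the insertion geometry they target
# ---------------------------------------------------------------------------

#: published primer pairs targeting the Y-specific insertion in the
#: sixth intron of cephx1y (pair 1 sits entirely inside the insertion;
#: pair 2 anchors its forward primer in the insertion with the reverse
#: in shared sequence)
CEPHX1_PRIMERS = {
    "cephx1_1": PrimerPair(
        "cephx1_1",
        forward="ATCCAACATTTCAAGATCAACAGGTT",
        reverse="GGGGACATCCTGATATCTAACCAATA",
    ),
    "cephx1_2": PrimerPair(
        "cephx1_2",
        forward="GCTAGTTTAGAAAATGACAGCTCACA",
        reverse="GTAAAATTCCAAGATGTGAACAAGCC",
    ),
}

#: geometry of the synthetic templates (offsets within the insertion)
_INS_LEN = 540
_FLANK = 1000
_F1_OFF = 50     # pair-1 product: 404 bp, fully inside the insertion
_P1_SIZE = 404
_F2_OFF = 340    # pair-2 product: 359 bp, spanning into the right flank
_P2_SIZE = 359
_DEL_OFF = 400   # 179-bp deletion removing pair-1's reverse site
_DEL_LEN = 179


def build_cephx1_templates(seed: int = 20240712) -> dict[str, str]:
    """Synthetic X/Y gene templates mirroring the published geometry.

    The true genomic sequences are not published; these templates are
    synthetic stand-ins that reproduce the printed amplicon logic: a
    540-bp Y-only insertion carrying the published primer sites so that
    pair cephx1_1 yields a 404-bp product and pair cephx1_2 a 359-bp
    product on the Y haplotype and nothing on X, plus a second Y variant
    ("y_short") with a 179-bp deletion that removes the cephx1_1 reverse
    site and shortens the cephx1_2 product to 180 bp.

    Returns records ``x``, ``y`` and ``y_short``.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    p1, p2 = CEPHX1_PRIMERS["cephx1_1"], CEPHX1_PRIMERS["cephx1_2"]
    ins = list(rand_seq(_INS_LEN))
    flank_l, flank_r = rand_seq(_FLANK), list(rand_seq(_FLANK))

    def plant(buf: list[str], offset: int, site: str) -> None:
        buf[offset : offset + len(site)] = list(site)

    plant(ins, _F1_OFF, p1.forward)
    plant(ins, _F1_OFF + _P1_SIZE - len(p1.reverse), revcomp(p1.reverse))
    plant(ins, _F2_OFF, p2.forward)
    # pair-2 reverse site lands in the shared right flank
    rev2_end = _F2_OFF + _P2_SIZE - _INS_LEN
    plant(flank_r, rev2_end - len(p2.reverse), revcomp(p2.reverse))

    flank_r = "".join(flank_r)
    ins_seq = "".join(ins)
    y = flank_l + ins_seq + flank_r
    x = flank_l + flank_r
    # deletion spans the insertion end into the flank, keeping both
    # pair-2 primer sites but removing pair-1's reverse site
    del_start = _FLANK + _DEL_OFF
    y_short = y[:del_start] + y[del_start + _DEL_LEN :]
    return {"x": x, "y": y, "y_short": y_short}
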