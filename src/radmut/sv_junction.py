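"""Structural-variant junction reconstruction and repair-mechanism inference.

Given a reference segment and the rearranged product sequence (the analog of
a Sanger-sequenced junction amplicon), the analyzer reconstructs the anatomy
of each rearrangement junction:

* **microhomology** — a short identical sequence shared by the two joined
  ends, which makes the exact junction placement ambiguous (reported when
  >= 2 bp; a single shared base is uninformative);
* **deletions**, split into bases lost *on* the microhomologous tract versus
  on the *adjacent* regions outside it;
* **insertions** — product bases attributable to neither side.

The junction is located by maximal exact extension from repeat-free anchor
flanks (>= 20 bp) on both sides; deviations from the two nominal breakpoints
are then attributed to the tract or the adjacent regions. Inversions are
assigned one of four junction classes:

    A  no microhomology, no deletion (blunt end joining)
    B  microhomology, no deletion
    C  microhomology with small deletions (every deletion <= 10 bp)
    D  microhomology with adjacent deletions > 10 bp

and a repair-mechanism call follows: classical non-homologous end joining
(cNHEJ), cNHEJ guided by microhomology (cNHEJ-MH; no adjacent deletion), or
microhomology-mediated end joining candidate (MMEJ; resection beyond 10 bp
next to the tract).

`build_inversion_product` is the forward model: it assembles the product an
inversion would leave given planted microhomology use, end resection and
insertion, and is the ground-truth generator for round-trip validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from ._util import round_half_up

__all__ = [
    "JunctionCase",
    "JunctionSideReport",
    "JunctionReport",
    "build_inversion_product",
    "analyze_junction",
    "classify_fig7",
    "infer_mechanism",
    "tabulate_junctions",
    "junction_microhomology",
]

MIN_MICROHOMOLOGY = 2  # 1-bp overlaps are uninformative
MIN_ANCHOR = 20
DEFAULT_WINDOW = 100
CNHEJ_MAX_DELETION = 10  # bp; larger adjacent deletions point to MMEJ


class InconsistentProductError(ValueError):
    """Product sequence cannot be derived from the hypothesized rearrangement."""


class AmbiguousJunctionError(ValueError):
    """Anchors align at multiple places; junction placement is not unique."""

    def __init__(self, message: str, candidates: list[int] | None = None):
        super().__init__(message)
        self.candidates = candidates or []


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def junction_microhomology(left: str, right: str, limit: int = DEFAULT_WINDOW) -> int:
    """Longest L such that the last L bases of ``left`` equal the first L of
    ``right`` — the shared sequence a junction between them could anneal on."""
    top = min(limit, len(left), len(right))
    for L in range(top, 0, -1):
        if left[-L:] == right[:L]:
            return L
    return 0


@dataclass(frozen=True)
class JunctionCase:
    """One junction-reconstruction problem.

    ``reference`` carries a declared genomic ``offset`` (1-based position of
    its first base); breakpoints are genomic positions inside the segment.
    ``product`` is the rearranged sequence over the same segment.
    """

    case_id: str
    reference: str
    product: str
    breakpoint1: int
    breakpoint2: int
    svtype: str  # inversion | deletion | duplication | translocation
    offset: int = 1
    group: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in ("inversion", "deletion", "duplication", "translocation"):
            raise ValueError(f"unknown rearrangement type {self.svtype!r}")
        b1, b2 = self.local_breakpoints
        if not b1 < b2:
            raise ValueError("breakpoints must be ordered bp1 < bp2")
        if b1 < 30 or len(self.reference) - b2 < 30:
            raise ValueError("breakpoints must lie >= 30 bp from the segment ends")

    @property
    def local_breakpoints(self) -> tuple[int, int]:
        """Breakpoints as 0-based offsets into the reference segment string."""
        return self.breakpoint1 - self.offset + 1, self.breakpoint2 - self.offset + 1


@dataclass(frozen=True)
class JunctionSideReport:
    """Anatomy of a single junction (one joined pair of ends)."""

    microhomology_len: int
    microhomology_seq: str
    deletion_on_overlap: int
    deletion_adjacent_left: int
    deletion_adjacent_right: int
    insertion_len: int
    insertion_seq: str

    @property
    def deletion_adjacent(self) -> int:
        return self.deletion_adjacent_left + self.deletion_adjacent_right


@dataclass(frozen=True)
class JunctionReport:
    """Aggregate junction anatomy for one rearrangement event."""

    case_id: str
    svtype: str
    junctions: tuple[JunctionSideReport, ...]
    group: str = ""

    @property
    def microhomology_len(self) -> int:
        return max(j.microhomology_len for j in self.junctions)

    @property
    def microhomology_seq(self) -> str:
        best = max(self.junctions, key=lambda j: j.microhomology_len)
        return best.microhomology_seq

    @property
    def deletion_on_overlap(self) -> int:
        return sum(j.deletion_on_overlap for j in self.junctions)

    @property
    def deletion_adjacent_left(self) -> int:
        """Total adjacent deletion at the first (left) junction."""
        return self.junctions[0].deletion_adjacent

    @property
    def deletion_adjacent_right(self) -> int:
        """Total adjacent deletion at the second junction (or the right side
        of a single-junction event)."""
        if len(self.junctions) > 1:
            return self.junctions[1].deletion_adjacent
        return self.junctions[0].deletion_adjacent_right

    @property
    def max_adjacent_deletion(self) -> int:
        return max(j.deletion_adjacent for j in self.junctions)

    @property
    def total_deletion(self) -> int:
        return self.deletion_on_overlap + sum(j.deletion_adjacent for j in self.junctions)

    @property
    def insertion_len(self) -> int:
        return sum(j.insertion_len for j in self.junctions)

    @property
    def has_microhomology(self) -> bool:
        return self.microhomology_len >= MIN_MICROHOMOLOGY

    @property
    def fig_class(self) -> str:
        return classify_fig7(self)

    @property
    def mechanism(self) -> str:
        return infer_mechanism(self)


def build_inversion_product(
    reference: str,
    bp1: int,
    bp2: int,
    use_microhomology: bool = False,
    resection: tuple[int, int, int, int] = (0, 0, 0, 0),
    insertion: str = "",
) -> str:
    """Forward model: assemble the product of an inversion of reference
    [bp1+1..bp2] (0-based cut positions bp1 < bp2).

    ``resection`` is (on-overlap, adjacent) for the left junction followed by
    the same pair for the right junction. On-overlap resection trims the
    single retained copy of the microhomologous tract (requires
    ``use_microhomology`` and a planted tract at least as long); adjacent resection
    removes bases outside the tract on the outer side (prefix end at the
    left junction, suffix start at the right one). ``insertion`` is placed at
    the left junction. Deterministic.
    """
    if not 0 < bp1 < bp2 < len(reference):
        raise ValueError("require 0 < bp1 < bp2 < len(reference)")
    prefix, mid, suffix = reference[:bp1], reference[bp1:bp2], reference[bp2:]
    inv = _revcomp(mid)
    t1, a1, t2, a2 = resection
    if min(resection) < 0:
        raise ValueError("resections must be non-negative")
    l1 = junction_microhomology(prefix, inv) if use_microhomology else 0
    l2 = junction_microhomology(inv, suffix) if use_microhomology else 0
    if t1 > l1 or t2 > l2:
        raise ValueError("on-overlap resection exceeds the microhomologous tract")
    if a1 + l1 >= bp1 or a2 + l2 >= len(suffix):
        raise ValueError("resection exceeds available sequence")
    if l1 + l2 + t1 + t2 >= len(inv):
        raise ValueError("resection exceeds available sequence")

    tract1 = prefix[bp1 - l1 :] if l1 else ""
    tract2 = inv[len(inv) - l2 :] if l2 else ""
    core = inv[l1 : len(inv) - l2] if l2 else inv[l1:]

    if a1 == 0:
        left = prefix[: bp1 - l1] + tract1[: l1 - t1]
    else:
        # adjacent loss on the prefix side; tract survives via the inverted copy
        left = prefix[: bp1 - l1 - a1] + tract1[t1:]
    if a2 == 0:
        right = (tract2[: l2 - t2] if l2 else "") + suffix[l2:]
    else:
        right = tract2[t2:] + suffix[l2 + a2 :]
    return left + insertion + core + right


def _check_anchor_unique(hay: str, anchor: str, what: str) -> int:
    first = hay.find(anchor)
    if first < 0:
        raise InconsistentProductError(f"{what} anchor not found in product")
    second = hay.find(anchor, first + 1)
    if second >= 0:
        raise AmbiguousJunctionError(
            f"{what} anchor aligns at multiple positions", candidates=[first, second]
        )
    return first


def _analyze_pair(
    left_src: str,
    right_src: str,
    segment: str,
    window: int,
    min_anchor: int = MIN_ANCHOR,
) -> JunctionSideReport:
    """Reconstruct one junction joining the end of ``left_src`` to the start
    of ``right_src``, observed in product ``segment``.

    Maximal exact extension from both anchors delimits the junction; the
    reference-level microhomology between the joined ends then lets missing
    bases be attributed to the tract ('on overlap') or the flanks
    ('adjacent').
    """
    qa = _lcp(left_src, segment)
    s = _lcs(right_src, segment)
    if qa < min_anchor:
        raise InconsistentProductError(
            f"left anchor match only {qa} bp (< {min_anchor}): "
            "product inconsistent with hypothesis"
        )
    if s < min_anchor:
        raise InconsistentProductError(
            f"right anchor match only {s} bp (< {min_anchor}): "
            "product inconsistent with hypothesis"
        )
    l_ref = junction_microhomology(left_src, right_src, limit=window)
    if l_ref < MIN_MICROHOMOLOGY:
        l_ref = 0
    miss_left = len(left_src) - qa
    miss_right = len(right_src) - s
    b_start = len(segment) - s
    ins_seq = segment[qa:b_start] if b_start > qa else ""
    tract = right_src[:l_ref]

    if (
        ins_seq
        and l_ref
        and miss_left >= l_ref
        and miss_right >= l_ref
        and ins_seq in tract
    ):
        # junction island equals part of the tract: retained microhomology cut
        # off from both direct extensions by flanking deletions
        mh_len = len(ins_seq)
        return JunctionSideReport(
            microhomology_len=mh_len if mh_len >= MIN_MICROHOMOLOGY else 0,
            microhomology_seq=ins_seq if mh_len >= MIN_MICROHOMOLOGY else "",
            deletion_on_overlap=l_ref - mh_len,
            deletion_adjacent_left=miss_left - l_ref,
            deletion_adjacent_right=miss_right - l_ref,
            insertion_len=0,
            insertion_seq="",
        )

    on_overlap = min(miss_left, miss_right, l_ref)
    mh_len = l_ref - on_overlap
    if miss_left <= miss_right:
        mh_seq = tract[:mh_len]
    else:
        mh_seq = tract[l_ref - mh_len :] if mh_len else ""
    if mh_len < MIN_MICROHOMOLOGY:
        mh_len, mh_seq = 0, ""
    return JunctionSideReport(
        microhomology_len=mh_len,
        microhomology_seq=mh_seq,
        deletion_on_overlap=on_overlap,
        deletion_adjacent_left=max(0, miss_left - l_ref),
        deletion_adjacent_right=max(0, miss_right - l_ref),
        insertion_len=len(ins_seq),
        insertion_seq=ins_seq,
    )


def analyze_junction(case: JunctionCase, window: int = DEFAULT_WINDOW) -> JunctionReport:
    """Reconstruct all junctions of a rearrangement case.

    Inversions contribute two junctions (prefix|inverted-segment and
    inverted-segment|suffix); deletions, tandem duplications and
    translocation-style joins contribute one. Raises
    `InconsistentProductError` when the product does not carry >= 20 bp
    exact anchor flanks of the hypothesized sources, and
    `AmbiguousJunctionError` when an anchor aligns at several places.
    """
    bp1, bp2 = case.local_breakpoints
    ref, product = case.reference, case.product

    if case.svtype == "inversion":
        inv = _revcomp(ref[bp1:bp2])
        c = max(MIN_ANCHOR, len(inv) // 2 - MIN_ANCHOR // 2)
        anchor = inv[c : c + MIN_ANCHOR]
        idx = _check_anchor_unique(product, anchor, "inverted-segment")
        j1 = _analyze_pair(
            ref[:bp1], inv[: c + MIN_ANCHOR], product[: idx + MIN_ANCHOR], window
        )
        j2 = _analyze_pair(inv[c:], ref[bp2:], product[idx:], window)
        junctions = (j1, j2)
    elif case.svtype in ("deletion", "translocation"):
        junctions = (_analyze_pair(ref[:bp1], ref[bp2:], product, window),)
    elif case.svtype == "duplication":
        # tandem duplication of [bp1..bp2]: junction joins copy end to copy start
        junctions = (_analyze_pair(ref[:bp2], ref[bp1:], product, window),)
    else:  # pragma: no cover - guarded in JunctionCase
        raise ValueError(case.svtype)
    return JunctionReport(
        case_id=case.case_id, svtype=case.svtype, junctions=junctions, group=case.group
    )


def classify_fig7(report: JunctionReport) -> str:
    """Four-way inversion-junction taxonomy (see module docstring)."""
    if not report.has_microhomology:
        return "A"
    if report.max_adjacent_deletion > CNHEJ_MAX_DELETION:
        return "D"
    if report.total_deletion == 0:
        return "B"
    return "C"


def infer_mechanism(report: JunctionReport) -> str:
    """Repair-mechanism call from the junction anatomy.

    Microhomology with zero adjacent deletion (breaks on or at the tract
    ends) -> cNHEJ-MH; adjacent deletion beyond 10 bp next to a
    microhomologous tract -> MMEJ candidate; everything else (no
    microhomology, or only small deletions) -> cNHEJ.
    """
    if report.has_microhomology:
        if report.max_adjacent_deletion > CNHEJ_MAX_DELETION:
            return "MMEJ-candidate"
        if sum(j.deletion_adjacent for j in report.junctions) == 0:
            return "cNHEJ-MH"
    return "cNHEJ"


def tabulate_junctions(reports_by_group: dict[str, list[JunctionReport]]) -> pd.DataFrame:
    """Per-group counts of junction features, with integer percentages of the
    group's total inversions formatted as ``"8 (89%)"``.

    Insertions at junctions with microhomology count as 'on overlap',
    otherwise as 'adjacent area'. Empty groups are dropped with a warning
    column absent (they simply do not appear).
    """
    rows = []
    for group, reports in reports_by_group.items():
        if not reports:
            continue
        total = len(reports)

        def cell(count: int) -> str:
            if count == 0:
                return "0"
            pct = int(round_half_up(100.0 * count / total, 0))
            return f"{count} ({pct}%)"

        with_overlap = sum(r.has_microhomology for r in reports)
        del_on = sum(r.deletion_on_overlap > 0 for r in reports)
        ins_on = sum(r.insertion_len > 0 and r.has_microhomology for r in reports)
        del_adj = sum(r.max_adjacent_deletion > 0 for r in reports)
        ins_adj = sum(r.insertion_len > 0 and not r.has_microhomology for r in reports)
        rows.append(
            {
                "group": group,
                "with_overlap": cell(with_overlap),
                "deletion_on_overlap": cell(del_on),
                "insertion_on_overlap": cell(ins_on),
                "deletion_adjacent": cell(del_adj),
                "insertion_adjacent": cell(ins_adj),
                "total": total,
            }
        )
    return pd.DataFrame(rows)


def write_reports_tsv(reports: list[JunctionReport], path: str | Path) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "case_id": r.case_id,
                "svtype": r.svtype,
                "group": r.group,
                "microhomology_len": r.microhomology_len,
                "microhomology_seq": r.microhomology_seq,
                "deletion_on_overlap": r.deletion_on_overlap,
                "deletion_adjacent_left": r.deletion_adjacent_left,
                "deletion_adjacent_right": r.deletion_adjacent_right,
                "insertion_len": r.insertion_len,
                "fig_class": r.fig_class if r.svtype == "inversion" else "",
                "mechanism": r.mechanism,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
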