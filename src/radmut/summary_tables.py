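"""Accounting over published-style summary tables.

Three table shapes are supported:

* **phenotype tables** — per irradiation source and dose, mutant counts by
  category (leaf colour / leaf shape / other, with sub-characteristics) and
  the number of M2 lines screened, from which phenotypic mutation rates
  (percent, 2 decimals, half-up) are recomputed;
* **rearrangement-event tables** — one row per junction-forming
  rearrangement event (inversion, deletion, duplication, interchromosomal
  translocation) with breakpoints in kb, zygosity and affected-gene counts.
  Events that arise in a single rearrangement process (e.g. the two paired
  inversions of one break-repair episode) share a process id, so event and
  process tallies can differ;
* **gene-impact tables** — per-group mean +/- SE counts of genes by coding
  consequence, with moderate/high-impact totals computed both including and
  excluding SV-driven categories (gene truncation, complete gene deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import round_half_up

__all__ = [
    "RearrangementEvent",
    "PhenotypeTable",
    "mutation_rate",
    "fragment_size",
    "count_events",
    "count_processes",
    "validate_fragment_sizes",
    "impact_summary",
    "impact_totals",
    "read_sv_events",
]

MODERATE_CATEGORIES = ("missense", "in_frame_deletion", "in_frame_insertion")
HIGH_CATEGORIES = ("start_loss", "premature_stop", "frameshift", "truncation", "complete_deletion")
SV_CATEGORIES = ("truncation", "complete_deletion")
SIZE_TOLERANCE_KB = 0.1


def mutation_rate(mutants: int, lines: int) -> float:
    """Phenotypic mutation rate, percent, 2 decimals half-up."""
    if lines <= 0:
        raise ValueError("lines screened must be positive")
    if not 0 <= mutants <= lines:
        raise ValueError("require 0 <= mutants <= lines")
    return round_half_up(100.0 * mutants / lines, 2)


@dataclass(frozen=True)
class RearrangementEvent:
    """One junction-forming rearrangement event (a table row)."""

    sample: str
    group: str
    svtype: str  # inversion | deletion | duplication | translocation
    chrom1: str
    pos1_kb: float
    chrom2: str
    pos2_kb: float
    zygosity: str
    size_kb: float | None = None
    chrom3: str | None = None  # extra breakpoint (3-breakpoint duplications)
    pos3_kb: float | None = None
    truncated_genes: int = 0
    deleted_genes: int = 0
    process: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in ("inversion", "deletion", "duplication", "translocation"):
            raise ValueError(f"unknown rearrangement type {self.svtype!r}")
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError(f"zygosity must be homozygous/heterozygous, got {self.zygosity!r}")

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2


def fragment_size(event: RearrangementEvent) -> float | None:
    """|pos2 - pos1| in kb, 1 decimal; None for interchromosomal events
    without a defined fragment."""
    if not event.intrachromosomal:
        return None
    return round_half_up(abs(event.pos2_kb - event.pos1_kb), 1)


def validate_fragment_sizes(
    events: list[RearrangementEvent], tolerance_kb: float = SIZE_TOLERANCE_KB
) -> list[tuple[RearrangementEvent, float, float]]:
    """Cross-check printed fragment sizes against |pos2 - pos1|.

    Returns the list of (event, computed, printed) whose discrepancy exceeds
    the rounding tolerance; published tables occasionally carry such
    internal inconsistencies, so this warns rather than raises.
    """
    bad = []
    for ev in events:
        if ev.size_kb is None or not ev.intrachromosomal:
            continue
        computed = fragment_size(ev)
        if abs(computed - ev.size_kb) > tolerance_kb + 1e-9:
            bad.append((ev, computed, ev.size_kb))
    return bad


def count_events(events: list[RearrangementEvent], by: str = "type") -> dict[str, int]:
    """Exact event tallies by 'type' or 'zygosity'; totals are preserved."""
    if by == "type":
        keys = [e.svtype for e in events]
    elif by == "zygosity":
        keys = [e.zygosity for e in events]
    else:
        raise ValueError("by must be 'type' or 'zygosity'")
    out: dict[str, int] = {}
    for k in keys:
        out[k] = out.get(k, 0) + 1
    return out


def count_processes(events: list[RearrangementEvent]) -> dict[str, int]:
    """Distinct rearrangement processes per group (events sharing a process
    id — e.g. paired inversions from one episode — count once)."""
    procs: dict[str, set[str]] = {}
    for ev in events:
        pid = ev.process or f"{ev.sample}:{ev.svtype}:{ev.chrom1}:{ev.pos1_kb}"
        procs.setdefault(ev.group, set()).add(pid)
    return {g: len(s) for g, s in procs.items()}


def read_sv_events(path: str | Path) -> list[RearrangementEvent]:
    """Read a rearrangement-event TSV (columns sample, group, svtype, chrom1,
    pos1_kb, chrom2, pos2_kb, [chrom3, pos3_kb,] size_kb, zygosity,
    truncated_genes, deleted_genes, process)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str, "chrom3": str})
    events = []
    for row in df.itertuples(index=False):
        size = getattr(row, "size_kb", None)
        size = None if size is None or (isinstance(size, float) and math.isnan(size)) else float(size)
        chrom3 = getattr(row, "chrom3", None)
        if isinstance(chrom3, float) and math.isnan(chrom3):
            chrom3 = None
        pos3 = getattr(row, "pos3_kb", None)
        pos3 = None if pos3 is None or (isinstance(pos3, float) and math.isnan(pos3)) else float(pos3)
        events.append(
            RearrangementEvent(
                sample=str(row.sample),
                group=str(row.group),
                svtype=str(row.svtype),
                chrom1=str(row.chrom1),
                pos1_kb=float(row.pos1_kb),
                chrom2=str(row.chrom2),
                pos2_kb=float(row.pos2_kb),
                zygosity=str(row.zygosity),
                size_kb=size,
                chrom3=chrom3,
                pos3_kb=pos3,
                truncated_genes=int(row.truncated_genes),
                deleted_genes=int(row.deleted_genes),
                process=str(row.process),
            )
        )
    return events


@dataclass
class PhenotypeTable:
    """Phenotypic mutant counts and screened-line totals.

    ``counts`` has columns category, characteristic, source, dose_gy, count;
    ``lines`` has columns source, dose_gy, lines.
    """

    counts: pd.DataFrame
    lines: pd.DataFrame

    def __post_init__(self) -> None:
        for source, dose in self.populations():
            if self.mutants(source, dose) > self.lines_screened(source, dose):
                raise ValueError(f"more mutants than screened lines in {source} {dose} Gy")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, lines_path: str | Path) -> "PhenotypeTable":
        return cls(
            counts=pd.read_csv(counts_path, sep="\t"),
            lines=pd.read_csv(lines_path, sep="\t"),
        )

    def populations(self) -> list[tuple[str, int]]:
        return [(str(r.source), int(r.dose_gy)) for r in self.lines.itertuples(index=False)]

    def lines_screened(self, source: str, dose: int) -> int:
        sel = self.lines[(self.lines["source"] == source) & (self.lines["dose_gy"] == dose)]
        if sel.empty:
            raise KeyError(f"no population {source} at {dose} Gy")
        return int(sel["lines"].iloc[0])

    def mutants(self, source: str, dose: int, category: str | None = None) -> int:
        sel = self.counts[(self.counts["source"] == source) & (self.counts["dose_gy"] == dose)]
        if category is not None:
            sel = sel[sel["category"] == category]
        return int(sel["count"].sum())

    def rate(self, source: str, dose: int) -> float:
        return mutation_rate(self.mutants(source, dose), self.lines_screened(source, dose))

    def rate_table(self) -> pd.DataFrame:
        rows = []
        for source, dose in self.populations():
            rows.append(
                {
                    "source": source,
                    "dose_gy": dose,
                    "mutants": self.mutants(source, dose),
                    "lines": self.lines_screened(source, dose),
                    "rate_percent": self.rate(source, dose),
                }
            )
        return pd.DataFrame(rows)

    def source_rate(self, source: str) -> float:
        """Pooled rate over all doses of one radiation source."""
        pops = [(s, d) for s, d in self.populations() if s == source]
        mutants = sum(self.mutants(s, d) for s, d in pops)
        lines = sum(self.lines_screened(s, d) for s, d in pops)
        return mutation_rate(mutants, lines)


def impact_totals(means: dict[str, float]) -> dict[str, float]:
    """Impact-category totals from per-category mean gene counts.

    moderate = missense + in-frame deletion + in-frame insertion;
    high = start loss + premature stop + frameshift + truncation + complete
    deletion; the SV-exclusive high total omits truncation and complete
    deletion (the SV-driven categories).
    """
    moderate = sum(means.get(c, 0.0) for c in MODERATE_CATEGORIES)
    high = sum(means.get(c, 0.0) for c in HIGH_CATEGORIES)
    high_excl = sum(
        means.get(c, 0.0) for c in HIGH_CATEGORIES if c not in SV_CATEGORIES
    )
    return {
        "moderate_total": round_half_up(moderate, 2),
        "high_total": round_half_up(high, 2),
        "high_total_excl_sv": round_half_up(high_excl, 2),
    }


def impact_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean +/- SE gene-impact summary from per-sample counts.

    ``per_sample`` columns: group, sample, then one column per consequence
    category. Requires >= 2 samples per group for a standard error. Returns
    one row per (group, category) with mean and se, plus total rows.
    """
    cats = [c for c in per_sample.columns if c not in ("group", "sample")]
    rows = []
    for group, grp in per_sample.groupby("group", sort=False):
        n = len(grp)
        if n < 2:
            raise ValueError(f"group {group!r} needs >= 2 samples for a standard error")
        means = {}
        for cat in cats:
            mean = float(grp[cat].mean())
            se = float(grp[cat].std(ddof=1) / math.sqrt(n))
            means[cat] = mean
            rows.append({"group": group, "category": cat, "mean": mean, "se": se})
        for name, value in impact_totals(means).items():
            rows.append({"group": group, "category": name, "mean": value, "se": float("nan")})
    return pd.DataFrame(rows)
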