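"""Structural-variant landscape analysis.

Covers cross-accession merging into a nonredundant SV set, type summaries,
genomic-context annotation, repeat-region enrichment (Fisher), inversion
hotspots, ancestor-inheritance partitioning and the Bonferroni threshold
used for genome-wide association scans.

SVs shorter than 21 bp are outside the model (the >20 bp floor); the five
types are deletions (DEL), insertions (INS), duplications (DUP),
inversions (INV) and translocations (TRA).  Insertions occupy a
zero-length anchor point whose ``length`` carries the inserted-sequence
length, matching VCF symbolic-allele semantics.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .errors import InputError, ParameterError

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")
_INTERVAL_TYPES = ("DEL", "DUP", "INV")


@dataclass(frozen=True)
class SvRecord:
    """One SV call in one accession (0-based half-open span)."""

    accession: str
    chromosome: str
    span: tuple[int, int]
    type: str
    length: int
    inserted_seq: str | None = None

    def __post_init__(self):
        if self.type not in SV_TYPES:
            raise InputError(f"unknown SV type {self.type!r}")
        if self.length <= 20:
            raise InputError(f"SV length {self.length} below the >20 bp floor")
        s, e = self.span
        if self.type == "INS":
            if s != e:
                raise InputError("INS span must be a zero-length anchor")
        elif not 0 <= s < e:
            raise InputError(f"invalid span {self.span}")

    @property
    def midpoint(self) -> int:
        return (self.span[0] + self.span[1]) // 2


@dataclass
class NonredundantSv:
    """A merged cross-accession SV with a presence vector."""

    id: str
    chromosome: str
    span: tuple[int, int]
    type: str
    representative_length: int
    presence: dict[str, bool]
    members: tuple[SvRecord, ...] = ()

    @property
    def length(self) -> int:
        return self.representative_length

    @property
    def midpoint(self) -> int:
        return (self.span[0] + self.span[1]) // 2

    def carriers(self) -> list[str]:
        return [a for a, p in self.presence.items() if p]


@dataclass
class AnnotatedSv:
    sv: NonredundantSv
    context: str                 # cds | genic_noncds | flank2kb | intergenic
    in_repeat: bool
    coding_effect: str           # none | inframe | frameshift | structural


@dataclass
class AncestryPartition:
    counts: dict[str, int]       # onlyA, onlyB, both, neither
    total: int


@dataclass
class TypeSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    repeat_density: list[float]      # SV midpoints per Mb, per 500-kb bin
    nonrepeat_density: list[float]
    flagged: bool = False


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def mergeable(a, b, reciprocal_overlap: float = 0.5, ins_window: int = 100,
              ins_len_ratio: float = 0.5) -> bool:
    """Pairwise merge criterion between two same-type SVs.

    DEL/DUP/INV merge on reciprocal overlap; INS on anchor proximity plus
    a min/max length ratio; TRA when both breakpoints are within the
    window.  Mixed types or chromosomes never merge.
    """
    if a.type != b.type or a.chromosome != b.chromosome:
        return False
    if a.type == "INS":
        return (abs(a.span[0] - b.span[0]) <= ins_window and
                min(a.length, b.length) / max(a.length, b.length)
                >= ins_len_ratio)
    if a.type == "TRA":
        return (abs(a.span[0] - b.span[0]) <= ins_window and
                abs(a.span[1] - b.span[1]) <= ins_window)
    ov = min(a.span[1], b.span[1]) - max(a.span[0], b.span[0])
    if ov <= 0:
        return False
    return (ov / (a.span[1] - a.span[0]) >= reciprocal_overlap and
            ov / (b.span[1] - b.span[0]) >= reciprocal_overlap)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_svs(records, reciprocal_overlap: float = 0.5,
              ins_window: int = 100, ins_len_ratio: float = 0.5
              ) -> list[NonredundantSv]:
    """Merge per-accession SVs into a nonredundant set.

    ``records`` is either a flat iterable of :class:`SvRecord` or a mapping
    accession -> list of records.  Merging takes connected components of
    the pairwise criterion; the representative is the member with median
    length (ties by accession then position) and presence vectors union
    the member accessions over all input accessions.
    """
    if isinstance(records, dict):
        accessions = list(records)
        flat = [r for recs in records.values() for r in recs]
    else:
        flat = list(records)
        accessions = sorted({r.accession for r in flat})
    if not flat:
        return []

    flat.sort(key=lambda r: (r.chromosome, r.type, r.span[0], r.span[1],
                             r.accession))
    uf = _UnionFind(len(flat))
    # same (chromosome, type) runs are contiguous after the sort
    i = 0
    n = len(flat)
    while i < n:
        j = i
        key = (flat[i].chromosome, flat[i].type)
        while j < n and (flat[j].chromosome, flat[j].type) == key:
            j += 1
        group = range(i, j)
        for gi in group:
            a = flat[gi]
            horizon = (a.span[0] + ins_window if a.type in ("INS", "TRA")
                       else a.span[1])
            for gj in range(gi + 1, j):
                b = flat[gj]
                if b.span[0] > horizon:
                    break
                if mergeable(a, b, reciprocal_overlap, ins_window,
                             ins_len_ratio):
                    uf.union(gi, gj)
        i = j

    components: dict[int, list[SvRecord]] = {}
    for idx, rec in enumerate(flat):
        components.setdefault(uf.find(idx), []).append(rec)

    merged = []
    for members in components.values():
        by_len = sorted(members, key=lambda r: (r.length, r.accession,
                                                r.span[0]))
        rep = by_len[(len(by_len) - 1) // 2]
        present = {r.accession for r in members}
        merged.append(NonredundantSv(
            id="", chromosome=rep.chromosome, span=rep.span, type=rep.type,
            representative_length=rep.length,
            presence={a: a in present for a in accessions},
            members=tuple(members)))
    merged.sort(key=lambda m: (m.chromosome, m.span[0], m.span[1], m.type))
    for k, m in enumerate(merged, 1):
        m.id = f"nsv{k:06d}"
    return merged


# ---------------------------------------------------------------------------
# Type summary
# ---------------------------------------------------------------------------

def _round_half_up(x: float, digits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * digits),
                                           rounding=ROUND_HALF_UP))


def summarize_types(svs) -> TypeSummary:
    """Counts and percentages (rounded half-up, 2 decimals) per SV type.

    Accepts SV objects with a ``type`` attribute, or a mapping
    type -> count.
    """
    counts = dict.fromkeys(SV_TYPES, 0)
    if isinstance(svs, dict):
        for t, c in svs.items():
            if t not in counts:
                raise InputError(f"unknown SV type {t!r}")
            counts[t] += int(c)
    else:
        for sv in svs:
            counts[sv.type] += 1
    total = sum(counts.values())
    if total == 0:
        return TypeSummary(counts=counts,
                           percentages=dict.fromkeys(SV_TYPES, 0.0), total=0)
    pct = {t: _round_half_up(100.0 * c / total) for t, c in counts.items()}
    return TypeSummary(counts=counts, percentages=pct, total=total)


# ---------------------------------------------------------------------------
# Genomic-context annotation
# ---------------------------------------------------------------------------

def annotate_svs(svs: list[NonredundantSv], genes, repeats,
                 flank: int = 2_000):
    """Annotate each SV with genomic context, repeat overlap, coding effect.

    Context precedence is cds > genic_noncds > flank2kb > intergenic,
    decided by any-overlap of the SV span (insertions: anchor point) with
    CDS parts, gene spans and gene spans +- ``flank`` bp.  Coding effect
    applies to CDS-overlapping SVs: DEL/INS/DUP are frameshift iff length
    mod 3 != 0 (else inframe); INV/TRA are structural.

    Returns ``(annotated, summary)``; SVs on chromosomes absent from the
    annotation are excluded from the summary fractions and counted in
    ``summary["n_flagged"]``.
    """
    cds_t: dict[str, IntervalTree] = {}
    gene_t: dict[str, IntervalTree] = {}
    flank_t: dict[str, IntervalTree] = {}
    rep_t: dict[str, IntervalTree] = {}
    known = set()
    for g in genes:
        known.add(g.chromosome)
        gene_t.setdefault(g.chromosome, IntervalTree()).addi(*g.span)
        fs = max(0, g.span[0] - flank)
        flank_t.setdefault(g.chromosome, IntervalTree()).addi(
            fs, g.span[1] + flank)
        for part in g.cds_parts:
            cds_t.setdefault(g.chromosome, IntervalTree()).addi(*part)
    for r in repeats:
        known.add(r.chromosome)
        rep_t.setdefault(r.chromosome, IntervalTree()).addi(*r.span)

    def hits(trees, sv):
        t = trees.get(sv.chromosome)
        if t is None:
            return False
        s, e = sv.span
        return bool(t.overlap(s, e if e > s else s + 1))

    annotated, n_flagged = [], 0
    for sv in svs:
        if sv.chromosome not in known:
            n_flagged += 1
            continue
        if hits(cds_t, sv):
            context = "cds"
            effect = ("structural" if sv.type in ("INV", "TRA")
                      else ("inframe" if sv.length % 3 == 0 else "frameshift"))
        elif hits(gene_t, sv):
            context, effect = "genic_noncds", "none"
        elif hits(flank_t, sv):
            context, effect = "flank2kb", "none"
        else:
            context, effect = "intergenic", "none"
        annotated.append(AnnotatedSv(sv=sv, context=context,
                                     in_repeat=hits(rep_t, sv),
                                     coding_effect=effect))
    n = len(annotated)
    contexts = ("cds", "genic_noncds", "flank2kb", "intergenic")
    summary = {
        "context_fractions": {c: (sum(a.context == c for a in annotated) / n
                                  if n else 0.0) for c in contexts},
        "repeat_fraction": (sum(a.in_repeat for a in annotated) / n
                            if n else 0.0),
        "coding_change_fraction": (sum(a.coding_effect != "none"
                                       for a in annotated) / n if n else 0.0),
        "n_flagged": n_flagged,
    }
    return annotated, summary


# ---------------------------------------------------------------------------
# Repeat enrichment
# ---------------------------------------------------------------------------

def fisher_test(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sided means the sum of probabilities of all tables (with the
    observed margins) no more likely than the observed one.  This is the
    significance pathway used by :func:`repeat_enrichment`.
    """
    odds, p = fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def _merge_spans(spans):
    out = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def repeat_enrichment(svs, repeats, chromosome_lengths: dict[str, int],
                      bin_size: int = 500_000) -> EnrichmentResult:
    """Test whether SV midpoints are enriched in repeat regions.

    Builds the 2x2 table [[midpoints in repeat, in nonrepeat],
    [repeat bp, nonrepeat bp]] and applies a two-sided Fisher exact test
    (two-sided = sum of all tables with probability <= observed).  Also
    reports per-bin SV densities (midpoints per Mb of class sequence) at
    ``bin_size`` resolution for the repetitive and nonrepetitive fractions.
    """
    rep_by_chrom = {}
    for c in chromosome_lengths:
        spans = _merge_spans([r.span for r in repeats if r.chromosome == c])
        spans = [(s, min(e, chromosome_lengths[c])) for s, e in spans
                 if s < chromosome_lengths[c]]
        rep_by_chrom[c] = spans

    def in_repeat(c, pos):
        spans = rep_by_chrom.get(c, [])
        i = bisect_right([s for s, _ in spans], pos) - 1
        return i >= 0 and pos < spans[i][1]

    sv_rep = sv_non = 0
    mids_by_chrom: dict[str, list[int]] = {}
    for sv in svs:
        if sv.chromosome not in chromosome_lengths:
            continue
        mid = sv.midpoint
        mids_by_chrom.setdefault(sv.chromosome, []).append(mid)
        if in_repeat(sv.chromosome, mid):
            sv_rep += 1
        else:
            sv_non += 1

    rep_bp = sum(e - s for spans in rep_by_chrom.values() for s, e in spans)
    non_bp = sum(chromosome_lengths.values()) - rep_bp

    rep_density, non_density = [], []
    for c, L in chromosome_lengths.items():
        mids = sorted(mids_by_chrom.get(c, []))
        for bs in range(0, L, bin_size):
            be = min(bs + bin_size, L)
            r_bp = sum(max(0, min(e, be) - max(s, bs))
                       for s, e in rep_by_chrom[c])
            n_bp = (be - bs) - r_bp
            lo = bisect_right(mids, bs - 1)
            hi = bisect_right(mids, be - 1)
            r_cnt = sum(1 for m in mids[lo:hi] if in_repeat(c, m))
            n_cnt = (hi - lo) - r_cnt
            if r_bp > 0:
                rep_density.append(r_cnt / (r_bp / 1e6))
            if n_bp > 0:
                non_density.append(n_cnt / (n_bp / 1e6))

    table = ((sv_rep, sv_non), (rep_bp, non_bp))
    flagged = 0 in (sv_rep + sv_non, rep_bp + non_bp,
                    sv_rep + rep_bp, sv_non + non_bp)
    if flagged:
        odds, p = float("nan"), float("nan")
    else:
        odds, p = fisher_test(table)
    return EnrichmentResult(table=table, odds_ratio=odds, p_value=p,
                            repeat_density=rep_density,
                            nonrepeat_density=non_density, flagged=flagged)


# ---------------------------------------------------------------------------
# Ancestry partition
# ---------------------------------------------------------------------------

def ancestry_partition(target_svs, set_a, set_b,
                       reciprocal_overlap: float = 0.5,
                       ins_window: int = 100, ins_len_ratio: float = 0.5
                       ) -> AncestryPartition:
    """Partition target SVs by presence in two candidate ancestor call sets.

    Membership in either set uses the same pairwise criterion as merging.
    Counts are onlyA (inherited from ancestor A alone), onlyB, both, and
    neither (novel in the target group).
    """
    def hits(sv, pool) -> bool:
        return any(mergeable(sv, r, reciprocal_overlap, ins_window,
                             ins_len_ratio) for r in pool)

    counts = {"onlyA": 0, "onlyB": 0, "both": 0, "neither": 0}
    set_a, set_b = list(set_a), list(set_b)
    for sv in target_svs:
        a = hits(sv, set_a)
        b = hits(sv, set_b)
        key = ("both" if a and b else "onlyA" if a
               else "onlyB" if b else "neither")
        counts[key] += 1
    return AncestryPartition(counts=counts, total=sum(counts.values()))


def core_svs(merged: list[NonredundantSv], group: list[str]
             ) -> list[NonredundantSv]:
    """SVs present in every accession of ``group`` (the group's core SVs)."""
    return [m for m in merged if all(m.presence.get(a, False) for a in group)]


# ---------------------------------------------------------------------------
# Inversion hotspots
# ---------------------------------------------------------------------------

def inversion_hotspots(svs, window: int = 1_000_000, step: int = 100_000,
                       min_count: int = 3) -> list[tuple[str, int, int]]:
    """Windows with a clustered excess of inversion midpoints.

    Windows of ``window`` bp slide by ``step``; windows holding at least
    ``min_count`` INV midpoints qualify and overlapping qualifying windows
    are merged.
    """
    mids: dict[str, list[int]] = {}
    for sv in svs:
        if sv.type == "INV":
            mids.setdefault(sv.chromosome, []).append(sv.midpoint)
    hotspots = []
    for c in sorted(mids):
        ms = sorted(mids[c])
        qual = []
        first = max(0, (ms[0] - window) // step * step)
        for ws in range(first, ms[-1] + 1, step):
            we = ws + window
            cnt = bisect_right(ms, we - 1) - bisect_right(ms, ws - 1)
            if cnt >= min_count:
                qual.append((ws, we))
        for s, e in _merge_spans(qual):
            hotspots.append((c, s, e))
    return hotspots


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return alpha / n_tests
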