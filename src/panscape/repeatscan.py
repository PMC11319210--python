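"""Tandem-repeat detection, monomer clustering and centromere/telomere calls.

Plant centromeres are megabase-scale arrays of a tandemly repeated monomer
(tens to hundreds of bp), embedded in a Gypsy-LTR-rich, gene-poor
neighbourhood; chromosome ends carry (CCCTAAA)n telomere tracts.  This
module locates all three signals on assembled chromosomes.

Tandem arrays are found by k-mer-anchored period estimation: a k-mer
recurring at distance p votes for period p at that locus, and voted
periods are then verified by shifted-self identity (the fraction of
positions i with s[i] == s[i+p]) and extended while per-monomer identity
stays above a threshold.  Divisor periods are collapsed so the smallest
valid period is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .io_formats import GeneModel, GenomeAnnotationBundle, RepeatFeature
from .phylo import monomer_distance, reverse_complement

TELOMERE_MOTIF = "CCCTAAA"

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass
class TandemArray:
    """A detected tandem repeat array (0-based half-open span)."""

    id: str
    chromosome: str
    span: tuple[int, int]
    period: int
    copy_number: float
    consensus_monomer: str
    mean_identity: float

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class MonomerCluster:
    """Identity-clustered array monomers; abundance sums member copy counts."""

    representative: str
    members: list[tuple[str, str]]      # (array id, monomer)
    abundance: float
    rank: int = 0


@dataclass
class CentromereCall:
    chromosome: str
    span: tuple[int, int]
    score: float
    dominant_cluster: int
    evidence: dict = field(default_factory=dict)


@dataclass
class TelomereCall:
    chromosome: str
    end: str                             # "5prime" or "3prime"
    motif_copies: int
    present: bool


# ---------------------------------------------------------------------------
# Tandem repeat detection
# ---------------------------------------------------------------------------

def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-5 integer id of every k-mer (N contributes its own digit)."""
    n = len(codes) - k + 1
    ids = np.zeros(n, dtype=np.int64)
    for j in range(k):
        ids = ids * 5 + codes[j:j + n]
    return ids


def _candidate_periods(codes: np.ndarray, min_period: int, max_period: int,
                       k: int, bucket: int = 256, vote_min: int = 3) -> set[int]:
    """Periods supported by >= vote_min recurring k-mers in some bucket."""
    if len(codes) < k + min_period:
        return set()
    ids = _kmer_ids(codes, k)
    order = np.argsort(ids, kind="stable")
    sid = ids[order]
    same = sid[1:] == sid[:-1]
    dist = order[1:] - order[:-1]        # stable sort keeps positions ascending
    ok = same & (dist >= min_period) & (dist <= max_period)
    if not ok.any():
        return set()
    pos = order[:-1][ok]
    d = dist[ok]
    key = (pos // bucket).astype(np.int64) * (max_period + 1) + d
    uniq, counts = np.unique(key, return_counts=True)
    return {int(u % (max_period + 1)) for u, c in zip(uniq, counts)
            if c >= vote_min}


def _good_runs(good: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True, bridging internal gaps shorter than ``gap``."""
    idx = np.flatnonzero(good)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def _consensus(codes: np.ndarray, span: tuple[int, int], p: int) -> str:
    s, e = span
    k = (e - s) // p
    block = codes[s:s + k * p].reshape(k, p)
    cons = np.empty(p, dtype=np.uint8)
    for col in range(p):
        counts = np.bincount(block[:, col], minlength=5)[:4]
        cons[col] = counts.argmax()
    return "".join("ACGT"[c] for c in cons)


def find_tandem_repeats(sequence: str, chromosome: str = "seq",
                        min_period: int = 5, max_period: int = 500,
                        min_copies: float = 5, min_identity: float = 0.8,
                        ) -> list[TandemArray]:
    """Detect tandem repeat arrays by voted periods + shifted-self identity.

    Returns non-overlapping arrays; where candidate arrays overlap the
    higher-scoring (covered bp x identity) period wins.  The smallest
    divisor period passing ``min_identity`` is reported.
    """
    if len(sequence) < 2 * min_period:
        raise InputError("sequence shorter than twice the minimum period")
    codes = _encode(sequence)
    n = len(codes)
    k = max(3, min(8, min_period))
    periods = _candidate_periods(codes, min_period, max_period, k)

    eq_cache: dict[int, np.ndarray] = {}
    runs_cache: dict[int, list[tuple[int, int]]] = {}

    def eq(p: int) -> np.ndarray:
        if p not in eq_cache:
            a, b = codes[:-p], codes[p:]
            eq_cache[p] = (a == b) & (a != 4)
        return eq_cache[p]

    def runs(p: int) -> list[tuple[int, int]]:
        """Spans where the one-monomer windowed identity at period p stays
        above threshold (single divergent monomers are bridged)."""
        if p not in runs_cache:
            e = eq(p)
            if len(e) < p:
                runs_cache[p] = []
            else:
                csum = np.concatenate(([0], np.cumsum(e, dtype=np.int64)))
                wid = (csum[p:] - csum[:-p]) / p
                runs_cache[p] = [(i0, min(i1 - 1 + 2 * p, n))
                                 for i0, i1 in _good_runs(wid >= min_identity,
                                                          gap=p)]
        return runs_cache[p]

    raw: list[TandemArray] = []
    seen: set[tuple[int, int, int]] = set()
    for p in sorted(periods):
        for span in runs(p):
            if span[1] - span[0] < min_copies * p:
                continue
            period = p
            # collapse to the smallest divisor that still validates
            for q in sorted(q for q in range(min_period, p)
                            if p % q == 0):
                eq_q = eq(q)[span[0]:span[1] - q]
                if len(eq_q) and eq_q.mean() >= min_identity:
                    period = q
                    break
            if period != p:
                # take boundaries from the collapsed period's own identity
                # profile: smaller shifts localize array edges more sharply
                overlapping = [r for r in runs(period)
                               if r[0] < span[1] and r[1] > span[0]]
                if overlapping:
                    span = max(overlapping,
                               key=lambda r: min(r[1], span[1])
                               - max(r[0], span[0]))
            ident = float(eq(period)[span[0]:span[1] - period].mean())
            if ident < min_identity:
                continue
            copy_number = (span[1] - span[0]) / period
            if copy_number < min_copies:
                continue
            key = (span[0], span[1], period)
            if key in seen:
                continue
            seen.add(key)
            raw.append(TandemArray(
                id=f"{chromosome}:{span[0]}-{span[1]}", chromosome=chromosome,
                span=span, period=period, copy_number=copy_number,
                consensus_monomer=_consensus(codes, span, period),
                mean_identity=ident))

    # resolve overlaps: higher score (covered bp x identity) wins
    raw.sort(key=lambda a: (-(a.length * a.mean_identity), a.span[0], a.period))
    kept: list[TandemArray] = []
    for arr in raw:
        if all(arr.span[1] <= o.span[0] or arr.span[0] >= o.span[1]
               for o in kept):
            kept.append(arr)
    kept.sort(key=lambda a: a.span[0])
    return kept


# ---------------------------------------------------------------------------
# Monomer clustering
# ---------------------------------------------------------------------------

def cluster_monomers(arrays: list[TandemArray],
                     identity_threshold: float = 0.8) -> list[MonomerCluster]:
    """Greedy incremental clustering of array consensus monomers.

    Monomers are processed by decreasing length; each joins the first
    cluster whose representative identity (best of forward and reverse
    complement) reaches the threshold, otherwise it founds a new cluster.
    Cluster abundance is the summed copy number of member arrays; ranks
    are 1-based by decreasing abundance.
    """
    if not arrays:
        raise InputError("no monomers to cluster")
    clusters: list[MonomerCluster] = []
    for arr in sorted(arrays, key=lambda a: (-len(a.consensus_monomer), a.id)):
        mono = arr.consensus_monomer
        placed = False
        for cl in clusters:
            ident = 1.0 - min(monomer_distance(cl.representative, mono),
                              monomer_distance(cl.representative,
                                               reverse_complement(mono)))
            if ident >= identity_threshold:
                cl.members.append((arr.id, mono))
                cl.abundance += arr.copy_number
                placed = True
                break
        if not placed:
            clusters.append(MonomerCluster(representative=mono,
                                           members=[(arr.id, mono)],
                                           abundance=arr.copy_number))
    clusters.sort(key=lambda c: (-c.abundance, c.representative))
    for rank, cl in enumerate(clusters, 1):
        cl.rank = rank
    return clusters


def top_clusters(clusters: list[MonomerCluster], k: int = 8
                 ) -> list[MonomerCluster]:
    """The (at most) k most abundant clusters, by rank."""
    return sorted(clusters, key=lambda c: c.rank)[:k]


# ---------------------------------------------------------------------------
# Centromere calling
# ---------------------------------------------------------------------------

def _coverage_bp(spans: list[tuple[int, int]], lo: int, hi: int) -> int:
    total = 0
    for s, e in spans:
        total += max(0, min(e, hi) - max(s, lo))
    return total


def call_centromere(bundle: GenomeAnnotationBundle, chromosome: str,
                    arrays: list[TandemArray], clusters: list[MonomerCluster],
                    window: int = 100_000, step: int = 50_000,
                    weights: tuple[float, float, float] = (1.0, 0.3, 0.3),
                    coverage_min: float = 0.3, top_k: int = 8,
                    ) -> CentromereCall | None:
    """Score sliding windows and call at most one centromere per chromosome.

    Window score = w1 * (bp covered by monomers of the top clusters) / window
    + w2 * (Gypsy bp fraction) - w3 * (gene count / max gene count).
    The call is the maximal run of consecutive windows with monomer
    coverage >= ``coverage_min`` that has the highest mean score (ties go
    leftmost); its reported span is clipped to the extent of the
    contributing arrays so the boundaries are monomer-resolution, not
    window-resolution.
    """
    length = len(bundle.assembly[chromosome])
    top_ids = {aid for cl in top_clusters(clusters, top_k)
               for aid, _ in cl.members}
    cent_spans = [a.span for a in arrays
                  if a.chromosome == chromosome and a.id in top_ids]
    gypsy = [r.span for r in bundle.repeats
             if r.chromosome == chromosome and "Gypsy" in r.class_label]
    gene_spans = [g.span for g in bundle.genes if g.chromosome == chromosome]

    starts = list(range(0, max(1, length - window + step), step))
    cov, gyp, gcount = [], [], []
    for ws in starts:
        we = min(ws + window, length)
        size = we - ws
        cov.append(_coverage_bp(cent_spans, ws, we) / size)
        gyp.append(_coverage_bp(gypsy, ws, we) / size)
        gcount.append(sum(1 for s, e in gene_spans if s < we and e > ws))
    cov = np.array(cov)
    gyp = np.array(gyp)
    gcount = np.array(gcount, dtype=float)
    gmax = gcount.max() if len(gcount) and gcount.max() > 0 else 1.0
    w1, w2, w3 = weights
    score = w1 * cov + w2 * gyp - w3 * gcount / gmax

    runs = _good_runs(cov >= coverage_min, gap=0)
    if not runs:
        return None
    best = max(runs, key=lambda r: (score[r[0]:r[1]].mean(), -r[0]))
    lo = starts[best[0]]
    hi = min(starts[best[1] - 1] + window, length)
    inside = [(s, e) for s, e in cent_spans if s < hi and e > lo]
    if inside:
        lo = max(lo, min(s for s, _ in inside))
        hi = min(hi, max(e for _, e in inside))
    # dominant cluster = the one contributing most bp to the called span
    best_rank, best_bp = 0, -1
    for cl in top_clusters(clusters, top_k):
        bp = _coverage_bp([a.span for a in arrays
                           if a.id in {aid for aid, _ in cl.members}
                           and a.chromosome == chromosome], lo, hi)
        if bp > best_bp:
            best_rank, best_bp = cl.rank, bp
    return CentromereCall(
        chromosome=chromosome, span=(lo, hi),
        score=float(score[best[0]:best[1]].mean()),
        dominant_cluster=best_rank,
        evidence={"window_starts": starts, "monomer_coverage": cov.tolist(),
                  "gypsy_fraction": gyp.tolist(),
                  "gene_count": gcount.tolist()})


# ---------------------------------------------------------------------------
# Telomere detection
# ---------------------------------------------------------------------------

def detect_telomeres(sequence: str, chromosome: str = "seq",
                     motif: str = TELOMERE_MOTIF,
                     terminal_window: int = 10_000, min_copies: int = 10,
                     ) -> list[TelomereCall]:
    """Count telomere motif copies in both terminal windows.

    The plant motif CCCTAAA is searched on the 5' end and its reverse
    complement (TTTAGGG) on the 3' end; an end is telomere-complete iff
    at least ``min_copies`` copies are found.
    """
    if len(sequence) <= 2 * terminal_window:
        raise InputError("sequence must be longer than twice terminal_window")
    seq = sequence.upper()
    five = seq[:terminal_window].count(motif.upper())
    three = seq[-terminal_window:].count(reverse_complement(motif))
    return [
        TelomereCall(chromosome, "5prime", five, five >= min_copies),
        TelomereCall(chromosome, "3prime", three, three >= min_copies),
    ]
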