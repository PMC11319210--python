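"""Pangenome composition, saturation/closure and diversity statistics.

The substrate is a presence--absence (PAV) matrix of gene families across
accessions.  Families are partitioned into four classes:

* **core** -- present in every accession;
* **softcore** -- absent in exactly one or two accessions;
* **private** -- present in exactly one accession;
* **dispensable** -- everything else.

At the species level (presence = present in at least one member of the
species) the partition is three-way: core / private / dispensable, since
"absent in one or two accessions" has no species analogue.

Closure of the pangenome is judged by a Heaps'-law fit to the mean number
of new families contributed by the n-th added genome,
``delta(n) = kappa * n**(-alpha)``; ``alpha > 1`` means the discovery curve
converges, i.e. the pangenome is closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from .errors import InputError

CLASS_ORDER = ("core", "softcore", "dispensable", "private")


@dataclass
class PavMatrix:
    """Boolean gene-family x accession presence table with a species map."""

    families: list[str]
    accessions: list[str]
    presence: np.ndarray  # shape (n_families, n_accessions), bool
    species_of: dict[str, str]

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.families), len(self.accessions)):
            raise InputError("presence matrix shape mismatch")
        if len(set(self.accessions)) != len(self.accessions):
            raise InputError("duplicate accession ids")
        missing = [a for a in self.accessions if a not in self.species_of]
        if missing:
            raise InputError(f"accessions without species: {missing}")
        if self.presence.size and not self.presence.any(axis=1).all():
            raise InputError("PAV matrix contains an all-zero family row")

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def species_presence(self) -> tuple[list[str], np.ndarray]:
        """Collapse columns to species: present iff present in >=1 member."""
        species = sorted(set(self.species_of.values()))
        cols = []
        for sp in species:
            idx = [i for i, a in enumerate(self.accessions)
                   if self.species_of[a] == sp]
            cols.append(self.presence[:, idx].any(axis=1))
        return species, np.column_stack(cols)


@dataclass
class PanClassification:
    level: str
    label_of: dict[str, str]
    composition: dict[str, dict[str, float]]  # class -> {count, fraction}


@dataclass
class SaturationCurve:
    """Pan/core sizes for n = 1..N over R random accession orderings."""

    n_values: np.ndarray          # shape (N,)
    pan_sizes: np.ndarray         # shape (R, N)
    core_sizes: np.ndarray        # shape (R, N)
    replicates: int


@dataclass
class ClosureFit:
    alpha: float
    kappa: float
    fit_error: float
    verdict: str                  # "open" or "closed"
    n_points: int


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_families(pav: PavMatrix, level: str = "accession") -> PanClassification:
    """Partition families into core/softcore/dispensable/private.

    Precedence is core > softcore > private > dispensable: a family seen in
    exactly one accession is both "absent in more than two" and "exclusive
    to one"; exclusivity wins so that the private class exists.
    """
    if pav.n_families == 0:
        raise InputError("empty PAV matrix")
    if level == "accession":
        if pav.n_accessions < 4:
            raise InputError("accession-level classification needs >=4 accessions")
        counts = pav.presence.sum(axis=1)
        n = pav.n_accessions
        labels = np.full(pav.n_families, "dispensable", dtype=object)
        labels[counts == n] = "core"
        labels[(counts == n - 1) | (counts == n - 2)] = "softcore"
        labels[counts == 1] = "private"
    elif level == "species":
        species, pres = pav.species_presence()
        if len(species) < 3:
            raise InputError("species-level classification needs >=3 species")
        counts = pres.sum(axis=1)
        labels = np.full(pav.n_families, "dispensable", dtype=object)
        labels[counts == len(species)] = "core"
        labels[counts == 1] = "private"
    else:
        raise InputError(f"unknown level {level!r}")

    label_of = dict(zip(pav.families, labels))
    total = pav.n_families
    composition = {}
    for cls in CLASS_ORDER:
        if level == "species" and cls == "softcore":
            continue
        cnt = int((labels == cls).sum())
        composition[cls] = {"count": cnt, "fraction": cnt / total}
    return PanClassification(level=level, label_of=label_of,
                             composition=composition)


# ---------------------------------------------------------------------------
# Saturation and closure
# ---------------------------------------------------------------------------

def saturation_curves(pav: PavMatrix, replicates: int = 100,
                      seed: int | np.random.Generator = 0) -> SaturationCurve:
    """Pan- and core-genome sizes under random accession orderings.

    Each replicate draws one uniform permutation of the accessions (sampling
    without replacement); pan size at n counts families present in >=1 of
    the first n accessions, core size those present in all of them.
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    if pav.n_families == 0:
        raise InputError("empty PAV matrix")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    N = pav.n_accessions
    pan = np.empty((replicates, N), dtype=np.int64)
    core = np.empty((replicates, N), dtype=np.int64)
    for r in range(replicates):
        order = rng.permutation(N)
        m = pav.presence[:, order]
        pan[r] = np.logical_or.accumulate(m, axis=1).sum(axis=0)
        core[r] = np.logical_and.accumulate(m, axis=1).sum(axis=0)
    return SaturationCurve(n_values=np.arange(1, N + 1), pan_sizes=pan,
                           core_sizes=core, replicates=replicates)


def fit_closure(curve: SaturationCurve) -> ClosureFit:
    """Fit Heaps'-law decay to mean new-family counts and call open/closed.

    ``delta(n)`` is the increment of the mean pan size from n-1 to n genomes,
    fitted as ``kappa * n**(-alpha)`` by least squares on log-transformed
    values over n = 2..N; zero increments are dropped.  If every increment
    is zero the pangenome is trivially closed (alpha = +inf sentinel).
    """
    N = curve.n_values[-1]
    if N < 4:
        raise InputError("closure fit needs N >= 4 accessions")
    mean_pan = curve.pan_sizes.mean(axis=0)
    delta = np.diff(mean_pan)               # delta(n) for n = 2..N
    ns = curve.n_values[1:].astype(float)
    usable = delta > 0
    if not usable.any():
        return ClosureFit(alpha=math.inf, kappa=0.0, fit_error=0.0,
                          verdict="closed", n_points=0)
    if usable.sum() < 3:
        raise InputError("fewer than 3 usable points for closure fit")
    x = np.log(ns[usable])
    y = np.log(delta[usable])
    (slope, intercept), res = np.polyfit(x, y, 1, full=True)[:2]
    alpha = -slope
    kappa = math.exp(intercept)
    fit_error = float(res[0]) if len(res) else 0.0
    return ClosureFit(alpha=float(alpha), kappa=kappa, fit_error=fit_error,
                      verdict="closed" if alpha > 1 else "open",
                      n_points=int(usable.sum()))


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(alignment: list[str]) -> float:
    """Per-site nucleotide diversity (pi) of an equal-length alignment.

    pi = [2 / (n (n-1))] * sum_{i<j} d_ij / L_ij, where d_ij counts
    mismatching positions and positions carrying a gap or N in either
    sequence are excluded from both d_ij and that pair's effective length.
    """
    n = len(alignment)
    if n < 2:
        raise InputError("pi needs at least 2 sequences")
    L = len(alignment[0])
    if L == 0 or any(len(s) != L for s in alignment):
        raise InputError("sequences must be equal length > 0")
    arr = np.array([list(s.upper()) for s in alignment])
    valid = ~np.isin(arr, ["-", "N"])
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            eff = int(ok.sum())
            if eff == 0:
                raise InputError(
                    f"pair ({i},{j}) has no comparable sites; pi undefined")
            d = int((arr[i][ok] != arr[j][ok]).sum())
            total += d / eff
    return 2.0 * total / (n * (n - 1))


# ---------------------------------------------------------------------------
# PAV distance
# ---------------------------------------------------------------------------

def pav_distance(pav: PavMatrix) -> DistanceMatrix:
    """Jaccard distance 1 - |A&B| / |A|B| between accession family sets."""
    if pav.n_accessions < 2:
        raise InputError("need >=2 accessions for a distance matrix")
    m = pav.presence.astype(np.int64)
    empty = [a for a, c in zip(pav.accessions, m.sum(axis=0)) if c == 0]
    if empty:
        raise InputError(f"accessions with empty family sets: {empty}")
    inter = m.T @ m
    sizes = m.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(pav.accessions))
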