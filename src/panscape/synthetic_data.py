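"""Synthetic genomes, PAV matrices and SV call sets with known ground truth.

Every generator returns, alongside its data product, a
:class:`SimulationManifest` recording the true values (family classes,
centromere spans, SV origins) so that downstream detectors can be tested
by parameter recovery instead of against downloads.  All randomness flows
through one ``numpy`` Generator seeded from an integer; the same seed
reproduces every output bit-identically.

The defaults mirror the study system: 28 accessions in seven species
groups, a class mix of roughly 43% core / 9% softcore / 46% dispensable /
2% private families, five SV types dominated by deletions and insertions,
and (CCCTAAA)n telomeres flanking monomer-array centromeres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterError
from .io_formats import GeneModel, GenomeAnnotationBundle, RepeatFeature
from .svscape import SvRecord

PAV_CLASSES = ("core", "softcore", "dispensable", "private")
SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")

#: Default species composition of the 28-accession panel.
DEFAULT_SPECIES_COUNTS = {
    "C.lanatus": 14, "C.amarus": 5, "C.colocynthis": 4,
    "C.mucosospermus": 2, "C.rehmii": 1, "C.ecirrhosus": 1,
    "C.naudinianus": 1,
}

#: Default family-class mix (core, softcore, dispensable, private).
DEFAULT_CLASS_PROPORTIONS = (0.43, 0.09, 0.46, 0.02)

#: Default SV type mix (DEL, INS, DUP, INV, TRA).
DEFAULT_TYPE_PROPORTIONS = (0.4699, 0.5188, 0.0067, 0.0028, 0.0018)

#: Default ancestor-inheritance mix (ancestorA, ancestorB, both, novel).
DEFAULT_ORIGIN_PROPORTIONS = (33 / 362, 68 / 362, 200 / 362, 61 / 362)

#: Per-type log-normal length parameters (mean of log-bp, sigma).
SV_LENGTH_PARAMS = {
    "DEL": (4.8, 1.2), "INS": (4.8, 1.2), "DUP": (6.7, 1.0),
    "INV": (8.0, 1.0), "TRA": (6.9, 1.0),
}

TELOMERE_MOTIF = "CCCTAAA"
TELOMERE_MOTIF_RC = "TTTAGGG"


@dataclass
class SimulationManifest:
    """Ground truth emitted by every generator."""

    seed: int
    true_family_classes: dict[str, str] = field(default_factory=dict)
    true_centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    true_telomere_ends: dict[str, int] = field(default_factory=dict)
    true_sv_origin: dict[str, str] = field(default_factory=dict)
    generator_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationManifest":
        data = json.loads(text)
        data["true_centromeres"] = {
            k: tuple(v) for k, v in data.get("true_centromeres", {}).items()}
        return cls(**data)


@dataclass(frozen=True)
class AncestryDesign:
    """Names the target group and the two candidate ancestor accessions."""

    target_group: tuple[str, ...]
    ancestor_a: str
    ancestor_b: str
    origin_proportions: tuple[float, float, float, float] = \
        DEFAULT_ORIGIN_PROPORTIONS


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# PAV matrix
# ---------------------------------------------------------------------------

def default_species_map(accessions: list[str]) -> dict[str, str]:
    """Assign accessions to the seven species groups (study-panel mix for
    28 accessions, round-robin over seven groups otherwise)."""
    if len(accessions) == sum(DEFAULT_SPECIES_COUNTS.values()):
        species = [sp for sp, c in DEFAULT_SPECIES_COUNTS.items()
                   for _ in range(c)]
    else:
        names = list(DEFAULT_SPECIES_COUNTS)
        species = [names[i % len(names)] for i in range(len(accessions))]
    return dict(zip(accessions, species))


def simulate_pav(n_accessions: int = 28, species_map: dict | None = None,
                 n_families: int = 20_000,
                 class_proportions: tuple = DEFAULT_CLASS_PROPORTIONS,
                 seed: int = 0, geometric_p: float = 0.3):
    """Draw a PAV matrix with known family classes.

    Families are assigned a class by the stated proportions and then a
    presence pattern that realises the class definition exactly: core rows
    are all-ones, softcore rows lack 1-2 uniformly chosen accessions,
    private rows keep a single accession, and dispensable rows keep k
    accessions with k drawn from a geometric distribution (success
    probability ``geometric_p``) truncated to 2 <= k <= n-3, which yields
    the descending occupancy spectrum typical of dispensable families.
    """
    from .pangenome import PavMatrix

    if n_accessions < 4:
        raise ParameterError("simulate_pav needs n_accessions >= 4")
    if abs(sum(class_proportions) - 1.0) > 1e-9:
        raise ParameterError("class proportions must sum to 1")
    rng = _rng(seed)
    accessions = [f"acc{i + 1:02d}" for i in range(n_accessions)]
    if species_map is None:
        species_map = default_species_map(accessions)
    classes = rng.choice(len(PAV_CLASSES), size=n_families,
                         p=list(class_proportions))
    # truncated geometric pmf over k = 2..n-3
    ks = np.arange(2, n_accessions - 2)
    pmf = geometric_p * (1 - geometric_p) ** (ks - 2)
    pmf /= pmf.sum()

    presence = np.zeros((n_families, n_accessions), dtype=bool)
    families = [f"fam{i + 1:05d}" for i in range(n_families)]
    true = {}
    for i, ci in enumerate(classes):
        cls = PAV_CLASSES[ci]
        true[families[i]] = cls
        if cls == "core":
            presence[i] = True
        elif cls == "softcore":
            presence[i] = True
            n_absent = int(rng.integers(1, 3))
            presence[i, rng.choice(n_accessions, n_absent, replace=False)] = False
        elif cls == "private":
            presence[i, int(rng.integers(n_accessions))] = True
        else:
            k = int(rng.choice(ks, p=pmf))
            presence[i, rng.choice(n_accessions, k, replace=False)] = True

    pav = PavMatrix(families=families, accessions=accessions,
                    presence=presence, species_of=dict(species_map))
    manifest = SimulationManifest(
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        true_family_classes=true,
        generator_params={
            "n_accessions": n_accessions, "n_families": n_families,
            "class_proportions": list(class_proportions),
            "geometric_p": geometric_p})
    return pav, manifest


# ---------------------------------------------------------------------------
# Chromosome with centromere, repeats, genes and telomeres
# ---------------------------------------------------------------------------

def _random_dna(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return codes.tobytes().translate(bytes.maketrans(
        bytes(range(4)), b"ACGT")).decode()


def _mutate(rng, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _place_elements(rng, lo: int, hi: int, target_fraction: float,
                    mean_len: float, sigma: float, min_len: int
                    ) -> list[tuple[int, int]]:
    """Place non-overlapping elements covering ~target_fraction of [lo, hi)."""
    if target_fraction <= 0 or hi - lo < min_len:
        return []
    mean_gap = mean_len * (1 - target_fraction) / target_fraction
    spans = []
    pos = lo + rng.exponential(mean_gap)
    while pos < hi:
        elen = max(min_len, int(rng.lognormal(np.log(mean_len), sigma)))
        end = min(int(pos) + elen, hi)
        if end - int(pos) >= min_len:
            spans.append((int(pos), end))
        pos = end + rng.exponential(mean_gap)
    return spans


def simulate_chromosome(length: int = 400_000,
                        centromere_span: tuple[int, int] | None = None,
                        monomer_length: int = 171,
                        monomer_divergence: float = 0.05,
                        gypsy_enrichment: float = 3.0,
                        gene_density_profile: float = 1 / 15_000,
                        telomere_copies: int = 100,
                        seed: int = 0, chromosome: str = "chr01"):
    """Simulate one chromosome carrying a centromeric tandem array.

    The centromere span is filled with tandem copies of one random monomer,
    each copy independently substituted at per-base rate
    ``monomer_divergence`` (substitutions only, so the true period is
    preserved).  Gypsy-labelled repeat annotations are placed with a
    ``gypsy_enrichment``-fold elevated density inside the centromere;
    genes are placed outside it at ``gene_density_profile`` genes per bp.
    Both ends begin/end with ``telomere_copies`` copies of CCCTAAA and its
    reverse complement respectively.
    """
    rng = _rng(seed)
    if centromere_span is None:
        centromere_span = (int(0.40 * length), int(0.60 * length))
    if not 50 <= monomer_length <= 2000:
        raise ParameterError("monomer_length must be in [50, 2000]")
    cs, ce = centromere_span
    if not 0 <= cs < ce <= length:
        raise ParameterError("centromere_span must lie within the chromosome")
    tel_len = telomere_copies * len(TELOMERE_MOTIF)
    if 2 * tel_len >= length:
        raise ParameterError("telomeres longer than the chromosome")
    if cs < tel_len or ce > length - tel_len:
        raise ParameterError("centromere overlaps a telomere")

    codes = _random_dna(rng, length)
    # telomeres
    motif = np.array(["ACGT".index(c) for c in TELOMERE_MOTIF], dtype=np.uint8)
    motif_rc = np.array(["ACGT".index(c) for c in TELOMERE_MOTIF_RC],
                        dtype=np.uint8)
    codes[:tel_len] = np.tile(motif, telomere_copies)
    codes[length - tel_len:] = np.tile(motif_rc, telomere_copies)
    # centromeric array
    monomer = _random_dna(rng, monomer_length)
    pos = cs
    while pos < ce:
        copy = _mutate(rng, monomer, monomer_divergence)
        n = min(monomer_length, ce - pos)
        codes[pos:pos + n] = copy[:n]
        pos += n

    # repeat annotations
    base_gypsy = 0.15
    inside = min(0.85, base_gypsy * gypsy_enrichment)
    repeats = []
    for lo, hi, frac in ((tel_len, cs, base_gypsy),
                         (cs, ce, inside),
                         (ce, length - tel_len, base_gypsy)):
        for span in _place_elements(rng, lo, hi, frac, 3000, 0.5, 300):
            repeats.append(RepeatFeature(chromosome, span, "LTR/Gypsy"))
    for span in _place_elements(rng, tel_len, length - tel_len, 0.05,
                                2000, 0.5, 300):
        repeats.append(RepeatFeature(chromosome, span, "LTR/Copia"))

    # genes outside the centromere and telomeres
    genes = []
    gid = 0
    for lo, hi in ((tel_len, cs), (ce, length - tel_len)):
        pos = lo + rng.exponential(1 / gene_density_profile)
        while pos < hi:
            glen = int(rng.integers(1_000, 5_000))
            start = int(pos)
            end = min(start + glen, hi)
            if end - start >= 300:
                gid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                n_cds = int(rng.integers(1, 5))
                bounds = np.sort(rng.choice(
                    np.arange(start, end), 2 * n_cds, replace=False))
                cds = [(int(bounds[2 * i]), int(bounds[2 * i + 1]))
                       for i in range(n_cds)
                       if bounds[2 * i + 1] > bounds[2 * i]]
                if strand == "-":
                    cds = cds[::-1]
                genes.append(GeneModel(
                    id=f"{chromosome}_g{gid:04d}", chromosome=chromosome,
                    span=(start, end), strand=strand, cds_parts=tuple(cds)))
            pos = end + rng.exponential(1 / gene_density_profile)

    sequence = _to_str(codes)
    bundle = GenomeAnnotationBundle(
        assembly={chromosome: sequence}, genes=genes, repeats=repeats
    ).validate()
    manifest = SimulationManifest(
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        true_centromeres={chromosome: (cs, ce)},
        true_telomere_ends={chromosome: 2},
        generator_params={
            "length": length, "monomer_length": monomer_length,
            "monomer_divergence": monomer_divergence,
            "gypsy_enrichment": gypsy_enrichment,
            "telomere_copies": telomere_copies,
            "monomer": _to_str(monomer)})
    return sequence, bundle, manifest


def simulate_genome(n_chromosomes: int = 11, seed: int = 0,
                    **chromosome_kwargs):
    """Simulate a multi-chromosome genome (watermelon has 11 chromosomes).

    Each chromosome uses an independent substream spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chromosomes)
    assembly, genes, repeats = {}, [], []
    manifest = SimulationManifest(seed=int(seed))
    for i, child in enumerate(children):
        name = f"chr{i + 1:02d}"
        _, bundle, sub = simulate_chromosome(
            seed=np.random.default_rng(child), chromosome=name,
            **chromosome_kwargs)
        assembly.update(bundle.assembly)
        genes.extend(bundle.genes)
        repeats.extend(bundle.repeats)
        manifest.true_centromeres.update(sub.true_centromeres)
        manifest.true_telomere_ends.update(sub.true_telomere_ends)
        manifest.generator_params[name] = sub.generator_params
    bundle = GenomeAnnotationBundle(assembly=assembly, genes=genes,
                                    repeats=repeats).validate()
    return bundle, manifest


# ---------------------------------------------------------------------------
# SV landscape
# ---------------------------------------------------------------------------

def _merged_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class _PositionSampler:
    """Sample SV midpoints with odds multiplied inside repeat regions."""

    def __init__(self, bundle: GenomeAnnotationBundle, factor: float):
        self.chroms = sorted(bundle.assembly)
        self.rep = {}
        self.nonrep = {}
        weights = []
        for c in self.chroms:
            L = len(bundle.assembly[c])
            rep = _merged_intervals(
                [r.span for r in bundle.repeats if r.chromosome == c])
            nonrep, pos = [], 0
            for s, e in rep + [(L, L)]:
                if s > pos:
                    nonrep.append((pos, s))
                pos = max(pos, e)
            self.rep[c] = rep
            self.nonrep[c] = nonrep
            rep_bp = sum(e - s for s, e in rep)
            weights.append((L - rep_bp) + factor * rep_bp)
        self.factor = factor
        self.weights = np.array(weights) / sum(weights)

    def draw(self, rng) -> tuple[str, int]:
        c = self.chroms[int(rng.choice(len(self.chroms), p=self.weights))]
        rep_bp = sum(e - s for s, e in self.rep[c])
        nonrep_bp = sum(e - s for s, e in self.nonrep[c])
        p_rep = self.factor * rep_bp / (self.factor * rep_bp + nonrep_bp)
        pool = self.rep[c] if rng.random() < p_rep else self.nonrep[c]
        lens = np.array([e - s for s, e in pool], dtype=float)
        i = int(rng.choice(len(pool), p=lens / lens.sum()))
        s, e = pool[i]
        return c, int(rng.integers(s, e))


def simulate_sv_landscape(accessions: list[str],
                          ancestry_design: AncestryDesign,
                          n_svs: int = 2_000,
                          type_proportions: tuple = DEFAULT_TYPE_PROPORTIONS,
                          repeat_enrichment_factor: float = 1.0,
                          annotation_bundle: GenomeAnnotationBundle = None,
                          seed: int = 0):
    """Simulate per-accession SV call sets with a two-ancestor structure.

    Each of ``n_svs`` ground-truth SVs receives a type (five categories),
    a length (per-type log-normal, floored at 21 bp), a midpoint whose odds
    of falling in a repeat region are multiplied by
    ``repeat_enrichment_factor``, and an inheritance origin: present in
    every target-group accession, and in ancestor A / B / both / neither
    per the origin proportions.  Per-accession records are jittered within
    the standard merge tolerance so that cross-accession merging is
    non-trivially exercised.
    """
    if abs(sum(type_proportions) - 1.0) > 1e-9:
        raise ParameterError("type proportions must sum to 1")
    if abs(sum(ancestry_design.origin_proportions) - 1.0) > 1e-9:
        raise ParameterError("origin proportions must sum to 1")
    if annotation_bundle is None:
        raise ParameterError("an annotation bundle is required")
    if repeat_enrichment_factor != 1.0 and not annotation_bundle.repeats:
        raise ParameterError(
            "repeat enrichment != 1 requires repeat features in the bundle")
    named = set(ancestry_design.target_group) | \
        {ancestry_design.ancestor_a, ancestry_design.ancestor_b}
    if not named <= set(accessions):
        raise ParameterError("ancestry design names unknown accessions")

    rng = _rng(seed)
    sampler = _PositionSampler(annotation_bundle, repeat_enrichment_factor)
    chrom_len = annotation_bundle.chromosome_lengths()
    origins = ("ancestorA", "ancestorB", "both", "novel")
    calls: dict[str, list[SvRecord]] = {a: [] for a in accessions}
    manifest = SimulationManifest(
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        generator_params={
            "n_svs": n_svs, "type_proportions": list(type_proportions),
            "repeat_enrichment_factor": repeat_enrichment_factor,
            "origin_proportions": list(ancestry_design.origin_proportions)})

    for i in range(n_svs):
        svtype = SV_TYPES[int(rng.choice(5, p=list(type_proportions)))]
        mu, sigma = SV_LENGTH_PARAMS[svtype]
        length = 0
        while length <= 20:
            length = int(rng.lognormal(mu, sigma))
        chrom, mid = sampler.draw(rng)
        L = chrom_len[chrom]
        if svtype == "INS":
            anchor = min(max(mid, 0), L)
            span = (anchor, anchor)
        else:
            s = max(0, mid - length // 2)
            e = min(L, s + length)
            s = max(0, e - length)
            span = (s, e)
        origin = origins[int(rng.choice(
            4, p=list(ancestry_design.origin_proportions)))]
        sv_id = f"sv{i + 1:06d}"
        manifest.true_sv_origin[sv_id] = origin

        carriers = list(ancestry_design.target_group)
        if origin in ("ancestorA", "both"):
            carriers.append(ancestry_design.ancestor_a)
        if origin in ("ancestorB", "both"):
            carriers.append(ancestry_design.ancestor_b)
        jmax = max(1, length // 10)
        for acc in carriers:
            if svtype == "INS":
                a = int(np.clip(span[0] + rng.integers(-25, 26), 0, L))
                jspan = (a, a)
                seq = _to_str(_random_dna(rng, min(length, 500)))
                rec = SvRecord(accession=acc, chromosome=chrom, span=jspan,
                               type="INS", length=length, inserted_seq=seq)
            else:
                delta = int(rng.integers(-jmax, jmax + 1))
                s = int(np.clip(span[0] + delta, 0, L - length))
                rec = SvRecord(accession=acc, chromosome=chrom,
                               span=(s, s + length), type=svtype,
                               length=length)
            calls[acc].append(rec)

    for acc in calls:
        calls[acc].sort(key=lambda r: (r.chromosome, r.span[0], r.type))
    return calls, manifest
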