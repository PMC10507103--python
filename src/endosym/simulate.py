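"""Synthetic-data generators with known truth for every pipeline stage.

Every generator is a pure function of its parameters and a seed: the same
call produces byte-identical output.  Each generator also returns a
:class:`Truth` record so downstream modules can be scored against a known
answer without any external data.

Sequence model: order-3 Markov chains over {A,C,G,T}, parameterized by a
target GC fraction plus a seeded random perturbation of each conditional
distribution.  This is the minimal model that gives two sources distinct
tetranucleotide signatures while controlling GC.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import dendropy
import numpy as np

from .model import AnnotationSet, Association, Contig, GeneRecord, HitRecord, HitTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])

DEFAULT_HOST_GC = 0.48
DEFAULT_SYMBIONT_GC = 0.25
DEFAULT_HOST_COV = 60.0
DEFAULT_SYMBIONT_COV = 300.0

ANNOTATED_PRODUCT_POOL = [
    "DNA polymerase III subunit alpha",
    "elongation factor Tu",
    "50S ribosomal protein L2",
    "30S ribosomal protein S12",
    "ABC transporter ATP-binding protein",
    "chaperone protein DnaK",
    "preprotein translocase subunit SecY",
    "DNA gyrase subunit A",
    "cell division protein FtsZ",
    "ATP synthase subunit beta",
]

DEFAULT_TAXA_POOL = {
    "fungal": [
        ("Linnemannia_elongata", ["Fungi", "Mucoromycota", "Mortierellomycotina"]),
        ("Benniella_erionia", ["Fungi", "Mucoromycota", "Mortierellomycotina"]),
        ("Rhizopus_oryzae", ["Fungi", "Mucoromycota", "Mucoromycotina"]),
        ("Basidiobolus_meristosporus", ["Fungi", "Zoopagomycota"]),
    ],
    "glomeromycotina": [
        ("Rhizophagus_irregularis", ["Fungi", "Mucoromycota", "Glomeromycotina"]),
        ("Gigaspora_margarita", ["Fungi", "Mucoromycota", "Glomeromycotina"]),
        ("Diversispora_epigaea", ["Fungi", "Mucoromycota", "Glomeromycotina"]),
    ],
    "bacterial": [
        ("Mycoplasma_pneumoniae", ["Bacteria", "Mycoplasmatota", "Mollicutes"]),
        ("Spiroplasma_citri", ["Bacteria", "Mycoplasmatota", "Mollicutes"]),
        ("Bacillus_subtilis", ["Bacteria", "Bacillota", "Bacilli"]),
        ("Escherichia_coli", ["Bacteria", "Pseudomonadota", "Gammaproteobacteria"]),
    ],
}


# ---------------------------------------------------------------------------
# Composition sources and genome generation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompositionSource:
    """An order-3 Markov sequence source with a target GC fraction.

    ``markov`` has shape (64, 4): row = base-4 code of the previous 3-mer,
    columns = P(next base | previous 3-mer); each row sums to 1.
    """

    gc: float
    markov: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.markov = np.asarray(self.markov, dtype=float)
        if self.markov.shape != (64, 4):
            raise ValueError("markov table must have shape (64, 4)")
        if np.any(self.markov < 0) or np.any(self.markov > 1):
            raise ValueError("markov probabilities must be in [0, 1]")
        if not np.allclose(self.markov.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each markov row must sum to 1")

    @classmethod
    def from_gc(cls, gc: float, label: str, seed: int = 0,
                perturbation: float = 0.15) -> "CompositionSource":
        """Build a source whose stationary GC is close to ``gc``.

        Each conditional distribution is the GC-matched base distribution
        times a seeded lognormal perturbation of the given magnitude, then
        renormalized with the AT/GC mass re-pinned to the target.
        """
        rng = np.random.default_rng(seed)
        base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        rows = base * np.exp(perturbation * rng.standard_normal((64, 4)))
        # re-pin AT vs GC mass per row so realized GC tracks the target
        at = rows[:, [0, 3]].sum(axis=1, keepdims=True)
        gcm = rows[:, [1, 2]].sum(axis=1, keepdims=True)
        rows[:, [0, 3]] *= (1 - gc) / at
        rows[:, [1, 2]] *= gc / gcm
        rows /= rows.sum(axis=1, keepdims=True)
        return cls(gc=gc, markov=rows, label=label)


def gen_genome(source: CompositionSource, length: int, seed: int,
               contig_id: str = "genome") -> Contig:
    """Sample one contig of the given length from the source."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    cumulative = np.cumsum(source.markov, axis=1)
    cumulative[:, -1] = 1.0
    base_probs = np.array([(1 - source.gc) / 2, source.gc / 2,
                           source.gc / 2, (1 - source.gc) / 2])
    out = np.empty(length, dtype=np.int64)
    out[:3] = rng.choice(4, size=3, p=base_probs)
    u = rng.random(length)
    state = out[0] * 16 + out[1] * 4 + out[2]
    for i in range(3, length):
        nxt = int(np.searchsorted(cumulative[state], u[i], side="right"))
        out[i] = nxt
        state = (state * 4 + nxt) % 64
    return Contig(id=contig_id, seq=_BASES[out].tobytes().decode())


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    base_idx = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        base_idx[ord(b)] = i
    idx = base_idx[arr]
    hit = (rng.random(arr.size) < rate) & (idx >= 0)
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    idx[hit] = (idx[hit] + shifts) % 4
    arr[idx >= 0] = _BASES[idx[idx >= 0]]
    return arr.tobytes().decode()


def revcomp_seq(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Truth:
    """Ground-truth labels emitted alongside generated data."""

    contig_labels: dict[str, str] = dataclasses.field(default_factory=dict)
    read_origin: dict[str, str] = dataclasses.field(default_factory=dict)
    hgt_genes: set[str] = dataclasses.field(default_factory=set)
    excluded_genes: set[str] = dataclasses.field(default_factory=set)
    feature_intervals: list[tuple[str, int, int, str]] = dataclasses.field(default_factory=list)
    blocks: list[tuple[int, int, int, int, str]] = dataclasses.field(default_factory=list)
    duplicated_blocks: list[tuple[int, int, int, int, str]] = dataclasses.field(default_factory=list)
    congruent: Optional[bool] = None


# ---------------------------------------------------------------------------
# Metagenome and reads
# ---------------------------------------------------------------------------

def gen_metagenome(n_host: int = 40, n_symb: int = 8,
                   len_mean_host: int = 30_000, len_mean_symb: int = 40_000,
                   host_source: Optional[CompositionSource] = None,
                   symb_source: Optional[CompositionSource] = None,
                   cov_host: float = DEFAULT_HOST_COV,
                   cov_symb: float = DEFAULT_SYMBIONT_COV,
                   seed: int = 0) -> tuple[list[Contig], dict[str, float], Truth]:
    """Generate a mixed host/symbiont assembly with depths and truth labels.

    Contig lengths are lognormal around the class mean; depths are lognormal
    around the class coverage with ~10% spread.
    """
    if n_host == 0 and n_symb == 0:
        raise ValueError("need at least one contig")
    if cov_host <= 0 or cov_symb <= 0:
        raise ValueError("coverages must be > 0")
    rng = np.random.default_rng(seed)
    if host_source is None:
        host_source = CompositionSource.from_gc(DEFAULT_HOST_GC, "host", seed=1)
    if symb_source is None:
        symb_source = CompositionSource.from_gc(DEFAULT_SYMBIONT_GC, "symbiont", seed=2)

    contigs: list[Contig] = []
    depths: dict[str, float] = {}
    truth = Truth()
    plan = [("host", i) for i in range(n_host)] + [("symb", i) for i in range(n_symb)]
    for label, i in plan:
        source = host_source if label == "host" else symb_source
        cov = cov_host if label == "host" else cov_symb
        len_mean = len_mean_host if label == "host" else len_mean_symb
        length = max(1000, int(len_mean * rng.lognormal(0, 0.25)))
        cid = f"{label}_{i:04d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        contig = gen_genome(source, length, sub_seed, contig_id=cid)
        depth = float(cov * rng.lognormal(0, 0.0975))
        contig.depth = depth
        contig.truth = "host" if label == "host" else "symbiont"
        contigs.append(contig)
        depths[cid] = depth
        truth.contig_labels[cid] = contig.truth
    return contigs, depths, truth


def gen_reads(contigs: Sequence[Contig], depths: dict[str, float],
              read_len: int = 100, error_rate: float = 0.0, seed: int = 0,
              k: int = 31) -> tuple[list[Contig], Truth]:
    """Simulate single-end substitution-only reads at each contig's depth.

    Per-contig read count is ``round(depth * contig_len / read_len)``.
    """
    if read_len < k:
        raise ValueError(f"read_len {read_len} < k {k}")
    rng = np.random.default_rng(seed)
    reads: list[Contig] = []
    truth = Truth()
    for contig in contigs:
        depth = depths.get(contig.id, contig.depth or 0.0)
        n_reads = int(round(depth * len(contig.seq) / read_len))
        if len(contig.seq) < read_len:
            continue
        starts = rng.integers(0, len(contig.seq) - read_len + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for j, (start, minus) in enumerate(zip(starts, strands)):
            frag = contig.seq[start : start + read_len]
            if minus:
                frag = revcomp_seq(frag)
            frag = _mutate(frag, error_rate, rng)
            rid = f"{contig.id}_read_{j:06d}"
            reads.append(Contig(id=rid, seq=frag))
            truth.read_origin[rid] = contig.id
    return reads, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def gen_annotation(genome: Contig, gene_density: float = 0.75,
                   pseudo_frac: float = 0.03, repeat_frac: float = 0.04,
                   phage_frac: float = 0.0, hyp_frac: float = 0.5,
                   annotated_length_ratio: float = 1.5,
                   seed: int = 0,
                   genome_id: Optional[str] = None) -> tuple[AnnotationSet, Truth]:
    """Generate a gene annotation with controlled per-class genome fractions.

    Feature lengths per class are drawn, then the last feature is clipped so
    per-class totals hit their bp targets exactly; features are shuffled and
    separated by multinomially distributed gaps, so realized fractions match
    requests to rounding accuracy.  ``hyp_frac`` of CDS get the product
    "hypothetical protein"; the rest draw real product names and are longer
    on average by ``annotated_length_ratio``.
    """
    for name, frac in [("gene_density", gene_density), ("pseudo_frac", pseudo_frac),
                       ("repeat_frac", repeat_frac), ("phage_frac", phage_frac),
                       ("hyp_frac", hyp_frac)]:
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    total_frac = gene_density + pseudo_frac + repeat_frac + phage_frac
    if total_frac > 0.9:
        raise ValueError(
            f"interval class fractions sum to {total_frac:.3f} > 0.9: infeasible packing"
        )
    rng = np.random.default_rng(seed)
    L = len(genome.seq)

    def draw_lengths(target_bp: int, mean_len: float, min_len: int = 60) -> list[int]:
        lengths: list[int] = []
        total = 0
        while total < target_bp:
            length = max(min_len, int(rng.lognormal(np.log(mean_len), 0.35)))
            length = min(length, target_bp - total) if target_bp - total < length else length
            lengths.append(length)
            total += length
        if lengths and total > target_bp:
            lengths[-1] -= total - target_bp
            if lengths[-1] < 1:
                lengths.pop()
        return lengths

    # CDS: split the coding budget between hypothetical and annotated genes so
    # that counts follow hyp_frac and annotated genes are longer on average.
    cds_target = int(round(gene_density * L))
    hyp_mean = 600.0
    ann_mean = hyp_mean * annotated_length_ratio
    mean_len = hyp_frac * hyp_mean + (1 - hyp_frac) * ann_mean
    features: list[tuple[str, int, Optional[str]]] = []  # (class, length, product)
    total = 0
    while total < cds_target:
        hypothetical = rng.random() < hyp_frac
        mean = hyp_mean if hypothetical else ann_mean
        length = max(90, int(rng.lognormal(np.log(mean), 0.30)))
        length = 3 * (length // 3)
        if cds_target - total < 90:
            break
        length = min(length, 3 * ((cds_target - total) // 3))
        if length < 90:
            break
        product = ("hypothetical protein" if hypothetical
                   else ANNOTATED_PRODUCT_POOL[int(rng.integers(len(ANNOTATED_PRODUCT_POOL)))])
        features.append(("CDS", length, product))
        total += length
    for cls, frac, mean in [("pseudogene", pseudo_frac, 450.0),
                            ("repeat", repeat_frac, 300.0),
                            ("phage", phage_frac, 2500.0)]:
        for length in draw_lengths(int(round(frac * L)), mean):
            features.append((cls, length, None))

    order = rng.permutation(len(features))
    features = [features[i] for i in order]
    feature_bp = sum(f[1] for f in features)
    gap_bp = L - feature_bp
    if gap_bp < 0:
        raise ValueError("infeasible packing: features exceed genome length")
    gaps = rng.multinomial(gap_bp, np.ones(len(features) + 1) / (len(features) + 1))

    records: list[GeneRecord] = []
    truth = Truth()
    pos = 0
    for i, (cls, length, product) in enumerate(features):
        pos += int(gaps[i])
        start, end = pos, pos + length
        gene_id = f"{genome.id}_g{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "CDS":
            records.append(GeneRecord(gene_id, genome.id, start, end, strand,
                                      "CDS", product or "hypothetical protein",
                                      protein_length=max(1, length // 3 - 1)))
        else:
            records.append(GeneRecord(gene_id, genome.id, start, end, strand, cls,
                                      product=cls))
        truth.feature_intervals.append((genome.id, start, end, cls))
        pos = end
    annotation = AnnotationSet(
        genome_id=genome_id or genome.id,
        records=records,
        genome_length=L,
        contig_lengths={genome.id: L},
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# HGT hit tables
# ---------------------------------------------------------------------------

def gen_hgt_hit_table(annotation: AnnotationSet, n_hgt: int,
                      taxa_pool: Optional[dict] = None, seed: int = 0,
                      glom_only_frac: float = 0.05) -> tuple[HitTable, Truth]:
    """Plant ``n_hgt`` HGT-positive genes among the CDS of an annotation.

    Truth-positive queries receive fungal:bacterial valid-hit counts with a
    ratio margin of at least one hit over the 2x rule; negatives receive
    bacterial-majority hits.  ``glom_only_frac`` of negatives instead get
    ratio-passing fungal hits exclusively from Glomeromycotina (truth label:
    excluded).  A few filter-failing decoy hits are added to every query.
    """
    if taxa_pool is None:
        taxa_pool = DEFAULT_TAXA_POOL
    if not taxa_pool or not taxa_pool.get("fungal") or not taxa_pool.get("bacterial"):
        raise ValueError("taxa_pool must provide fungal and bacterial taxa")
    cds = annotation.cds()
    if n_hgt > len(cds):
        raise ValueError(f"n_hgt {n_hgt} exceeds CDS count {len(cds)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cds))
    hgt_idx = set(order[:n_hgt].tolist())
    remaining = [i for i in order[n_hgt:].tolist()]
    n_glom = int(round(glom_only_frac * len(remaining)))
    glom_idx = set(remaining[:n_glom])

    truth = Truth()
    hits: list[HitRecord] = []

    def emit(query: GeneRecord, kingdom: str, taxon: tuple[str, list[str]],
             valid: bool = True) -> None:
        qlen = query.protein_length or 100
        if valid:
            evalue = 10.0 ** float(rng.uniform(-50, -8))
            qcov = float(rng.uniform(0.6, 1.0))
        else:
            fail_on_e = rng.random() < 0.5
            evalue = 10.0 ** float(rng.uniform(-4, -1)) if fail_on_e else 10.0 ** float(rng.uniform(-50, -8))
            qcov = float(rng.uniform(0.6, 1.0)) if fail_on_e else float(rng.uniform(0.05, 0.45))
        aln_len = max(1, int(round(qcov * qlen)))
        hits.append(HitRecord(
            query_id=query.gene_id,
            subject_id=f"{taxon[0]}_p{int(rng.integers(1, 99999)):05d}",
            subject_kingdom=kingdom,
            subject_lineage=list(taxon[1]),
            evalue=evalue,
            qcov=aln_len / qlen if qlen else 1.0,
            pct_identity=float(rng.uniform(30, 95)),
            aln_len=aln_len,
        ))

    fungal_pool = taxa_pool["fungal"]
    glom_pool = taxa_pool.get("glomeromycotina", fungal_pool)
    bact_pool = taxa_pool["bacterial"]

    for i, gene in enumerate(cds):
        if i in hgt_idx:
            n_b = int(rng.integers(0, 4))
            if n_b == 0:
                n_f = int(rng.integers(3, 8))
            else:
                n_f = 2 * n_b + 1 + int(rng.integers(0, 4))
            # fungal hits from the non-Glomeromycotina pool (at least one)
            for _ in range(n_f):
                emit(gene, "fungal", fungal_pool[int(rng.integers(len(fungal_pool)))])
            for _ in range(n_b):
                emit(gene, "bacterial", bact_pool[int(rng.integers(len(bact_pool)))])
            truth.hgt_genes.add(gene.gene_id)
        elif i in glom_idx:
            n_b = int(rng.integers(0, 2))
            n_f = max(3, 2 * n_b + 1 + int(rng.integers(0, 3)))
            for _ in range(n_f):
                emit(gene, "fungal", glom_pool[int(rng.integers(len(glom_pool)))])
            for _ in range(n_b):
                emit(gene, "bacterial", bact_pool[int(rng.integers(len(bact_pool)))])
            truth.excluded_genes.add(gene.gene_id)
        else:
            n_b = int(rng.integers(2, 9))
            n_f = int(rng.integers(0, max(1, n_b // 2)))  # <= 2x with margin
            for _ in range(n_b):
                emit(gene, "bacterial", bact_pool[int(rng.integers(len(bact_pool)))])
            for _ in range(n_f):
                emit(gene, "fungal", fungal_pool[int(rng.integers(len(fungal_pool)))])
        # decoy hits that must fail validity filters
        for _ in range(int(rng.integers(0, 3))):
            emit(gene, "fungal", fungal_pool[int(rng.integers(len(fungal_pool)))],
                 valid=False)
    return HitTable(hits), truth


# ---------------------------------------------------------------------------
# Rearranged genome pairs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RearrangementOp:
    """One rearrangement applied to the ancestor to derive genome B.

    Intervals are in ancestor coordinates and must be pairwise disjoint;
    ``destination`` (a point, also in ancestor coordinates and outside all
    op intervals) is required for translocation and duplication.
    """

    kind: str  # {inversion, translocation, deletion, duplication}
    start: int
    end: int
    destination: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation", "deletion", "duplication"):
            raise ValueError(f"unknown op kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("bad op interval")
        if self.kind in ("translocation", "duplication") and self.destination is None:
            raise ValueError(f"{self.kind} requires a destination")


def _random_ops(length: int, n_inv: int, n_trans: int,
                rng: np.random.Generator) -> list[RearrangementOp]:
    """Sample disjoint op intervals covering 4-10% of the genome each."""
    ops: list[RearrangementOp] = []
    taken: list[tuple[int, int]] = []

    def free(start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in taken)

    kinds = ["inversion"] * n_inv + ["translocation"] * n_trans
    for kind in kinds:
        for _ in range(200):
            size = int(length * rng.uniform(0.04, 0.10))
            start = int(rng.integers(0, length - size))
            if not free(start, start + size):
                continue
            dest = None
            if kind == "translocation":
                for _ in range(200):
                    cand = int(rng.integers(0, length))
                    if free(cand, cand + 1) and not (start <= cand <= start + size):
                        dest = cand
                        break
                if dest is None:
                    continue
            taken.append((start, start + size))
            ops.append(RearrangementOp(kind, start, start + size, dest))
            break
        else:
            raise ValueError("could not place disjoint rearrangement ops")
    return ops


def gen_synteny_pair(ancestor_len: int = 300_000,
                     ops: Optional[Sequence[RearrangementOp]] = None,
                     n_inv: int = 0, n_trans: int = 0,
                     mut_rate: float = 0.0, seed: int = 0,
                     source: Optional[CompositionSource] = None,
                     ) -> tuple[Contig, Contig, list[tuple[int, int, int, int, str]], Truth]:
    """Generate (A, B, true blocks): B is A with rearrangements + mutations.

    True blocks are maximal runs unbroken by any op, reported as
    ``(a_start, a_end, b_start, b_end, strand)`` with adjacent same-strand
    collinear segments merged.  Duplication copies are reported separately
    in ``truth.duplicated_blocks`` (they break the 1:1 property).
    """
    rng = np.random.default_rng(seed)
    if source is None:
        source = CompositionSource.from_gc(DEFAULT_SYMBIONT_GC, "symbiont", seed=2)
    ancestor = gen_genome(source, ancestor_len, int(rng.integers(0, 2**31 - 1)),
                          contig_id="genomeA")
    if ops is None:
        ops = _random_ops(ancestor_len, n_inv, n_trans, rng)
    ops = list(ops)
    intervals = sorted((op.start, op.end) for op in ops)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("overlapping rearrangement ops")
    for op in ops:
        if op.end > ancestor_len:
            raise ValueError("op interval outside genome bounds")
        if op.destination is not None:
            if any(o.start < op.destination < o.end for o in ops):
                raise ValueError("op destination inside another op interval")

    # segment the ancestor at every op boundary and destination
    cuts = {0, ancestor_len}
    for op in ops:
        cuts.update((op.start, op.end))
        if op.destination is not None:
            cuts.add(op.destination)
    bounds = sorted(cuts)
    segments = [[s, e, "+"] for s, e in zip(bounds, bounds[1:])]  # B order, A coords
    duplicated: list[list[int]] = []

    def span(start: int, end: int) -> tuple[int, int]:
        idx = [i for i, (s, e, _) in enumerate(segments) if s >= start and e <= end]
        if not idx or idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError("op interval no longer contiguous in B")
        return idx[0], idx[-1] + 1

    for op in ops:
        lo, hi = span(op.start, op.end)
        if op.kind == "inversion":
            block = segments[lo:hi][::-1]
            segments[lo:hi] = [[s, e, "-" if st == "+" else "+"] for s, e, st in block]
        elif op.kind == "deletion":
            del segments[lo:hi]
        elif op.kind in ("translocation", "duplication"):
            block = [list(seg) for seg in segments[lo:hi]]
            if op.kind == "translocation":
                del segments[lo:hi]
            dest_idx = None
            for i, (s, e, _) in enumerate(segments):
                if s == op.destination:
                    dest_idx = i
                    break
            if dest_idx is None:
                dest_idx = len(segments)
            if op.kind == "duplication":
                duplicated.extend(block)
            segments[dest_idx:dest_idx] = block

    # build B sequence and block list
    parts: list[str] = []
    blocks: list[tuple[int, int, int, int, str]] = []
    b_pos = 0
    dup_set = {tuple(seg) for seg in duplicated}
    dup_seen: set[tuple] = set()
    raw: list[tuple[int, int, int, int, str, bool]] = []
    for s, e, strand in segments:
        seq = ancestor.seq[s:e]
        if strand == "-":
            seq = revcomp_seq(seq)
        parts.append(seq)
        key = (s, e, strand)
        is_dup_copy = key in dup_set and key in dup_seen
        if key in dup_set:
            dup_seen.add(key)
        raw.append((s, e, b_pos, b_pos + (e - s), strand, is_dup_copy))
        b_pos += e - s

    merged: list[list] = []
    for s, e, bs, be, strand, is_dup in raw:
        if merged and not is_dup:
            ps, pe, pbs, pbe, pst, pdup = merged[-1]
            if not pdup and pst == strand and pbe == bs:
                if strand == "+" and pe == s:
                    merged[-1] = [ps, e, pbs, be, strand, False]
                    continue
                if strand == "-" and ps == e:
                    merged[-1] = [s, pe, pbs, be, strand, False]
                    continue
        merged.append([s, e, bs, be, strand, is_dup])

    truth = Truth()
    for s, e, bs, be, strand, is_dup in merged:
        entry = (s, e, bs, be, strand)
        if is_dup:
            truth.duplicated_blocks.append(entry)
        else:
            truth.blocks.append(entry)
    genome_b = Contig(id="genomeB", seq=_mutate("".join(parts), mut_rate, rng))
    return ancestor, genome_b, list(truth.blocks), truth


# ---------------------------------------------------------------------------
# Tree pairs
# ---------------------------------------------------------------------------

def _random_tree(labels: Sequence[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random binary topology via sequential random joins, exp branch lengths."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.edge.length = float(rng.exponential(0.1))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(0.1))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    return tree


def gen_tree_pair(n: int, congruent: bool = True, n_swaps: int = 0,
                  seed: int = 0) -> tuple[dendropy.Tree, dendropy.Tree, Association, Truth]:
    """Generate a host tree and a symbiont tree with a leaf association.

    Congruent pairs have identical topology up to relabeling (RF = 0);
    incongruent pairs apply ``n_swaps`` random leaf-pair exchanges to the
    symbiont tree.
    """
    if n < 4:
        raise ValueError("need n >= 4 leaves")
    if congruent and n_swaps > 0:
        raise ValueError("n_swaps > 0 contradicts congruent=True")
    rng = np.random.default_rng(seed)
    hosts = [f"H{i + 1:02d}" for i in range(n)]
    host_tree = _random_tree(hosts, rng)

    mapping = {h: f"S{i + 1:02d}" for i, h in enumerate(hosts)}
    newick = host_tree.as_string(schema="newick", suppress_rooting=True)
    symb_tree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
    for leaf in symb_tree.leaf_node_iter():
        leaf.taxon = dendropy.Taxon(mapping[leaf.taxon.label])
    if not congruent:
        symb_labels = [mapping[h] for h in hosts]
        for _ in range(n_swaps):
            i, j = rng.choice(n, size=2, replace=False).tolist()
            a, b = symb_labels[i], symb_labels[j]
            for leaf in symb_tree.leaf_node_iter():
                if leaf.taxon.label == a:
                    leaf.taxon.label = "__tmp__"
            for leaf in symb_tree.leaf_node_iter():
                if leaf.taxon.label == b:
                    leaf.taxon.label = a
            for leaf in symb_tree.leaf_node_iter():
                if leaf.taxon.label == "__tmp__":
                    leaf.taxon.label = b
    symb_tree.taxon_namespace = dendropy.TaxonNamespace(
        [leaf.taxon for leaf in symb_tree.leaf_node_iter()]
    )
    assoc = Association([(h, mapping[h]) for h in hosts])
    truth = Truth(congruent=congruent)
    return host_tree, symb_tree, assoc, truth
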