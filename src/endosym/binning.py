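"""Endosymbiont contig binning and k-mer read recruitment.

Separates symbiont contigs from a host metagenome assembly by clustering a
standardized feature matrix of [GC, log10(depth+1), top tetranucleotide
principal components], with optional per-contig taxonomy calls overriding
the clustering.  Read recruitment matches exact canonical 31-mers against a
target k-mer set and recruits a read when at least a minimum fraction of its
k-mers are found, mirroring bbduk's ``k=31 mm=f mkf=0.05`` behaviour.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .config import DEFAULT_CONFIG, Config
from .model import Contig

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> Optional[float]:
    """(G+C) / (A+C+G+T); N is excluded from the denominator.

    Returns None (with a warning) for sequences without any unambiguous base.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        logger.warning("gc_content: sequence has no unambiguous bases")
        return None
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# Canonical tetranucleotide profiles
# ---------------------------------------------------------------------------

def _canonical_kmer_index(k: int) -> dict[str, int]:
    """Map every k-mer over ACGT to a canonical slot (k-mer pooled with its
    reverse complement).  For k=4 this yields 136 slots."""
    index: dict[str, int] = {}
    slots = 0
    for kmer_tuple in itertools.product("ACGT", repeat=k):
        kmer = "".join(kmer_tuple)
        rc = revcomp(kmer)
        canon = min(kmer, rc)
        if canon not in index:
            index[canon] = slots
            slots += 1
        index[kmer] = index[canon]
    return index

_TETRA_INDEX = _canonical_kmer_index(4)
N_TETRA_SLOTS = len(set(_TETRA_INDEX.values()))  # 136

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_CANON_SLOT_BY_CODE = np.empty(256, dtype=np.int64)
for _kmer, _slot in _TETRA_INDEX.items():
    _code = 0
    for _ch in _kmer:
        _code = _code * 4 + int(_BASE_CODE[ord(_ch)])
    _CANON_SLOT_BY_CODE[_code] = _slot


def tetra_freqs(seq: str) -> Optional[np.ndarray]:
    """Canonical tetranucleotide frequency vector (136 entries, sums to 1).

    Every 4-base window free of N is counted, pooled with its reverse
    complement.  Returns None when no valid window exists.
    """
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4")
    codes = _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    valid = codes >= 0
    # window code via base-4 positional encoding; windows containing N dropped
    w = (
        codes[:-3] * 64
        + codes[1:-2] * 16
        + codes[2:-1] * 4
        + codes[3:]
    )
    ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    w = w[ok]
    if w.size == 0:
        return None
    counts = np.bincount(_CANON_SLOT_BY_CODE[w], minlength=N_TETRA_SLOTS).astype(float)
    return counts / counts.sum()


@dataclasses.dataclass
class CompositionProfile:
    contig_id: str
    gc: float
    log_depth: float
    tetra: np.ndarray


@dataclasses.dataclass
class BinAssignment:
    contig_id: str
    bin: str  # {host, symbiont, ambiguous}
    score: float  # margin between distances to the two cluster centroids
    evidence: str  # {taxonomy, composition, coverage} (comma-joined)
    gc: float = float("nan")
    depth: float = float("nan")
    pc1: float = float("nan")
    pc2: float = float("nan")


def build_profiles(contigs: Sequence[Contig],
                   depths: Optional[dict[str, float]] = None) -> list[CompositionProfile]:
    profiles = []
    for contig in contigs:
        gc = gc_content(contig.seq)
        tetra = tetra_freqs(contig.seq) if len(contig.seq) >= 4 else None
        if gc is None or tetra is None:
            logger.warning("skipping contig %s: no unambiguous composition", contig.id)
            continue
        depth = contig.depth
        if depths is not None and contig.id in depths:
            depth = depths[contig.id]
        profiles.append(
            CompositionProfile(
                contig_id=contig.id,
                gc=gc,
                log_depth=float(np.log10((depth or 0.0) + 1.0)),
                tetra=tetra,
            )
        )
    return profiles


def composition_pca(profiles: Sequence[CompositionProfile],
                    n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the tetranucleotide matrix (column-centered, unscaled).

    Returns (scores, explained-variance fractions).  When fewer profiles
    than requested components are available, the component count is reduced
    with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for PCA")
    X = np.vstack([p.tetra for p in profiles])
    max_comp = min(len(profiles), X.shape[1])
    if n_components > max_comp:
        logger.warning("reducing PCA components from %d to %d", n_components, max_comp)
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # zero total variance (identical profiles) yields 0/0; report 0
    evr = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return scores, evr


def classify_contigs(contigs: Sequence[Contig],
                     depths: Optional[dict[str, float]] = None,
                     taxonomy: Optional[dict[str, str]] = None,
                     config: Config = DEFAULT_CONFIG) -> list[BinAssignment]:
    """Assign each contig to {host, symbiont, ambiguous}.

    Features: [gc, log10(depth+1), PC1..PCm] column-standardized, clustered
    with seeded 2-means.  The symbiont cluster is the one holding the
    majority of symbiont-like taxonomy calls when any are given, else the
    lower-mean-GC cluster.  A taxonomy call overrides clustering for its
    contig.  Contigs whose centroid-distance margin falls below
    ``ambiguous_quantile`` x median margin are reported ambiguous.
    """
    if len(contigs) < 4:
        raise ValueError("need at least 4 contigs to classify")
    taxonomy = taxonomy or {}
    profiles = build_profiles(contigs, depths)
    scores, _ = composition_pca(profiles, config.pca_components)

    X = np.column_stack(
        [
            np.array([p.gc for p in profiles]),
            np.array([p.log_depth for p in profiles]),
            scores,
        ]
    )
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    km = KMeans(n_clusters=config.kmeans_k, n_init=10, random_state=config.rng_seed)
    labels = km.fit_predict(Z)
    dists = np.linalg.norm(Z[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    margins = np.abs(dists[:, 0] - dists[:, 1])

    degenerate = len(set(labels)) < 2
    if degenerate:
        logger.warning("degenerate clustering: one cluster empty; assigning all to host")

    # identify the symbiont cluster
    symb_cluster = None
    tax_votes = {0: 0, 1: 0}
    for i, p in enumerate(profiles):
        call = taxonomy.get(p.contig_id)
        if call == "symbiont-like":
            tax_votes[labels[i]] += 1
        elif call == "host-like":
            tax_votes[1 - labels[i]] += 1
    if any(tax_votes.values()):
        symb_cluster = max(tax_votes, key=lambda c: tax_votes[c])
    else:
        mean_gc = [np.mean([p.gc for i, p in enumerate(profiles) if labels[i] == c])
                   if np.any(labels == c) else np.inf
                   for c in (0, 1)]
        symb_cluster = int(np.argmin(mean_gc))

    margin_floor = config.ambiguous_quantile * float(np.median(margins))
    assignments: list[BinAssignment] = []
    for i, p in enumerate(profiles):
        call = taxonomy.get(p.contig_id)
        depth = 10 ** p.log_depth - 1.0
        pc1 = float(scores[i, 0])
        pc2 = float(scores[i, 1]) if scores.shape[1] > 1 else float("nan")
        if call is not None:
            bin_ = "symbiont" if call == "symbiont-like" else "host"
            evidence = "taxonomy"
        elif degenerate:
            bin_ = "host"
            evidence = "composition"
        elif margins[i] < margin_floor:
            bin_ = "ambiguous"
            evidence = "composition,coverage"
        else:
            bin_ = "symbiont" if labels[i] == symb_cluster else "host"
            evidence = "composition,coverage"
        assignments.append(
            BinAssignment(
                contig_id=p.contig_id,
                bin=bin_,
                score=float(margins[i]),
                evidence=evidence,
                gc=p.gc,
                depth=depth,
                pc1=pc1,
                pc2=pc2,
            )
        )
    return assignments


# ---------------------------------------------------------------------------
# k-mer read recruitment
# ---------------------------------------------------------------------------

def _window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of every k-mer window, with a validity mask (no N).

    Requires k <= 31 so codes fit an int64.
    """
    codes = _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        ok &= col >= 0
        out = out * 4 + np.where(col >= 0, col, 0)
    return out, ok


def _canonical_window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window canonical codes (min of forward and reverse-complement)."""
    fwd, ok = _window_codes(seq, k)
    rev, _ = _window_codes(revcomp(seq), k)
    # window i of seq corresponds to window n-1-i of its reverse complement
    return np.minimum(fwd, rev[::-1]), ok


def target_kmer_set(contigs: Iterable[Contig], k: int) -> set[int]:
    """Set of canonical k-mer codes over all target contigs."""
    kmers: set[int] = set()
    for contig in contigs:
        canon, ok = _canonical_window_codes(contig.seq, k)
        kmers.update(canon[ok].tolist())
    return kmers


def recruit_reads(reads: Sequence[Contig],
                  target: Sequence[Contig],
                  k: Optional[int] = None,
                  mkf: Optional[float] = None,
                  config: Config = DEFAULT_CONFIG) -> list[str]:
    """Recruit reads sharing at least ``mkf`` of their canonical k-mers with
    the target.

    The matched fraction denominator is the number of k-mer windows of the
    read, ``read_len - k + 1`` (windows containing N count toward the
    denominator but can never match).
    """
    k = k if k is not None else config.recruit_k
    mkf = mkf if mkf is not None else config.recruit_mkf
    if not target:
        raise ValueError("empty target")
    for read in reads:
        if len(read.seq) < k:
            raise ValueError(f"read {read.id!r} shorter than k={k}")
    kmers = target_kmer_set(target, k)
    recruited: list[str] = []
    for read in reads:
        canon, ok = _canonical_window_codes(read.seq, k)
        n_windows = len(read.seq) - k + 1
        n_match = sum(1 for code in canon[ok].tolist() if code in kmers)
        if n_windows > 0 and n_match / n_windows >= mkf:
            recruited.append(read.id)
    return recruited
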