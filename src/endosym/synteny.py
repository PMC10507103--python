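"""Translated-anchor synteny: maximal exact amino-acid matches between two
genomes, collinear chaining, and a two-axis 1:1 filter.

Anchors are maximal exact matches of length >= ``anchor_min_aa`` between any
forward reading frame of genome A and any frame of genome B (both strands),
mapped back to nucleotide coordinates.  Stop codons and ambiguous codons
break translations and therefore anchors.  Anchors are chained greedily into
strand-consistent, coordinate-bimonotonic blocks, and a weighted
interval-scheduling pass on each genome axis retains a set of blocks with a
single match in each genome (``one_to_one``).

Anchor enumeration is a vectorized hash join (exact, no probabilistic
filtering): seeds of length min(min_aa, 8) are matched via integer codes,
reduced to left-maximal seed pairs, and extended to full maximal matches.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .config import DEFAULT_CONFIG, Config

logger = logging.getLogger(__name__)

DEFAULT_TRANSLATION_TABLE = 4  # Mollicutes / Mycoplasma code (UGA = Trp)


@dataclasses.dataclass
class Anchor:
    """A maximal exact translated match, in nucleotide coordinates.

    ``b_start``/``b_end`` are always on the forward strand of B; ``strand``
    records the orientation of the match (B relative to A).
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    aa_len: int
    frame_a: int
    frame_b: int

    def __post_init__(self) -> None:
        if self.a_end - self.a_start != 3 * self.aa_len:
            raise ValueError("anchor nucleotide span must be 3x aa_len")

    @property
    def nt_len(self) -> int:
        return 3 * self.aa_len


@dataclasses.dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    anchored_bp: int
    one_to_one: bool = False


@dataclasses.dataclass
class SyntenySummary:
    total_one_to_one_bp: int
    longest_block_bp: int
    block_count: int
    one_to_one_count: int


# ---------------------------------------------------------------------------
# Anchor finding
# ---------------------------------------------------------------------------

def _translate_frames(seq: str, table: int) -> list[str]:
    """Amino-acid strings of the three forward frames ('*' marks stops)."""
    frames = []
    for f in range(3):
        sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
        frames.append(str(Seq(sub).translate(table=table)) if sub else "")
    return frames


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _encode_side(frames: Sequence[str], stop_char: str, x_char: str,
                 sep_char: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate frames with separators; remap stop/ambiguous codons to a
    side-specific sentinel so they can never match across sides.

    Returns (byte array, frame index per position, aa index per position).
    """
    chunks: list[str] = []
    frame_idx: list[np.ndarray] = []
    aa_idx: list[np.ndarray] = []
    for fi, frame in enumerate(frames):
        remapped = frame.replace("*", stop_char).replace("X", x_char).replace("J", x_char)
        chunks.append(remapped)
        frame_idx.append(np.full(len(remapped), fi, dtype=np.int64))
        aa_idx.append(np.arange(len(remapped), dtype=np.int64))
        chunks.append(sep_char)
        frame_idx.append(np.full(1, -1, dtype=np.int64))
        aa_idx.append(np.full(1, -1, dtype=np.int64))
    arr = np.frombuffer("".join(chunks).encode("ascii"), dtype=np.uint8)
    return arr, np.concatenate(frame_idx), np.concatenate(aa_idx)


def _seed_codes(arr: np.ndarray, k: int) -> np.ndarray:
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 128 + arr[j : j + n]
    return out


def _maximal_matches(a: np.ndarray, b: np.ndarray, min_len: int,
                     chunk_pairs: int = 2_000_000) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= min_len between byte arrays.

    Returns (a_pos, b_pos, length) triples.  Exact: every maximal match is
    found exactly once via its unique left-maximal seed.
    """
    ks = min(min_len, 8)
    ac = _seed_codes(a, ks)
    bc = _seed_codes(b, ks)
    if ac.size == 0 or bc.size == 0:
        return []
    order = np.argsort(bc, kind="stable")
    bc_sorted = bc[order]
    lo = np.searchsorted(bc_sorted, ac, side="left")
    hi = np.searchsorted(bc_sorted, ac, side="right")
    counts = hi - lo
    matches: list[tuple[int, int, int]] = []

    a_positions = np.nonzero(counts)[0]
    cum = 0
    batch: list[int] = []
    batches: list[list[int]] = []
    for i in a_positions.tolist():
        batch.append(i)
        cum += counts[i]
        if cum >= chunk_pairs:
            batches.append(batch)
            batch, cum = [], 0
    if batch:
        batches.append(batch)

    for batch in batches:
        bi = np.asarray(batch, dtype=np.int64)
        reps = counts[bi]
        ai = np.repeat(bi, reps)
        # flatten the sorted-range indices for each a position
        offsets = np.concatenate([np.arange(lo[i], hi[i]) for i in batch])
        bj = order[offsets]
        # left-maximality: previous characters differ (or at a boundary)
        ok = (ai == 0) | (bj == 0)
        inner = ~ok
        ok[inner] = a[ai[inner] - 1] != b[bj[inner] - 1]
        ai, bj = ai[ok], bj[ok]
        # extend right, all pairs in lockstep
        lengths = np.full(ai.size, ks, dtype=np.int64)
        active = np.arange(ai.size)
        while active.size:
            ia = ai[active] + lengths[active]
            jb = bj[active] + lengths[active]
            inbounds = (ia < a.size) & (jb < b.size)
            same = np.zeros(active.size, dtype=bool)
            same[inbounds] = a[ia[inbounds]] == b[jb[inbounds]]
            lengths[active[same]] += 1
            active = active[same]
        keep = lengths >= min_len
        matches.extend(zip(ai[keep].tolist(), bj[keep].tolist(),
                           lengths[keep].tolist()))
    return matches


def _six_frames(seq: str, table: int) -> list[str]:
    """Frames 0-2: forward; frames 3-5: reverse complement."""
    return (_translate_frames(seq, table)
            + _translate_frames(_revcomp(seq), table))


def _nt_interval(frame6: int, aa_idx: int, aa_len: int,
                 genome_len: int) -> tuple[int, int, str]:
    """Map a frame-local amino-acid run to forward-strand nt coordinates."""
    if frame6 < 3:
        start = frame6 + 3 * aa_idx
        return start, start + 3 * aa_len, "+"
    f = frame6 - 3
    end = genome_len - (f + 3 * aa_idx)
    return end - 3 * aa_len, end, "-"


def find_anchors(genome_a: str, genome_b: str,
                 min_aa: Optional[int] = None,
                 translation_table: int = DEFAULT_TRANSLATION_TABLE,
                 config: Config = DEFAULT_CONFIG) -> list[Anchor]:
    """All maximal exact amino-acid matches of length >= min_aa over the full
    6x6 grid of reading-frame pairs (both strands of both genomes).

    All 36 frame pairs are required for genome-swap symmetry: an amino-acid
    match between a forward frame of A and a reverse frame of B does not
    imply the corresponding match between the complementary frames, because
    translation does not commute with reverse complementation.
    """
    min_aa = min_aa if min_aa is not None else config.anchor_min_aa
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be non-empty")
    genome_a = genome_a.upper()
    genome_b = genome_b.upper()
    len_a, len_b = len(genome_a), len(genome_b)

    arr_a, frame_a, aa_a = _encode_side(_six_frames(genome_a, translation_table),
                                        "#", "!", "^")
    arr_b, frame_b, aa_b = _encode_side(_six_frames(genome_b, translation_table),
                                        "$", "?", "~")

    seen: set[tuple[int, int, int, int, str]] = set()
    anchors: list[Anchor] = []
    for apos, bpos, length in _maximal_matches(arr_a, arr_b, min_aa):
        fa6, ia = int(frame_a[apos]), int(aa_a[apos])
        fb6, ib = int(frame_b[bpos]), int(aa_b[bpos])
        a_start, a_end, sa = _nt_interval(fa6, ia, length, len_a)
        b_start, b_end, sb = _nt_interval(fb6, ib, length, len_b)
        strand = "+" if sa == sb else "-"
        key = (a_start, a_end, b_start, b_end, strand)
        if key in seen:  # same nt match seen through complementary frames
            continue
        seen.add(key)
        anchors.append(Anchor(a_start, a_end, b_start, b_end, strand,
                              length, fa6, fb6))
    anchors.sort(key=lambda x: (x.a_start, x.b_start, x.strand))
    return anchors


# ---------------------------------------------------------------------------
# Chaining and the 1:1 filter
# ---------------------------------------------------------------------------

class _Chain:
    """An open chain: its anchors plus tip coordinates.

    ``a_tip`` is the rightmost A-end seen; ``b_tip`` the rightmost B-end
    ('+') or leftmost B-start ('-').
    """

    __slots__ = ("anchors", "strand", "a_min", "a_tip", "b_min", "b_max", "b_tip")

    def __init__(self, anchor: Anchor):
        self.anchors = [anchor]
        self.strand = anchor.strand
        self.a_min = anchor.a_start
        self.a_tip = anchor.a_end
        self.b_min = anchor.b_start
        self.b_max = anchor.b_end
        # direction of travel on B: rightmost end for '+', leftmost start for '-'
        self.b_tip = anchor.b_end if anchor.strand == "+" else anchor.b_start

    def gaps(self, anchor: Anchor, max_gap_nt: int) -> Optional[tuple[int, int]]:
        """Chaining gaps, or None when the anchor cannot join this chain.

        An anchor fully inside the chain hull on both axes is absorbed at
        zero cost.  Otherwise positive gaps are bounded by ``max_gap_nt``
        and negative gaps (overlap) by the anchor's own length plus the gap
        bound, which admits tip-extending anchors while keeping distant
        repeat matches out.
        """
        if anchor.strand != self.strand:
            return None
        if (self.a_min <= anchor.a_start and anchor.a_end <= self.a_tip
                and self.b_min <= anchor.b_start and anchor.b_end <= self.b_max):
            return 0, 0
        slack = anchor.nt_len + max_gap_nt
        a_gap = anchor.a_start - self.a_tip
        if a_gap > max_gap_nt or a_gap < -slack:
            return None
        if self.strand == "+":
            b_gap = anchor.b_start - self.b_tip
        else:
            b_gap = self.b_tip - anchor.b_end
        if b_gap > max_gap_nt or b_gap < -slack:
            return None
        return a_gap, b_gap

    def add(self, anchor: Anchor) -> None:
        self.anchors.append(anchor)
        self.a_min = min(self.a_min, anchor.a_start)
        self.a_tip = max(self.a_tip, anchor.a_end)
        self.b_min = min(self.b_min, anchor.b_start)
        self.b_max = max(self.b_max, anchor.b_end)
        if self.strand == "+":
            self.b_tip = max(self.b_tip, anchor.b_end)
        else:
            self.b_tip = min(self.b_tip, anchor.b_start)


def _chain(anchors: list[Anchor], max_gap_nt: int) -> list[SyntenyBlock]:
    """Greedy chaining into strand-consistent, diagonal-coherent runs."""
    blocks: list[SyntenyBlock] = []
    open_chains: list[_Chain] = []
    for anchor in sorted(anchors, key=lambda x: (x.a_start, x.b_start)):
        # retire chains that no later anchor (sorted by a_start) can join
        still_open = []
        for chain in open_chains:
            if anchor.a_start - chain.a_tip > max_gap_nt:
                blocks.append(_close(chain.anchors))
            else:
                still_open.append(chain)
        open_chains = still_open

        joinable = [chain for chain in open_chains
                    if chain.gaps(anchor, max_gap_nt) is not None]
        if not joinable:
            open_chains.append(_Chain(anchor))
        else:
            # an anchor compatible with several chains links them: merge so
            # parallel runs along one diagonal (e.g. from complementary
            # frame pairs) become a single block
            target = joinable[0]
            for chain in joinable[1:]:
                for prev in chain.anchors:
                    target.add(prev)
                open_chains.remove(chain)
            target.add(anchor)
    blocks.extend(_close(chain.anchors) for chain in open_chains)
    return blocks


def _close(chain: list[Anchor]) -> SyntenyBlock:
    return SyntenyBlock(
        anchors=list(chain),
        a_start=min(a.a_start for a in chain),
        a_end=max(a.a_end for a in chain),
        b_start=min(a.b_start for a in chain),
        b_end=max(a.b_end for a in chain),
        strand=chain[0].strand,
        anchored_bp=sum(a.nt_len for a in chain),
    )


def _weighted_non_overlapping(blocks: list[SyntenyBlock],
                              axis: str, tol: int = 0) -> set[int]:
    """Indices of the max-weight subset of blocks pairwise non-overlapping on
    one axis (classic weighted interval scheduling).

    ``tol`` forgives boundary overlaps (anchors at rearrangement breakpoints
    commonly poke one codon into the adjacent block) by shrinking each
    interval's left edge, by at most half the interval so a fully contained
    duplicate still conflicts with its container.
    """
    if not blocks:
        return set()
    if axis == "a":
        iv = [(b.a_start, b.a_end, i) for i, b in enumerate(blocks)]
    else:
        iv = [(b.b_start, b.b_end, i) for i, b in enumerate(blocks)]
    iv = [(s + min(tol, (e - s) // 2), e, i) for s, e, i in iv]
    iv.sort(key=lambda x: x[1])
    ends = [x[1] for x in iv]
    n = len(iv)
    import bisect
    prev = [bisect.bisect_right(ends, iv[i][0]) - 1 for i in range(n)]
    weight = [blocks[iv[i][2]].anchored_bp for i in range(n)]
    dp = [0.0] * (n + 1)
    take = [False] * n
    for i in range(n):
        with_i = weight[i] + dp[prev[i] + 1]
        if with_i > dp[i]:
            dp[i + 1] = with_i
            take[i] = True
        else:
            dp[i + 1] = dp[i]
    chosen: set[int] = set()
    i = n - 1
    while i >= 0:
        if take[i]:
            chosen.add(iv[i][2])
            i = prev[i]
        else:
            i -= 1
    return chosen


def chain_and_filter(anchors: Sequence[Anchor],
                     max_gap_aa: Optional[int] = None,
                     min_block_aa: int = 20,
                     config: Config = DEFAULT_CONFIG) -> list[SyntenyBlock]:
    """Chain anchors into blocks and mark a 1:1 subset.

    Blocks totalling fewer than ``min_block_aa`` matched amino acids are
    dropped.  The 1:1 subset maximizes anchored bp under the constraint of
    no overlap on the A axis, then again on the B axis; survivors get
    ``one_to_one=True`` and all other blocks are retained flagged False.
    """
    max_gap_aa = max_gap_aa if max_gap_aa is not None else config.chain_max_gap_aa
    max_gap_nt = 3 * max_gap_aa
    blocks = _chain(list(anchors), max_gap_nt)
    blocks = [b for b in blocks if b.anchored_bp >= 3 * min_block_aa]
    chosen_a = _weighted_non_overlapping(blocks, "a", tol=max_gap_nt)
    survivors = [blocks[i] for i in sorted(chosen_a)]
    chosen_b_local = _weighted_non_overlapping(survivors, "b", tol=max_gap_nt)
    selected = [survivors[i] for i in sorted(chosen_b_local)]
    selected = _prune_residual_conflicts(selected, max_gap_nt)
    chosen = {id(block) for block in selected}
    for block in blocks:
        block.one_to_one = id(block) in chosen
    return blocks


def _prune_residual_conflicts(selected: list[SyntenyBlock],
                              tol: int) -> list[SyntenyBlock]:
    """Drop lighter blocks whose raw overlap with a heavier one exceeds the
    boundary tolerance (capped at half of either block).

    The interval-scheduling pass tolerates small boundary overlaps by edge
    shrinking, which can let a short block nested near the start of a long
    one slip through; this pass enforces the pairwise rule exactly.
    """
    kept = sorted(selected, key=lambda b: -b.anchored_bp)
    result: list[SyntenyBlock] = []
    for block in kept:
        ok = True
        for other in result:
            for axis in ("a", "b"):
                s1, e1 = ((block.a_start, block.a_end) if axis == "a"
                          else (block.b_start, block.b_end))
                s2, e2 = ((other.a_start, other.a_end) if axis == "a"
                          else (other.b_start, other.b_end))
                overlap = min(e1, e2) - max(s1, s2)
                limit = min(tol, (e1 - s1) // 2, (e2 - s2) // 2)
                if overlap > limit:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            result.append(block)
    return result


def synteny_summary(blocks: Sequence[SyntenyBlock],
                    len_a: Optional[int] = None,
                    len_b: Optional[int] = None) -> SyntenySummary:
    """Total 1:1 length (union of A-axis spans of 1:1 blocks) and extremes.

    The union (rather than a plain sum) keeps codon-sized boundary overlaps
    between adjacent blocks from being counted twice, so the total can never
    exceed the smaller genome.
    """
    one = [b for b in blocks if b.one_to_one]
    from .genome_stats import interval_union_length

    total = interval_union_length([(b.a_start, b.a_end) for b in one])
    longest = max((b.a_end - b.a_start for b in one), default=0)
    if len_a is not None and len_b is not None and total > min(len_a, len_b):
        logger.warning("1:1 total exceeds the smaller genome; check inputs")
    return SyntenySummary(
        total_one_to_one_bp=total,
        longest_block_bp=longest,
        block_count=len(blocks),
        one_to_one_count=len(one),
    )


def dotplot_table(anchors: Sequence[Anchor]) -> list[tuple[int, int, int, int, str]]:
    return [(a.a_start, a.a_end, a.b_start, a.b_end, a.strand) for a in anchors]


# ---------------------------------------------------------------------------
# Ortholog link collinearity
# ---------------------------------------------------------------------------

def _lis_length(values: Sequence[int]) -> int:
    """Longest strictly increasing subsequence (patience sorting)."""
    import bisect
    tails: list[int] = []
    for v in values:
        pos = bisect.bisect_left(tails, v)
        if pos == len(tails):
            tails.append(v)
        else:
            tails[pos] = v
    return len(tails)


@dataclasses.dataclass
class OrthologLinks:
    links: list[tuple[str, int, int]]  # (ortholog_id, a position, b position)
    shared_count: int
    collinearity: float  # LIS fraction on the better-oriented axis
    inverted: bool


def ortholog_links(rows: Sequence[tuple[str, int, int]]) -> OrthologLinks:
    """Collinearity of single-copy ortholog positions in two genomes.

    Duplicated ortholog ids are excluded (not single copy) with a warning.
    The collinearity score is the fraction of orthologs in the longest
    order-preserving subsequence, computed on the forward B axis and on the
    reversed axis; the better orientation wins and sets ``inverted``.
    """
    counts: dict[str, int] = {}
    for oid, _, _ in rows:
        counts[oid] = counts.get(oid, 0) + 1
    dups = {oid for oid, c in counts.items() if c > 1}
    if dups:
        logger.warning("excluding %d duplicated ortholog ids", len(dups))
    links = [(oid, a, b) for oid, a, b in rows if oid not in dups]
    if not links:
        return OrthologLinks([], 0, 0.0, False)
    links.sort(key=lambda r: r[1])
    b_order = [b for _, _, b in links]
    fwd = _lis_length(b_order)
    rev = _lis_length([-b for b in b_order])
    inverted = rev > fwd
    best = max(fwd, rev)
    return OrthologLinks(links, len(links), best / len(links), inverted)
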