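"""Host-to-symbiont horizontal-gene-transfer screening.

A gene is an HGT candidate when its valid similarity hits contain strictly
more than ``hgt_ratio`` (default 2x) as many fungal hits as bacterial hits.
Validity requires E-value strictly below 1e-5 and query coverage strictly
above 50%.  Queries whose fungal hits all come from an excluded lineage
(default Glomeromycotina, a likely source of unrecognized endobacterial
contamination) are set aside, unless the product matches a configured
exception pattern (PknD / LRR kinases, which are known repeat transfers).

The phage-origin filter is deliberately separate: its coverage bound is
inclusive (>= 50%) where the HGT filter is strict.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Optional, Sequence

from .binning import classify_contigs
from .config import DEFAULT_CONFIG, Config
from .model import AnnotationSet, Contig, GeneRecord, HitRecord, HitTable

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_LINEAGE = "Glomeromycotina"
DEFAULT_EXCEPTION_PATTERNS = ("PknD", "leucine-rich repeat", "leucine rich repeat", "LRR")
DEFAULT_SELF_TAXA = ("MRE",)
DEFAULT_HIT_CAP = 500


@dataclasses.dataclass
class HgtVerdict:
    query_id: str
    status: str  # {candidate, not_candidate, excluded_lineage_only, no_valid_hits}
    n_fungal: int
    n_bacterial: int
    ratio: float
    exception_applied: bool = False


@dataclasses.dataclass
class FlankContext:
    query_id: str
    upstream: list[tuple[str, str, str]]  # (gene_id, product, best-hit kingdom)
    downstream: list[tuple[str, str, str]]


def filter_hits(hits: Sequence[HitRecord],
                e_max: Optional[float] = None,
                qcov_min: Optional[float] = None,
                self_taxa: Sequence[str] = DEFAULT_SELF_TAXA,
                config: Config = DEFAULT_CONFIG) -> list[HitRecord]:
    """Keep hits with evalue strictly below ``e_max`` and qcov strictly above
    ``qcov_min``; drop self-hits (subject id or lineage matching a self taxon).
    """
    e_max = e_max if e_max is not None else config.hgt_e_max
    qcov_min = qcov_min if qcov_min is not None else config.hgt_qcov_min
    kept = []
    for hit in hits:
        if any(taxon in hit.subject_id or taxon in hit.subject_lineage
               for taxon in self_taxa):
            continue
        if hit.evalue < e_max and hit.qcov > qcov_min:
            kept.append(hit)
    return kept


def classify_hgt(valid_hits: Sequence[HitRecord],
                 product: str = "",
                 query_id: str = "",
                 excluded_lineage: str = DEFAULT_EXCLUDED_LINEAGE,
                 exception_patterns: Sequence[str] = DEFAULT_EXCEPTION_PATTERNS,
                 unique_taxa: bool = False,
                 config: Config = DEFAULT_CONFIG) -> HgtVerdict:
    """Apply the fungal:bacterial ratio rule to one query's valid hits.

    Candidate iff n_fungal > hgt_ratio * n_bacterial; with zero bacterial
    hits, at least ``hgt_min_fungal_when_no_bacterial`` fungal hits are
    required instead.  Archaeal/viral/other hits enter neither count.  With
    ``unique_taxa`` hits are collapsed to unique subject organisms first.
    """
    if not valid_hits:
        return HgtVerdict(query_id, "no_valid_hits", 0, 0, 0.0)

    fungal = [h for h in valid_hits if h.subject_kingdom == "fungal"]
    bacterial = [h for h in valid_hits if h.subject_kingdom == "bacterial"]
    if unique_taxa:
        def n_unique(hits: list[HitRecord]) -> int:
            return len({tuple(h.subject_lineage) + (h.subject_id.rsplit("_p", 1)[0],)
                        for h in hits})
        n_f, n_b = n_unique(fungal), n_unique(bacterial)
    else:
        n_f, n_b = len(fungal), len(bacterial)

    ratio = n_f / max(n_b, 1)
    if n_b > 0:
        is_candidate = n_f > config.hgt_ratio * n_b
    else:
        is_candidate = n_f >= config.hgt_min_fungal_when_no_bacterial

    exception_applied = False
    if is_candidate and fungal:
        glom_only = all(excluded_lineage in h.subject_lineage for h in fungal)
        if glom_only:
            matches_exception = any(
                re.search(re.escape(pat), product, re.IGNORECASE)
                for pat in exception_patterns
            )
            if matches_exception:
                exception_applied = True
            else:
                return HgtVerdict(query_id, "excluded_lineage_only", n_f, n_b, ratio)

    status = "candidate" if is_candidate else "not_candidate"
    return HgtVerdict(query_id, status, n_f, n_b, ratio, exception_applied)


def _best_hit_kingdom(hits: Sequence[HitRecord]) -> str:
    if not hits:
        return "none"
    best = min(hits, key=lambda h: h.evalue)
    return best.subject_kingdom


def flank_context(annotation: AnnotationSet, gene: GeneRecord,
                  hit_table: HitTable, window: int = 5) -> FlankContext:
    """Neighbouring genes on the same contig, ordered by genomic distance,
    truncated at contig ends."""
    same_contig = sorted(
        (r for r in annotation.records if r.contig_id == gene.contig_id),
        key=lambda r: r.start,
    )
    idx = next(i for i, r in enumerate(same_contig) if r.gene_id == gene.gene_id)
    upstream = [
        (r.gene_id, r.product, _best_hit_kingdom(hit_table.hits_for(r.gene_id)))
        for r in reversed(same_contig[max(0, idx - window) : idx])
    ]
    downstream = [
        (r.gene_id, r.product, _best_hit_kingdom(hit_table.hits_for(r.gene_id)))
        for r in same_contig[idx + 1 : idx + 1 + window]
    ]
    return FlankContext(gene.gene_id, upstream, downstream)


@dataclasses.dataclass
class HgtReport:
    verdicts: list[HgtVerdict]
    contexts: dict[str, FlankContext]
    summary: dict[str, int]


def screen_genome(annotation: AnnotationSet, hit_table: HitTable,
                  flank_window: int = 5,
                  hit_cap: int = DEFAULT_HIT_CAP,
                  unique_taxa: bool = False,
                  exception_patterns: Sequence[str] = DEFAULT_EXCEPTION_PATTERNS,
                  config: Config = DEFAULT_CONFIG) -> HgtReport:
    """One verdict per CDS with hits; candidates carry flank context.

    Hits beyond ``hit_cap`` per query are dropped before validity filtering.
    """
    verdicts: list[HgtVerdict] = []
    contexts: dict[str, FlankContext] = {}
    genes_by_id = {r.gene_id: r for r in annotation.records}
    query_ids = [r.gene_id for r in annotation.cds()]
    query_ids += [q for q in hit_table.queries() if q not in genes_by_id]
    for query_id in query_ids:
        gene = genes_by_id.get(query_id)
        if gene is None:
            logger.warning("query %s not in annotation; no flank context", query_id)
        hits = hit_table.hits_for(query_id)[:hit_cap]
        valid = filter_hits(hits, config=config)
        verdict = classify_hgt(
            valid,
            product=gene.product if gene else "",
            query_id=query_id,
            exception_patterns=exception_patterns,
            unique_taxa=unique_taxa,
            config=config,
        )
        verdicts.append(verdict)
        if verdict.status == "candidate" and gene is not None:
            contexts[query_id] = flank_context(annotation, gene, hit_table,
                                               window=flank_window)
    summary: dict[str, int] = {}
    for verdict in verdicts:
        summary[verdict.status] = summary.get(verdict.status, 0) + 1
    return HgtReport(verdicts, contexts, summary)


def flag_contamination(contigs: Sequence[Contig],
                       depths: Optional[dict[str, float]] = None,
                       symbiont_hit_flags: Optional[set[str]] = None,
                       config: Config = DEFAULT_CONFIG) -> dict[str, str]:
    """Flag likely endosymbiont contamination in a (fungal) assembly.

    Contigs falling in the minority composition cluster are 'contaminated'
    when they carry a symbiont-like hit flag and 'suspect' otherwise.
    """
    symbiont_hit_flags = symbiont_hit_flags or set()
    assignments = classify_contigs(contigs, depths, config=config)
    by_bin: dict[str, int] = {}
    for a in assignments:
        if a.bin in ("host", "symbiont"):
            by_bin[a.bin] = by_bin.get(a.bin, 0) + 1
    if len(by_bin) < 2:
        return {}
    minority = min(by_bin, key=lambda b: by_bin[b])
    flags: dict[str, str] = {}
    for a in assignments:
        if a.bin == minority:
            flags[a.contig_id] = ("contaminated" if a.contig_id in symbiont_hit_flags
                                  else "suspect")
    return flags


def phage_origin_filter(hits: Sequence[HitRecord],
                        config: Config = DEFAULT_CONFIG) -> list[str]:
    """Protein ids with viral hits at evalue < phage_e_max and qcov >=
    phage_qcov_min (inclusive coverage bound, unlike the HGT filter)."""
    kept: list[str] = []
    seen: set[str] = set()
    for hit in hits:
        if hit.subject_kingdom != "viral":
            continue
        if hit.evalue < config.phage_e_max and hit.qcov >= config.phage_qcov_min:
            if hit.query_id not in seen:
                seen.add(hit.query_id)
                kept.append(hit.query_id)
    return kept
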