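"""Domain types shared by all pipeline stages.

Coordinate convention: all intervals are 0-based half-open in memory and
1-based inclusive on disk (GFF3).  Converting twice is the identity.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Iterator, Optional

VALID_BASES = frozenset("ACGTN")
FEATURE_CLASSES = ("CDS", "pseudogene", "repeat", "phage", "tRNA", "rRNA")
KINGDOMS = ("fungal", "bacterial", "archaeal", "viral", "other")


@dataclasses.dataclass
class Contig:
    """A named DNA sequence, the unit of binning.

    ``depth`` is the mean mapped read coverage, when known; ``truth`` is the
    simulation-truth source label ({'host','symbiont'}), when known.
    """

    id: str
    seq: str
    depth: Optional[float] = None
    truth: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: sequence must be non-empty")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"contig {self.id!r}: depth must be >= 0")
        if self.truth is not None and self.truth not in ("host", "symbiont"):
            raise ValueError(f"contig {self.id!r}: bad truth label {self.truth!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass
class GeneRecord:
    """A located genome feature with a free-text product annotation."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_class: str
    product: str = "hypothetical protein"
    protein_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown feature class {self.feature_class!r}"
            )
        if self.feature_class == "CDS":
            if self.protein_length is None or self.protein_length < 1:
                raise ValueError(
                    f"gene {self.gene_id!r}: CDS requires protein_length >= 1"
                )
        elif self.protein_length is not None:
            raise ValueError(
                f"gene {self.gene_id!r}: protein_length only valid for CDS"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class AnnotationSet:
    """All gene records of one genome plus the genome length."""

    genome_id: str
    records: list[GeneRecord]
    genome_length: int
    contig_lengths: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.contig_lengths:
            total = sum(self.contig_lengths.values())
            if total != self.genome_length:
                raise ValueError(
                    f"{self.genome_id}: genome_length {self.genome_length} != "
                    f"sum of contig lengths {total}"
                )
            for rec in self.records:
                if rec.contig_id not in self.contig_lengths:
                    raise ValueError(
                        f"{self.genome_id}: gene {rec.gene_id!r} references "
                        f"unknown contig {rec.contig_id!r}"
                    )
                if rec.end > self.contig_lengths[rec.contig_id]:
                    raise ValueError(
                        f"{self.genome_id}: gene {rec.gene_id!r} extends past "
                        f"end of contig {rec.contig_id!r}"
                    )

    def cds(self) -> list[GeneRecord]:
        return [r for r in self.records if r.feature_class == "CDS"]

    def by_class(self, feature_class: str) -> list[GeneRecord]:
        return [r for r in self.records if r.feature_class == feature_class]

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclasses.dataclass
class HitRecord:
    """One similarity hit of a query gene against a taxon-labelled subject."""

    query_id: str
    subject_id: str
    subject_kingdom: str
    subject_lineage: list[str]
    evalue: float
    qcov: float
    pct_identity: float
    aln_len: int

    def __post_init__(self) -> None:
        if self.subject_kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {self.subject_kingdom!r}")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")
        if not 0 <= self.qcov <= 1:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: qcov outside [0,1]")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity outside [0,100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


class HitTable:
    """Hit records grouped by query, preserving file order."""

    def __init__(self, hits: Iterable[HitRecord] = ()):
        self._by_query: dict[str, list[HitRecord]] = {}
        for hit in hits:
            self._by_query.setdefault(hit.query_id, []).append(hit)

    def queries(self) -> list[str]:
        return list(self._by_query)

    def hits_for(self, query_id: str) -> list[HitRecord]:
        return list(self._by_query.get(query_id, []))

    def all_hits(self) -> list[HitRecord]:
        return [h for hits in self._by_query.values() for h in hits]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_query.values())

    def __contains__(self, query_id: str) -> bool:
        return query_id in self._by_query

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HitTable):
            return NotImplemented
        return self._by_query == other._by_query


@dataclasses.dataclass
class Association:
    """Host-leaf to symbiont-leaf pairing for tree-congruence tests.

    A host may map to multiple symbionts; each pair is one row.
    """

    pairs: list[tuple[str, str]]

    def hosts(self) -> list[str]:
        return [h for h, _ in self.pairs]

    def symbionts(self) -> list[str]:
        return [s for _, s in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


_PRODUCT_SANITIZE = re.compile(r"[\t\n\r]")


def sanitize_product(product: str) -> str:
    """Replace characters that would break TSV/GFF round trips."""
    return _PRODUCT_SANITIZE.sub(" ", product)
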