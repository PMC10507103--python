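"""Pipeline configuration.

Every numeric threshold used by any operation lives here exactly once, so a
single flat key=value file fully determines a run.  The config (and its hash)
is echoed into the ``#`` comment header of every TSV the pipeline writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path


@dataclasses.dataclass
class Config:
    """All tunable thresholds of the pipeline.

    Attributes
    ----------
    hgt_e_max : float
        HGT hit validity: E-value must be strictly below this.
    hgt_qcov_min : float
        HGT hit validity: query coverage must be strictly above this.
    hgt_ratio : float
        HGT call: fungal hit count must strictly exceed ``hgt_ratio`` times
        the bacterial hit count.
    hgt_min_fungal_when_no_bacterial : int
        With zero bacterial hits the ratio is undefined; require at least
        this many fungal hits instead.
    phage_e_max, phage_qcov_min : float
        Phage-origin filter; coverage bound is inclusive (>=), unlike the
        strict HGT filter.
    recruit_k : int
        k-mer size for read recruitment.
    recruit_mkf : float
        Minimum fraction of a read's k-mers that must match the target.
    tetra_k : int
        Word size for composition profiles (canonical tetranucleotides).
    anchor_min_aa : int
        Minimum exact translated match length, in amino acids.
    chain_max_gap_aa : int
        Maximum chaining gap between anchors, in amino-acid equivalents
        (3x this in nucleotides on each axis).
    pca_components : int
        Number of principal components of the tetranucleotide matrix used
        as binning features.
    kmeans_k : int
        Number of clusters for contig binning (host vs symbiont).
    ambiguous_quantile : float
        Contigs whose cluster-margin falls below this fraction of the
        median margin are reported as ambiguous.
    bonferroni_m : int
        Number of simultaneous comparisons for Bonferroni adjustment.
    rng_seed : int
        Seed for every stochastic step (k-means init, permutation tests).
    """

    hgt_e_max: float = 1e-5
    hgt_qcov_min: float = 0.50
    hgt_ratio: float = 2.0
    hgt_min_fungal_when_no_bacterial: int = 3
    phage_e_max: float = 1e-5
    phage_qcov_min: float = 0.50
    recruit_k: int = 31
    recruit_mkf: float = 0.05
    tetra_k: int = 4
    anchor_min_aa: int = 6
    chain_max_gap_aa: int = 30
    pca_components: int = 2
    kmeans_k: int = 2
    ambiguous_quantile: float = 0.05
    bonferroni_m: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if field.name == "rng_seed":
                continue
            if value <= 0:
                raise ValueError(f"config field {field.name!r} must be positive, got {value}")
        if not 0 < self.ambiguous_quantile < 1:
            raise ValueError("ambiguous_quantile must be in (0, 1)")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        kwargs: dict[str, object] = {}
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in field_types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = int if field_types[key] == "int" else float
            kwargs[key] = caster(value.strip())
        return cls(**kwargs)  # type: ignore[arg-type]

    def hash(self) -> str:
        """Short stable digest of the full configuration, for output headers."""
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = Config()
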