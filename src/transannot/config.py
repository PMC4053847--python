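"""Pipeline configuration.

All tunable thresholds of the processing pipeline live in a single
:class:`PipelineConfig` so that a run is fully described by one object
(and one flat ``key=value`` file on disk).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Thresholds and knobs for one annotation run.

    Attributes
    ----------
    evalue_cutoff:
        Similarity-search hits with a larger E-value are discarded at
        ingest time.
    topk_majority:
        Number of top hits considered by majority-vote family assignment.
    consensus_fraction:
        A functional term is transferred from a family when at least this
        fraction of family members carry it.
    trim_fraction:
        Fraction of family CDS lengths trimmed from each end before the
        completeness statistics are computed.
    sd_multiplier:
        A transcript ORF shorter than ``mean - sd_multiplier * sd`` of the
        trimmed family CDS lengths is labelled Partial.
    min_family_size_meta:
        Families smaller than this give the "No Information" label.
    stringent_gap_threshold:
        Alignment columns with gap fraction strictly above this are removed
        in stringent editing (plus flanking columns).
    relaxed_gap_threshold:
        Columns with gap fraction at or above this are removed in relaxed
        editing.
    flank_width:
        Columns removed on each side of a gap column in stringent editing.
    alpha:
        Significance level for Bonferroni-adjusted enrichment p-values.
    rng_seed:
        Seed for any stochastic step (none in the core pipeline; kept in
        the manifest for provenance).
    """

    evalue_cutoff: float = 1e-5
    topk_majority: int = 5
    consensus_fraction: float = 0.5
    trim_fraction: float = 0.1
    sd_multiplier: float = 2.0
    min_family_size_meta: int = 5
    stringent_gap_threshold: float = 0.10
    relaxed_gap_threshold: float = 0.25
    flank_width: int = 1
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must be in (0, 1]")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        for name in ("stringent_gap_threshold", "relaxed_gap_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.flank_width < 0:
            raise ValueError("flank_width must be >= 0")
        if self.topk_majority < 1:
            raise ValueError("topk_majority must be >= 1")
        if self.min_family_size_meta < 1:
            raise ValueError("min_family_size_meta must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key=value`` config file; unknown keys are an error."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = int if "int" in str(fields[key]) else float
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def write(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")
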