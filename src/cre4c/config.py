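"""Pipeline configuration: one structured config drives the whole analysis.

Defaults reproduce the standard stage parameters (40 bp minimum fragment
length, +/-5 kb viewpoint exclusion, 30-fragment smoothing, 5 kb bins over
+/-1 Mb, 2.5% viewpoint fraction, 40 bp merge gap, 10,000 permutations,
100 bp correlation bins, oligomer lengths 6 and 7).  Unknown keys are
rejected so configs fail loudly on typos.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlantSpec(_Strict):
    center: int
    half_width: int = 10  # in fragments
    fold: float = 6.0


class CellLineSpec(_Strict):
    name: str
    planted_interactions: list[PlantSpec] = Field(default_factory=list)


class SimSection(_Strict):
    genome_length: int = 1_200_000
    site_rate_primary: float = 2.0
    site_rate_secondary: float = 2.0
    viewpoint_pos: int = 600_000
    decay_amplitude: float = 100.0
    decay_exponent: float = 1.0
    decay_scale: float = 50_000.0
    nb_dispersion: float = 5.0
    n_replicates: int = 2
    cell_lines: list[CellLineSpec] = Field(
        default_factory=lambda: [
            CellLineSpec(
                name="expressing",
                planted_interactions=[
                    PlantSpec(center=800_000),
                    PlantSpec(center=250_000),
                    PlantSpec(center=1_050_000),
                ],
            ),
            CellLineSpec(name="baseline1", planted_interactions=[PlantSpec(center=250_000)]),
        ]
    )


class ProfileSection(_Strict):
    min_fragment_len: int = 40
    viewpoint_exclusion: int = 5000
    smoothing_window: int = 30
    bin_size: int = 5000
    span: int = 1_000_000
    target_total: float = 1e6


class CallerSection(_Strict):
    viewpoint_fraction: float = 0.025
    snr_k: float = 2.5
    coverage_window: int = 30
    coverage_quantile: float = 0.75
    merge_gap: int = 40
    flank: int = 1_000_000


class PeakDesign(_Strict):
    mark: str
    n_replicates: int = 2
    n_peaks: int = 150
    overlap_with: str | None = None  # "gained" | "lost" | None
    overlap_fraction: float = 0.0
    width_mean: float = 500.0
    width_sd: float = 150.0


class EnrichmentSection(_Strict):
    n_permutations: int = 10_000
    peak_designs: list[PeakDesign] = Field(
        default_factory=lambda: [
            PeakDesign(mark="H3K27ac", overlap_with="gained", overlap_fraction=0.6),
            PeakDesign(mark="H3K4me3", overlap_with="gained", overlap_fraction=0.3),
            PeakDesign(mark="H3K27me3", overlap_with="lost", overlap_fraction=0.4),
            PeakDesign(mark="H3K9me3", overlap_with=None, overlap_fraction=0.0),
        ]
    )


class CorrelationSection(_Strict):
    width: int = 100


class MotifSection(_Strict):
    k: list[int] = Field(default_factory=lambda: [6, 7])
    e_value_threshold: float = 1.0


class PipelineConfig(_Strict):
    seed: int = 0
    sim: SimSection = Field(default_factory=SimSection)
    profile: ProfileSection = Field(default_factory=ProfileSection)
    caller: CallerSection = Field(default_factory=CallerSection)
    enrichment: EnrichmentSection = Field(default_factory=EnrichmentSection)
    correlation: CorrelationSection = Field(default_factory=CorrelationSection)
    motif: MotifSection = Field(default_factory=MotifSection)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
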