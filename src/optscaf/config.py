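"""Pipeline configuration: every tunable constant, visible and overridable.

The upstream procedure leaves most tolerances unstated; here they all live
in one YAML-serialisable structure with printed defaults, so a run is
fully described by (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .align import AlignParams
from .conflicts import ConflictTolerances
from .core import ENZYMES, RecognitionSpec


@dataclass(frozen=True)
class AnchoringConfig:
    min_markers: int = 2  # markers required to anchor a scaffold
    join_gap_bp: int = 1000  # fixed N spacer between anchored scaffolds


@dataclass(frozen=True)
class PlacementConfig:
    margin: float = 3.0  # confidence lead required over a rival locus
    overlap_tol_bp: int = 20_000
    min_gap_bp: int = 13


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    The confidence ladder (initial 10 / extension 11 / merge 15, in
    -log10 units) mirrors the 1e-10 / 1e-11 / 1e-15 significance rungs of
    the consensus-map toolchain: 10 gates initial alignment and placement,
    11 gates re-alignment of freshly split scaffold pieces, 15 gates
    second-round super-scaffold merges.
    """

    enzyme1: str = "dle1"  # direct-label map (round 1)
    enzyme2: str = "bspqi"  # nicking map (arbitration + round 2)
    digest_min_label_distance_bp: int = 0
    align: AlignParams = field(default_factory=AlignParams)
    confidence_initial: float = 10.0
    confidence_extension: float = 11.0
    confidence_merge: float = 15.0
    tolerances: ConflictTolerances = field(default_factory=ConflictTolerances)
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    anchoring: AnchoringConfig = field(default_factory=AnchoringConfig)

    def enzyme_spec(self, which: int) -> RecognitionSpec:
        key = self.enzyme1 if which == 1 else self.enzyme2
        try:
            return ENZYMES[key]
        except KeyError:
            raise KeyError(f"unknown enzyme {key!r}; known: {sorted(ENZYMES)}") from None

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if "align" in kwargs:
            kwargs["align"] = AlignParams(**kwargs["align"])
        if "tolerances" in kwargs:
            kwargs["tolerances"] = ConflictTolerances(**kwargs["tolerances"])
        if "placement" in kwargs:
            kwargs["placement"] = PlacementConfig(**kwargs["placement"])
        if "anchoring" in kwargs:
            kwargs["anchoring"] = AnchoringConfig(**kwargs["anchoring"])
        return cls(**kwargs)
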