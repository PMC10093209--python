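"""Run configuration: schema-validated YAML with a single fan-out seed.

Every stage draws its own random generator from the run seed through
:func:`stage_seed`, so any stage can be re-run in isolation and reproduce
its part of a pipeline run.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

#: fixed stage identifiers used to derive per-stage seeds from the run seed
STAGE_IDS = {
    "simulate": 1,
    "fuse": 2,
    "extract": 3,
    "train": 4,
    "score": 5,
    "evaluate": 6,
    "ablate": 7,
}


def stage_seed(run_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(run_seed), STAGE_IDS[stage], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateParams(_Strict):
    n_slides: int = 2
    slide_size_px: tuple[int, int] = (512, 512)
    tile_size_px: int = 160
    tile_overlap_px: int = 32
    jitter_max_px: int = 5
    n_cells_target: int = 400
    tumour_coverage: float = 0.5
    pixel_size_um: float = 0.32


class ExtractParams(_Strict):
    radius_px: float = 300.0
    min_area: int = 15
    baseline_percentile: float = 5.0
    backend: str = "reference"


class TrainParams(_Strict):
    model: str = "icf"  # icf | manova | mlp | unet
    normalisation: str = "feature_specific"
    n_select: int = 5
    mlp_epochs: int = 1
    mlp_subsample_stride: int = 10
    unet_epochs: int = 200
    unet_patch_px: int = 128
    threshold: float = 0.5


class EvaluateParams(_Strict):
    roi_size_fields: int = 16
    rois_per_class: int = 10
    purity: float = 0.95
    thresholds: list[float] = Field(default_factory=lambda: [0.3, 0.4, 0.5, 0.6, 0.7])


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    simulate: SimulateParams = Field(default_factory=SimulateParams)
    extract: ExtractParams = Field(default_factory=ExtractParams)
    train: TrainParams = Field(default_factory=TrainParams)
    evaluate: EvaluateParams = Field(default_factory=EvaluateParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def echo(self, out_dir: str | Path) -> None:
        """Write the resolved configuration into the output directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.yaml").write_text(yaml.safe_dump(self.model_dump(mode="json")))
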