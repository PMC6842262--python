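"""Pipeline configuration: defaults, YAML round-trip, seed fan-out."""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["PipelineConfig", "stage_seed"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run.

    Defaults are the method's reference settings: 1000 permutations for both
    permutation procedures, 1000 random signatures per size template, the
    dual selection thresholds (empirical 0, log10 nominal -10), diffusion
    bandwidth beta = 0.3, and calling cutoff alpha = 0.05.
    """

    expression: str = ""
    survival: str = ""
    templates: str = ""
    network: str = ""
    pathways: str = ""
    outdir: str = "randsig_out"
    n_perm_signature: int = 1000
    n_random_per_template: int = 1000
    empirical_threshold: float = 0.0
    log10_nominal_threshold: float = -10.0
    beta: float = 0.3
    n_perm_diffusion: int = 1000
    alpha: float = 0.05
    null_mode: str = "as-printed"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.null_mode not in ("as-printed", "raw-scores"):
            raise ValueError(f"unknown null_mode {self.null_mode!r}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
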