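"""Pipeline configuration: every adaptive threshold in one place.

The two headline thresholds were calibrated empirically by the method's
authors against benchmark databases (accumulated TC-difference curves):
families with avg(PID) below 18 % are routed to non-progressive sequence
annealing, and among progressively aligned families those with
σ(PID) < 11.5 % get a WPGMA guide tree instead of UPGMA.  Both
comparisons are strict ``<``; the boundary value takes the other branch.
Because those calibrations depend on the PID convention of the original
implementation, every threshold here is configurable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import InputError


@dataclass
class PipelineConfig:
    #: avg(PID) below this -> non-progressive sequence annealing
    anneal_threshold: float = 0.18
    #: σ(PID) below this -> WPGMA guide tree, else UPGMA (τ)
    tree_sd_threshold: float = 0.115
    #: avg(PID) at or above this -> global pair-HMM, else local model set
    hmm_global_threshold: float = 0.40
    #: consistency-transformation rounds
    consistency_rounds: int = 2
    #: posterior entries below this are dropped (also the annealing cutoff)
    sparsity_cutoff: float = 0.01
    #: iterative refinement on/off and its RNG seed
    refine: bool = True
    seed: int = 0
    #: PID convention: denominator and gap penalties of the NW alignment
    pid_denominator: str = "aligned"
    pid_gap_open: float = 10.0
    pid_gap_extend: float = 1.0
    #: output format: "fasta" or "clustal"
    output_format: str = "fasta"
    #: optional path to a flat key-value pair-HMM parameter file
    hmm_params_file: str | None = None

    def __post_init__(self) -> None:
        for name in ("anneal_threshold", "tree_sd_threshold", "hmm_global_threshold",
                     "sparsity_cutoff"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {value}")
        if self.consistency_rounds < 0:
            raise InputError("consistency_rounds must be >= 0")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise InputError("config file must contain a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
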