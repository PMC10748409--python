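"""Configuration for the synthetic-data generators.

One config object (loadable from YAML) drives every generator; the
defaults mirror the study conditions the pipeline is meant for: a
600-subject genotype panel for block estimation, a 29-sample cohort
with 7 lost to follow-up, and three-caller variant calls filtered at
QUAL 20.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class BlockSpec:
    """One planted haplotype block: markers, bp span, and the
    recombination probability between this block and the previous one
    (1.0 = free recombination)."""

    n_markers: int
    span_bp: int
    recomb_rate_between: float = 1.0

    def validate(self) -> None:
        if self.n_markers < 2:
            raise ValueError("a block needs at least 2 markers")
        if self.span_bp < self.n_markers:
            raise ValueError(
                f"span {self.span_bp} bp cannot hold {self.n_markers} markers"
            )
        if not 0 <= self.recomb_rate_between <= 1:
            raise ValueError("recomb_rate_between must be a probability")


DEFAULT_BLOCKS = [
    BlockSpec(8, 5000, 1.0),
    BlockSpec(10, 8000, 1.0),
    BlockSpec(6, 4000, 1.0),
    BlockSpec(8, 6000, 1.0),
    BlockSpec(10, 7000, 1.0),
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_snps: int = 100
    n_subjects: int = 600

    # LD-panel structure
    block_spec: list[BlockSpec] = field(default_factory=lambda: list(DEFAULT_BLOCKS))
    founder_haplotypes: int = 4
    mutation_rate: float = 0.0
    inter_block_gap_bp: int = 30_000

    # genome-pair edits (counts of planted liftover outcomes)
    n_no_ortholog: int = 0
    n_too_long: int = 0
    n_unplaced: int = 0
    n_gap_at_snp: int = 0
    n_inverted: int = 0
    substitution_rate: float = 0.0

    # caller emulation
    caller_fn_rate: float = 0.0
    caller_fp_rate: float = 0.0
    caller_lowqual_rate: float = 0.0
    indel_jitter_rate: float = 0.0

    # survival
    beta: list[float] = field(default_factory=list)
    censor_fraction: float = 7 / 29
    baseline_hazard: float = 1 / 300  # events per day
    weibull_shape: float = 1.0  # 1.0 = exponential baseline

    def validate(self) -> None:
        probs = {
            "caller_fn_rate": self.caller_fn_rate,
            "caller_fp_rate": self.caller_fp_rate,
            "caller_lowqual_rate": self.caller_lowqual_rate,
            "indel_jitter_rate": self.indel_jitter_rate,
            "censor_fraction": self.censor_fraction,
            "mutation_rate": self.mutation_rate,
            "substitution_rate": self.substitution_rate,
        }
        for name, v in probs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        planted = (
            self.n_no_ortholog + self.n_too_long + self.n_unplaced
            + self.n_gap_at_snp + self.n_inverted
        )
        if planted > self.n_snps:
            raise ValueError(
                f"{planted} planted non-trivial liftover outcomes exceed n_snps={self.n_snps}"
            )
        if self.founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        if any(not (b == b and abs(b) < float("inf")) for b in self.beta):
            raise ValueError("beta coefficients must be finite")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        for b in self.block_spec:
            b.validate()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        blocks = [BlockSpec(**b) for b in d.pop("block_spec", [])]
        cfg = cls(block_spec=blocks or list(DEFAULT_BLOCKS), **d)
        cfg.validate()
        return cfg
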