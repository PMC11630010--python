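"""Pipeline configuration.

All tunables of the analysis live here: the edge-significance level, the
community-resolution exponent alpha, the merge threshold beta, the node
influence variant, and the core-disease selection rule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class PipelineConfig:
    #: two-sided significance level for correlation and regression edges
    p_threshold: float = 0.05
    #: resolution exponent of the community fitness f = k_in / (k_in + k_out)**alpha;
    #: smaller alpha yields larger communities
    alpha: float = 1.0
    #: overlap-similarity threshold above which communities are merged
    beta: float = 0.5
    rng_seed: int = 0
    missing_policy: str = "drop_row"
    #: "quotient": NI_i = sum_j A_ij / D_j  (default); "product": sum_j A_ij * D_j
    influence_variant: str = "quotient"
    #: core diseases = top-k non-bridge by influence; or absolute cutoff if set
    core_k: int = 3
    core_threshold: float | None = None
    #: compute Eq.4/5 metrics on the disease-only subnetwork ("disease") or the
    #: full integrated graph ("full")
    metrics_scope: str = "disease"
    #: re-check members for removal after each LFM insertion
    lfm_removal: bool = True
    #: "random": uniformly random uncovered seed; "strength": highest-strength uncovered
    seed_strategy: str = "random"
    #: min-max rescale weights per edge kind before integration (sensitivity switch)
    rescale_weights: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.influence_variant not in ("quotient", "product"):
            raise ValueError("influence_variant must be 'quotient' or 'product'")
        if self.metrics_scope not in ("disease", "full"):
            raise ValueError("metrics_scope must be 'disease' or 'full'")
        if self.seed_strategy not in ("random", "strength"):
            raise ValueError("seed_strategy must be 'random' or 'strength'")

    def to_dict(self) -> dict:
        return asdict(self)
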