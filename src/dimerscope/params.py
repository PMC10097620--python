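"""Tuning constants of the analysis pipeline.

Defaults reproduce the published Perseus/R settings: downshift imputation
with width 0.3 and down-shift 1.8 (separately per column), permutation FDR
0.1 with s0 = 0.1 over 250 randomisations, and differential calls at linear
fold change > 1.5 with BH-adjusted P < 0.05. The valid-value filters keep
proteins with >= 3 observed values in at least one condition and discard
proteins with more than 2 missing values in every condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError


@dataclass
class AnalysisParams:
    width: float = 0.3            # imputation sd multiplier (unitless)
    downshift: float = 1.8        # imputation mean shift, in column sds
    s0: float = 0.1               # artificial within-group variance (log2 units)
    target_fdr: float = 0.1       # permutation-FDR level for the cutoff curve
    n_randomisations: int = 250
    fold_change: float = 1.5      # linear-scale enrichment gate
    alpha: float = 0.05           # BH-adjusted significance level
    min_valid: int = 3            # observed values required in >=1 condition
    max_missing_per_condition: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.target_fdr < 1 and 0 < self.alpha < 1):
            raise ConfigurationError("target_fdr and alpha must lie in (0, 1)")
        if self.width <= 0:
            raise ConfigurationError("width must be > 0")
        if self.s0 < 0:
            raise ConfigurationError("s0 must be >= 0")
        if self.fold_change <= 1:
            raise ConfigurationError("fold_change must be > 1 (linear scale)")
        if self.n_randomisations < 1 or self.min_valid < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.max_missing_per_condition < 0:
            raise ConfigurationError("max_missing_per_condition must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def stage_seeds(self) -> dict[str, int]:
        """Derive independent per-stage seeds from the master seed.

        Stages can be re-run in isolation and still reproduce the full-run
        draws because each consumes its own child of the master seed.
        """
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("simulate", "downshift", "lognormal", "permutation")
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for name, child in zip(names, children)
        }
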