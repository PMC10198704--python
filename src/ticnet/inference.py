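"""Shared permutation-inference configuration types."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PermutationScheme", "TfceParams"]


@dataclass(frozen=True)
class PermutationScheme:
    """Monte-Carlo permutation settings.

    With ``n_perm`` permutations the smallest attainable p-value is
    ``1 / (n_perm + 1)`` (add-one rule, observed data counted as one member of
    the null).
    """

    n_perm: int = 1000
    rng_seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def min_p(self) -> float:
        return 1.0 / (self.n_perm + 1.0)


@dataclass(frozen=True)
class TfceParams:
    """Threshold-free cluster enhancement parameters.

    ``E`` and ``H`` are the extent and height exponents (neuroimaging defaults
    0.5 and 2.0); the integral over thresholds is approximated with
    ``n_steps`` equal steps from 0 to the map maximum; cluster extents use the
    given 3-D connectivity.
    """

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("TFCE exponents E and H must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
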