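"""Analysis configuration shared by the library, model class and CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError
from .rank_stats import DEFAULT_EXACT_THRESHOLD, DEFAULT_LAMBDA_GRID

__all__ = ["AnalysisConfig", "DUPLICATE_POLICIES", "TEST_METHODS"]

DUPLICATE_POLICIES = ("error", "mean", "median", "first")
TEST_METHODS = ("auto", "exact", "normal_approx", "permutation")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of one enrichment run.

    Attributes
    ----------
    databases
        Member databases to analyse (None = all in the annotation store).
        Each selected database is tested and FDR-corrected independently.
    min_set_size
        Smallest number of associated identifiers for a feature to be tested.
        Defaults to 2: domain families are often tiny and the exact test
        handles them.
    exact_threshold
        Largest min(n_domain, n_rest) for the exact U null distribution
        (tie-free samples only).
    alpha
        BH significance level used by reporting helpers.
    lambda_grid, pi0_min_tests
        Storey pi0 estimation grid and the minimum family size below which
        pi0 falls back to 1.
    duplicate_policy
        What to do with repeated measurement identifiers: "error" (default),
        or aggregate by "mean"/"median", or "first".
    case_fold
        Case-insensitive identifier matching (off by default; gene symbols
        are case-meaningful across species).
    test_method, n_permutations, seed
        Test path selection; the seed only affects the optional permutation
        mode (and simulation, elsewhere).
    """

    databases: tuple[str, ...] | None = None
    min_set_size: int = 2
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD
    alpha: float = 0.05
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    pi0_min_tests: int = 100
    duplicate_policy: str = "error"
    case_fold: bool = False
    test_method: str = "auto"
    n_permutations: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_set_size < 1:
            raise ConfigurationError("min_set_size must be >= 1")
        if self.exact_threshold < 0:
            raise ConfigurationError("exact_threshold must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.pi0_min_tests < 1:
            raise ConfigurationError("pi0_min_tests must be >= 1")
        if any(not 0.0 <= l < 1.0 for l in self.lambda_grid):
            raise ConfigurationError("lambda_grid values must lie in [0, 1)")
        if self.duplicate_policy not in DUPLICATE_POLICIES:
            raise ConfigurationError(
                f"duplicate_policy must be one of {DUPLICATE_POLICIES}"
            )
        if self.test_method not in TEST_METHODS:
            raise ConfigurationError(f"test_method must be one of {TEST_METHODS}")
        if self.n_permutations < 100:
            raise ConfigurationError("n_permutations must be >= 100")

    def snapshot(self) -> dict:
        """JSON-serialisable reproducibility snapshot for report metadata."""
        out = asdict(self)
        out["databases"] = list(self.databases) if self.databases else None
        out["lambda_grid"] = list(self.lambda_grid)
        return out
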