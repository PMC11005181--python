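"""Shared permutation-test machinery and set-enrichment utilities."""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class PermutationReport:
    """Outcome of a permutation test.

    ``p_value`` follows the add-one convention ``(k + 1) / (n + 1)``, except
    that a test with zero exceedances at ``n`` permutations is reported as
    ``1 / n`` (so 0 hits in 1000 permutations prints as p = 0.001).
    """

    statistic: str
    observed: float
    n_perm: int
    n_exceeding: int
    p_value: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def permutation_pvalue(n_exceeding: int, n_perm: int) -> float:
    """Empirical p-value with the add-one correction.

    Zero exceedances are reported as ``1 / n_perm`` rather than
    ``1 / (n_perm + 1)``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not 0 <= n_exceeding <= n_perm:
        raise ValueError("n_exceeding outside [0, n_perm]")
    if n_exceeding == 0:
        return 1.0 / n_perm
    return (n_exceeding + 1) / (n_perm + 1)


def make_report(
    statistic: str,
    observed: float,
    null: np.ndarray,
    *,
    direction: str,
    seed: int | None = None,
) -> PermutationReport:
    """Build a :class:`PermutationReport` from an observed value and a null sample.

    ``direction`` is the tail counted as at least as extreme: ``"ge"`` counts
    null values >= observed, ``"le"`` counts null values <= observed.
    """
    null = np.asarray(null, dtype=float)
    if direction == "ge":
        k = int(np.sum(null >= observed))
    elif direction == "le":
        k = int(np.sum(null <= observed))
    else:
        raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
    return PermutationReport(
        statistic=statistic,
        observed=float(observed),
        n_perm=null.size,
        n_exceeding=k,
        p_value=permutation_pvalue(k, null.size),
        seed=seed,
    )


def set_enrichment_permutation(
    set_a,
    set_b,
    universe,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Overlap enrichment of two gene/region sets against a sampling null.

    The null redraws ``|set_a|`` elements uniformly without replacement from
    the universe and records the overlap with ``set_b``; the fold change is
    the observed overlap over the mean null overlap.
    """
    set_a, set_b, universe = set(set_a), set(set_b), list(dict.fromkeys(universe))
    uni = set(universe)
    if not set_a <= uni or not set_b <= uni:
        raise ValueError("set_a and set_b must be subsets of the universe")
    if len(set_a) > len(universe):
        raise ValueError("set_a larger than universe")
    rng = np.random.default_rng(seed)
    in_b = np.fromiter((u in set_b for u in universe), dtype=bool, count=len(universe))
    observed = len(set_a & set_b)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(universe), size=len(set_a), replace=False)
        null[i] = in_b[idx].sum()
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else np.inf
    report = make_report(
        "set_overlap", observed, null, direction="ge", seed=seed
    )
    return {"overlap": observed, "fold_vs_null": fold, "report": report}
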