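"""Rank-based inverse normal transformation (rkt).

Maps each value to the standard-normal quantile of its (tie-averaged) rank,
the normalization routinely applied to expression phenotypes before eQTL
analysis.  Because the map depends only on ranks it is invariant to any
strictly increasing transform of the input -- which is precisely why it can
create or destroy *interaction* signal, whose definition is scale-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = ["RankTransformSpec", "rank_inverse_normal", "DegenerateInputError"]


class DegenerateInputError(ValueError):
    """Input has no rank structure (constant vector)."""


@dataclass(frozen=True)
class RankTransformSpec:
    """Quantile-position and tie conventions for the rank transform.

    ``offset_rule="half"`` places rank r at quantile (r - 0.5)/n (default);
    ``"blom"`` uses (r - 3/8)/(n + 1/4).  Ties always take average ranks.
    """

    offset_rule: Literal["half", "blom"] = "half"
    tie_rule: Literal["average"] = "average"


_DEFAULT_SPEC = RankTransformSpec()


def rank_inverse_normal(
    values: np.ndarray, spec: RankTransformSpec = _DEFAULT_SPEC
) -> np.ndarray:
    """Transform ``values`` to normal quantiles of their ranks.

    Element i maps to ``Phi^-1((r_i - 0.5)/n)`` (or the Blom position) where
    r_i is the tie-averaged rank.  Output has sample mean ~0 and variance ~1
    for large tie-free inputs, and sorted output is exactly symmetric about 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("rank_inverse_normal expects a 1-D vector")
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.all(v == v[0]):
        raise DegenerateInputError("constant vector: ranks are undefined")
    r = stats.rankdata(v, method=spec.tie_rule)
    if spec.offset_rule == "half":
        q = (r - 0.5) / n
    elif spec.offset_rule == "blom":
        q = (r - 0.375) / (n + 0.25)
    else:  # pragma: no cover - frozen dataclass guards this
        raise ValueError(f"unknown offset_rule {spec.offset_rule!r}")
    return stats.norm.ppf(q)
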