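"""Recovery metrics against planted ground truth."""

from __future__ import annotations

from typing import Hashable, Mapping

from sklearn.metrics import adjusted_rand_score


def partition_ari(found: Mapping[Hashable, Hashable],
                  truth: Mapping[Hashable, Hashable]) -> float:
    """Adjusted Rand index between a detected assignment and planted labels,
    over the vertices present in ``found``."""
    keys = sorted(found, key=str)
    if not keys:
        raise ValueError("empty partition")
    return float(adjusted_rand_score([truth[k] for k in keys],
                                     [found[k] for k in keys]))
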