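"""Individual-based rarefaction: expected richness under subsampling.

For a community with per-taxon counts ``N_i`` (total ``N``), the expected
number of taxa seen in a uniform random subsample of ``n`` individuals
drawn without replacement is

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

Binomial ratios are evaluated in log space (``gammaln``) so totals in the
millions do not overflow; the result is exact (to floating point) for
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .community import CommunityMatrix
from .formats import PathLike


@dataclass(frozen=True)
class RarefactionCurve:
    sample: str
    depths: tuple[int, ...]
    expected_richness: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.expected_richness):
            raise ValueError("depths and expected_richness must align")
        if any(b <= a for a, b in zip(self.depths, self.depths[1:])):
            raise ValueError("depths must be strictly increasing")


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def expected_richness(counts: Sequence[int], n: int) -> float:
    """Expected taxon richness in a subsample of ``n`` individuals.

    ``counts`` are non-negative integers (zero-count taxa are ignored);
    ``n`` must satisfy 0 <= n <= sum(counts).
    """
    arr = np.asarray(counts)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integers (read counts)")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("negative counts")
    arr = arr[arr > 0].astype(np.float64)
    total = arr.sum()
    if not 0 <= n <= total:
        raise ValueError(f"subsample size {n} out of [0, {int(total)}]")
    if n == 0 or arr.size == 0:
        return 0.0
    # P(taxon i absent) = C(N - N_i, n) / C(N, n); zero when N - N_i < n
    rest = total - arr
    p_absent = np.zeros_like(arr)
    feasible = rest >= n
    if feasible.any():
        log_p = _log_choose(rest[feasible], float(n)) - _log_choose(total, float(n))
        p_absent[feasible] = np.exp(log_p)
    return float(np.sum(1.0 - p_absent))


def auto_depths(total: int, n_points: int = 20) -> tuple[int, ...]:
    """Up to ``n_points`` evenly spaced integer depths from 1 to ``total``."""
    if total < 1:
        raise ValueError("community is empty")
    grid = np.unique(np.linspace(1, total, min(n_points, total)).round().astype(int))
    return tuple(int(d) for d in grid)


def rarefaction_curve(
    matrix: CommunityMatrix,
    sample: str,
    depths: Sequence[int] | None = None,
) -> RarefactionCurve:
    """Expected richness for one sample's community row at each depth.

    ``depths`` defaults to 20 evenly spaced depths from 1 to the sample's
    total count; a depth beyond the total is an error.
    """
    if sample not in matrix.samples:
        raise KeyError(f"sample {sample!r} not in matrix")
    counts = matrix.row(sample)
    total = int(counts.sum())
    if depths is None:
        chosen = auto_depths(total)
    else:
        chosen = tuple(int(d) for d in depths)
        for d in chosen:
            if d > total:
                raise ValueError(f"depth {d} exceeds sample total {total}")
    return RarefactionCurve(
        sample=sample,
        depths=chosen,
        expected_richness=tuple(expected_richness(counts, d) for d in chosen),
    )


def curves_for_matrix(
    matrix: CommunityMatrix,
    depths: Sequence[int] | None = None,
    exclude_taxa: Sequence[str] = ("Total",),
) -> list[RarefactionCurve]:
    """One curve per sample, skipping samples with an empty community."""
    keep = [j for j, t in enumerate(matrix.taxa) if t not in set(exclude_taxa)]
    curves = []
    for sample in matrix.samples:
        counts = matrix.row(sample)[keep]
        total = int(counts.sum())
        if total == 0:
            continue
        sub = CommunityMatrix(
            samples=(sample,),
            taxa=tuple(matrix.taxa[j] for j in keep),
            counts=counts.reshape(1, -1),
        )
        curves.append(rarefaction_curve(sub, sample, depths))
    return curves


def saturation_depth(curve: RarefactionCurve, tolerance: float = 0.01) -> int | None:
    """Smallest depth where the curve is within ``tolerance`` taxa of its end.

    Plateau heuristic only; not used by any acceptance property.
    """
    final = curve.expected_richness[-1]
    for d, r in zip(curve.depths, curve.expected_richness):
        if final - r <= tolerance:
            return d
    return None


def write_curves_csv(curves: Sequence[RarefactionCurve], path: PathLike) -> None:
    """Long-format CSV: sample, depth, expected_richness."""
    rows = [
        {"sample": c.sample, "depth": d, "expected_richness": r}
        for c in curves
        for d, r in zip(c.depths, c.expected_richness)
    ]
    pd.DataFrame(rows, columns=["sample", "depth", "expected_richness"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def plot_curves(curves: Sequence[RarefactionCurve], path: PathLike) -> None:
    """Optional per-sample plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.plot(c.depths, c.expected_richness, label=c.sample)
    ax.set_xlabel("subsample size")
    ax.set_ylabel("expected richness")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
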