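"""Bayesian false-discovery-rate thresholding of PIP maps.

Across the (hundreds of thousands of) voxels in a mask, the posterior
inclusion probability pi_k(v) of a covariate is thresholded so that the
posterior expected proportion of false inclusions among the declared
voxels stays below a level delta: sort the PIPs descending (Psi), take
the largest k* whose running mean of (1 - Psi) is <= delta, and declare
every voxel with PIP >= phi_delta = Psi[k*]. Thresholding is applied
per covariate; a pooled mode over all covariate columns at once exists
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_DELTA = 0.10


@dataclass(frozen=True)
class FDRResult:
    """Outcome of Bayesian FDR thresholding for one covariate.

    ``phi`` is the realized PIP threshold (+inf sentinel when even the
    top voxel fails, giving an empty set), ``xi`` the number of
    surviving voxels, and ``significant_voxels`` their indices paired
    with their PIPs. Ties at the threshold are all included.
    """

    covariate_name: str
    delta: float
    phi: float
    xi: int
    significant_voxels: list[tuple[int, float]]

    @property
    def indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.significant_voxels], dtype=int)


def bfdr_threshold(
    pips: np.ndarray, delta: float = DEFAULT_DELTA, covariate_name: str = ""
) -> FDRResult:
    """Threshold one covariate's PIPs at Bayesian FDR level delta."""
    if not 0 < delta < 1:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    pips = np.asarray(pips, dtype=float).reshape(-1)
    if pips.size and (np.min(pips) < 0 or np.max(pips) > 1):
        raise ValueError("PIPs must lie in [0, 1]")
    if pips.size == 0:
        return FDRResult(covariate_name, delta, np.inf, 0, [])

    order = np.argsort(-pips, kind="stable")
    psi = pips[order]
    running_mean = np.cumsum(1.0 - psi) / np.arange(1, len(psi) + 1)
    ok = np.flatnonzero(running_mean <= delta)
    if ok.size == 0:
        return FDRResult(covariate_name, delta, np.inf, 0, [])
    k_star = int(ok[-1]) + 1
    phi = float(psi[k_star - 1])
    sig_idx = np.flatnonzero(pips >= phi)
    sig = [(int(i), float(pips[i])) for i in sig_idx]
    return FDRResult(covariate_name, delta, phi, len(sig), sig)


def realized_bayes_fdr(result: FDRResult) -> float:
    """Realized Bayesian FDR of a declared set: mean of (1 - PIP) over it.

    This is the posterior expected proportion of false inclusions among
    the declared voxels — the quantity the thresholding rule bounds by
    delta. Empty sets have realized FDR 0.
    """
    if result.xi == 0:
        return 0.0
    return float(np.mean([1.0 - p for _, p in result.significant_voxels]))


def fdr_all_covariates(
    pip_map: np.ndarray,
    delta: float = DEFAULT_DELTA,
    covariate_names: Sequence[str] | None = None,
    pooled: bool = False,
) -> list[FDRResult]:
    """Apply :func:`bfdr_threshold` to each column of a voxels x k PIP matrix.

    With ``pooled=True`` a single threshold is computed from all columns
    stacked together and then applied to each column (sensitivity mode);
    the default is fully independent per-covariate thresholding.
    """
    pip_map = np.asarray(pip_map, dtype=float)
    if pip_map.ndim != 2:
        raise ValueError("pip_map must be voxels x covariates")
    k = pip_map.shape[1]
    if covariate_names is None:
        covariate_names = [f"x{i}" for i in range(k)]
    if len(covariate_names) != k:
        raise ValueError("covariate_names length mismatch")

    if not pooled:
        return [
            bfdr_threshold(pip_map[:, c], delta, covariate_names[c]) for c in range(k)
        ]

    pooled_res = bfdr_threshold(pip_map.T.reshape(-1), delta, "pooled")
    phi = pooled_res.phi
    out = []
    for c in range(k):
        col = pip_map[:, c]
        sig_idx = np.flatnonzero(col >= phi) if np.isfinite(phi) else np.array([], int)
        sig = [(int(i), float(col[i])) for i in sig_idx]
        out.append(FDRResult(covariate_names[c], delta, phi, len(sig), sig))
    return out
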