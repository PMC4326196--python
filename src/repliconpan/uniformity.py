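"""Positional uniformity of shared genes along a replicon.

The observed sample is the pooled start and end coordinates of the shared
genes on one replicon. Three methods are offered:

* ``paper_single_draw`` — compare the observed positions against ONE uniform
  random sample of equal size on [1, L] with a two-sided Mann-Whitney test;
* ``averaged_resample`` (default) — repeat that construction over many seeded
  draws and report the median p plus the fraction of draws rejecting at
  alpha = 0.05, removing the single-draw resampling noise;
* ``ks`` — a one-sample Kolmogorov-Smirnov test against Uniform(1, L), the
  principled location+shape cross-check.

The Mann-Whitney construction is location-sensitive only: clustering split
symmetrically between both replicon ends can evade it. That behaviour is kept
deliberately (the KS method is the remedy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .composition import mann_whitney
from .records import Gene, Replicon


@dataclass
class UniformityResult:
    replicon_id: str
    n_positions: int
    statistic: float
    p_value: float
    method: str
    n_resamples: int
    seed: int
    rejection_fraction: float | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0
        assert self.n_positions >= 1


def shared_positions(
    replicon: Replicon, genes: list[Gene], partition, family_of: dict[str, str]
) -> list[int]:
    """Pooled, sorted start+end coordinates of shared genes on a replicon.

    ``family_of`` maps gene_id -> family_id. Replicons without shared genes
    yield an empty list (the test is then skipped)."""
    shared_fams = set(partition.shared_family_ids())
    positions: list[int] = []
    for g in genes:
        if g.replicon_id != replicon.replicon_id:
            continue
        fam = family_of.get(g.gene_id)
        if fam in shared_fams:
            positions.extend([g.start, g.end])
    return sorted(positions)


def uniformity_test(
    positions: list[int],
    replicon_length: int,
    method: str = "averaged_resample",
    n_resamples: int = 1000,
    seed: int = 0,
    replicon_id: str = "",
) -> UniformityResult:
    """Test the position sample against a uniform distribution on [1, L]."""
    if not positions:
        raise ValueError("empty position list")
    pos = np.asarray(positions, dtype=float)
    if pos.min() < 1 or pos.max() > replicon_length:
        raise ValueError("positions outside [1, replicon_length]")

    rng = np.random.default_rng(seed)
    if method == "paper_single_draw":
        draw = rng.uniform(1, replicon_length, size=pos.size)
        u, p = mann_whitney(pos, draw)
        return UniformityResult(replicon_id, pos.size, u, p, method, 1, seed)
    if method == "averaged_resample":
        ps = np.empty(n_resamples)
        for i in range(n_resamples):
            draw = rng.uniform(1, replicon_length, size=pos.size)
            _, ps[i] = mann_whitney(pos, draw)
        return UniformityResult(
            replicon_id,
            pos.size,
            float(np.median(ps)),
            float(np.median(ps)),
            method,
            n_resamples,
            seed,
            rejection_fraction=float((ps < 0.05).mean()),
        )
    if method == "ks":
        stat, p = stats.kstest(pos, "uniform", args=(1, replicon_length - 1))
        return UniformityResult(replicon_id, pos.size, float(stat), float(p), method, 0, seed)
    raise ValueError(f"unknown method {method!r}")
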