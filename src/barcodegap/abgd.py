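"""Automatic barcode-gap partitioning of a distance matrix.

The barcode gap is the discontinuity between the intraspecific and
interspecific parts of the ranked pairwise-distance distribution.  For each
prior maximum intraspecific divergence P (a log-spaced grid), the detector

1. locates the highest-ranked distance still compatible with the prior
   (largest distance <= P) — distances up to that rank are presumed
   intraspecific and are not eligible gap locations;
2. scans the subsequent rank intervals (d_i, d_{i+1}) and flags the first
   whose width exceeds X times a local slope estimate of the preceding
   ranks (sliding window of max(10, 5% of pairs) ranks), X being the
   relative gap width;
3. partitions sequences by graph connectivity at the gap's lower bound
   (edges d <= gap_low), then re-applies gap detection inside each group
   until no further significant gap splits a group.

Inside a subgroup the effective prior is capped at the subgroup's mean
pairwise distance: after a split, distances that the parent pass treated as
intraspecific (because they sat below the global prior) must become eligible
gap locations, otherwise nested divergence scales can never be resolved.

One partition is finally chosen by a stability rule: the modal recursive
group count across the prior grid, earliest prior on ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .delimit import LineagePartition, _components, label_components
from .distances import DistanceMatrix


@dataclass(frozen=True)
class AbgdConfig:
    """Prior grid and gap-significance settings.

    Defaults follow the method's canonical web defaults (priors log-spaced
    from 0.001 to 0.1 in 10 steps) with relative gap width X = 1.0.
    """

    p_min: float = 0.001
    p_max: float = 0.1
    n_steps: int = 10
    rel_gap_width: float = 1.0  # X
    n_bins: int = 20  # diagnostic histogram only

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min < self.p_max < 1.0):
            raise ValueError("need 0 < p_min < p_max < 1")
        if self.n_steps < 1 or self.rel_gap_width <= 0:
            raise ValueError("n_steps >= 1 and X > 0 required")

    @property
    def priors(self) -> np.ndarray:
        return np.geomspace(self.p_min, self.p_max, self.n_steps)


class GapInterval(NamedTuple):
    low: float
    high: float


def find_gap(sorted_pairs, prior_p: float, X: float = 1.0,
             window: int | None = None,
             width_rel_location: bool = False) -> GapInterval | None:
    """First significant gap in an ascending list of pairwise distances.

    A rank interval (d_i, d_{i+1}) qualifies when d_i is at or beyond the
    prior-derived intraspecific limit (the largest distance <= prior_p; if
    every distance exceeds the prior the scan starts at the first rank), at
    least three ranks of intraspecific evidence precede it, and its width
    exceeds X times the local mean rank spacing estimated over the preceding
    ``window`` ranks (default max(10, 5% of pairs)).  Returns None when no
    interval qualifies or fewer than two distinct distances exist.

    With ``width_rel_location`` the width must additionally exceed X times
    the gap's own lower edge (divergence must grow by the relative gap
    width across the gap) and a full window of preceding ranks is required
    — the stricter criterion used for recursive splits, which claim a
    coarser divergence scale nested inside a group.
    """
    d = np.sort(np.asarray(list(sorted_pairs), dtype=float))
    d = d[~np.isnan(d)]
    n = len(d)
    if n < 2 or len(np.unique(d)) < 2:
        return None
    w = window if window is not None else max(10, math.ceil(0.05 * n))
    # last rank still presumed intraspecific under the prior
    start = int(np.searchsorted(d, prior_p, side="right")) - 1
    min_evidence = w if width_rel_location else 3
    for i in range(max(start, min_evidence), n - 1):
        width = d[i + 1] - d[i]
        if width <= 0.0:
            continue
        lo = max(0, i - w)
        slope = (d[i] - d[lo]) / (i - lo)
        floor = max(slope, d[i]) if width_rel_location else slope
        if width > X * floor:
            return GapInterval(float(d[i]), float(d[i + 1]))
    return None


@dataclass
class PriorResult:
    prior: float
    gap: GapInterval | None
    initial: LineagePartition
    recursive: LineagePartition


@dataclass
class GapPartitionResult:
    """Per-prior initial/recursive partitions plus the chosen stable one."""

    per_prior: list[PriorResult]
    chosen: LineagePartition
    chosen_prior: float

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"prior": r.prior,
             "gap_low": r.gap.low if r.gap else math.nan,
             "gap_high": r.gap.high if r.gap else math.nan,
             "n_groups_initial": r.initial.n_lineages,
             "n_groups_recursive": r.recursive.n_lineages}
            for r in self.per_prior
        ])


def _within_distances(dm: DistanceMatrix, ids: list[str]) -> np.ndarray:
    idx = [dm.index(i) for i in ids]
    sub = dm.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(ids), k=1)
    vals = sub[iu]
    return vals[~np.isnan(vals)]


def _split_once(dm: DistanceMatrix, ids: list[str], prior: float, X: float,
                width_rel_location: bool = False
                ) -> tuple[GapInterval | None, list[list[str]]]:
    vals = _within_distances(dm, ids)
    gap = find_gap(vals, prior, X, width_rel_location=width_rel_location)
    if gap is None:
        return None, [sorted(ids)]
    comps = _components(dm, ids, gap.low, strict=False)
    return gap, comps


def _recurse(dm: DistanceMatrix, ids: list[str], prior: float,
             X: float) -> list[list[str]]:
    if len(ids) < 3:
        return [sorted(ids)]
    vals = _within_distances(dm, ids)
    if len(vals) == 0:
        return [sorted(ids)]
    eff_prior = min(prior, float(np.mean(vals)))
    gap, comps = _split_once(dm, ids, eff_prior, X, width_rel_location=True)
    if gap is None or len(comps) < 2:
        # a "gap" that does not disconnect the graph is not a split
        return [sorted(ids)]
    out: list[list[str]] = []
    for comp in comps:
        out.extend(_recurse(dm, comp, prior, X))
    return out


def abgd_partition(dm: DistanceMatrix,
                   cfg: AbgdConfig | None = None) -> GapPartitionResult:
    """Barcode-gap partition across the prior grid, with recursive refinement.

    For each prior: the initial partition cuts at the first significant gap
    of the global ranked distances; the recursive partition re-applies gap
    detection within each group until no gap splits a group.  The chosen
    partition is the recursive partition from the stability rule: the
    contiguous run of priors yielding an identical group count that spans
    the largest prior range (each grid point owns the linear interval
    between the geometric midpoints to its neighbours), earliest run on
    ties.
    """
    cfg = cfg or AbgdConfig()
    ids = list(dm.ids)
    if len(ids) <= 2:
        trivial = label_components([sorted(ids)], prefix="G")
        import warnings
        warnings.warn("fewer than 3 sequences: trivial single-group partition")
        return GapPartitionResult(
            [PriorResult(float(p), None, trivial, trivial)
             for p in cfg.priors],
            trivial, float(cfg.priors[0]))

    per_prior: list[PriorResult] = []
    for prior in cfg.priors:
        gap, comps = _split_once(dm, ids, float(prior), cfg.rel_gap_width)
        initial = label_components(comps, prefix="G")
        rec_comps: list[list[str]] = []
        for comp in comps:
            rec_comps.extend(_recurse(dm, comp, float(prior),
                                      cfg.rel_gap_width))
        rec_comps.sort(key=lambda c: c[0])
        recursive = label_components(rec_comps, prefix="G")
        per_prior.append(PriorResult(float(prior), gap, initial, recursive))

    chosen_res = per_prior[_stable_index(
        [r.prior for r in per_prior],
        [r.recursive.n_lineages for r in per_prior])]
    return GapPartitionResult(per_prior, chosen_res.recursive,
                              chosen_res.prior)


def _stable_index(priors: list[float], counts: list[int]) -> int:
    """Index into the run of identical counts spanning the widest prior range.

    Each grid point represents the linear prior interval between the
    geometric midpoints to its neighbours (grid endpoints own their half
    cell); the widths of a contiguous equal-count run are summed and the
    widest run wins, earliest on ties."""
    edges = [priors[0]]
    for a, b in zip(priors, priors[1:]):
        edges.append(math.sqrt(a * b))
    edges.append(priors[-1])
    widths = [edges[i + 1] - edges[i] for i in range(len(priors))]
    best_i, best_w = 0, -1.0
    i = 0
    while i < len(counts):
        j = i
        while j < len(counts) and counts[j] == counts[i]:
            j += 1
        run_w = sum(widths[i:j])
        if run_w > best_w + 1e-15:
            best_i, best_w = i, run_w
        i = j
    return best_i


def distance_histogram(dm: DistanceMatrix, n_bins: int = 20) -> pd.DataFrame:
    """Ranked-distance histogram (bin edges and counts) for gap diagnostics."""
    vals = dm.condensed()
    counts, edges = np.histogram(vals, bins=n_bins)
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                         "count": counts})
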