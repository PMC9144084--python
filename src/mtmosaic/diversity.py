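"""Nucleotide diversity, divergence, sliding-window profiles, and trees.

All distances are raw p-distances (proportion of differing sites among
comparable sites, no multiple-hit correction).  A site is *comparable* for
a pair when both sequences carry an unambiguous base (``A/C/G/T``); gaps
and ``N`` are excluded.  Two deletion policies are supported:

``pairwise``
    each pair is compared over its own comparable sites (default, and the
    accounting under which per-region fragment lengths "excluding
    alignment gaps" are reported);
``complete``
    only columns comparable in *every* sequence of the alignment enter any
    pair's comparison.

Standard errors come from a seeded site bootstrap (columns resampled with
replacement), which is method-agnostic: the same machinery serves single
pairs and the multi-sequence diversity estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .alignio import AlignmentError, MultipleAlignment, SequenceRecord

__all__ = [
    "DistanceEstimate",
    "DiversityEstimate",
    "SlidingProfile",
    "HDRegion",
    "p_distance",
    "nucleotide_diversity",
    "sliding_profile",
    "detect_hd_regions",
    "distance_matrix",
    "PDistanceMatrix",
    "nj_tree",
    "DEFAULT_BOOTSTRAP_SEED",
]

DEFAULT_BOOTSTRAP_SEED = 1729
DeletionPolicy = Literal["pairwise", "complete"]


class UndefinedDistanceError(AlignmentError):
    """No comparable sites between two sequences."""


@dataclass(frozen=True)
class DistanceEstimate:
    """A p-distance with bootstrap SE and the number of sites used."""

    value: float
    se: float
    n_sites: int


@dataclass(frozen=True)
class DiversityEstimate:
    """Mean pairwise p-distance (pi) over a sequence sample."""

    pi: float
    se: float
    n_sequences: int


@dataclass(frozen=True)
class SlidingProfile:
    """Per-window statistic values assigned to window midpoints.

    Windows start at columns 1, 1+step, ... and only full windows are
    kept; ``midpoint = start + (window - 1) // 2``.  Windows in which no
    pair had a comparable site carry value 0 and are flagged.
    """

    window: int
    step: int
    stat: str
    midpoints: np.ndarray  # 1-based columns, increasing by `step`
    values: np.ndarray
    n_comparable: np.ndarray  # total comparable sites summed over pairs
    flagged: np.ndarray  # True where no comparable sites at all

    def window_start(self, i: int) -> int:
        return int(self.midpoints[i]) - (self.window - 1) // 2

    def window_end(self, i: int) -> int:
        return self.window_start(i) + self.window - 1

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("midpoint\tvalue\tn_comparable_sites\n")
            for m, v, n in zip(self.midpoints, self.values, self.n_comparable):
                fh.write(f"{int(m)}\t{v:.6f}\t{int(n)}\n")


@dataclass(frozen=True)
class HDRegion:
    """A contiguous high-divergence interval on the alignment."""

    start: int
    end: int
    peak_midpoint: int
    peak_value: float
    background: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# distance core

def _pair_arrays(
    aln: MultipleAlignment, i: int, j: int, global_mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """(diff, comparable) boolean vectors over alignment columns for rows i, j."""
    bm = aln.base_mask()
    comp = bm[i] & bm[j]
    if global_mask is not None:
        comp = comp & global_mask
    diff = (aln.matrix[i] != aln.matrix[j]) & comp
    return diff, comp


def _complete_mask(aln: MultipleAlignment) -> np.ndarray:
    return aln.base_mask().all(axis=0)


def _bootstrap_se_pairs(
    diffs: np.ndarray,
    comps: np.ndarray,
    n_bootstrap: int,
    seed: int,
) -> float:
    """SE of the mean-over-pairs ratio statistic under column resampling.

    ``diffs``/``comps`` are (n_pairs, L) float matrices.  Columns are
    resampled jointly for all pairs, which keeps pairs' estimates coupled
    exactly as in the observed data.
    """
    if n_bootstrap <= 0:
        return 0.0
    L = diffs.shape[1]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        num = diffs @ w
        den = comps @ w
        ok = den > 0
        reps[b] = (num[ok] / den[ok]).mean() if ok.any() else np.nan
    reps = reps[np.isfinite(reps)]
    return float(reps.std(ddof=1)) if len(reps) > 1 else 0.0


def p_distance(
    a: SequenceRecord,
    b: SequenceRecord,
    deletion_policy: DeletionPolicy = "pairwise",
    n_bootstrap: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> DistanceEstimate:
    """Raw p-distance between two aligned records, with site-bootstrap SE.

    For a single pair the two deletion policies coincide.
    """
    if len(a) != len(b):
        raise AlignmentError("p_distance requires equal-length (aligned) records")
    aln = MultipleAlignment([a, b])
    diff, comp = _pair_arrays(aln, 0, 1, None)
    n = int(comp.sum())
    if n == 0:
        raise UndefinedDistanceError(
            f"no comparable sites between {a.id!r} and {b.id!r}"
        )
    value = float(diff.sum()) / n
    se = _bootstrap_se_pairs(
        diff[None, :].astype(float), comp[None, :].astype(float), n_bootstrap, seed
    )
    if value == 0.0:
        se = 0.0
    return DistanceEstimate(value=value, se=se, n_sites=n)


def _all_pair_arrays(
    aln: MultipleAlignment, deletion_policy: DeletionPolicy
) -> tuple[np.ndarray, np.ndarray]:
    gm = _complete_mask(aln) if deletion_policy == "complete" else None
    pairs = list(combinations(range(len(aln)), 2))
    diffs = np.empty((len(pairs), aln.length))
    comps = np.empty((len(pairs), aln.length))
    for k, (i, j) in enumerate(pairs):
        d, c = _pair_arrays(aln, i, j, gm)
        diffs[k] = d
        comps[k] = c
    return diffs, comps


def nucleotide_diversity(
    aln: MultipleAlignment,
    deletion_policy: DeletionPolicy = "pairwise",
    n_bootstrap: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> DiversityEstimate:
    """pi: the mean p-distance over all unordered sequence pairs."""
    diffs, comps = _all_pair_arrays(aln, deletion_policy)
    den = comps.sum(axis=1)
    if (den == 0).any():
        k = int(np.argmax(den == 0))
        i, j = list(combinations(range(len(aln)), 2))[k]
        raise UndefinedDistanceError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    pi = float((diffs.sum(axis=1) / den).mean())
    se = _bootstrap_se_pairs(diffs, comps, n_bootstrap, seed)
    if pi == 0.0:
        se = 0.0
    return DiversityEstimate(pi=pi, se=se, n_sequences=len(aln))


@dataclass(frozen=True)
class PDistanceMatrix:
    """Symmetric p-distance matrix with per-pair SEs and site counts."""

    ids: tuple[str, ...]
    values: np.ndarray
    se: np.ndarray
    n_sites: np.ndarray

    def get(self, a: str, b: str) -> DistanceEstimate:
        i, j = self.ids.index(a), self.ids.index(b)
        return DistanceEstimate(
            float(self.values[i, j]), float(self.se[i, j]), int(self.n_sites[i, j])
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(
                    rid + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]) + "\n"
                )


def distance_matrix(
    aln: MultipleAlignment,
    deletion_policy: DeletionPolicy = "pairwise",
    n_bootstrap: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> PDistanceMatrix:
    """All unordered pairs via :func:`p_distance`; zero diagonal."""
    n = len(aln)
    gm = _complete_mask(aln) if deletion_policy == "complete" else None
    values = np.zeros((n, n))
    se = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        d, c = _pair_arrays(aln, i, j, gm)
        nc = int(c.sum())
        if nc == 0:
            raise UndefinedDistanceError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        v = float(d.sum()) / nc
        s = _bootstrap_se_pairs(
            d[None, :].astype(float), c[None, :].astype(float), n_bootstrap, seed
        )
        if v == 0.0:
            s = 0.0
        values[i, j] = values[j, i] = v
        se[i, j] = se[j, i] = s
        ns[i, j] = ns[j, i] = nc
    np.fill_diagonal(ns, aln.length)
    return PDistanceMatrix(tuple(aln.ids), values, se, ns)


# ---------------------------------------------------------------------------
# sliding windows

def sliding_profile(
    aln: MultipleAlignment,
    stat: Literal["pi", "dxy"] = "pi",
    window: int = 100,
    step: int = 25,
    deletion_policy: DeletionPolicy = "pairwise",
) -> SlidingProfile:
    """Sliding-window pi (all pairs) or dxy (exactly two sequences).

    Windows are defined on alignment columns: gaps occupy columns of the
    span but are excluded from the statistic.  Trailing partial windows
    are dropped.  Pairs with zero comparable sites in a window are left
    out of that window's mean; a window where every pair is empty gets
    value 0 and is flagged.
    """
    if window > aln.length:
        raise AlignmentError(
            f"window {window} exceeds alignment length {aln.length}"
        )
    if step < 1:
        raise AlignmentError("step must be >= 1")
    if stat == "dxy" and len(aln) != 2:
        raise AlignmentError("stat='dxy' requires an alignment of exactly 2 sequences")

    diffs, comps = _all_pair_arrays(aln, deletion_policy)
    cd = np.concatenate([np.zeros((diffs.shape[0], 1)), diffs.cumsum(axis=1)], axis=1)
    cc = np.concatenate([np.zeros((comps.shape[0], 1)), comps.cumsum(axis=1)], axis=1)

    starts = np.arange(0, aln.length - window + 1, step)  # 0-based
    num = cd[:, starts + window] - cd[:, starts]  # (n_pairs, n_windows)
    den = cc[:, starts + window] - cc[:, starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    any_pair = (den > 0).any(axis=0)
    values = np.where(any_pair, np.nanmean(ratio, axis=0), 0.0)
    midpoints = starts + 1 + (window - 1) // 2
    return SlidingProfile(
        window=window,
        step=step,
        stat=stat,
        midpoints=midpoints.astype(int),
        values=values,
        n_comparable=den.sum(axis=0).astype(int),
        flagged=~any_pair,
    )


def detect_hd_regions(
    profile: SlidingProfile,
    fold_threshold: float = 5.0,
    min_windows: int = 2,
    absolute_floor: float = 0.02,
) -> list[HDRegion]:
    """Find high-divergence regions: runs of windows far above background.

    Background is the median window value.  Candidate windows exceed
    ``max(fold_threshold * background, absolute_floor)``; maximal runs of
    candidates separated by at most one non-candidate window are merged;
    runs with fewer than ``min_windows`` candidate windows are discarded.
    Peak ties break toward the smaller midpoint.
    """
    values = np.asarray(profile.values, dtype=float)
    if len(values) == 0:
        raise AlignmentError("empty profile")
    background = float(np.median(values))
    threshold = max(fold_threshold * background, absolute_floor)
    cand = values > threshold
    if not cand.any():
        return []

    idx = np.flatnonzero(cand)
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][-1] <= 2:  # gap of at most one non-candidate window
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])

    regions = []
    for run in runs:
        if len(run) < min_windows:
            continue
        first, last = run[0], run[-1]
        run_slice = values[first : last + 1]
        peak_rel = int(np.argmax(run_slice))  # argmax takes first max: smaller midpoint
        regions.append(
            HDRegion(
                start=profile.window_start(first),
                end=profile.window_end(last),
                peak_midpoint=int(profile.midpoints[first + peak_rel]),
                peak_value=float(run_slice[peak_rel]),
                background=background,
            )
        )
    # overlapping windows can make neighbouring runs overlap in column span;
    # such regions describe one divergent interval and are merged
    merged: list[HDRegion] = []
    for reg in regions:
        if merged and reg.start <= merged[-1].end:
            prev = merged[-1]
            best = prev if prev.peak_value >= reg.peak_value else reg
            merged[-1] = HDRegion(
                start=prev.start,
                end=max(prev.end, reg.end),
                peak_midpoint=best.peak_midpoint,
                peak_value=best.peak_value,
                background=background,
            )
        else:
            merged.append(reg)
    return merged


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(matrix: "PDistanceMatrix | np.ndarray", ids: Sequence[str] | None = None) -> str:
    """Neighbor-joining newick string from a distance matrix.

    Accepts either a :class:`PDistanceMatrix` or a raw square array plus
    ids.  Negative branch lengths are clamped to zero.  Used for
    phylogenetic-discordance checks of per-region sub-alignments.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    if isinstance(matrix, PDistanceMatrix):
        vals, taxa = matrix.values, list(matrix.ids)
    else:
        if ids is None:
            raise AlignmentError("ids required with a raw matrix")
        vals, taxa = np.asarray(matrix, dtype=float), list(ids)
    if len(taxa) < 3:
        raise AlignmentError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(vals)):
        raise AlignmentError("non-finite distances")
    tree = skbio_nj(SkbioDM(vals, taxa))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
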