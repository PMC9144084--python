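"""Recombination detection: PHI permutation test, MaxChi breakpoint
scanning, triplet closer-parent scanning, and event calling.

The pairwise homoplasy index (PHI) asks whether nearby pairs of
parsimony-informative sites are more *compatible* with a single genealogy
than randomly placed pairs would be.  Recombination makes nearby sites
share a local tree while distant sites do not, so the observed mean
incompatibility over nearby pairs falls below its permutation null; the
reported p-value is the lower tail of the permuted statistic.

MaxChi localises breakpoints on a sequence pair: at each candidate cut
between consecutive variable sites it forms the 2x2 table of
(match, mismatch) x (left k-site half-window, right k-site half-window)
and maximises the chi-square statistic; significance again by permuting
the match/mismatch labels.

Event calling composes the two with a triplet closer-parent scan and a
conservative per-event p (the maximum over component tests), Bonferroni
corrected over the number of candidate x minor-parent x segment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .alignio import AlignmentError, MultipleAlignment, RegionSpec
from .diversity import sliding_profile

__all__ = [
    "InformativeSiteSet",
    "PhiResult",
    "MaxChiResult",
    "TripletScan",
    "RecombinationEvent",
    "RecombConfig",
    "ConfigurationError",
    "informative_sites",
    "phi_test",
    "triplet_scan",
    "maxchi_scan",
    "call_events",
    "bonferroni",
]


class ConfigurationError(ValueError):
    """Invalid candidate/reference configuration for event calling."""


# ---------------------------------------------------------------------------
# informative sites

@dataclass(frozen=True)
class InformativeSiteSet:
    """Parsimony-informative columns and their residue patterns.

    ``columns`` are 1-based alignment columns (increasing); ``patterns``
    is the raw residue sub-matrix (n_sequences x n_sites, uint8).
    """

    columns: np.ndarray
    patterns: np.ndarray
    ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.columns)


def informative_sites(aln: MultipleAlignment) -> InformativeSiteSet:
    """Columns with >= 2 states each carried by >= 2 sequences.

    Gap and ``N`` carriers are excluded from the state counts; a column
    qualifies on its unambiguous bases alone.
    """
    m = aln.matrix
    counts = np.stack([(m == ord(b)).sum(axis=0) for b in "ACGT"])  # (4, L)
    informative = (counts >= 2).sum(axis=0) >= 2
    cols = np.flatnonzero(informative)
    return InformativeSiteSet(
        columns=cols + 1, patterns=m[:, cols].copy(), ids=tuple(aln.ids)
    )


# ---------------------------------------------------------------------------
# PHI

@dataclass(frozen=True)
class PhiResult:
    statistic: float
    p_value: float
    n_informative: int
    n_pairs: int  # informative-site pairs within w of each other
    window_w: int
    n_permutations: int
    seed: int | None
    computable: bool = True
    note: str = ""


def _binarize(sites: InformativeSiteSet) -> tuple[np.ndarray, np.ndarray]:
    """Binary encoding of each informative column on its two most frequent
    states; rows carrying other states, gaps or N are missing for that
    column.  Returns (is_state2, observed) boolean matrices of shape
    (n_sites, n_rows).  Frequency ties break by byte order (A<C<G<T)."""
    pat = sites.patterns.T  # (n_sites, n_rows)
    n_sites, n_rows = pat.shape
    is_b = np.stack([pat == ord(b) for b in "ACGT"], axis=0)  # (4, n_sites, n_rows)
    counts = is_b.sum(axis=2)  # (4, n_sites)
    order = np.argsort(-counts, axis=0, kind="stable")  # ties -> smaller base index
    top1, top2 = order[0], order[1]
    ar = np.arange(n_sites)
    state1 = is_b[top1, ar, :]  # (n_sites, n_rows)
    state2 = is_b[top2, ar, :]
    observed = state1 | state2
    return state2, observed


def _pack_bits(rows_bool: np.ndarray) -> np.ndarray:
    """Pack (n_sites, n_rows) booleans into (n_sites, n_words) uint64."""
    n_sites, n_rows = rows_bool.shape
    n_words = (n_rows + 63) // 64
    out = np.zeros((n_sites, n_words), dtype=np.uint64)
    for w in range(n_words):
        chunk = rows_bool[:, w * 64 : (w + 1) * 64]
        weights = (np.uint64(1) << np.arange(chunk.shape[1], dtype=np.uint64))
        out[:, w] = (chunk.astype(np.uint64) * weights).sum(axis=1, dtype=np.uint64)
    return out


def _incompatibility_matrix(sites: InformativeSiteSet) -> np.ndarray:
    """Boolean (n_sites, n_sites) matrix of four-gamete violations between
    binarized informative columns, computed over rows observed at both."""
    state2, observed = _binarize(sites)
    x = _pack_bits(state2)
    o = _pack_bits(observed)
    n = len(sites)
    M = np.zeros((n, n), dtype=bool)
    # chunk rows to bound memory on large site sets
    chunk = max(1, int(4e7) // max(n, 1))
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        xs, os_ = x[s:e, None, :], o[s:e, None, :]
        m = os_ & o[None, :, :]
        a11 = np.bitwise_count(xs & x[None, :, :] & m).sum(axis=2)
        a10 = np.bitwise_count(xs & ~x[None, :, :] & m).sum(axis=2)
        a01 = np.bitwise_count(~xs & x[None, :, :] & m).sum(axis=2)
        a00 = np.bitwise_count(~xs & ~x[None, :, :] & m).sum(axis=2)
        M[s:e] = (a11 > 0) & (a10 > 0) & (a01 > 0) & (a00 > 0)
    np.fill_diagonal(M, False)
    return M


def _close_rank_pairs(positions: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (r, s), r < s, with positions[s] - positions[r] <= w."""
    ra, rb = [], []
    hi = np.searchsorted(positions, positions + w, side="right")
    for r in range(len(positions)):
        if hi[r] > r + 1:
            ra.append(np.full(hi[r] - r - 1, r))
            rb.append(np.arange(r + 1, hi[r]))
    if not ra:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(ra), np.concatenate(rb)


def phi_test(
    aln: MultipleAlignment,
    w: int = 100,
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> PhiResult:
    """PHI permutation test for recombination on a whole alignment.

    The statistic is the mean four-gamete incompatibility over pairs of
    informative sites separated by at most ``w`` alignment columns.  The
    null distribution permutes the order of the informative columns over
    their observed positions; ``p = (1 + #{perm <= observed}) / (n + 1)``
    (recombination depresses the observed statistic).
    """
    sites = informative_sites(aln)
    n_i = len(sites)
    if n_i < 2:
        return PhiResult(np.nan, np.nan, n_i, 0, w, n_permutations, seed,
                         computable=False, note="fewer than 2 informative sites")
    ra, rb = _close_rank_pairs(sites.columns, w)
    if len(ra) == 0:
        return PhiResult(np.nan, np.nan, n_i, 0, w, n_permutations, seed,
                         computable=False,
                         note=f"no informative-site pairs within {w} columns")
    M = _incompatibility_matrix(sites)
    observed = float(M[ra, rb].mean())

    rng = np.random.default_rng(seed)
    n_le = 0
    batch = max(1, min(2000, int(2e7) // max(n_i, 1)))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        perm = np.argsort(rng.random((b, n_i)), axis=1)
        stats = M[perm[:, ra], perm[:, rb]].mean(axis=1)
        n_le += int((stats <= observed + 1e-12).sum())
        done += b
    p = (1 + n_le) / (n_permutations + 1)
    return PhiResult(
        statistic=observed, p_value=p, n_informative=n_i, n_pairs=len(ra),
        window_w=w, n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# MaxChi

@dataclass(frozen=True)
class MaxChiResult:
    pair: tuple[str, str]
    columns: np.ndarray  # alignment column of each candidate cut
    chi_profile: np.ndarray
    best_breakpoint: int
    max_chi: float
    p_value: float
    k: int
    n_sites: int
    n_permutations: int
    seed: int | None
    computable: bool = True
    note: str = ""


def _variable_pair_sites(
    aln: MultipleAlignment, a: str, b: str, region: RegionSpec | None
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered (columns, mismatch-labels) for the pair over alignment-variable
    sites where both pair members carry unambiguous bases."""
    bm = aln.base_mask()
    m = aln.matrix
    counts = np.stack([(m == ord(x)).sum(axis=0) for x in "ACGT"])
    variable = (counts > 0).sum(axis=0) >= 2
    ia, ib = aln.index_of(a), aln.index_of(b)
    ok = variable & bm[ia] & bm[ib]
    if region is not None:
        region.check_within(aln.length)
        sel = np.zeros(aln.length, dtype=bool)
        sel[region.start - 1 : region.end] = True
        ok &= sel
    cols = np.flatnonzero(ok)
    return cols + 1, (m[ia, cols] != m[ib, cols])


def _chi_profile(y: np.ndarray, k: int) -> np.ndarray:
    """Chi-square (no continuity correction) at each cut j = k..n-k of the
    label sequence y (True = mismatch), using k-site half-windows."""
    cs = np.concatenate([[0], np.cumsum(y)])
    j = np.arange(k, len(y) - k + 1)
    left_mis = cs[j] - cs[j - k]
    right_mis = cs[j + k] - cs[j]
    a = k - left_mis  # left matches
    b = left_mis
    c = k - right_mis
    d = right_mis
    col1 = a + c  # total matches
    col2 = b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = 2 * k * (a * d - b * c) ** 2 / (k * k * col1 * col2)
    return np.where((col1 == 0) | (col2 == 0), 0.0, chi)


def maxchi_scan(
    candidate_id: str,
    parent_id: str,
    aln: MultipleAlignment,
    k: int = 30,
    n_permutations: int = 1000,
    seed: int | None = None,
    region: RegionSpec | None = None,
) -> MaxChiResult:
    """MaxChi breakpoint scan between a candidate and one parent.

    The reported breakpoint is the alignment column of the last variable
    site in the left half-window at the maximising cut; ties break toward
    the smallest column.
    """
    cols, y = _variable_pair_sites(aln, candidate_id, parent_id, region)
    n = len(y)
    if n < 2 * k:
        return MaxChiResult(
            (candidate_id, parent_id), np.empty(0, dtype=int), np.empty(0),
            -1, np.nan, np.nan, k, n, n_permutations, seed,
            computable=False, note=f"{n} variable sites < 2k = {2 * k}",
        )
    chi = _chi_profile(y.astype(np.int64), k)
    cut_cols = cols[np.arange(k, n - k + 1) - 1]  # last left-half site per cut
    best = int(np.argmax(chi))  # first max -> smallest column
    obs = float(chi[best])

    rng = np.random.default_rng(seed)
    count = 0
    batch = max(1, min(1000, int(2e7) // max(n, 1)))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        perm = np.argsort(rng.random((b, n)), axis=1)
        yb = y[perm].astype(np.int64)
        cs = np.concatenate([np.zeros((b, 1), dtype=np.int64), yb.cumsum(axis=1)], axis=1)
        j = np.arange(k, n - k + 1)
        lm = cs[:, j] - cs[:, j - k]
        rm = cs[:, j + k] - cs[:, j]
        a_, b_, c_, d_ = k - lm, lm, k - rm, rm
        col1, col2 = a_ + c_, b_ + d_
        with np.errstate(invalid="ignore", divide="ignore"):
            chib = 2 * k * (a_ * d_ - b_ * c_) ** 2 / (k * k * col1 * col2)
        chib = np.where((col1 == 0) | (col2 == 0), 0.0, chib)
        count += int((chib.max(axis=1) >= obs - 1e-12).sum())
        done += b
    p = (1 + count) / (n_permutations + 1)
    return MaxChiResult(
        pair=(candidate_id, parent_id), columns=cut_cols, chi_profile=chi,
        best_breakpoint=int(cut_cols[best]), max_chi=obs, p_value=p,
        k=k, n_sites=n, n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# triplet closer-parent scan

@dataclass(frozen=True)
class TripletScan:
    """Per-window closer-parent calls for (candidate, parentA, parentB)."""

    candidate_id: str
    parent_a: str
    parent_b: str
    window: int
    step: int
    midpoints: np.ndarray
    dist_a: np.ndarray
    dist_b: np.ndarray
    calls: np.ndarray  # array of 'A' | 'B' | 'tie'

    def segments(self) -> list[tuple[int, int]]:
        """Maximal runs of 'B' calls as (start_column, end_column) spans."""
        half = (self.window - 1) // 2
        isb = self.calls == "B"
        out = []
        i = 0
        while i < len(isb):
            if isb[i]:
                j = i
                while j + 1 < len(isb) and isb[j + 1]:
                    j += 1
                start = int(self.midpoints[i]) - half
                end = int(self.midpoints[j]) - half + self.window - 1
                out.append((start, end))
                i = j + 1
            else:
                i += 1
        return out


def triplet_scan(
    candidate_id: str,
    parent_a_id: str,
    parent_b_id: str,
    aln: MultipleAlignment,
    window: int = 100,
    step: int = 25,
) -> TripletScan:
    """Window-by-window comparison of the candidate to two parents.

    A window is called ``B`` where the candidate is strictly closer to
    parent B, ``A`` where strictly closer to parent A, and ``tie``
    otherwise (including windows with no comparable sites for either
    pair).  Runs of ``B`` are the raw recombinant-segment proposals.
    """
    if len({candidate_id, parent_a_id, parent_b_id}) != 3:
        raise ConfigurationError("triplet requires three distinct ids")
    sub = aln.subset([candidate_id, parent_a_id])
    pa = sliding_profile(sub, "dxy", window, step)
    sub_b = aln.subset([candidate_id, parent_b_id])
    pb = sliding_profile(sub_b, "dxy", window, step)
    da = np.where(pa.flagged, np.nan, pa.values)
    db = np.where(pb.flagged, np.nan, pb.values)
    calls = np.full(len(da), "tie", dtype=object)
    with np.errstate(invalid="ignore"):
        calls[np.less(da, db, where=~(np.isnan(da) | np.isnan(db)),
                      out=np.zeros(len(da), dtype=bool))] = "A"
        calls[np.less(db, da, where=~(np.isnan(da) | np.isnan(db)),
                      out=np.zeros(len(da), dtype=bool))] = "B"
    return TripletScan(
        candidate_id=candidate_id, parent_a=parent_a_id, parent_b=parent_b_id,
        window=window, step=step, midpoints=pa.midpoints,
        dist_a=pa.values, dist_b=pb.values, calls=np.asarray(calls, dtype=object),
    )


# ---------------------------------------------------------------------------
# event calling

@dataclass(frozen=True)
class RecombinationEvent:
    recombinant_id: str
    major_parent_id: str
    minor_parent_id: str
    begin: int
    end: int
    span: int
    ungapped_length: int
    p_values: Mapping[str, float]
    mismatches: int

    def region(self, label: str = "") -> RegionSpec:
        return RegionSpec(self.begin, self.end, label or self.recombinant_id)


@dataclass(frozen=True)
class RecombConfig:
    """Knobs for event calling; defaults follow the package-wide scan
    geometry (100-column windows, 25-column steps)."""

    window: int = 100
    step: int = 25
    phi_w: int = 100
    phi_permutations: int = 100_000
    maxchi_k: int = 30
    maxchi_permutations: int = 1000
    maxchi_flank: int = 1500  # columns examined either side of a breakpoint
    alpha: float = 0.05
    seed: int | None = None


def bonferroni(p: float, m: int) -> float:
    """min(1, m * p)."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def _pair_distance_over(
    aln: MultipleAlignment, a: str, b: str, mask: np.ndarray
) -> float:
    bm = aln.base_mask()
    ia, ib = aln.index_of(a), aln.index_of(b)
    comp = bm[ia] & bm[ib] & mask
    n = comp.sum()
    if n == 0:
        return np.inf
    return float(((aln.matrix[ia] != aln.matrix[ib]) & comp).sum() / n)


def _refine_segment(
    aln: MultipleAlignment,
    cand: str,
    major: str,
    minor: str,
    start: int,
    end: int,
    conspecifics: Sequence[str] = (),
) -> tuple[int, int] | None:
    """Trim a proposed run to first..last minor-diagnostic anchor site.

    An anchor is a (candidate vs major) variable site inside the run at
    which the candidate matches the minor parent.  When other same-group
    sequences are available (``conspecifics``: the candidate's group minus
    candidate and major), an anchor additionally requires at least half of
    them to carry the major's residue, so that the site separates the two
    parental lineages rather than reflecting a private mutation of the
    major (co-recombinants sharing the fragment vote against and are
    tolerated as a minority).
    """
    bm = aln.base_mask()
    ic, ij, im = aln.index_of(cand), aln.index_of(major), aln.index_of(minor)
    sel = np.zeros(aln.length, dtype=bool)
    sel[max(0, start - 1) : min(aln.length, end)] = True
    diff_major = (aln.matrix[ic] != aln.matrix[ij]) & bm[ic] & bm[ij] & sel
    match_minor = (aln.matrix[ic] == aln.matrix[im]) & bm[im]
    anchor = diff_major & match_minor
    others = [g for g in conspecifics if g not in (cand, major)]
    if others:
        rows = np.array([aln.index_of(g) for g in others])
        votes_for_major = ((aln.matrix[rows] == aln.matrix[ij]) & bm[rows]).sum(axis=0)
        votes_total = bm[rows].sum(axis=0)
        anchor &= 2 * votes_for_major >= votes_total
    hits = np.flatnonzero(anchor)
    if len(hits) == 0:
        return None
    # the true breakpoint lies between the outermost anchor and the nearest
    # contradicting site (candidate siding with the major against the minor);
    # report the midpoint of that bracket rather than the anchor itself
    anti = (
        (aln.matrix[ic] == aln.matrix[ij])
        & (aln.matrix[ij] != aln.matrix[im])
        & bm[ic] & bm[ij] & bm[im]
    )
    left_anti = np.flatnonzero(anti[: hits[0]])
    right_anti = np.flatnonzero(anti[hits[-1] + 1 :])
    lo = int(left_anti[-1]) if len(left_anti) else -1
    hi = int(right_anti[0] + hits[-1] + 1) if len(right_anti) else aln.length
    begin = (lo + int(hits[0])) // 2 + 2  # 1-based, first column after midpoint
    end = (int(hits[-1]) + hi) // 2 + 1
    return int(begin), int(end)


def _count_mismatches(
    aln: MultipleAlignment, a: str, b: str, begin: int, end: int
) -> int:
    bm = aln.base_mask()
    ia, ib = aln.index_of(a), aln.index_of(b)
    sl = slice(begin - 1, end)
    comp = bm[ia, sl] & bm[ib, sl]
    return int(((aln.matrix[ia, sl] != aln.matrix[ib, sl]) & comp).sum())


def call_events(
    aln: MultipleAlignment,
    candidates: Sequence[str],
    groups: Mapping[str, str],
    config: RecombConfig = RecombConfig(),
) -> list[RecombinationEvent]:
    """Detect and test recombination events for each candidate genome.

    ``groups`` maps every participating sequence id to a group (species)
    label; ids in ``groups`` that are not candidates serve as references.
    For each candidate, triplet scans against every (conspecific major,
    other-group minor) pair propose segments; overlapping proposals are
    clustered; each cluster is refined, assigned parents by distance
    (major: conspecific minimising the genome-minus-segments distance;
    minor: other-group reference minimising the within-segment distance),
    and tested (MaxChi at both flanks, PHI on segment +/- one window).
    The per-event p is the maximum over computable component tests,
    Bonferroni corrected by the number of candidate x minor x segment
    tests; events pass at ``config.alpha``.
    """
    for cid in candidates:
        if cid not in aln.ids:
            raise ConfigurationError(f"candidate {cid!r} not in alignment")
        if cid not in groups:
            raise ConfigurationError(f"candidate {cid!r} has no group label")
    references = [i for i in aln.ids if i in groups and i not in set(candidates)]
    rng = np.random.default_rng(config.seed)

    # --- propose segments per candidate
    proposals: dict[str, list[tuple[int, int]]] = {c: [] for c in candidates}
    minors_of: dict[str, list[str]] = {}
    for cand in candidates:
        grp = groups[cand]
        majors = [i for i in aln.ids if i in groups and groups[i] == grp and i != cand]
        minors = [r for r in references if groups[r] != grp]
        minors_of[cand] = minors
        if not minors:
            raise ConfigurationError(
                f"no reference from a group other than {grp!r} for candidate {cand!r}"
            )
        if not majors:
            raise ConfigurationError(
                f"no conspecific (group {grp!r}) sequence available as major parent "
                f"for candidate {cand!r}"
            )
        for major in majors:
            for minor in minors:
                scan = triplet_scan(cand, major, minor, aln, config.window, config.step)
                for s, e in scan.segments():
                    refined = _refine_segment(
                        aln, cand, major, minor, s, e, conspecifics=majors
                    )
                    if refined is not None:
                        proposals[cand].append(refined)

    # --- cluster overlapping proposals per candidate
    clusters_of: dict[str, list[tuple[int, int]]] = {}
    for cand in candidates:
        segs = sorted(proposals[cand])
        clusters: list[list[int]] = []
        for s, e in segs:
            if clusters and s <= clusters[-1][1]:
                clusters[-1][1] = max(clusters[-1][1], e)
            else:
                clusters.append([s, e])
        clusters_of[cand] = [(s, e) for s, e in clusters]

    # --- assign parents and refine; only refinable segments become tests
    testable: list[tuple[str, str, str, int, int]] = []
    n_tests = 0
    for cand in candidates:
        grp = groups[cand]
        majors = [i for i in aln.ids if i in groups and groups[i] == grp and i != cand]
        all_spans = np.zeros(aln.length, dtype=bool)
        for s, e in clusters_of[cand]:
            all_spans[s - 1 : e] = True
        # conspecifics ranked by backbone (genome-minus-segments) distance;
        # a co-recombinant sharing a fragment cannot anchor that fragment's
        # refinement, so the first rank yielding a valid segment is the major
        ranked_majors = sorted(
            majors,
            key=lambda r: (_pair_distance_over(aln, cand, r, ~all_spans),
                           aln.index_of(r)),
        )
        for s, e in clusters_of[cand]:
            span_mask = np.zeros(aln.length, dtype=bool)
            span_mask[s - 1 : e] = True
            minor = min(
                minors_of[cand],
                key=lambda r: (_pair_distance_over(aln, cand, r, span_mask),
                               aln.index_of(r)),
            )
            for major in ranked_majors:
                refined = _refine_segment(
                    aln, cand, major, minor, s, e, conspecifics=majors
                )
                if refined is None:
                    continue
                begin, end = refined
                # definitional check: within the segment the minor parent must
                # be strictly the candidate's closest relative among all
                # same-group alternatives, else the fragment is native variation
                seg_mask = np.zeros(aln.length, dtype=bool)
                seg_mask[begin - 1 : end] = True
                d_minor = _pair_distance_over(aln, cand, minor, seg_mask)
                if any(
                    _pair_distance_over(aln, cand, g, seg_mask) <= d_minor
                    for g in majors
                ):
                    break  # native variation; no other major changes that
                testable.append((cand, major, minor, begin, end))
                n_tests += len(minors_of[cand])
                break
    if n_tests == 0:
        return []

    events: list[RecombinationEvent] = []
    for cand, major, minor, begin, end in testable:
        # half-window capped at the number of pair-variable sites inside the
        # segment: a short fragment would otherwise be diluted by flank sites
        n_seg = len(
            _variable_pair_sites(aln, cand, major, RegionSpec(begin, end))[0]
        )
        k_eff = max(5, min(config.maxchi_k, n_seg))
        p_components: dict[str, float] = {}
        for name, lo, hi in (
            ("maxchi_left", begin - config.maxchi_flank, begin + config.maxchi_flank),
            ("maxchi_right", end - config.maxchi_flank, end + config.maxchi_flank),
        ):
            reg = RegionSpec(max(1, lo), min(aln.length, hi))
            res = maxchi_scan(
                cand, major, aln, k=k_eff,
                n_permutations=config.maxchi_permutations,
                seed=int(rng.integers(2**31)), region=reg,
            )
            if res.computable:
                p_components[name] = res.p_value
        if not p_components:
            continue
        # conservative per-event p: worst breakpoint-localisation p-value;
        # the locally restricted PHI is reported alongside as a diagnostic
        # (it is underpowered on short segments and is not used as a veto)
        combined = max(p_components.values())
        corrected = bonferroni(combined, n_tests)
        phi_reg = (max(1, begin - config.maxchi_flank),
                   min(aln.length, end + config.maxchi_flank))
        sub = extract_columns(aln, phi_reg[0], phi_reg[1])
        phi = phi_test(sub, w=config.phi_w,
                       n_permutations=config.phi_permutations,
                       seed=int(rng.integers(2**31)))
        if phi.computable:
            p_components["phi_local"] = phi.p_value
        if corrected >= config.alpha:
            continue
        seg_len = end - begin + 1
        row = aln[cand].residues[begin - 1 : end]
        events.append(
            RecombinationEvent(
                recombinant_id=cand,
                major_parent_id=major,
                minor_parent_id=minor,
                begin=begin,
                end=end,
                span=seg_len,
                ungapped_length=seg_len - row.count("-"),
                p_values={**p_components, "combined": combined,
                          "corrected": corrected},
                mismatches=_count_mismatches(aln, cand, minor, begin, end),
            )
        )
    events.sort(key=lambda ev: (aln.index_of(ev.recombinant_id), ev.begin))
    return events


def extract_columns(aln: MultipleAlignment, start: int, end: int) -> MultipleAlignment:
    """Column-range sub-alignment (1-based inclusive); thin helper."""
    from .alignio import extract_region

    return extract_region(aln, RegionSpec(start, end))
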