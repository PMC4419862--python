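"""The window statistic proper: M scores, omega scores, scanning, calling.

For a chosen cluster size ``ncl``, every window of ``ncl`` consecutive
genes (a virtual cluster, VC) receives the sum of the Z-scored per-gene
induction ratios of its genes::

    M[i, ncl] = sum_{k=i}^{i+ncl-1} (m_k - mean(m)) / sd(m)

Background windows sum independent near-zero terms, so M is close to
normal with mean ~0; a co-regulated cluster concentrates same-signed
terms in one window and pushes its M far into a tail.  The omega score
amplifies exactly that deviation by combining a d-th order moment with
a rareness term::

    Z_M   = (M - mean(M)) / sd(M)          (over all windows at ncl)
    omega = -(Z_M)**d * log(P)

where ``d`` is an odd positive integer (default 3) and ``P`` is the
two-sided tail probability of |Z_M|.  ``log P`` is negative, so omega
carries the sign of Z_M: positive for windows induced in the numerator
(producing) condition, negative for repressed windows.

``P`` is computed from a standard-normal fit to the Z-scored M values
by default.  An empirical-frequency alternative exists behind the
``tail="empirical"`` flag, but it is quantized at 1/#windows, which
caps the rareness term for precisely the extreme windows the statistic
must emphasize.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from middascan.errors import DegenerateStatisticsError, InputError
from middascan.expression_stats import (
    ConditionPair,
    ExpressionMatrix,
    InductionProfile,
    compute_m_values,
    zscore,
)
from middascan.genome_model import GeneOrder

__all__ = [
    "ClusterCall",
    "MScoreTrack",
    "OmegaTrack",
    "call_clusters",
    "m_scores",
    "omega_scores",
    "permutation_null",
    "scan",
    "standardize_profile",
]

#: Tail probabilities are floored here so ln(P) stays finite.
P_FLOOR = 1e-300


@dataclass
class MScoreTrack:
    """Per-window M sums at one cluster size, with pooled moments.

    Window order matches ``enumerate_virtual_clusters``; ``mean`` and
    ``sd`` (population) are pooled over all windows of all contigs.
    """

    ncl: int
    contig: np.ndarray  # str per window
    start_index: np.ndarray  # 1-based ordinal of first gene
    M: np.ndarray
    mean: float
    sd: float
    ccc: str | None = None

    @property
    def n_windows(self) -> int:
        return len(self.M)


@dataclass
class OmegaTrack:
    """Standardized M scores, tail probabilities and omega per window."""

    ncl: int
    contig: np.ndarray
    start_index: np.ndarray
    M: np.ndarray
    z_m: np.ndarray
    p: np.ndarray
    omega: np.ndarray
    d: int
    ccc: str | None = None

    @property
    def n_windows(self) -> int:
        return len(self.omega)

    def peak(self) -> int:
        """Index of the window with maximal |omega|."""
        return int(np.argmax(np.abs(self.omega)))


@dataclass(frozen=True)
class ClusterCall:
    """A predicted co-regulated cluster.

    ``gene_ids`` is the window of maximal |omega| among the merged
    significant windows; genes of weaker overlapping windows are listed
    as ``extension_candidates``.  ``sign`` is +1 for induction in the
    numerator (producing) condition, -1 for repression.
    """

    contig: str
    gene_ids: tuple[str, ...]
    peak_omega: float
    peak_ncl: int
    peak_start_index: int
    ccc: str
    sign: int
    extension_candidates: tuple[str, ...] = ()


def standardize_profile(profile: InductionProfile) -> np.ndarray:
    """Z-score a profile's m-values over genes with a defined m.

    Genes flagged undefined get z = 0 (the post-centering mean) so that
    window sums stay aligned to the gene order.
    """
    defined = ~profile.undefined
    if defined.sum() < 2:
        raise DegenerateStatisticsError("fewer than 2 genes with defined m")
    z = np.zeros(len(profile.m))
    z[defined] = zscore(profile.m[defined])
    return z


def m_scores(z: np.ndarray, order: GeneOrder, ncl: int) -> MScoreTrack:
    """Window sums of the standardized induction ratios.

    ``z`` must be aligned to ``order.gene_ids()``.  Needs at least two
    windows genome-wide for the pooled standard deviation to exist.
    """
    if ncl < 1:
        raise InputError(f"ncl must be >= 1, got {ncl}")
    z = np.asarray(z, dtype=float)
    if len(z) != len(order):
        raise InputError(
            f"z has {len(z)} values but the gene order has {len(order)} genes"
        )
    contigs: list[str] = []
    starts: list[np.ndarray] = []
    sums: list[np.ndarray] = []
    offset = 0
    for contig in order.contigs:
        g = len(order.genes_on(contig))
        zc = z[offset : offset + g]
        offset += g
        n_win = g - ncl + 1
        if n_win <= 0:
            continue
        # sliding-window sums via cumulative sums
        cs = np.concatenate(([0.0], np.cumsum(zc)))
        m = cs[ncl:] - cs[:-ncl]
        contigs.extend([contig] * n_win)
        starts.append(np.arange(1, n_win + 1))
        sums.append(m)
    if not sums:
        raise DegenerateStatisticsError(
            f"no window of size {ncl} fits on any contig"
        )
    M = np.concatenate(sums)
    if len(M) < 2:
        raise DegenerateStatisticsError(
            "fewer than 2 windows genome-wide: sd of M undefined"
        )
    return MScoreTrack(
        ncl=ncl,
        contig=np.array(contigs, dtype=object),
        start_index=np.concatenate(starts),
        M=M,
        mean=float(M.mean()),
        sd=float(M.std()),  # population sd
    )


def omega_scores(
    track: MScoreTrack,
    d: int = 3,
    tail: str = "parametric",
    p_floor: float = P_FLOOR,
) -> OmegaTrack:
    """Moment x rareness score per window.

    ``d`` must be a positive odd integer so that omega keeps the sign
    of Z_M.  ``tail`` selects how the occurrence probability P is
    estimated: ``parametric`` (two-sided standard-normal tail of the
    Z-scored M values, the default) or ``empirical`` (two-sided
    empirical frequency among the windows themselves).
    """
    if d < 1 or d % 2 == 0:
        raise InputError(f"moment order d must be a positive odd integer, got {d}")
    if track.sd <= 0:
        raise DegenerateStatisticsError(
            "sd of M scores is zero: omega undefined (constant M track)"
        )
    z_m = (track.M - track.mean) / track.sd
    if tail == "parametric":
        p = 2.0 * stats.norm.sf(np.abs(z_m))
    elif tail == "empirical":
        # two-sided frequency: share of windows at least as extreme;
        # ties share the same count, so P is always >= 1/n
        abs_z = np.abs(z_m)
        n = len(abs_z)
        sorted_abs = np.sort(abs_z)
        count_ge = n - np.searchsorted(sorted_abs, abs_z, side="left")
        p = count_ge / n
    else:
        raise InputError(f"unknown tail mode {tail!r}; expected parametric or empirical")
    p = np.maximum(p, p_floor)
    omega = -(z_m**d) * np.log(p)
    return OmegaTrack(
        ncl=track.ncl,
        contig=track.contig,
        start_index=track.start_index,
        M=track.M,
        z_m=z_m,
        p=p,
        omega=omega,
        d=d,
        ccc=track.ccc,
    )


def scan(
    matrix: ExpressionMatrix,
    order: GeneOrder,
    pairs: Sequence[ConditionPair],
    ncl_range: Iterable[int],
    d: int = 3,
    pseudocount: float = 1.0,
    log_base: str = "log2",
    tail: str = "parametric",
) -> dict[tuple[str, int], OmegaTrack]:
    """Omega tracks for every (condition pair, cluster size) combination.

    Deterministic given its inputs; tracks are keyed by
    ``(pair.label, ncl)``.
    """
    ncls = sorted(set(int(n) for n in ncl_range))
    if not ncls:
        raise InputError("empty ncl range")
    max_genes = max(len(order.genes_on(c)) for c in order.contigs)
    for ncl in ncls:
        if ncl < 1 or ncl > max_genes:
            raise InputError(
                f"ncl {ncl} outside [1, {max_genes}] (largest contig gene count)"
            )
    if not pairs:
        raise InputError("no condition pairs to scan")
    missing = [g for g in order.gene_ids() if g not in set(matrix.gene_ids)]
    if missing:
        raise InputError(
            f"{len(missing)} annotated genes missing from the matrix, e.g. {missing[0]}"
        )
    aligned = matrix.values.loc[order.gene_ids()]
    aligned_matrix = ExpressionMatrix(aligned, matrix.sample_sheet.reset_index())
    tracks: dict[tuple[str, int], OmegaTrack] = {}
    for pair in pairs:
        profile = compute_m_values(
            aligned_matrix, pair, pseudocount=pseudocount, log_base=log_base
        )
        z = standardize_profile(profile)
        for ncl in ncls:
            track = m_scores(z, order, ncl)
            track.ccc = pair.label
            tracks[(pair.label, ncl)] = omega_scores(track, d=d, tail=tail)
    return tracks


def _merge_windows_one_track(
    track: OmegaTrack, order: GeneOrder, significant: np.ndarray
) -> list[ClusterCall]:
    """Transitively merge overlapping significant windows of one track.

    Each merged group is reported as one call whose gene set is the
    window of maximal |omega|; remaining genes of the group become
    extension candidates.
    """
    calls: list[ClusterCall] = []
    ncl = track.ncl
    idx = np.flatnonzero(significant)
    if idx.size == 0:
        return calls
    # group by contig, then chain windows whose index ranges overlap
    by_contig: dict[str, list[int]] = {}
    for j in idx:
        by_contig.setdefault(str(track.contig[j]), []).append(int(j))
    for contig, members in by_contig.items():
        members.sort(key=lambda j: int(track.start_index[j]))
        genes_on = [r.gene_id for r in order.genes_on(contig)]
        group: list[int] = []
        group_end = -1
        groups: list[list[int]] = []
        for j in members:
            s = int(track.start_index[j])
            if group and s > group_end + 1:
                groups.append(group)
                group = []
            group.append(j)
            group_end = max(group_end, s + ncl - 1)
        if group:
            groups.append(group)
        for grp in groups:
            peak_j = max(grp, key=lambda j: (abs(track.omega[j]), -int(track.start_index[j])))
            peak_start = int(track.start_index[peak_j])
            peak_genes = tuple(genes_on[peak_start - 1 : peak_start - 1 + ncl])
            union: set[str] = set()
            for j in grp:
                s = int(track.start_index[j])
                union.update(genes_on[s - 1 : s - 1 + ncl])
            extensions = tuple(sorted(union - set(peak_genes)))
            calls.append(
                ClusterCall(
                    contig=contig,
                    gene_ids=peak_genes,
                    peak_omega=float(track.omega[peak_j]),
                    peak_ncl=ncl,
                    peak_start_index=peak_start,
                    ccc=track.ccc or "",
                    sign=1 if track.z_m[peak_j] >= 0 else -1,
                    extension_candidates=extensions,
                )
            )
    return calls


def _peak_gene(call: ClusterCall) -> str:
    """Representative gene of a call: the center of its peak window."""
    return call.gene_ids[(len(call.gene_ids) - 1) // 2]


def call_clusters(
    tracks: Mapping[tuple[str, int], OmegaTrack] | Sequence[OmegaTrack],
    order: GeneOrder,
    threshold: float,
    mode: str = "positive",
) -> list[ClusterCall]:
    """Threshold omega tracks and merge significant windows into calls.

    ``mode="positive"`` keeps windows with omega >= threshold (induced
    clusters); ``mode="absolute"`` keeps |omega| >= threshold, catching
    clusters repressed in the numerator condition as well.  Merging is
    transitive over shared genes within one (CCC, ncl) track, then
    across cluster sizes of the same CCC when one call contains the
    other's peak (center) gene.  Calls from different CCCs are never
    merged; they are reported side by side.
    """
    if threshold <= 0:
        raise InputError(f"threshold must be > 0, got {threshold}")
    if mode not in ("positive", "absolute"):
        raise InputError(f"unknown mode {mode!r}; expected positive or absolute")
    track_list = list(tracks.values()) if isinstance(tracks, Mapping) else list(tracks)
    if not track_list:
        raise InputError("no tracks to call clusters from")
    per_ccc: dict[str, list[ClusterCall]] = {}
    for track in track_list:
        if mode == "positive":
            significant = track.omega >= threshold
        else:
            significant = np.abs(track.omega) >= threshold
        for call in _merge_windows_one_track(track, order, significant):
            per_ccc.setdefault(call.ccc, []).append(call)
    merged: list[ClusterCall] = []
    for ccc in sorted(per_ccc):
        calls = sorted(
            per_ccc[ccc],
            key=lambda c: (-abs(c.peak_omega), c.contig, c.peak_start_index, c.peak_ncl),
        )
        kept: list[ClusterCall] = []
        for call in calls:
            absorbed = False
            for k, prev in enumerate(kept):
                if prev.contig != call.contig:
                    continue
                if _peak_gene(call) in prev.gene_ids or _peak_gene(prev) in call.gene_ids:
                    extra = (set(call.gene_ids) | set(call.extension_candidates)) - set(
                        prev.gene_ids
                    )
                    kept[k] = replace(
                        prev,
                        extension_candidates=tuple(
                            sorted(set(prev.extension_candidates) | extra)
                        ),
                    )
                    absorbed = True
                    break
            if not absorbed:
                kept.append(call)
        merged.extend(kept)
    merged.sort(key=lambda c: (c.ccc, c.contig, c.peak_start_index))
    return merged


def permutation_null(
    matrix: ExpressionMatrix,
    order: GeneOrder,
    pair: ConditionPair,
    ncl: int,
    d: int = 3,
    n_perm: int = 100,
    seed: int = 0,
    quantiles: Sequence[float] = (0.5, 0.9, 0.95, 0.99),
    pseudocount: float = 1.0,
    log_base: str = "log2",
    tail: str = "parametric",
) -> dict[float, float]:
    """Empirical null quantiles of max |omega| under gene-label shuffles.

    Permuting the gene labels of the m-vector destroys the physical
    clustering of co-regulated genes while preserving the marginal
    m distribution, so the max |omega| over permutations calibrates a
    call threshold for this dataset.  Seeded and deterministic.
    """
    if n_perm < 10:
        raise InputError(f"n_perm must be >= 10, got {n_perm}")
    aligned = matrix.values.loc[order.gene_ids()]
    aligned_matrix = ExpressionMatrix(aligned, matrix.sample_sheet.reset_index())
    profile = compute_m_values(
        aligned_matrix, pair, pseudocount=pseudocount, log_base=log_base
    )
    z = standardize_profile(profile)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        zp = rng.permutation(z)
        track = m_scores(zp, order, ncl)
        omega = omega_scores(track, d=d, tail=tail)
        maxima[b] = np.abs(omega.omega).max()
    return {float(q): float(np.quantile(maxima, q)) for q in quantiles}
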