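"""Expression matrices, condition pairs, and per-gene induction indexes.

The induction-ratio indexes implemented here are the per-gene summaries
used to rank candidate biosynthesis genes against a producing vs
non-producing condition pair:

* ``m``   -- log2 induction ratio of replicate means,
* ``t``   -- Welch two-sample t statistic on log2 replicate values,
* ``a``   -- average expression level across both conditions,
* ``mxa`` -- the product m * a, which up-weights highly expressed
  induced genes.

A condition pair is called a CCC (culture condition combination): one
unordered pair of condition labels, compared as producing (numerator)
vs non-producing (denominator).  With n conditions there are
C(n, 2) = n(n-1)/2 CCCs; 28 conditions give 378.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from middascan.errors import DegenerateStatisticsError, InputError

__all__ = [
    "ConditionPair",
    "ExpressionMatrix",
    "InductionProfile",
    "compute_a_values",
    "compute_m_values",
    "compute_t_values",
    "enumerate_cccs",
    "zscore",
]


@dataclass(frozen=True)
class ConditionPair:
    """One CCC: numerator (producing) over denominator (non-producing)."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise InputError(f"condition pair with identical labels: {self.numerator}")

    @property
    def label(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    def swapped(self) -> "ConditionPair":
        return ConditionPair(self.denominator, self.numerator)


class ExpressionMatrix:
    """Genes x samples expression values plus a sample sheet.

    Values are non-negative reals in whatever normalized unit the input
    provides (middascan performs no normalization).  The sample sheet
    maps each sample to exactly one condition label and a replicate id.
    """

    def __init__(self, values: pd.DataFrame, sample_sheet: pd.DataFrame):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise InputError(f"duplicate gene id in matrix: {dup}")
        if (values.to_numpy() < 0).any():
            raise InputError("expression matrix contains negative values")
        required = {"sample_id", "condition", "replicate"}
        if not required.issubset(sample_sheet.columns):
            raise InputError(f"sample sheet must have columns {sorted(required)}")
        sheet = sample_sheet.set_index("sample_id")
        if sheet.index.has_duplicates:
            raise InputError("sample sheet assigns a sample more than once")
        missing = set(values.columns) - set(sheet.index)
        if missing:
            raise InputError(f"samples without condition assignment: {sorted(missing)}")
        self.values = values.astype(float)
        self.sample_sheet = sheet.loc[list(values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.sample_sheet["condition"].unique())

    def samples_for(self, condition: str) -> list[str]:
        mask = self.sample_sheet["condition"] == condition
        samples = list(self.sample_sheet.index[mask])
        if not samples:
            raise InputError(f"no samples for condition {condition!r}")
        return samples

    @classmethod
    def from_tsv(
        cls, matrix_path: str | os.PathLike, samples_path: str | os.PathLike
    ) -> "ExpressionMatrix":
        """Read a genes x samples TSV (first column gene_id) and a
        sample sheet TSV (sample_id, condition, replicate)."""
        for p in (matrix_path, samples_path):
            if not os.path.exists(p):
                raise InputError(f"file not found: {p}")
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        return cls(values, sheet)

    def to_tsv(self, matrix_path: str | os.PathLike, samples_path: str | os.PathLike) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id", lineterminator="\n")
        self.sample_sheet.reset_index().to_csv(
            samples_path, sep="\t", index=False, lineterminator="\n"
        )


@dataclass
class InductionProfile:
    """Per-gene m/t/a/mxa values for one condition pair.

    ``undefined`` flags genes whose m could not be computed (both means
    zero with pseudocount 0); their m is set to 0 so downstream window
    arithmetic stays aligned to the gene order.  ``t_available`` is
    False when either condition has fewer than two replicates.
    """

    gene_ids: list[str]
    pair: ConditionPair
    m: np.ndarray
    undefined: np.ndarray
    a: np.ndarray | None = None
    mxa: np.ndarray | None = None
    t: np.ndarray | None = None
    t_available: bool = False
    t_infinite: np.ndarray | None = None
    log_base: str = "log2"

    def index_values(self, index: str) -> np.ndarray:
        """The per-gene vector for one of the indexes m, t, a, mxa."""
        if index == "m":
            return self.m
        if index == "t":
            if not self.t_available or self.t is None:
                raise InputError("t-values unavailable (need >= 2 replicates per condition)")
            return self.t
        if index == "a":
            if self.a is None:
                raise InputError("a-values not computed")
            return self.a
        if index == "mxa":
            if self.mxa is None:
                raise InputError("mxa-values not computed")
            return self.mxa
        raise InputError(f"unknown index {index!r}; expected m, t, a or mxa")

    def to_frame(self) -> pd.DataFrame:
        flags = np.where(self.undefined, "undefined_m", "")
        if self.t_infinite is not None:
            inf = np.where(self.t_infinite, "infinite_t", "")
            flags = np.char.add(
                flags, np.where((flags != "") & (inf != ""), ";", "")
            )
            flags = np.char.add(flags, inf)
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "m": self.m,
                "t": self.t if self.t is not None else np.nan,
                "a": self.a if self.a is not None else np.nan,
                "mxa": self.mxa if self.mxa is not None else np.nan,
                "flags": flags,
            }
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def enumerate_cccs(conditions: list[str]) -> list[ConditionPair]:
    """All unordered condition pairs, canonically oriented.

    The canonical orientation puts the lexicographically smaller label
    in the numerator; the scan reports signed scores, so the opposite
    orientation is recoverable by negation.
    """
    labels = sorted(set(conditions))
    if len(labels) < 2:
        raise InputError("need at least 2 distinct condition labels")
    return [ConditionPair(a, b) for a, b in itertools.combinations(labels, 2)]


def _log(x: np.ndarray, base: str) -> np.ndarray:
    if base == "log2":
        return np.log2(x)
    if base == "ln":
        return np.log(x)
    raise InputError(f"unknown log base {base!r}; expected log2, ln or ratio")


def compute_m_values(
    matrix: ExpressionMatrix,
    pair: ConditionPair,
    pseudocount: float = 1.0,
    log_base: str = "log2",
) -> InductionProfile:
    """Per-gene induction ratio m for one condition pair.

    m = log((mean_num + pseudocount) / (mean_den + pseudocount)), means
    taken over replicates.  ``log_base`` is ``log2`` (default), ``ln``,
    or ``ratio`` for the raw un-logged quotient.  A gene with both means
    zero at pseudocount 0 is flagged undefined and assigned m = 0 (the
    post-centering mean), never silently dropped.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    num = matrix.values[matrix.samples_for(pair.numerator)].mean(axis=1).to_numpy()
    den = matrix.values[matrix.samples_for(pair.denominator)].mean(axis=1).to_numpy()
    num = num + pseudocount
    den = den + pseudocount
    undefined = (num == 0) | (den == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
        if log_base == "ratio":
            m = ratio
        else:
            m = _log(ratio, log_base)
    m = np.where(undefined, 0.0, m)
    return InductionProfile(
        gene_ids=matrix.gene_ids,
        pair=pair,
        m=m,
        undefined=undefined,
        log_base=log_base,
    )


def compute_t_values(
    matrix: ExpressionMatrix,
    pair: ConditionPair,
    profile: InductionProfile | None = None,
    pseudocount: float = 1.0,
    log_transform: bool = True,
) -> InductionProfile:
    """Welch two-sample t statistic per gene.

    By default replicates are log2(x + pseudocount)-transformed first,
    putting t on the same (log-fold) scale as m; ``log_transform=False``
    computes Welch t on the raw values.  Requires at least two
    replicates in each condition; otherwise the profile is returned
    with ``t_available = False``.  Zero variance in both groups gives
    t = 0 for equal means and a flagged +/-inf for unequal means.
    """
    if profile is None:
        profile = compute_m_values(matrix, pair, pseudocount=pseudocount)
    xs = matrix.values[matrix.samples_for(pair.numerator)].to_numpy()
    ys = matrix.values[matrix.samples_for(pair.denominator)].to_numpy()
    if xs.shape[1] < 2 or ys.shape[1] < 2:
        profile.t = None
        profile.t_available = False
        return profile
    if log_transform:
        lx = np.log2(xs + pseudocount) if pseudocount > 0 else np.log2(np.maximum(xs, np.finfo(float).tiny))
        ly = np.log2(ys + pseudocount) if pseudocount > 0 else np.log2(np.maximum(ys, np.finfo(float).tiny))
    else:
        lx, ly = xs.astype(float), ys.astype(float)
    nx, ny = lx.shape[1], ly.shape[1]
    mx, my = lx.mean(axis=1), ly.mean(axis=1)
    vx, vy = lx.var(axis=1, ddof=1), ly.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 == 0
    t = np.where(degenerate & (diff == 0), 0.0, t)
    t_infinite = degenerate & (diff != 0)
    t = np.where(t_infinite, np.where(diff > 0, np.inf, -np.inf), t)
    profile.t = t
    profile.t_available = True
    profile.t_infinite = t_infinite
    return profile


def compute_a_values(
    matrix: ExpressionMatrix,
    pair: ConditionPair,
    profile: InductionProfile,
) -> InductionProfile:
    """Average expression level a over all samples of both conditions,
    and the product index mxa = m * a."""
    samples = matrix.samples_for(pair.numerator) + matrix.samples_for(pair.denominator)
    a = matrix.values[samples].mean(axis=1).to_numpy()
    profile.a = a
    profile.mxa = profile.m * a
    return profile


def full_profile(
    matrix: ExpressionMatrix,
    pair: ConditionPair,
    pseudocount: float = 1.0,
    log_base: str = "log2",
) -> InductionProfile:
    """m, t, a and mxa in one call."""
    profile = compute_m_values(matrix, pair, pseudocount=pseudocount, log_base=log_base)
    profile = compute_t_values(matrix, pair, profile=profile, pseudocount=pseudocount)
    return compute_a_values(matrix, pair, profile)


def zscore(values: np.ndarray) -> np.ndarray:
    """Z-score transform with population (1/N) standard deviation.

    Centers to mean 0 and scales to standard deviation 1.  Population
    rather than sample sd because the vector is a census of all genes
    (or all windows), not a sample from a larger population.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise DegenerateStatisticsError("zscore needs >= 2 finite values")
    if not finite.all():
        raise DegenerateStatisticsError("zscore input contains non-finite values")
    sd = x.std()  # ddof=0
    if sd == 0 or not math.isfinite(sd):
        raise DegenerateStatisticsError("zscore undefined: zero standard deviation")
    return (x - x.mean()) / sd
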