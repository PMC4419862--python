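"""Synthetic genomes and transcriptomes with planted co-regulated clusters.

The generator emulates the statistical structure the window scan
assumes: a genome of ordered genes whose baseline expression follows a
log-normal law, multiplicative log-normal replicate noise, and one or
more blocks of consecutive genes whose expression is multiplied by a
fold-induction factor in designated "producing" conditions only.

The default scenario is one contig of 2,000 genes with a single
10-gene cluster induced 8-fold in one of four conditions, three
replicates each, baseline log-normal with median 100 expression units
(sd of log 1.0) and replicate noise with sd of log 0.5.  Everything is
driven by one integer seed; the same config and seed always reproduce
the same matrix bit for bit.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from middascan.errors import InputError
from middascan.expression_stats import ExpressionMatrix
from middascan.genome_model import GeneOrder, GeneRecord, write_annotation

__all__ = [
    "BENCHMARK_SEEDS",
    "ClusterSpec",
    "SimulationConfig",
    "make_fixture_suite",
    "simulate",
]

#: Seeds of the standard benchmark replicate set used for recovery-rate
#: estimates.
BENCHMARK_SEEDS = tuple(range(1, 101))

_GENE_LENGTH = 1000
_GENE_SPACING = 1500


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster: size, fold induction and the condition
    labels in which it is induced."""

    size: int
    fold: float
    producing: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.size < 2:
            raise InputError(f"cluster size must be >= 2, got {self.size}")
        if not self.fold > 0:
            raise InputError(f"fold induction must be > 0, got {self.fold}")
        if not self.producing:
            raise InputError("cluster needs at least one producing condition")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset.

    ``conditions`` maps condition label to replicate count.  Baseline
    expression for gene g is lognormal(baseline_mean_log,
    baseline_sd_log); each sample value multiplies the baseline by the
    cluster fold (planted genes, producing conditions only) and by
    lognormal(0, noise_sd_log) replicate noise.
    """

    n_genes: int = 2000
    n_contigs: int = 1
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec(size=10, fold=8.0, producing=("prod",)),
    )
    conditions: tuple[tuple[str, int], ...] = (
        ("prod", 3),
        ("veg1", 3),
        ("veg2", 3),
        ("veg3", 3),
    )
    baseline_mean_log: float = math.log(100.0)
    baseline_sd_log: float = 1.0
    noise_sd_log: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_contigs < 1:
            raise InputError("n_genes and n_contigs must be >= 1")
        if self.n_contigs > self.n_genes:
            raise InputError("more contigs than genes")
        if self.noise_sd_log < 0 or self.baseline_sd_log < 0:
            raise InputError("sd-log parameters must be >= 0")
        labels = [c for c, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise InputError("duplicate condition label")
        if any(n < 1 for _, n in self.conditions):
            raise InputError("each condition needs >= 1 replicate")
        for spec in self.clusters:
            unknown = set(spec.producing) - set(labels)
            if unknown:
                raise InputError(f"unknown producing condition: {sorted(unknown)[0]}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "clusters" in raw:
            raw["clusters"] = tuple(
                ClusterSpec(c["size"], c["fold"], tuple(c["producing"]))
                for c in raw["clusters"]
            )
        if "conditions" in raw:
            raw["conditions"] = tuple(
                (str(label), int(n)) for label, n in dict(raw["conditions"]).items()
            )
        return cls(**raw)


def _place_genes(config: SimulationConfig) -> GeneOrder:
    """Genes in contiguous chunks over contigs, evenly split, fixed
    spacing, alternating strand."""
    records = []
    per = np.full(config.n_contigs, config.n_genes // config.n_contigs)
    per[: config.n_genes % config.n_contigs] += 1
    gid = 0
    for c, n in enumerate(per, start=1):
        for i in range(int(n)):
            gid += 1
            start = i * _GENE_SPACING + 1
            records.append(
                GeneRecord(
                    gene_id=f"g{gid:05d}",
                    contig=f"chr{c}",
                    start=start,
                    end=start + _GENE_LENGTH - 1,
                    strand="+" if gid % 2 else "-",
                )
            )
    return GeneOrder(records)


def _place_clusters(
    config: SimulationConfig, order: GeneOrder, rng: np.random.Generator
) -> list[tuple[ClusterSpec, str, int]]:
    """Random non-overlapping consecutive index ranges, one per cluster."""
    contig_sizes = {c: len(order.genes_on(c)) for c in order.contigs}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in order.contigs}
    placements = []
    for spec in config.clusters:
        candidates = [c for c, g in contig_sizes.items() if g >= spec.size]
        if not candidates:
            raise InputError(
                f"cluster of {spec.size} genes exceeds every contig's capacity"
            )
        placed = False
        for _ in range(1000):
            contig = candidates[rng.integers(len(candidates))]
            start = int(rng.integers(1, contig_sizes[contig] - spec.size + 2))
            span = (start, start + spec.size - 1)
            if all(span[1] < lo or span[0] > hi for lo, hi in occupied[contig]):
                occupied[contig].append(span)
                placements.append((spec, contig, start))
                placed = True
                break
        if not placed:
            raise InputError("could not place clusters without overlap")
    return placements


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[GeneOrder, ExpressionMatrix, pd.DataFrame]:
    """Generate (gene order, expression matrix, truth table).

    ``seed`` overrides ``config.seed`` when given.  The truth table has
    one row per planted gene: cluster_id, gene_id, contig, start_index,
    size, fold, producing (comma-joined labels).
    """
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    order = _place_genes(config)
    placements = _place_clusters(config, order, rng)

    gene_ids = order.gene_ids()
    n = len(gene_ids)
    baseline = rng.lognormal(config.baseline_mean_log, config.baseline_sd_log, size=n)

    fold_factor: dict[str, np.ndarray] = {
        label: np.ones(n) for label, _ in config.conditions
    }
    pos = {g: k for k, g in enumerate(gene_ids)}
    truth_rows = []
    for cid, (spec, contig, start) in enumerate(placements, start=1):
        genes = [r.gene_id for r in order.genes_on(contig)[start - 1 : start - 1 + spec.size]]
        for label in spec.producing:
            fold_factor[label][[pos[g] for g in genes]] *= spec.fold
        for g in genes:
            truth_rows.append(
                {
                    "cluster_id": cid,
                    "gene_id": g,
                    "contig": contig,
                    "start_index": start,
                    "size": spec.size,
                    "fold": spec.fold,
                    "producing": ",".join(spec.producing),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["cluster_id", "gene_id", "contig", "start_index", "size", "fold", "producing"],
    )

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for label, n_rep in config.conditions:
        for rep in range(1, n_rep + 1):
            sample = f"{label}_r{rep}"
            noise = (
                np.exp(rng.normal(0.0, config.noise_sd_log, size=n))
                if config.noise_sd_log > 0
                else np.ones(n)
            )
            columns[sample] = baseline * fold_factor[label] * noise
            sheet_rows.append({"sample_id": sample, "condition": label, "replicate": str(rep)})
    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    matrix = ExpressionMatrix(values, pd.DataFrame(sheet_rows))
    return order, matrix, truth


def make_fixture_suite(out_dir: str | os.PathLike, seed: int = 1) -> list[str]:
    """Write the default benchmark scenario to ``out_dir``.

    Emits annotation.tsv, matrix.tsv, samples.tsv and truth.tsv, all in
    the dialects the readers of this package consume.  Returns the list
    of paths written.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise InputError(f"output directory not writable: {out_dir}")
    config = SimulationConfig(seed=seed)
    order, matrix, truth = simulate(config)
    paths = {
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "matrix": os.path.join(out_dir, "matrix.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_annotation(order, paths["annotation"])
    matrix.to_tsv(paths["matrix"], paths["samples"])
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    return list(paths.values())
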