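"""Leakage-aware zero-shot train/validation/test splits.

Zero-shot evaluation requires that the kinase classes seen in training are
disjoint from those used for validation and testing.  Beyond disjointness,
three criteria guard against optimistic estimates:

1. every test (validation) kinase keeps a minimum number of association
   pairs, so per-class average precision is estimated from enough sites;
2. test kinases are drawn per kinase group (stratified), so each branch of
   the kinome taxonomy is represented when possible;
3. kinases whose domain sequences align at or above an identity threshold
   are clustered and assigned to the same side of the split, so a model
   cannot be trained on a near-duplicate of a held-out class.

Identity is computed from end-to-end (global) pairwise alignment of the
kinase domains, with gap columns counted in the denominator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .dataset import (
    AssociationTable,
    Dataset,
    KinaseRecord,
    PhoszslError,
    write_pairs,
    read_pairs,
)


class SplitError(PhoszslError):
    """Infeasible split configuration or malformed split."""


# ---------------------------------------------------------------------------
# Pairwise identity and clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring; defaults follow EMBOSS needle."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Fraction of identical positions after global alignment.

    The denominator is the full alignment length including gap columns,
    which is the strictest convention and therefore the safest for leakage
    screening: identity can only be overestimated by shrinking the
    denominator, never by this choice.
    """
    if not seq_a or not seq_b:
        raise SplitError("cannot align an empty sequence")
    if aligner is None:
        aligner = (scoring or AlignmentScoring()).make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def identity_matrix(
    kinases: Mapping[str, KinaseRecord],
    scoring: AlignmentScoring | None = None,
) -> tuple[list[str], np.ndarray]:
    """All-vs-all identity for a kinase table (symmetric, unit diagonal)."""
    ids = list(kinases)
    aligner = (scoring or AlignmentScoring()).make_aligner()
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = kinases[ids[i]].domain_sequence, kinases[ids[j]].domain_sequence
            ident = 1.0 if a == b else pairwise_identity(a, b, aligner=aligner)
            mat[i, j] = mat[j, i] = ident
    return ids, mat


def cluster_by_identity(
    kinases: Mapping[str, KinaseRecord],
    threshold: float = 0.90,
    scoring: AlignmentScoring | None = None,
    precomputed: tuple[list[str], np.ndarray] | None = None,
) -> list[frozenset[str]]:
    """Single-linkage clusters of kinases at >= ``threshold`` identity.

    Clusters are the connected components of the graph whose edges join
    kinase pairs with identity at or above the threshold; every kinase
    falls in exactly one cluster.
    """
    ids, mat = precomputed if precomputed is not None else identity_matrix(
        kinases, scoring
    )
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if mat[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, kid in enumerate(ids):
        groups.setdefault(find(i), set()).add(kid)
    clusters = [frozenset(g) for g in groups.values()]
    clusters.sort(key=lambda c: sorted(c)[0])
    return clusters


# ---------------------------------------------------------------------------
# Split construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitConfig:
    """Parameters of the zero-shot split.

    ``test_min`` / ``val_min`` are the per-kinase pair minimums for held-out
    kinases; ``identity_threshold`` is the leakage cutoff on domain-sequence
    identity; ``target_fractions`` are (train, validation, test) shares of
    association pairs.
    """

    test_min: int = 15
    val_min: int = 10
    identity_threshold: float = 0.90
    target_fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def __post_init__(self) -> None:
        if abs(sum(self.target_fractions) - 1.0) > 1e-9:
            raise SplitError("target_fractions must sum to 1")
        if not 0 < self.identity_threshold <= 1:
            raise SplitError("identity_threshold must lie in (0, 1]")


@dataclass
class BenchmarkSplit:
    """Disjoint train/validation/test kinase sets with their pair tables."""

    train_kinases: frozenset[str]
    val_kinases: frozenset[str]
    test_kinases: frozenset[str]
    train_pairs: AssociationTable
    val_pairs: AssociationTable
    test_pairs: AssociationTable
    seed: int = 0

    def fractions(self) -> tuple[float, float, float]:
        total = len(self.train_pairs) + len(self.val_pairs) + len(self.test_pairs)
        if total == 0:
            return (0.0, 0.0, 0.0)
        return (
            len(self.train_pairs) / total,
            len(self.val_pairs) / total,
            len(self.test_pairs) / total,
        )


def _select_holdout(
    clusters: Sequence[frozenset[str]],
    counts: Mapping[str, int],
    groups: Mapping[str, str],
    min_pairs: int,
    target_pairs: float,
    test_frac: float,
    rng: np.random.Generator,
) -> set[str]:
    """Pick held-out kinases (one split side) at cluster granularity.

    Procedure: clusters containing any kinase below ``min_pairs`` are forced
    to stay in training; remaining multi-member clusters are pre-assigned
    wholly to the held-out side with probability ``test_frac``; then a
    stratified draw over kinase groups tops up the held-out pair count to
    ``target_pairs``.  A first pass guarantees one cluster from every group
    with at least three eligible kinases.
    """
    cluster_pairs = {c: sum(counts.get(k, 0) for k in c) for c in clusters}
    eligible = [
        c for c in clusters if all(counts.get(k, 0) >= min_pairs for k in c)
    ]
    held: set[frozenset[str]] = set()
    total = 0.0
    # pre-assign whole multi-member clusters at the target rate; clusters
    # larger than the remaining pair deficit stay in train (the safe side)
    singles: list[frozenset[str]] = []
    for c in eligible:
        if len(c) > 1:
            if rng.random() < test_frac and cluster_pairs[c] <= target_pairs - total:
                held.add(c)
                total += cluster_pairs[c]
        else:
            singles.append(c)
    remaining = [c for c in eligible if len(c) > 1 and c not in held] + singles

    def cluster_group(c: frozenset[str]) -> str:
        # a cluster takes the group of its best-covered member
        best = max(c, key=lambda k: (counts.get(k, 0), k))
        return groups[best]

    by_group: dict[str, list[frozenset[str]]] = {}
    for c in remaining:
        by_group.setdefault(cluster_group(c), []).append(c)
    for g in by_group:
        by_group[g].sort(key=lambda c: sorted(c)[0])
    group_pairs = {
        g: sum(cluster_pairs[c] for c in cs) for g, cs in by_group.items()
    }
    group_order = sorted(by_group, key=lambda g: (-group_pairs[g], g))

    def draw_from(g: str) -> None:
        # uniform among clusters fitting the remaining pair deficit; when
        # none fits, the group's smallest cluster bounds the overshoot
        nonlocal total
        cs = by_group[g]
        deficit = target_pairs - total
        fitting = [c for c in cs if cluster_pairs[c] <= deficit]
        if fitting:
            c = fitting[int(rng.integers(len(fitting)))]
        else:
            c = min(cs, key=lambda c: (cluster_pairs[c], sorted(c)[0]))
        cs.remove(c)
        held.add(c)
        total += cluster_pairs[c]

    # guarantee pass: one cluster from every group with >= 3 eligible kinases
    for g in group_order:
        n_elig = sum(len(c) for c in by_group[g])
        already = any(cluster_group(c) == g for c in held)
        if n_elig >= 3 and by_group[g] and not already:
            draw_from(g)
    # top-up passes until the pair target is first reached
    while total < target_pairs:
        available = [g for g in group_order if by_group[g]]
        if not available:
            break
        for g in available:
            if total >= target_pairs:
                break
            if by_group[g]:
                draw_from(g)
    out: set[str] = set()
    for c in held:
        out.update(c)
    return out


def make_split(
    dataset: Dataset,
    config: SplitConfig | None = None,
    clusters: Sequence[frozenset[str]] | None = None,
) -> BenchmarkSplit:
    """Generate a reproducible zero-shot split.

    Steps: (1) kinases below ``test_min`` pairs are train-only; (2) identity
    clusters are formed and assigned wholesale (never separated); (3) test
    kinases are drawn per kinase group until the test pair count reaches its
    target fraction; (4) the same procedure picks validation kinases from
    the remaining training kinases with the ``val_min`` threshold; (5) pair
    tables are materialised from kinase membership, preserving input order.

    ``clusters`` may carry precomputed identity clusters (e.g. reused across
    seeds); otherwise they are computed from the kinase domain sequences.
    """
    config = config or SplitConfig()
    rng = np.random.default_rng(config.seed)
    counts = dataset.table.pair_counts()
    for kid in dataset.kinases:
        counts.setdefault(kid, 0)
    if clusters is None:
        clusters = cluster_by_identity(
            dataset.kinases, config.identity_threshold, config.scoring
        )
    groups = {kid: rec.group for kid, rec in dataset.kinases.items()}
    total_pairs = len(dataset.table)
    frac_train, frac_val, frac_test = config.target_fractions

    if not any(
        all(counts[k] >= config.test_min for k in c) for c in clusters
    ):
        raise SplitError(
            f"infeasible split: no identity cluster has every member with "
            f">= {config.test_min} pairs, so the test set would be empty"
        )

    test_ids = _select_holdout(
        clusters,
        counts,
        groups,
        min_pairs=config.test_min,
        target_pairs=frac_test * total_pairs,
        test_frac=frac_test,
        rng=rng,
    )
    if not test_ids:
        raise SplitError("infeasible split: stratified draw selected no test kinase")
    rest = [c for c in clusters if not (c & test_ids)]
    val_ids = _select_holdout(
        rest,
        counts,
        groups,
        min_pairs=config.val_min,
        target_pairs=frac_val * total_pairs,
        test_frac=frac_val,
        rng=rng,
    )
    train_ids = {
        k for c in clusters for k in c if k not in test_ids and k not in val_ids
    }
    return BenchmarkSplit(
        train_kinases=frozenset(train_ids),
        val_kinases=frozenset(val_ids),
        test_kinases=frozenset(test_ids),
        train_pairs=dataset.table.restrict_to_kinases(train_ids),
        val_pairs=dataset.table.restrict_to_kinases(val_ids),
        test_pairs=dataset.table.restrict_to_kinases(test_ids),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Split validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    rule: str
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        if self.ok:
            return "split valid: no violations"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.rule}] {v.detail}" for v in self.violations]
        return "\n".join(lines)


def validate_split(
    dataset: Dataset,
    split: BenchmarkSplit,
    config: SplitConfig | None = None,
    precomputed_identity: tuple[list[str], np.ndarray] | None = None,
) -> ValidationReport:
    """Audit a split (generated here or supplied externally) against the
    zero-shot criteria: disjoint kinase sets, pair-membership consistency,
    per-kinase minimums, and absence of cross-split identity leakage."""
    config = config or SplitConfig()
    v: list[Violation] = []
    sets = {
        "train": split.train_kinases,
        "val": split.val_kinases,
        "test": split.test_kinases,
    }
    for a, b in [("train", "val"), ("train", "test"), ("val", "test")]:
        overlap = sets[a] & sets[b]
        if overlap:
            v.append(
                Violation("disjointness", f"{a}/{b} share kinases {sorted(overlap)}")
            )
    tables = {
        "train": split.train_pairs,
        "val": split.val_pairs,
        "test": split.test_pairs,
    }
    for name, table in tables.items():
        for site_id, kinase_id in table.pairs:
            if kinase_id not in sets[name]:
                v.append(
                    Violation(
                        "membership",
                        f"{name} pair ({site_id}, {kinase_id}) names a kinase "
                        f"outside the {name} kinase set",
                    )
                )
                break
    for name, minimum in [("test", config.test_min), ("val", config.val_min)]:
        counts = tables[name].pair_counts()
        for kid in sorted(sets[name]):
            if counts.get(kid, 0) < minimum:
                v.append(
                    Violation(
                        "min-pairs",
                        f"{name} kinase {kid} has {counts.get(kid, 0)} pairs "
                        f"(< {minimum})",
                    )
                )
    # identity leakage across split boundaries
    if precomputed_identity is not None:
        ids, mat = precomputed_identity
    else:
        ids, mat = identity_matrix(dataset.kinases, config.scoring)
    index = {kid: i for i, kid in enumerate(ids)}
    assignment = {k: name for name, kset in sets.items() for k in kset}
    keys = [k for k in ids if k in assignment]
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if assignment[a] != assignment[b]:
                ident = mat[index[a], index[b]]
                if ident >= config.identity_threshold:
                    v.append(
                        Violation(
                            "identity-leakage",
                            f"{a} ({assignment[a]}) and {b} ({assignment[b]}) "
                            f"align at {ident:.3f} identity "
                            f">= {config.identity_threshold}",
                        )
                    )
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# Split IO
# ---------------------------------------------------------------------------


def write_split(
    split: BenchmarkSplit, directory: str | Path, config: SplitConfig | None = None
) -> None:
    """Write train/val/test pair TSVs plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pairs(split.train_pairs, directory / "train_pairs.tsv")
    write_pairs(split.val_pairs, directory / "val_pairs.tsv")
    write_pairs(split.test_pairs, directory / "test_pairs.tsv")
    manifest = {
        "seed": split.seed,
        "n_train_kinases": len(split.train_kinases),
        "n_val_kinases": len(split.val_kinases),
        "n_test_kinases": len(split.test_kinases),
        "n_train_pairs": len(split.train_pairs),
        "n_val_pairs": len(split.val_pairs),
        "n_test_pairs": len(split.test_pairs),
        "train_kinases": sorted(split.train_kinases),
        "val_kinases": sorted(split.val_kinases),
        "test_kinases": sorted(split.test_kinases),
    }
    if config is not None:
        manifest["config"] = {
            "test_min": config.test_min,
            "val_min": config.val_min,
            "identity_threshold": config.identity_threshold,
            "target_fractions": list(config.target_fractions),
            "scoring": dataclasses.asdict(config.scoring),
        }
    with open(directory / "split_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_split(directory: str | Path) -> BenchmarkSplit:
    """Read a split written by :func:`write_split`."""
    directory = Path(directory)
    train = read_pairs(directory / "train_pairs.tsv")
    val = read_pairs(directory / "val_pairs.tsv")
    test = read_pairs(directory / "test_pairs.tsv")
    with open(directory / "split_manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return BenchmarkSplit(
        train_kinases=frozenset(manifest["train_kinases"]),
        val_kinases=frozenset(manifest["val_kinases"]),
        test_kinases=frozenset(manifest["test_kinases"]),
        train_pairs=train,
        val_pairs=val,
        test_pairs=test,
        seed=int(manifest.get("seed", 0)),
    )
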