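"""Multilabel zero-shot ranking metrics.

The central metric is macro average precision: for each kinase class, all
test sites are ranked by that kinase's score column, AP summarises the
resulting precision-recall behaviour, and the per-kinase APs are averaged
with equal class weight.  Complementary views: phosphosite AP (rank kinases
per site), family/group-aggregated AP (class scores pooled over taxonomy
members), masked-group AP (scores outside a site's true kinase groups set
to -inf, isolating within-group ranking), hit@k, and a Monte-Carlo
random-ranking baseline.

AP is the non-interpolated information-retrieval definition: the mean over
positives of precision at each positive's rank, with descending stable
sort so score ties resolve by input order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PhoszslError

logger = logging.getLogger(__name__)


class MetricError(PhoszslError):
    """Metric undefined on the given input (e.g. no positive labels)."""


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Non-interpolated average precision of a single ranking.

    ``scores`` may contain ``-inf`` (items ranked strictly last); ties are
    broken by stable input order.  Raises :class:`MetricError` when there
    is no positive label, so callers can skip undefined classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError("scores and labels must be 1-D arrays of equal length")
    if np.isnan(scores).any():
        raise MetricError("scores contain NaN")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise MetricError("average precision undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    cum_pos = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    precision_at_pos = cum_pos[ranked] / ranks[ranked]
    return float(precision_at_pos.mean())


@dataclass
class ScoreMatrix:
    """Scores for (site, kinase) with explicit row/column identifiers."""

    values: np.ndarray
    site_ids: list[str]
    kinase_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.kinase_ids)):
            raise MetricError(
                f"score matrix shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.kinase_ids)} kinases"
            )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values,
            index=pd.Index(self.site_ids, name="site_id"),
            columns=self.kinase_ids,
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            site_ids=[str(i) for i in df.index],
            kinase_ids=[str(c) for c in df.columns],
        )


def _label_matrix(scores: ScoreMatrix, site_labels: Mapping[str, set[str]]) -> np.ndarray:
    kin_index = {k: j for j, k in enumerate(scores.kinase_ids)}
    y = np.zeros(scores.values.shape, dtype=bool)
    for i, site in enumerate(scores.site_ids):
        for k in site_labels.get(site, ()):
            j = kin_index.get(k)
            if j is not None:
                y[i, j] = True
    return y


def macro_ap(
    scores: ScoreMatrix, site_labels: Mapping[str, set[str]]
) -> tuple[float, dict[str, float]]:
    """Per-kinase AP over site rankings, averaged with equal class weight.

    Kinases with no positive site among the scored sites are excluded from
    the mean with a logged warning.
    """
    y = _label_matrix(scores, site_labels)
    per_kinase: dict[str, float] = {}
    skipped = []
    for j, kid in enumerate(scores.kinase_ids):
        try:
            per_kinase[kid] = average_precision(scores.values[:, j], y[:, j])
        except MetricError:
            skipped.append(kid)
    if skipped:
        logger.warning(
            "macro AP: %d kinase(s) without positive sites excluded: %s",
            len(skipped),
            skipped[:5],
        )
    if not per_kinase:
        raise MetricError("no kinase has a positive site; macro AP undefined")
    return float(np.mean(list(per_kinase.values()))), per_kinase


def phosphosite_ap(
    scores: ScoreMatrix, site_labels: Mapping[str, set[str]]
) -> float:
    """Per-site AP over kinase rankings, averaged over sites."""
    y = _label_matrix(scores, site_labels)
    values = []
    skipped = []
    for i, site in enumerate(scores.site_ids):
        try:
            values.append(average_precision(scores.values[i], y[i]))
        except MetricError:
            skipped.append(site)
    if skipped:
        logger.warning(
            "phosphosite AP: %d site(s) without evaluable positives excluded: %s",
            len(skipped),
            skipped[:5],
        )
    if not values:
        raise MetricError("no site has an evaluable positive; phosphosite AP undefined")
    return float(np.mean(values))


def aggregated_ap(
    scores: ScoreMatrix,
    site_labels: Mapping[str, set[str]],
    mapping: Mapping[str, str],
    agg: str = "max",
) -> float:
    """Macro AP after pooling kinases into taxonomy classes (family/group).

    A site's score for a class is the ``max`` (or ``sum``) over its member
    kinases' scores, and the site is positive for a class iff any of its
    true kinases maps to that class.
    """
    missing = [k for k in scores.kinase_ids if k not in mapping]
    if missing:
        raise MetricError(f"mapping missing for kinases: {missing[:5]}")
    classes = sorted({mapping[k] for k in scores.kinase_ids})
    members = {
        c: [j for j, k in enumerate(scores.kinase_ids) if mapping[k] == c]
        for c in classes
    }
    if agg == "max":
        pooled = np.stack(
            [scores.values[:, members[c]].max(axis=1) for c in classes], axis=1
        )
    elif agg == "sum":
        pooled = np.stack(
            [scores.values[:, members[c]].sum(axis=1) for c in classes], axis=1
        )
    else:
        raise MetricError(f"unknown aggregation {agg!r}")
    class_labels = {
        site: {mapping[k] for k in kset if k in mapping}
        for site, kset in site_labels.items()
    }
    pooled_matrix = ScoreMatrix(pooled, scores.site_ids, classes)
    value, _ = macro_ap(pooled_matrix, class_labels)
    return value


def masked_group_ap(
    scores: ScoreMatrix,
    site_labels: Mapping[str, set[str]],
    group_mapping: Mapping[str, str],
) -> float:
    """Macro AP after masking kinases outside each site's true group(s).

    For each site, the allowed groups are the union of its true kinases'
    groups; scores of kinases outside those groups are set to ``-inf`` so
    they rank strictly below every finite score.  This isolates the model's
    ability to rank kinases *within* the correct group.
    """
    missing = [k for k in scores.kinase_ids if k not in group_mapping]
    if missing:
        raise MetricError(f"group mapping missing for kinases: {missing[:5]}")
    masked = scores.values.astype(float).copy()
    kin_groups = np.array([group_mapping[k] for k in scores.kinase_ids])
    for i, site in enumerate(scores.site_ids):
        allowed = {
            group_mapping[k]
            for k in site_labels.get(site, ())
            if k in group_mapping
        }
        keep = np.isin(kin_groups, sorted(allowed))
        masked[i, ~keep] = -np.inf
    value, _ = macro_ap(
        ScoreMatrix(masked, scores.site_ids, scores.kinase_ids), site_labels
    )
    return value


def hit_at_k(
    scores: ScoreMatrix,
    site_labels: Mapping[str, set[str]],
    ks: Sequence[int],
) -> dict[int, float]:
    """Fraction of sites with a true kinase among the top-k predictions."""
    if any(k < 1 for k in ks):
        raise MetricError("k must be >= 1")
    y = _label_matrix(scores, site_labels)
    out: dict[int, float] = {}
    n_sites, n_kin = scores.values.shape
    order = np.argsort(-scores.values, axis=1, kind="stable")
    for k in ks:
        top = order[:, : min(k, n_kin)]
        hits = np.array([y[i, top[i]].any() for i in range(n_sites)])
        out[int(k)] = float(hits.mean()) if n_sites else 0.0
    return out


def random_baseline_ap(
    site_labels: Mapping[str, set[str]],
    kinase_ids: Sequence[str],
    n_runs: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo macro AP of uniformly random kinase rankings.

    Each run draws an independent uniform score for every (site, kinase)
    cell, which realises a uniformly random kinase ranking for every site
    (and, for every kinase, a uniformly random ordering of sites); the
    macro AP of each random matrix is computed and the mean and standard
    deviation over runs are returned.
    """
    if n_runs < 1:
        raise MetricError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    site_ids = list(site_labels)
    n_kin = len(kinase_ids)
    values = np.empty(n_runs)
    for r in range(n_runs):
        random_scores = rng.random((len(site_ids), n_kin))
        value, _ = macro_ap(
            ScoreMatrix(random_scores, site_ids, list(kinase_ids)), site_labels
        )
        values[r] = value
    return float(values.mean()), float(values.std(ddof=1)) if n_runs > 1 else 0.0


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """All ranking metrics for one score matrix."""

    macro_ap: float
    per_kinase_ap: dict[str, float]
    phosphosite_ap: float
    family_ap: float | None
    group_ap: float | None
    masked_group_ap: float | None
    hit_at_k: dict[int, float]
    n_sites: int
    n_kinases: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "macro_ap": self.macro_ap,
            "phosphosite_ap": self.phosphosite_ap,
            "family_ap": self.family_ap,
            "group_ap": self.group_ap,
            "masked_group_ap": self.masked_group_ap,
            "hit_at_k": {str(k): v for k, v in self.hit_at_k.items()},
            "n_sites": self.n_sites,
            "n_kinases": self.n_kinases,
            "per_kinase_ap": self.per_kinase_ap,
        }
        text = json.dumps(payload, indent=2, sort_keys=False)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def per_kinase_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.per_kinase_ap.items()), columns=["kinase_id", "ap"]
        ).to_csv(path, sep="\t", index=False)


def evaluate(
    scores: ScoreMatrix,
    site_labels: Mapping[str, set[str]],
    family_mapping: Mapping[str, str] | None = None,
    group_mapping: Mapping[str, str] | None = None,
    ks: Sequence[int] = (1, 3, 5, 10),
) -> EvalReport:
    """Compute the full metric suite for one score matrix."""
    macro, per_kinase = macro_ap(scores, site_labels)
    return EvalReport(
        macro_ap=macro,
        per_kinase_ap=per_kinase,
        phosphosite_ap=phosphosite_ap(scores, site_labels),
        family_ap=(
            aggregated_ap(scores, site_labels, family_mapping)
            if family_mapping
            else None
        ),
        group_ap=(
            aggregated_ap(scores, site_labels, group_mapping)
            if group_mapping
            else None
        ),
        masked_group_ap=(
            masked_group_ap(scores, site_labels, group_mapping)
            if group_mapping
            else None
        ),
        hit_at_k=hit_at_k(scores, site_labels, ks),
        n_sites=len(scores.site_ids),
        n_kinases=len(scores.kinase_ids),
    )
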