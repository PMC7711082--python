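"""Rank-based single-sample signature scoring.

Given a signed, weighted gene signature, each sample receives one score
measuring how strongly the up-weighted genes concentrate at the top of
that sample's expression ranking and the down-weighted genes at the
bottom.  The statistic is a weighted two-distribution running sum in the
BASE family of single-sample enrichment scores:

* Rank the sample's genes by descending expression (ties broken by
  ascending gene id, for determinism across platforms).
* For a magnitude vector v (|weight| on set genes, 0 elsewhere), walk the
  ranking and track the foreground cumulative share
  ``F(k) = sum_{i<=k} v_i / sum_i v_i`` against the background share
  ``B(k) = sum_{i<=k} (1 - v_i) / sum_i (1 - v_i)``.
* The pre-score is ``D(k*) = F(k*) - B(k*)`` at the position k* with the
  largest |F - B| (smallest k on ties).  It lies in [-1, 1] and is
  positive when the weighted genes sit near the top of the ranking.
* The pre-score is normalized by the mean |pre-score| under M uniform
  permutations of the magnitude vector over the gene universe (seeded,
  reproducible).  This normalization is sign-preserving and scale-free:
  a score of +2 means twice the deviation expected for a random gene set
  of the same weight profile.

A sample's final score is (normalized up-set score) - (normalized
down-set score), computed with one shared permutation stream per sample,
so high scores mean "up-genes high AND down-genes low" and negating
every signature weight negates every score exactly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .iokit import Signature, ValidationError, validate_expression

logger = logging.getLogger("fusionsig")

#: Identifier of the scoring variant recorded in output metadata.
STATISTIC_VARIANT = "weighted-running-sum/max-deviation, mean-abs permutation normalization"


@dataclasses.dataclass(frozen=True)
class Ranking:
    """Deterministic per-sample gene ordering (descending expression)."""

    genes: tuple[str, ...]
    tie_rule: str = "descending expression, ties by ascending gene id"

    def __len__(self) -> int:
        return len(self.genes)


@dataclasses.dataclass(frozen=True)
class ScoreVector:
    """Per-sample signature scores with scoring provenance."""

    scores: pd.Series
    n_permutations: int
    seed: int
    signature_id: str
    statistic: str = STATISTIC_VARIANT
    dropped_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("non-finite sample score")

    def metadata(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "signature_id": self.signature_id,
            "statistic": self.statistic,
            "n_dropped_genes": len(self.dropped_genes),
            "dropped_genes": list(self.dropped_genes),
            "n_samples": int(self.scores.size),
        }


def rank_genes(sample_expr: pd.Series) -> Ranking:
    """Order one sample's genes by descending expression.

    Exact ties are broken by ascending gene identifier so the ranking is
    deterministic.  Missing values are rejected (rank-based scoring is
    undefined on them).
    """
    values = sample_expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = sample_expr.index[~np.isfinite(values)].tolist()
        raise ValidationError(f"missing/non-finite expression for gene(s): {bad[:5]}")
    order = sorted(range(values.size), key=lambda i: (-values[i], str(sample_expr.index[i])))
    return Ranking(tuple(str(sample_expr.index[i]) for i in order))


def _prescore_from_ordered(v: np.ndarray) -> float:
    """Pre-score for magnitudes already arranged in ranked order."""
    # totals are the final entries of the running sums, so every quantity
    # in D(k) comes from one strict left-to-right accumulation
    cum_fg = np.cumsum(v)
    cum_bg = np.cumsum(1.0 - v)
    total_fg = cum_fg[-1]
    total_bg = cum_bg[-1]
    if total_fg == 0.0:
        raise ValidationError("all magnitudes are zero")
    if total_bg == 0.0:
        raise ValidationError("background is empty (every magnitude equals 1)")
    d = cum_fg / total_fg - cum_bg / total_bg
    k_star = int(np.argmax(np.abs(d)))  # first max = smallest k on ties
    return float(d[k_star])


def running_sum_score(ranking: Ranking, magnitudes: dict | pd.Series) -> float:
    """Evaluate the running-sum pre-score for one sample.

    Parameters
    ----------
    ranking
        The sample's gene ordering.
    magnitudes
        Per-gene weights in [0, 1]; genes absent from the mapping count
        as 0 (background only).  At least one magnitude must be positive.

    Returns
    -------
    float
        ``D(k*) = F(k*) - B(k*)`` in [-1, 1].
    """
    mags = pd.Series(magnitudes, dtype=float)
    v = mags.reindex(list(ranking.genes), fill_value=0.0).to_numpy()
    if np.any((v < 0.0) | (v > 1.0)):
        raise ValidationError("magnitudes must lie in [0, 1]")
    return _prescore_from_ordered(v)


def normalize_score(
    pre_score: float,
    ranking: Ranking,
    magnitudes: dict | pd.Series,
    n_permutations: int,
    seed: int,
) -> float:
    """Divide a pre-score by its mean |pre-score| under permutation.

    Draws ``n_permutations`` uniform permutations of the magnitude vector
    over the gene universe from ``np.random.default_rng(seed)`` (one
    ``rng.permutation(N)`` call per draw, in order) and returns
    ``pre_score / mean_m |p_m|``.  Sign-preserving; zero maps to zero.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    mags = pd.Series(magnitudes, dtype=float)
    v = mags.reindex(list(ranking.genes), fill_value=0.0).to_numpy()
    if np.any((v < 0.0) | (v > 1.0)):
        raise ValidationError("magnitudes must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(v.size) for _ in range(n_permutations)])
    denom = _mean_abs_prescore(v[perms])
    if denom == 0.0:
        raise ValidationError("degenerate magnitude vector: permuted pre-scores are all zero")
    return float(pre_score) / denom


def _mean_abs_prescore(vmat: np.ndarray) -> float:
    """Mean |pre-score| over rows of an (M, N) magnitude matrix.

    Totals are accumulated per row so a row's pre-score is bit-identical
    to evaluating :func:`running_sum_score` on that row alone.
    """
    cum_fg = np.cumsum(vmat, axis=1)
    cum_bg = np.cumsum(1.0 - vmat, axis=1)
    d = np.abs(cum_fg / cum_fg[:, -1:] - cum_bg / cum_bg[:, -1:])
    return float(d.max(axis=1).mean())


def score_samples(
    expr: pd.DataFrame,
    signature: Signature,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ScoreVector:
    """Score every sample of an expression matrix against a signature.

    The signature is split into its up-set (positive weights) and
    down-set (negative weights); each yields a normalized running-sum
    score on the full gene universe, and the sample score is their
    difference (up minus down; an empty set contributes 0).  The
    permutation stream is seeded per sample as
    ``default_rng([seed, sample_index])`` and shared between the up and
    down computations, which makes scores deterministic and exactly
    antisymmetric under weight negation.

    Signature genes absent from the matrix are dropped with a warning;
    if none remain, or the matrix carries duplicate gene ids, an error
    is raised.
    """
    validate_expression(expr)
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    weights = signature.as_series()
    present = weights.index.isin(expr.index)
    dropped = tuple(weights.index[~present])
    if dropped:
        logger.warning(
            "%d signature gene(s) absent from the matrix; dropping them", len(dropped)
        )
    weights = weights[present]
    if weights.empty:
        raise ValidationError("no signature gene is present in the expression matrix")

    genes = expr.index.to_numpy(dtype=object)
    v_up = pd.Series(0.0, index=expr.index)
    v_up[weights.index[weights > 0]] = weights[weights > 0].to_numpy()
    v_down = pd.Series(0.0, index=expr.index)
    v_down[weights.index[weights < 0]] = -weights[weights < 0].to_numpy()
    up = v_up.to_numpy()
    down = v_down.to_numpy()
    has_up = up.sum() > 0
    has_down = down.sum() > 0

    n_genes = genes.size
    values = expr.to_numpy()
    # rank once per sample: descending expression, ties by ascending gene id
    gene_rank_by_id = np.argsort(np.argsort(genes.astype(str)))
    scores = np.empty(expr.shape[1])
    for j, sample in enumerate(expr.columns):
        order = np.lexsort((gene_rank_by_id, -values[:, j]))
        rng = np.random.default_rng([seed, j])
        perms = np.stack([rng.permutation(n_genes) for _ in range(n_permutations)])
        score = 0.0
        if has_up:
            pre = _prescore_from_ordered(up[order])
            score += pre / _mean_abs_prescore(up[perms[:, order]])
        if has_down:
            pre = _prescore_from_ordered(down[order])
            score -= pre / _mean_abs_prescore(down[perms[:, order]])
        scores[j] = score

    return ScoreVector(
        scores=pd.Series(scores, index=expr.columns, name="score"),
        n_permutations=n_permutations,
        seed=seed,
        signature_id=signature.name,
        dropped_genes=dropped,
    )


def write_scores(sv: ScoreVector, path, sidecar: bool = True) -> None:
    """Write ``sample_id<TAB>score`` rows (6 decimals) plus JSON metadata."""
    from pathlib import Path

    from .iokit import write_json

    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tscore\n")
        for sample, s in sv.scores.items():
            fh.write(f"{sample}\t{s:.6f}\n")
    if sidecar:
        write_json(sv.metadata(), path.with_suffix(path.suffix + ".json"))


def read_scores(path) -> pd.Series:
    """Read a ``sample_id<TAB>score`` file back into a Series."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns[:2]) != ["sample_id", "score"]:
        raise ValidationError(f"{path}: expected columns sample_id, score")
    return pd.Series(df["score"].to_numpy(dtype=float), index=df["sample_id"], name="score")
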