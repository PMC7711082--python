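"""Derivation of the signed, weighted fusion signature.

One logistic regression per gene models TMPRSS2-ERG fusion status
(positive vs not) as a function of that gene's expression plus age and
Gleason score as covariates.  The K genes with the smallest Wald p-values
on the expression coefficient form the signature; each selected gene g
receives the weight

    w_g = sign(beta_g) * (-log10 p_g) / max_selected(-log10 p)

so that all weights lie in [-1, 1], the largest magnitude is exactly 1,
and the sign marks up-/downregulation in fusion-positive tumors.

Degenerate fits (constant expression, perfect separation, non-convergent
likelihood) are flagged non-informative (coefficient 0, p-value 1) rather
than silently refit with a penalized method.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .iokit import Signature, ValidationError, align_samples

logger = logging.getLogger("fusionsig")

#: |coefficient| above this is treated as a diverging (separated) fit.
_COEF_DIVERGENCE_LIMIT = 1e2

#: Number of top genes kept by default.
DEFAULT_TOP_K = 700


@dataclasses.dataclass(frozen=True)
class GeneStat:
    """Per-gene logistic-regression result.

    ``coefficient`` is the log-odds of fusion positivity per expression
    unit, adjusted for age and Gleason; ``p_value`` is the two-sided Wald
    p-value of that coefficient.  Non-informative genes (degenerate or
    non-convergent fits) carry coefficient 0 and p-value 1.
    """

    gene: str
    coefficient: float
    p_value: float
    informative: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"{self.gene}: p_value must lie in (0, 1]")
        if not self.informative and (self.coefficient != 0.0 or self.p_value != 1.0):
            raise ValidationError(
                f"{self.gene}: non-informative genes must carry coefficient 0, p-value 1"
            )


def _uninformative(gene: str) -> GeneStat:
    return GeneStat(gene=gene, coefficient=0.0, p_value=1.0, informative=False)


def fit_gene_logistic(
    expr_row: np.ndarray | pd.Series,
    fusion_labels: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame,
    gene: str = "gene",
) -> GeneStat:
    """Fit ``fusion ~ expression + age + gleason`` for one gene.

    Parameters
    ----------
    expr_row
        Expression of the gene across samples.
    fusion_labels
        Binary response per sample (1 = fusion-positive).
    covariates
        Per-sample covariate columns (age, Gleason as numeric), aligned
        with ``expr_row``.  Gleason is treated as an ordinal numeric
        severity rather than categorical dummies.
    """
    x = np.asarray(expr_row, dtype=float)
    y = np.asarray(fusion_labels, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if not (x.shape[0] == y.shape[0] == cov.shape[0]):
        raise ValidationError(
            f"misaligned inputs: expression n={x.shape[0]}, labels n={y.shape[0]}, "
            f"covariates n={cov.shape[0]}"
        )
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or not np.isin(classes, (0.0, 1.0)).all():
        raise ValidationError("fusion labels must contain both classes, coded 0/1")
    if counts.min() < 2:
        raise ValidationError("need at least 2 samples per fusion class")

    if np.ptp(x) == 0.0:
        return _uninformative(gene)

    design = sm.add_constant(np.column_stack([x, cov]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        except Exception:
            logger.debug("gene %s: logistic fit failed (separation/degenerate)", gene)
            return _uninformative(gene)
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    converged = bool(fit.mle_retvals.get("converged", False))
    if (
        not converged
        or not np.isfinite(coef)
        or not np.isfinite(se)
        or se == 0.0
        or abs(coef) > _COEF_DIVERGENCE_LIMIT
    ):
        logger.debug("gene %s: non-convergent or diverging fit", gene)
        return _uninformative(gene)
    p = float(fit.pvalues[1])
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return GeneStat(gene=gene, coefficient=coef, p_value=p, informative=True)


def select_top_genes(stats: list[GeneStat], k: int) -> list[GeneStat]:
    """Keep the K informative genes with the smallest p-values.

    Ties are broken by ascending gene id, making selection deterministic.
    """
    if k <= 0:
        raise ValidationError("K must be a positive integer")
    informative = [s for s in stats if s.informative]
    if k > len(informative):
        raise ValidationError(
            f"K={k} exceeds the {len(informative)} informative genes; lower K"
        )
    ranked = sorted(informative, key=lambda s: (s.p_value, s.gene))
    return ranked[:k]


def assign_weights(selected: list[GeneStat], name: str = "signature") -> Signature:
    """Convert selected gene stats to signed weights in [-1, 1].

    ``w_g = sign(coef_g) * (-log10 p_g) / max(-log10 p)`` over the
    selected set, so the most significant gene anchors |w| = 1.
    p-values of exactly 0 are clamped to the smallest positive float
    before taking the log (with a warning).
    """
    if not selected:
        raise ValidationError("cannot assign weights to an empty selection")
    p = np.array([s.p_value for s in selected], dtype=float)
    if np.any(p <= 0.0):
        logger.warning("clamping %d zero p-value(s) before log", int((p <= 0).sum()))
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    neglog = -np.log10(p)
    top = float(neglog.max())
    if top == 0.0:
        # every selected p-value is 1: no significance ordering to encode
        raise ValidationError("all selected p-values are 1; cannot derive weights")
    signs = np.sign([s.coefficient for s in selected])
    if np.any(signs == 0):
        raise ValidationError("selected gene with zero coefficient cannot carry a sign")
    weights = signs * neglog / top
    # weights of exactly 0 (p=1 entries alongside smaller ones) cannot enter
    keep = weights != 0.0
    if not np.all(keep):
        logger.warning("dropping %d selected gene(s) with p=1 (zero weight)", int((~keep).sum()))
    genes = tuple(s.gene for s, k in zip(selected, keep) if k)
    return Signature(genes, tuple(float(w) for w, k in zip(weights, keep) if k), name=name)


def derive_signature(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    k: int = DEFAULT_TOP_K,
    name: str = "signature",
) -> tuple[Signature, pd.DataFrame]:
    """Derive the fusion signature from a labeled cohort.

    Runs :func:`fit_gene_logistic` for every gene in the matrix, selects
    the ``k`` most significant, and assigns normalized signed weights.
    Samples with missing age or Gleason are dropped (logged).  The fusion
    response is positive vs not-positive; ``erg_other`` samples count as
    negative, mirroring their TMPRSS2-ERG-negative labels.

    Returns
    -------
    (signature, stats_table)
        ``stats_table`` is the full per-gene audit table with columns
        ``coefficient, p_value, informative``, indexed by gene.
    """
    clinical = align_samples(expr, clinical)
    usable = clinical[["age", "gleason"]].notna().all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("dropping %d sample(s) with missing age/Gleason", n_dropped)
    clin = clinical.loc[usable]
    mat = expr.loc[:, clin.index]
    y = (clin["fusion_status"] == "positive").to_numpy(dtype=float)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValidationError("need at least 2 samples per fusion class after filtering")
    cov = clin[["age", "gleason"]].to_numpy(dtype=float)

    stats = [
        fit_gene_logistic(row, y, cov, gene=gene)
        for gene, row in zip(mat.index, mat.to_numpy())
    ]
    n_info = sum(s.informative for s in stats)
    logger.info("fitted %d genes (%d informative)", len(stats), n_info)
    selected = select_top_genes(stats, k)
    signature = assign_weights(selected, name=name)
    table = pd.DataFrame(
        {
            "coefficient": [s.coefficient for s in stats],
            "p_value": [s.p_value for s in stats],
            "informative": [s.informative for s in stats],
        },
        index=pd.Index([s.gene for s in stats], name="gene"),
    )
    return signature, table
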