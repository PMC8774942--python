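"""Two-group differential expression with empirical-Bayes variance
moderation, and the red-yellow-blue node-fill color scale.

The model is the standard hierarchical one for gene-wise variances: the
residual variance of gene g, :math:`s_g^2` on :math:`d` degrees of freedom,
is shrunk toward a prior :math:`s_0^2` with prior degrees of freedom
:math:`d_0`,

.. math:: s_{post}^2 = \\frac{d_0 s_0^2 + d s_g^2}{d_0 + d},

and the moderated t-statistic ``logfc / (s_post * sqrt(1/n1 + 1/n2))`` is
referred to a t distribution with :math:`d_0 + d` degrees of freedom.  The
hyperparameters are estimated by method of moments on :math:`\\log s_g^2`:
under the scaled-inverse-chi-square prior, ``log s^2`` has variance
``trigamma(d/2) + trigamma(d0/2)`` and a closed-form mean offset in
digamma terms, so ``d0`` comes from a one-dimensional trigamma inversion
and ``s0^2`` from the corrected mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "read_expression",
    "read_sample_sheet",
    "normalize_log2",
    "estimate_variance_prior",
    "de_two_group",
    "de_to_frame",
    "map_color",
    "to_hex",
    "NEUTRAL_GREY",
    "write_overlay",
]

GROUPS = ("treated", "untreated")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a two-group sample sheet."""

    values: pd.DataFrame  # index: genes, columns: samples
    groups: dict[str, str]  # sample -> 'treated' | 'untreated'
    logged: bool = False

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group: {sorted(missing)}")
        bad = {s: g for s, g in self.groups.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def read_expression(expr_path: str | Path, sheet_path: str | Path,
                    logged: bool = False) -> ExpressionMatrix:
    """Expression TSV (first column gene) plus sample-sheet TSV (sample, group)."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    groups = dict(zip(sheet["sample"], sheet["group"]))
    return ExpressionMatrix(values=values, groups=groups, logged=logged)


def normalize_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform; a no-op if the matrix is flagged as logged."""
    if matrix.logged:
        return matrix
    if (matrix.values.values < 0).any():
        raise ValueError("negative raw intensities cannot be log-transformed")
    out = ExpressionMatrix(values=np.log2(matrix.values + 1.0),
                           groups=dict(matrix.groups), logged=True)
    med = {g: float(np.median(out.values[out.samples_in(g)].values)) for g in GROUPS
           if out.samples_in(g)}
    if len(med) == 2 and abs(med["treated"] - med["untreated"]) > 1.0:
        logger.warning("group median intensities differ by > 1 log2 unit "
                       "(%.2f vs %.2f); matrices may not be comparable",
                       med["treated"], med["untreated"])
    return out


@dataclass
class DEResult:
    gene: str
    logfc: float  # log2(treated) - log2(untreated)
    se: float
    t_stat: float
    p_value: float
    moderated: bool
    d0: Optional[float] = None
    s0_sq: Optional[float] = None


def _solve_trigamma(target: float) -> float:
    """Solve trigamma(x) = target for x > 0 (target > 0); inf if target ~ 0."""
    if target <= 1e-8:
        return math.inf
    # trigamma is decreasing; bracket then brentq
    lo, hi = 1e-6, 1e8
    f = lambda x: float(special.polygamma(1, x)) - target
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) from gene-wise variances on d df.

    Uses z = log s^2:  Var(z) = trigamma(d/2) + trigamma(d0/2) and
    E(z) = log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2).
    Genes with zero variance are excluded from the moments.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 positive gene variances to estimate the prior")
    z = np.log(s2)
    excess = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2.0))
    d0 = 2.0 * _solve_trigamma(excess) if excess > 0 else math.inf
    mean_z = float(np.mean(z))
    offset = float(special.digamma(d / 2.0)) - math.log(d / 2.0)
    if math.isinf(d0):
        s0_sq = math.exp(mean_z - offset)
    else:
        prior_offset = float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        s0_sq = math.exp(mean_z - offset + prior_offset)
    return d0, s0_sq


def de_two_group(matrix: ExpressionMatrix, moderation: bool = True) -> list[DEResult]:
    """Per-gene treated-vs-untreated contrast on a logged matrix.

    logfc = mean(treated) - mean(untreated); the pooled residual variance
    has n1 + n2 - 2 degrees of freedom.  With ``moderation`` the variance
    is shrunk toward the method-of-moments prior before forming t.
    """
    if not matrix.logged:
        raise ValueError("matrix must be log-transformed first (normalize_log2)")
    t_samples = matrix.samples_in("treated")
    u_samples = matrix.samples_in("untreated")
    n1, n2 = len(t_samples), len(u_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} treated, {n2} untreated)")

    X1 = matrix.values[t_samples].values
    X2 = matrix.values[u_samples].values
    logfc = X1.mean(axis=1) - X2.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((X1 - X1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((X2 - X2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / d
    scale = 1.0 / n1 + 1.0 / n2

    d0 = s0_sq = None
    if moderation:
        d0, s0_sq = estimate_variance_prior(s2, d)
        if math.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
    else:
        s2_post = s2
        df_total = d

    se = np.sqrt(s2_post * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    return [
        DEResult(gene=str(g), logfc=float(logfc[i]), se=float(se[i]),
                 t_stat=float(t[i]), p_value=float(p[i]), moderated=moderation,
                 d0=d0 if moderation else None, s0_sq=s0_sq if moderation else None)
        for i, g in enumerate(matrix.values.index)
    ]


def de_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": r.gene, "logfc": r.logfc, "se": r.se, "t": r.t_stat,
          "p": r.p_value, "moderated": r.moderated} for r in results]
    )


# ---------------------------------------------------------------------------
# Color scale
# ---------------------------------------------------------------------------

_RED = (1.0, 0.0, 0.0)
_YELLOW = (1.0, 1.0, 0.0)
_DARK_BLUE = (0.0, 0.0, 0.545)
NEUTRAL_GREY = (0.7, 0.7, 0.7)


def _lerp(a, b, t: float):
    return tuple(ai + (bi - ai) * t for ai, bi in zip(a, b))


def map_color(logfc: Optional[float], cap: float = 1.0):
    """Expression fill color: red (over) - yellow (no change) - dark blue (under).

    Linear in logfc on [-cap, +cap], clamped outside; ``None`` maps to a
    neutral grey for genes without expression data.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if logfc is None:
        return NEUTRAL_GREY
    x = max(-1.0, min(1.0, logfc / cap))
    if x >= 0:
        return _lerp(_YELLOW, _RED, x)
    return _lerp(_YELLOW, _DARK_BLUE, -x)


def to_hex(rgb) -> str:
    return "#{:02x}{:02x}{:02x}".format(*(round(255 * c) for c in rgb))


def write_overlay(results: Sequence[DEResult], path: str | Path, cap: float = 1.0) -> None:
    """Overlay TSV: gene, logfc, hex fill color."""
    rows = [{"gene": r.gene, "logfc": r.logfc,
             "color": to_hex(map_color(r.logfc, cap=cap))} for r in results]
    pd.DataFrame(rows, columns=["gene", "logfc", "color"]).to_csv(path, sep="\t", index=False)
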