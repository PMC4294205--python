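"""Expression-correlation screening of called RBP-lncRNA pairs.

Each cohort (e.g. one cancer type) is an independent screen: for every
candidate (RBP, lncRNA) pair measured in a cohort, a Pearson correlation is
computed across samples (optionally after log2(x+1)), a two-sided p-value is
taken from the t distribution with n-2 degrees of freedom, and
Benjamini-Hochberg q-values are computed within the cohort over all tested
pairs.  A pair is flagged significant if it passes the chosen criterion
(raw p by default; q selectable) in at least one cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix for one cohort."""

    cohort: str
    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"cohort {self.cohort}: duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError(f"cohort {self.cohort}: duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path, cohort: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(cohort, df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class CorrelationResult:
    rbp: str
    lncrna: str
    cohort: str
    n: int
    r: float
    p: float
    q: float = float("nan")
    significant: bool = False


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN signals zero variance (pair skipped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r under the null, via t with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def coexpression_screen(
    pairs: Iterable[tuple[str, str]],
    matrices: Iterable[ExpressionMatrix],
    alpha: float = 0.05,
    criterion: str = "p",
    log_transform: bool = True,
) -> tuple[list[CorrelationResult], pd.DataFrame]:
    """Screen candidate pairs across cohorts.

    Returns per-(pair, cohort) results plus a per-pair summary with the
    number of cohorts tested and passing, and the overall significance flag
    (passes in >= 1 cohort).  Pairs measured in no cohort appear in the
    summary as untested.  Samples missing either gene's value are dropped
    pairwise; pairs with < 3 complete samples or zero variance are skipped
    with a log message.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if criterion not in ("p", "q"):
        raise ValueError(f"criterion must be 'p' or 'q', got {criterion!r}")
    pairs = list(dict.fromkeys(pairs))
    results: list[CorrelationResult] = []
    for mat in matrices:
        vals = mat.values
        if log_transform:
            vals = np.log2(vals + 1.0)
        cohort_res: list[CorrelationResult] = []
        n_skipped = 0
        for rbp, lnc in pairs:
            if rbp not in vals.index or lnc not in vals.index:
                continue
            x = vals.loc[rbp].to_numpy(dtype=float)
            y = vals.loc[lnc].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if x.size < 3:
                n_skipped += 1
                continue
            r = pearson_r(x, y)
            if np.isnan(r):
                n_skipped += 1
                continue
            p = corr_pvalue(r, x.size)
            cohort_res.append(CorrelationResult(rbp, lnc, mat.cohort, x.size, r, p))
        if n_skipped:
            logger.info(
                "cohort %s: skipped %d pairs (too few samples or zero variance)",
                mat.cohort,
                n_skipped,
            )
        if cohort_res:
            qvals = bh_fdr([cr.p for cr in cohort_res])
            for cr, q in zip(cohort_res, qvals):
                cr.q = float(q)
                stat = cr.p if criterion == "p" else cr.q
                cr.significant = bool(stat < alpha)
        results.extend(cohort_res)

    rows = []
    by_pair: dict[tuple[str, str], list[CorrelationResult]] = {}
    for cr in results:
        by_pair.setdefault((cr.rbp, cr.lncrna), []).append(cr)
    for rbp, lnc in pairs:
        crs = by_pair.get((rbp, lnc), [])
        rows.append(
            {
                "rbp": rbp,
                "lncrna": lnc,
                "n_cohorts_tested": len(crs),
                "n_cohorts_passing": sum(cr.significant for cr in crs),
                "significant": any(cr.significant for cr in crs),
                "untested": len(crs) == 0,
            }
        )
    summary = pd.DataFrame(rows)
    return results, summary


def results_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rbp": cr.rbp,
                "lncrna": cr.lncrna,
                "cohort": cr.cohort,
                "n": cr.n,
                "r": cr.r,
                "p": cr.p,
                "q": cr.q,
                "significant": cr.significant,
            }
            for cr in results
        ]
    )
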