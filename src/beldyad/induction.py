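"""Comparative-threshold-cycle (Livak) fold changes and linker correlation.

Per replicate, dCt = target Ct − reference-gene Ct; ddCt is the difference
of condition means (transgenic − WT) and the linear fold change is
2^(−ddCt), so the WT calibrator sits at 1.  Significance is a two-sided
two-sample Student's t-test on the per-replicate dCt values (the scale on
which the measurement noise is approximately Gaussian), with an optional
Welch variant.  Stars follow the 0.05 / 0.01 / 0.001 convention.

An optional efficiency-corrected mode replaces base 2 with (1 + E) for a
measured primer efficiency E.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeResult",
    "fold_change",
    "fold_change_table",
    "linker_induction_correlation",
    "induction_report",
    "stars_for",
]

_REQUIRED_COLUMNS = {"gene", "condition", "replicate", "target_ct", "reference_ct"}


def stars_for(p_value: float | None) -> int:
    """0–3 significance stars at thresholds 0.05, 0.01, 0.001."""
    if p_value is None or (isinstance(p_value, float) and math.isnan(p_value)):
        return 0
    return int(p_value < 0.05) + int(p_value < 0.01) + int(p_value < 0.001)


@dataclass(frozen=True)
class FoldChangeResult:
    """Fold change of one gene (transgenic vs WT calibrator)."""

    gene: str
    fold_change: float
    log2_fold_change: float
    p_value: float  # NaN when untestable (single replicate)
    stars: int
    n_transgenic: int
    n_wt: int
    ci_low: float = float("nan")  # 95% CI on the linear fold change
    ci_high: float = float("nan")


def _delta_ct(table: pd.DataFrame, gene: str, condition: str) -> np.ndarray:
    sub = table[(table["gene"] == gene) & (table["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"gene {gene!r} has no rows for condition {condition!r}")
    d = (sub["target_ct"] - sub["reference_ct"]).to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError(f"non-finite Ct values for gene {gene!r}")
    return d


def fold_change(
    table: pd.DataFrame,
    gene: str,
    *,
    treatment: str = "transgenic",
    control: str = "WT",
    equal_var: bool = True,
    efficiency: float | None = None,
) -> FoldChangeResult:
    """2^(−ddCt) fold change of ``gene`` with replicate t-test significance.

    ``efficiency`` switches to the efficiency-corrected base ``1 + E``
    (E = 1 is the ideal doubling assumed by the default).  With a single
    replicate in either condition the fold change is still computed but the
    p-value is reported as NaN.
    """
    missing = _REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    d_trt = _delta_ct(table, gene, treatment)
    d_ctl = _delta_ct(table, gene, control)
    ddct = float(d_trt.mean() - d_ctl.mean())
    base = 2.0 if efficiency is None else 1.0 + efficiency
    fc = base**-ddct
    n1, n2 = len(d_trt), len(d_ctl)
    p = float("nan")
    lo = hi = float("nan")
    if n1 >= 2 and n2 >= 2:
        p = float(stats.ttest_ind(d_trt, d_ctl, equal_var=equal_var).pvalue)
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * d_trt.var(ddof=1) + (n2 - 1) * d_ctl.var(ddof=1)) / df
            se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        else:
            v1, v2 = d_trt.var(ddof=1) / n1, d_ctl.var(ddof=1) / n2
            se = math.sqrt(v1 + v2)
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if v1 + v2 > 0 else n1 + n2 - 2
        tcrit = stats.t.ppf(0.975, df)
        lo = base ** -(ddct + tcrit * se)
        hi = base ** -(ddct - tcrit * se)
    return FoldChangeResult(
        gene=gene,
        fold_change=float(fc),
        log2_fold_change=float(-ddct * math.log2(base)),
        p_value=p,
        stars=stars_for(p),
        n_transgenic=n1,
        n_wt=n2,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def fold_change_table(table: pd.DataFrame, **kwargs) -> list[FoldChangeResult]:
    """Fold changes for every gene present in the Ct table (input order)."""
    return [fold_change(table, g, **kwargs) for g in pd.unique(table["gene"])]


def linker_induction_correlation(
    results: list[FoldChangeResult],
    linkers: dict[str, int],
) -> tuple[float, float]:
    """Spearman rank correlation of fold change against linker length.

    Returns ``(rho, p)``; genes missing from either input are dropped.  At
    least three paired genes are required; constant input yields NaN.
    """
    pairs = [(linkers[r.gene], r.fold_change) for r in results if r.gene in linkers]
    if len(pairs) < 3:
        raise ValueError("need >= 3 genes with both a fold change and a linker length")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def induction_report(
    scan_output: pd.DataFrame,
    results: list[FoldChangeResult],
) -> pd.DataFrame:
    """Join per-gene dyad calls with fold changes.

    ``scan_output`` needs columns ``gene_id``, ``orientation``,
    ``linker_length`` (e.g. from :func:`beldyad.io.dyads_to_frame`); one row
    per fold-change result is returned with ``motif_present`` flagging
    whether the scanner found any dyad for that gene — the expected pattern
    is that motif-absent genes are uninduced.
    """
    by_gene: dict[str, pd.DataFrame] = {}
    if len(scan_output):
        by_gene = {g: sub for g, sub in scan_output.groupby("gene_id")}
    result_genes = {r.gene for r in results}
    orphans = sorted(set(by_gene) - result_genes)
    if orphans:
        logger.warning("scan output for %s has no matching fold-change result", orphans)
    rows = []
    for r in results:
        sub = by_gene.get(r.gene)
        present = sub is not None and len(sub) > 0
        rows.append(
            {
                "gene": r.gene,
                "motif_present": present,
                "n_dyads": int(len(sub)) if present else 0,
                "orientations": ",".join(sorted(set(sub["orientation"]))) if present else "",
                "min_linker": int(sub["linker_length"].min()) if present else None,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "stars": r.stars,
            }
        )
    return pd.DataFrame(rows)
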