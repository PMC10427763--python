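"""Statistical layer: ROUT outlier detection, t test, Pearson r², 2^−ΔΔCt.

ROUT (robust regression and outlier removal) is implemented for the
location-only model used on univariate box-plot data: a robust center is fit
by iteratively reweighted least squares with Lorentzian weights, the robust
SD of the residuals (RSDR) comes from the 68.27th percentile of absolute
residuals with an n/(n−1) small-sample correction, and outliers are flagged
from the most extreme residual inward while the two-tailed t-tail
probability stays below the false-discovery ladder α_i = (Q/100)·i/n.

The fold-change analysis follows the ΔΔCt convention: per-sample ΔCt against
a housekeeping gene, ΔΔCt = mean ΔCt(treated) − mean ΔCt(control), relative
expression 2^−ΔΔCt, with |log2FC| > 0.5 (strict) as the significance zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RoutResult",
    "FoldChangeResult",
    "rout_outliers",
    "unpaired_t_test",
    "pearson_r2",
    "ddct",
]


@dataclass(frozen=True)
class RoutResult:
    robust_center: float
    rsdr: float  # robust SD of the residuals
    outlier_flags: np.ndarray  # bool per observation
    q: float  # FDR level in percent

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())

    def cleaned(self, values) -> np.ndarray:
        return np.asarray(values, dtype=float)[~self.outlier_flags]


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    delta_ct_control: float  # mean ΔCt of the control group (cycles)
    delta_ct_treated: float
    delta_delta_ct: float
    fold_change: float  # 2^−ΔΔCt
    log2_fc: float  # −ΔΔCt
    significant: bool  # |log2FC| > 0.5, strict


# ---------------------------------------------------------------------------
# ROUT


def _rsdr(residuals: np.ndarray) -> float:
    n = residuals.size
    p = float(np.percentile(np.abs(residuals), 68.27))
    return p * n / (n - 1)


def rout_outliers(values, q: float = 1.0, max_iter: int = 100, tol: float = 1e-10) -> RoutResult:
    """Identify outliers in a univariate sample with the ROUT procedure (Q %).

    Fits the robust center, computes the RSDR, converts each residual into a
    two-tailed t-tail probability (df = n − 1), and flags observations from
    the most extreme inward while p < (Q/100)·i/n.  All-identical samples
    (RSDR 0) flag nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1D")
    n = x.size
    if n < 3:
        raise ValueError("ROUT needs at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("values contain non-finite entries")

    center = float(np.median(x))
    for _ in range(max_iter):
        r = x - center
        scale = _rsdr(r)
        if scale == 0:
            break
        w = 1.0 / (1.0 + (r / scale) ** 2)
        new_center = float(np.sum(w * x) / np.sum(w))
        if abs(new_center - center) < tol * max(1.0, abs(center)):
            center = new_center
            break
        center = new_center

    resid = x - center
    rsdr = _rsdr(resid)
    flags = np.zeros(n, dtype=bool)
    if rsdr > 0:
        t = np.abs(resid) / rsdr
        order = np.argsort(-t)  # most extreme first
        pvals = 2.0 * sps.t.sf(t[order], df=n - 1)
        alpha = (q / 100.0) * (np.arange(1, n + 1) / n)
        for i, (idx, p) in enumerate(zip(order, pvals)):
            if p < alpha[i]:
                flags[idx] = True
            else:
                break
    return RoutResult(robust_center=center, rsdr=float(rsdr), outlier_flags=flags, q=q)


# ---------------------------------------------------------------------------
# t test / correlation


def unpaired_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t test; Student's pooled variance by default.

    Degenerate zero-variance input follows the documented convention:
    identical group means give (0, 1); distinct means with zero pooled
    variance give (±inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch:
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if sp2 == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            warnings.warn("zero pooled variance with unequal means", stacklevel=2)
            return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def pearson_r2(x, y, confidence: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Pearson r², two-tailed p, and the Fisher-z confidence interval of r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = sps.pearsonr(x, y)
    n = x.size
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = sps.norm.ppf(0.5 + confidence / 2.0)
        ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    else:
        ci = (float(r), float(r))
    return float(r**2), float(p), ci


# ---------------------------------------------------------------------------
# ΔΔCt


def ddct(
    table,
    housekeeping: str = "HPRT",
    control_group: str = "control",
    gene_col: str = "gene",
    group_col: str = "group",
    sample_col: str = "sample",
    ct_col: str = "ct",
    significance_cutoff: float = 0.5,
) -> list[FoldChangeResult]:
    """Relative expression 2^−ΔΔCt per gene from a long-format Ct table.

    Every sample must carry a Ct for the housekeeping gene; ΔCt is computed
    per sample, averaged per group, and ΔΔCt is the treated − control
    difference.  ``significant`` is True iff |log2FC| strictly exceeds the
    cutoff (default 0.5).
    """
    import pandas as pd

    df = pd.DataFrame(table)
    hk = df[df[gene_col] == housekeeping].set_index(sample_col)[ct_col]
    samples = df[sample_col].unique()
    missing = [s for s in samples if s not in hk.index]
    if missing:
        raise ValueError(f"samples missing housekeeping Ct: {missing}")
    groups = df[df[gene_col] != housekeeping][group_col].unique().tolist()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not found in {groups}")
    treated_groups = [g for g in groups if g != control_group]
    results = []
    for gene, sub in df[df[gene_col] != housekeeping].groupby(gene_col, sort=True):
        dct = sub[ct_col].to_numpy() - hk.loc[sub[sample_col]].to_numpy()
        by_group = pd.Series(dct, index=sub[group_col].to_numpy()).groupby(level=0).mean()
        dct_ctrl = float(by_group[control_group])
        for tg in treated_groups:
            dct_treat = float(by_group[tg])
            dd = dct_treat - dct_ctrl
            log2fc = -dd
            results.append(
                FoldChangeResult(
                    gene=str(gene),
                    delta_ct_control=dct_ctrl,
                    delta_ct_treated=dct_treat,
                    delta_delta_ct=dd,
                    fold_change=float(2.0 ** (-dd)),
                    log2_fc=log2fc,
                    significant=abs(log2fc) > significance_cutoff,
                )
            )
    return results
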