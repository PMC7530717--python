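"""Per-variant marginal association scans.

Produces the exposure / outcome summary statistics every two-sample estimator
in this package consumes.  Scans regress the phenotype on one standardized
dosage column at a time (mean 0, variance 1 within the analysis cohort), with
classical residual-based standard errors and p-values from the t distribution
with n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_sim import GenotypeMatrix

__all__ = ["SummaryStats", "marginal_scan"]

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


@dataclass
class SummaryStats:
    """Per-variant marginal association records.

    Wraps a DataFrame in the GCTA ``.ma`` column layout
    (``SNP A1 A2 freq b se p N``).  Monomorphic variants are kept as rows
    with NaN effect fields and ``valid == False`` rather than dropped, so
    variant indexing stays aligned with the genotype matrix.
    """

    table: pd.DataFrame
    standardized: bool = True
    phenotype_standardized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in MA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if "valid" not in self.table.columns:
            self.table = self.table.assign(valid=np.isfinite(self.table["se"]))
        ok = self.table["valid"]
        bad_se = ok & (self.table["se"] <= 0)
        if bad_se.any():
            raise ValueError("se must be positive for valid records")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["SNP"].to_numpy(dtype=object)

    @property
    def beta(self) -> np.ndarray:
        return self.table["b"].to_numpy(dtype=float)

    @property
    def se(self) -> np.ndarray:
        return self.table["se"].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.table["N"].to_numpy(dtype=float)

    @property
    def freq(self) -> np.ndarray:
        return self.table["freq"].to_numpy(dtype=float)


def _scan_arrays(
    X_std: np.ndarray, y: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope/SE/p of simple regressions of ``y`` on each standardized column.

    With columns at mean 0 and variance 1 (population convention), the OLS
    slope is ``x'y / n`` and the residual variance follows from the usual
    two-moment identity.  Returns (beta, se, p); columns that are all zero
    (monomorphic after standardization) come back NaN.
    """
    yc = y - y.mean()
    beta = (X_std.T @ yc) / n
    var_y = float(yc @ yc) / n
    # residual SS / n = var_y - beta^2 (x has unit variance)
    rss_n = np.maximum(var_y - beta**2, 0.0)
    dof = n - 2
    # se = sqrt(RSS / dof / sum(x^2)) with sum(x^2) = n; floored so an exact
    # noiseless fit yields a p underflow rather than a zero SE
    se = np.maximum(np.sqrt(rss_n / dof), np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    zero_col = X_std.std(axis=0) == 0
    beta[zero_col] = np.nan
    se[zero_col] = np.nan
    p[zero_col] = np.nan
    return beta, se, p


def marginal_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    standardize: bool = True,
    standardize_phenotype: bool = False,
) -> SummaryStats:
    """Marginal association scan of phenotype ``y`` against every variant.

    Parameters
    ----------
    G
        Genotype cohort; dosages count the A1 (effect) allele.
    y
        Quantitative phenotype, one value per individual.
    standardize
        Standardize dosages to mean 0, variance 1 within this cohort (the
        within-cohort convention of standard GWAS pipelines).  With
        ``standardize=False`` effects are per allele copy.
    standardize_phenotype
        Scale ``y`` to mean 0, variance 1 first, so effect sizes match
        eQTL-like summary statistics.
    """
    y = np.asarray(y, dtype=np.float64)
    n = G.n_individuals
    if len(y) != n:
        raise ValueError("phenotype length must equal individual count")
    if y.std() == 0:
        raise ValueError("phenotype has zero variance")
    if standardize_phenotype:
        y = (y - y.mean()) / y.std()

    if standardize:
        X = G.standardized().astype(np.float64)
    else:
        X = G.dosages.astype(np.float64)
        X = X - X.mean(axis=0)
    if not standardize:
        # generic per-allele scale: rescale the standardized-form solution
        sd = G.dosages.std(axis=0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        beta, se, p = _scan_arrays(X / sd_safe, y, n)
        # identical formulas; X/sd is exactly the standardized matrix
        beta, se = beta / sd_safe, se / sd_safe
    else:
        beta, se, p = _scan_arrays(X, y, n)

    table = pd.DataFrame(
        {
            "SNP": G.variant_ids,
            "A1": G.a1,
            "A2": G.a2,
            "freq": G.allele_frequency(),
            "b": beta,
            "se": se,
            "p": p,
            "N": n,
            "valid": np.isfinite(se),
        }
    )
    return SummaryStats(
        table=table,
        standardized=standardize,
        phenotype_standardized=standardize_phenotype,
    )
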