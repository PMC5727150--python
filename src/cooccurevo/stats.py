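"""Non-phylogenetic co-occurrence statistics with genome-size awareness.

These are the "flat" statistics of the analysis: 2x2 contingency tables of
two binary systems across genomes, Fisher exact tests of association,
expected co-occurrence counts under independence, a chi-square test on a
logistic fit for genome-size confounding, a rank-sum comparison of genome
sizes, and species-level aggregation (a species carries a system when
strictly more than half of its genomes do).

Genome tables are plain :class:`pandas.DataFrame` objects with columns
``genome_id, species, phylum, size_bp`` plus 0/1 trait columns.  The size
filter is strict ("smaller than"), with 1 Mb = 10^6 bp exactly.

All p-values are reported raw, as in the source analysis; a
Benjamini-Hochberg helper is provided as a clearly-labeled extension and
is never applied implicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "LogisticSizeResult",
    "validate_genome_table",
    "filter_genomes",
    "contingency",
    "fisher_exact",
    "expected_cooccurrence",
    "logistic_size_test",
    "ranksum_size_test",
    "aggregate_by_species",
    "benjamini_hochberg",
]

GENOME_COLUMNS = ("genome_id", "species", "phylum", "size_bp")

MB = 10 ** 6


def validate_genome_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(GENOME_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"genome table missing columns: {sorted(missing)}")
    if table["genome_id"].duplicated().any():
        dup = table.loc[table["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome_id: {dup[:5]}")
    if (table["size_bp"] <= 0).any():
        raise ValueError("size_bp must be positive")
    return table


def filter_genomes(table: pd.DataFrame, max_size_bp: int = 5 * MB,
                   phyla=None) -> pd.DataFrame:
    """Keep genomes strictly smaller than ``max_size_bp`` and in ``phyla``.

    The size bound is exclusive: a genome of exactly ``max_size_bp`` is
    dropped.  An empty result is a warning, not an error.
    """
    validate_genome_table(table)
    n0 = len(table)
    out = table[table["size_bp"] < max_size_bp]
    n_size = n0 - len(out)
    n_phy = 0
    if phyla is not None:
        phyla = set(phyla)
        kept = out[out["phylum"].isin(phyla)]
        n_phy = len(out) - len(kept)
        out = kept
    logger.info("filter_genomes: %d input, %d dropped by size, %d by phylum, %d kept",
                n0, n_size, n_phy, len(out))
    if len(out) == 0:
        warnings.warn("genome filter left no genomes")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 co-occurrence counts: a=(1,1), b=(1,0), c=(0,1), d=(0,0)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def contingency(table: pd.DataFrame, trait_x: str, trait_y: str) -> ContingencyTable:
    """2x2 counts of two 0/1 trait columns."""
    for col in (trait_x, trait_y):
        if col not in table.columns:
            raise ValueError(f"missing trait column {col!r}")
        vals = set(table[col].unique()) - {0, 1}
        if vals:
            raise ValueError(f"trait column {col!r} has non-binary values {vals}")
    x = table[trait_x].astype(int)
    y = table[trait_y].astype(int)
    return ContingencyTable(
        a=int(((x == 1) & (y == 1)).sum()),
        b=int(((x == 1) & (y == 0)).sum()),
        c=int(((x == 0) & (y == 1)).sum()),
        d=int(((x == 0) & (y == 0)).sum()),
    )


def fisher_exact(ct: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness by the point-probability method: the p-value sums the
    hypergeometric probabilities of all tables (with the observed margins)
    no more probable than the observed one.
    """
    _, p = sps.fisher_exact(ct.as_array(), alternative="two-sided")
    return float(p)


def expected_cooccurrence(ct: ContingencyTable) -> float:
    """Expected (1,1) count if the two systems were randomly distributed:
    product of the marginal presence counts over the total."""
    if ct.n == 0:
        raise ValueError("empty contingency table")
    return (ct.a + ct.b) * (ct.a + ct.c) / ct.n


@dataclass
class LogisticSizeResult:
    """Likelihood-ratio test of presence ~ genome size (chi-square, df=1)."""

    lrt_stat: float
    p: float
    slope_per_mb: float
    n: int
    separation_warning: bool = False


def logistic_size_test(presence, size_bp) -> LogisticSizeResult:
    """Chi-square test on a logistic fit of presence against genome size.

    Compares presence ~ 1 + size against the intercept-only model by
    likelihood ratio, referred to chi-square(1).  The covariate is
    standardized internally, so the p-value is invariant to affine
    rescaling of the sizes (bp vs Mb give identical results).  Perfect
    separation is flagged, not raised.
    """
    y = np.asarray(presence, dtype=float)
    x = np.asarray(size_bp, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("presence and size_bp must be equal-length vectors")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("presence must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("presence is constant; logistic test undefined")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct sizes")
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    z = (x - x.mean()) / x.std()
    sep = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            full = sm.Logit(y, sm.add_constant(z)).fit(disp=0, maxiter=200)
            llf_full = full.llf
            slope_z = full.params[1]
        except (PerfectSeparationWarning, PerfectSeparationError):
            # ridge-like refit just to obtain a finite likelihood bound
            sep = True
            full = sm.Logit(y, sm.add_constant(z)).fit_regularized(
                disp=0, alpha=1e-6, maxiter=500)
            llf_full = sm.Logit(y, sm.add_constant(z)).loglike(full.params)
            slope_z = full.params[1]
    pbar = y.mean()
    llf_null = len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    lrt = max(2.0 * (llf_full - llf_null), 0.0)
    p = float(sps.chi2.sf(lrt, df=1))
    if sep:
        warnings.warn("perfect separation in logistic size test; p is approximate")
    return LogisticSizeResult(
        lrt_stat=float(lrt), p=p,
        slope_per_mb=float(slope_z / x.std() * MB),
        n=len(y), separation_warning=sep,
    )


def ranksum_size_test(sizes_group1, sizes_group2) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two size samples.

    Exact when both groups are small (<= 10) and tie-free; otherwise the
    normal approximation with tie correction.
    """
    g1 = np.asarray(sizes_group1, dtype=float)
    g2 = np.asarray(sizes_group2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([g1, g2])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(g1) <= 10 and len(g2) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.pvalue)


def aggregate_by_species(table: pd.DataFrame, trait: str) -> pd.Series:
    """Species-level presence: 1 iff strictly more than half the genomes
    of the species carry the trait (ties count as absent)."""
    validate_genome_table(table)
    if trait not in table.columns:
        raise ValueError(f"missing trait column {trait!r}")

    def majority(s: pd.Series) -> int:
        return int(s.sum() > len(s) / 2)

    return table.groupby("species")[trait].agg(majority)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (extension; the core analysis reports raw p)."""
    from statsmodels.stats.multitest import multipletests
    _, adj, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return adj
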