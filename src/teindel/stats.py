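"""Rank correlation and resampling tests for windowed genome statistics.

The windowed rate and bias variables are far from normal, so association is
measured with Kendall's tie-corrected tau_b throughout. Group comparisons
(sex chromosome vs. autosomes) use a stratified label-permutation bootstrap
that preserves subfamily composition within each category; the
per-chromosome analysis uses a randomization test on the mean within-
chromosome tau. All permutation p-values use the add-one convention
p = (1 + #extreme) / (R + 1), which keeps p > 0 and makes the null
distribution of p (sub)uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    tau: float
    p_value: float
    n: int


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall's tau_b with tie correction; p from the normal approximation.

    Pairs with a missing value in either vector are dropped. An all-tied
    vector leaves tau undefined (NaN tau, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(tau=float("nan"), p_value=1.0, n=n)
    tau, p = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult(tau=float(tau), p_value=float(p), n=n)


# ---------------------------------------------------------------------------
# stratified bootstrap (Z vs autosome comparisons)
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSpec:
    """Specification of a two-category stratified label-permutation test.

    ``statistic`` is 'mean-length-diff' (difference of mean element lengths)
    or 'bias-diff' (difference of deletion biases, each computed as
    sum(deleted bp)/sum(inserted bp) over the category's elements). Strata
    (subfamilies) not present in both categories are excluded.
    """

    categories: tuple[str, str]
    replicates: int = 10_000
    seed: int = 0
    statistic: str = "bias-diff"


@dataclass
class BootstrapResult:
    observed: float
    p_two_sided: float
    p_one_sided: float
    replicates: int
    n_redrawn: int = 0
    excluded_strata: list[str] = field(default_factory=list)


def _category_stat(spec: BootstrapSpec, df: pd.DataFrame, mask: np.ndarray) -> float:
    if spec.statistic == "mean-length-diff":
        return float(df["length"].values[mask].mean())
    if spec.statistic == "bias-diff":
        ins = float(df["inserted_bp"].values[mask].sum())
        if ins == 0:
            return float("nan")
        return float(df["deleted_bp"].values[mask].sum() / ins)
    raise ValueError(f"unknown statistic {spec.statistic!r}")


def stratified_bootstrap_diff(
    spec: BootstrapSpec, elements: pd.DataFrame
) -> BootstrapResult:
    """Observed category difference and its stratified-permutation p-value.

    ``elements`` needs columns 'category' and 'stratum', plus 'length'
    (mean-length-diff) or 'deleted_bp'/'inserted_bp' (bias-diff). Each
    replicate reshuffles category labels independently within every stratum,
    preserving both category sizes and stratum composition, and recomputes
    the difference. Replicates in which a category has zero inserted bp
    (undefined bias) are redrawn and counted.
    """
    cat1, cat2 = spec.categories
    df = elements[elements["category"].isin([cat1, cat2])].reset_index(drop=True)
    present = df.groupby("stratum")["category"].nunique()
    excluded = sorted(present[present < 2].index.tolist())
    if excluded:
        logger.info("excluding %d stratum/strata absent from a category", len(excluded))
        df = df[~df["stratum"].isin(excluded)].reset_index(drop=True)
    n = len(df)
    in1 = (df["category"] == cat1).values
    if in1.sum() < 1 or n - in1.sum() < 1:
        raise ValueError("each category needs at least one element")

    obs = _category_stat(spec, df, in1) - _category_stat(spec, df, ~in1)
    rng = np.random.default_rng(spec.seed)
    strata_idx = [idx.values for _, idx in df.groupby("stratum").groups.items()]
    strata_idx = [np.asarray(ix) for ix in strata_idx]
    a_per_stratum = [int(in1[ix].sum()) for ix in strata_idx]

    R = spec.replicates
    deltas = np.empty(R)
    n_redrawn = 0
    mask = np.zeros(n, dtype=bool)
    for r in range(R):
        for _ in range(100):
            mask[:] = False
            for ix, a_s in zip(strata_idx, a_per_stratum):
                chosen = rng.permutation(len(ix))[:a_s]
                mask[ix[chosen]] = True
            d = _category_stat(spec, df, mask) - _category_stat(spec, df, ~mask)
            if np.isfinite(d):
                break
            n_redrawn += 1
        deltas[r] = d

    p_two = (1 + np.sum(np.abs(deltas) >= abs(obs))) / (R + 1)
    p_one = (1 + np.sum(deltas >= obs)) / (R + 1)
    if obs < 0:
        p_one = (1 + np.sum(deltas <= obs)) / (R + 1)
    return BootstrapResult(
        observed=float(obs),
        p_two_sided=float(p_two),
        p_one_sided=float(p_one),
        replicates=R,
        n_redrawn=n_redrawn,
        excluded_strata=excluded,
    )


# ---------------------------------------------------------------------------
# per-chromosome randomization test
# ---------------------------------------------------------------------------


def _sign_matrix(v: np.ndarray) -> np.ndarray:
    return np.sign(v[:, None] - v[None, :]).astype(np.int8)


def _tau_b_denominator(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    n0 = n * (n - 1) / 2

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return float(np.sum(counts * (counts - 1) / 2))

    return float(np.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y))))


@dataclass
class RandomizationResult:
    per_chromosome: pd.DataFrame  # chromosome, tau, n_windows
    mean_tau: float
    p_value: float
    replicates: int


def chromosome_randomization_test(
    windows: pd.DataFrame,
    x_col: str,
    y_col: str,
    min_windows: int = 20,
    replicates: int = 1_000_000,
    seed: int = 0,
    batch: int = 2_000,
    alternative: str = "greater",
) -> RandomizationResult:
    """Mean within-chromosome tau with a permutation null.

    Chromosomes with fewer than ``min_windows`` complete (x, y) pairs are
    excluded. The statistic is the unweighted mean of per-chromosome tau_b;
    its null is built by permuting the y variable independently within each
    chromosome, which preserves each chromosome's x distribution, tie
    structure and window count. The add-one p-value is one-sided for the
    directional claim — 'greater' (default) tests for a positive mean
    correlation, 'less' for a negative one.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = np.random.default_rng(seed)
    per_chrom = []
    chrom_data = []
    for chrom, sub in windows.groupby("chromosome", sort=True):
        x = sub[x_col].to_numpy(dtype=float)
        y = sub[y_col].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if len(x) < min_windows:
            continue
        denom = _tau_b_denominator(x, y)
        if denom == 0:
            continue
        sx = _sign_matrix(x)
        sy = _sign_matrix(y)
        tau = float(np.sum(sx * sy)) / 2.0 / denom
        per_chrom.append({"chromosome": chrom, "tau": tau, "n_windows": len(x)})
        chrom_data.append((sx, sy, denom))
    if not per_chrom:
        raise ValueError(f"no chromosome with >= {min_windows} complete windows")

    obs = float(np.mean([c["tau"] for c in per_chrom]))
    n_chrom = len(per_chrom)
    count = 0
    done = 0
    while done < replicates:
        b = min(batch, replicates - done)
        mean_taus = np.zeros(b)
        for sx, sy, denom in chrom_data:
            n = sx.shape[0]
            perms = np.argsort(rng.random((b, n)), axis=1)
            sy_p = sy[perms[:, :, None], perms[:, None, :]]
            nums = np.einsum("ij,bij->b", sx, sy_p, dtype=np.int64) / 2.0
            mean_taus += nums / denom
        mean_taus /= n_chrom
        if alternative == "greater":
            count += int(np.sum(mean_taus >= obs))
        else:
            count += int(np.sum(mean_taus <= obs))
        done += b
    p = (1 + count) / (replicates + 1)
    return RandomizationResult(
        per_chromosome=pd.DataFrame(per_chrom),
        mean_tau=obs,
        p_value=float(p),
        replicates=replicates,
    )


# ---------------------------------------------------------------------------
# multiple testing and the indel site-frequency test
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SFSTestResult:
    proportion_rare: dict[str, float]  # per kind
    table: pd.DataFrame  # kind x {rare, common} counts
    chi_square: float
    p_value: float


def sfs_contingency_test(
    polymorphisms, context: str, maf_cut: float = 0.05
) -> SFSTestResult:
    """Compare the rare-allele fraction of segregating insertions vs deletions.

    Builds the 2x2 table kind x {MAF < maf_cut, MAF >= maf_cut} for one
    context class and applies Pearson's chi-square (1 df, no continuity
    correction). Under purifying selection the site frequency spectrum is
    shifted toward rare alleles, so a selective disadvantage of insertions
    would surface as a higher rare fraction among insertions.
    """
    recs = [p for p in polymorphisms if p.context == context]
    counts = {"insertion": [0, 0], "deletion": [0, 0]}
    for p in recs:
        counts[p.kind][0 if p.maf < maf_cut else 1] += 1
    table = pd.DataFrame(counts, index=["rare", "common"]).T
    if (table.sum(axis=1) == 0).any():
        raise ValueError(f"context {context!r} lacks one indel kind entirely")
    chi2, p_value, _, _ = sps.chi2_contingency(table.values, correction=False)
    prop = {
        kind: counts[kind][0] / sum(counts[kind]) for kind in ("insertion", "deletion")
    }
    return SFSTestResult(
        proportion_rare=prop,
        table=table,
        chi_square=float(chi2),
        p_value=float(p_value),
    )
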