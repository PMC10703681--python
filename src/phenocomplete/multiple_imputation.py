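"""Bootstrap multiple imputation, Rubin's-rule pooling and GWAS utilities.

A single imputed matrix hides the uncertainty of the imputation model itself.
Here the model is refitted m times (default 10), each time on a bootstrap
resample of the individuals and with fresh random streams (initialization,
shuffling, copy-mask draws), and each fitted model imputes the *original*
dataset. Downstream statistics computed per imputation are then pooled with
Rubin's rule: total variance = mean within-imputation variance plus
(1 + 1/m) times the between-imputation variance of the point estimates.

Also included are the small downstream utilities used when taking imputed
phenotypes into genetic association analysis: the effective sample size
N_eff = N_observed + r^2 * N_imputed, an exact two-sided sign-concordance
binomial test, distance-window locus clumping, and pooling of PLINK-style
per-imputation association tables (columns SNP, CHR, BP, BETA, SE, P).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .autoencoder import FitResult, ModelSpec, TrainConfig, fit, impute
from .phenotype_io import MaskedPhenotypeMatrix

ASSOC_COLUMNS = ("SNP", "CHR", "BP", "BETA", "SE", "P")


@dataclass
class ImputationSet:
    """m completed matrices from independent bootstrap refits.

    All matrices share the source data's shape and ID order; observed cells
    are identical across imputations (exact passthrough), only imputed cells
    vary. ``replicate_seeds`` and ``bootstrap_rows`` record how each
    replicate was produced.
    """

    source: MaskedPhenotypeMatrix
    imputations: list[np.ndarray]
    replicate_seeds: list[int]
    bootstrap_rows: list[np.ndarray]
    fit_results: list[FitResult] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.imputations)

    def between_imputation_variance(self) -> np.ndarray:
        """Cellwise variance (ddof=1) of imputed cells across replicates;
        zero at observed cells by the passthrough contract."""
        stack = np.stack(self.imputations)
        return stack.var(axis=0, ddof=1) if self.m > 1 else np.zeros_like(self.imputations[0])


def bootstrap_multiple_impute(
    data: MaskedPhenotypeMatrix,
    config: TrainConfig | None = None,
    spec: ModelSpec | None = None,
    m: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Fit m models on bootstrap-resampled individuals; impute the original data.

    Replicate r uses seed ``seed + r + 1`` for both the row resampling and the
    training streams, so weights initialize differently, minibatches shuffle
    differently and copy-mask draws differ across replicates. Any replicate
    whose training diverges invalidates the whole set (the failure is
    re-raised with the replicate index).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    config = config or TrainConfig()
    imputations: list[np.ndarray] = []
    seeds: list[int] = []
    rows_record: list[np.ndarray] = []
    fits: list[FitResult] = []
    n = data.n_samples
    for r in range(m):
        rep_seed = int(seed) + r + 1
        rng = np.random.default_rng(rep_seed)
        rows = np.sort(rng.integers(0, n, size=n))
        # bootstrap duplicates break the unique-ID invariant; rename
        boot = MaskedPhenotypeMatrix(
            ids=tuple(f"b{r}_{k}" for k in range(n)),
            values=data.values[rows].copy(),
            mask=data.mask[rows].copy(),
            schema=data.schema,
        )
        rep_config = TrainConfig(**{**config.to_dict(), "seed": rep_seed})
        try:
            result = fit(boot, rep_config, spec)
        except RuntimeError as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
        completed = impute(data, result.params, result.spec, result.stats)
        imputations.append(completed)
        seeds.append(rep_seed)
        rows_record.append(rows)
        fits.append(result)
    return ImputationSet(
        source=data,
        imputations=imputations,
        replicate_seeds=seeds,
        bootstrap_rows=rows_record,
        fit_results=fits,
    )


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rule pooled statistic.

    T = W_bar + (1 + 1/m) B; SE = sqrt(T). The p-value uses a t reference
    with df = (m - 1) (1 + W_bar / ((1 + 1/m) B))^2, falling back to the
    normal when B = 0 or m = 1.
    """

    q_bar: float
    w_bar: float
    b: float
    t: float
    se: float
    df: float
    p: float
    m: int


def rubin_pool(
    estimates: Sequence[float],
    ses: Sequence[float],
    reference: str = "t",
) -> PooledEstimate:
    """Pool m point estimates and standard errors with Rubin's rule.

    With m = 1 the inputs pass through unchanged under a normal reference.
    ``reference='normal'`` forces a normal p-value regardless of df.
    """
    q = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if q.size == 0:
        raise ValueError("no estimates to pool")
    if q.shape != s.shape:
        raise ValueError("estimates and ses must have equal length")
    if not (np.isfinite(q).all() and np.isfinite(s).all()):
        raise ValueError("non-finite estimates or standard errors")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    m = q.size
    q_bar = float(q.mean())
    w_bar = float((s**2).mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t_var = w_bar + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(t_var))
    if m == 1 or b == 0.0 or reference == "normal":
        df = float("inf")
        p = float(2.0 * sps.norm.sf(abs(q_bar) / se))
    else:
        df = (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b)) ** 2
        p = float(2.0 * sps.t.sf(abs(q_bar) / se, df))
    return PooledEstimate(q_bar=q_bar, w_bar=w_bar, b=b, t=t_var, se=se, df=df, p=p, m=m)


def read_association_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited association table with PLINK-like columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"association table {path} lacks columns {sorted(missing)}")
    if (df["SE"] <= 0).any():
        raise ValueError("standard errors must be positive")
    if (df["BP"] <= 0).any():
        raise ValueError("positions must be positive integers")
    return df


def pool_association_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Rubin-pool m per-imputation association tables variant by variant.

    All tables must cover the same variant set with consistent CHR/BP
    metadata; the pooled table carries the pooled BETA, SE and P.
    """
    if len(tables) == 0:
        raise ValueError("no tables to pool")
    base = tables[0].set_index("SNP")
    for i, tab in enumerate(tables[1:], start=1):
        t = tab.set_index("SNP")
        only_a = set(base.index) - set(t.index)
        only_b = set(t.index) - set(base.index)
        if only_a or only_b:
            missing = sorted(only_a | only_b)
            raise ValueError(f"variant set mismatch in table {i}: {missing[:10]}")
        t = t.loc[base.index]
        if not (t["CHR"].to_numpy() == base["CHR"].to_numpy()).all() or not (
            t["BP"].to_numpy() == base["BP"].to_numpy()
        ).all():
            bad = base.index[
                (t["CHR"].to_numpy() != base["CHR"].to_numpy())
                | (t["BP"].to_numpy() != base["BP"].to_numpy())
            ]
            raise ValueError(f"inconsistent position metadata for variants {list(bad[:10])}")
    rows = []
    aligned = [t.set_index("SNP").loc[base.index] for t in tables]
    for snp in base.index:
        est = [t.at[snp, "BETA"] for t in aligned]
        ses = [t.at[snp, "SE"] for t in aligned]
        pooled = rubin_pool(est, ses)
        rows.append(
            {
                "SNP": snp,
                "CHR": base.at[snp, "CHR"],
                "BP": base.at[snp, "BP"],
                "BETA": pooled.q_bar,
                "SE": pooled.se,
                "P": pooled.p,
            }
        )
    return pd.DataFrame(rows, columns=list(ASSOC_COLUMNS))


def effective_sample_size(
    n_observed: int, r2: float, n_imputed: int
) -> tuple[float, float]:
    """(N_eff, fold increase): N_eff = N_obs + r^2 N_imp.

    The fold increase is (N_eff - N_obs) / N_obs, the relative gain in
    information-equivalent sample size from imputing the missing entries at
    accuracy r^2 (measured in simulation).
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 must be in [0, 1]")
    if n_observed < 0 or n_imputed < 0:
        raise ValueError("counts must be non-negative")
    n_eff = n_observed + r2 * n_imputed
    if n_observed == 0:
        raise ValueError("fold increase undefined for n_observed = 0")
    return float(n_eff), float((n_eff - n_observed) / n_observed)


def sign_concordance_test(n_matching: int, n_total: int) -> float:
    """Exact two-sided binomial p-value for sign concordance under p = 0.5.

    Two-sidedness follows the minimum-likelihood convention (sum the
    probabilities of all outcomes no more likely than the observed count),
    which for the symmetric p = 0.5 null equals twice the one-sided tail.
    """
    if n_total < 1 or not (0 <= n_matching <= n_total):
        raise ValueError("invalid counts")
    return float(sps.binomtest(n_matching, n_total, 0.5, alternative="two-sided").pvalue)


def clump_loci(
    records: pd.DataFrame,
    threshold: float = 5e-8,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Reduce significant variants to independent loci by distance clumping.

    Per chromosome: take the most significant remaining variant with
    P < threshold as a locus, discard all significant variants within
    ``window`` bp of it (inclusive), and repeat. Ties in P break toward the
    smaller position. Returns the index variants sorted by chromosome and
    position.
    """
    needed = {"SNP", "CHR", "BP", "P"}
    if not needed.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(needed)}")
    hits = records.loc[records["P"] < threshold]
    loci = []
    for chrom, group in hits.groupby("CHR"):
        g = group.sort_values(["P", "BP"], kind="mergesort").reset_index(drop=True)
        remaining = g
        while len(remaining):
            top = remaining.iloc[0]
            loci.append(top)
            far = (remaining["BP"] - top["BP"]).abs() > window
            remaining = remaining.loc[far]
    if not loci:
        return pd.DataFrame(columns=list(records.columns))
    out = pd.DataFrame(loci)
    return out.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
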