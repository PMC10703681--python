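"""Copy-masking: propagating observed missingness patterns.

Biobank missingness is structured — whole questionnaire blocks are absent
together — so hiding cells uniformly at random misrepresents the imputation
problem. Copy-masking instead withholds observed entries by applying
missingness patterns sampled from other individuals' actual mask rows. It is
used two ways:

* as a training-time augmentation (each row receives, with probability rho,
  a pattern drawn from the mask matrix; the loss still covers every
  originally observed cell, giving the denoising objective), and
* to simulate evaluation missingness: donor patterns are applied to recipient
  rows until a target fraction of observed cells has been withheld.

A uniform-random masking baseline is included for ablations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotype_io import MaskedPhenotypeMatrix


@dataclass(frozen=True)
class CopyMaskPlan:
    """Training-time copy-mask configuration.

    rho is the probability a row receives a mask on a given pass;
    pattern_source holds the mask rows patterns are drawn from (typically the
    training split's mask, so no test patterns leak into training).
    ``mode='uniform'`` is the ablation baseline: instead of copying a pattern
    row, each cell of a selected row is hidden independently with probability
    equal to the mean missingness of the pattern source, so the expected
    corruption matches the copy-mask arm while destroying its block
    structure.
    """

    rho: float
    pattern_source: np.ndarray
    seed: int = 0
    mode: str = "copy"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.mode not in ("copy", "uniform"):
            raise ValueError("mode must be 'copy' or 'uniform'")
        src = np.asarray(self.pattern_source, dtype=bool)
        if src.ndim != 2 or src.shape[0] < 1:
            raise ValueError("pattern_source must be a non-empty 2-D mask")
        object.__setattr__(self, "pattern_source", src)

    @property
    def uniform_rate(self) -> float:
        """Per-cell hiding probability used in uniform mode."""
        return float(1.0 - self.pattern_source.mean())


@dataclass
class EvaluationMask:
    """Cells withheld for accuracy measurement, with their true values."""

    rows: np.ndarray
    cols: np.ndarray
    truth: np.ndarray
    target_fraction: float
    achieved_fraction: float

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    def apply(self, data: MaskedPhenotypeMatrix) -> MaskedPhenotypeMatrix:
        """Return a copy of ``data`` with the withheld cells set missing."""
        out = data.copy()
        out.values[self.rows, self.cols] = np.nan
        out.mask[self.rows, self.cols] = False
        return out

    def to_frame(self, data: MaskedPhenotypeMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "IID": [data.ids[i] for i in self.rows],
                "phenotype": [data.schema.names[j] for j in self.cols],
                "true_value": self.truth,
            }
        )


def apply_copy_mask(
    batch_values: np.ndarray,
    batch_mask: np.ndarray,
    plan: CopyMaskPlan,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply copy-mask augmentation to a batch.

    Each row independently receives, with probability rho, a pattern m~
    sampled uniformly from ``plan.pattern_source``; the row's effective input
    mask becomes M_i AND m~. Returns the augmented input values (cells outside
    the effective mask zero-filled) and the per-row effective input mask. The
    original observedness mask is untouched and remains the loss mask.
    """
    n = batch_mask.shape[0]
    eff_mask = batch_mask.copy()
    if plan.rho > 0:
        selected = rng.random(n) < plan.rho
        if selected.any():
            k = int(selected.sum())
            if plan.mode == "copy":
                pat_idx = rng.integers(0, plan.pattern_source.shape[0], size=k)
                eff_mask[selected] &= plan.pattern_source[pat_idx]
            else:
                keep = rng.random((k, batch_mask.shape[1])) >= plan.uniform_rate
                eff_mask[selected] &= keep
    out_values = np.where(eff_mask, batch_values, 0.0)
    return out_values, eff_mask


def simulate_missingness_copy(
    data: MaskedPhenotypeMatrix,
    target_fraction: float,
    seed: int,
    futile_limit_factor: int = 100,
) -> EvaluationMask:
    """Withhold observed cells by copying existing missingness patterns.

    Repeatedly samples a donor row and a recipient row (both uniform with
    replacement) and withholds the recipient's observed entries wherever the
    donor's pattern is missing, until the cumulative withheld count first
    reaches target_fraction x (total observed). The final donor application is
    applied in full, so the achieved fraction may overshoot by less than one
    pattern's worth; it is always reported.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must be in (0, 1)")
    mask = data.mask
    n = mask.shape[0]
    total_observed = int(mask.sum())
    if total_observed == 0:
        raise ValueError("data has no observed entries")
    target_cells = target_fraction * total_observed
    rng = np.random.default_rng(seed)
    withheld = np.zeros_like(mask)
    count = 0
    futile = 0
    futile_limit = futile_limit_factor * max(n, 1)
    while count < target_cells:
        donor = int(rng.integers(n))
        recipient = int(rng.integers(n))
        new = mask[recipient] & ~mask[donor] & ~withheld[recipient]
        k = int(new.sum())
        if k == 0:
            futile += 1
            if futile >= futile_limit:
                raise RuntimeError(
                    f"copy-mask simulation stalled after {futile} futile draws; "
                    "patterns may be fully observed"
                )
            continue
        withheld[recipient] |= new
        count += k
    rows, cols = np.nonzero(withheld)
    return EvaluationMask(
        rows=rows,
        cols=cols,
        truth=data.values[rows, cols].copy(),
        target_fraction=target_fraction,
        achieved_fraction=count / total_observed,
    )


def simulate_missingness_uniform(
    data: MaskedPhenotypeMatrix,
    target_fraction: float,
    seed: int,
) -> EvaluationMask:
    """Withhold cells drawn uniformly without replacement from observed cells."""
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must be in (0, 1)")
    obs_rows, obs_cols = np.nonzero(data.mask)
    total_observed = len(obs_rows)
    if total_observed == 0:
        raise ValueError("data has no observed entries")
    k = int(round(target_fraction * total_observed))
    rng = np.random.default_rng(seed)
    pick = rng.choice(total_observed, size=k, replace=False)
    rows, cols = obs_rows[pick], obs_cols[pick]
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    return EvaluationMask(
        rows=rows,
        cols=cols,
        truth=data.values[rows, cols].copy(),
        target_fraction=target_fraction,
        achieved_fraction=k / total_observed,
    )


def pattern_statistics(mask: np.ndarray) -> pd.DataFrame:
    """Tabulate the distinct row patterns of an observedness mask.

    Returns a frame with one row per distinct pattern (as a 0/1 string) and
    its count, sorted by decreasing count; counts sum to N.
    """
    mask = np.asarray(mask, dtype=bool)
    patterns, counts = np.unique(mask, axis=0, return_counts=True)
    rows = [
        {"pattern": "".join("1" if b else "0" for b in pat), "count": int(c)}
        for pat, c in zip(patterns, counts)
    ]
    df = pd.DataFrame(rows, columns=["pattern", "count"])
    return df.sort_values(["count", "pattern"], ascending=[False, True], ignore_index=True)


def missingness_correlation(indicator: np.ndarray) -> np.ndarray:
    """Between-column Pearson correlation of a missingness indicator matrix.

    Zero-variance columns yield zero correlation entries (diagonal set to 1).
    Used to check that copy-simulated evaluation masks preserve the original
    block structure better than uniform masks do.
    """
    ind = np.asarray(indicator, dtype=float)
    p = ind.shape[1]
    sd = ind.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ind, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    if corr.shape == ():  # P == 1 degenerate
        corr = np.ones((1, 1))
    np.fill_diagonal(corr, 1.0)
    # columns with zero variance carry no correlation information
    zero = sd == 0
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr
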