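"""Brood sex-ratio statistics and the binomial randomization test.

A brood is one egg sac's worth of offspring from a single cross; its sex
ratio (BSR) is the proportion of males.  If each offspring's sex were an
independent Bernoulli draw with a common probability, the across-brood
variance of BSR would be fully determined by brood sizes — the
brood-size-preserving randomization test asks whether the observed variance
is extra-binomial, i.e. whether broods differ in their underlying male
tendency (the signature of heritable sex tendency).

All statistics operate on a pandas DataFrame with one row per brood and
columns ``cross_id, dam, sire, block, cross_type, generation, n_male,
n_female, brood_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BroodRecord",
    "RandomizationResult",
    "broods_to_frame",
    "select_analysis_brood",
    "apply_brood_filter",
    "bsr_summary_table",
    "binomial_null_test",
    "qnorm_sd_by_group",
    "read_broods_csv",
    "write_broods_csv",
]

BROOD_COLUMNS = [
    "cross_id",
    "dam",
    "sire",
    "block",
    "cross_type",
    "generation",
    "n_male",
    "n_female",
    "brood_index",
]


@dataclass(frozen=True)
class BroodRecord:
    """Offspring sex counts of one brood (egg sac) of one cross."""

    cross_id: str
    dam: str
    sire: str
    block: int
    cross_type: str
    generation: int
    n_male: int
    n_female: int
    brood_index: int = 1

    @property
    def size(self) -> int:
        return self.n_male + self.n_female

    @property
    def bsr(self) -> float:
        return self.n_male / self.size


def broods_to_frame(broods: Sequence[BroodRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(b) for b in broods], columns=BROOD_COLUMNS)
    return df


def _as_frame(broods) -> pd.DataFrame:
    if isinstance(broods, pd.DataFrame):
        return broods
    return broods_to_frame(list(broods))


def select_analysis_brood(broods) -> pd.DataFrame:
    """Keep one brood per cross: the largest, ties broken by lowest brood_index.

    Mirrors the analysis convention of using a single brood per cross to
    avoid unequal within-cross sample sizes.
    """
    df = _as_frame(broods).copy()
    df["_n"] = df["n_male"] + df["n_female"]
    df = df.sort_values(["cross_id", "_n", "brood_index"], ascending=[True, False, True], kind="mergesort")
    out = df.groupby("cross_id", sort=False).head(1).drop(columns="_n")
    return out.reset_index(drop=True)


def apply_brood_filter(broods, min_size: int = 12) -> tuple[pd.DataFrame, int]:
    """Drop broods smaller than ``min_size`` offspring (default keeps n > 11).

    Returns the retained frame and the number of broods dropped.
    """
    df = _as_frame(broods)
    n = df["n_male"] + df["n_female"]
    keep = n >= min_size
    return df[keep].reset_index(drop=True), int((~keep).sum())


def bsr_summary_table(broods, by: Sequence[str] = ("cross_type", "block")) -> pd.DataFrame:
    """Per-group brood count, mean BSR, its standard error and sample variance.

    Variance uses the n-1 denominator and is reported as missing for groups
    with fewer than two broods.
    """
    df = _as_frame(broods).copy()
    n = df["n_male"] + df["n_female"]
    df["bsr"] = df["n_male"] / n
    rows = []
    for key, g in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        k = len(g)
        var = float(g["bsr"].var(ddof=1)) if k >= 2 else np.nan
        rows.append(
            dict(
                zip(by, key),
                n_broods=k,
                mean_bsr=float(g["bsr"].mean()),
                se_bsr=(np.sqrt(var / k) if k >= 2 else np.nan),
                var_bsr=var,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class RandomizationResult:
    """Outcome of the brood-size-preserving binomial randomization test."""

    observed_variance: float
    null_median: float
    null_ci_low: float
    null_ci_high: float
    n_sims: int
    p_value: float
    seed: Optional[int]
    pooled_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def binomial_null_test(
    broods,
    n_sims: int = 5000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> RandomizationResult:
    """Test for extra-binomial across-brood variance in proportion male.

    The pooled proportion male p-hat is computed over all input broods; each
    of ``n_sims`` replicates redraws every brood's male count as
    Binomial(n_i, p-hat) (brood sizes preserved) and records the
    across-brood sample variance of proportion male.  The p-value is the
    +1-corrected proportion of null variances at least as large as observed;
    the null interval is the 2.5/97.5 percentile band.
    """
    df = _as_frame(broods)
    if len(df) < 2:
        raise ValueError("need at least two broods")
    sizes = (df["n_male"] + df["n_female"]).to_numpy()
    if sizes.sum() == 0:
        raise ValueError("degenerate input: all broods have size 0")
    if (sizes == 0).any():
        raise ValueError("degenerate input: brood of size 0")
    males = df["n_male"].to_numpy()
    p_hat = males.sum() / sizes.sum()
    observed = float(np.var(males / sizes, ddof=1))

    if rng is None:
        rng = np.random.default_rng(seed)
    sim_males = rng.binomial(sizes[None, :], p_hat, size=(n_sims, len(sizes)))
    null_vars = np.var(sim_males / sizes[None, :], axis=1, ddof=1)
    p_value = (1.0 + np.sum(null_vars >= observed)) / (n_sims + 1.0)
    lo, med, hi = np.percentile(null_vars, [2.5, 50.0, 97.5])
    return RandomizationResult(
        observed_variance=observed,
        null_median=float(med),
        null_ci_low=float(lo),
        null_ci_high=float(hi),
        n_sims=n_sims,
        p_value=float(p_value),
        seed=seed,
        pooled_p=float(p_hat),
    )


def qnorm_sd_by_group(
    broods, by: Sequence[str] = ("generation", "cross_type")
) -> pd.DataFrame:
    """Per-group SD of probit-transformed BSR.

    Uses the continuity-corrected transform Phi^-1((n_male + 0.5)/(n + 1)) so
    broods with BSR of 0 or 1 stay finite.  Groups with fewer than two broods
    are reported as missing.
    """
    from scipy.stats import norm

    df = _as_frame(broods).copy()
    n = df["n_male"] + df["n_female"]
    df["qnorm_bsr"] = norm.ppf((df["n_male"] + 0.5) / (n + 1.0))
    rows = []
    for key, g in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(
                zip(by, key),
                n_broods=len(g),
                sd_qnorm_bsr=(float(g["qnorm_bsr"].std(ddof=1)) if len(g) >= 2 else np.nan),
            )
        )
    return pd.DataFrame(rows)


def read_broods_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BROOD_COLUMNS if c not in df.columns and c != "brood_index"]
    if missing:
        raise ValueError(f"broods CSV missing columns {missing}")
    if "brood_index" not in df.columns:
        df["brood_index"] = 1
    return df


def write_broods_csv(broods, path) -> None:
    _as_frame(broods).to_csv(path, index=False)
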