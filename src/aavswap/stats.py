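"""Swap tallies, bootstrap percentile intervals / FDR, and Fisher's exact test.

A read enters a tally only if it survived the whole parse cascade (layout,
demultiplex, separately valid barcodes, full BC-to-BC length).  Uncertainty on
the per-sample discordant fraction comes from nonparametric read-level
bootstrap (each read is a Bernoulli outcome, resampled with replacement
within its sample).  Two samples are compared with a one-sided bootstrap
false discovery rate: the fraction of resample iterations in which the
hypothesized ordering of concordant-pair fractions is violated, ties counted
at weight 1/2 so that comparing a sample against itself centers at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class SwapTally:
    """Concordant/discordant counts for one sample (and optional stratum)."""

    sample_id: str
    n_concordant: int
    n_discordant: int
    strata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_concordant < 0 or self.n_discordant < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_concordant + self.n_discordant

    @property
    def fraction_discordant(self) -> float:
        """Discordant fraction; NaN when the denominator is empty."""
        return self.n_discordant / self.n if self.n else float("nan")


@dataclass
class BootstrapComparison:
    """One-sided bootstrap comparison of two samples' concordant fractions.

    ``fdr`` uses tie weight 1/2; ``fdr_strict``/``fdr_weak`` bracket it with
    strict (ties are not violations) and weak (ties are violations) ordering,
    reported because the tie convention matters only at small n.
    """

    sample_a: str
    sample_b: str
    direction: str  # 'a_lower_concordant': a hypothesized to have more swaps
    n_resamples: int
    seed: int
    fdr: float
    fdr_strict: float
    fdr_weak: float
    interval_a: Tuple[float, float]
    interval_b: Tuple[float, float]


def tally_swaps(
    parsed: pd.DataFrame,
    sample_col: str = "library_id",
    stratifiers: Optional[Sequence[str]] = None,
) -> List[SwapTally]:
    """Tally concordant vs discordant pairs over qualifying reads.

    Qualifying reads are rows with ``qualifies`` true (full parse cascade) and
    a defined ``concordant`` flag.  Strata (e.g. full_itr_to_itr, is_dimer)
    are reported as separate tallies.  An empty qualifying set yields a tally
    with zero counts and an undefined fraction (with a warning).
    """
    df = parsed
    if "qualifies" in df.columns:
        df = df[df["qualifies"].astype(bool)]
    df = df[df["concordant"].notna()]
    group_cols = [sample_col] + list(stratifiers or [])
    tallies: List[SwapTally] = []
    if df.empty:
        import warnings

        warnings.warn("no qualifying reads; emitting empty tally")
        return [SwapTally("all", 0, 0)]
    for key, sub in df.groupby(group_cols, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        conc = sub["concordant"].astype(bool)
        tallies.append(
            SwapTally(
                sample_id=str(key[0]),
                n_concordant=int(conc.sum()),
                n_discordant=int((~conc).sum()),
                strata=dict(zip(stratifiers or [], key[1:])),
            )
        )
    return tallies


def _resample_fractions(
    tally: SwapTally, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap discordant fractions: read-level resampling with replacement
    is binomial in the two-outcome representation."""
    if tally.n < 1:
        raise ValueError("tally denominator must be >= 1")
    return rng.binomial(tally.n, tally.fraction_discordant, size=n_resamples) / tally.n


def bootstrap_interval(
    tally: SwapTally,
    n_resamples: int = 100_000,
    lo: float = 0.20,
    hi: float = 0.80,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile interval (default 20th-80th) of the resampled discordant
    fraction."""
    rng = np.random.default_rng(seed)
    frac = _resample_fractions(tally, n_resamples, rng)
    return tuple(np.quantile(frac, [lo, hi]))


def bootstrap_fdr(
    tally_a: SwapTally,
    tally_b: SwapTally,
    n_resamples: int = 100_000,
    seed: int = 0,
    lo: float = 0.20,
    hi: float = 0.80,
) -> BootstrapComparison:
    """One-sided bootstrap FDR for the hypothesis that sample *a* has the
    lower concordant-pair fraction (i.e. more swaps) than sample *b*.

    Each iteration independently resamples both samples; the FDR is the
    fraction of iterations violating the hypothesized order (a's concordant
    fraction coming out higher than b's), ties at weight 1/2.  Deterministic
    under seed.
    """
    rng = np.random.default_rng(seed)
    disc_a = _resample_fractions(tally_a, n_resamples, rng)
    disc_b = _resample_fractions(tally_b, n_resamples, rng)
    conc_a, conc_b = 1.0 - disc_a, 1.0 - disc_b
    strict = conc_a > conc_b
    ties = conc_a == conc_b
    fdr_strict = float(np.mean(strict))
    fdr_weak = float(np.mean(strict | ties))
    return BootstrapComparison(
        sample_a=tally_a.sample_id,
        sample_b=tally_b.sample_id,
        direction="a_lower_concordant",
        n_resamples=n_resamples,
        seed=seed,
        fdr=float(np.mean(strict) + 0.5 * np.mean(ties)),
        fdr_strict=fdr_strict,
        fdr_weak=fdr_weak,
        interval_a=tuple(np.quantile(disc_a, [lo, hi])),
        interval_b=tuple(np.quantile(disc_b, [lo, hi])),
    )


def exhaustive_fdr(tally_a: SwapTally, tally_b: SwapTally) -> float:
    """Exact expectation of the bootstrap FDR by enumerating all resample
    outcomes (binomial representation); tractable for small tallies and used
    as the oracle for the Monte-Carlo estimator."""
    from scipy.stats import binom

    na, nb = tally_a.n, tally_b.n
    pa = tally_a.fraction_discordant
    pb = tally_b.fraction_discordant
    ka = np.arange(na + 1)
    kb = np.arange(nb + 1)
    wa = binom.pmf(ka, na, pa)
    wb = binom.pmf(kb, nb, pb)
    conc_a = 1.0 - ka / na
    conc_b = 1.0 - kb / nb
    gt = conc_a[:, None] > conc_b[None, :]
    eq = conc_a[:, None] == conc_b[None, :]
    w = wa[:, None] * wb[None, :]
    return float((w * (gt + 0.5 * eq)).sum())


def fisher_exact_2x2(
    table: Union[Sequence[Sequence[int]], np.ndarray],
    alternative: str = "two-sided",
) -> float:
    """Fisher's exact test on a 2x2 table by hypergeometric enumeration.

    One-sided tails are exact hypergeometric tail sums; the two-sided p-value
    sums all tables (at fixed margins) whose probability does not exceed the
    observed table's.  A zero margin yields p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        import warnings

        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    if alternative == "two-sided":
        p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def tallies_to_frame(tallies: Sequence[SwapTally]) -> pd.DataFrame:
    rows = []
    for t in tallies:
        row = {
            "sample_id": t.sample_id,
            "n_concordant": t.n_concordant,
            "n_discordant": t.n_discordant,
            "fraction_discordant": t.fraction_discordant,
        }
        row.update(t.strata)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_swap_vs_length(
    tallies: Sequence[SwapTally],
    lengths: Dict[str, float],
    ax=None,
    n_resamples: int = 10_000,
    seed: int = 0,
):
    """Discordant fraction vs BC-to-BC length with 20th-80th bootstrap bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for t in tallies:
        if t.sample_id not in lengths or t.n == 0:
            continue
        x = lengths[t.sample_id]
        y = t.fraction_discordant
        lo, hi = bootstrap_interval(t, n_resamples=n_resamples, seed=seed)
        ax.errorbar(x, y, yerr=[[y - lo], [hi - y]], fmt="o", capsize=3)
        ax.annotate(t.sample_id, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("full-length BC-to-BC size (nt)")
    ax.set_ylabel("fraction discordant pairs")
    ax.set_ylim(bottom=0)
    return ax
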