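"""Reward statistics: does nectar reward track bee-perceived flower colour?

Species are dichotomized into high/low soluble-sugar classes at the
(subset-specific) median, cross-tabulated against hexagon colour sector,
and tested with a Pearson χ² whose p-value comes from Monte-Carlo
simulation under fixed margins.  Chromatic contrast is related to sugar
content with Kendall's τ-b.  The nested subsets mirror the study design:
drop the UV-sector species, then the Asteraceae (compound heads), then
the Orchidaceae (food deception), re-computing the median threshold each
time.

The canonical container is a pandas DataFrame with columns
``species, family, site, sugar_ug, x, y, hue_deg, contrast, sector``
(``reward_class`` is added by :func:`dichotomize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .vision import ColourLocus, classify_sector, hue_and_contrast

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesRecord",
    "ContingencyResult",
    "CorrelationResult",
    "records_to_frame",
    "median_mad",
    "dichotomize",
    "make_subsets",
    "contingency_table",
    "pearson_chisq",
    "monte_carlo_p",
    "kendall_tau",
    "run_reward_analysis",
]

#: Normal-consistency scale factor for the MAD (matches R's mad()).
DEFAULT_MAD_CONSTANT = 1.4826

#: Subset labels, in the order the analysis reports them.
SUBSET_ORDER = ("complete", "SS1", "SS2", "SS3", "orchids")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: identity, nectar sugar, and its colour locus."""

    species: str
    family: str
    site: str
    sugar_ug: float
    locus: ColourLocus

    def __post_init__(self) -> None:
        if self.sugar_ug < 0:
            raise ValueError(f"{self.species}: sugar must be non-negative")


def records_to_frame(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    """Flatten SpeciesRecord objects into the canonical DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "family": r.family,
                "site": r.site,
                "sugar_ug": r.sugar_ug,
                "x": r.locus.x,
                "y": r.locus.y,
                "hue_deg": r.locus.hue_deg,
                "contrast": r.locus.contrast,
                "sector": r.locus.sector,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyResult:
    """A reward-by-sector contingency test."""

    table: pd.DataFrame  # rows: high/low, columns: sectors
    chisq: float
    p_mc: float
    n_sim: int
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    """Kendall τ-b correlation with its two-sided p-value."""

    n: int
    tau: float
    p: float


def median_mad(
    values: Iterable[float], mad_constant: float = DEFAULT_MAD_CONSTANT
) -> tuple[float, float]:
    """Sample median and median absolute deviation.

    MAD = mad_constant × median(|x − median(x)|); the 1.4826 default makes
    the MAD a consistent estimator of σ under normality (R convention).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty input")
    if np.any(~np.isfinite(arr)):
        raise ValueError("non-finite values")
    med = float(np.median(arr))
    mad = float(mad_constant * np.median(np.abs(arr - med)))
    return med, mad


def dichotomize(frame: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Label each species 'high' (sugar > threshold) or 'low' (≤ threshold).

    A species exactly at the threshold — in particular the median species
    of an odd-sized subset — is classed low.  Returns a copy with a
    ``reward_class`` column.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = frame.copy()
    out["reward_class"] = np.where(out["sugar_ug"] > threshold, "high", "low")
    return out


def make_subsets(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The nested species subsets of the analysis.

    complete → SS1 (drop UV-sector species) → SS2 (drop Asteraceae)
    → SS3 (drop Orchidaceae); ``orchids`` are the Orchidaceae members of
    SS1, analysed separately.  Each subset is returned re-dichotomized at
    its own median sugar content.
    """
    known = {"Asteraceae", "Orchidaceae"}
    fams = set(frame["family"].dropna().unique())
    # Unknown family labels are expected (most families play no special
    # role); warn only on likely misspellings of the two that do.
    for f in fams:
        if f.lower() in {k.lower() for k in known} and f not in known:
            logger.warning("family label %r differs from %s in case", f, known)

    subsets: dict[str, pd.DataFrame] = {}
    subsets["complete"] = frame
    ss1 = frame[frame["sector"] != "U"]
    subsets["SS1"] = ss1
    ss2 = ss1[ss1["family"] != "Asteraceae"]
    subsets["SS2"] = ss2
    subsets["SS3"] = ss2[ss2["family"] != "Orchidaceae"]
    subsets["orchids"] = ss1[ss1["family"] == "Orchidaceae"]

    out = {}
    for name, sub in subsets.items():
        if len(sub):
            threshold, _ = median_mad(sub["sugar_ug"])
            out[name] = dichotomize(sub, threshold)
        else:
            out[name] = sub.copy()
    return out


def contingency_table(frame: pd.DataFrame) -> pd.DataFrame:
    """2×K counts of reward class (rows high/low) by colour sector.

    Sectors with no species are dropped (with a log note): after the
    standard exclusions the study's tables are 2×5.
    """
    if "reward_class" not in frame.columns:
        raise ValueError("records must be dichotomized first")
    counts = (
        frame.groupby(["reward_class", "sector"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(index=["high", "low"], fill_value=0)
    empty = [c for c in counts.columns if counts[c].sum() == 0]
    if empty:
        logger.info("dropping empty sectors from contingency table: %s", empty)
        counts = counts.drop(columns=empty)
    order = [s for s in ("B", "BG", "G", "UG", "U", "UB") if s in counts.columns]
    return counts[order]


def pearson_chisq(table: pd.DataFrame | np.ndarray) -> float:
    """Pearson χ² statistic Σ (O−E)²/E with margin-derived expectations."""
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, _, _, _ = scipy.stats.chi2_contingency(obs, correction=False)
    return float(stat)


def monte_carlo_p(
    table: pd.DataFrame | np.ndarray, n_sim: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo p-value for the Pearson χ² under fixed margins.

    Tables are drawn uniformly from all tables sharing both margins
    (Patefield's algorithm, the convention of R's
    ``chisq.test(simulate.p.value=TRUE)``), and

        p = (1 + #{χ²_sim ≥ χ²_obs}) / (n_sim + 1),

    which can never return zero.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be ≥ 1")
    obs = np.asarray(table, dtype=float)
    observed_stat = pearson_chisq(obs)
    row = obs.sum(axis=1).astype(int)
    col = obs.sum(axis=0).astype(int)
    rng = np.random.default_rng(seed)
    dist = scipy.stats.random_table(row, col)
    sims = dist.rvs(n_sim, method="patefield", random_state=rng)
    expected = np.outer(row, col) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = np.nansum((sims - expected) ** 2 / expected, axis=(1, 2))
    exceed = int(np.count_nonzero(stats >= observed_stat - 1e-12))
    return (1 + exceed) / (n_sim + 1)


def kendall_tau(xs: Iterable[float], ys: Iterable[float]) -> CorrelationResult:
    """Kendall τ-b (tie-corrected) with a two-sided p-value.

    The p-value uses the tie-adjusted normal approximation; for n ≤ 10
    without ties scipy switches to the exact null distribution.
    """
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input vector")
    res = scipy.stats.kendalltau(x, y, variant="b")
    return CorrelationResult(n=x.size, tau=float(res.statistic), p=float(res.pvalue))


@dataclass(frozen=True)
class SubsetReport:
    """Everything the analysis computes for one species subset."""

    name: str
    n: int
    threshold: float
    mad: float
    contingency: ContingencyResult | None
    correlation: CorrelationResult | None
    sector_counts: Mapping[str, int] = field(default_factory=dict)
    proportion_high: Mapping[str, float] = field(default_factory=dict)


def run_reward_analysis(
    frame: pd.DataFrame,
    n_sim: int = 100_000,
    seed: int = 0,
    mad_constant: float = DEFAULT_MAD_CONSTANT,
) -> dict[str, SubsetReport]:
    """Full reward analysis over the nested subsets.

    For every subset: the median sugar threshold (± MAD), Kendall τ of
    sugar against chromatic contrast, per-sector counts and the
    proportion of high-reward species per sector.  Contingency χ² with a
    Monte-Carlo p-value is computed for SS1, SS2 and SS3 (the three
    tables of the study design).
    """
    subsets = make_subsets(frame)
    reports: dict[str, SubsetReport] = {}
    for i, name in enumerate(SUBSET_ORDER):
        sub = subsets[name]
        if len(sub) == 0:
            reports[name] = SubsetReport(name, 0, float("nan"), float("nan"), None, None)
            continue
        threshold, mad = median_mad(sub["sugar_ug"], mad_constant)
        contingency = None
        if name in ("SS1", "SS2", "SS3") and sub["sector"].nunique() >= 2:
            table = contingency_table(sub)
            chisq = pearson_chisq(table)
            p_mc = monte_carlo_p(table, n_sim=n_sim, seed=seed + i)
            contingency = ContingencyResult(table, chisq, p_mc, n_sim, seed + i)
        correlation = None
        if len(sub) >= 2 and sub["contrast"].nunique() > 1 and sub["sugar_ug"].nunique() > 1:
            correlation = kendall_tau(sub["sugar_ug"], sub["contrast"])
        counts = sub.groupby("sector", observed=True).size()
        prop_high = (
            sub.assign(is_high=sub["reward_class"] == "high")
            .groupby("sector", observed=True)["is_high"]
            .mean()
        )
        reports[name] = SubsetReport(
            name=name,
            n=len(sub),
            threshold=threshold,
            mad=mad,
            contingency=contingency,
            correlation=correlation,
            sector_counts=counts.to_dict(),
            proportion_high=prop_high.to_dict(),
        )
    return reports
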