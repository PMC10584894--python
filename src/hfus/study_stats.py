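"""Longitudinal aggregation and the study's sample-size/power analysis.

The study design is a two-way repeated-measures ANOVA: subjects in
``n_groups`` treatment arms, each measured ``n_measurements`` times, with
compound-symmetric correlation ``rho`` among the repeats.  Power of the
between-group main effect follows the standard noncentral-F formulation:
with effect size eta-squared converted to Cohen's f² = η²/(1−η²), the
noncentrality is

    λ = f² · N · m / (1 + (m − 1) ρ)

— averaging over m correlated repeats inflates the effective sample size
by m / (1 + (m − 1) ρ) — and power is the probability that a noncentral
F(k−1, N−k, λ) variate exceeds the central-F critical value at alpha.

A direct Monte-Carlo simulator of the same model is provided as an
independent cross-check of the analytic power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ManifestError


@dataclass(frozen=True)
class StudyDesign:
    """Inputs of the repeated-measures power computation."""

    alpha: float = 0.05
    target_power: float = 0.9
    n_groups: int = 2
    n_measurements: int = 6
    rho: float = 0.53
    eta_squared: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.n_measurements < 2:
            raise ValueError("n_measurements must be >= 2")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.eta_squared < 1:
            raise ValueError("eta_squared must lie in (0, 1)")

    @property
    def cohens_f2(self) -> float:
        return self.eta_squared / (1.0 - self.eta_squared)


def rm_anova_between_power(design: StudyDesign, n_total: int) -> float:
    """Power of the between-group main effect at total sample size N."""
    if n_total <= design.n_groups:
        raise ValueError("n_total must exceed n_groups")
    m = design.n_measurements
    lam = design.cohens_f2 * n_total * m / (1.0 + (m - 1) * design.rho)
    df1 = design.n_groups - 1
    df2 = n_total - design.n_groups
    f_crit = stats.f.ppf(1.0 - design.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(design: StudyDesign, n_max: int = 10 ** 6) -> int:
    """Smallest multiple of n_groups whose between-factor power reaches
    the target."""
    n = design.n_groups * 2
    while n <= n_max:
        if rm_anova_between_power(design, n) >= design.target_power:
            return n
        n += design.n_groups
    raise RuntimeError(f"target power {design.target_power} not reached below n_total={n_max}")


def simulate_rejection_rate(
    design: StudyDesign,
    n_total: int,
    n_reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the between-group F test.

    Simulates the compound-symmetry model directly: per subject,
    y_ij = μ_g + b_i + e_ij with Var(b) = ρ and Var(e) = 1 − ρ (unit total
    variance), group means ±δ/2 calibrated so the between-group variance
    matches Cohen's f² = η²/(1−η²).  The test is the one-way ANOVA F test
    on subject means (exactly the between-factor test of the
    repeated-measures model).  Only ``n_groups = 2`` is simulated.
    """
    if design.n_groups != 2:
        raise NotImplementedError("the simulator covers the two-group design")
    if n_total % 2:
        raise ValueError("n_total must be even for two equal groups")
    rng = np.random.default_rng(seed)
    n_per = n_total // 2
    m = design.n_measurements
    delta = 2.0 * np.sqrt(design.cohens_f2)  # group means at ±delta/2, sigma_total=1

    b = rng.normal(0.0, np.sqrt(design.rho), size=(n_reps, n_total))
    e = rng.normal(0.0, np.sqrt(1.0 - design.rho), size=(n_reps, n_total, m))
    y = b[:, :, None] + e
    y[:, :n_per, :] += delta / 2.0
    y[:, n_per:, :] -= delta / 2.0

    ybar = y.mean(axis=2)                       # subject means
    g1 = ybar[:, :n_per].mean(axis=1)
    g2 = ybar[:, n_per:].mean(axis=1)
    grand = ybar.mean(axis=1)
    ss_between = n_per * ((g1 - grand) ** 2 + (g2 - grand) ** 2)
    ss_within = ((ybar[:, :n_per] - g1[:, None]) ** 2).sum(axis=1) + (
        (ybar[:, n_per:] - g2[:, None]) ** 2
    ).sum(axis=1)
    f_stat = ss_between / (ss_within / (n_total - 2))
    f_crit = stats.f.ppf(1.0 - design.alpha, 1, n_total - 2)
    return float(np.mean(f_stat > f_crit))


# ---------------------------------------------------------------------------
# longitudinal aggregation
# ---------------------------------------------------------------------------

_KEY = ["subject_id", "group", "timepoint", "location", "roi", "parameter"]


def aggregate_series(records: Sequence, statistic: str = "mean") -> pd.DataFrame:
    """Aggregate per-image records over each acquisition series.

    Several dozen frames are collected per (subject, timepoint, location)
    series; this collapses them to one value per parameter with the chosen
    statistic (mean or median), skipping missing constituent values and
    reporting how many frames contributed.

    Raises :class:`ManifestError` when a subject carries conflicting group
    labels.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    rows = []
    for rec in records:
        rows.extend(rec.to_rows())
    df = pd.DataFrame(rows)
    groups_per_subject = df.groupby("subject_id")["group"].nunique()
    bad = groups_per_subject[groups_per_subject > 1]
    if len(bad):
        raise ManifestError(f"subjects with conflicting group labels: {list(bad.index)}")
    agg = (
        df.groupby(_KEY, dropna=False)["value"]
        .agg(value=statistic, image_count="count")
        .reset_index()
    )
    return agg
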