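"""Negative-binomial exact-test differential expression.

Per comparison the workflow is: drop weakly expressed features (log2 of the
across-sample mean RPM below 1, i.e. mean RPM < 2), scale counts to a common
library size (pseudo-counts, rounded to the nearest integer), estimate a
single common NB dispersion by maximising the conditional likelihood summed
over features, and test each feature with the conditional exact test on the
two group totals.  A feature is called differentially expressed when
|log2 fold change| > 1 and raw p < 0.05 (strict inequalities); BH-adjusted
FDR is reported alongside but does not drive the calls.

The conditional exact test: with ``n_a``/``n_b`` replicates per group, a
common dispersion phi (size r = 1/phi) and equal per-sample library sizes,
the group-A total given the grand total z follows a negative
hypergeometric law

    P(Z_a = k | z) = C(k + n_a r - 1, k) C(z - k + n_b r - 1, z - k)
                     / C(z + (n_a + n_b) r - 1, z).

The two-sided p-value is the sum of the probabilities of all splits no more
likely than the observed one.  In the Poisson limit (phi = 0) this reduces
to the conditional binomial test with success probability
``n_a / (n_a + n_b)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .quantify import FeatureCountMatrix, rpm_normalize

DE_UP = "up"
DE_DOWN = "down"
DE_NOT = "not_de"

#: log-probability slack when collecting splits "no more likely than
#: observed"; absorbs last-ulp asymmetries between mirror-image splits.
_LOG_TIE_TOL = 1e-10


@dataclass(frozen=True)
class Comparison:
    """Two disjoint sample groups; the fold change is a over b."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    generation: Optional[str] = None
    lineage: Optional[str] = None

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"{self.name}: groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"{self.name}: each group needs >= 2 samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group_a + self.group_b


@dataclass(frozen=True)
class DEThresholds:
    min_log2_mean_rpm: float = 1.0
    lfc: float = 1.0
    p: float = 0.05
    prior_rpm: float = 0.5
    max_dispersion: float = 10.0


def filter_low_expression(
    rpm: pd.DataFrame, comparison: Comparison, min_log2_mean_rpm: float = 1.0
) -> pd.Index:
    """Features whose mean RPM across the comparison's samples is at least
    ``2 ** min_log2_mean_rpm`` (boundary kept)."""
    mean_rpm = rpm[list(comparison.samples)].mean(axis=1)
    return rpm.index[mean_rpm >= 2.0**min_log2_mean_rpm]


def pseudo_counts(
    counts: pd.DataFrame, library_sizes: pd.Series | Mapping[str, int]
) -> tuple[pd.DataFrame, float]:
    """Scale counts to the geometric-mean library size, rounded to integers.

    Equal effective library sizes make the conditional exact test and the
    conditional dispersion likelihood well defined.
    """
    lib = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    if (lib <= 0).any():
        bad = list(lib[lib <= 0].index)
        raise ValueError(f"zero library size for sample(s) {bad}")
    common = float(np.exp(np.log(lib).mean()))
    scaled = counts * (common / lib)
    return scaled.round().astype("int64"), common


def _group_cond_loglik(y: np.ndarray, r: float) -> float:
    """Conditional NB log-likelihood of a features x samples block, summed
    over features, given per-feature totals (mean parameter conditioned out)."""
    n = y.shape[1]
    z = y.sum(axis=1)
    keep = z > 0
    if not keep.any():
        return 0.0
    y = y[keep]
    z = z[keep]
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    counts: pd.DataFrame,
    comparison: Comparison,
    library_sizes: pd.Series | Mapping[str, int],
    max_dispersion: float = 10.0,
) -> float:
    """Common NB dispersion maximising the summed conditional likelihood.

    Counts are first scaled to equal library sizes (pseudo-counts).  The
    estimate is clamped to ``[0, max_dispersion]``; values indistinguishable
    from the Poisson boundary are returned as 0.0.
    """
    for group in (comparison.group_a, comparison.group_b):
        if len(group) < 2:
            raise ValueError("dispersion estimation needs >= 2 samples per group")
    sub = counts[list(comparison.samples)]
    lib = pd.Series(library_sizes).reindex(sub.columns)
    pseudo, _ = pseudo_counts(sub, lib)
    blocks = [
        pseudo[list(comparison.group_a)].to_numpy(),
        pseudo[list(comparison.group_b)].to_numpy(),
    ]

    def neg_ll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        return -sum(_group_cond_loglik(b, r) for b in blocks)

    lo, hi = np.log(1e-6), np.log(max_dispersion)
    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    phi = float(np.exp(res.x))
    # boundary check: if the Poisson edge is at least as good, report 0
    if phi <= 2e-6 or neg_ll(lo) <= res.fun + 1e-9:
        return 0.0
    return min(phi, max_dispersion)


def exact_test_totals(
    total_a: int, total_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided conditional exact p-value for the split of the grand total."""
    z = total_a + total_b
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi <= 0:
        logp = binom.logpmf(k, z, n_a / (n_a + n_b))
    else:
        r = 1.0 / phi
        logp = (
            gammaln(k + n_a * r)
            - gammaln(k + 1)
            + gammaln(z - k + n_b * r)
            - gammaln(z - k + 1)
        )
        logp = logp - logsumexp(logp)
    obs = logp[total_a]
    p = float(np.exp(logsumexp(logp[logp <= obs + _LOG_TIE_TOL])))
    return min(p, 1.0)


def log2_fold_change(
    rpm: pd.DataFrame, comparison: Comparison, prior_rpm: float = 0.5
) -> pd.Series:
    """log2 of prior-augmented group mean RPM, group A over group B."""
    mean_a = rpm[list(comparison.group_a)].mean(axis=1)
    mean_b = rpm[list(comparison.group_b)].mean(axis=1)
    return np.log2(mean_a + prior_rpm) - np.log2(mean_b + prior_rpm)


def call_de(
    results: pd.DataFrame, lfc: float = 1.0, p: float = 0.05
) -> pd.DataFrame:
    """Assign up / down / not_de status with strict thresholds."""
    out = results.copy()
    sig = (~out["filtered"]) & (out["p_value"] < p)
    out["de_status"] = DE_NOT
    out.loc[sig & (out["log2fc"] > lfc), "de_status"] = DE_UP
    out.loc[sig & (out["log2fc"] < -lfc), "de_status"] = DE_DOWN
    return out


def run_comparison(
    fcm: FeatureCountMatrix,
    comparison: Comparison,
    thresholds: DEThresholds = DEThresholds(),
    dispersion: Optional[float] = None,
) -> pd.DataFrame:
    """Full DE workflow for one comparison.

    Returns one row per feature: mean_rpm, log2fc, p_value, fdr,
    dispersion_used, de_status and the low-expression ``filtered`` flag.
    Filtered features keep NaN p-values and are never called DE.
    """
    samples = list(comparison.samples)
    missing = [s for s in samples if s not in fcm.counts.columns]
    if missing:
        raise ValueError(f"{comparison.name}: unknown samples {missing}")
    counts = fcm.counts[samples]
    lib = fcm.library_sizes.reindex(samples)
    rpm = rpm_normalize(counts, lib)

    retained = filter_low_expression(rpm, comparison, thresholds.min_log2_mean_rpm)
    filtered_mask = ~counts.index.isin(retained)

    if dispersion is None:
        if len(retained):
            dispersion = estimate_common_dispersion(
                counts.loc[retained], comparison, lib,
                max_dispersion=thresholds.max_dispersion,
            )
        else:
            dispersion = 0.0

    pseudo, _ = pseudo_counts(counts, lib)
    tot_a = pseudo[list(comparison.group_a)].sum(axis=1)
    tot_b = pseudo[list(comparison.group_b)].sum(axis=1)
    n_a, n_b = len(comparison.group_a), len(comparison.group_b)

    pvals = pd.Series(np.nan, index=counts.index)
    for f in retained:
        pvals[f] = exact_test_totals(
            int(tot_a[f]), int(tot_b[f]), n_a, n_b, dispersion
        )

    lfc = log2_fold_change(rpm, comparison, thresholds.prior_rpm)
    fdr = pd.Series(np.nan, index=counts.index)
    if len(retained):
        fdr[retained] = multipletests(pvals[retained].to_numpy(), method="fdr_bh")[1]

    results = pd.DataFrame(
        {
            "mean_rpm": rpm.mean(axis=1),
            "log2fc": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "dispersion_used": dispersion,
            "filtered": filtered_mask,
        }
    )
    results.index.name = "feature_id"
    return call_de(results, lfc=thresholds.lfc, p=thresholds.p)


def de_sets(results: pd.DataFrame) -> tuple[set, set]:
    """The (up, down) feature-id sets of one DE table."""
    up = set(results.index[results["de_status"] == DE_UP])
    down = set(results.index[results["de_status"] == DE_DOWN])
    return up, down
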