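"""Leave-three-out robustness of the FT4 association screen.

The screen is re-run on subsets of participants: 100 random leave-three-out
draws plus one fixed subset excluding the designated idiosyncratic responders,
giving 101 distinct subsets on a 16-subject cohort.  FDR is re-computed
within each subset; estimates and FDR-adjusted values are then averaged
across subsets, and a feature is called significant when its mean adjusted
value falls below 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .association import associate_layer

__all__ = ["SubsetPlan", "make_subsets", "robust_associate", "aggregate_subset_results"]

logger = logging.getLogger(__name__)

# enumerate all triples exactly when feasible; otherwise rejection-sample
_ENUMERATION_LIMIT = 250_000


@dataclass(frozen=True)
class SubsetPlan:
    """Ordered leave-three-out exclusions over a fixed participant set."""

    subjects: tuple
    excluded: tuple  # tuple of sorted 3-subject tuples
    is_fixed: tuple  # parallel flags; the fixed exclusion appears exactly once
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.excluded)

    def kept(self, i: int) -> tuple:
        drop = set(self.excluded[i])
        return tuple(s for s in self.subjects if s not in drop)


def make_subsets(
    subject_ids,
    n_random: int = 100,
    fixed_exclusion=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SubsetPlan:
    """Draw ``n_random`` distinct leave-three-out exclusions plus a fixed one.

    Random triples are drawn uniformly without repetition and never collide
    with the fixed exclusion, so the plan holds ``n_random + 1`` pairwise
    distinct subsets (``n_random`` when no fixed exclusion is given).
    """
    subjects = tuple(dict.fromkeys(subject_ids))
    n = len(subjects)
    if n < 5:
        raise ValueError(f"need at least 5 subjects for leave-three-out, got {n}")
    fixed = None
    if fixed_exclusion is not None:
        fixed = tuple(sorted(fixed_exclusion))
        if len(set(fixed)) != 3:
            raise ValueError("fixed_exclusion must contain exactly 3 distinct subjects")
        if not set(fixed) <= set(subjects):
            raise ValueError("fixed_exclusion must be a subset of subject_ids")
    n_total = n_random + (1 if fixed else 0)
    n_triples = math.comb(n, 3)
    if n_triples < n_total:
        raise ValueError(
            f"only {n_triples} distinct triples exist for {n} subjects; "
            f"cannot build {n_total} distinct subsets"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    if n_triples <= _ENUMERATION_LIMIT:
        pool = [t for t in combinations(subjects, 3) if t != fixed]
        picks = rng.choice(len(pool), size=n_random, replace=False) if n_random else []
        chosen = [pool[i] for i in picks]
    else:
        seen, chosen = set(), []
        while len(chosen) < n_random:
            t = tuple(sorted(rng.choice(subjects, size=3, replace=False)))
            if t == fixed or t in seen:
                continue
            seen.add(t)
            chosen.append(t)

    excluded = tuple(chosen) + ((fixed,) if fixed else ())
    is_fixed = (False,) * len(chosen) + ((True,) if fixed else ())
    logger.info("robustness plan: %d subsets (%d random%s)", len(excluded),
                len(chosen), ", 1 fixed" if fixed else "")
    return SubsetPlan(subjects=subjects, excluded=excluded, is_fixed=is_fixed, seed=seed)


def aggregate_subset_results(results: list[pd.DataFrame], min_converged_frac: float = 0.8) -> pd.DataFrame:
    """Average per-subset association tables into the robust summary.

    Each input table must carry feature_id, beta, q and converged columns (as
    produced by :func:`thyromics.association.associate_layer`).  Per feature,
    the mean and SD of beta and q are taken over the subsets in which the fit
    converged; a feature receives a significance call only when it converged
    in at least ``min_converged_frac`` of the subsets, and is significant when
    its mean q lies below 0.05.
    """
    if not results:
        raise ValueError("no subset results to aggregate")
    n_subsets = len(results)
    features = results[0]["feature_id"]
    beta = np.full((n_subsets, len(features)), np.nan)
    q = np.full((n_subsets, len(features)), np.nan)
    for i, res in enumerate(results):
        res = res.set_index("feature_id").reindex(features)
        ok = res["converged"].fillna(False).to_numpy(dtype=bool)
        beta[i, ok] = res.loc[ok, "beta"]
        q[i, ok] = res.loc[ok, "q"]

    n_conv = np.sum(~np.isnan(q), axis=0)
    with np.errstate(invalid="ignore"):
        mean_beta = np.nanmean(beta, axis=0)
        mean_q = np.nanmean(q, axis=0)
        sd_beta = _nan_sd(beta)
        sd_q = _nan_sd(q)
    called = n_conv >= min_converged_frac * n_subsets
    significant = called & (mean_q < 0.05)
    out = pd.DataFrame(
        {
            "feature_id": features.to_numpy(),
            "mean_beta": mean_beta,
            "sd_beta": sd_beta,
            "mean_q": mean_q,
            "sd_q": sd_q,
            "n_subsets_converged": n_conv.astype(int),
            "called": called,
            "significant": significant,
        },
        index=features.to_numpy(),
    )
    out.index.name = None
    return out


def _nan_sd(a: np.ndarray) -> np.ndarray:
    """Column-wise sample SD over non-missing entries (0 for a single value)."""
    n = np.sum(~np.isnan(a), axis=0)
    sd = np.zeros(a.shape[1])
    multi = n > 1
    if multi.any():
        with np.errstate(invalid="ignore"):
            sd[multi] = np.nanstd(a[:, multi], axis=0, ddof=1)
    sd[n == 0] = np.nan
    return sd


def robust_associate(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    plan: SubsetPlan,
    layer: str,
    min_converged_frac: float = 0.8,
    **assoc_kwargs,
) -> pd.DataFrame:
    """Run the association screen on every subset of ``plan`` and aggregate.

    Excluding a participant removes all of their samples; FDR is re-computed
    within each subset before q values are averaged.
    """
    results = []
    for i in range(len(plan)):
        keep = samples["subject_id"].isin(plan.kept(i))
        sub_samples = samples.loc[keep]
        sub_matrix = matrix.reindex(sub_samples.index)
        results.append(associate_layer(sub_matrix, sub_samples, layer, **assoc_kwargs))
    return aggregate_subset_results(results, min_converged_frac=min_converged_frac)
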