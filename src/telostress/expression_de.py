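"""Differential expression by detection-call filtering and two-class SAM.

Operates downstream of normalization: the input is a normalized (log-scale)
genes x samples matrix with per-cell Present/Marginal/Absent detection calls
and a sample-to-condition map. Genes called Absent in more than half of the
samples are dropped. Each stress (3 arrays) is contrasted against the common
control group (4 arrays) with the SAM moderated difference statistic

    d_i = (mean_stress_i - mean_control_i) / (s_i + s0)

where s_i is the pooled standard error of the mean difference and s0 a fudge
factor chosen to decouple the spread of d from the gene's expression-level
variance. Per-gene false discovery rates are estimated by permuting sample
labels; the working significance set is taken at q < 0.01.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionBundle",
    "SamResult",
    "StressDESets",
    "filter_absent",
    "sam_d",
    "pooled_se",
    "choose_s0",
    "sam_fdr",
    "extract_de",
    "stress_specific_sets",
]


@dataclass(frozen=True)
class ExpressionBundle:
    """Normalized expression matrix + detection calls + condition labels.

    matrix : genes x samples DataFrame, log-scale normalized expression
    calls : same-shape DataFrame of single characters in {'P', 'M', 'A'}
    groups : Series mapping sample ID -> condition label
    """

    matrix: pd.DataFrame
    calls: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.matrix.shape != self.calls.shape:
            raise ValueError("matrix and calls must share dimensions")
        if not self.matrix.index.equals(self.calls.index):
            raise ValueError("matrix and calls must share gene order")
        if not self.matrix.columns.equals(self.calls.columns):
            raise ValueError("matrix and calls must share sample order")
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        counts = self.groups.loc[self.matrix.columns].value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"each condition needs >= 2 samples; too few in {small}")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.groups.loc[self.matrix.columns]))

    def subset(self, conditions) -> "ExpressionBundle":
        """Restrict to samples of the given conditions (order preserved)."""
        keep = [s for s in self.matrix.columns if self.groups[s] in set(conditions)]
        return ExpressionBundle(
            matrix=self.matrix[keep], calls=self.calls[keep], groups=self.groups[keep]
        )


@dataclass(frozen=True)
class SamResult:
    """Output of one two-class SAM run."""

    d: pd.Series
    s0: float
    q: pd.Series
    significant: frozenset
    n_perm: int
    seed: int
    fdr_threshold: float


@dataclass(frozen=True)
class StressDESets:
    """Per-stress DE sets with per-stress-specific and direction-specific views."""

    de: dict
    specific: dict
    direction_groups: dict
    direction_specific: dict = field(default_factory=dict)


def filter_absent(bundle: ExpressionBundle) -> ExpressionBundle:
    """Drop genes with more than half of their detection calls Absent.

    A gene with exactly half 'A' calls is kept (the rule is strict '>').
    Idempotent; gene order is otherwise preserved.
    """
    n = bundle.calls.shape[1]
    n_absent = (bundle.calls == "A").sum(axis=1)
    keep = n_absent <= n / 2
    if not keep.any():
        warnings.warn("detection-call filter removed every gene", stacklevel=2)
    return ExpressionBundle(
        matrix=bundle.matrix.loc[keep],
        calls=bundle.calls.loc[keep],
        groups=bundle.groups,
    )


def _two_group_masks(groups, columns, stress=None, control=None):
    labels = pd.Series(groups).loc[list(columns)]
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    if control is None and stress is None:
        control, stress = levels
    elif control is None:
        control = next(l for l in levels if l != stress)
    elif stress is None:
        stress = next(l for l in levels if l != control)
    if {control, stress} != set(levels):
        raise ValueError(f"labels {control!r}/{stress!r} do not match conditions {levels}")
    return (labels == stress).to_numpy(), (labels == control).to_numpy(), stress, control


def pooled_se(x: np.ndarray, stress_mask: np.ndarray, control_mask: np.ndarray) -> np.ndarray:
    """Pooled standard error s_i of the per-gene group mean difference."""
    xs, xc = x[:, stress_mask], x[:, control_mask]
    n1, n2 = xs.shape[1], xc.shape[1]
    ss = ((xs - xs.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sc = ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * (ss + sc) / (n1 + n2 - 2))


def sam_d(matrix, groups, s0: float = 0.0, stress=None, control=None) -> pd.Series:
    """Per-gene SAM statistic d_i = (mean_stress - mean_control) / (s_i + s0).

    With s0 = 0 this is exactly the pooled-variance two-sample t statistic.
    `groups` labels the matrix columns with exactly two conditions; by default
    the first-seen condition is taken as control, the other as stress.
    """
    mat = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    sm, cm, _, _ = _two_group_masks(groups, mat.columns, stress, control)
    if sm.sum() < 2 or cm.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    x = mat.to_numpy(dtype=float)
    diff = x[:, sm].mean(axis=1) - x[:, cm].mean(axis=1)
    s = pooled_se(x, sm, cm)
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError(
            "zero-variance gene with s0=0: statistic undefined (set s0 > 0)"
        )
    return pd.Series(diff / denom, index=mat.index, name="d")


def choose_s0(matrix, groups, stress=None, control=None, n_bins: int = 100) -> float:
    """Select the SAM fudge factor s0.

    Scans candidate s0 over the 0,5,...,100 percentiles of {s_i} and picks the
    candidate minimizing the coefficient of variation of the median absolute
    deviation of d across s_i-quantile bins — the value that makes the spread
    of d flattest as a function of the gene's standard error.
    """
    mat = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    sm, cm, _, _ = _two_group_masks(groups, mat.columns, stress, control)
    x = mat.to_numpy(dtype=float)
    diff = x[:, sm].mean(axis=1) - x[:, cm].mean(axis=1)
    s = pooled_se(x, sm, cm)
    if np.allclose(s, s[0]):
        warnings.warn("all s_i equal; s0 set to 0", stacklevel=2)
        return 0.0

    n_bins = max(2, min(n_bins, len(s) // 5))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    candidates = np.percentile(s, np.arange(0, 101, 5))

    best_s0, best_cv = 0.0, np.inf
    for s0_cand in candidates:
        d = diff / (s + s0_cand)
        mads = np.array(
            [1.4826 * np.median(np.abs(d[b] - np.median(d[b]))) for b in bins]
        )
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0_cand)
    return best_s0


def _distinct_assignment_count(n: int, n_stress: int) -> int:
    from math import comb

    return comb(n, n_stress)


def sam_fdr(
    bundle: ExpressionBundle,
    n_perm: int = 200,
    fdr_threshold: float = 0.01,
    seed: int = 0,
    stress=None,
    control=None,
    s0: float | None = None,
    estimator: str = "median",
) -> SamResult:
    """Two-class SAM with permutation-estimated per-gene FDR.

    For each gene i, the working threshold is |d_i|; the estimated FDR is

        q_i = (median over label permutations of #{|d*| >= |d_i|})
              / #{observed |d| >= |d_i|}

    forced monotone nonincreasing in |d| and clipped to [0, 1]. When the
    number of distinct label assignments is at most `n_perm`, all are
    enumerated (with a warning); otherwise `n_perm` assignments are sampled
    uniformly with the given seed. `estimator` selects the median (SAM
    convention) or the 90th percentile ('q90') of the permuted false counts.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if estimator not in ("median", "q90"):
        raise ValueError("estimator must be 'median' or 'q90'")
    sm, cm, stress, control = _two_group_masks(
        bundle.groups, bundle.matrix.columns, stress, control
    )
    use = sm | cm
    x = bundle.matrix.to_numpy(dtype=float)[:, use]
    sm_u, cm_u = sm[use], cm[use]
    n, n_stress = int(use.sum()), int(sm_u.sum())

    if s0 is None:
        s0 = choose_s0(bundle.matrix.loc[:, bundle.matrix.columns[use]],
                       bundle.groups, stress=stress, control=control)

    def d_for(mask_stress: np.ndarray) -> np.ndarray:
        mask_control = ~mask_stress
        diff = x[:, mask_stress].mean(axis=1) - x[:, mask_control].mean(axis=1)
        s = pooled_se(x, mask_stress, mask_control)
        return diff / (s + s0)

    d_obs = d_for(sm_u)

    n_distinct = _distinct_assignment_count(n, n_stress)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label assignments exist; enumerating all "
            f"instead of sampling {n_perm}",
            stacklevel=2,
        )
        assignments = []
        for idx in itertools.combinations(range(n), n_stress):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            assignments.append(m)
    else:
        rng = np.random.default_rng(seed)
        assignments = []
        for _ in range(n_perm):
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=n_stress, replace=False)] = True
            assignments.append(m)

    perm_abs = np.sort(np.abs(np.stack([d_for(m) for m in assignments])), axis=1)

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    n_genes = len(abs_obs)

    # observed count admitted at each gene's threshold (ties admit all)
    sorted_abs = np.sort(abs_obs)
    observed = n_genes - np.searchsorted(sorted_abs, thresholds, side="left")

    # permuted exceedance counts at every threshold, per permutation
    false_counts = n_genes - np.stack(
        [np.searchsorted(row, thresholds, side="left") for row in perm_abs]
    )
    if estimator == "median":
        false_est = np.median(false_counts, axis=0)
    else:
        false_est = np.percentile(false_counts, 90, axis=0)

    q_sorted = np.clip(false_est / observed, 0.0, 1.0)
    # monotone: a gene with larger |d| never has a larger q
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]

    q = np.empty(n_genes)
    q[order] = q_sorted
    q = pd.Series(q, index=bundle.matrix.index, name="q")
    significant = frozenset(q.index[q < fdr_threshold])
    return SamResult(
        d=pd.Series(d_obs, index=bundle.matrix.index, name="d"),
        s0=float(s0),
        q=q,
        significant=significant,
        n_perm=len(assignments),
        seed=seed,
        fdr_threshold=fdr_threshold,
    )


def extract_de(
    bundle: ExpressionBundle,
    control: str = "control",
    n_perm: int = 200,
    fdr_threshold: float = 0.01,
    seed: int = 0,
) -> dict:
    """Run filter + SAM for every stress against the common control group.

    Returns {stress: SamResult}; the per-stress DE set is `result.significant`.
    """
    filtered = filter_absent(bundle)
    stresses = [c for c in filtered.conditions if c != control]
    if not stresses:
        raise ValueError(f"no stress conditions besides control {control!r}")
    out = {}
    for i, stress in enumerate(stresses):
        sub = filtered.subset([control, stress])
        out[stress] = sam_fdr(
            sub,
            n_perm=n_perm,
            fdr_threshold=fdr_threshold,
            seed=seed + i,
            stress=stress,
            control=control,
        )
    return out


def stress_specific_sets(de: dict, direction_groups: dict | None = None) -> StressDESets:
    """Form stress-specific and direction-specific gene sets.

    specific[s] = de[s] minus the union of every other stress's DE set.
    For each direction group (e.g. elongating / shortening / neutral), the
    direction-specific set holds genes DE under *every* stress of that group
    and under *no* stress outside it.
    """
    if len(de) < 2:
        raise ValueError("need >= 2 stresses to form specific sets")
    de = {s: set(g) for s, g in de.items()}
    specific = {
        s: de[s] - set().union(*(de[t] for t in de if t != s)) for s in de
    }
    direction_specific: dict = {}
    if direction_groups:
        for direction, stresses in direction_groups.items():
            unknown = [s for s in stresses if s not in de]
            if unknown:
                raise ValueError(
                    f"direction group {direction!r} names unknown stresses {unknown}"
                )
        for direction, stresses in direction_groups.items():
            if not stresses:
                direction_specific[direction] = set()
                continue
            inside = set.intersection(*(de[s] for s in stresses))
            outside = [t for t in de if t not in stresses]
            if outside:
                inside -= set().union(*(de[t] for t in outside))
            direction_specific[direction] = inside
    return StressDESets(
        de=de,
        specific=specific,
        direction_groups=dict(direction_groups or {}),
        direction_specific=direction_specific,
    )
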