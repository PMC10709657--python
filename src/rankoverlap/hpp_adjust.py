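"""Correlation-aware adjustment of the minimal overlap P-value.

The minimal coordinate P-value of a quadrant is selected among ~n^2
highly dependent coordinates, so it needs an empirical null.  Re-running
the upstream differential analysis under sample permutation is
prohibitively slow, and plain label permutation ignores inter-feature
correlation.  The hybrid prediction-permutation (HPP) scheme used here:

1. partitions the features into a *predictor* set (mutually
   unpredictable) and a *predicted* set, each predicted feature tied to
   its best significant linear predictor fitted on log-expression
   matrices;
2. draws a null replicate by permuting the predictor values and filling
   in each predicted feature from its predictor — for fold changes
   ``logFC_y = beta1 * logFC_x``, for P-value lists the correlation-
   weighted bootstrap mixture ``P_y = |r| P_x + (1 - |r|) P_hat``;
3. repeats R times (default 100), re-running the minimal-P search on
   each replicate, giving per-quadrant null samples of minimal P-values;
4. fits a beta distribution by the method of moments (Kolmogorov-Smirnov
   checked; empirical 5th percentile as fallback) and rescales the
   observed minimal P by the resulting 5% significance threshold:
   ``p_adj = 0.05 * p_min / CDF^-1(0.05)``, computed in log space.

With independent features the scheme degenerates to plain permutation of
the lists, which is also what is used when no expression matrices are
available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .minp_search import EAParams, ea_search_frame, grid_search_frame
from .overlap_engine import frame_from_down_positions
from .ranked_io import QUADRANTS, RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorAssignment",
    "BetaFit",
    "select_predictors",
    "hpp_permute",
    "null_min_logp",
    "fit_beta_mom",
    "adjust_pvalue",
    "adjust_results",
]

# Below this, a P-value sample point is clamped before the beta fit.
_P_CLAMP = 1e-300


@dataclass
class PredictorAssignment:
    """HPP partition of the feature universe.

    ``predicted_map`` maps a predicted label to ``(predictor_label,
    model)`` where ``model`` is the regression slope beta1 (fold-change
    flavour) or the correlation magnitude |r| (P-value flavour).
    Prediction chains are allowed; cycles are forbidden (broken at fit
    time).  ``topo_order`` lists predicted labels so that every
    predictor appears (in the predictor set or earlier in the order)
    before its dependants.
    """

    predictor_set: list[str]
    predicted_map: dict[str, tuple[str, float]]
    flavour: str = "fold_change"
    topo_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.predictor_set) & set(self.predicted_map)
        if overlap:
            raise ValueError(f"labels in both sets: {sorted(overlap)[:5]}")
        if not self.topo_order:
            self.topo_order = self._toposort()

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(lab: str) -> None:
            stack = [(lab, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 2
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    raise ValueError(f"prediction cycle through {node!r}")
                if state.get(node) == 2 or node not in self.predicted_map:
                    continue
                state[node] = 1
                stack.append((node, True))
                stack.append((self.predicted_map[node][0], False))

        for lab in self.predicted_map:
            if state.get(lab) != 2:
                visit(lab)
        return order


@dataclass
class BetaFit:
    """Method-of-moments beta fit of a null P-value sample."""

    alpha: float
    beta: float
    ks_p: float
    accepted: bool


def _best_predictors(
    X: np.ndarray, alpha_sig: float, chunk: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature best significant predictor by |r|.

    Returns ``(best_idx, best_r, sd)`` with ``best_idx[y] = -1`` when no
    candidate slope is significant.  Computed in row chunks so memory
    stays O(chunk * n) even for transcript-scale matrices; since the
    best predictor is simply the argmax of |r| among significant
    candidates, no candidate cap is needed for exactness.
    """
    nf, m = X.shape
    sd = X.std(axis=1, ddof=1)
    ok = sd > 0
    z = np.zeros_like(X)
    z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / (
        sd[ok, None] * np.sqrt(m - 1)
    )
    # significance cutoff on |r| from the slope t-test at alpha_sig
    t_crit = stats.t.isf(alpha_sig / 2.0, df=m - 2)
    r_crit = t_crit / np.sqrt(m - 2 + t_crit**2)
    best_idx = np.full(nf, -1, dtype=np.int64)
    best_r = np.zeros(nf)
    for lo in range(0, nf, chunk):
        hi = min(lo + chunk, nf)
        r = np.clip(z[lo:hi] @ z.T, -1.0, 1.0)
        rows = np.arange(lo, hi)
        r[rows - lo, rows] = 0.0
        r[:, ~ok] = 0.0
        r[~ok[lo:hi], :] = 0.0
        a = np.abs(r)
        idx = np.argmax(a, axis=1)
        amax = a[np.arange(hi - lo), idx]
        sig = amax > r_crit
        best_idx[rows[sig]] = idx[sig]
        best_r[rows[sig]] = r[np.arange(hi - lo), idx][sig]
    return best_idx, best_r, sd


def select_predictors(
    expr: pd.DataFrame,
    flavour: str = "fold_change",
    alpha_sig: float = 0.05,
) -> PredictorAssignment:
    """Partition features into HPP predictor and predicted sets.

    ``expr`` is a feature-by-sample log-expression matrix (>= 3
    samples).  For each feature the best predictor is the significant
    (slope t-test at ``alpha_sig``) candidate with minimal mean squared
    error — which, the candidate models being simple regressions of the
    same response, is the one with maximal |r|; the P-value flavour
    selects the best significant |r| directly.  Features with no
    significant predictor, and constant-expression features, go to the
    predictor set.  Mutual best-predictor cycles are broken by moving
    the lexicographically smallest label of the cycle to the predictor
    set.
    """
    if flavour not in ("fold_change", "pvalue"):
        raise ValueError(f"unknown flavour {flavour!r}")
    if expr.shape[1] < 3:
        raise ValueError("HPP predictor selection needs at least 3 samples")
    labels = expr.index.astype(str).to_numpy()
    X = expr.to_numpy(dtype=float)
    best_idx, best_r, sd = _best_predictors(X, alpha_sig)

    predicted_map: dict[str, tuple[str, float]] = {}
    for y in np.flatnonzero(best_idx >= 0):
        x = int(best_idx[y])
        if flavour == "fold_change":
            model = float(best_r[y] * sd[y] / sd[x])
        else:
            model = float(abs(best_r[y]))
        predicted_map[str(labels[y])] = (str(labels[x]), model)

    # Break cycles in the functional best-predictor graph.
    state: dict[str, int] = {}
    for start in sorted(predicted_map):
        path: list[str] = []
        node = start
        while node in predicted_map and state.get(node, 0) == 0:
            state[node] = 1
            path.append(node)
            node = predicted_map[node][0]
        if state.get(node, 0) == 1:
            # Found a new cycle: node .. path[-1].
            cycle = path[path.index(node):]
            drop = min(cycle)
            del predicted_map[drop]
        for lab in path:
            state[lab] = 2

    predictor_set = sorted(set(map(str, labels)) - set(predicted_map))
    return PredictorAssignment(
        predictor_set=predictor_set,
        predicted_map=predicted_map,
        flavour=flavour,
    )


def plain_assignment(labels) -> PredictorAssignment:
    """Degenerate assignment: everything in the predictor set, so an HPP
    draw is a plain permutation of the list."""
    return PredictorAssignment(
        predictor_set=sorted(map(str, labels)), predicted_map={},
        flavour="fold_change",
    )


def hpp_permute(
    assignment: PredictorAssignment,
    values: pd.Series,
    rng: np.random.Generator,
    flavour: Optional[str] = None,
) -> pd.Series:
    """One HPP null replicate of a ranked-statistic vector.

    Predictor-set values are permuted among predictor-set features; each
    predicted feature is then filled in along the prediction chains.
    ``values`` must be indexed by feature label and cover the universe.
    """
    flavour = flavour or assignment.flavour
    out = values.astype(float).copy()
    missing = (set(assignment.predictor_set) | set(assignment.predicted_map)) - set(
        map(str, values.index)
    )
    if missing:
        raise ValueError(f"values missing for labels {sorted(missing)[:5]}")
    preds = assignment.predictor_set
    out.loc[preds] = rng.permutation(out.loc[preds].to_numpy())
    if assignment.predicted_map:
        pool = values.to_numpy(dtype=float)
        draws = rng.choice(pool, size=len(assignment.topo_order), replace=True)
        for k, y in enumerate(assignment.topo_order):
            x, model = assignment.predicted_map[y]
            if flavour == "fold_change":
                out.loc[y] = model * out.loc[x]
            else:
                w = abs(model)
                out.loc[y] = w * out.loc[x] + (1.0 - w) * draws[k]
    return out


def _down_positions(values: np.ndarray) -> tuple[np.ndarray, int]:
    order = np.argsort(values, kind="stable")
    pos = np.empty(values.size, dtype=np.int64)
    pos[order] = np.arange(values.size)
    return pos, int(np.sum(values < 0.0))


def null_min_logp(
    a: RankedList,
    b: RankedList,
    assignments: tuple[Optional[PredictorAssignment], Optional[PredictorAssignment]],
    config,
    R: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-quadrant null samples of the minimal log P-value.

    Draws ``R`` independent HPP replicates of both lists (plain
    permutation when an assignment is None), re-ranks them, re-runs the
    configured minimal-P search in each requested quadrant, and collects
    the minimal log P (0 when no coordinate of the expected sign
    exists).  The same R replicates serve all quadrants.
    """
    if R < 20:
        raise ValueError("need at least 20 permutations")
    assign_a, assign_b = assignments
    labels = np.array(sorted(a.labels.tolist()), dtype=object)
    idx = pd.Index(labels.astype(str))
    vals_a = pd.Series(a.values, index=a.labels.astype(str)).loc[idx].to_numpy()
    vals_b = pd.Series(b.values, index=b.labels.astype(str)).loc[idx].to_numpy()
    quad_names = tuple(config.quadrant_names)
    out = {q: np.zeros(R) for q in quad_names}
    root = np.random.SeedSequence((seed, 0xADB))
    for rep, ss in enumerate(root.spawn(R)):
        rng = np.random.default_rng(ss)
        if assign_a is None:
            pa = rng.permutation(vals_a)
        else:
            pa = hpp_permute(assign_a, pd.Series(vals_a, index=idx), rng).to_numpy()
        if assign_b is None:
            pb = rng.permutation(vals_b)
        else:
            pb = hpp_permute(assign_b, pd.Series(vals_b, index=idx), rng).to_numpy()
        pos_a, split_a = _down_positions(pa)
        pos_b, split_b = _down_positions(pb)
        for qi, qname in enumerate(quad_names):
            q = QUADRANTS[qname]
            frame = frame_from_down_positions(
                labels, pos_a, pos_b, split_a, split_b, q
            )
            # The null statistic is the minimal P-value of the permuted
            # pair whatever its sign: permuted data carry no direction of
            # effect, and the unfiltered minimum is the sharper (hence
            # conservative) reference for the sign-consistent observed
            # minima adjusted against it.
            if config.algorithm == "grid":
                best = grid_search_frame(frame, q, step=config.step,
                                         mode=config.mode, require_sign=False)
            else:
                params = EAParams(
                    generations=config.generations,
                    population=config.population,
                    elite_fraction=config.elite_fraction,
                    mutation_scale=config.mutation_scale,
                    mutation_prob=config.mutation_prob,
                    seed=int(ss.generate_state(1)[0] % (2**31)) + qi,
                )
                best = ea_search_frame(frame, q, params=params,
                                       mode=config.mode, require_sign=False)
            out[qname][rep] = 0.0 if best is None else best.slp.log_p
    return out


def fit_beta_mom(sample: np.ndarray) -> BetaFit:
    """Method-of-moments beta fit with a Kolmogorov-Smirnov check.

    The fit is rejected (``accepted=False``) for degenerate samples
    (zero variance, non-positive shape parameters), when more than 10%
    of the sample had to be clamped away from 0, or when the KS test
    rejects at the 5% level.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 20:
        raise ValueError("need at least 20 null samples to fit")
    clamped = np.clip(sample, _P_CLAMP, 1.0 - 1e-12)
    frac_clamped = np.mean(sample < _P_CLAMP)
    m = float(clamped.mean())
    v = float(clamped.var(ddof=1))
    if v <= 0.0:
        return BetaFit(alpha=np.nan, beta=np.nan, ks_p=0.0, accepted=False)
    k = m * (1.0 - m) / v - 1.0
    alpha = m * k
    beta = (1.0 - m) * k
    if k <= 0.0 or alpha <= 0.0 or beta <= 0.0:
        return BetaFit(alpha=alpha, beta=beta, ks_p=0.0, accepted=False)
    ks_p = float(stats.kstest(clamped, "beta", args=(alpha, beta)).pvalue)
    accepted = ks_p >= 0.05 and frac_clamped <= 0.10
    return BetaFit(alpha=float(alpha), beta=float(beta), ks_p=ks_p,
                   accepted=accepted)


def significance_threshold(fit: BetaFit, sample: np.ndarray) -> float:
    """The null 5% significance threshold: beta quantile if the fit is
    accepted, the empirical 5th percentile otherwise."""
    if fit.accepted:
        return float(stats.beta.ppf(0.05, fit.alpha, fit.beta))
    return float(np.quantile(np.asarray(sample, dtype=float), 0.05))


def adjust_pvalue(
    min_p: Optional[float],
    fit: BetaFit,
    sample: np.ndarray,
    log_min_p: Optional[float] = None,
) -> tuple[float, float]:
    """Rescale a minimal P-value by the null 5% threshold.

    ``adjusted = min(1, 0.05 * min_p / t)`` computed in log space so that
    observed minima far below double-precision remain ordered.  Returns
    ``(p_adjusted, log_p_adjusted)``.  Pass either ``min_p`` or
    ``log_min_p``.
    """
    if log_min_p is None:
        if min_p is None or not (0.0 < min_p <= 1.0):
            raise ValueError("min_p must be in (0, 1]")
        log_min_p = math.log(min_p)
    t = significance_threshold(fit, sample)
    if t <= 0.0:
        logger.warning("degenerate null sample (threshold 0); adjusted P set to 1")
        return 1.0, 0.0
    log_adj = min(0.0, math.log(0.05) + log_min_p - math.log(t))
    return float(np.exp(log_adj)), float(log_adj)


def adjust_results(
    a: RankedList,
    b: RankedList,
    results: dict,
    config,
    expr_a: Optional[pd.DataFrame] = None,
    expr_b: Optional[pd.DataFrame] = None,
) -> None:
    """Attach adjusted P-values to per-quadrant results, in place."""
    flavour = getattr(config, "hpp_flavour", "fold_change")
    assign_a = assign_b = None
    if config.adjust == "hpp" and expr_a is not None:
        common = pd.Index(sorted(map(str, a.labels)))
        sub = expr_a.loc[expr_a.index.astype(str).isin(common)]
        missing = common.difference(sub.index.astype(str))
        if missing.size:
            raise ValueError(
                f"expression matrix a lacks {missing.size} list features "
                f"(e.g. {list(missing[:3])})"
            )
        assign_a = select_predictors(sub, flavour=flavour)
    if config.adjust == "hpp" and expr_b is not None:
        common = pd.Index(sorted(map(str, b.labels)))
        sub = expr_b.loc[expr_b.index.astype(str).isin(common)]
        missing = common.difference(sub.index.astype(str))
        if missing.size:
            raise ValueError(
                f"expression matrix b lacks {missing.size} list features "
                f"(e.g. {list(missing[:3])})"
            )
        assign_b = select_predictors(sub, flavour=flavour)
    null = null_min_logp(
        a, b, (assign_a, assign_b), config, R=config.permutations,
        seed=config.seed,
    )
    # The null of the *analysis-wide* minimal P-value: per replicate, the
    # minimum across the searched quadrants.  Every quadrant's observed
    # minimum is adjusted against this shared null, so "some quadrant is
    # significant" is a single family-level event (the global minimum
    # crossing the null 5% threshold) rather than four separate 5% tests.
    pooled = np.minimum.reduce([null[q] for q in null])
    sample = np.exp(np.maximum(pooled, math.log(_P_CLAMP)))
    fit = fit_beta_mom(sample)
    for qname, res in results.items():
        if res.best is None:
            res.p_adjusted, res.log_p_adjusted = 1.0, 0.0
            continue
        res.beta_fit = fit
        res.p_adjusted, res.log_p_adjusted = adjust_pvalue(
            None, fit, sample, log_min_p=res.best.slp.log_p
        )
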