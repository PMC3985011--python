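"""BIC-approximate Bayesian model averaging for linear regression.

Every subset of candidate predictors defines an ordinary-least-squares
model M_k.  With uniform model priors, the marginal likelihood of M_k is
approximated through its Bayesian information criterion,

    BIC_k = n ln(RSS_k / n) + (q_k + 1) ln(n),

with q_k the number of included predictors (the +1 counts the intercept),
and the posterior model probability is

    P(M_k | D) = exp(-(BIC_k - BIC_min)/2) / sum_j exp(-(BIC_j - BIC_min)/2).

Occam's window discards models whose posterior probability falls below a
fixed fraction of the best model's; inclusion probabilities and
model-averaged coefficients are then computed over the surviving models,
with a variable's slope counted as 0 in models that exclude it (the
"shrinkage" of averaged estimates).

For candidate sets too large to enumerate, :func:`ibma_select` applies the
iterated-BMA scheme: variables are processed in descending univariate-R^2
order through a fixed-size window; after each enumeration only the
variables whose inclusion probability exceeds a retention threshold stay
in the active set, the rest being replaced by the next-ranked candidates,
until every variable has been examined.
"""
from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import OUTCOME_INDEXES, ProcessedDataset, RegressionProblem, build_problem

logger = logging.getLogger(__name__)

#: Largest candidate set enumerate_bma will fit exhaustively (2^cap models).
ENUMERATION_CAP = 20


class CollinearityError(ValueError):
    """A predictor subset is rank deficient (exactly collinear)."""


@dataclass
class SubsetModelFit:
    """OLS fit of one predictor subset (intercept always included)."""

    mask: np.ndarray  # boolean inclusion indicator over the candidate set
    intercept: float
    coefficients: np.ndarray  # slopes of the masked-in variables, in order
    rss: float
    bic: float
    pmp: float = math.nan  # set after normalization over a model set

    @property
    def k(self) -> int:
        return int(self.mask.sum())


@dataclass
class BMAResult:
    """Model-averaged summary over a (post-Occam's-window) model set."""

    names: list[str]  # all candidate variables offered
    model_names: list[str]  # variables spanning the enumerated model space
    models: list[SubsetModelFit]
    inclusion_prob: pd.Series  # per variable, P(effect != 0 | data)
    avg_coefficient: pd.Series  # per variable, model-averaged slope
    retained: list[str]
    settings: dict = field(default_factory=dict)


def fit_subset(
    y: np.ndarray, X: np.ndarray, mask, names: Sequence[str] | None = None
) -> SubsetModelFit:
    """Least-squares fit of the masked-in predictors plus an intercept.

    The BIC uses an RSS floor of ``1e-12 * Var(y) * n`` so perfect fits
    keep a finite criterion.  Rank-deficient subsets raise
    :class:`CollinearityError` naming the variables involved.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = y.shape[0]
    k = int(mask.sum())
    if k > n - 2:
        raise ValueError(
            f"subset with {k} predictors exceeds the small-sample cap n-2={n - 2}"
        )
    A = np.empty((n, k + 1))
    A[:, 0] = 1.0
    A[:, 1:] = X[:, mask]
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < k + 1:
        involved = (
            [names[i] for i in np.flatnonzero(mask)] if names is not None
            else np.flatnonzero(mask).tolist()
        )
        raise CollinearityError(f"collinear predictor subset: {involved}")
    resid = y - A @ beta
    rss = float(resid @ resid)
    eps_rss = max(1e-12 * float(np.var(y)) * n, 1e-30)
    bic = n * math.log(max(rss, eps_rss) / n) + (k + 1) * math.log(n)
    return SubsetModelFit(
        mask=mask, intercept=float(beta[0]), coefficients=beta[1:].copy(),
        rss=rss, bic=bic,
    )


def _assign_pmp(models: list[SubsetModelFit]) -> None:
    """Posterior model probabilities from BIC differences (uniform priors)."""
    bics = np.array([m.bic for m in models])
    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    for m, p in zip(models, w):
        m.pmp = float(p)


def occam_window(models: list[SubsetModelFit], ratio: float) -> list[SubsetModelFit]:
    """Keep models whose posterior probability is within ``ratio`` of the best.

    The best model is always retained; surviving probabilities are
    renormalized.  ``ratio`` >= 1, with infinity keeping every model.
    Implemented on BIC differences (pmp_best/pmp = exp(dBIC/2)) so
    underflow cannot drop models spuriously.
    """
    if not models:
        raise ValueError("occam_window requires at least one model")
    if ratio < 1:
        raise ValueError("Occam's window ratio must be >= 1")
    bic_min = min(m.bic for m in models)
    if math.isinf(ratio):
        kept = list(models)
    else:
        cutoff = 2.0 * math.log(ratio)
        kept = [m for m in models if m.bic - bic_min <= cutoff]
    _assign_pmp(kept)
    return kept


def _summarize(
    models: list[SubsetModelFit],
    model_names: Sequence[str],
    all_names: Sequence[str],
    retention_threshold: float,
    settings: dict,
) -> BMAResult:
    inclusion = pd.Series(0.0, index=list(all_names))
    avg_coef = pd.Series(0.0, index=list(all_names))
    for m in models:
        idx = np.flatnonzero(m.mask)
        for pos, j in enumerate(idx):
            name = model_names[j]
            inclusion[name] += m.pmp
            avg_coef[name] += m.pmp * m.coefficients[pos]
    retained = [v for v in model_names if inclusion[v] > retention_threshold]
    return BMAResult(
        names=list(all_names), model_names=list(model_names), models=models,
        inclusion_prob=inclusion, avg_coefficient=avg_coef, retained=retained,
        settings=dict(settings),
    )


def enumerate_bma(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    occam_ratio: float = 20.0,
    retention_threshold: float = 0.5,
) -> BMAResult:
    """Exhaustive BMA over all 2^p predictor subsets.

    Subsets larger than n-2 predictors are outside the model space;
    exactly collinear subsets are skipped with a logged warning (their
    full-rank sub-models carry the same information).  Refuses p above
    :data:`ENUMERATION_CAP`, pointing to :func:`ibma_select`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if p > ENUMERATION_CAP:
        raise ValueError(
            f"p={p} exceeds the enumeration cap {ENUMERATION_CAP}; "
            "use ibma_select for iterated variable selection"
        )
    models: list[SubsetModelFit] = []
    n_skipped = 0
    bit = np.arange(p)
    for code in range(2 ** p):
        mask = ((code >> bit) & 1).astype(bool)
        if mask.sum() > n - 2:
            continue
        try:
            models.append(fit_subset(y, X, mask, names))
        except CollinearityError as exc:
            n_skipped += 1
            logger.warning("skipping rank-deficient subset: %s", exc)
    if n_skipped:
        logger.warning("%d collinear subset(s) skipped during enumeration", n_skipped)
    kept = occam_window(models, occam_ratio)
    settings = {"occam_ratio": occam_ratio,
                "retention_threshold": retention_threshold}
    return _summarize(kept, names, names, retention_threshold, settings)


def rank_variables(
    y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None
) -> list[str]:
    """Variables ordered by descending univariate R^2 against y.

    Ties (including zero-variance columns, which score 0) break
    lexicographically by variable name.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    r2 = np.zeros(p)
    for j in range(p):
        xc = X[:, j] - X[:, j].mean()
        ss_x = float(xc @ xc)
        if ss_x > 0 and ss_y > 0:
            r2[j] = float(xc @ yc) ** 2 / (ss_x * ss_y)
    order = sorted(range(p), key=lambda j: (-r2[j], names[j]))
    return [names[j] for j in order]


def ibma_select(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    window_size: int | None = None,
    retention_threshold: float = 0.5,
    occam_ratio: float = 20.0,
) -> BMAResult:
    """Iterated BMA variable selection over a large candidate set.

    Candidates enter a fixed-size active window in descending univariate
    goodness-of-fit order; after each exhaustive BMA call on the window,
    variables with inclusion probability above ``retention_threshold``
    survive and the rest are replaced by the next-ranked unseen
    candidates.  If every window variable survives, the weakest survivor
    is evicted (logged) so the scan can continue.  The result of the final
    BMA call - the first covering the last candidates - is returned;
    variables never reaching the final window report inclusion probability
    and averaged coefficient 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if not 0.0 < retention_threshold < 1.0:
        raise ValueError("retention_threshold must lie in (0, 1)")
    if window_size is None:
        window_size = min(8, n - 3)
        if window_size < min(8, p):
            logger.info(
                "window size capped at n-3 = %d by the small sample (n=%d)",
                window_size, n,
            )
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1 (n={n} is too small)")
    if window_size >= n - 1:
        raise ValueError(
            f"window_size {window_size} >= n-1 = {n - 1}: subset fits would "
            "exhaust the residual degrees of freedom (small-sample cap)"
        )
    window_size = min(window_size, p)
    col = {name: j for j, name in enumerate(names)}
    queue = deque(rank_variables(y, X, names))
    active: list[str] = []
    settings = {
        "occam_ratio": occam_ratio,
        "retention_threshold": retention_threshold,
        "window_size": window_size,
    }
    while True:
        while queue and len(active) < window_size:
            active.append(queue.popleft())
        # canonical (input) column order inside the window, so a single
        # window reproduces enumerate_bma bit for bit
        window = sorted(active, key=col.__getitem__)
        idx = [col[v] for v in window]
        res = enumerate_bma(
            y, X[:, idx], names=window,
            occam_ratio=occam_ratio, retention_threshold=retention_threshold,
        )
        survivors = [v for v in active if res.inclusion_prob[v] > retention_threshold]
        if not queue:
            final = _summarize(
                res.models, window, names, retention_threshold, settings
            )
            return final
        if len(survivors) == window_size:
            weakest = min(survivors, key=lambda v: (res.inclusion_prob[v], v))
            logger.debug(
                "window saturated; evicting weakest survivor %r (p=%.3f)",
                weakest, res.inclusion_prob[weakest],
            )
            survivors.remove(weakest)
        active = survivors


@dataclass
class BMASettings:
    """Knobs of the averaging/selection stage (all config-exposed)."""

    occam_ratio: float = 20.0
    window_size: int | None = None
    retention_threshold: float = 0.5


def run_all_indexes(
    dataset: ProcessedDataset,
    group_filter: str = "pooled",
    settings: BMASettings | None = None,
) -> dict[str, BMAResult]:
    """One iterated-BMA selection per outcome index, identical settings."""
    settings = settings or BMASettings()
    results: dict[str, BMAResult] = {}
    for outcome in OUTCOME_INDEXES:
        problem = build_problem(dataset, outcome=outcome, group_filter=group_filter)
        results[outcome] = ibma_select(
            problem.y, problem.X, names=problem.names,
            window_size=settings.window_size,
            retention_threshold=settings.retention_threshold,
            occam_ratio=settings.occam_ratio,
        )
    return results


def write_bma_results(results: Mapping[str, BMAResult], directory) -> None:
    """Persist bma_result_<index>.csv and models_<index>.csv per outcome."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for index, res in results.items():
        table = pd.DataFrame(
            {
                "variable": res.names,
                "inclusion_prob": res.inclusion_prob.loc[res.names].to_numpy(),
                "avg_coefficient": res.avg_coefficient.loc[res.names].to_numpy(),
                "retained": [v in res.retained for v in res.names],
            }
        )
        table.to_csv(directory / f"bma_result_{index}.csv", index=False)
        models = pd.DataFrame(
            {
                "mask": ["".join("1" if b else "0" for b in m.mask) for m in res.models],
                "bic": [m.bic for m in res.models],
                "pmp": [m.pmp for m in res.models],
            }
        )
        models.to_csv(directory / f"models_{index}.csv", index=False)


def read_bma_results(directory) -> dict[str, BMAResult]:
    """Rebuild per-index summaries (without model lists) from CSV artifacts."""
    directory = Path(directory)
    results: dict[str, BMAResult] = {}
    for index in OUTCOME_INDEXES:
        path = directory / f"bma_result_{index}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing BMA artifact {path}")
        table = pd.read_csv(path)
        names = table["variable"].astype(str).tolist()
        inclusion = pd.Series(table["inclusion_prob"].to_numpy(), index=names)
        coef = pd.Series(table["avg_coefficient"].to_numpy(), index=names)
        retained = table.loc[table["retained"], "variable"].astype(str).tolist()
        results[index] = BMAResult(
            names=names, model_names=names, models=[],
            inclusion_prob=inclusion, avg_coefficient=coef,
            retained=retained, settings={},
        )
    return results
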