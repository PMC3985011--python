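"""Replicate studies quantifying the pipeline's statistical behaviour.

These routines are the package's own validation battery: exhaustive-oracle
agreement for the averaging core, parameter recovery and null calibration
for the iterated selection, and the small-group degeneracy of per-group
runs.  They are consumed by the test suite and by scripts/acceptance.py.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .bma import enumerate_bma, ibma_select, run_all_indexes
from .congruence import SelectionTable, run_congruence
from .preprocess import OUTCOME_INDEXES, build_problem, preprocess_cohort
from .synthetic import GeneratorConfig, generate_cohort, protein_names

# ---------------------------------------------------------------------------
# independent brute-force reference for the averaging core


def bruteforce_bma_reference(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusion probabilities and averaged coefficients over all 2^p subsets.

    Deliberately written as a separate code path from the production
    enumeration: subsets come from itertools.combinations and each fit
    solves the normal equations directly.  Returns (inclusion, avg_coef)
    arrays aligned with the columns of X.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    subsets: list[tuple[int, ...]] = []
    bics: list[float] = []
    slopes: list[dict[int, float]] = []
    eps_rss = max(1e-12 * float(np.var(y)) * n, 1e-30)
    for size in range(0, p + 1):
        if size > n - 2:
            break
        for subset in itertools.combinations(range(p), size):
            A = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            resid = y - A @ beta
            rss = float(resid @ resid)
            bic = n * math.log(max(rss, eps_rss) / n) + (size + 1) * math.log(n)
            subsets.append(subset)
            bics.append(bic)
            slopes.append({j: beta[i + 1] for i, j in enumerate(subset)})
    b = np.array(bics)
    w = np.exp(-(b - b.min()) / 2.0)
    w /= w.sum()
    inclusion = np.zeros(p)
    avg_coef = np.zeros(p)
    for subset, weight, slope in zip(subsets, w, slopes):
        for j in subset:
            inclusion[j] += weight
            avg_coef[j] += weight * slope[j]
    return inclusion, avg_coef


def oracle_agreement_study(
    seed: int, n_datasets: int = 25, n: int = 30
) -> dict[str, float]:
    """Worst-case deviation of enumerate_bma / ibma_select from brute force.

    Datasets have p in 3..8 with a sparse planted signal; the Occam window
    is disabled (ratio = infinity) so both routes average the full model
    space.  ibma_select is run with window_size >= p, where it must reduce
    to exhaustive enumeration.
    """
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    max_dev_ibma = 0.0
    for i in range(n_datasets):
        p = 3 + i % 6
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[: max(1, p // 3)] = rng.choice([-1.0, 1.0], size=max(1, p // 3))
        y = X @ beta + rng.normal(scale=0.5, size=n)
        ref_incl, ref_coef = bruteforce_bma_reference(y, X)
        res = enumerate_bma(y, X, occam_ratio=math.inf)
        dev = max(
            np.abs(res.inclusion_prob.to_numpy() - ref_incl).max(),
            np.abs(res.avg_coefficient.to_numpy() - ref_coef).max(),
        )
        max_dev = max(max_dev, dev)
        res_i = ibma_select(y, X, window_size=p, occam_ratio=math.inf)
        dev_i = max(
            np.abs(res_i.inclusion_prob.to_numpy() - ref_incl).max(),
            np.abs(res_i.avg_coefficient.to_numpy() - ref_coef).max(),
        )
        max_dev_ibma = max(max_dev_ibma, dev_i)
    return {
        "enumerate_max_abs_dev": float(max_dev),
        "ibma_max_abs_dev": float(max_dev_ibma),
        "n_datasets": n_datasets,
    }


# ---------------------------------------------------------------------------
# parameter recovery and null calibration under the synthetic generator


def recovery_config(seed: int = 0) -> GeneratorConfig:
    """Boosted-n cohort for recovery studies: 40 treated cases, 50 candidates.

    14 circulatory candidates (7 analytes x 2 timepoints, TG excluded) plus
    36 secretome proteins; three planted unit effects (two positive, one
    negative) on proteins; case-level noise SD 0.3 on the log scale.
    """
    pnames = protein_names(36)
    return GeneratorConfig(
        n_cntl=6,
        n_hf=20,
        n_hhf=20,
        n_proteins=36,
        true_effect_map={pnames[0]: 1.0, pnames[1]: 1.0, pnames[2]: -1.0},
        noise_sd=0.3,
        seed=seed,
    )


def recovery_study(
    seed: int, n_reps: int = 200, outcome: str = "IT_mean"
) -> dict[str, float]:
    """Planted-effect recovery of the full generate->preprocess->iBMA chain.

    Reports the mean inclusion probability over planted and null
    variables, and the percentage of replicates in which a retained
    planted variable's averaged coefficient carries the planted sign.
    """
    base = recovery_config()
    planted = dict(base.true_effect_map)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    planted_incl: list[float] = []
    null_incl: list[float] = []
    sign_hits = 0
    sign_total = 0
    for s in seeds:
        cohort = generate_cohort(replace(base, seed=int(s)))
        dataset = preprocess_cohort(cohort)
        problem = build_problem(dataset, outcome=outcome, group_filter="pooled")
        res = ibma_select(problem.y, problem.X, names=problem.names)
        for v in problem.names:
            if v in planted:
                planted_incl.append(float(res.inclusion_prob[v]))
            else:
                null_incl.append(float(res.inclusion_prob[v]))
        for v, effect in planted.items():
            if v in res.retained:
                sign_total += 1
                if math.copysign(1.0, res.avg_coefficient[v]) == math.copysign(1.0, effect):
                    sign_hits += 1
    return {
        "planted_mean_inclusion": float(np.mean(planted_incl)),
        "null_mean_inclusion": float(np.mean(null_incl)),
        "sign_agreement_pct": 100.0 * sign_hits / max(sign_total, 1),
        "n_replicates": n_reps,
    }


def _ledger_retained_count(cohort, group_filter: str = "pooled") -> int:
    dataset = preprocess_cohort(cohort)
    results = run_all_indexes(dataset, group_filter=group_filter)
    ledger = run_congruence(results)
    return len(ledger.retained)


def null_calibration_study(seed: int, n_reps: int = 100) -> dict[str, float]:
    """False-positive behaviour of the whole pipeline under the null.

    Default-size cohorts (3 CNTL / 4 HF / 6 HHF, 40 proteins) with no
    planted effects; reports the mean number of variables the congruence
    ledger retains per replicate.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    counts = [
        _ledger_retained_count(generate_cohort(GeneratorConfig(seed=int(s))))
        for s in seeds
    ]
    return {
        "mean_retained": float(np.mean(counts)),
        "max_retained": int(np.max(counts)),
        "n_replicates": n_reps,
    }


def group_degeneracy_study(seed: int, n_reps: int = 50) -> dict[str, float]:
    """Pooled versus HF-only congruence yield on default-size null cohorts.

    The 4-case HF group caps the iBMA window at n-3 = 1 (univariate
    screening), which should depress the ledger yield below the pooled
    run's.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    pooled: list[int] = []
    hf_only: list[int] = []
    for s in seeds:
        cohort = generate_cohort(GeneratorConfig(seed=int(s)))
        pooled.append(_ledger_retained_count(cohort, "pooled"))
        hf_only.append(_ledger_retained_count(cohort, "HF"))
    return {
        "pooled_mean_retained": float(np.mean(pooled)),
        "hf_mean_retained": float(np.mean(hf_only)),
        "n_replicates": n_reps,
    }


# ---------------------------------------------------------------------------
# reference cross-index selection pattern for the congruence filter


def reference_selection_table() -> SelectionTable:
    """Synthetic reference selection pattern with a known congruence outcome.

    Encodes a pooled-run selection landscape over lipoproteins,
    inflammatory factors and artery-secreted proteins: which of the four
    histology indexes selected each variable, and averaged coefficients
    whose signs/magnitudes exercise every branch of the two-stage filter.
    Expected verdicts: OXLDL_END, HDL_END, TNFA_BAS, TNFA_END, CATA, CATD,
    BGH3 and S10AA retained positive; FABPH retained negative; IL6_BAS,
    ICAM1_BAS (IT-only) and ICAM1_END (LA-only) discarded at stage 1; G3P,
    CPNS1 and ANXA4 discarded for sign incongruence; PPCE discarded for
    negligible magnitude.
    """
    cells: dict[str, dict[str, float]] = {
        # circulatory factors
        "ICAM1_BAS": {"IT_mean": 0.21, "IT_median": 0.18},
        "IL6_BAS": {"IT_mean": 0.15, "IT_median": 0.12},
        "TNFA_BAS": {"IT_mean": 0.45, "LA_mean": 0.38},
        "TNFA_END": {"IT_median": 0.40, "LA_mean": 0.33},
        "OXLDL_END": {"IT_mean": 0.50, "LA_median": 0.42},
        "HDL_END": {"IT_median": 0.35, "LA_median": 0.30},
        "ICAM1_END": {"LA_mean": 0.25, "LA_median": 0.2},
        # artery-secreted proteins
        "CATA": {"IT_mean": 0.60, "IT_median": 0.55, "LA_mean": 0.50, "LA_median": 0.45},
        "CATD": {"IT_mean": 0.48, "LA_mean": 0.44, "LA_median": 0.40},
        "BGH3": {"IT_mean": 0.42, "LA_mean": 0.39, "LA_median": 0.36},
        "S10AA": {"IT_mean": 0.41, "IT_median": 0.37, "LA_mean": 0.34},
        "G3P": {"IT_mean": 0.30, "IT_median": 0.28, "LA_median": -0.27},
        "CPNS1": {"IT_mean": 0.20, "IT_median": -0.22, "LA_mean": 0.19},
        "ANXA4": {"IT_mean": 0.25, "LA_mean": -0.21, "LA_median": 0.18},
        "PPCE": {"IT_median": 0.0004, "LA_mean": 0.0006, "LA_median": 0.0002},
        "FABPH": {"IT_mean": -0.30, "LA_mean": -0.25},
    }
    variables = list(cells)
    selected = pd.DataFrame(False, index=variables, columns=list(OUTCOME_INDEXES))
    coefficients = pd.DataFrame(0.0, index=variables, columns=list(OUTCOME_INDEXES))
    for var, per_index in cells.items():
        for index, coef in per_index.items():
            selected.loc[var, index] = True
            coefficients.loc[var, index] = coef
    return SelectionTable(selected=selected, coefficients=coefficients)


REFERENCE_RETAINED_POSITIVE = (
    "OXLDL_END", "HDL_END", "TNFA_BAS", "TNFA_END", "CATA", "CATD", "BGH3", "S10AA",
)
REFERENCE_RETAINED_NEGATIVE = ("FABPH",)
REFERENCE_STAGE1_DISCARDS = ("ICAM1_BAS", "IL6_BAS", "ICAM1_END")
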