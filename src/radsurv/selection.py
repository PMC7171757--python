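"""Bootstrap-stabilized feature ranking with penalized Cox models.

Each bootstrap resample of the training set is ranked three times — ridge,
lasso and elastic-net penalized proportional-hazards fits, penalty strength
chosen by internal cross-validation of the held-out log partial likelihood —
and each penalty's top-k list is collected. All collected lists are pooled
and aggregated by the simple-ensemble method: a feature's consensus score
is its mean rank across lists, with features absent from a list assigned
rank ``top_k + 1``.

For the sparse penalties (lasso, elastic-net) a per-bootstrap list contains
only features with nonzero coefficients, so it may be shorter than
``top_k``; ridge lists always have ``top_k`` entries. Ties are broken
lexicographically everywhere, which makes the whole procedure
deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .errors import ConfigurationError

__all__ = [
    "PENALTIES",
    "RankedFeatureList",
    "rank_once",
    "bootstrap_select",
    "take_top",
    "outcomes_to_surv",
]

PENALTIES = ("ridge", "lasso", "elastic_net")

#: elastic-net mixing parameter (balance of L1 and L2)
ELASTIC_NET_L1_RATIO = 0.5
#: lasso expressed in the same solver: pure L1
LASSO_L1_RATIO = 1.0


def outcomes_to_surv(outcomes: pd.DataFrame, index) -> np.ndarray:
    """Align a long-format outcome table to *index* and convert to the
    structured (event, time) array survival estimators expect."""
    sub = outcomes.set_index("patient_id").loc[list(index)]
    return Surv.from_arrays(sub["event"].astype(bool).values,
                            sub["time_months"].astype(float).values)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _log_partial_likelihood(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of linear predictors *lp*."""
    order = np.argsort(time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # suffix log-sum-exp of lp: denom for an event at t = logsumexp over time >= t
    rev = lp[::-1]
    suffix = np.logaddexp.accumulate(rev)[::-1]
    idx = np.searchsorted(time, time, side="left")
    ll = lp[event.astype(bool)] - suffix[idx[event.astype(bool)]]
    return float(ll.sum())


def _order_by_coefficients(names: list[str], coefs: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Descending |coefficient|; zeros after all nonzeros; ties and the
    zero block ordered lexicographically."""
    absc = np.abs(coefs)
    is_zero = (absc == 0).astype(int)
    order = sorted(range(len(names)), key=lambda i: (is_zero[i], -absc[i], names[i]))
    return [names[i] for i in order], absc[order]


def _fit_coxnet(x: np.ndarray, y: np.ndarray, l1_ratio: float, n_alphas: int,
                cv_folds: int, rng_seed: int) -> np.ndarray:
    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01, fit_baseline_model=False)
    path.fit(x, y)
    alphas = path.alphas_
    scores = np.zeros(len(alphas))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    for tr, te in kf.split(x):
        if y[tr]["event"].sum() == 0 or y[te]["event"].sum() == 0:
            continue
        fold = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                      fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-zero path at strong penalties
            fold.fit(_standardize(x[tr]), y[tr])
        # coefficient path on the shared alpha grid (the solver may stop early)
        coefs = np.zeros((x.shape[1], len(alphas)))
        for col, a in enumerate(fold.alphas_):
            k = int(np.argmin(np.abs(alphas - a)))
            coefs[:, k] = fold.coef_[:, col]
        lp = _standardize(x[te]) @ coefs  # (n_test, n_alphas)
        for k in range(len(alphas)):
            scores[k] += _log_partial_likelihood(lp[:, k], y[te]["time"], y[te]["event"])
    best = int(np.argmax(scores))
    return path.coef_[:, best]


_RIDGE_ALPHA_GRID = np.logspace(-2, 3, 8)


def _fit_ridge(x: np.ndarray, y: np.ndarray, cv_folds: int, rng_seed: int,
               alphas: np.ndarray = _RIDGE_ALPHA_GRID) -> np.ndarray:
    scores = np.full(len(alphas), -np.inf)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    folds = [f for f in kf.split(x)
             if y[f[0]]["event"].sum() > 0 and y[f[1]]["event"].sum() > 0]
    for k, a in enumerate(alphas):
        total = 0.0
        ok = True
        for tr, te in folds:
            try:
                model = CoxPHSurvivalAnalysis(alpha=a, n_iter=100)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # baseline exp overflow at tiny alpha
                    model.fit(_standardize(x[tr]), y[tr])
            except Exception:
                ok = False
                break
            lp = _standardize(x[te]) @ model.coef_
            total += _log_partial_likelihood(lp, y[te]["time"], y[te]["event"])
        if ok:
            scores[k] = total
    best = int(np.argmax(scores))
    try:
        model = CoxPHSurvivalAnalysis(alpha=float(alphas[best]), n_iter=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, y)
    except Exception as exc:
        raise RuntimeError(
            f"ridge Cox fit failed to converge at alpha={alphas[best]:.4g}") from exc
    return model.coef_


def rank_once(table: pd.DataFrame, outcomes: pd.DataFrame, penalty: str,
              n_alphas: int = 50, cv_folds: int = 5, seed: int = 0) -> list[str]:
    """Order features by one penalized proportional-hazards fit.

    Features are ordered by decreasing |standardized coefficient|; for the
    sparse penalties, zeroed features rank below all nonzero ones (among
    themselves: lexicographic).
    """
    names, coefs = _rank_with_coefficients(table, outcomes, penalty, n_alphas,
                                           cv_folds, seed)
    return names


def _rank_with_coefficients(table: pd.DataFrame, outcomes: pd.DataFrame, penalty: str,
                            n_alphas: int, cv_folds: int, seed: int
                            ) -> tuple[list[str], np.ndarray]:
    if penalty not in PENALTIES:
        raise ConfigurationError(f"penalty must be one of {PENALTIES}, got {penalty!r}")
    x = _standardize(table.values.astype(float))
    y = outcomes_to_surv(outcomes, table.index)
    if y["event"].sum() == 0:
        raise ValueError("no events in outcome data; ranking undefined")
    if penalty == "ridge":
        coefs = _fit_ridge(x, y, cv_folds, seed)
    else:
        l1 = LASSO_L1_RATIO if penalty == "lasso" else ELASTIC_NET_L1_RATIO
        try:
            coefs = _fit_coxnet(x, y, l1, n_alphas, cv_folds, seed)
        except Exception as exc:
            raise RuntimeError(f"{penalty} Cox path fit failed: {exc}") from exc
    return _order_by_coefficients(list(table.columns), coefs)


@dataclass
class RankedFeatureList:
    """Consensus feature ordering plus per-feature diagnostics."""

    features: list[str]
    scores: dict[str, float]  # mean aggregated rank (lower = better)
    frequencies: dict[str, float]  # fraction of per-penalty lists containing the feature
    provenance: dict = field(default_factory=dict)


def bootstrap_select(table: pd.DataFrame, outcomes: pd.DataFrame,
                     n_boot: int = 100, top_k: int = 10, seed: int = 0,
                     penalties: tuple[str, ...] = PENALTIES,
                     n_alphas: int = 50, cv_folds: int = 5,
                     max_redraws: int = 50) -> RankedFeatureList:
    """Simple-ensemble rank aggregation over bootstrap resamples.

    Each of ``n_boot`` resamples (with replacement, the size of the
    training set) is ranked once per penalty; each penalty contributes its
    top-``top_k`` list (sparse penalties truncated to nonzero
    coefficients). A resample with no events is redrawn. The consensus
    score of a feature is its mean rank over all collected lists with
    absent features assigned rank ``top_k + 1``.
    """
    if n_boot < 1:
        raise ConfigurationError(f"n_boot must be >= 1, got {n_boot}")
    if not 1 <= top_k <= table.shape[1]:
        raise ConfigurationError(
            f"top_k must be in [1, {table.shape[1]}], got {top_k}")
    all_names = sorted(table.columns)
    outcome_events = outcomes.set_index("patient_id").loc[list(table.index), "event"]
    n = len(table)
    root = np.random.SeedSequence(seed)
    lists: list[list[str]] = []
    for b, child in enumerate(root.spawn(n_boot)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        redraws = 0
        while outcome_events.iloc[idx].sum() < 2:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("could not draw a bootstrap resample with events")
            warnings.warn(f"bootstrap resample {b} had <2 events; redrawn", stacklevel=2)
            idx = rng.integers(0, n, size=n)
        boot_tab = table.iloc[idx]
        boot_tab = boot_tab.set_axis([f"r{i}" for i in range(n)], axis=0)
        boot_out = outcomes.set_index("patient_id").loc[table.index[idx]].reset_index()
        boot_out["patient_id"] = boot_tab.index
        fold_seed = int(rng.integers(0, 2**31 - 1))
        for penalty in penalties:
            names, coefs = _rank_with_coefficients(
                boot_tab, boot_out, penalty, n_alphas, cv_folds, fold_seed)
            top = names[:top_k]
            if penalty != "ridge":
                nonzero = int((coefs > 0).sum())
                top = top[: min(top_k, nonzero)]
            lists.append(top)

    sentinel = float(top_k + 1)
    ranks = {name: [] for name in all_names}
    for lst in lists:
        pos = {name: i + 1.0 for i, name in enumerate(lst)}
        for name in all_names:
            ranks[name].append(pos.get(name, sentinel))
    scores = {name: float(np.mean(r)) for name, r in ranks.items()}
    freqs = {name: float(np.mean([name in lst for lst in lists])) for name in all_names}
    ordered = sorted(all_names, key=lambda nm: (scores[nm], nm))
    return RankedFeatureList(
        features=ordered, scores=scores, frequencies=freqs,
        provenance={"n_bootstraps": n_boot, "top_k": top_k,
                    "penalties": list(penalties), "seed": seed,
                    "n_lists": len(lists)},
    )


def take_top(ranked: RankedFeatureList, k: int) -> list[str]:
    """First *k* consensus features."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if k > len(ranked.features):
        raise ConfigurationError(
            f"k={k} exceeds the {len(ranked.features)} ranked features")
    return ranked.features[:k]
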