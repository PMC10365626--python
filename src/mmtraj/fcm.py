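"""Fuzzy c-means clustering with grid validation and validity indices.

Fuzzy c-means minimizes ``J = sum_i sum_c u_ic^m d^2(x_i, v_c)`` subject to
memberships summing to 1 per row, by alternating the closed-form updates
``u_ic = 1 / sum_j (d_ic / d_ij)^(2/(m-1))`` and
``v_c = sum_i u_ic^m x_i / sum_i u_ic^m``.  The fuzziness degree ``m > 1``
controls how soft the partition is; as ``m -> 1`` the algorithm approaches
k-means.

Model selection follows the protocol of validating a (k, m) grid with
repeated random initialization on a person-level subset, scoring each cell
with the partition coefficient (PC, maximize), partition entropy (PE,
minimize) and the Xie-Beni index (XB, minimize), and picking the cell with
the best mean rank; a user-fixed k can override the analytic choice, since
cluster counts in practice are also chosen on substantive grounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

_ZERO = 1e-300


@dataclass
class FuzzyModel:
    k: int
    m: float
    centroids: np.ndarray            # k x dims
    memberships: np.ndarray          # rows x k, rows sum to 1
    objective: float
    objective_trace: list[float]
    n_iter: int
    converged: bool
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k, "m": self.m, "seed": self.seed,
            "objective": self.objective, "n_iter": self.n_iter,
            "converged": self.converged,
            "centroids": self.centroids.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "FuzzyModel":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], m=d["m"], centroids=np.array(d["centroids"]),
                   memberships=np.empty((0, d["k"])), objective=d["objective"],
                   objective_trace=[], n_iter=d["n_iter"],
                   converged=d["converged"], seed=d["seed"])


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; exact ties at zero distance
    split membership equally among coincident centroids."""
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    # work on distance ratios (>= 1) so the power never overflows
    dmin = d2.min(axis=1, keepdims=True)
    ratio = d2 / np.where(dmin > 0.0, dmin, 1.0)
    with np.errstate(under="ignore", divide="ignore", invalid="ignore"):
        inv = np.power(ratio, -1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.flatnonzero(any_zero)
        u[rows] = 0.0
        z = zero[rows]
        u[rows] = z / z.sum(axis=1, keepdims=True)
    return u


def memberships_for(centroids: np.ndarray, m: float, X: np.ndarray) -> np.ndarray:
    """Memberships of arbitrary points under a fitted model's centroids."""
    return _memberships(cdist(X, centroids, "sqeuclidean"), m)


def fcm_fit(
    scores: np.ndarray,
    k: int,
    m: float,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> FuzzyModel:
    """Fit fuzzy c-means from one random initialization.

    Centroids are initialized at ``k`` distinct rows drawn at random; the
    alternating updates stop when the maximum absolute membership change
    drops below ``tol`` or after ``max_iter`` iterations.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be a 2-D array")
    if not np.isfinite(X).all():
        raise ValueError("scores contain non-finite values")
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    if m <= 1:
        raise ValueError("fuzziness degree m must be > 1")

    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    u = _memberships(cdist(X, centroids, "sqeuclidean"), m)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u**m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = cdist(X, centroids, "sqeuclidean")
        trace.append(float((um * d2).sum()))
        u_new = _memberships(d2, m)
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            converged = True
            break
    objective = float(((u**m) * cdist(X, centroids, "sqeuclidean")).sum())
    return FuzzyModel(k=k, m=m, centroids=centroids, memberships=u,
                      objective=objective, objective_trace=trace,
                      n_iter=n_iter, converged=converged, seed=seed)


def validity_indices(model: FuzzyModel, scores: np.ndarray) -> dict[str, float]:
    """Partition coefficient, partition entropy, and Xie-Beni index.

    ``PC = (1/n) sum u^2`` (1 for a crisp partition, 1/k for a uniform one),
    ``PE = -(1/n) sum u log u`` (0 crisp, log k uniform), and
    ``XB = J2 / (n * min inter-centroid d^2)`` where J2 weights squared
    distances by squared memberships.  Coincident centroids give XB = inf.
    """
    u = model.memberships
    n = u.shape[0]
    pc = float((u**2).sum() / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        logu = np.where(u > 0, np.log(u), 0.0)
    pe = float(-(u * logu).sum() / n)
    d2 = cdist(np.asarray(scores, dtype=float), model.centroids, "sqeuclidean")
    j2 = float(((u**2) * d2).sum())
    sep = cdist(model.centroids, model.centroids, "sqeuclidean")
    np.fill_diagonal(sep, np.inf)
    min_sep = sep.min()
    xb = float("inf") if min_sep <= 0 else j2 / (n * min_sep)
    return {"PC": pc, "PE": pe, "XB": xb}


def assign_patterns(
    model: FuzzyModel, scores: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hard assignment: argmax membership per row (ties -> lowest index).

    With ``scores`` given, memberships are recomputed from the centroids so
    held-out rows can be assigned; otherwise the training memberships are
    used.  Returns (pattern ids, max membership values).
    """
    u = model.memberships if scores is None else memberships_for(
        model.centroids, model.m, np.asarray(scores, dtype=float))
    labels = u.argmax(axis=1)
    return labels, u[np.arange(len(u)), labels]


@dataclass
class ValidationReport:
    results: pd.DataFrame          # k, m, rep, seed, objective, PC, PE, XB, converged
    aggregated: pd.DataFrame       # per (k, m): mean/sd of each index + mean rank
    selected_k: int
    selected_m: float
    fixed_k: int | None = None
    subset_persons: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))


def _derived_seeds(seed: int | None, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32) % (2**31)


def grid_validate(
    scores: np.ndarray,
    person_ids: np.ndarray,
    k_range: tuple[int, int] | list[int] = (2, 15),
    m_set: tuple[float, ...] = (1.1, 1.2, 1.4, 1.8),
    n_reps: int = 100,
    subset_size: int | None = None,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 300,
    fixed_k: int | None = None,
) -> ValidationReport:
    """Validate the (k, m) grid on a person-level subset.

    The subset is drawn by sampling persons (all their person-years enter);
    each grid cell is fitted ``n_reps`` times with distinct derived seeds.
    Cells are aggregated over converged runs and ranked (PC descending, PE
    and XB ascending); the selected (k, m) minimizes the mean rank, with
    ties broken toward smaller k then smaller m.  ``fixed_k`` restricts the
    selection to that k without suppressing the full grid results.
    """
    ks = (list(range(k_range[0], k_range[1] + 1))
          if isinstance(k_range, tuple) and len(k_range) == 2 else list(k_range))
    ms = list(m_set)
    if not ks or not ms:
        raise ValueError("empty (k, m) grid")
    X = np.asarray(scores, dtype=float)
    person_ids = np.asarray(person_ids)
    unique_persons = pd.unique(person_ids)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if subset_size is not None and subset_size < len(unique_persons):
        chosen = rng.choice(unique_persons, size=subset_size, replace=False)
    else:
        if subset_size is not None and subset_size > len(unique_persons):
            raise ValueError("subset_size exceeds the number of unique persons")
        chosen = unique_persons
    mask = np.isin(person_ids, chosen)
    Xs = X[mask]

    seeds = _derived_seeds(seed, len(ks) * len(ms) * n_reps)
    rows = []
    i = 0
    for k in ks:
        for m in ms:
            for rep in range(n_reps):
                s = int(seeds[i]); i += 1
                model = fcm_fit(Xs, k, m, seed=s, tol=tol, max_iter=max_iter)
                idx = validity_indices(model, Xs)
                rows.append({"k": k, "m": m, "rep": rep, "seed": s,
                             "objective": model.objective, "PC": idx["PC"],
                             "PE": idx["PE"], "XB": idx["XB"],
                             "converged": model.converged})
    results = pd.DataFrame(rows)

    done = results[results["converged"]]
    if done.empty:
        done = results
    agg = done.groupby(["k", "m"]).agg(
        objective_mean=("objective", "mean"),
        PC_mean=("PC", "mean"), PC_sd=("PC", "std"),
        PE_mean=("PE", "mean"), PE_sd=("PE", "std"),
        XB_mean=("XB", "mean"), XB_sd=("XB", "std"),
        n_converged=("converged", "size"),
    ).reset_index()
    agg["rank_PC"] = agg["PC_mean"].rank(ascending=False)
    agg["rank_PE"] = agg["PE_mean"].rank(ascending=True)
    agg["rank_XB"] = agg["XB_mean"].rank(ascending=True)
    agg["mean_rank"] = agg[["rank_PC", "rank_PE", "rank_XB"]].mean(axis=1)

    pool = agg[agg["k"] == fixed_k] if fixed_k is not None else agg
    if pool.empty:
        raise ValueError(f"fixed_k={fixed_k} not in the validated grid")
    best = pool.sort_values(["mean_rank", "k", "m"]).iloc[0]
    return ValidationReport(results=results, aggregated=agg,
                            selected_k=int(best["k"]), selected_m=float(best["m"]),
                            fixed_k=fixed_k, subset_persons=chosen)


def fit_best(
    scores: np.ndarray,
    k: int,
    m: float,
    n_reps: int = 10,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> FuzzyModel:
    """Best-of-repetitions fit: minimum objective among converged runs
    (falling back to all runs if none converged)."""
    seeds = _derived_seeds(seed, n_reps)
    models = [fcm_fit(scores, k, m, seed=int(s), tol=tol, max_iter=max_iter)
              for s in seeds]
    converged = [mo for mo in models if mo.converged]
    pool = converged if converged else models
    return min(pool, key=lambda mo: mo.objective)
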