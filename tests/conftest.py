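"""Shared fixtures: benchmark datasets, fitted pipelines, random candidate sets."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import dictreg as dr


@pytest.fixture(scope="session")
def example1():
    X, y = dr.gen_example1(n=1000, seed=11)
    return X, y


@pytest.fixture(scope="session")
def example2():
    X, y = dr.gen_example2(n=1000, seed=22)
    return X, y


@pytest.fixture(scope="session")
def example1_model(example1):
    X, y = example1
    return dr.run_parameter_selection(X, y, dr.Hyperparams(sigma=0.5))


@pytest.fixture(scope="session")
def example2_model(example2):
    X, y = example2
    return dr.run_parameter_selection(X, y, dr.Hyperparams(sigma=0.8))


def random_candidate_set(seed: int, n: int = 120):
    """A random correlated column set plus a response, for search tests.

    Columns are linear mixes of a few latent Gaussian factors plus noise, so
    the set carries moderate, varied collinearity; the response loads on a
    random sparse subset of the columns plus noise.
    """
    rng = np.random.default_rng(seed)
    m = int(rng.integers(3, 11))
    q = int(rng.integers(2, m + 1))
    latent = rng.normal(size=(n, q))
    W = rng.normal(size=(q, m))
    cols = latent @ W + 0.6 * rng.normal(size=(n, m))
    k_true = int(rng.integers(1, min(3, m) + 1))
    support = rng.choice(m, size=k_true, replace=False)
    beta = rng.normal(size=k_true) * 2.0
    y = cols[:, support] @ beta + rng.normal(size=n)
    names = [f"c{j + 1}" for j in range(m)]
    return names, cols, y


def brute_force_best_subset(names, matrix, y, vif_limit=10.0, k_max=8):
    """Naive exhaustive subset search: an independent oracle.

    Re-fits every subset with a raw lstsq on the design matrix, computes VIFs
    by regressing each standardized column on the others, and applies the
    same tie convention as the package (adjusted-R² band, then parsimony,
    then names).  Deliberately shares no code with the implementation.
    """
    matrix = np.asarray(matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = matrix.shape
    tss = float(((y - y.mean()) ** 2).sum())
    best = None  # (r2_adj, k, names_tuple, idx)
    for k in range(1, min(k_max, m, n - 2) + 1):
        for idx in itertools.combinations(range(m), k):
            cols = matrix[:, idx]
            A = np.column_stack([np.ones(n), cols])
            if np.linalg.matrix_rank(A) < k + 1:
                continue
            if k >= 2:
                S = (cols - cols.mean(axis=0)) / cols.std(axis=0)
                max_vif = 0.0
                for j in range(k):
                    others = np.delete(S, j, axis=1)
                    beta, *_ = np.linalg.lstsq(others, S[:, j], rcond=None)
                    resid = S[:, j] - others @ beta
                    frac = float(resid @ resid) / n
                    max_vif = max(max_vif, np.inf if frac < 1e-12 else 1.0 / frac)
                if max_vif > vif_limit:
                    continue
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(((y - A @ beta) ** 2).sum())
            r2 = min(max(1.0 - rss / tss, 0.0), 1.0)
            r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
            cand = (r2_adj, k, tuple(names[i] for i in idx), idx)
            if best is None or _oracle_better(cand, best):
                best = cand
    return best


def _oracle_better(cand, best, tol=dr.core.R2_TIE_TOL):
    if cand[0] > best[0] + tol:
        return True
    if cand[0] < best[0] - tol:
        return False
    if cand[1] != best[1]:
        return cand[1] < best[1]
    return cand[2] < best[2]
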