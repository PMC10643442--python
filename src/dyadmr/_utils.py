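"""Shared numerical helpers: seeded substreams and design-matrix assembly."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream derived from a master seed and a label.

    The label is hashed so adding a new consumer never perturbs the draws
    of existing ones.
    """
    digest = hashlib.blake2s(f"{name}".encode(), digest_size=4).digest()
    salt = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, salt]))


def as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def design_matrix(covariates, n: int, add_intercept: bool = True):
    """Assemble a numeric design matrix from None / array / DataFrame.

    Categorical and object DataFrame columns are one-hot encoded dropping
    the first level. Returns (matrix, column_names).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(n))
        names.append("const")
    if covariates is None:
        pass
    elif isinstance(covariates, pd.DataFrame):
        for c in covariates.columns:
            s = covariates[c]
            if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(s, prefix=str(c), drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
                    names.append(str(dc))
            else:
                cols.append(s.to_numpy(dtype=float))
                names.append(str(c))
    else:
        arr = as_2d(covariates)
        if arr.shape[0] != n:
            raise ValueError(f"covariates have {arr.shape[0]} rows, expected {n}")
        for j in range(arr.shape[1]):
            cols.append(arr[:, j])
            names.append(f"x{j}")
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming (approximately) collinear columns if X is rank deficient."""
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns by incremental QR
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            sub = X[:, kept + [j]]
            if np.linalg.matrix_rank(sub) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta
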