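"""Multiblock data model: paired blocks, connection design, constraints.

A *block* is one omics modality measured on a common set of samples
(n samples x p_j features).  All blocks of a dataset share the same
samples in the same order; the model weights live on block features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "ConnectionDesign",
    "SparsityConstraint",
    "GraphPenaltyConfig",
    "preprocess_block",
    "pair_covariance",
    "read_block",
    "check_paired",
]


@dataclass
class Block:
    """One named data matrix (samples x features) with labels.

    Parameters
    ----------
    name : str
        Block label (e.g. ``"mrna"``).
    matrix : ndarray, shape (n, p)
        Numeric data, one row per sample.
    feature_names : list of str
        Column labels, unique within the block.
    sample_ids : list of str
        Row labels, shared (same order) across all blocks of a dataset.
    """

    name: str
    matrix: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    # preprocessing state recorded by preprocess_block, reused at transform time
    center_: np.ndarray | None = field(default=None, repr=False)
    scale_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"block {self.name!r}: matrix must be 2-D")
        n, p = self.matrix.shape
        if n < 2:
            raise ValueError(f"block {self.name!r}: needs at least 2 samples, got {n}")
        if p < 1:
            raise ValueError(f"block {self.name!r}: needs at least 1 feature")
        if len(self.feature_names) != p:
            raise ValueError(
                f"block {self.name!r}: {len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError(f"block {self.name!r}: duplicate feature names")
        if len(self.sample_ids) != n:
            raise ValueError(
                f"block {self.name!r}: {len(self.sample_ids)} sample ids for {n} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_samples(self, indices: np.ndarray) -> "Block":
        """Row-subset of the block (used by the bootstrap harness)."""
        idx = np.asarray(indices)
        return Block(
            name=self.name,
            matrix=self.matrix[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class ConnectionDesign:
    """J x J symmetric 0/1 matrix c: c[j, k] = 1 links blocks j and k."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        J = self.c.shape[0]
        if self.c.shape != (J, J):
            raise ValueError("connection design must be square")
        if not np.array_equal(self.c, self.c.T):
            raise ValueError("connection design must be symmetric")
        if np.any(np.diag(self.c) != 0):
            raise ValueError("connection design must have zero diagonal")
        if not np.all(np.isin(self.c, (0.0, 1.0))):
            raise ValueError("connection design entries must be 0 or 1")
        if self.c.sum() == 0:
            raise ValueError("connection design links no blocks")

    @classmethod
    def complete(cls, n_blocks: int) -> "ConnectionDesign":
        """All blocks connected to all others (c_jk = 1 for j != k)."""
        c = np.ones((n_blocks, n_blocks)) - np.eye(n_blocks)
        return cls(c)


@dataclass
class SparsityConstraint:
    """Per-block l1 radii s_j; feasibility with the unit l2 ball
    requires 1 <= s_j <= sqrt(p_j)."""

    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s < 1):
            raise ValueError("sparsity radii s_j must be >= 1")

    def validate_against(self, blocks: list[Block]) -> None:
        if len(self.s) != len(blocks):
            raise ValueError(
                f"{len(self.s)} sparsity values for {len(blocks)} blocks"
            )
        for sj, b in zip(self.s, blocks):
            bound = np.sqrt(b.n_features)
            if sj > bound + 1e-12:
                # With ||w||2 <= 1 active, ||w||1 <= sqrt(p); larger radii are
                # inert and most likely a configuration mistake.
                raise ValueError(
                    f"block {b.name!r}: s={sj} exceeds sqrt(p)={bound:.4g}; "
                    "values in [1, sqrt(p)] are required"
                )


@dataclass
class GraphPenaltyConfig:
    """GraphNet penalty configuration: which block, gamma, Laplacian variant."""

    target_block: str
    gamma: float
    laplacian_variant: str = "raw"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.laplacian_variant not in ("raw", "normalized"):
            raise ValueError("laplacian_variant must be 'raw' or 'normalized'")


def preprocess_block(block: Block, center: bool = True, scale: bool = True) -> Block:
    """Column-centre (and optionally unit-variance scale) a block.

    Constant columns are centred to zero and left unscaled, with a warning.
    The centring/scaling vectors are stored on the returned block so the
    identical transformation can be replayed on new data.
    """
    X = block.matrix
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X))
        i, j = bad[0]
        raise ValueError(
            f"block {block.name!r}: non-finite value in column "
            f"{block.feature_names[j]!r} (row {block.sample_ids[i]!r})"
        )
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    sd = np.ones(X.shape[1])
    if scale:
        col_sd = Xc.std(axis=0, ddof=0)
        constant = col_sd <= 1e-15
        if np.any(constant):
            names = [block.feature_names[j] for j in np.flatnonzero(constant)[:5]]
            msg = (
                f"block {block.name!r}: {int(constant.sum())} constant column(s) "
                f"(e.g. {names}) centred but not scaled"
            )
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
        sd = np.where(constant, 1.0, col_sd)
        Xc = Xc / sd
    out = Block(
        name=block.name,
        matrix=Xc,
        feature_names=list(block.feature_names),
        sample_ids=list(block.sample_ids),
    )
    out.center_ = mean
    out.scale_ = sd
    return out


def pair_covariance(
    block_j: Block, w_j: np.ndarray, block_k: Block, w_k: np.ndarray
) -> float:
    """cov(X_j w_j, X_k w_k) = (1/n) (X_j w_j)^T (X_k w_k) on centred blocks.

    The 1/n denominator (not 1/(n-1)) is a fixed convention; it only scales
    the objective globally.
    """
    if block_j.n_samples != block_k.n_samples:
        raise ValueError(
            f"sample-count mismatch: {block_j.name!r} has {block_j.n_samples}, "
            f"{block_k.name!r} has {block_k.n_samples}"
        )
    n = block_j.n_samples
    tj = block_j.matrix @ np.asarray(w_j, dtype=float)
    tk = block_k.matrix @ np.asarray(w_k, dtype=float)
    return float(tj @ tk) / n


def check_paired(blocks: list[Block]) -> None:
    """All blocks must share identical sample ids in identical order."""
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValueError(
                f"block {b.name!r} sample ids differ from block {blocks[0].name!r}"
            )


def read_block(path, name: str | None = None, delimiter: str | None = None) -> Block:
    """Read a block from TSV/CSV: first column sample id, header = features.

    The delimiter is sniffed from the header line (tab wins over comma)
    unless given explicitly.
    """
    path = str(path)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns found")
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entries: {exc}") from exc
    if np.isnan(mat).any():
        col = df.columns[int(np.argwhere(np.isnan(mat))[0, 1])]
        raise ValueError(f"{path}: missing values (e.g. column {col!r}); "
                         "complete-case input is required")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(path))[0]
    return Block(
        name=name,
        matrix=mat,
        feature_names=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )
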