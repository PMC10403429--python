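"""netSGCCA: sparse multiblock canonical correlation with a GraphNet penalty.

The model extends sparse generalized CCA (SGCCA).  Given J paired blocks
X_1..X_J (n x p_j, column-centred) and a design matrix c linking blocks,
it minimises

    sum_{j != k} -c_jk cov(X_j w_j, X_k w_k)
        + (gamma / lambda_max) w_g' L_g w_g

subject to ||w_j||_2 <= 1 and ||w_j||_1 <= s_j for every block.  L_g is
the (raw or normalized) Laplacian of a prior interaction graph over the
features of one designated block; scaling by its largest eigenvalue
lambda_max makes gamma comparable across graphs, since
w' L w <= lambda_max whenever ||w||_2 <= 1.

Optimisation is block-cyclic: each w_j is updated in turn by FISTA with
backtracking, the constraints being handled by a Dykstra projection onto
the intersection of the l1 and l2 balls.  Setting gamma = 0 recovers plain
SGCCA with inequality l2 constraints.

The public surface follows the model/results convention: build a
:class:`NetSGCCA` from blocks, call :meth:`NetSGCCA.fit`, and work with
the returned :class:`NetSGCCAResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import (
    Block,
    ConnectionDesign,
    GraphPenaltyConfig,
    SparsityConstraint,
    check_paired,
    pair_covariance,
    preprocess_block,
)
from .graph import GraphLaplacian, PriorGraph, align_graph, build_laplacian
from .projections import ConstraintPair, project_constraint_pair

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyTerm",
    "SolverSettings",
    "NetSGCCA",
    "NetSGCCAResults",
    "objective",
    "graphnet_value",
    "block_gradient",
    "initial_step",
    "deflate",
]

_STEP_UNDERFLOW = 1e-16


@dataclass
class PenaltyTerm:
    """Materialised GraphNet penalty: (gamma / lambda_max) * w' L w on one block."""

    laplacian: GraphLaplacian
    gamma: float
    block_index: int

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")

    @property
    def scale(self) -> float:
        """gamma / lambda_max (0 when gamma is 0)."""
        if self.gamma == 0:
            return 0.0
        lam = self.laplacian.lambda_max
        if lam <= 0:
            raise ValueError(
                "the aligned graph has no edges (lambda_max = 0); the "
                "lambda_max-scaled penalty is undefined — set gamma = 0"
            )
        return self.gamma / lam


@dataclass
class SolverSettings:
    """Tolerances, caps and reproducibility knobs for the solver."""

    outer_tol: float = 1e-6
    outer_max_iter: int = 200
    inner_max_iter: int = 100
    inner_tol: float = 1e-8
    init: str = "svd"
    seed: int = 0
    selection_threshold: float = 1e-8
    dykstra_max_cycles: int = 1000
    dykstra_tol: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.outer_tol, self.inner_tol, self.dykstra_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if min(self.outer_max_iter, self.inner_max_iter, self.dykstra_max_cycles) < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.init not in ("svd", "random"):
            raise ValueError("init must be 'svd' or 'random'")


# ---------------------------------------------------------------------------
# objective / gradient primitives (operate on plain matrices + weights)
# ---------------------------------------------------------------------------

def graphnet_value(w: np.ndarray, penalty: PenaltyTerm) -> float:
    """(gamma / lambda_max) * w' L w."""
    w = np.asarray(w, dtype=float)
    if penalty.laplacian.shape[0] != w.shape[0]:
        raise ValueError(
            f"penalty dimension {penalty.laplacian.shape[0]} does not match "
            f"weight dimension {w.shape[0]}"
        )
    if penalty.gamma == 0:
        return 0.0
    return penalty.scale * float(w @ (penalty.laplacian.matrix @ w))


def _as_penalty_list(penalty) -> list[PenaltyTerm]:
    if penalty is None:
        return []
    if isinstance(penalty, PenaltyTerm):
        return [penalty]
    return list(penalty)


def objective(blocks: list[Block], weights: list[np.ndarray],
              design: ConnectionDesign, penalty=None) -> float:
    """Full model objective: ordered-pair covariance sum plus penalties."""
    J = len(blocks)
    total = 0.0
    for j in range(J):
        for k in range(J):
            if j != k and design.c[j, k]:
                total -= design.c[j, k] * pair_covariance(
                    blocks[j], weights[j], blocks[k], weights[k]
                )
    for term in _as_penalty_list(penalty):
        total += graphnet_value(weights[term.block_index], term)
    return total


def block_gradient(j: int, blocks: list[Block], weights: list[np.ndarray],
                   design: ConnectionDesign, penalty=None) -> np.ndarray:
    """Gradient of the smooth objective w.r.t. w_j, all other weights fixed.

    The covariance double sum counts each unordered pair twice, so the
    linear part is -(2/n) X_j' sum_k c_jk X_k w_k; a penalty on block j
    contributes 2 (gamma / lambda_max) L w_j.
    """
    n = blocks[j].n_samples
    z = np.zeros(n)
    for k in range(len(blocks)):
        if k != j and design.c[j, k]:
            z += design.c[j, k] * (blocks[k].matrix @ weights[k])
    grad = -(2.0 / n) * (blocks[j].matrix.T @ z)
    for term in _as_penalty_list(penalty):
        if term.block_index == j and term.gamma > 0:
            grad = grad + 2.0 * term.scale * (term.laplacian.matrix @ weights[j])
    return grad


def initial_step(gamma_total: float) -> float:
    """Initial FISTA step for a block.

    The smooth part is linear in w_j except for the quadratic penalty,
    whose Hessian 2 (gamma / lambda_max) L has spectral norm at most
    2 gamma after the lambda_max scaling — so 1 / (2 gamma) is a valid
    Lipschitz step for a penalized block, and 1.0 (arbitrary, backtracked)
    for an unpenalized one.
    """
    if gamma_total > 0:
        return 1.0 / (2.0 * gamma_total)
    return 1.0


def deflate(block: Block, component: np.ndarray) -> tuple[Block, np.ndarray]:
    """Remove a component's contribution: X <- X - t (t't)^-1 t' X.

    Returns the deflated block and the loading vector p = X' t / (t't)
    needed to replay the deflation on new data.
    """
    t = np.asarray(component, dtype=float)
    tt = float(t @ t)
    if tt <= 0:
        raise ValueError("cannot deflate by a zero component")
    loading = block.matrix.T @ t / tt
    out = Block(
        name=block.name,
        matrix=block.matrix - np.outer(t, loading),
        feature_names=list(block.feature_names),
        sample_ids=list(block.sample_ids),
    )
    out.center_ = block.center_
    out.scale_ = block.scale_
    return out, loading


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class NetSGCCA:
    """Sparse generalized CCA with an optional GraphNet penalty.

    Parameters
    ----------
    blocks : list of Block
        Paired data blocks (identical sample ids, identical order).
    design : ConnectionDesign, optional
        Block connection matrix; defaults to the complete design
        (every block linked to every other).
    sparsity : SparsityConstraint or sequence of float
        Per-block l1 radii, each in [1, sqrt(p_j)].
    penalty : GraphPenaltyConfig or list thereof, optional
        GraphNet penalty specification(s); each names a target block.
    graph : PriorGraph or dict of {block name: PriorGraph}, optional
        Prior graph(s) for the penalized block(s); aligned to the block's
        feature list internally (missing features become isolated nodes).
    center, scale : bool
        Column preprocessing applied once at construction.  Centring is
        required by the covariance objective and defaults on; scaling to
        unit variance also defaults on.
    """

    def __init__(self, blocks, design=None, sparsity=None, penalty=None,
                 graph=None, center=True, scale=True):
        check_paired(blocks)
        self.raw_blocks = list(blocks)
        self.blocks = [preprocess_block(b, center=center, scale=scale)
                       for b in blocks]
        self.block_names = [b.name for b in blocks]
        J = len(blocks)
        self.design = design if design is not None else ConnectionDesign.complete(J)
        if self.design.c.shape[0] != J:
            raise ValueError("design dimension does not match block count")
        if sparsity is None:
            sparsity = [np.sqrt(b.n_features) for b in blocks]
        if not isinstance(sparsity, SparsityConstraint):
            sparsity = SparsityConstraint(np.asarray(sparsity, dtype=float))
        sparsity.validate_against(self.blocks)
        self.sparsity = sparsity
        self.center = center
        self.scale = scale
        self.penalties = self._build_penalties(penalty, graph)

    def _build_penalties(self, penalty, graph) -> list[PenaltyTerm]:
        if penalty is None:
            return []
        configs = penalty if isinstance(penalty, (list, tuple)) else [penalty]
        terms = []
        for cfg in configs:
            if not isinstance(cfg, GraphPenaltyConfig):
                raise TypeError("penalty must be GraphPenaltyConfig(s)")
            if cfg.target_block not in self.block_names:
                raise ValueError(f"unknown penalty target block {cfg.target_block!r}")
            j = self.block_names.index(cfg.target_block)
            if isinstance(graph, dict):
                g = graph.get(cfg.target_block)
            else:
                g = graph
            if g is None:
                raise ValueError(
                    f"penalty on block {cfg.target_block!r} requires a graph"
                )
            if not isinstance(g, PriorGraph):
                raise TypeError("graph must be a PriorGraph")
            aligned = align_graph(g, self.blocks[j].feature_names)
            lap = build_laplacian(aligned, variant=cfg.laplacian_variant)
            term = PenaltyTerm(laplacian=lap, gamma=cfg.gamma, block_index=j)
            if cfg.gamma > 0:
                term.scale  # raises when lambda_max = 0
            terms.append(term)
        return terms

    @classmethod
    def from_dataframes(cls, frames: dict[str, pd.DataFrame], **kwargs) -> "NetSGCCA":
        """Build from {block name: DataFrame} (rows = samples, columns = features)."""
        blocks = []
        for name, df in frames.items():
            blocks.append(Block(
                name=name,
                matrix=df.to_numpy(dtype=float),
                feature_names=[str(c) for c in df.columns],
                sample_ids=[str(i) for i in df.index],
            ))
        return cls(blocks, **kwargs)

    # -- solver -------------------------------------------------------------

    def _init_weights(self, work_blocks, settings: SolverSettings,
                      rng: np.random.Generator) -> list[np.ndarray]:
        ws = []
        for j, b in enumerate(work_blocks):
            if settings.init == "svd":
                # first right singular direction of X_j (deterministic)
                _, _, vt = np.linalg.svd(b.matrix, full_matrices=False)
                w = vt[0]
                # fix SVD sign ambiguity deterministically
                imax = int(np.argmax(np.abs(w)))
                if w[imax] < 0:
                    w = -w
            else:
                w = rng.standard_normal(b.n_features)
                w /= np.linalg.norm(w)
            pair = ConstraintPair(self.sparsity.s[j])
            ws.append(project_constraint_pair(
                w, pair, settings.dykstra_max_cycles, settings.dykstra_tol))
        return ws

    def _block_smooth(self, j, w, z, penalty_terms, n):
        """Smooth objective restricted to block j (others fixed, constants
        dropped): -(2/n) w' X_j' z + penalty(w)."""
        val = -(2.0 / n) * float(w @ z)
        for term in penalty_terms:
            if term.block_index == j and term.gamma > 0:
                val += term.scale * float(w @ (term.laplacian.matrix @ w))
        return val

    def _fista_block(self, j, work_blocks, weights, settings) -> np.ndarray:
        """One constrained FISTA solve for block j, others held fixed.

        Monotone safeguard: FISTA iterates are not monotone, so the best
        iterate seen (including the start) is returned — this keeps the
        outer objective trace non-increasing.
        """
        n = work_blocks[j].n_samples
        Xj = work_blocks[j].matrix
        z = np.zeros(n)
        for k in range(len(work_blocks)):
            if k != j and self.design.c[j, k]:
                z += self.design.c[j, k] * (work_blocks[k].matrix @ weights[k])
        XjTz = Xj.T @ z
        terms = [t for t in self.penalties if t.block_index == j and t.gamma > 0]
        gamma_total = sum(t.gamma for t in terms)

        def smooth(w):
            val = -(2.0 / n) * float(w @ XjTz)
            for t in terms:
                val += t.scale * float(w @ (t.laplacian.matrix @ w))
            return val

        def grad(w):
            g = -(2.0 / n) * XjTz
            for t in terms:
                g = g + 2.0 * t.scale * (t.laplacian.matrix @ w)
            return g

        pair = ConstraintPair(self.sparsity.s[j])

        def proj(v):
            return project_constraint_pair(
                v, pair, settings.dykstra_max_cycles, settings.dykstra_tol)

        w = weights[j].copy()
        w_prev = w.copy()
        best_w, best_f = w.copy(), smooth(w)
        tk = 1.0
        step = initial_step(gamma_total)
        for _ in range(settings.inner_max_iter):
            tk_next = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
            y = w + ((tk - 1.0) / tk_next) * (w - w_prev)
            gy = grad(y)
            fy = smooth(y)
            # backtracking on the FISTA majorization condition
            while True:
                cand = proj(y - step * gy)
                d = cand - y
                if smooth(cand) <= fy + float(gy @ d) + float(d @ d) / (2.0 * step) + 1e-12:
                    break
                step /= 2.0
                if step < _STEP_UNDERFLOW:
                    raise RuntimeError(
                        f"backtracking step underflow on block "
                        f"{self.block_names[j]!r} (step < {_STEP_UNDERFLOW})"
                    )
            w_prev, w, tk = w, cand, tk_next
            fw = smooth(w)
            if fw < best_f:
                best_f, best_w = fw, w.copy()
            if np.linalg.norm(w - w_prev) < settings.inner_tol:
                break
        return best_w

    def fit(self, n_components: int = 1,
            settings: SolverSettings | None = None) -> "NetSGCCAResults":
        """Fit the model; returns a :class:`NetSGCCAResults`.

        Components beyond the first are extracted after block-wise
        deflation of every block by its own score vector.
        """
        if settings is None:
            settings = SolverSettings()
        rng = np.random.default_rng(settings.seed)
        J = len(self.blocks)
        work = [Block(b.name, b.matrix.copy(), list(b.feature_names),
                      list(b.sample_ids)) for b in self.blocks]

        all_weights: list[list[np.ndarray]] = []
        all_components: list[list[np.ndarray]] = []
        all_loadings: list[list[np.ndarray | None]] = []
        traces: list[list[float]] = []
        converged: list[bool] = []

        for _comp in range(n_components):
            weights = self._init_weights(work, settings, rng)
            trace = [objective(work, weights, self.design, self.penalties)]
            ok = False
            for it in range(settings.outer_max_iter):
                for j in range(J):
                    weights[j] = self._fista_block(j, work, weights, settings)
                f = objective(work, weights, self.design, self.penalties)
                f_prev = trace[-1]
                if f > f_prev + 1e-9 * (1.0 + abs(f_prev)):
                    raise RuntimeError(
                        f"objective increased at outer iteration {it} "
                        f"({f_prev:.6e} -> {f:.6e}); solver state inconsistent"
                    )
                trace.append(f)
                if abs(f_prev - f) <= settings.outer_tol * (1.0 + abs(f_prev)):
                    ok = True
                    break
            # sign canonicalization: largest-|w| entry of the first block positive
            ref = weights[0]
            if ref[int(np.argmax(np.abs(ref)))] < 0:
                weights = [-w for w in weights]
            comps = [work[j].matrix @ weights[j] for j in range(J)]
            all_weights.append(weights)
            all_components.append(comps)
            traces.append(trace)
            converged.append(ok)
            if _comp < n_components - 1:
                loads: list[np.ndarray | None] = []
                for j in range(J):
                    t = comps[j]
                    if float(t @ t) > 1e-12:
                        work[j], pl = deflate(work[j], t)
                        loads.append(pl)
                    else:
                        loads.append(None)
                all_loadings.append(loads)

        return NetSGCCAResults(
            model=self,
            settings=settings,
            weights=all_weights,
            components=all_components,
            deflation_loadings=all_loadings,
            objective_traces=traces,
            converged=converged,
        )


class NetSGCCAResults:
    """Fitted netSGCCA: per-block weight vectors, score vectors, traces.

    Attributes
    ----------
    weights : list over components of lists over blocks of ndarray
    components : list over components of lists over blocks of ndarray
        Score vectors t_j = X_j w_j on the (preprocessed, deflated) blocks.
    objective_traces : list over components of lists of float
    converged : list of bool per component
    """

    def __init__(self, model, settings, weights, components,
                 deflation_loadings, objective_traces, converged):
        self.model = model
        self.settings = settings
        self.weights = weights
        self.components = components
        self.deflation_loadings = deflation_loadings
        self.objective_traces = objective_traces
        self.converged = converged

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def block_names(self) -> list[str]:
        return self.model.block_names

    def weight_frame(self, block: str) -> pd.DataFrame:
        """Weights of one block as a (feature x component) DataFrame."""
        j = self.block_names.index(block)
        data = {f"component_{k + 1}": self.weights[k][j]
                for k in range(self.n_components)}
        return pd.DataFrame(data, index=self.model.blocks[j].feature_names)

    def selected(self, block: str, component: int | None = None) -> set:
        """Features with |w| above the selection threshold.

        Dykstra returns exact zeros from the l1 projection but can leave
        numerically tiny entries; the threshold (default 1e-8) separates
        the two.  ``component=None`` unions over components.
        """
        j = self.block_names.index(block)
        thr = self.settings.selection_threshold
        names = np.asarray(self.model.blocks[j].feature_names)
        if component is not None:
            mask = np.abs(self.weights[component][j]) > thr
            return set(names[mask])
        out: set = set()
        for k in range(self.n_components):
            out |= set(names[np.abs(self.weights[k][j]) > thr])
        return out

    def objective_value(self, component: int = 0) -> float:
        return self.objective_traces[component][-1]

    def component_frame(self) -> pd.DataFrame:
        """Scores as a (sample x block.component) DataFrame."""
        cols = {}
        for k in range(self.n_components):
            for j, name in enumerate(self.block_names):
                cols[f"{name}.component_{k + 1}"] = self.components[k][j]
        return pd.DataFrame(cols, index=self.model.blocks[0].sample_ids)

    def transform(self, new_blocks, partial: bool = False) -> dict[str, np.ndarray]:
        """Score new data with the fitted weights.

        New blocks are matched to training blocks by name; columns are
        aligned by feature name (any order); the training centring/scaling
        is replayed, and multi-component scores replay the training
        deflation through the stored loadings.  With ``partial=True``,
        blocks absent from ``new_blocks`` are skipped instead of raising —
        used when a training-only block (e.g. the survival residual block)
        has no test-time counterpart.
        """
        if isinstance(new_blocks, dict):
            items = new_blocks
        else:
            items = {b.name: b for b in new_blocks}
        out: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.block_names):
            if name not in items:
                if partial:
                    continue
                raise ValueError(f"missing block {name!r} in new data")
            nb = items[name]
            train = self.model.blocks[j]
            if set(nb.feature_names) != set(train.feature_names):
                missing = set(train.feature_names) - set(nb.feature_names)
                extra = set(nb.feature_names) - set(train.feature_names)
                raise ValueError(
                    f"block {name!r}: feature mismatch "
                    f"(missing: {sorted(missing)[:5]}, extra: {sorted(extra)[:5]})"
                )
            order = [nb.feature_names.index(f) for f in train.feature_names]
            X = np.asarray(nb.matrix, dtype=float)[:, order]
            if train.center_ is not None:
                X = X - train.center_
            if train.scale_ is not None:
                X = X / train.scale_
            scores = np.empty((X.shape[0], self.n_components))
            for k in range(self.n_components):
                t = X @ self.weights[k][j]
                scores[:, k] = t
                if k < self.n_components - 1:
                    pl = self.deflation_loadings[k][j]
                    if pl is not None:
                        X = X - np.outer(t, pl)
            out[name] = scores
        return out

    def summary(self) -> str:
        """Plain-text fit summary."""
        lines = ["netSGCCA fit", "=" * 60]
        pens = {t.block_index: t for t in self.model.penalties}
        lines.append(f"blocks: {len(self.block_names)}   "
                     f"samples: {self.model.blocks[0].n_samples}   "
                     f"components: {self.n_components}")
        for k in range(self.n_components):
            tr = self.objective_traces[k]
            conv = "yes" if self.converged[k] else "NO"
            lines.append(f"component {k + 1}: objective {tr[-1]:.6g} "
                         f"({len(tr) - 1} outer iterations, converged: {conv})")
        lines.append("-" * 60)
        lines.append(f"{'block':<14}{'p':>8}{'s':>8}{'gamma':>8}{'selected':>10}")
        for j, name in enumerate(self.block_names):
            g = pens[j].gamma if j in pens else 0.0
            nsel = len(self.selected(name))
            lines.append(f"{name:<14}{self.model.blocks[j].n_features:>8}"
                         f"{self.model.sparsity.s[j]:>8.3g}{g:>8.3g}{nsel:>10}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Serialize weights, components, traces and run metadata as TSV/JSON."""
        import os

        os.makedirs(outdir, exist_ok=True)
        for name in self.block_names:
            self.weight_frame(name).to_csv(
                os.path.join(outdir, f"weights_{name}.tsv"), sep="\t",
                index_label="feature")
        self.component_frame().to_csv(
            os.path.join(outdir, "components.tsv"), sep="\t",
            index_label="sample")
        with open(os.path.join(outdir, "objective_trace.tsv"), "w") as fh:
            fh.write("component\touter_iteration\tobjective\n")
            for k, tr in enumerate(self.objective_traces):
                for i, v in enumerate(tr):
                    fh.write(f"{k + 1}\t{i}\t{v!r}\n")
        meta = {
            "blocks": {n: int(b.n_features)
                       for n, b in zip(self.block_names, self.model.blocks)},
            "n_samples": int(self.model.blocks[0].n_samples),
            "sparsity": [float(s) for s in self.model.sparsity.s],
            "penalties": [
                {"block": self.block_names[t.block_index],
                 "gamma": float(t.gamma),
                 "variant": t.laplacian.variant,
                 "lambda_max": float(t.laplacian.lambda_max)}
                for t in self.model.penalties
            ],
            "settings": {
                "outer_tol": self.settings.outer_tol,
                "outer_max_iter": self.settings.outer_max_iter,
                "inner_max_iter": self.settings.inner_max_iter,
                "inner_tol": self.settings.inner_tol,
                "init": self.settings.init,
                "seed": self.settings.seed,
                "selection_threshold": self.settings.selection_threshold,
            },
            "converged": [bool(c) for c in self.converged],
        }
        with open(os.path.join(outdir, "run_metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
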