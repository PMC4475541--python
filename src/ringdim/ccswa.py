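"""Common Components and Specific Weights Analysis (CCSWA / ComDim).

CCSWA extracts, one at a time, *common components*: unit global score
vectors ``q_a`` describing sample dispersion shared across K data tables
X_1..X_K (all centered and scaled to unit total variance here, so that the
per-block *saliences* read directly as fractions of each block's variance).

For each component the algorithm alternates

    W = sum_k lambda_k * X_k X_k'      (salience-weighted compromise)
    q = dominant unit eigenvector of W
    lambda_k = q' X_k X_k' q           (block k's variance along q)

from ``lambda_k = 1`` until the saliences stabilize, then deflates every
block by the global score, ``X_k <- X_k - q q' X_k``, and proceeds to the
next component.  Successive global scores are exactly orthonormal because
deflation removes ``q`` from every block's row space.

With a single block the procedure reduces to PCA of that block: the global
scores are its normalized principal-component score directions and the
saliences its eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .blocks import Block, BlockSet
from .errors import ConfigError, ConvergenceError, DomainError


def _prepared(values: np.ndarray, instrument_id: str) -> np.ndarray:
    """Center columns and scale to unit Frobenius norm (unit total variance)."""
    X = np.asarray(values, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(X)
    if norm == 0:
        raise DomainError(f"block {instrument_id!r} is constant after centering")
    return X / norm


def _dominant_eigvec(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenpair of a symmetric matrix, with a deterministic sign.

    The eigenvector is oriented so its largest-magnitude entry (first such
    entry on ties) is positive, making the fit reproducible across runs and
    invariant to sign flips of the input blocks.
    """
    w, v = scipy.linalg.eigh(W)
    q = v[:, -1]
    i = int(np.argmax(np.abs(q)))
    if q[i] < 0:
        q = -q
    return float(w[-1]), q


@dataclass
class ComDimModel:
    """Fitted CCSWA model.

    Attributes
    ----------
    scores:
        (n, A) orthonormal global scores; column ``a`` is common component
        ``a + 1``.
    saliences:
        (K, A) nonnegative specific weights; entry (k, a) is the fraction of
        block k's (unit) total variance carried by component ``a + 1``.
    loadings:
        Per block, the (p_k, A) matrix of ``X_k' q_a`` computed on the
        deflated-at-step-a block.
    eigenvalues:
        Top eigenvalue of the weighted compromise W at convergence, per
        component.
    salience_totals:
        ``sum_k saliences[k, a]`` — the total variance, over blocks, carried
        by each component; used for variance-scaled scores.
    residual_variances:
        (K, A + 1) squared Frobenius norms of the blocks before extraction
        (column 0, equal to 1) and after each deflation; non-increasing.
    """

    block_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    saliences: np.ndarray
    loadings: list[np.ndarray]
    eigenvalues: np.ndarray
    salience_totals: np.ndarray
    residual_variances: np.ndarray
    convergence: list[dict]
    tol: float

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def component_names(self) -> list[str]:
        return [f"CC{a + 1}" for a in range(self.n_components)]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.sample_ids, columns=self.component_names()
        )

    def scaled_scores_frame(self) -> pd.DataFrame:
        """Scores scaled by the square root of each component's total salience."""
        scaled = self.scores * np.sqrt(self.salience_totals)[None, :]
        return pd.DataFrame(
            scaled, index=self.sample_ids, columns=self.component_names()
        )

    def saliences_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.saliences, index=self.block_ids, columns=self.component_names()
        )

    def block_index(self, instrument_id: str) -> int:
        try:
            return self.block_ids.index(instrument_id)
        except ValueError:
            raise ConfigError(
                f"block {instrument_id!r} was not part of the fitted set "
                f"{self.block_ids}"
            ) from None


def fit_ccswa(
    blocks: BlockSet | Sequence[Block],
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> ComDimModel:
    """Fit a CCSWA/ComDim model.

    Blocks are column-centered and scaled to unit total variance internally
    (idempotent with the same preprocessing step).  ``tol`` bounds the
    maximum absolute salience change between iterations; non-convergence
    raises :class:`ConvergenceError` naming the component.
    """
    blocks = list(blocks.blocks) if isinstance(blocks, BlockSet) else list(blocks)
    if not blocks:
        raise ConfigError("fit_ccswa needs at least one block")
    sample_ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != sample_ids:
            raise ConfigError(
                f"block {b.instrument_id!r} is not aligned with "
                f"{blocks[0].instrument_id!r}"
            )
    n = len(sample_ids)
    k = len(blocks)
    if not 1 <= n_components <= n - 1:
        raise ConfigError(
            f"n_components must lie in [1, n_samples - 1] = [1, {n - 1}], "
            f"got {n_components}"
        )

    Xs = [_prepared(b.values, b.instrument_id) for b in blocks]

    scores = np.empty((n, n_components))
    saliences = np.empty((k, n_components))
    eigenvalues = np.empty(n_components)
    loadings_parts: list[list[np.ndarray]] = [[] for _ in range(k)]
    residual = np.empty((k, n_components + 1))
    residual[:, 0] = [float(np.sum(X * X)) for X in Xs]
    convergence: list[dict] = []

    for a in range(n_components):
        grams = [X @ X.T for X in Xs]
        lam = np.ones(k)
        delta = np.inf
        q = None
        top = 0.0
        for iteration in range(1, max_iter + 1):
            W = np.zeros((n, n))
            for g, l in zip(grams, lam):
                W += l * g
            top, q = _dominant_eigvec(W)
            lam_new = np.array([float(q @ g @ q) for g in grams])
            delta = float(np.max(np.abs(lam_new - lam)))
            lam = lam_new
            if delta < tol:
                break
        else:
            raise ConvergenceError(component=a, delta=delta, max_iter=max_iter)

        scores[:, a] = q
        saliences[:, a] = np.maximum(lam, 0.0)
        eigenvalues[a] = top
        for i in range(k):
            loadings_parts[i].append(Xs[i].T @ q)
            Xs[i] = Xs[i] - np.outer(q, q @ Xs[i])
            residual[i, a + 1] = float(np.sum(Xs[i] * Xs[i]))
        convergence.append({"component": a + 1, "iterations": iteration, "delta": delta})

    return ComDimModel(
        block_ids=[b.instrument_id for b in blocks],
        sample_ids=list(sample_ids),
        scores=scores,
        saliences=saliences,
        loadings=[np.column_stack(cols) for cols in loadings_parts],
        eigenvalues=eigenvalues,
        salience_totals=saliences.sum(axis=0),
        residual_variances=residual,
        convergence=convergence,
        tol=tol,
    )


def explained_variance(
    model: ComDimModel, blockset: BlockSet | None = None
) -> pd.DataFrame:
    """Fraction of each block's total variance carried by each component.

    Because blocks are scaled to unit total variance inside the fit, this is
    exactly the salience table; each row sums to at most 1 and reaches 1
    when extraction exhausts the block.
    """
    if blockset is not None:
        ids = (
            blockset.block_ids
            if isinstance(blockset, BlockSet)
            else [b.instrument_id for b in blockset]
        )
        if ids != model.block_ids:
            raise ConfigError("blockset does not match the fitted model's blocks")
    return model.saliences_frame()


# ---------------------------------------------------------------------------
# block projections and the barycentre representation
# ---------------------------------------------------------------------------


@dataclass
class BlockProjection:
    """Per-block sample scores on the common space, with their barycentre.

    ``block_scores[instrument_id]`` holds the (n, A) projection of that
    block's rows onto the common components at unit-salience scaling,
    ``t_ka = X_k X_k' q_a / sqrt(lambda_ka)``.  ``barycentre`` is the
    arithmetic mean over blocks per sample and component; ``dispersion`` the
    root-mean-square distance of the block scores to the barycentre.
    Components with salience below 1e-12 for a block are undefined (NaN)
    and flagged in ``defined``.
    """

    sample_ids: list[str]
    component_names: list[str]
    block_scores: dict[str, np.ndarray]
    barycentre: np.ndarray  # (n, A)
    dispersion: np.ndarray  # (n, A)
    defined: pd.DataFrame  # blocks x components, bool


def project_block(model: ComDimModel, block: Block) -> np.ndarray:
    """Project one fitted (pre-deflation) block onto the common components.

    Returns the (n, A) block-score matrix ``X X' q_a / sqrt(lambda_a)``;
    columns whose salience is below 1e-12 are NaN.
    """
    kidx = model.block_index(block.instrument_id)
    if block.sample_ids != model.sample_ids:
        raise ConfigError(
            f"block {block.instrument_id!r} samples differ from the fitted model"
        )
    X = _prepared(block.values, block.instrument_id)
    S = X @ X.T
    out = np.full((len(model.sample_ids), model.n_components), np.nan)
    for a in range(model.n_components):
        lam = model.saliences[kidx, a]
        if lam >= 1e-12:
            out[:, a] = S @ model.scores[:, a] / np.sqrt(lam)
    return out


def barycentre_projection(
    model: ComDimModel, blockset: BlockSet | Sequence[Block]
) -> BlockProjection:
    """Project every block and summarize each sample as the barycentre of
    the per-platform scores, with the dispersion of the platforms around it."""
    blocks = list(blockset.blocks) if isinstance(blockset, BlockSet) else list(blockset)
    scores = {b.instrument_id: project_block(model, b) for b in blocks}
    stack = np.stack([scores[b.instrument_id] for b in blocks])  # (K, n, A)
    barycentre = stack.mean(axis=0)
    dispersion = np.sqrt(np.mean((stack - barycentre[None]) ** 2, axis=0))
    defined = pd.DataFrame(
        {
            name: [np.isfinite(scores[b.instrument_id][:, a]).all() for b in blocks]
            for a, name in enumerate(model.component_names())
        },
        index=[b.instrument_id for b in blocks],
    )
    return BlockProjection(
        sample_ids=list(model.sample_ids),
        component_names=model.component_names(),
        block_scores=scores,
        barycentre=barycentre,
        dispersion=dispersion,
        defined=defined,
    )


# ---------------------------------------------------------------------------
# group separation on a common component
# ---------------------------------------------------------------------------


@dataclass
class SeparationResult:
    """Standardized group separation of one component's global scores."""

    component: int  # 0-based index into the model's components
    statistic: float  # standardized mean difference (pooled SD)
    p_value: float  # permutation p-value, two-sided on |statistic|
    n_perm: int
    seed: int | None


def _standardized_mean_diff(x: np.ndarray, mask: np.ndarray) -> float:
    a, b = x[mask], x[~mask]
    va = a.var(ddof=1) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) if len(b) > 1 else 0.0
    pooled = np.sqrt(
        ((len(a) - 1) * va + (len(b) - 1) * vb) / max(len(a) + len(b) - 2, 1)
    )
    diff = a.mean() - b.mean()
    if pooled == 0:
        return np.inf if diff != 0 else 0.0
    return float(diff / pooled)


def score_group_separation(
    model: ComDimModel,
    labels: Sequence,
    component: int = 0,
    n_perm: int = 199,
    seed: int | None = None,
) -> SeparationResult:
    """Permutation test of group separation along one common component.

    The statistic is the standardized mean difference of the component's
    global scores between the two label groups; the null is obtained by
    reshuffling the labels (seeded), and the p-value is
    ``(1 + #{|d_perm| >= |d_obs|}) / (n_perm + 1)``.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != len(model.sample_ids):
        raise ConfigError(
            f"{len(labels)} labels for {len(model.sample_ids)} samples"
        )
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ConfigError(f"binary labels required, got {uniq}")
    if not 0 <= component < model.n_components:
        raise ConfigError(
            f"component must lie in [0, {model.n_components - 1}], got {component}"
        )
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    q = model.scores[:, component]
    mask = labels == uniq[1]
    observed = _standardized_mean_diff(q, mask)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_mask = rng.permutation(mask)
        if abs(_standardized_mean_diff(q, perm_mask)) >= abs(observed):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return SeparationResult(
        component=component, statistic=observed, p_value=p, n_perm=n_perm, seed=seed
    )
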