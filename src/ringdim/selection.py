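"""Correlation-threshold feature selection on a common component.

Features characterizing a chosen common component (the group contrast or an
outlier dimension) are selected by the correlation of each feature with the
component's global scores: either an absolute-correlation threshold
(|r| > 0.8 by default, the convention for LC-MS tables) or a z-score
threshold applied to the standardized correlation vector (|z| > 2 by
default, the convention for NMR tables, whose binned features are far fewer
and more collinear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import Block
from .ccswa import ComDimModel
from .errors import ConfigError, DomainError

RULES = ("abs_r", "zscore")


@dataclass
class FeatureCorrelations:
    """Pearson correlations of one block's features with a global score."""

    block_id: str
    component: int  # 0-based
    values: pd.Series  # indexed by feature ID, in [-1, 1]
    zero_variance: pd.Series  # flag: correlation undefined, reported as 0


def cc_feature_correlations(
    block: Block, model: ComDimModel, component: int = 0
) -> FeatureCorrelations:
    """Correlate each feature of a fitted block with a common component.

    Zero-variance features have no defined correlation; they are reported as
    0 and flagged.
    """
    model.block_index(block.instrument_id)  # must be part of the fitted set
    if block.sample_ids != model.sample_ids:
        raise ConfigError(
            f"block {block.instrument_id!r} samples differ from the fitted model"
        )
    if not 0 <= component < model.n_components:
        raise ConfigError(
            f"component must lie in [0, {model.n_components - 1}], got {component}"
        )
    X = block.values - block.values.mean(axis=0, keepdims=True)
    q = model.scores[:, component]
    qc = q - q.mean()
    qn = np.linalg.norm(qc)
    norms = np.linalg.norm(X, axis=0)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    r = (X.T @ qc) / (safe * qn)
    r[zero] = 0.0
    r = np.clip(r, -1.0, 1.0)
    idx = pd.Index(block.feature_ids, name="feature_id")
    return FeatureCorrelations(
        block_id=block.instrument_id,
        component=component,
        values=pd.Series(r, index=idx),
        zero_variance=pd.Series(zero, index=idx),
    )


@dataclass
class SelectionResult:
    """Outcome of a threshold rule applied to a correlation vector."""

    block_id: str
    component: int
    rule: str
    threshold: float
    correlations: pd.Series
    zscores: pd.Series | None
    selected: list[str]
    degenerate: bool = False  # zscore rule with zero spread: empty selection

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select_by_threshold(
    correlations: FeatureCorrelations | pd.Series,
    rule: str = "abs_r",
    threshold: float | None = None,
) -> SelectionResult:
    """Select features by strict threshold on |r| or on its |z-score|.

    ``abs_r`` keeps features with ``|r| > threshold`` (default 0.8);
    ``zscore`` standardizes the correlation vector across the block's
    features and keeps ``|z| > threshold`` (default 2.0).  Thresholds are
    strict, so ties at the threshold are excluded, and raising the threshold
    can only shrink the selection.
    """
    if rule not in RULES:
        raise ConfigError(f"rule must be one of {RULES}, got {rule!r}")
    if isinstance(correlations, FeatureCorrelations):
        block_id, component, r = (
            correlations.block_id,
            correlations.component,
            correlations.values,
        )
    else:
        block_id, component, r = "", 0, correlations
    if len(r) == 0:
        raise DomainError("empty correlation vector")
    if threshold is None:
        threshold = 0.8 if rule == "abs_r" else 2.0

    zscores = None
    degenerate = False
    if rule == "abs_r":
        keep = r.abs() > threshold
    else:
        sd = float(r.std(ddof=0))
        if sd == 0:
            keep = pd.Series(False, index=r.index)
            degenerate = True
            zscores = pd.Series(0.0, index=r.index)
        else:
            zscores = (r - r.mean()) / sd
            keep = zscores.abs() > threshold
    return SelectionResult(
        block_id=block_id,
        component=component,
        rule=rule,
        threshold=float(threshold),
        correlations=r,
        zscores=zscores,
        selected=list(r.index[keep]),
        degenerate=degenerate,
    )


@dataclass
class OverlapResult:
    """Agreement between two feature selections from the same block."""

    n_a: int
    n_b: int
    n_shared: int
    percent_shared: float | None  # 100 * |A & B| / |A|; None when A is empty


def selection_overlap(
    selection_a: SelectionResult | set | list,
    selection_b: SelectionResult | set | list,
) -> OverlapResult:
    """Intersection size and percentage of selection A recovered in B.

    The percentage is relative to the first selection (by convention the
    CCSWA-based one), matching the usual ring-trial reporting of the share
    of component-selected features also found by each laboratory's own
    statistics.
    """
    a = set(selection_a.selected if isinstance(selection_a, SelectionResult) else selection_a)
    b = set(selection_b.selected if isinstance(selection_b, SelectionResult) else selection_b)
    shared = a & b
    pct = 100.0 * len(shared) / len(a) if a else None
    return OverlapResult(
        n_a=len(a), n_b=len(b), n_shared=len(shared), percent_shared=pct
    )
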