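"""Feature-table I/O, sample alignment and normalization.

Normalizations here are the per-sample intensity corrections used in urine
and plasma profiling:

* specific-gravity correction ``(SG_ref - 1) / (SG_i - 1)`` per sample,
* total-area (unit row sum) normalization,
* division by an internal-standard feature (e.g. TSP in NMR),

plus the column centering and unit-total-variance scaling expected by the
RV and CCSWA statistics.  All of them are row-wise or global scalings, so
they commute with feature subsetting.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .blocks import Block, BlockSet
from .errors import AlignmentError, ConfigError, DomainError, ParseError

logger = logging.getLogger("ringdim")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_feature_table(
    path: str | Path,
    instrument_id: str,
    technology: str,
    ion_mode: str = "none",
) -> Block:
    """Read a delimited feature table (sample-ID first column, feature header).

    The delimiter is sniffed from the extension (``.tsv``/``.txt`` -> tab,
    otherwise comma).  Duplicate IDs, missing values and non-numeric cells
    raise :class:`ParseError` naming the offending cells.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"feature table not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ParseError(f"{path}: duplicate sample IDs {dupes[:5]}")
    if raw.columns.duplicated().any():
        dupes = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise ParseError(f"{path}: duplicate feature IDs {dupes[:5]}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (raw == "")
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        cells = ", ".join(
            f"(row {raw.index[i]!r}, column {raw.columns[j]!r}: {raw.iat[i, j]!r})"
            for i, j in list(zip(rows, cols))[:5]
        )
        raise ParseError(f"{path}: non-numeric or missing cells at {cells}")
    return Block.from_frame(
        numeric.astype(float), instrument_id=instrument_id,
        technology=technology, ion_mode=ion_mode,
    )


def write_feature_table(block: Block, path: str | Path) -> Path:
    """Write a block as CSV (round-trips through :func:`read_feature_table`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    block.to_frame().to_csv(path, float_format="%.10g", index_label="sample_id")
    return path


def read_manifest(path: str | Path) -> list[dict]:
    """Read a block manifest (YAML/JSON list of instrument entries)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    entries = data.get("blocks", data) if isinstance(data, dict) else data
    if not isinstance(entries, list):
        raise ParseError(f"{path}: manifest must be a list of block entries")
    required = {"instrument_id", "technology", "path"}
    for entry in entries:
        missing = required - set(entry)
        if missing:
            raise ParseError(f"{path}: manifest entry missing keys {sorted(missing)}")
    return entries


def read_blocks_from_manifest(path: str | Path) -> list[Block]:
    """Read every feature table listed in a manifest, paths relative to it."""
    path = Path(path)
    blocks = []
    for entry in read_manifest(path):
        table = Path(entry["path"])
        if not table.is_absolute():
            table = path.parent / table
        blocks.append(
            read_feature_table(
                table,
                instrument_id=entry["instrument_id"],
                technology=entry["technology"],
                ion_mode=entry.get("ion_mode", "none"),
            )
        )
    return blocks


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata CSV (sample-ID first column)."""
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.duplicated().any():
        raise ParseError(f"{path}: duplicate sample IDs in metadata")
    return meta


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_blocks(
    blocks: Sequence[Block], metadata: pd.DataFrame | None = None
) -> BlockSet:
    """Restrict all blocks to their common samples, in one shared order.

    The shared order follows the metadata row order when metadata is given,
    else the sorted common sample IDs; either way the result does not depend
    on the order blocks are passed in.  Dropped samples are logged per block.
    """
    if len(blocks) < 2:
        raise ConfigError("alignment needs at least 2 blocks")
    common = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if metadata is not None:
        common &= set(metadata.index.astype(str))
        order = [s for s in metadata.index.astype(str) if s in common]
    else:
        order = sorted(common)
    if len(order) < 3:
        raise AlignmentError(
            f"only {len(order)} samples common to all blocks (need >= 3)"
        )
    aligned = []
    for b in blocks:
        dropped = sorted(set(b.sample_ids) - common)
        if dropped:
            logger.info(
                "align_blocks: dropping %d sample(s) from %s: %s",
                len(dropped), b.instrument_id, dropped[:10],
            )
        aligned.append(b.subset_samples(order))
    meta = metadata.loc[order] if metadata is not None else None
    return BlockSet(blocks=aligned, metadata=meta)


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------


def _sg_array(
    block: Block, sg_values: Mapping[str, float] | pd.Series | np.ndarray
) -> np.ndarray:
    if isinstance(sg_values, pd.Series):
        try:
            return sg_values.loc[block.sample_ids].to_numpy(dtype=float)
        except KeyError as exc:
            raise DomainError(f"specific gravity missing for sample {exc}") from None
    if isinstance(sg_values, Mapping):
        missing = [s for s in block.sample_ids if s not in sg_values]
        if missing:
            raise DomainError(f"specific gravity missing for samples {missing[:5]}")
        return np.array([float(sg_values[s]) for s in block.sample_ids])
    arr = np.asarray(sg_values, dtype=float)
    if arr.shape != (block.n_samples,):
        raise DomainError(
            f"specific gravity array has shape {arr.shape}, "
            f"expected ({block.n_samples},)"
        )
    return arr


def sg_normalize(
    block: Block,
    sg_values: Mapping[str, float] | pd.Series | np.ndarray,
    sg_reference: float | None = None,
) -> Block:
    """Specific-gravity dilution correction.

    Row ``i`` is multiplied by ``(SG_ref - 1) / (SG_i - 1)``.  The reference
    defaults to the median specific gravity of the block's samples.
    """
    sg = _sg_array(block, sg_values)
    if np.any(sg <= 1.0):
        bad = [block.sample_ids[i] for i in np.nonzero(sg <= 1.0)[0][:5]]
        raise DomainError(
            f"specific gravity must exceed 1.0 (correction undefined) "
            f"for samples {bad}"
        )
    ref = float(np.median(sg)) if sg_reference is None else float(sg_reference)
    if ref <= 1.0:
        raise DomainError(f"sg_reference must exceed 1.0, got {ref}")
    factors = (ref - 1.0) / (sg - 1.0)
    return block.with_values(block.values * factors[:, None], step="sg")


def total_area_normalize(block: Block) -> Block:
    """Scale every sample (row) to unit total intensity."""
    sums = block.values.sum(axis=1)
    if np.any(sums <= 0):
        bad = [block.sample_ids[i] for i in np.nonzero(sums <= 0)[0][:5]]
        raise DomainError(f"nonpositive total intensity for samples {bad}")
    return block.with_values(block.values / sums[:, None], step="total_area")


def internal_standard_normalize(block: Block, feature_id: str) -> Block:
    """Divide every sample by its internal-standard intensity.

    The standard feature becomes the constant 1 in the result.
    """
    if feature_id not in block.feature_ids:
        raise DomainError(
            f"internal standard {feature_id!r} not found in block "
            f"{block.instrument_id!r}"
        )
    j = block.feature_ids.index(feature_id)
    std = block.values[:, j]
    if np.any(std <= 0):
        bad = [block.sample_ids[i] for i in np.nonzero(std <= 0)[0][:5]]
        raise DomainError(
            f"internal standard {feature_id!r} nonpositive for samples {bad}"
        )
    return block.with_values(block.values / std[:, None], step=f"istd:{feature_id}")


def center_and_scale(block: Block, scale: str = "none") -> Block:
    """Column-center a block; optionally scale to unit total variance.

    ``scale="unit_block_variance"`` divides the centered matrix by its
    Frobenius norm so the block's total variance is 1 — the convention under
    which CCSWA saliences read directly as fractions of a block's variance.
    Both steps are idempotent.
    """
    if block.n_samples < 2:
        raise DomainError("centering needs at least 2 samples")
    if scale not in ("none", "unit_block_variance"):
        raise ConfigError(f"unknown scale mode {scale!r}")
    values = block.values - block.values.mean(axis=0, keepdims=True)
    step = "center"
    if scale == "unit_block_variance":
        norm = np.linalg.norm(values)
        if norm == 0:
            raise DomainError(
                f"block {block.instrument_id!r} is constant; cannot scale to "
                f"unit variance"
            )
        values = values / norm
        step = "center+unit_block_variance"
    return block.with_values(values, step=step)


NORMALIZERS = ("none", "sg", "total-area", "istd")


def normalize_blockset(
    blockset: BlockSet,
    method: str = "none",
    sg_reference: float | None = None,
    istd_feature: Mapping[str, str] | str | None = None,
    scale: str = "unit_block_variance",
) -> BlockSet:
    """Apply one normalization method plus centering/scaling to every block.

    ``istd_feature`` may be a single feature ID or a mapping from instrument
    ID to feature ID.  Specific gravities are taken from the metadata column
    ``specific_gravity``.
    """
    if method not in NORMALIZERS:
        raise ConfigError(f"normalize must be one of {NORMALIZERS}, got {method!r}")

    def _one(block: Block) -> Block:
        out = block
        if method == "sg":
            if "specific_gravity" not in blockset.metadata.columns:
                raise ConfigError(
                    "sg normalization requires a 'specific_gravity' metadata column"
                )
            out = sg_normalize(
                out, blockset.metadata["specific_gravity"], sg_reference
            )
        elif method == "total-area":
            out = total_area_normalize(out)
        elif method == "istd":
            if istd_feature is None:
                raise ConfigError("istd normalization requires istd_feature")
            feat = (
                istd_feature.get(block.instrument_id)
                if isinstance(istd_feature, Mapping)
                else istd_feature
            )
            if feat is None:
                raise ConfigError(
                    f"no internal standard given for block {block.instrument_id!r}"
                )
            out = internal_standard_normalize(out, feat)
        return center_and_scale(out, scale=scale)

    return blockset.map_blocks(_one)
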