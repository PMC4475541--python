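"""Core containers: the per-instrument feature table and the aligned multi-table set.

A *block* is one instrument's samples x features intensity matrix together
with its identity metadata (instrument ID, technology, ionization mode).  A
*block set* is an ordered collection of blocks sharing one ordered sample
list; it is the unit on which all multiblock statistics operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError

TECHNOLOGIES = ("NMR", "LCMS")
ION_MODES = ("pos", "neg", "none")


@dataclass
class Block:
    """One instrument's samples x features intensity matrix.

    Parameters
    ----------
    instrument_id:
        Unique identifier of the instrument/platform (e.g. ``"N1"``, ``"Q3P"``).
    technology:
        ``"NMR"`` or ``"LCMS"``.
    ion_mode:
        ``"pos"``, ``"neg"`` or ``"none"`` (NMR has no ionization mode).
    sample_ids, feature_ids:
        Ordered, unique identifiers for rows and columns.
    values:
        ``(n_samples, n_features)`` array of finite intensities.
    normalizations:
        Provenance trail of normalization/scaling steps applied, in order.
    """

    instrument_id: str
    technology: str
    ion_mode: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    normalizations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.technology not in TECHNOLOGIES:
            raise ConfigError(
                f"block {self.instrument_id!r}: technology must be one of "
                f"{TECHNOLOGIES}, got {self.technology!r}"
            )
        if self.ion_mode not in ION_MODES:
            raise ConfigError(
                f"block {self.instrument_id!r}: ion_mode must be one of "
                f"{ION_MODES}, got {self.ion_mode!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError(
                f"block {self.instrument_id!r}: values must be 2-D, "
                f"got shape {self.values.shape}"
            )
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ConfigError(
                f"block {self.instrument_id!r}: matrix shape {self.values.shape} "
                f"does not match {len(self.sample_ids)} samples x "
                f"{len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigError(f"block {self.instrument_id!r}: duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ConfigError(f"block {self.instrument_id!r}: duplicate feature IDs")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[:5]
            cells = ", ".join(
                f"({self.sample_ids[i]}, {self.feature_ids[j]})" for i, j in bad
            )
            raise ConfigError(
                f"block {self.instrument_id!r}: non-finite values at {cells}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        instrument_id: str,
        technology: str,
        ion_mode: str = "none",
        normalizations: tuple[str, ...] = (),
    ) -> "Block":
        return cls(
            instrument_id=instrument_id,
            technology=technology,
            ion_mode=ion_mode,
            sample_ids=list(frame.index.astype(str)),
            feature_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            normalizations=normalizations,
        )

    def with_values(self, values: np.ndarray, step: str | None = None) -> "Block":
        """Return a copy with new values and, optionally, a provenance flag."""
        norms = self.normalizations + ((step,) if step else ())
        return replace(self, values=np.asarray(values, dtype=float), normalizations=norms)

    def subset_samples(self, sample_ids: Sequence[str]) -> "Block":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(
                f"block {self.instrument_id!r} lacks samples: {missing[:5]}"
            )
        rows = [index[s] for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), values=self.values[rows])

    def subset_features(self, feature_ids: Sequence[str]) -> "Block":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise ConfigError(
                f"block {self.instrument_id!r} lacks features: {missing[:5]}"
            )
        cols = [index[f] for f in feature_ids]
        return replace(self, feature_ids=list(feature_ids), values=self.values[:, cols])


@dataclass
class BlockSet:
    """Blocks aligned on one shared, ordered sample list.

    ``metadata`` is indexed by sample ID (same order as the blocks) and
    typically carries ``group``, ``individual``, ``pair`` and
    ``specific_gravity`` columns.
    """

    blocks: list[Block]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ConfigError("a BlockSet needs at least 2 blocks")
        ids = [b.instrument_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate instrument IDs in BlockSet: {ids}")
        ref = self.blocks[0].sample_ids
        if len(ref) < 3:
            raise ConfigError("a BlockSet needs at least 3 samples")
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise AlignmentError(
                    f"block {b.instrument_id!r} sample order differs from "
                    f"block {self.blocks[0].instrument_id!r}; align blocks first"
                )
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(ref, name="sample_id"))
        else:
            self.metadata = self.metadata.copy()
            self.metadata.index = self.metadata.index.astype(str)
            if list(self.metadata.index) != ref:
                try:
                    self.metadata = self.metadata.loc[ref]
                except KeyError as exc:
                    raise AlignmentError(
                        f"metadata does not cover all aligned samples: {exc}"
                    ) from None

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    @property
    def block_ids(self) -> list[str]:
        return [b.instrument_id for b in self.blocks]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)

    def __getitem__(self, key: int | str) -> Block:
        if isinstance(key, str):
            for b in self.blocks:
                if b.instrument_id == key:
                    return b
            raise KeyError(key)
        return self.blocks[key]

    def map_blocks(self, func) -> "BlockSet":
        """Apply ``func(block) -> Block`` to every block, keeping metadata."""
        new = [func(b) for b in self.blocks]
        bs = BlockSet.__new__(BlockSet)
        bs.blocks = new
        bs.metadata = self.metadata
        # re-validate via __post_init__ semantics
        BlockSet.__post_init__(bs)
        return bs
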