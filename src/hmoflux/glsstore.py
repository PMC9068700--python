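"""Chunked on-disk store for large GLS matrices.

A GLS matrix over millions of candidate models does not fit comfortably in
memory as a DataFrame; the store shards the models axis into fixed-size
float32 chunks (``.npy``) with a JSON header mapping columns to
(linkage, gene) pairs, and streams shards back either lazily (for chunked
consumers such as the scoring stage) or concatenated.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["GlsStore"]


class GlsStore:
    def __init__(self, directory: str | Path, chunk_rows: int = 100_000):
        self.dir = Path(directory)
        self.chunk_rows = chunk_rows
        self._columns: list[tuple[str, str]] | None = None
        self._buffer: list[pd.DataFrame] = []
        self._buffered = 0
        self._n_shards = 0

    @property
    def header_path(self) -> Path:
        return self.dir / "header.json"

    def append(self, gls: pd.DataFrame) -> None:
        cols = [tuple(c) for c in gls.columns]
        if self._columns is None:
            self._columns = cols
            self.dir.mkdir(parents=True, exist_ok=True)
        elif cols != self._columns:
            raise ValueError("chunk columns differ from the store header")
        self._buffer.append(gls)
        self._buffered += len(gls)
        while self._buffered >= self.chunk_rows:
            block = pd.concat(self._buffer)
            self._write_shard(block.iloc[: self.chunk_rows])
            rest = block.iloc[self.chunk_rows :]
            self._buffer = [rest] if len(rest) else []
            self._buffered = len(rest)

    def _write_shard(self, block: pd.DataFrame) -> None:
        np.save(
            self.dir / f"shard_{self._n_shards:05d}.npy",
            block.to_numpy(dtype=np.float32),
        )
        self._n_shards += 1

    def close(self) -> None:
        if self._buffered:
            self._write_shard(pd.concat(self._buffer))
            self._buffer, self._buffered = [], 0
        self.header_path.write_text(
            json.dumps(
                {
                    "columns": [list(c) for c in (self._columns or [])],
                    "n_shards": self._n_shards,
                    "chunk_rows": self.chunk_rows,
                }
            )
        )

    # -- reading -----------------------------------------------------------
    def iter_chunks(self) -> Iterator[pd.DataFrame]:
        header = json.loads(self.header_path.read_text())
        columns = pd.MultiIndex.from_tuples(
            [tuple(c) for c in header["columns"]], names=["linkage", "gene"]
        )
        offset = 0
        for i in range(header["n_shards"]):
            arr = np.load(self.dir / f"shard_{i:05d}.npy")
            yield pd.DataFrame(
                arr, columns=columns, index=range(offset, offset + len(arr))
            )
            offset += len(arr)

    def read_all(self) -> pd.DataFrame:
        return pd.concat(self.iter_chunks())
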