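"""Pseudonymisation of patient identifiers.

Every unique true identifier (e.g. an NHI number) is assigned a random
10-character anonymous ID over an unambiguous alphabet (uppercase letters and
digits, excluding O/0 and I/1).  The true-to-anonymous mapping is a bijection
kept in a lookup table that is written to its own file, never alongside the
de-identified dataset.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigurationError, InputError

ALPHABET = "ABCDEFGHJKLMNPQRSTUVWXYZ23456789"  # no O/0, no I/1
ID_LENGTH = 10


@dataclass
class LookupTable:
    """Bijective map true identifier -> 10-character anonymous ID."""

    mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        self._used = set(self.mapping.values())
        if len(self._used) != len(self.mapping):
            raise InputError("lookup table is not a bijection")
        for anon in self._used:
            if len(anon) != ID_LENGTH:
                raise InputError(f"anonymous ID {anon!r} is not {ID_LENGTH} characters")

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, true_id: str) -> bool:
        return true_id in self.mapping

    def get(self, true_id: str) -> Optional[str]:
        return self.mapping.get(true_id)

    def assign(self, true_id: str, rng: random.Random) -> str:
        """Return the stable anonymous ID for ``true_id``, drawing a fresh one
        (redrawing on collision) if unseen."""
        if true_id in self.mapping:
            return self.mapping[true_id]
        while True:
            anon = "".join(rng.choice(ALPHABET) for _ in range(ID_LENGTH))
            if anon not in self._used:
                break
        self.mapping[true_id] = anon
        self._used.add(anon)
        return anon


def anonymize(records: pd.DataFrame, existing: Optional[LookupTable] = None,
              seed: int = 0, id_column: str = "patient_id",
              out_column: str = "anonymous_id"
              ) -> tuple[pd.DataFrame, LookupTable]:
    """Replace true identifiers with anonymous IDs.

    Deterministic given the seed and input order; previously seen patients in
    ``existing`` keep their prior IDs.  Records with an empty identifier raise
    an :class:`InputError` listing the offending row indices.
    """
    if id_column not in records.columns:
        raise InputError(f"column {id_column!r} not present")
    ids = records[id_column].astype(str)
    bad = [i for i, v in enumerate(ids) if not v.strip() or v.strip().lower() == "nan"]
    if bad:
        raise InputError(f"records with missing identifier at row indices {bad}")
    table = existing if existing is not None else LookupTable()
    rng = random.Random(seed)
    anon = [table.assign(v, rng) for v in ids]
    out = records.copy()
    out[id_column] = anon
    if out_column != id_column:
        out = out.rename(columns={id_column: out_column})
    return out, table


def write_lookup(table: LookupTable, path: str,
                 dataset_path: Optional[str] = None) -> None:
    """Write the lookup table as two-column delimited text.

    Refuses to write to the same path as the de-identified dataset: the table
    must be stored separately from the data it protects.
    """
    if dataset_path is not None and os.path.abspath(path) == os.path.abspath(dataset_path):
        raise ConfigurationError(
            "lookup table must be stored separately from the de-identified "
            f"dataset (both paths resolve to {os.path.abspath(path)})"
        )
    df = pd.DataFrame(
        {"true_id": list(table.mapping), "anonymous_id": list(table.mapping.values())}
    )
    df.to_csv(path, index=False)


def read_lookup(path: str) -> LookupTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != ["true_id", "anonymous_id"]:
        raise InputError(f"{path}: expected columns true_id, anonymous_id")
    return LookupTable(dict(zip(df["true_id"], df["anonymous_id"])))


def assert_no_true_ids(text: str, table: LookupTable) -> None:
    """Raise if any true identifier appears as a substring of ``text``."""
    leaked = [t for t in table.mapping if t in text]
    if leaked:
        raise InputError(f"true identifiers leaked into output: {leaked[:5]}")
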