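"""One-hot encoding of patient metadata.

Three categorical fields — sex (2 categories), anatomic site (8), age
group in 5-year steps 0..85 (18) — are encoded as concatenated one-hot
blocks, giving a binary feature vector of fixed length 2 + 8 + 18 = 28.
Missing fields encode as an all-zero block so the vector dimension never
changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SEX_CATEGORIES",
    "SITE_CATEGORIES",
    "AGE_CATEGORIES",
    "VECTOR_LENGTH",
    "MetadataRecord",
    "CategoryCodebook",
    "encode_sex",
    "encode_site",
    "encode_age",
    "encode_record",
    "decode_vector",
    "encode_dataframe",
]

# Position of the 1 follows the canonical coding tables: female=(1,0),
# male=(0,1); sites in alphabetical row order; ages 0,5,...,85.
SEX_CATEGORIES = ("female", "male")
SITE_CATEGORIES = (
    "anterior torso",
    "head/neck",
    "lateral torso",
    "lower extremity",
    "oral/genital",
    "palms/soles",
    "posterior torso",
    "upper extremity",
)
AGE_CATEGORIES = tuple(range(0, 90, 5))

VECTOR_LENGTH = len(SEX_CATEGORIES) + len(SITE_CATEGORIES) + len(AGE_CATEGORIES)


@dataclass(frozen=True)
class MetadataRecord:
    """A patient metadata triple; ``None`` marks a missing field."""

    sex: Optional[str] = None
    anatom_site: Optional[str] = None
    age: Optional[int] = None


@dataclass(frozen=True)
class CategoryCodebook:
    """Fixed category orderings used for encoding and decoding.

    Serializing and reloading the codebook preserves every encoding
    bit-exactly; the default reproduces the canonical coding tables.
    """

    sexes: Sequence[str] = SEX_CATEGORIES
    sites: Sequence[str] = SITE_CATEGORIES
    ages: Sequence[int] = AGE_CATEGORIES

    @property
    def cardinalities(self) -> tuple:
        return (len(self.sexes), len(self.sites), len(self.ages))

    @property
    def vector_length(self) -> int:
        return sum(self.cardinalities)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sexes": list(self.sexes),
                    "sites": list(self.sites),
                    "ages": list(self.ages),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CategoryCodebook":
        d = json.loads(Path(path).read_text())
        return cls(
            sexes=tuple(d["sexes"]),
            sites=tuple(d["sites"]),
            ages=tuple(int(a) for a in d["ages"]),
        )


def _one_hot(value, categories, field: str) -> np.ndarray:
    vec = np.zeros(len(categories), dtype=np.int8)
    if value is None:
        return vec
    try:
        vec[list(categories).index(value)] = 1
    except ValueError:
        raise ValueError(f"unknown {field} value {value!r}; expected one of {list(categories)}") from None
    return vec


def encode_sex(value: Optional[str], codebook: Optional[CategoryCodebook] = None) -> np.ndarray:
    """female -> (1,0); male -> (0,1); missing -> (0,0)."""
    cb = codebook or CategoryCodebook()
    return _one_hot(value, cb.sexes, "sex")


def encode_site(value: Optional[str], codebook: Optional[CategoryCodebook] = None) -> np.ndarray:
    """Unit vector in the codebook's site row order; missing -> zeros."""
    cb = codebook or CategoryCodebook()
    return _one_hot(value, cb.sites, "anatom_site")


def encode_age(value: Optional[int], codebook: Optional[CategoryCodebook] = None) -> np.ndarray:
    """Age group 5k -> unit vector at position k; missing -> zeros.

    Values outside the closed 5-year grid are rejected rather than
    silently binned.
    """
    cb = codebook or CategoryCodebook()
    if value is None:
        return np.zeros(len(cb.ages), dtype=np.int8)
    if isinstance(value, float) and np.isnan(value):
        return np.zeros(len(cb.ages), dtype=np.int8)
    value = int(value)
    return _one_hot(value, cb.ages, "age")


def encode_record(record: MetadataRecord, codebook: Optional[CategoryCodebook] = None) -> np.ndarray:
    """Concatenated [sex | site | age] one-hot vector of length 28."""
    cb = codebook or CategoryCodebook()
    return np.concatenate(
        [
            encode_sex(record.sex, cb),
            encode_site(record.anatom_site, cb),
            encode_age(record.age, cb),
        ]
    )


def decode_vector(vector: np.ndarray, codebook: Optional[CategoryCodebook] = None) -> MetadataRecord:
    """Inverse of :func:`encode_record`; all-zero blocks decode to None."""
    cb = codebook or CategoryCodebook()
    vector = np.asarray(vector)
    if vector.shape != (cb.vector_length,):
        raise ValueError(f"expected vector of length {cb.vector_length}, got shape {vector.shape}")
    n_sex, n_site, n_age = cb.cardinalities
    blocks = (
        (vector[:n_sex], cb.sexes),
        (vector[n_sex : n_sex + n_site], cb.sites),
        (vector[n_sex + n_site :], cb.ages),
    )
    decoded = []
    for block, categories in blocks:
        ones = np.flatnonzero(block)
        if len(ones) == 0:
            decoded.append(None)
        elif len(ones) == 1:
            decoded.append(categories[ones[0]])
        else:
            raise ValueError(f"block {block.tolist()} is not one-hot")
    return MetadataRecord(sex=decoded[0], anatom_site=decoded[1], age=decoded[2])


def encode_dataframe(df: pd.DataFrame, codebook: Optional[CategoryCodebook] = None) -> np.ndarray:
    """Encode a (sex, anatom_site, age) table into an (n, 28) int8 matrix.

    NaN cells are treated as missing.
    """
    cb = codebook or CategoryCodebook()
    rows = []
    for _, row in df.iterrows():
        sex = row.get("sex")
        site = row.get("anatom_site")
        age = row.get("age")
        rec = MetadataRecord(
            sex=None if pd.isna(sex) else str(sex),
            anatom_site=None if pd.isna(site) else str(site),
            age=None if pd.isna(age) else int(age),
        )
        rows.append(encode_record(rec, cb))
    if not rows:
        return np.zeros((0, cb.vector_length), dtype=np.int8)
    return np.stack(rows)
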