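"""Amino-acid physicochemical property scales for the PDT transform.

The physicochemical distance transform needs an ordered bank of numeric
amino-acid scales, each standardized to zero mean and unit standard
deviation over the 20 standard residues. Two sources are supported:

* :meth:`PropertyTable.from_aaindex` parses the AAindex1 flat-file format
  (``H``/``I`` records) for users who have that database locally; entries
  with missing values are dropped, the remainder sorted by accession, and
  the first ``n`` retained.
* :meth:`PropertyTable.synthetic` generates a reproducible synthetic bank
  of standardized scales from a fixed internal seed. This is the packaged
  default: for learning, any frozen diverse bank of standardized scales is
  equivalent, but the bank must be identical at train and predict time, so
  its manifest (source, seed, count) is recorded with every trained model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Canonical one-letter amino-acid alphabet, alphabetical order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Column order AAindex1 uses inside ``I`` records.
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

_DEFAULT_N = 500
_DEFAULT_SEED = 190502  # frozen; part of the packaged table's identity


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd


@dataclass(frozen=True)
class PropertyTable:
    """An ordered bank of standardized amino-acid scales.

    ``values[k, i]`` is property ``k`` evaluated on residue
    ``AA_ALPHABET[i]``; every row has mean 0 and population SD 1.
    """

    names: tuple[str, ...]
    values: np.ndarray  # shape (n_properties, 20)
    manifest: dict  # provenance: how to rebuild this exact table

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError("values must have shape (n_properties, 20)")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names/values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("property values must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]

    @classmethod
    def synthetic(cls, n: int = _DEFAULT_N, seed: int = _DEFAULT_SEED) -> "PropertyTable":
        """Deterministic synthetic bank of ``n`` standardized scales."""
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal((n, 20))
        values = _standardize(raw)
        names = tuple(f"SYN{seed}_{k:04d}" for k in range(n))
        return cls(names=names, values=values,
                   manifest={"source": "synthetic", "seed": seed, "n": n})

    @classmethod
    def from_aaindex(cls, path: str | Path, n: int = _DEFAULT_N) -> "PropertyTable":
        """Parse an AAindex1 flat file; keep the first ``n`` complete entries
        in accession order."""
        entries: dict[str, np.ndarray] = {}
        accession = None
        rows: list[str] = []
        in_values = False
        for line in Path(path).read_text().splitlines():
            if line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("I "):
                in_values = True
                rows = []
            elif in_values:
                if line.startswith("//"):
                    tokens = " ".join(rows).split()
                    in_values = False
                    if accession and len(tokens) == 20 and "NA" not in tokens:
                        vals = np.array([float(t) for t in tokens])
                        # reorder from AAindex column order to alphabetical
                        reordered = np.empty(20)
                        for col, aa in enumerate(_AAINDEX_ORDER):
                            reordered[AA_INDEX[aa]] = vals[col]
                        entries[accession] = reordered
                    accession = None
                else:
                    rows.append(line)
            elif line.startswith("//"):
                accession = None
        if len(entries) < n:
            raise ValueError(
                f"only {len(entries)} complete AAindex entries found, need {n}")
        names = tuple(sorted(entries)[:n])
        values = _standardize(np.stack([entries[a] for a in names]))
        return cls(names=names, values=values,
                   manifest={"source": "aaindex1", "file": str(path), "n": n,
                             "accessions_sha": hash(names) & 0x7FFFFFFF})


_default: PropertyTable | None = None


def default_table() -> PropertyTable:
    """The packaged default property bank (synthetic, frozen seed)."""
    global _default
    if _default is None:
        _default = PropertyTable.synthetic()
    return _default


def table_from_manifest(manifest: dict) -> PropertyTable:
    """Rebuild the property bank a trained model was fitted with."""
    if manifest["source"] == "synthetic":
        return PropertyTable.synthetic(n=manifest["n"], seed=manifest["seed"])
    if manifest["source"] == "aaindex1":
        return PropertyTable.from_aaindex(manifest["file"], n=manifest["n"])
    raise ValueError(f"unknown property table source {manifest['source']!r}")
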