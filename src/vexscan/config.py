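"""Run configuration: every tunable of the pipeline with validated defaults.

A single :class:`RunConfig` travels through scan, featurization, training,
prediction and the bootstrap loop, and is echoed into every output directory
so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

#: Fixed locus order used for tie-breaking and serialization.
LOCI = ("IGHV", "IGKV", "IGLV", "TRAV_D", "TRBV", "TRGV")

_TRANSFORMS = ("aa_pairs", "pdt", "hybrid")
_SCORE_SIGNS = ("as_printed", "negated")
_COMBINE = ("mean", "geometric")
_BACKGROUND = ("shuffle", "uniform")


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid."""


@dataclass
class RunConfig:
    """All pipeline tunables.

    Defaults follow the published method where it states a value
    (20 kbp chunks / 1 kbp overlap, 275-330 bp exon window, 440/500-dim
    transforms, 500 trees, 3:1 signal ratio, eps 0.17, terminal tau 0.7)
    and this package's frozen choices elsewhere (depth 2, sigma 0.05,
    p_min 0.7).
    """

    # genome chunking
    chunk_size: int = 20000
    overlap: int = 1000
    # exon search window (inner AG..CAC span, both bounds inclusive)
    len_min: int = 275
    len_max: int = 330
    # multiresolution decomposition and featurization
    depth: int = 2
    transform: str = "aa_pairs"
    pdt_lambda: int = 1
    # for transform == "hybrid": level -> "aa_pairs" or "pdt:<lam>"
    level_map: dict[int, str] | None = None
    # classifier ensembles
    n_trees: int = 500
    signal_ratio: float = 3.0
    # acceptance criteria
    eps: float = 0.17
    terminal_tau: float = 0.7
    sigma: float = 0.05
    p_min: float = 0.7
    score_exponent_sign: str = "as_printed"
    combine: str = "mean"
    background: str = "shuffle"
    # bootstrap convergence rule
    min_new_fraction: float = 0.01
    max_iterations: int = 10
    # master seed; every downstream RNG is derived from it
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.overlap >= self.chunk_size:
            raise ConfigError("overlap must be < chunk_size")
        if self.overlap <= 0 or self.chunk_size <= 0:
            raise ConfigError("chunk_size and overlap must be positive")
        # a candidate spans at most len_max bases plus the flanking AG/CAC
        # motifs; it must fit inside one chunk overlap to make the chunked
        # scan equivalent to the whole-contig scan.
        if self.overlap < self.len_max + 5:
            raise ConfigError(
                "overlap must be >= len_max + 5 so every candidate interval "
                "is wholly contained in at least one chunk"
            )
        if not (0 < self.len_min <= self.len_max):
            raise ConfigError("need 0 < len_min <= len_max")
        if self.depth < 0:
            raise ConfigError("depth must be >= 0")
        if self.transform not in _TRANSFORMS:
            raise ConfigError(f"transform must be one of {_TRANSFORMS}")
        if self.transform == "hybrid" and not self.level_map:
            raise ConfigError("hybrid transform requires level_map")
        if self.pdt_lambda < 1:
            raise ConfigError("pdt_lambda must be >= 1")
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.signal_ratio <= 0:
            raise ConfigError("signal_ratio must be positive")
        if self.eps <= 0:
            raise ConfigError("eps must be positive")
        if not (0 <= self.terminal_tau <= 1):
            raise ConfigError("terminal_tau must be in [0, 1]")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if not (0 <= self.p_min <= 1):
            raise ConfigError("p_min must be in [0, 1]")
        if self.score_exponent_sign not in _SCORE_SIGNS:
            raise ConfigError(f"score_exponent_sign must be one of {_SCORE_SIGNS}")
        if self.combine not in _COMBINE:
            raise ConfigError(f"combine must be one of {_COMBINE}")
        if self.background not in _BACKGROUND:
            raise ConfigError(f"background must be one of {_BACKGROUND}")
        if not (0 <= self.min_new_fraction < 1):
            raise ConfigError("min_new_fraction must be in [0, 1)")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.level_map is not None:
            for lvl, spec in self.level_map.items():
                if not (0 <= int(lvl) <= self.depth):
                    raise ConfigError(f"level_map level {lvl} outside 0..depth")
                if spec != "aa_pairs" and not spec.startswith("pdt"):
                    raise ConfigError(f"unknown level transform {spec!r}")
            if self.transform == "hybrid":
                missing = set(range(self.depth + 1)) - {int(k) for k in self.level_map}
                if missing:
                    raise ConfigError(f"level_map misses levels {sorted(missing)}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["level_map"] is not None:
            d["level_map"] = {int(k): v for k, v in d["level_map"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("level_map"):
            d["level_map"] = {int(k): v for k, v in d["level_map"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def derive_seed(master: int, *tags: object) -> int:
    """Deterministically expand a master seed into a per-stage seed < 2**31.

    Stable across runs and platforms: hashes the repr of the tag tuple with
    SHA-256 and folds in the master seed.
    """
    payload = repr((int(master),) + tuple(str(t) for t in tags)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
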