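"""File validation and provenance records for pipeline runs."""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import tifffile

from . import __version__

__all__ = ["IOValidationError", "validate_io", "ProvenanceRecord",
           "sha256_file", "config_hash"]

_CSV_SCHEMAS = {
    "curve_csv": ({"height_m", "segment"}, [{"deflection_V"}, {"force_N"}]),
    "group_csv": ({"factorA", "value"}, []),
    "ct_csv": ({"sample", "condition", "gene", "ct"}, []),
}


class IOValidationError(ValueError):
    """Structured diagnostic for a file that fails format validation."""


def validate_io(path: str | os.PathLike, expected: str):
    """Parse ``path`` as one of the pipeline's formats or raise a
    diagnostic naming the first offending column/frame.

    ``expected`` is one of ``tiff_stack``, ``mask_tiff``, ``curve_csv``,
    ``group_csv``, ``ct_csv``, ``truth_json``.  An 8-bit TIFF where 16-bit
    is expected is promoted with a warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOValidationError(f"{path}: file does not exist")
    if expected in ("tiff_stack", "mask_tiff"):
        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise IOValidationError(f"{path}: unreadable TIFF ({exc})") from exc
        if expected == "tiff_stack":
            if arr.ndim == 2:
                arr = arr[None]
            if arr.ndim != 3:
                raise IOValidationError(
                    f"{path}: expected a (frames, H, W) stack, got shape "
                    f"{arr.shape}")
            if arr.dtype == np.uint8:
                warnings.warn(f"{path}: 8-bit TIFF where 16-bit expected; "
                              "promoting", stacklevel=2)
                arr = arr.astype(np.uint16)
            elif arr.dtype != np.uint16:
                raise IOValidationError(
                    f"{path}: expected uint16 frames, got {arr.dtype}")
        else:
            if arr.ndim != 2:
                raise IOValidationError(
                    f"{path}: mask must be a single 2-D label image, got "
                    f"shape {arr.shape}")
        return arr
    if expected in _CSV_SCHEMAS:
        required, alternatives = _CSV_SCHEMAS[expected]
        df = pd.read_csv(path)
        missing = required - set(df.columns)
        if missing:
            raise IOValidationError(
                f"{path}: missing column(s) {sorted(missing)}")
        if alternatives and not any(alt <= set(df.columns)
                                    for alt in alternatives):
            names = " or ".join("/".join(sorted(a)) for a in alternatives)
            raise IOValidationError(f"{path}: missing column(s): one of {names}")
        for col in required:
            bad = df[df[col].isna()]
            if not bad.empty:
                raise IOValidationError(
                    f"{path}: row {int(bad.index[0]) + 2} has empty {col!r}")
        return df
    if expected == "truth_json":
        with open(path) as fh:
            obj = json.load(fh)
        if "schema_version" not in obj:
            raise IOValidationError(f"{path}: truth JSON lacks schema_version")
        return obj
    raise ValueError(f"unknown expected format {expected!r}")


def sha256_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON dump of a config dict."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class ProvenanceRecord:
    """What produced an output file: tool version, config hash, input
    hashes, timestamp and seed.  Rehashing the stored config must
    reproduce ``config_sha256``."""

    config: dict
    config_sha256: str = ""
    input_sha256: dict = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.config_sha256:
            self.config_sha256 = config_hash(self.config)
        elif self.config_sha256 != config_hash(self.config):
            raise ValueError("stored config hash does not match the config")
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @classmethod
    def for_run(cls, config: dict, inputs: list[str | os.PathLike] = (),
                seed: int | None = None) -> "ProvenanceRecord":
        return cls(config=config,
                   input_sha256={os.fspath(p): sha256_file(p) for p in inputs},
                   seed=seed)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)
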