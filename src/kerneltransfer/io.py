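"""Delimited-matrix and config I/O, model serialization, run manifests, logging."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np

from .kernels import KernelSpec
from .regression import KernelModel, LinearModel

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_config",
    "RunManifest",
    "write_manifest",
    "save_model",
    "load_model",
    "configure_logging",
    "ConfigError",
]

FLOAT_FORMAT = "%.12g"  # round-trip precision of written matrices

logger = logging.getLogger("kerneltransfer")


def configure_logging(level: str = "INFO", logfile: str | None = None) -> None:
    """Timestamped, level-tagged logging to stderr and optionally a file."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("kerneltransfer")
    root.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)
    root.setLevel(getattr(logging, level.upper()))


class ConfigError(ValueError):
    """Raised with every schema violation found in a run configuration."""


def read_matrix(path, delimiter: str = ",", header: bool = False):
    """Read a rectangular numeric matrix from delimited text.

    Returns ``(matrix, column_names)`` where the names are None unless
    ``header=True``.  Ragged rows and non-numeric cells are rejected with
    the offending line and column named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    names = None
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(delimiter)]
            if header and names is None:
                names = cells
                width = len(cells)
                continue
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row with {len(cells)} cells, expected {width}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                bad = next(i for i, c in enumerate(cells) if not _is_float(c))
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell {cells[bad]!r} in column {bad + 1}"
                ) from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.array(rows, dtype=float), names


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_matrix(path, M, delimiter: str = ",", names=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    M = np.atleast_2d(np.asarray(M, dtype=float))
    head = delimiter.join(names) if names is not None else ""
    np.savetxt(path, M, fmt=FLOAT_FORMAT, delimiter=delimiter, header=head, comments="")


def read_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


@dataclasses.dataclass
class RunManifest:
    """Record of one run: command, config digest, root seed, artifacts."""

    command: str
    arguments: dict
    config_digest: str
    seed: int | None
    artifacts: list
    version: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(out_dir, command: str, arguments: dict, seed=None, artifacts=()) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        arguments={k: str(v) for k, v in arguments.items()},
        config_digest=_digest(arguments),
        seed=seed,
        artifacts=[str(a) for a in artifacts],
        version=__version__,
    )
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    return path


def save_model(model, out_dir) -> None:
    """Serialize a fitted model as a directory of matrices plus a config block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(model, KernelModel):
        config = {"type": "kernel", "spec": model.spec.to_dict(), "ridge": model.ridge}
        write_matrix(out_dir / "X_train.csv", model.X_train)
        write_matrix(out_dir / "alpha.csv", model.alpha)
    elif isinstance(model, LinearModel):
        config = {"type": "linear"}
        write_matrix(out_dir / "weights.csv", model.weights)
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    with open(out_dir / "model.json", "w") as fh:
        json.dump(config, fh, indent=2)


def load_model(model_dir):
    model_dir = Path(model_dir)
    with open(model_dir / "model.json") as fh:
        config = json.load(fh)
    if config["type"] == "kernel":
        X, _ = read_matrix(model_dir / "X_train.csv")
        alpha, _ = read_matrix(model_dir / "alpha.csv")
        return KernelModel(
            spec=KernelSpec.from_dict(config["spec"]),
            X_train=X,
            alpha=alpha,
            ridge=float(config.get("ridge", 0.0)),
        )
    if config["type"] == "linear":
        W, _ = read_matrix(model_dir / "weights.csv")
        return LinearModel(weights=W)
    raise ConfigError(f"unknown model type {config['type']!r} in {model_dir}")
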