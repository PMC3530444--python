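"""File round-tripping: run configs (JSON), images (TIFF/PNG), series (CSV),
and run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .energy import ConfigurationError
from .engine import SimulationTrace
from .gonad import GonadModelConfig
from .lattice import CellKind
from .synthetic import SyntheticGonadSpec


def save_run_config(path: str | Path, config: GonadModelConfig, **run_kwargs) -> None:
    doc = {"config": dataclasses.asdict(config), "run": run_kwargs}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_run_config(path: str | Path) -> tuple[GonadModelConfig, dict]:
    """Parse a run-config JSON; raises ConfigurationError naming bad fields."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ConfigurationError(f"malformed JSON in {path}: {err}") from err
    if "config" not in doc:
        raise ConfigurationError("missing required field 'config'")
    cfg_doc = doc["config"]
    known = {f.name for f in dataclasses.fields(GonadModelConfig)}
    unknown = set(cfg_doc) - known
    if unknown:
        raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
    if "dims" in cfg_doc and cfg_doc["dims"] is not None:
        cfg_doc["dims"] = tuple(cfg_doc["dims"])
    try:
        config = GonadModelConfig(**cfg_doc)
    except TypeError as err:
        raise ConfigurationError(str(err)) from err
    return config, doc.get("run", {})


def save_synth_spec(path: str | Path, spec: SyntheticGonadSpec) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(spec), indent=2) + "\n")


def load_synth_spec(path: str | Path) -> SyntheticGonadSpec:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ConfigurationError(f"malformed JSON in {path}: {err}") from err
    known = {f.name for f in dataclasses.fields(SyntheticGonadSpec)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown spec field(s): {sorted(unknown)}")
    if "dims" in doc:
        doc["dims"] = tuple(doc["dims"])
    return SyntheticGonadSpec(**doc)


def save_label_image(path: str | Path, labels: np.ndarray) -> None:
    """Write a label image as 16-bit TIFF (or PNG by extension)."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    arr16 = arr.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    else:
        iio.imwrite(path, arr16)


def load_label_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path)).astype(np.int32)
    return np.asarray(iio.imread(path)).astype(np.int32)


def save_intensity_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def load_intensity_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    return np.asarray(iio.imread(path), dtype=float)


def save_snapshot_stack(path: str | Path, trace: SimulationTrace) -> None:
    """All recorded snapshots as a multi-page 16-bit TIFF."""
    stack = np.stack([labels.astype(np.uint16) for _, labels in trace.snapshots])
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def trace_series_frame(trace: SimulationTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mcs": trace.mcs,
            "energy": trace.energies,
            "gonad_circularity": trace.circularities,
            "accepted_flips": trace.accepted,
        }
    )


def save_kinds_table(path: str | Path, kinds: np.ndarray) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(1, len(kinds)),
            "kind": [CellKind(int(k)).name for k in kinds[1:]],
        }
    ).to_csv(path, index=False)


def load_kinds_table(path: str | Path, n_labels: int) -> np.ndarray:
    df = pd.read_csv(path)
    kinds = np.zeros(n_labels, dtype=np.int8)
    for _, row in df.iterrows():
        cid = int(row["cell_id"])
        if cid < n_labels:
            kinds[cid] = CellKind[str(row["kind"])]
    return kinds


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    subcommand: str
    config: dict
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    started: str = ""
    elapsed_s: float = 0.0

    def write(self, path: str | Path) -> None:
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest lists missing output {out}")
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


class ManifestTimer:
    def __init__(self, manifest: RunManifest) -> None:
        self.manifest = manifest

    def __enter__(self) -> RunManifest:
        self._t0 = time.monotonic()
        self.manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self.manifest

    def __exit__(self, *exc) -> None:
        self.manifest.elapsed_s = round(time.monotonic() - self._t0, 3)
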