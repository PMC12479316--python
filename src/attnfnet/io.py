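"""Dataset archives, manifests and image export.

A dataset directory holds one compressed array archive per split
(``train.npz`` / ``val.npz`` / ``test.npz`` with keys ``depth``,
``pressure``, ``posture``, ``subject_id``, ``calibration_kpa``) plus a
``manifest.json`` recording the generation seed and parameters, the
subject-to-split map and the per-subject latent parameters, so any archive
can be regenerated or reloaded losslessly.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np

from .synthetic import (PRESSURE_SHAPE, PairedSample, SyntheticDataset,
                        SyntheticSubject)

__all__ = ["write_archive", "read_archive", "save_png"]

_KEYS = ("depth", "pressure", "posture", "subject_id", "calibration_kpa")
SPLITS = ("train", "val", "test")


class SchemaError(ValueError):
    """Archive does not match the expected layout."""


def write_archive(dataset: SyntheticDataset, path: str | Path) -> None:
    """Write one npz per split plus the JSON manifest into ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for split in SPLITS:
        samples = dataset.subset(split)
        np.savez_compressed(
            path / f"{split}.npz",
            depth=np.stack([s.depth for s in samples]) if samples
            else np.zeros((0, 1, 1)),
            pressure=np.stack([s.pressure for s in samples]) if samples
            else np.zeros((0,) + PRESSURE_SHAPE),
            posture=np.array([s.posture for s in samples], dtype="U16"),
            subject_id=np.array([s.subject_id for s in samples], dtype="U16"),
            calibration_kpa=np.array([s.calibration_kpa for s in samples]),
        )
    manifest = {
        "meta": dataset.meta,
        "split": dataset.split,
        "subjects": {sid: {"subject_id": s.subject_id, "mass_kg": s.mass_kg,
                           "length_scale": s.length_scale,
                           "width_scale": s.width_scale, "seed": s.seed}
                     for sid, s in dataset.subjects.items()},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                   sort_keys=True))


def read_archive(path: str | Path) -> SyntheticDataset:
    """Load a dataset directory written by :func:`write_archive`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"missing manifest.json in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"manifest.json is not valid JSON: {e}") from e
    samples: list[PairedSample] = []
    for split in SPLITS:
        f = path / f"{split}.npz"
        if not f.exists():
            raise SchemaError(f"missing archive {f.name}")
        try:
            with np.load(f) as data:
                missing = [k for k in _KEYS if k not in data.files]
                if missing:
                    raise SchemaError(f"{f.name}: missing keys {missing}")
                arrays = {k: data[k] for k in _KEYS}
        except (OSError, ValueError, zipfile.BadZipFile) as e:
            raise SchemaError(f"{f.name}: unreadable archive ({e})") from e
        n = arrays["depth"].shape[0]
        for k in _KEYS:
            if arrays[k].shape[0] != n:
                raise SchemaError(f"{f.name}: field {k!r} has "
                                  f"{arrays[k].shape[0]} records, expected {n}")
        if n and arrays["pressure"].shape[1:] != PRESSURE_SHAPE:
            raise SchemaError(
                f"{f.name}: pressure grid is {arrays['pressure'].shape[1:]}, "
                f"expected {PRESSURE_SHAPE} (axis 0 = 27 sensels across the "
                f"bed width, axis 1 = 64 along the bed length)")
        for i in range(n):
            samples.append(PairedSample(
                depth=arrays["depth"][i],
                pressure=arrays["pressure"][i],
                posture=str(arrays["posture"][i]),
                subject_id=str(arrays["subject_id"][i]),
                calibration_kpa=float(arrays["calibration_kpa"][i]),
            ))
    subjects = {sid: SyntheticSubject(**sd)
                for sid, sd in manifest.get("subjects", {}).items()}
    return SyntheticDataset(samples=samples, split=manifest["split"],
                            subjects=subjects, meta=manifest.get("meta", {}))


def save_png(img: np.ndarray, path: str | Path, kind: str = "pressure",
             vmin: float | None = None, vmax: float | None = None) -> None:
    """Export a map as a PNG heatmap.

    Pressure uses a blue (low) to red (high) colormap; depth uses the
    reversed map so near (high) surfaces read red.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = "coolwarm" if kind == "pressure" else "coolwarm_r"
    fig, ax = plt.subplots(figsize=(4, 3))
    im = ax.imshow(img, cmap=cmap, vmin=vmin, vmax=vmax)
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)
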