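"""Core data containers: labeled image sets and neural recording sets.

An :class:`ImageSet` pairs an ``(n, H, W, C)`` stack of images in [0, 1]
with integer class labels.  A :class:`RecordingSet` is a trials-by-features
matrix of neural measurements (static mode) or trials-by-timebins-by-features
(temporal mode), row-aligned with an image set.  Readers and writers use
plain formats only: PNG directories with a CSV label table or a single HDF5
file for images; CSV for static recordings and HDF5 for temporal ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class ImageSet:
    """n labeled images sharing one (H, W, C) shape, values in [0, 1]."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    split_tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError("images must be (n, H, W, C)")
        n = self.images.shape[0]
        if n < 1 or self.labels.shape != (n,):
            raise ValueError("labels must align with images")
        m = len(self.class_names)
        if self.labels.min(initial=0) < 0 or (n and self.labels.max() >= m):
            raise ValueError("every label must be in [0, n_classes)")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "ImageSet":
        tags = [self.split_tags[i] for i in idx] if self.split_tags else None
        return ImageSet(self.images[idx], self.labels[idx], list(self.class_names), tags)


@dataclass
class RecordingSet:
    """Neural features aligned row-for-row with an image set.

    ``data`` is (n, d) in static mode or (n, T, d) in temporal mode, where
    features are electrodes/voxels and T time bins are ``bin_width`` ms wide
    with signed onsets relative to stimulus onset.
    """

    data: np.ndarray
    region_name: str = "region"
    bin_width: float | None = None
    bin_onsets: np.ndarray | None = None
    alignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError("data must be (n, d) or (n, T, d)")
        if self.data.shape[-1] < 1:
            raise ValueError("need at least one neural feature")
        if self.temporal:
            if self.bin_width is None or self.bin_width <= 0:
                raise ValueError("temporal mode requires bin_width > 0")
            onsets = np.asarray(self.bin_onsets, dtype=np.float64)
            if onsets.shape != (self.data.shape[1],) or np.any(np.diff(onsets) <= 0):
                raise ValueError("bin_onsets must be strictly increasing, one per bin")
            self.bin_onsets = onsets
        if self.alignment is None:
            self.alignment = np.arange(self.data.shape[0])

    @property
    def temporal(self) -> bool:
        return self.data.ndim == 3

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def d(self) -> int:
        return self.data.shape[-1]

    @property
    def n_bins(self) -> int:
        if not self.temporal:
            raise ValueError("static recording has no time bins")
        return self.data.shape[1]

    def at_bin(self, t: int) -> "RecordingSet":
        """Static view of one time bin of a temporal recording."""
        return RecordingSet(self.data[:, t, :], region_name=self.region_name,
                            alignment=self.alignment)


@dataclass
class DynamicsSpec:
    """Two-region temporal generative settings (V4-like and IT-like).

    Lags are in bins: ``feedforward_lag`` delays the stimulus-driven rate
    from the V4-like to the IT-like region; ``feedback_lag`` delays the
    class-information signal from the IT-like back to the V4-like region.
    """

    t_bins: int = 45
    stimulus_on: int = 2
    stimulus_off: int = 12
    feedforward_lag: int = 2
    feedback_lag: int = 3
    class_gain_it: float = 1.0
    class_gain_feedback: float = 0.8
    stimulus_gain: float = 1.0
    noise_sd: float = 0.3
    bin_width: float = 10.0
    first_onset_ms: float = -20.0
    drive_jitter: float = 0.5
    class_jitter: float = 0.5

    def __post_init__(self) -> None:
        if self.feedforward_lag < 1 or self.feedback_lag < 1:
            raise ValueError("lags must be >= 1 bin")
        if not (0 <= self.stimulus_on < self.stimulus_off <= self.t_bins):
            raise ValueError("need stimulus_on < stimulus_off <= t_bins")
        if max(self.feedforward_lag, self.feedback_lag) >= self.t_bins:
            raise ValueError("lags must be smaller than t_bins")

    @property
    def bin_onsets(self) -> np.ndarray:
        return self.first_onset_ms + self.bin_width * np.arange(self.t_bins)


def check_alignment(images: ImageSet, recordings: RecordingSet) -> None:
    """Positional row-alignment integrity check."""
    if recordings.n != images.n:
        raise ValueError(
            f"recordings have {recordings.n} rows but image set has {images.n}"
        )


# ---------------------------------------------------------------------------
# readers / writers


def write_imageset_dir(images: ImageSet, out_dir: str | Path) -> None:
    """PNG directory plus a labels.csv table (filename, label, class_name)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(images.n):
        fname = f"img_{i:05d}.png"
        arr = np.clip(images.images[i] * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr.squeeze()).save(out / fname)
        lab = int(images.labels[i])
        rows.append((fname, lab, images.class_names[lab]))
    pd.DataFrame(rows, columns=["filename", "label", "class_name"]).to_csv(
        out / "labels.csv", index=False
    )


def read_imageset_dir(in_dir: str | Path) -> ImageSet:
    src = Path(in_dir)
    table = pd.read_csv(src / "labels.csv")
    for col in ("filename", "label"):
        if col not in table.columns:
            raise ValueError(f"labels.csv is missing required column {col!r}")
    if table["label"].isna().any():
        row = int(table["label"].isna().idxmax())
        raise ValueError(f"labels.csv row {row} has a missing label")
    imgs, labels = [], []
    for _, rec in table.iterrows():
        arr = np.asarray(Image.open(src / rec["filename"]), dtype=np.float32) / 255.0
        if arr.ndim == 2:
            arr = arr[:, :, None]
        imgs.append(arr)
        labels.append(int(rec["label"]))
    if "class_name" in table.columns:
        m = int(table["label"].max()) + 1
        names = [""] * m
        for _, rec in table.iterrows():
            names[int(rec["label"])] = str(rec["class_name"])
    else:
        names = [str(i) for i in range(int(table["label"].max()) + 1)]
    return ImageSet(np.stack(imgs), np.asarray(labels), names)


def write_imageset_h5(images: ImageSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images.images)
        f.create_dataset("labels", data=images.labels)
        f.attrs["class_names"] = [str(c) for c in images.class_names]


def read_imageset_h5(path: str | Path) -> ImageSet:
    with h5py.File(path, "r") as f:
        return ImageSet(
            f["images"][()], f["labels"][()], [str(c) for c in f.attrs["class_names"]]
        )


def write_recordingset(rec: RecordingSet, path: str | Path) -> None:
    """CSV for static recordings, HDF5 (suffix .h5/.hdf5) for temporal ones."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.create_dataset("alignment", data=rec.alignment)
            f.attrs["region_name"] = rec.region_name
            if rec.temporal:
                f.attrs["bin_width"] = rec.bin_width
                f.create_dataset("bin_onsets", data=rec.bin_onsets)
    else:
        if rec.temporal:
            raise ValueError("temporal recordings require an HDF5 path (.h5)")
        df = pd.DataFrame(rec.data, columns=[f"f{j}" for j in range(rec.d)])
        df.insert(0, "row", rec.alignment)
        df.to_csv(path, index=False)


def read_recordingset(path: str | Path, region_name: str | None = None) -> RecordingSet:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            kwargs = dict(
                region_name=region_name or str(f.attrs.get("region_name", "region")),
                alignment=f["alignment"][()],
            )
            if data.ndim == 3:
                kwargs["bin_width"] = float(f.attrs["bin_width"])
                kwargs["bin_onsets"] = f["bin_onsets"][()]
            return RecordingSet(data, **kwargs)
    df = pd.read_csv(path)
    if "row" not in df.columns:
        raise ValueError("static recording CSV must contain a 'row' column")
    align = df.pop("row").to_numpy()
    return RecordingSet(df.to_numpy(float), region_name=region_name or path.stem,
                        alignment=align)
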