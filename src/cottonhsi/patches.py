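"""Center-labeled spatial-spectral patch datasets and stratified splitting.

Each labeled (nonzero) pixel of a cube yields exactly one ``s x s x d``
patch centered on it, with mirror padding at the borders so that corner
pixels receive full-size patches without injecting out-of-scene values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import HsiCube, LabelMap

__all__ = ["PatchDataset", "extract_patches", "split_dataset", "save_dataset", "load_dataset"]


@dataclass
class PatchDataset:
    """Patches with center-pixel labels, centers, and a train/test split flag.

    ``patches`` has shape ``(n, s, s, d)``; ``labels`` the center-pixel class
    per patch (1..C); ``coords`` the (row, col) of each center; ``split`` is
    ``'train'``/``'test'`` per patch (empty string before splitting).
    """

    patches: np.ndarray
    labels: np.ndarray
    coords: np.ndarray
    patch_size: int
    class_names: list = field(default_factory=list)
    split: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.split is None:
            self.split = np.full(self.labels.shape[0], "", dtype="<U5")

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    def subset(self, which: str) -> tuple:
        """Return ``(patches, labels)`` of the requested split partition."""
        mask = self.split == which
        return self.patches[mask], self.labels[mask]

    @property
    def train(self) -> tuple:
        return self.subset("train")

    @property
    def test(self) -> tuple:
        return self.subset("test")


def mirror_pad(data: np.ndarray, margin: int) -> np.ndarray:
    """Reflect-pad the two spatial axes by ``margin`` pixels."""
    return np.pad(data, ((margin, margin), (margin, margin), (0, 0)), mode="reflect")


def extract_patches(cube: HsiCube, labels: LabelMap, s: int) -> PatchDataset:
    """One ``s x s x d`` patch per labeled pixel, centered on it.

    ``s`` must be odd and no larger than the smaller spatial dimension.
    Borders are mirror-padded by ``s // 2``.
    """
    if s % 2 == 0 or s < 1:
        raise ValueError(f"patch size must be a positive odd integer, got {s}")
    if s > min(cube.rows, cube.cols):
        raise ValueError(f"patch size {s} exceeds scene extent {cube.rows}x{cube.cols}")
    labels.check_matches(cube)
    rows_idx, cols_idx = np.nonzero(labels.labels)
    if rows_idx.size == 0:
        raise ValueError("label map has no labeled (nonzero) pixels")
    half = s // 2
    padded = mirror_pad(np.asarray(cube.data, dtype=np.float32), half)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (s, s), axis=(0, 1))
    # windows[r, c] is the patch centered at (r, c): shape (bands, s, s)
    pat = windows[rows_idx, cols_idx]  # (n, bands, s, s)
    pat = np.ascontiguousarray(pat.transpose(0, 2, 3, 1))  # (n, s, s, bands)
    y = labels.labels[rows_idx, cols_idx].astype(np.int64)
    coords = np.stack([rows_idx, cols_idx], axis=1)
    return PatchDataset(pat, y, coords, s, list(labels.class_names))


def split_dataset(dataset: PatchDataset, train_fraction: float, seed: int) -> PatchDataset:
    """Stratified train/test assignment, in place and returned.

    Per class the train count is ``round(fraction * class count)`` with a
    minimum of 1; the assignment is a deterministic function of ``seed``.
    Classes with no samples are skipped with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    split = np.full(len(dataset), "test", dtype="<U5")
    for cls in np.unique(dataset.labels):
        idx = np.nonzero(dataset.labels == cls)[0]
        n_train = max(1, int(np.rint(train_fraction * idx.size)))
        n_train = min(n_train, idx.size)
        chosen = rng.permutation(idx)[:n_train]
        split[chosen] = "train"
    dataset.split = split
    dataset.seed = seed
    return dataset


def save_dataset(dataset: PatchDataset, path: str) -> None:
    """Serialize to a compressed ``.npz`` container with an index."""
    np.savez_compressed(
        path,
        patches=dataset.patches,
        labels=dataset.labels,
        coords=dataset.coords,
        split=dataset.split,
        patch_size=np.array(dataset.patch_size),
        class_names=np.array(dataset.class_names, dtype=object),
        seed=np.array(-1 if dataset.seed is None else dataset.seed),
    )


def load_dataset(path: str) -> PatchDataset:
    with np.load(path, allow_pickle=True) as z:
        seed = int(z["seed"])
        return PatchDataset(
            patches=z["patches"],
            labels=z["labels"],
            coords=z["coords"],
            patch_size=int(z["patch_size"]),
            class_names=list(z["class_names"]),
            split=z["split"],
            seed=None if seed < 0 else seed,
        )
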