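"""Grayscale feature images and image datasets.

Per-channel ERDS maps (46 x 31) are concatenated horizontally in fixed
channel order into one grayscale image per 5-trial average:

* EEG-only:  9 channels -> 46 x 279
* EMG-only:  4 channels -> 46 x 124
* fused:     EEG then EMG -> 46 x 403

For transfer learning a single modality can be *padded* into the fused
layout: the present modality occupies its fused-layout columns and the
absent modality's columns are filled with zeros ("blank"), so one network
input shape (46 x 403 x 1) serves every condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neurofuse.erds import ERDSSpec, _erds_from_powers, compute_trial_powers, to_grayscale
from neurofuse.simulate import TrialSet

__all__ = [
    "FeatureImage",
    "ImageDataset",
    "assemble_image",
    "build_dataset",
    "LAYOUT_MODES",
]

LAYOUT_MODES = ("eeg_only", "emg_only", "fused", "eeg_padded", "emg_padded")

EEG_WIDTH_PER_CH = 31
EMG_WIDTH_PER_CH = 31


@dataclass
class FeatureImage:
    """A 46 x W grayscale matrix in [0, 1] with its column layout.

    ``layout`` lists (channel, modality, (col_start, col_stop)) entries;
    the ranges are disjoint and tile the width (padded blank regions are
    listed with channel ``"<blank>"``).
    """

    pixels: np.ndarray
    layout: list[tuple[str, str, tuple[int, int]]]
    label: int | None = None

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def assemble_image(eeg_maps: list[np.ndarray] | None,
                   emg_maps: list[np.ndarray] | None,
                   layout_mode: str,
                   eeg_channels: tuple[str, ...] = (),
                   emg_channels: tuple[str, ...] = (),
                   label: int | None = None) -> FeatureImage:
    """Concatenate per-channel grayscale maps into one feature image.

    ``eeg_maps``/``emg_maps`` are lists of (46, 31) matrices in fixed
    channel order.  In the padded modes the absent modality's columns are
    zero-filled to keep the fused 46 x 403 geometry.
    """
    if layout_mode not in LAYOUT_MODES:
        raise ValueError(f"layout_mode must be one of {LAYOUT_MODES}")

    def check(maps, chans, modality, per_ch):
        if len(chans) != len(maps):
            chans = tuple(f"{modality}{i}" for i in range(len(maps)))
        for name, m in zip(chans, maps):
            m = np.asarray(m)
            if m.ndim != 2 or m.shape[1] != per_ch:
                raise ValueError(
                    f"channel {name!r} ({modality}): expected (time, {per_ch}) "
                    f"grayscale map, got {m.shape}")
        return [np.asarray(m) for m in maps], chans

    blocks: list[np.ndarray] = []
    layout: list[tuple[str, str, tuple[int, int]]] = []
    col = 0

    def push(mat, name, modality):
        nonlocal col
        blocks.append(mat)
        layout.append((name, modality, (col, col + mat.shape[1])))
        col += mat.shape[1]

    need_eeg = layout_mode in ("eeg_only", "fused", "eeg_padded")
    need_emg = layout_mode in ("emg_only", "fused", "emg_padded")
    if need_eeg:
        if not eeg_maps:
            raise ValueError(f"layout {layout_mode!r} requires EEG maps")
        eeg_maps, eeg_channels = check(eeg_maps, eeg_channels, "eeg", EEG_WIDTH_PER_CH)
        nrows = eeg_maps[0].shape[0]
    if need_emg:
        if not emg_maps:
            raise ValueError(f"layout {layout_mode!r} requires EMG maps")
        emg_maps, emg_channels = check(emg_maps, emg_channels, "emg", EMG_WIDTH_PER_CH)
        nrows = emg_maps[0].shape[0]

    if layout_mode in ("eeg_only", "fused", "eeg_padded"):
        for name, m in zip(eeg_channels, eeg_maps):
            push(m, name, "eeg")
    elif layout_mode == "emg_padded":
        pad = np.zeros((nrows, 9 * EEG_WIDTH_PER_CH))
        push(pad, "<blank>", "eeg")
    if layout_mode in ("emg_only", "fused", "emg_padded"):
        for name, m in zip(emg_channels, emg_maps):
            push(m, name, "emg")
    elif layout_mode == "eeg_padded":
        pad = np.zeros((nrows, 4 * EMG_WIDTH_PER_CH))
        push(pad, "<blank>", "emg")

    return FeatureImage(pixels=np.concatenate(blocks, axis=1), layout=layout,
                        label=label)


@dataclass
class ImageDataset:
    """Feature images with labels, split assignment, and provenance.

    ``split`` holds ``"train"`` / ``"val"`` / ``"test"`` per image;
    ``provenance[i]`` lists the trial indices averaged into image i.
    """

    images: np.ndarray              # (n, 46, W)
    labels: np.ndarray              # (n,)
    split: np.ndarray               # (n,) of str
    provenance: list[np.ndarray]
    layout: list[tuple[str, str, tuple[int, int]]]
    layout_mode: str = "fused"

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.split)):
            raise ValueError("images, labels and split must have equal length")

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.split == which
        return self.images[sel], self.labels[sel]

    @property
    def width(self) -> int:
        return self.images.shape[2]

    def counts(self) -> dict[str, int]:
        return {k: int((self.split == k).sum()) for k in ("train", "val", "test")}


def _normalize_split(split) -> tuple[float, float, float]:
    if np.isscalar(split):
        tr = float(split)
        return tr, 0.0, 1.0 - tr
    vals = tuple(float(v) for v in split)
    if len(vals) == 2:
        vals = (vals[0], 0.0, vals[1])
    if len(vals) != 3 or abs(sum(vals) - 1.0) > 1e-9 or min(vals) < 0:
        raise ValueError("split must be train fraction or (train, val, test) "
                         "fractions summing to 1")
    return vals


def build_dataset(ts: TrialSet,
                  eeg_spec: ERDSSpec | None = None,
                  emg_spec: ERDSSpec | None = None,
                  layout_mode: str = "fused",
                  n_maps_per_class: int = 100,
                  split=0.7,
                  seed: int = 0,
                  clip_range: tuple[float, float] = (-100.0, 150.0),
                  strict_no_leakage: bool = False,
                  eeg_cache: np.ndarray | None = None,
                  emg_cache: np.ndarray | None = None,
                  trial_pools: dict | None = None) -> ImageDataset:
    """Build an image dataset of trial-averaged ERDS feature images.

    Per class, ``n_maps_per_class`` images are formed by drawing
    ``trials_per_map`` trials without replacement within each map
    (independently across maps), computing per-channel ERDS maps, and
    assembling them in ``layout_mode``.  Images are split train/val/test
    at the map level (default 70/30).  With ``strict_no_leakage`` the
    class's raw trials are first partitioned by the split fractions and
    each map draws only from its own partition, so no trial feeds both a
    train and a test image.

    Fully deterministic for a fixed ``seed``.
    """
    if layout_mode not in LAYOUT_MODES:
        raise ValueError(f"layout_mode must be one of {LAYOUT_MODES}")
    if eeg_spec is None:
        eeg_spec = ERDSSpec.eeg_preset()
    if emg_spec is None:
        emg_spec = ERDSSpec.emg_preset()
    if eeg_spec.trials_per_map != emg_spec.trials_per_map:
        raise ValueError("EEG and EMG specs must agree on trials_per_map")
    k = eeg_spec.trials_per_map
    fracs = _normalize_split(split)
    rng = np.random.default_rng(seed)

    need_eeg = layout_mode in ("eeg_only", "fused", "eeg_padded")
    need_emg = layout_mode in ("emg_only", "fused", "emg_padded")
    if need_eeg and eeg_cache is None:
        eeg_cache = compute_trial_powers(ts, eeg_spec, "eeg")
    if need_emg and emg_cache is None:
        emg_cache = compute_trial_powers(ts, emg_spec, "emg")

    classes = np.unique(ts.labels)
    images, labels, splits, prov = [], [], [], []
    for cls in classes:
        cls_trials = np.where(ts.labels == cls)[0]
        if len(cls_trials) < k:
            raise ValueError(
                f"class {cls}: {len(cls_trials)} trials < {k} needed per map")
        # split assignment at the map level
        n_tr = int(round(fracs[0] * n_maps_per_class))
        n_va = int(round(fracs[1] * n_maps_per_class))
        assign = np.array(["train"] * n_tr + ["val"] * n_va +
                          ["test"] * (n_maps_per_class - n_tr - n_va))
        rng.shuffle(assign)

        pools = {"train": cls_trials, "val": cls_trials, "test": cls_trials}
        if strict_no_leakage:
            if trial_pools is not None:
                # caller-supplied partition, shared across several datasets
                # built from the same recording (e.g. fused + padded layouts)
                pools = trial_pools[int(cls)]
            else:
                perm = rng.permutation(cls_trials)
                a = int(round(fracs[0] * len(perm)))
                b = a + int(round(fracs[1] * len(perm)))
                pools = {"train": perm[:a], "val": perm[a:b], "test": perm[b:]}
            for name, pool in pools.items():
                if (assign == name).any() and len(pool) < k:
                    raise ValueError(
                        f"strict split leaves class {cls} {name} pool with "
                        f"{len(pool)} trials < {k} needed per map")

        for part in assign:
            idx = rng.choice(pools[part], size=k, replace=False)
            eeg_maps = emg_maps = None
            if need_eeg:
                eeg_maps = [to_grayscale(
                    _erds_from_powers(eeg_cache[idx, c], eeg_spec,
                                      eeg_spec.power_floor), clip_range)
                    for c in range(eeg_cache.shape[1])]
            if need_emg:
                emg_maps = [to_grayscale(
                    _erds_from_powers(emg_cache[idx, c], emg_spec,
                                      emg_spec.power_floor), clip_range)
                    for c in range(emg_cache.shape[1])]
            img = assemble_image(eeg_maps, emg_maps, layout_mode,
                                 eeg_channels=ts.eeg_channel_names,
                                 emg_channels=ts.emg_channel_names,
                                 label=int(cls))
            images.append(img.pixels)
            labels.append(int(cls))
            splits.append(part)
            prov.append(idx)
            layout = img.layout

    return ImageDataset(images=np.asarray(images), labels=np.asarray(labels),
                        split=np.asarray(splits), provenance=prov,
                        layout=layout, layout_mode=layout_mode)
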