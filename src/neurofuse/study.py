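"""End-to-end synthetic studies: simulate -> preprocess -> features ->
{single-EEG, single-EMG, multimodal pretrain, TL-EEG, TL-EMG} -> evaluate.

Each seed plays the role of one subject: a fresh synthetic recording
session is simulated, feature-image datasets are built for every layout,
the five models are trained, and their test accuracies enter the report.
Across seeds the report runs the paired Wilcoxon signed-rank comparison of
transfer-learned EEG against single-modal EEG (and likewise for EMG).

The default simulation encodes the asymmetry the method targets: weakly
informative EEG (shallow ERD, low oscillation SNR) and strongly
informative EMG, so multimodal pretraining has something to transfer.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from neurofuse.classification import (
    ModelBundle,
    NetSpec,
    TrainConfig,
    build_network,
    predict,
    train,
    transfer_learn,
)
from neurofuse.erds import ERDSSpec, compute_trial_powers
from neurofuse.evaluation import PairedTestResult, accuracy, compare_paired
from neurofuse.images import LAYOUT_MODES, ImageDataset, build_dataset
from neurofuse.preprocessing import standard_chain
from neurofuse.simulate import (
    SimConfig,
    default_erd_depth,
    default_emg_gain,
    simulate_trialset,
)

logger = logging.getLogger("neurofuse")

MODEL_NAMES = ("single_eeg", "single_emg", "multimodal", "tl_eeg", "tl_emg")

__all__ = ["StudyConfig", "EvalReport", "run_study", "MODEL_NAMES"]


def weak_eeg_sim(seed: int = 0, trials_per_class: int = 60,
                 base_depth: float = 0.4, contrast: float = 0.5,
                 snr: float = 3.0, emg_gain: float = 3.0) -> SimConfig:
    """Simulation preset: weakly informative EEG, strongly informative EMG.

    All classes desynchronize the same motor channels (base ERD depth
    ``base_depth``), differing only by a small class-specific modulation
    (``contrast`` scales the somatotopic preference pattern).  This overlap
    is what makes single-modal EEG genuinely hard — mirroring real motor
    EEG, where wrist and hand movements engage largely the same cortex —
    while the EMG keeps its distinct per-muscle activation patterns.
    """
    pattern = default_erd_depth(depth=1.0)
    depth = np.clip(base_depth + contrast * (pattern - pattern.mean()),
                    0.0, 0.95)
    gain = default_emg_gain(gain=emg_gain)
    return SimConfig(trials_per_class=trials_per_class, erd_depth=depth,
                     emg_gain=gain, snr=snr, seed=seed)


@dataclass
class StudyConfig:
    """Everything one study run needs; fully determined by ``seed``."""

    sim: SimConfig = field(default_factory=lambda: weak_eeg_sim())
    eeg_spec: ERDSSpec = field(default_factory=ERDSSpec.eeg_preset)
    emg_spec: ERDSSpec = field(default_factory=ERDSSpec.emg_preset)
    net: NetSpec | None = None          # None -> full-size filter defaults per width
    small_net: bool = False             # low-capacity preset for quick studies
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    tl_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(learning_rate=3e-4))
    n_maps_per_class: int = 60
    split: tuple[float, float, float] = (0.7, 0.0, 0.3)
    clip_range: tuple[float, float] = (-100.0, 150.0)
    n_seeds: int = 10
    seed: int = 0
    models: tuple[str, ...] = MODEL_NAMES
    skip_tl: bool = False
    preprocess: bool = True
    ica_threshold: float = 5.0
    # test accuracies are only meaningful when no raw trial feeds both a
    # train and a test map; the unrestricted free draw is available by
    # switching this off
    strict_no_leakage: bool = True

    def config_hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]

    def active_models(self) -> tuple[str, ...]:
        models = self.models
        if self.skip_tl:
            models = tuple(m for m in models if not m.startswith("tl_"))
        return models


@dataclass
class EvalReport:
    """Per-seed, per-model accuracies plus nonparametric comparisons.

    ``table`` has one row per seed (synthetic subject) and one column per
    model, accuracies in percent.  ``comparisons`` maps a description to a
    :class:`PairedTestResult`.
    """

    table: pd.DataFrame
    comparisons: dict[str, PairedTestResult]
    confusions: dict[str, np.ndarray]
    config_hash: str
    seeds: list[int]

    def mean_accuracy(self, model: str) -> float:
        return float(self.table[model].mean())

    def summary(self) -> str:
        lines = ["Synthetic study report",
                 "======================",
                 f"config hash: {self.config_hash}",
                 f"seeds: {self.seeds}",
                 "",
                 "Mean accuracy (%) over seeds:"]
        for m in self.table.columns:
            lines.append(f"  {m:<12} {self.table[m].mean():6.2f} "
                         f"+- {self.table[m].std(ddof=1):.2f}")
        for name, r in self.comparisons.items():
            p = "degenerate" if r.degenerate else f"p={r.p_value:.4f}"
            lines.append(f"{name}: median diff {r.median_difference:+.2f} pp, "
                         f"Wilcoxon signed-rank {p} (n={r.n})")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="seed")

    def subject_table(self) -> pd.DataFrame:
        """Per-subject rows in the conventional column layout: single-modal
        EEG, multimodal EEG+EMG, transfer-learned EEG, and the EEG
        difference before/after transfer."""
        cols = {}
        if "single_eeg" in self.table:
            cols["single_modal_eeg"] = self.table["single_eeg"]
        if "multimodal" in self.table:
            cols["multimodal_eeg_emg"] = self.table["multimodal"]
        if "tl_eeg" in self.table:
            cols["transfer_learned_eeg"] = self.table["tl_eeg"]
        if "single_eeg" in self.table and "tl_eeg" in self.table:
            cols["eeg_difference"] = (self.table["tl_eeg"]
                                      - self.table["single_eeg"])
        return pd.DataFrame(cols, index=self.table.index)


def _build_all_datasets(cfg: StudyConfig, seed: int) -> dict[str, ImageDataset]:
    sim = replace(cfg.sim, seed=seed)
    ts = simulate_trialset(sim)
    if cfg.preprocess:
        ts, ica = standard_chain(ts, ica_threshold=cfg.ica_threshold, seed=seed)
        logger.info("seed %d: ICA rejected %s", seed, ica.rejected)

    needed_layouts: set[str] = set()
    models = cfg.active_models()
    if "single_eeg" in models:
        needed_layouts.add("eeg_only")
    if "single_emg" in models:
        needed_layouts.add("emg_only")
    if "multimodal" in models or "tl_eeg" in models or "tl_emg" in models:
        needed_layouts.add("fused")
    if "tl_eeg" in models:
        needed_layouts.add("eeg_padded")
    if "tl_emg" in models:
        needed_layouts.add("emg_padded")

    eeg_cache = emg_cache = None
    if needed_layouts - {"emg_only"}:
        eeg_cache = compute_trial_powers(ts, cfg.eeg_spec, "eeg")
    if needed_layouts - {"eeg_only"}:
        emg_cache = compute_trial_powers(ts, cfg.emg_spec, "emg")

    # one trial partition per recording, shared by every layout: if each
    # dataset partitioned independently, the fused-pretrained model would
    # have trained on raw trials that sit in the TL dataset's test pool,
    # and transfer would score above chance even on a null simulation
    trial_pools = None
    if cfg.strict_no_leakage:
        prng = np.random.default_rng(seed * 31 + 17)
        trial_pools = {}
        for cls in np.unique(ts.labels):
            perm = prng.permutation(np.where(ts.labels == cls)[0])
            a = int(round(cfg.split[0] * len(perm)))
            b = a + int(round(cfg.split[1] * len(perm)))
            trial_pools[int(cls)] = {"train": perm[:a], "val": perm[a:b],
                                     "test": perm[b:]}

    # the per-layout seed is derived from the layout NAME, so a dataset is
    # identical whether or not other layouts are built alongside it
    datasets = {}
    for layout in sorted(needed_layouts):
        datasets[layout] = build_dataset(
            ts, cfg.eeg_spec, cfg.emg_spec, layout_mode=layout,
            n_maps_per_class=cfg.n_maps_per_class, split=cfg.split,
            seed=seed * 31 + LAYOUT_MODES.index(layout),
            clip_range=cfg.clip_range,
            strict_no_leakage=cfg.strict_no_leakage,
            eeg_cache=eeg_cache, emg_cache=emg_cache,
            trial_pools=trial_pools)
    return datasets


def _netspec(cfg: StudyConfig, width: int) -> NetSpec:
    if cfg.net is not None:
        return cfg.net if cfg.net.input_shape[1] == width else \
            replace(cfg.net, input_shape=(cfg.net.input_shape[0], width,
                                          cfg.net.input_shape[2]))
    return NetSpec.small(width) if cfg.small_net else NetSpec.for_width(width)


def _fit_scratch(cfg: StudyConfig, ds: ImageDataset, seed: int) -> ModelBundle:
    """From-scratch training with a training-convergence fallback.

    SGDM at the default rate occasionally fails to leave the uniform
    plateau; when the fitted model cannot even fit its own training split
    (train accuracy < 50%), retry once at a tenth of the learning rate —
    the cheap stand-in for the per-subject learning-rate grid search.
    Only training metrics are consulted.
    """
    tc = cfg.train_cfg.replace(seed=seed)
    fitted = train(build_network(_netspec(cfg, ds.width), seed=seed), ds, tc)
    X_tr, y_tr = ds.subset("train")
    if accuracy(predict(fitted, X_tr)[0], y_tr) < 50.0:
        logger.info("seed %d: retraining at lr/10 (training did not converge)",
                    seed)
        tc = tc.replace(learning_rate=tc.learning_rate / 10)
        fitted = train(build_network(_netspec(cfg, ds.width), seed=seed), ds, tc)
    return fitted


def _test_accuracy(bundle: ModelBundle, ds: ImageDataset) -> tuple[float, np.ndarray]:
    X, y = ds.subset("test")
    pred, _ = predict(bundle, X)
    k = bundle.spec.n_classes
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y, pred), 1)
    return accuracy(pred, y), cm


def run_study(cfg: StudyConfig) -> EvalReport:
    """Run the full multi-seed study and return its :class:`EvalReport`."""
    models = cfg.active_models()
    rows: list[dict[str, float]] = []
    confusions = {m: None for m in models}
    seeds = [cfg.seed + s for s in range(cfg.n_seeds)]
    for seed in seeds:
        try:
            datasets = _build_all_datasets(cfg, seed)
        except Exception as e:
            raise RuntimeError(
                f"stage 'features' failed for seed {seed} "
                f"(config {cfg.config_hash()}): {e}") from e
        row: dict[str, float] = {}
        pretrained: ModelBundle | None = None
        try:
            if "multimodal" in models or not cfg.skip_tl and (
                    "tl_eeg" in models or "tl_emg" in models):
                ds = datasets["fused"]
                pretrained = _fit_scratch(cfg, ds, seed)
                pretrained.provenance = "pretrained_multimodal"
                if "multimodal" in models:
                    row["multimodal"], cm = _test_accuracy(pretrained, ds)
                    confusions["multimodal"] = cm if confusions["multimodal"] is None \
                        else confusions["multimodal"] + cm
            for name, layout in (("single_eeg", "eeg_only"),
                                 ("single_emg", "emg_only")):
                if name in models:
                    ds = datasets[layout]
                    fitted = _fit_scratch(cfg, ds, seed)
                    row[name], cm = _test_accuracy(fitted, ds)
                    confusions[name] = cm if confusions[name] is None \
                        else confusions[name] + cm
            for name, layout in (("tl_eeg", "eeg_padded"),
                                 ("tl_emg", "emg_padded")):
                if name in models:
                    ds = datasets[layout]
                    fitted = transfer_learn(pretrained, ds,
                                            cfg.tl_cfg.replace(seed=seed))
                    row[name], cm = _test_accuracy(fitted, ds)
                    confusions[name] = cm if confusions[name] is None \
                        else confusions[name] + cm
        except Exception as e:
            raise RuntimeError(
                f"stage 'classification' failed for seed {seed} "
                f"(config {cfg.config_hash()}): {e}") from e
        rows.append(row)
        logger.info("seed %d: %s", seed,
                    {k: f"{v:.1f}" for k, v in row.items()})

    table = pd.DataFrame(rows, index=seeds)[list(models)]
    comparisons: dict[str, PairedTestResult] = {}
    if "tl_eeg" in models and "single_eeg" in models and len(table) >= 5:
        comparisons["tl_eeg - single_eeg"] = compare_paired(
            table["tl_eeg"], table["single_eeg"])
    if "tl_emg" in models and "single_emg" in models and len(table) >= 5:
        comparisons["tl_emg - single_emg"] = compare_paired(
            table["tl_emg"], table["single_emg"])
    return EvalReport(table=table, comparisons=comparisons,
                      confusions={k: v for k, v in confusions.items() if v is not None},
                      config_hash=cfg.config_hash(), seeds=seeds)
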