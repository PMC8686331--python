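"""Alternating LSTM/SOM training and the recursive binary split schedule.

One *round* of training alternates three steps on random batches of 100
encoded mutations: (1) extract feature vectors, (2) run one frozen-layer
SOM batch update, which also feeds each input vector back opposite to the
aggregate unit motion, and (3) fit the extractor to the fed-back vectors
for 2 gradient passes.  The loop stops once the feature vectors of a
fixed probe subset stop moving (mean per-epoch displacement below a
tolerance) or at an epoch cap, after which the final feature vectors of
*all* samples are read out into exactly two groups.

The schedule applies rounds recursively: each of the 2^rounds leaves is
produced with a fresh extractor and fresh competition layer (derived
seeds), and afterwards the largest leaves are split one extra time.  With
3 rounds and 2 extra splits this yields the 10 mutation-blot classes,
numbered MB 1..k by decreasing size.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import AgglomerativeClustering, KMeans

from .feature_extractor import ExtractorConfig, FeatureExtractor
from .som import CompetitionLayer, SOMConfig, batch_update, init_layer
from .sbs_io import SBSRecord

logger = logging.getLogger(__name__)


@dataclass
class RoundConfig:
    """Configuration for a single binary training round.

    ``auto_sigma_scale``: if not None, the SOM neighborhood constant
    sigma is calibrated at layer initialization to this fraction of the
    mean distance of the first batch's feature vectors to their
    centroid, so the Gaussian decay acts at the scale the features
    actually occupy.  Set to None to use ``som.sigma`` verbatim.
    """

    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    som: SOMConfig = field(default_factory=SOMConfig)
    max_epochs: int = 100
    stability_tol: float = 2e-5
    probe_size: int = 256
    readout: str = "ward"  # or "kmeans" / "units"
    auto_sigma_scale: Optional[float] = 0.1
    seed: int = 0


@dataclass
class ScheduleConfig:
    rounds: int = 3
    extra_split_count: int = 2
    max_epochs_per_round: int = 100
    stability_tol: float = 2e-5
    batch_size: int = 100
    readout: str = "ward"
    auto_sigma_scale: Optional[float] = 0.1
    seed: int = 0
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    som: SOMConfig = field(default_factory=SOMConfig)

    def __post_init__(self) -> None:
        if self.rounds < 0 or self.extra_split_count < 0:
            raise ValueError("rounds and extra_split_count must be >= 0")


@dataclass
class MBLabeling:
    """Per-SBS mutation-blot assignment plus the split tree that made it.

    ``labels`` holds 1-based class numbers (MB 1..n_classes, numbered by
    decreasing leaf size, ties by tree path); ``tree`` records each
    binary split as (parent path, child sizes).
    """

    labels: np.ndarray
    n_classes: int
    tree: list[dict]
    leaf_paths: list[str]

    def label_names(self) -> list[str]:
        return [f"MB {k}" for k in range(1, self.n_classes + 1)]

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def to_frame(self, records: Sequence[SBSRecord]) -> pd.DataFrame:
        if len(records) != self.labels.size:
            raise ValueError("records/labels length mismatch")
        return pd.DataFrame(
            {
                "sample_barcode": [r.sample_barcode for r in records],
                "chromosome": [r.chromosome for r in records],
                "position": [r.position for r in records],
                "ref_allele": [r.ref_allele for r in records],
                "alt_allele": [r.alt_allele for r in records],
                "gene_symbol": [r.gene_symbol for r in records],
                "mb": [f"MB {k}" for k in self.labels],
            }
        )

    def write_tsv(self, records: Sequence[SBSRecord], path: str | Path) -> None:
        self.to_frame(records).to_csv(path, sep="\t", index=False)


def derive_seed(seed: int, *tags) -> int:
    """Stable sub-seed (< 2^31) from a root seed and a tag path."""
    digest = hashlib.sha256(
        ("/".join([str(seed), *map(str, tags)])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def binary_readout(features: np.ndarray, method: str = "ward",
                   seed: int = 0, layer: Optional[CompetitionLayer] = None
                   ) -> np.ndarray:
    """Split final feature vectors into exactly two groups.

    "ward": hierarchical 2-group Ward linkage on the features (default;
    merges whole point clouds before cutting, so it does not bisect a
    tight cluster the way a centroid method can).  "kmeans": 2-means
    directly on the features.  "units": 2-means on the competition
    units, samples assigned to their nearest unit's group.  Group 0 is
    always the larger group (ties: the group of the first sample),
    making the labeling canonical.
    """
    if method == "ward":
        groups = AgglomerativeClustering(
            n_clusters=2, linkage="ward"
        ).fit_predict(features)
    elif method == "kmeans":
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        groups = km.fit_predict(features)
    elif method == "units":
        if layer is None:
            raise ValueError("'units' readout needs the competition layer")
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        unit_groups = km.fit_predict(layer.units)
        d = ((features[:, None, :] - layer.units[None, :, :]) ** 2).sum(axis=2)
        groups = unit_groups[np.argmin(d, axis=1)]
    else:
        raise ValueError(f"unknown readout method {method!r}")
    n1 = int(groups.sum())
    n0 = groups.size - n1
    if n1 > n0 or (n1 == n0 and groups[0] == 1):
        groups = 1 - groups
    return groups.astype(np.int64)


def extract_in_chunks(extractor: FeatureExtractor, encodings: np.ndarray,
                      chunk: int = 1024) -> np.ndarray:
    parts = [
        extractor.extract_features(encodings[i:i + chunk])
        for i in range(0, encodings.shape[0], chunk)
    ]
    return np.concatenate(parts, axis=0)


def train_round(
    encodings: np.ndarray, config: Optional[RoundConfig] = None
) -> tuple[np.ndarray, dict]:
    """One round: alternate extractor/SOM training, then a binary readout.

    ``encodings`` is the (N, 2F+1, 4) stack of encoded mutations.
    Returns (group labels in {0,1} of length N, diagnostics dict).
    """
    config = config or RoundConfig()
    encodings = np.asarray(encodings, dtype=np.float64)
    N = encodings.shape[0]
    if N < 2:
        raise ValueError("need at least 2 samples to split")

    batch_size = config.som.batch_size
    if N < 2 * batch_size:
        batch_size = max(2, N // 2)
        logger.warning(
            "train_round: %d samples < 2 x batch, shrinking batch to %d",
            N, batch_size,
        )

    rng = np.random.default_rng(derive_seed(config.seed, "round"))
    extractor = FeatureExtractor(
        ExtractorConfig(
            **{**asdict(config.extractor), "seed": derive_seed(config.seed, "lstm")}
        )
    )
    som_cfg = SOMConfig(**{**asdict(config.som), "batch_size": batch_size,
                           "seed": derive_seed(config.seed, "som")})

    probe_idx = rng.choice(N, size=min(config.probe_size, N), replace=False)
    layer: Optional[CompetitionLayer] = None
    prev_probe: Optional[np.ndarray] = None
    displacement_history: list[float] = []
    converged = False
    epochs_run = 0

    for epoch in range(config.max_epochs):
        idx = rng.choice(N, size=batch_size, replace=False)
        feats = extractor.extract_features(encodings[idx])
        if layer is None:
            layer = init_layer(
                feats, som_cfg.n_units,
                np.random.default_rng(som_cfg.seed),
            )
            if config.auto_sigma_scale is not None:
                scale = float(
                    np.linalg.norm(feats - feats.mean(axis=0), axis=1).mean()
                )
                som_cfg.sigma = max(config.auto_sigma_scale * scale, 1e-12)
                logger.info("train_round: auto sigma = %.3g", som_cfg.sigma)
        result = batch_update(feats, layer, som_cfg)
        layer = result.updated_layer
        extractor.fit_to_labels(encodings[idx], result.updated_inputs)
        epochs_run = epoch + 1

        probe = extractor.extract_features(encodings[probe_idx])
        if prev_probe is not None:
            disp = float(np.linalg.norm(probe - prev_probe, axis=1).mean())
            displacement_history.append(disp)
            if disp < config.stability_tol:
                converged = True
                prev_probe = probe
                break
        prev_probe = probe

    if not converged:
        logger.warning(
            "train_round: no convergence after %d epochs (last displacement %s)",
            epochs_run,
            displacement_history[-1] if displacement_history else "n/a",
        )

    features = extract_in_chunks(extractor, encodings)
    groups = binary_readout(
        features, method=config.readout,
        seed=derive_seed(config.seed, "readout"), layer=layer,
    )
    diagnostics = {
        "converged": converged,
        "epochs": epochs_run,
        "displacement_history": displacement_history,
        "features": features,
        "extractor": extractor,
        "layer": layer,
    }
    return groups, diagnostics


MIN_SPLIT_SIZE = 4


def _split_leaf(encodings, indices, path, schedule) -> Optional[tuple]:
    if indices.size < MIN_SPLIT_SIZE:
        logger.warning("leaf %r too small to split (%d samples)", path, indices.size)
        return None
    cfg = RoundConfig(
        extractor=schedule.extractor,
        som=SOMConfig(**{**asdict(schedule.som), "batch_size": schedule.batch_size}),
        max_epochs=schedule.max_epochs_per_round,
        stability_tol=schedule.stability_tol,
        readout=schedule.readout,
        auto_sigma_scale=schedule.auto_sigma_scale,
        seed=derive_seed(schedule.seed, "leaf", path),
    )
    groups, _ = train_round(encodings[indices], cfg)
    left = indices[groups == 0]
    right = indices[groups == 1]
    if left.size == 0 or right.size == 0:  # degenerate readout
        logger.warning("leaf %r produced an empty side; kept intact", path)
        return None
    return left, right


def run_schedule(
    encodings: np.ndarray, schedule: Optional[ScheduleConfig] = None
) -> MBLabeling:
    """Recursive binary splitting into mutation-blot classes.

    ``rounds`` rounds of independent per-leaf splits (2^rounds leaves),
    then the ``extra_split_count`` largest leaves are split once more;
    defaults give the 10-class labeling.
    """
    schedule = schedule or ScheduleConfig()
    encodings = np.asarray(encodings, dtype=np.float64)
    N = encodings.shape[0]
    if N == 0:
        raise ValueError("no samples")

    leaves: list[tuple[str, np.ndarray]] = [("", np.arange(N))]
    tree: list[dict] = []

    for _ in range(schedule.rounds):
        next_leaves = []
        for path, indices in leaves:
            split = _split_leaf(encodings, indices, path, schedule)
            if split is None:
                next_leaves.append((path, indices))
                continue
            left, right = split
            tree.append(
                {"parent": path, "children": (path + "0", path + "1"),
                 "sizes": (int(left.size), int(right.size))}
            )
            next_leaves.append((path + "0", left))
            next_leaves.append((path + "1", right))
        leaves = next_leaves

    # extra round on the largest leaves (size desc, ties by path)
    order = sorted(range(len(leaves)),
                   key=lambda i: (-leaves[i][1].size, leaves[i][0]))
    extra = order[: schedule.extra_split_count]
    for i in sorted(extra):
        path, indices = leaves[i]
        split = _split_leaf(encodings, indices, path, schedule)
        if split is None:
            continue
        left, right = split
        tree.append(
            {"parent": path, "children": (path + "0", path + "1"),
             "sizes": (int(left.size), int(right.size))}
        )
        leaves[i] = (path + "0", left)
        leaves.append((path + "1", right))

    # MB numbering: by leaf size descending, ties by path
    leaves.sort(key=lambda leaf: (-leaf[1].size, leaf[0]))
    labels = np.zeros(N, dtype=np.int64)
    for mb, (_, indices) in enumerate(leaves, start=1):
        labels[indices] = mb
    return MBLabeling(
        labels=labels,
        n_classes=len(leaves),
        tree=tree,
        leaf_paths=[path for path, _ in leaves],
    )


def write_run_manifest(path: str | Path, schedule: ScheduleConfig,
                       extra: Optional[dict] = None) -> None:
    """Echo all seeds and configuration of a run into a YAML manifest."""
    payload = {"schedule": asdict(schedule)}
    if extra:
        payload.update(extra)
    Path(path).write_text(yaml.safe_dump(payload))
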