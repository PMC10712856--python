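"""Seeded synthetic data emulating the study's simulation design.

A sparse binary GLM: covariates are i.i.d. standard normal, the true
coefficient vector has ``s`` nonzero entries of magnitude
``beta_magnitude`` with random signs at seeded random positions (the rest
exactly zero), and labels are Bernoulli draws through the chosen link.
Label noise is class-conditional flipping: within each observed class c,
floor(rho * n_c) samples are chosen uniformly without replacement and their
labels flipped, with the flipped set recorded in ``flip_mask``.

The simulation grid of interest pairs training sizes 200x500, 500x1000 and
1000x1500 (n x d, so n < d throughout) with flip ratios 0.1 through 0.8.
Datasets round-trip through plain CSV (feature columns f1..fd, then
y_observed and optionally y_true / flip_mask) with a JSON sidecar recording
the generating spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .glm_core import Dataset, success_prob

__all__ = [
    "SimulationSpec",
    "generate_clean",
    "flip_labels",
    "train_test_split",
    "save_dataset_csv",
    "load_dataset_csv",
    "load_breast_cancer_csv",
]

# The (n_train, n_test, d) grid used throughout the simulation study.
GRID_DIMENSIONS = ((200, 100, 500), (500, 200, 1000), (1000, 200, 1500))
NOISE_RATIOS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic draw.

    ``s`` true nonzero coefficients of size ``beta_magnitude`` (random
    signs); ``noise_ratio`` is the per-class flip fraction applied to both
    the training and the test set (with independent seeded streams).
    """

    n_train: int = 500
    n_test: int = 200
    d: int = 1000
    s: int = 10
    beta_magnitude: float = 1.0
    link: str = "logit"
    noise_ratio: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 0 or self.d < 1:
            raise ValueError("n_train, d must be positive; n_test nonnegative")
        if not 1 <= self.s <= self.d:
            raise ValueError(f"s must lie in [1, d], got s={self.s}, d={self.d}")
        if not self.beta_magnitude >= 0:
            raise ValueError("beta_magnitude must be nonnegative")
        if not 0.0 <= self.noise_ratio < 1.0:
            raise ValueError("noise_ratio must lie in [0, 1)")


def _draw(rng: np.random.Generator, n: int, beta: np.ndarray, link: str) -> Dataset:
    X = rng.standard_normal((n, beta.shape[0]))
    pi = success_prob(X, beta, link) if np.any(beta) else np.full(n, 0.5)
    y = rng.binomial(1, pi).astype(np.int8)
    return Dataset(X=X, y_observed=y, y_true=y.copy(),
                   flip_mask=np.zeros(n, dtype=bool))


def generate_clean(spec: SimulationSpec) -> tuple[Dataset, Dataset, np.ndarray]:
    """Generate (train, test, beta_true) with no label noise applied yet."""
    rng = np.random.default_rng(spec.seed)
    beta_true = np.zeros(spec.d)
    support = rng.choice(spec.d, size=spec.s, replace=False)
    signs = rng.choice((-1.0, 1.0), size=spec.s)
    beta_true[support] = signs * spec.beta_magnitude
    train = _draw(rng, spec.n_train, beta_true, spec.link)
    test = _draw(rng, spec.n_test, beta_true, spec.link)
    return train, test, beta_true


def flip_labels(dataset: Dataset, rho: float, seed: int) -> Dataset:
    """Class-conditional label flipping at ratio rho.

    Within each observed class c, floor(rho * n_c) samples are selected
    uniformly without replacement (seeded) and their labels flipped.
    ``y_true`` is preserved; ``flip_mask`` records disagreement with it.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    y = dataset.y_observed.copy()
    for c in (0, 1):
        members = np.flatnonzero(dataset.y_observed == c)
        k = int(np.floor(rho * members.size))
        if k > 0:
            chosen = rng.choice(members, size=k, replace=False)
            y[chosen] = 1 - y[chosen]
    y_true = dataset.y_true if dataset.y_true is not None else dataset.y_observed
    return Dataset(X=dataset.X, y_observed=y, y_true=y_true.copy(),
                   flip_mask=y != y_true, feature_names=dataset.feature_names)


def train_test_split(dataset: Dataset, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[Dataset, Dataset]:
    """Seeded uniform split; train gets floor(train_fraction * n) rows."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n_train = int(np.floor(train_fraction * dataset.n))
    if n_train == 0 or n_train == dataset.n:
        raise ValueError(f"degenerate split sizes for n={dataset.n}, "
                         f"fraction={train_fraction}")
    perm = np.random.default_rng(seed).permutation(dataset.n)
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _feature_frame(dataset: Dataset) -> pd.DataFrame:
    names = (list(dataset.feature_names) if dataset.feature_names is not None
             else [f"f{j + 1}" for j in range(dataset.d)])
    df = pd.DataFrame(dataset.X, columns=names)
    df["y_observed"] = dataset.y_observed
    if dataset.y_true is not None:
        df["y_true"] = dataset.y_true
    if dataset.flip_mask is not None:
        df["flip_mask"] = dataset.flip_mask.astype(int)
    return df


def save_dataset_csv(dataset: Dataset, path: Union[str, Path],
                     spec: Optional[SimulationSpec] = None) -> None:
    """Write the dataset as CSV plus a JSON sidecar with spec metadata."""
    path = Path(path)
    _feature_frame(dataset).to_csv(path, index=False)
    meta = {"n": dataset.n, "d": dataset.d,
            "spec": asdict(spec) if spec is not None else None}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_dataset_csv(path: Union[str, Path]) -> Dataset:
    df = pd.read_csv(path)
    label_cols = [c for c in ("y_observed", "y_true", "flip_mask") if c in df.columns]
    if "y_observed" not in label_cols:
        raise ValueError(f"{path}: missing required column 'y_observed'")
    feats = [c for c in df.columns if c not in label_cols]
    return Dataset(
        X=df[feats].to_numpy(dtype=float),
        y_observed=df["y_observed"].to_numpy(),
        y_true=df["y_true"].to_numpy() if "y_true" in df else None,
        flip_mask=df["flip_mask"].to_numpy(dtype=bool) if "flip_mask" in df else None,
        feature_names=feats,
    )


def load_breast_cancer_csv(path: Union[str, Path],
                           label_column: str = "diagnosis",
                           positive_label: str = "M") -> Dataset:
    """Load a user-supplied copy of the UCI breast-cancer diagnostic table.

    No download is performed; the caller provides a local CSV with a header
    row.  The label column (malignant/benign) is mapped to 1/0 and an 'id'
    column, if present, is dropped.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"{path}: missing label column {label_column!r}")
    y = (df[label_column].astype(str) == positive_label).astype(int).to_numpy()
    feats = [c for c in df.columns if c not in (label_column, "id", "ID")]
    return Dataset(X=df[feats].to_numpy(dtype=float), y_observed=y,
                   feature_names=feats)
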