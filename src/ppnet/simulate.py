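"""Synthetic two-modality datasets with controllable node- and edge-level signal.

Samples are drawn from class-conditional multivariate Gaussians.  Node-level
signal is a mean shift on a designated subset of features; edge-level signal
is a class-dependent equicorrelated block in the covariance.  The two are
orthogonal by construction, so a classifier that only looks at feature
values (node level) sees nothing when only the correlation differs between
two balanced classes, while a classifier built on co-expression (edge
level) sees nothing when only the means differ.

With ``shared_block_factor`` the correlated block of the two modalities is
driven by one latent factor per sample, which also induces cross-modality
correlation of the same strength — the situation where early fusion can
select edges linking features of different modalities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import FeatureMatrix, LabelVector, ValidationError

CLASS_NAMES = ("case", "control")


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of one simulated two-class, two-modality dataset.

    ``block_rho`` gives the within-block correlation per class; the block
    spans the first ``block_size`` features of each modality.  The mean
    shift is applied, for the first class only, to the ``n_shift`` features
    following the block, so node and edge signal never share a feature.
    """

    n_train: int = 100          # per class
    n_test: int = 50            # per class
    p_a: int = 30               # features in modality "a"
    p_b: int = 30               # features in modality "b"
    mean_shift: float = 0.0
    n_shift: int = 10
    block_size: int = 10
    block_rho: tuple[float, float] = (0.0, 0.0)   # per-class correlation
    noise_sd: float = 1.0
    shared_block_factor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in self.block_rho:
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"correlation {rho} outside (-1, 1)")
            if self.shared_block_factor and rho < 0:
                raise ValidationError("shared-factor blocks require rho >= 0")
        for p in (self.p_a, self.p_b):
            if self.block_size > p:
                raise ValidationError("block size exceeds modality feature count")
            if self.block_size + self.n_shift > p:
                raise ValidationError("block and shifted features overlap")
        if self.n_train < 2 or self.n_test < 2:
            raise ValidationError("need >= 2 samples per class per split")
        if self.mean_shift < 0:
            raise ValidationError("mean shift must be nonnegative")
        for rho in self.block_rho:
            _class_cov(max(self.p_a, self.p_b), self.block_size, rho, self.noise_sd)


def _class_cov(p: int, block: int, rho: float, sd: float) -> np.ndarray:
    cov = np.eye(p)
    cov[:block, :block] = rho
    np.fill_diagonal(cov, 1.0)
    cov *= sd ** 2
    # equicorrelated blocks with rho > -1/(block-1) are positive definite
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            f"covariance block (size={block}, rho={rho}) is not positive definite"
        ) from exc
    return cov


def _feature_names(tag: str, p: int) -> list[str]:
    return [f"{tag.upper()}{k:03d}" for k in range(p)]


def simulate_dataset(spec: SimulationSpec):
    """Draw a dataset from the spec.

    Returns ``(train, test, labels_train, labels_test)`` where ``train`` and
    ``test`` map modality name ("a", "b") to a :class:`FeatureMatrix`.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = {"train": spec.n_train, "test": spec.n_test}
    modalities = (("a", spec.p_a), ("b", spec.p_b))

    chol = {
        tag: [
            np.linalg.cholesky(_class_cov(p, spec.block_size, rho, spec.noise_sd))
            for rho in spec.block_rho
        ]
        for tag, p in modalities
    }

    out = {"train": {}, "test": {}}
    labels = {}
    counter = 0
    for split, n in sizes.items():
        ids, labs = [], []
        per_class_x = {tag: [] for tag, _ in modalities}
        for ci, cls in enumerate(CLASS_NAMES):
            ids += [f"{split[:2]}{counter + k:04d}" for k in range(n)]
            labs += [cls] * n
            counter += n
            rho = spec.block_rho[ci]
            factor = rng.standard_normal(n) if spec.shared_block_factor else None
            for tag, p in modalities:
                if spec.shared_block_factor and rho > 0:
                    x = rng.standard_normal((n, p))
                    b = spec.block_size
                    x[:, :b] = (
                        np.sqrt(rho) * factor[:, None]
                        + np.sqrt(1.0 - rho) * x[:, :b]
                    )
                    x *= spec.noise_sd
                else:
                    z = rng.standard_normal((n, p))
                    x = z @ chol[tag][ci].T
                if ci == 0 and spec.mean_shift > 0:
                    lo = spec.block_size
                    x[:, lo:lo + spec.n_shift] += spec.mean_shift
                per_class_x[tag].append(x)
        labels[split] = LabelVector(pd.Series(labs, index=ids, name="label"))
        for tag, p in modalities:
            df = pd.DataFrame(
                np.vstack(per_class_x[tag]), index=ids, columns=_feature_names(tag, p)
            )
            out[split][tag] = FeatureMatrix(df, modality=tag)

    return out["train"], out["test"], labels["train"], labels["test"]


def fixture_suite(seed: int = 0) -> dict:
    """Named small datasets covering the node/edge signal combinations.

    Keys: ``node_signal_only``, ``edge_signal_only``, ``both_signals``,
    ``null``.  Each value is the 4-tuple returned by
    :func:`simulate_dataset`.
    """
    specs = {
        "node_signal_only": SimulationSpec(
            n_train=150, n_test=50, mean_shift=2.0, block_rho=(0.0, 0.0), seed=seed
        ),
        "edge_signal_only": SimulationSpec(
            n_train=150, n_test=50, mean_shift=0.0, block_rho=(0.8, 0.0),
            seed=seed + 1,
        ),
        "both_signals": SimulationSpec(
            n_train=150, n_test=50, mean_shift=2.0, block_rho=(0.8, 0.0),
            shared_block_factor=True, seed=seed + 2,
        ),
        "null": SimulationSpec(
            n_train=60, n_test=40, mean_shift=0.0, block_rho=(0.0, 0.0), seed=seed + 3
        ),
    }
    return {name: simulate_dataset(s) for name, s in specs.items()}
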