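"""Synthetic paired-view generator with known sparse nonnegative loadings.

Emulates the structure sparse CCA assumes: each latent factor is a per-sample
score shared by both views, expressed in each view through a sparse,
nonnegative, unit-norm loading vector, plus independent Gaussian noise.  For
one factor with strength ``signal`` and noise sd ``noise_sd``, the population
correlation between the two views' best projections is
``signal**2 / (signal**2 + noise_sd**2)`` — the defaults (3.0, 1.0) put it at
0.9, the magnitude regime of drug-response perfusion studies this generator
stands in for (the real scans are not redistributable).

Support sizes may differ between views (``s1 != s2``), emulating drugs with
unequal spatial extent of effect; supports of distinct factors are disjoint
within a view.  A "spatial" variant lays supports out as contiguous blocks so
that fixtures written as masked volumes look like compact clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticTruth",
    "generate_paired_views",
    "generate_null_views",
    "support_metrics",
    "export_nifti_fixture",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one latent factor: unit nonnegative loading vectors
    with known support, the per-sample latent scores, and the noise level."""

    u_true: np.ndarray
    v_true: np.ndarray
    latent: np.ndarray
    noise_sd: float
    seed: int | None
    index: int = 1

    @property
    def support_u(self) -> np.ndarray:
        return np.flatnonzero(self.u_true)

    @property
    def support_v(self) -> np.ndarray:
        return np.flatnonzero(self.v_true)


def _supports(p: int, s: int, n_factors: int, rng: np.random.Generator,
              spatial: bool) -> list[np.ndarray]:
    if s * n_factors > p:
        raise ValueError(
            f"cannot place {n_factors} disjoint supports of size {s} in {p} features"
        )
    if spatial:
        # contiguous blocks at the start of equal-width chunks
        chunk = p // n_factors
        return [np.arange(f * chunk, f * chunk + s) for f in range(n_factors)]
    pool = rng.permutation(p)[: s * n_factors]
    return [np.sort(pool[f * s : (f + 1) * s]) for f in range(n_factors)]


def _loading(p: int, support: np.ndarray, rng: np.random.Generator,
             nonnegative: bool) -> np.ndarray:
    w = np.zeros(p)
    vals = 1.0 - rng.uniform(0.0, 0.5, size=support.size)  # in (0.5, 1]
    if not nonnegative:
        vals *= rng.choice([-1.0, 1.0], size=support.size)
    w[support] = vals
    return w / np.linalg.norm(w)


def generate_paired_views(
    n: int = 50,
    p1: int = 500,
    p2: int = 500,
    s1: int = 10,
    s2: int = 10,
    signal: float = 3.0,
    noise_sd: float = 1.0,
    n_factors: int = 1,
    seed: int | None = None,
    *,
    nonnegative: bool = True,
    spatial: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[SyntheticTruth]]:
    """Raw (unstandardized) paired views sharing sparse latent factors.

    ``X_k = sum_f signal * latent_f loading_fk' + noise``, with
    ``latent_f ~ N(0, 1)`` per sample and independent ``N(0, noise_sd^2)``
    noise in each view.  Returns the two matrices plus one
    :class:`SyntheticTruth` per factor.  Identical seeds give bit-identical
    output.
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    if signal < 0 or noise_sd < 0:
        raise ValueError("signal and noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    sup1 = _supports(p1, s1, n_factors, rng, spatial)
    sup2 = _supports(p2, s2, n_factors, rng, spatial)
    X1 = np.zeros((n, p1))
    X2 = np.zeros((n, p2))
    truths: list[SyntheticTruth] = []
    for f in range(n_factors):
        latent = rng.standard_normal(n)
        u = _loading(p1, sup1[f], rng, nonnegative)
        v = _loading(p2, sup2[f], rng, nonnegative)
        X1 += signal * np.outer(latent, u)
        X2 += signal * np.outer(latent, v)
        truths.append(
            SyntheticTruth(u_true=u, v_true=v, latent=latent,
                           noise_sd=noise_sd, seed=seed, index=f + 1)
        )
    X1 += rng.normal(0.0, noise_sd, size=(n, p1)) if noise_sd > 0 else 0.0
    X2 += rng.normal(0.0, noise_sd, size=(n, p2)) if noise_sd > 0 else 0.0
    return X1, X2, truths


def generate_null_views(
    n: int, p1: int, p2: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Independent standard-normal views: no inter-view association."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, p1)), rng.standard_normal((n, p2))


def support_metrics(w: np.ndarray, w_true: np.ndarray) -> dict[str, float]:
    """Support-recovery scores of an estimated weight vector against the
    true loading: sensitivity (recall on the true support), specificity
    (true-negative rate off support), and F1 of support membership.

    Both vectors must live in the same feature space; pass the inflated
    estimate when zero-variance columns were dropped.
    """
    w = np.asarray(w)
    w_true = np.asarray(w_true)
    if w.shape != w_true.shape:
        raise ValueError("weight vectors must have the same length")
    est = w != 0
    true = w_true != 0
    tp = int(np.count_nonzero(est & true))
    fp = int(np.count_nonzero(est & ~true))
    fn = int(np.count_nonzero(~est & true))
    tn = int(np.count_nonzero(~est & ~true))
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    f1 = 2 * tp / max(2 * tp + fp + fn, 1)
    return {"sensitivity": sens, "specificity": spec, "f1": f1}


def export_nifti_fixture(
    out_dir: str | Path,
    shape: tuple[int, int, int] = (10, 10, 10),
    *,
    n: int = 20,
    p1: int = 200,
    p2: int = 200,
    s1: int = 5,
    s2: int = 5,
    signal: float = 3.0,
    noise_sd: float = 1.0,
    n_factors: int = 1,
    seed: int | None = 0,
) -> dict[str, Path]:
    """Write a tiny masked-volume dataset: per-subject 3-D volumes for each
    view, a binary mask per view, image-list files, and a JSON truth sidecar.

    In-mask voxels are the first ``p`` grid positions in C order, matching
    the column order the reader uses, so fixture matrices and ingested
    matrices coincide exactly.  Supports are laid out as contiguous blocks
    (``spatial=True``) so weight maps show compact clusters.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nvox = int(np.prod(shape))
    if max(p1, p2) > nvox:
        raise ValueError(f"grid {shape} holds only {nvox} voxels")
    X1, X2, truths = generate_paired_views(
        n=n, p1=p1, p2=p2, s1=s1, s2=s2, signal=signal, noise_sd=noise_sd,
        n_factors=n_factors, seed=seed, spatial=True,
    )
    affine = np.eye(4)
    paths: dict[str, Path] = {}
    for view, X, p in (("x1", X1, p1), ("x2", X2, p2)):
        mask = np.zeros(nvox)
        mask[:p] = 1.0
        mask_path = out_dir / f"{view}_mask.nii"
        nib.save(nib.Nifti1Image(mask.reshape(shape), affine), mask_path)
        paths[f"{view}_mask"] = mask_path
        img_paths = []
        for i in range(n):
            vol = np.zeros(nvox)
            vol[:p] = X[i]
            path = out_dir / f"{view}_sub{i:03d}.nii"
            nib.save(nib.Nifti1Image(vol.reshape(shape), affine), path)
            img_paths.append(path)
        list_path = out_dir / f"{view}_images.txt"
        list_path.write_text("".join(f"{p_}\n" for p_ in img_paths))
        paths[f"{view}_list"] = list_path
    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seed": seed,
                "shape": list(shape),
                "factors": [
                    {
                        "index": t.index,
                        "support_u": t.support_u.tolist(),
                        "support_v": t.support_v.tolist(),
                        "u_true": t.u_true.tolist(),
                        "v_true": t.v_true.tolist(),
                        "noise_sd": t.noise_sd,
                    }
                    for t in truths
                ],
            },
            indent=1,
        )
    )
    paths["truth"] = truth_path
    return paths
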