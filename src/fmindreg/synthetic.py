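"""Synthetic multi-modal registration cases with exact ground truth.

Emulates a download-free evaluation protocol: a structured phantom volume,
a second "modality" of the same anatomy obtained by a nonlinear intensity
remap plus noise, a smooth ground-truth deformation built as a linear
combination of Gaussian radial basis functions, and automatically picked
high-gradient landmarks.  The float image is constructed so that the exact
recovery field (the one a perfect registration would estimate) equals the
sampled RBF field at every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .pipeline import LandmarkSet
from .transform import DeformationField, invert_displacement, warp

REMAP_MODES = ("identity", "invert", "gamma", "nonmonotone-bands")

#: Knots of the non-monotone piecewise-linear intensity transfer function.
#: Deliberately folds the intensity axis so no monotone mapping relates the
#: two modalities, the regime self-similarity descriptors are built for.
_BAND_X = (0.0, 0.25, 0.5, 0.75, 1.0)
_BAND_Y = (0.9, 0.2, 0.8, 0.1, 0.6)

_GAMMA = 2.2


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic registration case."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_blobs: int = 12
    remap_mode: str = "nonmonotone-bands"
    noise_sigma: float = 0.02
    n_centers: int = 10
    amplitude: float = 4.0
    rbf_sigma: float = 24.0
    seed: int = 0


def make_phantom(spec: SyntheticSpec) -> np.ndarray:
    """Structured phantom: smooth blobs and sharp-edged ellipsoids on a low
    background, rescaled to [0, 1].  Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    vol = np.full(shape, 0.1)
    coords = np.indices(shape, dtype=float)
    for b in range(spec.n_blobs):
        center = rng.uniform(0.15, 0.85, size=3) * np.asarray(shape)
        radii = rng.uniform(0.06, 0.18, size=3) * np.asarray(shape)
        amp = rng.uniform(0.3, 1.0)
        q = sum(((coords[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        if b % 2 == 0:
            vol += amp * np.exp(-0.5 * q * 4.0)  # smooth blob
        else:
            vol += amp * ndimage.gaussian_filter((q <= 1.0).astype(float), 1.0)
    lo, hi = vol.min(), vol.max()
    if hi > lo:
        vol = (vol - lo) / (hi - lo)
    return vol


def remap_modality(
    volume: np.ndarray, remap_mode: str, noise_sigma: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Voxelwise intensity transfer plus Gaussian noise, clipped to [0, 1]."""
    volume = np.asarray(volume, dtype=float)
    if remap_mode == "identity":
        out = volume.copy()
    elif remap_mode == "invert":
        out = 1.0 - volume
    elif remap_mode == "gamma":
        out = np.clip(volume, 0.0, 1.0) ** _GAMMA
    elif remap_mode == "nonmonotone-bands":
        out = np.interp(volume, _BAND_X, _BAND_Y)
    else:
        raise InvalidArgumentError(
            f"unknown remap mode {remap_mode!r}; choose from {REMAP_MODES}"
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def rbf_displacement_at(points, centers, weights, rbf_sigma) -> np.ndarray:
    """Unscaled RBF field sampled at points: sum_k w_k exp(-|x-c_k|^2 / 2 sigma^2)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-d2 / (2.0 * rbf_sigma**2))
    return phi @ weights


def sample_rbf_deformation(
    shape, n_centers: int, amplitude: float, rbf_sigma: float, seed: int = 0
) -> DeformationField:
    """Smooth ground-truth warp: linear combination of Gaussian RBFs.

    Random centers and per-component weights; the field is globally scaled
    so the maximum displacement magnitude over the volume equals
    ``amplitude`` (zero amplitude gives the identity field).
    """
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be non-negative")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, 1.0, size=(n_centers, 3)) * np.asarray(shape)
    weights = rng.standard_normal((n_centers, 3))
    disp = np.zeros(shape + (3,))
    coords = np.indices(shape, dtype=float)
    for k in range(n_centers):
        d2 = sum((coords[a] - centers[k, a]) ** 2 for a in range(3))
        phi = np.exp(-d2 / (2.0 * rbf_sigma**2))
        disp += phi[..., None] * weights[k][None, None, None, :]
    mags = np.linalg.norm(disp, axis=3)
    peak = float(mags.max())
    if amplitude == 0.0 or peak == 0.0:
        return DeformationField(displacements=np.zeros(shape + (3,)))
    return DeformationField(displacements=disp * (amplitude / peak))


def pick_landmarks(
    volume: np.ndarray,
    n: int,
    seed: int = 0,
    min_distance: float = 3.0,
    margin: int = 4,
) -> LandmarkSet:
    """Pick ``n`` distinct high-gradient voxels as evaluation landmarks.

    Candidates are voxels in the top decile of gradient magnitude, at least
    ``margin`` voxels from the boundary; a shuffled greedy pass enforces the
    minimum mutual distance.  Deterministic per seed.
    """
    if n < 1:
        raise InvalidArgumentError("need at least one landmark")
    volume = np.asarray(volume, dtype=float)
    gm = np.linalg.norm(np.stack(np.gradient(volume)), axis=0)
    thr = np.percentile(gm, 90.0)
    ok = gm >= thr
    inner = np.zeros_like(ok)
    sl = tuple(slice(margin, s - margin) for s in volume.shape)
    inner[sl] = True
    cand = np.argwhere(ok & inner)
    if len(cand) < n:
        raise InvalidArgumentError(
            f"only {len(cand)} candidate voxels for {n} landmarks"
        )
    rng = np.random.default_rng(seed)
    cand = cand[rng.permutation(len(cand))]
    chosen: list[np.ndarray] = []
    for p in cand:
        if all(np.linalg.norm(p - q) >= min_distance for q in chosen):
            chosen.append(p)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise InvalidArgumentError(
            f"could not place {n} landmarks at min distance {min_distance}"
        )
    return LandmarkSet(points=np.asarray(chosen, dtype=float))


@dataclass
class SyntheticCase:
    reference: np.ndarray
    float_img: np.ndarray
    true_field: DeformationField  # exact recovery field at every voxel
    landmarks: LandmarkSet
    spec: SyntheticSpec


def make_registration_case(spec: SyntheticSpec, n_landmarks: int = 30) -> SyntheticCase:
    """Full case: phantom reference, remapped+warped float, exact ground truth.

    The float image is the remapped phantom warped by the *inverse* of the
    sampled RBF field, so that pulling the float back through the RBF field
    reproduces the remapped phantom exactly (up to interpolation): the RBF
    field itself is the ground-truth recovery deformation compared against
    the registration estimate.
    """
    phantom = make_phantom(spec)
    modal = remap_modality(phantom, spec.remap_mode, spec.noise_sigma, seed=spec.seed + 1)
    # both scans of a real protocol carry acquisition noise; the reference
    # keeps its own modality but gets an independent noise realization
    ref = remap_modality(phantom, "identity", spec.noise_sigma, seed=spec.seed + 4)
    t_true = sample_rbf_deformation(
        spec.shape, spec.n_centers, spec.amplitude, spec.rbf_sigma, seed=spec.seed + 2
    )
    inv = invert_displacement(t_true)
    float_img = warp(modal, inv)
    # landmarks sit on the clean phantom's strong gradients
    landmarks = pick_landmarks(phantom, n_landmarks, seed=spec.seed + 3)
    return SyntheticCase(
        reference=ref,
        float_img=float_img,
        true_field=t_true,
        landmarks=landmarks,
        spec=spec,
    )
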