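"""Synthetic cohorts with known ground-truth Hurst structure.

Per-voxel BOLD series are simulated as unit-variance fractional Gaussian
noise (fGn) — the stationary increment process of fractional Brownian
motion — plus additive white measurement noise.  A healthy-control (HC)
baseline Hurst exponent applies everywhere except in a configurable set of
"affected" atlas regions, where the patient (MCI) group receives a shifted
exponent.  Because the generative law is exact, the cohort doubles as the
oracle for the rescaled-range estimator downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .exceptions import EmbeddingFallbackWarning, InvalidParameterError

__all__ = [
    "FgnParams",
    "SyntheticCohortSpec",
    "CohortData",
    "fgn_autocovariance",
    "simulate_fgn",
    "simulate_fgn_batch",
    "build_block_atlas",
    "simulate_cohort",
]


@dataclass(frozen=True)
class FgnParams:
    """Parameters of a fractional Gaussian noise draw."""

    H: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        _check_h(self.H)
        if self.n < 2:
            raise InvalidParameterError(f"series length must be >= 2, got {self.n}")


def _check_h(h: float) -> None:
    if not (0.0 < h < 1.0):
        raise InvalidParameterError(f"Hurst exponent must lie in (0, 1), got {h}")


def fgn_autocovariance(h: float, lags) -> np.ndarray:
    """Autocovariance gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H) of unit fGn."""
    _check_h(h)
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * (
        np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h)
    )


@lru_cache(maxsize=64)
def _circulant_eigenvalues(h: float, n: int) -> tuple[np.ndarray | None, int]:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    Returns ``(eigenvalues, m)`` where *m* is the embedding size, or
    ``(None, m)`` when the embedding is not nonnegative definite and the
    sequential sampler must be used instead.
    """
    m = 2 * (n - 1) if n > 1 else 2
    gamma = fgn_autocovariance(h, np.arange(n))
    # first row of the circulant: gamma_0 .. gamma_{n-1}, gamma_{n-2} .. gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        return None, m
    return np.clip(lam, 0.0, None), m


def _sample_circulant(
    lam: np.ndarray, m: int, n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    xi = rng.standard_normal((size, m)) + 1j * rng.standard_normal((size, m))
    y = np.fft.fft(xi * np.sqrt(lam / m), axis=1)
    return y[:, :n].real


def _sample_hosking(
    h: float, n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact sequential sampler via the Levinson-Durbin recursion, O(n^2)."""
    gamma = fgn_autocovariance(h, np.arange(n))
    x = np.empty((size, n))
    z = rng.standard_normal((size, n))
    v = gamma[0]
    x[:, 0] = math.sqrt(v) * z[:, 0]
    phi = np.zeros(n)
    for t in range(1, n):
        if t == 1:
            phi_tt = gamma[1] / v if v > 0 else 0.0
        else:
            phi_tt = (gamma[t] - phi[1:t] @ gamma[1:t][::-1]) / v
        phi[1:t] = phi[1:t] - phi_tt * phi[1:t][::-1]
        phi[t] = phi_tt
        v *= 1.0 - phi_tt * phi_tt
        mean = x[:, :t] @ phi[1 : t + 1][::-1]
        x[:, t] = mean + math.sqrt(max(v, 0.0)) * z[:, t]
    return x


def simulate_fgn_batch(
    h: float, n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` independent unit-variance fGn series of length ``n``.

    Uses exact circulant-embedding (Davies-Harte) sampling; falls back to the
    exact sequential (Hosking) recursion when the embedding has negative
    eigenvalues, with a warning.
    """
    _check_h(h)
    if n < 2:
        raise InvalidParameterError(f"series length must be >= 2, got {n}")
    lam, m = _circulant_eigenvalues(h, n)
    if lam is None:
        warnings.warn(
            f"circulant embedding failed for H={h}, n={n}; "
            "using sequential sampler",
            EmbeddingFallbackWarning,
            stacklevel=2,
        )
        return _sample_hosking(h, n, size, rng)
    return _sample_circulant(lam, m, n, size, rng)


def simulate_fgn(params: FgnParams) -> np.ndarray:
    """Draw one fGn series; reproducible for a given seed."""
    rng = np.random.default_rng(params.seed)
    return simulate_fgn_batch(params.H, params.n, 1, rng)[0]


def _near_cubic_factors(v: int) -> tuple[int, int, int]:
    """Factor v into three integers as close to a cube as possible."""
    best = (v, 1, 1)
    best_cost = float("inf")
    for a in range(1, int(round(v ** (1 / 3))) + 2):
        if v % a:
            continue
        rest = v // a
        for b in range(a, int(math.isqrt(rest)) + 1):
            if rest % b:
                continue
            c = rest // b
            cost = c - a
            if cost < best_cost:
                best_cost = cost
                best = (a, b, c)
    return best


def build_block_atlas(n_rois: int, voxels_per_roi: int) -> np.ndarray:
    """Integer label volume of contiguous cuboid ROIs, labels 1..n_rois.

    Each label occupies exactly ``voxels_per_roi`` voxels; 0 is background
    (only present as padding when the ROI grid is not full).
    """
    if n_rois < 1 or voxels_per_roi < 1:
        raise InvalidParameterError("n_rois and voxels_per_roi must be >= 1")
    bx, by, bz = _near_cubic_factors(voxels_per_roi)
    gx, gy, gz = _near_cubic_factors(n_rois)
    atlas = np.zeros((gx * bx, gy * by, gz * bz), dtype=np.int32)
    label = 1
    for i in range(gx):
        for j in range(gy):
            for k in range(gz):
                atlas[
                    i * bx : (i + 1) * bx,
                    j * by : (j + 1) * by,
                    k * bz : (k + 1) * bz,
                ] = label
                label += 1
    return atlas


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-design parameters of a two-group synthetic cohort.

    Defaults mirror a resting-state acquisition of 229 retained volumes at
    TR = 2 s parcellated into 246 regions.  ``delta_H`` is the Hurst shift
    applied to ``affected_rois`` in the MCI group only; its default is a
    moderate reduction, the direction commonly reported for impaired
    long-range temporal structure.
    """

    n_mci: int
    n_hc: int
    n_timepoints: int = 229
    tr_seconds: float = 2.0
    n_rois: int = 246
    voxels_per_roi: int = 8
    baseline_H: float = 0.7
    delta_H: float = -0.15
    affected_rois: frozenset[int] = field(default_factory=frozenset)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mci < 1 or self.n_hc < 1:
            raise InvalidParameterError("each group needs at least one subject")
        _check_h(self.baseline_H)
        if not (0.0 < self.baseline_H + self.delta_H < 1.0):
            raise InvalidParameterError(
                "baseline_H + delta_H must stay inside (0, 1)"
            )
        bad = set(self.affected_rois) - set(range(1, self.n_rois + 1))
        if bad:
            raise InvalidParameterError(f"affected_rois outside 1..n_rois: {sorted(bad)}")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        object.__setattr__(self, "affected_rois", frozenset(self.affected_rois))


@dataclass
class CohortData:
    """In-memory synthetic cohort: one 4D array per subject plus metadata."""

    bold: list[np.ndarray]
    atlas: np.ndarray
    participants: pd.DataFrame
    spec: SyntheticCohortSpec


def simulate_cohort(spec: SyntheticCohortSpec) -> CohortData:
    """Generate the cohort: fGn voxel series + white noise, block atlas, table.

    Every voxel of every HC subject, and every unaffected voxel of every MCI
    subject, follows fGn(baseline_H); affected-ROI voxels of MCI subjects
    follow fGn(baseline_H + delta_H).  Each subject consumes an independent
    spawned child seed, so cohorts are bit-reproducible for a given seed.
    """
    atlas = build_block_atlas(spec.n_rois, spec.voxels_per_roi)
    labels_flat = atlas.ravel()
    in_atlas = labels_flat > 0
    affected_voxel = np.isin(labels_flat, sorted(spec.affected_rois)) & in_atlas
    base_voxel = in_atlas & ~affected_voxel

    n_subjects = spec.n_mci + spec.n_hc
    groups = ["MCI"] * spec.n_mci + ["HC"] * spec.n_hc
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_subjects)]
    children = np.random.SeedSequence(spec.seed).spawn(n_subjects)

    shifted_h = spec.baseline_H + spec.delta_H
    t = spec.n_timepoints
    bold: list[np.ndarray] = []
    for group, child in zip(groups, children):
        rng = np.random.default_rng(child)
        flat = np.zeros((labels_flat.size, t))
        if group == "MCI" and affected_voxel.any():
            flat[base_voxel] = simulate_fgn_batch(
                spec.baseline_H, t, int(base_voxel.sum()), rng
            )
            flat[affected_voxel] = simulate_fgn_batch(
                shifted_h, t, int(affected_voxel.sum()), rng
            )
        else:
            flat[in_atlas] = simulate_fgn_batch(
                spec.baseline_H, t, int(in_atlas.sum()), rng
            )
        if spec.noise_sd > 0:
            flat[in_atlas] += spec.noise_sd * rng.standard_normal(
                (int(in_atlas.sum()), t)
            )
        bold.append(flat.reshape(atlas.shape + (t,)))

    participants = pd.DataFrame({"subject_id": subject_ids, "group": groups})
    return CohortData(bold=bold, atlas=atlas, participants=participants, spec=spec)
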