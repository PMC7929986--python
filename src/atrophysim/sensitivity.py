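"""Conductivity sensitivity of the shrinkage attenuation.

Sweeps CSF and skull conductivity over their published ranges (CSF
1.2-1.8 S/m, skull 0.003-0.015 S/m, 100 linearly spaced values each,
endpoints included) and recomputes the single-electrode spherical power
reduction at a fixed shrinkage (default 10%) for every pair, with both the
intact and the shrunk state evaluated at the same conductivities.  The
spherical model is used (exact series), which makes the full grid a single
vectorized evaluation of the per-degree transfer factors.

Two summaries are reported: the max-min spread over the grid, and the
maximum absolute deviation from the attenuation at the default
conductivities — the latter is the primary answer to "how much can
conductivity uncertainty alter the attenuation".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import SphericalModel, make_icosphere, median_centroid, shrink
from .shrinkage_analysis import PatchSpec
from .sphere_forward import SphereSeriesParams, gain_factors

__all__ = ["SensitivityGrid", "conductivity_grid"]


@dataclass
class SensitivityGrid:
    """Attenuation (dB) over a skull x CSF conductivity grid."""

    csf_values: np.ndarray  # (n_csf,) S/m ascending
    skull_values: np.ndarray  # (n_skull,) S/m ascending
    reduction_db: np.ndarray  # (n_skull, n_csf)
    default_reduction_db: float  # at the model's own conductivities
    shrink_fraction: float

    def __post_init__(self) -> None:
        if self.reduction_db.shape != (len(self.skull_values), len(self.csf_values)):
            raise ValueError("grid shape does not match the value lists")
        if not np.all(np.isfinite(self.reduction_db)):
            raise ValueError("non-finite grid entries")

    @property
    def spread(self) -> float:
        """max - min over the grid (dB)."""
        return float(self.reduction_db.max() - self.reduction_db.min())

    @property
    def max_deviation(self) -> float:
        """Largest |grid - default-conductivity attenuation| (dB): how much
        conductivity uncertainty can alter the attenuation."""
        return float(np.abs(self.reduction_db - self.default_reduction_db).max())

    def summary(self) -> dict:
        return {
            "min_db": float(self.reduction_db.min()),
            "max_db": float(self.reduction_db.max()),
            "spread_db": self.spread,
            "default_db": self.default_reduction_db,
            "max_deviation_db": self.max_deviation,
            "shrink_fraction": self.shrink_fraction,
        }


def conductivity_grid(
    model: SphericalModel | None = None,
    s: float = 0.10,
    csf_range: tuple[float, float, int] = (1.2, 1.8, 100),
    skull_range: tuple[float, float, int] = (0.003, 0.015, 100),
    spec: PatchSpec | None = None,
    source_subdivision: int = 4,
    electrode_direction=(0.0, 0.0, 1.0),
    params: SphereSeriesParams | None = None,
    n_terms: int = 200,
) -> SensitivityGrid:
    """dB power reduction at fixed shrinkage over a conductivity grid.

    Follows the single-electrode spherical protocol (20-dipole closest
    patch, electrode radially above the patch centroid, coherent patch
    sum); the brain shell shrinks with the sources so the CSF expands.
    ``n_terms`` fixes the series truncation for the vectorized sweep (the
    terms decay like (0.77)^n, so 200 terms reach ~1e-22).
    """
    model = model or SphericalModel()
    spec = spec or PatchSpec()
    if s < 0 or s >= 1:
        raise ValueError("shrink fraction must lie in [0, 1)")
    for lo, hi, steps in (csf_range, skull_range):
        if lo <= 0 or hi < lo:
            raise ValueError("conductivity ranges must be positive and non-decreasing")
        if steps < 1 or (steps == 1 and hi != lo):
            raise ValueError("step count must be >= 2 for a non-degenerate range")

    # Geometry of the spherical protocol (identical to the shrinkage run).
    dirs = make_icosphere(source_subdivision, 1.0).vertices
    pos = dirs * model.source_radius
    e_dir = np.asarray(electrode_direction, dtype=np.float64)
    e_dir /= np.linalg.norm(e_dir)
    anchor = pos[int(np.argmax(dirs @ e_dir))]
    electrode = anchor / np.linalg.norm(anchor) * model.scalp_radius
    d2e = np.linalg.norm(pos - electrode, axis=1)
    patch = np.sort(np.argsort(d2e, kind="stable")[: spec.size])
    centroid = pos[patch].mean(axis=0)
    electrode = centroid / np.linalg.norm(centroid) * model.scalp_radius

    center = median_centroid(pos)
    model_s = model.with_brain_shrunk(s)
    pos_s = shrink(pos, center, s)

    n = np.arange(1, n_terms + 1)
    t_intact = _patch_series_terms(model, pos[patch], dirs[patch], electrode, n)
    t_shrunk = _patch_series_terms(model_s, pos_s[patch], dirs[patch], electrode, n)

    csf_vals = np.linspace(*csf_range[:2], int(csf_range[2]))
    skull_vals = np.linspace(*skull_range[:2], int(skull_range[2]))
    scalp, _, _, brain = model.conductivities
    sig = np.empty((len(skull_vals), len(csf_vals), 4))
    sig[..., 0] = scalp
    sig[..., 1] = skull_vals[:, None]
    sig[..., 2] = csf_vals[None, :]
    sig[..., 3] = brain

    def grid_db(sig_arr):
        G0 = gain_factors(model.radii, sig_arr, n)
        Gs = gain_factors(model_s.radii, sig_arr, n)
        v0 = G0 @ t_intact / model.brain_radius**2
        vs = Gs @ t_shrunk / model_s.brain_radius**2
        return 20.0 * np.log10(np.abs(v0) / np.abs(vs))

    reduction = grid_db(sig)
    default_db = float(grid_db(np.asarray(model.conductivities)))
    return SensitivityGrid(
        csf_values=csf_vals,
        skull_values=skull_vals,
        reduction_db=reduction,
        default_reduction_db=default_db,
        shrink_fraction=s,
    )


def _patch_series_terms(
    model: SphericalModel,
    positions: np.ndarray,
    orientations: np.ndarray,
    electrode: np.ndarray,
    n: np.ndarray,
) -> np.ndarray:
    """Conductivity-independent per-degree series terms, summed over the
    patch: t_n = sum_d x_d^(n-1) [n m_r P_n + m_t P_n'] (single electrode).

    The scalp potential is then ``(1/4 pi sigma_brain R_brain^2) G @ t``;
    the constant prefactor ``1/(4 pi sigma_brain)`` is common to intact and
    shrunk states and drops out of the dB ratio.
    """
    b = np.linalg.norm(positions, axis=1)
    if np.any(b >= model.brain_radius):
        raise ValueError("dipole(s) outside the brain shell")
    d_hat = positions / b[:, None]
    e_hat = electrode / np.linalg.norm(electrode)
    cosg = np.clip(d_hat @ e_hat, -1.0, 1.0)
    m_r = np.einsum("dk,dk->d", orientations, d_hat)
    m_te = orientations @ e_hat - cosg * m_r
    x = b / model.brain_radius

    out = np.empty((len(n), len(positions)))
    P_prev = np.ones_like(cosg)
    P = cosg.copy()
    dP_prev = np.zeros_like(cosg)
    dP = np.ones_like(cosg)
    xpow = np.ones_like(x)
    for k, nn in enumerate(n):
        out[k] = (nn * m_r * P + m_te * dP) * xpow
        P_next = ((2 * nn + 1) * cosg * P - nn * P_prev) / (nn + 1)
        dP_next = dP_prev + (2 * nn + 1) * P
        P_prev, P = P, P_next
        dP_prev, dP = dP, dP_next
        xpow = xpow * x
    return out.sum(axis=1)
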