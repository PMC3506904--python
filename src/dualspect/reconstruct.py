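"""OS-EM reconstruction with intermittent Monte-Carlo scatter updates.

The dual-isotope reconstruction runs in three steps: (1) Tc-99m OS-EM with
MC self-scatter correction, (2) MC simulation of Tc-99m down-scatter into
the Tl-201 window from the reconstructed Tc-99m volume, (3) Tl-201 OS-EM
where the frozen down-scatter estimate is added to the Tl-201 self-scatter
term.  Scatter estimates are refreshed only during the first few iterations
(intermittent modelling): iteration 1 runs scatter-free, the estimate is
recomputed from the current volume at the start of iterations
2 .. 1 + scatter_update_iters, then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import ActivityVolume, AttenuationMap, ProjectionSet
from .mcscatter import (McConfig, ScatterEstimate, simulate_downscatter,
                        simulate_scatter)
from .physics import (TC99M, TL201, TC_WINDOW, TL_WINDOW, EmissionSpec,
                      EnergyWindow, MaterialTable, default_material_table,
                      window_acceptance)
from .projector import CollimatorModel, Geometry, SpectSystem

__all__ = [
    "ReconConfig",
    "DualReconResult",
    "ZeroScatter",
    "SelfScatterProvider",
    "osem",
    "reconstruct_dual",
    "gaussian_postfilter",
]

_TINY = 1e-20


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction knobs for one OS-EM run.

    ``scatter_update_iters`` counts the leading iterations whose start
    refreshes the MC self-scatter estimate; afterwards it stays frozen.
    """

    iterations: int = 10
    subsets: int = 8
    scatter_update_iters: int = 2
    mc: McConfig = field(default_factory=McConfig)
    postfilter_fwhm_cm: float = 0.9
    compute_fit: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.subsets < 1:
            raise ValueError("iterations and subsets must be positive")
        if not 0 <= self.scatter_update_iters <= self.iterations:
            raise ValueError(
                "scatter_update_iters must lie in [0, iterations]")
        if self.postfilter_fwhm_cm < 0:
            raise ValueError("post-filter FWHM must be non-negative")


@dataclass
class DualReconResult:
    """Outcome of the three-step dual-isotope reconstruction."""

    tc: ActivityVolume
    tl: ActivityVolume
    downscatter: ScatterEstimate
    tc_log: list
    tl_log: list


class ZeroScatter:
    """Scatter provider that always returns a zero additive term."""

    def __call__(self, x: ActivityVolume, iteration: int,
                 shape) -> np.ndarray:
        return np.zeros(shape, dtype=np.float32)


class SelfScatterProvider:
    """MC self-scatter of the reconstructed isotope, plus an optional frozen
    additive term (the down-scatter estimate in step 3)."""

    def __init__(self, mu_map: AttenuationMap, emission: EmissionSpec,
                 window: EnergyWindow, geometry: Geometry,
                 collimator: CollimatorModel, mc: McConfig,
                 table: MaterialTable | None = None,
                 resolution_frac: float | None = None,
                 frozen_term: np.ndarray | None = None):
        self.mu_map = mu_map
        self.emission = emission
        self.window = window
        self.geometry = geometry
        self.collimator = collimator
        self.mc = mc
        self.table = table
        self.resolution_frac = resolution_frac
        self.frozen_term = frozen_term

    def __call__(self, x: ActivityVolume, iteration: int,
                 shape) -> np.ndarray:
        seed = (self.mc.seed + 1009 * iteration) % (2 ** 31)
        cfg = replace(self.mc, seed=seed)
        est, _ = simulate_scatter(x, self.mu_map, self.emission, self.window,
                                  self.geometry, self.collimator, cfg,
                                  table=self.table,
                                  resolution_frac=self.resolution_frac)
        out = est.data
        if self.frozen_term is not None:
            out = out + self.frozen_term
        return out.astype(np.float32)


def _bit_reversed(n: int):
    bits = max(n - 1, 1).bit_length()
    order = sorted(range(n), key=lambda i: int(f"{i:0{bits}b}"[::-1], 2))
    return order


def _kl_divergence(y: np.ndarray, q: np.ndarray) -> float:
    """Poisson data fit sum(q - y + y log(y/q)) over bins with y > 0."""
    q = np.maximum(q, _TINY)
    pos = y > 0
    out = float(q.sum(dtype=np.float64) - y.sum(dtype=np.float64))
    out += float((y[pos] * np.log(y[pos] / q[pos])).sum(dtype=np.float64))
    return out


def gaussian_postfilter(values: np.ndarray, fwhm_cm: float,
                        voxel_mm: float) -> np.ndarray:
    """Separable 3-D Gaussian filter with the stated FWHM in cm."""
    if fwhm_cm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_cm == 0:
        return np.asarray(values).copy()
    sigma_vox = (fwhm_cm * 10.0 / 2.354820045) / voxel_mm
    return gaussian_filter(np.asarray(values, dtype=np.float32), sigma_vox,
                           mode="constant")


def osem(projections: ProjectionSet, mu_map: AttenuationMap | None,
         geometry: Geometry, collimator: CollimatorModel,
         config: ReconConfig, scatter_provider=None,
         emission: EmissionSpec = TC99M, window: EnergyWindow = TC_WINDOW,
         resolution_frac: float = 0.099,
         table: MaterialTable | None = None):
    """Ordered-subsets EM with an additive scatter term.

    Multiplicative update per subset:
    x <- x * [A_s' (y_s / (A_s x + s_s + eps))] / A_s' 1,
    where s is the scatter provider's projection-domain term, refreshed at
    the start of iterations 2 .. 1 + scatter_update_iters and frozen after.
    The final volume is post-filtered with the configured 3-D Gaussian.

    Returns ``(ActivityVolume, log)`` with one log entry per iteration.
    """
    y = projections.data
    if np.any(y < 0):
        raise ValueError("projection data must be non-negative")
    n_views = geometry.n_views
    if n_views % config.subsets:
        raise ValueError(
            f"subsets ({config.subsets}) must divide views ({n_views})")
    table = table or default_material_table()
    provider = scatter_provider or ZeroScatter()
    eff = float(window_acceptance(emission.energy_kev, window,
                                  resolution_frac))
    voxel_mm = projections.pixel_mm
    system = SpectSystem(geometry, mu_map, collimator, emission.energy_kev,
                         voxel_mm, efficiency=eff, table=table)

    subsets = [list(range(s, n_views, config.subsets))
               for s in range(config.subsets)]
    subset_order = _bit_reversed(config.subsets)
    sens = [system.sensitivity(v) for v in subsets]
    infield = [s > 0 for s in sens]

    nu, nz = geometry.detector_shape
    x = np.ones((nu, nu, nz), dtype=np.float32)
    flux = float(system.forward(x).sum(dtype=np.float64))
    if flux > 0 and y.sum() > 0:
        x *= float(y.sum(dtype=np.float64)) / flux
    mean_y = float(y.mean(dtype=np.float64))
    eps = 1e-10 * mean_y if mean_y > 0 else np.float32(1e-12)

    s_term = np.zeros_like(y)
    log = []
    n_updates = 0
    for it in range(1, config.iterations + 1):
        updated = False
        if 2 <= it <= 1 + config.scatter_update_iters:
            raw = np.asarray(
                provider(ActivityVolume(x, voxel_mm, emission.isotope), it,
                         y.shape), dtype=np.float32)
            # damped fixed-point refresh: the scatter term and the volume
            # relax jointly and the undamped map oscillates (the first,
            # scatter-free iteration over-attributes counts to activity, the
            # next update over-corrects, ...); averaging halves the
            # oscillation so that freezing after few updates lands near the
            # joint fixed point
            s_term = raw if n_updates == 0 else 0.5 * (s_term + raw)
            n_updates += 1
            updated = True
        for s in subset_order:
            views = subsets[s]
            q = system.forward(x, views) + s_term[views] + eps
            ratio = y[views] / np.maximum(q, _TINY)
            upd = system.backward(ratio, views)
            x = np.where(infield[s], x * upd / np.maximum(sens[s], _TINY),
                         x).astype(np.float32)
        entry = {"iteration": it, "scatter_updated": updated,
                 "scatter_total": float(s_term.sum(dtype=np.float64))}
        if config.compute_fit:
            q_full = system.forward(x) + s_term + eps
            entry["kl_fit"] = _kl_divergence(y, q_full)
        log.append(entry)

    x = gaussian_postfilter(x, config.postfilter_fwhm_cm, voxel_mm)
    vol = ActivityVolume(np.maximum(x, 0.0), voxel_mm, emission.isotope)
    return vol, log


def reconstruct_dual(tc_projections: ProjectionSet,
                     tl_projections: ProjectionSet,
                     mu_map: AttenuationMap, geometry: Geometry,
                     collimator: CollimatorModel, tc_config: ReconConfig,
                     downscatter_mc: McConfig, tl_config: ReconConfig,
                     tc_window: EnergyWindow = TC_WINDOW,
                     tl_window: EnergyWindow = TL_WINDOW,
                     resolution_frac: float = 0.099,
                     table: MaterialTable | None = None) -> DualReconResult:
    """Three-step simultaneous Tl-201/Tc-99m reconstruction.

    (1) Tc-99m OS-EM with MC self-scatter; (2) MC down-scatter simulation
    into the Tl-201 window from the reconstructed Tc-99m volume; (3) Tl-201
    OS-EM whose scatter term is the Tl self-scatter plus the frozen
    down-scatter estimate.
    """
    if tc_projections.data.shape != tl_projections.data.shape:
        raise ValueError("Tc and Tl projection sets must share geometry")
    table = table or default_material_table()

    tc_provider = SelfScatterProvider(mu_map, TC99M, tc_window, geometry,
                                      collimator, tc_config.mc, table,
                                      resolution_frac)
    tc_vol, tc_log = osem(tc_projections, mu_map, geometry, collimator,
                          tc_config, tc_provider, emission=TC99M,
                          window=tc_window, resolution_frac=resolution_frac,
                          table=table)

    ds = simulate_downscatter(tc_vol, mu_map, tl_window, geometry, collimator,
                              downscatter_mc, table=table,
                              resolution_frac=resolution_frac)

    tl_provider = SelfScatterProvider(mu_map, TL201, tl_window, geometry,
                                      collimator, tl_config.mc, table,
                                      resolution_frac, frozen_term=ds.data)
    tl_vol, tl_log = osem(tl_projections, mu_map, geometry, collimator,
                          tl_config, tl_provider, emission=TL201,
                          window=tl_window, resolution_frac=resolution_frac,
                          table=table)
    return DualReconResult(tc_vol, tl_vol, ds, tc_log, tl_log)
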